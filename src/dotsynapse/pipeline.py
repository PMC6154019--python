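"""Top-level per-cell pipeline: RICM segmentation → adhesion class →
cluster segmentation/colocalization → morphometrics, with a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import adhesion, clusters, morphometry, substrate
from .core import Image

logger = logging.getLogger("dotsynapse")


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the per-cell pipeline, echoed into outputs."""

    pixel_size: float = 0.16  # μm/px
    pitch: float = 2.0  # μm
    dot_fwhm: float = 0.75  # μm
    cluster_cutoff_px: int = 10
    cluster_conv_step: float = 0.05
    cluster_trim_step: float = 0.8
    clearance_circle_um: float = 1.2
    variance_radius_px: int = 4
    exclusion_alpha: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_size", "pitch", "dot_fwhm", "clearance_circle_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass(frozen=True)
class CellInputs:
    """Matched images for one cell. ``substrate_image`` (the ligand-dot
    channel) is optional; without it colocalization is skipped."""

    cell_id: str
    ricm: Image
    receptor: Image | None = None
    actin: Image | None = None
    substrate_image: Image | None = None


def analyze_cell(cell: CellInputs, config: PipelineConfig) -> dict:
    """All measurements for one cell as a flat record."""
    row: dict = {"cell_id": cell.cell_id}
    mask = adhesion.segment_cell_ricm(cell.ricm, config.variance_radius_px)
    row["area_um2"] = mask.area_um2
    cls = adhesion.classify_adhesion(
        cell.ricm, mask, config.pitch, config.dot_fwhm
    )
    row["adhesion_label"] = cls.label
    row["n_patches"] = cls.n_qualifying_patches

    if cell.receptor is not None:
        cs = clusters.segment_clusters(
            cell.receptor,
            mask,
            config.cluster_cutoff_px,
            config.cluster_conv_step,
            config.cluster_trim_step,
        )
        row["n_clusters"] = len(cs)
        row["median_cluster_area_um2"] = (
            float(np.median(cs.areas_um2)) if len(cs) else np.nan
        )
        if cell.substrate_image is not None and len(cs):
            dots, _ = substrate.detect_dots(
                cell.substrate_image, config.dot_fwhm, config.pitch
            )
            _, overlap = clusters.colocalize(cs, dots, config.dot_fwhm)
            row["dot_overlap_fraction"] = overlap
        cz = morphometry.centralization_index(cell.receptor, mask)
        row["centralization_index"] = cz.index
        row["centralization_tag"] = cz.definition_tag

    if cell.actin is not None:
        cl = morphometry.actin_clearance(
            cell.actin, mask, config.clearance_circle_um
        )
        row["actin_clearance"] = cl.ratio
    return row


def run_pipeline(
    config: PipelineConfig, inputs: Sequence[CellInputs]
) -> tuple[pd.DataFrame, dict]:
    """Run every stage for every cell; failures skip the cell, not the run.

    Returns the per-cell results table and a JSON-serializable run manifest
    (config, config hash, versions, skip log).
    """
    rows: list[dict] = []
    skipped: list[Mapping[str, str]] = []
    for cell in inputs:
        try:
            rows.append(analyze_cell(cell, config))
        except Exception as exc:  # noqa: BLE001 - any stage error skips the cell
            logger.warning("cell %s skipped: %s", cell.cell_id, exc)
            skipped.append({"cell_id": cell.cell_id, "error": str(exc)})
    table = pd.DataFrame(rows)
    if not table.empty:
        table["config_hash"] = config.config_hash
    import dotsynapse

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "seed": config.seed,
        "n_cells": len(rows),
        "skipped": skipped,
        "versions": {
            "dotsynapse": dotsynapse.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    return table, manifest
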