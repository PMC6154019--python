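"""Cohort statistics: summaries, Mann–Whitney comparisons, effect sizes and
the leave-one-out outlier-sample exclusion.

Comparisons are two-tailed Wilcoxon–Mann–Whitney rank tests; significance
stars follow the convention *** for P ≤ 1e-7, ** for P ≤ 1e-4, * for
P ≤ 0.01 and NS above (an alternative figure-caption convention, NS for
P ≥ 0.05, is available behind a flag). The effect size between populations
deemed different is the difference of their medians.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .core import DotsynapseError


class EmptyGroupError(DotsynapseError):
    """A comparison group is empty."""


@dataclass(frozen=True)
class ComparisonResult:
    u_statistic: float
    p_value: float
    stars: str
    effect_size: float  # median(a) - median(b)
    n_a: int
    n_b: int


def summarize(values) -> dict:
    """Mean, sample SD (n−1), SEM, median and n of a sample."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise EmptyGroupError("cannot summarize an empty sample")
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return {
        "mean": float(v.mean()),
        "sd": sd,
        "sem": sd / np.sqrt(v.size),
        "median": float(np.median(v)),
        "n": int(v.size),
    }


def stars(p: float, convention: str = "methods") -> str:
    """Significance label for a p-value.

    ``methods`` (default): *** P ≤ 1e-7, ** P ≤ 1e-4, * P ≤ 0.01, NS > 0.01.
    ``figures``: NS for P ≥ 0.05, * below (the looser caption convention).
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value {p} outside [0, 1]")
    if convention == "methods":
        if p <= 1e-7:
            return "***"
        if p <= 1e-4:
            return "**"
        if p <= 0.01:
            return "*"
        return "NS"
    if convention == "figures":
        return "NS" if p >= 0.05 else "*"
    raise ValueError(f"unknown star convention {convention!r}")


def effect_size(a, b) -> float:
    """Difference of medians, median(a) − median(b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise EmptyGroupError("effect size requires two non-empty groups")
    return float(np.median(a) - np.median(b))


EXACT_MAX_N = 8


def mann_whitney(a, b, convention: str = "methods") -> ComparisonResult:
    """Two-tailed Wilcoxon–Mann–Whitney rank test.

    The exact null distribution is used when the smaller group has at most
    8 observations and there are no ties; otherwise the normal approximation
    with midrank tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise EmptyGroupError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = (
        "exact" if (min(a.size, b.size) <= EXACT_MAX_N and not has_ties)
        else "asymptotic"
    )
    res = mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    p = float(min(res.pvalue, 1.0))
    return ComparisonResult(
        u_statistic=float(res.statistic),
        p_value=p,
        stars=stars(p, convention),
        effect_size=effect_size(a, b),
        n_a=int(a.size),
        n_b=int(b.size),
    )


def exclude_outlier_samples(
    table: pd.DataFrame,
    alpha: float = 1e-4,
    value_col: str = "area_um2",
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Leave-one-out vetting of samples against their condition aggregate.

    For each condition, every sample's cells are compared by Mann–Whitney to
    the pooled cells of all *other* samples of the same condition; samples
    with p < ``alpha`` are rejected. Single pass — rejections do not trigger
    re-pooling. Conditions with a single sample pass through with a warning.

    Returns ``(filtered_table, rejected)`` where ``rejected`` is a list of
    ``(condition, sample_id)`` pairs.
    """
    rejected: list[tuple[str, str]] = []
    for condition, grp in table.groupby("condition", sort=False):
        sample_ids = grp["sample_id"].unique()
        if len(sample_ids) < 2:
            warnings.warn(
                f"condition {condition!r} has a single sample; passed "
                "through without vetting",
                stacklevel=2,
            )
            continue
        for sid in sample_ids:
            own = grp.loc[grp["sample_id"] == sid, value_col].to_numpy()
            rest = grp.loc[grp["sample_id"] != sid, value_col].to_numpy()
            if mann_whitney(own, rest).p_value < alpha:
                rejected.append((str(condition), str(sid)))
    bad = {sid for _, sid in rejected}
    filtered = table[~table["sample_id"].isin(bad)].reset_index(drop=True)
    return filtered, rejected


def compare_conditions(
    table: pd.DataFrame,
    value_col: str = "area_um2",
    convention: str = "methods",
) -> pd.DataFrame:
    """Pairwise Mann–Whitney comparisons between all conditions.

    Returns one row per unordered condition pair with columns
    ``condition_a, condition_b, n_a, n_b, u, p, stars, effect_size``.
    """
    conditions = list(table["condition"].unique())
    rows = []
    for i, ca in enumerate(conditions):
        for cb in conditions[i + 1:]:
            a = table.loc[table["condition"] == ca, value_col].to_numpy()
            b = table.loc[table["condition"] == cb, value_col].to_numpy()
            r = mann_whitney(a, b, convention)
            rows.append(
                {
                    "condition_a": ca,
                    "condition_b": cb,
                    "n_a": r.n_a,
                    "n_b": r.n_b,
                    "u": r.u_statistic,
                    "p": r.p_value,
                    "stars": r.stars,
                    "effect_size": r.effect_size,
                }
            )
    return pd.DataFrame(rows)
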