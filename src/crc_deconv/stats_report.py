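"""Group comparisons and figure-style reporting.

Morphometric and intensity features are compared across cell-type groups
with the Kruskal-Wallis omnibus test followed by Dunn's pairwise post hoc
z-tests with multiplicity correction, and p-values are annotated with the
usual significance stars. Helper arithmetic covers rare-cell enumeration
summaries (cells/mL) and spike-in recovery percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Star-annotation thresholds (closed: p <= threshold earns the stars);
#: four stars are reserved for p below 1e-5.
DEFAULT_P_THRESHOLDS: tuple[tuple[str, float], ...] = (
    ("****", 0.00001),
    ("***", 0.001),
    ("**", 0.01),
    ("*", 0.05),
)


@dataclass
class GroupComparison:
    groups: dict[str, np.ndarray]
    omnibus_statistic: float
    omnibus_p: float
    pairwise: pd.DataFrame  # group_a, group_b, z, p_raw, p_adjusted, annotation
    adjustment: str


def annotate_p(
    p: float, thresholds: tuple[tuple[str, float], ...] = DEFAULT_P_THRESHOLDS
) -> str:
    """Map a p-value to {ns, *, **, ***, ****}.

    Defaults: * for p <= 0.05, ** for p <= 0.01, *** for p <= 0.001 and
    **** for p < 0.00001 (the four-star band follows the strict "<"
    convention of the figure legends it reproduces). Monotone: a smaller p
    never receives fewer stars.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value out of [0, 1]: {p}")
    stars_4, t4 = thresholds[0]
    if p < t4:
        return stars_4
    for stars, t in thresholds[1:]:
        if p <= t:
            return stars
    return "ns"


def _dunn_pairwise(groups: dict[str, np.ndarray], adjustment: str) -> pd.DataFrame:
    names = list(groups)
    values = np.concatenate([groups[g] for g in names])
    sizes = {g: len(groups[g]) for g in names}
    n = len(values)
    ranks = stats.rankdata(values)
    mean_rank = {}
    start = 0
    for g in names:
        mean_rank[g] = ranks[start : start + sizes[g]].mean()
        start += sizes[g]
    # tie correction to the rank variance
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n - 1)) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term
    rows = []
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    m = len(pairs)
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z)) if se > 0 else 1.0
        if adjustment == "bonferroni":
            p_adj = min(1.0, p_raw * m)
        elif adjustment == "none":
            p_adj = p_raw
        else:
            raise ValueError(f"unknown adjustment {adjustment!r}")
        rows.append((a, b, z, p_raw, p_adj, annotate_p(p_adj)))
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "z", "p_raw", "p_adjusted", "annotation"]
    )


def compare_groups(
    groups: dict[str, list | np.ndarray], adjustment: str = "bonferroni"
) -> GroupComparison:
    """Kruskal-Wallis omnibus plus Dunn's pairwise post hoc comparisons.

    The omnibus statistic is tie-corrected; Dunn's pairwise z-tests use the
    pooled-rank variance with tie correction, adjusted over all pairs
    (Bonferroni by default, recorded in the result). Degenerate input where
    every value is identical returns p = 1 throughout.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {name!r} has no values")
        arrays[name] = arr
    pooled = np.concatenate(list(arrays.values()))
    if np.all(pooled == pooled[0]):
        pairwise = _dunn_pairwise(arrays, adjustment)
        return GroupComparison(arrays, 0.0, 1.0, pairwise, adjustment)
    h, p = stats.kruskal(*arrays.values())
    pairwise = _dunn_pairwise(arrays, adjustment)
    return GroupComparison(arrays, float(h), float(p), pairwise, adjustment)


def summarize_enumeration(per_sample_counts: list[float] | np.ndarray) -> dict:
    """Mean / median / range of per-sample cell concentrations (cells/mL).

    The headline mean is additionally reported rounded to the nearest
    integer, matching how enumeration averages are usually quoted.
    """
    arr = np.asarray(per_sample_counts, dtype=float)
    if arr.size == 0:
        raise ValueError("no samples")
    return {
        "mean": float(arr.mean()),
        "mean_headline": int(round(arr.mean())),
        "median": float(np.median(arr)),
        "range": (float(arr.min()), float(arr.max())),
        "n": int(arr.size),
    }


def compute_recovery(detected: float, spiked: float) -> float:
    """Spike-in recovery, percent: 100 * detected / spiked."""
    if spiked <= 0:
        raise ValueError("spiked count must be > 0")
    if detected < 0:
        raise ValueError("detected count must be >= 0")
    return 100.0 * detected / spiked
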