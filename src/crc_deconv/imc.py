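"""Targeted-proteomics (imaging mass cytometry) processing.

Cells of interest found by immunofluorescence are relocated in the IMC
coordinate frame, ion counts are corrected by subtracting the background
measured in negative mask space, corrected counts are z-scored against a
leukocyte-anchored reference population, and per-marker positivity is called
at a z cutoff. Markers absent from a slide's panel are carried as missing,
never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

TISSUE_MARKERS = ("ER", "HER2", "AR", "PSA", "PSMA")
ENDOTHELIAL_MARKER = "CD31"


class DegenerateMarkerError(ValueError):
    """A marker column has zero variance in the normalization population."""


@dataclass
class CoiMatching:
    pairs: list[tuple[str, str]]  # (coi_id, imc_id)
    unmatched: list[str]  # coi ids with no partner within max_dist


def match_cois(
    if_coords: pd.DataFrame,
    imc_coords: pd.DataFrame,
    max_dist: float,
) -> CoiMatching:
    """One-to-one nearest-neighbour relocation of COIs into the IMC frame.

    Both inputs need ``x``/``y`` columns indexed by cell id. Candidate pairs
    within ``max_dist`` are accepted greedily in order of increasing
    distance, each id used at most once; COIs left over are reported
    unmatched. Duplicate coordinates on either side trigger an ambiguity
    warning listing the ids involved.
    """
    for name, df in (("if", if_coords), ("imc", imc_coords)):
        dup = df.duplicated(subset=["x", "y"], keep=False)
        if dup.any():
            warnings.warn(
                f"duplicate {name} coordinates for ids {sorted(df.index[dup])}",
                stacklevel=2,
            )
    a = if_coords[["x", "y"]].to_numpy(float)
    b = imc_coords[["x", "y"]].to_numpy(float)
    if len(a) == 0 or len(b) == 0:
        return CoiMatching(pairs=[], unmatched=list(if_coords.index))
    d = np.hypot(a[:, None, 0] - b[None, :, 0], a[:, None, 1] - b[None, :, 1])
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None, kind="stable"), d.shape))[0]
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for i, j in order:
        if d[i, j] > max_dist:
            break
        if i in used_a or j in used_b:
            continue
        used_a.add(int(i))
        used_b.add(int(j))
        pairs.append((if_coords.index[i], imc_coords.index[j]))
    unmatched = [if_coords.index[i] for i in range(len(a)) if i not in used_a]
    return CoiMatching(pairs=pairs, unmatched=unmatched)


def subtract_background(
    ion_table: pd.DataFrame, background: pd.Series
) -> pd.DataFrame:
    """Subtract per-marker background (negative mask space) from ion counts.

    ``corrected = max(0, cell_mean - background_mean)`` per marker; negative
    ion counts are unphysical, hence the floor. Idempotent once background
    is zero. Markers missing a background estimate raise.
    """
    missing = [m for m in ion_table.columns if m not in background.index]
    if missing:
        raise KeyError(f"no background estimate for markers: {missing}")
    if (ion_table < 0).any().any():
        raise ValueError("ion counts must be >= 0 before subtraction")
    corrected = ion_table.sub(background[ion_table.columns], axis=1)
    return corrected.clip(lower=0.0)


def zscore_normalize(
    corrected: pd.DataFrame,
    reference_ids: list[str],
    population: str = "reference",
) -> pd.DataFrame:
    """Z-score ion counts against a leukocyte-anchored normalization population.

    ``population="reference"`` (default) anchors the mean/SD on the reference
    leukocyte rows alone, so a marker's z-scores read as SDs above the
    leukocyte background regardless of how many COIs express it;
    ``population="pooled"`` uses COIs and reference rows together. The SD is
    the sample SD (n-1). A zero-variance marker raises, naming the marker.
    """
    if population not in ("reference", "pooled"):
        raise ValueError(f"unknown normalization population {population!r}")
    ref = corrected.loc[reference_ids] if population == "reference" else corrected
    if len(ref) < 2:
        raise ValueError("normalization population needs >= 2 rows")
    mean = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=1)
    bad = sd.index[(sd == 0) | sd.isna()].tolist()
    bad = [m for m in bad if not corrected[m].isna().all()]
    if bad:
        raise DegenerateMarkerError(f"zero variance in normalization population: {bad}")
    return (corrected - mean) / sd


def call_markers(
    z: pd.DataFrame,
    cutoffs: dict[str, float] | float = 1.5,
) -> pd.DataFrame:
    """Call per-marker positivity at a z cutoff (default 1.5, per-marker override).

    Positivity is ``z >= cutoff`` (closed); missing markers stay negative
    but remain NaN in the z table. Adds the convenience flags
    ``tissue_marker_positive`` (any of ER/HER2/AR/PSA/PSMA present in the
    panel) and ``endothelial_positive`` (CD31). Positivity is monotone
    non-increasing in the cutoff.
    """
    if np.isscalar(cutoffs):
        cutoffs = {m: float(cutoffs) for m in z.columns}
    missing_cut = [m for m in z.columns if m not in cutoffs]
    if missing_cut:
        cutoffs = {**{m: 1.5 for m in missing_cut}, **cutoffs}
    calls = pd.DataFrame(
        {m: z[m] >= cutoffs[m] for m in z.columns}, index=z.index
    ).fillna(False)
    tissue_present = [m for m in TISSUE_MARKERS if m in z.columns]
    calls["tissue_marker_positive"] = (
        calls[tissue_present].any(axis=1) if tissue_present else False
    )
    calls["endothelial_positive"] = (
        calls[ENDOTHELIAL_MARKER] if ENDOTHELIAL_MARKER in z.columns else False
    )
    return calls
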