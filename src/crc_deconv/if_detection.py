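"""Immunofluorescence rare-cell detection.

Candidate rare cells are DAPI+/CK+/CD45- events on a leukocyte-dominated
monolayer. Cytokeratin (CK) positivity is expressed as standard deviations
over the mean (SDOM) of the surrounding leukocytes' CK signal — the
leukocytes are the in-frame negative control — with a default threshold of
six. Vimentin is scored positive/negative against the leukocyte vimentin
distribution and reported as raw fluorescent intensity (RFI). Cell shape is
summarized by the eccentricity of the equivalent ellipse derived from the
mask's central second moments (0 = circle, 1 = line).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class DegenerateReferenceError(ValueError):
    """Reference leukocyte population cannot support an SDOM (SD == 0 or n < 2)."""


class MissingReferenceError(KeyError):
    """A frame has no reference leukocyte population."""


@dataclass(frozen=True)
class ReferencePopulation:
    """Surrounding-leukocyte intensities for one frame.

    CK is the negative-control channel for the SDOM statistic; vimentin and
    the auxiliary channels anchor the Vim cutoff and the DAPI/CD45 gates.
    """

    frame_id: str
    ck: np.ndarray
    vim: np.ndarray
    dapi: np.ndarray = field(default_factory=lambda: np.empty(0))
    cd45: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        for name in ("ck", "vim", "dapi", "cd45"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.size and np.any(arr < 0):
                raise ValueError(f"{name} reference intensities must be >= 0")
        if self.ck.size < 2:
            raise DegenerateReferenceError(
                f"frame {self.frame_id}: reference needs >= 2 leukocytes, got {self.ck.size}"
            )


def compute_sdom(cell_ck: float, reference: ReferencePopulation) -> float:
    """CK intensity in units of the reference leukocytes' SD over their mean.

    Returns ``(cell_ck - mean(ref)) / sd(ref)`` with the sample SD
    (n-1 denominator). A zero reference SD signals a pathological frame and
    raises :class:`DegenerateReferenceError`.
    """
    ref = reference.ck
    sd = float(np.std(ref, ddof=1))
    if sd == 0.0:
        raise DegenerateReferenceError(
            f"frame {reference.frame_id}: reference CK SD is zero"
        )
    return (float(cell_ck) - float(np.mean(ref))) / sd


def vim_cutoff(reference: ReferencePopulation, n_sd: float = 2.0) -> float:
    """Vimentin positivity cutoff: mean + ``n_sd`` SD of leukocyte vimentin."""
    vim = reference.vim
    if vim.size < 2:
        raise DegenerateReferenceError(
            f"frame {reference.frame_id}: vim reference needs >= 2 leukocytes"
        )
    return float(np.mean(vim) + n_sd * np.std(vim, ddof=1))


def score_vim(
    cell_vim: float, reference: ReferencePopulation, n_sd: float = 2.0
) -> tuple[bool, float]:
    """Score vimentin in a CK+ candidate.

    Returns ``(vim_call, vim_rfi)`` where the RFI is the raw per-cell
    intensity and the call is positive iff the RFI exceeds the
    reference-relative cutoff (mean + ``n_sd`` SD of leukocyte vimentin).
    """
    rfi = float(cell_vim)
    if rfi < 0:
        raise ValueError("vim intensity must be >= 0")
    return rfi > vim_cutoff(reference, n_sd=n_sd), rfi


def compute_eccentricity(mu20: float, mu02: float, mu11: float) -> float:
    """Eccentricity of the equivalent ellipse from central second moments.

    With eigenvalues ``lam1 >= lam2`` of ``[[mu20, mu11], [mu11, mu02]]``,
    returns ``sqrt(1 - lam2/lam1)``: 0 for a circle, approaching 1 for a
    line. Raises on degenerate (non-positive-definite) moment matrices.
    """
    if mu20 <= 0 or mu02 <= 0:
        raise ValueError("mu20 and mu02 must be > 0")
    t = 0.5 * (mu20 + mu02)
    d = np.hypot(0.5 * (mu20 - mu02), mu11)
    lam1, lam2 = t + d, t - d
    if lam1 <= 0 or lam2 < -1e-12 * lam1:
        raise ValueError("degenerate moment matrix (non-positive eigenvalue)")
    lam2 = max(lam2, 0.0)
    return float(np.sqrt(1.0 - lam2 / lam1))


def reference_from_frame(frame: pd.DataFrame, frame_id: str) -> ReferencePopulation:
    """Build the surrounding-leukocyte reference for a frame.

    CD45-positive membership is decided without ground truth: leukocytes
    dominate every frame, so cells with ``cd45 >= median(cd45)/2`` are taken
    as the CD45+ reference. Rare cells (CD45 orders of magnitude lower) never
    enter it.
    """
    thr = 0.5 * float(frame["cd45"].median())
    wbc = frame[frame["cd45"] >= thr]
    return ReferencePopulation(
        frame_id=frame_id,
        ck=wbc["ck"].to_numpy(float),
        vim=wbc["vim"].to_numpy(float),
        dapi=wbc["dapi"].to_numpy(float),
        cd45=wbc["cd45"].to_numpy(float),
    )


def build_references(cells: pd.DataFrame) -> dict[str, ReferencePopulation]:
    """One reference population per frame in a cell table."""
    return {
        str(fid): reference_from_frame(sub, str(fid))
        for fid, sub in cells.groupby("frame_id", sort=True)
    }


def detect_candidates(
    cells: pd.DataFrame,
    references: dict[str, ReferencePopulation] | None = None,
    sdom_threshold: float = 6.0,
    vim_n_sd: float = 2.0,
    dapi_n_sd: float = 2.0,
    cd45_percentile: float = 10.0,
) -> pd.DataFrame:
    """Identify DAPI+/CK+/CD45- candidate rare cells.

    A cell is a candidate iff its DAPI exceeds the frame floor
    (leukocyte mean − ``dapi_n_sd``·SD), its CK SDOM is ≥ ``sdom_threshold``
    (closed: a tie at the threshold passes), and its CD45 falls below the
    ``cd45_percentile``-th percentile of the frame leukocytes. Returned
    candidates carry ``ck_sdom``, ``vim_call``, ``vim_rfi`` and
    ``eccentricity`` columns; the input order is preserved.

    Raises :class:`MissingReferenceError` naming any frame that lacks a
    reference population.
    """
    if references is None:
        references = build_references(cells)
    out_rows = []
    for fid, sub in cells.groupby("frame_id", sort=False):
        fid = str(fid)
        if fid not in references:
            raise MissingReferenceError(f"no reference population for frame {fid!r}")
        ref = references[fid]
        mean_ck = float(np.mean(ref.ck))
        sd_ck = float(np.std(ref.ck, ddof=1))
        if sd_ck == 0.0:
            raise DegenerateReferenceError(f"frame {fid}: reference CK SD is zero")
        dapi_floor = float(np.mean(ref.dapi) - dapi_n_sd * np.std(ref.dapi, ddof=1))
        cd45_ceiling = float(np.percentile(ref.cd45, cd45_percentile))
        v_cut = vim_cutoff(ref, n_sd=vim_n_sd)

        sdom = (sub["ck"].to_numpy(float) - mean_ck) / sd_ck
        keep = (
            (sub["dapi"].to_numpy(float) >= dapi_floor)
            & (sdom >= sdom_threshold)
            & (sub["cd45"].to_numpy(float) <= cd45_ceiling)
        )
        cand = sub.loc[keep].copy()
        cand["ck_sdom"] = sdom[keep]
        cand["vim_rfi"] = cand["vim"].astype(float)
        cand["vim_call"] = cand["vim_rfi"] > v_cut
        cand["eccentricity"] = [
            compute_eccentricity(m20, m02, m11)
            for m20, m02, m11 in zip(cand["mu20"], cand["mu02"], cand["mu11"])
        ]
        out_rows.append(cand)
    if not out_rows:
        return cells.iloc[0:0].copy()
    return pd.concat(out_rows).sort_index()
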