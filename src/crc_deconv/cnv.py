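"""Single-cell copy-number profiling.

Sparse single-cell read counts are aggregated into genomic bins (5,000 by
default), GC-corrected with a locally weighted regression of log count on
bin GC fraction, and expressed as ratio-to-median profiles. Circular binary
segmentation (CBS) on the log2 ratios yields segments whose mean ratios are
called as gain (> 1.25), loss (< 0.75) or neutral (the closed interval
[0.75, 1.25]). Clonality — evidence of common tumor lineage — is two or more
altered cells sharing copy-number breakpoints; a lone altered cell can be
rescued as clonal when its alterations overlap supplied cancer-typical
regions.

The genome here is abstract: chromosome names and lengths are inputs, bins
are equal-width within each chromosome, and segmentation runs per
chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

GAIN_THRESHOLD = 1.25
LOSS_THRESHOLD = 0.75

BIN_COLUMNS = ["chrom", "start", "end", "gc"]


class SegmentationError(ValueError):
    pass


# --------------------------------------------------------------------------
# bins
# --------------------------------------------------------------------------

def default_genome(n_chrom: int = 22, genome_size: int = 3_000_000_000) -> dict[str, int]:
    """Abstract autosome set with smoothly decreasing chromosome lengths."""
    weights = np.linspace(1.6, 0.4, n_chrom)
    lengths = np.round(genome_size * weights / weights.sum()).astype(np.int64)
    return {f"chr{i + 1}": int(l) for i, l in enumerate(lengths)}


def _apportion(lengths: np.ndarray, n_bins: int) -> np.ndarray:
    """Largest-remainder apportionment of bins to chromosomes by length."""
    quota = n_bins * lengths / lengths.sum()
    base = np.floor(quota).astype(int)
    rem = n_bins - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:rem]] += 1
    return base


def make_bins(
    chrom_lengths: dict[str, int],
    n_bins: int = 5000,
    gc_track: np.ndarray | None = None,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Partition a genome into ``n_bins`` bins (0-based, half-open).

    Bins are allocated to chromosomes proportionally to length (largest
    remainder) and are equal-width within a chromosome, with the final bin
    absorbing the division remainder. GC fractions come from ``gc_track``
    (one value per bin) or, if absent, are simulated as a smooth bounded
    random walk around 0.42 seeded by ``seed``.
    """
    if not chrom_lengths:
        raise ValueError("chrom_lengths is empty")
    names = list(chrom_lengths)
    lengths = np.asarray([chrom_lengths[c] for c in names], dtype=np.int64)
    if np.any(lengths <= 0):
        raise ValueError("chromosome lengths must be > 0")
    alloc = _apportion(lengths, n_bins)
    if np.any(alloc > lengths):
        raise ValueError("more bins than base pairs on a chromosome (zero-width bins)")
    rows = []
    for name, length, k in zip(names, lengths, alloc):
        if k == 0:
            continue
        width = length // k
        starts = np.arange(k, dtype=np.int64) * width
        ends = np.append(starts[1:], length)
        for s, e in zip(starts, ends):
            rows.append((name, int(s), int(e)))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    if gc_track is not None:
        gc = np.asarray(gc_track, dtype=float)
        if gc.shape != (len(bins),):
            raise ValueError(f"gc_track must have {len(bins)} values, got {gc.shape}")
        if np.any((gc < 0) | (gc > 1)):
            raise ValueError("GC fractions must lie in [0, 1]")
    else:
        rng = np.random.default_rng(seed)
        steps = rng.normal(0.0, 0.004, size=len(bins))
        walk = 0.42 + np.cumsum(steps) - np.linspace(0, steps.sum(), len(bins))
        gc = np.clip(walk + rng.normal(0, 0.01, size=len(bins)), 0.30, 0.60)
    bins["gc"] = gc
    return bins


def write_bins_bed(bins: pd.DataFrame, path) -> None:
    """BED-style TSV (chrom, start, end, gc), no header."""
    bins[BIN_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bins_bed(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=BIN_COLUMNS)


# --------------------------------------------------------------------------
# counting and normalization
# --------------------------------------------------------------------------

def count_reads(reads: pd.DataFrame, bins: pd.DataFrame) -> np.ndarray:
    """Bin aligned read positions (columns ``chrom``, ``pos``).

    A read at position p falls in the unique bin with start <= p < end
    (half-open). Reads on unknown chromosomes or beyond the last bin are
    dropped. Returns the per-bin count vector.
    """
    counts = np.zeros(len(bins), dtype=np.int64)
    if len(reads) == 0:
        return counts
    offsets = {}
    for chrom, sub in bins.groupby("chrom", sort=False):
        offsets[chrom] = (sub.index[0], sub["start"].to_numpy(), sub["end"].to_numpy())
    for chrom, sub in reads.groupby("chrom", sort=False):
        if chrom not in offsets:
            continue
        off, starts, ends = offsets[chrom]
        pos = sub["pos"].to_numpy(np.int64)
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        np.add.at(counts, off + idx[ok], 1)
    return counts


def gc_normalize(
    counts: np.ndarray,
    gc: np.ndarray,
    span: float = 0.3,
    pseudocount: float = 0.5,
) -> np.ndarray:
    """GC-correct binned counts and return the ratio-to-median profile.

    Fits a LOWESS curve of log count versus GC fraction (``span`` = fraction
    of bins in each local window), divides out the fitted trend, and rescales
    so the profile median is exactly 1. Zero-count bins are floored at
    ``pseudocount`` reads before the log.
    """
    counts = np.asarray(counts, dtype=float)
    gc = np.asarray(gc, dtype=float)
    if counts.shape != gc.shape:
        raise ValueError("counts and gc must have the same length")
    nonzero = int(np.count_nonzero(counts))
    if nonzero == 0:
        raise ValueError("all-zero count profile; exclude this cell upstream")
    if nonzero < 100:
        raise ValueError(f"need >= 100 bins with nonzero counts, got {nonzero}")
    y = np.log(np.maximum(counts, pseudocount))
    delta = 0.01 * (gc.max() - gc.min())
    # tied GC values trip a harmless divide FPE inside the smoother
    with np.errstate(invalid="ignore"):
        fit = lowess(y, gc, frac=span, delta=delta, return_sorted=False)
    if not np.all(np.isfinite(fit)):
        raise ValueError("GC trend fit produced non-finite values")
    ratio = np.exp(y - fit)
    med = np.median(ratio)
    if med <= 0:
        raise ValueError("non-positive median ratio after GC correction")
    return ratio / med


def normalize_matrix(
    counts: pd.DataFrame, bins: pd.DataFrame, span: float = 0.3
) -> pd.DataFrame:
    """GC-normalize a cells x bins count matrix into ratio-to-median profiles."""
    gc = bins["gc"].to_numpy()
    out = {cid: gc_normalize(row.to_numpy(), gc, span=span) for cid, row in counts.iterrows()}
    return pd.DataFrame.from_dict(out, orient="index", columns=counts.columns)


# --------------------------------------------------------------------------
# circular binary segmentation
# --------------------------------------------------------------------------

def _arc_scales(n: int, ks: np.ndarray, sigma: float) -> np.ndarray:
    return 1.0 / (sigma * np.sqrt(ks * (n - ks) / n))


def max_arc_statistic(x: np.ndarray, min_width: int = 3):
    """Maximal circular two-sample mean-shift statistic over all arcs.

    For centered values with cumulative sum c and overall SD sigma, the arc
    [i, j) of length k scores ``|c[j] - c[i]| / (sigma * sqrt(k (n-k) / n))``
    — a t-like contrast of the arc mean against its complement. Returns
    ``(stat, (i, j))``; ``(0.0, None)`` when no admissible arc exists or the
    segment is constant.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2 * min_width:
        return 0.0, None
    sigma = float(np.std(x))
    if sigma == 0.0:
        return 0.0, None
    xc = x - x.mean()
    c = np.concatenate(([0.0], np.cumsum(xc)))
    best, best_arc = -np.inf, None
    for k in range(min_width, n - min_width + 1):
        d = np.abs(c[k:] - c[:-k])
        i = int(np.argmax(d))
        s = d[i] / (sigma * np.sqrt(k * (n - k) / n))
        if s > best:
            best, best_arc = float(s), (i, i + k)
    return best, best_arc


def _permutation_pvalue(
    x: np.ndarray,
    observed: float,
    n_perm: int,
    alpha: float,
    min_width: int,
    rng: np.random.Generator,
) -> float:
    """Permutation p-value of the max arc statistic, with early stopping.

    Processes permutations in chunks; stops as soon as the eventual p-value
    (with the +1 correction) can no longer fall below ``alpha``. Returns a
    lower bound on p in that case, which is all the split decision needs.
    """
    n = len(x)
    sigma = float(np.std(x))
    xc = x - x.mean()
    ks = np.arange(min_width, n - min_width + 1)
    scales = _arc_scales(n, ks.astype(float), sigma)
    exceed = 0
    done = 0
    chunk = 50
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = rng.permuted(np.broadcast_to(xc, (m, n)).copy(), axis=1)
        c = np.concatenate([np.zeros((m, 1)), np.cumsum(perms, axis=1)], axis=1)
        best = np.zeros(m)
        for k, scale in zip(ks, scales):
            d = np.abs(c[:, k:] - c[:, :-k]).max(axis=1) * scale
            np.maximum(best, d, out=best)
        exceed += int(np.sum(best >= observed - 1e-12))
        done += m
        if (1 + exceed) / (n_perm + 1) >= alpha:
            return (1 + exceed) / (n_perm + 1)
    return (1 + exceed) / (n_perm + 1)


def _segment_recursive(
    x: np.ndarray,
    lo: int,
    hi: int,
    alpha: float,
    n_perm: int,
    min_width: int,
    rng: np.random.Generator,
    cuts: list[int],
) -> None:
    n = hi - lo
    if n < 2 * min_width:
        return
    stat, arc = max_arc_statistic(x[lo:hi], min_width=min_width)
    if arc is None:
        return
    p = _permutation_pvalue(x[lo:hi], stat, n_perm, alpha, min_width, rng)
    if p >= alpha:
        return
    i, j = arc
    for cut in (lo + i, lo + j):
        if lo < cut < hi:
            cuts.append(cut)
    pieces = sorted({lo, lo + i, lo + j, hi})
    for a, b in zip(pieces[:-1], pieces[1:]):
        _segment_recursive(x, a, b, alpha, n_perm, min_width, rng, cuts)


@dataclass
class SegmentSet:
    """Segmentation of one cell's ratio profile.

    ``segments`` has columns ``chrom``, ``start_bin``, ``end_bin`` (global
    bin indices, half-open), ``mean_ratio``, ``mean_log2`` and ``state``
    (empty until :func:`call_states`). Segments partition ``[0, n_bins)``.
    """

    cell_id: str
    segments: pd.DataFrame
    n_bins: int

    def breakpoints(self) -> list[int]:
        """Bin indices where the called state changes between adjacent bins.

        Requires states (see :func:`call_states`); neutral-to-neutral segment
        boundaries are not copy-number breakpoints.
        """
        if (self.segments["state"] == "").any():
            raise ValueError("call_states must run before extracting breakpoints")
        bps = []
        seg = self.segments.sort_values("start_bin").reset_index(drop=True)
        for a, b in zip(seg.itertuples(), seg.iloc[1:].itertuples()):
            if a.state != b.state:
                bps.append(int(b.start_bin))
        return bps

    def state_per_bin(self) -> np.ndarray:
        states = np.empty(self.n_bins, dtype=object)
        for s in self.segments.itertuples():
            states[s.start_bin : s.end_bin] = s.state
        return states

    @property
    def is_altered(self) -> bool:
        return bool((self.segments["state"].isin(["gain", "loss"])).any())


def segment_cbs(
    ratios: np.ndarray,
    bins: pd.DataFrame,
    cell_id: str = "cell",
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 3,
    merge_tol: float = 0.1,
    seed: int | None = 0,
) -> SegmentSet:
    """Circular binary segmentation of a ratio-to-median profile.

    Operates on log2 ratios, independently per chromosome: recursively find
    the arc maximizing the circular mean-shift statistic, accept the split if
    its permutation p-value falls below ``alpha`` (``n_perm`` permutations),
    and recurse into the resulting pieces. Adjacent segments whose log2 means
    differ by less than ``merge_tol`` are re-merged. The returned segments
    partition the bin axis.
    """
    ratios = np.asarray(ratios, dtype=float)
    if not np.all(np.isfinite(ratios)):
        raise SegmentationError("ratio profile contains non-finite values")
    if len(ratios) != len(bins):
        raise SegmentationError("ratio profile and bin set disagree in length")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives a coarse permutation p-value; use >= 100",
            stacklevel=2,
        )
    x = np.log2(np.maximum(ratios, 1e-6))
    rng = np.random.default_rng(seed)

    rows = []
    offset = 0
    for chrom, sub in bins.groupby("chrom", sort=False):
        n = len(sub)
        if n < 2 * min_width:
            boundaries = [offset, offset + n]
        else:
            cuts: list[int] = []
            _segment_recursive(x, offset, offset + n, alpha, n_perm, min_width, rng, cuts)
            boundaries = [offset] + sorted(set(cuts)) + [offset + n]
        # merge adjacent segments with close log2 means
        bounds = list(boundaries)
        merged = True
        while merged and len(bounds) > 2:
            merged = False
            means = [x[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
            diffs = [abs(m1 - m2) for m1, m2 in zip(means[:-1], means[1:])]
            k = int(np.argmin(diffs))
            if diffs[k] < merge_tol:
                del bounds[k + 1]
                merged = True
        for a, b in zip(bounds[:-1], bounds[1:]):
            rows.append(
                (chrom, a, b, float(np.mean(ratios[a:b])), float(np.mean(x[a:b])), "")
            )
        offset += n
    segments = pd.DataFrame(
        rows,
        columns=["chrom", "start_bin", "end_bin", "mean_ratio", "mean_log2", "state"],
    )
    return SegmentSet(cell_id=cell_id, segments=segments, n_bins=len(ratios))


def call_states(
    segset: SegmentSet,
    gain_threshold: float = GAIN_THRESHOLD,
    loss_threshold: float = LOSS_THRESHOLD,
) -> SegmentSet:
    """Call gain/loss/neutral per segment from its mean ratio-to-median.

    Gain is mean ratio strictly above ``gain_threshold`` (1.25), loss
    strictly below ``loss_threshold`` (0.75); the neutral interval
    [0.75, 1.25] is closed at both ends. Breakpoints are never changed.
    """
    seg = segset.segments.copy()
    mr = seg["mean_ratio"].to_numpy()
    state = np.where(mr > gain_threshold, "gain", np.where(mr < loss_threshold, "loss", "neutral"))
    seg["state"] = state
    return SegmentSet(cell_id=segset.cell_id, segments=seg, n_bins=segset.n_bins)


# --------------------------------------------------------------------------
# clonality
# --------------------------------------------------------------------------

@dataclass
class ClonalityResult:
    cell_id: str
    is_altered: bool
    clonal_group: str | None
    rationale: str  # shared_breakpoints | cancer_typical_single | none
    breakpoints: list[int] = field(default_factory=list)


def shared_breakpoint_count(a: list[int], b: list[int], tol: int) -> int:
    """One-to-one matches between two sorted breakpoint lists within ``tol`` bins."""
    i = j = shared = 0
    while i < len(a) and j < len(b):
        if abs(a[i] - b[j]) <= tol:
            shared += 1
            i += 1
            j += 1
        elif a[i] < b[j]:
            i += 1
        else:
            j += 1
    return shared


def _cells_linked(a: list[int], b: list[int], tol: int, min_shared: int) -> bool:
    if not a or not b:
        return False
    required = max(1, min(min_shared, len(a), len(b)))
    return shared_breakpoint_count(a, b, tol) >= required


def _segment_overlaps_regions(
    segset: SegmentSet, bins: pd.DataFrame, regions: pd.DataFrame
) -> bool:
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    chroms = bins["chrom"].to_numpy()
    for s in segset.segments.itertuples():
        if s.state not in ("gain", "loss"):
            continue
        chrom = chroms[s.start_bin]
        g_start = int(starts[s.start_bin])
        g_end = int(ends[s.end_bin - 1])
        hit = regions[
            (regions["chrom"] == chrom)
            & (regions["start"] < g_end)
            & (regions["end"] > g_start)
        ]
        if len(hit):
            return True
    return False


def detect_clonality(
    segment_sets: list[SegmentSet],
    breakpoint_tol_bins: int = 2,
    min_shared: int = 2,
    cancer_typical_regions: pd.DataFrame | None = None,
    bins: pd.DataFrame | None = None,
) -> list[ClonalityResult]:
    """Group altered cells into clones by shared copy-number breakpoints.

    Two altered cells share a breakpoint when positions differ by at most
    ``breakpoint_tol_bins``; cells sharing at least ``min_shared``
    breakpoints (or all of them, for cells with fewer) are linked, and clonal
    groups are the transitive closure of links. A lone altered cell joins no
    group but is flagged ``cancer_typical_single`` when one of its called
    gains/losses overlaps a supplied cancer-typical region (BED-style
    ``chrom``/``start``/``end``; requires ``bins`` for coordinates).

    Grouping is symmetric and invariant to the input order of cells.
    """
    if breakpoint_tol_bins < 0:
        raise ValueError("breakpoint_tol_bins must be >= 0")
    order = np.argsort([s.cell_id for s in segment_sets], kind="stable")
    cells = [segment_sets[i] for i in order]
    bps = {c.cell_id: c.breakpoints() for c in cells}
    altered = [c for c in cells if c.is_altered]

    parent = {c.cell_id: c.cell_id for c in altered}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for i, a in enumerate(altered):
        for b in altered[i + 1 :]:
            if _cells_linked(bps[a.cell_id], bps[b.cell_id], breakpoint_tol_bins, min_shared):
                parent[find(a.cell_id)] = find(b.cell_id)

    groups: dict[str, list[str]] = {}
    for c in altered:
        groups.setdefault(find(c.cell_id), []).append(c.cell_id)
    group_names = {}
    next_id = 1
    for root in sorted(groups, key=lambda r: min(groups[r])):
        if len(groups[root]) >= 2:
            group_names[root] = f"clone_{next_id}"
            next_id += 1

    results = {}
    for c in cells:
        if not c.is_altered:
            results[c.cell_id] = ClonalityResult(c.cell_id, False, None, "none", bps[c.cell_id])
            continue
        root = find(c.cell_id)
        if root in group_names:
            results[c.cell_id] = ClonalityResult(
                c.cell_id, True, group_names[root], "shared_breakpoints", bps[c.cell_id]
            )
        elif (
            cancer_typical_regions is not None
            and bins is not None
            and _segment_overlaps_regions(c, bins, cancer_typical_regions)
        ):
            results[c.cell_id] = ClonalityResult(
                c.cell_id, True, f"single_{c.cell_id}", "cancer_typical_single", bps[c.cell_id]
            )
        else:
            results[c.cell_id] = ClonalityResult(c.cell_id, True, None, "none", bps[c.cell_id])
    return [results[s.cell_id] for s in segment_sets]


def clonality_table(results: list[ClonalityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in results],
            "is_altered": [r.is_altered for r in results],
            "clonal_group": [r.clonal_group if r.clonal_group else "" for r in results],
            "rationale": [r.rationale for r in results],
            "breakpoints": [",".join(map(str, r.breakpoints)) for r in results],
        }
    )
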