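"""Synthetic inputs for the rare-cell deconvolution pipeline.

Everything the pipeline consumes can be generated here with known ground
truth: slide frames of leukocytes plus rare cells with the assay's
intensity and morphology structure, sparse binned read counts drawn from
clonal copy-number profiles with GC bias, imaging-mass-cytometry ion counts
with additive background, and endothelial-cell spike-in frames. A single
master seed fans out to independent child streams per generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    DEFAULT_AREA,
    DEFAULT_ECCENTRICITY_RANGE,
    PEMT_VIM_RANGE,
    RARE_LABELS,
    WBC,
    ChannelIntensity,
    ConfigError,
    SimulationConfig,
)

CELL_TABLE_COLUMNS = [
    "cell_id",
    "frame_id",
    "x",
    "y",
    "area_px",
    "mu20",
    "mu02",
    "mu11",
    "dapi",
    "ck",
    "vim",
    "cd45",
    "truth_label",
]

TISSUE_MARKERS = ("ER", "HER2", "AR", "PSA", "PSMA")
ENDOTHELIAL_MARKER = "CD31"

#: Imaging-mass-cytometry antibody panel (metal tag -> protein target),
#: mirroring the targeted-proteomics panel plus the endothelial marker CD31.
DEFAULT_PANEL = pd.DataFrame(
    {
        "metal_tag": [
            "Yb174", "Pr141", "Dy163", "Nd148", "Y89",
            "Tm169", "Gd160", "Sm154", "Nd145",
        ],
        "target": [
            "CK8_18", "EpCAM", "ER", "HER2", "CD45",
            "PSMA", "PSA", "AR", "CD31",
        ],
    }
)


def allocate_labels(composition: dict[str, float], n: int) -> list[str]:
    """Deterministic largest-remainder split of ``n`` cells by composition."""
    labels = [l for l in RARE_LABELS if composition.get(l, 0.0) > 0]
    fracs = np.array([composition[l] for l in labels])
    quota = n * fracs
    counts = np.floor(quota).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:rem]] += 1
    out = []
    for label, k in zip(labels, counts):
        out.extend([label] * int(k))
    return out


def _ellipse_moments(
    area: np.ndarray, ecc: np.ndarray, theta: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Central second moments of an ellipse mask with given area/eccentricity.

    The principal moments of an ellipse of area A with axis ratio
    r = b/a = sqrt(1 - e^2) are lam1 = A^2/(4 pi r), lam2 = lam1 r^2;
    rotating by theta mixes them into (mu20, mu02, mu11).
    """
    r = np.sqrt(1.0 - ecc**2)
    lam1 = area**2 / (4.0 * np.pi * r)
    lam2 = lam1 * r**2
    c, s = np.cos(theta), np.sin(theta)
    mu20 = lam1 * c**2 + lam2 * s**2
    mu02 = lam1 * s**2 + lam2 * c**2
    mu11 = (lam1 - lam2) * s * c
    return mu20, mu02, mu11


def _sample_cells(
    labels: list[str],
    config: SimulationConfig,
    rng: np.random.Generator,
    frame_id: str,
    start_index: int = 0,
) -> pd.DataFrame:
    n = len(labels)
    labels_arr = np.asarray(labels)
    df = pd.DataFrame(
        {
            "cell_id": [f"{frame_id}_c{start_index + i:05d}" for i in range(n)],
            "frame_id": frame_id,
            "x": rng.uniform(0, 20000, n),
            "y": rng.uniform(0, 20000, n),
        }
    )
    area = np.empty(n)
    ecc = np.empty(n)
    chan = {name: np.empty(n) for name in ("dapi", "ck", "vim", "cd45")}
    for label in set(labels):
        idx = np.where(labels_arr == label)[0]
        area[idx] = DEFAULT_AREA[label].sample(rng, len(idx))
        lo, hi = DEFAULT_ECCENTRICITY_RANGE[label]
        ecc[idx] = rng.uniform(lo, hi, len(idx))
        for name in chan:
            if name == "vim" and label == "pEMT.CTC":
                # Vim+ clonal cells: RFI log-uniform on the printed Vim+ range
                lo_v, hi_v = PEMT_VIM_RANGE
                chan[name][idx] = np.exp(
                    rng.uniform(np.log(lo_v), np.log(hi_v), len(idx))
                )
            else:
                chan[name][idx] = config.intensity_params[name][label].sample(rng, len(idx))
    theta = rng.uniform(0, np.pi, n)
    mu20, mu02, mu11 = _ellipse_moments(area, ecc, theta)
    df["area_px"] = area
    df["mu20"], df["mu02"], df["mu11"] = mu20, mu02, mu11
    for name in ("dapi", "ck", "vim", "cd45"):
        df[name] = chan[name]
    df["truth_label"] = labels_arr
    return df


def generate_frame(
    config: SimulationConfig, frame_id: str = "F1"
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate one slide frame: leukocyte monolayer plus rare cells.

    Returns the cell table (one row per cell, channel intensities and mask
    moments) and the ground-truth label series indexed by cell_id. Rare-cell
    counts follow the configured composition exactly (largest-remainder
    apportionment); rare cells are drawn with CK intensities that exceed the
    6-SDOM detection criterion against the leukocyte CK distribution.
    """
    rng = config.child_rngs("frame")["frame"]
    labels = [WBC] * config.n_wbc_per_frame + allocate_labels(config.composition, config.n_rare)
    cells = _sample_cells(labels, config, rng, frame_id)
    truth = cells.set_index("cell_id")["truth_label"]
    return cells, truth


# --------------------------------------------------------------------------
# copy-number ground truth and read counts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruthProfile:
    """Per-bin integer copy number for one cell (ploidy baseline 2).

    ``breakpoints`` are the bin indices where the copy number changes
    between consecutive bins (strictly increasing); members of a clone share
    them exactly, neutral cells have none.
    """

    cell_id: str
    copy_numbers: np.ndarray
    breakpoints: tuple[int, ...]
    clone_id: str  # clone name, or "neutral"

    def __post_init__(self):
        cn = np.asarray(self.copy_numbers, dtype=int)
        object.__setattr__(self, "copy_numbers", cn)
        bp = tuple(int(b) for b in self.breakpoints)
        object.__setattr__(self, "breakpoints", bp)
        if list(bp) != sorted(set(bp)):
            raise ValueError("breakpoints must be strictly increasing")
        derived = tuple(np.flatnonzero(np.diff(cn)) + 1)
        if derived != bp:
            raise ValueError("breakpoints inconsistent with copy-number vector")
        if self.clone_id == "neutral" and len(bp):
            raise ValueError("neutral profiles must have constant copy number")


def make_clone_template(
    bins: pd.DataFrame,
    rng: np.random.Generator,
    n_altered_chroms: int = 3,
    min_event_bins: int = 30,
    max_event_bins: int = 60,
) -> np.ndarray:
    """Random clonal copy-number template: focal events on a few chromosomes.

    Events (copy number 1, 3 or 4 against a diploid baseline) are placed
    inside chromosomes with neutral flanks, so every event contributes two
    breakpoints and the genome-wide median copy number stays 2.
    """
    cn = np.full(len(bins), 2, dtype=int)
    sizes = bins.groupby("chrom", sort=False).size()
    eligible = [c for c in sizes.index if sizes[c] >= max_event_bins + 20]
    chosen = rng.choice(len(eligible), size=min(n_altered_chroms, len(eligible)), replace=False)
    offset = {}
    pos = 0
    for c in sizes.index:
        offset[c] = pos
        pos += sizes[c]
    for ci in sorted(chosen):
        chrom = eligible[ci]
        n = int(sizes[chrom])
        width = int(rng.integers(min_event_bins, max_event_bins + 1))
        start = int(rng.integers(5, n - width - 5))
        level = int(rng.choice([1, 3, 4]))
        cn[offset[chrom] + start : offset[chrom] + start + width] = level
    return cn


def profiles_for_labels(
    truth_labels: pd.Series,
    bins: pd.DataFrame,
    config: SimulationConfig,
    clone_template: np.ndarray | None = None,
) -> list[GroundTruthProfile]:
    """Ground-truth profiles: one shared clone for tumor cells, neutral otherwise.

    EPI.CTC and pEMT.CTC cells all carry the same clonal template (identical
    breakpoints — the tumor lineage); CECs and leukocytes are copy-number
    neutral.
    """
    rng = config.child_rngs("clone")["clone"]
    if clone_template is None:
        clone_template = make_clone_template(bins, rng)
    bp = tuple(int(b) for b in np.flatnonzero(np.diff(clone_template)) + 1)
    profiles = []
    for cell_id, label in truth_labels.items():
        if label in ("EPI.CTC", "pEMT.CTC"):
            profiles.append(GroundTruthProfile(cell_id, clone_template.copy(), bp, "clone_1"))
        else:
            profiles.append(
                GroundTruthProfile(cell_id, np.full(len(bins), 2, dtype=int), (), "neutral")
            )
    return profiles


def simulate_read_counts(
    profiles: list[GroundTruthProfile],
    bins: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Draw binned read counts from ground-truth copy-number profiles.

    Expected count per bin is proportional to copy number x bin width x a
    log-linear GC bias ``exp(gc_bias_strength * (gc - 0.45))``, scaled so
    each cell totals ``reads_per_cell`` in expectation. Noise is Poisson or
    gamma-overdispersed Poisson (negative binomial).
    """
    widths = (bins["end"] - bins["start"]).to_numpy(float)
    if np.any(widths <= 0):
        raise ValueError("zero-width bins")
    gc = bins["gc"].to_numpy(float)
    if np.any((gc < 0) | (gc > 1)):
        raise ValueError("GC fractions must lie in [0, 1]")
    bias = np.exp(config.gc_bias_strength * (gc - 0.45))
    rng = config.child_rngs("reads")["reads"]
    rows = {}
    for prof in profiles:
        w = prof.copy_numbers * widths * bias
        lam = config.reads_per_cell * w / w.sum()
        if config.noise_model == "negative_binomial" and config.nb_dispersion > 0:
            shape = 1.0 / config.nb_dispersion
            lam = lam * rng.gamma(shape, 1.0 / shape, size=len(lam))
        rows[prof.cell_id] = rng.poisson(lam)
    return pd.DataFrame.from_dict(rows, orient="index", columns=range(len(bins)))


# --------------------------------------------------------------------------
# imaging mass cytometry
# --------------------------------------------------------------------------

#: Mean ion counts (ions/pixel) by marker for expressing vs non-expressing
#: cells; non-expressed markers sit at the leukocyte baseline so that the
#: WBC-anchored z-score reference is meaningful.
_IMC_BASELINE = 0.05
_IMC_LEVELS = {
    "CK8_18": {"EPI.CTC": 6.0, "pEMT.CTC": 6.0, "CEC": 1.5},
    "EpCAM": {},  # handled via the co-expression fraction
    "CD45": {WBC: 8.0},
    "CD31": {"CEC": 6.0},
    "ER": {},
    "HER2": {},
    "AR": {},
    "PSA": {},
    "PSMA": {},
}
_TISSUE_LEVEL = 4.0
_EPCAM_LEVEL = 5.0
_IMC_CV = 0.25  # multiplicative noise, sd/mean


def simulate_imc(
    truth_labels: pd.Series,
    panel: pd.DataFrame,
    config: SimulationConfig,
    n_reference_wbc: int = 150,
    cancer_type: str = "prostate",
    cell_area_px: int = 400,
    background_area_px: int = 20000,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Simulate mean ion counts per cell mask for a marker panel.

    Tumor-labelled cells express the cancer-type tissue markers (AR/PSA/PSMA
    for prostate, ER/HER2 for breast) plus CK8/18, with EpCAM elevated in an
    exact ``epcam_coexpression_fraction`` subset; CECs express CD31; the
    appended reference leukocytes express CD45. A uniform additive Poisson
    background at ``imc_background_rate`` ions/pixel contaminates every mask
    and is separately observable in the negative mask space.

    Returns ``(ion_table, background_by_marker, reference_ids)``.
    """
    if len(panel) == 0:
        raise ValueError("empty antibody panel")
    markers = list(panel["target"])
    rng = config.child_rngs("imc")["imc"]
    tissue = {"prostate": ("AR", "PSA", "PSMA"), "breast": ("ER", "HER2")}.get(cancer_type)
    if tissue is None:
        raise ConfigError(f"unknown cancer_type {cancer_type!r}")

    ids = list(truth_labels.index) + [f"refWBC_{i:03d}" for i in range(n_reference_wbc)]
    labels = list(truth_labels.values) + [WBC] * n_reference_wbc
    reference_ids = ids[len(truth_labels) :]

    ctc_idx = [i for i, l in enumerate(labels) if l in ("EPI.CTC", "pEMT.CTC")]
    n_epcam = int(round(config.epcam_coexpression_fraction * len(ctc_idx)))
    epcam_pos = set(
        rng.choice(ctc_idx, size=n_epcam, replace=False) if n_epcam else []
    )

    table = np.empty((len(ids), len(markers)))
    for j, marker in enumerate(markers):
        levels = _IMC_LEVELS.get(marker, {})
        for i, label in enumerate(labels):
            mean = levels.get(label, _IMC_BASELINE)
            if marker in tissue and label in ("EPI.CTC", "pEMT.CTC"):
                mean = _TISSUE_LEVEL
            if marker == "EpCAM" and i in epcam_pos:
                mean = _EPCAM_LEVEL
            table[i, j] = ChannelIntensity(mean, _IMC_CV * mean).sample(rng, 1)[0]
        # additive background inside every mask
        table[:, j] += rng.poisson(
            config.imc_background_rate * cell_area_px, size=len(ids)
        ) / cell_area_px
    background = pd.Series(
        rng.poisson(config.imc_background_rate * background_area_px, size=len(markers))
        / background_area_px,
        index=markers,
        name="background",
    )
    ion_table = pd.DataFrame(table, index=ids, columns=markers)
    ion_table.index.name = "cell_id"
    return ion_table, background, reference_ids


# --------------------------------------------------------------------------
# spike-in frames
# --------------------------------------------------------------------------

def generate_spike_in(
    concentration: float,
    volume_ml: float,
    config: SimulationConfig,
    frame_id: str = "SPIKE1",
) -> pd.DataFrame:
    """Normal-donor frame with endothelial cell-line cells spiked in.

    Spiked cells (``truth_label == "SPIKE"``) carry the endothelial
    intensity profile: CK dim-positive, vimentin high, CD45 negative. The
    number of spiked cells is exactly ``round(concentration * volume_ml)``.
    """
    if concentration < 0 or volume_ml < 0:
        raise ValueError("concentration and volume must be >= 0")
    n_spike = int(round(concentration * volume_ml))
    rng = config.child_rngs("spike")["spike"]
    labels = [WBC] * config.n_wbc_per_frame + ["CEC"] * n_spike
    cells = _sample_cells(labels, config, rng, frame_id)
    cells.loc[cells["truth_label"] == "CEC", "truth_label"] = "SPIKE"
    return cells


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def write_cell_table(cells: pd.DataFrame, path) -> None:
    cells[CELL_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_cell_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ground_truth(profiles: list[GroundTruthProfile], path) -> None:
    payload = [
        {
            "cell_id": p.cell_id,
            "clone_id": p.clone_id,
            "breakpoints": list(p.breakpoints),
            "copy_numbers": p.copy_numbers.tolist(),
        }
        for p in profiles
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh)


def index_patient_draws() -> list[dict]:
    """Four-draw longitudinal scenario for the index patient.

    Tumor cells dominate at active disease (~90% CTC, ~10% CEC) and
    endothelial cells at stable disease (~75% CEC), with ~40% of the clonal
    cells vimentin-positive throughout.
    """
    ad = {"EPI.CTC": 0.54, "pEMT.CTC": 0.36, "CEC": 0.10}
    sd = {"EPI.CTC": 0.15, "pEMT.CTC": 0.10, "CEC": 0.75}
    return [
        {"draw_id": "D1", "timepoint_weeks": 0, "disease_status": "AD", "composition": ad},
        {"draw_id": "D2", "timepoint_weeks": 8, "disease_status": "SD", "composition": sd},
        {"draw_id": "D3", "timepoint_weeks": 16, "disease_status": "SD", "composition": sd},
        {"draw_id": "D4", "timepoint_weeks": 28, "disease_status": "AD", "composition": ad},
    ]
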