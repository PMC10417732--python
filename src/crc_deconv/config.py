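"""Simulation configuration for the synthetic rare-cell study.

The defaults encode the study conditions the pipeline is designed for: slide
monolayers dominated by leukocytes with a handful of rare cells, single-cell
sequencing at ~500,000 mapped reads per cell binned into 5,000 genomic bins,
and imaging-mass-cytometry ion counts with additive background.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

RARE_LABELS = ("EPI.CTC", "pEMT.CTC", "CEC")
WBC = "WBC"

#: Printed vimentin RFI range of Vim+ clonal cells; pEMT vim intensities are
#: drawn log-uniformly on this interval.
PEMT_VIM_RANGE = (0.0032, 0.0522)


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and SD."""
    if mean <= 0:
        raise ConfigError(f"log-normal mean must be > 0, got {mean}")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


@dataclass(frozen=True)
class ChannelIntensity:
    """Log-normal intensity model for one channel of one cell label.

    ``mean``/``sd`` are on the arithmetic (linear fluorescence) scale, in
    arbitrary units consistent within a channel.
    """

    mean: float
    sd: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        mu, sigma = _lognormal_params(self.mean, self.sd)
        return rng.lognormal(mu, sigma, size=n)


# WBC CK baseline mean 1.0 / sd 0.15 puts the 6-SDOM detection boundary at
# ~1.9 arbitrary units; rare-cell CK means sit comfortably above it, with the
# CEC mean lower ("CK dim") but still detectable. Vimentin baselines are on
# the RFI scale of the printed Vim+ range.
DEFAULT_INTENSITY_PARAMS: dict[str, dict[str, ChannelIntensity]] = {
    # rare cells carry larger nuclei than leukocytes; their DAPI content sits
    # well above the leukocyte-derived detection floor (mean - 2 SD)
    "dapi": {
        WBC: ChannelIntensity(10.0, 1.2),
        "EPI.CTC": ChannelIntensity(13.0, 1.3),
        "pEMT.CTC": ChannelIntensity(13.0, 1.3),
        "CEC": ChannelIntensity(13.0, 1.3),
    },
    "ck": {
        WBC: ChannelIntensity(1.0, 0.15),
        "EPI.CTC": ChannelIntensity(3.2, 0.45),
        "pEMT.CTC": ChannelIntensity(3.2, 0.45),
        "CEC": ChannelIntensity(2.6, 0.26),
    },
    "vim": {
        WBC: ChannelIntensity(0.002, 0.0004),
        "EPI.CTC": ChannelIntensity(0.002, 0.0004),
        # pEMT vim is drawn log-uniformly on PEMT_VIM_RANGE instead; the
        # entry here is only a fallback mean for reporting.
        "pEMT.CTC": ChannelIntensity(0.013, 0.008),
        "CEC": ChannelIntensity(0.03, 0.012),
    },
    "cd45": {
        WBC: ChannelIntensity(5.0, 1.0),
        "EPI.CTC": ChannelIntensity(0.05, 0.015),
        "pEMT.CTC": ChannelIntensity(0.05, 0.015),
        "CEC": ChannelIntensity(0.05, 0.015),
    },
}

#: Eccentricity (0 = circle, 1 = degenerate ellipse) ranges per label; CECs
#: are elongated, tumor cells and WBCs round.
DEFAULT_ECCENTRICITY_RANGE: dict[str, tuple[float, float]] = {
    WBC: (0.10, 0.55),
    "EPI.CTC": (0.10, 0.55),
    "pEMT.CTC": (0.10, 0.60),
    "CEC": (0.85, 0.97),
}

#: Cell mask area (pixels) per label: rare cells are larger than leukocytes.
DEFAULT_AREA: dict[str, ChannelIntensity] = {
    WBC: ChannelIntensity(60.0, 12.0),
    "EPI.CTC": ChannelIntensity(160.0, 35.0),
    "pEMT.CTC": ChannelIntensity(160.0, 35.0),
    "CEC": ChannelIntensity(140.0, 30.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic blood-draw simulation.

    Parameters
    ----------
    seed
        Master seed. A :class:`numpy.random.SeedSequence` fans it out to
        independent child streams per generator, so adding one generator
        never perturbs another.
    n_wbc_per_frame
        Leukocytes per slide frame (monolayer density at detection time).
    composition
        Ground-truth fractions over the rare-cell labels
        ``{"EPI.CTC", "pEMT.CTC", "CEC"}``; must sum to 1.
    n_rare
        Number of rare cells in the frame.
    reads_per_cell
        Target sequencing depth per cell (mapped reads); the study depth is
        ~500,000 with a floor of 250,000.
    n_bins
        Genomic bins the reads are aggregated into.
    gc_bias_strength
        Slope of the log-linear GC bias injected into expected bin counts
        (0 disables the bias).
    noise_model
        ``"poisson"`` or ``"negative_binomial"`` bin-count noise.
    nb_dispersion
        Dispersion of the negative-binomial model (variance
        ``mu + dispersion * mu**2``).
    intensity_params
        Per-channel, per-label log-normal intensity models.
    imc_background_rate
        Additive ion-count background, ions/pixel, uniform across the ROI.
    epcam_coexpression_fraction
        Fraction of CTC-labelled cells with elevated EpCAM in the IMC panel.
    """

    seed: int = 0
    n_wbc_per_frame: int = 5000
    composition: dict[str, float] = field(
        default_factory=lambda: {"EPI.CTC": 0.54, "pEMT.CTC": 0.36, "CEC": 0.10}
    )
    n_rare: int = 200
    reads_per_cell: int = 500_000
    n_bins: int = 5000
    gc_bias_strength: float = 1.0
    noise_model: Literal["poisson", "negative_binomial"] = "poisson"
    nb_dispersion: float = 0.1
    intensity_params: dict[str, dict[str, ChannelIntensity]] = field(
        default_factory=lambda: DEFAULT_INTENSITY_PARAMS
    )
    imc_background_rate: float = 0.1
    epcam_coexpression_fraction: float = 0.5

    def __post_init__(self) -> None:
        unknown = set(self.composition) - set(RARE_LABELS)
        if unknown:
            raise ConfigError(f"unknown rare-cell labels in composition: {sorted(unknown)}")
        fracs = np.asarray(list(self.composition.values()), dtype=float)
        if len(fracs) and (np.any(fracs < 0) or np.any(fracs > 1)):
            raise ConfigError("composition fractions must lie in [0, 1]")
        if len(fracs) and abs(fracs.sum() - 1.0) > 1e-9:
            raise ConfigError(
                f"composition fractions must sum to 1 (got {fracs.sum():.12g})"
            )
        for name, value in (
            ("n_wbc_per_frame", self.n_wbc_per_frame),
            ("n_rare", self.n_rare),
            ("reads_per_cell", self.reads_per_cell),
            ("n_bins", self.n_bins),
        ):
            if value < 0:
                raise ConfigError(f"{name} must be >= 0, got {value}")
        if self.gc_bias_strength < 0:
            raise ConfigError("gc_bias_strength must be >= 0")
        if self.noise_model not in ("poisson", "negative_binomial"):
            raise ConfigError(f"unknown noise model {self.noise_model!r}")
        if not 0.0 <= self.epcam_coexpression_fraction <= 1.0:
            raise ConfigError("epcam_coexpression_fraction must lie in [0, 1]")

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def child_rngs(self, *names: str) -> dict[str, np.random.Generator]:
        """Independent child generators, one per requested stream name.

        Streams are keyed by name order-independently (hash of the name is
        folded into the seed sequence), so the set of generators a caller
        requests does not change the streams of the others.
        """
        out = {}
        for name in names:
            key = zlib.crc32(name.encode())
            ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(key,))
            out[name] = np.random.default_rng(ss)
        return out
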