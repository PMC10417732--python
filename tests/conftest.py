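import numpy as np
import pandas as pd
import pytest

from crc_deconv import cnv
from crc_deconv.config import SimulationConfig
from crc_deconv.pipeline import run_draw


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """Scaled-down study conditions for fast unit tests."""
    return SimulationConfig(
        seed=42,
        n_wbc_per_frame=600,
        n_rare=30,
        n_bins=800,
        reads_per_cell=80_000,
    )


@pytest.fixture
def small_bins(small_config):
    return cnv.make_bins(
        cnv.default_genome(n_chrom=8), small_config.n_bins, seed=small_config.seed
    )


@pytest.fixture(scope="session")
def stable_disease_draw():
    """Full-pipeline run at study scale: 75% CEC / 25% CTC, n = 200 rare cells."""
    cfg = SimulationConfig(
        seed=7,
        n_rare=200,
        composition={"EPI.CTC": 0.15, "pEMT.CTC": 0.10, "CEC": 0.75},
    )
    return run_draw(cfg, draw_id="SD1", disease_status="SD", n_perm=200)


@pytest.fixture(scope="session")
def progression_draw():
    """Full-pipeline run at study scale: 90% CTC / 10% CEC, n = 200 rare cells."""
    cfg = SimulationConfig(
        seed=11,
        n_rare=200,
        composition={"EPI.CTC": 0.54, "pEMT.CTC": 0.36, "CEC": 0.10},
    )
    return run_draw(cfg, draw_id="AD1", disease_status="AD", n_perm=200)


def binomial_ci(p: float, n: int, z: float = 1.96) -> tuple[float, float]:
    half = z * np.sqrt(p * (1 - p) / n)
    return p - half, p + half
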