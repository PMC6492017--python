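import numpy as np
import pandas as pd
import pytest

from loyscan.cn_index import Arm, GenomeArms, SegmentRecord
from loyscan.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def genome():
    return GenomeArms.grch37()


@pytest.fixture(scope="session")
def toy_genome():
    """Four small autosome arms plus X/Y with a PAR-like exclusion on Y."""
    arms = [
        Arm("1", "p", 0, 1000),
        Arm("1", "q", 1200, 2000),
        Arm("2", "p", 0, 600),
        Arm("2", "q", 700, 1500),
        Arm("X", "p", 0, 800),
        Arm("X", "q", 900, 1600),
        Arm("Y", "p", 0, 500),
        Arm("Y", "q", 600, 1200),
    ]
    exclusions = {"Y": [(0, 50), (1150, 1200)], "X": [(0, 50), (1550, 1600)]}
    return GenomeArms(arms, exclusions, excluded_arms=frozenset())


@pytest.fixture(scope="session")
def default_cohort():
    """The acceptance-scale cohort: n=400, pi=0.25, purity Beta(8,2), noise 0.05."""
    config = SimulationConfig(
        n_samples=400,
        loy_prevalence=0.25,
        purity_alpha=8.0,
        purity_beta=2.0,
        segment_noise_sd=0.05,
        n_genes=400,
        n_y_genes=12,
        n_immune_genes=40,
        n_redox_genes=20,
        nb_dispersion=0.02,
        seed=20240205,
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def small_cohort():
    config = SimulationConfig(
        n_samples=80, n_genes=120, n_y_genes=8, n_immune_genes=20,
        n_redox_genes=10, seed=99,
    )
    return simulate_cohort(config)


def make_segments(sample, rows):
    """rows: (chromosome, start, end, linear_cn)."""
    return [SegmentRecord(sample, c, s, e, None, v) for c, s, e, v in rows]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
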