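"""Shared fixtures: small random blocks and planted synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from subpls import DataBlocks, SyntheticConfig, fit_pls, generate_cohort

STRONG_GAMMA = 6.0  # well inside the high-signal regime for recovery checks


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_blocks(rng) -> DataBlocks:
    """Unstructured 30-subject blocks for algebraic checks."""
    return DataBlocks(X=rng.normal(size=(30, 8)), Y=rng.normal(size=(30, 5)))


@pytest.fixture(scope="session")
def planted_cohort():
    """Strong planted component, n=500, moderate dimensionality (shared)."""
    cfg = SyntheticConfig(n=500, p=300, q=37, gamma_x=STRONG_GAMMA,
                          gamma_y=STRONG_GAMMA, seed=7)
    blocks, subjects, truth = generate_cohort(cfg)
    return blocks, subjects, truth


@pytest.fixture(scope="session")
def planted_model(planted_cohort):
    blocks, _, _ = planted_cohort
    return fit_pls(blocks)
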