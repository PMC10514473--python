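"""Shared fixtures and helpers for the clockmr test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from clockmr import SimulationConfig, kept_pairs, harmonize, simulate_mr_triplet


def make_pairs(bx, sx, by, sy, snp_ids=None) -> pd.DataFrame:
    """Build a harmonized-pair table directly from effect arrays."""
    bx = np.asarray(bx, float)
    n = len(bx)
    return pd.DataFrame(
        {
            "snp_id": snp_ids if snp_ids is not None else [f"s{i:03d}" for i in range(n)],
            "beta_x": bx,
            "se_x": np.broadcast_to(np.asarray(sx, float), (n,)).copy(),
            "beta_y": np.asarray(by, float),
            "se_y": np.broadcast_to(np.asarray(sy, float), (n,)).copy(),
            "status": "kept",
        }
    )


def random_instance(rng, n=None):
    """A small random instrument set with heterogeneous weights."""
    n = n if n is not None else rng.integers(3, 9)
    bx = rng.uniform(0.1, 0.5, n) * rng.choice([-1, 1], n)
    sx = rng.uniform(0.02, 0.06, n)
    sy = rng.uniform(0.02, 0.08, n)
    theta = rng.normal(0, 0.2)
    by = theta * bx + rng.normal(0, sy)
    return make_pairs(bx, sx, by, sy), theta


def triplet_pairs(config: SimulationConfig, seed: int):
    """Simulate a triplet and return harmonized exposure/outcome pairs."""
    trip = simulate_mr_triplet(config, seed=seed)
    return kept_pairs(harmonize(trip.exposure, trip.outcome))


@pytest.fixture
def rng():
    return np.random.default_rng(20230908)


@pytest.fixture
def mr_null_config():
    """Null causal effect, no pleiotropy, instrument SNPs only."""
    return SimulationConfig(
        direct_effect=0.0, n_mediator_snps=0, palindromic_fraction=0.0
    )


@pytest.fixture
def mr_effect_config():
    """The headline effect regime: theta = 0.065 with strong instruments."""
    return SimulationConfig(
        direct_effect=0.065, n_mediator_snps=0, palindromic_fraction=0.0
    )
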