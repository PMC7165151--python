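"""Shared fixtures: small seeded cohorts and reusable simulation configs."""

import numpy as np
import pytest

from codsig import SimulationConfig, simulate_cohort


def small_config(seed: int, **overrides) -> SimulationConfig:
    """A fast cohort with clean group structure for recovery tests."""
    params = dict(
        n_genes=600, n_int_module=60, n_cod_module=90,
        effect_size=2.0, noise_sd=0.5, seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


def validation_config(seed: int, **overrides) -> SimulationConfig:
    """A diffuse-only cohort (INT/COD latent mix) for classifier evaluation."""
    params = dict(
        n_genes=600, n_int_module=60, n_cod_module=90,
        effect_size=2.0, noise_sd=0.5, seed=seed,
        n_normal=2, n_intestinal=2, n_diffuse=80,
        diffuse_subtype_props=(0.0, 0.45, 0.55),
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def small_cohort():
    """One derivation-scale cohort shared across read-only tests."""
    return simulate_cohort(small_config(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
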