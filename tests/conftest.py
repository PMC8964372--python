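import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from survimage import (
    SimulationSpec,
    build_labeled_cohort,
    simulate_annotation,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_spec():
    """Desk-sized cohort for unit tests; the default spec is exercised in
    the acceptance suite."""
    return SimulationSpec(
        n_samples=120,
        n_genes=60,
        n_signal_genes=8,
        n_groups=5,
        n_pathways=6,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    expression, clinical, signal_genes = simulate_cohort(small_spec)
    cohort = build_labeled_cohort(expression, clinical, horizon=small_spec.horizon)
    return cohort, signal_genes


@pytest.fixture(scope="session")
def small_annotation(small_spec):
    return simulate_annotation(
        small_spec.n_genes,
        small_spec.n_groups,
        small_spec.n_pathways,
        seed=small_spec.seed,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
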