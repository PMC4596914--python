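import numpy as np
import pytest

from kirimp import ForestParams, default_spec, simulate_panel


@pytest.fixture(scope="session")
def perfect_spec():
    """Small noiseless region: every locus perfectly tagged."""
    return default_spec(
        n_snps_cen=6, n_snps_tel=6, n_haplotypes=120,
        tagging_strength=1.0, error_rate=0.0, seed=11,
    )


@pytest.fixture(scope="session")
def perfect_panel(perfect_spec):
    panel, truth, copy_map = simulate_panel(perfect_spec)
    return panel, truth, copy_map


@pytest.fixture(scope="session")
def noisy_panel():
    spec = default_spec(
        n_snps_cen=8, n_snps_tel=8, n_haplotypes=200,
        tagging_strength=0.9, error_rate=0.01, seed=17,
    )
    return simulate_panel(spec)


@pytest.fixture()
def small_params():
    return ForestParams(n_trees=30, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
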