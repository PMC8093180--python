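import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pgsnurture import SimConfig, extract_family_table, simulate_population

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def no_am_pops():
    """VT-only equilibrium population (Model 0 conditions), 20k families."""
    cfg = SimConfig(
        n_families=20_000, delta=0.5, a=0.0, f=0.2, r_mate=0.0, V_eps=0.545,
        m_obs=30, m_lat=1, n_generations=10, seed=42, store_haplotypes=False,
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def no_am_table(no_am_pops):
    return extract_family_table(no_am_pops)


@pytest.fixture(scope="session")
def am_m2_pops():
    """AM + VT + latent genetics at equilibrium (Model 2 conditions)."""
    cfg = SimConfig(
        n_families=20_000, delta=0.3, a=0.55, f=0.12, r_mate=0.3, V_eps=0.4,
        m_obs=30, m_lat=30, n_generations=15, seed=43, store_haplotypes=False,
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def am_m2_table(am_m2_pops):
    return extract_family_table(am_m2_pops)


@pytest.fixture(scope="session")
def small_fixture_pops():
    """Small population with haplotypes kept, for VCF round-trip tests."""
    cfg = SimConfig(
        n_families=200, delta=0.4, a=0.3, f=0.15, r_mate=0.25, V_eps=0.5,
        m_obs=25, m_lat=10, n_generations=4, seed=5,
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def exported_fixture(small_fixture_pops, tmp_path_factory):
    from pgsnurture import export_fixture

    out = tmp_path_factory.mktemp("fixture")
    return export_fixture(small_fixture_pops, out_dir=out)


def mc_se_cov(S: np.ndarray, n: int) -> np.ndarray:
    """Large-sample standard error of each sample-covariance entry."""
    d = np.diag(S)
    return np.sqrt((np.outer(d, d) + S**2) / n)
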