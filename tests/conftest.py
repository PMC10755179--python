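import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")

from dictyvar import FilterConfig, SimConfig
from dictyvar.pipeline import simulate_experiment
from dictyvar.tables import data_path, load_snp_fixture, load_table1


@pytest.fixture(scope="session")
def small_experiment():
    """A 4-line simulated experiment shared across tests."""
    # 6 lines is the smallest scale at which every injected failure class
    # is constructible (missingness needs more than 10 of 13 samples missing)
    cfg = SimConfig(n_lines=6, seed=11, ancestral_poly_sites=10, fp_sites=11)
    genome, truth, counts, emulated = simulate_experiment(cfg)
    return cfg, genome, truth, counts, emulated


@pytest.fixture(scope="session")
def table2_rows():
    return load_snp_fixture(data_path("table2.tsv"))


@pytest.fixture(scope="session")
def table1():
    return load_table1(data_path("table1.tsv"))


@pytest.fixture()
def fcfg():
    return FilterConfig()
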