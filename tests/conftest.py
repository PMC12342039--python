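import pytest
from hypothesis import HealthCheck, settings

from tbisig import SimConfig, simulate_study

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """Modest study with interaction signal in the top-ranked case genes."""
    cfg = SimConfig(
        n_participants=200, n_case_genes=50, n_control_genes=250,
        variants_per_gene=4, missing_rate=0.02,
        signal_fraction=0.5, signal_rank_band=(0.0, 10.0),
        beta_main=0.2, beta_interaction=0.6, seed=11,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def null_study():
    """All-zero-truth study: no variant touches the outcome."""
    cfg = SimConfig(
        n_participants=200, n_case_genes=40, n_control_genes=160,
        variants_per_gene=4, missing_rate=0.0,
        signal_fraction=0.0, beta_main=0.0, beta_interaction=0.0, seed=13,
    )
    return simulate_study(cfg)
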