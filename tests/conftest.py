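import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_cohort():
    """A very small but structurally complete 2x2 cohort (fast fixture)."""
    from rlddm.cohort import generate_cohort, preset_expt1

    truth = preset_expt1(n_subjects_per_context=2, seed=424242)
    log, truth_table = generate_cohort(
        truth, design_template={"block_length": 60, "max_blocks": 2}
    )
    return log, truth_table, truth


@pytest.fixture(scope="session")
def tiny_integrative_fit(tiny_cohort):
    from rlddm.inference import ModelSpec, build_model, fit_model

    log, _, _ = tiny_cohort
    model = build_model(ModelSpec.integrative(), log)
    fit = fit_model(model, n_samples=300, n_burn=100, n_chains=1, seed=7)
    return model, fit


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)
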