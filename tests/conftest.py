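import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=25,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def normal_result():
    """100-seed normal-condition run shared by the acceptance tests."""
    from scenegate import ExperimentSpec, run_experiment

    return run_experiment(ExperimentSpec(condition="normal", n_seeds=100, seed=0))
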