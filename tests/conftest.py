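import pytest

from balfrepo import RunConfig, SyntheticConfig, generate_study, run_pipeline


@pytest.fixture(scope="session")
def cfg():
    """Benchmark generator conditions used across the suite."""
    return SyntheticConfig(seed=11)


@pytest.fixture(scope="session")
def study(cfg):
    return generate_study(cfg)


@pytest.fixture(scope="session")
def pipeline_result(cfg):
    return run_pipeline(RunConfig(seed=11, synthetic=cfg))
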