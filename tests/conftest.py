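import warnings

import pytest

from promatch.pipeline import PipelineConfig
from promatch.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (n=1600) with its ground truth."""
    return simulate_cohort(SimulationConfig())


@pytest.fixture(scope="session")
def big_cohort():
    """A large draw for asymptotic checks."""
    return simulate_cohort(SimulationConfig(n=20000, seed=42))


@pytest.fixture()
def pipeline_config(tmp_path):
    return PipelineConfig(input_path="unused", output_dir=tmp_path / "bundle")


@pytest.fixture(scope="session")
def default_pipeline_result(default_cohort):
    """Full pipeline run on the default synthetic cohort (no output dir)."""
    from promatch.pipeline import run_pipeline
    cohort, _ = default_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(PipelineConfig(input_path="unused"), cohort=cohort)
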