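import warnings

import pytest

from cortemf import PipelineConfig, run_pipeline
from cortemf.synth import apply_injury, default_baseline, default_injury

warnings.filterwarnings("ignore", message="peak_spacing_dispersion undefined")


@pytest.fixture(scope="session")
def baseline_config():
    return default_baseline()


@pytest.fixture(scope="session")
def injured_config(baseline_config):
    return apply_injury(baseline_config, default_injury())


@pytest.fixture(scope="session")
def default_result():
    """Full pipeline run of the packaged immediate-stimulation scenario."""
    return run_pipeline(PipelineConfig.default(seed=0))


@pytest.fixture(scope="session")
def default_result_repeat():
    """Second run with the identical configuration, for determinism checks."""
    return run_pipeline(PipelineConfig.default(seed=0))
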