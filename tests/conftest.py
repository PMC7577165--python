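import hypothesis
import pytest

from dorpk import pipeline
from dorpk.trial_data import AnalysisConfig

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None
)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def ana():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def default_pipeline(tmp_path_factory):
    """One seeded full-size pipeline run shared by the end-to-end tests."""
    out = tmp_path_factory.mktemp("pipeline")
    return pipeline.run_pipeline(outdir=str(out), seed=101, compute_se=False)
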