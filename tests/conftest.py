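import pytest

from occmine.pipeline import PipelineConfig, run_all
from occmine.synth import SynthConfig, generate_corpus


@pytest.fixture(scope="session")
def small_synth():
    """A small generated corpus with structured fields and covariates."""
    return generate_corpus(SynthConfig(n_patients=60, seed=11))


@pytest.fixture(scope="session")
def trained():
    """A fully trained small pipeline (shared: training is the slow part)."""
    config = PipelineConfig(seed=5, splits=(60, 20, 80),
                            synth={"n_patients": 100, "docs_per_patient": 2.5},
                            out_dir="unused")
    return run_all(config, write_outputs=False)
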