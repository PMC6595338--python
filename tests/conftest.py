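import pytest

from neogc.reference import load_reference_cohort
from neogc.synth import CohortConfig, generate


@pytest.fixture(scope="session")
def reference():
    """The packaged 32-patient reference cohort (patients, summaries, drivers)."""
    return load_reference_cohort()


@pytest.fixture(scope="session")
def small_cohort():
    """A small deterministic synthetic cohort for pipeline-level tests."""
    cfg = CohortConfig(n_patients=8, seed=11, burden_log_mean=3.4, n_genes=60)
    return cfg, generate(cfg)
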