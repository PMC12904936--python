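import warnings

import pytest

from ssnhl_ipta.pipeline import build_analysis_table
from ssnhl_ipta.simulate import default_config, generate_cohort

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def study_cohort():
    """One study-sized cohort from the calibrated default configuration."""
    return generate_cohort(default_config(n=253), seed=11)


@pytest.fixture(scope="session")
def study_table(study_cohort):
    return build_analysis_table(study_cohort.records)
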