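import numpy as np
import pandas as pd
import pytest

from epiperform.performance import NormativeTable
from epiperform.synthetic import CohortConfig, generate_methylation, \
    generate_normative_table, generate_participants


@pytest.fixture(scope="session")
def default_config() -> CohortConfig:
    return CohortConfig(seed=11)


@pytest.fixture(scope="session")
def cohort(default_config):
    return generate_participants(default_config)


@pytest.fixture(scope="session")
def norms(default_config) -> NormativeTable:
    return generate_normative_table(default_config)


@pytest.fixture(scope="session")
def methylation(default_config, cohort):
    """(BetaMatrix, SyntheticTruth, ClockDefinition) for the default cohort."""
    return generate_methylation(cohort, default_config)


@pytest.fixture()
def simple_norms() -> NormativeTable:
    """One hand-built band per test: within = [10, 20] everywhere."""
    rows = []
    for test in ("gait_speed", "grip", "sls", "cst30", "step2min"):
        for sex in ("F", "M"):
            rows.append({"test": test, "sex": sex, "age_low": 0,
                         "age_high": 120, "lower": 10.0, "upper": 20.0})
    return NormativeTable(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
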