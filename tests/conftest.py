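import pandas as pd
import pytest

from cfsr.registry import default_registry
from cfsr.synthetic import default_scenarios, generate_survey, generate_trait_fixture


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def trait_fixture():
    return generate_trait_fixture()


@pytest.fixture(scope="session")
def demo_survey(registry) -> pd.DataFrame:
    """One shared synthetic survey (293 respondents, 4 communities)."""
    return generate_survey(default_scenarios(), seed=20260101, registry=registry)
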