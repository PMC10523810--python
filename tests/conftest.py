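import pandas as pd
import pytest

from roadmort import default_registry, load_standard_population
from roadmort.io import validate_mortality
from roadmort.synthetic import SimulationConfig, simulate_panel
from roadmort.taxonomy import NonspecificCategory as NC


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def standard():
    return load_standard_population()


ALL_FRACTIONS = {
    NC.ILL_DEFINED: 0.10,
    NC.UNDETERMINED_INTENT: 0.20,
    NC.UNSPEC_UNINTENTIONAL: 0.15,
    NC.UNSPEC_TRANSPORT: 0.25,
    NC.UNSPEC_RT: 0.30,
}


@pytest.fixture(scope="session")
def det_panel():
    """Small deterministic panel with garbage in every category."""
    cfg = SimulationConfig(
        n_countries=3,
        years=(2015, 2017),
        sampling="deterministic",
        garbage_fractions=dict(ALL_FRACTIONS),
        seed=11,
    )
    return simulate_panel(cfg)


def toy_table(rows):
    """rows: (country, year, sex, age_group, cause, deaths)."""
    df = pd.DataFrame(
        rows, columns=["country", "year", "sex", "age_group", "cause", "deaths"]
    )
    return validate_mortality(df)
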