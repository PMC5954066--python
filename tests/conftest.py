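import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from abca7vntr.simulate import SimConfig, simulate_cohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort():
    """One full synthetic cohort (all measurement layers), shared read-only."""
    return simulate_cohort(SimConfig(seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """A fast subject/allele-only cohort for association-level tests."""
    return simulate_cohort(SimConfig(seed=11, n_patients=120, n_controls=80, layers=()))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_subjects(ids, phenotype, **cols) -> pd.DataFrame:
    base = {
        "id": ids,
        "phenotype": phenotype,
        "aao": [70.0] * len(ids),
        "gender": ["F"] * len(ids),
        "apoe_e4": [0] * len(ids),
        "rs3764650": [0] * len(ids),
        "rs78117248": [0] * len(ids),
        "excluded_reason": ["none"] * len(ids),
    }
    base.update(cols)
    return pd.DataFrame(base)
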