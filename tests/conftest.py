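import numpy as np
import pandas as pd
import pytest

import frailtykit as fk
from frailtykit.params import POLYPHARMACY


@pytest.fixture(scope="session")
def params():
    return fk.load_params()


@pytest.fixture(scope="session")
def codelists():
    return fk.default_codelists()


@pytest.fixture(scope="session")
def mapping():
    return fk.default_mapping()


@pytest.fixture(scope="session")
def ehr_cohort(params, codelists):
    """A generated EHR cohort with its raw records and ground truth."""
    cfg = params.cohort_config(fk.EHR, 1200, seed=42)
    persons = fk.generate_population(cfg)
    records = fk.generate_ehr_records(
        persons,
        params.ehr_models,
        codelists,
        params.polypharmacy,
        params.index_date,
        seed=4242,
        polypharmacy_name=POLYPHARMACY,
    )
    return persons, records


@pytest.fixture(scope="session")
def survey_cohort(params):
    """A generated survey cohort with wide responses and ground truth."""
    cfg = params.cohort_config(fk.SURVEY, 1200, seed=43)
    persons = fk.generate_population(cfg)
    records = fk.generate_survey_responses(
        persons, params.survey_models, params.missingness, seed=4343
    )
    return persons, records


def make_persons(n, ages=None, sexes=None, source=fk.SURVEY, seed=0, latent=None):
    """Hand-rolled person table for unit tests."""
    rng = np.random.default_rng(seed)
    code = {fk.SURVEY: 0, fk.EHR: 1}[source]
    return pd.DataFrame(
        {
            "person_id": [f"p{i}" for i in range(n)],
            "age": ages if ages is not None else rng.integers(65, 95, n),
            "sex": sexes if sexes is not None else rng.integers(0, 2, n),
            "source": code,
            "registration_start": pd.NaT,
            "latent_u": latent if latent is not None else np.zeros(n),
        }
    )
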