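import numpy as np
import pandas as pd
import pytest

from preopbayes import BetaParams, published_bedsize_table, update


@pytest.fixture(scope="session")
def bedsize_table():
    return published_bedsize_table()


@pytest.fixture(scope="session")
def posteriors(bedsize_table):
    """Uniform-prior posteriors for the two bed-size groups."""
    t = bedsize_table
    prior = BetaParams(1.0, 1.0)
    small = update(prior, t.z_small, t.n_small, "beds<100")
    large = update(prior, t.z_large, t.n_large, "beds>=100")
    return small, large


def make_raw(rows: list[dict]) -> pd.DataFrame:
    """Build a raw claims table from partial row dicts with valid defaults."""
    defaults = {
        "patient_id": 0,
        "age": 40,
        "sex": "F",
        "institution_id": 1,
        "institution_beds": 50,
        "surgery_date": "2014-06-01",
        "enrollment_months_before": 24,
        "inpatient": False,
        "emergency_or_additional": False,
        "cbc_date": None,
        "metabolic_panel_date": None,
        "coagulation_date": None,
        "lft_date": None,
    }
    data = [{**defaults, "patient_id": i, **row} for i, row in enumerate(rows)]
    df = pd.DataFrame(data)
    for col in ["surgery_date", "cbc_date", "metabolic_panel_date",
                "coagulation_date", "lft_date"]:
        df[col] = pd.to_datetime(df[col])
    return df


@pytest.fixture
def raw_builder():
    return make_raw
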