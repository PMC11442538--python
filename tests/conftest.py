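from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

import carecost as cc
from carecost.config import AGE_BANDS_WORKING
from carecost.records import COLUMNS


@pytest.fixture(scope="session")
def costs():
    return cc.default_unit_costs()


@pytest.fixture(scope="session")
def flat_costs():
    """Gender-flat labour cost (40 €/h) and flat imputation (32 h/week):
    makes the worked examples transparent."""
    return cc.default_unit_costs(
        labour_cost_by_gender={"male": 40.0, "female": 40.0},
        imputed_workhours={
            b: {"male": 32.0, "female": 32.0} for b in AGE_BANDS_WORKING
        },
    )


_RECORD_DEFAULTS = dict(
    id="x",
    weight=1.0,
    is_caregiver=True,
    gender="male",
    age=40,
    age_band="36_45",
    care_hours_week=10.0,
    care_weeks_year=52.0,
    oop_bracket="none",
    employed_now=True,
    worked_past_year=True,
    work_hours_week=30.0,
    stopped_work_prolonged=False,
    stopped_work_temporary=False,
    reduced_hours=False,
    distraction_freq="rarely_never",
    concentration_loss="none",
)


def record(**overrides):
    """A caregiver record stub for the scalar cost functions."""
    payload = dict(_RECORD_DEFAULTS)
    payload.update(overrides)
    return SimpleNamespace(**payload)


def make_df(rows):
    """Canonical microdata frame from minimal per-row dicts."""
    full = []
    for i, row in enumerate(rows):
        payload = dict(_RECORD_DEFAULTS)
        payload["id"] = f"r{i}"
        payload.update(row)
        if not payload["is_caregiver"]:
            for f in ("care_hours_week", "care_weeks_year"):
                payload[f] = np.nan
            payload["oop_bracket"] = None
            payload["distraction_freq"] = None
            payload["concentration_loss"] = None
        if not (payload["worked_past_year"] or payload["employed_now"]):
            payload["work_hours_week"] = np.nan
        full.append(payload)
    df = pd.DataFrame(full, columns=COLUMNS)
    for col in ("weight", "care_hours_week", "care_weeks_year", "work_hours_week"):
        df[col] = df[col].astype(float)
    return df


@pytest.fixture(scope="session")
def survey_small():
    return cc.generate(cc.GeneratorSpec(n_respondents=4000, seed=11))


@pytest.fixture(scope="session")
def survey_large():
    return cc.generate(cc.GeneratorSpec(n_respondents=100_000, seed=11))
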