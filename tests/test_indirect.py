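"""Productivity costs: PTO, TTO, RHW and presenteeism under HCA and FCA."""

import numpy as np
import pytest

import carecost as cc
from carecost.indirect import FCA, HCA, PopulationWorkStats, tto_weeks
from conftest import make_df, record


# --- population RHW delta --------------------------------------------------


def test_rhw_delta_weighted_mean_oracle():
    """Hand-computed weighted means on a 5-row fixture."""
    df = make_df(
        [
            dict(is_caregiver=False, work_hours_week=30.0, weight=1.0),
            dict(is_caregiver=False, work_hours_week=34.0, weight=3.0),
            dict(reduced_hours=True, work_hours_week=28.0, weight=2.0),
            dict(reduced_hours=True, work_hours_week=31.0, weight=1.0),
            dict(work_hours_week=40.0, weight=5.0),  # non-reducing caregiver
        ]
    )
    stats = cc.compute_rhw_delta(df)
    # spreadsheet: (30*1 + 34*3)/4 = 33 ; (28*2 + 31*1)/3 = 29
    assert stats.mean_workhours_noncaregivers == pytest.approx(33.0)
    assert stats.mean_workhours_reducers == pytest.approx(29.0)
    assert stats.rhw_delta == pytest.approx(4.0)


def test_rhw_delta_floor_and_no_reducer_warning():
    df = make_df(
        [
            dict(is_caregiver=False, work_hours_week=28.0),
            dict(reduced_hours=True, work_hours_week=31.0),
        ]
    )
    assert cc.compute_rhw_delta(df).rhw_delta == 0.0  # floored at zero
    df2 = make_df(
        [
            dict(is_caregiver=False, work_hours_week=30.0),
            dict(work_hours_week=30.0),
        ]
    )
    with pytest.warns(UserWarning):
        assert cc.compute_rhw_delta(df2).rhw_delta == 0.0


# --- per-record components --------------------------------------------------


def test_pto_formula_and_friction_cap(flat_costs):
    r = record(stopped_work_prolonged=True, employed_now=False,
               work_hours_week=None)
    assert cc.pto_cost(r, flat_costs, HCA) == pytest.approx(32 * 40 * 46)
    assert cc.pto_cost(r, flat_costs, FCA) == pytest.approx(32 * 40 * 12)
    assert cc.pto_cost(record(), flat_costs, HCA) == 0.0  # flag unset
    r76 = record(stopped_work_prolonged=True, employed_now=False,
                 work_hours_week=None, age=80, age_band="76_plus")
    assert cc.pto_cost(r76, flat_costs, HCA) == 0.0  # outside 16-75 window


def test_tto_half_care_weeks_and_friction_cap(flat_costs):
    r = record(stopped_work_temporary=True, care_weeks_year=40,
               work_hours_week=30)
    assert cc.tto_cost(r, flat_costs, HCA) == pytest.approx(30 * 20 * 40)
    assert cc.tto_cost(r, flat_costs, FCA) == pytest.approx(30 * 12 * 40)
    short = record(stopped_work_temporary=True, care_weeks_year=20,
                   work_hours_week=30)
    assert cc.tto_cost(short, flat_costs, FCA) == pytest.approx(30 * 10 * 40)
    missing = record(stopped_work_temporary=True, work_hours_week=None)
    with pytest.raises(ValueError, match="work hours"):
        cc.tto_cost(missing, flat_costs, HCA)


def test_rhw_double_counting_deduction(flat_costs):
    stats = PopulationWorkStats(31.08, 28.93, 2.15)
    r = record(reduced_hours=True)
    assert cc.rhw_cost(r, stats, flat_costs, HCA) == pytest.approx(2.15 * 40 * 46)
    both = record(reduced_hours=True, stopped_work_temporary=True,
                  care_weeks_year=40)  # TTO duration 20 weeks
    assert cc.rhw_cost(both, stats, flat_costs, HCA) == pytest.approx(
        2.15 * 40 * 26
    )
    zero = PopulationWorkStats(30.0, 30.0, 0.0)
    assert cc.rhw_cost(r, zero, flat_costs, HCA) == 0.0


def test_presenteeism_item_conversion(flat_costs):
    r = record(concentration_loss="a_bit", distraction_freq="weekly",
               work_hours_week=30)
    # 25% impairment x 20% of days x 30 h = 1.5 h/week
    assert cc.presenteeism_cost(r, flat_costs) == pytest.approx(1.5 * 40 * 46)
    worst = record(concentration_loss="very_much", distraction_freq="daily",
                   work_hours_week=40)
    assert cc.presenteeism_cost(worst, flat_costs) == pytest.approx(36_800)
    assert cc.presenteeism_cost(record(concentration_loss="none"), flat_costs) == 0.0
    assert cc.presenteeism_cost(
        record(concentration_loss="missing", distraction_freq="daily"), flat_costs
    ) == 0.0


def test_friction_never_exceeds_human_capital(survey_small, costs):
    stats = cc.compute_rhw_delta(survey_small)
    caregivers = survey_small[survey_small["is_caregiver"]]
    n_checked = 0
    for row in caregivers.itertuples(index=False):
        ic = cc.indirect_costs(row, stats, costs)
        assert ic.pto_fca <= ic.pto_hca
        assert ic.tto_fca <= ic.tto_hca
        assert ic.rhw_fca <= ic.rhw_hca
        assert ic.lost_work_hours_fca <= ic.lost_work_hours_hca
        # equality iff the relevant duration fits in the friction period
        if ic.tto_hca > 0:
            dur = tto_weeks(row, costs, HCA)
            assert (ic.tto_fca == ic.tto_hca) == (dur <= costs.friction_weeks)
            n_checked += 1
    assert n_checked > 0


def test_costs_proportional_to_hours(flat_costs):
    stats = PopulationWorkStats(31.0, 29.0, 2.0)
    r = record(stopped_work_temporary=True, reduced_hours=True,
               care_weeks_year=30, work_hours_week=25)
    ic = cc.indirect_costs(r, stats, flat_costs)
    rate = flat_costs.labour_cost_by_gender["male"]
    assert ic.tto_hca + ic.rhw_hca == pytest.approx(
        ic.lost_work_hours_hca * rate
    )


def test_no_flags_no_indirect_costs(flat_costs):
    stats = PopulationWorkStats(31.0, 29.0, 2.0)
    ic = cc.indirect_costs(record(), stats, flat_costs)
    assert ic.pto_hca == ic.tto_hca == ic.rhw_hca == 0.0
    assert ic.lost_work_hours_hca == 0.0
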