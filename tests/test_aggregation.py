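"""Weighted national aggregation: netting, additivity, equivariance, oracles."""

import numpy as np
import pandas as pd
import pytest

import carecost as cc
from carecost.aggregate import CELLS
from conftest import make_df


@pytest.mark.parametrize(
    "indirect,caretime,expected", [(1000, 400, 600), (400, 1000, 0), (123, 0, 123)]
)
def test_net_indirect_proxy(indirect, caretime, expected):
    assert cc.net_indirect_proxy(indirect, caretime) == expected


def test_net_floor_switch():
    assert cc.net_indirect_proxy(400, 1000, floor=False) == -600


def test_aggregate_matches_hand_weighted_sums(costs):
    """3-record fixture against a spreadsheet-style weighted-sum oracle."""
    df = make_df(
        [
            dict(weight=2.0, care_hours_week=3, care_weeks_year=52,
                 oop_bracket="none", gender="female", work_hours_week=30.0),
            dict(weight=5.0, care_hours_week=10, care_weeks_year=26,
                 oop_bracket="50_100", work_hours_week=40.0),
            dict(weight=3.0, is_caregiver=False, work_hours_week=31.0),
        ]
    )
    bd = cc.compute_breakdowns(df, costs)
    rep = cc.aggregate(bd, df)
    r = costs.leisure_value
    # care time: w*h*weeks*rate summed over the two caregivers
    care_oc = 2 * 3 * 52 * r + 5 * 10 * 26 * r
    oop = 5 * 75 * 26 * 12 / 52  # only record 2 has an OOP bracket
    cell = rep.cells[("oc", "hca")]
    assert cell.component_totals["care_time"] == pytest.approx(care_oc)
    assert cell.component_totals["oop"] == pytest.approx(oop)
    assert cell.total == pytest.approx(care_oc + oop)  # no impact flags
    assert rep.weighted_caregivers == 7.0
    assert cell.mean == pytest.approx((care_oc + oop) / 7.0)
    # F:M care-time ratio from the same sums
    assert cell.fm_ratios["care_time"] == pytest.approx(
        (2 * 3 * 52) / (5 * 10 * 26)
    )


def test_vectorised_pipeline_matches_per_record_route(survey_small, costs):
    """The frame-level pipeline equals the scalar per-record functions."""
    df = survey_small.head(600)
    stats = cc.compute_rhw_delta(survey_small)
    bd = cc.compute_breakdowns(df, costs, stats=stats,
                               include_presenteeism=True)
    for i, row in enumerate(df.itertuples(index=False)):
        if not row.is_caregiver:
            assert bd.loc[i, "total_oc_hca"] == 0.0
            continue
        d = cc.direct_costs(row, costs)
        ic = cc.indirect_costs(row, stats, costs)
        assert bd.loc[i, "caretime_oc_hca"] == pytest.approx(d.care_time_cost_oc, rel=1e-12)
        assert bd.loc[i, "caretime_pg"] == pytest.approx(d.care_time_cost_pg, rel=1e-12)
        assert bd.loc[i, "oop"] == pytest.approx(d.oop_cost, rel=1e-12)
        assert bd.loc[i, "pto_hca"] == pytest.approx(ic.pto_hca, rel=1e-12)
        assert bd.loc[i, "tto_fca"] == pytest.approx(ic.tto_fca, rel=1e-12)
        assert bd.loc[i, "rhw_hca"] == pytest.approx(ic.rhw_hca, rel=1e-12)
        assert bd.loc[i, "presenteeism_hca"] == pytest.approx(
            ic.presenteeism_hca, rel=1e-12
        )
        indirect = ic.pto_hca + ic.tto_hca + ic.rhw_hca + ic.presenteeism_hca
        assert bd.loc[i, "indirect_pg_hca"] == pytest.approx(
            cc.net_indirect_proxy(indirect, d.care_time_cost_pg), rel=1e-12, abs=1e-9
        )


def test_cell_additivity(survey_small, costs):
    bd = cc.compute_breakdowns(survey_small, costs)
    rep = cc.aggregate(bd, survey_small)
    for key in CELLS:
        cell = rep.cells[key]
        assert cell.total == pytest.approx(
            cell.direct_subtotal + cell.indirect_subtotal, rel=1e-12
        )
        assert cell.total == pytest.approx(sum(cell.component_totals.values()),
                                           rel=1e-12)
        assert sum(cell.shares.values()) == pytest.approx(100.0)


def test_weight_scale_equivariance(survey_small, costs):
    bd = cc.compute_breakdowns(survey_small, costs)
    rep1 = cc.aggregate(bd, survey_small)
    doubled = survey_small.copy()
    doubled["weight"] = doubled["weight"] * 2
    rep2 = cc.aggregate(cc.compute_breakdowns(doubled, costs), doubled)
    for key in CELLS:
        assert rep2.cells[key].total == pytest.approx(2 * rep1.cells[key].total)
        assert rep2.cells[key].mean == pytest.approx(rep1.cells[key].mean)
        assert rep2.cells[key].fm_ratio_total == pytest.approx(
            rep1.cells[key].fm_ratio_total
        )
        for comp in rep1.cells[key].shares:
            assert rep2.cells[key].shares[comp] == pytest.approx(
                rep1.cells[key].shares[comp]
            )


def test_gender_totals_partition(survey_small, costs):
    bd = cc.compute_breakdowns(survey_small, costs)
    w = survey_small["weight"].to_numpy()
    female = (survey_small["gender"] == "female").to_numpy()
    x = bd["total_oc_hca"].to_numpy()
    total = np.sum(w * x)
    assert np.sum(w[female] * x[female]) + np.sum(w[~female] * x[~female]) == (
        pytest.approx(total)
    )


def test_method_approach_orderings(survey_small, costs):
    rep = cc.aggregate(cc.compute_breakdowns(survey_small, costs), survey_small)
    assert rep.cells[("oc", "hca")].total >= rep.cells[("oc", "fca")].total
    # proxy rate > leisure value => PG direct subtotal exceeds OC's
    assert rep.cells[("pg", "hca")].direct_subtotal > (
        rep.cells[("oc", "hca")].direct_subtotal
    )
    # net adjustment never increases indirect costs
    assert rep.cells[("pg", "hca")].indirect_subtotal <= (
        rep.cells[("oc", "hca")].indirect_subtotal
    )


def test_zero_caregiver_weight_rejected(costs):
    df = make_df([dict(weight=0.0), dict(is_caregiver=False, weight=1.0)])
    bd = cc.compute_breakdowns(df, costs)
    with pytest.raises(ValueError, match="caregiver weight"):
        cc.aggregate(bd, df)


def test_context_metrics_units(costs):
    ctx = cc.context_metrics(
        813e9 * 0.02, costs, total_care_hours=1836.0, workers_weighted=1e6
    )
    assert ctx.fte_equivalents == pytest.approx(1.0)
    assert ctx.pct_of_gdp == pytest.approx(2.0)
    assert ctx.per_adult_contribution == pytest.approx(
        813e9 * 0.02 / costs.macro.adult_population_weighted
    )
    assert ctx.per_worker_tax_equivalent == pytest.approx(813e9 * 0.02 / 1e6)
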