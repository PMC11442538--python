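"""Indirect (productivity) costs: absenteeism and presenteeism.

Three forms of care-related absenteeism are costed per caregiver, each only
for ages 16-75 and only where the corresponding survey flag is set:

* PTO (prolonged time off, workforce exit): imputed weekly work hours (from an
  age x gender national-average table, since the caregiver no longer works)
  x gender-specific hourly labour cost, annualised over the work weeks per
  year (46 by default).
* TTO (temporary time off): reported weekly work hours x duration of absence
  x labour cost.  The absence duration is taken as half the weeks of care
  provided in the year.
* RHW (reduced hours at work): a population-level weekly hours gap -- the
  weighted mean difference between non-caregivers' and reducers' work hours,
  computed once per dataset -- x labour cost, annualised over the work weeks
  net of any TTO absence (double-counting deduction).

Presenteeism converts two survey items into a weekly hours-equivalent:
impairment share (none 0%, a bit 25%, very much 50%) x share of working days
with distraction (daily 100%, weekly 20%, monthly 5%, rarely/never 0%) x
reported weekly work hours, annualised and monetised like RHW.  Missing items
mean zero presenteeism; only the human-capital variant is defined.

Each component exists in a human-capital (HCA) and a friction-cost (FCA)
variant: under FCA every duration is additionally capped at the friction
period (12 weeks by default), so FCA <= HCA pointwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigError, UnitCostSet
from .records import PRODUCTIVITY_AGE_MAX, PRODUCTIVITY_AGE_MIN

#: Concentration-loss item -> work-impairment share.
IMPAIRMENT_SHARE = {"none": 0.0, "a_bit": 0.25, "very_much": 0.50, "missing": 0.0}
#: Distraction-frequency item -> share of working days affected
#: (4-week month of 5-day weeks).
DISTRACTION_SHARE = {
    "daily": 1.0, "weekly": 0.20, "monthly": 0.05,
    "rarely_never": 0.0, "missing": 0.0,
}

HCA = "hca"
FCA = "fca"


@dataclass(frozen=True)
class IndirectCosts:
    """Per-caregiver annual productivity costs under both approaches."""

    pto_hca: float
    pto_fca: float
    tto_hca: float
    tto_fca: float
    rhw_hca: float
    rhw_fca: float
    presenteeism_hca: float
    lost_work_hours_hca: float  # absenteeism hours/year (PTO+TTO+RHW)
    lost_work_hours_fca: float


@dataclass(frozen=True)
class PopulationWorkStats:
    """Dataset-level weekly work-hours statistics feeding the RHW component."""

    mean_workhours_noncaregivers: float
    mean_workhours_reducers: float
    rhw_delta: float  # hours/week, floored at 0


def _in_window(record) -> bool:
    return PRODUCTIVITY_AGE_MIN <= record.age <= PRODUCTIVITY_AGE_MAX


def _rate(record, costs: UnitCostSet) -> float:
    return costs.labour_cost_by_gender[record.gender]


def compute_rhw_delta(df: pd.DataFrame) -> PopulationWorkStats:
    """Weighted work-hours gap between non-caregivers and hour-reducers.

    Computed once per dataset over (a) non-caregivers who worked in the past
    year and (b) caregivers flagged as having reduced their hours; the delta
    is floored at zero and applied uniformly to all reducers.
    """
    w = df["weight"].to_numpy(float)
    noncg = (~df["is_caregiver"] & df["worked_past_year"]).to_numpy()
    red = df["reduced_hours"].to_numpy()
    if not noncg.any():
        raise ValueError("dataset contains no working non-caregivers")
    wh = df["work_hours_week"].to_numpy(float)
    a = float(np.sum(wh[noncg] * w[noncg]) / np.sum(w[noncg]))
    if not red.any():
        warnings.warn("no hour-reducing caregivers; RHW delta set to 0")
        return PopulationWorkStats(a, float("nan"), 0.0)
    b = float(np.sum(wh[red] * w[red]) / np.sum(w[red]))
    return PopulationWorkStats(a, b, max(0.0, a - b))


def tto_weeks(record, costs: UnitCostSet, approach: str) -> float:
    """Duration (weeks) of temporary time off under the given approach.

    Half the weeks of care for the year; capped at the friction period under
    FCA; zero when the record has no TTO.
    """
    if not (record.stopped_work_temporary and record.employed_now and _in_window(record)):
        return 0.0
    dur = record.care_weeks_year / 2.0
    if approach == FCA:
        dur = min(dur, costs.friction_weeks)
    return dur


def pto_cost(record, costs: UnitCostSet, approach: str = HCA) -> float:
    """Annual cost of prolonged work cessation (workforce exit).

    Weekly hours are imputed from the age-band x gender national-average
    table (the caregiver is no longer employed, so none are observed).
    """
    if not (record.stopped_work_prolonged and not record.employed_now and _in_window(record)):
        return 0.0
    try:
        hours = costs.imputed_workhours[record.age_band][record.gender]
    except KeyError:
        raise ConfigError(
            f"no imputed work hours for ({record.age_band}, {record.gender})"
        ) from None
    weeks = costs.work_weeks_per_year
    if approach == FCA:
        weeks = min(weeks, costs.friction_weeks)
    return hours * _rate(record, costs) * weeks


def tto_cost(record, costs: UnitCostSet, approach: str = HCA) -> float:
    """Annual cost of temporary work cessation."""
    dur = tto_weeks(record, costs, approach)
    if dur == 0.0:
        return 0.0
    if record.work_hours_week is None or record.work_hours_week != record.work_hours_week:
        raise ValueError(f"record {record.id}: TTO flagged but work hours missing")
    return record.work_hours_week * dur * _rate(record, costs)


def _effective_weeks(record, costs: UnitCostSet, approach: str) -> float:
    """Annualisation weeks for RHW/presenteeism, net of TTO double counting."""
    weeks = costs.work_weeks_per_year - tto_weeks(record, costs, approach)
    if approach == FCA:
        weeks = min(weeks, costs.friction_weeks)
    return max(0.0, weeks)


def rhw_cost(
    record, stats: PopulationWorkStats, costs: UnitCostSet, approach: str = HCA
) -> float:
    """Annual cost of reduced working hours (uniform population-level delta)."""
    if not (record.reduced_hours and record.worked_past_year and _in_window(record)):
        return 0.0
    return stats.rhw_delta * _rate(record, costs) * _effective_weeks(record, costs, approach)


def presenteeism_cost(record, costs: UnitCostSet) -> float:
    """Annual presenteeism cost (human-capital approach only)."""
    if not (record.worked_past_year and _in_window(record)):
        return 0.0
    impair = IMPAIRMENT_SHARE.get(record.concentration_loss or "missing", 0.0)
    distract = DISTRACTION_SHARE.get(record.distraction_freq or "missing", 0.0)
    if impair == 0.0 or distract == 0.0:
        return 0.0
    wh = record.work_hours_week
    if wh is None or wh != wh:
        return 0.0
    weekly_hours = impair * distract * wh
    return weekly_hours * _rate(record, costs) * _effective_weeks(record, costs, HCA)


def indirect_costs(
    record, stats: PopulationWorkStats, costs: UnitCostSet
) -> IndirectCosts:
    """All productivity-cost components for one record, both approaches."""
    rate = _rate(record, costs)
    out = {}
    for approach in (HCA, FCA):
        pto = pto_cost(record, costs, approach)
        tto = tto_cost(record, costs, approach)
        rhw = rhw_cost(record, stats, costs, approach)
        out[approach] = (pto, tto, rhw, (pto + tto + rhw) / rate)
    return IndirectCosts(
        pto_hca=out[HCA][0], pto_fca=out[FCA][0],
        tto_hca=out[HCA][1], tto_fca=out[FCA][1],
        rhw_hca=out[HCA][2], rhw_fca=out[FCA][2],
        presenteeism_hca=presenteeism_cost(record, costs),
        lost_work_hours_hca=out[HCA][3],
        lost_work_hours_fca=out[FCA][3],
    )
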