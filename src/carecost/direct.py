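"""Direct costs: informal-care time (two valuation methods) and out-of-pocket.

Annual care-time cost is quantity x unit cost: weekly care hours (after the
joint work+care time cap) x weeks of care per year x an hourly shadow price.
The same formula serves both valuation methods -- the opportunity-cost method
prices an hour at the value of forgone leisure, the proxy-good method at the
market rate of a professional household-care substitute -- so per caregiver
the two costs differ exactly by the rate ratio.

The time cap embodies a minimum daily leisure floor (default 6 h/day, hence at
most (24-6)x7 = 126 h/week for work plus care): where reported work + care
hours exceed it, the surplus is subtracted from care time only.

Out-of-pocket expenses are bracketed monthly amounts; the midpoint of the
bracket (300 for the open-ended top bracket) is scaled by months of care,
with months = weeks x 12/52 (continuous, not rounded).
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import UnitCostSet


@dataclass(frozen=True)
class DirectCosts:
    """Per-caregiver annual direct costs."""

    care_hours_capped: float  # hours/week after the joint time cap
    care_time_cost_oc: float  # euros/year, opportunity-cost valuation
    care_time_cost_pg: float  # euros/year, proxy-good valuation
    oop_cost: float  # euros/year


def cap_care_hours(
    care_hours: float, work_hours: float, costs: UnitCostSet
) -> float:
    """Apply the joint weekly time cap to reported care hours.

    With a leisure floor of f hours/day the cap is (24 - f) x 7 hours/week for
    work plus care.  If work + care exceeds it, the surplus comes out of care
    time only (never out of work time), floored at zero.
    """
    cap = costs.time_cap_hours_per_week
    if care_hours + work_hours <= cap:
        return care_hours
    return max(0.0, cap - work_hours)


def care_time_cost(capped_hours: float, weeks: float, rate: float) -> float:
    """Annual care-time cost: capped weekly hours x weeks of care x hourly rate."""
    return capped_hours * rate * weeks


def oop_cost(bracket: str, weeks: float, costs: UnitCostSet) -> float:
    """Annual out-of-pocket cost from a monthly expense bracket.

    Monthly value is the bracket midpoint (open top bracket valued at its
    lower bound; missing imputed as the lowest non-zero bracket, or zero under
    ``oop_missing_as_zero``), annualised over months = weeks x 12/52.
    """
    monthly = costs.oop_monthly_value(bracket)
    return monthly * weeks * 12.0 / 52.0


def direct_costs(record, costs: UnitCostSet) -> DirectCosts:
    """All direct cost components for one caregiver record.

    ``record`` is any object with ``care_hours_week``, ``care_weeks_year``,
    ``oop_bracket``, ``work_hours_week`` and ``worked_past_year`` attributes.
    """
    work = record.work_hours_week if record.worked_past_year else 0.0
    if work is None or work != work:  # NaN guard
        work = 0.0
    capped = cap_care_hours(record.care_hours_week, work, costs)
    weeks = record.care_weeks_year
    return DirectCosts(
        care_hours_capped=capped,
        care_time_cost_oc=care_time_cost(capped, weeks, costs.leisure_value),
        care_time_cost_pg=care_time_cost(capped, weeks, costs.proxy_rate),
        oop_cost=oop_cost(record.oop_bracket, weeks, costs),
    )
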