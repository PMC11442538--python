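"""Deterministic one-way sensitivity analysis over the costing assumptions.

Each :class:`Scenario` varies one assumption from the base case -- the leisure
shadow price (willingness-to-pay or willingness-to-accept instead of the
travel-time-saving value), dropping the 126-h weekly time cap, deducting lost
paid-work time from care time before opportunity-cost valuation, or adding
presenteeism to the indirect costs -- and re-runs the full pipeline.  Results
are reported as the scenario's national total for its method x approach cell
and the percent change against the base case, ordered tornado-style by
magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict

from .aggregate import aggregate, compute_breakdowns
from .config import UnitCostSet


class Scenario(BaseModel):
    """A one-way variant of the base-case costing assumptions."""

    model_config = ConfigDict(extra="forbid")

    name: str
    method: Literal["oc", "pg"] = "oc"
    approach: Literal["hca", "fca"] = "hca"
    leisure_rate: Literal["base", "wtp", "wta"] = "base"
    apply_cap: bool = True
    adjust_care_time: bool = False
    #: force a single lost-hours measure in the care-time adjustment
    #: (default: each approach uses its own)
    adjust_approach: Optional[Literal["hca", "fca"]] = None
    include_presenteeism: bool = False

    def is_base(self) -> bool:
        return (
            self.leisure_rate == "base"
            and self.apply_cap
            and not self.adjust_care_time
            and not self.include_presenteeism
        )


def base_scenario(method: str = "oc", approach: str = "hca") -> Scenario:
    return Scenario(name="base", method=method, approach=approach)


@dataclass(frozen=True)
class ScenarioResult:
    scenario: Scenario
    total: float
    base_total: float
    pct_change_vs_base: float


def _cell_total(df: pd.DataFrame, costs: UnitCostSet, scenario: Scenario) -> float:
    bd = compute_breakdowns(
        df,
        costs,
        leisure_rate=scenario.leisure_rate,
        apply_cap=scenario.apply_cap,
        adjust_care_time=scenario.adjust_care_time,
        adjust_approach=scenario.adjust_approach,
        include_presenteeism=scenario.include_presenteeism,
    )
    report = aggregate(bd, df)
    return report.cells[(scenario.method, scenario.approach)].total


def run_scenario(
    df: pd.DataFrame,
    costs: UnitCostSet,
    scenario: Scenario,
    base_total: Optional[float] = None,
) -> ScenarioResult:
    """Re-run the pipeline under a scenario and compare with the base case.

    The base total (same method x approach cell, all-base settings) is
    recomputed unless supplied.
    """
    total = _cell_total(df, costs, scenario)
    if base_total is None:
        base_total = _cell_total(
            df, costs, base_scenario(scenario.method, scenario.approach)
        )
    pct = 100.0 * (total - base_total) / base_total
    return ScenarioResult(scenario, total, base_total, pct)


def standard_scenarios(method: str = "oc", approach: str = "hca") -> list[Scenario]:
    """The canonical one-way set for a given cell: leisure WTP/WTA, no cap,
    adjusted care time, presenteeism included."""
    return [
        base_scenario(method, approach),
        Scenario(name="leisure_wtp", method=method, approach=approach,
                 leisure_rate="wtp"),
        Scenario(name="leisure_wta", method=method, approach=approach,
                 leisure_rate="wta"),
        Scenario(name="no_time_cap", method=method, approach=approach,
                 apply_cap=False),
        Scenario(name="adjusted_care_time", method=method, approach=approach,
                 adjust_care_time=True),
        Scenario(name="with_presenteeism", method=method, approach=approach,
                 include_presenteeism=True),
    ]


def scenario_table(results: Iterable[ScenarioResult]) -> pd.DataFrame:
    """Tornado-ordered table: scenario, cell, total, % change vs base."""
    results = list(results)
    if not results:
        raise ValueError("no scenario results")
    rows = [
        {
            "scenario": r.scenario.name,
            "method": r.scenario.method,
            "approach": r.scenario.approach,
            "total": r.total,
            "pct_change_vs_base": r.pct_change_vs_base,
        }
        for r in results
    ]
    out = pd.DataFrame(rows)
    return out.reindex(
        out["pct_change_vs_base"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)
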