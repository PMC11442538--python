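"""Per-caregiver cost assembly and survey-weighted national aggregation.

:func:`compute_breakdowns` evaluates every cost component for every respondent
in one vectorised pass and assembles the four method x approach cells:
{opportunity cost, proxy good} x {human capital, friction cost}.  Each cell's
per-caregiver total is direct subtotal (care time + out-of-pocket) plus
indirect subtotal.  Under the proxy-good method the indirect subtotal is the
*net* societal productivity loss: per caregiver, productivity costs minus the
proxy-good value of the care supplied, floored at zero (configurable) --
reallocating time from paid work to care produces offsetting output.  The
opportunity-cost cells use unadjusted productivity costs (base case).

:func:`aggregate` expands per-caregiver totals with survey weights into
national totals, means per caregiver, component shares and female-to-male cost
ratios; :func:`context_metrics` converts a national total into macro context
(share of GDP, FTE-equivalents of care time, per-adult and per-worker
contributions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import UnitCostSet
from .indirect import (
    DISTRACTION_SHARE,
    IMPAIRMENT_SHARE,
    PopulationWorkStats,
    compute_rhw_delta,
)
from .records import PRODUCTIVITY_AGE_MAX, PRODUCTIVITY_AGE_MIN

CELLS = (("oc", "hca"), ("oc", "fca"), ("pg", "hca"), ("pg", "fca"))


def net_indirect_proxy(
    indirect: float, caretime_pg: float, floor: bool = True
) -> float:
    """Net societal productivity loss under the proxy-good view.

    Deducts the proxy-good value of the care supplied from the caregiver's
    productivity costs; floored at zero unless ``floor`` is disabled.
    """
    net = indirect - caretime_pg
    return max(0.0, net) if floor else net


def compute_breakdowns(
    df: pd.DataFrame,
    costs: UnitCostSet,
    *,
    leisure_rate: str = "base",
    apply_cap: bool = True,
    adjust_care_time: bool = False,
    adjust_approach: Optional[str] = None,
    include_presenteeism: bool = False,
    stats: Optional[PopulationWorkStats] = None,
) -> pd.DataFrame:
    """Per-respondent cost breakdown across all four method x approach cells.

    Non-caregivers contribute zero everywhere (they stay in the frame: the
    RHW hours gap needs them).  Scenario knobs: ``leisure_rate`` swaps the
    opportunity-cost shadow price (base/wtp/wta); ``apply_cap=False`` skips
    the weekly time cap; ``adjust_care_time`` deducts lost paid-work time
    (prorated per care week, under each cell's own approach unless
    ``adjust_approach`` forces one) from care hours before opportunity-cost
    valuation; ``include_presenteeism`` adds presenteeism to the indirect
    subtotal.
    """
    n = len(df)
    cg = df["is_caregiver"].to_numpy(bool)
    age = df["age"].to_numpy(int)
    window = (age >= PRODUCTIVITY_AGE_MIN) & (age <= PRODUCTIVITY_AGE_MAX)
    employed = df["employed_now"].to_numpy(bool)
    worked = df["worked_past_year"].to_numpy(bool)
    gender = df["gender"].to_numpy(object)
    rate = np.where(
        gender == "female",
        costs.labour_cost_by_gender["female"],
        costs.labour_cost_by_gender["male"],
    )

    hours = np.nan_to_num(df["care_hours_week"].to_numpy(float))
    weeks = np.nan_to_num(df["care_weeks_year"].to_numpy(float))
    work_hours = df["work_hours_week"].to_numpy(float)
    work_for_cap = np.where(worked, np.nan_to_num(work_hours), 0.0)

    # --- absenteeism components --------------------------------------------
    W = costs.work_weeks_per_year
    F = costs.friction_weeks

    pto_mask = df["stopped_work_prolonged"].to_numpy(bool) & ~employed & window
    imputed = np.zeros(n)
    if pto_mask.any():
        bands = df["age_band"].to_numpy(object)
        imputed[pto_mask] = [
            costs.imputed_workhours[b][g]
            for b, g in zip(bands[pto_mask], gender[pto_mask])
        ]
    pto_hca = np.where(pto_mask, imputed * rate * W, 0.0)
    pto_fca = np.where(pto_mask, imputed * rate * min(W, F), 0.0)

    tto_mask = df["stopped_work_temporary"].to_numpy(bool) & employed & window
    if tto_mask.any() and np.isnan(work_hours[tto_mask]).any():
        bad = df.loc[tto_mask & np.isnan(work_hours), "id"].tolist()[:5]
        raise ValueError(f"TTO flagged but work hours missing: records {bad}")
    tto_weeks_hca = np.where(tto_mask, weeks / 2.0, 0.0)
    tto_weeks_fca = np.minimum(tto_weeks_hca, F)
    wh0 = np.nan_to_num(work_hours)
    tto_hca = wh0 * tto_weeks_hca * rate
    tto_fca = wh0 * tto_weeks_fca * rate

    if stats is None:
        stats = compute_rhw_delta(df)
    rhw_mask = df["reduced_hours"].to_numpy(bool) & worked & window
    eff_hca = np.maximum(0.0, W - tto_weeks_hca)
    eff_fca = np.maximum(0.0, np.minimum(W - tto_weeks_fca, F))
    rhw_hca = np.where(rhw_mask, stats.rhw_delta * rate * eff_hca, 0.0)
    rhw_fca = np.where(rhw_mask, stats.rhw_delta * rate * eff_fca, 0.0)

    pres_mask = cg & worked & window
    impair = (
        df["concentration_loss"].map(IMPAIRMENT_SHARE).fillna(0.0).to_numpy(float)
    )
    distract = (
        df["distraction_freq"].map(DISTRACTION_SHARE).fillna(0.0).to_numpy(float)
    )
    pres_hca = np.where(
        pres_mask, impair * distract * wh0 * rate * eff_hca, 0.0
    )

    lost_hca = (pto_hca + tto_hca + rhw_hca) / rate
    lost_fca = (pto_fca + tto_fca + rhw_fca) / rate

    # --- direct costs -------------------------------------------------------
    cap = costs.time_cap_hours_per_week

    def capped_hours(h: np.ndarray) -> np.ndarray:
        if not apply_cap:
            return h
        return np.where(h + work_for_cap <= cap, h, np.maximum(0.0, cap - work_for_cap))

    r_oc = costs.leisure_rate(leisure_rate)
    capped = np.where(cg, capped_hours(hours), 0.0)
    caretime_pg = capped * costs.proxy_rate * weeks

    caretime_oc = {}
    for approach, lost in (("hca", lost_hca), ("fca", lost_fca)):
        if adjust_care_time:
            if adjust_approach is not None:
                lost = lost_hca if adjust_approach == "hca" else lost_fca
            with np.errstate(invalid="ignore", divide="ignore"):
                weekly_lost = np.where(weeks > 0, lost / np.maximum(weeks, 1e-12), 0.0)
            adj = np.maximum(0.0, hours - weekly_lost)
            ch = np.where(cg, capped_hours(adj), 0.0)
        else:
            ch = capped
        caretime_oc[approach] = ch * r_oc * weeks

    oop = np.zeros(n)
    if cg.any():
        brackets = df.loc[cg, "oop_bracket"].to_numpy(object)
        monthly = np.array([costs.oop_monthly_value(b) for b in brackets])
        oop[cg] = monthly * weeks[cg] * 12.0 / 52.0

    # --- cells --------------------------------------------------------------
    out = pd.DataFrame({"id": df["id"].to_numpy()})
    out["capped_hours"] = capped
    out["caretime_oc_hca"] = np.where(cg, caretime_oc["hca"], 0.0)
    out["caretime_oc_fca"] = np.where(cg, caretime_oc["fca"], 0.0)
    out["caretime_pg"] = np.where(cg, caretime_pg, 0.0)
    out["oop"] = oop
    for name, arr in (
        ("pto_hca", pto_hca), ("pto_fca", pto_fca),
        ("tto_hca", tto_hca), ("tto_fca", tto_fca),
        ("rhw_hca", rhw_hca), ("rhw_fca", rhw_fca),
        ("presenteeism_hca", pres_hca),
        ("lost_hours_hca", lost_hca), ("lost_hours_fca", lost_fca),
    ):
        out[name] = np.where(cg, arr, 0.0)

    pres_add = out["presenteeism_hca"].to_numpy() if include_presenteeism else 0.0
    for app in ("hca", "fca"):
        indirect = (
            out[f"pto_{app}"] + out[f"tto_{app}"] + out[f"rhw_{app}"]
        ).to_numpy() + pres_add
        out[f"indirect_oc_{app}"] = indirect
        net = indirect - out["caretime_pg"].to_numpy()
        out[f"indirect_pg_{app}"] = np.maximum(0.0, net) if costs.net_floor else net
        out[f"direct_oc_{app}"] = out[f"caretime_oc_{app}"] + out["oop"]
        out[f"total_oc_{app}"] = out[f"direct_oc_{app}"] + out[f"indirect_oc_{app}"]
    out["direct_pg"] = out["caretime_pg"] + out["oop"]
    for app in ("hca", "fca"):
        out[f"total_pg_{app}"] = out["direct_pg"] + out[f"indirect_pg_{app}"]

    out.attrs["include_presenteeism"] = include_presenteeism
    out.attrs["rhw_delta"] = stats.rhw_delta
    return out


# --------------------------------------------------------------------------
# weighted national aggregation


def mean_per_caregiver(total: float, weighted_caregivers: float) -> float:
    """National total divided by the weighted caregiver count."""
    if weighted_caregivers <= 0:
        raise ValueError("weighted caregiver count must be positive")
    return total / weighted_caregivers


def component_share(component_total: float, cell_total: float) -> float:
    """Component share of the cell total, in percent."""
    return 100.0 * component_total / cell_total if cell_total else float("nan")


def female_male_ratio(female_total: float, male_total: float) -> float:
    """Female-to-male cost ratio."""
    return female_total / male_total if male_total else float("inf")


@dataclass
class CellSummary:
    """One method x approach cell of the national cost table."""

    component_totals: dict[str, float]
    direct_subtotal: float
    indirect_subtotal: float
    total: float
    mean: float
    shares: dict[str, float]
    fm_ratios: dict[str, float]
    fm_ratio_total: float


@dataclass
class ContextMetrics:
    """Macro context for one national cost total."""

    total_care_hours: float
    fte_equivalents: float
    pct_of_gdp: float
    per_adult_contribution: float
    per_worker_tax_equivalent: Optional[float] = None


@dataclass
class AggregateReport:
    """Survey-weighted national cost report across all four cells."""

    cells: dict[tuple[str, str], CellSummary]
    weighted_caregivers: float
    weighted_population: float
    weighted_workers: float
    total_care_hours: float
    total_lost_hours: dict[str, float] = field(default_factory=dict)

    def context(self, costs: UnitCostSet, method: str, approach: str) -> ContextMetrics:
        return context_metrics(
            self.cells[(method, approach)].total,
            costs,
            total_care_hours=self.total_care_hours,
            workers_weighted=self.weighted_workers,
        )


def _cell_components(method: str, approach: str, include_presenteeism: bool):
    if method == "oc":
        comps = {
            "care_time": f"caretime_oc_{approach}",
            "oop": "oop",
            "rhw": f"rhw_{approach}",
            "tto": f"tto_{approach}",
            "pto": f"pto_{approach}",
        }
        if include_presenteeism:
            comps["presenteeism"] = "presenteeism_hca"
        direct = ("care_time", "oop")
    else:
        comps = {
            "care_time": "caretime_pg",
            "oop": "oop",
            "indirect_net": f"indirect_pg_{approach}",
        }
        direct = ("care_time", "oop")
    return comps, direct


def aggregate(breakdowns: pd.DataFrame, df: pd.DataFrame) -> AggregateReport:
    """Expand per-caregiver costs into the national Table-4/5-shaped report.

    Totals are survey-weighted sums over all respondents (non-caregivers carry
    zeros); means divide by the weighted caregiver count; component shares and
    female-to-male ratios are computed per cell.
    """
    if len(breakdowns) != len(df):
        raise ValueError("breakdowns and microdata are not aligned")
    w = df["weight"].to_numpy(float)
    cg = df["is_caregiver"].to_numpy(bool)
    female = (df["gender"] == "female").to_numpy(bool)
    w_cg = float(np.sum(w[cg]))
    if w_cg <= 0:
        raise ValueError("zero caregiver weight sum")
    include_pres = bool(breakdowns.attrs.get("include_presenteeism", False))

    def wtotal(col: str, mask=None) -> float:
        x = breakdowns[col].to_numpy(float)
        if mask is None:
            return float(np.sum(w * x))
        return float(np.sum(w[mask] * x[mask]))

    cells: dict[tuple[str, str], CellSummary] = {}
    for method, approach in CELLS:
        comps, direct_names = _cell_components(method, approach, include_pres)
        totals = {name: wtotal(col) for name, col in comps.items()}
        direct_subtotal = sum(totals[nm] for nm in direct_names)
        indirect_subtotal = sum(
            v for nm, v in totals.items() if nm not in direct_names
        )
        total = direct_subtotal + indirect_subtotal
        fm = {
            name: female_male_ratio(wtotal(col, female), wtotal(col, ~female))
            for name, col in comps.items()
        }
        total_col = f"total_{method}_{approach}"
        cells[(method, approach)] = CellSummary(
            component_totals=totals,
            direct_subtotal=direct_subtotal,
            indirect_subtotal=indirect_subtotal,
            total=total,
            mean=mean_per_caregiver(total, w_cg),
            shares={nm: component_share(v, total) for nm, v in totals.items()},
            fm_ratios=fm,
            fm_ratio_total=female_male_ratio(
                wtotal(total_col, female), wtotal(total_col, ~female)
            ),
        )

    weeks = np.nan_to_num(df["care_weeks_year"].to_numpy(float))
    care_hours_total = float(
        np.sum(w * breakdowns["capped_hours"].to_numpy(float) * weeks)
    )
    workers = float(np.sum(w[df["worked_past_year"].to_numpy(bool)]))
    return AggregateReport(
        cells=cells,
        weighted_caregivers=w_cg,
        weighted_population=float(np.sum(w)),
        weighted_workers=workers,
        total_care_hours=care_hours_total,
        total_lost_hours={
            app: wtotal(f"lost_hours_{app}") for app in ("hca", "fca")
        },
    )


def context_metrics(
    total_cost: float,
    costs: UnitCostSet,
    *,
    total_care_hours: float,
    workers_weighted: Optional[float] = None,
) -> ContextMetrics:
    """Macro context: FTE-equivalents, GDP share, per-adult and per-worker load."""
    m = costs.macro
    return ContextMetrics(
        total_care_hours=total_care_hours,
        fte_equivalents=total_care_hours / costs.fte_hours_per_year,
        pct_of_gdp=100.0 * total_cost / m.gdp,
        per_adult_contribution=total_cost / m.adult_population_weighted,
        per_worker_tax_equivalent=(
            total_cost / workers_weighted if workers_weighted else None
        ),
    )
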