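"""Unit-cost configuration: shadow prices, imputation tables and structural constants.

All monetary parameters of the costing model live in a :class:`UnitCostSet`
loaded from YAML or JSON.  Nothing in the cost modules hard-codes a rate:
the hourly value of leisure (opportunity-cost shadow price), the household-care
proxy rate, gender-specific labour costs, the age x gender work-hours
imputation table, out-of-pocket bracket midpoints, CPI factors and the macro
context (GDP, adult population) are all configuration.  Structural constants
default to the standard Dutch costing-manual values: 46 work weeks per year,
a 12-week friction period, a 6 h/day leisure floor (hence a 126 h/week cap on
work plus care) and 1836 working hours per FTE.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator


class ConfigError(ValueError):
    """Raised when a unit-cost configuration is missing or inconsistent."""


#: Gender labels used throughout (survey codebook).
GENDERS = ("male", "female")

#: Out-of-pocket expense brackets from the survey codebook (monthly euros).
OOP_BRACKETS = ("none", "lt50", "50_100", "100_200", "200_300", "gt300")

#: Decadal age bands over the productivity-eligible window 16-75, plus the
#: out-of-labour-force band for respondents older than 75.
AGE_BANDS_WORKING = ("16_25", "26_35", "36_45", "46_55", "56_65", "66_75")
AGE_BAND_RETIRED = "76_plus"

#: Default monthly euro value per OOP bracket: range midpoints, 300 for the
#: open-ended top bracket.
DEFAULT_OOP_VALUES = {
    "none": 0.0,
    "lt50": 25.0,
    "50_100": 75.0,
    "100_200": 150.0,
    "200_300": 250.0,
    "gt300": 300.0,
}


class MacroContext(BaseModel):
    """National accounts context used for GDP shares and per-capita figures."""

    model_config = ConfigDict(extra="forbid")

    gdp: float = Field(gt=0, description="GDP in euros for the price year")
    adult_population_weighted: float = Field(
        gt=0, description="Weighted adult (16+) population the survey expands to"
    )
    mean_gross_income: float = Field(
        gt=0, description="National average annual gross income, euros"
    )


class UnitCostSet(BaseModel):
    """All shadow prices, imputation tables and structural constants.

    Monetary rates are euros in ``price_year`` prices.  ``leisure_value`` is
    the base-case opportunity-cost shadow price (value of one hour of
    non-business travel-time saving); ``leisure_wtp`` / ``leisure_wta`` are the
    contingent-valuation alternatives used only in sensitivity scenarios.
    ``proxy_rate`` is the standard hourly rate of household care (the
    proxy-good substitute wage).
    """

    model_config = ConfigDict(extra="forbid")

    leisure_value: float = Field(gt=0)
    leisure_wtp: Optional[float] = Field(default=None, gt=0)
    leisure_wta: Optional[float] = Field(default=None, gt=0)
    proxy_rate: float = Field(gt=0)
    labour_cost_by_gender: dict[str, float]
    imputed_workhours: dict[str, dict[str, float]]
    work_weeks_per_year: float = Field(default=46.0, gt=0, le=52)
    friction_weeks: float = Field(default=12.0, gt=0)
    leisure_floor_hours_per_day: float = Field(default=6.0, ge=0, lt=24)
    fte_hours_per_year: float = Field(default=1836.0, gt=0)
    oop_bracket_values: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_OOP_VALUES)
    )
    oop_missing_as_zero: bool = False
    net_floor: bool = True
    price_year: int = 2019
    cpi_index: dict[int, float] = Field(default_factory=lambda: {2019: 100.0})
    macro: MacroContext

    @model_validator(mode="after")
    def _check_consistency(self) -> "UnitCostSet":
        for g in GENDERS:
            if g not in self.labour_cost_by_gender:
                raise ValueError(f"labour_cost_by_gender missing entry for {g!r}")
        for g, rate in self.labour_cost_by_gender.items():
            if rate <= 0:
                raise ValueError(f"labour cost for {g!r} must be positive, got {rate}")
        for band in AGE_BANDS_WORKING:
            cell = self.imputed_workhours.get(band)
            if cell is None:
                raise ValueError(f"imputed_workhours missing age band {band!r}")
            for g in GENDERS:
                if g not in cell:
                    raise ValueError(
                        f"imputed_workhours[{band!r}] missing gender {g!r}"
                    )
                if cell[g] < 0:
                    raise ValueError(
                        f"imputed_workhours[{band!r}][{g!r}] must be >= 0"
                    )
        if self.friction_weeks > self.work_weeks_per_year:
            raise ValueError(
                "friction_weeks must not exceed work_weeks_per_year "
                f"({self.friction_weeks} > {self.work_weeks_per_year})"
            )
        for bracket in OOP_BRACKETS:
            if bracket not in self.oop_bracket_values:
                raise ValueError(f"oop_bracket_values missing bracket {bracket!r}")
        for bracket, value in self.oop_bracket_values.items():
            if value < 0:
                raise ValueError(f"OOP value for {bracket!r} must be >= 0")
        if self.price_year not in self.cpi_index:
            raise ValueError(
                f"cpi_index has no entry for price_year {self.price_year}"
            )
        return self

    @property
    def time_cap_hours_per_week(self) -> float:
        """Weekly hours available for work plus care: (24 - leisure floor) x 7."""
        return (24.0 - self.leisure_floor_hours_per_day) * 7.0

    def leisure_rate(self, variant: str = "base") -> float:
        """Leisure shadow price for a valuation variant (base / wtp / wta)."""
        if variant == "base":
            return self.leisure_value
        if variant == "wtp":
            if self.leisure_wtp is None:
                raise ConfigError("leisure_wtp requested but not configured")
            return self.leisure_wtp
        if variant == "wta":
            if self.leisure_wta is None:
                raise ConfigError("leisure_wta requested but not configured")
            return self.leisure_wta
        raise ConfigError(f"unknown leisure rate variant {variant!r}")

    def oop_monthly_value(self, bracket: str) -> float:
        """Monthly euro value for an OOP bracket, with missing-value imputation."""
        if bracket == "missing":
            return 0.0 if self.oop_missing_as_zero else self.oop_bracket_values["lt50"]
        try:
            return self.oop_bracket_values[bracket]
        except KeyError:
            raise ConfigError(f"unknown out-of-pocket bracket {bracket!r}") from None


def load_unit_costs(path: str | Path) -> UnitCostSet:
    """Load and validate a unit-cost configuration from YAML or JSON.

    Defaults (46 work weeks, 12 friction weeks, 6 h leisure floor, 1836 FTE
    hours, bracket midpoints) are applied for omitted optional keys.

    Raises
    ------
    ConfigError
        If the file is missing, unparsable, or fails schema validation; the
        message names the offending field.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"unit-cost configuration not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} must contain a mapping at the top level")
    # YAML 1.1 reads an unquoted band key like 16_25 as the integer 1625;
    # restore the canonical lo_hi form.
    table = raw.get("imputed_workhours")
    if isinstance(table, dict):
        raw["imputed_workhours"] = {
            (f"{k // 100}_{k % 100}" if isinstance(k, int) else k): v
            for k, v in table.items()
        }
    try:
        return UnitCostSet(**raw)
    except ValidationError as exc:
        fields = ", ".join(
            ".".join(str(p) for p in err["loc"]) or "<root>" for err in exc.errors()
        )
        raise ConfigError(f"invalid unit-cost configuration ({fields}): {exc}") from exc


def cpi_adjust(amount: float, from_year: int, costs: UnitCostSet) -> float:
    """Re-express ``amount`` (euros of ``from_year``) in price-year euros.

    Multiplicative CPI indexing: amount x index[price_year] / index[from_year].
    """
    idx = costs.cpi_index
    for year in (from_year, costs.price_year):
        if year not in idx:
            raise ConfigError(
                f"no CPI index for year {year}; available: {sorted(idx)}"
            )
    return amount * idx[costs.price_year] / idx[from_year]


def default_unit_costs(**overrides) -> UnitCostSet:
    """Illustrative 2019 Dutch unit-cost set used by the examples and tests.

    The rates are placeholders of realistic magnitude (the authoritative
    registry values are user-supplied configuration); keyword overrides
    replace individual fields.
    """
    base = dict(
        leisure_value=8.02,
        leisure_wtp=10.34,
        leisure_wta=17.15,
        proxy_rate=15.14,
        labour_cost_by_gender={"male": 39.6, "female": 33.0},
        imputed_workhours={
            "16_25": {"male": 26.0, "female": 22.0},
            "26_35": {"male": 36.0, "female": 28.0},
            "36_45": {"male": 37.0, "female": 26.0},
            "46_55": {"male": 36.0, "female": 25.0},
            "56_65": {"male": 33.0, "female": 23.0},
            "66_75": {"male": 12.0, "female": 8.0},
        },
        cpi_index={2014: 96.4, 2018: 98.3, 2019: 100.0},
        price_year=2019,
        macro=dict(
            gdp=813e9,
            adult_population_weighted=14_222_458,
            mean_gross_income=36_500.0,
        ),
    )
    base.update(overrides)
    return UnitCostSet(**base)
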