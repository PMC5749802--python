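"""Stock-level aggregation, consumption ratios, extrapolation, sensitivity.

Cohort budgets (per fish, per branch) are scaled to the stock with the
cohort abundances and growth-split fractions and collected into a tidy
consumption table with daily/monthly/annual views per prey group.  On top of
that sit the derived quantities: mean daily specific consumption rates,
consumption-to-biomass (C/B) ratios, the extrapolation of mean C/B to other
years' biomass, and a multiplicative parameter-sensitivity sweep.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .budget import LengthCohort
from .species import PREY_GROUPS, PreyEnergyTable

if TYPE_CHECKING:  # pragma: no cover
    from .model import ConsumptionModel


def doy_to_month(doy: int) -> int:
    """Calendar month of a day of year on the non-leap calendar."""
    return (_dt.date(2001, 1, 1) + _dt.timedelta(days=int(doy) - 1)).month


@dataclass
class ConsumptionTable:
    """Tidy stock-level consumption with aggregation views.

    ``daily`` has one row per (species, year, day, prey_group) with consumed
    biomass in tonnes and energy in Joules.  ``stock`` has one row per
    (species, year, day) with the stock biomass (g), total consumption
    (g and J), abundance and the abundance-weighted sum of per-fish specific
    rates (for the unweighted-rate view).
    """

    daily: pd.DataFrame
    stock: pd.DataFrame

    def monthly(self) -> pd.DataFrame:
        df = self.daily.assign(month=self.daily["day"].map(doy_to_month))
        return (
            df.groupby(["species", "year", "month", "prey_group"], as_index=False)[
                ["tonnes", "joules"]
            ].sum()
        )

    def annual(self) -> pd.DataFrame:
        return (
            self.daily.groupby(["species", "year"], as_index=False)[
                ["tonnes", "joules"]
            ].sum()
        )

    def annual_by_group(self) -> pd.DataFrame:
        return (
            self.daily.groupby(["species", "year", "prey_group"], as_index=False)[
                ["tonnes", "joules"]
            ].sum()
        )

    def total_joules(self, species: str | None = None) -> float:
        df = self.daily
        if species is not None:
            df = df[df["species"] == species]
        return float(df["joules"].sum())

    @staticmethod
    def concat(tables: Iterable["ConsumptionTable"]) -> "ConsumptionTable":
        tables = list(tables)
        return ConsumptionTable(
            daily=pd.concat([t.daily for t in tables], ignore_index=True),
            stock=pd.concat([t.stock for t in tables], ignore_index=True),
        )


def aggregate(
    cohort_runs: Sequence[tuple[LengthCohort, Mapping[str, pd.DataFrame]]],
    species: str,
    year: int,
    prey_ed: PreyEnergyTable,
) -> ConsumptionTable:
    """Scale per-fish branch budgets to the stock.

    Stock daily consumption is the sum over cohorts of
    abundance x (RdL_lower x lower branch + RdL_upper x upper branch).
    """
    if not cohort_runs:
        raise ValueError("no cohorts to aggregate")
    gram_cols = [f"grams_{g}" for g in PREY_GROUPS]
    ed = prey_ed.as_array()

    daily_acc: pd.DataFrame | None = None
    stock_acc: pd.DataFrame | None = None
    for cohort, branches in cohort_runs:
        if set(branches) != {"lower", "upper"}:
            raise ValueError(
                f"cohort {cohort.length_group}: expected branches lower/upper, "
                f"got {sorted(branches)}"
            )
        for branch, frac in (
            ("lower", cohort.split.rdl_lower),
            ("upper", cohort.split.rdl_upper),
        ):
            if frac == 0.0:
                continue
            frame = branches[branch]
            w = cohort.abundance * frac
            grams = frame[gram_cols].to_numpy() * w
            contrib = pd.DataFrame(grams, columns=gram_cols)
            contrib.insert(0, "day", frame["t"].to_numpy())
            stock_part = pd.DataFrame(
                {
                    "day": frame["t"].to_numpy(),
                    "biomass_g": frame["weight"].to_numpy() * w,
                    "consumption_g": grams.sum(axis=1),
                    "consumption_j": frame["C"].to_numpy() * w,
                    "abundance": w,
                    "rate_abundance_sum": frame["specific_C"].to_numpy() * w,
                }
            )
            daily_acc = (
                contrib
                if daily_acc is None
                else pd.concat([daily_acc, contrib], ignore_index=True)
            )
            stock_acc = (
                stock_part
                if stock_acc is None
                else pd.concat([stock_acc, stock_part], ignore_index=True)
            )

    assert daily_acc is not None and stock_acc is not None
    by_day = daily_acc.groupby("day", as_index=False).sum()
    long = by_day.melt(id_vars="day", var_name="prey_group", value_name="grams")
    long["prey_group"] = long["prey_group"].str.removeprefix("grams_")
    ed_map = {g: e for g, e in zip(PREY_GROUPS, ed)}
    long["tonnes"] = long["grams"] / 1e6
    long["joules"] = long["grams"] * long["prey_group"].map(ed_map)
    long.insert(0, "species", species)
    long.insert(1, "year", year)
    daily = long[["species", "year", "day", "prey_group", "tonnes", "joules"]]

    stock = stock_acc.groupby("day", as_index=False).sum()
    stock.insert(0, "species", species)
    stock.insert(1, "year", year)
    return ConsumptionTable(daily=daily.reset_index(drop=True), stock=stock)


def mean_daily_specific_rate(
    table: ConsumptionTable,
    species: str | None = None,
    year: int | None = None,
    weighting: str = "gram_days",
) -> float:
    """Mean daily specific consumption rate (g prey per g fish per day).

    ``weighting="gram_days"`` (default) divides total prey grams by total
    fish gram-days -- the interpretation under which a per-gram rate
    aggregates consistently across fish sizes and days.
    ``weighting="per_fish"`` averages each fish's own specific rate,
    weighted by abundance only.
    """
    df = table.stock
    if species is not None:
        df = df[df["species"] == species]
    if year is not None:
        df = df[df["year"] == year]
    if df.empty:
        raise ValueError("no rows selected from the consumption table")
    if weighting == "gram_days":
        return float(df["consumption_g"].sum() / df["biomass_g"].sum())
    if weighting == "per_fish":
        return float(df["rate_abundance_sum"].sum() / df["abundance"].sum())
    raise ValueError(f"unknown weighting {weighting!r}")


def cb_ratio(
    table: ConsumptionTable, biomass_tonnes: float, species: str, year: int
) -> float:
    """Annual consumed prey tonnes over the assessment biomass (dimensionless)."""
    if biomass_tonnes <= 0:
        raise ValueError("biomass must be positive")
    annual = table.annual()
    row = annual[(annual["species"] == species) & (annual["year"] == year)]
    if row.empty:
        raise ValueError(f"no consumption for {species} {year}")
    return float(row["tonnes"].iloc[0]) / biomass_tonnes


def extrapolate_consumption(
    mean_cb: Mapping[str, float], biomass_series: pd.DataFrame
) -> pd.DataFrame:
    """Per-year consumption from mean C/B ratios and a biomass series.

    ``biomass_series`` has columns species, year, biomass_tonnes.  Returns
    per-species rows plus a combined total per year (species="all").
    """
    bad = {sp: cb for sp, cb in mean_cb.items() if not cb > 0}
    if bad:
        raise ValueError(f"mean C/B must be positive: {bad}")
    df = biomass_series.copy()
    df["consumption_tonnes"] = df.apply(
        lambda r: mean_cb[r["species"]] * r["biomass_tonnes"], axis=1
    )
    combined = (
        df.groupby("year", as_index=False)["consumption_tonnes"]
        .sum()
        .assign(species="all", biomass_tonnes=np.nan)
    )
    return pd.concat(
        [df, combined[df.columns]], ignore_index=True
    ).sort_values(["species", "year"], ignore_index=True)


SENSITIVITY_PARAMETERS = (
    "ambient_temperature",
    "swimming_speed",
    "somatic_growth",
    "sda_omega",
)


def sensitivity_sweep(
    model: "ConsumptionModel",
    parameter: str,
    factors: Sequence[float],
) -> pd.DataFrame:
    """Percent change in total energy consumption under a scaled parameter.

    Reruns the full pipeline with the chosen parameter multiplied by each
    factor and reports (C_factor - C_base)/C_base * 100 per species.  A
    ``somatic_growth`` factor scales the annual length increment dL (factor
    0 reproduces the no-length-growth comparison).
    """
    if parameter not in SENSITIVITY_PARAMETERS:
        raise ValueError(
            f"unknown parameter {parameter!r}; choose from {SENSITIVITY_PARAMETERS}"
        )
    if any(f < 0 for f in factors):
        raise ValueError("factors must be >= 0")
    base = model.fit()
    base_j = {
        sp.value: base.table.total_joules(sp.value) for sp in model.species_list
    }
    rows = []
    for factor in factors:
        res = model.perturbed(parameter, factor).fit()
        for sp in model.species_list:
            total = res.table.total_joules(sp.value)
            rows.append(
                {
                    "species": sp.value,
                    "parameter": parameter,
                    "factor": factor,
                    "total_joules": total,
                    "pct_change": (total - base_j[sp.value])
                    / base_j[sp.value]
                    * 100.0,
                }
            )
    return pd.DataFrame(rows)
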