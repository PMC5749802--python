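"""Model/Results interface over the full consumption pipeline.

:class:`ConsumptionModel` is built from the survey-like inputs (gridded
temperature and fish-density fields, seasonal and winter biological samples,
assessment tables, diet compositions) for one or more species and years;
:meth:`ConsumptionModel.fit` runs the whole chain -- ambient temperature,
length-structured population, growth fits and cohort trajectories, daily
energy budgets, prey allocation, stock aggregation -- and returns a
:class:`ConsumptionResults` carrying the consumption tables, daily specific
rates, C/B ratios and diagnostics, with ``summary()``, sensitivity and
extrapolation hanging off it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import reporting
from .budget import LengthCohort, run_cohort
from .diet import DietComposition, fill_missing_composition, load_diet_table
from .growth import (
    WeightAtDayFit,
    annual_increment,
    build_weight_trajectory,
    estimate_k,
    fit_weight_at_day,
    split_growth,
)
from .population import (
    BIOMASS_REFERENCE_DOY,
    build_length_distribution,
    estimate_sd_by_age,
    scale_to_biomass,
)
from .reporting import ConsumptionTable, cb_ratio, mean_daily_specific_rate
from .species import (
    DEFAULT_LIVER,
    DEFAULT_SPECIES,
    LiverModelParams,
    PreyEnergyTable,
    Species,
    SpeciesParams,
)
from .temperature import GriddedField, ambient_temperature

log = logging.getLogger(__name__)


@dataclass
class SpeciesInputs:
    """All inputs the pipeline needs for one species."""

    params: SpeciesParams
    #: (year, period) -> (temperature field, density field)
    fields: Mapping[tuple[int, str], tuple[GriddedField, GriddedField]]
    seasonal_samples: pd.DataFrame  # doy, length_cm, weight_g
    winter_samples: pd.DataFrame  # year, age, length_cm
    numbers_at_age: pd.DataFrame  # year, age, numbers, mean_weight_g
    biomass: pd.DataFrame  # year, biomass_tonnes, kind
    diet: Sequence[DietComposition]
    k_by_year: Mapping[int, float] | None = None  # None: estimate from winter data


@dataclass(frozen=True)
class ModelOptions:
    """Behavioural switches and sensitivity perturbations.

    ``biomass_ref`` selects the day at which start-of-season weights enter
    the biomass rescaling: the fixed day 91 (as used in the source method
    for all species) or each species' own feeding start.  The ``*_scale``
    factors implement the multiplicative sensitivity sweep.
    """

    biomass_ref: str = "t91"  # or "feeding_start"
    rate_weighting: str = "gram_days"  # or "per_fish"
    ambient_temperature_scale: float = 1.0
    swimming_speed_scale: float = 1.0
    somatic_growth_scale: float = 1.0
    sda_omega_scale: float = 1.0


_PERTURBATION_FIELD = {
    "ambient_temperature": "ambient_temperature_scale",
    "swimming_speed": "swimming_speed_scale",
    "somatic_growth": "somatic_growth_scale",
    "sda_omega": "sda_omega_scale",
}


class ConsumptionModel:
    """Bioenergetics consumption model for one or more pelagic stocks.

    Parameters
    ----------
    inputs
        Per-species input bundles.
    years
        Years to simulate (defaults to the years present in the biomass
        tables).
    prey_energy, liver, options
        Prey energy-density table, liver-submodel constants and behaviour
        switches.
    """

    def __init__(
        self,
        inputs: Mapping[Species, SpeciesInputs],
        years: Sequence[int] | None = None,
        prey_energy: PreyEnergyTable | None = None,
        liver: LiverModelParams = DEFAULT_LIVER,
        options: ModelOptions | None = None,
    ) -> None:
        if not inputs:
            raise ValueError("at least one species input bundle is required")
        self.inputs = dict(inputs)
        self.prey_energy = prey_energy or PreyEnergyTable()
        self.liver = liver
        self.options = options or ModelOptions()
        if years is None:
            years = sorted(
                {
                    int(y)
                    for inp in self.inputs.values()
                    for y in inp.biomass["year"].unique()
                }
            )
        self.years = list(years)

    @property
    def species_list(self) -> list[Species]:
        return list(self.inputs)

    @classmethod
    def from_scenario(
        cls,
        scenario,
        prey_energy: PreyEnergyTable | None = None,
        options: ModelOptions | None = None,
    ) -> "ConsumptionModel":
        """Build a model from a :class:`~planktivore.synthetic.SyntheticScenario`."""
        from .synthetic import (
            generate_assessment,
            generate_fish_samples,
            generate_temperature_fields,
            load_k_table,
        )

        diet_all = load_diet_table()
        ktbl = load_k_table()
        inputs: dict[Species, SpeciesInputs] = {}
        for sp in scenario.species:
            fields = {}
            for year in scenario.years:
                per = generate_temperature_fields(scenario, sp, year)
                for period, pair in per.items():
                    fields[(year, period)] = pair
            seasonal, winter = generate_fish_samples(scenario, sp)
            naa, biomass = generate_assessment(scenario, sp)
            krows = ktbl[ktbl["species"] == sp.value]
            inputs[sp] = SpeciesInputs(
                params=DEFAULT_SPECIES[sp],
                fields=fields,
                seasonal_samples=seasonal,
                winter_samples=winter,
                numbers_at_age=naa,
                biomass=biomass,
                diet=[c for c in diet_all if c.species == sp.value],
                k_by_year={int(r["year"]): float(r["k"]) for _, r in krows.iterrows()},
            )
        return cls(
            inputs,
            years=list(scenario.years),
            prey_energy=prey_energy,
            options=options,
        )

    def perturbed(self, parameter: str, factor: float) -> "ConsumptionModel":
        """Copy of the model with one sensitivity parameter scaled."""
        fname = _PERTURBATION_FIELD[parameter]
        new_opts = replace(self.options, **{fname: factor})
        return ConsumptionModel(
            self.inputs,
            years=self.years,
            prey_energy=self.prey_energy,
            liver=self.liver,
            options=new_opts,
        )

    # -- fitting ----------------------------------------------------------

    def _effective_params(self, params: SpeciesParams) -> SpeciesParams:
        o = self.options
        changes = {}
        if o.swimming_speed_scale != 1.0:
            changes["swimming_speed"] = params.swimming_speed * o.swimming_speed_scale
        if o.sda_omega_scale != 1.0:
            changes["omega"] = params.omega * o.sda_omega_scale
        return replace(params, **changes) if changes else params

    def _weight_fits(self, inp: SpeciesInputs) -> dict[int, WeightAtDayFit]:
        params = inp.params
        df = inp.seasonal_samples
        groups = np.floor(df["length_cm"]).astype(int)
        fits: dict[int, WeightAtDayFit] = {}
        for g in sorted(groups.unique()):
            sub = df[groups == g]
            try:
                fits[int(g)] = fit_weight_at_day(
                    sub,
                    int(g),
                    window=(params.feeding_start, params.feeding_end),
                )
            except ValueError as err:
                log.warning("weight fit skipped for group %d: %s", g, err)
        return fits

    def _k_for_year(self, inp: SpeciesInputs, year: int) -> float:
        if inp.k_by_year is not None:
            table = dict(inp.k_by_year)
        else:
            means = (
                inp.winter_samples.groupby(["year", "age"])["length_cm"]
                .mean()
                .rename("mean_length_cm")
                .reset_index()
            )
            table = estimate_k(means, inp.params.lmax)
        if year in table:
            return table[year]
        filler = float(np.mean(list(table.values())))
        log.info("no k for year %d; using cross-year mean %.3f", year, filler)
        return filler

    def _sd_lookup(self, inp: SpeciesInputs, year: int) -> dict[int, float]:
        sds = estimate_sd_by_age(inp.winter_samples)
        this_year = sds[sds["year"] == year].set_index("age")["sd_cm"]
        pooled = sds.groupby("age")["sd_cm"].mean()
        out: dict[int, float] = {}
        for age in inp.numbers_at_age["age"].unique():
            age = int(age)
            if age in this_year.index and this_year[age] > 0:
                out[age] = float(this_year[age])
            elif age in pooled.index and pooled[age] > 0:
                out[age] = float(pooled[age])
        return out

    def _fit_species_year(
        self, sp: Species, inp: SpeciesInputs, year: int, fits: dict[int, WeightAtDayFit]
    ) -> tuple[ConsumptionTable, dict]:
        params = self._effective_params(inp.params)
        o = self.options

        try:
            temps_may, dens_may = inp.fields[(year, "May")]
            temps_july, dens_july = inp.fields[(year, "July")]
        except KeyError as err:
            raise KeyError(f"{sp.value} {year}: missing gridded fields") from err
        fixed = 10.0 if sp is Species.MACKEREL else None
        at_may = ambient_temperature(temps_may, dens_may, fixed_depth_m=fixed)
        at_july = ambient_temperature(temps_july, dens_july, fixed_depth_m=fixed)
        at_may *= o.ambient_temperature_scale
        at_july *= o.ambient_temperature_scale

        naa_year = inp.numbers_at_age[inp.numbers_at_age["year"] == year]
        if naa_year.empty:
            raise ValueError(f"{sp.value}: no numbers-at-age for {year}")
        sd_by_age = self._sd_lookup(inp, year)
        dist = build_length_distribution(naa_year, sd_by_age, params, year=year)

        ref_day = (
            BIOMASS_REFERENCE_DOY if o.biomass_ref == "t91" else params.feeding_start
        )

        def weight_at_start(L: int) -> float:
            if L not in fits:
                raise KeyError(f"{sp.value}: no weight fit for group {L}")
            return fits[L](float(ref_day))

        brow = inp.biomass[inp.biomass["year"] == year]
        if brow.empty:
            raise ValueError(f"{sp.value}: no biomass for {year}")
        biomass_tonnes = float(brow["biomass_tonnes"].iloc[0])
        scaled = scale_to_biomass(dist, biomass_tonnes, weight_at_start)

        k = self._k_for_year(inp, year)
        window = (params.feeding_start, params.feeding_end)
        diet_may = fill_missing_composition(inp.diet, sp.value, year, "May")
        diet_july = fill_missing_composition(inp.diet, sp.value, year, "July")

        cohort_runs = []
        for _, row in scaled.to_cm_groups().iterrows():
            L = int(row["length_group"])
            abundance = float(row["abundance"])
            if abundance <= 0:
                continue
            dl = annual_increment(k, L, params.lmax) * o.somatic_growth_scale
            split = split_growth(dl)
            traj_lower = build_weight_trajectory(L, split.dg_lower, fits, window)
            traj_upper = build_weight_trajectory(L, split.dg_upper, fits, window)
            cohort = LengthCohort(
                length_group=L,
                abundance=abundance,
                split=split,
                traj_lower=traj_lower,
                traj_upper=traj_upper,
            )
            branches = run_cohort(
                cohort,
                at_may,
                at_july,
                diet_may,
                diet_july,
                params,
                self.prey_energy,
                liver=self.liver,
            )
            cohort_runs.append((cohort, branches))

        table = reporting.aggregate(cohort_runs, sp.value, year, self.prey_energy)
        meta = {
            "species": sp.value,
            "year": year,
            "at_may": at_may,
            "at_july": at_july,
            "k": k,
            "biomass_tonnes": biomass_tonnes,
            "n_cohorts": len(cohort_runs),
        }
        return table, meta

    def fit(self) -> "ConsumptionResults":
        """Run the full pipeline and return results."""
        tables: list[ConsumptionTable] = []
        metas: list[dict] = []
        for sp, inp in self.inputs.items():
            fits = self._weight_fits(inp)
            for year in self.years:
                table, meta = self._fit_species_year(sp, inp, year, fits)
                tables.append(table)
                metas.append(meta)
        return ConsumptionResults(self, ConsumptionTable.concat(tables), pd.DataFrame(metas))


class ConsumptionResults:
    """Fitted consumption estimates and derived quantities.

    Attributes
    ----------
    table : ConsumptionTable
        Tidy daily consumption per species/year/prey group plus stock-level
        biomass series.
    diagnostics : pandas.DataFrame
        Per (species, year): ambient temperatures, growth coefficient k,
        assessment biomass and cohort count.
    """

    def __init__(
        self, model: ConsumptionModel, table: ConsumptionTable, diagnostics: pd.DataFrame
    ) -> None:
        self.model = model
        self.table = table
        self.diagnostics = diagnostics

    # -- derived quantities ----------------------------------------------

    def specific_rates(self) -> pd.DataFrame:
        """Mean daily specific consumption rate per (species, year)."""
        rows = []
        for _, m in self.diagnostics.iterrows():
            rows.append(
                {
                    "species": m["species"],
                    "year": int(m["year"]),
                    "rate_g_per_g_day": mean_daily_specific_rate(
                        self.table,
                        species=m["species"],
                        year=int(m["year"]),
                        weighting=self.model.options.rate_weighting,
                    ),
                }
            )
        return pd.DataFrame(rows)

    def mean_specific_rates(self) -> dict[str, float]:
        """Cross-year mean daily specific rate per species."""
        df = self.specific_rates()
        return df.groupby("species")["rate_g_per_g_day"].mean().to_dict()

    def cb_ratios(self) -> pd.DataFrame:
        """Annual consumption over assessment biomass per (species, year)."""
        rows = []
        for _, m in self.diagnostics.iterrows():
            rows.append(
                {
                    "species": m["species"],
                    "year": int(m["year"]),
                    "cb_ratio": cb_ratio(
                        self.table,
                        float(m["biomass_tonnes"]),
                        m["species"],
                        int(m["year"]),
                    ),
                }
            )
        return pd.DataFrame(rows)

    def mean_cb_ratios(self) -> dict[str, float]:
        df = self.cb_ratios()
        return df.groupby("species")["cb_ratio"].mean().to_dict()

    def extrapolate(self, biomass_series: pd.DataFrame | None = None) -> pd.DataFrame:
        """Extrapolate mean C/B to a biomass series (default: the fitted years)."""
        if biomass_series is None:
            biomass_series = pd.concat(
                [
                    inp.biomass.assign(species=sp.value)[
                        ["species", "year", "biomass_tonnes"]
                    ]
                    for sp, inp in self.model.inputs.items()
                ],
                ignore_index=True,
            )
        return reporting.extrapolate_consumption(self.mean_cb_ratios(), biomass_series)

    def sensitivity(self, parameter: str, factors: Sequence[float]) -> pd.DataFrame:
        """Sensitivity sweep around this model's configuration."""
        return reporting.sensitivity_sweep(self.model, parameter, factors)

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary of rates, annual consumption and C/B ratios."""
        rates = self.specific_rates()
        cbs = self.cb_ratios()
        annual = self.table.annual()
        merged = (
            rates.merge(cbs, on=["species", "year"])
            .merge(annual, on=["species", "year"])
            .merge(
                self.diagnostics[["species", "year", "at_may", "at_july", "k"]],
                on=["species", "year"],
            )
        )
        lines = [
            "Bioenergetics consumption estimates",
            "=" * 78,
            f"{'species':<14}{'year':>6}{'aT May':>8}{'aT Jul':>8}{'k':>7}"
            f"{'rate g/g/d':>12}{'C tonnes':>14}{'C/B':>8}",
            "-" * 78,
        ]
        for _, r in merged.iterrows():
            lines.append(
                f"{r['species']:<14}{int(r['year']):>6}{r['at_may']:>8.2f}"
                f"{r['at_july']:>8.2f}{r['k']:>7.2f}{r['rate_g_per_g_day']:>12.4f}"
                f"{r['tonnes']:>14.3e}{r['cb_ratio']:>8.2f}"
            )
        lines.append("-" * 78)
        for sp, rate in sorted(self.mean_specific_rates().items()):
            cb = self.mean_cb_ratios()[sp]
            lines.append(f"{sp:<14} mean rate {rate:.4f} g/g/d   mean C/B {cb:.2f}")
        return "\n".join(lines)

    def plot_seasonal(self, species: str | None = None, ax=None):
        """Monthly consumed tonnes per prey group (stacked bars)."""
        import matplotlib.pyplot as plt

        monthly = self.table.monthly()
        if species is not None:
            monthly = monthly[monthly["species"] == species]
        pivot = monthly.pivot_table(
            index="month", columns="prey_group", values="tonnes", aggfunc="sum"
        ).fillna(0.0)
        if ax is None:
            _, ax = plt.subplots()
        pivot.plot(kind="bar", stacked=True, ax=ax)
        ax.set_xlabel("month")
        ax.set_ylabel("consumed prey (tonnes)")
        ax.set_title(species or "all species")
        return ax

    def plot_annual(self, ax=None):
        """Annual consumed tonnes per species."""
        import matplotlib.pyplot as plt

        annual = self.table.annual()
        pivot = annual.pivot(index="year", columns="species", values="tonnes")
        if ax is None:
            _, ax = plt.subplots()
        pivot.plot(kind="bar", ax=ax)
        ax.set_ylabel("consumed prey (tonnes)")
        return ax
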