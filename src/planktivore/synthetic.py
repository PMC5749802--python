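"""Synthetic survey-like inputs with known ground truth.

The original analysis consumed gridded CTD/acoustic survey fields, seasonal
and winter biological samples, and assessment tables.  This module generates
statistically similar inputs from a seeded scenario so the full pipeline can
run and be validated without external data: every generated quantity has a
known generating value (true growth coefficient k, true weight-at-day
quadratics, true ambient temperature levels), which parameter-recovery tests
exploit.  Diet tables and the per-year k values ship as packaged fixtures
transcribed from the source surveys and are not fabricated here.

What the generator emulates: the gridded structure of temperature and fish
density (including a configurable fish-temperature association so that the
density-weighted ambient temperature differs measurably from the plain
mean), seasonal weight-at-length growth, winter length-at-age cohorts whose
consecutive-winter increments encode k, and assessment-style numbers-at-age
with a matching biomass total.  What it does not emulate: survey design,
acoustic physics, spatial migration, measurement gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .population import build_length_distribution
from .species import DEFAULT_SPECIES, Species, SpeciesParams
from .temperature import GriddedField

#: (May, July) ambient-temperature levels (degC) per species: surface-layer
#: feeders (mackerel, herring) in the 8-11 degC band, the deeper-dwelling
#: blue whiting in the 4-8 degC band.  The levels are set so that the
#: realized density-weighted ambient temperatures, which sit ~0.3-0.5 degC
#: above the level because fish aggregate in warm-anomaly cells, stay inside
#: those bands.
DEFAULT_TEMPERATURE_LEVELS: dict[Species, tuple[float, float]] = {
    Species.MACKEREL: (8.5, 10.3),
    Species.HERRING: (8.3, 10.0),
    Species.BLUE_WHITING: (4.5, 7.5),
}

#: Seasonal relative gain in weight at fixed length (condition) over the
#: feeding window.  Herring fatten substantially; mackerel's energetic gain
#: is mostly carried by its steep seasonal energy-density curve, so its
#: weight-at-length gain is kept modest; the gadoid blue whiting stores
#: energy in the liver and gains little muscle mass.
DEFAULT_CONDITION_GAIN: dict[Species, float] = {
    Species.MACKEREL: 0.10,
    Species.HERRING: 0.25,
    Species.BLUE_WHITING: 0.10,
}

#: Ages present in the assessment input per species.
AGE_RANGE: dict[Species, tuple[int, int]] = {
    Species.MACKEREL: (2, 17),
    Species.HERRING: (4, 17),
    Species.BLUE_WHITING: (2, 13),
}


def load_k_table() -> pd.DataFrame:
    """Packaged per-year growth coefficients k (columns species, year, k)."""
    with resources.as_file(
        resources.files("planktivore.data").joinpath("k_table.csv")
    ) as p:
        return pd.read_csv(p)


@dataclass(frozen=True)
class SyntheticScenario:
    """A seeded specification of all synthetic inputs.

    The defaults describe the study conditions: temperature levels per
    species as above, packaged k values, 0.5 cm within-age length SD and
    200 winter samples per age, and a 3x3 cell grid with five 10 m depth
    bins.  ``six_year_default`` switches on all six study years.
    """

    seed: int = 0
    years: tuple[int, ...] = (2005,)
    species: tuple[Species, ...] = (
        Species.MACKEREL,
        Species.HERRING,
        Species.BLUE_WHITING,
    )
    n_cells: int = 9
    n_depth_bins: int = 5
    temperature_levels: Mapping[Species, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TEMPERATURE_LEVELS)
    )
    condition_gain: Mapping[Species, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_GAIN)
    )
    temp_cell_sd: float = 0.3  # degC, spatial noise between cells
    temp_depth_gradient: float = 0.15  # degC per 10 m bin, warmer up
    density_sigma: float = 0.7  # lognormal sigma of fish density
    fish_temperature_association: float = 0.5  # >0: fish prefer warm cells
    n_seasonal_per_group: int = 200
    seasonal_weight_cv: float = 0.04
    n_winter_per_age: int = 200
    winter_length_sd: float = 0.5  # cm, within (year, age)
    biomass_perturbation: float = 1.0  # multiplies the consistent biomass

    @classmethod
    def six_year_default(cls, seed: int = 0) -> "SyntheticScenario":
        """All three species over the six survey years."""
        return cls(seed=seed, years=tuple(range(2005, 2011)))

    def rng(self, *stream) -> np.random.Generator:
        """Independent generator for a named substream (pure in (seed, stream))."""
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, *map(_stable_hash, stream)])
        )

    # -- ground truth -----------------------------------------------------

    def true_k(self, species: Species, year: int) -> float:
        tbl = load_k_table()
        row = tbl[(tbl["species"] == species.value) & (tbl["year"] == year)]
        if row.empty:
            sp = tbl[tbl["species"] == species.value]
            return float(sp["k"].mean())
        return float(row["k"].iloc[0])

    def true_weight(self, species: Species, length_group: int, t) -> np.ndarray:
        """True weight-at-day curve for a 1 cm length group (g).

        Lean (winter) weight at the group midpoint from the allometric
        regression, times a quadratic seasonal condition factor
        1 + gain * (u + u^2)/2 with u the clipped position in the feeding
        window -- so the curve is exactly quadratic in t inside the window.
        """
        p = DEFAULT_SPECIES[species]
        lean = p.weight_from_length(length_group + 0.5)
        t = np.asarray(t, dtype=float)
        u = np.clip((t - p.feeding_start) / p.feeding_days, 0.0, 1.0)
        w = lean * (1.0 + self.condition_gain[species] * (u + u**2) / 2.0)
        return float(w) if w.ndim == 0 else w

    def true_weight_coefficients(
        self, species: Species, length_group: int
    ) -> tuple[float, float, float]:
        """(a, b, c) of the true quadratic W = a t^2 + b t + c on the window."""
        p = DEFAULT_SPECIES[species]
        lean = p.weight_from_length(length_group + 0.5)
        gain = self.condition_gain[species]
        t0, T = p.feeding_start, p.feeding_days
        # 1 + gain/2 * ((t-t0)/T + (t-t0)^2/T^2)
        a = lean * gain / (2 * T**2)
        b = lean * gain / 2 * (1 / T - 2 * t0 / T**2)
        c = lean * (1 + gain / 2 * (t0**2 / T**2 - t0 / T))
        return a, b, c

    def base_length_at_age(self, species: Species, age: int) -> float:
        """Mean winter length at age in the first winter (cm).

        Saturating curve whose asymptote sits one cm below the growth
        ceiling Lmax, so every age group keeps a well-conditioned increment
        denominator (Lmax - L) for the growth-coefficient estimator.
        """
        p = DEFAULT_SPECIES[species]
        lo, hi = p.length_range
        a0 = AGE_RANGE[species][0]
        asymptote = min(hi, p.lmax) - 1.0
        return lo + (asymptote - lo) * (1.0 - np.exp(-0.30 * (age - a0 + 1)))

    def winter_mean_lengths(self, species: Species) -> pd.DataFrame:
        """True winter mean length-at-age per year (columns year, age, mean_length_cm).

        Consecutive winters encode the true k: the cohort at (year, age)
        appears at (year+1, age+1) with increment k_year * (Lmax - L),
        while each year's youngest age restarts at the base length.
        Winters run from the first study year through one past the last, so
        every study year has an increment pair.
        """
        p = DEFAULT_SPECIES[species]
        a_lo, a_hi = AGE_RANGE[species]
        winters = list(range(min(self.years), max(self.years) + 2))
        means: dict[tuple[int, int], float] = {}
        for age in range(a_lo, a_hi + 1):
            means[(winters[0], age)] = self.base_length_at_age(species, age)
        for yr in winters[:-1]:
            k = self.true_k(species, yr)
            for age in range(a_lo, a_hi + 1):
                if age + 1 <= a_hi:
                    L = means[(yr, age)]
                    means[(yr + 1, age + 1)] = L + max(k * (p.lmax - L), 0.0)
            means[(yr + 1, a_lo)] = self.base_length_at_age(species, a_lo)
        rows = [
            {"year": yr, "age": age, "mean_length_cm": L}
            for (yr, age), L in sorted(means.items())
        ]
        return pd.DataFrame(rows)


def _stable_hash(obj) -> int:
    """Deterministic small non-negative int from a label (no PYTHONHASHSEED)."""
    import zlib

    return zlib.crc32(str(obj).encode())


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def generate_temperature_fields(
    scenario: SyntheticScenario, species: Species, year: int
) -> dict[str, tuple[GriddedField, GriddedField]]:
    """Gridded (temperature, density) field pairs for May and July.

    Temperature per cell and 10 m depth bin is the species' seasonal level
    plus a cell anomaly and a vertical gradient (warmer near the surface).
    Fish density is lognormal and, with positive
    ``fish_temperature_association``, concentrates in warm-anomaly cells so
    the weighted ambient temperature measurably exceeds the plain mean.
    Mackerel density is a surface CPUE field at a single fixed depth.
    """
    p = DEFAULT_SPECIES[species]
    levels = scenario.temperature_levels[species]
    out: dict[str, tuple[GriddedField, GriddedField]] = {}
    for period, level in zip(("May", "July"), levels):
        rng = scenario.rng("fields", species.value, year, period)
        cells = np.arange(scenario.n_cells)
        anom = rng.normal(0.0, scenario.temp_cell_sd, scenario.n_cells)
        mids = 5.0 + 10.0 * np.arange(scenario.n_depth_bins)
        depth_term = scenario.temp_depth_gradient * (
            (mids.mean() - mids) / 10.0
        )  # warmer above the mean depth
        temp_rows = []
        for ci, cell in enumerate(cells):
            for d, dt in zip(mids, depth_term):
                temp_rows.append(
                    {
                        "period": period,
                        "cell_id": int(cell),
                        "depth_mid_m": d,
                        "value": level + anom[ci] + dt,
                    }
                )
        temps = GriddedField(period, "temperature", pd.DataFrame(temp_rows))

        assoc = scenario.fish_temperature_association
        if species is Species.MACKEREL:
            cpue = rng.lognormal(0.0, scenario.density_sigma, scenario.n_cells)
            cpue *= np.exp(assoc * anom / max(scenario.temp_cell_sd, 1e-9))
            dens = pd.DataFrame(
                {
                    "period": period,
                    "cell_id": cells.astype(int),
                    "depth_mid_m": 5.0,
                    "value": cpue,
                }
            )
            density = GriddedField(period, "cpue", dens)
        else:
            sa = rng.lognormal(
                np.log(100.0), scenario.density_sigma, (scenario.n_cells, mids.size)
            )
            # fish prefer warm cells and mid depths
            sa *= np.exp(assoc * anom[:, None] / max(scenario.temp_cell_sd, 1e-9))
            rows = []
            for ci, cell in enumerate(cells):
                for di, d in enumerate(mids):
                    rows.append(
                        {
                            "period": period,
                            "cell_id": int(cell),
                            "depth_mid_m": d,
                            "value": sa[ci, di],
                        }
                    )
            density = GriddedField(period, "sa", pd.DataFrame(rows))
        out[period] = (temps, density)
    return out


def generate_fish_samples(
    scenario: SyntheticScenario, species: Species
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seasonal length-weight samples and winter length-at-age samples.

    Seasonal samples are drawn on the true quadratic weight-at-day curves
    with multiplicative Gaussian noise, pooled over the scenario years, for
    every 1 cm group from the species minimum to two groups above the
    maximum (growth trajectories may step past the nominal range).  Winter
    samples are Gaussian around the true winter mean length-at-age, whose
    consecutive-winter increments encode the true k.
    """
    p = DEFAULT_SPECIES[species]
    lo, hi = (int(p.length_range[0]), int(p.length_range[1]))
    rng = scenario.rng("seasonal", species.value)
    rows = []
    n = scenario.n_seasonal_per_group
    for group in range(lo, hi + 3):
        doy = rng.integers(p.feeding_start, p.feeding_end + 1, n)
        true_w = scenario.true_weight(species, group, doy)
        w = true_w * (1.0 + rng.normal(0.0, scenario.seasonal_weight_cv, n))
        for year_pick, t, wt in zip(
            rng.choice(scenario.years, n), doy, w
        ):
            rows.append(
                {
                    "species": species.value,
                    "year": int(year_pick),
                    "doy": int(t),
                    "length_cm": group + 0.5,
                    "weight_g": float(wt),
                }
            )
    seasonal = pd.DataFrame(rows)

    rng_w = scenario.rng("winter", species.value)
    means = scenario.winter_mean_lengths(species)
    wrows = []
    for _, r in means.iterrows():
        lengths = rng_w.normal(
            r["mean_length_cm"], scenario.winter_length_sd, scenario.n_winter_per_age
        )
        for L in lengths:
            wrows.append(
                {
                    "species": species.value,
                    "year": int(r["year"]),
                    "age": int(r["age"]),
                    "length_cm": float(L),
                }
            )
    winter = pd.DataFrame(wrows)
    return seasonal, winter


def generate_assessment(
    scenario: SyntheticScenario, species: Species
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assessment-style numbers-at-age and biomass tables.

    Numbers decline exponentially with age; mean weight-at-age follows the
    winter mean length through the allometric regression, so inverting it in
    the pipeline recovers the age's mean length exactly.  The biomass total
    is computed from the implied start-of-season length distribution with
    the true day-91 weights (times ``biomass_perturbation``), so with the
    default perturbation of 1 the assessment is consistent with the
    population the pipeline reconstructs.
    """
    p = DEFAULT_SPECIES[species]
    a_lo, a_hi = AGE_RANGE[species]
    means = scenario.winter_mean_lengths(species).set_index(["year", "age"])[
        "mean_length_cm"
    ]
    naa_rows = []
    biomass_rows = []
    for year in scenario.years:
        ages = np.arange(a_lo, a_hi + 1)
        numbers = 1e9 * np.exp(-0.35 * (ages - a_lo))
        naa = pd.DataFrame(
            {
                "species": species.value,
                "year": year,
                "age": ages,
                "numbers": numbers,
                "mean_weight_g": [
                    p.weight_from_length(means[(year, a)]) for a in ages
                ],
            }
        )
        naa_rows.append(naa)
        sd_by_age = {int(a): scenario.winter_length_sd for a in ages}
        dist = build_length_distribution(naa, sd_by_age, p, year=year)
        groups = dist.to_cm_groups()
        w91 = np.array(
            [
                scenario.true_weight(species, int(L), 91.0)
                for L in groups["length_group"]
            ]
        )
        biomass_g = float((w91 * groups["abundance"].to_numpy()).sum())
        biomass_rows.append(
            {
                "species": species.value,
                "year": year,
                "biomass_tonnes": biomass_g / 1e6 * scenario.biomass_perturbation,
                "kind": "ssb" if species is Species.HERRING else "tsb",
            }
        )
    return pd.concat(naa_rows, ignore_index=True), pd.DataFrame(biomass_rows)
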