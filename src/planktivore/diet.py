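"""Diet composition per species/year/day and prey-biomass allocation.

Stomach-content surveys provide prey-group percentages for May and July of
each year; the model needs a composition for every day of the feeding
season.  Missing survey cells are filled by cross-year averages (mackerel,
sampled only in July, uses its July diet all season), and daily compositions
follow the same plateau-linear-plateau interpolation as ambient temperature.
Consumed energy is converted to prey biomass by treating the proportions as
wet-weight shares: the total prey mass is the energy divided by the
composition-weighted mean prey energy density.

Sub-percent survey entries are printed as "<1"; they are read as 0.5% before
the row is renormalized to fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .species import PREY_GROUPS, PreyEnergyTable
from .temperature import INTERP_END_DOY, INTERP_START_DOY

#: Value (percent) substituted for sub-percent "<1" table entries.
SUB_PERCENT_VALUE = 0.5


@dataclass(frozen=True)
class DietComposition:
    """Normalized wet-weight prey-group proportions for one species/year/season."""

    species: str
    year: int
    season: str  # "May" or "July"
    proportions: tuple[float, ...]  # aligned with PREY_GROUPS, sums to 1

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions)
        if len(p) != len(PREY_GROUPS):
            raise ValueError(f"expected {len(PREY_GROUPS)} prey groups, got {len(p)}")
        if (p < 0).any():
            raise ValueError("proportions must be >= 0")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {p.sum()!r}")

    @classmethod
    def from_percentages(
        cls, species: str, year: int, season: str, percentages: Sequence[float]
    ) -> "DietComposition":
        p = np.asarray(percentages, dtype=float)
        if p.sum() <= 0:
            raise ValueError("all-zero composition")
        p = p / p.sum()
        return cls(species, int(year), season, tuple(p))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.proportions)

    def mean_prey_energy_density(self, prey_ed: PreyEnergyTable) -> float:
        """Composition-weighted mean prey energy density (J g^-1)."""
        return float(self.as_array() @ prey_ed.as_array())


def parse_percentage(value) -> float:
    """Parse a diet-table cell; sub-percent '<1' entries become 0.5."""
    if isinstance(value, str) and value.strip() == "<1":
        return SUB_PERCENT_VALUE
    return float(value)


def load_diet_table(
    path: str | Path | None = None, include_filled: bool = True
) -> list[DietComposition]:
    """Load a diet table CSV into compositions.

    The packaged default transcribes the survey diet percentages for
    2005-2010; rows whose percentages were themselves cross-year fills in
    the source are tagged ``filled`` and can be excluded with
    ``include_filled=False`` (e.g. to recompute the fills from observed
    donors via :func:`fill_missing_composition`).
    """
    if path is None:
        with resources.as_file(
            resources.files("planktivore.data").joinpath("diet_table.csv")
        ) as p:
            df = pd.read_csv(p, dtype=str)
    else:
        df = pd.read_csv(path, dtype=str)
    if not include_filled and "source" in df.columns:
        df = df[df["source"] != "filled"]
    out = []
    for _, row in df.iterrows():
        pct = [parse_percentage(row[g]) for g in PREY_GROUPS]
        out.append(
            DietComposition.from_percentages(
                row["species"], int(row["year"]), row["season"], pct
            )
        )
    return out


def find_composition(
    comps: Iterable[DietComposition], species: str, year: int, season: str
) -> DietComposition | None:
    for c in comps:
        if c.species == species and c.year == year and c.season == season:
            return c
    return None


def fill_missing_composition(
    comps: Sequence[DietComposition], species: str, year: int, season: str
) -> DietComposition:
    """Composition for a (species, year, season), filling gaps by convention.

    If the cell was observed it is returned as is.  A missing July (or May)
    cell for herring/blue whiting is filled with the per-group mean over the
    observed years for that species and season, renormalized.  Mackerel has
    no May surveys: its May composition is that year's July composition
    (itself filled the same way if missing).
    """
    direct = find_composition(comps, species, year, season)
    if direct is not None:
        return direct
    if species == "mackerel" and season == "May":
        july = fill_missing_composition(comps, species, year, "July")
        return DietComposition(species, year, "May", july.proportions)
    donors = [c for c in comps if c.species == species and c.season == season]
    if not donors:
        raise ValueError(
            f"no donor compositions for {species} {season}; cannot fill {year}"
        )
    if len(donors) == 1:  # exact copy, no renormalization round-off
        return DietComposition(species, year, season, donors[0].proportions)
    mean = np.mean([c.as_array() for c in donors], axis=0)
    return DietComposition.from_percentages(species, year, season, mean)


def daily_diet(
    may: DietComposition, july: DietComposition, t: float
) -> DietComposition:
    """Daily composition: May before 1 June, July after 1 July, linear between.

    Each prey group is interpolated independently and the result is
    renormalized to sum to one.
    """
    if (may.species, may.year) != (july.species, july.year):
        raise ValueError("May and July compositions must share species and year")
    if t <= INTERP_START_DOY:  # plateau: exact copy of the May composition
        return DietComposition(may.species, may.year, "May", may.proportions)
    if t >= INTERP_END_DOY:
        return DietComposition(july.species, july.year, "July", july.proportions)
    frac = (t - INTERP_START_DOY) / (INTERP_END_DOY - INTERP_START_DOY)
    p = (1 - frac) * may.as_array() + frac * july.as_array()
    return DietComposition.from_percentages(may.species, may.year, "interp", p)


def daily_diet_matrix(
    may: DietComposition, july: DietComposition, days: np.ndarray
) -> np.ndarray:
    """Vectorized daily compositions: (n_days, n_groups), rows sum to 1."""
    days = np.asarray(days, dtype=float)
    frac = np.clip(
        (days - INTERP_START_DOY) / (INTERP_END_DOY - INTERP_START_DOY), 0.0, 1.0
    )[:, None]
    p = (1 - frac) * may.as_array()[None, :] + frac * july.as_array()[None, :]
    return p / p.sum(axis=1, keepdims=True)


def allocate_prey(
    consumed_energy_j: float,
    comp: DietComposition,
    prey_ed: PreyEnergyTable,
) -> dict[str, float]:
    """Convert consumed energy (J) to grams per prey group.

    Proportions are wet-weight shares, so the total prey mass is
    M = E / sum_i(p_i ED_i) and each group receives M p_i grams; the
    energy-weighted sum of the allocated grams reconstructs E exactly.
    """
    if consumed_energy_j < 0:
        raise ValueError("consumed energy must be >= 0")
    p = comp.as_array()
    mean_ed = comp.mean_prey_energy_density(prey_ed)
    total_g = consumed_energy_j / mean_ed
    return {g: float(total_g * pi) for g, pi in zip(PREY_GROUPS, p)}
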