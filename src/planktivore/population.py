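"""Length-structured start-of-season population from assessment tables.

Stock-assessment output (numbers-at-age with mean weight-at-age) is converted
to a 1 cm length-structured population: mean length at age is obtained by
inverting the allometric length-weight regression, numbers are spread over
0.1 cm bins with a Gaussian kernel whose SD per age comes from winter
commercial samples, and the resulting distribution is rescaled so that its
start-of-season biomass matches the assessment biomass (total-stock biomass
for mackerel and blue whiting, spawning-stock biomass for herring).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .species import SpeciesParams

#: Resolution of the fine length grid (cm).
FINE_BIN_CM = 0.1

#: Day-of-year at which start-of-season weights are evaluated for biomass
#: scaling (1 April, as used for all species regardless of feeding start).
BIOMASS_REFERENCE_DOY = 91


class MissingSDError(ValueError):
    """No length SD available for one or more ages present in the input."""


@dataclass
class LengthDistribution:
    """Abundance on a 0.1 cm length grid for one species/year.

    ``bins`` maps bin lower edges (cm, at 0.1 resolution) to abundance.
    """

    year: int
    lengths: np.ndarray  # bin lower edges, cm
    abundance: np.ndarray
    length_range: tuple[float, float]

    def __post_init__(self) -> None:
        if (self.abundance < 0).any():
            raise ValueError("abundances must be >= 0")

    @property
    def total(self) -> float:
        return float(self.abundance.sum())

    def to_cm_groups(self) -> pd.DataFrame:
        """Aggregate the fine grid to integer 1 cm length groups."""
        groups = np.floor(self.lengths + 1e-9).astype(int)
        df = pd.DataFrame({"length_group": groups, "abundance": self.abundance})
        return df.groupby("length_group", as_index=False)["abundance"].sum()

    def scaled(self, factor: float) -> "LengthDistribution":
        return LengthDistribution(
            year=self.year,
            lengths=self.lengths,
            abundance=self.abundance * factor,
            length_range=self.length_range,
        )


def mean_length_at_age(weight_g: float, lw_a: float, lw_b: float) -> float:
    """Invert W = a L^b to the mean length (cm) at an assessment weight (g)."""
    if weight_g <= 0:
        raise ValueError(f"weight must be positive, got {weight_g}")
    return (weight_g / lw_a) ** (1.0 / lw_b)


def estimate_sd_by_age(winter_samples: pd.DataFrame) -> pd.DataFrame:
    """Sample SD of length within (year, age) from winter length-at-age data.

    ``winter_samples`` has columns year, age, length_cm.  Returns a frame
    with columns year, age, sd_cm (ddof=1).
    """
    out = (
        winter_samples.groupby(["year", "age"])["length_cm"]
        .std(ddof=1)
        .rename("sd_cm")
        .reset_index()
    )
    return out


def build_length_distribution(
    naa: pd.DataFrame,
    sd_by_age: Mapping[int, float],
    params: SpeciesParams,
    year: int | None = None,
) -> LengthDistribution:
    """Spread numbers-at-age over a 0.1 cm length grid.

    Each age's numbers are distributed over bins by a normal density centred
    at the age's mean length (from inverting the length-weight regression on
    the assessment weight-at-age) with the age's winter-sample SD, and
    renormalized within the species length range so truncation at the range
    limits loses no fish.  ``naa`` has columns age, numbers, mean_weight_g
    (and optionally year).

    Total abundance is conserved: the bin sum equals the input numbers.
    """
    if year is None:
        year = int(naa["year"].iloc[0]) if "year" in naa.columns else 0
    missing = [int(a) for a in naa["age"] if int(a) not in sd_by_age]
    if missing:
        raise MissingSDError(f"no length SD for ages {sorted(set(missing))}")
    bad_sd = [a for a in naa["age"] if not sd_by_age[int(a)] > 0]
    if bad_sd:
        raise MissingSDError(f"non-positive SD for ages {sorted(set(map(int, bad_sd)))}")

    lo, hi = params.length_range
    edges = np.round(np.arange(lo, hi + FINE_BIN_CM / 2, FINE_BIN_CM), 6)
    lowers = edges[:-1]
    abundance = np.zeros_like(lowers)

    for _, row in naa.iterrows():
        n = float(row["numbers"])
        if n == 0:
            continue
        mu = mean_length_at_age(float(row["mean_weight_g"]), params.lw_a, params.lw_b)
        sd = float(sd_by_age[int(row["age"])])
        cdf = norm.cdf(edges, loc=mu, scale=sd)
        mass = np.diff(cdf)
        total = mass.sum()
        if total <= 0:
            # mean so far outside the range that all mass truncates; put the
            # numbers in the nearest edge bin to conserve abundance
            idx = 0 if mu < lo else len(lowers) - 1
            abundance[idx] += n
            continue
        abundance += n * mass / total

    return LengthDistribution(
        year=year, lengths=lowers, abundance=abundance, length_range=(lo, hi)
    )


def scale_to_biomass(
    dist: LengthDistribution,
    biomass_tonnes: float,
    weight_at_start: Callable[[float], float] | Mapping[int, float],
) -> LengthDistribution:
    """Rescale a length distribution so its biomass matches the assessment.

    ``weight_at_start`` gives the start-of-season weight (g) of a 1 cm
    length group, either as a callable of the group's integer length or a
    mapping.  The returned distribution satisfies
    sum_L W(L, t=91) * ABD'(L) = biomass exactly (one common scale factor on
    every bin, so the distribution shape is preserved).
    """
    if biomass_tonnes <= 0:
        raise ValueError("biomass must be positive")
    getw = (
        weight_at_start
        if callable(weight_at_start)
        else lambda L: weight_at_start[int(L)]
    )
    groups = dist.to_cm_groups()
    weights = np.array([getw(int(L)) for L in groups["length_group"]], dtype=float)
    pre_biomass_g = float((weights * groups["abundance"].to_numpy()).sum())
    if pre_biomass_g <= 0:
        raise ValueError("pre-scaling biomass is zero; cannot rescale")
    factor = biomass_tonnes * 1e6 / pre_biomass_g
    return dist.scaled(factor)
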