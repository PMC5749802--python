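"""Per-species parameter sets and seasonal predator energy-density models.

This module is the single home of all species-specific constants used by the
bioenergetics pipeline: the feeding windows, respiration parameters, waste
fractions, length-weight regressions and maximum lengths for growth, the prey
energy-density table, and the seasonal predator energy-density models
(a cubic for mackerel, a piecewise polynomial for herring, and a
muscle-plus-liver model for the gadoid blue whiting).

Units
-----
The internal energy currency of the package is the Joule.  The predator
energy-density polynomials are parameterised in kJ g^-1 wet weight (their
magnitudes, ~8-32, match observed whole-fish energy densities on that scale)
and are converted to J g^-1 on output.  Respiration constants are in
g O2 g^-1 day^-1 and are converted to energy with the oxycalorific
coefficient of 13560 J per gram of oxygen respired.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from pathlib import Path
from typing import Mapping

log = logging.getLogger(__name__)

#: Oxycalorific coefficient: energy equivalent of respired oxygen (J g^-1 O2).
OXYCAL_J_PER_G_O2 = 13560.0

#: Prey groups, in the order used by diet tables throughout the package.
PREY_GROUPS = (
    "copepods",
    "euphausiids",
    "amphipods",
    "other_crustaceans",
    "appendicularians",
    "fish",
    "other",
)


class Species(str, Enum):
    """The three pelagic planktivore stocks handled by the model."""

    MACKEREL = "mackerel"
    HERRING = "herring"
    BLUE_WHITING = "blue_whiting"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class RespirationForm(str, Enum):
    """Functional form of the temperature dependence of respiration."""

    EXPONENTIAL = "exponential"  # R ~ e^(rho * aT), mackerel and herring
    TEMPERATURE_DOME = "temperature_dome"  # dome with optimum, blue whiting


class ParameterError(ValueError):
    """A parameter set violates a well-posedness constraint."""


class EnergyDensityWindowError(ValueError):
    """Energy-density model evaluated outside its valid day-of-year window."""


class LiverModelError(ValueError):
    """Liver submodel produced a physically impossible fraction.

    Raised when the oil fraction is non-positive or the dry-matter fraction
    falls outside (0, 1); this typically signals a logarithm-base or offset
    misconfiguration in the liver coefficients.
    """


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesParams:
    """All per-species constants of the bioenergetics model.

    Attributes
    ----------
    feeding_start, feeding_end
        Day-of-year limits of the feeding window (non-leap calendar).
    length_range
        (min, max) body length in cm of the stock fraction modelled.
    swimming_speed
        Sustained swimming speed in body lengths per second.
    RA, beta, rho, topt, tmax, act
        Respiration parameters: allometric intercept (g O2 g^-1 day^-1) and
        slope, temperature slope, the per-species "Topt" constant (a slope on
        swimming speed for mackerel/herring, the optimal temperature in degC
        for blue whiting), the maximum (lethal) temperature (degC, blue
        whiting only) and the Winberg activity multiplier (blue whiting only).
    theta, epsilon, omega
        Egested proportion of consumption, excreted proportion of assimilated
        food, and the specific-dynamic-action coefficient.
    lmax
        Maximum length for growth (cm) of the length-increment growth model.
    lw_a, lw_b
        Length-weight regression constants, W = a L^b with W in g, L in cm.
    ed_window
        Day-of-year interval on which the predator energy-density model is
        defined; may be wider than the feeding window.
    """

    species: Species
    feeding_start: int
    feeding_end: int
    length_range: tuple[float, float]
    RA: float
    beta: float
    rho: float
    topt: float
    theta: float
    epsilon: float
    omega: float
    lmax: float
    lw_a: float
    lw_b: float
    ed_window: tuple[int, int]
    respiration_form: RespirationForm
    swimming_speed: float = 1.0
    tmax: float | None = None
    act: float | None = None
    oxycal: float = OXYCAL_J_PER_G_O2

    def __post_init__(self) -> None:
        if not (1 <= self.feeding_start < self.feeding_end <= 365):
            raise ParameterError(
                f"feeding window {self.feeding_start}-{self.feeding_end} must "
                "satisfy 1 <= start < end <= 365"
            )
        for name in ("theta", "epsilon", "omega"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ParameterError(f"{name}={v} must lie in (0, 1)")
        if self.waste_denominator <= 0.0:
            raise ParameterError(
                "1 - theta - (epsilon + omega)(1 - theta) must be positive "
                f"for the consumption solve; got {self.waste_denominator}"
            )
        if self.respiration_form is RespirationForm.TEMPERATURE_DOME:
            if self.tmax is None or self.act is None:
                raise ParameterError(
                    "temperature-dome respiration requires tmax and act"
                )
            if self.tmax <= self.topt:
                raise ParameterError("tmax must exceed topt for the dome form")

    @property
    def waste_denominator(self) -> float:
        """Denominator of the closed-form consumption solve.

        D = 1 - theta - (epsilon + omega)(1 - theta); daily consumption is
        C = (R + G) / D.
        """
        return 1.0 - self.theta - (self.epsilon + self.omega) * (1.0 - self.theta)

    @property
    def feeding_days(self) -> int:
        return self.feeding_end - self.feeding_start

    def weight_from_length(self, length_cm: float) -> float:
        """Allometric weight (g) at a given length (cm)."""
        return self.lw_a * length_cm**self.lw_b


@dataclass(frozen=True)
class PreyEnergyTable:
    """Energy density (J g^-1 wet weight) per prey group."""

    values: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREY_ENERGY_J_PER_G)
    )

    def __post_init__(self) -> None:
        missing = set(PREY_GROUPS) - set(self.values)
        if missing:
            raise ParameterError(f"prey energy table missing groups: {sorted(missing)}")
        bad = {g: v for g, v in self.values.items() if not v > 0}
        if bad:
            raise ParameterError(f"prey energy densities must be positive: {bad}")

    def __getitem__(self, group: str) -> float:
        return self.values[group]

    def as_array(self):
        import numpy as np

        return np.array([self.values[g] for g in PREY_GROUPS], dtype=float)


DEFAULT_PREY_ENERGY_J_PER_G: dict[str, float] = {
    "copepods": 3600.0,
    "euphausiids": 4000.0,
    "amphipods": 4000.0,
    "other_crustaceans": 3600.0,
    "appendicularians": 3600.0,
    "fish": 8500.0,
    "other": 3600.0,
}


@dataclass(frozen=True)
class LiverModelParams:
    """Constants of the gadoid liver-energy submodel.

    The liver index L_ind (liver mass as % of body mass) grows linearly from
    ``lind_intercept`` at 1 April by one unit per ``lind_slope_divisor`` days.
    Liver energy density combines a dry-matter fraction and an oil fraction,
    both logarithmic in L_ind; the logarithm base is natural by default (a
    base-10 logarithm yields a negative oil fraction at L_ind = 4, which is
    physically impossible and triggers :class:`LiverModelError`).
    """

    lind_intercept: float = 4.0  # percent of body mass at 1 April
    lind_slope_divisor: float = 30.33  # days per percentage point
    muscle_ed: float = 4500.0  # constant gadoid muscle energy density, J g^-1
    oil_ed_kj: float = 39.55  # energy density of liver oil, kJ g^-1
    dm_c0: float = 1.085
    dm_c1: float = 0.824
    dm_c2: float = 0.276
    oil_c0: float = 0.276
    oil_c1: float = 0.2
    ed_attenuation: float = 16.49
    ed_decay: float = 0.235
    log_base: float = math.e


DEFAULT_LIVER = LiverModelParams()

#: Day-of-year of 1 April (non-leap calendar), the liver-model time origin.
LIVER_T0_DOY = 91


# ---------------------------------------------------------------------------
# Liver submodel (blue whiting / gadoids)
# ---------------------------------------------------------------------------


def liver_index(t_rel: float, params: LiverModelParams = DEFAULT_LIVER) -> float:
    """Liver mass as a percent of body mass, ``t_rel`` days after 1 April.

    Linear accumulation: 4% at 1 April rising to ~9% by 1 September
    (153 days later).
    """
    if t_rel < 0:
        raise ValueError(f"t_rel={t_rel} must be >= 0 (days since 1 April)")
    return params.lind_intercept + t_rel / params.lind_slope_divisor


def _log(x: float, base: float) -> float:
    return math.log(x) if base == math.e else math.log(x, base)


def liver_dry_fraction(l_ind: float, params: LiverModelParams = DEFAULT_LIVER) -> float:
    """Proportion of dry material in the liver as a function of liver index."""
    return (
        params.dm_c0
        - params.dm_c1 / l_ind
        - params.dm_c2 * _log(l_ind, params.log_base)
    )


def liver_oil_fraction(l_ind: float, params: LiverModelParams = DEFAULT_LIVER) -> float:
    """Proportion of oil in the liver as a function of liver index."""
    return params.oil_c0 * _log(l_ind, params.log_base) - params.oil_c1


def liver_energy_density(
    l_ind: float, params: LiverModelParams = DEFAULT_LIVER
) -> float:
    """Liver energy density (J g^-1 liver) at a given liver index.

    Combines the non-oil dry matter (whose energy density saturates towards
    the oil value as the liver fattens) and the oil fraction at the full oil
    energy density.  Raises :class:`LiverModelError` on impossible fractions.
    """
    dm = liver_dry_fraction(l_ind, params)
    oil = liver_oil_fraction(l_ind, params)
    if oil <= 0.0:
        raise LiverModelError(
            f"oil fraction {oil:.4f} <= 0 at liver index {l_ind:.3f}; "
            "check logarithm base / offsets of the liver coefficients"
        )
    if not 0.0 < dm < 1.0:
        raise LiverModelError(
            f"dry-matter fraction {dm:.4f} outside (0, 1) at liver index "
            f"{l_ind:.3f}; check liver coefficients"
        )
    ed_kj = (
        dm * (params.oil_ed_kj - params.ed_attenuation * math.exp(-params.ed_decay * l_ind))
        + params.oil_ed_kj * oil
    )
    return ed_kj * 1000.0


def liver_energy(
    weight: float, t_rel: float, params: LiverModelParams = DEFAULT_LIVER
) -> float:
    """Total liver energy content (J) of a fish of ``weight`` g.

    ``t_rel`` is days since 1 April.  Liver mass is L_ind percent of body
    mass; total energy is liver mass times liver energy density.
    """
    if weight <= 0:
        raise ValueError(f"weight={weight} must be positive")
    l_ind = liver_index(t_rel, params)
    w_liver = l_ind / 100.0 * weight
    return w_liver * liver_energy_density(l_ind, params)


# ---------------------------------------------------------------------------
# Predator energy density
# ---------------------------------------------------------------------------

# Seasonal whole-body energy density polynomials, kJ g^-1 wet weight, with t
# in day of year.  Mackerel: a single cubic over days 121-243.  Herring: a
# cubic up to day 195 and a declining line from day 196.
_MACKEREL_ED_KJ = (-3.367e-5, 0.019, -3.282, 191.171)  # t^3, t^2, t, 1
_HERRING_ED_EARLY_KJ = (2.749e-6, -2.807e-4, -0.027, 11.067)
_HERRING_ED_LATE_KJ = (-0.053, 25.771)  # t, 1
_HERRING_ED_BREAK = 195  # last day of the early piece


def _polyval(coeffs: tuple[float, ...], t: float) -> float:
    out = 0.0
    for c in coeffs:
        out = out * t + c
    return out


def predator_energy_density(
    params: SpeciesParams,
    t: float,
    weight: float | None = None,
    liver: LiverModelParams = DEFAULT_LIVER,
    clamp: bool = True,
) -> float:
    """Whole-body energy density (J g^-1 wet weight) of the predator at day t.

    Mackerel and herring use seasonal polynomials fitted to lipid/energy
    observations.  Blue whiting, a gadoid, stores seasonal energy in the
    liver: its energy density is the constant muscle value plus the liver
    energy spread per gram of body mass, which requires ``weight``.

    Evaluation outside the species' valid window clamps to the nearest
    endpoint with a logged warning when ``clamp`` is true, and raises
    :class:`EnergyDensityWindowError` otherwise.
    """
    lo, hi = params.ed_window
    if not lo <= t <= hi:
        if not clamp:
            raise EnergyDensityWindowError(
                f"day {t} outside the {params.species.value} energy-density "
                f"window {lo}-{hi}"
            )
        log.warning(
            "energy-density day %s outside %s window %d-%d; clamping",
            t,
            params.species.value,
            lo,
            hi,
        )
        t = min(max(t, lo), hi)

    if params.species is Species.MACKEREL:
        return _polyval(_MACKEREL_ED_KJ, t) * 1000.0
    if params.species is Species.HERRING:
        piece = _HERRING_ED_EARLY_KJ if t <= _HERRING_ED_BREAK else _HERRING_ED_LATE_KJ
        return _polyval(piece, t) * 1000.0
    if params.species is Species.BLUE_WHITING:
        if weight is None or weight <= 0:
            raise ValueError("blue whiting energy density requires weight > 0")
        t_rel = max(t - LIVER_T0_DOY, 0.0)
        # Total liver energy spread per gram of body mass, on top of the
        # constant gadoid muscle density.
        return liver.muscle_ed + liver_energy(weight, t_rel, liver) / weight
    raise ValueError(f"unknown species {params.species!r}")


def total_energy(
    params: SpeciesParams,
    t: float,
    weight: float,
    liver: LiverModelParams = DEFAULT_LIVER,
) -> float:
    """Total body energy content (J) of a fish of ``weight`` g at day t.

    For mackerel/herring this is weight times the seasonal energy density;
    for blue whiting it is muscle energy plus total liver energy, which is
    algebraically the same as weight times its composed energy density.
    """
    return weight * predator_energy_density(params, t, weight=weight, liver=liver)


# ---------------------------------------------------------------------------
# Packaged default parameter sets
# ---------------------------------------------------------------------------

DEFAULT_SPECIES: dict[Species, SpeciesParams] = {
    Species.MACKEREL: SpeciesParams(
        species=Species.MACKEREL,
        feeding_start=136,  # 16 May
        feeding_end=243,  # 31 August
        length_range=(25.0, 45.0),
        RA=0.00264,
        beta=-0.217,
        rho=0.06818,
        topt=0.0234,  # slope on swimming speed
        theta=0.16,
        epsilon=0.10,
        omega=0.172,
        lmax=42.0,
        lw_a=0.00338,
        lw_b=3.241,
        ed_window=(121, 243),
        respiration_form=RespirationForm.EXPONENTIAL,
    ),
    Species.HERRING: SpeciesParams(
        species=Species.HERRING,
        feeding_start=91,  # 1 April
        feeding_end=258,  # 15 September
        length_range=(28.0, 38.0),
        RA=0.0033,
        beta=-0.227,
        rho=0.0548,
        topt=0.03,  # slope on swimming speed
        theta=0.16,
        epsilon=0.10,
        omega=0.175,
        lmax=36.0,
        lw_a=0.00322,
        lw_b=3.22,
        ed_window=(74, 259),
        respiration_form=RespirationForm.EXPONENTIAL,
    ),
    Species.BLUE_WHITING: SpeciesParams(
        species=Species.BLUE_WHITING,
        feeding_start=91,  # 1 April
        feeding_end=273,  # 30 September
        length_range=(15.0, 40.0),
        RA=0.008,
        beta=-0.172,
        rho=1.88,
        topt=21.0,  # optimal temperature, degC
        tmax=24.0,
        act=1.25,
        theta=0.17,
        epsilon=0.09,
        omega=0.17,
        lmax=35.0,
        lw_a=0.00375,
        lw_b=3.082,
        ed_window=(91, 273),
        respiration_form=RespirationForm.TEMPERATURE_DOME,
    ),
}


def get_species_params(species: Species | str) -> SpeciesParams:
    """Packaged default parameter set for a species."""
    return DEFAULT_SPECIES[Species(species)]


# ---------------------------------------------------------------------------
# Plain-text config serialization
# ---------------------------------------------------------------------------

_SCALAR_FIELDS = (
    "feeding_start",
    "feeding_end",
    "swimming_speed",
    "RA",
    "beta",
    "rho",
    "topt",
    "tmax",
    "act",
    "theta",
    "epsilon",
    "omega",
    "lmax",
    "lw_a",
    "lw_b",
    "oxycal",
)


def save_params(
    path: str | Path,
    species_params: Mapping[Species, SpeciesParams] | None = None,
    prey_energy: PreyEnergyTable | None = None,
) -> None:
    """Serialize parameter sets to a plain ``key: value`` text config.

    Float values are written with ``repr`` so that a load/save round trip is
    bit-exact.
    """
    species_params = species_params or DEFAULT_SPECIES
    prey_energy = prey_energy or PreyEnergyTable()
    lines: list[str] = ["# planktivore parameter config"]
    for sp, p in species_params.items():
        prefix = sp.value
        lines.append(f"{prefix}.respiration_form: {p.respiration_form.value}")
        lines.append(f"{prefix}.length_range: {p.length_range[0]!r}, {p.length_range[1]!r}")
        lines.append(f"{prefix}.ed_window: {p.ed_window[0]}, {p.ed_window[1]}")
        for name in _SCALAR_FIELDS:
            v = getattr(p, name)
            if v is None:
                continue
            lines.append(f"{prefix}.{name}: {v!r}")
    for group in PREY_GROUPS:
        lines.append(f"prey_energy.{group}: {prey_energy[group]!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_params(
    path: str | Path,
) -> tuple[dict[Species, SpeciesParams], PreyEnergyTable]:
    """Load species parameters and the prey energy table from a text config."""
    raw: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key: value', got {line!r}")
        key, _, value = line.partition(":")
        raw[key.strip()] = value.strip()

    species_out: dict[Species, SpeciesParams] = {}
    for sp in Species:
        prefix = f"{sp.value}."
        entries = {k[len(prefix):]: v for k, v in raw.items() if k.startswith(prefix)}
        if not entries:
            continue
        lr = tuple(float(x) for x in entries.pop("length_range").split(","))
        ed = tuple(int(float(x)) for x in entries.pop("ed_window").split(","))
        form = RespirationForm(entries.pop("respiration_form"))
        kwargs: dict = {}
        for name, v in entries.items():
            if name not in _SCALAR_FIELDS:
                raise ValueError(f"unknown parameter {prefix}{name}")
            kwargs[name] = (
                int(v) if name in ("feeding_start", "feeding_end") else float(v)
            )
        species_out[sp] = SpeciesParams(
            species=sp,
            length_range=lr,  # type: ignore[arg-type]
            ed_window=ed,  # type: ignore[arg-type]
            respiration_form=form,
            **kwargs,
        )

    prey = {
        k.split(".", 1)[1]: float(v)
        for k, v in raw.items()
        if k.startswith("prey_energy.")
    }
    prey_table = PreyEnergyTable(prey) if prey else PreyEnergyTable()
    return species_out, prey_table
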