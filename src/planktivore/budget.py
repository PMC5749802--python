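"""Daily energy budget: respiration, growth energy and the consumption solve.

The Wisconsin-type balance C = R + F + E + S + G is solved in closed form
each day.  With egestion F = theta*C, excretion E = eps*(C - F) and specific
dynamic action S = omega*(C - F), consumption is

    C = (R + G) / D,   D = 1 - theta - (eps + omega)(1 - theta),

all in Joules per fish per day.  Respiration converts a specific oxygen
consumption rate to energy with the oxycalorific coefficient; growth energy
is the day-over-day change in total body energy (weight times seasonal
energy density, or muscle-plus-liver energy for the gadoid blue whiting).
Days on which the body-energy drawdown exceeds respiration are floored at
zero consumption (a fish cannot eat negative mass); the flooring count is
logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diet import DietComposition, daily_diet_matrix
from .growth import GrowthSplit, WeightTrajectory
from .species import (
    DEFAULT_LIVER,
    LIVER_T0_DOY,
    LiverModelParams,
    PreyEnergyTable,
    RespirationForm,
    Species,
    SpeciesParams,
    liver_energy,
    predator_energy_density,
)
from .temperature import daily_temperature_series

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DailyBudget:
    """One day's energy budget for a single fish (J fish^-1 day^-1)."""

    t: int
    weight: float
    C: float
    R: float
    F: float
    E: float
    S: float
    G: float
    specific_C: float  # g prey per g fish per day
    prey_grams: dict[str, float] = field(default_factory=dict)


@dataclass
class LengthCohort:
    """A 1 cm length class with its abundance and growth branches."""

    length_group: int
    abundance: float
    split: GrowthSplit
    traj_lower: WeightTrajectory
    traj_upper: WeightTrajectory


def thornton_lessem_exponent(rho: float, tmax: float, topt: float) -> float:
    """Shape exponent x of the temperature dome.

    x = Z^2 (1 + sqrt(1 + 40/Y))^2 / 400 with Z = ln(rho)(Tmax - Topt) and
    Y = ln(rho)(Tmax - Topt + 2).
    """
    z = math.log(rho) * (tmax - topt)
    y = math.log(rho) * (tmax - topt + 2.0)
    return z**2 * (1.0 + math.sqrt(1.0 + 40.0 / y)) ** 2 / 400.0


def respiration(params: SpeciesParams, weight: float, at: float) -> float:
    """Respiration cost in J per fish per day.

    The specific rate RA * W^beta (g O2 g^-1 day^-1) is modulated by an
    exponential temperature/swimming-speed factor for mackerel and herring,
    or by a temperature dome with optimum Topt and lethal limit Tmax times
    the Winberg activity multiplier for blue whiting.  The activity
    multiplier scales linearly with relative swimming speed, so faster
    cruising raises metabolic cost for all three species.
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    specific = params.RA * weight**params.beta
    if params.respiration_form is RespirationForm.EXPONENTIAL:
        factor = math.exp(params.rho * at) * math.exp(params.topt * params.swimming_speed)
    else:
        assert params.tmax is not None and params.act is not None
        if at >= params.tmax:
            raise ValueError(
                f"ambient temperature {at} degC >= lethal Tmax {params.tmax}"
            )
        v = (params.tmax - at) / (params.tmax - params.topt)
        x = thornton_lessem_exponent(params.rho, params.tmax, params.topt)
        factor = v**x * math.exp(x * (1.0 - v)) * params.act * params.swimming_speed
    return specific * factor * weight * params.oxycal


def _temperature_factor_series(params: SpeciesParams, at: np.ndarray) -> np.ndarray:
    if params.respiration_form is RespirationForm.EXPONENTIAL:
        return np.exp(params.rho * at) * math.exp(params.topt * params.swimming_speed)
    if (at >= params.tmax).any():
        raise ValueError(f"ambient temperature reaches lethal Tmax {params.tmax}")
    v = (params.tmax - at) / (params.tmax - params.topt)
    x = thornton_lessem_exponent(params.rho, params.tmax, params.topt)
    return v**x * np.exp(x * (1.0 - v)) * params.act * params.swimming_speed


def growth_energy(
    params: SpeciesParams,
    trajectory: WeightTrajectory,
    t: int,
    liver: LiverModelParams = DEFAULT_LIVER,
) -> float:
    """Growth energy G (J fish^-1 day^-1) at day ``t``: E(t) - E(t-1).

    Total body energy is weight times the seasonal energy density for
    mackerel/herring; for blue whiting it is muscle energy plus total liver
    energy.  May be negative early or late in the season (energy drawdown);
    the consumption solve floors the combined R + G at zero.
    """
    t0, t1 = trajectory.window
    if not (t0 < t <= t1):
        raise ValueError(f"day {t} (and {t - 1}) must lie inside window {t0}-{t1}")
    return _total_energy(params, trajectory, t, liver) - _total_energy(
        params, trajectory, t - 1, liver
    )


def _total_energy(params, trajectory, t, liver):
    w = trajectory(t)
    if params.species is Species.BLUE_WHITING:
        t_rel = max(t - LIVER_T0_DOY, 0.0)
        return w * liver.muscle_ed + liver_energy(w, t_rel, liver)
    return w * predator_energy_density(params, t)


def solve_daily_consumption(
    r_j: float, g_j: float, params: SpeciesParams
) -> dict[str, float]:
    """Closed-form solve of C = R + F + E + S + G, all in J fish^-1 day^-1.

    G is floored at -R so consumption is never negative; the returned budget
    restores the identity with the (possibly floored) G.
    """
    d = params.waste_denominator
    if d <= 0:
        raise ValueError("waste denominator must be positive")
    g_eff = max(g_j, -r_j)
    c = (r_j + g_eff) / d
    f = params.theta * c
    e = params.epsilon * (c - f)
    s = params.omega * (c - f)
    return {"C": c, "R": r_j, "F": f, "E": e, "S": s, "G": g_eff}


def run_cohort(
    cohort: LengthCohort,
    at_may: float,
    at_july: float,
    diet_may: DietComposition,
    diet_july: DietComposition,
    params: SpeciesParams,
    prey_ed: PreyEnergyTable,
    liver: LiverModelParams = DEFAULT_LIVER,
) -> dict[str, pd.DataFrame]:
    """Daily budgets for both growth branches of a cohort.

    The simulation runs with daily steps over the feeding window; day t's
    growth energy is the body-energy change from t-1 to t, so budgets are
    produced for days feeding_start+1 .. feeding_end.  Each day the solved
    consumption energy is allocated to prey-group grams with that day's
    interpolated diet.  Returns per-branch frames with one row per day and
    columns t, weight, C, R, F, E, S, G, specific_C, floored, plus one
    gram column per prey group; abundances are NOT applied here (see
    :mod:`planktivore.reporting`).
    """
    out: dict[str, pd.DataFrame] = {}
    for branch, traj in (("lower", cohort.traj_lower), ("upper", cohort.traj_upper)):
        out[branch] = _run_branch(
            traj, at_may, at_july, diet_may, diet_july, params, prey_ed, liver
        )
    return out


def _run_branch(
    traj: WeightTrajectory,
    at_may: float,
    at_july: float,
    diet_may: DietComposition,
    diet_july: DietComposition,
    params: SpeciesParams,
    prey_ed: PreyEnergyTable,
    liver: LiverModelParams,
) -> pd.DataFrame:
    t0, t1 = traj.window
    days = np.arange(t0 + 1, t1 + 1)
    all_days = np.arange(t0, t1 + 1)
    weights = traj(all_days.astype(float))
    if (weights <= 0).any():
        raise ValueError("non-positive weight in trajectory")

    # Total body energy on every day of the window, vectorized per species.
    if params.species is Species.BLUE_WHITING:
        t_rel = np.maximum(all_days - LIVER_T0_DOY, 0.0)
        liv = np.array(
            [liver_energy(w, tr, liver) for w, tr in zip(weights, t_rel)]
        )
        energy = weights * liver.muscle_ed + liv
    else:
        ed = np.array([predator_energy_density(params, float(t)) for t in all_days])
        energy = weights * ed

    g = np.diff(energy)
    w_t = weights[1:]
    at = daily_temperature_series(at_may, at_july, days)
    r = params.RA * w_t**params.beta * _temperature_factor_series(params, at) * w_t * params.oxycal

    g_eff = np.maximum(g, -r)
    floored = g_eff > g + 1e-12
    n_floor = int(floored.sum())
    if n_floor:
        log.info(
            "%s group %d +%d cm: consumption floored at 0 on %d day(s)",
            params.species.value,
            traj.length_group,
            traj.dg,
            n_floor,
        )
    d = params.waste_denominator
    c = (r + g_eff) / d
    f = params.theta * c
    e = params.epsilon * (c - f)
    s = params.omega * (c - f)

    diet = daily_diet_matrix(diet_may, diet_july, days)  # (n_days, n_groups)
    mean_ed = diet @ prey_ed.as_array()
    total_grams = c / mean_ed
    prey_grams = diet * total_grams[:, None]

    frame = pd.DataFrame(
        {
            "t": days,
            "weight": w_t,
            "C": c,
            "R": r,
            "F": f,
            "E": e,
            "S": s,
            "G": g_eff,
            "specific_C": total_grams / w_t,
            "floored": floored,
        }
    )
    from .species import PREY_GROUPS

    for j, grp in enumerate(PREY_GROUPS):
        frame[f"grams_{grp}"] = prey_grams[:, j]
    return frame
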