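"""Seasonal weight-at-day fits, length increments and cohort trajectories.

Somatic growth over the feeding season combines two observations: weight at
a fixed length rises through the season (condition), captured by quadratic
weight-at-day fits per 1 cm length group pooled across years; and fish grow
in length, captured by a length-increment model dL = k (Lmax - Ls), a
time-free variant of von Bertalanffy growth in which the annual increment
shrinks linearly to zero at Lmax.  Because the simulated population lives on
an integer-cm grid, a fractional increment dL is split between the two
bracketing integer increments with convex weights, and each branch gets its
own quadratic daily weight trajectory through three anchor points.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class FitError(ValueError):
    """Weight-at-day fit is infeasible (too few points or singular design)."""


@dataclass(frozen=True)
class WeightAtDayFit:
    """Quadratic weight-at-day model W(t) = a t^2 + b t + c for one length group."""

    length_group: int
    a: float
    b: float
    c: float
    n: int = 0
    residual_sd: float = float("nan")
    #: OLS standard errors of (a, b, c); NaN when the fit is exact/degenerate.
    coef_se: tuple[float, float, float] = (float("nan"),) * 3

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = self.a * t**2 + self.b * t + self.c
        return float(out) if out.ndim == 0 else out

    @property
    def coefficients(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)


@dataclass(frozen=True)
class GrowthSplit:
    """Convex split of a fractional annual length increment dL.

    ``dg_lower``/``dg_upper`` are the bracketing integer cm increments and
    ``rdl_lower``/``rdl_upper`` the population fractions assigned to each,
    chosen so the expected increment equals dL exactly.
    """

    dl: float
    dg_lower: int
    dg_upper: int
    rdl_lower: float
    rdl_upper: float


@dataclass(frozen=True)
class WeightTrajectory:
    """Daily weight of a growth branch over the feeding window.

    A quadratic through the branch's three anchor points: the start-of-window
    weight of the origin group, the end-of-window weight of the destination
    group (origin + dG), and a midpoint equidistant from both groups' own
    seasonal curves.
    """

    length_group: int
    dg: int
    a: float
    b: float
    c: float
    window: tuple[int, int]

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = self.a * t**2 + self.b * t + self.c
        return float(out) if out.ndim == 0 else out


def fit_weight_at_day(
    samples: pd.DataFrame,
    length_group: int,
    window: tuple[int, int] | None = None,
) -> WeightAtDayFit:
    """OLS quadratic of weight on day-of-year for one 1 cm length group.

    ``samples`` has columns doy, length_group (or length_cm), weight_g;
    samples are pooled across years.  Requires at least 3 points on at least
    3 distinct days inside the window.
    """
    df = samples
    if "length_group" not in df.columns:
        df = df.assign(length_group=np.floor(df["length_cm"]).astype(int))
    df = df[df["length_group"] == length_group]
    if window is not None:
        df = df[(df["doy"] >= window[0]) & (df["doy"] <= window[1])]
    t = df["doy"].to_numpy(dtype=float)
    w = df["weight_g"].to_numpy(dtype=float)
    if len(t) < 3 or np.unique(t).size < 3:
        raise FitError(
            f"length group {length_group}: need >= 3 samples on >= 3 distinct "
            f"days, got n={len(t)} on {np.unique(t).size} days"
        )
    coeffs = np.polyfit(t, w, 2)
    resid = w - np.polyval(coeffs, t)
    dof = max(len(t) - 3, 1)
    resid_var = (resid**2).sum() / dof
    design = np.vander(t, 3)
    try:
        cov = resid_var * np.linalg.inv(design.T @ design)
        se = tuple(float(s) for s in np.sqrt(np.diag(cov)))
    except np.linalg.LinAlgError:  # pragma: no cover - guarded by checks above
        se = (float("nan"),) * 3
    return WeightAtDayFit(
        length_group=length_group,
        a=float(coeffs[0]),
        b=float(coeffs[1]),
        c=float(coeffs[2]),
        n=len(t),
        residual_sd=float(np.sqrt(resid_var)),
        coef_se=se,
    )


def estimate_k(
    winter_lengths: pd.DataFrame,
    lmax: float,
) -> dict[int, float]:
    """Annual growth coefficient k from winter mean length-at-age.

    For each age group with mean lengths in consecutive winters,
    k_age = (L[x+1, age+1] - L[x, age]) / (Lmax - L[x, age]); the returned k
    for winter-year x is the unweighted mean over age groups.  Age groups at
    or above Lmax are skipped with a warning.  ``winter_lengths`` has columns
    year, age, mean_length_cm.
    """
    tbl = winter_lengths.set_index(["year", "age"])["mean_length_cm"]
    years = sorted(winter_lengths["year"].unique())
    out: dict[int, float] = {}
    for x in years:
        ks = []
        for (yr, age), ls in tbl.items():
            if yr != x:
                continue
            key = (x + 1, age + 1)
            if key not in tbl.index:
                continue
            if ls >= lmax:
                log.warning(
                    "estimate_k: year %d age %d mean length %.2f >= Lmax %.1f; "
                    "skipped",
                    x,
                    age,
                    ls,
                    lmax,
                )
                continue
            ks.append((tbl[key] - ls) / (lmax - ls))
        if ks:
            out[int(x)] = float(np.mean(ks))
    if not out:
        raise ValueError("no consecutive-winter age pairs below Lmax; cannot estimate k")
    return out


def annual_increment(k: float, length: float, lmax: float) -> float:
    """Annual length increment dL = k (Lmax - L), floored at zero above Lmax."""
    return max(k * (lmax - length), 0.0)


def split_growth(dl: float) -> GrowthSplit:
    """Split a fractional increment dL across the bracketing integer increments.

    The unique convex split whose expected increment equals dL: the fraction
    ``dl - floor(dl)`` of the cohort takes the upper integer increment and
    the rest the lower.  For dL = 1.3 this assigns 70% to +1 cm and 30% to
    +2 cm; an integer dL puts all mass on that increment.
    """
    if dl < 0:
        raise ValueError(f"dL must be >= 0, got {dl}")
    dg_lower = math.floor(dl)
    dg_upper = math.ceil(dl)
    rdl_upper = dl - dg_lower
    rdl_lower = 1.0 - rdl_upper
    if dg_lower == dg_upper:  # integer increment
        rdl_lower, rdl_upper = 1.0, 0.0
    return GrowthSplit(
        dl=dl,
        dg_lower=dg_lower,
        dg_upper=dg_upper,
        rdl_lower=rdl_lower,
        rdl_upper=rdl_upper,
    )


def window_midpoint(window: tuple[int, int]) -> int:
    """Midpoint day of a feeding window, half-days rounded up.

    For the herring window (91, 258) this is day 175.
    """
    return math.floor((window[0] + window[1]) / 2 + 0.5)


def build_weight_trajectory(
    length_group: int,
    dg: int,
    fits: Mapping[int, WeightAtDayFit],
    window: tuple[int, int],
) -> WeightTrajectory:
    """Quadratic daily weight for a cohort branch growing by ``dg`` cm.

    The trajectory interpolates three points: (t_start, W_L(t_start)) on the
    origin group's curve, (t_end, W_{L+dG}(t_end)) on the destination
    group's curve, and the window midpoint at the average of the two groups'
    curves there (equidistant from both).
    """
    if length_group not in fits:
        raise KeyError(f"no weight-at-day fit for length group {length_group}")
    if length_group + dg not in fits:
        raise KeyError(f"no weight-at-day fit for length group {length_group + dg}")
    t0, t1 = window
    tm = window_midpoint(window)
    w_lo = fits[length_group]
    w_hi = fits[length_group + dg]
    ts = np.array([t0, tm, t1], dtype=float)
    ws = np.array([w_lo(t0), 0.5 * (w_lo(tm) + w_hi(tm)), w_hi(t1)])
    coeffs = np.polyfit(ts, ws, 2)
    traj = WeightTrajectory(
        length_group=length_group,
        dg=dg,
        a=float(coeffs[0]),
        b=float(coeffs[1]),
        c=float(coeffs[2]),
        window=window,
    )
    days = np.arange(t0, t1 + 1)
    wdays = traj(days)
    if (np.diff(wdays) < 0).any():
        log.info(
            "trajectory for group %d +%d cm is not monotone over the window",
            length_group,
            dg,
        )
    if (wdays <= 0).any():
        raise ValueError(
            f"trajectory for group {length_group} +{dg} cm has non-positive "
            "weight inside the window"
        )
    return traj


#: Default modal length group (cm) per species for the feeding-window
#: diagnostic: the most frequent length group in the survey samples.
DEFAULT_MODAL_LENGTH = {"mackerel": 34, "herring": 32, "blue_whiting": 26}


def feeding_window_diagnostic(
    samples: pd.DataFrame,
    modal_length: int,
    bin_days: int = 15,
) -> pd.DataFrame:
    """Mean weight in 15-day bins for the modal length group.

    Advisory only: the feeding windows used by the model are fixed printed
    constants; this table lets a user eyeball when weight-at-length starts
    and stops increasing.  Returns columns bin_start_doy, mean_weight_g, n;
    empty bins are absent.
    """
    df = samples
    if "length_group" not in df.columns:
        df = df.assign(length_group=np.floor(df["length_cm"]).astype(int))
    df = df[df["length_group"] == modal_length]
    if df.empty:
        return pd.DataFrame(columns=["bin_start_doy", "mean_weight_g", "n"])
    bins = ((df["doy"] - 1) // bin_days * bin_days + 1).astype(int)
    out = (
        df.assign(bin_start_doy=bins)
        .groupby("bin_start_doy")["weight_g"]
        .agg(mean_weight_g="mean", n="size")
        .reset_index()
    )
    if len(out) < 2:
        log.warning("feeding_window_diagnostic: samples span fewer than 2 bins")
    return out
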