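"""Fish-density-weighted ambient temperature from co-gridded survey fields.

The ambient temperature a stock experiences is estimated by weighting CTD
temperatures, averaged onto a 1deg x 1deg grid with 10 m depth bins, by the
fish density observed in the same (cell, depth) bins: acoustic backscatter
(SA) for herring and blue whiting, or surface-trawl CPUE at a fixed depth for
mackerel.  Two survey snapshots (May and July) anchor a plateau-linear-plateau
daily interpolation over the feeding season.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Day-of-year breakpoints of the May->July interpolation (1 June, 1 July).
INTERP_START_DOY = 152
INTERP_END_DOY = 182


class EmptyIntersectionError(ValueError):
    """Temperature and density fields share no usable (cell, depth) pairs."""


class ZeroWeightError(ValueError):
    """Total density weight is zero; weighted temperature is undefined."""


@dataclass
class GriddedField:
    """Values on (grid cell, depth bin) coordinates for one survey period.

    ``data`` has columns ``cell_id``, ``depth_mid_m`` and ``value``.  Depth
    bins are 10 m wide with midpoints 5, 15, 25, ...  ``kind`` is
    ``"temperature"`` (degC), ``"sa"`` (acoustic backscatter) or ``"cpue"``
    (kg m^-2, mackerel surface trawls).
    """

    period: str  # "May" or "July"
    kind: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"cell_id", "depth_mid_m", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"GriddedField missing columns {sorted(missing)}")
        mids = np.asarray(self.data["depth_mid_m"], dtype=float)
        if not np.allclose((mids - 5.0) % 10.0, 0.0):
            raise ValueError("depth bin midpoints must be 5, 15, 25, ... m")
        if self.kind in ("sa", "cpue") and (self.data["value"] < 0).any():
            raise ValueError("density values must be >= 0")
        dup = self.data.duplicated(["cell_id", "depth_mid_m"])
        if self.kind != "temperature" and dup.any():
            raise ValueError("each (cell, depth) may appear at most once")

    @classmethod
    def from_csv(cls, path: str | Path, kind: str, period: str | None = None):
        """Read a field from CSV with columns period, cell_id, depth_mid_m, value."""
        df = pd.read_csv(path, comment="#")
        if period is not None and "period" in df.columns:
            df = df[df["period"] == period]
        per = period if period is not None else str(df["period"].iloc[0])
        return cls(period=per, kind=kind, data=df.reset_index(drop=True))

    def mean_by_bin(self) -> pd.DataFrame:
        """Per-(cell, depth) mean; several profiles in a cell are averaged."""
        return (
            self.data.groupby(["cell_id", "depth_mid_m"], as_index=False)["value"]
            .mean()
        )


def ambient_temperature(
    temps: GriddedField,
    density: GriddedField,
    fixed_depth_m: float | None = None,
) -> float:
    """Density-weighted mean temperature over matched (cell, depth) bins.

    Parameters
    ----------
    temps, density
        Co-gridded temperature and fish-density fields for the same period.
    fixed_depth_m
        Mackerel (CPUE) mode: the density field is two-dimensional (one value
        per cell) and is paired with the temperature of the depth bin whose
        midpoint is nearest to this fixed depth (ties resolve to the
        shallower bin).  ``None`` (default) matches bins directly, the
        acoustic mode.

    Returns the convex combination sum(T * w) / sum(w); bins present in only
    one field are dropped with a logged count.
    """
    if temps.period != density.period:
        raise ValueError(
            f"period mismatch: temperatures {temps.period!r} vs density "
            f"{density.period!r}"
        )
    t = temps.mean_by_bin().rename(columns={"value": "temp"})
    d = density.mean_by_bin().rename(columns={"value": "w"})

    if fixed_depth_m is not None:
        mids = np.sort(t["depth_mid_m"].unique())
        if mids.size == 0:
            raise EmptyIntersectionError("temperature field is empty")
        # nearest midpoint to the fixed depth, ties to the shallower bin
        target = mids[np.lexsort((mids, np.abs(mids - fixed_depth_m)))[0]]
        t = t[t["depth_mid_m"] == target]
        d = d.groupby("cell_id", as_index=False)["w"].sum()
        merged = t.merge(d, on="cell_id", how="outer", indicator=True)
    else:
        merged = t.merge(d, on=["cell_id", "depth_mid_m"], how="outer", indicator=True)

    unmatched = int((merged["_merge"] != "both").sum())
    if unmatched:
        log.info(
            "ambient_temperature: dropped %d (cell, depth) pairs present in "
            "only one field",
            unmatched,
        )
    both = merged[merged["_merge"] == "both"]
    if both.empty:
        raise EmptyIntersectionError(
            "temperature and density fields have no (cell, depth) overlap"
        )
    wsum = float(both["w"].sum())
    if wsum <= 0.0:
        raise ZeroWeightError("total density weight is zero")
    return float((both["temp"] * both["w"]).sum() / wsum)


def daily_temperature(at_may: float, at_july: float, t: float) -> float:
    """Daily ambient temperature from the May and July survey estimates.

    The May value applies before 1 June (day 152), the July value after
    1 July (day 182), with a linear ramp in between.
    """
    if t <= INTERP_START_DOY:
        return float(at_may)
    if t >= INTERP_END_DOY:
        return float(at_july)
    frac = (t - INTERP_START_DOY) / (INTERP_END_DOY - INTERP_START_DOY)
    return float(at_may + (at_july - at_may) * frac)


def daily_temperature_series(at_may: float, at_july: float, days: np.ndarray) -> np.ndarray:
    """Vectorized :func:`daily_temperature` over an array of days."""
    days = np.asarray(days, dtype=float)
    frac = np.clip((days - INTERP_START_DOY) / (INTERP_END_DOY - INTERP_START_DOY), 0, 1)
    return at_may + (at_july - at_may) * frac
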