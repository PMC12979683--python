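"""Survey-table preparation: gillnet effort, seasons, age classes, CPUE,
and interpolation of point environmental observations onto the estuary grid.

Effort follows the gillnet convention of *yard-minutes*: soak duration in
minutes times net area in square yards.  Age classes for this species are
length-based: males under 1.34 m and females under 1.38 m stretch total
length (STL) are age-0; anything above 1.86 m is older than age-1 and is
excluded from the juvenile analysis.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

YARDS_PER_METRE = 1.09361

#: STL (m) at or below which a fish counts as juvenile (age-0 or age-1)
JUVENILE_MAX_STL = 1.86
#: age-0 upper STL bounds (strict) by sex
AGE0_MAX_STL = {"M": 1.34, "F": 1.38}
SPRING_SUMMER_MONTHS = frozenset(range(3, 9))  # March-August


def compute_effort(
    start_time: dt.datetime,
    end_time: dt.datetime,
    net_length_m: float,
    net_height_m: float,
) -> float:
    """Soak effort in yard-minutes: minutes x net area (square yards)."""
    minutes = (end_time - start_time).total_seconds() / 60.0
    if minutes <= 0:
        raise ValueError("soak duration must be positive")
    if net_length_m <= 0 or net_height_m <= 0:
        raise ValueError("net dimensions must be positive")
    area_yd2 = (net_length_m * YARDS_PER_METRE) * (net_height_m * YARDS_PER_METRE)
    return minutes * area_yd2


def assign_season(date) -> str:
    """'Spring/Summer' for March-August sampling, otherwise 'Fall/Winter'."""
    month = pd.Timestamp(date).month
    return "Spring/Summer" if month in SPRING_SUMMER_MONTHS else "Fall/Winter"


def filter_juveniles(fish: pd.DataFrame, stl_col: str = "stl_m") -> pd.DataFrame:
    """Keep fish of 1.86 m STL or less (approximate age-0/age-1 classes).

    Records with missing STL are dropped with a warning.
    """
    missing = fish[stl_col].isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} fish with missing STL excluded")
    kept = fish[~missing]
    return kept[kept[stl_col] <= JUVENILE_MAX_STL]


def assign_age_class(stl_m: float, sex: str, unknown_sex_cutoff: float = 1.36) -> str:
    """Length/sex age rule: 'age0', 'age1' or 'older'.

    Males under 1.34 m and females under 1.38 m are age-0; fish above
    1.86 m are older than age-1; the remainder are age-1.  Fish of
    unknown sex use a configurable midpoint cutoff (default 1.36 m).
    """
    if stl_m <= 0:
        raise ValueError("STL must be positive")
    if stl_m > JUVENILE_MAX_STL:
        return "older"
    if sex in AGE0_MAX_STL:
        cutoff = AGE0_MAX_STL[sex]
    else:
        log.info("unknown sex; midpoint age-0 cutoff %.2f m applied", unknown_sex_cutoff)
        cutoff = unknown_sex_cutoff
    return "age0" if stl_m < cutoff else "age1"


def cpue(
    catch: pd.Series | np.ndarray,
    effort: pd.Series | np.ndarray,
    by: pd.DataFrame | pd.Series | None = None,
) -> pd.Series | float:
    """Catch per 10^6 yard-minutes, optionally per group.

    Empty groups report 0 catch over their recorded effort rather than NA.
    """
    catch = np.asarray(catch, dtype=float)
    effort = np.asarray(effort, dtype=float)
    if by is None:
        tot = effort.sum()
        if tot <= 0:
            raise ValueError("total effort must be positive")
        return float(catch.sum() / tot * 1e6)
    df = pd.DataFrame({"catch": catch, "effort": effort})
    if isinstance(by, pd.Series):
        by = by.to_frame()
    keys = list(by.columns)
    df = pd.concat([df, by.reset_index(drop=True)], axis=1)
    g = df.groupby(keys, observed=True).sum(numeric_only=True)
    if (g["effort"] <= 0).any():
        raise ValueError("group with non-positive effort")
    return g["catch"] / g["effort"] * 1e6


@dataclass
class OrdinaryKriging:
    """Ordinary kriging with an exponential variogram.

    gamma(h) = nugget + sill * (1 - exp(-h / range_)).  With zero nugget
    the predictor interpolates the data exactly.  This stands in for
    proprietary geostatistical interpolators; the analysis only needs a
    smooth daily covariate surface honouring the observations.
    """

    range_: float = 2000.0
    sill: float = 1.0
    nugget: float = 0.0

    def _gamma(self, h):
        return self.nugget + self.sill * (1.0 - np.exp(-h / self.range_))

    def __call__(self, obs_xy: np.ndarray, obs_val: np.ndarray,
                 pred_xy: np.ndarray) -> np.ndarray:
        obs_xy = np.asarray(obs_xy, float)
        obs_val = np.asarray(obs_val, float)
        pred_xy = np.asarray(pred_xy, float)
        n = len(obs_xy)
        d_oo = np.linalg.norm(obs_xy[:, None, :] - obs_xy[None, :, :], axis=-1)
        a = np.empty((n + 1, n + 1))
        a[:n, :n] = self._gamma(d_oo)
        np.fill_diagonal(a[:n, :n], 0.0)
        a[n, :n] = 1.0
        a[:n, n] = 1.0
        a[n, n] = 0.0
        d_po = np.linalg.norm(pred_xy[:, None, :] - obs_xy[None, :, :], axis=-1)
        b = np.empty((n + 1, len(pred_xy)))
        b[:n] = self._gamma(d_po).T
        b[n] = 1.0
        try:
            w = np.linalg.solve(a, b)
        except np.linalg.LinAlgError:
            return idw(obs_xy, obs_val, pred_xy)
        return w[:n].T @ obs_val


def idw(obs_xy, obs_val, pred_xy, power: float = 2.0) -> np.ndarray:
    """Inverse-distance-weighted fallback interpolator."""
    obs_xy = np.asarray(obs_xy, float)
    obs_val = np.asarray(obs_val, float)
    pred_xy = np.asarray(pred_xy, float)
    d = np.linalg.norm(pred_xy[:, None, :] - obs_xy[None, :, :], axis=-1)
    out = np.empty(len(pred_xy))
    exact = d < 1e-9
    has_exact = exact.any(axis=1)
    w = 1.0 / np.maximum(d, 1e-9) ** power
    out = (w * obs_val).sum(axis=1) / w.sum(axis=1)
    if has_exact.any():
        idx = np.argmax(exact[has_exact], axis=1)
        out[has_exact] = obs_val[idx]
    return out


def daily_means(obs: pd.DataFrame, value_col: str,
                loc_cols=("x", "y"), date_col: str = "date") -> pd.DataFrame:
    """Average sub-daily observations at each location by day."""
    keys = [date_col, *loc_cols]
    return obs.groupby(keys, as_index=False)[value_col].mean()


def interpolate_environment(
    obs: pd.DataFrame,
    grid_xy: np.ndarray,
    value_col: str,
    date_col: str = "date",
    interpolator=None,
    min_points: int = 3,
) -> pd.DataFrame:
    """Interpolate per-day point observations onto grid-cell centres.

    Sub-daily records are averaged per location per day first.  Days with
    fewer than ``min_points`` observations fall back to the mean field of
    all observations in the table (season-mean surrogate), logged.

    Returns a long table (date, cell, value).
    """
    if interpolator is None:
        interpolator = OrdinaryKriging()
    obs = daily_means(obs, value_col, date_col=date_col)
    frames = []
    fallback = None
    for date, day in obs.groupby(date_col):
        xy = day[["x", "y"]].to_numpy()
        vals = day[value_col].to_numpy()
        if len(day) < min_points:
            log.warning("%s: %d points < %d; season-mean fallback", date, len(day), min_points)
            if fallback is None:
                all_xy = obs[["x", "y"]].to_numpy()
                all_v = obs[value_col].to_numpy()
                fallback = interpolator(all_xy, all_v, grid_xy)
            field = fallback
        else:
            field = interpolator(xy, vals, grid_xy)
        frames.append(pd.DataFrame({
            date_col: date, "cell": np.arange(len(grid_xy)), value_col: field,
        }))
    return pd.concat(frames, ignore_index=True)
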