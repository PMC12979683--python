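"""Posterior-simulation abundance estimation and trend testing.

The fitted density model is extrapolated over a prediction grid: the
sampling microgrids clipped to within 61 m of the shoreline with cells
deeper than 3 m removed (the working depth of the gillnets).  Each
cell's *soak area* is its clipped polygon area, playing the role of
effort in the offset.  Coefficient uncertainty is propagated by
sampling the model posterior (1000 draws by default); each draw yields
a total abundance per year and season, for the sampled domain (cells
that ever held a survey set) and the full domain.  Draws orders of
magnitude above the median — projections into poorly sampled parameter
space — are trimmed before variance estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import DensityGAMResults
from .scene import EstuaryScene

log = logging.getLogger(__name__)

SQYD_PER_SQM = 1.19599
SEASONS = ("Spring/Summer", "Fall/Winter")


@dataclass
class PredictionGrid:
    """Shore-clipped, depth-limited prediction cells with soak areas."""

    cells: pd.DataFrame  # microgrid_id, x, y, soak_area_yd2, in_sampling_universe, ...

    def __post_init__(self):
        if self.cells.empty:
            raise ValueError("empty prediction grid")
        if (self.cells["soak_area_yd2"] <= 0).any():
            raise ValueError("non-positive soak area")

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def build_prediction_grid(
    scene: EstuaryScene,
    survey: pd.DataFrame | None = None,
    max_shore_dist_m: float = 61.0,
    max_depth_m: float = 3.0,
) -> PredictionGrid:
    """Clip microgrids to <= 61 m from shore, drop depths > 3 m.

    The depth rule removes cells strictly deeper than the limit (a cell
    at exactly 3 m is retained).  ``in_sampling_universe`` flags cells
    whose microgrid ever held a survey set.
    """
    buffer = scene.shoreline.buffer(max_shore_dist_m)
    rows = []
    sampled_ids = set()
    if survey is not None and len(survey):
        sampled_ids = set(survey["microgrid_id"].astype(int))
    for _, cell in scene.cells.iterrows():
        if cell["depth_min_m"] > max_depth_m:
            continue
        poly = scene.microgrids[int(cell["microgrid_id"])]
        clipped = poly.intersection(buffer)
        if clipped.is_empty or clipped.area <= 0:
            continue
        rows.append({
            "microgrid_id": int(cell["microgrid_id"]),
            "x": cell["x"], "y": cell["y"],
            "depth_min_m": cell["depth_min_m"],
            "sum_mnn": cell["sum_mnn"], "min_mdts": cell["min_mdts"],
            "river": cell["river"], "dist_to_rm_m": cell["dist_to_rm_m"],
            "developed_sl": int(cell["developed_sl"]),
            "area_m2": clipped.area,
            "soak_area_yd2": clipped.area * SQYD_PER_SQM,
            "in_sampling_universe": int(cell["microgrid_id"]) in sampled_ids,
            # row position in scene.cells (== microgrid_id by construction),
            # used to index environmental fields
            "cell_index": int(cell.name),
        })
    if not rows:
        raise ValueError("prediction grid is empty after clipping")
    return PredictionGrid(pd.DataFrame(rows))


@dataclass
class AbundanceDraws:
    """Total-abundance realizations by (draw, year, season, domain).

    ``totals`` has shape (n_draws, n_years, 2 seasons, 2 domains) with
    domain 0 = sampled, 1 = full; ``retained`` is the post-trim mask of
    the same shape.
    """

    totals: np.ndarray
    years: list
    seasons: tuple = SEASONS
    domains: tuple = ("sampled", "full")
    trim_factor: float = 100.0
    retained: np.ndarray | None = None

    def __post_init__(self):
        if self.retained is None:
            self.retained = self._trim_mask()

    def _trim_mask(self) -> np.ndarray:
        keep = np.isfinite(self.totals) & (self.totals > 0)
        if not np.isfinite(self.trim_factor):
            return keep
        med = np.nanmedian(np.where(keep, self.totals, np.nan), axis=0,
                           keepdims=True)
        return keep & (self.totals <= self.trim_factor * med)

    def summary(self) -> pd.DataFrame:
        """Median/mean +/- SD and range of retained draws per stratum."""
        rows = []
        for yi, year in enumerate(self.years):
            for si, season in enumerate(self.seasons):
                for di, domain in enumerate(self.domains):
                    v = self.totals[:, yi, si, di]
                    v = v[self.retained[:, yi, si, di]]
                    if len(v) == 0:
                        raise ValueError("all draws trimmed: degenerate fit")
                    rows.append({
                        "year": year, "season": season, "domain": domain,
                        "median": float(np.median(v)),
                        "mean": float(np.mean(v)),
                        "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
                        "lo": float(v.min()), "hi": float(v.max()),
                        "q025": float(np.quantile(v, 0.025)),
                        "q975": float(np.quantile(v, 0.975)),
                        "n_draws": int(len(v)),
                    })
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        """Long (draw, year, season, domain, total, retained) table."""
        n, ny, ns, nd = self.totals.shape
        idx = np.indices((n, ny, ns, nd)).reshape(4, -1)
        return pd.DataFrame({
            "draw": idx[0],
            "year": np.asarray(self.years)[idx[1]],
            "season": np.asarray(self.seasons)[idx[2]],
            "domain": np.asarray(self.domains)[idx[3]],
            "total": self.totals.ravel(),
            "retained": self.retained.ravel(),
        })


def estimate_abundance(
    result: DensityGAMResults,
    draws: np.ndarray,
    grid: PredictionGrid,
    env,
    years,
    seasons=SEASONS,
    trim_factor: float = 100.0,
    every_days: int = 7,
) -> AbundanceDraws:
    """Totals per posterior draw, year and season over both domains.

    Cell-level density uses season-averaged environmental fields; the
    soak-area offset converts density to expected individuals per cell,
    summed over the sampled and full domains.
    """
    cells = grid.cells
    sampled = cells["in_sampling_universe"].to_numpy(bool)
    soak = cells["soak_area_yd2"].to_numpy()
    years = list(years)
    totals = np.empty((len(draws), len(years), len(seasons), 2))
    for yi, year in enumerate(years):
        for si, season in enumerate(seasons):
            mean_env = env.season_mean(year, season, every_days=every_days)
            frame = cells.copy()
            for v in ("avg_temp", "avg_do", "avg_salin", "avg_ph"):
                frame[v] = mean_env.loc[cells["cell_index"], v].to_numpy()
            frame["year"] = year
            frame["season"] = season
            eta = result.linear_predictor(frame, params=draws)  # (ncell, ndraw)
            mu = soak[:, None] * np.exp(eta)
            totals[:, yi, si, 1] = mu.sum(axis=0)
            totals[:, yi, si, 0] = mu[sampled].sum(axis=0)
    return AbundanceDraws(totals, years, tuple(seasons), trim_factor=trim_factor)


def compare_years(
    ab: AbundanceDraws, season: str = "Spring/Summer", domain: str = "sampled",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA across years on draw-level totals, Tukey HSD, and a
    compact letter display (years sharing a letter are indistinguishable).
    """
    si = list(ab.seasons).index(season)
    di = list(ab.domains).index(domain)
    groups, labels = [], []
    for yi, year in enumerate(ab.years):
        v = ab.totals[:, yi, si, di][ab.retained[:, yi, si, di]]
        if len(v) >= 2:
            groups.append(v)
            labels.append(year)
    if len(groups) < 2:
        return pd.DataFrame({"year": labels, "letters": ["a"] * len(labels)})
    f_stat, p = stats.f_oneway(*groups)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(groups)
    keys = np.concatenate([[str(l)] * len(g) for l, g in zip(labels, groups)])
    tukey = pairwise_tukeyhsd(values, keys, alpha=alpha)
    res = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
    different = {
        frozenset((str(r["group1"]), str(r["group2"])))
        for _, r in res.iterrows() if bool(r["reject"])
    }
    letters = _compact_letters([str(l) for l in labels],
                               [float(np.mean(g)) for g in groups], different)
    return pd.DataFrame({
        "year": labels,
        "mean": [float(np.mean(g)) for g in groups],
        "letters": [letters[str(l)] for l in labels],
        "anova_F": f_stat, "anova_p": p,
    })


def _compact_letters(groups, means, different) -> dict:
    """Greedy compact letter display in mean order."""
    order = [g for _, g in sorted(zip(means, groups))]
    classes: list[set] = []
    for g in order:
        placed = False
        for cls in classes:
            if all(frozenset((g, other)) not in different for other in cls):
                cls.add(g)
                placed = True
        if not placed:
            classes.append({g})
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for i, cls in enumerate(classes):
        for g in cls:
            out[g] += alphabet[i % len(alphabet)]
    return out


def interannual_change(yearly_medians) -> dict:
    """Year-over-year abundance ratios N_{t+1} / N_t and their summary."""
    v = np.asarray(list(yearly_medians), float)
    if len(v) < 2:
        raise ValueError("need at least two years")
    if np.any(v <= 0):
        raise ValueError("non-positive yearly median")
    ratios = v[1:] / v[:-1]
    return {
        "ratios": ratios,
        "mean": float(ratios.mean()),
        "sd": float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0,
        "range": (float(ratios.min()), float(ratios.max())),
    }
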