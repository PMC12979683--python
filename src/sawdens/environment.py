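"""Daily synthetic environmental fields over the estuary.

Temperature, dissolved oxygen, salinity and pH are generated per water
cell and day as a deterministic seasonal + spatial mean surface plus
spatially correlated noise, clipped to configurable physical envelopes
(defaults follow the observed ranges in the study system: temperature
14.7-35.8 degC, DO 0.4-11.9 mg/L, salinity 0.1-35.9).  Salinity falls
monotonically upriver (fresh at the river head, marine at the mouth).

Fields are computed lazily and deterministically per day: the generator
for day *d* is seeded by (base seed, day ordinal), so any date can be
reproduced without storing the whole series.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .scene import EstuaryScene

VARIABLES = ("avg_temp", "avg_do", "avg_salin", "avg_ph")


@dataclass
class EnvConfig:
    """Amplitudes and envelopes of the synthetic environmental fields."""

    temp_mean: float = 25.5
    temp_amp: float = 7.0  # seasonal semi-amplitude, degC
    temp_noise: float = 1.0
    do_base: float = 8.6
    do_temp_slope: float = -0.12  # mg/L per degC above 20
    do_noise: float = 0.7
    salin_mouth: float = 33.0
    salin_gradient: float = 28.0  # drop from mouth to river head
    salin_noise: float = 1.0
    ph_base: float = 7.9
    ph_noise: float = 0.05
    noise_smooth_cells: float = 2.0
    clip: dict = field(default_factory=lambda: {
        "avg_temp": (14.7, 35.8),
        "avg_do": (0.4, 11.9),
        "avg_salin": (0.1, 35.9),
        "avg_ph": (6.8, 8.8),
    })


class EnvFieldSeries:
    """Lazy per-day environmental fields on the scene's water cells."""

    def __init__(self, scene: EstuaryScene, config: EnvConfig | None = None,
                 seed: int = 0, epoch: dt.date = dt.date(2010, 1, 1)):
        self.scene = scene
        self.config = config or EnvConfig()
        self.seed = int(seed)
        self.epoch = epoch
        cells = scene.cells
        self._dist_up = np.clip(cells["dist_to_rm_m"].to_numpy(), 0.0, None)
        self._river_len = max(self._dist_up.max(), 1.0)
        self._rowcol = cells[["row", "col"]].to_numpy()
        self._grid_shape = (scene.config.ny, scene.config.nx)
        self._cache: dict = {}

    def _correlated_noise(self, rng, sd: float) -> np.ndarray:
        """Spatially correlated cell noise with marginal SD ``sd``."""
        if sd == 0:
            return np.zeros(len(self._rowcol))
        z = rng.standard_normal(self._grid_shape)
        z = ndimage.gaussian_filter(z, sigma=self.config.noise_smooth_cells)
        z = z / max(z.std(), 1e-12) * sd
        return z[self._rowcol[:, 0], self._rowcol[:, 1]]

    def fields(self, date) -> pd.DataFrame:
        """Per-cell temperature, DO, salinity and pH for one day."""
        date = pd.Timestamp(date).date()
        if date < self.epoch:
            raise ValueError(f"date {date} precedes scene epoch {self.epoch}")
        if date in self._cache:
            return self._cache[date]
        cfg = self.config
        doy = date.timetuple().tm_yday
        seasonal = np.cos(2.0 * np.pi * (doy - 213) / 365.25)  # peak early Aug
        rng = np.random.default_rng([self.seed, 17, date.toordinal()])
        upfrac = self._dist_up / self._river_len

        temp = (
            cfg.temp_mean + cfg.temp_amp * seasonal
            + 0.5 * upfrac
            + rng.normal(0.0, 0.3)  # estuary-wide daily anomaly
            + self._correlated_noise(rng, cfg.temp_noise)
        )
        do = (
            cfg.do_base + cfg.do_temp_slope * (temp - 20.0)
            - 0.6 * upfrac
            + self._correlated_noise(rng, cfg.do_noise)
        )
        salin = (
            cfg.salin_mouth
            - cfg.salin_gradient * upfrac
            - 1.5 * seasonal  # fresher in the wet season
            + self._correlated_noise(rng, cfg.salin_noise)
        )
        ph = (
            cfg.ph_base + 0.1 * seasonal - 0.15 * upfrac
            + self._correlated_noise(rng, cfg.ph_noise)
        )
        out = pd.DataFrame({
            "avg_temp": np.clip(temp, *cfg.clip["avg_temp"]),
            "avg_do": np.clip(do, *cfg.clip["avg_do"]),
            "avg_salin": np.clip(salin, *cfg.clip["avg_salin"]),
            "avg_ph": np.clip(ph, *cfg.clip["avg_ph"]),
        })
        if len(self._cache) < 64:
            self._cache[date] = out
        return out

    def season_mean(self, year: int, season: str, every_days: int = 7) -> pd.DataFrame:
        """Per-cell mean field over the season, sampled every few days.

        Seasons follow the sampling convention: Spring/Summer is
        March-August, Fall/Winter the remaining months of that year.
        """
        if season == "Spring/Summer":
            start, end = dt.date(year, 3, 1), dt.date(year, 8, 31)
            dates = pd.date_range(start, end, freq=f"{every_days}D")
        else:
            d1 = pd.date_range(dt.date(year, 1, 1), dt.date(year, 2, 28),
                               freq=f"{every_days}D")
            d2 = pd.date_range(dt.date(year, 9, 1), dt.date(year, 12, 31),
                               freq=f"{every_days}D")
            dates = d1.append(d2)
        dates = [d for d in dates if d.date() >= self.epoch]
        if not dates:
            raise ValueError("season precedes scene epoch")
        acc = None
        for d in dates:
            f = self.fields(d)
            acc = f if acc is None else acc + f
        return acc / len(dates)
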