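"""Habitat covariate construction from imagery and bathymetry.

Implements the mangrove-mapping chain: supervised maximum-likelihood
classification of multiband shoreline imagery with per-pixel class
priors (down-weighting mangroves in urban areas), Euclidean distance
from mangrove cells to the shoreline within a 10 m buffer, focal sums of
mangrove presence over an 8 x 8 neighbourhood (values 1..64), and zonal
statistics of those rasters onto 200-m sampling microgrids.

Rasters are plain numpy arrays with an affine georeference: cell
centres, row-major, origin at the upper-left corner, metres in a
projected plane.  NaN is the null value.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import shapely


@dataclass
class Raster:
    """Single- or multi-band raster; ``data`` is (H, W) or (bands, H, W)."""

    data: np.ndarray
    x0: float = 0.0  # x of the upper-left corner
    y0: float = 0.0  # y of the upper-left corner
    cell: float = 1.0  # pixel size, metres

    @property
    def shape(self):
        return self.data.shape[-2:]

    def cell_centers(self):
        """(H, W) arrays of pixel-centre x and y."""
        h, w = self.shape
        xs = self.x0 + (np.arange(w) + 0.5) * self.cell
        ys = self.y0 - (np.arange(h) + 0.5) * self.cell
        return np.meshgrid(xs, ys)

    def write_tiff(self, path):
        """Write as TIFF with a JSON georeference sidecar."""
        import tifffile

        tifffile.imwrite(str(path), np.asarray(self.data))
        with open(str(path) + ".json", "w") as fh:
            json.dump({"x0": self.x0, "y0": self.y0, "cell": self.cell}, fh)

    @classmethod
    def read_tiff(cls, path):
        import tifffile

        data = tifffile.imread(str(path))
        try:
            with open(str(path) + ".json") as fh:
                geo = json.load(fh)
        except FileNotFoundError:
            geo = {"x0": 0.0, "y0": 0.0, "cell": 1.0}
        return cls(data, **geo)


CLASS_LABELS = ("mangrove", "other_vegetation", "non_vegetation")


@dataclass
class ClassSignature:
    """Spectral signature of one land-cover class."""

    label: str
    mean: np.ndarray
    cov: np.ndarray
    n: int

    def __post_init__(self):
        self.mean = np.asarray(self.mean, float)
        self.cov = np.asarray(self.cov, float)
        if self.cov.shape != (len(self.mean), len(self.mean)):
            raise ValueError("covariance shape does not match mean")


def train_signatures(
    image: Raster,
    points: np.ndarray,
    labels: np.ndarray,
    ridge_rel: float = 1e-6,
) -> list[ClassSignature]:
    """Per-class band means and covariances at labelled training points.

    ``points`` are (n, 2) projected coordinates; band values are sampled
    at the enclosing pixel.  A degenerate (singular) class covariance is
    regularized by adding ``ridge_rel * trace / n_bands`` to the diagonal
    (with an absolute floor when the trace itself is zero), with a warning.
    """
    data = image.data if image.data.ndim == 3 else image.data[None]
    nbands, h, w = data.shape
    points = np.asarray(points, float)
    cols = ((points[:, 0] - image.x0) / image.cell).astype(int)
    rows = ((image.y0 - points[:, 1]) / image.cell).astype(int)
    if (cols < 0).any() or (cols >= w).any() or (rows < 0).any() or (rows >= h).any():
        raise ValueError("training point outside image extent")
    values = data[:, rows, cols].T  # (n, bands)
    sigs = []
    for label in np.unique(labels):
        sel = values[np.asarray(labels) == label]
        if len(sel) < nbands + 1:
            raise ValueError(f"class {label!r}: need >= bands+1 training points")
        mean = sel.mean(axis=0)
        cov = np.cov(sel, rowvar=False)
        cov = np.atleast_2d(cov)
        # regularize if singular
        if np.linalg.matrix_rank(cov) < nbands:
            ridge = ridge_rel * max(np.trace(cov) / nbands, 1.0)
            warnings.warn(f"class {label!r}: singular covariance; ridge {ridge:g} added")
            cov = cov + ridge * np.eye(nbands)
        sigs.append(ClassSignature(str(label), mean, cov, len(sel)))
    return sigs


def uniform_priors(shape) -> np.ndarray:
    """Equal a-priori class probabilities everywhere; (3, H, W)."""
    return np.full((len(CLASS_LABELS), *shape), 1.0 / len(CLASS_LABELS))


def urban_priors(urban_mask: np.ndarray, mangrove_prior: float = 0.02) -> np.ndarray:
    """Priors with the mangrove probability reduced in urban pixels.

    Urban pixels get ``mangrove_prior`` (default 2%) for mangrove while
    the other two classes split the remaining probability equally;
    non-urban pixels keep equal priors.
    """
    pri = uniform_priors(urban_mask.shape)
    rest = (1.0 - mangrove_prior) / 2.0
    pri[0][urban_mask] = mangrove_prior
    pri[1][urban_mask] = rest
    pri[2][urban_mask] = rest
    return pri


def classify_mlc(
    image: Raster,
    signatures: list[ClassSignature],
    priors: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel maximum-likelihood classification with a-priori weights.

    Each pixel is assigned argmax_c [ log N(x; mu_c, cov_c) + log prior_c ].
    Returns ``(class_index_raster, mangrove_mask)`` where the mangrove
    mask is the binary set-null product: True where classified mangrove.
    """
    order = {s.label: i for i, s in enumerate(signatures)}
    if set(order) != set(CLASS_LABELS):
        raise ValueError(f"signatures must cover classes {CLASS_LABELS}")
    sigs = sorted(signatures, key=lambda s: CLASS_LABELS.index(s.label))
    data = image.data if image.data.ndim == 3 else image.data[None]
    nbands, h, w = data.shape
    if priors is None:
        priors = uniform_priors((h, w))
    priors = np.asarray(priors, float)
    if np.any(priors.sum(axis=0) <= 0):
        raise ValueError("pixel with all-zero priors")
    x = data.reshape(nbands, -1).T  # (npix, bands)
    scores = np.empty((len(sigs), h * w))
    for i, sig in enumerate(sigs):
        diff = x - sig.mean
        cov_inv = np.linalg.inv(sig.cov)
        _, logdet = np.linalg.slogdet(sig.cov)
        maha = np.einsum("ij,jk,ik->i", diff, cov_inv, diff)
        loglik = -0.5 * (maha + logdet + nbands * np.log(2 * np.pi))
        with np.errstate(divide="ignore"):
            scores[i] = loglik + np.log(priors[i].ravel())
    classes = scores.argmax(axis=0).reshape(h, w)
    return classes, classes == 0


def mangrove_distance_to_shore(
    mangrove: Raster,
    shoreline,
    buffer_m: float = 10.0,
) -> Raster:
    """Euclidean distance (m) from mangrove cell centres to the shoreline.

    Only mangrove cells whose centre lies within ``buffer_m`` of the
    shoreline get a value; everything else is NaN (null).
    """
    if shoreline is None or shapely.is_empty(shoreline):
        raise ValueError("empty shoreline")
    mask = np.asarray(mangrove.data, bool)
    xs, ys = mangrove.cell_centers()
    out = np.full(mask.shape, np.nan)
    rows, cols = np.nonzero(mask)
    if len(rows):
        pts = shapely.points(xs[rows, cols], ys[rows, cols])
        d = shapely.distance(pts, shoreline)
        keep = d <= buffer_m
        out[rows[keep], cols[keep]] = d[keep]
    return Raster(out, mangrove.x0, mangrove.y0, mangrove.cell)


def mangrove_focal_sum(mangrove: Raster) -> Raster:
    """Count of mangrove cells in each mangrove cell's 8 x 8 neighbourhood.

    The even window is anchored with the focal cell at (row 4, col 4) of
    the window, i.e. rows -4..+3 and cols -4..+3 around the focal cell;
    cells beyond the raster edge count as non-mangrove.  Mangrove cells
    carry values in [1, 64]; non-mangrove cells are NaN.
    """
    mask = np.asarray(mangrove.data, bool).astype(np.int64)
    h, w = mask.shape
    # integral image: S[i, j] = sum of mask[:i, :j]
    s = np.zeros((h + 1, w + 1), dtype=np.int64)
    s[1:, 1:] = mask.cumsum(0).cumsum(1)
    i = np.arange(h)[:, None]
    j = np.arange(w)[None, :]
    r0 = np.clip(i - 4, 0, h)
    r1 = np.clip(i + 4, 0, h)
    c0 = np.clip(j - 4, 0, w)
    c1 = np.clip(j + 4, 0, w)
    r0 = np.broadcast_to(r0, (h, w))
    r1 = np.broadcast_to(r1, (h, w))
    c0 = np.broadcast_to(c0, (h, w))
    c1 = np.broadcast_to(c1, (h, w))
    counts = s[r1, c1] - s[r0, c1] - s[r1, c0] + s[r0, c0]
    out = np.where(mask.astype(bool), counts.astype(float), np.nan)
    return Raster(out, mangrove.x0, mangrove.y0, mangrove.cell)


def zonal_stats(
    microgrids,
    distance: Raster,
    focal: Raster,
    depth: Raster | None = None,
):
    """Per-microgrid habitat covariates.

    For each polygon: ``min_mdts`` = minimum mangrove distance-to-shore
    (NaN if the grid holds no mangrove), ``sum_mnn`` = sum of focal-sum
    values (0 if none: no mangrove habitat), and optionally ``min_depth``.
    Pixels belong to the polygon containing their centre.
    """
    import pandas as pd

    xs, ys = distance.cell_centers()
    rows = []
    for gid, poly in enumerate(microgrids):
        minx, miny, maxx, maxy = poly.bounds
        c0 = max(int(np.floor((minx - distance.x0) / distance.cell)), 0)
        c1 = min(int(np.ceil((maxx - distance.x0) / distance.cell)), distance.shape[1])
        r0 = max(int(np.floor((distance.y0 - maxy) / distance.cell)), 0)
        r1 = min(int(np.ceil((distance.y0 - miny) / distance.cell)), distance.shape[0])
        if c1 <= c0 or r1 <= r0:
            rows.append((gid, np.nan, 0.0, np.nan))
            continue
        sub_x = xs[r0:r1, c0:c1]
        sub_y = ys[r0:r1, c0:c1]
        inside = shapely.contains_xy(poly, sub_x.ravel(), sub_y.ravel()).reshape(sub_x.shape)
        d = distance.data[r0:r1, c0:c1][inside]
        f = focal.data[r0:r1, c0:c1][inside]
        min_mdts = np.nanmin(d) if np.isfinite(d).any() else np.nan
        sum_mnn = np.nansum(f) if f.size else 0.0
        if depth is not None:
            dd = depth.data[r0:r1, c0:c1][inside]
            min_depth = np.nanmin(dd) if np.isfinite(dd).any() else np.nan
        else:
            min_depth = np.nan
        rows.append((gid, float(min_mdts), float(sum_mnn), float(min_depth)))
    return pd.DataFrame(rows, columns=["microgrid_id", "min_mdts", "sum_mnn", "min_depth"])
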