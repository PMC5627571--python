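"""Spatial interpolation of diversity measures by ordinary kriging.

Point-wise diversity values (per-site singleton proportions, expected
heterozygosities) are interpolated onto a regular lon/lat grid with
ordinary kriging under a fitted exponential variogram.  Distances are
great-circle (in km) for extents above 5 degrees and Euclidean (in degrees)
below, unless forced by the ``great_circle`` flag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

logger = logging.getLogger(__name__)

__all__ = [
    "VariogramModel",
    "DiversitySurface",
    "fit_variogram",
    "krige",
    "kriging_weights",
    "render_surface",
    "surface_correlation",
]

_EARTH_RADIUS_KM = 6371.0


def great_circle_distance(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Haversine distance in kilometres (inputs in degrees)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def _auto_great_circle(lons, lats, flag) -> bool:
    if flag is not None:
        return bool(flag)
    extent = max(np.ptp(lons), np.ptp(lats))
    return extent > 5.0


def _distance_matrix(lons, lats, use_gc: bool) -> np.ndarray:
    if use_gc:
        return great_circle_distance(
            lons[:, None], lats[:, None], lons[None, :], lats[None, :]
        )
    pts = np.column_stack([lons, lats])
    return squareform(pdist(pts))


@dataclass
class VariogramModel:
    """Exponential variogram: gamma(h) = nugget + sill * (1 - exp(-h/range))."""

    nugget: float
    sill: float
    range_: float
    family: str = "exponential"
    great_circle: bool = False

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.sill < 0 or self.range_ <= 0:
            raise ValueError("variogram parameters out of range")

    def semivariance(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        g = self.nugget + self.sill * (1.0 - np.exp(-h / self.range_))
        return np.where(h == 0, 0.0, g)

    def covariance(self, h: np.ndarray) -> np.ndarray:
        """Covariance counterpart C(h) = nugget + sill - gamma(h)."""
        h = np.asarray(h, dtype=float)
        c = self.sill * np.exp(-h / self.range_)
        return np.where(h == 0, c + self.nugget, c)


@dataclass
class DiversitySurface:
    """Interpolated values on a regular lon/lat grid (row 0 = north)."""

    lons: np.ndarray  # cell-centre longitudes, ascending
    lats: np.ndarray  # cell-centre latitudes, descending (row order)
    values: np.ndarray
    mask: np.ndarray  # True = cell outside the region (no value)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.lats), len(self.lons)):
            raise ValueError("surface shape mismatch")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape mismatch")
        self.values = np.where(self.mask, np.nan, self.values)


def fit_variogram(
    lons: np.ndarray,
    lats: np.ndarray,
    values: np.ndarray,
    n_bins: int = 12,
    great_circle: bool | None = None,
) -> VariogramModel:
    """Fit an exponential variogram by weighted least squares.

    The empirical semivariogram is binned by pair distance; the model is
    fitted with weights equal to the bin pair counts.  A constant field
    yields a pure-nugget (zero sill) model with a warning.
    """
    lons = np.asarray(lons, float)
    lats = np.asarray(lats, float)
    values = np.asarray(values, float)
    if len(values) < 10:
        raise ValueError("need at least 10 points to fit a variogram")
    use_gc = _auto_great_circle(lons, lats, great_circle)
    D = _distance_matrix(lons, lats, use_gc)
    iu = np.triu_indices(len(values), k=1)
    h = D[iu]
    if np.ptp(h) == 0:
        raise ValueError("degenerate point configuration")
    gam = 0.5 * (values[iu[0]] - values[iu[1]]) ** 2
    if np.allclose(values, values[0]):
        warnings.warn("constant field: returning a pure-nugget variogram")
        return VariogramModel(0.0, 0.0, float(h.max()), great_circle=use_gc)
    edges = np.linspace(0, h.max() * 1.0001, n_bins + 1)
    which = np.digitize(h, edges) - 1
    hb, gb, wb = [], [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() > 0:
            hb.append(h[sel].mean())
            gb.append(gam[sel].mean())
            wb.append(sel.sum())
    hb, gb, wb = map(np.asarray, (hb, gb, wb))

    var = values.var()
    x0 = np.array([1e-6, max(var, 1e-12), max(h.max() / 3.0, 1e-9)])

    def resid(x):
        nug, sill, rng_ = np.abs(x)
        model = nug + sill * (1.0 - np.exp(-hb / max(rng_, 1e-12)))
        return np.sqrt(wb) * (model - gb)

    sol = least_squares(resid, x0, method="lm", max_nfev=10_000)
    nug, sill, rng_ = np.abs(sol.x)
    if sill <= 0:
        warnings.warn("fitted sill is zero: pure-nugget variogram")
    return VariogramModel(float(nug), float(sill), float(max(rng_, 1e-9)),
                          great_circle=use_gc)


def _dedupe(lons, lats, values):
    pts = np.column_stack([lons, lats])
    uniq, inv = np.unique(pts, axis=0, return_inverse=True)
    if len(uniq) == len(pts):
        return lons, lats, values
    logger.info("krige: averaged %d duplicate points", len(pts) - len(uniq))
    vals = np.zeros(len(uniq))
    for k in range(len(uniq)):
        vals[k] = values[inv == k].mean()
    return uniq[:, 0], uniq[:, 1], vals


def kriging_weights(
    lons, lats, variogram: VariogramModel, tlon, tlat
) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary-kriging weights for target points.

    Returns ``(weights, lagrange)`` with ``weights`` of shape
    ``(n_targets, n_points)``; rows sum to 1 by the unbiasedness constraint.
    """
    lons = np.asarray(lons, float)
    lats = np.asarray(lats, float)
    tlon = np.atleast_1d(np.asarray(tlon, float))
    tlat = np.atleast_1d(np.asarray(tlat, float))
    m = len(lons)
    D = _distance_matrix(lons, lats, variogram.great_circle)
    A = np.empty((m + 1, m + 1))
    A[:m, :m] = variogram.covariance(D)
    A[m, :m] = 1.0
    A[:m, m] = 1.0
    A[m, m] = 0.0
    if variogram.nugget == 0 and variogram.sill == 0:
        A[:m, :m] += 1e-12 * np.eye(m)
    if variogram.great_circle:
        d0 = great_circle_distance(
            tlon[:, None], tlat[:, None], lons[None, :], lats[None, :]
        )
    else:
        d0 = np.sqrt(
            (tlon[:, None] - lons[None, :]) ** 2
            + (tlat[:, None] - lats[None, :]) ** 2
        )
    B = np.empty((m + 1, len(tlon)))
    B[:m] = variogram.covariance(d0).T
    B[m] = 1.0
    try:
        sol = np.linalg.solve(A, B)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(A, B, rcond=None)[0]
    return sol[:m].T, sol[m]


def krige(
    lons,
    lats,
    values,
    variogram: VariogramModel,
    grid_lons: np.ndarray,
    grid_lats: np.ndarray,
    mask: np.ndarray | None = None,
) -> DiversitySurface:
    """Ordinary kriging of point values onto a regular grid.

    ``grid_lons`` ascending and ``grid_lats`` descending (row 0 = north);
    ``mask`` marks cells outside the region of interest.  Duplicate data
    points are averaged first.  With a zero nugget the prediction at a data
    location reproduces the data value.
    """
    lons, lats, values = _dedupe(
        np.asarray(lons, float), np.asarray(lats, float), np.asarray(values, float)
    )
    grid_lons = np.asarray(grid_lons, float)
    grid_lats = np.asarray(grid_lats, float)
    if mask is None:
        mask = np.zeros((len(grid_lats), len(grid_lons)), dtype=bool)
    glon, glat = np.meshgrid(grid_lons, grid_lats)
    tsel = ~mask.ravel()
    W, _ = kriging_weights(lons, lats, variogram, glon.ravel()[tsel],
                           glat.ravel()[tsel])
    out = np.full(glon.size, np.nan)
    out[tsel] = W @ values
    return DiversitySurface(grid_lons, grid_lats, out.reshape(glon.shape), mask)


def render_surface(
    surface: DiversitySurface,
    path,
    points: tuple[np.ndarray, np.ndarray] | None = None,
    title: str | None = None,
) -> None:
    """Render a surface to an image file (optional convenience export)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    extent = (
        surface.lons[0], surface.lons[-1], surface.lats[-1], surface.lats[0]
    )
    im = ax.imshow(surface.values, extent=extent, origin="upper",
                   cmap="viridis")
    if points is not None:
        ax.plot(points[0], points[1], "k.", ms=3)
    if title:
        ax.set_title(title)
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def surface_correlation(a: DiversitySurface, b: DiversitySurface) -> float:
    """Pearson correlation of two surfaces over jointly unmasked cells."""
    if a.values.shape != b.values.shape:
        raise ValueError("surfaces have different grids")
    if not (np.allclose(a.lons, b.lons) and np.allclose(a.lats, b.lats)):
        raise ValueError("surfaces have different grids")
    ok = ~(a.mask | b.mask) & np.isfinite(a.values) & np.isfinite(b.values)
    if ok.sum() < 3:
        return float("nan")
    return float(pearsonr(a.values[ok], b.values[ok])[0])
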