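"""Fine-resolution accessibility surfaces.

The per-cell response times sampled on the 250 m analysis grid are
interpolated to a finer output grid (100 m by default) with ordinary
kriging, cleaned of isolated outliers with a focal-statistics rule, and
masked to populated cells. The kriging here uses a single fitted
variogram with a moving prediction neighborhood — an open, documented
approximation to the empirical Bayesian kriging of commercial GIS
packages, whose role in the workflow is simply smooth spatial prediction
of response times. An inverse-distance-weighting (IDW) fallback is
available for robustness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .grids import GridSpec, PopulationGrid, resample_population
from .travel_time import ResponseField


class NumericalDegeneracyError(RuntimeError):
    """Coincident samples with conflicting values, or a singular kriging system."""


@dataclass
class InterpConfig:
    """Interpolation settings.

    method:
        "kriging" (ordinary kriging, default) or "idw".
    variogram:
        "exponential" or "linear"; fit to the empirical semivariogram.
    nugget:
        Micro-scale variance; 0 makes the predictor exact at sample points.
    n_neighbors:
        Size of the moving prediction neighborhood.
    drift:
        "none" or "linear"; with "linear" a least-squares plane is removed
        before kriging and added back (trend-aware configuration).
    clip_to_sample_range:
        Clamp predictions into [min(z), max(z)]; keeps response times at or
        above the dispatch floor despite negative kriging weights.
    """

    method: str = "kriging"
    variogram: str = "exponential"
    nugget: float = 0.0
    n_neighbors: int = 16
    drift: str = "none"
    idw_power: float = 2.0
    max_pairs: int = 2000
    n_lags: int = 15
    clip_to_sample_range: bool = True


@dataclass
class AccessSurface:
    """Response-time raster (minutes) for one period, with a validity mask."""

    grid: GridSpec
    period: str
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("surface values do not match grid shape")
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid.shape:
                raise ValueError("mask does not match grid shape")

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]


def surface_from_field(field_: ResponseField, period: str) -> AccessSurface:
    """View a response field directly as a surface on its own grid."""
    return AccessSurface(field_.grid, period, field_.as_raster(period))


# ---------------------------------------------------------------------------
# variogram + kriging


def _dedupe(xy: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    _, idx, inv = np.unique(xy, axis=0, return_index=True, return_inverse=True)
    if len(idx) != len(xy):
        for u in range(len(idx)):
            vals = z[inv == u]
            if np.ptp(vals) > 1e-9:
                raise NumericalDegeneracyError(
                    f"coincident samples at {xy[idx[u]]} carry conflicting values {vals}"
                )
        xy, z = xy[np.sort(idx)], z[np.sort(idx)]
    return xy, z


def _fit_variogram(xy: np.ndarray, z: np.ndarray, cfg: InterpConfig, rng: np.random.Generator):
    """Return gamma(h), a semivariogram function fitted to the samples."""
    n = len(xy)
    if n > cfg.max_pairs:
        sel = rng.choice(n, size=cfg.max_pairs, replace=False)
        xs, zs = xy[sel], z[sel]
    else:
        xs, zs = xy, z
    d = np.hypot(xs[:, 0:1] - xs[None, :, 0], xs[:, 1:2] - xs[None, :, 1])
    g = 0.5 * (zs[:, None] - zs[None, :]) ** 2
    iu = np.triu_indices(len(xs), k=1)
    d, g = d[iu], g[iu]
    h_max = d.max()
    bins = np.linspace(0, h_max / 2, cfg.n_lags + 1)
    which = np.digitize(d, bins) - 1
    h_emp, g_emp = [], []
    for b in range(cfg.n_lags):
        m = which == b
        if m.sum() >= 5:
            h_emp.append(d[m].mean())
            g_emp.append(g[m].mean())
    h_emp, g_emp = np.array(h_emp), np.array(g_emp)
    nug = cfg.nugget

    if cfg.variogram == "linear" or len(h_emp) < 3:
        slope = max(float(np.sum(h_emp * (g_emp - nug)) / np.sum(h_emp**2)), 1e-12)
        return lambda h: nug + slope * h

    def expo(h, sill, rng_):
        return nug + sill * (1.0 - np.exp(-3.0 * h / rng_))

    try:
        p0 = (max(g_emp.max() - nug, 1e-9), max(h_emp.max() / 2, 1e-6))
        popt, _ = curve_fit(
            expo, h_emp, g_emp, p0=p0, bounds=([1e-12, 1e-9], [np.inf, np.inf]), maxfev=5000
        )
        sill, vrange = popt
        return lambda h: expo(h, sill, vrange)
    except Exception:
        slope = max(float(np.sum(h_emp * (g_emp - nug)) / np.sum(h_emp**2)), 1e-12)
        return lambda h: nug + slope * h


def krige_points(
    xy: np.ndarray,
    z: np.ndarray,
    query_xy: np.ndarray,
    cfg: InterpConfig | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Ordinary kriging of scattered samples at arbitrary query points.

    Weights solve the standard unbiased system per query over the
    ``n_neighbors`` nearest samples; with a zero nugget the predictor
    honors the samples exactly. A fitted least-squares plane can be
    removed first (``drift="linear"``).
    """
    cfg = cfg or InterpConfig()
    xy = np.asarray(xy, float)
    z = np.asarray(z, float)
    query_xy = np.asarray(query_xy, float)
    xy, z = _dedupe(xy, z)
    if len(xy) < 10:
        raise ValueError(f"kriging needs at least 10 sample points, got {len(xy)}")
    rng = np.random.default_rng(seed)

    trend = np.zeros(len(query_xy))
    resid = z
    if cfg.drift == "linear":
        A = np.column_stack([np.ones(len(xy)), xy])
        coef, *_ = np.linalg.lstsq(A, z, rcond=None)
        resid = z - A @ coef
        trend = np.column_stack([np.ones(len(query_xy)), query_xy]) @ coef
    elif cfg.drift != "none":
        raise ValueError(f"unknown drift {cfg.drift!r}")

    if np.ptp(resid) < 1e-12:  # constant (or exactly planar) field
        return trend + resid[0]

    gamma = _fit_variogram(xy, resid, cfg, rng)
    k = min(cfg.n_neighbors, len(xy))
    tree = cKDTree(xy)
    d_q, idx = tree.query(query_xy, k=k)
    d_q = np.atleast_2d(d_q)
    idx = np.atleast_2d(idx)

    out = np.empty(len(query_xy))
    ones = np.ones(k)
    for i in range(len(query_xy)):
        nb = idx[i]
        pts = xy[nb]
        dmat = np.hypot(pts[:, 0:1] - pts[None, :, 0], pts[:, 1:2] - pts[None, :, 1])
        G = gamma(dmat)
        np.fill_diagonal(G, 0.0)
        A = np.empty((k + 1, k + 1))
        A[:k, :k] = G
        A[k, :k] = A[:k, k] = 1.0
        A[k, k] = 0.0
        b = np.empty(k + 1)
        b[:k] = gamma(d_q[i])
        b[k] = 1.0
        try:
            w = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            raise NumericalDegeneracyError(
                f"singular kriging system at query point {query_xy[i]}"
            ) from exc
        out[i] = w[:k] @ resid[nb]
    out += trend
    if cfg.clip_to_sample_range:
        out = np.clip(out, z.min(), z.max())
    return out


def idw_points(
    xy: np.ndarray, z: np.ndarray, query_xy: np.ndarray, cfg: InterpConfig | None = None
) -> np.ndarray:
    """Inverse-distance-weighted interpolation (exact at sample points)."""
    cfg = cfg or InterpConfig(method="idw")
    xy, z = _dedupe(np.asarray(xy, float), np.asarray(z, float))
    k = min(cfg.n_neighbors, len(xy))
    d, idx = cKDTree(xy).query(np.asarray(query_xy, float), k=k)
    d = np.atleast_2d(d)
    idx = np.atleast_2d(idx)
    out = np.empty(len(query_xy))
    exact = d[:, 0] < 1e-12
    out[exact] = z[idx[exact, 0]]
    rest = ~exact
    w = 1.0 / d[rest] ** cfg.idw_power
    out[rest] = (w * z[idx[rest]]).sum(axis=1) / w.sum(axis=1)
    return out


def interpolate_surface(
    field_: ResponseField,
    out_grid: GridSpec,
    period: str,
    cfg: InterpConfig | None = None,
    seed: int = 0,
) -> AccessSurface:
    """Interpolate one period of a response field onto ``out_grid``."""
    cfg = cfg or InterpConfig()
    xy = field_.grid.cell_centers_flat()
    z = field_.values[period]
    x0, y0, x1, y1 = field_.grid.extent
    ox0, oy0, ox1, oy1 = out_grid.extent
    if ox0 < x0 - field_.grid.cell_size or ox1 > x1 + field_.grid.cell_size:
        warnings.warn("output grid extends beyond the sample extent; edges are extrapolated")
    q = out_grid.cell_centers_flat()
    if cfg.method == "kriging":
        vals = krige_points(xy, z, q, cfg, seed=seed)
    elif cfg.method == "idw":
        vals = idw_points(xy, z, q, cfg)
    else:
        raise ValueError(f"unknown interpolation method {cfg.method!r}")
    return AccessSurface(out_grid, period, vals.reshape(out_grid.shape))


# ---------------------------------------------------------------------------
# focal outlier removal and population masking


def focal_clean(surface: AccessSurface, window: int = 3, z_thresh: float = 3.0) -> AccessSurface:
    """Replace focal outliers by their neighborhood mean.

    A valid cell whose value deviates from the mean of its (window x
    window) neighbors — the cell itself excluded — by more than
    ``z_thresh`` neighborhood standard deviations is replaced by that
    mean. All other cells are untouched, so the operation is idempotent on
    an already-clean surface.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    v = np.where(surface.mask, surface.values, 0.0)
    m = surface.mask.astype(float)
    kernel = np.ones((window, window))
    s1 = ndimage.convolve(v, kernel, mode="constant", cval=0.0)
    s2 = ndimage.convolve(v * v, kernel, mode="constant", cval=0.0)
    n = ndimage.convolve(m, kernel, mode="constant", cval=0.0)
    # exclude the center cell from its own neighborhood
    s1 = s1 - v
    s2 = s2 - v * v
    n = n - m
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / n
        var = np.clip(s2 / n - mean**2, 0.0, None)
        sd = np.sqrt(var)
        dev = np.abs(surface.values - mean)
        flag = surface.mask & (n >= 1) & (dev > z_thresh * sd)
    out = surface.values.copy()
    out[flag] = mean[flag]
    return AccessSurface(surface.grid, surface.period, out, surface.mask.copy())


def mask_populated(surface: AccessSurface, pop: PopulationGrid) -> AccessSurface:
    """Mask the surface to cells that hold population.

    The population raster is resampled to the surface grid with
    mass-conserving area weighting; cells receiving zero people are
    masked out.
    """
    pop_on = resample_population(pop, surface.grid)
    new_mask = surface.mask & (pop_on.values > 0)
    return AccessSurface(surface.grid, surface.period, surface.values.copy(), new_mask)
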