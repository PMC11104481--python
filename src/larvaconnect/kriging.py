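"""Ordinary kriging of site connectivity values onto a fine grid.

An exponential semivariogram (nugget, partial sill, range) is fitted to
the empirical semivariogram by weighted least squares (weights = pair
counts per lag bin), then the ordinary-kriging system is solved for
every grid node.  With a zero nugget the interpolator is exact at the
observation sites.  If the kriging system is singular the surface falls
back to inverse-distance weighting with a logged warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import xarray as xr
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist

from .grids import M_PER_DEG_LAT, meters_per_degree_lon

logger = logging.getLogger(__name__)

__all__ = [
    "VariogramModel",
    "fit_variogram",
    "empirical_semivariogram",
    "krige_surface",
    "krige_at_points",
]


@dataclass(frozen=True)
class VariogramModel:
    """Exponential semivariogram gamma(h) = nugget + sill*(1 - exp(-h/range))."""

    nugget: float
    sill: float  # partial sill
    range_m: float

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        g = self.nugget + self.sill * (1.0 - np.exp(-h / max(self.range_m, 1e-9)))
        return np.where(h == 0, 0.0, g)  # gamma(0) = 0 by definition


def _local_xy(lon, lat, lat_ref):
    x = np.asarray(lon, dtype=float) * meters_per_degree_lon(lat_ref)
    y = np.asarray(lat, dtype=float) * M_PER_DEG_LAT
    return np.column_stack([x, y])


def empirical_semivariogram(xy: np.ndarray, values: np.ndarray, n_bins: int = 10):
    """Binned empirical semivariogram: (lag centres, gamma, pair counts)."""
    d = cdist(xy, xy)
    iu = np.triu_indices_from(d, k=1)
    h = d[iu]
    sq = 0.5 * (values[:, None] - values[None, :]) ** 2
    g = sq[iu]
    hmax = h.max()
    edges = np.linspace(0, hmax * (1 + 1e-12), n_bins + 1)
    which = np.clip(np.digitize(h, edges) - 1, 0, n_bins - 1)
    lag, gamma, count = [], [], []
    for b in range(n_bins):
        m = which == b
        if m.any():
            lag.append(h[m].mean())
            gamma.append(g[m].mean())
            count.append(int(m.sum()))
    return np.array(lag), np.array(gamma), np.array(count)


def fit_variogram(xy: np.ndarray, values: np.ndarray, n_bins: int = 10, nugget: float | None = None) -> VariogramModel:
    """WLS fit of the exponential model to the empirical semivariogram.

    ``nugget`` may be pinned (e.g. 0 for an exact interpolator);
    otherwise it is estimated along with sill and range.
    """
    lag, gamma, count = empirical_semivariogram(xy, values, n_bins)
    if gamma.max() <= 0:
        # constant field: any model reproduces it; use a flat variogram
        return VariogramModel(0.0, 0.0, max(float(lag.max()), 1.0) if lag.size else 1.0)
    w = np.sqrt(count.astype(float))
    sill0 = float(gamma.max())
    range0 = float(lag.max() / 3) if lag.size else 1.0

    if nugget is None:
        def resid(p):
            n0, s, r = np.abs(p)
            m = n0 + s * (1 - np.exp(-lag / max(r, 1e-9)))
            return w * (m - gamma)

        fit = least_squares(resid, x0=[0.0, sill0, range0], max_nfev=2000)
        n0, s, r = np.abs(fit.x)
    else:
        def resid(p):
            s, r = np.abs(p)
            m = nugget + s * (1 - np.exp(-lag / max(r, 1e-9)))
            return w * (m - gamma)

        fit = least_squares(resid, x0=[sill0, range0], max_nfev=2000)
        s, r = np.abs(fit.x)
        n0 = nugget
    return VariogramModel(float(n0), float(s), float(max(r, 1e-6)))


def _idw(xy_obs, values, xy_pred, power: float = 2.0) -> np.ndarray:
    d = cdist(xy_pred, xy_obs)
    with np.errstate(divide="ignore"):
        w = 1.0 / d**power
    exact = d == 0
    w[np.any(exact, axis=1)] = exact[np.any(exact, axis=1)]
    w /= w.sum(axis=1, keepdims=True)
    return w @ values


def _ok_solve(xy_obs, vals, xy_pred, model: VariogramModel):
    """Solve the ordinary-kriging system; returns (predictions, method)."""
    n = vals.size
    K = np.empty((n + 1, n + 1))
    K[:n, :n] = model(cdist(xy_obs, xy_obs))  # gamma(0)=0 on the diagonal -> exact
    K[n, :n] = 1.0
    K[:n, n] = 1.0
    K[n, n] = 0.0
    rhs = np.empty((n + 1, xy_pred.shape[0]))
    rhs[:n] = model(cdist(xy_obs, xy_pred))
    rhs[n] = 1.0
    try:
        lam = np.linalg.solve(K, rhs)
        return lam[:n].T @ vals, "ordinary_kriging"
    except np.linalg.LinAlgError:
        msg = "kriging system singular; falling back to inverse-distance weighting"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=3)
        return _idw(xy_obs, vals, xy_pred), "idw_fallback"


def krige_at_points(
    site_lons,
    site_lats,
    site_values,
    pred_lons,
    pred_lats,
    variogram: VariogramModel | None = None,
    nugget: float | None = None,
    n_bins: int = 10,
) -> np.ndarray:
    """Ordinary-kriging predictions at arbitrary points (e.g. for
    leave-one-out cross-validation)."""
    lons = np.asarray(site_lons, dtype=float)
    lats = np.asarray(site_lats, dtype=float)
    vals = np.asarray(site_values, dtype=float)
    if vals.size < 4:
        raise ValueError("kriging needs at least 4 sites with finite values")
    lat_ref = float(np.mean(lats))
    xy_obs = _local_xy(lons, lats, lat_ref)
    xy_pred = _local_xy(np.atleast_1d(pred_lons), np.atleast_1d(pred_lats), lat_ref)
    if np.ptp(vals) == 0:
        return np.full(xy_pred.shape[0], vals[0])
    model = variogram or fit_variogram(xy_obs, vals, n_bins=n_bins, nugget=nugget)
    pred, _ = _ok_solve(xy_obs, vals, xy_pred, model)
    return pred


def krige_surface(
    site_lons,
    site_lats,
    site_values,
    extent: tuple[float, float, float, float] | None = None,
    resolution_deg: float = 0.01,
    variogram: VariogramModel | None = None,
    nugget: float | None = None,
    n_bins: int = 10,
) -> xr.DataArray:
    """Ordinary-kriging interpolation of site values onto a regular grid.

    ``extent`` is (lon_min, lon_max, lat_min, lat_max); defaults to the
    bounding box of the sites.  Requires at least 4 sites with finite
    values.  Returns a DataArray on cell centres with the fitted
    variogram in ``attrs``.
    """
    lons = np.asarray(site_lons, dtype=float)
    lats = np.asarray(site_lats, dtype=float)
    vals = np.asarray(site_values, dtype=float)
    ok = np.isfinite(vals)
    lons, lats, vals = lons[ok], lats[ok], vals[ok]
    if vals.size < 4:
        raise ValueError("kriging needs at least 4 sites with finite values")

    if extent is None:
        extent = (lons.min(), lons.max(), lats.min(), lats.max())
    lon_edges = np.arange(extent[0], extent[1] + 0.5 * resolution_deg, resolution_deg)
    lat_edges = np.arange(extent[2], extent[3] + 0.5 * resolution_deg, resolution_deg)
    lon_c = 0.5 * (lon_edges[:-1] + lon_edges[1:])
    lat_c = 0.5 * (lat_edges[:-1] + lat_edges[1:])
    LON, LAT = np.meshgrid(lon_c, lat_c)
    lat_ref = 0.5 * (extent[2] + extent[3])

    xy_obs = _local_xy(lons, lats, lat_ref)
    xy_pred = _local_xy(LON.ravel(), LAT.ravel(), lat_ref)

    if np.ptp(vals) == 0:
        # constant observations reproduce as a constant surface
        surf = np.full(LON.shape, vals[0])
        model = VariogramModel(0.0, 0.0, 1.0)
        method = "constant"
    else:
        model = variogram or fit_variogram(xy_obs, vals, n_bins=n_bins, nugget=nugget)
        pred, method = _ok_solve(xy_obs, vals, xy_pred, model)
        surf = pred.reshape(LON.shape)

    return xr.DataArray(
        surf,
        coords={"lat": lat_c, "lon": lon_c},
        dims=("lat", "lon"),
        name="connectivity",
        attrs={
            "method": method,
            "variogram_nugget": model.nugget,
            "variogram_sill": model.sill,
            "variogram_range_m": model.range_m,
            "resolution_deg": resolution_deg,
        },
    )
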