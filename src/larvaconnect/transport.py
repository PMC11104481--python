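"""Passive Lagrangian particle tracking over a gridded flow field.

A minimal fixed-depth tracker: bilinear horizontal interpolation with
land-aware weight renormalization, nearest depth level, linear time
interpolation, Euler or RK4 stepping, optional horizontal diffusion, and
specular coastline reflection.  Backward tracing integrates the negated
velocity field along a reversed field-time axis, which is the exact
adjoint of the deterministic forward step.

Positions are stored hourly regardless of the internal integration step;
per-particle trajectory time is "age" (hours since that particle's
release), so the output array is rectangular even when releases are
staggered over weeks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grids import BathymetryGrid, FlowFieldSeries, M_PER_DEG_LAT, meters_per_degree_lon

__all__ = [
    "TrackerConfig",
    "TrajectorySet",
    "sample_velocity",
    "sample_temperature",
    "advect",
    "positions_during",
]

STATUS_DRIFTING = 0
STATUS_LOST_DOMAIN = 1
STATUS_HALTED = 2


@dataclass(frozen=True)
class TrackerConfig:
    time_step_minutes: float = 30.0
    horizontal_diffusivity: float = 1.0  # m^2/s
    scheme: str = "rk4"  # or "euler"
    coast: str = "reflect"  # or "halt"
    output_step_hours: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.horizontal_diffusivity < 0:
            raise ValueError("diffusivity must be >= 0")
        if self.scheme not in ("euler", "rk4"):
            raise ValueError("scheme must be 'euler' or 'rk4'")
        if self.coast not in ("reflect", "halt"):
            raise ValueError("coast must be 'reflect' or 'halt'")


@dataclass
class TrajectorySet:
    """Hourly particle positions on a shared age axis.

    ``lon``/``lat`` have shape ``(n_particles, n_ages)``; ``age_hours``
    is the shared axis (0 = release).  ``release_time`` is each
    particle's release hour on the field clock; in backward mode field
    time decreases with age (``field_time = release_time - age``).
    """

    lon: np.ndarray
    lat: np.ndarray
    age_hours: np.ndarray
    release_time: np.ndarray
    drift_depth: np.ndarray
    site_id: np.ndarray
    status: np.ndarray
    mode: str

    @property
    def n_particles(self) -> int:
        return self.lon.shape[0]

    @property
    def span_hours(self) -> float:
        return float(self.age_hours[-1] - self.age_hours[0])

    def field_time(self) -> np.ndarray:
        """Field-clock time for every (particle, age) sample."""
        sign = -1.0 if self.mode == "backward" else 1.0
        return self.release_time[:, None] + sign * self.age_hours[None, :]


# ---------------------------------------------------------------------------
# field sampling
# ---------------------------------------------------------------------------


def _bilinear_setup(field: FlowFieldSeries, lon, lat):
    """Stencil indices and land-aware weights for bilinear interpolation."""
    b = field.bathy
    lon_c, lat_c = b.lon_centers, b.lat_centers
    ix0 = np.clip(np.searchsorted(lon_c, lon) - 1, 0, lon_c.size - 2)
    iy0 = np.clip(np.searchsorted(lat_c, lat) - 1, 0, lat_c.size - 2)
    fx = np.clip((lon - lon_c[ix0]) / (lon_c[ix0 + 1] - lon_c[ix0]), 0.0, 1.0)
    fy = np.clip((lat - lat_c[iy0]) / (lat_c[iy0 + 1] - lat_c[iy0]), 0.0, 1.0)
    water = b.water_mask
    w = np.empty((4,) + np.shape(lon))
    iys = (iy0, iy0, iy0 + 1, iy0 + 1)
    ixs = (ix0, ix0 + 1, ix0, ix0 + 1)
    w[0] = (1 - fx) * (1 - fy)
    w[1] = fx * (1 - fy)
    w[2] = (1 - fx) * fy
    w[3] = fx * fy
    for k in range(4):
        w[k] = w[k] * water[iys[k], ixs[k]]
    wsum = w.sum(axis=0)
    return iys, ixs, w, wsum


def _time_weights(field: FlowFieldSeries, t):
    times = field.times
    if times.size == 1:
        f0 = np.zeros(np.shape(t), dtype=int)
        return f0, f0, np.zeros(np.shape(t))
    dt_h = times[1] - times[0]
    f = np.clip(((t - times[0]) / dt_h).astype(int), 0, times.size - 2)
    alpha = np.clip((t - times[f]) / dt_h, 0.0, 1.0)
    return f, f + 1, alpha


def _sample(field: FlowFieldSeries, arrs, lon, lat, kz, t):
    """Interpolate one or more (time, depth, lat, lon) arrays; returns a list.

    Positions whose full bilinear stencil is land get value 0 and are
    reported in the returned ``dry`` mask.
    """
    iys, ixs, w, wsum = _bilinear_setup(field, lon, lat)
    dry = wsum == 0
    wsafe = np.where(dry, 1.0, wsum)
    f0, f1, alpha = _time_weights(field, t)
    out = []
    for arr in arrs:
        acc = np.zeros(np.shape(lon))
        for k in range(4):
            v0 = arr[f0, kz, iys[k], ixs[k]]
            v1 = arr[f1, kz, iys[k], ixs[k]]
            acc += w[k] * ((1 - alpha) * v0 + alpha * v1)
        out.append(np.where(dry, 0.0, acc / wsafe))
    return out, dry


def sample_velocity(field: FlowFieldSeries, lon, lat, depth, t):
    """(u, v) in m/s at the given positions, depth and field time.

    Bilinear in lon/lat among water cells (land cells are dropped from
    the stencil and the weights renormalized), nearest depth level,
    linear in time.  Raises if a point is over land or ``t`` is outside
    the field's time span.
    """
    scalar = np.ndim(lon) == 0
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if t.size == 1 and lon.size > 1:
        t = np.full(lon.shape, t[0])
    if np.any(t < field.times[0] - 1e-9) or np.any(t > field.times[-1] + 1e-9):
        raise ValueError("t outside the flow-field time span")
    if not np.all(field.bathy.is_water(lon, lat)):
        raise ValueError("sample position on land or outside the domain")
    kz = field.nearest_depth_index(depth)
    if kz.size == 1 and lon.size > 1:
        kz = np.full(lon.shape, int(kz[0]))
    (u, v), _ = _sample(field, (field.u, field.v), lon, lat, kz, t)
    if scalar:
        return float(u[0]), float(v[0])
    return u, v


def sample_temperature(field: FlowFieldSeries, lon, lat, depth, t):
    """Temperature in degC with the same interpolation contract as velocity."""
    scalar = np.ndim(lon) == 0
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if t.size == 1 and lon.size > 1:
        t = np.full(lon.shape, t[0])
    if np.any(t < field.times[0] - 1e-9) or np.any(t > field.times[-1] + 1e-9):
        raise ValueError("t outside the flow-field time span")
    if not np.all(field.bathy.is_water(lon, lat)):
        raise ValueError("sample position on land or outside the domain")
    kz = field.nearest_depth_index(depth)
    if kz.size == 1 and lon.size > 1:
        kz = np.full(lon.shape, int(kz[0]))
    (temp,), _ = _sample(field, (field.temperature,), lon, lat, kz, t)
    if scalar:
        return float(temp[0])
    return temp


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


def _velocity_deg_per_h(field, lon, lat, kz, t, sign):
    """Velocity converted to degrees/hour (equirectangular metric)."""
    (u, v), _ = _sample(field, (field.u, field.v), lon, lat, kz, t)
    dlon = sign * u * 3600.0 / meters_per_degree_lon(lat)
    dlat = sign * v * 3600.0 / M_PER_DEG_LAT
    return dlon, dlat


def _reflect_or_revert(bathy, lon0, lat0, lon1, lat1, hit, coast):
    """Resolve land hits: specular reflection off the crossed cell face,
    falling back to the pre-step position when reflection fails."""
    lon1 = lon1.copy()
    lat1 = lat1.copy()
    halted = np.zeros(lon1.shape, dtype=bool)
    idx = np.nonzero(hit)[0]
    if idx.size == 0:
        return lon1, lat1, halted
    if coast == "halt":
        lon1[idx] = lon0[idx]
        lat1[idx] = lat0[idx]
        halted[idx] = True
        return lon1, lat1, halted
    b = bathy
    iy0, ix0 = b.cell_index(lon0[idx], lat0[idx])
    iy1, ix1 = b.cell_index(lon1[idx], lat1[idx])
    cross_x = ix1 != ix0
    cross_y = iy1 != iy0
    edge_lon = b.lon_edges[np.clip(np.maximum(ix0, ix1), 0, b.lon_edges.size - 1)]
    edge_lat = b.lat_edges[np.clip(np.maximum(iy0, iy1), 0, b.lat_edges.size - 1)]
    ref_lon = np.where(cross_x, 2 * edge_lon - lon1[idx], lon1[idx])
    ref_lat = np.where(cross_y, 2 * edge_lat - lat1[idx], lat1[idx])
    # candidate order: mirror only the crossed coordinate(s), then both
    cands = [
        (ref_lon, lat1[idx]),
        (lon1[idx], ref_lat),
        (ref_lon, ref_lat),
    ]
    resolved = np.zeros(idx.size, dtype=bool)
    out_lon = lon0[idx].copy()
    out_lat = lat0[idx].copy()
    for clon, clat in cands:
        ok = ~resolved & np.asarray(b.is_water(clon, clat))
        out_lon[ok] = clon[ok]
        out_lat[ok] = clat[ok]
        resolved |= ok
    lon1[idx] = out_lon
    lat1[idx] = out_lat
    return lon1, lat1, halted


def advect(
    schedule: Sequence,
    field: FlowFieldSeries,
    bathy: BathymetryGrid | None = None,
    config: TrackerConfig = TrackerConfig(),
    mode: str | None = None,
    duration_days: float | None = None,
) -> TrajectorySet:
    """Integrate every release event for ``duration_days`` at fixed depth.

    ``schedule`` is a sequence of release events (``site_id``, ``time``,
    ``lon``, ``lat``, ``drift_depth``, ``mode`` attributes).  Forward
    mode defaults to 33 days of drift (the end of the competency
    window), backward mode to 27 days of back-tracing.  Particles
    leaving the open boundary are flagged ``lost_domain`` and frozen;
    land hits are reflected or halted per the tracker config.
    Deterministic given the config seed.
    """
    if bathy is None:
        bathy = field.bathy
    if not schedule:
        raise ValueError("empty release schedule")
    if mode is None:
        mode = getattr(schedule[0], "mode", "forward")
    if duration_days is None:
        duration_days = 33.0 if mode == "forward" else 27.0
    sign = 1.0 if mode == "forward" else -1.0

    rel_t = np.array([e.time for e in schedule], dtype=float)
    lon = np.array([e.lon for e in schedule], dtype=float)
    lat = np.array([e.lat for e in schedule], dtype=float)
    depth = np.array([e.drift_depth for e in schedule], dtype=float)
    site_id = np.array([e.site_id for e in schedule], dtype=int)
    n = lon.size

    # field coverage check
    need_lo = rel_t.min() if sign > 0 else rel_t.min() - duration_days * 24
    need_hi = rel_t.max() + duration_days * 24 if sign > 0 else rel_t.max()
    if need_lo < field.times[0] - 1e-9 or need_hi > field.times[-1] + 1e-9:
        raise ValueError(
            "flow field does not cover the drift horizon: need "
            f"[{need_lo:.1f}, {need_hi:.1f}] h, have "
            f"[{field.times[0]:.1f}, {field.times[-1]:.1f}] h"
        )
    if not np.all(bathy.is_water(lon, lat)):
        raise ValueError("release positions must be on water")

    dt_h = config.time_step_minutes / 60.0
    n_steps = int(round(duration_days * 24.0 / dt_h))
    out_every = max(int(round(config.output_step_hours / dt_h)), 1)
    n_out = n_steps // out_every + 1
    ages = np.arange(n_out) * out_every * dt_h

    kz = field.nearest_depth_index(depth)
    rng = np.random.default_rng(config.seed)
    kh = config.horizontal_diffusivity
    sigma_m = np.sqrt(2.0 * kh * dt_h * 3600.0)

    out_lon = np.full((n, n_out), np.nan)
    out_lat = np.full((n, n_out), np.nan)
    out_lon[:, 0] = lon
    out_lat[:, 0] = lat
    status = np.full(n, STATUS_DRIFTING, dtype=np.int8)

    for step in range(1, n_steps + 1):
        age0 = (step - 1) * dt_h
        active = status == STATUS_DRIFTING
        if np.any(active):
            a = np.nonzero(active)[0]
            la, lo = lat[a], lon[a]
            t0 = rel_t[a] + sign * age0
            kz_a = kz[a]
            if config.scheme == "euler":
                dlon, dlat = _velocity_deg_per_h(field, lo, la, kz_a, t0, sign)
                nlon = lo + dlon * dt_h
                nlat = la + dlat * dt_h
            else:  # rk4
                k1x, k1y = _velocity_deg_per_h(field, lo, la, kz_a, t0, sign)
                th = t0 + sign * dt_h / 2
                k2x, k2y = _velocity_deg_per_h(
                    field, lo + k1x * dt_h / 2, la + k1y * dt_h / 2, kz_a, th, sign
                )
                k3x, k3y = _velocity_deg_per_h(
                    field, lo + k2x * dt_h / 2, la + k2y * dt_h / 2, kz_a, th, sign
                )
                t1 = t0 + sign * dt_h
                k4x, k4y = _velocity_deg_per_h(
                    field, lo + k3x * dt_h, la + k3y * dt_h, kz_a, t1, sign
                )
                nlon = lo + (k1x + 2 * k2x + 2 * k3x + k4x) * dt_h / 6
                nlat = la + (k1y + 2 * k2y + 2 * k3y + k4y) * dt_h / 6
            if kh > 0:
                nlon = nlon + rng.normal(0, sigma_m, size=a.size) / meters_per_degree_lon(la)
                nlat = nlat + rng.normal(0, sigma_m, size=a.size) / M_PER_DEG_LAT
            inside = np.asarray(field.bathy.in_domain(nlon, nlat))
            lost = ~inside
            status[a[lost]] = STATUS_LOST_DOMAIN  # frozen at last inside position
            keep = ~lost
            if np.any(keep):
                ak = a[keep]
                on_land = ~np.asarray(bathy.is_water(nlon[keep], nlat[keep]))
                rlon, rlat, halted = _reflect_or_revert(
                    bathy, lo[keep], la[keep], nlon[keep], nlat[keep], on_land, config.coast
                )
                lon[ak] = rlon
                lat[ak] = rlat
                status[ak[halted]] = STATUS_HALTED
        if step % out_every == 0:
            j = step // out_every
            out_lon[:, j] = lon
            out_lat[:, j] = lat

    return TrajectorySet(
        lon=out_lon,
        lat=out_lat,
        age_hours=ages,
        release_time=rel_t,
        drift_depth=depth,
        site_id=site_id,
        status=status,
        mode=mode,
    )


def positions_during(traj: TrajectorySet, t_start_days: float, t_end_days: float):
    """Sub-track over an age window, with per-sample dwell durations.

    Each stored sample at age ``a`` represents the interval
    ``[a, a + output step)``; the returned dwell weights sum to the
    window length for every particle.  Used by settlement scoring.
    """
    a0 = t_start_days * 24.0
    a1 = t_end_days * 24.0
    if a0 < traj.age_hours[0] - 1e-9 or a1 > traj.age_hours[-1] + 1e-9 + (
        traj.age_hours[1] - traj.age_hours[0] if traj.age_hours.size > 1 else 0.0
    ):
        raise ValueError("window outside the trajectory span")
    if a1 < a0:
        raise ValueError("window end before window start")
    step = traj.age_hours[1] - traj.age_hours[0] if traj.age_hours.size > 1 else 1.0
    sel = (traj.age_hours >= a0 - 1e-9) & (traj.age_hours < a1 - 1e-9)
    idx = np.nonzero(sel)[0]
    dwell = np.full(idx.size, step)
    return traj.lon[:, idx], traj.lat[:, idx], dwell
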