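"""Shared fixtures: small synthetic domains and hand-built trajectories."""

from __future__ import annotations

import numpy as np
import pytest

from larvaconnect.grids import BathymetryGrid, FlowFieldSeries
from larvaconnect.synthetic import CoastalDomainConfig, make_coastal_bathymetry
from larvaconnect.transport import TrajectorySet, STATUS_DRIFTING


@pytest.fixture(scope="session")
def flat_bathy() -> BathymetryGrid:
    """All-water 1°x1° sloped shelf, 0.05° cells (20x20)."""
    cfg = CoastalDomainConfig(
        lon_min=10.0, lon_max=11.0, lat_min=58.0, lat_max=59.0,
        step_deg=0.05, mainland=False, islands=(), fjords=(),
    )
    return make_coastal_bathymetry(cfg)


@pytest.fixture(scope="session")
def mini_domain() -> BathymetryGrid:
    from larvaconnect.synthetic import mini_skagerrak_config

    return make_coastal_bathymetry(mini_skagerrak_config())


def make_uniform_field(
    bathy: BathymetryGrid,
    u0: float,
    v0: float,
    duration_h: float = 48.0,
    temperature_c: float = 12.0,
    depth_levels=(5.0, 15.0, 25.0),
) -> FlowFieldSeries:
    """Spatially and temporally constant flow over ``bathy``."""
    nz = len(depth_levels)
    ny, nx = bathy.shape
    shape = (2, nz, ny, nx)
    u = np.full(shape, float(u0))
    v = np.full(shape, float(v0))
    u[..., bathy.land_mask] = 0.0
    v[..., bathy.land_mask] = 0.0
    temp = np.full(shape, float(temperature_c))
    return FlowFieldSeries(
        bathy=bathy,
        times=np.array([0.0, duration_h]),
        depth_levels=np.asarray(depth_levels, dtype=float),
        u=u,
        v=v,
        temperature=temp,
    )


def make_trajectory(
    lon: np.ndarray,
    lat: np.ndarray,
    age_step_h: float = 1.0,
    release_time: float = 0.0,
    site_id: int = 1,
    mode: str = "forward",
    status=None,
) -> TrajectorySet:
    """Hand-built trajectory set from (n, T) position arrays."""
    lon = np.atleast_2d(np.asarray(lon, dtype=float))
    lat = np.atleast_2d(np.asarray(lat, dtype=float))
    n, T = lon.shape
    return TrajectorySet(
        lon=lon,
        lat=lat,
        age_hours=np.arange(T) * age_step_h,
        release_time=np.full(n, release_time),
        drift_depth=np.full(n, 5.0),
        site_id=np.full(n, site_id, dtype=int),
        status=np.full(n, STATUS_DRIFTING, dtype=np.int8) if status is None else np.asarray(status),
        mode=mode,
    )


def worked_settlement_example():
    """The textbook scoring case: a larva spending 50% of the competency
    window in one shallow cell and 10% in another.

    Returns (bathy, traj, cell_a, cell_b) on a 0.015° grid; the
    trajectory is sampled every 0.6 h so the 144-hour window holds 240
    samples, of which exactly 120 sit in cell A and 24 in cell B.
    """
    step = 0.015
    lon_edges = 10.0 + step * np.arange(6)
    lat_edges = 58.0 + step * np.arange(6)
    depth = np.full((5, 5), 50.0)
    cell_a, cell_b = (2, 1), (2, 3)
    depth[cell_a] = 5.0
    depth[cell_b] = 5.0
    bathy = BathymetryGrid(lon_edges, lat_edges, depth, np.zeros((5, 5), bool))
    lon_c, lat_c = bathy.lon_centers, bathy.lat_centers

    ages = np.arange(1321) * 0.6  # 0 .. 792 h (33 d) at 0.6 h sampling
    lon = np.full(ages.size, lon_c[2])  # deep cell (2,2) by default
    lat = np.full(ages.size, lat_c[2])
    in_window = (ages >= 648.0 - 1e-9) & (ages < 792.0 - 1e-9)
    w_idx = np.nonzero(in_window)[0]
    assert w_idx.size == 240
    lon[w_idx[:120]] = lon_c[cell_a[1]]
    lat[w_idx[:120]] = lat_c[cell_a[0]]
    lon[w_idx[120:144]] = lon_c[cell_b[1]]
    lat[w_idx[120:144]] = lat_c[cell_b[0]]
    traj = make_trajectory(lon, lat, age_step_h=0.6)
    return bathy, traj, cell_a, cell_b
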