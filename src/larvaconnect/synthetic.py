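"""Synthetic coastal domains: bathymetry, circulation and site placement.

The generators emulate the geography and circulation the connectivity
analysis assumes — a mainland coast fringed by shallow mussel habitat,
islands, semi-enclosed fjord basins reached through narrow straits, and a
prevailing counterclockwise circulation whose coastal limb forms an
along-shore jet — without any real hydrodynamic forcing.  Everything is
deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .grids import (
    BathymetryGrid,
    FlowFieldSeries,
    M_PER_DEG_LAT,
    Site,
    SiteSet,
    meters_per_degree_lon,
)

__all__ = [
    "IslandSpec",
    "FjordSpec",
    "CoastalDomainConfig",
    "FlowConfig",
    "make_coastal_bathymetry",
    "make_flow_field",
    "place_sites",
    "mini_skagerrak_config",
]


@dataclass(frozen=True)
class IslandSpec:
    lon: float
    lat: float
    radius_deg: float


@dataclass(frozen=True)
class FjordSpec:
    """A rectangular basin carved into the mainland behind a narrow strait.

    ``mouth_lat`` is the latitude of the strait centreline; the basin sits
    east of the coastline, connected to open water only through the strait.
    """

    mouth_lat: float
    basin_width_deg: float = 0.15
    basin_height_deg: float = 0.15
    strait_width_deg: float = 0.05
    strait_length_deg: float = 0.12
    basin_depth_m: float = 8.0


@dataclass(frozen=True)
class CoastalDomainConfig:
    lon_min: float = 10.0
    lon_max: float = 12.0
    lat_min: float = 57.5
    lat_max: float = 59.5
    step_deg: float = 0.015
    mainland: bool = True
    #: longitude of the (mean) coastline; land lies east of it
    coast_lon: float = 11.6
    #: amplitude of the seeded coastline wiggle, degrees
    coast_wiggle_deg: float = 0.04
    #: width of the shallow (<10 m) fringe west of the coastline
    fringe_width_deg: float = 0.06
    max_depth_m: float = 80.0
    islands: tuple[IslandSpec, ...] = ()
    fjords: tuple[FjordSpec, ...] = ()
    seed: int = 0


def mini_skagerrak_config(**overrides) -> CoastalDomainConfig:
    """Default 2°x2° archipelago domain: mainland coast, two islands, one fjord."""
    cfg = CoastalDomainConfig(
        islands=(
            IslandSpec(11.30, 58.05, 0.06),
            IslandSpec(11.15, 58.90, 0.05),
        ),
        fjords=(FjordSpec(mouth_lat=58.55),),
        seed=1,
    )
    return replace(cfg, **overrides)


def _coastline_lon(cfg: CoastalDomainConfig, lat: np.ndarray) -> np.ndarray:
    """Mean coastline longitude plus a smooth seeded wiggle."""
    if cfg.coast_wiggle_deg == 0:
        return np.full_like(np.asarray(lat, dtype=float), cfg.coast_lon)
    rng = np.random.default_rng(cfg.seed)
    span = cfg.lat_max - cfg.lat_min
    phases = rng.uniform(0, 2 * np.pi, size=3)
    amps = cfg.coast_wiggle_deg * np.array([1.0, 0.5, 0.25])
    t = (np.asarray(lat, dtype=float) - cfg.lat_min) / span
    wiggle = sum(a * np.sin(2 * np.pi * (k + 1) * t + p) for k, (a, p) in enumerate(zip(amps, phases)))
    return cfg.coast_lon + wiggle


def make_coastal_bathymetry(config: CoastalDomainConfig) -> BathymetryGrid:
    """Build a synthetic coastal bathymetry grid.

    The water column deepens away from the coastline: a shallow (<10 m)
    fringe of configurable width hugs the coast (and every island), then
    the shelf slopes down to ``max_depth_m``.  Fjord basins are carved
    into the mainland and connected to open water by a strait.  With no
    mainland, islands or fjords the result is an all-water sloped shelf.
    """
    cfg = config
    if cfg.step_deg <= 0:
        raise ValueError("grid step must be positive")
    if cfg.lon_max <= cfg.lon_min or cfg.lat_max <= cfg.lat_min:
        raise ValueError("degenerate domain extent")

    lon_edges = np.arange(cfg.lon_min, cfg.lon_max + 0.5 * cfg.step_deg, cfg.step_deg)
    lat_edges = np.arange(cfg.lat_min, cfg.lat_max + 0.5 * cfg.step_deg, cfg.step_deg)
    lon_c = 0.5 * (lon_edges[:-1] + lon_edges[1:])
    lat_c = 0.5 * (lat_edges[:-1] + lat_edges[1:])
    LON, LAT = np.meshgrid(lon_c, lat_c)

    shelf_slope = (cfg.max_depth_m - 10.0) / max(
        (cfg.coast_lon - cfg.fringe_width_deg) - cfg.lon_min, cfg.step_deg
    )

    if cfg.mainland:
        coast = _coastline_lon(cfg, LAT)
        doff = coast - LON  # degrees west of the coastline (positive over water)
        land = doff <= 0
        depth = np.where(
            doff < cfg.fringe_width_deg,
            1.0 + 8.5 * doff / cfg.fringe_width_deg,  # 1 -> 9.5 m fringe
            10.0 + shelf_slope * (doff - cfg.fringe_width_deg),
        )
    else:
        land = np.zeros(LON.shape, dtype=bool)
        # sloped shelf deepening westward, shallowest at the eastern edge
        frac = (cfg.lon_max - LON) / (cfg.lon_max - cfg.lon_min)
        depth = 5.0 + (cfg.max_depth_m - 5.0) * frac

    depth = np.clip(depth, 1.0, cfg.max_depth_m)

    for isl in cfg.islands:
        dist = np.hypot(LON - isl.lon, LAT - isl.lat)
        land |= dist <= isl.radius_deg
        ring = (dist > isl.radius_deg) & (dist <= isl.radius_deg + cfg.fringe_width_deg)
        taper = 1.0 + 8.5 * (dist - isl.radius_deg) / cfg.fringe_width_deg
        depth = np.where(ring, np.minimum(depth, taper), depth)

    fjord_polys = []
    for fj in cfg.fjords:
        if not cfg.mainland:
            raise ValueError("a fjord requires a mainland to be carved into")
        lat0 = fj.mouth_lat - fj.basin_height_deg / 2
        lat1 = fj.mouth_lat + fj.basin_height_deg / 2
        basin_lon0 = cfg.coast_lon + cfg.coast_wiggle_deg + fj.strait_length_deg
        basin_lon1 = basin_lon0 + fj.basin_width_deg
        if basin_lon1 > cfg.lon_max or lat0 < cfg.lat_min or lat1 > cfg.lat_max:
            raise ValueError("fjord spec does not fit inside the domain extent")
        in_basin = (LON >= basin_lon0) & (LON < basin_lon1) & (LAT >= lat0) & (LAT < lat1)
        strait_lat0 = fj.mouth_lat - fj.strait_width_deg / 2
        strait_lat1 = fj.mouth_lat + fj.strait_width_deg / 2
        strait_lon0 = cfg.coast_lon - cfg.coast_wiggle_deg - 2 * cfg.step_deg
        in_strait = (
            (LON >= strait_lon0)
            & (LON < basin_lon0)
            & (LAT >= strait_lat0)
            & (LAT < strait_lat1)
        )
        land &= ~(in_basin | in_strait)
        depth = np.where(in_basin, fj.basin_depth_m, depth)
        depth = np.where(in_strait, np.minimum(depth, 6.0), depth)
        fjord_polys.append(
            {
                "lon_min": basin_lon0,
                "lon_max": basin_lon1,
                "lat_min": lat0,
                "lat_max": lat1,
                "mouth_lat": fj.mouth_lat,
            }
        )

    features = {
        "fjords": fjord_polys,
        "islands": [(i.lon, i.lat, i.radius_deg) for i in cfg.islands],
        "coast_lon": cfg.coast_lon if cfg.mainland else None,
        "fringe_width_deg": cfg.fringe_width_deg,
        "config": cfg,
    }
    return BathymetryGrid(lon_edges, lat_edges, depth, land, features=features)


# ---------------------------------------------------------------------------
# flow fields
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FlowConfig:
    """Parameters of the synthetic circulation.

    The interior flow is derived from a streamfunction evaluated on cell
    centres and differentiated with centred differences, which makes the
    matching discrete divergence vanish identically.  A counterclockwise
    basin gyre (peak speed ``gyre_strength``) and a northward along-coast
    jet (surface speed ``jet_speed`` decaying offshore over
    ``jet_width_deg``) are superposed; both decay with depth as
    ``exp(-z / depth_efold_m)``.
    """

    gyre_strength: float = 0.1  # m/s peak surface speed of the basin gyre
    gyre_mode: str = "streamfunction"  # or "solid_body"
    jet_speed: float = 0.15  # m/s northward surface jet at the coastline
    jet_width_deg: float = 0.1
    depth_efold_m: float = 10.0
    noise_amplitude: float = 0.0  # m/s, seeded white noise on u and v
    duration_days: float = 60.0
    time_step_hours: float = 24.0
    steady: bool = True  # steady flow: store only two frames
    depth_levels: tuple[float, ...] = (5.0, 15.0, 25.0)
    # seasonal temperature: T(t) = mean + amp * sin(2*pi*(doy - phase)/365)
    temp_mean_c: float = 12.0
    temp_amplitude_c: float = 6.0
    temp_phase_day: float = 130.0
    start_day_of_year: float = 135.0  # mid-May spawning season start
    seed: int = 0


def _streamfunction(bathy: BathymetryGrid, cfg: FlowConfig) -> np.ndarray:
    """Streamfunction (m^2/s) on cell centres.

    Positive-outward bowl => counterclockwise circulation (positive
    vorticity).  East of the coastline (inside fjords) the streamfunction
    is constant, so carved basins are quiescent.
    """
    lon_c = bathy.lon_centers
    lat_c = bathy.lat_centers
    LON, LAT = np.meshgrid(lon_c, lat_c)
    lat_mid = 0.5 * (bathy.lat_edges[0] + bathy.lat_edges[-1])
    mdeg_lon = meters_per_degree_lon(lat_mid)

    coast_lon = bathy.features.get("coast_lon") or bathy.lon_edges[-1]

    # basin gyre over the open-water extent [lon_min, coast_lon]
    xt = np.clip((LON - bathy.lon_edges[0]) / (coast_lon - bathy.lon_edges[0]), 0, 1)
    yt = np.clip((LAT - bathy.lat_edges[0]) / (bathy.lat_edges[-1] - bathy.lat_edges[0]), 0, 1)
    Ly_m = (bathy.lat_edges[-1] - bathy.lat_edges[0]) * M_PER_DEG_LAT
    Lx_m = (coast_lon - bathy.lon_edges[0]) * mdeg_lon
    # scale by the shorter axis so the peak gyre speed is ~gyre_strength
    psi_gyre = (
        -cfg.gyre_strength * (min(Lx_m, Ly_m) / np.pi) * np.sin(np.pi * xt) * np.sin(np.pi * yt)
    )

    # along-coast jet: v = J * exp(-offshore distance / width), zero east of coast
    w_m = cfg.jet_width_deg * mdeg_lon
    doff_m = np.maximum(coast_lon - LON, 0.0) * mdeg_lon
    psi_jet = cfg.jet_speed * w_m * np.exp(-doff_m / w_m)

    return psi_gyre + psi_jet


def _centered_uv(psi: np.ndarray, bathy: BathymetryGrid) -> tuple[np.ndarray, np.ndarray]:
    """u = -dpsi/dy, v = dpsi/dx by centred differences on cell centres."""
    lat_mid = 0.5 * (bathy.lat_edges[0] + bathy.lat_edges[-1])
    dx_m = np.gradient(bathy.lon_centers) * meters_per_degree_lon(lat_mid)
    dy_m = np.gradient(bathy.lat_centers) * M_PER_DEG_LAT
    dpsi_dy = np.gradient(psi, axis=0) / dy_m[:, None]
    dpsi_dx = np.gradient(psi, axis=1) / dx_m[None, :]
    return -dpsi_dy, dpsi_dx


def make_flow_field(bathy: BathymetryGrid, config: FlowConfig) -> FlowFieldSeries:
    """Generate the synthetic flow-and-temperature series on ``bathy``."""
    cfg = config
    n_levels = len(cfg.depth_levels)
    if cfg.steady:
        times = np.array([0.0, cfg.duration_days * 24.0])
    else:
        times = np.arange(0.0, cfg.duration_days * 24.0 + 0.5 * cfg.time_step_hours, cfg.time_step_hours)
    ny, nx = bathy.shape

    if cfg.gyre_mode == "solid_body":
        LON, LAT = np.meshgrid(bathy.lon_centers, bathy.lat_centers)
        lat_mid = 0.5 * (bathy.lat_edges[0] + bathy.lat_edges[-1])
        lon_mid = 0.5 * (bathy.lon_edges[0] + bathy.lon_edges[-1])
        x_m = (LON - lon_mid) * meters_per_degree_lon(lat_mid)
        y_m = (LAT - lat_mid) * M_PER_DEG_LAT
        r_max = min(
            0.5 * (bathy.lon_edges[-1] - bathy.lon_edges[0]) * meters_per_degree_lon(lat_mid),
            0.5 * (bathy.lat_edges[-1] - bathy.lat_edges[0]) * M_PER_DEG_LAT,
        )
        omega = cfg.gyre_strength / r_max  # rad/s; CCW
        u0 = -omega * y_m
        v0 = omega * x_m
    elif cfg.gyre_mode == "streamfunction":
        psi = _streamfunction(bathy, cfg)
        u0, v0 = _centered_uv(psi, bathy)
    else:
        raise ValueError(f"unknown gyre_mode {cfg.gyre_mode!r}")

    depth_factors = np.exp(-np.asarray(cfg.depth_levels) / cfg.depth_efold_m)
    u = (u0[None, None] * depth_factors[None, :, None, None]).astype(float)
    v = (v0[None, None] * depth_factors[None, :, None, None]).astype(float)
    u = np.repeat(u, times.size, axis=0)
    v = np.repeat(v, times.size, axis=0)

    if cfg.noise_amplitude > 0:
        rng = np.random.default_rng(cfg.seed)
        u = u + rng.normal(0, cfg.noise_amplitude, size=u.shape)
        v = v + rng.normal(0, cfg.noise_amplitude, size=v.shape)

    land = bathy.land_mask
    u[..., land] = 0.0
    v[..., land] = 0.0

    doy = cfg.start_day_of_year + times / 24.0
    temp_t = cfg.temp_mean_c + cfg.temp_amplitude_c * np.sin(
        2 * np.pi * (doy - cfg.temp_phase_day) / 365.0
    )
    temperature = np.broadcast_to(
        temp_t[:, None, None, None], (times.size, n_levels, ny, nx)
    ).copy()

    return FlowFieldSeries(
        bathy=bathy,
        times=times,
        depth_levels=np.asarray(cfg.depth_levels, dtype=float),
        u=u,
        v=v,
        temperature=temperature,
    )


# ---------------------------------------------------------------------------
# site placement
# ---------------------------------------------------------------------------


def place_sites(
    bathy: BathymetryGrid,
    n_sites: int,
    seed: int = 0,
    offshore_frac: float = 0.5,
    margin_deg: float = 0.1,
) -> SiteSet:
    """Place mussel-bed sites on shallow water cells.

    One site is placed at the centre of every fjord basin and classified
    ``inner`` (land bodies restrict its access to open water); the
    remaining sites are spread at evenly spaced latitudes along the
    shallow coastal fringe (or, without a mainland, along the shallow
    eastern edge of the shelf) and classified ``outer``.  ``seed`` only
    perturbs nothing here — placement is fully deterministic — but is
    kept in the signature for symmetry with the other generators.
    """
    if n_sites < 2:
        raise ValueError("need at least 2 sites")
    if int(bathy.water_mask.sum()) < n_sites:
        raise ValueError("fewer water cells than requested sites")

    cfg = bathy.features.get("config")
    fjords = bathy.features.get("fjords", [])
    fringe = bathy.features.get("fringe_width_deg", 0.06)
    coast_lon = bathy.features.get("coast_lon")

    sites: list[Site] = []
    next_id = 1
    for fj in fjords[: max(n_sites - 1, 0)]:
        lon = 0.5 * (fj["lon_min"] + fj["lon_max"])
        lat = 0.5 * (fj["lat_min"] + fj["lat_max"])
        sites.append(Site(next_id, f"fjord_{next_id}", lon, lat, "inner"))
        next_id += 1

    n_outer = n_sites - len(sites)
    lats = np.linspace(bathy.lat_edges[0] + margin_deg, bathy.lat_edges[-1] - margin_deg, n_outer)
    if cfg is not None and cfg.mainland:
        coast = _coastline_lon(cfg, lats)
        lons = coast - offshore_frac * fringe
    else:
        # all-water shelf: shallowest water is along the eastern edge
        lons = np.full(n_outer, bathy.lon_edges[-1] - 2.5 * (bathy.lon_edges[1] - bathy.lon_edges[0]))
    for lon, lat in zip(lons, lats):
        lon, lat = _snap_to_water(bathy, float(lon), float(lat))
        sites.append(Site(next_id, f"coast_{next_id}", lon, lat, "outer"))
        next_id += 1

    for s in sites:
        if not bool(np.asarray(bathy.is_water(s.lon, s.lat))):
            raise ValueError(f"site {s.site_id} fell on land at ({s.lon:.3f}, {s.lat:.3f})")
    return SiteSet(sites)


def _snap_to_water(bathy: BathymetryGrid, lon: float, lat: float) -> tuple[float, float]:
    """Move a point to the centre of the nearest water cell if needed."""
    if bool(np.asarray(bathy.is_water(lon, lat))):
        return lon, lat
    LON, LAT = np.meshgrid(bathy.lon_centers, bathy.lat_centers)
    d2 = (LON - lon) ** 2 + (LAT - lat) ** 2
    d2[bathy.land_mask] = np.inf
    iy, ix = np.unravel_index(np.argmin(d2), d2.shape)
    return float(LON[iy, ix]), float(LAT[iy, ix])
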