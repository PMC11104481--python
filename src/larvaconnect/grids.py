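"""Gridded domain containers: bathymetry, flow fields and site sets.

Conventions used throughout the package:

* Grid cells are half-open intervals ``[edge_i, edge_{i+1})`` in both
  longitude and latitude; a position exactly on an upper edge belongs to
  the next cell.
* Depth is in metres, positive down.  Land is encoded in ``land_mask``,
  never by a depth sentinel, so downstream arithmetic never meets NaN.
* Velocities live on cell centres at fixed depth levels; there is no
  vertical velocity (larvae are treated as fixed-depth passive drifters).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "EARTH_RADIUS_M",
    "M_PER_DEG_LAT",
    "BathymetryGrid",
    "FlowFieldSeries",
    "Site",
    "SiteSet",
    "meters_per_degree_lon",
]

EARTH_RADIUS_M = 6_371_000.0
#: metres spanned by one degree of latitude on a spherical Earth
M_PER_DEG_LAT = EARTH_RADIUS_M * np.pi / 180.0


def meters_per_degree_lon(lat_deg: np.ndarray | float) -> np.ndarray | float:
    """Local metres per degree of longitude (equirectangular metric).

    The model domains are a few degrees across, so a local cos(lat)
    scaling is used instead of full great-circle geodesy.
    """
    return M_PER_DEG_LAT * np.cos(np.deg2rad(lat_deg))


@dataclass
class BathymetryGrid:
    """Rectilinear bathymetry with a boolean land mask.

    Parameters
    ----------
    lon_edges, lat_edges
        Strictly increasing cell edges in degrees; ``depth`` and
        ``land_mask`` have shape ``(len(lat_edges)-1, len(lon_edges)-1)``.
    depth
        Water depth in metres, positive down.  Values on land cells are
        ignored (the mask is authoritative).
    land_mask
        ``True`` where the cell is land.
    features
        Optional metadata from the synthetic generator (fjord polygons,
        island centres); not required for any computation.
    """

    lon_edges: np.ndarray
    lat_edges: np.ndarray
    depth: np.ndarray
    land_mask: np.ndarray
    features: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lon_edges = np.asarray(self.lon_edges, dtype=float)
        self.lat_edges = np.asarray(self.lat_edges, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        if np.any(np.diff(self.lon_edges) <= 0) or np.any(np.diff(self.lat_edges) <= 0):
            raise ValueError("grid edges must be strictly increasing")
        shape = (self.lat_edges.size - 1, self.lon_edges.size - 1)
        if self.depth.shape != shape or self.land_mask.shape != shape:
            raise ValueError(
                f"depth/land_mask shape {self.depth.shape} does not match grid {shape}"
            )
        water = ~self.land_mask
        d = self.depth[water]
        if d.size and (not np.all(np.isfinite(d)) or np.any(d <= 0)):
            raise ValueError("depth must be finite and > 0 on water cells")

    # -- geometry -----------------------------------------------------
    @property
    def lon_centers(self) -> np.ndarray:
        return 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])

    @property
    def lat_centers(self) -> np.ndarray:
        return 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])

    @property
    def shape(self) -> tuple[int, int]:
        return self.land_mask.shape

    @property
    def water_mask(self) -> np.ndarray:
        return ~self.land_mask

    @property
    def land_fraction(self) -> float:
        return float(self.land_mask.mean())

    def cell_index(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Map positions to (iy, ix) under the half-open cell convention.

        Out-of-domain positions get index -1 or n; combine with
        :meth:`in_domain` before indexing arrays.
        """
        ix = np.searchsorted(self.lon_edges, np.asarray(lon, dtype=float), side="right") - 1
        iy = np.searchsorted(self.lat_edges, np.asarray(lat, dtype=float), side="right") - 1
        return iy, ix

    def in_domain(self, lon, lat) -> np.ndarray:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.lon_edges[0])
            & (lon < self.lon_edges[-1])
            & (lat >= self.lat_edges[0])
            & (lat < self.lat_edges[-1])
        )

    def is_water(self, lon, lat) -> np.ndarray:
        """True where the position is inside the domain and over water."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        ok = self.in_domain(lon, lat)
        iy, ix = self.cell_index(np.clip(lon, self.lon_edges[0], None), np.clip(lat, self.lat_edges[0], None))
        iy = np.clip(iy, 0, self.shape[0] - 1)
        ix = np.clip(ix, 0, self.shape[1] - 1)
        return ok & self.water_mask[iy, ix]


@dataclass
class FlowFieldSeries:
    """Time series of u, v and temperature on a bathymetry grid.

    ``times`` are hours since simulation start with a uniform step;
    ``u``, ``v`` (m/s) and ``temperature`` (degC) have shape
    ``(time, depth, lat, lon)`` on cell centres.  Velocities are zero on
    land cells by construction.
    """

    bathy: BathymetryGrid
    times: np.ndarray
    depth_levels: np.ndarray
    u: np.ndarray
    v: np.ndarray
    temperature: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.depth_levels = np.asarray(self.depth_levels, dtype=float)
        expected = (self.times.size, self.depth_levels.size) + self.bathy.shape
        for name in ("u", "v", "temperature"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != expected:
                raise ValueError(f"{name} has shape {arr.shape}, expected {expected}")
            setattr(self, name, arr)
        if self.times.size > 1:
            steps = np.diff(self.times)
            if not np.allclose(steps, steps[0]):
                raise ValueError("times must have a uniform step")
        land = self.bathy.land_mask
        if np.any(self.u[..., land] != 0) or np.any(self.v[..., land] != 0):
            raise ValueError("velocities must be zero on land cells")
        water = ~land
        for name in ("u", "v"):
            if not np.all(np.isfinite(getattr(self, name)[..., water])):
                raise ValueError(f"{name} must be finite over water")

    @property
    def time_step_hours(self) -> float:
        if self.times.size < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    @property
    def duration_hours(self) -> float:
        return float(self.times[-1] - self.times[0])

    def nearest_depth_index(self, depth_m) -> np.ndarray:
        z = np.atleast_1d(np.asarray(depth_m, dtype=float))
        return np.argmin(np.abs(z[:, None] - self.depth_levels[None, :]), axis=1)


# default mussel-bed depth distribution: 70% of beds at 0.5 m, the
# remainder split evenly over 2, 4 and 6 m
DEFAULT_BED_DEPTHS: tuple[tuple[float, float], ...] = (
    (0.5, 0.7),
    (2.0, 0.1),
    (4.0, 0.1),
    (6.0, 0.1),
)


@dataclass
class Site:
    site_id: int
    name: str
    lon: float
    lat: float
    category: str  # "inner" | "outer"
    bed_depths: tuple[tuple[float, float], ...] = DEFAULT_BED_DEPTHS

    def __post_init__(self) -> None:
        if self.category not in ("inner", "outer"):
            raise ValueError(f"category must be 'inner' or 'outer', got {self.category!r}")
        w = sum(w for _, w in self.bed_depths)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("bed-depth weights must sum to 1")


class SiteSet:
    """An ordered collection of release/settlement sites."""

    def __init__(self, sites: Sequence[Site]):
        self.sites = list(sites)
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValueError("site_id values must be unique")

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def __getitem__(self, i: int) -> Site:
        return self.sites[i]

    def by_id(self, site_id: int) -> Site:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(f"no site with id {site_id}")

    @property
    def site_ids(self) -> list[int]:
        return [s.site_id for s in self.sites]

    @property
    def categories(self) -> dict[int, str]:
        return {s.site_id: s.category for s in self.sites}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "site_id": [s.site_id for s in self.sites],
                "name": [s.name for s in self.sites],
                "lon": [s.lon for s in self.sites],
                "lat": [s.lat for s in self.sites],
                "category": [s.category for s in self.sites],
            }
        )
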