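"""Settlement-probability scoring and site-to-site connectivity.

A larva may settle while "competent" (by default days 27–33 after
release) wherever the water is shallower than 10 m.  Because when in
that window settlement actually happens is unknown, each larva's unit of
settlement probability is spread over the grid cells it visits in
proportion to dwell time: the fraction of the competency window spent in
a shallow cell is that cell's settlement probability for the larva.
Summing over larvae gives a settlement field; attributing shallow cells
near each named site (its "catchment") gives site-to-site transfer
percentages, the retention diagonal, and donor/recipient degree counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .grids import BathymetryGrid, SiteSet
from .transport import TrajectorySet, positions_during, STATUS_LOST_DOMAIN

__all__ = [
    "SettlementGridSpec",
    "SettlementField",
    "ConnectivityMatrix",
    "build_settlement_grid",
    "settlement_weights",
    "settlement_probability_map",
    "sum_settlement",
    "build_catchments",
    "catchments_to_geojson",
    "connectivity_matrix",
]


@dataclass(frozen=True)
class SettlementGridSpec:
    resolution_deg: float = 0.015
    depth_threshold_m: float = 10.0
    competency_window_days: tuple[float, float] = (27.0, 33.0)

    def __post_init__(self) -> None:
        if self.resolution_deg <= 0:
            raise ValueError("resolution must be positive")
        w0, w1 = self.competency_window_days
        if not w0 < w1:
            raise ValueError("competency window start must precede its end")


def build_settlement_grid(bathy: BathymetryGrid, spec: SettlementGridSpec) -> BathymetryGrid:
    """The settlement grid over the same extent, at the requested resolution.

    If the resolution matches the bathymetry grid the grid is reused;
    otherwise depth and mask are sampled at the new cell centres.
    """
    step = bathy.lon_edges[1] - bathy.lon_edges[0]
    if abs(step - spec.resolution_deg) < 1e-12:
        return bathy
    res = spec.resolution_deg
    lon_edges = np.arange(bathy.lon_edges[0], bathy.lon_edges[-1] + 0.5 * res, res)
    lat_edges = np.arange(bathy.lat_edges[0], bathy.lat_edges[-1] + 0.5 * res, res)
    lon_c = 0.5 * (lon_edges[:-1] + lon_edges[1:])
    lat_c = 0.5 * (lat_edges[:-1] + lat_edges[1:])
    LON, LAT = np.meshgrid(lon_c, lat_c)
    iy, ix = bathy.cell_index(LON.ravel(), LAT.ravel())
    iy = np.clip(iy, 0, bathy.shape[0] - 1)
    ix = np.clip(ix, 0, bathy.shape[1] - 1)
    depth = bathy.depth[iy, ix].reshape(LON.shape)
    land = bathy.land_mask[iy, ix].reshape(LON.shape)
    return BathymetryGrid(lon_edges, lat_edges, depth, land, features=bathy.features)


def settlement_weights(
    traj: TrajectorySet,
    grid: BathymetryGrid,
    spec: SettlementGridSpec = SettlementGridSpec(),
) -> sp.csr_matrix:
    """Per-larva settlement probabilities over grid cells.

    Returns a sparse ``(n_particles, n_cells)`` matrix: row ``p`` holds
    larva ``p``'s probability mass, the fraction of the competency
    window it spent in each settleable (water, depth below threshold)
    cell.  Rows sum to at most 1.  Larvae lost from the domain get
    all-zero rows, as do trajectories that end before the window opens.
    """
    w0, w1 = spec.competency_window_days
    if traj.span_hours < w0 * 24.0 - 1e-9:
        # immature: the track never reaches the competency window
        return sp.csr_matrix((traj.n_particles, grid.shape[0] * grid.shape[1]))
    w1_eff = min(w1, traj.span_hours / 24.0)
    lon_w, lat_w, dwell = positions_during(traj, w0, w1_eff)
    window_h = (w1 - w0) * 24.0

    ny, nx = grid.shape
    n, m = lon_w.shape
    lon_f = lon_w.ravel()
    lat_f = lat_w.ravel()
    valid = np.isfinite(lon_f) & np.asarray(grid.is_water(np.nan_to_num(lon_f), np.nan_to_num(lat_f)))
    iy, ix = grid.cell_index(np.nan_to_num(lon_f), np.nan_to_num(lat_f))
    iy = np.clip(iy, 0, ny - 1)
    ix = np.clip(ix, 0, nx - 1)
    shallow = grid.depth[iy, ix] < spec.depth_threshold_m
    ok = valid & shallow & np.repeat(traj.status != STATUS_LOST_DOMAIN, m)

    rows = np.repeat(np.arange(n), m)[ok]
    cols = (iy * nx + ix)[ok]
    vals = np.tile(dwell / window_h, n)[ok]
    mat = sp.coo_matrix((vals, (rows, cols)), shape=(n, ny * nx)).tocsr()
    mat.sum_duplicates()
    return mat


def settlement_probability_map(
    traj: TrajectorySet,
    grid: BathymetryGrid,
    spec: SettlementGridSpec = SettlementGridSpec(),
    particle: int = 0,
) -> dict[tuple[int, int], float]:
    """One larva's settlement probabilities as ``{(iy, ix): weight}``."""
    row = settlement_weights(traj, grid, spec).getrow(particle).tocoo()
    nx = grid.shape[1]
    return {(int(c // nx), int(c % nx)): float(v) for c, v in zip(row.col, row.data)}


@dataclass
class SettlementField:
    """Summed settlement probability mass per grid cell."""

    grid: BathymetryGrid
    mass: np.ndarray  # (ny, nx)
    n_larvae: int

    @property
    def total_mass(self) -> float:
        return float(self.mass.sum())


def sum_settlement(weights: sp.spmatrix | list, grid: BathymetryGrid) -> SettlementField:
    """Cellwise sum of per-larva settlement maps.

    ``weights`` is one sparse per-larva matrix or a list of them (all on
    the same grid).  Total mass never exceeds the larva count.
    """
    mats = weights if isinstance(weights, list) else [weights]
    ncells = grid.shape[0] * grid.shape[1]
    mass = np.zeros(ncells)
    n = 0
    for m in mats:
        if m.shape[1] != ncells:
            raise ValueError("settlement maps are not on the given grid")
        mass += np.asarray(m.sum(axis=0)).ravel()
        n += m.shape[0]
    return SettlementField(grid=grid, mass=mass.reshape(grid.shape), n_larvae=n)


# ---------------------------------------------------------------------------
# catchments and connectivity
# ---------------------------------------------------------------------------


def build_catchments(
    grid: BathymetryGrid,
    sites: SiteSet,
    radius_deg: float = 0.03,
    depth_threshold_m: float = 10.0,
) -> dict[int, np.ndarray]:
    """Flat cell indices attributed to each site.

    A cell belongs to a site's catchment when its centre lies within
    ``radius_deg`` of the site and its depth is below the settlement
    threshold.  Overlapping catchments (sites closer than twice the
    radius) are allowed but warned about.
    """
    LON, LAT = np.meshgrid(grid.lon_centers, grid.lat_centers)
    shallow = grid.water_mask & (grid.depth < depth_threshold_m)
    out: dict[int, np.ndarray] = {}
    for s in sites:
        near = (np.hypot(LON - s.lon, LAT - s.lat) <= radius_deg) & shallow
        out[s.site_id] = np.nonzero(near.ravel())[0]
    for i, a in enumerate(sites):
        for b_ in sites.sites[i + 1 :]:
            if np.hypot(a.lon - b_.lon, a.lat - b_.lat) < 2 * radius_deg:
                warnings.warn(
                    f"catchments of sites {a.site_id} and {b_.site_id} may overlap",
                    stacklevel=2,
                )
    return out


def catchments_to_geojson(grid: BathymetryGrid, catchments: dict[int, np.ndarray], path=None) -> dict:
    """Catchments as a GeoJSON FeatureCollection of dissolved cell polygons."""
    import json

    from shapely.geometry import box, mapping
    from shapely.ops import unary_union

    nx = grid.shape[1]
    features = []
    for site_id, cells in catchments.items():
        boxes = [
            box(
                grid.lon_edges[c % nx],
                grid.lat_edges[c // nx],
                grid.lon_edges[c % nx + 1],
                grid.lat_edges[c // nx + 1],
            )
            for c in cells
        ]
        geom = mapping(unary_union(boxes)) if boxes else None
        features.append(
            {"type": "Feature", "properties": {"site_id": int(site_id)}, "geometry": geom}
        )
    collection = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(collection, fh)
    return collection


@dataclass
class ConnectivityMatrix:
    """Site-by-site transfer percentages.

    ``values`` rows are origin sites, columns destination sites, in
    percent of larvae released from the origin.  In backward mode the
    "origin" is the settlement site and the columns are inferred source
    sites.  Degree counts use the printed-matrix dialect: a transfer
    counts only if it is still nonzero after rounding to 2 decimals.
    """

    direction: str
    values: pd.DataFrame  # % of released larvae, full precision
    released: pd.Series
    display_decimals: int = 2

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("connectivity values must be non-negative")

    @property
    def retention(self) -> pd.Series:
        return pd.Series(np.diag(self.values), index=self.values.index, name="retention")

    def displayed(self) -> pd.DataFrame:
        return self.values.round(self.display_decimals)

    @property
    def recipients_per_site(self) -> pd.Series:
        """Per origin site, the number of other sites it donated larvae to."""
        d = self.displayed().to_numpy().copy()
        np.fill_diagonal(d, 0.0)
        return pd.Series((d > 0).sum(axis=1), index=self.values.index, name="n_donated_to")

    @property
    def donors_per_site(self) -> pd.Series:
        """Per destination site, the number of other sites it received from."""
        d = self.displayed().to_numpy().copy()
        np.fill_diagonal(d, 0.0)
        return pd.Series((d > 0).sum(axis=0), index=self.values.columns, name="n_received_from")

    def to_csv(self, path) -> None:
        out = self.displayed().copy()
        out["n_donated_to"] = self.recipients_per_site
        out.to_csv(path)


def connectivity_matrix(
    maps_by_origin: dict[int, sp.spmatrix],
    catchments: dict[int, np.ndarray],
    released: dict[int, int],
    direction: str = "forward",
) -> ConnectivityMatrix:
    """Aggregate per-larva settlement maps into site-to-site percentages.

    ``value(i, j) = 100 × (settlement mass of larvae from i inside
    catchment j) / released(i)``; the diagonal is local retention.
    """
    origins = list(maps_by_origin)
    dests = list(catchments)
    for i in origins:
        if i not in released:
            raise KeyError(f"no released count for site {i}")
    vals = np.zeros((len(origins), len(dests)))
    for r, i in enumerate(origins):
        m = maps_by_origin[i]
        cell_mass = np.asarray(m.sum(axis=0)).ravel()
        for c, j in enumerate(dests):
            vals[r, c] = 100.0 * cell_mass[catchments[j]].sum() / released[i]
    values = pd.DataFrame(vals, index=origins, columns=dests)
    rel = pd.Series({i: released[i] for i in origins}, name="released")
    return ConnectivityMatrix(direction=direction, values=values, released=rel)
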