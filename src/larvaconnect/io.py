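"""File interchange: NetCDF fields, CSV tables, minimal VCF genotypes.

NetCDF files use CF-style axes (lon, lat, depth, time) written through
xarray's scipy backend (classic NETCDF3_64BIT), so they round-trip
without compiled NetCDF4 libraries.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .grids import BathymetryGrid, FlowFieldSeries, Site, SiteSet
from .genotypes import GenotypeDataset, MISSING
from .release import ReleaseEvent, SpawningConfig
from .transport import TrajectorySet

__all__ = [
    "save_bathymetry",
    "load_bathymetry",
    "save_flow_field",
    "load_flow_field",
    "save_sites",
    "load_sites",
    "save_schedule",
    "load_schedule",
    "save_trajectories",
    "load_trajectories",
    "save_dosage_csv",
    "load_dosage_csv",
    "read_vcf_dosages",
    "load_admixture_csv",
    "load_spawning_config_yaml",
]

_NC = dict(engine="scipy", format="NETCDF3_64BIT")


def _decode(value) -> str:
    return value.decode() if isinstance(value, bytes) else str(value)


def save_bathymetry(bathy: BathymetryGrid, path) -> None:
    ds = xr.Dataset(
        {
            "depth": (("lat", "lon"), bathy.depth),
            "land_mask": (("lat", "lon"), bathy.land_mask.astype(np.int8)),
        },
        coords={
            "lon": bathy.lon_centers,
            "lat": bathy.lat_centers,
            "lon_edges": ("lon_edge", bathy.lon_edges),
            "lat_edges": ("lat_edge", bathy.lat_edges),
        },
        attrs={"depth_units": "m positive down"},
    )
    ds.to_netcdf(path, **_NC)


def load_bathymetry(path) -> BathymetryGrid:
    with xr.open_dataset(path, engine="scipy") as ds:
        return BathymetryGrid(
            lon_edges=ds["lon_edges"].values,
            lat_edges=ds["lat_edges"].values,
            depth=ds["depth"].values,
            land_mask=ds["land_mask"].values.astype(bool),
        )


def save_flow_field(field: FlowFieldSeries, path) -> None:
    ds = xr.Dataset(
        {
            "u": (("time", "depth", "lat", "lon"), field.u),
            "v": (("time", "depth", "lat", "lon"), field.v),
            "temperature": (("time", "depth", "lat", "lon"), field.temperature),
            "bathy_depth": (("lat", "lon"), field.bathy.depth),
            "land_mask": (("lat", "lon"), field.bathy.land_mask.astype(np.int8)),
        },
        coords={
            "time": field.times,
            "depth": field.depth_levels,
            "lon": field.bathy.lon_centers,
            "lat": field.bathy.lat_centers,
            "lon_edges": ("lon_edge", field.bathy.lon_edges),
            "lat_edges": ("lat_edge", field.bathy.lat_edges),
        },
        attrs={"time_units": "hours since simulation start", "velocity_units": "m s-1"},
    )
    ds.to_netcdf(path, **_NC)


def load_flow_field(path) -> FlowFieldSeries:
    with xr.open_dataset(path, engine="scipy") as ds:
        bathy = BathymetryGrid(
            lon_edges=ds["lon_edges"].values,
            lat_edges=ds["lat_edges"].values,
            depth=ds["bathy_depth"].values,
            land_mask=ds["land_mask"].values.astype(bool),
        )
        return FlowFieldSeries(
            bathy=bathy,
            times=ds["time"].values,
            depth_levels=ds["depth"].values,
            u=ds["u"].values,
            v=ds["v"].values,
            temperature=ds["temperature"].values,
        )


def save_sites(sites: SiteSet, path) -> None:
    sites.to_frame().to_csv(path, index=False)


def load_sites(path) -> SiteSet:
    df = pd.read_csv(path)
    return SiteSet(
        [
            Site(int(r.site_id), str(r.name), float(r.lon), float(r.lat), str(r.category))
            for r in df.itertuples(index=False)
        ]
    )


def save_schedule(events: list[ReleaseEvent], path) -> None:
    pd.DataFrame(
        {
            "site_id": [e.site_id for e in events],
            "mode": [e.mode for e in events],
            "time_h": [e.time for e in events],
            "lon": [e.lon for e in events],
            "lat": [e.lat for e in events],
            "release_depth_m": [e.release_depth for e in events],
            "drift_depth_m": [e.drift_depth for e in events],
        }
    ).to_csv(path, index=False)


def load_schedule(path) -> list[ReleaseEvent]:
    df = pd.read_csv(path)
    return [
        ReleaseEvent(
            site_id=int(r.site_id),
            time=float(r.time_h),
            lon=float(r.lon),
            lat=float(r.lat),
            release_depth=float(r.release_depth_m),
            drift_depth=float(r.drift_depth_m),
            mode=str(r.mode),
        )
        for r in df.itertuples(index=False)
    ]


def save_trajectories(traj: TrajectorySet, path) -> None:
    ds = xr.Dataset(
        {
            "lon": (("particle", "age"), traj.lon),
            "lat": (("particle", "age"), traj.lat),
            "status": (("particle",), traj.status.astype(np.int8)),
            "release_time": (("particle",), traj.release_time),
            "drift_depth": (("particle",), traj.drift_depth),
            "site_id": (("particle",), traj.site_id.astype(np.int32)),
        },
        coords={"age": traj.age_hours},
        attrs={"trace_mode": traj.mode, "age_units": "hours since release"},
    )
    ds.to_netcdf(path, **_NC)


def load_trajectories(path) -> TrajectorySet:
    with xr.open_dataset(path, engine="scipy") as ds:
        return TrajectorySet(
            lon=ds["lon"].values,
            lat=ds["lat"].values,
            age_hours=ds["age"].values,
            release_time=ds["release_time"].values,
            drift_depth=ds["drift_depth"].values,
            site_id=ds["site_id"].values.astype(int),
            status=ds["status"].values,
            mode=_decode(ds.attrs["trace_mode"]),
        )


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def save_dosage_csv(data: GenotypeDataset, path) -> None:
    """Individuals as rows, loci as columns; missing cells left empty."""
    df = pd.DataFrame(
        data.dosages.astype(float),
        index=data.individuals,
        columns=[f"locus_{j}" for j in range(data.n_loci)],
    )
    df[data.dosages == MISSING] = np.nan
    df.insert(0, "pop_label", data.pop_label)
    df.insert(1, "depth_fraction", data.depth_fraction)
    df.to_csv(path, index_label="individual", float_format="%.6g")


def load_dosage_csv(path) -> GenotypeDataset:
    df = pd.read_csv(path, index_col="individual")
    pop = df.pop("pop_label").tolist() if "pop_label" in df else ["unknown"] * len(df)
    depth = (
        df.pop("depth_fraction").to_numpy()
        if "depth_fraction" in df
        else np.ones(len(df))
    )
    dosages = df.to_numpy(dtype=float)
    out = np.where(np.isnan(dosages), MISSING, dosages).astype(np.int8)
    n = out.shape[0]
    return GenotypeDataset(
        individuals=list(df.index.astype(str)),
        dosages=out,
        depth_fraction=np.asarray(depth, dtype=float),
        pop_label=pop,
        true_admixture=np.full((n, 1), 1.0),
        replicate_of=np.full(n, -1),
        relative_of=np.full(n, -1),
    )


def read_vcf_dosages(path) -> tuple[list[str], np.ndarray]:
    """Alternate-allele dosages from a minimal diploid VCF (GT only).

    Returns (sample names, individuals x loci dosage matrix with -1 for
    './.' missing calls).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols = []
    for variant in vcf:
        geno = np.array([g[:2] for g in variant.genotypes], dtype=int)
        dose = geno.sum(axis=1)
        dose[(geno < 0).any(axis=1)] = MISSING
        cols.append(dose.astype(np.int8))
    vcf.close()
    if not cols:
        raise ValueError("VCF contains no variant records")
    return samples, np.column_stack(cols)


def load_admixture_csv(path) -> pd.DataFrame:
    """Admixture table: index = individual, one column per cluster."""
    df = pd.read_csv(path, index_col=0)
    keep = [c for c in df.columns if np.issubdtype(df[c].dtype, np.number)]
    return df[keep]


def load_spawning_config_yaml(path) -> SpawningConfig:
    """Read a spawning configuration from YAML.

    Expected keys: ``windows`` (list of {start, end, fraction} ISO
    dates), optional ``n_total``, ``min_per_hour`` and ``t0``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    windows = tuple(
        (
            dt.date.fromisoformat(str(w["start"])),
            dt.date.fromisoformat(str(w["end"])),
            float(w["fraction"]),
        )
        for w in raw["windows"]
    )
    kw = {}
    if "n_total" in raw:
        kw["n_total"] = int(raw["n_total"])
    if "min_per_hour" in raw:
        kw["min_per_hour"] = int(raw["min_per_hour"])
    if "t0" in raw:
        kw["t0"] = dt.date.fromisoformat(str(raw["t0"]))
    return SpawningConfig(windows=windows, **kw)
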