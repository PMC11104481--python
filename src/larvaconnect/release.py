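"""Release scheduling and the temperature–development-time model.

Spawning windows, the 75/25 split between the main and late season, the
at-least-one-larva-per-hour constraint, drift-depth and bed-depth quota
assignment, and the logarithmic temperature vs. days-to-settlement curve.

All apportionment is deterministic (largest-remainder quotas) so that the
configured proportions are realized exactly; the seeded RNG only places
depths uniformly inside ranged bands and shuffles the depth-to-event
assignment.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grids import Site, FlowFieldSeries

__all__ = [
    "SpawningConfig",
    "DepthQuota",
    "DRIFT_DEPTH_QUOTA",
    "BED_DEPTH_QUOTA",
    "DevelopmentModel",
    "ReleaseEvent",
    "schedule_releases",
    "assign_depths",
    "development_time",
    "site_mean_development_time",
]


@dataclass(frozen=True)
class DepthQuota:
    """Depth bands with weights summing to 1.

    A band is either a range ``(lower, upper, weight)`` — depths drawn
    uniformly inside — or a point ``(value, weight)``.
    """

    bands: tuple[tuple, ...]

    def __post_init__(self) -> None:
        w = sum(b[-1] for b in self.bands)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("quota weights must sum to 1")
        ranges = [b for b in self.bands if len(b) == 3]
        ranges.sort(key=lambda b: b[0])
        for a, b in zip(ranges, ranges[1:]):
            if b[0] < a[1]:
                raise ValueError("quota bands must not overlap")


#: larval drift depth: 40% at 0–10 m, 40% at 10–20 m, 20% at 20–30 m
DRIFT_DEPTH_QUOTA = DepthQuota(((0.0, 10.0, 0.4), (10.0, 20.0, 0.4), (20.0, 30.0, 0.2)))
#: mussel-bed depth: 70% at 0.5 m, 10% each at 2, 4 and 6 m
BED_DEPTH_QUOTA = DepthQuota(((0.5, 0.7), (2.0, 0.1), (4.0, 0.1), (6.0, 0.1)))


@dataclass(frozen=True)
class SpawningConfig:
    """Release windows (inclusive dates) with fractions, and the totals.

    ``t0`` anchors the simulation clock: hour 0 is midnight of ``t0``.
    Forward (spawning) defaults put 75% of releases in May 15 – Jul 14 and
    25% in Jul 15 – Aug 14; backward (settlement) windows are those plus
    30 days.  3000 larvae per site with at least one release per hour.
    """

    windows: tuple[tuple[dt.date, dt.date, float], ...]
    n_total: int = 3000
    min_per_hour: int = 1
    t0: dt.date | None = None

    def __post_init__(self) -> None:
        if abs(sum(f for _, _, f in self.windows) - 1.0) > 1e-9:
            raise ValueError("window fractions must sum to 1")
        spans = sorted((s, e) for s, e, _ in self.windows)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("windows must not overlap")
        if self.n_total < self.total_hours * self.min_per_hour:
            raise ValueError(
                "cannot satisfy min-per-hour: "
                f"{self.n_total} releases over {self.total_hours} hours"
            )

    @property
    def start(self) -> dt.date:
        return self.t0 if self.t0 is not None else min(s for s, _, _ in self.windows)

    def window_hours(self) -> list[tuple[int, int]]:
        """Per window: (start hour since t0, number of hour slots)."""
        out = []
        for s, e, _ in self.windows:
            start_h = (s - self.start).days * 24
            n_h = ((e - s).days + 1) * 24  # end date inclusive
            out.append((start_h, n_h))
        return out

    @property
    def total_hours(self) -> int:
        return sum(h for _, h in self.window_hours())

    @classmethod
    def forward_default(cls, year: int = 2017, **kw) -> "SpawningConfig":
        return cls(
            windows=(
                (dt.date(year, 5, 15), dt.date(year, 7, 14), 0.75),
                (dt.date(year, 7, 15), dt.date(year, 8, 14), 0.25),
            ),
            **kw,
        )

    @classmethod
    def backward_default(cls, year: int = 2017, **kw) -> "SpawningConfig":
        # spawning windows shifted +30 days: settlement-period releases
        return cls(
            windows=(
                (dt.date(year, 6, 15), dt.date(year, 8, 14), 0.75),
                (dt.date(year, 8, 15), dt.date(year, 9, 14), 0.25),
            ),
            **kw,
        )


@dataclass(frozen=True)
class DevelopmentModel:
    """Days to settlement as a logarithmic function of temperature.

    ``days = a * ln(temperature_C) + b``; fitted to published larval
    rearing data (the ``r_squared`` is metadata of that fit, not used in
    computation).  Valid only for temperatures > 0 °C.
    """

    a: float = -28.06
    b: float = 101.32
    r_squared: float = 0.7545
    valid_range_c: tuple[float, float] = (1.0, 25.0)


@dataclass(frozen=True)
class ReleaseEvent:
    site_id: int
    time: float  # hours since simulation start (t0)
    lon: float
    lat: float
    release_depth: float  # m, at the mussel bed
    drift_depth: float  # m, fixed depth the larva drifts at
    mode: str  # "forward" | "backward"


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _window_counts(config: SpawningConfig) -> list[int]:
    counts = [_round_half_up(f * config.n_total) for _, _, f in config.windows]
    counts[0] += config.n_total - sum(counts)  # remainder to the first window
    return counts


def _hour_counts(n_events: int, n_hours: int) -> np.ndarray:
    """Spread ``n_events`` over ``n_hours`` slots: floor quota everywhere,
    the remainder at evenly spaced hour indices."""
    base = n_events // n_hours
    counts = np.full(n_hours, base, dtype=int)
    r = n_events - base * n_hours
    if r > 0:
        idx = (np.arange(r) * n_hours) // r
        counts[idx] += 1
    return counts


def schedule_releases(
    site: Site,
    config: SpawningConfig,
    mode: str = "forward",
    seed: int = 0,
    drift_quota: DepthQuota = DRIFT_DEPTH_QUOTA,
    bed_quota: DepthQuota = BED_DEPTH_QUOTA,
) -> list[ReleaseEvent]:
    """Build the deterministic release schedule for one site.

    Exactly ``config.n_total`` events; window counts follow the configured
    fractions by round-half-up apportionment, hours within a window by an
    even deterministic quota, so every hour slot of every window receives
    at least ``min_per_hour`` events.  Only the within-band depth draws
    and the depth-to-event shuffle consume the seed.
    """
    if mode not in ("forward", "backward"):
        raise ValueError(f"mode must be 'forward' or 'backward', got {mode!r}")
    counts = _window_counts(config)
    times: list[float] = []
    for (start_h, n_h), n_w in zip(config.window_hours(), counts):
        if n_w < n_h * config.min_per_hour:
            raise ValueError(
                f"cannot satisfy min-per-hour: window has {n_w} events for {n_h} hours"
            )
        per_hour = _hour_counts(n_w, n_h)
        for h, c in enumerate(per_hour):
            times.extend([float(start_h + h)] * int(c))

    n = len(times)
    assert n == config.n_total
    rng = np.random.default_rng(seed)
    drift_depths = assign_depths(n, drift_quota, seed=rng.integers(2**31))
    bed_depths = assign_depths(n, bed_quota, seed=rng.integers(2**31))
    # decouple depth from release time
    rng.shuffle(drift_depths)
    rng.shuffle(bed_depths)

    return [
        ReleaseEvent(
            site_id=site.site_id,
            time=t,
            lon=site.lon,
            lat=site.lat,
            release_depth=float(bd),
            drift_depth=float(dd),
            mode=mode,
        )
        for t, dd, bd in zip(times, drift_depths, bed_depths)
    ]


def assign_depths(n: int, quota: DepthQuota, seed: int = 0) -> np.ndarray:
    """Draw ``n`` depths honouring the quota weights exactly.

    Band counts come from largest-remainder apportionment of
    ``weight * n`` (ties broken by band order); ranged bands are filled
    uniformly at random, point bands return the point value.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    weights = np.array([b[-1] for b in quota.bands])
    ideal = weights * n
    counts = np.floor(ideal).astype(int)
    remainder = n - counts.sum()
    if remainder > 0:
        order = np.argsort(-(ideal - counts), kind="stable")
        counts[order[:remainder]] += 1
    rng = np.random.default_rng(seed)
    depths = []
    for band, c in zip(quota.bands, counts):
        if len(band) == 3:
            lo, hi, _ = band
            depths.append(rng.uniform(lo, hi, size=c))
        else:
            depths.append(np.full(c, band[0]))
    return np.concatenate(depths)


def development_time(temperature_c, model: DevelopmentModel = DevelopmentModel()):
    """Days from release to settlement at the given water temperature."""
    x = np.asarray(temperature_c, dtype=float)
    if np.any(x <= 0):
        raise ValueError("development model requires temperature > 0 degC")
    out = model.a * np.log(x) + model.b
    return float(out) if out.ndim == 0 else out


def site_mean_development_time(
    site: Site,
    field: FlowFieldSeries,
    window_hours: tuple[float, float],
    model: DevelopmentModel = DevelopmentModel(),
    depth_m: float | None = None,
) -> float:
    """Mean predicted development time from hourly site temperatures.

    Temperatures are sampled at the site position (nearest water cell,
    nearest depth level, linear in time) at every whole hour in
    ``window_hours``; land cells are never sampled.
    """
    from .transport import sample_temperature

    t0, t1 = window_hours
    if t0 < field.times[0] or t1 > field.times[-1] or t1 <= t0:
        raise ValueError("window outside the flow-field time span")
    hours = np.arange(t0, t1 + 1e-9)
    z = field.depth_levels[0] if depth_m is None else depth_m
    temps = sample_temperature(
        field,
        np.full(hours.size, site.lon),
        np.full(hours.size, site.lat),
        np.full(hours.size, z),
        hours,
    )
    return float(np.mean(development_time(temps, model)))
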