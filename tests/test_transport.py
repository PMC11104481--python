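"""Tracker physics: interpolation, advection, diffusion, reversibility."""

import numpy as np
import pytest

from conftest import make_uniform_field
from larvaconnect.grids import meters_per_degree_lon, M_PER_DEG_LAT
from larvaconnect.release import ReleaseEvent
from larvaconnect.synthetic import FlowConfig, make_flow_field
from larvaconnect.transport import (
    STATUS_DRIFTING,
    STATUS_LOST_DOMAIN,
    TrackerConfig,
    advect,
    positions_during,
    sample_velocity,
)


def _event(lon=10.5, lat=58.5, t=0.0, depth=5.0, mode="forward", site=1):
    return ReleaseEvent(site, t, lon, lat, 0.5, depth, mode)


class TestSampleVelocity:
    def test_constant_field_everywhere(self, flat_bathy):
        f = make_uniform_field(flat_bathy, 0.1, 0.0)
        u, v = sample_velocity(f, [10.3, 10.7], [58.2, 58.9], [5.0, 5.0], [0.0, 10.0])
        np.testing.assert_allclose(u, 0.1)
        np.testing.assert_allclose(v, 0.0)

    def test_identity_at_cell_center_and_stored_time(self, flat_bathy):
        f = make_uniform_field(flat_bathy, 0.0, 0.0)
        f.u[:, :, 10, 10] = 0.37
        lon_c = flat_bathy.lon_centers[10]
        lat_c = flat_bathy.lat_centers[10]
        u, _ = sample_velocity(f, lon_c, lat_c, 5.0, 0.0)
        assert u == pytest.approx(0.37, abs=1e-15)

    def test_midpoint_bilinear_average(self, flat_bathy):
        f = make_uniform_field(flat_bathy, 0.0, 0.0)
        f.u[:, :, 10, 10] = 0.0
        f.u[:, :, 10, 11] = 0.2
        mid = 0.5 * (flat_bathy.lon_centers[10] + flat_bathy.lon_centers[11])
        u, _ = sample_velocity(f, mid, flat_bathy.lat_centers[10], 5.0, 0.0)
        assert u == pytest.approx(0.1, abs=1e-12)

    def test_land_point_rejected(self, mini_domain):
        f = make_flow_field(mini_domain, FlowConfig())
        land_lat = 58.0
        with pytest.raises(ValueError, match="land"):
            sample_velocity(f, 11.95, land_lat, 5.0, 0.0)

    def test_time_outside_span_rejected(self, flat_bathy):
        f = make_uniform_field(flat_bathy, 0.1, 0.0, duration_h=24.0)
        with pytest.raises(ValueError, match="time span"):
            sample_velocity(f, 10.5, 58.5, 5.0, 100.0)


class TestAdvection:
    def test_uniform_flow_matches_closed_form(self, flat_bathy):
        """u*t displacement within 0.1% after one day of eastward drift."""
        f = make_uniform_field(flat_bathy, 0.1, 0.0)
        cfg = TrackerConfig(horizontal_diffusivity=0.0)
        traj = advect([_event()], f, config=cfg, duration_days=1.0)
        dlon = traj.lon[0, -1] - traj.lon[0, 0]
        lat = traj.lat[0, -1]
        disp_m = dlon * meters_per_degree_lon(lat)
        assert disp_m == pytest.approx(0.1 * 86400.0, rel=1e-3)
        assert traj.lat[0, -1] == pytest.approx(58.5, abs=1e-12)

    def test_zero_field_keeps_position_exactly(self, flat_bathy):
        f = make_uniform_field(flat_bathy, 0.0, 0.0)
        cfg = TrackerConfig(horizontal_diffusivity=0.0)
        traj = advect([_event()], f, config=cfg, duration_days=1.0)
        assert traj.lon[0, -1] == 10.5
        assert traj.lat[0, -1] == 58.5

    def test_forward_backward_time_reversal_closure(self, flat_bathy):
        """27 d forward then 27 d backward in a steady gyre returns to the
        start within 1e-3 of the excursion distance (RK4, no diffusion)."""
        f = make_flow_field(
            flat_bathy,
            FlowConfig(gyre_strength=0.05, jet_speed=0.0, duration_days=30.0),
        )
        cfg = TrackerConfig(horizontal_diffusivity=0.0)
        start = (10.3, 58.4)
        fwd = advect([_event(*start)], f, config=cfg, mode="forward", duration_days=27.0)
        assert fwd.status[0] == STATUS_DRIFTING
        q = (fwd.lon[0, -1], fwd.lat[0, -1])
        back_ev = _event(q[0], q[1], t=27.0 * 24.0, mode="backward")
        bwd = advect([back_ev], f, config=cfg, mode="backward", duration_days=27.0)
        p2 = (bwd.lon[0, -1], bwd.lat[0, -1])
        mlon = meters_per_degree_lon(58.4)
        excursion = np.hypot((q[0] - start[0]) * mlon, (q[1] - start[1]) * M_PER_DEG_LAT)
        error = np.hypot((p2[0] - start[0]) * mlon, (p2[1] - start[1]) * M_PER_DEG_LAT)
        assert excursion > 1000  # the particle actually went somewhere
        assert error < 1e-3 * excursion

    def test_backward_field_time_decreases(self, flat_bathy):
        f = make_uniform_field(flat_bathy, 0.05, 0.0, duration_h=48.0)
        traj = advect(
            [_event(t=48.0, mode="backward")],
            f,
            config=TrackerConfig(horizontal_diffusivity=0.0),
            duration_days=1.0,
        )
        ft = traj.field_time()[0]
        assert np.all(np.diff(ft) < 0)

    def test_diffusion_displacement_statistics(self, flat_bathy):
        """With zero mean flow, per-axis displacement variance after time t
        is 2*Kh*t and the mean is 0, within 3 SE over 1000 particles."""
        f = make_uniform_field(flat_bathy, 0.0, 0.0, duration_h=30.0)
        kh = 1.0
        cfg = TrackerConfig(horizontal_diffusivity=kh, seed=123)
        events = [_event() for _ in range(1000)]
        t_days = 1.0
        traj = advect(events, f, config=cfg, duration_days=t_days)
        t_s = t_days * 86400.0
        dx = (traj.lon[:, -1] - traj.lon[:, 0]) * meters_per_degree_lon(58.5)
        dy = (traj.lat[:, -1] - traj.lat[:, 0]) * M_PER_DEG_LAT
        expected = 2.0 * kh * t_s
        n = dx.size
        se_var = expected * np.sqrt(2.0 / (n - 1))
        for d in (dx, dy):
            assert abs(d.var(ddof=1) - expected) < 3 * se_var
            assert abs(d.mean()) < 3 * np.sqrt(expected / n)

    def test_zero_diffusion_is_seed_independent(self, flat_bathy):
        f = make_uniform_field(flat_bathy, 0.05, 0.02)
        t1 = advect([_event()], f, config=TrackerConfig(horizontal_diffusivity=0.0, seed=1), duration_days=1.0)
        t2 = advect([_event()], f, config=TrackerConfig(horizontal_diffusivity=0.0, seed=2), duration_days=1.0)
        assert np.array_equal(t1.lon, t2.lon)
        assert np.array_equal(t1.lat, t2.lat)

    def test_no_position_on_land_with_reflection(self, mini_domain):
        f = make_flow_field(mini_domain, FlowConfig(jet_speed=0.2, duration_days=12.0))
        rng = np.random.default_rng(0)
        # release on the shallow fringe where the jet pushes along the coast
        events = [
            _event(11.55 + rng.uniform(-0.01, 0.01), 57.7 + i * 0.01, depth=2.0)
            for i in range(40)
        ]
        traj = advect(events, f, config=TrackerConfig(seed=4), duration_days=10.0)
        drifting = traj.status == STATUS_DRIFTING
        for p in np.nonzero(drifting)[0]:
            assert np.all(mini_domain.is_water(traj.lon[p], traj.lat[p]))

    def test_boundary_crossing_flags_lost_and_freezes(self, flat_bathy):
        f = make_uniform_field(flat_bathy, 0.5, 0.0, duration_h=96.0)
        traj = advect(
            [_event(lon=10.95)], f, config=TrackerConfig(horizontal_diffusivity=0.0),
            duration_days=2.0,
        )
        assert traj.status[0] == STATUS_LOST_DOMAIN
        final = traj.lon[0, -1]
        assert final < 11.0
        # frozen: last positions stop changing
        assert traj.lon[0, -1] == traj.lon[0, -2]

    def test_insufficient_field_duration_rejected(self, flat_bathy):
        f = make_uniform_field(flat_bathy, 0.1, 0.0, duration_h=24.0)
        with pytest.raises(ValueError, match="does not cover"):
            advect([_event()], f, duration_days=33.0)


class TestPositionsDuring:
    def test_full_span_dwell_conserves_duration(self, flat_bathy):
        f = make_uniform_field(flat_bathy, 0.0, 0.0, duration_h=72.0)
        traj = advect([_event()], f, config=TrackerConfig(horizontal_diffusivity=0.0), duration_days=2.0)
        _, _, dwell = positions_during(traj, 0.0, 2.0)
        assert dwell.sum() == pytest.approx(48.0)

    def test_zero_length_window_is_empty(self, flat_bathy):
        f = make_uniform_field(flat_bathy, 0.0, 0.0, duration_h=72.0)
        traj = advect([_event()], f, config=TrackerConfig(horizontal_diffusivity=0.0), duration_days=2.0)
        lon, lat, dwell = positions_during(traj, 1.0, 1.0)
        assert dwell.size == 0 and lon.shape[1] == 0

    def test_stationary_particle_dwells_at_one_point(self, flat_bathy):
        f = make_uniform_field(flat_bathy, 0.0, 0.0, duration_h=24 * 7)
        traj = advect([_event()], f, config=TrackerConfig(horizontal_diffusivity=0.0), duration_days=6.0)
        lon, lat, dwell = positions_during(traj, 0.0, 6.0)
        assert np.unique(lon).size == 1
        assert dwell.sum() == pytest.approx(6 * 24.0)

    def test_window_outside_span_rejected(self, flat_bathy):
        f = make_uniform_field(flat_bathy, 0.0, 0.0, duration_h=72.0)
        traj = advect([_event()], f, config=TrackerConfig(horizontal_diffusivity=0.0), duration_days=2.0)
        with pytest.raises(ValueError):
            positions_during(traj, 1.0, 5.0)
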