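"""Time-fraction settlement scoring and connectivity aggregation."""

import numpy as np
import pytest
import scipy.sparse as sp

from conftest import make_trajectory, worked_settlement_example
from larvaconnect.grids import BathymetryGrid, Site, SiteSet
from larvaconnect.settlement import (
    SettlementGridSpec,
    build_catchments,
    build_settlement_grid,
    connectivity_matrix,
    settlement_probability_map,
    settlement_weights,
    sum_settlement,
)
from larvaconnect.transport import STATUS_LOST_DOMAIN


def small_grid(shallow_cells=(), n=5, step=0.015, deep=50.0):
    lon_edges = 10.0 + step * np.arange(n + 1)
    lat_edges = 58.0 + step * np.arange(n + 1)
    depth = np.full((n, n), deep)
    for c in shallow_cells:
        depth[c] = 5.0
    return BathymetryGrid(lon_edges, lat_edges, depth, np.zeros((n, n), bool))


class TestSettlementScoring:
    def test_worked_half_and_tenth_example(self):
        """50% of the settling window in one shallow cell and 10% in
        another yields per-cell probabilities 0.50 and 0.10 exactly."""
        bathy, traj, cell_a, cell_b = worked_settlement_example()
        weights = settlement_probability_map(traj, bathy)
        assert weights[cell_a] == pytest.approx(0.5, abs=1e-12)
        assert weights[cell_b] == pytest.approx(0.1, abs=1e-12)
        assert set(weights) == {cell_a, cell_b}

    def test_larva_over_deep_water_scores_zero(self):
        grid = small_grid()  # all deep
        lon = np.full(793, grid.lon_centers[2])
        lat = np.full(793, grid.lat_centers[2])
        traj = make_trajectory(lon, lat)
        assert settlement_weights(traj, grid).nnz == 0

    def test_stationary_larva_in_shallow_cell_scores_one(self):
        grid = small_grid(shallow_cells=[(2, 2)])
        lon = np.full(793, grid.lon_centers[2])
        lat = np.full(793, grid.lat_centers[2])
        traj = make_trajectory(lon, lat)
        m = settlement_probability_map(traj, grid)
        assert m[(2, 2)] == pytest.approx(1.0, abs=1e-12)

    def test_lost_larva_scores_zero(self):
        grid = small_grid(shallow_cells=[(2, 2)])
        lon = np.full((1, 793), grid.lon_centers[2])
        lat = np.full((1, 793), grid.lat_centers[2])
        traj = make_trajectory(lon, lat, status=np.array([STATUS_LOST_DOMAIN], dtype=np.int8))
        assert settlement_weights(traj, grid).nnz == 0

    def test_immature_trajectory_scores_zero(self):
        grid = small_grid(shallow_cells=[(2, 2)])
        lon = np.full(100, grid.lon_centers[2])  # only ~4 days of track
        traj = make_trajectory(lon, np.full(100, grid.lat_centers[2]))
        assert settlement_weights(traj, grid).nnz == 0

    def test_no_mass_before_day_27_or_after_day_33(self):
        """Competency gating: dwell outside the window never scores, by a
        brute-force oracle over randomized shallow/deep trajectories."""
        rng = np.random.default_rng(42)
        grid = small_grid(shallow_cells=[(i, j) for i in range(5) for j in range(0, 5, 2)])
        spec = SettlementGridSpec()
        lon_c, lat_c = grid.lon_centers, grid.lat_centers
        for _ in range(10):
            iy = rng.integers(0, 5, size=793)
            ix = rng.integers(0, 5, size=793)
            traj = make_trajectory(lon_c[ix], lat_c[iy])
            got = settlement_weights(traj, grid, spec).toarray().ravel()
            # oracle: count hourly samples with age in [648, 792) only
            oracle = np.zeros(25)
            for a in range(648, 792):
                if grid.depth[iy[a], ix[a]] < 10.0:
                    oracle[iy[a] * 5 + ix[a]] += 1.0 / 144.0
            np.testing.assert_allclose(got, oracle, atol=1e-12)

    def test_row_sums_never_exceed_one(self):
        rng = np.random.default_rng(7)
        grid = small_grid(shallow_cells=[(i, j) for i in range(5) for j in range(5)])
        iy = rng.integers(0, 5, size=(8, 793))
        ix = rng.integers(0, 5, size=(8, 793))
        traj = make_trajectory(grid.lon_centers[ix], grid.lat_centers[iy])
        sums = np.asarray(settlement_weights(traj, grid).sum(axis=1)).ravel()
        assert np.all(sums <= 1.0 + 1e-9)


class TestSumSettlement:
    def test_additivity(self):
        grid = small_grid(shallow_cells=[(0, 0)])
        a = sp.csr_matrix(([0.5], ([0], [0])), shape=(1, 25))
        b = sp.csr_matrix(([0.25], ([0], [0])), shape=(1, 25))
        field = sum_settlement([a, b], grid)
        assert field.mass[0, 0] == pytest.approx(0.75)
        assert field.total_mass == pytest.approx(0.75)

    def test_empty_input_gives_zero_field(self):
        grid = small_grid()
        field = sum_settlement(sp.csr_matrix((0, 25)), grid)
        assert field.total_mass == 0.0

    def test_total_mass_bounded_by_larva_count(self):
        rng = np.random.default_rng(3)
        grid = small_grid()
        w = sp.random(20, 25, density=0.3, random_state=3) * 0.04
        field = sum_settlement(w.tocsr(), grid)
        assert field.total_mass <= field.n_larvae
        # brute-force recount
        assert field.total_mass == pytest.approx(w.toarray().sum())

    def test_grid_mismatch_rejected(self):
        grid = small_grid()
        with pytest.raises(ValueError, match="grid"):
            sum_settlement(sp.csr_matrix((1, 9)), grid)


def _sites_for(grid, positions):
    return SiteSet(
        [
            Site(k + 1, f"s{k+1}", grid.lon_centers[j], grid.lat_centers[i], "outer")
            for k, (i, j) in enumerate(positions)
        ]
    )


class TestConnectivity:
    def test_single_larva_full_transfer(self):
        grid = small_grid(shallow_cells=[(0, 0), (4, 4)])
        sites = _sites_for(grid, [(0, 0), (4, 4)])
        catch = build_catchments(grid, sites)
        m = sp.csr_matrix(([1.0], ([0], [4 * 5 + 4])), shape=(1, 25))
        cm = connectivity_matrix({1: m}, catch, {1: 10})
        assert cm.values.loc[1, 2] == pytest.approx(100.0 / 10)
        assert cm.values.loc[1, 1] == 0.0

    def test_full_retention_everywhere(self):
        grid = small_grid(shallow_cells=[(0, 0), (4, 4)])
        sites = _sites_for(grid, [(0, 0), (4, 4)])
        catch = build_catchments(grid, sites)
        maps = {
            1: sp.csr_matrix(([1.0], ([0], [0])), shape=(1, 25)),
            2: sp.csr_matrix(([1.0], ([0], [24])), shape=(1, 25)),
        }
        cm = connectivity_matrix(maps, catch, {1: 1, 2: 1})
        assert np.allclose(np.diag(cm.values), 100.0)
        assert cm.retention.tolist() == [100.0, 100.0]

    def test_row_sums_match_recount_oracle(self):
        rng = np.random.default_rng(11)
        grid = small_grid(shallow_cells=[(i, j) for i in range(5) for j in range(5)])
        sites = _sites_for(grid, [(0, 0), (2, 2), (4, 4)])
        with pytest.warns(UserWarning):
            catch = build_catchments(grid, sites, radius_deg=0.05)
        maps = {}
        released = {}
        for sid in (1, 2, 3):
            w = (sp.random(15, 25, density=0.4, random_state=sid) * 0.05).tocsr()
            maps[sid] = w
            released[sid] = 15
        cm = connectivity_matrix(maps, catch, released)
        # brute-force recount: loop over larvae and catchment cells
        for r, sid in enumerate((1, 2, 3)):
            dense = maps[sid].toarray()
            for c, dst in enumerate((1, 2, 3)):
                expected = 100.0 * dense[:, catch[dst]].sum() / released[sid]
                assert cm.values.iloc[r, c] == pytest.approx(expected)

    def test_degree_counts_use_two_decimal_display_rule(self):
        import pandas as pd
        from larvaconnect.settlement import ConnectivityMatrix

        vals = pd.DataFrame(
            [[5.0, 0.004, 0.011], [0.0, 3.0, 0.0], [1.25, 0.0, 2.0]],
            index=[1, 2, 3],
            columns=[1, 2, 3],
        )
        cm = ConnectivityMatrix("forward", vals, pd.Series([10, 10, 10], index=[1, 2, 3]))
        # 0.004 rounds to 0.00 and is not a transfer; 0.011 rounds to 0.01
        assert cm.recipients_per_site.tolist() == [1, 0, 1]
        assert cm.donors_per_site.tolist() == [1, 0, 1]

    def test_unknown_site_rejected(self):
        grid = small_grid(shallow_cells=[(0, 0)])
        sites = _sites_for(grid, [(0, 0)])
        catch = build_catchments(grid, sites)
        m = sp.csr_matrix((1, 25))
        with pytest.raises(KeyError):
            connectivity_matrix({1: m}, catch, {99: 5})

    def test_catchment_geojson_export(self, tmp_path):
        from larvaconnect.settlement import catchments_to_geojson

        grid = small_grid(shallow_cells=[(0, 0), (0, 1), (4, 4)])
        sites = _sites_for(grid, [(0, 0), (4, 4)])
        catch = build_catchments(grid, sites)
        out = catchments_to_geojson(grid, catch, path=tmp_path / "catch.geojson")
        assert out["type"] == "FeatureCollection"
        assert [f["properties"]["site_id"] for f in out["features"]] == [1, 2]
        assert (tmp_path / "catch.geojson").exists()
        # the dissolved polygon of site 1 covers its two adjacent cells
        geom = out["features"][0]["geometry"]
        assert geom["type"] in ("Polygon", "MultiPolygon")

    def test_settlement_grid_resampling(self, mini_domain):
        spec = SettlementGridSpec(resolution_deg=0.03)
        g = build_settlement_grid(mini_domain, spec)
        assert g.lon_edges[1] - g.lon_edges[0] == pytest.approx(0.03)
        assert g.shape[0] < mini_domain.shape[0]
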