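"""Oracle checks for the environmental-layer operators: analytic planes for
the terrain derivatives, brute-force references for distances and kernel
smoothing, and definitional properties of the LOOCV bandwidth search."""

import numpy as np
import pandas as pd
import pytest

from stagedist import env_layers as el
from stagedist.io_core import GridLayer

from conftest import make_casts


def _grid(vals, cellsize=0.1):
    return GridLayer("depth", np.asarray(vals, dtype=float), -8.0, 54.0,
                     cellsize)


class TestSlopeAspect:
    def test_constant_depth_gives_zero_slope(self):
        slope, aspect = el.compute_slope_aspect(_grid(np.full((8, 8), 50.0)))
        assert np.allclose(slope.values, 0.0)
        assert np.allclose(aspect.values, 0.0)   # flat convention

    @pytest.mark.parametrize("direction", ["north", "east", "south", "west"])
    def test_plane_aspect_matches_compass(self, direction):
        g = _grid(np.zeros((10, 10)))
        kx, ky = g.cell_km()
        rows, cols = np.mgrid[0:10, 0:10]
        # depth increasing in the given direction -> downslope faces it
        northing = -rows * ky * 1000          # m, row 0 is northernmost
        easting = cols * kx * 1000
        k = 0.01
        depth = {"north": k * northing, "south": -k * northing,
                 "east": k * easting, "west": -k * easting}[direction]
        slope, aspect = el.compute_slope_aspect(g.like(depth - depth.min()
                                                       + 10, "depth"))
        expected = {"north": 0.0, "east": 90.0, "south": 180.0,
                    "west": 270.0}[direction]
        interior = aspect.values[1:-1, 1:-1]
        assert np.allclose(interior, expected, atol=1e-10)
        assert np.allclose(slope.values[1:-1, 1:-1], np.arctan(k), atol=1e-10)

    def test_plane_slope_magnitude_any_gradient(self):
        g = _grid(np.zeros((12, 12)))
        kx, ky = g.cell_km()
        rows, cols = np.mgrid[0:12, 0:12]
        gx, gy = 0.004, 0.003           # gradient of elevation, per metre
        z = gx * cols * kx * 1000 + gy * (-rows) * ky * 1000
        slope, _ = el.compute_slope_aspect(g.like(-z + z.max() + 5, "depth"))
        expected = np.arctan(np.hypot(gx, gy))
        assert np.allclose(slope.values[1:-1, 1:-1], expected, atol=1e-10)

    def test_nodata_propagates(self):
        vals = np.full((8, 8), 30.0)
        vals[4, 4] = np.nan
        slope, aspect = el.compute_slope_aspect(_grid(vals))
        assert np.isnan(slope.values[4, 4]) and np.isnan(aspect.values[4, 4])


class TestDistanceToShore:
    def test_adjacent_cell_is_half_cell_width(self):
        vals = np.zeros((6, 6))
        vals[:, 5] = 1.0                       # land strip on the east
        land = _grid(vals)
        kx, _ = land.cell_km()
        d = el.distance_to_shore(land)
        assert np.allclose(d.values[:, 4], 0.5 * kx * 1000)
        assert np.all(np.isnan(d.values[:, 5]))

    def test_nonnegative_and_increasing_away_from_coast(self):
        vals = np.zeros((6, 10))
        vals[:, 9] = 1.0
        d = el.distance_to_shore(_grid(vals))
        sea = d.values[:, :9]
        assert np.all(sea >= 0)
        assert np.all(np.diff(sea, axis=1) < 0)   # closer to coast eastwards

    def test_matches_brute_force_on_random_mask(self, rng):
        vals = (rng.random((20, 20)) < 0.15).astype(float)
        vals[0, 0] = 1.0                       # ensure land exists
        land = _grid(vals)
        d = el.distance_to_shore(land)
        kx, ky = land.cell_km()
        land_rc = np.argwhere(vals > 0.5)
        for r, c in [(3, 7), (10, 2), (19, 19), (5, 5)]:
            if vals[r, c] > 0.5:
                continue
            dk = np.sqrt(((land_rc[:, 0] - r) * ky) ** 2
                         + ((land_rc[:, 1] - c) * kx) ** 2).min()
            expected = max(dk - 0.5 * kx, 0.0) * 1000
            assert d.values[r, c] == pytest.approx(expected, rel=1e-9)


class TestSediment:
    def test_identity_mapping_unchanged(self):
        vals = np.tile(np.arange(5.0), (5, 1))
        out = el.reclassify_sediment(_grid(vals), {i: i for i in range(5)})
        assert np.array_equal(out.values, vals)

    def test_seventeen_codes_collapse_to_five(self, rng):
        vals = rng.integers(0, 17, size=(10, 10)).astype(float)
        vals.flat[:17] = np.arange(17)         # guarantee all codes occur
        out = el.reclassify_sediment(_grid(vals))
        assert set(np.unique(out.values)) == {0.0, 1.0, 2.0, 3.0, 4.0}

    def test_unmapped_code_fatal(self):
        with pytest.raises(ValueError, match=r"\[99\]"):
            el.reclassify_sediment(_grid(np.full((5, 5), 99.0)),
                                   el.DEFAULT_SEDIMENT_MERGE)

    def test_all_rock_flagged(self):
        with pytest.warns(UserWarning, match="Rock"):
            out = el.reclassify_sediment(_grid(np.full((5, 5), 14.0)))
        assert np.all(out.values == el.ROCK_CODE)


class TestBottomCtd:
    def test_max_pressure_record_kept(self):
        df = make_casts([-6] * 3, [55] * 3, [8.0, 9.0, 8.5])
        df["station_id"] = "stA"
        df["pressure"] = [10.0, 50.0, 30.0]
        out = el.select_bottom_ctd(df)
        assert len(out) == 1 and out["temperature"].iloc[0] == 9.0

    def test_single_record_station_is_itself(self):
        df = make_casts([-6.0], [55.0], [7.7])
        out = el.select_bottom_ctd(df)
        assert len(out) == 1 and out["temperature"].iloc[0] == 7.7

    def test_matches_groupby_max_oracle(self, rng):
        n = 60
        df = make_casts(rng.uniform(-8, -5, n), rng.uniform(53, 56, n),
                        rng.normal(9, 1, n))
        df["station_id"] = rng.choice([f"s{i}" for i in range(12)], n)
        df["pressure"] = rng.uniform(5, 200, n).round(1)
        out = el.select_bottom_ctd(df)
        oracle = df.groupby(["station_id", "year", "season"])["pressure"].max()
        merged = out.set_index(["station_id", "year", "season"])["pressure"]
        assert merged.sort_index().equals(oracle.sort_index())


class TestKernelSmoothing:
    def _template(self):
        return GridLayer("t", np.zeros((5, 5)), -7.0, 54.0, 0.2)

    def test_constant_casts_give_constant_surface(self, rng):
        casts = make_casts(rng.uniform(-7, -6, 8), rng.uniform(54, 55, 8),
                           np.full(8, 9.25))
        for theta in (5.0, 50.0, 500.0):
            out = el.kernel_smooth(casts, self._template(), theta)
            assert np.allclose(out.values, 9.25)

    def test_large_bandwidth_tends_to_mean(self, rng):
        vals = rng.normal(10, 1, 10)
        casts = make_casts(rng.uniform(-7, -6, 10), rng.uniform(54, 55, 10),
                           vals)
        out = el.kernel_smooth(casts, self._template(), 1e5)
        assert np.allclose(out.values, vals.mean(), atol=1e-6)

    def test_matches_double_loop_oracle(self, rng):
        casts = make_casts(rng.uniform(-7.2, -5.8, 10),
                           rng.uniform(53.8, 55.2, 10), rng.normal(9, 1, 10))
        template = self._template()
        theta = 30.0
        out = el.kernel_smooth(casts, template, theta)
        lons = template.lon_centers()
        lats = template.lat_centers()
        for r in range(5):
            for c in range(5):
                num = den = 0.0
                for _, cast in casts.iterrows():
                    d = el.haversine_km(lons[c], lats[r], cast.lon, cast.lat)
                    w = np.exp(-d ** 2 / (2 * theta ** 2))
                    num += w * cast.temperature
                    den += w
                assert out.values[r, c] == pytest.approx(num / den, rel=1e-12)

    def test_shift_scale_equivariance(self, rng):
        casts = make_casts(rng.uniform(-7, -6, 12), rng.uniform(54, 55, 12),
                           rng.normal(0, 1, 12))
        template = self._template()
        base = el.kernel_smooth(casts, template, 40.0)
        scaled = casts.copy()
        scaled["temperature"] = 3.0 * casts["temperature"] + 7.0
        out = el.kernel_smooth(scaled, template, 40.0)
        assert np.allclose(out.values, 3.0 * base.values + 7.0)


class TestBandwidthSelection:
    def test_score_minimal_at_returned_theta(self, rng):
        casts = make_casts(rng.uniform(-8, -5, 30), rng.uniform(53, 56, 30),
                           rng.normal(9, 1, 30))
        grid = np.geomspace(5, 500, 8)
        fit = el.select_bandwidth_loocv(casts, grid)
        assert fit.score == min(fit.scores)
        assert fit.theta_km in grid

    def test_loocv_is_exact_deletion(self, rng):
        """Removing cast i and predicting at x_i equals a fresh smooth
        without cast i."""
        casts = make_casts(rng.uniform(-7, -6, 8), rng.uniform(54, 55, 8),
                           rng.normal(9, 1, 8))
        theta = 40.0
        scores = el.loocv_scores(casts, [theta])
        total = 0.0
        for i in range(len(casts)):
            rest = casts.drop(index=i)
            d = el.haversine_km(casts.lon[i], casts.lat[i],
                                rest["lon"].to_numpy(), rest["lat"].to_numpy())
            w = np.exp(-d ** 2 / (2 * theta ** 2))
            pred = w @ rest["temperature"].to_numpy() / w.sum()
            total += (casts.temperature[i] - pred) ** 2
        assert scores[0] == pytest.approx(total, rel=1e-12)

    def test_colocated_casts_degenerate(self):
        casts = make_casts([-6.0] * 5, [55.0] * 5, [1.0, 2, 3, 4, 5])
        with pytest.warns(UserWarning, match="co-located"):
            fit = el.select_bandwidth_loocv(casts, np.geomspace(5, 500, 9))
        assert fit.degenerate


class TestExtractAtHauls:
    def test_cell_center_exact_and_off_grid_excluded(self, env):
        template = env.template
        lon = template.lon_centers()[5]
        lat = template.lat_centers()[10]
        hauls = pd.DataFrame({
            "haul_id": ["in", "out"], "survey": ["SWC_IBTS"] * 2,
            "year": [2011] * 2, "season": ["OCT_NOV"] * 2,
            "lon": [lon, -20.0], "lat": [lat, 56.0], "duration": [30] * 2})
        tab, excluded = el.extract_at_hauls(env, hauls)
        assert list(excluded["haul_id"]) == ["out"]
        assert excluded["reason"].iloc[0] == "off grid"
        if len(tab):
            assert tab["depth"].iloc[0] == env.layers["depth"].values[10, 5]

    def test_lookup_matches_nearest_centre_oracle(self, env, rng):
        from stagedist import synthetic as syn
        hauls = syn.generate_hauls(env, 40, (2011,), "OCT_NOV", 5)
        tab, _ = el.extract_at_hauls(env, hauls)
        template = env.template
        lons = template.lon_centers()
        lats = template.lat_centers()
        sub = hauls[hauls["haul_id"].isin(tab["haul_id"])].reset_index()
        for i in range(0, len(sub), 7):
            c = int(np.argmin(np.abs(lons - sub.lon[i])))
            r = int(np.argmin(np.abs(lats - sub.lat[i])))
            row = tab[tab["haul_id"] == sub.haul_id[i]].iloc[0]
            assert row["depth"] == env.layers["depth"].values[r, c]
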