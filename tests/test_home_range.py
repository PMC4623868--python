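"""Kernel UD estimation and isopleth home ranges."""

import numpy as np
import pytest
from scipy import stats

from kitetrails import geometry
from kitetrails.classifier import classify
from kitetrails.home_range import (
    KernelConfig,
    build_ud,
    compare_ranges,
    geodesic_polygon_area_km2,
    home_range,
    isopleth,
    weekly_ranges,
)


class TestBuildUD:
    def test_mass_conservation_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            pts = rng.normal(0, rng.uniform(0.1, 50), size=(rng.integers(1, 300), 2))
            ud = build_ud(pts)
            assert ud.masses.sum() == pytest.approx(1.0, abs=1e-9)
            assert (ud.masses >= 0).all()

    def test_single_point_mode(self):
        ud = build_ud([[3.2, -1.7]])
        iy, ix = np.unravel_index(np.argmax(ud.masses), ud.masses.shape)
        assert abs(ud.x_centers[ix] - 3.2) <= ud.cell_dx
        assert abs(ud.y_centers[iy] + 1.7) <= ud.cell_dy

    def test_identical_points_do_not_error(self):
        ud = build_ud(np.zeros((10, 2)))
        assert ud.masses.sum() == pytest.approx(1.0, abs=1e-9)
        assert ud.bandwidth_km == pytest.approx(0.5)  # floor

    def test_two_equal_clusters_split_mass(self):
        # Oracle: two well-separated clusters of equal size must each hold
        # half of the UD mass on their side of the mid-line.
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, size=(100, 2)) + [-30, 0]
        b = rng.normal(0, 1, size=(100, 2)) + [30, 0]
        ud = build_ud(np.vstack([a, b]))
        left = ud.masses[:, ud.x_centers < 0].sum()
        assert left == pytest.approx(0.5, abs=0.02)

    def test_mass_near_single_point_matches_gaussian_cdf(self):
        # Per-axis marginal bound: mass within one bandwidth of a single
        # input point is at least the 1-sigma central Gaussian mass (~68 %)
        # per axis, i.e. 0.68^2 jointly; the radial mass is even larger.
        ud = build_ud([[0.0, 0.0]], KernelConfig(bandwidth_km=2.0))
        gx, gy = np.meshgrid(ud.x_centers, ud.y_centers)
        disc = np.hypot(gx, gy) <= ud.bandwidth_km
        one_sigma_2d = 1.0 - np.exp(-0.5)  # radial CDF of a 2-D Gaussian
        assert ud.masses[disc].sum() == pytest.approx(one_sigma_2d, abs=0.02)
        square = (np.abs(gx) <= ud.bandwidth_km) & (np.abs(gy) <= ud.bandwidth_km)
        per_axis = stats.norm.cdf(1) - stats.norm.cdf(-1)
        assert ud.masses[square].sum() == pytest.approx(per_axis**2, abs=0.02)


class TestIsopleth:
    def test_level_guard(self):
        ud = build_ud([[0.0, 0.0]])
        with pytest.raises(ValueError):
            isopleth(ud, 1.0)
        with pytest.raises(ValueError):
            isopleth(ud, 0.0)

    def test_circular_gaussian_quantile_radius(self):
        # Closed-form oracle: the 90 % region of an isotropic Gaussian is a
        # disc of radius h * sqrt(2 ln 10).
        ud = build_ud([[0.0, 0.0]], KernelConfig(bandwidth_km=2.0))
        hr = isopleth(ud, 0.90)
        expected = 2.0 * np.sqrt(2.0 * np.log(10.0))
        got = np.sqrt(hr.area_km2 / np.pi)
        assert abs(got - expected) / expected < 0.05
        assert hr.n_parts == 1

    def test_point_cloud_gaussian_quantile_radius(self):
        # With points drawn from an isotropic Gaussian the UD is close to
        # N(0, sigma^2 + h^2) per axis.
        rng = np.random.default_rng(7)
        sigma = 5.0
        pts = rng.normal(0, sigma, size=(500, 2))
        cfg = KernelConfig()
        ud = build_ud(pts, cfg)
        hr = isopleth(ud, 0.90)
        var = pts.var(axis=0, mean=None).mean() + ud.bandwidth_km**2
        expected = np.sqrt(var * 2.0 * np.log(10.0))
        got = np.sqrt(hr.area_km2 / np.pi)
        assert abs(got - expected) / expected < 0.05

    def test_contained_mass_at_least_level(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            pts = rng.normal(0, 10, size=(rng.integers(2, 200), 2))
            for level in (0.5, 0.9, 0.95):
                hr = isopleth(build_ud(pts), level)
                assert hr.contained_mass >= level - 1e-12

    def test_two_clusters_two_parts(self):
        rng = np.random.default_rng(2)
        pts = np.vstack(
            [rng.normal(0, 1, (80, 2)) + [-40, 0], rng.normal(0, 1, (80, 2)) + [40, 0]]
        )
        hr = home_range(pts, KernelConfig(bandwidth_km=2.0))
        assert hr.n_parts == 2
        assert hr.contained_mass >= 0.90

    def test_grid_convergence(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(0, 8, size=(300, 2))
        a90 = home_range(pts, KernelConfig(grid_cells=90)).area_km2
        a180 = home_range(pts, KernelConfig(grid_cells=180)).area_km2
        assert abs(a180 - a90) / a90 < 0.03

    def test_planar_area_matches_geodesic(self):
        # Equal-area frame: the planar shoelace area of an isopleth polygon
        # agrees with its spherical area after inverse projection.
        rng = np.random.default_rng(6)
        pts = rng.normal(0, 15, size=(200, 2)) + [60, 30]
        hr = home_range(pts)
        planar = hr.area_km2
        geodesic = sum(
            geodesic_polygon_area_km2(p, 57.5, -4.0) for p in hr.polygon_list
        )
        assert abs(planar - geodesic) / planar < 5e-3


class TestCompareRanges:
    def test_no_excursions_identical(self, km_trajectory):
        rng = np.random.default_rng(8)
        xy = rng.normal(0, 2, size=(60, 2))
        xy[0] = 0.0
        traj = km_trajectory(xy, np.arange(60) * 4.0)
        labels = np.full(60, "settlement")
        out = compare_ranges(traj, labels)
        assert out["area_ratio"] == pytest.approx(1.0)
        assert out["symmetric_difference_km2"] == pytest.approx(0.0)
        assert out["hr_all"] is out["hr_settlement"]

    def test_excursions_shrink_range(self, km_trajectory):
        rng = np.random.default_rng(9)
        xy = rng.normal(0, 2, size=(80, 2))
        xy[0] = 0.0
        xy[40:44] = [[120, 0], [150, 5], [160, 10], [140, -5]]  # distant loop
        traj = km_trajectory(xy, np.arange(80) * 4.0)
        labels = np.full(80, "settlement")
        labels[40:44] = "excursion"
        out = compare_ranges(traj, labels)
        assert out["area_ratio"] < 1.0
        assert out["symmetric_difference_km2"] > 0.0

    def test_distant_cluster_in_excursions_only_drops_polygon(self, km_trajectory):
        rng = np.random.default_rng(10)
        home = rng.normal(0, 1.5, size=(60, 2))
        distant = rng.normal(0, 1.5, size=(25, 2)) + [90, 0]
        xy = np.vstack([home, distant])
        xy[0] = 0.0
        traj = km_trajectory(xy, np.arange(85) * 4.0)
        labels = np.array(["settlement"] * 60 + ["excursion"] * 25)
        out = compare_ranges(traj, labels, KernelConfig(bandwidth_km=2.0))
        assert out["hr_all"].n_parts == out["hr_settlement"].n_parts + 1

    def test_too_few_settlement_fixes(self, km_trajectory):
        traj = km_trajectory([[0, 0], [40, 0], [80, 0]], [0.0, 1.0, 2.0])
        labels = np.array(["settlement", "excursion", "excursion"])
        with pytest.raises(ValueError, match="threshold"):
            compare_ranges(traj, labels)


class TestWeeklyRanges:
    def test_static_bird_near_identical_weeks(self, km_trajectory):
        rng = np.random.default_rng(12)
        xy = rng.normal(0, 2, size=(84, 2))
        xy[0] = 0.0
        traj = km_trajectory(xy, np.arange(84) * 6.0)  # 21 days, 4 fixes/day
        labels = np.full(84, "settlement")
        from kitetrails.behavior import assign_weeks

        windows = assign_weeks(traj.times)
        ranges = weekly_ranges(traj, labels, KernelConfig(), windows)
        areas = [r.area_km2 for r in ranges if r is not None]
        assert len(areas) >= 3
        assert max(areas) / min(areas) < 1.6

    def test_relocation_adds_polygon(self, km_trajectory):
        rng = np.random.default_rng(14)
        first = rng.normal(0, 1.5, size=(56, 2))
        second = rng.normal(0, 1.5, size=(56, 2)) + [70, 0]
        xy = np.vstack([first, second])
        xy[0] = 0.0
        traj = km_trajectory(xy, np.arange(112) * 6.0)  # 4 weeks
        labels = np.full(112, "settlement")
        from kitetrails.behavior import assign_weeks

        windows = assign_weeks(traj.times)
        ranges = weekly_ranges(traj, labels, KernelConfig(bandwidth_km=2.0), windows)
        assert ranges[0].n_parts == 1
        assert ranges[-1].n_parts == 2

    def test_empty_week_carries_forward(self, km_trajectory):
        rng = np.random.default_rng(15)
        xy = rng.normal(0, 2, size=(28, 2))
        xy[0] = 0.0
        t = np.concatenate([np.arange(14) * 6.0, 14 * 24.0 + np.arange(14) * 6.0])
        traj = km_trajectory(xy, t)  # week 2 has no fixes
        labels = np.full(28, "settlement")
        from kitetrails.behavior import assign_weeks

        windows = assign_weeks(traj.times)
        ranges = weekly_ranges(traj, labels, KernelConfig(), windows)
        assert len(windows) == 3
        assert ranges[1] is ranges[0]  # carried forward unchanged


class TestConfigValidation:
    def test_bad_configs_rejected(self):
        with pytest.raises(ValueError):
            KernelConfig(grid_cells=5)
        with pytest.raises(ValueError):
            KernelConfig(smoothing=0.0)
        with pytest.raises(ValueError):
            KernelConfig(isopleth_level=1.0)
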