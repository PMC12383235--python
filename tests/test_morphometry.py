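"""Tracing, profiles, widths, heights, rings, and length statistics."""

import numpy as np
import pytest

from prefibril.containers import CrossProfile, DensityField, FilamentPath, LengthPopulation
from prefibril.morphometry import (
    afm_height,
    cross_profile,
    diameter_at_threshold,
    length_stats,
    path_length,
    ring_geometry,
    trace_filament,
)
from prefibril.synthetic_data import AssemblyGroundTruth, gen_density_field


def _gaussian_profile(sigma: float, baseline: float = 0.0, amp: float = 1.0):
    x = np.linspace(-8 * sigma, 8 * sigma, 4001)
    return CrossProfile(x, baseline + amp * np.exp(-0.5 * (x / sigma) ** 2), baseline)


class TestDiameterAtThreshold:
    def test_rectangular_profile_exact(self):
        x = np.linspace(-5, 5, 2001)
        v = np.where(np.abs(x) <= 1.4, 1.0, 0.0)
        d = diameter_at_threshold(CrossProfile(x, v, 0.0))
        assert d == pytest.approx(2.8, abs=2 * (x[1] - x[0]))

    @pytest.mark.parametrize("sigma", [0.5, 1.0, 2.7])
    def test_gaussian_closed_form(self, sigma):
        # width at 15% of a Gaussian: 2*sigma*sqrt(2*ln(1/0.15)) = 3.8962*sigma
        d = diameter_at_threshold(_gaussian_profile(sigma))
        expected = 2.0 * sigma * np.sqrt(2.0 * np.log(1.0 / 0.15))
        assert d == pytest.approx(expected, rel=1e-6)
        assert expected / sigma == pytest.approx(3.896, abs=1e-3)

    def test_affine_intensity_invariance_exact(self):
        prof = _gaussian_profile(1.3)
        d0 = diameter_at_threshold(prof)
        scaled = CrossProfile(
            prof.offsets, 7.5 * prof.values + 3.0, 7.5 * prof.baseline + 3.0
        )
        assert diameter_at_threshold(scaled) == pytest.approx(d0, rel=1e-12)

    def test_flat_profile_errors(self):
        x = np.linspace(-5, 5, 101)
        with pytest.raises(ValueError, match="no object"):
            diameter_at_threshold(CrossProfile(x, np.ones_like(x), 1.0))

    def test_central_dip_uses_outermost_crossings(self):
        # annulus-like profile: two walls, central dip below threshold
        x = np.linspace(-6, 6, 2401)
        v = np.where((np.abs(x) >= 1.0) & (np.abs(x) <= 3.75), 1.0, 0.0)
        d = diameter_at_threshold(CrossProfile(x, v, 0.0), max_gap=3.0)
        assert d == pytest.approx(7.5, abs=0.02)


class TestTracing:
    def test_straight_tube_length(self, straight_tube_field):
        paths = trace_filament(straight_tube_field)
        assert len(paths) == 1
        assert not paths[0].border and not paths[0].branched
        assert path_length(paths[0]) == pytest.approx(48.0, abs=1.0)

    def test_semicircle_arc_length(self):
        th = np.linspace(0, np.pi, 200)
        cl = np.column_stack([40 + 20 * np.sin(th), 40 + 20 * np.cos(th)])
        f = gen_density_field(
            [AssemblyGroundTruth("curvilinear", cl)], (160, 160), 0.5, blur_sd=0.1, seed=1
        )
        L = path_length(trace_filament(f)[0])
        assert L == pytest.approx(np.pi * 20, rel=0.02)

    def test_empty_field(self):
        f = DensityField(np.zeros((64, 64)), 0.5)
        assert trace_filament(f, threshold=0.5) == []

    def test_border_touching_flagged(self):
        cl = np.column_stack([np.full(60, 15.0), np.linspace(1.5, 31.0, 60)])
        grid = np.zeros((64, 64))
        f = DensityField(grid, 0.5)
        # draw the tube manually right up to the border
        yy, xx = (np.mgrid[:64, :64] + 0.5) * 0.5
        for p in cl:
            grid[np.hypot(yy - p[0], xx - p[1]) < 1.4] = 1.0
        paths = trace_filament(f, threshold=0.5)
        assert len(paths) == 1 and paths[0].border

    def test_rigid_motion_invariance(self):
        # same centerline, rotated 30 deg and translated: equal arc lengths
        th = np.linspace(0, np.pi / 2, 120)
        cl = np.column_stack([30 + 18 * np.sin(th), 30 + 18 * np.cos(th)])
        ang = np.pi / 6
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        cl2 = (cl - 30) @ R.T + 34
        L = []
        for c in (cl, cl2):
            f = gen_density_field(
                [AssemblyGroundTruth("curvilinear", c)], (280, 280), 0.25, blur_sd=0.1, seed=3
            )
            L.append(path_length(trace_filament(f)[0]))
        assert L[0] == pytest.approx(L[1], abs=0.25)

    def test_path_length_of_polyline(self):
        p = FilamentPath(np.column_stack([np.zeros(101), np.arange(101.0)]))
        assert path_length(p) == pytest.approx(100.0)
        p2 = FilamentPath(np.array([[0.0, 0.0], [6.0, 8.0]]))
        assert path_length(p2) == pytest.approx(10.0)


class TestCrossProfile:
    def test_symmetric_about_axis(self, straight_tube_field):
        p = trace_filament(straight_tube_field)[0]
        prof = cross_profile(straight_tube_field, p, 24.0, half_width=6.0)
        v = prof.values
        assert np.corrcoef(v, v[::-1])[0, 1] > 0.95
        # peak sits on the axis to within half a voxel
        assert abs(prof.offsets[np.argmax(v)]) <= 0.25

    def test_constant_field_baseline(self):
        f = DensityField(np.full((64, 64), 3.5), 0.5)
        p = FilamentPath(np.array([[16.0, 8.0], [16.0, 24.0]]))
        prof = cross_profile(f, p, 8.0, half_width=5.0)
        assert prof.baseline == pytest.approx(3.5)
        assert prof.values.max() - prof.baseline == pytest.approx(0.0)

    def test_window_exits_field_errors(self, straight_tube_field):
        p = trace_filament(straight_tube_field)[0]
        with pytest.raises(ValueError, match="exits the field"):
            cross_profile(straight_tube_field, p, 24.0, half_width=60.0)

    def test_blurred_tube_peak_matches_numeric_convolution(self):
        # projection profile of a 2.8 nm cylinder, blur 0.3 nm: compare the
        # measured peak against a 1D numeric convolution oracle
        from scipy.ndimage import gaussian_filter1d

        cl = np.column_stack([np.full(97, 40.0), np.linspace(16.0, 64.0, 97)])
        f = gen_density_field(
            [AssemblyGroundTruth("curvilinear", cl)], (320, 320), 0.25, blur_sd=0.3, seed=0
        )
        p = trace_filament(f)[0]
        prof = cross_profile(f, p, 24.0, half_width=6.0)
        dx = 0.005
        x = np.arange(-8, 8, dx)
        ref = gaussian_filter1d(
            np.where(np.abs(x) < 1.4, 2 * np.sqrt(np.clip(1.4**2 - x**2, 0, None)), 0.0),
            0.3 / dx,
        )
        assert prof.values.max() == pytest.approx(ref.max(), rel=0.02)


@pytest.fixture(scope="module")
def fine_series():
    from prefibril.synthetic_data import GrowthSimParams, gen_afm_series

    params = GrowthSimParams(
        seed=3, pixel_size=3.0, roughness_sd=0.0, n_frames=2, field_size=600.0
    )
    series, _, _ = gen_afm_series(params, initial_length=60.0)
    return series


class TestAfmHeight:
    def test_oligomer_height(self, fine_series):
        frame = fine_series.frames[1]
        p = max(trace_filament(frame, pixel_size=3.0), key=lambda q: q.arc_length[-1])
        h = afm_height(frame, p, path_length(p) / 2, pixel_size=3.0, search_length=6.0)
        assert h == pytest.approx(2.8, abs=0.15)

    def test_tilted_plane_removed(self, fine_series):
        frame = fine_series.frames[1]
        yy = np.mgrid[: frame.shape[0], : frame.shape[1]][0] * 3.0
        tilted = frame + yy * (1.0 / 783.0)  # 1 nm over 783 nm
        p = max(trace_filament(frame, pixel_size=3.0), key=lambda q: q.arc_length[-1])
        h0 = afm_height(frame, p, path_length(p) / 2, pixel_size=3.0, search_length=6.0)
        h1 = afm_height(tilted, p, path_length(p) / 2, pixel_size=3.0, search_length=6.0)
        assert h1 == pytest.approx(h0, abs=0.05)

    def test_object_covering_frame_errors(self):
        from prefibril.morphometry import flatten_plane

        with pytest.raises(ValueError, match="60%"):
            flatten_plane(np.ones((32, 32)), object_mask=np.ones((32, 32), bool))


class TestRingGeometry:
    def test_noiseless_torus(self, torus_field_3d):
        rg = ring_geometry(torus_field_3d, (12.0, 12.0, 12.0), half_width=8.0)
        assert rg.outer_diameter == pytest.approx(7.5, abs=0.25)
        assert rg.inner_diameter == pytest.approx(2.0, abs=0.25)
        assert rg.inner_diameter < rg.outer_diameter

    def test_reconstruction_annulus_with_channel(self):
        gt = AssemblyGroundTruth(
            "annulus",
            np.array([[12.0, 12.0, 12.0]]),
            ring_outer_diameter=6.0,
            ring_inner_diameter=1.25,
            channel_length=5.4,
        )
        f = gen_density_field([gt], (96, 96, 96), 0.25, blur_sd=0.0, seed=0)
        rg = ring_geometry(f, (12.0, 12.0, 12.0), half_width=8.0)
        assert rg.outer_diameter == pytest.approx(6.0, abs=0.25)
        assert rg.inner_diameter == pytest.approx(1.25, abs=0.25)
        assert rg.channel_length == pytest.approx(5.4, abs=0.25)

    def test_solid_disc_no_channel(self):
        yy, xx = (np.mgrid[:96, :96] + 0.5) * 0.25
        grid = (np.hypot(yy - 12, xx - 12) <= 3.0).astype(float)
        with pytest.raises(ValueError, match="no channel"):
            ring_geometry(DensityField(grid, 0.25), (12.0, 12.0), half_width=8.0)

    def test_projected_torus_wall_separation(self):
        # central-slice line profile peaks are one centerline diameter apart:
        # (7.5 + 2.0) / 2 = 4.75 nm
        from scipy.signal import find_peaks

        gt = AssemblyGroundTruth(
            "annulus", np.array([[15.0, 15.0]]),
            ring_outer_diameter=7.5, ring_inner_diameter=2.0,
        )
        f = gen_density_field([gt], (240, 240), 0.125, blur_sd=0.0, seed=0)
        row = f.grid[f.grid.shape[0] // 2 - 1]
        pk, _ = find_peaks(row, prominence=0.5 * row.max())
        sep = np.diff((pk + 0.5) * 0.125)
        assert sep[0] == pytest.approx(4.75, abs=0.25)


class TestLengthStats:
    def test_single_value(self):
        s = length_stats(LengthPopulation(np.array([42.0])))
        assert s["mode"] == s["median"] == 42.0

    def test_lognormal_mode_recovery(self):
        from prefibril.synthetic_data import gen_length_population

        pop = gen_length_population([0.0], [110.0], 0.4, 500, seed=11)[0]
        s = length_stats(pop)
        assert abs(s["mode"] - 110.0) / 110.0 <= 0.15

    def test_growth_series_modes_monotone(self):
        from prefibril.synthetic_data import gen_length_population

        pops = gen_length_population(
            [28, 30, 32, 34, 36], [5.0, 55.0, 110.0, 170.0, 225.0], 0.4, 150, seed=11
        )
        modes = [length_stats(p)["mode"] for p in pops]
        assert all(a < b for a, b in zip(modes, modes[1:]))

    def test_tie_breaks_to_smaller_length(self):
        s = length_stats(LengthPopulation(np.array([1.0, 1.1, 9.0, 9.1])))
        counts = s["counts"]
        assert counts.max() == counts[0] or s["mode"] <= s["median"]
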