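"""Generators: determinism, ground-truth bookkeeping, statistical structure."""

import numpy as np
import pytest

from prefibril.synthetic_data import (
    AssemblyGroundTruth,
    ChannelSimParams,
    GrowthSimParams,
    gen_afm_series,
    gen_current_trace,
    gen_density_field,
    gen_length_population,
    gen_tht_curve,
    persistent_path,
)


class TestDeterminism:
    def test_same_seed_identical_different_seed_differs(self):
        p = GrowthSimParams(seed=5, n_frames=3)
        s1, _, _ = gen_afm_series(p, 20.0)
        s2, _, _ = gen_afm_series(p, 20.0)
        assert np.array_equal(s1.frames, s2.frames)
        s3, _, _ = gen_afm_series(GrowthSimParams(seed=6, n_frames=3), 20.0)
        assert not np.array_equal(s1.frames, s3.frames)

    def test_current_trace_deterministic(self):
        p = ChannelSimParams()
        t1, st1 = gen_current_trace(p, 6000.0, seed=9)
        t2, st2 = gen_current_trace(p, 6000.0, seed=9)
        assert np.array_equal(t1.i, t2.i) and np.array_equal(st1, st2)


class TestAfmSeries:
    def test_symmetric_growth_bookkeeping(self):
        # 8.0 nm/min both ends, 8 min frames: +64 nm per end per frame
        p = GrowthSimParams(rate_end_a=8.0, rate_end_b=8.0, seed=1, n_frames=4)
        _, gts, truth = gen_afm_series(p, 20.0)
        assert np.allclose(np.diff(truth["end_a_excursion"]), 64.0)
        assert np.allclose(np.diff(truth["end_b_excursion"]), 64.0)
        assert np.allclose(np.diff(truth["total_length"]), 128.0)
        # ground-truth arc bookkeeping matches the polyline to high accuracy
        for gt, total in zip(gts, truth["total_length"]):
            seg = np.linalg.norm(np.diff(gt.centerline, axis=0), axis=1).sum()
            assert seg == pytest.approx(total, rel=1e-9)

    def test_zero_growth_frames_identical_up_to_noise(self):
        p = GrowthSimParams(rate_end_a=0.0, rate_end_b=0.0, seed=2, n_frames=3,
                            roughness_sd=0.0)
        s, _, truth = gen_afm_series(p, 30.0)
        assert np.array_equal(s.frames[0], s.frames[1])
        assert np.all(truth["total_length"] == truth["total_length"][0])

    def test_asymmetric_rates_exact_excursions(self):
        p = GrowthSimParams(rate_end_a=18.5, rate_end_b=9.6, seed=3, n_frames=3)
        _, _, truth = gen_afm_series(p, 20.0)
        t = 8.0 * np.arange(3)
        assert np.allclose(truth["end_a_excursion"], 18.5 * t, atol=0.5)
        assert np.allclose(truth["end_b_excursion"], 9.6 * t, atol=0.5)

    def test_heights_near_tube_diameter(self):
        p = GrowthSimParams(seed=4, pixel_size=3.0, roughness_sd=0.0, n_frames=2,
                            field_size=600.0)
        s, _, _ = gen_afm_series(p, 40.0)
        assert s.frames[1].max() == pytest.approx(2.8, abs=0.05)

    def test_rejects_unobservable_growth(self):
        with pytest.raises(ValueError, match="unobservable"):
            GrowthSimParams(rate_end_a=0.01, rate_end_b=8.0, pixel_size=19.0)


class TestDensityField:
    def test_overlapping_assemblies_rejected(self):
        a = AssemblyGroundTruth(
            "curvilinear", np.column_stack([np.full(20, 20.0), np.linspace(10, 30, 20)])
        )
        b = AssemblyGroundTruth(
            "curvilinear", np.column_stack([np.full(20, 21.0), np.linspace(10, 30, 20)])
        )
        with pytest.raises(ValueError, match="closer than"):
            gen_density_field([a, b], (160, 160), 0.25, seed=0)

    def test_margin_enforced(self):
        a = AssemblyGroundTruth(
            "curvilinear", np.column_stack([np.full(20, 1.0), np.linspace(5, 15, 20)])
        )
        with pytest.raises(ValueError, match="margin"):
            gen_density_field([a], (80, 80), 0.25, seed=0)

    def test_midtube_profile_plateau_before_blur(self):
        # 3D render: constant density inside the tube -> box cross-section
        cl = np.column_stack(
            [np.full(60, 10.0), np.full(60, 10.0), np.linspace(5, 15, 60)]
        )
        f = gen_density_field(
            [AssemblyGroundTruth("curvilinear", cl)], (80, 80, 80), 0.25,
            blur_sd=0.0, seed=0,
        )
        prof = f.grid[40, :, 40]
        width_vox = np.sum(prof > 0.5)
        assert width_vox * 0.25 == pytest.approx(2.8, abs=0.3)

    def test_length_population_round_trip(self):
        # render tubes of known lengths and re-measure the histogram
        from prefibril.morphometry import path_length, trace_filament

        rng = np.random.default_rng(42)
        lengths = rng.lognormal(np.log(30), 0.3, 8)
        measured = []
        for k, L in enumerate(lengths):
            r = np.random.default_rng(k)
            cl = persistent_path(L, r, start=(35.0, 20.0), direction=0.4,
                                 persistence_length=500.0)
            cl = cl - cl.mean(axis=0) + 35.0
            f = gen_density_field(
                [AssemblyGroundTruth("curvilinear", cl)], (280, 280), 0.25,
                blur_sd=0.1, seed=k,
            )
            measured.append(path_length(trace_filament(f)[0]))
        rel = np.abs(np.array(measured) - lengths) / lengths
        assert np.median(rel) < 0.05


class TestCurrentTrace:
    def test_open_level_current(self):
        p = ChannelSimParams(conductance_levels=(320.0,), baseline_sd=0.0)
        tr, st = gen_current_trace(p, 6000.0, seed=1)
        open_pos = (st > 0) & (tr.v == 80.0)
        assert np.median(tr.i[open_pos]) == pytest.approx(25.6, abs=0.05)
        open_neg = (st > 0) & (tr.v == -80.0)
        assert np.median(tr.i[open_neg]) == pytest.approx(-25.6, abs=0.05)

    def test_always_closed_limit(self):
        p = ChannelSimParams(open_rate=1e-6, baseline_sd=0.0)
        tr, st = gen_current_trace(p, 6000.0, seed=2)
        assert np.all(st == 0)
        assert np.abs(tr.i).max() < 0.1

    def test_stationary_open_probability(self):
        p = ChannelSimParams(open_rate=50.0, close_rate=50.0, baseline_sd=0.0)
        _, st = gen_current_trace(p, 120000.0, seed=5)
        # stationary P_open = 0.5; binomial-ish tolerance for correlated dwells
        assert np.mean(st > 0) == pytest.approx(0.5, abs=0.05)

    def test_zero_voltage_warns(self):
        p = ChannelSimParams(voltage_protocol=((1000.0, 0.0),))
        with pytest.warns(UserWarning, match="unobservable"):
            gen_current_trace(p, 3000.0, seed=0)

    def test_rejects_undersampled_filter(self):
        with pytest.raises(ValueError, match="sampling_rate"):
            ChannelSimParams(sampling_rate=300.0, filter_cutoff=200.0)


class TestKineticCurves:
    def test_logistic_ten_percent_crossing_at_lag(self):
        t = np.arange(0, 200, 0.05)
        c = gen_tht_curve(28.0, 50.0, 100.0, 0.0, t)
        i = np.searchsorted(t, 28.0)
        assert c.f[i] == pytest.approx(10.0, abs=0.01)

    def test_rejects_bad_lag(self):
        with pytest.raises(ValueError):
            gen_tht_curve(50.0, 28.0, 100.0, 0.0, np.arange(0, 80, 0.5))

    def test_lognormal_modes_match_request(self):
        # analytic mode of lognormal(mu, sigma) is exp(mu - sigma^2)
        pops = gen_length_population([0, 1], [5.0, 225.0], 0.4, 50000, seed=3)
        for pop, mode in zip(pops, (5.0, 225.0)):
            logs = np.log(pop.lengths)
            mu, sd = logs.mean(), logs.std()
            assert np.exp(mu - sd**2) == pytest.approx(mode, rel=0.02)

    def test_zero_dispersion_point_mass(self):
        pop = gen_length_population([0], [48.0], 0.0, 40, seed=1)[0]
        assert np.all(pop.lengths == 48.0)

    def test_small_n_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            gen_length_population([0], [10.0], 0.3, 10, seed=0)


class TestPersistentPath:
    def test_exact_arc_length_bookkeeping(self):
        rng = np.random.default_rng(0)
        pts = persistent_path(100.0, rng, step=0.5)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        assert seg.sum() == pytest.approx(100.0, rel=1e-9)
        assert np.allclose(seg, 0.5)

    def test_self_clearance(self):
        rng = np.random.default_rng(7)
        pts = persistent_path(400.0, rng, persistence_length=300.0, step=0.5)
        from scipy.spatial import cKDTree

        tree = cKDTree(pts)
        pairs = tree.query_pairs(2.8 * 0.9)
        # only near-neighbours along the chain may be that close
        assert all(abs(i - j) < 14 for i, j in pairs)
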