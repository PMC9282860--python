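"""Single-cell quantification: kymographs, memory estimators, fits."""

import numpy as np
import pytest

from ghostnav.motility import (NO_STIMULUS, UNIFORM_EGF, MotilityParams,
                               Track, cos_theta_series, simulate_mou)
from ghostnav.quantify import (classify_activation, egfrp_kymograph,
                               egfrp_timecourse, fit_inverse_sigmoid,
                               gradient_alignment, migration_memory,
                               morphology_memory, polarization_memory,
                               shape_metrics, single_cell_cos_memory,
                               takens_embedding)
from ghostnav.synth import (make_fluorescence_record,
                            make_parametric_kymograph, make_shape_series,
                            make_tracks)


class TestEgfrpKymograph:
    def test_proportional_channels_give_flat_kymograph(self):
        ky, _ = make_parametric_kymograph(memory_min=0, peak=0.05,
                                          baseline=0.05)
        rec, _ = make_fluorescence_record(ky, noise_level=0.0)
        out = egfrp_kymograph(rec)
        assert np.nanmax(np.abs(out.values)) < 1e-9 or \
            np.nanstd(out.values) < 1e-9

    def test_polarization_angle_round_trip(self):
        ky, gt = make_parametric_kymograph(memory_min=30.0, seed=1,
                                           angle=np.pi)
        rec, _ = make_fluorescence_record(ky, noise_level=0.0, seed=2)
        out = egfrp_kymograph(rec)
        sel = (out.times >= 30) & (out.times <= 60)
        prof = np.nanmean(out.values[:, sel], axis=1)
        angle = out.angles[int(np.argmax(prof))]
        assert abs(np.angle(np.exp(1j * (angle - gt.polarization_angle)))) \
            <= 2 * np.pi / 20 + 1e-9

    def test_global_rescaling_invariance(self):
        ky, _ = make_parametric_kymograph(memory_min=30.0, seed=3)
        rec, _ = make_fluorescence_record(ky, noise_level=0.02, seed=4)
        a = egfrp_kymograph(rec).values
        rec.ptb_pm *= 2.0
        rec.ptb_t *= 2.0
        rec.ptb_endo *= 2.0
        rec.egfr_pm *= 2.0
        rec.egfr_t *= 2.0
        b = egfrp_kymograph(rec).values
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_noiseless_round_trip_exact(self):
        ky, _ = make_parametric_kymograph(memory_min=25.0, seed=5)
        rec, _ = make_fluorescence_record(ky, noise_level=0.0)
        raw = egfrp_kymograph(rec, normalize=False)
        np.testing.assert_allclose(raw.values, ky.values, atol=1e-9)


class TestEgfrpTimecourse:
    def test_constant_record_normalizes_to_zero(self):
        ky, _ = make_parametric_kymograph(memory_min=0, peak=0.05,
                                          baseline=0.05)
        rec, _ = make_fluorescence_record(ky, noise_level=0.0)
        prof, _ = egfrp_timecourse(rec)
        assert np.allclose(prof, 0.0)

    def test_profile_peaks_at_one(self):
        ky, _ = make_parametric_kymograph(memory_min=30.0, seed=6)
        rec, _ = make_fluorescence_record(ky, noise_level=0.0)
        prof, _ = egfrp_timecourse(rec)
        assert prof.max() == pytest.approx(1.0)
        assert abs(prof[:5].mean()) < 1e-9

    def test_simulation_round_trip_correlates(self, regime_runs):
        protocol, runs = regime_runs
        ep = runs[1.26]["Ep"]
        rec, _ = make_fluorescence_record(ep, noise_level=0.02, seed=7)
        prof, _ = egfrp_timecourse(rec)
        mean_ep = ep.values.mean(axis=0)
        r = np.corrcoef(prof, mean_ep)[0, 1]
        assert r > 0.95

    def test_missing_baseline_rejected(self):
        ky, _ = make_parametric_kymograph(memory_min=0)
        rec, _ = make_fluorescence_record(ky)
        rec.t = rec.t + 10.0
        with pytest.raises(ValueError, match="baseline"):
            egfrp_timecourse(rec)


class TestClassifyActivation:
    @staticmethod
    def _population():
        recs, truth = [], []
        for i in range(10):
            ky, _ = make_parametric_kymograph(memory_min=30, seed=100 + i,
                                              baseline=0.05, peak=0.6)
            rec, _ = make_fluorescence_record(ky, noise_level=0.03,
                                              seed=200 + i)
            recs.append(rec)
            truth.append("activated")
        for i in range(10):
            ky, _ = make_parametric_kymograph(memory_min=0, seed=300 + i,
                                              baseline=0.05, peak=0.07)
            rec, _ = make_fluorescence_record(ky, noise_level=0.03,
                                              seed=400 + i)
            recs.append(rec)
            truth.append("non-activated")
        for i in range(5):
            ky, _ = make_parametric_kymograph(memory_min=0, seed=500 + i,
                                              baseline=0.6, peak=0.62)
            rec, _ = make_fluorescence_record(ky, noise_level=0.03,
                                              seed=600 + i)
            recs.append(rec)
            truth.append("pre-activated")
        return recs, truth

    def test_well_separated_populations_classified(self):
        recs, truth = self._population()
        labels, _ = classify_activation(recs)
        acc = np.mean([l == t for l, t in zip(labels, truth)])
        assert acc >= 0.95

    def test_identical_cells_do_not_crash(self):
        ky, _ = make_parametric_kymograph(memory_min=0, peak=0.05,
                                          baseline=0.05)
        rec, _ = make_fluorescence_record(ky, noise_level=0.0)
        labels, info = classify_activation([rec, rec, rec])
        assert len(set(labels)) == 1
        assert info.get("degenerate") or not info["pre_threshold_ok"]

    def test_thirty_percent_rule_is_strict(self):
        # a cell is pre-activated iff strictly more than 30% of its
        # pre-stimulus bins exceed the threshold
        recs, _ = self._population()
        labels, info = classify_activation(recs)
        thr = info["pre_threshold"]
        for rec, lab in zip(recs, labels):
            raw = egfrp_kymograph(rec, normalize=False)
            frac = np.mean(raw.values[:, raw.times <= 5.0] > thr)
            assert (lab == "pre-activated") == (frac > 0.30)


class TestPolarizationMemory:
    def test_plateau_duration_recovered(self):
        ky, gt = make_parametric_kymograph(memory_min=40.0, seed=8)
        est = polarization_memory(ky, gt.t_stim_end)
        assert abs(est.duration - 40.0) <= 2.0

    def test_unpolarized_kymograph_no_memory(self):
        ky, gt = make_parametric_kymograph(memory_min=0.0, peak=0.0505,
                                           baseline=0.05, seed=9)
        est = polarization_memory(ky, gt.t_stim_end)
        assert est.duration <= 4.0 or np.isnan(est.duration)

    def test_permanent_polarization_hits_window_sentinel(self):
        ky, gt = make_parametric_kymograph(memory_min=1000.0, seed=10)
        est = polarization_memory(ky, gt.t_stim_end)
        assert est.duration == np.inf

    def test_noise_robust_recovery(self):
        durs = []
        for seed in range(10):
            ky, gt = make_parametric_kymograph(memory_min=40.0, noise=0.10,
                                               seed=seed)
            rec, _ = make_fluorescence_record(ky, noise_level=0.05,
                                              seed=seed + 50)
            est = polarization_memory(egfrp_kymograph(rec), gt.t_stim_end)
            durs.append(est.duration)
        assert abs(np.median(durs) - 40.0) <= 4.0


class TestShapeMetrics:
    def test_convex_mask_solidity_one(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:30, 8:32] = True
        sol, _ = shape_metrics(mask[None], 0.1, area_threshold_um2=None)
        assert sol[0] > 0.98

    def test_plus_shape_solidity(self):
        # plus of 5 unit squares: area 5, convex hull is the octagon of
        # area 7 (pixelated at high resolution)
        n = 60
        mask = np.zeros((3 * n, 3 * n), dtype=bool)
        mask[n:2 * n, :] = True
        mask[:, n:2 * n] = True
        sol, _ = shape_metrics(mask[None], 1.0 / n,
                               area_threshold_um2=None)
        assert sol[0] == pytest.approx(5.0 / 7.0, rel=0.03)

    def test_rigid_translation_toward_source_is_frontal(self):
        masks = np.zeros((6, 50, 80), dtype=bool)
        for i in range(6):
            masks[i, 15:35, 50 - 4 * i:70 - 4 * i] = True  # moves in -x
        _, dpa = shape_metrics(masks, 0.2, gradient_direction=(-1.0, 0.0),
                               area_threshold_um2=None)
        assert dpa[1:].mean() > 0

    def test_circle_series_stays_solid(self):
        masks, times, _ = make_shape_series(mode="circle", t_total=20.0,
                                            seed=0)
        sol, _ = shape_metrics(masks, 0.1, area_threshold_um2=None)
        assert np.all(np.abs(sol - 1.0) < 0.01)


class TestMorphologyMemory:
    def test_constant_solidity_no_memory(self):
        times = np.arange(0.0, 180.0)
        est = morphology_memory(np.full(180, 0.95), times, 5.0, 65.0)
        assert np.isnan(est.duration)

    @pytest.mark.parametrize("truth", [20.0, 40.0])
    def test_blob_memory_recovered(self, truth):
        masks, times, _ = make_shape_series(memory_min=truth, seed=11)
        sol, _ = shape_metrics(masks, 0.1, area_threshold_um2=None)
        est = morphology_memory(sol, times, 5.0, 65.0)
        assert est.duration == pytest.approx(truth, abs=8.0)

    def test_instant_recovery_short_memory(self):
        masks, times, _ = make_shape_series(memory_min=0.0, seed=12)
        sol, _ = shape_metrics(masks, 0.1, area_threshold_um2=None)
        est = morphology_memory(sol, times, 5.0, 65.0)
        assert est.duration <= 5.0


class TestInverseSigmoid:
    def test_noiseless_parameters_recovered_exactly(self):
        t = np.arange(0, 181.0)
        y = 1000.0 / (10.0 ** 2.88 + t ** 2.88)
        fit = fit_inverse_sigmoid(t, y)
        assert fit.a0 == pytest.approx(1000.0, abs=1e-5)
        assert fit.a == pytest.approx(10.0, abs=1e-6)
        assert fit.n == pytest.approx(2.88, abs=1e-6)

    def test_fixed_scale_noisy_hill_recovery(self):
        rng = np.random.default_rng(13)
        t = np.arange(0, 121.0)
        ns = []
        for _ in range(30):
            y = 19.0 / (10.0 ** 1.28 + t ** 1.28)
            y = y + rng.normal(0, 0.05 * y[0], len(t))
            ns.append(fit_inverse_sigmoid(t, y, fix_a=10.0).n)
        assert np.median(ns) == pytest.approx(1.28, abs=0.15)

    def test_half_life_is_scale_parameter(self):
        # f(a) = a0/(2 a^n) = f(0)/2 holds identically
        for a0, a, n in [(1000, 10, 2.88), (19, 10, 1.28), (3, 25, 0.7)]:
            t = np.linspace(0, 8 * a, 200)
            fit = fit_inverse_sigmoid(t, a0 / (a ** n + t ** n))
            f0 = fit(0.0)
            assert fit(fit.half_life) == pytest.approx(f0 / 2, rel=1e-6)
            assert fit.half_life == fit.a

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            fit_inverse_sigmoid(np.arange(5.0), np.ones(5))


class TestTakensEmbedding:
    def test_sine_delay_near_analytic_value(self):
        # autocorrelation cos(2 pi lag/T) first drops below 1/e at
        # lag = T acos(1/e)/(2 pi) ~ 0.19 T
        t = np.arange(500)
        emb = takens_embedding(np.sin(2 * np.pi * t / 100),
                               smooth_window=0)
        assert 15 <= emb.delay <= 25
        assert emb.dim == 2

    def test_sine_embedding_closes_into_a_loop(self):
        from scipy.spatial import cKDTree
        t = np.arange(500)
        emb = takens_embedding(np.sin(2 * np.pi * t / 100),
                               smooth_window=0)
        pts = emb.embedded
        gap = cKDTree(pts).query(pts, k=2)[0][:, 1].max()
        diam = np.linalg.norm(np.ptp(pts, axis=0))
        assert gap < 0.05 * diam

    def test_white_noise_caps_dimension(self):
        rng = np.random.default_rng(14)
        emb = takens_embedding(rng.normal(size=400), smooth_window=0)
        assert emb.capped
        assert emb.fnn_fraction > 0.05

    def test_explicit_settings_override(self):
        x = np.sin(np.arange(300) / 10.0)
        emb = takens_embedding(x, delay=26, dim=3)
        assert (emb.delay, emb.dim) == (26, 3)
        assert emb.embedded.shape == (300 - 2 * 26, 3)


def _reference_costheta(n=60, seed=21):
    ref = simulate_mou(
        MotilityParams(tau=NO_STIMULUS["tau"], D=NO_STIMULUS["D"],
                       dt=2.0, duration=300.0), n, seed=seed)
    return np.concatenate([cos_theta_series(tr, (1.0, 0.0))[-25:]
                           for tr in ref.tracks])


class TestMigrationMemory:
    @staticmethod
    def _phases(bias_min):
        grad = MotilityParams(tau=UNIFORM_EGF["tau"], D=UNIFORM_EGF["D"],
                              bias=UNIFORM_EGF["bias"], dt=2.0)
        rw = MotilityParams(tau=0.0, D=NO_STIMULUS["D"], dt=2.0)
        return [(300.0, grad), (bias_min, grad), (250.0, rw)]

    def test_memory_detected_within_one_window(self):
        from ghostnav.synth import make_tracks
        ens, _ = make_tracks(self._phases(50.0), n=50, seed=15)
        est = migration_memory(ens, (1.0, 0.0), _reference_costheta(),
                               t_washout=300.0)
        assert abs(est.duration - 50.0) <= 10.0

    def test_unbiased_tracks_no_memory(self):
        rw = MotilityParams(tau=0.0, D=NO_STIMULUS["D"], dt=2.0)
        from ghostnav.synth import make_tracks
        ens, _ = make_tracks([(600.0, rw)], n=50, seed=16)
        est = migration_memory(ens, (1.0, 0.0), _reference_costheta(),
                               t_washout=300.0)
        assert est.duration <= 10.0

    def test_permanent_bias_hits_window_sentinel(self):
        grad = MotilityParams(tau=UNIFORM_EGF["tau"], D=UNIFORM_EGF["D"],
                              bias=UNIFORM_EGF["bias"], dt=2.0)
        from ghostnav.synth import make_tracks
        ens, _ = make_tracks([(500.0, grad)], n=50, seed=17)
        est = migration_memory(ens, (1.0, 0.0), _reference_costheta(),
                               t_washout=300.0)
        assert est.duration == np.inf


class TestSingleCellCosMemory:
    def test_straight_to_source_forever_is_window_sentinel(self):
        t = np.arange(0, 200.0, 2.0)
        tr = Track(0, t, np.column_stack([t * 0.5, np.zeros_like(t)]))
        est = single_cell_cos_memory(tr, (1.0, 0.0), t_washout=100.0)
        assert est.duration == np.inf

    def test_orthogonal_turn_at_washout_detected_fast(self):
        t = np.arange(0, 200.0, 2.0)
        xy = np.zeros((len(t), 2))
        for i in range(1, len(t)):
            step = np.array([1.0, 0.0]) if t[i] <= 100 else \
                np.array([0.0, 1.0])
            xy[i] = xy[i - 1] + step
        est = single_cell_cos_memory(Track(0, t, xy), (1.0, 0.0),
                                     t_washout=100.0)
        assert est.duration <= 16.0   # Kalman lag + 3-sample rule

    def test_per_cell_memory_median_recovered(self):
        from ghostnav.synth import make_tracks
        grad = MotilityParams(tau=UNIFORM_EGF["tau"], D=UNIFORM_EGF["D"],
                              bias=0.5, dt=2.0)
        rw = MotilityParams(tau=0.0, D=0.05, dt=2.0)
        ens, _ = make_tracks([(100.0, grad), (25.0, grad), (150.0, rw)],
                             n=50, seed=18)
        durs = [single_cell_cos_memory(tr, (1.0, 0.0),
                                       t_washout=100.0).duration
                for tr in ens.tracks]
        durs = [d for d in durs if np.isfinite(d)]
        assert abs(np.median(durs) - 25.0) <= 6.0

    def test_agreement_with_ensemble_estimator(self):
        from ghostnav.synth import make_tracks
        grad = MotilityParams(tau=UNIFORM_EGF["tau"], D=UNIFORM_EGF["D"],
                              bias=0.4, dt=2.0)
        rw = MotilityParams(tau=0.0, D=NO_STIMULUS["D"], dt=2.0)
        ens, _ = make_tracks([(300.0, grad), (40.0, grad), (250.0, rw)],
                             n=60, seed=19)
        ens_est = migration_memory(ens, (1.0, 0.0), _reference_costheta(),
                                   t_washout=300.0)
        durs = [single_cell_cos_memory(tr, (1.0, 0.0),
                                       t_washout=300.0).duration
                for tr in ens.tracks]
        durs = [d for d in durs if np.isfinite(d)]
        assert abs(np.median(durs) - ens_est.duration) <= 15.0


class TestGradientAlignment:
    @staticmethod
    def _record(egf_angle, ep_angle, seed=0, jitter_bins=0):
        rng = np.random.default_rng(seed)
        ky, _ = make_parametric_kymograph(memory_min=30.0, angle=ep_angle,
                                          seed=seed)
        n = 20
        ang = (np.arange(n) + 0.5) * 2 * np.pi / n
        shift = rng.integers(-jitter_bins, jitter_bins + 1) \
            if jitter_bins else 0
        d = np.angle(np.exp(1j * (ang - egf_angle)))
        egf = 0.1 + np.roll(np.exp(-0.5 * (d / 0.6) ** 2), shift)
        rec, _ = make_fluorescence_record(ky, noise_level=0.0,
                                          egf_profile=egf)
        return rec

    def test_same_bin_maxima_zero_angle(self):
        rec = self._record(np.pi, np.pi)
        ky = egfrp_kymograph(rec)
        _, angle = gradient_alignment(rec, ky, t_window=(30.0, 60.0))
        assert angle == 0.0

    def test_five_bins_apart_is_right_angle(self):
        rec = self._record(np.pi, np.pi + 5 * 2 * np.pi / 20)
        ky = egfrp_kymograph(rec)
        _, angle = gradient_alignment(rec, ky, t_window=(30.0, 60.0))
        assert angle == pytest.approx(np.pi / 2)

    def test_jittered_ensemble_stays_aligned(self):
        angles = []
        for seed in range(12):
            rec = self._record(np.pi, np.pi, seed=seed, jitter_bins=1)
            ky = egfrp_kymograph(rec)
            _, a = gradient_alignment(rec, ky, t_window=(30.0, 60.0))
            angles.append(a)
        assert np.median(angles) <= np.pi / 10

    def test_flat_profile_undefined(self):
        ky, _ = make_parametric_kymograph(memory_min=30.0)
        rec, _ = make_fluorescence_record(ky, egf_profile=np.ones(20))
        _, angle = gradient_alignment(rec, egfrp_kymograph(rec))
        assert np.isnan(angle)
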