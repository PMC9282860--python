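"""Reaction kinetics, homogeneous states and stochastic RD simulation."""

import numpy as np
import pytest

from ghostnav.signaling import (GaussianComponent, Kymograph, MembraneGrid,
                                SignalingParams, StimulusProtocol,
                                StimulusSegment, homogeneous_steady_state,
                                n2a_qss, polarization_metrics,
                                reaction_terms, simulate_rd)

from conftest import gradient_protocol


class TestReactionTerms:
    def test_autonomous_activation_from_empty_state(self):
        # with no phosphorylated receptor only the autonomous dimer term
        # remains: f1 = alpha1 * Et^2
        p = SignalingParams(Et=1.26)
        f1, _, _, _ = reaction_terms(0.0, 0.0, 0.3, 0.5, p, 0.0)
        assert f1 == pytest.approx(0.001 * 1.26 ** 2, rel=1e-12)

    def test_no_ligand_no_binding(self):
        p = SignalingParams()
        _, f2, _, _ = reaction_terms(0.2, 0.0, 0.3, 0.5, p, 0.0)
        assert f2 == 0.0

    def test_saturated_phosphatase_deactivates(self):
        # at RGa = RGt the activation term vanishes and decay wins
        p = SignalingParams()
        _, _, f3, _ = reaction_terms(0.3, 0.0, p.RGt, 0.5, p, 0.0)
        assert f3 < 0

    def test_negative_input_rejected(self):
        p = SignalingParams()
        with pytest.raises(ValueError):
            reaction_terms(-0.1, 0.0, 0.3, 0.5, p, 0.0)
        with pytest.raises(ValueError):
            reaction_terms(0.1, 0.0, 0.3, 0.5, p, -1.0)

    def test_epsilon_prefactor_on_slow_feedback(self):
        p1 = SignalingParams(epsilon=0.01)
        p2 = SignalingParams(epsilon=1.0)
        f4a = reaction_terms(0.3, 0.0, 0.3, 0.2, p1, 0.0)[3]
        f4b = reaction_terms(0.3, 0.0, 0.3, 0.2, p2, 0.0)[3]
        assert f4a == pytest.approx(0.01 * f4b, rel=1e-12)


class TestN2aQss:
    def test_zero_phosphorylation_splits_by_rate_ratio(self):
        p = SignalingParams()
        assert n2a_qss(0.0, 0.0, p) == pytest.approx(0.5)

    def test_hand_value_at_unit_phosphorylation(self):
        p = SignalingParams()
        assert n2a_qss(1.0, 0.0, p) == pytest.approx(1.6 / 2.1, rel=1e-12)

    def test_monotone_saturation_to_total(self):
        p = SignalingParams()
        s = np.linspace(0, 50, 200)
        v = n2a_qss(s, np.zeros_like(s), p)
        assert np.all(np.diff(v) > 0)
        assert v[-1] < p.N2t
        assert v[-1] > 0.95 * p.N2t


class TestHomogeneousSteadyState:
    def test_no_ligand_means_no_bound_receptor(self):
        st = homogeneous_steady_state(SignalingParams(Et=1.1), 0.0)
        assert np.all(st.EEp == 0.0)

    def test_residuals_below_tolerance(self):
        p = SignalingParams(Et=1.1)
        st = homogeneous_steady_state(p, 0.0)
        f = reaction_terms(st.Ep[0], st.EEp[0], st.RGa[0], st.N2a[0], p, 0.0)
        assert max(abs(float(x)) for x in f) < 1e-10

    def test_stationary_under_noise_free_integration(self, grid):
        p = SignalingParams(Et=1.26)
        st = homogeneous_steady_state(p, 0.0, n_bins=grid.n_bins)
        kys = simulate_rd(p, grid, None, t_end=100.0, dt=0.01,
                          noise_on=False, initial_state=st, record_dt=10.0)
        drift = np.max(np.abs(kys["Ep"].values - st.Ep[0]))
        assert drift < 1e-8

    def test_three_branches_in_bistable_window(self):
        states = homogeneous_steady_state(SignalingParams(Et=1.35), 0.0,
                                          branch="all", n_bins=1)
        assert len(states) == 3
        eps = [float(s.Ep[0]) for s in states]
        assert eps == sorted(eps)


class TestSimulateRd:
    def test_homogeneous_dynamics_stay_homogeneous(self, grid):
        kys = simulate_rd(SignalingParams(), grid, None, t_end=20.0,
                          dt=0.01, noise_on=False, record_dt=1.0)
        rng = kys["Ep"].values.max(axis=0) - kys["Ep"].values.min(axis=0)
        assert np.max(rng) < 1e-9

    def test_cfl_violation_refused(self, grid):
        with pytest.raises(ValueError, match="CFL"):
            simulate_rd(SignalingParams(D_Ep=100.0), grid, None,
                        t_end=1.0, dt=0.01)

    def test_seeded_runs_reproduce(self, grid):
        protocol = gradient_protocol()
        a = simulate_rd(SignalingParams(), grid, protocol, 20.0, 0.01,
                        seed=5, record_dt=1.0)
        b = simulate_rd(SignalingParams(), grid, protocol, 20.0, 0.01,
                        seed=5, record_dt=1.0)
        np.testing.assert_array_equal(a["Ep"].values, b["Ep"].values)

    def test_conservation_box_holds(self, regime_runs):
        _, runs = regime_runs
        for Et, kys in runs.items():
            p = SignalingParams(Et=Et)
            ep, eep = kys["Ep"].values, kys["EEp"].values
            assert np.all(ep >= 0) and np.all(eep >= 0)
            assert np.all(ep + eep <= p.Et + 1e-9)
            assert np.all((kys["RGa"].values >= 0)
                          & (kys["RGa"].values <= p.RGt + 1e-9))
            assert np.all((kys["N2a"].values >= 0)
                          & (kys["N2a"].values <= p.N2t + 1e-9))

    def test_clip_rate_small_at_criticality(self, regime_runs):
        # the basal state rides the zero bound under the default noise, so
        # some clipping is inherent; it must stay a small fraction of updates
        _, runs = regime_runs
        assert runs[1.26]["Ep"].meta["clip_fraction"] < 0.02

    def test_qss_matches_full_epsilon_near_stationarity(self, grid):
        p = SignalingParams(Et=1.26)
        a = simulate_rd(p, grid, None, 60.0, 0.01, seed=3, n2a_mode="qss",
                        record_dt=1.0)["Ep"]
        b = simulate_rd(p, grid, None, 60.0, 0.01, seed=3, n2a_mode="full",
                        record_dt=1.0)["Ep"]
        scale = np.sqrt(np.mean(a.values ** 2)) + 1e-12
        rms = np.sqrt(np.mean((a.values - b.values) ** 2)) / scale
        assert rms < 0.02


class TestRegimePhenotypes:
    """The four receptor-abundance regimes under the 1-h gradient."""

    def test_basal_no_memory(self, regime_runs):
        protocol, runs = regime_runs
        _, mem = polarization_metrics(runs[1.1]["Ep"], protocol)
        assert mem < 5.0

    def test_criticality_transient_memory(self, regime_runs):
        protocol, runs = regime_runs
        p_t, mem = polarization_metrics(runs[1.26]["Ep"], protocol)
        assert np.isfinite(mem) and 5.0 < mem < 200.0
        # signal-locked polarization during the stimulus
        i60 = np.argmin(np.abs(runs[1.26]["Ep"].times - 60.0))
        assert p_t[i60] > 0.2

    def test_stable_polarized_permanent_memory(self, regime_runs):
        protocol, runs = regime_runs
        _, mem = polarization_metrics(runs[1.35]["Ep"], protocol)
        assert mem == np.inf

    def test_pre_activated_high_uniform(self, regime_runs):
        protocol, runs = regime_runs
        ep = runs[1.85]["Ep"]
        _, mem = polarization_metrics(ep, protocol)
        assert mem < 5.0
        assert ep.values[:, -1].mean() > 1.0   # high uniform plateau


class TestPolarizationMetrics:
    def test_uniform_kymograph_zero_index(self):
        times = np.arange(10.0)
        ky = Kymograph(np.ones((20, 10)), times,
                       (np.arange(20) + 0.5) * np.pi / 10)
        p_t, mem = polarization_metrics(ky, t_stim_end=2.0)
        assert np.allclose(p_t, 0.0)
        assert mem == 0.0

    def test_synthetic_plateau_recovered(self):
        from ghostnav.synth import make_parametric_kymograph
        ky, gt = make_parametric_kymograph(memory_min=40.0, seed=7)
        _, mem = polarization_metrics(ky, t_stim_end=gt.t_stim_end)
        assert abs(mem - 40.0) <= 2.0

    def test_no_washout_returns_none(self):
        protocol = StimulusProtocol([
            StimulusSegment(0, 5, "none"),
            StimulusSegment(5, 65, "gaussian_gradient",
                            components=[GaussianComponent(0.1, 0.5)])])
        times = np.arange(0.0, 65.0)
        ky = Kymograph(np.ones((20, 65)), times,
                       (np.arange(20) + 0.5) * np.pi / 10)
        _, mem = polarization_metrics(ky, protocol)
        assert mem is None


class TestStimulusProtocol:
    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            StimulusProtocol([StimulusSegment(0, 10, "none"),
                              StimulusSegment(5, 15, "uniform",
                                              amplitude=1.0)])

    def test_field_nonnegative_and_localized(self, grid):
        protocol = gradient_protocol()
        egf = protocol.egf(grid.bin_centers, 30.0)
        assert np.all(egf >= 0)
        assert grid.bin_centers[np.argmax(egf)] == pytest.approx(
            np.pi, abs=2 * np.pi / 20)

    def test_linear_amplitude_schedule(self):
        seg = StimulusSegment(0, 10, "gaussian_gradient",
                              components=[GaussianComponent((0.0, 1.0),
                                                            0.5, np.pi)])
        protocol = StimulusProtocol([seg])
        a0 = protocol.egf(np.array([np.pi]), 0.0)[0]
        a5 = protocol.egf(np.array([np.pi]), 5.0)[0]
        assert a0 == pytest.approx(0.0, abs=1e-12)
        assert a5 == pytest.approx(0.5, rel=1e-9)

    def test_membrane_grid_validation(self):
        with pytest.raises(ValueError):
            MembraneGrid(n_bins=2)
        g = MembraneGrid()
        assert g.bin_length == pytest.approx(2 * np.pi * 2.0 / 20)
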