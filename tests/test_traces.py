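import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import bisect

from vesiclefill import synthgen
from vesiclefill.errors import (DegenerateTraceError, InvalidArgumentError,
                                OutOfRangeError)
from vesiclefill.traces import (BoutonTrace, PhotophysicsParams,
                                classify_boutons, deltaF_from_pH,
                                fit_monoexponential, normalize_trace,
                                pH_from_deltaF, plateau_pH)

PP = PhotophysicsParams()


def _forward(ph):
    """Independent evaluation of the printed Hill/HH fluorescence map."""
    f = lambda x: 1.0 / (1.0 + 10.0 ** (1.35 * (7.09 - x)))
    return (f(ph) - f(5.6)) * (1.0 + 10.0 ** (1.35 * (7.09 - 7.3)))


class TestDeltaFfromPH:
    def test_zero_at_resting_ph(self):
        assert deltaF_from_pH(5.6, PP) == pytest.approx(0.0, abs=1e-12)

    def test_surface_ph_value(self):
        # frozen from the direct-evaluation oracle of the printed formula
        assert deltaF_from_pH(7.3, PP) == pytest.approx(0.98533, abs=1e-4)

    def test_partial_reacidification_value(self):
        assert deltaF_from_pH(6.4, PP) == pytest.approx(0.14471, abs=1e-4)

    def test_agrees_with_oracle_on_grid(self):
        grid = np.linspace(3.5, 9.5, 25)
        assert np.allclose(deltaF_from_pH(grid, PP), _forward(grid))

    def test_strictly_increasing(self):
        grid = np.linspace(3.0, 10.0, 200)
        assert np.all(np.diff(deltaF_from_pH(grid, PP)) > 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(OutOfRangeError):
            deltaF_from_pH(2.0, PP)


class TestPHfromDeltaF:
    def test_zero_maps_to_resting_ph(self):
        assert pH_from_deltaF(0.0, PP) == pytest.approx(5.6, abs=1e-9)

    def test_one_over_e_value_matches_bisection_oracle(self):
        # the printed equations give pH 6.74 at ΔF = 1/e (not 6.4)
        expected = bisect(lambda x: _forward(x) - 0.368, 3.0, 10.0,
                          xtol=1e-12)
        assert pH_from_deltaF(0.368, PP) == pytest.approx(expected, abs=1e-9)
        assert pH_from_deltaF(0.368, PP) == pytest.approx(6.7394, abs=1e-3)

    @pytest.mark.parametrize("ph", [5.6, 6.0, 6.4, 7.0, 7.3])
    def test_roundtrip_exact(self, ph):
        assert pH_from_deltaF(deltaF_from_pH(ph, PP), PP) == \
            pytest.approx(ph, abs=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(OutOfRangeError):
            pH_from_deltaF(5.0, PP)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(min_value=3.0, max_value=10.0))
    def test_roundtrip_property(self, ph):
        assert pH_from_deltaF(deltaF_from_pH(ph, PP), PP) == \
            pytest.approx(ph, abs=1e-8)


class TestNormalizeTrace:
    def test_baseline_zero_stim_end_one(self, protocol):
        t = protocol.frame_times_s
        f = 100.0 + 50.0 * np.clip(
            (t - protocol.stim_start_s) / protocol.stim_duration_s, 0, 1)
        tr = normalize_trace(BoutonTrace(0, t, f), protocol)
        b0, b1 = protocol.baseline_window
        e0, e1 = protocol.stim_end_window()
        assert tr.f[b0:b1].mean() == pytest.approx(0.0, abs=1e-12)
        assert tr.f[e0:e1].mean() == pytest.approx(1.0, abs=1e-12)

    def test_constant_trace_is_degenerate(self, protocol):
        t = protocol.frame_times_s
        with pytest.raises(DegenerateTraceError):
            normalize_trace(BoutonTrace(0, t, np.full_like(t, 7.0)), protocol)

    def test_analytic_normalization(self, protocol, kinetics_default):
        trs, _ = synthgen.simulate_truth_traces(
            protocol, kinetics_default, 1, noise_sd=0.0, seed=0)
        kp = kinetics_default["glutamatergic"]
        ntr = normalize_trace(trs[0], protocol)
        expected = (trs[0].f - kp.baseline) / kp.amplitude
        # stim-end window average sits slightly below the peak of the ramp
        assert np.allclose(ntr.f, expected / expected[
            slice(*protocol.stim_end_window())].mean(), atol=1e-12)

    def test_quench_first_point_mode(self, quench_protocol, kinetics_default):
        trs, _ = synthgen.simulate_truth_traces(
            quench_protocol, kinetics_default, 1, noise_sd=0.0, seed=0)
        ntr = normalize_trace(trs[0], quench_protocol,
                              mode="quench-first-point")
        q0 = quench_protocol.quench_window[0]
        assert ntr.f[q0] == pytest.approx(1.0, abs=1e-12)

    def test_cypher_sign_inverted(self, protocol):
        t = protocol.frame_times_s
        f = 100.0 - 50.0 * np.clip(
            (t - protocol.stim_start_s) / protocol.stim_duration_s, 0, 1)
        tr = normalize_trace(BoutonTrace(0, t, f, channel="CypHer"), protocol)
        e0, e1 = protocol.stim_end_window()
        assert tr.f[e0:e1].mean() == pytest.approx(1.0, abs=1e-12)


class TestFitMonoexponential:
    def test_noiseless_exponential_recovered_exactly(self):
        t = np.arange(0, 30, 0.2)
        y = 0.1 + 0.9 * np.exp(-t / 4.9)
        fit = fit_monoexponential(t, y)
        assert fit.converged
        assert fit.tau_s == pytest.approx(4.9, abs=1e-4)
        assert fit.plateau == pytest.approx(0.1, abs=1e-6)

    def test_noisy_recovery_monte_carlo(self):
        # 2% noise, 100 replicates of tau = 0.5 s: mean within 0.5 +/- 0.05
        rng = np.random.default_rng(7)
        t = np.arange(0, 3, 0.02)
        taus = []
        for _ in range(100):
            y = np.exp(-t / 0.5) + rng.normal(0, 0.02, t.size)
            fit = fit_monoexponential(t, y)
            assert fit.converged
            taus.append(fit.tau_s)
        assert np.mean(taus) == pytest.approx(0.5, abs=0.05)

    def test_increasing_segment_does_not_converge(self):
        t = np.arange(0, 10, 0.5)
        fit = fit_monoexponential(t, 1.0 + 0.1 * t)
        assert not fit.converged

    def test_short_segment_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fit_monoexponential(np.arange(4.0), np.ones(4))

    def test_tau_invariant_under_affine_normalization(self):
        t = np.arange(0, 30, 0.2)
        y = 0.2 + 0.8 * np.exp(-t / 3.3)
        tau1 = fit_monoexponential(t, y).tau_s
        tau2 = fit_monoexponential(t, 5.0 * y + 2.0).tau_s
        assert tau1 == pytest.approx(tau2, rel=1e-9)


class TestPlateauPH:
    @pytest.mark.parametrize("plateau_df, expected_ph", [
        (0.0, 5.6),       # full re-acidification
        (0.145, 6.4),     # partial re-acidification regime
        (0.985, 7.3),     # no re-acidification (RB-like)
    ])
    def test_plateau_maps_to_expected_ph(self, protocol, plateau_df,
                                         expected_ph):
        kin = {"x": synthgen.KineticParams(tau_s=4.9, plateau_df=plateau_df)}
        trs, _ = synthgen.simulate_truth_traces(protocol, kin, 1,
                                                noise_sd=0.0, seed=0)
        ph, fit = plateau_pH(trs[0], protocol, PP)
        assert fit.converged
        assert ph == pytest.approx(expected_ph, abs=0.05)


class TestClassifyBoutons:
    def _population(self, protocol, inhibited_fraction, seed):
        kin = {
            "glutamatergic": synthgen.KineticParams(tau_s=4.9),
            "inhibited": synthgen.KineticParams(tau_s=4.9, plateau_df=0.985),
        }
        fr = {"glutamatergic": 1 - inhibited_fraction,
              "inhibited": inhibited_fraction}
        rb, truth = synthgen.simulate_truth_traces(
            protocol, kin, 200, class_fractions=fr, noise_sd=0.02, seed=seed)
        ctrl_kin = {k: synthgen.KineticParams(tau_s=4.9) for k in kin}
        ctrl, _ = synthgen.simulate_truth_traces(
            protocol, ctrl_kin, 200, class_fractions=fr, noise_sd=0.02,
            seed=seed)
        return ctrl, rb, truth

    def test_full_recovery_is_uninhibited(self, protocol):
        ctrl, _, _ = self._population(protocol, 0.0, 1)
        labels = classify_boutons(ctrl, ctrl, protocol)
        assert set(labels.values()) == {"uninhibited"}

    def test_inhibited_population_fraction_recovered(self, protocol):
        # ~30% of boutons contain another VGLUT isoform and stay inhibited
        ctrl, rb, truth = self._population(protocol, 0.30, 2)
        labels = classify_boutons(ctrl, rb, protocol)
        frac = np.mean([v == "inhibited" for v in labels.values()])
        # binomial error at n=200: sd ~ 0.032
        assert frac == pytest.approx(0.30, abs=0.10)
        truth_map = {p["bouton_id"]: p["class"] for p in truth.bouton_params}
        hits = [labels[b] == ("inhibited" if truth_map[b] == "inhibited"
                              else "uninhibited") for b in labels]
        assert np.mean(hits) > 0.95

    def test_unpaired_ids_rejected(self, protocol):
        ctrl, rb, _ = self._population(protocol, 0.0, 3)
        with pytest.raises(InvalidArgumentError):
            classify_boutons(ctrl, rb[:-1], protocol)
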