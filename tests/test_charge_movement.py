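"""PSS pipeline: trace utilities, relaxation/Boltzmann fits, rates, recovery."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gatkin import (InputDomainError, NoiseSpec, ProtocolMismatchError,
                    SolutionCondition, Sweep, VoltageStepProtocol,
                    simulate_condition_set, simulate_sweep)
from gatkin.charge_movement import (BoltzmannFit, QVPoint, RelaxationFit,
                                    derive_rates, fit_boltzmann, fit_relaxation,
                                    integrate_charge, measure_plateau_current,
                                    measure_steady_current, run_pss_pipeline,
                                    smooth_adjacent_average, subtract_blocker,
                                    trapezoid_charge)
from gatkin.simulate import default_tevc_noise_sd

from oracles import grid_search_exponential, windowed_mean


def _sweep(values, fs=1000.0, v=-100.0):
    values = np.asarray(values, float)
    return Sweep(v, np.arange(values.size) / fs, values)


class TestSmoothing:
    @pytest.mark.parametrize("values,window,expected", [
        ([-5.0] * 6, 5, [-5.0] * 6),                      # constant unchanged
        ([0, 0, 3, 0, 0], 3, [0, 1, 1, 1, 0]),            # worked example
        ([1, 2, 3, 4, 5], 1, [1, 2, 3, 4, 5]),            # identity
    ])
    def test_examples(self, values, window, expected):
        out = smooth_adjacent_average(_sweep(values), window)
        assert np.allclose(out.current_nA, expected)

    @given(st.lists(st.floats(-100, 100), min_size=12, max_size=40),
           st.integers(1, 11))
    def test_matches_brute_force_windowed_mean(self, values, window):
        out = smooth_adjacent_average(_sweep(values), window)
        assert np.allclose(out.current_nA, windowed_mean(values, window),
                           rtol=1e-12, atol=1e-12)

    def test_window_exceeding_trace_rejected(self):
        with pytest.raises(InputDomainError):
            smooth_adjacent_average(_sweep([1.0, 2.0, 3.0]), 7)


class TestSubtraction:
    def test_identical_sets_give_zero(self, noise_free_recordings):
        nd = noise_free_recordings["ND98"]
        diff = subtract_blocker(nd, nd)
        for v in nd.potentials():
            assert np.all(diff.sweep_at(v).current_nA == 0.0)

    def test_recovers_known_pss_component(self, protocol, cm_params, cell,
                                          quiet_cell, noise_free_recordings):
        """test = blocker + PSS  ==>  subtraction returns the PSS exactly."""
        blk = noise_free_recordings["blocker"]
        nd = noise_free_recordings["ND98"]
        diff = subtract_blocker(nd, blk)
        for v in protocol.test_potentials_mV:
            pure = simulate_sweep(protocol, v, cm_params, quiet_cell)
            assert np.allclose(diff.sweep_at(v).current_nA, pure.current_nA,
                               atol=1e-9)

    def test_protocol_mismatch_names_field(self, noise_free_recordings, cm_params,
                                           cell):
        other_proto = VoltageStepProtocol(test_potentials_mV=(-120.0, -60.0, 0.0))
        from gatkin import TwoSubstrateParams
        other = simulate_condition_set(
            other_proto, cm_params, cell, TwoSubstrateParams(),
            [SolutionCondition("b", blocker=True)])["b"]
        with pytest.raises(ProtocolMismatchError, match="test_potentials_mV"):
            subtract_blocker(noise_free_recordings["ND98"], other)


class TestRelaxationFit:
    def test_exact_recovery(self, protocol):
        """A = -10 nA, tau = 50 ms, baseline = -2 nA, referenced to onset."""
        t = protocol.time_axis()
        y = -10.0 * np.exp(-(t - protocol.step_start_s) / 0.05) - 2.0
        fit = fit_relaxation(Sweep(-100.0, t, y), protocol)
        assert fit.converged
        assert fit.amplitude_nA == pytest.approx(-10.0, rel=1e-6)
        assert fit.tau_s == pytest.approx(0.05, rel=1e-6)
        assert fit.baseline_nA == pytest.approx(-2.0, rel=1e-6)

    def test_constant_trace_not_converged(self, protocol):
        t = protocol.time_axis()
        fit = fit_relaxation(Sweep(-100.0, t, np.full_like(t, -7.0)), protocol)
        assert not fit.converged
        assert fit.amplitude_nA == pytest.approx(0.0, abs=1e-6)
        assert fit.baseline_nA == pytest.approx(-7.0, abs=1e-6)

    def test_agrees_with_grid_search_oracle(self, protocol):
        """Noisy fits land within one grid cell of the exhaustive SSE optimum."""
        rng = np.random.default_rng(11)
        t = protocol.time_axis()
        for _ in range(3):
            A = rng.uniform(-60.0, -20.0)
            tau = rng.uniform(0.02, 0.08)
            base = rng.uniform(-5.0, 5.0)
            y = A * np.exp(-(t - protocol.step_start_s) / tau) + base
            y += rng.normal(0.0, 0.5, t.size)
            fit = fit_relaxation(Sweep(-100.0, t, y), protocol)
            mask = (t >= fit.fit_window_s[0] - 1e-12) & (t < fit.fit_window_s[1] - 1e-12)
            gA, gtau, gbase, gsse = grid_search_exponential(
                t[mask], y[mask], protocol.step_start_s,
                (A - 10, A + 10), (tau / 2, tau * 2), (base - 2, base + 2))
            assert fit.converged
            assert fit.rss <= gsse * (1.0 + 1e-9)
            assert abs(fit.amplitude_nA - gA) <= 5 * 20.0 / 199
            assert abs(fit.tau_s - gtau) <= 5 * (tau * 1.5) / 199
            assert abs(fit.baseline_nA - gbase) <= 5 * 4.0 / 49

    def test_window_outside_step_rejected(self, protocol):
        t = protocol.time_axis()
        sw = Sweep(-100.0, t, np.zeros_like(t))
        with pytest.raises(InputDomainError):
            fit_relaxation(sw, protocol, 0.1, 0.9)  # end beyond step duration


class TestChargeIntegration:
    def test_analytic_product(self):
        fit = RelaxationFit(-100.0, -10.0, 0.05, 0.0, (0.105, 0.9), 0.1, 0.0, True)
        assert integrate_charge(fit).Q_nC == pytest.approx(-0.5)
        fit.amplitude_nA = 0.0
        assert integrate_charge(fit).Q_nC == 0.0

    def test_non_converged_rejected(self):
        fit = RelaxationFit(-100.0, -10.0, 0.05, 0.0, (0.105, 0.9), 0.1, 0.0, False)
        with pytest.raises(InputDomainError):
            integrate_charge(fit)

    def test_matches_trapezoid_on_isolated_pss(self, protocol, cm_params,
                                               quiet_cell):
        """Fitted A*tau equals the numeric trapezoid of the isolated PSS trace
        within 0.1%."""
        for v in (-140.0, -80.0, 0.0, 40.0):
            sw = simulate_sweep(protocol, v, cm_params, quiet_cell)
            fit = fit_relaxation(sw, protocol)
            q = integrate_charge(fit).Q_nC
            assert q == pytest.approx(trapezoid_charge(sw, protocol), rel=1e-3)


class TestBoltzmann:
    def test_exact_recovery_from_generating_equation(self):
        V = np.linspace(-120, 40, 9)
        Q = 5.0 / (1.0 + np.exp(-(V - (-40.0)) / 20.0))
        fit = fit_boltzmann([QVPoint(v, q) for v, q in zip(V, Q)])
        assert fit.converged
        assert fit.Qmax_nC == pytest.approx(5.0, rel=1e-6)
        assert fit.V_half_mV == pytest.approx(-40.0, rel=1e-6)
        assert fit.sigma_mV == pytest.approx(20.0, rel=1e-6)
        assert abs(fit.Q_offset_nC) < 1e-6

    def test_midpoint_and_asymptote_identities(self):
        V = np.linspace(-120, 40, 9)
        Q = 1.0 - 5.0 / (1.0 + np.exp(-(V + 30.0) / 15.0))  # decreasing limb
        fit = fit_boltzmann([QVPoint(v, q) for v, q in zip(V, Q)])
        assert fit.converged and fit.orientation == "decreasing"
        assert fit.sigma_mV > 0
        mid = fit.curve(fit.V_half_mV)
        assert mid == pytest.approx(fit.Q_offset_nC + fit.Qmax_nC / 2.0, rel=1e-12)
        lo, hi = fit.curve(-1e6), fit.curve(1e6)
        assert hi - lo == pytest.approx(fit.Qmax_nC, rel=1e-9)

    def test_preconditions(self):
        pts = [QVPoint(v, v / 100.0) for v in (-100.0, -50.0, 0.0, 50.0)]
        with pytest.raises(InputDomainError):
            fit_boltzmann(pts)  # < 5 points
        pts = [QVPoint(v, v / 100.0) for v in np.linspace(-30, 30, 6)]
        with pytest.raises(InputDomainError):
            fit_boltzmann(pts)  # span < 80 mV


class TestRates:
    def test_eq_identities(self):
        boltz = BoltzmannFit(-8.0, -35.0, 25.0, 8.0, converged=True)
        tau_table = {-120.0: 0.02, -35.0: 0.05, 0.0: 0.03}
        rt = derive_rates(boltz, tau_table)
        # inrate + outrate = 1/tau to machine precision at every potential
        assert np.allclose(rt.inrate_per_s + rt.outrate_per_s, 1.0 / rt.tau_s,
                           rtol=1e-15, atol=0)
        # at V_half both equal 1/(2 tau)
        i = list(rt.test_potentials_mV).index(-35.0)
        assert rt.inrate_per_s[i] == pytest.approx(1.0 / (2 * 0.05), rel=1e-12)
        assert rt.outrate_per_s[i] == pytest.approx(1.0 / (2 * 0.05), rel=1e-12)

    def test_invalid_tau_rejected(self):
        boltz = BoltzmannFit(-8.0, -35.0, 25.0, 8.0, converged=True)
        with pytest.raises(InputDomainError):
            derive_rates(boltz, {-100.0: -0.01})


class TestSteadyCurrents:
    def test_constant_minus_baseline(self, protocol):
        t = protocol.time_axis()
        y = np.where((t >= protocol.step_start_s) & (t < protocol.step_end_s),
                     -30.0, -4.0)
        assert measure_steady_current(Sweep(-100.0, t, y), protocol) == \
            pytest.approx(-26.0)

    def test_recovers_generator_steady_current(self, protocol, cm_params,
                                               quiet_cell):
        sw = simulate_sweep(protocol, -100.0, cm_params, quiet_cell,
                            steady_current=-50.0)
        assert measure_steady_current(sw, protocol) == pytest.approx(-50.0, abs=0.5)

    def test_tail_window_contracts(self, protocol):
        t = protocol.time_axis()
        sw = Sweep(-100.0, t, np.zeros_like(t))
        with pytest.raises(InputDomainError):
            measure_steady_current(sw, protocol, tail_s=2.0)

    def test_plateau_constant_and_ramp(self):
        t = np.arange(0.0, 8.0, 0.01)
        assert measure_plateau_current(Sweep(0.0, t, np.full_like(t, -30.0))) == \
            pytest.approx((-30.0, 0.0))
        mean, _ = measure_plateau_current(Sweep(0.0, t, 2.0 + 3.0 * t))
        assert mean == pytest.approx(2.0 + 3.0 * 5.0, rel=1e-3)

    def test_plateau_matches_brute_force(self):
        rng = np.random.default_rng(3)
        t = np.arange(0.0, 8.0, 0.01)
        y = -20.0 + rng.normal(0, 1.0, t.size)
        mean, sd = measure_plateau_current(Sweep(0.0, t, y))
        m = (t >= 4.0) & (t <= 6.0)
        assert mean == pytest.approx(float(np.mean(y[m])), rel=1e-12)
        assert sd == pytest.approx(float(np.std(y[m])), rel=1e-12)

    def test_uncovered_window_rejected(self):
        t = np.arange(0.0, 3.0, 0.01)
        with pytest.raises(InputDomainError):
            measure_plateau_current(Sweep(0.0, t, np.zeros_like(t)))


class TestPipeline:
    def test_noise_free_recovery(self, noise_free_recordings, cm_params):
        res = run_pss_pipeline(noise_free_recordings["ND98"],
                               noise_free_recordings["blocker"])
        b = res.boltzmann
        assert b.converged
        assert abs(b.V_half_mV - cm_params.V_half) / abs(cm_params.V_half) < 1e-4
        assert abs(abs(b.Qmax_nC) - cm_params.Qmax) / cm_params.Qmax < 1e-4
        assert abs(b.sigma_mV - cm_params.sigma_mV) / cm_params.sigma_mV < 1e-4

    def test_blocker_vs_blocker_flags_not_converged(self, noise_free_recordings):
        blk = noise_free_recordings["blocker"]
        res = run_pss_pipeline(blk, blk)
        assert not res.boltzmann.converged
        assert len(res.excluded) > 0

    def test_invariant_under_common_additive_component(
            self, protocol, cm_params, cell, transport, noise_free_recordings):
        """Adding any common component to test and blocker leaves every
        pipeline output unchanged (subtraction linearity)."""
        nd, blk = noise_free_recordings["ND98"], noise_free_recordings["blocker"]
        res0 = run_pss_pipeline(nd, blk)

        def shifted(rec):
            sweeps = {}
            for v in rec.potentials():
                sw = rec.sweep_at(v)
                extra = 5.0 * np.sin(2 * np.pi * 3.0 * sw.time_s) + 0.1 * v
                sweeps[v] = sw.copy_with(sw.current_nA + extra)
            from gatkin import RecordingSet
            return RecordingSet(rec.condition_label, rec.solution, sweeps,
                                rec.protocol)

        res1 = run_pss_pipeline(shifted(nd), shifted(blk))
        assert res1.boltzmann.V_half_mV == pytest.approx(res0.boltzmann.V_half_mV,
                                                         rel=1e-9)
        assert res1.boltzmann.Qmax_nC == pytest.approx(res0.boltzmann.Qmax_nC,
                                                       rel=1e-9)
        assert np.allclose(res1.qv["Q_nC"], res0.qv["Q_nC"], rtol=1e-9)

    def test_vhalf_bias_small_at_two_percent_noise(self, protocol, cm_params,
                                                   cell, transport):
        """20 seeded replicates at 2% (of observable PSS peak) noise: the mean
        V_half error stays below 1 mV."""
        sd = default_tevc_noise_sd(protocol, cm_params, fraction=0.02)
        errs = []
        for seed in range(20):
            recs = simulate_condition_set(
                protocol, cm_params, cell, transport,
                [SolutionCondition("blk", blocker=True), SolutionCondition("ND98")],
                NoiseSpec(sd_current=sd, seed=seed))
            res = run_pss_pipeline(recs["ND98"], recs["blk"])
            assert res.boltzmann.converged
            errs.append(res.boltzmann.V_half_mV - cm_params.V_half)
        assert abs(np.mean(errs)) < 1.0
        assert np.std(errs) < 2.0
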