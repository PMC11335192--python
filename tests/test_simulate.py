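"""Generator correctness: closed forms, independent ODE oracle, contracts."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gatkin import (ChargeMovementParams, EffluxSimParams, InputDomainError,
                    NoiseSpec, SolutionCondition, TwoSubstrateParams,
                    VoltageStepProtocol, hill_current, simulate_condition_set,
                    simulate_dose_response, simulate_efflux, simulate_sweep,
                    steady_state_two_substrate)
from gatkin.charge_movement import trapezoid_charge
from gatkin.simulate import peak_pss_amplitude

from oracles import depletion_percent_series, euler_two_state


class TestTwoSubstrate:
    @pytest.mark.parametrize("G,B,I_B,expected_of_IG", [
        (0.0, 0.0, -80.0, 0.0),      # empty numerator
        ("K_G", 0.0, -80.0, 0.5),    # half saturation
        ("K_G", "K_B", 0.0, 1 / 3),  # pure competitive inhibition by B
    ])
    def test_analytic_examples(self, flat_transport, G, B, I_B, expected_of_IG):
        tp = TwoSubstrateParams(I_B=I_B, voltage_scale=flat_transport.voltage_scale)
        G = tp.K_G if G == "K_G" else G
        B = tp.K_B if B == "K_B" else B
        assert steady_state_two_substrate(G, B, tp, -60.0) == pytest.approx(
            expected_of_IG * tp.I_G, abs=1e-12)

    def test_negative_concentration_rejected(self, transport):
        with pytest.raises(InputDomainError):
            steady_state_two_substrate(-1.0, 0.0, transport)
        with pytest.raises(InputDomainError):
            steady_state_two_substrate(0.0, -1.0, transport)

    @given(g=st.floats(0.01, 50.0), ib_frac=st.floats(0.01, 2.0))
    def test_pure_competitive_form_is_monotone_in_B(self, g, ib_frac):
        """Without the slowdown term the current is a Moebius function of B,
        hence strictly monotone along any betaine row."""
        tp = TwoSubstrateParams(I_B=-150.0 * ib_frac,
                                voltage_scale=lambda V: np.ones_like(np.asarray(V, float)))
        B = np.geomspace(1e-3, 500.0, 60)
        I = np.array([steady_state_two_substrate(g * tp.K_G, b, tp, -60.0) for b in B])
        d = np.diff(I)
        assert np.all(d <= 1e-12) or np.all(d >= -1e-12)

    def test_slowdown_term_creates_interior_minimum(self):
        tp = TwoSubstrateParams(K_inh=0.3)
        B = np.array([0.0, 0.001, 0.01, 0.1, 1.0, 3.0, 10.0, 30.0, 50.0])
        I = np.array([steady_state_two_substrate(10.0, b, tp, -60.0) for b in B])
        k = int(np.argmin(np.abs(I)))
        assert 0 < k < B.size - 1


class TestSweep:
    def test_midpoint_identities(self):
        """At V = V_half the occupancy is 1/2 and tau = 1/(2*k0)."""
        p = ChargeMovementParams(V_half=-40.0)
        assert p.occupancy(-40.0) == pytest.approx(0.5)
        assert p.tau(-40.0) == pytest.approx(1.0 / (2.0 * p.k0))

    def test_matches_euler_master_equation(self, quiet_cell):
        """The closed-form sweep agrees with explicit Euler integration of the
        two-state master equation (dt = 1 us)."""
        proto = VoltageStepProtocol()
        p = ChargeMovementParams(Qmax=10.0, V_half=-40.0)
        sw = simulate_sweep(proto, -40.0, p, quiet_cell)
        T = 0.1
        t_o, p_o, i_o = euler_two_state(p.Qmax, p.V_half, p.z_eff, p.k0,
                                        p.temperature_K, proto.holding_mV, -40.0,
                                        duration_s=T, dt=1e-6)
        dq_oracle = p.Qmax * (p_o[-1] - p_o[0])
        # charge moved by time T: dQ * (1 - exp(-T/tau)), dQ = 10*(1/2 - f(-60))
        dq_full = 10.0 * (0.5 - p.occupancy(-60.0))
        dq_expected = dq_full * (1.0 - np.exp(-T / p.tau(-40.0)))
        assert dq_oracle == pytest.approx(dq_expected, rel=1e-4)
        # compare trace samples inside the step against the oracle current
        mask = (sw.time_s >= proto.step_start_s + 1e-3) & \
               (sw.time_s < proto.step_start_s + 0.1)
        ts = sw.time_s[mask] - proto.step_start_s
        oracle_at = np.interp(ts, t_o, i_o)
        assert np.allclose(sw.current_nA[mask], oracle_at, rtol=2e-3, atol=1e-3)

    def test_step_integral_equals_displaced_charge(self, protocol, cm_params,
                                                   quiet_cell):
        """Noise-free isolated PSS traces integrate (trapezoid) to dQ(V)
        within 0.1% at every protocol potential."""
        for v in protocol.test_potentials_mV:
            if v == protocol.holding_mV:
                continue
            sw = simulate_sweep(protocol, v, cm_params, quiet_cell)
            dq = cm_params.delta_Q(v, protocol.holding_mV)
            assert trapezoid_charge(sw, protocol) == pytest.approx(dq, rel=1e-3)

    def test_contracts(self, protocol, cm_params, cell):
        with pytest.raises(InputDomainError):
            simulate_sweep(protocol, -55.0, cm_params, cell)  # not a protocol level
        with pytest.raises(InputDomainError):
            simulate_sweep(protocol, -100.0, cm_params, cell,
                           noise=NoiseSpec(sd_current=1.0))  # noisy without seed


class TestConditionSet:
    def test_blocker_is_capacitive_plus_leak_only(self, protocol, cm_params,
                                                  cell, transport):
        recs = simulate_condition_set(protocol, cm_params, cell, transport,
                                      [SolutionCondition("blk", blocker=True),
                                       SolutionCondition("ND98")])
        blk = recs["blk"]
        for v in protocol.test_potentials_mV:
            analytic = simulate_sweep(protocol, v, None, cell)
            assert np.array_equal(blk.sweep_at(v).current_nA, analytic.current_nA)

    def test_saturating_primary_substrate_quenches_pss(self, protocol, cm_params,
                                                       quiet_cell, transport):
        """At G >= 20*K_G the PSS transient observable after the capacitive
        window is < 1% of the substrate-free one."""
        sat = SolutionCondition("satG", gaba_uM=20.0 * transport.K_G)
        recs = simulate_condition_set(protocol, cm_params, quiet_cell, transport,
                                      [SolutionCondition("blk", blocker=True),
                                       SolutionCondition("ND98"), sat])
        off = 0.005
        from gatkin.simulate import modulated_charge_movement
        cm_sat = modulated_charge_movement(cm_params, transport, sat)
        amp_nd = peak_pss_amplitude(protocol, cm_params, at_offset_s=off)
        amp_sat = peak_pss_amplitude(protocol, cm_sat, at_offset_s=off)
        assert amp_sat < 0.01 * amp_nd

    def test_seed_determinism_bit_identical(self, protocol, cm_params, cell,
                                            transport):
        conds = [SolutionCondition("blk", blocker=True), SolutionCondition("ND98")]
        noise = NoiseSpec(sd_current=5.0, seed=42)
        a = simulate_condition_set(protocol, cm_params, cell, transport, conds, noise)
        b = simulate_condition_set(protocol, cm_params, cell, transport, conds, noise)
        for label in a:
            for v in protocol.test_potentials_mV:
                assert np.array_equal(a[label].sweep_at(v).current_nA,
                                      b[label].sweep_at(v).current_nA)

    def test_duplicate_labels_rejected(self, protocol, cm_params, cell, transport):
        with pytest.raises(InputDomainError):
            simulate_condition_set(protocol, cm_params, cell, transport,
                                   [SolutionCondition("x"), SolutionCondition("x")])


class TestDoseResponse:
    def test_noise_free_matches_closed_form(self):
        """Betaine-like design: Imax -76.15 nA, K0.5 11.57 mM, p = 1."""
        concs = [1.0, 3.0, 10.0, 30.0, 50.0]
        tab = simulate_dose_response(-76.15, 11.57, 1.0, concs)
        expected = [-76.15 * S / (S + 11.57) for S in concs]  # independent formula
        assert np.allclose(tab["mean_current_nA"], expected, rtol=1e-12)

    def test_half_saturation_and_asymptotes(self):
        tab = simulate_dose_response(-100.0, 5.0, 1.0, [5.0])
        assert tab["mean_current_nA"].iloc[0] == pytest.approx(-50.0)
        assert hill_current(1e-9, -100.0, 5.0) == pytest.approx(0.0, abs=1e-6)
        assert hill_current(1e9, -100.0, 5.0) == pytest.approx(-100.0, rel=1e-6)

    def test_contracts(self):
        with pytest.raises(InputDomainError):
            simulate_dose_response(-100.0, 5.0, 0.0, [1.0, 10.0])  # p <= 0
        with pytest.raises(InputDomainError):
            simulate_dose_response(-100.0, 5.0, 1.0, [0.0, 10.0])  # conc <= 0


class TestEfflux:
    def test_zero_dose_gives_basal_everywhere(self):
        tc = simulate_efflux(EffluxSimParams(), 0.0)
        pct = 100.0 * tc.released_counts / tc.total_counts
        expected = depletion_percent_series([0.12] * 9, 2.0)
        assert np.allclose(pct, expected, atol=1e-12)

    def test_basal_first_fraction_is_exact(self):
        """basal 0.12 %/min -> the first 2-min fraction releases 0.24%."""
        tc = simulate_efflux(EffluxSimParams(basal_rate=0.12), 10.0)
        pct = 100.0 * tc.released_counts / tc.total_counts
        assert pct[0] == pytest.approx(0.24, abs=1e-12)

    @given(dose=st.floats(0.0, 200.0), monensin=st.booleans(),
           basal=st.floats(0.0, 1.0), kmax=st.floats(0.0, 3.0))
    def test_conservation_and_monotone_depletion(self, dose, monensin, basal, kmax):
        params = EffluxSimParams(basal_rate=basal, k_max=kmax)
        tc = simulate_efflux(params, dose, monensin=monensin,
                             noise=NoiseSpec(sd_rel=0.05, seed=7))
        assert tc.released_counts.sum() + tc.remaining_counts == pytest.approx(
            params.total_load, rel=1e-12)
        assert np.all(tc.released_counts >= 0)

    def test_negative_dose_rejected(self):
        with pytest.raises(InputDomainError):
            simulate_efflux(EffluxSimParams(), -1.0)
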