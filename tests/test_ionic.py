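"""Single-cell ionic models: scaling contract, oracle integration checks,
gate invariants, convergence, and known electrophysiological behavior."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cardiopatch import analysis
from cardiopatch.ionic import (
    CurrentScalers,
    courtemanche,
    ionic_rhs,
    new_state,
    paci,
    run_single_cell,
)
from cardiopatch.protocols import PacingTrain, StimulusProtocol


class TestScalingContract:
    @pytest.mark.parametrize("model", [paci, courtemanche])
    def test_zero_s_na_removes_sodium_current(self, model):
        y = model.initial_state()
        y[0] = -20.0   # depolarized, channels open
        y[1:4] = 0.5
        cur = model.currents(y, s_na=0.0)
        assert cur["i_na"] == 0.0

    @pytest.mark.parametrize("model", [paci, courtemanche])
    def test_scaling_is_exactly_multiplicative(self, model):
        y = model.initial_state()
        y[0] = -30.0
        y[1:4] = 0.4
        base = model.currents(y, s_na=1.0, s_nak=1.0)
        half = model.currents(y, s_na=0.5, s_nak=0.5)
        assert half["i_na"] == pytest.approx(0.5 * base["i_na"], rel=1e-12)
        assert half["i_nak"] == pytest.approx(0.5 * base["i_nak"], rel=1e-12)
        # every other current untouched
        for k in base:
            if k not in ("i_na", "i_nak", "i_ion"):
                assert half[k] == base[k]

    def test_identity_scaling_matches_unscaled(self):
        state = new_state("paci_hipsc")
        dy1, _ = ionic_rhs(state)
        dy2, _ = ionic_rhs(state, CurrentScalers(1.0, 1.0))
        np.testing.assert_array_equal(dy1, dy2)

    def test_scaler_range_enforced(self):
        with pytest.raises(ValueError):
            CurrentScalers(s_na=-0.1)
        with pytest.raises(ValueError):
            CurrentScalers(s_nak=2.5)

    def test_nonfinite_state_rejected_with_variable_name(self):
        state = new_state("courtemanche")
        state.y[5] = np.nan
        with pytest.raises(ValueError, match="index 5"):
            ionic_rhs(state)

    def test_unknown_model_rejected(self):
        with pytest.raises(KeyError, match="unknown ionic model"):
            new_state("noble_1962")


class TestOracleIntegration:
    """Production path (tabulated Rush-Larsen) against an independent
    adaptive-step integration of the reference right-hand side."""

    def test_hipsc_spontaneous_cycle_matches_reference(self):
        def f(t, y):
            dy, _ = paci.rhs(y)
            return dy

        y0 = paci.initial_state()
        t_eval = np.arange(0, 6000.0, 1.0)
        sol = solve_ivp(f, (0, 6000.0), y0, method="LSODA", t_eval=t_eval,
                        rtol=1e-7, atol=1e-9, max_step=5.0)
        ref_acts = analysis.detect_activations(t_eval, sol.y[0], refractory=100.0)
        tr = run_single_cell("paci_hipsc", duration=6000.0, dt=0.02)
        acts = analysis.detect_activations(tr.time, tr.v_m, refractory=100.0)
        assert len(ref_acts) >= 2 and len(acts) >= 2
        cl_ref = np.diff(ref_acts)[-1]
        cl = np.diff(acts)[-1]
        assert cl == pytest.approx(cl_ref, rel=0.01)

    def test_atrial_apd_matches_reference(self):
        amp, dur, onset, cl = 20.0, 2.0, 20.0, 550.0

        def f(t, y):
            ph = (t - onset) % cl
            stim = amp if (t >= onset and ph < dur) else 0.0
            dy, _ = courtemanche.rhs(y, i_stim=stim)
            return dy

        y0 = courtemanche.initial_state()
        t_eval = np.arange(0, 1200.0, 0.5)
        sol = solve_ivp(f, (0, 1200.0), y0, method="LSODA", t_eval=t_eval,
                        rtol=1e-7, atol=1e-9, max_step=0.5)
        m_ref = analysis.ap_metrics(t_eval, sol.y[0],
                                    events=analysis.detect_activations(
                                        t_eval, sol.y[0], refractory=50.0))
        proto = StimulusProtocol(trains=[PacingTrain(onset, cl, 2, dur, amp)])
        tr = run_single_cell("courtemanche", protocol=proto, duration=1200.0,
                             dt=0.01, output_dt=0.5)
        m = analysis.ap_metrics(tr.time, tr.v_m)
        assert m.apd90[0] == pytest.approx(m_ref.apd90[0], rel=0.01)
        assert m.amplitude[0] == pytest.approx(m_ref.amplitude[0], rel=0.01)


class TestBehavior:
    def test_hipsc_beats_spontaneously(self):
        tr = run_single_cell("paci_hipsc", duration=10_000.0)
        acts = analysis.detect_activations(tr.time, tr.v_m, refractory=100.0)
        assert len(acts) >= 1

    def test_atrial_model_is_quiescent(self):
        tr = run_single_cell("courtemanche", duration=10_000.0)
        acts = analysis.detect_activations(tr.time, tr.v_m, refractory=50.0)
        assert len(acts) == 0

    def test_half_nak_depolarizes_diastolic_potential(self):
        ctrl = run_single_cell("paci_hipsc", duration=15_000.0)
        down = run_single_cell("paci_hipsc", scalers=CurrentScalers(s_nak=0.5),
                               duration=15_000.0)
        mdp_c = analysis.ap_metrics(ctrl.time, ctrl.v_m).mdp.mean()
        mdp_d = analysis.ap_metrics(down.time, down.v_m).mdp.mean()
        assert mdp_d > mdp_c

    def test_zero_duration_returns_empty_trace(self):
        state0 = new_state("courtemanche").y.copy()
        tr = run_single_cell("courtemanche", duration=0.0)
        assert tr.time.size == 0
        np.testing.assert_array_equal(tr.final_state, state0)


class TestNumerics:
    @pytest.mark.parametrize("model_id,dt", [("paci_hipsc", 0.02),
                                             ("courtemanche", 0.01)])
    def test_gates_stay_in_unit_interval(self, model_id, dt):
        from cardiopatch.ionic import get_model

        m = get_model(model_id)
        rng = np.random.default_rng(8)
        n = 32
        S = np.tile(m.initial_state(), (n, 1))
        # random valid perturbations of voltage and gates
        S[:, 0] = rng.uniform(-90.0, 30.0, n)
        S[:, m.GATE_SLICE] = rng.uniform(0.0, 1.0, S[:, m.GATE_SLICE].shape)
        tab = m.build_tables(dt)
        ra, rb = m.stepper_consts(dt)
        clamp = np.zeros(1, np.int64)
        istim = np.zeros(n)
        ones = np.ones(n)
        act = np.ones(n, np.uint8)
        for _ in range(500):
            m.step_cells(S, istim, ones, ones, act, dt, tab, ra, rb, clamp)
        gates = S[:, m.GATE_SLICE]
        assert np.isfinite(S).all()
        assert gates.min() >= 0.0 and gates.max() <= 1.0

    def test_atrial_trace_converges_with_dt(self):
        proto = StimulusProtocol(trains=[PacingTrain(20.0, 1000.0, 5, 2.0, 20.0)])
        a = run_single_cell("courtemanche", protocol=proto, duration=5000.0,
                            dt=0.01, output_dt=1.0)
        b = run_single_cell("courtemanche", protocol=proto, duration=5000.0,
                            dt=0.005, output_dt=1.0)
        rms = np.sqrt(np.mean((a.v_m - b.v_m) ** 2))
        assert rms < 0.5

    def test_hipsc_rate_converges_with_dt(self):
        a = run_single_cell("paci_hipsc", duration=10_000.0, dt=0.02)
        b = run_single_cell("paci_hipsc", duration=10_000.0, dt=0.01)
        ra = np.diff(analysis.detect_activations(a.time, a.v_m)).mean()
        rb = np.diff(analysis.detect_activations(b.time, b.v_m)).mean()
        assert ra == pytest.approx(rb, rel=0.01)
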