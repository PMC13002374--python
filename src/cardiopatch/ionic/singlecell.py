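"""Zero-dimensional (single cell) integration and the ionic model registry."""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numba import njit

from . import courtemanche, paci
from .base import CellState, check_scalers

MODELS = {paci.MODEL_ID: paci, courtemanche.MODEL_ID: courtemanche}

#: Default reaction time steps (ms): chosen for stable, converged
#: Rush-Larsen/forward-Euler integration of each model.
DEFAULT_DT = {paci.MODEL_ID: 0.02, courtemanche.MODEL_ID: 0.01}

#: Default activation-detection refractory windows (ms).
DEFAULT_REFRACTORY = {paci.MODEL_ID: 100.0, courtemanche.MODEL_ID: 50.0}

#: Pre-run time (ms) used to settle the hiPSC limit cycle before recorded
#: experiments; the atrial model starts from its published resting state.
SETTLE_MS = {paci.MODEL_ID: 10_000.0, courtemanche.MODEL_ID: 0.0}


def get_model(model_id: str):
    try:
        return MODELS[model_id]
    except KeyError:
        raise KeyError(
            f"unknown ionic model {model_id!r}; available: {sorted(MODELS)}"
        ) from None


def default_dt(model_id: str) -> float:
    return DEFAULT_DT[get_model(model_id).MODEL_ID]


def new_state(model_id: str) -> CellState:
    m = get_model(model_id)
    return CellState(
        model_id=m.MODEL_ID,
        y=m.initial_state(),
        gate_slice=m.GATE_SLICE,
        conc_slice=m.CONC_SLICE,
    )


def ionic_rhs(state: CellState, scalers=None, i_stim: float = 0.0, params=None):
    """Time derivative of the full state and the total ionic current.

    The I_Na term of the total current is exactly ``s_na`` times the
    unscaled current, the I_NaK term exactly ``s_nak`` times; all other
    currents are untouched.  Returns ``(dy/dt, currents)`` where
    ``currents`` maps current names to values (A/F) including ``i_ion``.
    """
    state.validate()
    m = get_model(state.model_id)
    s_na = getattr(scalers, "s_na", 1.0) if scalers is not None else 1.0
    s_nak = getattr(scalers, "s_nak", 1.0) if scalers is not None else 1.0
    check_scalers(s_na, s_nak)
    return m.rhs(state.y, s_na=s_na, s_nak=s_nak, i_stim=i_stim)


@dataclass
class Trace:
    """Uniformly sampled voltage trace with the final state for restart."""

    time: np.ndarray       # ms
    v_m: np.ndarray        # mV
    final_state: np.ndarray
    clamp_count: int = 0


def _make_single_driver(step_fn):
    @njit(cache=False)
    def driver(S, s_na, s_nak, dt, n_steps, out_every, tab, rl_a, rl_b,
               pulse_start, pulse_end, pulse_amp, v_out, clamp_count):
        active = np.ones(1, dtype=np.uint8)
        istim = np.zeros(1)
        n_pulses = pulse_start.shape[0]
        n_out = 0
        for s in range(n_steps):
            t = s * dt
            if s % out_every == 0:
                v_out[n_out] = S[0, 0]
                n_out += 1
            amp = 0.0
            for p in range(n_pulses):
                if pulse_start[p] <= t < pulse_end[p]:
                    amp += pulse_amp[p]
            istim[0] = amp
            step_fn(S, istim, s_na, s_nak, active, dt, tab, rl_a, rl_b, clamp_count)
            vv = S[0, 0]
            if not (-200.0 < vv < 200.0) or vv != vv:
                return s * dt  # blow-up time
        if n_out < v_out.shape[0]:
            v_out[n_out] = S[0, 0]
        return -1.0

    return driver


@lru_cache(maxsize=None)
def _driver_for(model_id: str):
    return _make_single_driver(get_model(model_id).step_cells)


def run_single_cell(
    model_id: str,
    scalers=None,
    protocol=None,
    duration: float = 10_000.0,
    dt: float | None = None,
    y0: np.ndarray | None = None,
    output_dt: float = 1.0,
) -> Trace:
    """Integrate one cell for ``duration`` ms and return its voltage trace.

    ``protocol`` may be ``None`` (no stimulus) or a
    :class:`~cardiopatch.protocols.StimulusProtocol`; only pulse timing and
    amplitude are used (single cell has no regions).
    """
    if duration < 0 or (dt is not None and dt <= 0):
        raise ValueError("duration must be >= 0 and dt > 0")
    m = get_model(model_id)
    if dt is None:
        dt = DEFAULT_DT[m.MODEL_ID]
    y = m.initial_state() if y0 is None else np.array(y0, dtype=float)
    if y.shape != (m.N_STATES,):
        raise ValueError(f"state vector must have shape ({m.N_STATES},)")
    if duration == 0:
        return Trace(np.empty(0), np.empty(0), y, 0)

    s_na = np.array([getattr(scalers, "s_na", 1.0) if scalers else 1.0])
    s_nak = np.array([getattr(scalers, "s_nak", 1.0) if scalers else 1.0])
    check_scalers(float(s_na[0]), float(s_nak[0]))

    starts, ends, amps = [], [], []
    if protocol is not None:
        for tr in protocol.trains:
            for b in range(tr.n_beats):
                t0 = tr.onset + b * tr.cycle_length
                starts.append(t0)
                ends.append(t0 + tr.pulse_duration)
                amps.append(tr.amplitude)
    pulse_start = np.array(starts, dtype=float)
    pulse_end = np.array(ends, dtype=float)
    pulse_amp = np.array(amps, dtype=float)

    n_steps = int(round(duration / dt))
    out_every = max(1, int(round(output_dt / dt)))
    n_out = n_steps // out_every + 1
    v_out = np.empty(n_out)
    S = y.reshape(1, -1).copy()
    tab = m.build_tables(dt)
    rl_a, rl_b = m.stepper_consts(dt)
    clamp_count = np.zeros(1, dtype=np.int64)

    t_fail = _driver_for(m.MODEL_ID)(
        S, s_na, s_nak, dt, n_steps, out_every, tab, rl_a, rl_b,
        pulse_start, pulse_end, pulse_amp, v_out, clamp_count,
    )
    if t_fail >= 0:
        raise RuntimeError(
            f"integration blow-up (|V_m| > 200 mV) at t = {t_fail:.3f} ms"
        )
    time = np.arange(n_out) * (out_every * dt)
    return Trace(time, v_out, S[0].copy(), int(clamp_count[0]))


@lru_cache(maxsize=None)
def settled_state(model_id: str, dt: float | None = None) -> np.ndarray:
    """Model state after the standard settling pre-run (control scalers)."""
    ms = SETTLE_MS[get_model(model_id).MODEL_ID]
    if ms == 0:
        return get_model(model_id).initial_state()
    tr = run_single_cell(model_id, duration=ms, dt=dt)
    return tr.final_state


def diastolic_state(model_id: str, after_ms: float = 600.0, dt: float | None = None) -> np.ndarray:
    """A quiescent, excitable state shortly after a spontaneous beat.

    Used to initialize cables/tissues so that a triggered wave can be
    measured before the next spontaneous activation.  For stimulus-driven
    models this is simply the resting state.
    """
    m = get_model(model_id)
    if m.MODEL_ID == courtemanche.MODEL_ID:
        return m.initial_state()
    from .. import analysis  # local import to avoid a cycle

    tr = run_single_cell(model_id, duration=30_000.0, dt=dt, output_dt=1.0)
    acts = analysis.detect_activations(tr.time, tr.v_m, refractory=100.0)
    if len(acts) == 0:
        raise RuntimeError("model did not beat spontaneously during settling")
    target = None
    for t_a in acts[::-1]:
        if t_a + after_ms <= tr.time[-1]:
            target = t_a + after_ms
            break
    if target is None:
        target = acts[0] + after_ms
    tr2 = run_single_cell(model_id, duration=float(target), dt=dt, output_dt=1000.0)
    return tr2.final_state
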