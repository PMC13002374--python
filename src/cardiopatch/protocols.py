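"""Experiment drivers: pacing protocols and conductivity calibration.

The stress-pacing protocol reproduces the whole-atria stimulation scheme:
10 sinus beats at 85 bpm (cycle length 700 ms) followed by 5 beats at
190 bpm (cycle length 310 ms) delivered at the sinus-node site, with the
fast train starting one fast cycle after the last sinus pulse.

Conductivity calibration finds the base diffusivity that yields a target
planar conduction velocity on a 1D cable, by bisection on log-diffusivity
bracketed with the cable-theory CV ~ sqrt(D) law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import analysis, tissue
from .ionic import singlecell

__all__ = [
    "PacingTrain",
    "StimulusProtocol",
    "spontaneous_protocol",
    "stress_pacing_protocol",
    "build_cable",
    "measure_cable_cv",
    "calibrate_conductivity",
    "CV_TARGETS",
]

#: Control conduction-velocity calibration targets (cm/s).
CV_TARGETS = {"paci_hipsc": 45.0, "courtemanche": 80.0}

#: Default stimulus pulses: duration (ms) and amplitude (A/F).
STIM_PULSE = {"paci_hipsc": (2.0, 60.0), "courtemanche": (2.0, 60.0)}


@dataclass(frozen=True)
class PacingTrain:
    onset: float            # ms
    cycle_length: float     # ms
    n_beats: int
    pulse_duration: float   # ms
    amplitude: float        # A/F
    region: str = "all"

    def __post_init__(self):
        if not (self.cycle_length > self.pulse_duration > 0):
            raise ValueError("require cycle_length > pulse_duration > 0")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")

    @property
    def last_pulse_time(self) -> float:
        return self.onset + (self.n_beats - 1) * self.cycle_length


@dataclass
class StimulusProtocol:
    """Ordered pacing trains; may be empty (spontaneous activity)."""

    trains: list = field(default_factory=list)
    duration: float | None = None

    def __post_init__(self):
        pulses = []
        for tr in self.trains:
            for b in range(tr.n_beats):
                t0 = tr.onset + b * tr.cycle_length
                pulses.append((t0, t0 + tr.pulse_duration, tr.region))
        pulses.sort()
        for (a0, a1, ra), (b0, b1, rb) in zip(pulses, pulses[1:]):
            if rb == ra and b0 < a1:
                raise ValueError("overlapping stimulus pulses in one region")

    @property
    def last_pulse_time(self) -> float:
        if not self.trains:
            return 0.0
        return max(tr.last_pulse_time for tr in self.trains)

    def to_dict(self) -> dict:
        return {
            "duration": self.duration,
            "trains": [
                {
                    "onset": tr.onset, "cycle_length": tr.cycle_length,
                    "n_beats": tr.n_beats, "pulse_duration": tr.pulse_duration,
                    "amplitude": tr.amplitude, "region": tr.region,
                }
                for tr in self.trains
            ],
        }


def spontaneous_protocol(duration: float = 50_000.0) -> StimulusProtocol:
    """Stimulus-free run of the given duration (default 50 s)."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    return StimulusProtocol(trains=[], duration=duration)


def stress_pacing_protocol(
    onset: float = 10.0,
    sinus_cl: float = 700.0,
    sinus_beats: int = 10,
    fast_cl: float = 310.0,
    fast_beats: int = 5,
    pulse_duration: float | None = None,
    amplitude: float | None = None,
    region: str = "pacing_site",
    post_window: float = 2500.0,
) -> StimulusProtocol:
    """Sinus pacing (85 bpm x 10) followed by stress tachycardia (190 bpm x 5).

    The fast train starts one fast cycle after the last sinus pulse; the
    protocol duration extends ``post_window`` ms past the last pulse so
    that self-sustained activity can be assessed.
    """
    dur, amp = STIM_PULSE["courtemanche"]
    if pulse_duration is None:
        pulse_duration = dur
    if amplitude is None:
        amp_ = amp
    else:
        amp_ = amplitude
    t_fast = onset + (sinus_beats - 1) * sinus_cl + fast_cl
    trains = [
        PacingTrain(onset, sinus_cl, sinus_beats, pulse_duration, amp_, region),
        PacingTrain(t_fast, fast_cl, fast_beats, pulse_duration, amp_, region),
    ]
    last = t_fast + (fast_beats - 1) * fast_cl
    return StimulusProtocol(trains=trains, duration=last + post_window)


# ---------------------------------------------------------------------------
# Conduction-velocity measurement and calibration
# ---------------------------------------------------------------------------

def build_cable(
    model_id: str, n_elements: int = 200, dx_um: float = 250.0,
    base_diffusivity: float = 1e-3, stim_elements: int = 4,
) -> tissue.TissueGrid:
    """1D cable with an edge stimulation region (``stim_edge``)."""
    grid = tissue.build_square_tissue(
        n_elements, 1, dx_um=dx_um, base_diffusivity=base_diffusivity,
        model_id=model_id,
    )
    mask = np.zeros((1, n_elements), dtype=bool)
    mask[0, :stim_elements] = True
    grid.regions["stim_edge"] = mask
    return grid


def measure_cable_cv(
    grid: tissue.TissueGrid,
    dt_reaction: float | None = None,
    probe_fracs: tuple = (0.25, 0.75),
    window: float = 600.0,
    stim_onset: float = 5.0,
) -> float:
    """Planar CV (cm/s) of a triggered wave between two cable probes.

    The cable starts from a quiescent excitable (diastolic) state, a single
    pulse is applied at the edge and the activation-time difference between
    probes at the given fractions of cable length yields the velocity.
    Returns 0 if the wave fails to reach the distal probe (conduction
    failure or too-slow propagation).
    """
    n = grid.nx
    if dt_reaction is None:
        # fine single-cell step: the CV measurement must remain CFL-stable
        # across the whole calibration bracket of diffusivities
        dt_reaction = singlecell.DEFAULT_DT[grid.model_id]
    dur, amp = STIM_PULSE[grid.model_id]
    proto = StimulusProtocol(
        trains=[PacingTrain(stim_onset, 1e9, 1, dur, amp, "stim_edge")],
        duration=window,
    )
    i0, i1 = (int(round(f * (n - 1))) for f in probe_fracs)
    res = tissue.run_tissue(
        grid, proto,
        output_spec=tissue.OutputSpec(frame_dt=0.5, probes=[(i0, 0), (i1, 0)]),
        dt_reaction=dt_reaction,
        init="diastolic",
    )
    ev0 = res.activation.events[i0]
    ev1 = res.activation.events[i1]
    if len(ev0) == 0 or len(ev1) == 0:
        return 0.0
    if ev0[0] < stim_onset:  # spontaneous focus fired before the stimulus
        raise RuntimeError("spontaneous activation invalidated the CV measurement")
    dt_act = ev1[0] - ev0[0]
    if dt_act <= 0:
        return 0.0
    return (i1 - i0) * grid.dx / dt_act * 1000.0   # cm/ms -> cm/s


def calibrate_conductivity(
    model_id: str,
    target_cv: float | None = None,
    tolerance: float = 0.02,
    n_elements: int = 200,
    dx_um: float = 250.0,
    dt_reaction: float | None = None,
    d_init: float = 1e-3,
    max_iter: int = 60,
) -> float:
    """Base diffusivity (cm^2/ms) giving the target planar CV (cm/s).

    Bisection on log-diffusivity; the initial bracket is seeded with the
    cable-theory scaling CV proportional to sqrt(D).  Raises if the target
    velocity is not attainable on this cable.
    """
    if target_cv is None:
        target_cv = CV_TARGETS[model_id]
    if target_cv <= 0:
        raise ValueError("target_cv must be > 0")

    def cv_of(d):
        g = build_cable(model_id, n_elements=n_elements, dx_um=dx_um,
                        base_diffusivity=d)
        return measure_cable_cv(g, dt_reaction=dt_reaction)

    # physically sensible search window for the base diffusivity; beyond it
    # the discrete cable is far outside the calibratable regime
    d_min, d_max = 1e-5, 5e-2

    d = d_init
    cv = cv_of(d)
    for _ in range(8):
        if cv > 0 or d >= d_max:
            break
        d *= 4.0
        cv = cv_of(d)
    if cv <= 0:
        raise RuntimeError("cable does not conduct for any tested diffusivity")

    d_guess = d * (target_cv / cv) ** 2
    lo = min(max(d_guess / 4.0, d_min), d_max)
    hi = min(max(d_guess * 4.0, d_min), d_max)
    cv_lo, cv_hi = cv_of(lo), cv_of(hi)
    while (cv_lo <= 0 or cv_lo >= target_cv) and lo > d_min:
        lo = max(lo / 4.0, d_min)
        cv_lo = cv_of(lo)
    while cv_hi <= target_cv and hi < d_max:
        hi = min(hi * 4.0, d_max)
        cv_hi = cv_of(hi)
    if not (0 < cv_lo < target_cv < cv_hi):
        raise RuntimeError(
            f"target CV {target_cv} cm/s not bracketable; achievable range "
            f"~[{cv_lo:.3g}, {cv_hi:.3g}] cm/s on this cable"
        )
    for _ in range(max_iter):
        mid = math.sqrt(lo * hi)
        cv_mid = cv_of(mid)
        if cv_mid <= 0 or cv_mid < target_cv:
            lo = mid
        else:
            hi = mid
        if cv_mid > 0 and abs(cv_mid - target_cv) / target_cv < 0.25 * tolerance:
            return mid
    return math.sqrt(lo * hi)
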