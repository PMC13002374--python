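"""Synthetic readout fixtures with known ground truth.

Generators emulating the study's experimental readouts — beat-event time
series (contraction video / calcium-peak / multi-electrode analysis),
electrode-grid activation-time maps, stylized sharp-electrode action
potential traces, and conduction-direction vector fields — so that every
analysis statistic can be verified against the generating parameters
without running tissue simulations.

All generators are deterministic under a fixed seed and return their
ground-truth parameters alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import ActivationMap, BeatSeries, ConductionField

__all__ = [
    "GeneratorSpec",
    "gen_beat_series",
    "gen_activation_map",
    "gen_ap_trace",
    "gen_vector_field",
]


@dataclass
class GeneratorSpec:
    """Parameters for one synthetic fixture.

    ``kind``: beat_series | activation_map | ap_trace | vector_field.
    Rates are per minute, speeds cm/s, durations ms, angles radians.
    """

    kind: str
    seed: int
    n: int = 100
    mean_rate: float = 60.0        # min^-1 (beat series / activation maps)
    rate_cv: float = 0.0           # percent
    wave_speed: float = 45.0       # cm/s
    geometry: str = "planar"       # planar | focal | collision | spiral
    nx: int = 20
    ny: int = 20
    dx: float = 0.025              # cm
    n_beats: int = 5
    jitter_sd: float = 0.0         # ms, activation-time jitter
    apd: float = 300.0             # ms
    cycle_length: float = 1000.0   # ms
    alternans_ratio: float = 1.0   # long/short APD scale
    amplitude: float = 100.0       # mV
    diastolic: float = -75.0       # mV
    kappa: float = 4.0             # von Mises concentration
    mean_angle: float = 0.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.mean_rate <= 0 or self.wave_speed <= 0:
            raise ValueError("rates and speeds must be > 0")
        if self.rate_cv < 0:
            raise ValueError("rate CV must be >= 0")


def gen_beat_series(spec: GeneratorSpec) -> BeatSeries:
    """Beat-event times with gamma-distributed inter-event intervals.

    The gamma shape k = 1/CV^2 reproduces the requested coefficient of
    variation with strictly positive support (no truncation bias); CV=0
    yields an exactly periodic series.
    """
    if spec.n < 3:
        raise ValueError("need n >= 3 events")
    mean_ms = 60_000.0 / spec.mean_rate
    cv = spec.rate_cv / 100.0
    rng = np.random.default_rng(spec.seed)
    if cv == 0.0:
        ivals = np.full(spec.n - 1, mean_ms)
    else:
        shape = 1.0 / cv ** 2
        scale = mean_ms / shape
        ivals = rng.gamma(shape, scale, size=spec.n - 1)
    events = np.concatenate([[0.0], np.cumsum(ivals)]) + mean_ms
    return BeatSeries(events)


def _surface(spec: GeneratorSpec):
    """Single-beat activation-time surface (ms) for the chosen geometry."""
    ny, nx, dx = spec.ny, spec.nx, spec.dx
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    x = xx * dx
    y = yy * dx
    v = spec.wave_speed / 1000.0   # cm/ms
    if spec.geometry == "planar":
        return x / v
    if spec.geometry == "focal":
        cx, cy = (nx - 1) / 2 * dx, (ny - 1) / 2 * dx
        return np.hypot(x - cx, y - cy) / v
    if spec.geometry == "collision":
        return np.minimum(x, (nx - 1) * dx - x) / v
    if spec.geometry == "spiral":
        cx, cy = (nx - 1) / 2 * dx, (ny - 1) / 2 * dx
        theta = np.arctan2(y - cy, x - cx)
        rad = np.hypot(x - cx, y - cy)
        return (np.mod(theta, 2 * np.pi) / (2 * np.pi)) * (
            60_000.0 / spec.mean_rate
        ) + rad / (4 * v)
    raise ValueError(f"unknown activation geometry {spec.geometry!r}")


def gen_activation_map(spec: GeneratorSpec) -> ActivationMap:
    """Analytic per-beat activation surfaces plus optional Gaussian jitter.

    Jitter is clipped so per-element activation times stay strictly
    increasing across beats.
    """
    base = _surface(spec)
    cl = 60_000.0 / spec.mean_rate
    rng = np.random.default_rng(spec.seed)
    n = spec.nx * spec.ny
    events = []
    flat = base.ravel()
    for i in range(n):
        t = flat[i] + cl * (1.0 + np.arange(spec.n_beats))
        if spec.jitter_sd > 0:
            j = rng.normal(0.0, spec.jitter_sd, size=spec.n_beats)
            lim = 0.45 * cl
            t = t + np.clip(j, -lim, lim)
            t = np.maximum.accumulate(t + np.arange(spec.n_beats) * 1e-9)
            if np.any(np.diff(t) <= 0):   # enforce monotonicity after clipping
                t = np.sort(t)
        events.append(t)
    return ActivationMap(shape=(spec.ny, spec.nx), events=events)


def gen_ap_trace(spec: GeneratorSpec, dt: float = 1.0):
    """Stylized action-potential train (fast upstroke, brief plateau,
    exponential repolarization), with optional APD alternans.

    Returns ``(time, v, true_apds)``; even beats carry the short APD,
    odd beats the long one (ratio = ``alternans_ratio``).
    """
    if spec.apd >= spec.cycle_length:
        raise ValueError("APD must be shorter than the cycle length")
    if spec.alternans_ratio <= 0:
        raise ValueError("alternans ratio must be > 0")
    n_t = int(round(spec.n_beats * spec.cycle_length / dt)) + 1
    t = np.arange(n_t) * dt
    v = np.full(n_t, spec.diastolic)
    apds = []
    upstroke = 2.0      # ms
    plateau_frac = 0.35
    for b in range(spec.n_beats):
        scale = spec.alternans_ratio if (b % 2 == 1) else 1.0
        apd = spec.apd * scale
        if apd >= spec.cycle_length - upstroke:
            raise ValueError("alternans-scaled APD exceeds the cycle length")
        apds.append(apd)
        t0 = b * spec.cycle_length + 10.0
        seg = (t >= t0) & (t < t0 + apd + 5 * dt)
        ts = t[seg] - t0
        peak = spec.diastolic + spec.amplitude
        prof = np.empty_like(ts)
        for k, tau in enumerate(ts):
            if tau < upstroke:
                prof[k] = spec.diastolic + spec.amplitude * tau / upstroke
            else:
                ph = (tau - upstroke) / apd
                if ph < plateau_frac:
                    prof[k] = peak - 0.1 * spec.amplitude * ph / plateau_frac
                else:
                    # exponential decay reaching 90 % repolarization at t0+apd
                    x = (ph - plateau_frac) / (1.0 - plateau_frac)
                    v_pl = peak - 0.1 * spec.amplitude
                    v_end = spec.diastolic + 0.1 * spec.amplitude
                    k_exp = 3.0
                    w = (1.0 - np.exp(-k_exp * x)) / (1.0 - np.exp(-k_exp))
                    prof[k] = v_pl + (v_end - v_pl) * w
        v[seg] = np.maximum(v[seg], prof)
        # complete repolarization shortly after APD
        tail = (t >= t0 + apd + 5 * dt) & (t < t0 + apd + 50)
        v[tail] = np.minimum(v[tail], spec.diastolic + 0.1 * spec.amplitude *
                             np.exp(-(t[tail] - (t0 + apd)) / 10.0))
    return t, v, np.array(apds)


def gen_vector_field(spec: GeneratorSpec) -> ConductionField:
    """Unit direction vectors with von Mises-distributed angles."""
    if spec.n < 2:
        raise ValueError("need n >= 2 vectors")
    if spec.kappa < 0:
        raise ValueError("kappa must be >= 0")
    rng = np.random.default_rng(spec.seed)
    if np.isinf(spec.kappa):
        ang = np.full(spec.n, spec.mean_angle)
    else:
        ang = rng.vonmises(spec.mean_angle, spec.kappa, size=spec.n)
    ux = np.cos(ang)
    uy = np.sin(ang)
    ones = np.ones(spec.n)
    return ConductionField(
        vx=ux * spec.wave_speed, vy=uy * spec.wave_speed,
        speed=ones * spec.wave_speed, ux=ux, uy=uy,
        valid=np.ones(spec.n, dtype=bool),
    )
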