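"""Readout statistics: activation detection, beat irregularity,
conduction-velocity mapping, heterogeneity index, action-potential
morphology metrics and sustained-activity (AF-like) classification.

Beat irregularity is the coefficient of variation of the instantaneous
beat rate in percent:

    irregularity (%) = SD(rate) / mean(rate) * 100,

with rate_i = 60000 / interval_i (per minute) for consecutive event
intervals in ms.  The conduction heterogeneity index is the circular
variance of conduction-direction unit vectors, 1 - |mean resultant|,
ranging from 0 (perfectly aligned propagation) to 1 (fully disordered).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "ActivationMap",
    "BeatSeries",
    "IrregularityResult",
    "ConductionField",
    "APMetrics",
    "detect_activations",
    "detect_activations_matrix",
    "beat_irregularity",
    "tissue_irregularity",
    "conduction_field",
    "heterogeneity_index",
    "ap_metrics",
    "detect_sustained_activity",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class BeatSeries:
    """Ordered beat-event times (ms) from a single source."""

    events: np.ndarray

    def __post_init__(self):
        self.events = np.asarray(self.events, dtype=float)
        if self.events.ndim != 1:
            raise ValueError("events must be a 1-D array of times")
        if np.any(np.diff(self.events) <= 0):
            raise ValueError("event times must be strictly increasing")

    @property
    def intervals(self) -> np.ndarray:
        return np.diff(self.events)

    @property
    def rates(self) -> np.ndarray:
        """Instantaneous rates, per minute."""
        return 60_000.0 / self.intervals


@dataclass
class IrregularityResult:
    irregularity: float      # percent
    n_beats: int
    mean_rate: float         # min^-1
    sd_rate: float           # min^-1
    mode: str = "single"     # single | median | mean
    n_excluded: int = 0


@dataclass
class ActivationMap:
    """Per-element activation (and optional repolarization) times.

    ``events`` is a flat list (row-major over a ``shape = (ny, nx)`` grid)
    of strictly increasing time arrays in ms.
    """

    shape: tuple
    events: list
    repol: list | None = None

    def __post_init__(self):
        ny, nx = self.shape
        if len(self.events) != ny * nx:
            raise ValueError("events list does not match grid shape")
        for ev in self.events:
            d = np.diff(ev)
            if d.size and np.any(d <= 0):
                raise ValueError("activation times must be strictly increasing")

    def counts(self) -> np.ndarray:
        return np.array([len(e) for e in self.events]).reshape(self.shape)

    def beat_surface(self, beat: int) -> np.ndarray:
        """Activation-time surface (ms) of one beat; NaN where missing."""
        ny, nx = self.shape
        out = np.full(ny * nx, np.nan)
        for i, ev in enumerate(self.events):
            if len(ev) > beat:
                out[i] = ev[beat]
        return out.reshape(self.shape)


@dataclass
class ConductionField:
    """Per-element conduction velocity vectors for one beat."""

    vx: np.ndarray          # cm/s
    vy: np.ndarray
    speed: np.ndarray       # cm/s
    ux: np.ndarray          # unit direction
    uy: np.ndarray
    valid: np.ndarray       # bool


@dataclass
class APMetrics:
    apd90: np.ndarray        # ms, per beat
    auc90: np.ndarray        # mV*ms, per beat
    amplitude: np.ndarray    # mV
    mdp: np.ndarray          # maximum diastolic potential, mV
    dvdt_max: np.ndarray     # V/s
    apd90_variance: float    # SD/mean * 100, percent
    auc90_variance: float
    n_dropped: int = 0


# ---------------------------------------------------------------------------
# Activation detection
# ---------------------------------------------------------------------------

def _check_uniform(time: np.ndarray) -> float:
    dt = np.diff(time)
    if dt.size == 0:
        return 0.0
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("trace must be uniformly sampled")
    return float(dt[0])


def detect_activations(time, v, threshold: float = 0.0, refractory: float = 100.0):
    """Times of upward threshold crossings, linearly interpolated.

    Crossings within ``refractory`` ms of the previous accepted event are
    ignored (debounce against noise / double counting).
    """
    time = np.asarray(time, dtype=float)
    v = np.asarray(v, dtype=float)
    _check_uniform(time)
    if v.size < 2:
        return np.empty(0)
    below = v[:-1] < threshold
    above = v[1:] >= threshold
    idx = np.flatnonzero(below & above)
    if idx.size == 0:
        return np.empty(0)
    frac = (threshold - v[idx]) / (v[idx + 1] - v[idx])
    t_cross = time[idx] + frac * (time[idx + 1] - time[idx])
    out = [t_cross[0]]
    for t in t_cross[1:]:
        if t - out[-1] >= refractory:
            out.append(t)
    return np.array(out)


@njit(cache=True)
def _detect_matrix(frames, times, threshold, refractory, out_times, out_counts):
    n_t, n = frames.shape
    max_ev = out_times.shape[1]
    for i in range(n):
        cnt = 0
        last = -1e18
        for t in range(n_t - 1):
            v0 = frames[t, i]
            v1 = frames[t + 1, i]
            if v0 < threshold <= v1:
                tc = times[t] + (threshold - v0) / (v1 - v0) * (times[t + 1] - times[t])
                if tc - last >= refractory:
                    if cnt < max_ev:
                        out_times[i, cnt] = tc
                        cnt += 1
                    last = tc
        out_counts[i] = cnt


def detect_activations_matrix(
    frames: np.ndarray,
    times: np.ndarray,
    shape: tuple,
    threshold: float = 0.0,
    refractory: float = 100.0,
    max_events: int = 512,
) -> ActivationMap:
    """Vectorized activation detection over decimated tissue frames.

    ``frames``: (n_t, n_elements) voltage matrix.  Semantically identical
    to calling :func:`detect_activations` per element.
    """
    times = np.asarray(times, dtype=float)
    _check_uniform(times)
    frames = np.asarray(frames)
    n = frames.shape[1]
    out_t = np.empty((n, max_events))
    out_c = np.zeros(n, dtype=np.int64)
    _detect_matrix(
        frames.astype(np.float64), times, float(threshold), float(refractory),
        out_t, out_c,
    )
    events = [out_t[i, : out_c[i]].copy() for i in range(n)]
    return ActivationMap(shape=shape, events=events)


# ---------------------------------------------------------------------------
# Beat irregularity (coefficient of variation of rate, percent)
# ---------------------------------------------------------------------------

def beat_irregularity(series, sd_mode: str = "sample") -> IrregularityResult:
    """Irregularity (%) = SD of instantaneous beat rate / mean rate * 100."""
    if not isinstance(series, BeatSeries):
        series = BeatSeries(np.asarray(series, dtype=float))
    if series.events.size < 3:
        raise ValueError("insufficient beats: need >= 3 events (>= 2 rates)")
    rates = series.rates
    ddof = 1 if sd_mode == "sample" else 0
    # exactly periodic series must give exactly zero (not rounding noise)
    sd = 0.0 if np.ptp(rates) == 0.0 else float(np.std(rates, ddof=ddof))
    mean = float(np.mean(rates))
    return IrregularityResult(
        irregularity=sd / mean * 100.0,
        n_beats=int(series.events.size),
        mean_rate=mean,
        sd_rate=sd,
    )


def tissue_irregularity(
    amap: ActivationMap, aggregation: str = "median", sd_mode: str = "sample",
) -> IrregularityResult:
    """Per-element beat irregularity aggregated across the tissue.

    Elements with fewer than 3 activations are excluded (and counted);
    raises if every element is excluded.
    """
    values, rates_mean, rates_sd, nb = [], [], [], []
    excluded = 0
    for ev in amap.events:
        if len(ev) < 3:
            excluded += 1
            continue
        res = beat_irregularity(BeatSeries(ev), sd_mode=sd_mode)
        values.append(res.irregularity)
        rates_mean.append(res.mean_rate)
        rates_sd.append(res.sd_rate)
        nb.append(res.n_beats)
    if not values:
        raise ValueError("all elements excluded: no element has >= 3 activations")
    agg = {"median": np.median, "mean": np.mean}[aggregation]
    return IrregularityResult(
        irregularity=float(agg(values)),
        n_beats=int(np.median(nb)),
        mean_rate=float(agg(rates_mean)),
        sd_rate=float(agg(rates_sd)),
        mode=aggregation,
        n_excluded=excluded,
    )


# ---------------------------------------------------------------------------
# Conduction velocity mapping and heterogeneity index
# ---------------------------------------------------------------------------

def conduction_field(
    amap: ActivationMap, beat: int, dx: float, grad_floor: float = 1e-4,
) -> ConductionField:
    """Finite-difference conduction velocities for one beat.

    The activation-time surface T (ms) is differentiated by central
    differences; the velocity vector is grad T / |grad T|^2 (the slowness
    vector inverted), reported in cm/s; unit direction vectors are
    grad T / |grad T|.  Elements whose gradient magnitude falls below
    ``grad_floor`` (ms/cm) or that miss the beat are marked invalid.
    """
    T = amap.beat_surface(beat)
    gy, gx = np.gradient(T, dx)
    g2 = gx ** 2 + gy ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        gmag = np.sqrt(g2)
        valid = np.isfinite(gmag) & (gmag > grad_floor)
        vx = np.where(valid, gx / g2, np.nan) * 1000.0   # cm/ms -> cm/s
        vy = np.where(valid, gy / g2, np.nan) * 1000.0
        speed = np.where(valid, 1.0 / gmag, np.nan) * 1000.0
        ux = np.where(valid, gx / gmag, np.nan)
        uy = np.where(valid, gy / gmag, np.nan)
    return ConductionField(vx=vx, vy=vy, speed=speed, ux=ux, uy=uy, valid=valid)


def heterogeneity_index(field: ConductionField, mode: str = "global") -> float:
    """Circular variance of conduction directions, in [0, 1].

    ``global``: 1 - |mean of unit vectors| over all valid elements.
    ``local``: mean over elements of the circular variance within each
    element's 3x3 neighborhood.
    """
    ux, uy, valid = field.ux, field.uy, field.valid
    if valid.sum() < 2:
        raise ValueError("need >= 2 valid conduction vectors")
    if mode == "global":
        mx = np.nanmean(ux[valid])
        my = np.nanmean(uy[valid])
        return float(1.0 - np.hypot(mx, my))
    if mode != "local":
        raise ValueError("mode must be 'global' or 'local'")
    ny, nx = valid.shape
    vals = []
    for j in range(ny):
        for i in range(nx):
            if not valid[j, i]:
                continue
            sl = (slice(max(j - 1, 0), j + 2), slice(max(i - 1, 0), i + 2))
            m = valid[sl]
            if m.sum() < 2:
                continue
            mx = ux[sl][m].mean()
            my = uy[sl][m].mean()
            vals.append(1.0 - np.hypot(mx, my))
    if not vals:
        raise ValueError("no element has >= 2 valid neighbors")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Action potential morphology
# ---------------------------------------------------------------------------

def ap_metrics(time, v, events=None, repol_fraction: float = 0.9) -> APMetrics:
    """Per-beat AP metrics from a voltage trace.

    For each beat: amplitude = peak - preceding diastolic minimum; APD90 =
    time from activation (maximum dV/dt during the upstroke) to 90 %
    repolarization of the amplitude; AUC90 = integral of (V - V_90) over
    the APD90 window.  The across-beat variance statistic is SD/mean * 100.
    A final AP that never repolarizes is dropped with a warning.
    """
    time = np.asarray(time, dtype=float)
    v = np.asarray(v, dtype=float)
    dt = _check_uniform(time)
    if events is None:
        events = detect_activations(time, v)
    events = np.asarray(events, dtype=float)
    if events.size < 2:
        raise ValueError("need >= 2 complete action potentials")

    apd90, auc90, amp, mdp, dvdt = [], [], [], [], []
    dropped = 0
    bounds = np.concatenate([[time[0]], events, [time[-1]]])
    for b in range(events.size):
        t_act = events[b]
        lo = np.searchsorted(time, bounds[b])         # previous event (diastole search)
        i_act = np.searchsorted(time, t_act)
        hi = np.searchsorted(time, bounds[b + 2])     # next event / end
        if hi - i_act < 3 or i_act - lo < 1:
            dropped += 1
            continue
        i_dia = lo + int(np.argmin(v[lo:i_act + 1]))
        dia = float(v[i_dia])
        # analyze from the diastolic minimum so the full upstroke is inside
        seg_t = time[i_dia:hi]
        seg_v = v[i_dia:hi]
        peak = float(np.max(seg_v))
        amplitude = peak - dia
        if amplitude <= 0:
            dropped += 1
            continue
        v90 = peak - repol_fraction * amplitude
        # activation = max dV/dt during the upstroke (up to the peak)
        i_peak = int(np.argmax(seg_v))
        dv = np.diff(seg_v[: i_peak + 1])
        i_up = int(np.argmax(dv)) if dv.size else 0
        t_up = seg_t[i_up]
        below = np.flatnonzero(seg_v[i_peak:] <= v90)
        if below.size == 0:
            dropped += 1
            warnings.warn("final action potential did not repolarize; dropped")
            continue
        k = i_peak + below[0]
        # linear interpolation of the crossing
        if k > 0 and seg_v[k - 1] > v90:
            frac = (seg_v[k - 1] - v90) / (seg_v[k - 1] - seg_v[k])
            t_rep = seg_t[k - 1] + frac * dt
        else:
            t_rep = seg_t[k]
        sel = (seg_t >= t_up) & (seg_t <= t_rep)
        a = float(np.trapezoid(np.clip(seg_v[sel] - v90, 0.0, None), seg_t[sel]))
        apd90.append(t_rep - t_up)
        auc90.append(a)
        amp.append(amplitude)
        mdp.append(dia)
        dvdt.append(float(np.max(dv)) / dt if dv.size else np.nan)  # mV/ms == V/s

    if len(apd90) < 1:
        raise ValueError("no complete action potential could be measured")

    def _cv(x):
        x = np.asarray(x)
        if x.size < 2:
            return 0.0
        return float(np.std(x, ddof=1) / np.mean(x) * 100.0)

    return APMetrics(
        apd90=np.array(apd90),
        auc90=np.array(auc90),
        amplitude=np.array(amp),
        mdp=np.array(mdp),
        dvdt_max=np.array(dvdt),
        apd90_variance=_cv(apd90),
        auc90_variance=_cv(auc90),
        n_dropped=dropped,
    )


# ---------------------------------------------------------------------------
# Sustained (AF-like) activity after pacing
# ---------------------------------------------------------------------------

def detect_sustained_activity(
    amap: ActivationMap,
    last_stimulus: float,
    window: float = 2000.0,
    blanking: float = 50.0,
    element_fraction: float = 0.25,
    min_activations: int = 2,
    sim_end: float | None = None,
):
    """Classify post-pacing activity as sustained (AF-like) or not.

    Sustained iff at least ``element_fraction`` of elements register
    ``min_activations`` or more activations after ``last_stimulus`` plus a
    blanking period.  Returns ``(sustained, extra_count_per_element)``.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    t0 = last_stimulus + blanking
    t1 = t0 + window
    if sim_end is not None and sim_end < t1:
        raise ValueError(
            f"simulation ends at {sim_end} ms, before the {t1} ms analysis window"
        )
    counts = np.array(
        [int(np.sum((ev > t0) & (ev <= t1))) for ev in amap.events]
    ).reshape(amap.shape)
    frac = float(np.mean(counts >= min_activations))
    return frac >= element_fraction, counts
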