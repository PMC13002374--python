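"""Monodomain reaction-diffusion solver on a 2D structured mesh.

The transmembrane voltage obeys  dV/dt = -I_ion(y)/Cm + div(D grad V)
with a per-element scalar diffusivity D (cm^2/ms) proportional to local
tissue conductivity.  Space is discretized on a regular square grid
(5-point Laplacian, harmonic-mean interface diffusivity, no-flux
boundaries); time integration uses Godunov operator splitting: ``nsub``
Rush-Larsen/forward-Euler reaction substeps of ``dt_reaction`` followed by
one explicit diffusion step of ``dt_diffusion = nsub * dt_reaction``.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from numba import njit

from . import analysis
from .ionic import singlecell
from .ionic.base import check_scalers

__all__ = [
    "TissueGrid",
    "PseudoAtriaConfig",
    "OutputSpec",
    "SimulationResult",
    "build_square_tissue",
    "build_pseudo_atria",
    "step_monodomain",
    "run_tissue",
]

#: Default cap on the diffusion macro time step (ms).
DT_DIFFUSION_MAX = 0.1

#: Reaction time steps used for tissue runs (ms).  Larger than the
#: single-cell defaults; chosen by convergence measurement (spontaneous
#: rate and APD90 change by <0.5 % versus the single-cell defaults, see
#: docs/methods.md).
TISSUE_DT = {"paci_hipsc": 0.1, "courtemanche": 0.02}


@dataclass
class TissueGrid:
    """2D structured mesh with per-element conductivity and cell scalers."""

    nx: int
    ny: int
    dx: float                      # cm
    base_diffusivity: float        # cm^2/ms
    model_id: str = "paci_hipsc"
    active: np.ndarray = None      # (ny, nx) uint8
    s_na: np.ndarray = None
    s_nak: np.ndarray = None
    s_cond: np.ndarray = None
    regions: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.nx < 1 or self.ny < 1 or self.dx <= 0 or self.base_diffusivity < 0:
            raise ValueError("grid dimensions and dx must be positive")
        shape = (self.ny, self.nx)
        if self.active is None:
            self.active = np.ones(shape, dtype=np.uint8)
        for name in ("s_na", "s_nak", "s_cond"):
            if getattr(self, name) is None:
                setattr(self, name, np.ones(shape))
        for arr in (self.active, self.s_na, self.s_nak, self.s_cond):
            if arr.shape != shape:
                raise ValueError("per-element maps must match (ny, nx)")

    @property
    def shape(self):
        return (self.ny, self.nx)

    @property
    def n_elements(self) -> int:
        return self.nx * self.ny

    @property
    def area_cm2(self) -> float:
        """Total active tissue area in cm^2."""
        return float(self.active.sum()) * self.dx ** 2

    @property
    def diffusivity(self) -> np.ndarray:
        """Per-element diffusivity (cm^2/ms), zero on inactive elements."""
        return self.base_diffusivity * self.s_cond * self.active

    def region_mask(self, name: str) -> np.ndarray:
        if name == "all":
            return self.active.astype(bool)
        try:
            return self.regions[name]
        except KeyError:
            raise KeyError(
                f"unknown region {name!r}; available: {sorted(self.regions)}"
            ) from None

    def config_dict(self) -> dict:
        return {
            "nx": self.nx, "ny": self.ny, "dx_cm": self.dx,
            "base_diffusivity": self.base_diffusivity, "model_id": self.model_id,
            "s_na_hash": _arr_hash(self.s_na), "s_nak_hash": _arr_hash(self.s_nak),
            "s_cond_hash": _arr_hash(self.s_cond), "active_hash": _arr_hash(self.active),
        }


def _arr_hash(a) -> str:
    return hashlib.sha1(np.ascontiguousarray(a).tobytes()).hexdigest()[:12]


def build_square_tissue(
    nx: int, ny: int, dx_um: float = 250.0,
    base_diffusivity: float = 1e-3, model_id: str = "paci_hipsc",
) -> TissueGrid:
    """Uniform control square tissue; ``dx`` given in micrometres."""
    if nx <= 0 or ny <= 0 or dx_um <= 0:
        raise ValueError("nx, ny and dx must be positive")
    return TissueGrid(nx=nx, ny=ny, dx=dx_um * 1e-4, base_diffusivity=base_diffusivity,
                      model_id=model_id)


@dataclass
class PseudoAtriaConfig:
    """Idealized two-chamber atrial sheet (reduction of whole-organ atria).

    Two rectangular chambers (right atrium on the left, left atrium on the
    right) separated by an inexcitable septal wall, connected by a
    conducting bridge (Bachmann-bundle analog).  A venous sub-zone spans
    the superior band of each chamber; the sinus-node pacing site sits at
    the superior border of the right atrium.
    """

    nx: int = 100
    ny: int = 50
    dx_um: float = 250.0
    base_diffusivity: float = 3e-3     # calibrated to the atrial CV target
    wall_thickness: int = 2
    # bridge sized like Bachmann's bundle (~0.4-1 cm wide): a too-narrow
    # isthmus depresses AP peaks at its exit below the 0 mV registration
    # threshold through source-sink expansion load
    bridge_fraction: float = 0.4       # of ny
    venous_fraction: float = 0.3       # of chamber rows
    pacing_size: int = 5               # elements per side
    model_id: str = "courtemanche"


def build_pseudo_atria(config: PseudoAtriaConfig | None = None) -> TissueGrid:
    cfg = config or PseudoAtriaConfig()
    nx, ny = cfg.nx, cfg.ny
    if nx < 10 or ny < 10:
        raise ValueError("pseudo-atria grid must be at least 10x10")
    bridge_rows = int(round(cfg.bridge_fraction * ny))
    if bridge_rows < 1:
        raise ValueError("zero-width bridge: chambers would be disconnected")

    active = np.ones((ny, nx), dtype=np.uint8)
    w0 = nx // 2 - cfg.wall_thickness // 2
    w1 = w0 + cfg.wall_thickness
    active[:, w0:w1] = 0
    b0 = (ny - bridge_rows) // 2
    active[b0:b0 + bridge_rows, w0:w1] = 1

    yy, xx = np.mgrid[0:ny, 0:nx]
    ra = (xx < w0) & active.astype(bool)
    la = (xx >= w1) & active.astype(bool)
    bridge = (xx >= w0) & (xx < w1) & active.astype(bool)
    ven_rows = int(round(cfg.venous_fraction * ny))
    venous_ra = ra & (yy < ven_rows)
    venous_la = la & (yy < ven_rows)
    pacing = np.zeros((ny, nx), dtype=bool)
    pacing[:cfg.pacing_size, :cfg.pacing_size] = True
    pacing &= ra

    from scipy import ndimage

    labels, n_comp = ndimage.label(active)
    if n_comp != 1:
        raise ValueError("disconnected chambers: active tissue is not contiguous")

    grid = TissueGrid(
        nx=nx, ny=ny, dx=cfg.dx_um * 1e-4, base_diffusivity=cfg.base_diffusivity,
        model_id=cfg.model_id, active=active,
    )
    grid.regions = {
        "RA": ra, "LA": la, "bridge": bridge,
        "venous_ra": venous_ra, "venous_la": venous_la,
        "pacing_site": pacing,
    }
    if not all(m.any() for m in grid.regions.values()):
        raise ValueError("pseudo-atria construction produced an empty region")
    return grid


# ---------------------------------------------------------------------------
# Diffusion
# ---------------------------------------------------------------------------

def interface_conductances(grid: TissueGrid):
    """Harmonic-mean interface diffusivities along x and y (no-flux edges)."""
    D = grid.diffusivity
    Dx0, Dx1 = D[:, :-1], D[:, 1:]
    Dy0, Dy1 = D[:-1, :], D[1:, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        wx = np.where(Dx0 + Dx1 > 0, 2.0 * Dx0 * Dx1 / np.where(Dx0 + Dx1 > 0, Dx0 + Dx1, 1.0), 0.0)
        wy = np.where(Dy0 + Dy1 > 0, 2.0 * Dy0 * Dy1 / np.where(Dy0 + Dy1 > 0, Dy0 + Dy1, 1.0), 0.0)
    return np.ascontiguousarray(wx), np.ascontiguousarray(wy)


@njit(cache=True)
def _diffusion_step(S, active, wx, wy, dtdx2, ny, nx, vbuf):
    for j in range(ny):
        for i in range(nx):
            idx = j * nx + i
            if not active[idx]:
                vbuf[idx] = S[idx, 0]
                continue
            v = S[idx, 0]
            acc = 0.0
            if i > 0:
                acc += wx[j, i - 1] * (S[idx - 1, 0] - v)
            if i < nx - 1:
                acc += wx[j, i] * (S[idx + 1, 0] - v)
            if j > 0:
                acc += wy[j - 1, i] * (S[idx - nx, 0] - v)
            if j < ny - 1:
                acc += wy[j, i] * (S[idx + nx, 0] - v)
            vbuf[idx] = v + dtdx2 * acc
    for idx in range(ny * nx):
        S[idx, 0] = vbuf[idx]


def cfl_limit(grid: TissueGrid) -> float:
    """Maximal admissible explicit diffusion step (ms)."""
    dmax = float(grid.diffusivity.max())
    if dmax == 0:
        return np.inf
    return grid.dx ** 2 / (4.0 * dmax)


def step_monodomain(grid, S, dt_reaction, dt_diffusion, istim=None):
    """One operator-splitting macro step (reaction substeps + diffusion).

    ``S`` is the (n_elements, n_states) state matrix, modified in place.
    ``dt_diffusion`` must be an integer multiple of ``dt_reaction`` and
    satisfy the CFL bound dx^2/(4 max D).
    """
    nsub = dt_diffusion / dt_reaction
    if abs(nsub - round(nsub)) > 1e-9 or round(nsub) < 1:
        raise ValueError("dt_diffusion must be a positive integer multiple of dt_reaction")
    nsub = int(round(nsub))
    limit = cfl_limit(grid)
    if dt_diffusion > limit * (1 + 1e-12):
        raise ValueError(
            f"CFL violation: dt_diffusion={dt_diffusion} ms exceeds the maximal "
            f"admissible step {limit:.6g} ms for this grid"
        )
    m = singlecell.get_model(grid.model_id)
    tab = m.build_tables(dt_reaction)
    ra, rb = m.stepper_consts(dt_reaction)
    active = np.ascontiguousarray(grid.active.ravel())
    sna = np.ascontiguousarray(grid.s_na.ravel())
    snak = np.ascontiguousarray(grid.s_nak.ravel())
    if istim is None:
        istim = np.zeros(grid.n_elements)
    clamp = np.zeros(1, dtype=np.int64)
    for _ in range(nsub):
        m.step_cells(S, istim, sna, snak, active, dt_reaction, tab, ra, rb, clamp)
    wx, wy = interface_conductances(grid)
    vbuf = np.empty(grid.n_elements)
    _diffusion_step(S, active, wx, wy, dt_diffusion / grid.dx ** 2,
                    grid.ny, grid.nx, vbuf)
    return S


# ---------------------------------------------------------------------------
# Full tissue runs
# ---------------------------------------------------------------------------

@dataclass
class OutputSpec:
    frame_dt: float = 1.0          # ms between stored voltage frames
    probes: list = field(default_factory=list)   # [(x, y), ...] element coords
    store_frames: bool = True
    threshold: float = 0.0         # mV, activation detection
    refractory: float | None = None


@dataclass
class SimulationResult:
    grid_shape: tuple
    frame_times: np.ndarray
    frames: np.ndarray | None
    probe_times: np.ndarray
    probe_traces: np.ndarray | None
    activation: analysis.ActivationMap
    metadata: dict
    final_states: np.ndarray | None = None
    failed: bool = False
    fail_time: float = -1.0


def _make_tissue_driver(step_fn):
    @njit(cache=False)
    def drv(S, sna, snak, active, wx, wy, dtdx2, dt_r, nsub, ndiff, n_macro,
            tab, ra, rb, pulse_start, pulse_end, pulse_amp, pulse_mask_row,
            masks, frame_every, frames, probe_idx, probe_out, clamp, ny, nx):
        n = ny * nx
        istim = np.zeros(n)
        vbuf = np.empty(n)
        stim_on = False
        fcount = 0
        pcount = 0
        n_pulses = pulse_start.shape[0]
        n_probes = probe_idx.shape[0]
        dt_macro = dt_r * nsub
        for ms_i in range(n_macro):
            t = ms_i * dt_macro
            if frames.shape[0] > 0 and ms_i % frame_every == 0 and fcount < frames.shape[0]:
                for i in range(n):
                    frames[fcount, i] = S[i, 0]
                fcount += 1
            if n_probes > 0 and pcount < probe_out.shape[0]:
                for pi in range(n_probes):
                    probe_out[pcount, pi] = S[probe_idx[pi], 0]
                pcount += 1
            any_p = False
            for p in range(n_pulses):
                if pulse_start[p] <= t < pulse_end[p]:
                    any_p = True
            if any_p:
                for i in range(n):
                    istim[i] = 0.0
                for p in range(n_pulses):
                    if pulse_start[p] <= t < pulse_end[p]:
                        mr = pulse_mask_row[p]
                        for i in range(n):
                            if masks[mr, i]:
                                istim[i] += pulse_amp[p]
                stim_on = True
            elif stim_on:
                for i in range(n):
                    istim[i] = 0.0
                stim_on = False
            for _ in range(nsub):
                step_fn(S, istim, sna, snak, active, dt_r, tab, ra, rb, clamp)
            for _ in range(ndiff):
                _diffusion_step(S, active, wx, wy, dtdx2, ny, nx, vbuf)
            if ms_i % 50 == 0:
                for i in range(n):
                    vv = S[i, 0]
                    if not (-200.0 < vv < 200.0) or vv != vv:
                        return t
        return -1.0

    return drv


@lru_cache(maxsize=None)
def _tissue_driver(model_id: str):
    return _make_tissue_driver(singlecell.get_model(model_id).step_cells)


def initial_tissue_state(grid: TissueGrid, mode: str = "settled") -> np.ndarray:
    """Per-element initial state matrix.

    ``settled``: the model's standard pre-run state (hiPSC limit cycle
    settled for 10 s; atrial published resting state).  ``diastolic``: a
    quiescent excitable state shortly after a beat (for triggered-wave
    measurements on spontaneous models).
    """
    if mode == "settled":
        y = singlecell.settled_state(grid.model_id)
    elif mode == "diastolic":
        y = singlecell.diastolic_state(grid.model_id)
    else:
        raise ValueError("mode must be 'settled' or 'diastolic'")
    return np.tile(y, (grid.n_elements, 1))


def run_tissue(
    grid: TissueGrid,
    protocol=None,
    duration: float | None = None,
    output_spec: OutputSpec | None = None,
    seed: int | None = None,
    dt_reaction: float | None = None,
    init: np.ndarray | str = "settled",
    keep_final_states: bool = False,
) -> SimulationResult:
    """Run the monodomain simulation and collect activation readouts.

    Deterministic given (grid, protocol, dt, init); ``seed`` is recorded in
    the metadata for provenance only.  An activation is registered for
    every element at each upward 0 mV crossing of its voltage trace
    (detected on the decimated frames, linearly interpolated).
    """
    spec = output_spec or OutputSpec()
    if duration is None:
        if protocol is None or getattr(protocol, "duration", None) is None:
            raise ValueError("duration must be given (directly or via protocol)")
        duration = protocol.duration
    if duration < 0:
        raise ValueError("duration must be >= 0")
    check_scalers(float(grid.s_na.min()), float(grid.s_nak.min()))
    m = singlecell.get_model(grid.model_id)
    if dt_reaction is None:
        dt_reaction = TISSUE_DT[m.MODEL_ID]
    limit = cfl_limit(grid)
    if dt_reaction <= 0.999 * limit:
        nsub = max(1, int(min(DT_DIFFUSION_MAX, 0.999 * limit) / dt_reaction))
        ndiff = 1
    else:
        # diffusion stability is tighter than the reaction step: keep the
        # reaction step and sub-cycle the (cheap) explicit diffusion update
        nsub = 1
        ndiff = math.ceil(dt_reaction / (0.999 * limit))
    dt_macro = nsub * dt_reaction

    if isinstance(init, str):
        S = initial_tissue_state(grid, init)
    else:
        S = np.array(init, dtype=float)
        if S.ndim == 1:
            S = np.tile(S, (grid.n_elements, 1))
    if S.shape != (grid.n_elements, m.N_STATES):
        raise ValueError("initial state shape mismatch")

    n_macro = int(round(duration / dt_macro))
    frame_every = max(1, int(round(spec.frame_dt / dt_macro)))
    n_frames = (n_macro + frame_every - 1) // frame_every if (spec.store_frames and n_macro > 0) else 0
    frames = np.empty((n_frames, grid.n_elements), dtype=np.float64)

    probe_idx = np.array(
        [int(y) * grid.nx + int(x) for (x, y) in spec.probes], dtype=np.int64
    )
    probe_out = np.empty((n_macro if probe_idx.size else 0, probe_idx.size))

    starts, ends, amps, mask_rows = [], [], [], []
    mask_list = []
    mask_index = {}
    if protocol is not None:
        for tr in protocol.trains:
            name = tr.region
            if name not in mask_index:
                mask_index[name] = len(mask_list)
                mask_list.append(
                    np.ascontiguousarray(
                        grid.region_mask(name).ravel().astype(np.uint8)
                    )
                )
            for b in range(tr.n_beats):
                t0 = tr.onset + b * tr.cycle_length
                starts.append(t0)
                ends.append(t0 + tr.pulse_duration)
                amps.append(tr.amplitude)
                mask_rows.append(mask_index[name])
    masks = (np.stack(mask_list) if mask_list
             else np.zeros((1, grid.n_elements), dtype=np.uint8))

    wx, wy = interface_conductances(grid)
    tab = m.build_tables(dt_reaction)
    ra, rb = m.stepper_consts(dt_reaction)
    clamp = np.zeros(1, dtype=np.int64)
    sna = np.ascontiguousarray(grid.s_na.ravel())
    snak = np.ascontiguousarray(grid.s_nak.ravel())
    active = np.ascontiguousarray(grid.active.ravel())

    fail_t = -1.0
    if n_macro > 0:
        fail_t = _tissue_driver(m.MODEL_ID)(
            S, sna, snak, active, wx, wy, dt_macro / ndiff / grid.dx ** 2,
            dt_reaction, nsub, ndiff, n_macro, tab, ra, rb,
            np.array(starts), np.array(ends), np.array(amps),
            np.array(mask_rows, dtype=np.int64), masks,
            frame_every, frames, probe_idx, probe_out, clamp, grid.ny, grid.nx,
        )

    frame_times = np.arange(n_frames) * frame_every * dt_macro
    refractory = (spec.refractory if spec.refractory is not None
                  else singlecell.DEFAULT_REFRACTORY[m.MODEL_ID])
    if n_frames >= 2:
        amap = analysis.detect_activations_matrix(
            frames, frame_times, grid.shape,
            threshold=spec.threshold, refractory=refractory,
        )
        inact = np.flatnonzero(~active.astype(bool))
        for i in inact:
            amap.events[i] = np.empty(0)
    else:
        amap = analysis.ActivationMap(
            shape=grid.shape, events=[np.empty(0)] * grid.n_elements
        )

    meta = {
        "model_id": m.MODEL_ID,
        "dt_reaction": dt_reaction,
        "dt_diffusion": dt_macro,
        "duration": duration,
        "seed": seed,
        "clamped_gate_updates": int(clamp[0]),
        "grid": grid.config_dict(),
        "protocol": None if protocol is None else protocol.to_dict(),
    }
    meta["config_hash"] = hashlib.sha1(
        json.dumps(meta, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]

    return SimulationResult(
        grid_shape=grid.shape,
        frame_times=frame_times,
        frames=frames if spec.store_frames else None,
        probe_times=np.arange(probe_out.shape[0]) * dt_macro,
        probe_traces=probe_out if probe_idx.size else None,
        activation=amap,
        metadata=meta,
        final_states=S if keep_final_states else None,
        failed=fail_t >= 0,
        fail_time=fail_t,
    )
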