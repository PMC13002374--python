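"""Shared infrastructure for single-cell ionic models.

Every model in this package exposes the same surface:

* a state vector (membrane voltage first, then gates, then concentrations),
* a plain-NumPy right-hand side (``rhs``) used as the reference
  implementation for API calls and fine-step oracle integrations,
* a voltage-tabulated Rush-Larsen stepper (numba) used by the tissue solver.

Voltage is in mV, time in ms, currents in A/F (numerically equal to mV/ms),
concentrations in mM.  Multiplicative scaling of the fast sodium current
(I_Na) and the Na+/K+ pump (I_NaK) models inflammatory downregulation of
SCN5A and ATP1A1 activity respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Voltage grid used for rate tabulation (mV).
TABLE_VMIN = -120.0
TABLE_VMAX = 80.0
TABLE_DV = 0.02

#: Hard sanity bounds on membrane voltage during a valid simulation (mV).
VM_MIN, VM_MAX = -120.0, 80.0


@dataclass(frozen=True)
class CurrentScalers:
    """Multiplicative scalers on remodeled currents (1.0 = control)."""

    s_na: float = 1.0
    s_nak: float = 1.0

    def __post_init__(self):
        for name, val in (("s_na", self.s_na), ("s_nak", self.s_nak)):
            if not (0.0 <= val <= 2.0):
                raise ValueError(f"{name}={val} outside the admissible range [0, 2]")


@dataclass
class CellState:
    """Full ionic state of one cell.

    ``y`` is the raw state vector in model order; convenience views expose
    membrane voltage, gating variables and concentrations.
    """

    model_id: str
    y: np.ndarray
    gate_slice: slice
    conc_slice: slice

    @property
    def v_m(self) -> float:
        return float(self.y[0])

    @property
    def gates(self) -> np.ndarray:
        return self.y[self.gate_slice]

    @property
    def concentrations(self) -> np.ndarray:
        return self.y[self.conc_slice]

    def validate(self) -> None:
        if not np.all(np.isfinite(self.y)):
            bad = int(np.flatnonzero(~np.isfinite(self.y))[0])
            raise ValueError(f"non-finite state variable at index {bad} ({self.model_id})")
        if not (VM_MIN <= self.v_m <= VM_MAX):
            raise ValueError(f"membrane voltage {self.v_m:.1f} mV outside [{VM_MIN}, {VM_MAX}]")


@dataclass
class CellParams:
    """Adjustable model parameters (maximal conductances etc.).

    Values default to the published parameter set of the model; overriding a
    key rescales that maximum.  All maxima must be non-negative.
    """

    model_id: str
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        for key, val in self.overrides.items():
            if val < 0:
                raise ValueError(f"parameter {key} must be >= 0, got {val}")


def table_grid() -> np.ndarray:
    """Voltage grid shared by all tabulated models."""
    n = int(round((TABLE_VMAX - TABLE_VMIN) / TABLE_DV)) + 1
    return np.linspace(TABLE_VMIN, TABLE_VMAX, n)


def check_scalers(s_na: float, s_nak: float) -> None:
    CurrentScalers(s_na=s_na, s_nak=s_nak)  # raises on violation
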