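"""Spatially heterogeneous inflammatory remodeling.

Inflammatory infiltration is modeled as circular patches within which the
fast sodium current (I_Na), the Na+/K+ pump (I_NaK) and/or tissue
conductivity are multiplicatively downregulated, while tissue outside the
patches keeps control properties.  Patches are placed by seeded rejection
sampling (non-overlapping, clipped at the region boundary) until a target
coverage fraction is reached.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .tissue import TissueGrid

__all__ = [
    "PatchSpec",
    "RemodelingMap",
    "Scenario",
    "place_circular_patches",
    "enumerate_hipsc_scenarios",
    "enumerate_atria_configs",
    "apply_remodeling",
    "scenario_remodeling",
]

AXES = ("i_na", "i_nak", "conductivity")

MAX_PLACEMENT_ATTEMPTS = 10_000
COVERAGE_TOL = 0.02      # +/- 2 percentage points around the target


@dataclass(frozen=True)
class PatchSpec:
    """One circular remodeling patch."""

    center: tuple          # (ix, iy) element coordinates
    radius: float          # cm
    s_na: float = 1.0
    s_nak: float = 1.0
    s_cond: float = 1.0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("patch radius must be > 0")
        for name in ("s_na", "s_nak", "s_cond"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name}={v} outside (0, 1]")


@dataclass
class RemodelingMap:
    """Per-element multiplicative scalers produced by a set of patches."""

    s_na: np.ndarray
    s_nak: np.ndarray
    s_cond: np.ndarray
    patches: list
    coverage: float          # achieved fraction of the target region
    remodeled: np.ndarray    # bool mask of remodeled elements

    @property
    def shape(self):
        return self.s_na.shape

    def to_dataframe(self):
        import pandas as pd

        ny, nx = self.shape
        yy, xx = np.mgrid[0:ny, 0:nx]
        return pd.DataFrame({
            "x": xx.ravel(), "y": yy.ravel(),
            "s_na": self.s_na.ravel(), "s_nak": self.s_nak.ravel(),
            "s_cond": self.s_cond.ravel(),
        })


@dataclass(frozen=True)
class Scenario:
    """One electrophysiological remodeling scenario."""

    name: str
    axes: tuple              # subset of AXES
    intensity: float         # fraction reduced (0.25 or 0.50)
    patch_radius: float      # cm
    geometry: str = "square" # square | atria tag "RA:spread,LA:control" etc.

    def __post_init__(self):
        if self.name != "control" and not self.axes:
            raise ValueError("non-control scenario must downregulate >= 1 axis")
        for a in self.axes:
            if a not in AXES:
                raise ValueError(f"unknown remodeling axis {a!r}")
        if not (0.0 <= self.intensity < 1.0):
            raise ValueError("intensity must be in [0, 1)")

    @property
    def scalers(self) -> dict:
        s = 1.0 - self.intensity
        return {
            "s_na": s if "i_na" in self.axes else 1.0,
            "s_nak": s if "i_nak" in self.axes else 1.0,
            "s_cond": s if "conductivity" in self.axes else 1.0,
        }

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "Scenario":
        d = json.loads(s)
        d["axes"] = tuple(d["axes"])
        return cls(**d)


def place_circular_patches(
    grid: TissueGrid,
    radius: float,
    target_fraction: float,
    seed: int,
    region_mask: np.ndarray | None = None,
    scalers: dict | None = None,
    max_attempts: int = MAX_PLACEMENT_ATTEMPTS,
) -> RemodelingMap:
    """Place non-overlapping circular patches covering ``target_fraction``
    of ``region_mask`` (default: all active tissue), within +/- 2 points.

    Candidate centers are drawn uniformly over the region; a candidate is
    rejected if its circle overlaps an accepted circle or would overshoot
    the coverage band.  Circles are clipped at the region boundary and the
    clipped area counts toward coverage.  Deterministic given ``seed``.
    """
    if not (0.0 < target_fraction <= 1.0):
        raise ValueError("target_fraction must be in (0, 1]")
    if radius < grid.dx:
        raise ValueError("patch radius must be at least one element edge")
    sc = {"s_na": 1.0, "s_nak": 1.0, "s_cond": 1.0, **(scalers or {})}

    ny, nx = grid.shape
    mask = grid.active.astype(bool) if region_mask is None else (
        np.asarray(region_mask, dtype=bool) & grid.active.astype(bool)
    )
    n_region = int(mask.sum())
    if n_region == 0:
        raise ValueError("empty region mask")

    s_na = np.ones((ny, nx))
    s_nak = np.ones((ny, nx))
    s_cond = np.ones((ny, nx))
    remodeled = np.zeros((ny, nx), dtype=bool)

    if target_fraction >= 1.0 - 1e-12:
        for arr, key in ((s_na, "s_na"), (s_nak, "s_nak"), (s_cond, "s_cond")):
            arr[mask] = sc[key]
        remodeled[:] = mask
        return RemodelingMap(s_na, s_nak, s_cond, [], 1.0, remodeled)

    cand_idx = np.flatnonzero(mask.ravel())
    yy, xx = np.mgrid[0:ny, 0:nx]
    r_el = radius / grid.dx
    lo_band = target_fraction - COVERAGE_TOL
    hi_band = target_fraction + COVERAGE_TOL

    # Rejection sampling can jam (no admissible candidate left without
    # overshooting the band); restart with a derived sub-seed when stuck.
    n_restarts = 8
    per_restart = max(1, max_attempts // n_restarts)
    best = 0.0
    patches: list[PatchSpec] = []
    coverage = 0.0
    for restart in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, restart]))
        patches = []
        remodeled[:] = False
        coverage = 0.0
        attempts = 0
        while coverage < lo_band and attempts < per_restart:
            attempts += 1
            k = int(rng.integers(0, cand_idx.size))
            cy, cx = divmod(int(cand_idx[k]), nx)
            ok = True
            for p in patches:
                px, py = p.center
                if np.hypot(cx - px, cy - py) * grid.dx < radius + p.radius:
                    ok = False
                    break
            if not ok:
                continue
            inside = ((xx - cx) ** 2 + (yy - cy) ** 2 <= r_el ** 2) & mask
            new_cov = (remodeled | inside).sum() / n_region
            if new_cov > hi_band:
                continue
            patches.append(PatchSpec(center=(cx, cy), radius=radius, **sc))
            remodeled |= inside
            coverage = new_cov
        best = max(best, coverage)
        if coverage >= lo_band:
            break
    else:
        raise RuntimeError(
            f"could not reach coverage {target_fraction:.2f} +/- "
            f"{COVERAGE_TOL:.2f} within {max_attempts} attempts; best "
            f"achieved {best:.3f}"
        )

    for arr, key in ((s_na, "s_na"), (s_nak, "s_nak"), (s_cond, "s_cond")):
        arr[remodeled] = sc[key]
    return RemodelingMap(s_na, s_nak, s_cond, patches, float(coverage), remodeled)


def enumerate_hipsc_scenarios(
    intensities: tuple = (0.25, 0.50), patch_radius: float = 0.5,
) -> list:
    """Control plus six electrophysiological variations (three single-axis,
    three paired downregulations) per intensity."""
    singles = [("i_na",), ("i_nak",), ("conductivity",)]
    pairs = [("i_na", "i_nak"), ("i_na", "conductivity"), ("i_nak", "conductivity")]
    out = [Scenario("control", (), 0.0, patch_radius)]
    short = {"i_na": "ina", "i_nak": "inak", "conductivity": "cond"}
    for inten in intensities:
        for axes in singles + pairs:
            name = "+".join(short[a] for a in axes) + f"_{int(inten * 100)}"
            out.append(Scenario(name, tuple(axes), inten, patch_radius))
    return out


def enumerate_atria_configs(patch_radius: float = 0.5, intensity: float = 0.50) -> list:
    """Nine pseudo-atria configurations: control plus the 8 combinations of
    {control, localized-venous, spread} infiltration per chamber (minus the
    all-control pair).  Remodeled patches downregulate I_NaK and
    conductivity by 50 %."""
    modes = ("control", "localized", "spread")
    out = [Scenario("control", (), 0.0, patch_radius, geometry="RA:control,LA:control")]
    for ra in modes:
        for la in modes:
            if ra == la == "control":
                continue
            out.append(Scenario(
                f"ra-{ra}_la-{la}",
                ("i_nak", "conductivity"),
                intensity,
                patch_radius,
                geometry=f"RA:{ra},LA:{la}",
            ))
    return out


def atria_region_masks(grid: TissueGrid, scenario: Scenario) -> list:
    """Per-chamber placement masks implied by an atria scenario geometry."""
    masks = []
    for part in scenario.geometry.split(","):
        chamber, mode = part.split(":")
        chamber = chamber.strip().upper()
        mode = mode.strip()
        if mode == "control":
            continue
        if mode == "localized":
            masks.append(grid.regions[f"venous_{chamber.lower()}"])
        elif mode == "spread":
            masks.append(grid.regions[chamber])
        else:
            raise ValueError(f"unknown infiltration mode {mode!r}")
    return masks


def apply_remodeling(grid: TissueGrid, rmap: RemodelingMap) -> TissueGrid:
    """Write a remodeling map's scalers onto the grid (in place; returned).

    Element diffusivity becomes base * s_cond; current scalers are set
    per element.  Idempotent for a control (all-ones) map.
    """
    if rmap.shape != grid.shape:
        raise ValueError(
            f"remodeling map shape {rmap.shape} does not match grid {grid.shape}"
        )
    grid.s_na = rmap.s_na.copy()
    grid.s_nak = rmap.s_nak.copy()
    grid.s_cond = rmap.s_cond.copy()
    return grid


def scenario_remodeling(
    grid: TissueGrid,
    scenario: Scenario,
    target_fraction: float = 0.5,
    seed: int = 0,
    region_masks: list | None = None,
) -> RemodelingMap:
    """Build and apply the remodeling map for one scenario.

    ``region_masks``: optional list of placement masks (one per infiltrated
    chamber for atria scenarios); default is the whole active tissue.
    """
    ny, nx = grid.shape
    if scenario.name == "control":
        rmap = RemodelingMap(
            np.ones((ny, nx)), np.ones((ny, nx)), np.ones((ny, nx)),
            [], 0.0, np.zeros((ny, nx), dtype=bool),
        )
        apply_remodeling(grid, rmap)
        return rmap

    masks = region_masks if region_masks is not None else [None]
    s_na = np.ones((ny, nx))
    s_nak = np.ones((ny, nx))
    s_cond = np.ones((ny, nx))
    remodeled = np.zeros((ny, nx), dtype=bool)
    patches = []
    covs = []
    for k, m in enumerate(masks):
        part = place_circular_patches(
            grid, scenario.patch_radius, target_fraction, seed + 1000 * k,
            region_mask=m, scalers=scenario.scalers,
        )
        sel = part.remodeled
        s_na[sel] = part.s_na[sel]
        s_nak[sel] = part.s_nak[sel]
        s_cond[sel] = part.s_cond[sel]
        remodeled |= sel
        patches.extend(part.patches)
        covs.append(part.coverage)
    rmap = RemodelingMap(s_na, s_nak, s_cond, patches, float(np.mean(covs)), remodeled)
    apply_remodeling(grid, rmap)
    return rmap
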