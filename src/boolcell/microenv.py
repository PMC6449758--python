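"""Voxelised extracellular space: diffusion, decay, sources and injections.

Substrates (TNF, oxygen, a non-diffusing extracellular-matrix density, ...)
live on a regular voxel mesh covering a rectangular 2-D or 3-D domain.
Each voxel stores the local concentration of every substrate.  Diffusion
and decay are integrated with an operator-split implicit scheme: one
backward-Euler tridiagonal (Thomas) sweep per axis followed by an exact
exponential decay factor.  The scheme is unconditionally stable, keeps
densities non-negative and conserves mass exactly under zero-flux
boundaries.

Treatment "injection" is modelled as a Dirichlet rim: while a schedule is
on, every boundary-adjacent voxel is held at the scheduled concentration
(the surrounding medium is perfused); while off, the rim is held at zero
so the substrate washes out.

Units: space µm, time min, TNF ng/mL, oxygen mmHg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import solve_banded

__all__ = [
    "SubstrateSpec",
    "InjectionSchedule",
    "VoxelGrid",
    "diffuse_decay",
    "apply_sources_sinks",
    "apply_injection",
    "ecm_modify",
]

#: Default voxel edge, µm.
DEFAULT_DX = 20.0
#: Reconstructed default transport constants (exact published values are
#: not available); exposed in the simulation config.
TNF_DIFFUSION = 1200.0      # µm²/min
TNF_DECAY = 0.0275          # 1/min
OXYGEN_DIFFUSION = 6000.0   # µm²/min


@dataclass(frozen=True)
class SubstrateSpec:
    """Physical constants of one diffusible (or fixed) substrate."""

    name: str
    diffusion_coefficient: float = 0.0   # µm²/min
    decay_rate: float = 0.0              # 1/min
    diffusing: bool = True
    boundary: str = "zero-flux"          # "zero-flux" | "fixed-value"
    boundary_value: float = 0.0
    max_density: float = math.inf        # clamp for deposited densities (ECM)

    def __post_init__(self):
        if self.diffusion_coefficient < 0 or self.decay_rate < 0:
            raise ValueError(f"substrate {self.name!r}: constants must be >= 0")
        if self.boundary not in ("zero-flux", "fixed-value"):
            raise ValueError(f"substrate {self.name!r}: unknown boundary {self.boundary!r}")


@dataclass(frozen=True)
class InjectionSchedule:
    """When and how strongly a substrate is supplied at the domain rim.

    Modes: ``none`` (never supplied), ``continuous``, ``pulsed``
    (on for ``pulse_duration`` at the start of every ``period``),
    ``stop_at`` (continuous until ``switch_time``, then off) and
    ``step_change`` (``concentration`` until ``switch_time``, then
    ``new_concentration``).
    """

    mode: str = "none"
    concentration: float = 0.0       # ng/mL
    pulse_duration: float = 0.0      # min
    period: float = 0.0              # min
    switch_time: float = 0.0         # min
    new_concentration: float = 0.0   # ng/mL

    def __post_init__(self):
        if self.mode not in ("none", "continuous", "pulsed", "stop_at", "step_change"):
            raise ValueError(f"unknown injection mode {self.mode!r}")
        if self.mode == "pulsed" and not (0 < self.pulse_duration <= self.period):
            raise ValueError("pulsed injection requires 0 < pulse_duration <= period")
        if self.mode in ("stop_at", "step_change") and not self.switch_time > 0:
            raise ValueError(f"{self.mode} injection requires switch_time > 0")

    def level_at(self, t: float) -> float | None:
        """Rim concentration at time ``t``, or ``None`` if no rim is imposed."""
        if self.mode == "none":
            return None
        if self.mode == "continuous":
            return self.concentration
        if self.mode == "pulsed":
            return self.concentration if (t % self.period) < self.pulse_duration else 0.0
        if self.mode == "stop_at":
            return self.concentration if t < self.switch_time else 0.0
        return self.concentration if t < self.switch_time else self.new_concentration


class VoxelGrid:
    """Per-substrate density fields on a regular 2-D or 3-D voxel mesh."""

    def __init__(
        self,
        bounds_min: Sequence[float],
        bounds_max: Sequence[float],
        dx: float = DEFAULT_DX,
        substrates: Iterable[SubstrateSpec] = (),
    ):
        self.bounds_min = np.asarray(bounds_min, dtype=float)
        self.bounds_max = np.asarray(bounds_max, dtype=float)
        self.dim = len(self.bounds_min)
        if self.dim not in (2, 3) or len(self.bounds_max) != self.dim:
            raise ValueError("domain must be 2-D or 3-D with matching bounds")
        if np.any(self.bounds_max <= self.bounds_min) or dx <= 0:
            raise ValueError("invalid domain bounds or voxel edge")
        self.dx = float(dx)
        self.shape = tuple(
            max(1, int(round((hi - lo) / dx)))
            for lo, hi in zip(self.bounds_min, self.bounds_max)
        )
        self._bmin = tuple(float(v) for v in self.bounds_min)
        self._bmax = tuple(float(v) for v in self.bounds_max)
        self.substrates: dict[str, SubstrateSpec] = {}
        self.fields: dict[str, np.ndarray] = {}
        for spec in substrates:
            self.add_substrate(spec)
        self._rim_mask: np.ndarray | None = None

    # -- construction ------------------------------------------------------

    def add_substrate(self, spec: SubstrateSpec, initial: float = 0.0) -> None:
        if spec.name in self.substrates:
            raise ValueError(f"duplicate substrate {spec.name!r}")
        self.substrates[spec.name] = spec
        self.fields[spec.name] = np.full(self.shape, float(initial))

    @property
    def voxel_volume(self) -> float:
        return self.dx ** self.dim

    @property
    def rim_mask(self) -> np.ndarray:
        """Boolean mask of boundary-adjacent (medium) voxels."""
        if self._rim_mask is None:
            mask = np.zeros(self.shape, dtype=bool)
            for axis in range(self.dim):
                sl_lo = [slice(None)] * self.dim
                sl_lo[axis] = 0
                mask[tuple(sl_lo)] = True
                sl_hi = [slice(None)] * self.dim
                sl_hi[axis] = self.shape[axis] - 1
                mask[tuple(sl_hi)] = True
            self._rim_mask = mask
        return self._rim_mask

    # -- geometry ----------------------------------------------------------

    def voxel_index(self, position: Sequence[float]) -> tuple[int, ...]:
        """Containing voxel of a position; raises if outside the domain."""
        # scalar arithmetic: this sits in the per-cell inner loop
        out = []
        for axis in range(self.dim):
            p = float(position[axis])
            lo = self._bmin[axis]
            if p < lo or p > self._bmax[axis]:
                raise ValueError(f"position {list(position)} outside the domain")
            i = int((p - lo) / self.dx)
            n = self.shape[axis]
            out.append(i if i < n else n - 1)
        return tuple(out)

    def voxel_centers(self, axis: int) -> np.ndarray:
        return self.bounds_min[axis] + self.dx * (np.arange(self.shape[axis]) + 0.5)

    def sample(self, substrate: str, position: Sequence[float]) -> float:
        """Concentration at a position, nearest-voxel convention."""
        return float(self.fields[substrate][self.voxel_index(position)])

    def total_mass(self, substrate: str) -> float:
        return float(self.fields[substrate].sum()) * self.voxel_volume

    def copy(self) -> "VoxelGrid":
        out = VoxelGrid(self.bounds_min, self.bounds_max, self.dx)
        out.substrates = dict(self.substrates)
        out.fields = {k: v.copy() for k, v in self.fields.items()}
        return out

    def write_csv(self, path) -> None:
        """Density snapshot: one row per voxel with its centre and densities."""
        names = list(self.fields)
        with open(path, "w") as fh:
            fh.write("voxel,x,y,z," + ",".join(names) + "\n")
            centers = [self.voxel_centers(axis) for axis in range(self.dim)]
            for flat, idx in enumerate(np.ndindex(self.shape)):
                coords = [float(centers[axis][idx[axis]]) for axis in range(self.dim)]
                coords += [0.0] * (3 - self.dim)
                values = ",".join(repr(float(self.fields[n][idx])) for n in names)
                fh.write(f"{flat},{coords[0]!r},{coords[1]!r},{coords[2]!r},{values}\n")


# --------------------------------------------------------------------------
# Operators
# --------------------------------------------------------------------------

def _axis_sweep(field: np.ndarray, axis: int, alpha: float, spec: SubstrateSpec) -> np.ndarray:
    """Backward-Euler diffusion along one axis: solve (I - alpha*L) x = b."""
    n = field.shape[axis]
    if n == 1:
        return field
    moved = np.moveaxis(field, axis, 0)
    flat = moved.reshape(n, -1)
    ab = np.zeros((3, n))
    ab[0, 1:] = -alpha
    ab[2, :-1] = -alpha
    ab[1, :] = 1 + 2 * alpha
    if spec.boundary == "zero-flux":
        ab[1, 0] = 1 + alpha
        ab[1, -1] = 1 + alpha
        rhs = flat
    else:  # fixed-value: ghost cells at the boundary value
        rhs = flat.copy()
        rhs[0] += alpha * spec.boundary_value
        rhs[-1] += alpha * spec.boundary_value
    sol = solve_banded((1, 1), ab, rhs, overwrite_ab=True, check_finite=False)
    return np.moveaxis(sol.reshape(moved.shape), 0, axis)


def diffuse_decay(grid: VoxelGrid, substrate: str, dt: float) -> None:
    """One operator-split implicit diffusion step plus exact decay.

    No-op for non-diffusing substrates (the ECM contract).  Modifies the
    grid in place.
    """
    spec = grid.substrates[substrate]
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if not spec.diffusing:
        return
    field = grid.fields[substrate]
    if spec.diffusion_coefficient > 0:
        alpha = spec.diffusion_coefficient * dt / grid.dx ** 2
        for axis in range(grid.dim):
            field = _axis_sweep(field, axis, alpha, spec)
    if spec.decay_rate > 0:
        field = field * math.exp(-spec.decay_rate * dt)
    np.maximum(field, 0.0, out=field)
    grid.fields[substrate] = field


def apply_sources_sinks(
    grid: VoxelGrid,
    substrate: str,
    agents: Sequence[tuple[Sequence[float], float, float, float]],
    dt: float,
) -> np.ndarray:
    """Cell-driven secretion and uptake, solved implicitly per voxel.

    ``agents`` is a sequence of ``(position, secretion_rate, uptake_rate,
    saturation)``; rates are 1/min, saturation in concentration units.
    Each agent modifies its containing voxel with the saturating-source /
    first-order-sink update

        dc/dt = secretion_rate * (saturation - c) - uptake_rate * c

    integrated with backward Euler (never produces a negative density).
    Returns the mass removed per agent (concentration x voxel volume),
    for receptor bookkeeping.
    """
    field = grid.fields[substrate]
    uptaken = np.zeros(len(agents))
    for i, (position, secretion, uptake, saturation) in enumerate(agents):
        if secretion < 0 or uptake < 0:
            raise ValueError("secretion and uptake rates must be >= 0")
        if secretion == 0 and uptake == 0:
            continue
        idx = grid.voxel_index(position)
        c = field[idx]
        c_new = (c + dt * secretion * saturation) / (1 + dt * (secretion + uptake))
        uptaken[i] = uptake * dt * c_new * grid.voxel_volume
        field[idx] = c_new
    return uptaken


def apply_injection(
    grid: VoxelGrid, substrate: str, schedule: InjectionSchedule, t: float
) -> None:
    """Impose the injection schedule's Dirichlet rim at time ``t``.

    While the schedule is on, boundary-adjacent voxels are held at the
    scheduled concentration; while off, at zero (wash-out).  Mode ``none``
    imposes nothing.
    """
    level = schedule.level_at(t)
    if level is None:
        return
    grid.fields[substrate][grid.rim_mask] = level


def ecm_modify(
    grid: VoxelGrid,
    ecm_substrate: str,
    agents: Sequence[tuple[Sequence[float], float, float]],
    dt: float,
) -> None:
    """Cell-contact degradation/deposition of the non-diffusing ECM density.

    ``agents``: ``(position, degrade_rate, deposit_rate)``.  Degradation is
    first-order in the local density (1/min); deposition is a constant rate
    (density/min).  The result is clamped to [0, max_density] and the field
    never diffuses.
    """
    spec = grid.substrates[ecm_substrate]
    if spec.diffusing:
        raise ValueError(f"{ecm_substrate!r} is a diffusing substrate, not an ECM density")
    field = grid.fields[ecm_substrate]
    for position, degrade, deposit in agents:
        idx = grid.voxel_index(position)
        value = field[idx] * (1 - degrade * dt) + deposit * dt
        field[idx] = min(max(value, 0.0), spec.max_density)
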