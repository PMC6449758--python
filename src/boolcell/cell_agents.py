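"""Off-lattice centre-based cell agents.

Cells are soft spheres with a cellular and a nuclear radius.  They push
and pull on each other through short-range pairwise forces (quadratic
repulsion inside the radii sum, quadratic adhesion out to a multiple of
it), move with overdamped dynamics (velocity proportional to net force,
drag absorbed into the force scale), grow toward phase-dependent target
volumes, progress through a stochastic cell cycle, and die through an
apoptotic (shrink) or necrosis-like (swell, NonACD) volume program.
Passive, pushable, degradable spheres stand in for a discrete
extracellular matrix.

Adhesion depends on who touches whom: each strain carries homotypic,
heterotypic and matrix adhesion strengths, modulated per cell by a
cadherin/integrin surface-density coefficient; pair strengths combine as
geometric means, so sorting of mixed populations by differential adhesion
emerges from the force law alone.

Units: µm, min, µm³.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "CellAgent",
    "StrainParams",
    "PassiveSphere",
    "FATES",
    "pairwise_force",
    "compute_forces",
    "integrate_motion",
    "update_volume",
    "cycle_and_divide",
    "set_fate",
    "oxygen_death_check",
    "update_polarity_motility",
    "degrade_passive_sphere",
    "radius_from_volume",
]

FATES = ("Proliferative", "Apoptosis", "NonACD")

#: Default cell geometry (config-exposed).
DEFAULT_VOLUME = 2494.0          # µm³, radius ~ 8.4 µm
DEFAULT_NUCLEAR_RADIUS = 5.0     # µm
DEFAULT_FLUID_FRACTION = 0.75

#: Mechanics defaults, drag absorbed into the force scale (µm/min).
DEFAULT_REPULSION = 10.0
DEFAULT_ADHESION = 0.4
DEFAULT_INTERACTION_MULTIPLIER = 1.25

#: Volume-program rates (1/min).
VOLUME_RELAX_RATE = 0.05         # growth relaxation toward target
APOPTOSIS_SHRINK_RATE = 0.006    # removal (below 5% volume) after ~8 h
NECROSIS_SWELL_RATE = 0.01       # swell toward 1.5x volume
NECROSIS_LYSIS_TIME = 360.0      # min in the swollen stage before removal
APOPTOSIS_REMOVAL_FRACTION = 0.05
NECROSIS_SWELL_FACTOR = 1.5

_TIE_BREAK_AXIS = np.array([1.0, 0.0, 0.0])  # repulsion direction when centres coincide


def radius_from_volume(volume: float) -> float:
    """Radius of the sphere of the given volume."""
    return (3.0 * max(volume, 0.0) / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass
class StrainParams:
    """Physical and genetic parameters shared by one cell strain."""

    name: str = "WT"
    adhesion_strength_homotypic: float = DEFAULT_ADHESION
    adhesion_strength_heterotypic: float = DEFAULT_ADHESION
    adhesion_strength_matrix: float = 0.0
    repulsion_strength: float = DEFAULT_REPULSION
    interaction_distance_multiplier: float = DEFAULT_INTERACTION_MULTIPLIER
    motility_speed: float = 0.0          # µm/min
    persistence_time: float = 10.0       # min
    cycle_duration: float = 1048.0       # min, Erlang mean (16 h population doubling)
    target_volume: float = DEFAULT_VOLUME
    nuclear_radius: float = DEFAULT_NUCLEAR_RADIUS
    fluid_fraction: float = DEFAULT_FLUID_FRACTION
    oxygen_necrosis_threshold: float = 5.0   # mmHg
    oxygen_uptake_rate: float = 2.0          # 1/min (calibrated: hypoxic core at desk-scale spheroid radii)
    tnf_secretion_rate: float = 0.0          # ng/mL/min into the cell's voxel
    ecm_degrade_rate: float = 0.0            # µm/min off passive-sphere radii
    rate_overrides: list = field(default_factory=list)

    def __post_init__(self):
        if self.cycle_duration <= 0:
            raise ValueError("cycle_duration must be > 0")
        for label in (
            "adhesion_strength_homotypic",
            "adhesion_strength_heterotypic",
            "adhesion_strength_matrix",
            "repulsion_strength",
        ):
            if getattr(self, label) < 0:
                raise ValueError(f"{label} must be >= 0")


@dataclass
class PassiveSphere:
    """A pushable, degradable ECM sphere."""

    id: int
    position: np.ndarray
    radius: float
    friction_coefficient: float = 1.0
    degradable: bool = True
    pinned: bool = False
    adhesion_coefficient: float = 1.0
    repulsion_strength: float = DEFAULT_REPULSION
    removal_radius: float = 0.5

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("positions are 3-vectors (z=0 in 2-D mode)")
        if self.radius < 0:
            raise ValueError("radius must be >= 0")

    @property
    def removed(self) -> bool:
        return self.radius < self.removal_radius


class CellAgent:
    """One cell: position, volumes, phase/fate, polarity and its signalling state."""

    __slots__ = (
        "id", "position", "volume", "fluid_volume", "nuclear_volume",
        "fate", "phase", "strain", "network_state", "polarity",
        "adhesion_coefficient", "activated_flag", "cycling_enabled",
        "cycle_clock", "cycle_length", "death_clock", "removed",
        "dim", "signalling_offset", "internalised_tnf", "bound_tnf",
        "secreting",
    )

    def __init__(
        self,
        id: int,
        position: Sequence[float],
        strain: StrainParams,
        dim: int = 3,
        volume: float | None = None,
        network_state=None,
        polarity: Sequence[float] | None = None,
    ):
        self.id = id
        self.position = np.zeros(3)
        self.position[: len(position)] = position
        if dim == 2:
            self.position[2] = 0.0
        self.dim = dim
        self.strain = strain
        self.volume = float(volume if volume is not None else strain.target_volume)
        self.fluid_volume = strain.fluid_fraction * self.volume
        self.nuclear_volume = min(
            4.0 / 3.0 * math.pi * strain.nuclear_radius ** 3, self.volume
        )
        self.fate = "Proliferative"
        self.phase = "cycling"
        self.network_state = network_state
        self.polarity = np.zeros(3)
        if polarity is not None:
            self.polarity[: len(polarity)] = polarity
        self.adhesion_coefficient = 1.0
        self.activated_flag = False
        self.cycling_enabled = True
        self.cycle_clock = 0.0
        self.cycle_length = strain.cycle_duration
        self.death_clock = 0.0
        self.removed = False
        self.signalling_offset = 0.0
        self.internalised_tnf = 0.0
        self.bound_tnf = 0.0
        self.secreting = False

    @property
    def radius(self) -> float:
        return radius_from_volume(self.volume)

    @property
    def nuclear_radius(self) -> float:
        return radius_from_volume(self.nuclear_volume)

    def draw_cycle_length(self, rng: np.random.Generator) -> None:
        """Erlang-distributed (shape 4) cycle duration around the strain mean."""
        self.cycle_length = float(rng.gamma(4.0, self.strain.cycle_duration / 4.0))

    def __repr__(self) -> str:
        return (
            f"CellAgent(id={self.id}, fate={self.fate}, "
            f"r={self.radius:.1f}, pos={np.round(self.position, 1).tolist()})"
        )


# --------------------------------------------------------------------------
# Mechanics
# --------------------------------------------------------------------------

def _pair_strength(a, b) -> tuple[float, float, float]:
    """(repulsion, adhesion, interaction multiplier) for one interacting pair."""
    a_cell = isinstance(a, CellAgent)
    b_cell = isinstance(b, CellAgent)
    if a_cell and b_cell:
        rep = math.sqrt(a.strain.repulsion_strength * b.strain.repulsion_strength)
        if a.strain.name == b.strain.name:
            s = a.strain.adhesion_strength_homotypic * b.strain.adhesion_strength_homotypic
        else:
            s = a.strain.adhesion_strength_heterotypic * b.strain.adhesion_strength_heterotypic
        adh = math.sqrt(s) * math.sqrt(a.adhesion_coefficient * b.adhesion_coefficient)
        f = 0.5 * (
            a.strain.interaction_distance_multiplier
            + b.strain.interaction_distance_multiplier
        )
    elif a_cell or b_cell:
        cell, sphere = (a, b) if a_cell else (b, a)
        rep = math.sqrt(cell.strain.repulsion_strength * sphere.repulsion_strength)
        adh = math.sqrt(
            cell.strain.adhesion_strength_matrix * sphere.adhesion_coefficient
        ) * math.sqrt(cell.adhesion_coefficient)
        f = cell.strain.interaction_distance_multiplier
    else:  # two passive spheres: pure repulsion
        rep = math.sqrt(a.repulsion_strength * b.repulsion_strength)
        adh = 0.0
        f = 1.0
    return rep, adh, f


def pairwise_force(a, b) -> np.ndarray:
    """Force exerted on ``a`` by ``b`` (the force on ``b`` is its negative).

    Quadratic repulsion inside the radii sum R, quadratic adhesion out to
    f*R.  Coincident centres repel along a fixed axis (never NaN).
    """
    delta = a.position - b.position
    d = float(np.linalg.norm(delta))
    R = a.radius + b.radius
    rep, adh, f = _pair_strength(a, b)
    if d >= f * R:
        return np.zeros(3)
    direction = delta / d if d > 0 else _TIE_BREAK_AXIS.copy()
    force = 0.0
    if d < R:
        force += rep * (1.0 - d / R) ** 2
    force -= adh * (1.0 - d / (f * R)) ** 2
    return force * direction


def _agent_arrays(agents: Sequence) -> dict[str, np.ndarray]:
    n = len(agents)
    arr = {
        "pos": np.empty((n, 3)),
        "radius": np.empty(n),
        "rep": np.empty(n),
        "homo": np.zeros(n),
        "het": np.zeros(n),
        "mat": np.zeros(n),
        "coef": np.ones(n),
        "fmul": np.full(n, np.nan),
        "is_cell": np.zeros(n, dtype=bool),
        "strain_id": np.full(n, -1),
    }
    strain_ids: dict[str, int] = {}
    for i, ag in enumerate(agents):
        arr["pos"][i] = ag.position
        arr["radius"][i] = ag.radius
        if isinstance(ag, CellAgent):
            s = ag.strain
            arr["is_cell"][i] = True
            arr["rep"][i] = s.repulsion_strength
            arr["homo"][i] = s.adhesion_strength_homotypic
            arr["het"][i] = s.adhesion_strength_heterotypic
            arr["mat"][i] = s.adhesion_strength_matrix
            arr["coef"][i] = ag.adhesion_coefficient
            arr["fmul"][i] = s.interaction_distance_multiplier
            arr["strain_id"][i] = strain_ids.setdefault(s.name, len(strain_ids))
        else:
            arr["rep"][i] = ag.repulsion_strength
            arr["mat"][i] = ag.adhesion_coefficient
    return arr


def _pair_forces(arr: dict[str, np.ndarray], pairs: np.ndarray, n: int) -> np.ndarray:
    """Vectorised evaluation of the pair force law over an (m, 2) pair list."""
    forces = np.zeros((n, 3))
    if len(pairs) == 0:
        return forces
    i, j = pairs[:, 0], pairs[:, 1]
    delta = arr["pos"][i] - arr["pos"][j]
    d = np.linalg.norm(delta, axis=1)
    R = arr["radius"][i] + arr["radius"][j]
    both_cells = arr["is_cell"][i] & arr["is_cell"][j]
    one_cell = arr["is_cell"][i] ^ arr["is_cell"][j]
    same = both_cells & (arr["strain_id"][i] == arr["strain_id"][j])
    s2 = np.where(
        same,
        arr["homo"][i] * arr["homo"][j],
        np.where(both_cells, arr["het"][i] * arr["het"][j], arr["mat"][i] * arr["mat"][j]),
    )
    adh = np.sqrt(s2) * np.sqrt(arr["coef"][i] * arr["coef"][j])
    rep = np.sqrt(arr["rep"][i] * arr["rep"][j])
    fi, fj = arr["fmul"][i], arr["fmul"][j]
    f = np.where(both_cells, 0.5 * (fi + fj), np.where(one_cell, np.fmax(fi, fj), 1.0))
    # f for cell-sphere pairs is the cell's multiplier (the sphere's is NaN)
    with np.errstate(invalid="ignore", divide="ignore"):
        direction = np.where(d[:, None] > 0, delta / np.where(d == 0, 1.0, d)[:, None],
                             _TIE_BREAK_AXIS)
        magnitude = np.where(d < R, rep * (1.0 - d / R) ** 2, 0.0)
        magnitude = magnitude - np.where(d < f * R, adh * (1.0 - d / (f * R)) ** 2, 0.0)
    contrib = magnitude[:, None] * direction
    np.add.at(forces, i, contrib)
    np.add.at(forces, j, -contrib)
    return forces


def interaction_reach(agents: Sequence) -> float:
    """Upper bound on any pair's interaction distance."""
    max_r = max(ag.radius for ag in agents)
    max_f = max(
        (ag.strain.interaction_distance_multiplier if isinstance(ag, CellAgent) else 1.0)
        for ag in agents
    )
    return 2.0 * max_f * max_r


def compute_forces(agents: Sequence, method: str = "tree") -> np.ndarray:
    """Net pairwise force on every agent (cells and passive spheres).

    ``method='all_pairs'`` evaluates every i<j pair; ``method='tree'``
    restricts to candidate pairs within the interaction reach found by a
    k-d tree, visited in the same lexicographic order.  Pairs beyond reach
    contribute an exact zero, so both methods return identical forces.
    """
    n = len(agents)
    if n < 2:
        return np.zeros((n, 3))
    arr = _agent_arrays(agents)
    if method == "all_pairs":
        iu = np.triu_indices(n, k=1)
        pairs = np.column_stack(iu)
    elif method == "tree":
        tree = cKDTree(arr["pos"])
        raw = tree.query_pairs(interaction_reach(agents), output_type="ndarray")
        if len(raw):
            order = np.lexsort((raw[:, 1], raw[:, 0]))
            pairs = raw[order]
        else:
            pairs = raw
    else:
        raise ValueError(f"unknown method {method!r}")
    return _pair_forces(arr, pairs, n)


def integrate_motion(
    cells: Sequence[CellAgent],
    spheres: Sequence[PassiveSphere],
    dt: float,
    motile_forces: np.ndarray | None = None,
    method: str = "tree",
) -> None:
    """One overdamped Euler step: velocity = (pair forces + motile)/drag.

    Cells have unit drag (absorbed into force scale); passive spheres are
    scaled by their friction coefficient, and pinned spheres do not move.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    agents = list(cells) + list(spheres)
    forces = compute_forces(agents, method=method)
    nc = len(cells)
    if motile_forces is not None:
        forces[:nc] += motile_forces
    for i, cell in enumerate(cells):
        cell.position = cell.position + forces[i] * dt
        if cell.dim == 2:
            cell.position[2] = 0.0
    for k, sphere in enumerate(spheres):
        if sphere.pinned or not math.isfinite(sphere.friction_coefficient):
            continue
        sphere.position = sphere.position + forces[nc + k] * dt / sphere.friction_coefficient


# --------------------------------------------------------------------------
# Volume, cycle and death
# --------------------------------------------------------------------------

def _relax(value: float, target: float, rate: float, dt: float) -> float:
    return value + (target - value) * (1.0 - math.exp(-rate * dt))


def update_volume(cell: CellAgent, dt: float) -> None:
    """Relax each volume compartment toward its phase-dependent target.

    Proliferative cells ramp their target from one to two reference
    volumes across the cycle; apoptotic cells shrink toward zero and are
    removed below 5% of the reference volume; NonACD cells swell toward
    1.5x and are removed after the lysis delay.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    strain = cell.strain
    v0 = strain.target_volume
    if cell.fate == "Proliferative":
        progress = min(cell.cycle_clock / cell.cycle_length, 1.0) if cell.cycling_enabled or cell.cycle_clock > 0 else 0.0
        target = v0 * (1.0 + progress)
        rate = VOLUME_RELAX_RATE
        nuclear_target = min(4.0 / 3.0 * math.pi * strain.nuclear_radius ** 3 * (1.0 + progress), target)
    elif cell.fate == "Apoptosis":
        target = 0.0
        nuclear_target = 0.0
        rate = APOPTOSIS_SHRINK_RATE
        cell.death_clock += dt
    else:  # NonACD: swell, then lyse
        target = NECROSIS_SWELL_FACTOR * v0
        nuclear_target = cell.nuclear_volume  # nucleus does not swell
        rate = NECROSIS_SWELL_RATE
        cell.death_clock += dt
    cell.volume = _relax(cell.volume, target, rate, dt)
    cell.nuclear_volume = min(_relax(cell.nuclear_volume, nuclear_target, rate, dt), cell.volume)
    cell.fluid_volume = strain.fluid_fraction * cell.volume
    if cell.fate == "Apoptosis" and cell.volume < APOPTOSIS_REMOVAL_FRACTION * v0:
        cell.removed = True
    if cell.fate == "NonACD" and cell.death_clock >= NECROSIS_LYSIS_TIME:
        cell.removed = True


def cycle_and_divide(
    cell: CellAgent, dt: float, rng: np.random.Generator, next_id
) -> list[CellAgent]:
    """Advance the cycle clock; divide when the timer and volume gate allow.

    Division splits the compartment volumes in half, places the daughters
    half a radius apart along a random direction, re-randomises polarity,
    and copies the mother's signalling network state into both daughters
    (state inheritance).  ``next_id`` is a callable yielding fresh ids.
    Non-proliferative cells never divide.
    """
    if cell.fate != "Proliferative" or cell.removed:
        return [cell]
    if cell.cycling_enabled:
        cell.cycle_clock += dt
    ready = (
        cell.cycle_clock >= cell.cycle_length
        and cell.volume >= 0.95 * 2.0 * cell.strain.target_volume
    )
    if not ready:
        return [cell]
    direction = _random_unit(rng, cell.dim)
    offset = 0.5 * cell.radius * direction
    daughters = []
    for sign in (+1.0, -1.0):
        d = CellAgent(
            id=next_id(),
            position=cell.position + sign * offset,
            strain=cell.strain,
            dim=cell.dim,
            volume=cell.volume / 2.0,
            network_state=cell.network_state.copy() if cell.network_state is not None else None,
        )
        d.fluid_volume = cell.fluid_volume / 2.0
        d.nuclear_volume = cell.nuclear_volume / 2.0
        d.polarity = _random_unit(rng, cell.dim)
        d.adhesion_coefficient = cell.adhesion_coefficient
        d.activated_flag = cell.activated_flag
        d.cycling_enabled = cell.cycling_enabled
        d.internalised_tnf = cell.internalised_tnf / 2.0
        d.bound_tnf = cell.bound_tnf / 2.0
        d.draw_cycle_length(rng)
        daughters.append(d)
    return daughters


def set_fate(cell: CellAgent, fate: str) -> None:
    """Change the cell fate; death fates latch (irreversible)."""
    if fate not in FATES:
        raise ValueError(f"unknown fate {fate!r}")
    if cell.fate in ("Apoptosis", "NonACD"):
        return
    if fate == cell.fate:
        return
    cell.fate = fate
    if fate == "Apoptosis":
        cell.phase = "apoptotic"
        cell.death_clock = 0.0
    elif fate == "NonACD":
        cell.phase = "necrotic"
        cell.death_clock = 0.0


def oxygen_death_check(cell: CellAgent, o2_local: float) -> None:
    """Commit to NonACD when local oxygen is strictly below the threshold."""
    if cell.fate != "Proliferative":
        return
    if o2_local < cell.strain.oxygen_necrosis_threshold:
        set_fate(cell, "NonACD")


def _random_unit(rng: np.random.Generator, dim: int) -> np.ndarray:
    v = np.zeros(3)
    while True:
        v[:dim] = rng.normal(size=dim)
        norm = np.linalg.norm(v)
        if norm > 1e-12:
            return v / norm


def update_polarity_motility(
    cell: CellAgent, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Persistent random-walk polarity update; returns the motile force.

    The polarity tumbles to a fresh random direction with probability
    dt/persistence_time per step, giving an exponentially decorrelating
    direction with the strain's persistence time; the motile force is
    speed x polarity (unit drag).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    strain = cell.strain
    if strain.motility_speed == 0.0:
        return np.zeros(3)
    tau = strain.persistence_time
    if np.linalg.norm(cell.polarity) < 1e-12:
        cell.polarity = _random_unit(rng, cell.dim)
    if math.isfinite(tau) and rng.random() < dt / tau:
        cell.polarity = _random_unit(rng, cell.dim)
    return strain.motility_speed * cell.polarity


def degrade_passive_sphere(
    cell: CellAgent, sphere: PassiveSphere, dt: float, rate: float | None = None
) -> None:
    """Shrink (or grow, negative rate) a contacted degradable ECM sphere."""
    if not sphere.degradable:
        return
    d = float(np.linalg.norm(cell.position - sphere.position))
    if d >= cell.radius + sphere.radius:
        return
    r = cell.strain.ecm_degrade_rate if rate is None else rate
    sphere.radius = max(sphere.radius - r * dt, 0.0)
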