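"""Orchestration of the multi-rate simulation loop.

Three layers run on their own clocks: the microenvironment (diffusion,
decay, injection, cell exchange) on the fastest step, cell mechanics
(forces, motion, volume, cycle, division, oxygen check) on an
intermediate step, and each cell's stochastic Boolean signalling model on
the slowest step.  Between layers, :class:`InputRule`\\ s translate local
environment quantities (internalised ligand, substrate levels, contacts)
into input-node values, and :class:`OutputRule`\\ s translate read-out
nodes into phenotype: death commitment (latching), cycle arrest,
secretion, adhesion modulation.

Reproducibility: one master seed; every cell owns an RNG stream derived
from (master seed, cell id), so the trajectory of a cell does not depend
on how many other cells divided before it.  Signalling updates are
staggered per cell by a random birth offset to avoid artificial
population-wide synchrony (a config switch restores synchronous updates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from . import cell_agents as ca
from . import microenv as me
from .boolean_engine import BooleanNetwork, NetworkState, advance, apply_overrides

__all__ = [
    "ClockConfig",
    "InputRule",
    "OutputRule",
    "ReceptorParams",
    "SimulationConfig",
    "SimulationOutput",
    "Simulation",
    "sync_inputs",
    "apply_outputs",
    "run",
]


@dataclass(frozen=True)
class ClockConfig:
    """Time steps (minutes) for the three layers plus run horizon."""

    dt_diffusion: float = 0.01
    dt_mechanics: float = 0.1
    dt_signalling: float = 10.0
    t_end: float = 1440.0
    snapshot_interval: float = 60.0

    def __post_init__(self):
        if not (0 < self.dt_diffusion <= self.dt_mechanics <= self.dt_signalling):
            raise ValueError("require 0 < dt_diffusion <= dt_mechanics <= dt_signalling")
        for big, small, label in (
            (self.dt_mechanics, self.dt_diffusion, "dt_mechanics/dt_diffusion"),
            (self.dt_signalling, self.dt_mechanics, "dt_signalling/dt_mechanics"),
        ):
            ratio = big / small
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(f"{label} must be an integer multiple, got {ratio}")
        if self.t_end < 0:
            raise ValueError("t_end must be >= 0")


@dataclass(frozen=True)
class ReceptorParams:
    """Three-pool ligand kinetics: free -> bound -> internalised -> cleared."""

    k_on: float = 0.1      # 1/min per (ng/mL)
    k_int: float = 0.5     # 1/min
    k_clear: float = 0.05  # 1/min
    threshold: float = 0.15  # internalised level that switches the input node on


@dataclass(frozen=True)
class InputRule:
    """Sets one input node from a local quantity exceeding a threshold.

    Sources: ``substrate-threshold`` (voxel concentration of ``substrate``),
    ``receptor-threshold`` (the cell's internalised ligand pool),
    ``contact-predicate`` (number of touching neighbours).
    """

    target: str
    source: str
    threshold: float
    substrate: str | None = None

    def __post_init__(self):
        if self.source not in ("substrate-threshold", "receptor-threshold", "contact-predicate"):
            raise ValueError(f"unknown input source {self.source!r}")
        if self.source == "substrate-threshold" and not self.substrate:
            raise ValueError("substrate-threshold rule needs a substrate name")


@dataclass(frozen=True)
class OutputRule:
    """Maps one read-out node onto a phenotype action.

    Actions: ``set_fate_apoptosis`` / ``set_fate_nonacd`` (latch),
    ``mark_survival`` (node on = cycling enabled, off = arrest),
    ``enable_secretion`` (node on = secrete ``substrate``; any activity
    also latches the cell's activated flag), ``adhesion_scale`` (node on
    scales the adhesion coefficient by ``factor``).
    """

    node: str
    action: str
    substrate: str | None = None
    factor: float = 1.0
    irreversible: bool = False

    def __post_init__(self):
        if self.action not in (
            "set_fate_apoptosis", "set_fate_nonacd", "mark_survival",
            "enable_secretion", "adhesion_scale",
        ):
            raise ValueError(f"unknown output action {self.action!r}")
        if self.action == "enable_secretion" and not self.substrate:
            raise ValueError("enable_secretion rule needs a substrate name")


# --------------------------------------------------------------------------
# Per-cell rule application
# --------------------------------------------------------------------------

def validate_rules(
    network: BooleanNetwork,
    input_rules: Sequence[InputRule],
    output_rules: Sequence[OutputRule],
) -> None:
    for rule in input_rules:
        if rule.target not in network.index:
            raise ValueError(f"input rule targets unknown node {rule.target!r}")
        if not network.node(rule.target).is_input:
            raise ValueError(f"input rule targets non-input node {rule.target!r}")
    for rule in output_rules:
        if rule.node not in network.index:
            raise ValueError(f"output rule reads unknown node {rule.node!r}")


def sync_inputs(
    cell: ca.CellAgent,
    grid: me.VoxelGrid | None,
    neighbours: int,
    rules: Sequence[InputRule],
    network: BooleanNetwork,
) -> None:
    """Set each input node to 1 iff its source quantity exceeds its threshold."""
    state = cell.network_state
    for rule in rules:
        if rule.source == "receptor-threshold":
            quantity = cell.internalised_tnf
        elif rule.source == "substrate-threshold":
            quantity = grid.sample(rule.substrate, cell.position) if grid is not None else 0.0
        else:
            quantity = neighbours
        state.bits[network.index[rule.target]] = 1 if quantity >= rule.threshold else 0


def apply_outputs(
    cell: ca.CellAgent,
    rules: Sequence[OutputRule],
    network: BooleanNetwork,
) -> None:
    """Translate the current read-out node values into phenotype.

    Death actions latch (a later 0 on the node never reverts the fate);
    survival and secretion follow the node reversibly, but any secretion
    activity permanently sets the cell's activated flag.
    """
    state = cell.network_state
    for rule in rules:
        value = int(state.bits[network.index[rule.node]])
        if rule.action == "set_fate_apoptosis":
            if value:
                ca.set_fate(cell, "Apoptosis")
        elif rule.action == "set_fate_nonacd":
            if value:
                ca.set_fate(cell, "NonACD")
        elif rule.action == "mark_survival":
            cell.cycling_enabled = bool(value)
        elif rule.action == "enable_secretion":
            cell.secreting = bool(value)
            if value:
                cell.activated_flag = True
        elif rule.action == "adhesion_scale":
            cell.adhesion_coefficient = rule.factor if value else 1.0


# --------------------------------------------------------------------------
# Configuration and output containers
# --------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Validated inputs of one run; see :class:`Simulation`."""

    network: BooleanNetwork | None
    strains: dict[str, ca.StrainParams]
    initial_cells: list[tuple[str, Sequence[float]]]  # (strain name, position)
    clock: ClockConfig = field(default_factory=ClockConfig)
    dim: int = 3
    bounds_min: Sequence[float] = (-200.0, -200.0, -200.0)
    bounds_max: Sequence[float] = (200.0, 200.0, 200.0)
    dx: float = me.DEFAULT_DX
    substrates: list[me.SubstrateSpec] = field(default_factory=list)
    initial_densities: dict[str, float] = field(default_factory=dict)
    schedules: dict[str, me.InjectionSchedule] = field(default_factory=dict)
    input_rules: list[InputRule] = field(default_factory=list)
    output_rules: list[OutputRule] = field(default_factory=list)
    receptor: ReceptorParams = field(default_factory=ReceptorParams)
    tnf_substrate: str = "TNF"
    oxygen_substrate: str | None = None
    passive_spheres: list[ca.PassiveSphere] = field(default_factory=list)
    stagger_signalling: bool = True
    force_method: str = "tree"
    seed: int = 0

    def validate(self) -> None:
        if not self.strains:
            raise ValueError("no strains defined")
        for name, pos in self.initial_cells:
            if name not in self.strains:
                raise ValueError(f"initial cell names unknown strain {name!r}")
        substrate_names = {s.name for s in self.substrates}
        for name in self.schedules:
            if name not in substrate_names:
                raise ValueError(f"schedule for unknown substrate {name!r}")
        if self.network is not None:
            validate_rules(self.network, self.input_rules, self.output_rules)
            for strain in self.strains.values():
                for ov in strain.rate_overrides:
                    if ov.node not in self.network.index:
                        raise ValueError(
                            f"strain {strain.name!r} override names unknown node {ov.node!r}"
                        )
        elif self.input_rules or self.output_rules:
            raise ValueError("signalling rules given but no network")


class SimulationOutput:
    """Population time series, cumulative commitment counters and snapshots."""

    def __init__(self, strains: Iterable[str]):
        self.strain_names = list(strains)
        self._rows: list[dict] = []
        self.snapshots: dict[float, list[dict]] = {}
        self.initial_viable: dict[str, int] = {}
        self.final_cells: list[ca.CellAgent] = []

    def record(self, t: float, cells: Sequence[ca.CellAgent],
               committed: dict[tuple[str, str], int]) -> None:
        present = [c for c in cells if not c.removed]
        for strain in self.strain_names:
            mine = [c for c in present if c.strain.name == strain]
            for fate in ca.FATES:
                self._rows.append({
                    "t": t,
                    "strain": strain,
                    "fate": fate,
                    "count": sum(1 for c in mine if c.fate == fate),
                    "activated": sum(1 for c in mine if c.fate == fate and c.activated_flag),
                    "cum_committed": committed.get((strain, fate), 0),
                })

    def record_snapshot(self, t: float, cells: Sequence[ca.CellAgent],
                        spheres: Sequence[ca.PassiveSphere]) -> None:
        records = [
            {
                "id": c.id, "type": "cell", "x": c.position[0], "y": c.position[1],
                "z": c.position[2], "radius": c.radius, "strain": c.strain.name,
                "fate": c.fate, "activated": int(c.activated_flag),
            }
            for c in cells if not c.removed
        ] + [
            {
                "id": s.id, "type": "sphere", "x": s.position[0], "y": s.position[1],
                "z": s.position[2], "radius": s.radius, "strain": "ECM",
                "fate": "ECM", "activated": 0,
            }
            for s in spheres if not s.removed
        ]
        self.snapshots[t] = records

    # -- accessors ---------------------------------------------------------

    @property
    def population(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows)

    def total_count(self, t: float | None = None, strain: str | None = None) -> int:
        df = self.population
        tt = df["t"].max() if t is None else t
        sel = df[df["t"] == tt]
        if strain is not None:
            sel = sel[sel["strain"] == strain]
        return int(sel["count"].sum())

    def committed_death(self, t: float | None = None, strain: str | None = None) -> int:
        df = self.population
        tt = df["t"].max() if t is None else t
        sel = df[(df["t"] == tt) & (df["fate"].isin(["Apoptosis", "NonACD"]))]
        if strain is not None:
            sel = sel[sel["strain"] == strain]
        return int(sel["cum_committed"].sum())

    def times(self) -> np.ndarray:
        return np.unique(self.population["t"].to_numpy())

    def counts_series(self, strain: str | None = None) -> pd.Series:
        df = self.population
        if strain is not None:
            df = df[df["strain"] == strain]
        return df.groupby("t")["count"].sum()

    def write_population_csv(self, path) -> None:
        self.population.to_csv(path, index=False)

    def write_snapshot_csvs(self, directory) -> None:
        import os

        for t, records in self.snapshots.items():
            pd.DataFrame(records).to_csv(
                os.path.join(directory, f"snapshot_{int(round(t))}.csv"), index=False
            )


# --------------------------------------------------------------------------
# The simulation engine
# --------------------------------------------------------------------------

class Simulation:
    """Owns the cell list, grid and clocks for one run."""

    def __init__(self, config: SimulationConfig):
        config.validate()
        self.config = config
        self.master_seed = int(config.seed)
        self.rng = np.random.default_rng([self.master_seed, 0xC0FFEE])
        self._next_id = 0
        self._cell_rngs: dict[int, np.random.Generator] = {}

        # per-strain networks with mutation overrides applied
        self.networks: dict[str, BooleanNetwork] = {}
        if config.network is not None:
            for name, strain in config.strains.items():
                self.networks[name] = (
                    apply_overrides(config.network, strain.rate_overrides)
                    if strain.rate_overrides else config.network
                )

        self.grid: me.VoxelGrid | None = None
        if config.substrates:
            self.grid = me.VoxelGrid(
                config.bounds_min[: config.dim],
                config.bounds_max[: config.dim],
                config.dx,
            )
            for spec in config.substrates:
                self.grid.add_substrate(spec, config.initial_densities.get(spec.name, 0.0))

        self.cells: list[ca.CellAgent] = []
        for strain_name, position in config.initial_cells:
            self._spawn(strain_name, position)
        self.spheres = list(config.passive_spheres)
        self.committed: dict[tuple[str, str], int] = {}
        self.t = 0.0

    # -- cell management ---------------------------------------------------

    def cell_rng(self, cell_id: int) -> np.random.Generator:
        """The cached per-cell RNG stream, keyed by (master seed, cell id)."""
        rng = self._cell_rngs.get(cell_id)
        if rng is None:
            rng = np.random.default_rng([self.master_seed, 1, cell_id])
            self._cell_rngs[cell_id] = rng
        return rng

    def _spawn(self, strain_name: str, position) -> ca.CellAgent:
        config = self.config
        cid = self._claim_id()
        strain = config.strains[strain_name]
        net = self.networks.get(strain_name)
        state = None
        crng = self.cell_rng(cid)
        if net is not None:
            bits = net.sample_initial_states(1, crng)[0]
            state = NetworkState(bits)
        cell = ca.CellAgent(cid, position, strain, dim=config.dim, network_state=state)
        cell.draw_cycle_length(crng)
        # random initial cycle phase: an asynchronously growing population
        cell.cycle_clock = crng.uniform(0.0, cell.cycle_length)
        cell.volume = strain.target_volume * (1.0 + cell.cycle_clock / cell.cycle_length)
        dt_sig = config.clock.dt_signalling
        cell.signalling_offset = (
            crng.uniform(0.0, dt_sig) if config.stagger_signalling else dt_sig
        )
        self.cells.append(cell)
        return cell

    def _register_daughter(self, cell: ca.CellAgent) -> None:
        """Give a newborn its own stream and next signalling due-time."""
        config = self.config
        crng = self.cell_rng(cell.id)
        dt_sig = config.clock.dt_signalling
        offset = crng.uniform(0.0, dt_sig) if config.stagger_signalling else dt_sig
        cell.signalling_offset = self.t + offset

    def _commit(self, cell: ca.CellAgent, before: str) -> None:
        if before == "Proliferative" and cell.fate in ("Apoptosis", "NonACD"):
            key = (cell.strain.name, cell.fate)
            self.committed[key] = self.committed.get(key, 0) + 1

    # -- layer steps -------------------------------------------------------

    def _diffusion_step(self, dt: float) -> None:
        grid, config = self.grid, self.config
        for name, schedule in config.schedules.items():
            me.apply_injection(grid, name, schedule, self.t)
        for name in grid.substrates:
            me.diffuse_decay(grid, name, dt)
        live = [c for c in self.cells if not c.removed]
        if not live:
            return
        # ligand receptor exchange + secretion (vectorised over cells)
        if config.tnf_substrate in grid.substrates and config.network is not None:
            self._receptor_exchange(live, dt)
        if config.oxygen_substrate and config.oxygen_substrate in grid.substrates:
            agents = [
                (c.position, 0.0, c.strain.oxygen_uptake_rate, 0.0) for c in live
            ]
            me.apply_sources_sinks(grid, config.oxygen_substrate, agents, dt)

    def _receptor_exchange(self, live: Sequence[ca.CellAgent], dt: float) -> None:
        """Explicit-Euler ligand exchange; mirrors tnf_model.receptor_update."""
        grid, rp = self.grid, self.config.receptor
        field = grid.fields[self.config.tnf_substrate]
        vol = grid.voxel_volume
        for cell in live:
            idx = grid.voxel_index(cell.position)
            conc = field[idx]
            uptake_conc = min(rp.k_on * conc * dt, conc)
            internalise = rp.k_int * cell.bound_tnf * dt
            cell.bound_tnf += uptake_conc - internalise
            cell.internalised_tnf += internalise - rp.k_clear * cell.internalised_tnf * dt
            field[idx] = conc - uptake_conc
            if cell.secreting and cell.strain.tnf_secretion_rate > 0:
                field[idx] += cell.strain.tnf_secretion_rate * dt

    def _mechanics_step(self, dt: float) -> None:
        live = [c for c in self.cells if not c.removed]
        if not live:
            return
        motile = None
        if any(c.strain.motility_speed > 0 for c in live):
            motile = np.zeros((len(live), 3))
            for i, cell in enumerate(live):
                motile[i] = ca.update_polarity_motility(cell, dt, self.cell_rng(cell.id))
        spheres = [s for s in self.spheres if not s.removed]
        ca.integrate_motion(live, spheres, dt, motile, method=self.config.force_method)
        new_cells: list[ca.CellAgent] = []
        for cell in live:
            ca.update_volume(cell, dt)
            if cell.removed:
                continue
            result = ca.cycle_and_divide(
                cell, dt, self.cell_rng(cell.id), self._claim_id
            )
            if len(result) == 2:
                cell.removed = True  # replaced by daughters
                for d in result:
                    self._register_daughter(d)
                    new_cells.append(d)
        self.cells.extend(new_cells)
        if self.config.oxygen_substrate and self.grid is not None:
            for cell in self.cells:
                if cell.removed or cell.fate != "Proliferative":
                    continue
                before = cell.fate
                o2 = self.grid.sample(self.config.oxygen_substrate, cell.position)
                ca.oxygen_death_check(cell, o2)
                self._commit(cell, before)
        # ECM sphere degradation on contact
        if spheres and any(c.strain.ecm_degrade_rate > 0 for c in live):
            for cell in live:
                if cell.strain.ecm_degrade_rate <= 0 or cell.removed:
                    continue
                for sphere in spheres:
                    ca.degrade_passive_sphere(cell, sphere, dt)

    def _claim_id(self) -> int:
        cid = self._next_id
        self._next_id += 1
        return cid

    def _signalling_step(self) -> None:
        """Update every cell whose next signalling due-time has been reached.

        ``cell.signalling_offset`` holds the next due-time; each update
        simulates the Boolean chain for one full signalling window.
        """
        config = self.config
        dt = config.clock.dt_signalling
        neighbour_counts: dict[int, int] = {}
        if any(r.source == "contact-predicate" for r in config.input_rules):
            live = [c for c in self.cells if not c.removed]
            if live:
                from scipy.spatial import cKDTree

                positions = np.array([c.position for c in live])
                reach = 2.0 * max(c.radius for c in live)
                tree = cKDTree(positions)
                counts = tree.query_ball_point(positions, reach, return_length=True)
                neighbour_counts = {c.id: int(n) - 1 for c, n in zip(live, counts)}
        for cell in self.cells:
            if cell.removed or cell.network_state is None:
                continue
            if self.t + 1e-9 < cell.signalling_offset:
                continue
            net = self.networks[cell.strain.name]
            before = cell.fate
            sync_inputs(cell, self.grid, neighbour_counts.get(cell.id, 0),
                        config.input_rules, net)
            cell.network_state = advance(net, cell.network_state, dt, self.cell_rng(cell.id))
            apply_outputs(cell, config.output_rules, net)
            self._commit(cell, before)
            cell.signalling_offset += dt

    # -- main loop ---------------------------------------------------------

    def run(self) -> SimulationOutput:
        config = self.config
        clock = config.clock
        out = SimulationOutput(config.strains.keys())
        out.initial_viable = {
            name: sum(
                1 for c in self.cells
                if c.strain.name == name and c.fate == "Proliferative"
            )
            for name in config.strains
        }
        out.record(0.0, self.cells, self.committed)
        out.record_snapshot(0.0, self.cells, self.spheres)
        if clock.t_end <= 0:
            out.final_cells = [c for c in self.cells if not c.removed]
            return out

        n_mech = int(round(clock.t_end / clock.dt_mechanics))
        n_diff_per_mech = int(round(clock.dt_mechanics / clock.dt_diffusion))
        next_record = clock.snapshot_interval
        for step in range(1, n_mech + 1):
            if self.grid is not None:
                for sub in range(n_diff_per_mech):
                    self._diffusion_step(clock.dt_diffusion)
                    self.t = (step - 1) * clock.dt_mechanics + (sub + 1) * clock.dt_diffusion
            self.t = step * clock.dt_mechanics
            self._mechanics_step(clock.dt_mechanics)
            if config.network is not None:
                self._signalling_step()
            if self.t + 1e-9 >= next_record:
                out.record(self.t, self.cells, self.committed)
                out.record_snapshot(self.t, self.cells, self.spheres)
                next_record += clock.snapshot_interval
        if not math.isclose(self.t, next_record - clock.snapshot_interval, abs_tol=1e-6):
            out.record(self.t, self.cells, self.committed)
        out.final_cells = [c for c in self.cells if not c.removed]
        return out


def run(config: SimulationConfig) -> SimulationOutput:
    """Validate the configuration and execute the full multi-rate loop."""
    return Simulation(config).run()
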