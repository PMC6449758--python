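"""The TNF cell-fate case study.

Bundles three things: (1) a reconstructed death-receptor cell-fate Boolean
network (Survival / Apoptosis / NonACD read-outs, TNF as sole input, mRNA
intermediate nodes slowing NFkB-driven transcription), shipped as ordinary
model text files so the engine parses it like any user model; (2) a linear
three-pool receptor scheme (free ligand -> surface-bound -> internalised,
with clearance) that converts the local TNF concentration into the
internalised pool that switches the network's TNF input node; and (3)
NFkB-gated autocrine/paracrine TNF secretion into the cell's voxel.

The network fixture is a SYNTHETIC RECONSTRUCTION of the published
cell-fate topology with calibrated (not measured) rates; swap in real
model files via :func:`boolcell.boolean_engine.parse_network_files`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np

from . import cell_agents as ca
from . import coupling
from . import microenv as me
from .boolean_engine import (
    BooleanNetwork,
    RateOverride,
    overexpression,
    parse_network,
)

__all__ = [
    "ReceptorState",
    "receptor_update",
    "secretion_update",
    "build_cell_fate_network",
    "cell_fate_model_text",
    "activation_census",
    "default_input_rules",
    "default_output_rules",
    "MUTANT_PRESETS",
    "READOUTS",
]

READOUTS = ("Survival", "Apoptosis", "NonACD")

#: Names of the mRNA delay nodes in the bundled fixture.
MRNA_NODES = ("mXIAP", "mROS")

#: Over-expression preset genotypes (generic, config-composable).
MUTANT_PRESETS: dict[str, list[RateOverride]] = {
    "IKK+_cFLIP+": [overexpression("IKK"), overexpression("cFLIP")],
    "pro_apoptotic": [overexpression("CASP8")],
    "pro_nonacd": [overexpression("ROS")],
}


@dataclass
class ReceptorState:
    """Per-cell ligand pools (ng-equivalents) and kinetic constants (1/min)."""

    bound: float = 0.0
    internalised: float = 0.0
    k_on: float = 0.1
    k_int: float = 0.5
    k_clear: float = 0.05

    def __post_init__(self):
        if min(self.bound, self.internalised, self.k_on, self.k_int, self.k_clear) < 0:
            raise ValueError("receptor quantities and rates must be >= 0")


def receptor_update(
    rs: ReceptorState, local_conc: float, dt: float
) -> tuple[ReceptorState, float]:
    """One explicit-Euler step of the three-pool receptor kinetics.

    d(bound)/dt = k_on*c - k_int*bound;
    d(internalised)/dt = k_int*bound - k_clear*internalised.
    Returns the updated state and the amount taken up from the local
    medium (capped so the voxel density cannot go negative).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    uptaken = min(rs.k_on * local_conc * dt, local_conc)
    internalise = rs.k_int * rs.bound * dt
    new = ReceptorState(
        bound=rs.bound + uptaken - internalise,
        internalised=rs.internalised + internalise - rs.k_clear * rs.internalised * dt,
        k_on=rs.k_on,
        k_int=rs.k_int,
        k_clear=rs.k_clear,
    )
    return new, uptaken


def secretion_update(
    cell: ca.CellAgent, grid: me.VoxelGrid, dt: float, substrate: str = "TNF"
) -> None:
    """NFkB-gated TNF release: add rate*dt to the cell's voxel while secreting."""
    if not cell.secreting or cell.strain.tnf_secretion_rate <= 0:
        return
    idx = grid.voxel_index(cell.position)
    grid.fields[substrate][idx] += cell.strain.tnf_secretion_rate * dt


# --------------------------------------------------------------------------
# Bundled network fixture
# --------------------------------------------------------------------------

def cell_fate_model_text() -> tuple[str, str]:
    """The bundled model and configuration texts (reconstruction fixture)."""
    pkg = resources.files("boolcell") / "data"
    return (
        (pkg / "cellfate.bnd").read_text(),
        (pkg / "cellfate.cfg").read_text(),
    )


def build_cell_fate_network(transcription_rate_scale: float = 1.0) -> BooleanNetwork:
    """Parse the bundled cell-fate fixture, scaling mRNA transcription rates.

    ``transcription_rate_scale`` multiplies the activation rate of every
    mRNA node (mXIAP, mROS) relative to the calibrated baseline; raising
    it accelerates both XIAP-mediated apoptosis inhibition and ROS
    production, shifting the fate balance toward NonACD.
    """
    if transcription_rate_scale <= 0:
        raise ValueError("transcription_rate_scale must be > 0")
    model_text, config_text = cell_fate_model_text()
    net = parse_network(model_text, config_text)
    if transcription_rate_scale != 1.0:
        from .boolean_engine import apply_overrides

        net = apply_overrides(
            net,
            [
                RateOverride(name, rate_up=net.node(name).rate_up * transcription_rate_scale)
                for name in MRNA_NODES
            ],
        )
    return net


def default_input_rules(receptor: coupling.ReceptorParams | None = None) -> list[coupling.InputRule]:
    """TNF input node driven by the internalised ligand pool."""
    threshold = (receptor or coupling.ReceptorParams()).threshold
    return [coupling.InputRule(target="TNF", source="receptor-threshold", threshold=threshold)]


def default_output_rules(tnf_substrate: str = "TNF") -> list[coupling.OutputRule]:
    """Standard read-out wiring of the cell-fate model.

    Apoptosis / NonACD latch the corresponding death program; Survival
    gates cycling; NFkB activity switches on TNF secretion and marks the
    cell as (ever-)activated.
    """
    return [
        coupling.OutputRule(node="Apoptosis", action="set_fate_apoptosis", irreversible=True),
        coupling.OutputRule(node="NonACD", action="set_fate_nonacd", irreversible=True),
        coupling.OutputRule(node="Survival", action="mark_survival"),
        coupling.OutputRule(node="NFkB", action="enable_secretion", substrate=tnf_substrate),
    ]


def activation_census(
    cells: Sequence[ca.CellAgent], initial_viable: int
) -> float:
    """Fraction of ever-NFkB-activated cells relative to the initial census.

    Counts cells still present (not removed) whose activated flag is set,
    divided by the number of viable cells at t = 0.
    """
    if initial_viable <= 0:
        raise ValueError("initial viable count must be > 0")
    activated = sum(1 for c in cells if not c.removed and c.activated_flag)
    return activated / initial_viable
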