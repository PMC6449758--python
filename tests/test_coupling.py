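"""Tests for the multi-rate orchestration layer."""

import numpy as np
import pytest

from boolcell import boolean_engine as be
from boolcell import cell_agents as ca
from boolcell import coupling
from boolcell import microenv as me
from boolcell.tnf_model import default_input_rules, default_output_rules


def minimal_config(**kwargs):
    defaults = dict(
        network=None,
        strains={"WT": ca.StrainParams()},
        initial_cells=[("WT", (0.0, 0.0, 0.0))],
        clock=coupling.ClockConfig(0.5, 0.5, 10.0, 10.0, 10.0),
        dim=2,
        bounds_min=[-100] * 3,
        bounds_max=[100] * 3,
        seed=0,
    )
    defaults.update(kwargs)
    return coupling.SimulationConfig(**defaults)


class TestClockConfig:
    def test_defaults_valid(self):
        coupling.ClockConfig()

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(dt_diffusion=1.0, dt_mechanics=0.5),      # ordering violated
            dict(dt_mechanics=20.0, dt_signalling=10.0),   # ordering violated
            dict(dt_diffusion=0.3, dt_mechanics=1.0),      # not an integer multiple
            dict(dt_diffusion=0.0),
            dict(t_end=-1.0),
        ],
    )
    def test_invalid_clocks_rejected(self, kwargs):
        with pytest.raises(ValueError):
            coupling.ClockConfig(**kwargs)


class TestRules:
    def test_input_rule_must_target_input_node(self, cellfate_network):
        rule = coupling.InputRule(target="NFkB", source="receptor-threshold", threshold=0.1)
        with pytest.raises(ValueError, match="non-input"):
            coupling.validate_rules(cellfate_network, [rule], [])

    def test_unknown_nodes_rejected(self, cellfate_network):
        with pytest.raises(ValueError, match="Ghost"):
            coupling.validate_rules(
                cellfate_network,
                [coupling.InputRule(target="Ghost", source="receptor-threshold", threshold=1)],
                [],
            )
        with pytest.raises(ValueError, match="Ghost"):
            coupling.validate_rules(
                cellfate_network,
                [],
                [coupling.OutputRule(node="Ghost", action="mark_survival")],
            )

    def test_sync_inputs_threshold(self, cellfate_network):
        cell = ca.CellAgent(0, (0, 0, 0), ca.StrainParams(), network_state=None)
        cell.network_state = be.NetworkState(np.zeros(len(cellfate_network), dtype=np.uint8))
        rules = [coupling.InputRule(target="TNF", source="receptor-threshold", threshold=0.3)]
        cell.internalised_tnf = 0.0
        coupling.sync_inputs(cell, None, 0, rules, cellfate_network)
        assert cell.network_state.bits[cellfate_network.index["TNF"]] == 0
        cell.internalised_tnf = 0.31
        coupling.sync_inputs(cell, None, 0, rules, cellfate_network)
        assert cell.network_state.bits[cellfate_network.index["TNF"]] == 1

    def test_disjoint_rules_commute(self, fork_network):
        cell = ca.CellAgent(0, (0, 0, 0), ca.StrainParams())
        r1 = coupling.InputRule(target="X", source="receptor-threshold", threshold=0.1)
        cell.internalised_tnf = 1.0
        for order in ([r1], [r1]):
            cell.network_state = be.NetworkState(np.zeros(3, dtype=np.uint8))
            coupling.sync_inputs(cell, None, 0, order, fork_network)
            assert cell.network_state.bits[fork_network.index["X"]] == 1

    def test_apply_outputs_death_latches(self, cellfate_network):
        cell = ca.CellAgent(0, (0, 0, 0), ca.StrainParams())
        cell.network_state = be.NetworkState(np.zeros(len(cellfate_network), dtype=np.uint8))
        rules = default_output_rules()
        idx = cellfate_network.index["Apoptosis"]
        cell.network_state.bits[idx] = 1
        coupling.apply_outputs(cell, rules, cellfate_network)
        assert cell.fate == "Apoptosis"
        cell.network_state.bits[idx] = 0  # node decays later; the fate must not
        coupling.apply_outputs(cell, rules, cellfate_network)
        assert cell.fate == "Apoptosis"

    def test_nfkb_secretion_reversible_activation_latched(self, cellfate_network):
        cell = ca.CellAgent(0, (0, 0, 0), ca.StrainParams())
        cell.network_state = be.NetworkState(np.zeros(len(cellfate_network), dtype=np.uint8))
        rules = default_output_rules()
        idx = cellfate_network.index["NFkB"]
        cell.network_state.bits[idx] = 1
        coupling.apply_outputs(cell, rules, cellfate_network)
        assert cell.secreting and cell.activated_flag
        cell.network_state.bits[idx] = 0
        coupling.apply_outputs(cell, rules, cellfate_network)
        assert not cell.secreting
        assert cell.activated_flag  # transient activation is remembered

    def test_all_readouts_zero_is_identity(self, cellfate_network):
        cell = ca.CellAgent(0, (0, 0, 0), ca.StrainParams())
        cell.network_state = be.NetworkState(np.zeros(len(cellfate_network), dtype=np.uint8))
        cell.cycling_enabled = False
        coupling.apply_outputs(cell, default_output_rules(), cellfate_network)
        assert cell.fate == "Proliferative" and not cell.secreting and not cell.activated_flag


class TestRun:
    def test_t_end_zero_gives_initial_census_only(self):
        out = coupling.run(minimal_config(clock=coupling.ClockConfig(0.5, 0.5, 10.0, 0.0, 10.0)))
        assert list(out.times()) == [0.0]
        assert out.total_count(0.0) == 1

    def test_identical_seed_bitwise_identical_output(self, cellfate_network, tmp_path):
        def one_run(path):
            config = minimal_config(
                network=cellfate_network,
                initial_cells=[("WT", (x * 15.0, 0.0, 0.0)) for x in range(5)],
                clock=coupling.ClockConfig(0.5, 0.5, 10.0, 120.0, 60.0),
                substrates=[me.SubstrateSpec("TNF", 1200.0, 0.0275)],
                schedules={"TNF": me.InjectionSchedule("continuous", 1.0)},
                input_rules=default_input_rules(),
                output_rules=default_output_rules(),
                seed=42,
            )
            out = coupling.run(config)
            out.write_population_csv(path)
            return path.read_bytes()

        assert one_run(tmp_path / "a.csv") == one_run(tmp_path / "b.csv")

    def test_fate_transitions_form_a_dag(self, cellfate_network):
        config = minimal_config(
            network=cellfate_network,
            initial_cells=[("WT", (x * 12.0 - 40.0, 0.0, 0.0)) for x in range(8)],
            clock=coupling.ClockConfig(0.5, 0.5, 10.0, 360.0, 60.0),
            substrates=[me.SubstrateSpec("TNF", 1200.0, 0.0275)],
            schedules={"TNF": me.InjectionSchedule("continuous", 2.0)},
            input_rules=default_input_rules(),
            output_rules=default_output_rules(),
            seed=7,
        )
        sim = coupling.Simulation(config)
        clock = config.clock
        n_steps = int(clock.t_end / clock.dt_mechanics)
        fate_history: dict[int, list[str]] = {}
        for step in range(1, n_steps + 1):
            for _ in range(int(clock.dt_mechanics / clock.dt_diffusion)):
                sim._diffusion_step(clock.dt_diffusion)
            sim.t = step * clock.dt_mechanics
            sim._mechanics_step(clock.dt_mechanics)
            sim._signalling_step()
            for cell in sim.cells:
                hist = fate_history.setdefault(cell.id, [])
                if not hist or hist[-1] != cell.fate:
                    hist.append(cell.fate)
        for hist in fate_history.values():
            # once a death fate appears it must be the final entry
            for fate in ("Apoptosis", "NonACD"):
                if fate in hist:
                    assert hist[-1] == fate
                    assert hist.count(fate) == 1

    def test_decoupled_cells_ignore_substrates(self, cellfate_network):
        """With no input rules the population dynamics are substrate-independent."""
        def census(initial_density):
            config = minimal_config(
                network=cellfate_network,
                initial_cells=[("WT", (x * 15.0, 0.0, 0.0)) for x in range(5)],
                clock=coupling.ClockConfig(0.5, 0.5, 10.0, 240.0, 60.0),
                substrates=[me.SubstrateSpec("TNF", 1200.0, 0.0275)],
                initial_densities={"TNF": initial_density},
                input_rules=[],
                output_rules=default_output_rules(),
                seed=11,
            )
            return coupling.run(config).population

        a, b = census(0.0), census(5.0)
        assert a.equals(b)

    def test_signalling_updates_track_the_clock(self, cellfate_network):
        config = minimal_config(
            network=cellfate_network,
            clock=coupling.ClockConfig(0.5, 0.5, 10.0, 100.0, 50.0),
            seed=3,
        )
        sim = coupling.Simulation(config)
        out = sim.run()
        for cell in out.final_cells:
            # next due time is within one signalling window of the end time
            assert cell.signalling_offset > sim.t - 1e-9
            assert cell.signalling_offset <= sim.t + config.clock.dt_signalling + 1e-9

    def test_mixture_with_unknown_strain_rejected(self):
        with pytest.raises(ValueError, match="unknown strain"):
            coupling.run(minimal_config(initial_cells=[("Nope", (0, 0, 0))]))

    def test_strain_override_with_unknown_node_rejected(self, cellfate_network):
        strain = ca.StrainParams(rate_overrides=[be.RateOverride("Ghost", rate_up=1.0)])
        with pytest.raises(ValueError, match="Ghost"):
            coupling.run(minimal_config(network=cellfate_network, strains={"WT": strain}))


def test_contact_predicate_input_rule():
    """A contact-driven input node reads the local neighbour count."""
    net = be.parse_network(
        "Contact { logic = Contact; rate_up=0; rate_down=0; }\n"
        "Out { logic = Contact; rate_up = 100; rate_down = 100; }",
        "Contact.is_input = TRUE;",
    )
    rule = coupling.InputRule(target="Contact", source="contact-predicate", threshold=1)
    config = minimal_config(
        network=net,
        strains={"WT": ca.StrainParams()},
        initial_cells=[("WT", (0.0, 0.0, 0.0)), ("WT", (10.0, 0.0, 0.0)),
                       ("WT", (80.0, 0.0, 0.0))],
        clock=coupling.ClockConfig(0.5, 0.5, 10.0, 20.0, 10.0),
        input_rules=[rule],
        output_rules=[],
        stagger_signalling=False,
        seed=5,
    )
    sim = coupling.Simulation(config)
    out = sim.run()
    touching = [c for c in out.final_cells if c.position[0] < 40]
    isolated = [c for c in out.final_cells if c.position[0] >= 40]
    idx = net.index["Contact"]
    assert all(c.network_state.bits[idx] == 1 for c in touching)
    assert all(c.network_state.bits[idx] == 0 for c in isolated)


def test_every_cell_id_is_accounted_for(cellfate_network):
    """Present + removed cells cover every id ever created."""
    config = minimal_config(
        network=cellfate_network,
        initial_cells=[("WT", (x * 12.0 - 40.0, 0.0, 0.0)) for x in range(8)],
        clock=coupling.ClockConfig(0.5, 0.5, 10.0, 480.0, 120.0),
        substrates=[me.SubstrateSpec("TNF", 1200.0, 0.0275)],
        schedules={"TNF": me.InjectionSchedule("continuous", 2.0)},
        input_rules=default_input_rules(),
        output_rules=default_output_rules(),
        seed=13,
    )
    sim = coupling.Simulation(config)
    sim.run()
    ids = {c.id for c in sim.cells}
    assert ids == set(range(sim._next_id))
    present = sum(1 for c in sim.cells if not c.removed)
    removed = sum(1 for c in sim.cells if c.removed)
    assert present + removed == sim._next_id
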