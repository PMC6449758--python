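"""Unit and property tests for the stochastic Boolean network engine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boolcell import boolean_engine as be


# --------------------------------------------------------------------------
# Parsing
# --------------------------------------------------------------------------

class TestParsing:
    def test_minimal_node_with_symbolic_rate(self):
        net = be.parse_network("A { logic=1; rate_up=$u; rate_down=0; }", "$u=0.5;")
        assert net.names == ["A"]
        assert net.node("A").rate_up == 0.5
        assert net.node("A").rate_down == 0.0

    def test_maboss_style_conditional_rates(self):
        net = be.parse_network(
            "node A { logic = B; rate_up = @logic ? $u : 0; rate_down = @logic ? 0 : 1.5; }\n"
            "node B { logic = 1; rate_up = 1; rate_down = 0; }",
            "$u = 2.0;",
        )
        assert net.node("A").rate_up == 2.0
        assert net.node("A").rate_down == 1.5

    def test_undeclared_reference_names_the_node(self):
        with pytest.raises(be.NetworkParseError, match="Z"):
            be.parse_network("A { logic = Z; rate_up=1; rate_down=1; }", "")

    def test_duplicate_node_rejected(self):
        text = "A { logic=1; rate_up=1; rate_down=0; }\nA { logic=0; rate_up=1; rate_down=0; }"
        with pytest.raises(be.NetworkParseError, match="duplicate"):
            be.parse_network(text, "")

    def test_unresolved_rate_symbol_is_config_error(self):
        with pytest.raises(be.NetworkConfigError, match=r"\$u"):
            be.parse_network("A { logic=1; rate_up=$u; rate_down=0; }", "")

    def test_negative_rate_rejected(self):
        with pytest.raises(be.NetworkParseError):
            be.NodeSpec("A", ("const", 1), rate_up=-1.0)

    def test_config_flags_and_istate(self):
        net = be.parse_network(
            "A { logic=1; rate_up=1; rate_down=0; }\nB { logic=A; rate_up=1; rate_down=1; }",
            "A.is_input = TRUE;\nA.istate = 1;\nB.is_internal = TRUE;",
        )
        assert net.node("A").is_input
        assert net.node("B").is_internal
        assert net.initial_probabilities[net.index["A"]] == 1.0
        assert net.readout_names == []

    def test_cellfate_fixture_readouts(self, cellfate_network):
        assert set(cellfate_network.readout_names) == {"Survival", "Apoptosis", "NonACD"}
        assert cellfate_network.input_names == ["TNF"]
        for name in ("mXIAP", "mROS"):
            assert name in cellfate_network.index

    def test_logic_operators_all_spellings(self):
        net = be.parse_network(
            "A { logic = (B & C) | (!B && D) OR NOT C; rate_up=1; rate_down=1; }\n"
            "B { logic=1; rate_up=1; rate_down=0; }\n"
            "C { logic=1; rate_up=1; rate_down=0; }\n"
            "D { logic=0; rate_up=0; rate_down=1; }",
            "",
        )
        assert be.logic_variables(net.node("A").logic) == {"B", "C", "D"}


# --------------------------------------------------------------------------
# Transition rates
# --------------------------------------------------------------------------

@pytest.fixture(scope="module")
def two_node_net():
    return be.parse_network(
        "A { logic = A; rate_up=0; rate_down=0; }\n"
        "B { logic = A; rate_up = 2; rate_down = 1; }",
        "A.is_input = TRUE;",
    )


class TestTransitionRate:
    @pytest.mark.parametrize(
        "active, expected",
        [(["A"], 2.0), ([], 0.0), (["A", "B"], 0.0), (["B"], 1.0)],
    )
    def test_definition(self, two_node_net, active, expected):
        s = two_node_net.state_from(active)
        assert be.transition_rate(two_node_net, s, "B") == expected

    def test_input_node_has_no_transition(self, two_node_net):
        with pytest.raises(ValueError, match="input"):
            be.transition_rate(two_node_net, two_node_net.zero_state(), "A")


# --------------------------------------------------------------------------
# Gillespie kernel
# --------------------------------------------------------------------------

class TestGillespie:
    def test_absorbing_state_waits_forever(self, rng):
        net = be.parse_network("A { logic=A; rate_up=1; rate_down=0; }", "")
        s = net.state_from(["A"])  # logic satisfied, no transition
        s2, wait = be.gillespie_step(net, s, rng)
        assert wait == math.inf and s2 == s

    def test_waiting_time_is_exponential(self, rng):
        u = 0.5
        net = be.parse_network(f"A {{ logic=1; rate_up={u}; rate_down=0; }}", "")
        waits = np.array(
            [be.gillespie_step(net, net.zero_state(), rng)[1] for _ in range(10_000)]
        )
        se = waits.std() / math.sqrt(len(waits))
        assert abs(waits.mean() - 1 / u) < 3 * se

    def test_fork_fires_proportionally_to_rates(self, fork_network, rng):
        first_a = 0
        n = 4000
        for _ in range(n):
            s = fork_network.state_from(["X"])
            s2, _ = be.gillespie_step(fork_network, s, rng)
            first_a += int(s2.bits[fork_network.index["A"]])
        p = first_a / n
        se = math.sqrt(2 / 3 * 1 / 3 / n)
        assert abs(p - 2 / 3) < 4 * se

    def test_exactly_one_bit_flips(self, fork_network, rng):
        s = fork_network.state_from(["X"])
        s2, _ = be.gillespie_step(fork_network, s, rng)
        assert int(np.sum(s.bits ^ s2.bits)) == 1


class TestAdvance:
    def test_zero_window_is_identity(self, fork_network, rng):
        s = fork_network.state_from(["X"])
        assert be.advance(fork_network, s, 0.0, rng) == s

    def test_one_node_activation_probability(self, rng):
        u, t, n = 0.2, 5.0, 10_000
        net = be.parse_network(f"A {{ logic=1; rate_up={u}; rate_down=0; }}", "")
        hits = sum(
            int(be.advance(net, net.zero_state(), t, rng).bits[0]) for _ in range(n)
        )
        p_exact = 1 - math.exp(-u * t)
        se = math.sqrt(p_exact * (1 - p_exact) / n)
        assert abs(hits / n - p_exact) < 4 * se

    def test_absorbing_state_never_leaves(self, rng):
        net = be.parse_network("A { logic=A; rate_up=1; rate_down=0; }", "")
        s = net.state_from(["A"])
        for window in (1.0, 100.0, 1e6):
            assert be.advance(net, s, window, rng) == s

    def test_seed_determinism(self, fork_network):
        s = fork_network.state_from(["X"])
        a = be.advance(fork_network, s, 50.0, np.random.default_rng(7))
        b = be.advance(fork_network, s, 50.0, np.random.default_rng(7))
        assert a == b

    def test_asynchrony_along_trajectory(self, cellfate_network):
        rng = np.random.default_rng(5)
        s = cellfate_network.state_from(["TNF", "ATP", "Survival"])
        previous = s
        for _ in range(100):
            nxt, wait = be.gillespie_step(cellfate_network, previous, rng)
            if wait == math.inf:
                break
            assert int(np.sum(previous.bits ^ nxt.bits)) == 1
            previous = nxt


# --------------------------------------------------------------------------
# Ensembles
# --------------------------------------------------------------------------

class TestEnsembleFates:
    def test_single_always_on_readout(self, rng):
        net = be.parse_network("Win { logic=1; rate_up=10; rate_down=0; }", "")
        fd = be.ensemble_fates(net, None, 10.0, 500, rng, readout_priority=["Win"])
        assert fd["Win"] == 1.0

    def test_fork_long_horizon_matches_competing_exponentials(self, fork_network, rng):
        fd = be.ensemble_fates(
            fork_network, None, 200.0, 10_000, rng,
            readout_priority=["A", "B"], pinned={"X": 1},
        )
        se = math.sqrt(2 / 9 / fd.n)
        assert abs(fd["A"] - 2 / 3) < 4 * se
        assert fd["A"] + fd["B"] == pytest.approx(1.0)

    def test_probabilities_sum_to_one(self, cellfate_network, rng):
        fd = be.ensemble_fates(cellfate_network, None, 300.0, 500, rng, pinned={"TNF": 1})
        assert sum(fd.probabilities.values()) == pytest.approx(1.0, abs=1e-12)

    def test_invalid_trajectory_count(self, fork_network, rng):
        with pytest.raises(ValueError):
            be.ensemble_fates(fork_network, None, 1.0, 0, rng)


class TestOverrides:
    def test_overexpression_wins_regardless_of_logic(self, rng):
        net = be.parse_network("A { logic=0; rate_up=0; rate_down=1; }", "")
        mutant = be.apply_overrides(net, [be.overexpression("A")])
        on = sum(int(be.advance(mutant, mutant.zero_state(), 1.0, rng).bits[0])
                 for _ in range(2000))
        assert on / 2000 >= 0.999

    def test_knockout_pins_at_zero(self, rng):
        net = be.parse_network("A { logic=1; rate_up=5; rate_down=0; }", "")
        mutant = be.apply_overrides(net, [be.knockout("A")])
        s = be.advance(mutant, mutant.state_from(["A"]), 5.0, rng)
        assert s.bits[0] == 0

    def test_empty_override_list_is_identity(self, cellfate_network):
        out = be.apply_overrides(cellfate_network, [])
        assert [n.rate_up for n in out.nodes] == [n.rate_up for n in cellfate_network.nodes]

    def test_unknown_node_rejected(self, cellfate_network):
        with pytest.raises(KeyError, match="NotANode"):
            be.apply_overrides(cellfate_network, [be.RateOverride("NotANode", rate_up=1.0)])

    def test_overrides_compose_last_wins(self, cellfate_network):
        out = be.apply_overrides(
            cellfate_network,
            [be.RateOverride("IKK", rate_up=5.0), be.RateOverride("IKK", rate_up=7.0)],
        )
        assert out.node("IKK").rate_up == 7.0
        assert out.node("IKK").logic == cellfate_network.node("IKK").logic

    def test_plain_rate_override_stays_logic_gated(self, rng):
        net = be.parse_network("A { logic=0; rate_up=1; rate_down=0; }", "")
        scaled = be.apply_overrides(net, [be.RateOverride("A", rate_up=100.0)])
        s = be.advance(scaled, scaled.zero_state(), 10.0, rng)
        assert s.bits[0] == 0  # logic target is 0: no activation despite the huge rate


# --------------------------------------------------------------------------
# Master-equation cross-check (small chain)
# --------------------------------------------------------------------------

def test_master_equation_matches_gillespie_small_net(fork_network):
    rng = np.random.default_rng(99)
    t = 0.7
    n = 10_000
    init = np.tile(fork_network.state_from(["X"]).bits, (n, 1))
    final = be.simulate_ensemble(fork_network, init, t, rng)
    exact = be.master_equation_distribution(
        fork_network, fork_network.state_from(["X"]), t
    )
    for state, p in exact.items():
        empirical = np.mean(np.all(final == np.array(state), axis=1))
        se = math.sqrt(max(p * (1 - p), 1e-12) / n)
        assert abs(empirical - p) < 3 * se + 1e-9


# --------------------------------------------------------------------------
# Property tests
# --------------------------------------------------------------------------

@settings(max_examples=25, deadline=None)
@given(bits=st.lists(st.integers(0, 1), min_size=3, max_size=3), seed=st.integers(0, 10_000))
def test_trajectories_deterministic_and_asynchronous(fork_network, bits, seed):
    """Identical seeds give identical trajectories; states flip one bit at a time."""
    s = be.NetworkState(np.array(bits, dtype=np.uint8))
    a = be.advance(fork_network, s, 30.0, np.random.default_rng(seed))
    b = be.advance(fork_network, s, 30.0, np.random.default_rng(seed))
    assert a == b


def test_fate_table_csv(tmp_path, fork_network, rng):
    fd = be.ensemble_fates(fork_network, None, 50.0, 200, rng,
                           readout_priority=["A", "B"], pinned={"X": 1})
    path = tmp_path / "fates.csv"
    fd.write_csv(path)
    lines = path.read_text().strip().splitlines()
    assert lines[0] == "fate,probability,n"
    assert len(lines) >= 2
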