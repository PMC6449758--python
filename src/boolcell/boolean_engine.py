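"""Stochastic continuous-time Boolean networks.

A Boolean network here is a set of binary variables (genes, proteins,
protein activities) connected by logic rules over AND/OR/NOT.  Instead of
synchronous discrete updates, the network is simulated as a continuous-time
Markov chain on the state transition graph: a node whose logic rule
disagrees with its current value flips with an exponential waiting time
governed by its ``rate_up`` (activation) or ``rate_down`` (deactivation)
rate.  Exactly one node changes per transition (asynchronous update), and
states with no applicable transition are absorbing.

Models are written in a documented subset of the MaBoSS two-file dialect:
a ``.bnd`` file declaring node blocks (``logic``, ``rate_up``,
``rate_down``) and a ``.cfg`` file assigning ``$``-prefixed rate symbols,
``is_internal`` / ``is_input`` flags and initial-state probabilities.
See :func:`parse_network` for the grammar.

Input nodes are pinned by the caller (typically the environment coupling
layer) and contribute no transitions of their own.  Mutations are expressed
as :class:`RateOverride` objects that replace a node's transition rates
without touching the logic — e.g. over-expression is a huge activation rate
with zero deactivation.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "BooleanNetwork",
    "NodeSpec",
    "NetworkState",
    "RateOverride",
    "FateDistribution",
    "NetworkParseError",
    "NetworkConfigError",
    "parse_network",
    "parse_network_files",
    "transition_rate",
    "gillespie_step",
    "advance",
    "ensemble_fates",
    "apply_overrides",
    "OVEREXPRESSION_RATE",
    "overexpression",
    "knockout",
]

#: Activation rate used to model over-expression: effectively instantaneous
#: on the signalling time scale (>= 1e4 x any physiological rate, 1/min).
OVEREXPRESSION_RATE = 1.0e6

#: Default priority used to classify a trajectory when several read-out
#: nodes are active simultaneously.  Death read-outs are irreversible, so
#: they outrank survival; apoptosis commits faster and outranks NonACD.
DEFAULT_READOUT_PRIORITY = ("Apoptosis", "NonACD", "Survival")


class NetworkParseError(ValueError):
    """Raised for syntax or semantic errors in a model (.bnd) text."""


class NetworkConfigError(ValueError):
    """Raised for errors in a configuration (.cfg) text."""


# --------------------------------------------------------------------------
# Logic expressions
# --------------------------------------------------------------------------
# ASTs are plain tuples: ("var", name) | ("const", 0 | 1)
# | ("not", x) | ("and", a, b) | ("or", a, b)

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+|//[^\n]*|\#[^\n]*|/\*.*?\*/)
  | (?P<num>\d+(\.\d*)?([eE][-+]?\d+)?|\.\d+([eE][-+]?\d+)?)
  | (?P<sym>\$[A-Za-z_]\w*)
  | (?P<at>@[A-Za-z_]\w*)
  | (?P<name>[A-Za-z_]\w*)
  | (?P<op>&&|\|\||[&|!{}();=?:.\[\],])
    """,
    re.VERBOSE | re.DOTALL,
)


def _tokenize(text: str, err: type[ValueError]) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            snippet = text[pos : pos + 20].splitlines()[0]
            raise err(f"unexpected character at {snippet!r}")
        pos = m.end()
        kind = m.lastgroup
        if kind == "ws":
            continue
        tokens.append((kind, m.group()))
    tokens.append(("eof", ""))
    return tokens


class _TokenStream:
    def __init__(self, tokens: list[tuple[str, str]], err: type[ValueError]):
        self.tokens = tokens
        self.i = 0
        self.err = err

    def peek(self) -> tuple[str, str]:
        return self.tokens[self.i]

    def next(self) -> tuple[str, str]:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, value: str) -> tuple[str, str]:
        kind, text = self.next()
        if text != value:
            raise self.err(f"expected {value!r}, found {text or 'end of input'!r}")
        return kind, text


def _parse_or(ts: _TokenStream):
    node = _parse_and(ts)
    while ts.peek()[1] in ("|", "||") or ts.peek()[1].upper() == "OR":
        ts.next()
        node = ("or", node, _parse_and(ts))
    return node


def _parse_and(ts: _TokenStream):
    node = _parse_not(ts)
    while ts.peek()[1] in ("&", "&&") or ts.peek()[1].upper() == "AND":
        ts.next()
        node = ("and", node, _parse_not(ts))
    return node


def _parse_not(ts: _TokenStream):
    if ts.peek()[1] == "!" or ts.peek()[1].upper() == "NOT":
        ts.next()
        return ("not", _parse_not(ts))
    return _parse_atom(ts)


def _parse_atom(ts: _TokenStream):
    kind, text = ts.next()
    if text == "(":
        node = _parse_or(ts)
        ts.expect(")")
        return node
    if kind == "num":
        if text not in ("0", "1"):
            raise ts.err(f"logic constants must be 0 or 1, found {text!r}")
        return ("const", int(text))
    if kind == "name":
        upper = text.upper()
        if upper == "TRUE":
            return ("const", 1)
        if upper == "FALSE":
            return ("const", 0)
        return ("var", text)
    raise ts.err(f"unexpected token {text or 'end of input'!r} in logic expression")


def parse_logic(text: str) -> tuple:
    """Parse a Boolean expression (AND/OR/NOT over node names) to an AST."""
    ts = _TokenStream(_tokenize(text, NetworkParseError), NetworkParseError)
    node = _parse_or(ts)
    if ts.peek()[0] != "eof":
        raise NetworkParseError(f"trailing input after logic expression: {ts.peek()[1]!r}")
    return node


def logic_variables(ast: tuple) -> set[str]:
    op = ast[0]
    if op == "var":
        return {ast[1]}
    if op == "const":
        return set()
    out: set[str] = set()
    for child in ast[1:]:
        out |= logic_variables(child)
    return out


def _emit(ast: tuple, fmt: Callable[[int], str], index: Mapping[str, int]) -> str:
    op = ast[0]
    if op == "var":
        return fmt(index[ast[1]])
    if op == "const":
        return str(ast[1])
    if op == "not":
        return f"({_emit(ast[1], fmt, index)}^1)"
    sym = "&" if op == "and" else "|"
    return f"({_emit(ast[1], fmt, index)}{sym}{_emit(ast[2], fmt, index)})"


def logic_to_str(ast: tuple) -> str:
    op = ast[0]
    if op == "var":
        return ast[1]
    if op == "const":
        return str(ast[1])
    if op == "not":
        return f"!{logic_to_str(ast[1])}"
    sym = " & " if op == "and" else " | "
    return "(" + sym.join(logic_to_str(c) for c in ast[1:]) + ")"


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NodeSpec:
    """One Boolean variable: its logic rule and transition rates (1/min)."""

    name: str
    logic: tuple
    rate_up: float = 1.0
    rate_down: float = 1.0
    is_internal: bool = False
    is_input: bool = False
    # set by unconditional rate overrides: the rate fires irrespective of
    # the logic target (constitutive over-expression / knockout)
    force_up: bool = False
    force_down: bool = False

    def __post_init__(self):
        for label, rate in (("rate_up", self.rate_up), ("rate_down", self.rate_down)):
            if not math.isfinite(rate) or rate < 0:
                raise NetworkParseError(
                    f"node {self.name!r}: {label} must be finite and >= 0, got {rate}"
                )


@dataclass(frozen=True)
class RateOverride:
    """Replacement transition rates for one node (a mutation).

    ``None`` leaves the corresponding rate unchanged.  Overrides compose
    left-to-right; the last one naming a node wins.  With ``unconditional``
    set, the overridden rates fire regardless of the node's logic target —
    the encoding of constitutive over-expression or knockout, where the
    mutated gene escapes its normal regulation without touching the
    network structure.
    """

    node: str
    rate_up: float | None = None
    rate_down: float | None = None
    unconditional: bool = False

    def __post_init__(self):
        if self.rate_up is None and self.rate_down is None:
            raise ValueError(f"override for {self.node!r} specifies neither rate")


def overexpression(node: str) -> RateOverride:
    """Pin a node at 1 regardless of its logic: huge activation, no deactivation."""
    return RateOverride(node, rate_up=OVEREXPRESSION_RATE, rate_down=0.0, unconditional=True)


def knockout(node: str) -> RateOverride:
    """Pin a node at 0 regardless of its logic: no activation, huge deactivation."""
    return RateOverride(node, rate_up=0.0, rate_down=OVEREXPRESSION_RATE, unconditional=True)


class NetworkState:
    """Bit vector of node activities plus elapsed internal time (minutes)."""

    __slots__ = ("bits", "time")

    def __init__(self, bits: Sequence[int] | np.ndarray, time: float = 0.0):
        self.bits = np.asarray(bits, dtype=np.uint8).copy()
        if self.bits.ndim != 1:
            raise ValueError("state must be one-dimensional")
        if not np.all((self.bits == 0) | (self.bits == 1)):
            raise ValueError("state entries must be 0 or 1")
        self.time = float(time)

    def copy(self) -> "NetworkState":
        return NetworkState(self.bits, self.time)

    def __len__(self) -> int:
        return len(self.bits)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, NetworkState)
            and len(self.bits) == len(other.bits)
            and bool(np.all(self.bits == other.bits))
        )

    def __repr__(self) -> str:
        return f"NetworkState({self.bits.tolist()}, time={self.time:g})"


@dataclass
class FateDistribution:
    """Empirical probabilities of each read-out fate in an ensemble."""

    probabilities: dict[str, float]
    n: int

    def __post_init__(self):
        total = sum(self.probabilities.values())
        if any(p < 0 for p in self.probabilities.values()) or abs(total - 1.0) > 1e-12:
            raise ValueError(f"fate probabilities must be >= 0 and sum to 1, got {total}")

    def __getitem__(self, fate: str) -> float:
        return self.probabilities.get(fate, 0.0)

    def to_rows(self) -> list[tuple[str, float, int]]:
        return [(fate, p, self.n) for fate, p in sorted(self.probabilities.items())]

    def write_csv(self, path) -> None:
        """Write the fate table as CSV with columns fate, probability, n."""
        with open(path, "w") as fh:
            fh.write("fate,probability,n\n")
            for fate, p, n in self.to_rows():
                fh.write(f"{fate},{p!r},{n}\n")


class BooleanNetwork:
    """An ordered collection of :class:`NodeSpec` with a name->index table."""

    def __init__(self, nodes: Iterable[NodeSpec],
                 initial_probabilities: Mapping[str, float] | None = None):
        self.nodes: list[NodeSpec] = list(nodes)
        self.index: dict[str, int] = {}
        for i, node in enumerate(self.nodes):
            if node.name in self.index:
                raise NetworkParseError(f"duplicate node {node.name!r}")
            self.index[node.name] = i
        for node in self.nodes:
            for ref in logic_variables(node.logic):
                if ref not in self.index:
                    raise NetworkParseError(
                        f"logic of node {node.name!r} references undeclared node {ref!r}"
                    )
        self.initial_probabilities = np.zeros(len(self.nodes))
        for name, p in (initial_probabilities or {}).items():
            if name not in self.index:
                raise NetworkConfigError(f"istate for undeclared node {name!r}")
            if not 0.0 <= p <= 1.0:
                raise NetworkConfigError(f"istate for {name!r} must be in [0,1], got {p}")
            self.initial_probabilities[self.index[name]] = p
        self._compiled: _Compiled | None = None

    # -- introspection -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, name: str) -> NodeSpec:
        try:
            return self.nodes[self.index[name]]
        except KeyError:
            raise KeyError(f"unknown node {name!r}") from None

    @property
    def names(self) -> list[str]:
        return [n.name for n in self.nodes]

    @property
    def input_names(self) -> list[str]:
        return [n.name for n in self.nodes if n.is_input]

    @property
    def readout_names(self) -> list[str]:
        """Nodes that are neither internal nor inputs: the fate read-outs."""
        return [n.name for n in self.nodes if not n.is_internal and not n.is_input]

    # -- state helpers -----------------------------------------------------

    def zero_state(self) -> NetworkState:
        return NetworkState(np.zeros(len(self.nodes), dtype=np.uint8))

    def state_from(self, active: Iterable[str]) -> NetworkState:
        s = self.zero_state()
        for name in active:
            s.bits[self.index[name]] = 1
        return s

    def sample_initial_states(self, n: int, rng: np.random.Generator,
                              pinned: Mapping[str, int] | None = None) -> np.ndarray:
        """Draw n initial states from the per-node Bernoulli distribution."""
        probs = self.initial_probabilities
        states = (rng.random((n, len(self.nodes))) < probs).astype(np.uint8)
        for name, value in (pinned or {}).items():
            states[:, self.index[name]] = value
        return states

    # -- compilation -------------------------------------------------------

    @property
    def compiled(self) -> "_Compiled":
        if self._compiled is None:
            self._compiled = _Compiled(self)
        return self._compiled


class _Compiled:
    """Rate arrays and codegen'd target-value evaluators for a network.

    The logic of every node is translated once into a Python function that
    computes, for each node, the value it is being driven toward.  Two
    variants are generated: a scalar one over a 1-D uint8 state vector and
    a vectorised one over an (n_trajectories, n_nodes) matrix.
    """

    def __init__(self, net: BooleanNetwork):
        n = len(net)
        self.rate_up = np.array([node.rate_up for node in net.nodes])
        self.rate_down = np.array([node.rate_down for node in net.nodes])
        self.is_input = np.array([node.is_input for node in net.nodes], dtype=bool)
        self.force_up = np.array([node.force_up for node in net.nodes], dtype=bool)
        self.force_down = np.array([node.force_down for node in net.nodes], dtype=bool)
        idx = net.index

        scalar_lines = ["def _targets(s, out):"]
        vector_lines = ["def _targets_v(S, out):"]
        for i, node in enumerate(net.nodes):
            if node.is_input:
                scalar_lines.append(f"    out[{i}] = s[{i}]")
                vector_lines.append(f"    out[:, {i}] = S[:, {i}]")
            else:
                scalar_lines.append(
                    f"    out[{i}] = " + _emit(node.logic, lambda j: f"s[{j}]", idx)
                )
                vector_lines.append(
                    f"    out[:, {i}] = " + _emit(node.logic, lambda j: f"S[:, {j}]", idx)
                )
        scalar_lines.append("    return out")
        vector_lines.append("    return out")
        ns: dict = {}
        exec("\n".join(scalar_lines), ns)
        exec("\n".join(vector_lines), ns)
        self.targets = ns["_targets"]
        self.targets_vector = ns["_targets_v"]
        self._scratch = np.empty(n, dtype=np.uint8)

    def rates(self, bits: np.ndarray) -> np.ndarray:
        """Per-node transition propensities in the given state."""
        t = self.targets(bits, self._scratch)
        out = np.where(bits == 0, self.rate_up, self.rate_down)
        forced = np.where(bits == 0, self.force_up, self.force_down)
        out[(t == bits) & ~forced] = 0.0
        out[self.is_input] = 0.0
        return out

    def rates_vector(self, states: np.ndarray, scratch: np.ndarray) -> np.ndarray:
        t = self.targets_vector(states, scratch)
        out = np.where(states == 0, self.rate_up, self.rate_down)
        forced = np.where(states == 0, self.force_up, self.force_down)
        out[(t == states) & ~forced] = 0.0
        out[:, self.is_input] = 0.0
        return out


# --------------------------------------------------------------------------
# Parsing the two-file dialect
# --------------------------------------------------------------------------

def _parse_rate_value(ts: _TokenStream, which: str, node: str):
    """Parse a rate right-hand side: NUM, $sym, or ``@logic ? a : b``.

    The conditional form is accepted only in the standard shapes
    ``rate_up = @logic ? r : 0`` and ``rate_down = @logic ? 0 : r``,
    which coincide with this engine's semantics (the rate applies when the
    node is off its logic target).
    """

    def simple():
        kind, text = ts.next()
        if kind == "num":
            return float(text)
        if kind == "sym":
            return text  # resolved later from the config
        raise NetworkParseError(f"node {node!r}: bad {which} value {text!r}")

    if ts.peek()[0] == "at":
        _, at = ts.next()
        if at != "@logic":
            raise NetworkParseError(f"node {node!r}: unsupported reference {at!r}")
        ts.expect("?")
        true_val = simple()
        ts.expect(":")
        false_val = simple()
        if which == "rate_up":
            if false_val != 0.0:
                raise NetworkParseError(
                    f"node {node!r}: rate_up conditional must have 0 else-branch"
                )
            return true_val
        if true_val != 0.0:
            raise NetworkParseError(
                f"node {node!r}: rate_down conditional must have 0 then-branch"
            )
        return false_val
    return simple()


def _parse_bnd(model_text: str) -> list[dict]:
    ts = _TokenStream(_tokenize(model_text, NetworkParseError), NetworkParseError)
    blocks: list[dict] = []
    while ts.peek()[0] != "eof":
        kind, text = ts.next()
        if kind != "name":
            raise NetworkParseError(f"expected a node declaration, found {text!r}")
        if text.lower() == "node" and ts.peek()[0] == "name":
            _, text = ts.next()
        name = text
        ts.expect("{")
        fields: dict = {"name": name}
        while ts.peek()[1] != "}":
            fkind, fname = ts.next()
            if fkind != "name" or fname not in ("logic", "rate_up", "rate_down"):
                raise NetworkParseError(
                    f"node {name!r}: unsupported field {fname!r} "
                    "(subset: logic, rate_up, rate_down)"
                )
            ts.expect("=")
            if fname == "logic":
                # consume tokens up to ';' and parse as an expression
                expr_tokens = []
                while ts.peek()[1] != ";":
                    if ts.peek()[0] == "eof":
                        raise NetworkParseError(f"node {name!r}: unterminated logic")
                    expr_tokens.append(ts.next())
                sub = _TokenStream(expr_tokens + [("eof", "")], NetworkParseError)
                ast = _parse_or(sub)
                if sub.peek()[0] != "eof":
                    raise NetworkParseError(
                        f"node {name!r}: trailing tokens in logic: {sub.peek()[1]!r}"
                    )
                fields["logic"] = ast
            else:
                fields[fname] = _parse_rate_value(ts, fname, name)
            ts.expect(";")
        ts.expect("}")
        blocks.append(fields)
    return blocks


_CFG_FLAGS = ("is_internal", "is_input", "istate")


def _parse_cfg(config_text: str) -> tuple[dict[str, float], dict[str, dict]]:
    """Return ($symbol -> value, node -> {is_internal, is_input, istate})."""
    ts = _TokenStream(_tokenize(config_text, NetworkConfigError), NetworkConfigError)
    symbols: dict[str, float] = {}
    node_attrs: dict[str, dict] = {}

    def number() -> float:
        kind, text = ts.next()
        neg = False
        if text == "-":  # pragma: no cover - '-' not in token set, kept for clarity
            neg = True
            kind, text = ts.next()
        if kind != "num":
            raise NetworkConfigError(f"expected a number, found {text!r}")
        return -float(text) if neg else float(text)

    while ts.peek()[0] != "eof":
        kind, text = ts.next()
        if kind == "sym":
            ts.expect("=")
            symbols[text] = number()
            ts.expect(";")
        elif kind == "name":
            node = text
            ts.expect(".")
            _, attr = ts.next()
            if attr not in _CFG_FLAGS:
                raise NetworkConfigError(
                    f"unsupported attribute {node}.{attr} (subset: {', '.join(_CFG_FLAGS)})"
                )
            ts.expect("=")
            if attr == "istate":
                value: float | bool = number()
            else:
                _, word = ts.next()
                if word.upper() in ("TRUE", "1"):
                    value = True
                elif word.upper() in ("FALSE", "0"):
                    value = False
                else:
                    raise NetworkConfigError(f"{node}.{attr}: expected TRUE/FALSE, got {word!r}")
            node_attrs.setdefault(node, {})[attr] = value
            ts.expect(";")
        else:
            raise NetworkConfigError(f"unexpected token {text!r} in configuration")
    return symbols, node_attrs


def parse_network(model_text: str, config_text: str = "") -> BooleanNetwork:
    """Parse a model and configuration text pair into a :class:`BooleanNetwork`.

    Dialect subset (documented grammar)::

        bnd    :=  block*
        block  :=  ["node"] NAME "{" field* "}"
        field  :=  "logic" "=" expr ";"
                |  ("rate_up"|"rate_down") "=" (NUMBER | $SYMBOL
                      | "@logic" "?" value ":" value) ";"
        expr   :=  NAME | "0" | "1" | TRUE | FALSE | "!" expr | "(" expr ")"
                |  expr ("&"|"&&"|AND) expr | expr ("|"|"||"|OR) expr

        cfg    :=  stmt*
        stmt   :=  $SYMBOL "=" NUMBER ";"
                |  NAME ".is_internal" "=" TRUE|FALSE ";"
                |  NAME ".is_input"    "=" TRUE|FALSE ";"
                |  NAME ".istate"      "=" NUMBER ";"   # P(node starts at 1)

    ``//``, ``#`` and ``/* */`` comments are ignored.  Symbolic rates in the
    model must all be assigned in the config.  Constructs outside this
    subset raise :class:`NetworkParseError` / :class:`NetworkConfigError`.
    """
    blocks = _parse_bnd(model_text)
    symbols, node_attrs = _parse_cfg(config_text)
    declared = {b["name"] for b in blocks}
    for node in node_attrs:
        if node not in declared:
            raise NetworkConfigError(f"configuration refers to undeclared node {node!r}")

    def resolve(value, node, which):
        if isinstance(value, str):
            if value not in symbols:
                raise NetworkConfigError(
                    f"node {node!r}: rate symbol {value!r} ({which}) not assigned in config"
                )
            return symbols[value]
        return value

    nodes = []
    istate: dict[str, float] = {}
    for b in blocks:
        name = b["name"]
        attrs = node_attrs.get(name, {})
        if "logic" not in b:
            raise NetworkParseError(f"node {name!r}: missing logic rule")
        nodes.append(
            NodeSpec(
                name=name,
                logic=b["logic"],
                rate_up=resolve(b.get("rate_up", 1.0), name, "rate_up"),
                rate_down=resolve(b.get("rate_down", 1.0), name, "rate_down"),
                is_internal=bool(attrs.get("is_internal", False)),
                is_input=bool(attrs.get("is_input", False)),
            )
        )
        if "istate" in attrs:
            istate[name] = float(attrs["istate"])
    return BooleanNetwork(nodes, istate)


def parse_network_files(model_path, config_path) -> BooleanNetwork:
    """Read and parse the two model files from disk."""
    with open(model_path) as fh:
        model_text = fh.read()
    with open(config_path) as fh:
        config_text = fh.read()
    return parse_network(model_text, config_text)


# --------------------------------------------------------------------------
# Simulation
# --------------------------------------------------------------------------

def transition_rate(net: BooleanNetwork, s: NetworkState, node: str) -> float:
    """Propensity of the given node flipping in state ``s``.

    ``rate_up`` if the logic target is 1 and the node is 0, ``rate_down``
    if the target is 0 and the node is 1, else 0 (node at its target).
    Unconditionally overridden nodes (over-expression/knockout) fire their
    rate irrespective of the target.  Input nodes are pinned externally
    and have no transition.
    """
    spec = net.node(node)
    if spec.is_input:
        raise ValueError(f"node {node!r} is an input node; it is pinned by the coupling layer")
    comp = net.compiled
    targets = comp.targets(s.bits, np.empty(len(net), dtype=np.uint8))
    i = net.index[node]
    current = int(s.bits[i])
    target = int(targets[i])
    if current == 0 and (target == 1 or spec.force_up):
        return spec.rate_up
    if current == 1 and (target == 0 or spec.force_down):
        return spec.rate_down
    return 0.0


def gillespie_step(
    net: BooleanNetwork, s: NetworkState, rng: np.random.Generator
) -> tuple[NetworkState, float]:
    """One exact stochastic simulation step.

    Returns the next state and the exponential waiting time.  In an
    absorbing state (total exit rate 0) the wait is ``inf`` and the state
    is returned unchanged.
    """
    comp = net.compiled
    rates = comp.rates(s.bits)
    total = rates.sum()
    if total <= 0.0:
        return s.copy(), math.inf
    wait = rng.exponential(1.0 / total)
    u = rng.random() * total
    node_idx = int(np.searchsorted(np.cumsum(rates), u, side="right"))
    node_idx = min(node_idx, len(rates) - 1)
    s2 = s.copy()
    s2.bits[node_idx] ^= 1
    s2.time += wait
    return s2, wait


def advance(
    net: BooleanNetwork, s: NetworkState, window: float, rng: np.random.Generator
) -> NetworkState:
    """Simulate the chain for ``window`` minutes and return the end state.

    Applies Gillespie steps until the cumulative waiting time would exceed
    the window; the state occupied at the window end is returned with its
    internal clock advanced by exactly ``window``.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    out = s.copy()
    bits = out.bits
    comp = net.compiled
    remaining = window
    while True:
        rates = comp.rates(bits)
        total = rates.sum()
        if total <= 0.0:
            break
        wait = rng.exponential(1.0 / total)
        if wait > remaining:
            break
        remaining -= wait
        u = rng.random() * total
        node_idx = int(np.searchsorted(np.cumsum(rates), u, side="right"))
        bits[min(node_idx, len(rates) - 1)] ^= 1
    out.time = s.time + window
    return out


def _classify(
    states: np.ndarray,
    net: BooleanNetwork,
    priority: Sequence[str],
) -> list[str]:
    labels = []
    cols = {name: net.index[name] for name in priority}
    for row in states:
        label = "None"
        for name in priority:
            if row[cols[name]]:
                label = name
                break
        labels.append(label)
    return labels


def simulate_ensemble(
    net: BooleanNetwork,
    initial_states: np.ndarray,
    horizon: float,
    rng: np.random.Generator,
    max_events: int = 100_000,
    track_ever: Sequence[str] | None = None,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Run one trajectory per row of ``initial_states`` up to ``horizon``.

    All trajectories are advanced in lock-step (one Gillespie event per
    iteration, vectorised across trajectories); returns the matrix of end
    states.  With ``track_ever`` given, additionally returns a boolean
    (n, len(track_ever)) matrix flagging trajectories in which each named
    node was active at any point.  Also serves the master-equation
    cross-checks on small networks.
    """
    states = np.array(initial_states, dtype=np.uint8, copy=True)
    n, k = states.shape
    comp = net.compiled
    t = np.zeros(n)
    active = np.ones(n, dtype=bool)
    scratch = np.empty_like(states)
    ever_cols = [net.index[name] for name in (track_ever or [])]
    ever = states[:, ever_cols].astype(bool) if ever_cols else None
    for _ in range(max_events):
        if not active.any():
            break
        rates = comp.rates_vector(states, scratch)
        total = rates.sum(axis=1)
        absorbing = active & (total <= 0.0)
        active &= ~absorbing
        if not active.any():
            break
        safe_total = np.where(total > 0, total, 1.0)
        waits = rng.exponential(1.0, size=n) / safe_total
        u = rng.random(n) * safe_total
        cum = np.cumsum(rates, axis=1)
        chosen = (cum > u[:, None]).argmax(axis=1)
        t_new = t + waits
        fire = active & (t_new <= horizon)
        active &= t_new <= horizon  # trajectories whose next event is past the horizon stop
        rows = np.nonzero(fire)[0]
        states[rows, chosen[rows]] ^= 1
        t[rows] = t_new[rows]
        if ever is not None:
            ever[rows] |= states[rows][:, ever_cols].astype(bool)
    else:
        raise RuntimeError(f"ensemble did not settle within {max_events} events")
    if ever is not None:
        return states, ever
    return states


def ensemble_fates(
    net: BooleanNetwork,
    init: np.ndarray | Mapping[str, float] | None,
    horizon: float,
    n: int,
    rng: np.random.Generator,
    readout_priority: Sequence[str] | None = None,
    pinned: Mapping[str, int] | None = None,
) -> FateDistribution:
    """Empirical fate probabilities from ``n`` independent trajectories.

    ``init`` may be an explicit (n, nodes) matrix of start states, a
    per-node Bernoulli probability mapping, or ``None`` to use the
    network's configured initial-state distribution.  ``pinned`` fixes
    input-node values for the whole run (e.g. sustained TNF).  Each
    trajectory is classified by the highest-priority read-out node active
    at the horizon; ``None`` if no read-out is active.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(init, np.ndarray):
        states0 = np.asarray(init, dtype=np.uint8)
        if states0.shape != (n, len(net)):
            raise ValueError("initial state matrix has wrong shape")
        states0 = states0.copy()
        for name, value in (pinned or {}).items():
            states0[:, net.index[name]] = value
    elif isinstance(init, Mapping):
        probs = dict(zip(net.names, net.initial_probabilities))
        probs.update(init)
        p = np.array([probs[name] for name in net.names])
        states0 = (rng.random((n, len(net))) < p).astype(np.uint8)
        for name, value in (pinned or {}).items():
            states0[:, net.index[name]] = value
    else:
        states0 = net.sample_initial_states(n, rng, pinned)

    final = simulate_ensemble(net, states0, horizon, rng)
    readouts = net.readout_names
    if readout_priority is None:
        priority = [r for r in DEFAULT_READOUT_PRIORITY if r in readouts]
        priority += [r for r in readouts if r not in priority]
    else:
        priority = list(readout_priority)
    labels = _classify(final, net, priority)
    counts: dict[str, int] = {}
    for label in labels:
        counts[label] = counts.get(label, 0) + 1
    probabilities = {label: c / n for label, c in counts.items()}
    return FateDistribution(probabilities, n)


def apply_overrides(
    net: BooleanNetwork, overrides: Sequence[RateOverride]
) -> BooleanNetwork:
    """Return a copy of the network with transition rates replaced.

    Logic rules are untouched: mutations act purely on the kinetics, so the
    wild-type and mutant share one network structure.
    """
    effective: dict[str, tuple[float | None, float | None, bool]] = {}
    for ov in overrides:
        if ov.node not in net.index:
            raise KeyError(f"override names unknown node {ov.node!r}")
        prev_up, prev_down, _ = effective.get(ov.node, (None, None, False))
        effective[ov.node] = (
            ov.rate_up if ov.rate_up is not None else prev_up,
            ov.rate_down if ov.rate_down is not None else prev_down,
            ov.unconditional,  # last override naming the node wins
        )
    nodes = []
    for node in net.nodes:
        if node.name not in effective:
            nodes.append(node)
            continue
        up, down, unconditional = effective[node.name]
        nodes.append(
            replace(
                node,
                rate_up=up if up is not None else node.rate_up,
                rate_down=down if down is not None else node.rate_down,
                force_up=unconditional if up is not None else node.force_up,
                force_down=unconditional if down is not None else node.force_down,
            )
        )
    istate = {name: p for name, p in zip(net.names, net.initial_probabilities) if p > 0}
    return BooleanNetwork(nodes, istate)


def master_equation_distribution(
    net: BooleanNetwork,
    initial: NetworkState,
    t: float,
    pinned: Mapping[str, int] | None = None,
) -> dict[tuple[int, ...], float]:
    """Exact state distribution at time ``t`` via the 2^k master equation.

    Enumerate all states over the non-input nodes (inputs stay fixed at
    their initial values), build the CTMC generator from single-node flip
    rates, and compute expm(Q^T t) applied to the initial distribution.
    Exponential in node count — intended as an oracle for small networks.
    """
    from scipy.linalg import expm

    free = [i for i, node in enumerate(net.nodes) if not node.is_input]
    if len(free) > 12:
        raise ValueError("master-equation oracle limited to <= 12 non-input nodes")
    comp = net.compiled
    base = initial.bits.copy()
    for name, value in (pinned or {}).items():
        base[net.index[name]] = value
    n_states = 2 ** len(free)

    def decode(code: int) -> np.ndarray:
        bits = base.copy()
        for j, i in enumerate(free):
            bits[i] = (code >> j) & 1
        return bits

    def encode(bits: np.ndarray) -> int:
        code = 0
        for j, i in enumerate(free):
            code |= int(bits[i]) << j
        return code

    Q = np.zeros((n_states, n_states))
    for code in range(n_states):
        bits = decode(code)
        rates = comp.rates(bits)
        for j, i in enumerate(free):
            if rates[i] > 0:
                Q[code, code ^ (1 << j)] += rates[i]
        Q[code, code] = -Q[code].sum()
    p0 = np.zeros(n_states)
    p0[encode(base)] = 1.0
    p_t = p0 @ expm(Q * t)
    out: dict[tuple[int, ...], float] = {}
    for code in range(n_states):
        out[tuple(int(b) for b in decode(code))] = float(p_t[code])
    return out
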