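"""Random Boolean networks and an independent brute-force attractor oracle.

The study this package supports has no raw dataset: its "data" is the state
space of a hand-built logical model.  Validation therefore rests on seeded
random Boolean networks with known statistical structure (node count,
in-degree bound, rule family) whose attractor landscapes can be computed two
independent ways:

* the production engine (:func:`cd8net.network.enumerate_state_space`),
  which composes bit-vectorised successor maps and follows trajectories, and
* :func:`brute_force_attractors` here, which materialises the explicit
  state-transition graph over (state, schedule-phase) product nodes, finds
  terminal strongly-connected components with networkx, and counts basins by
  propagating along the condensation DAG.

The two deliberately share no dynamics code; agreement on attractor sets and
exact basin sizes is the package's core correctness property.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np

from .expr import And, BooleanExpression, Not, Or, Var
from .network import (
    Attractor,
    AttractorAtlas,
    BooleanNetwork,
    NodeSpec,
    Scenario,
    UpdateSchedule,
    _collapse,
    _min_rotation,
)

__all__ = [
    "RandomNetworkSpec",
    "FixtureCase",
    "random_network",
    "brute_force_attractors",
    "fixture_library",
]

RULE_FAMILIES = ("random_truth_table", "nested_canalizing", "and_or_not")


@dataclass(frozen=True)
class RandomNetworkSpec:
    """Parameters of a seeded random Boolean network."""

    n_internal: int
    n_inputs: int = 0
    max_in_degree: int = 3
    rule_family: str = "random_truth_table"
    seed: int = 0

    def __post_init__(self):
        if self.n_internal < 1:
            raise ValueError("n_internal must be >= 1")
        if self.n_inputs < 0 or self.max_in_degree < 1:
            raise ValueError("n_inputs must be >= 0 and max_in_degree >= 1")
        if self.rule_family not in RULE_FAMILIES:
            raise ValueError(f"rule_family must be one of {RULE_FAMILIES}")


def _literal(name: str, positive: bool) -> BooleanExpression:
    return Var(name) if positive else Not(Var(name))


def _truth_table_expr(regs: list[str], rows: np.ndarray) -> BooleanExpression:
    """DNF expression over ``regs`` matching truth-table ``rows`` (2**k bits)."""
    k = len(regs)
    if not rows.any():  # contradiction, expressed over a sampled regulator
        return And([Var(regs[0]), Not(Var(regs[0]))])
    if rows.all():  # tautology
        return Or([Var(regs[0]), Not(Var(regs[0]))])
    minterms = []
    for code in np.flatnonzero(rows):
        lits = [_literal(regs[i], bool((int(code) >> i) & 1)) for i in range(k)]
        minterms.append(lits[0] if k == 1 else And(lits))
    return minterms[0] if len(minterms) == 1 else Or(minterms)


def _nested_canalizing_expr(regs: list[str], rng: np.random.Generator) -> BooleanExpression:
    """Chain of literals joined by AND/OR: l1 op (l2 op (...)), canalizing at
    every layer."""
    expr = _literal(regs[-1], bool(rng.integers(2)))
    for name in reversed(regs[:-1]):
        lit = _literal(name, bool(rng.integers(2)))
        expr = And([lit, expr]) if rng.integers(2) else Or([lit, expr])
    return expr


def _and_or_not_expr(regs: list[str], rng: np.random.Generator) -> BooleanExpression:
    lits = [_literal(r, bool(rng.integers(2))) for r in regs]
    if len(lits) == 1:
        return lits[0]
    split = int(rng.integers(1, len(lits))) if len(lits) > 2 else 1
    left = lits[:split]
    right = lits[split:]
    inner = [
        left[0] if len(left) == 1 else (And(left) if rng.integers(2) else Or(left)),
        right[0] if len(right) == 1 else (And(right) if rng.integers(2) else Or(right)),
    ]
    return And(inner) if rng.integers(2) else Or(inner)


def random_network(spec: RandomNetworkSpec) -> BooleanNetwork:
    """Deterministically generate the random network described by ``spec``.

    Each network draws from a dedicated random stream keyed by the full spec,
    so generating other fixtures never shifts an existing network.
    """
    rng = np.random.default_rng(
        [abs(int(spec.seed)), spec.n_internal, spec.n_inputs, spec.max_in_degree,
         RULE_FAMILIES.index(spec.rule_family)]
    )
    internal = [f"x{i}" for i in range(spec.n_internal)]
    inputs = [f"u{i}" for i in range(spec.n_inputs)]
    vocab = internal + inputs
    nodes = []
    for name in internal:
        k = int(rng.integers(1, spec.max_in_degree + 1))
        k = min(k, len(vocab))
        regs = [vocab[j] for j in rng.choice(len(vocab), size=k, replace=False)]
        if spec.rule_family == "random_truth_table":
            rows = rng.integers(0, 2, size=1 << k).astype(bool)
            rule = _truth_table_expr(regs, rows)
        elif spec.rule_family == "nested_canalizing":
            rule = _nested_canalizing_expr(regs, rng)
        else:
            rule = _and_or_not_expr(regs, rng)
        classes = ("metabolite", "signaling", "transcription_factor", "expressed_protein")
        nodes.append(NodeSpec(name, rule, classes[int(rng.integers(4))]))
    return BooleanNetwork(nodes, inputs, name=f"random-{spec.rule_family}-{spec.seed}")


# ---------------------------------------------------------------------------
# Brute-force oracle


def _truth_tables(network: BooleanNetwork):
    """Per-node truth table over its own regulators (independent eval path)."""
    tables = {}
    for spec in network.internal_nodes:
        regs = sorted(spec.rule.leaves())
        if len(regs) > 20:
            raise ValueError(f"rule for {spec.name!r} has too many regulators for the oracle")
        table = {}
        for bits in itertools.product((0, 1), repeat=len(regs)):
            table[bits] = int(spec.rule.evaluate(dict(zip(regs, bits)))) & 1
        tables[spec.name] = (regs, table)
    return tables


def brute_force_attractors(
    network: BooleanNetwork,
    scenario: Scenario,
    schedule: UpdateSchedule | None = None,
) -> AttractorAtlas:
    """Exact attractors and basins via explicit graph traversal.

    Builds the full (state, phase) transition graph, extracts terminal
    strongly-connected components of its condensation, and counts, for every
    phase-0 initial state, which terminal component its trajectory enters.
    Intended as the independent oracle for the production engine; refuses
    networks beyond 2**16 states (2**12 for multi-phase schedules).
    """
    schedule = schedule or UpdateSchedule.synchronous()
    scenario.validate(network)
    phases = schedule.phase_count(network)
    cap = 16 if phases == 1 else 12
    if network.n > cap:
        raise ValueError(
            f"oracle refuses n={network.n} with {phases} phase(s); cap is {cap}"
        )
    tables = _truth_tables(network)
    names = network.names
    omega = network.omega

    def successor(code: int, phase: int) -> int:
        bits = network.decode(code)
        val = dict(zip(names, bits))
        val.update(scenario.input_clamps)
        out = 0
        for i, name in enumerate(names):
            if name in scenario.perturbations:
                b = scenario.perturbations[name]
            elif schedule.is_due(name, phase):
                regs, table = tables[name]
                b = table[tuple(val[r] for r in regs)]
            else:
                b = bits[i]
            out |= b << i
        return out

    graph = nx.DiGraph()
    for code in range(omega):
        for phase in range(phases):
            graph.add_edge((code, phase), (successor(code, phase), (phase + 1) % phases))

    condensation = nx.condensation(graph)
    terminal = [c for c in condensation.nodes if condensation.out_degree(c) == 0]
    # Every component reaches exactly one terminal component (out-degree one
    # dynamics); resolve by walking the condensation in reverse topological order.
    reaches: dict[int, int] = {c: c for c in terminal}
    for comp in reversed(list(nx.topological_sort(condensation))):
        if comp not in reaches:
            (nxt,) = condensation.successors(comp)
            reaches[comp] = reaches[nxt]

    basin_counts: dict[int, int] = {c: 0 for c in terminal}
    mapping = condensation.graph["mapping"]
    for code in range(omega):
        basin_counts[reaches[mapping[(code, 0)]]] += 1

    attractors = []
    for comp in terminal:
        members = condensation.nodes[comp]["members"]
        # Start the walk at schedule phase 0 so the sequence layout matches
        # the engine's; the attractor identity is phase-alignment aware.
        start = min(m for m in members if m[1] == 0)
        seq_states = []
        node = start
        while True:
            seq_states.append(network.decode(node[0]))
            node = (successor(node[0], node[1]), (node[1] + 1) % phases)
            if node == start:
                break
        seq = tuple(seq_states)
        collapsed = _collapse(seq)
        kind = "fixed_point" if len(collapsed) == 1 else "cycle"
        canon = _min_rotation(seq, phases)
        attractors.append(
            Attractor(
                kind=kind,
                states=_collapse(canon),
                basin_size=basin_counts[comp],
                canonical_key=(kind, canon),
            )
        )
    attractors.sort(key=lambda a: (-a.basin_size, a.canonical_key))
    atlas = AttractorAtlas(network, scenario, schedule, attractors)
    atlas.validate()
    return atlas


# ---------------------------------------------------------------------------
# Hand-checkable fixtures


@dataclass(frozen=True)
class FixtureCase:
    """A tiny network with a scenario and its oracle-verified atlas."""

    name: str
    network: BooleanNetwork
    scenario: Scenario
    schedule: UpdateSchedule
    expected: AttractorAtlas = field(compare=False)

    @property
    def expected_basins(self) -> dict[tuple, int]:
        return {a.canonical_key: a.basin_size for a in self.expected.attractors}


def _case(name, network, scenario=None, schedule=None) -> FixtureCase:
    scenario = scenario or Scenario(label=name)
    schedule = schedule or UpdateSchedule.synchronous()
    expected = brute_force_attractors(network, scenario, schedule)
    return FixtureCase(name, network, scenario, schedule, expected)


def fixture_library() -> list[FixtureCase]:
    """Small networks whose attractor landscape is checkable by hand.

    * ``toggle``: one self-negating node; a single synchronous 2-cycle.
    * ``self_activators``: three independent self-activators; 8 fixed
      points, each with basin 1.
    * ``toggle_switch``: mutual inhibition A = !B, B = !A; two stable
      polarised states plus a 2-cycle through (0,0)/(1,1).
    * ``frustrated_ring``: a 3-ring with one negative arc; no stable state,
      synchronous limit cycles only.
    * ``clamped_input``: an input-driven node with the input clamped high.
    * ``clamped_toggle``: the toggle with its node knock-in clamped; the
      clamp forces a unique fixed point owning the whole state space.
    """
    cases = []
    toggle = BooleanNetwork([NodeSpec("A", Not(Var("A")))], name="toggle")
    cases.append(_case("toggle", toggle))

    selfacts = BooleanNetwork(
        [NodeSpec(nm, Var(nm)) for nm in ("A", "B", "C")], name="self_activators"
    )
    cases.append(_case("self_activators", selfacts))

    switch = BooleanNetwork(
        [NodeSpec("A", Not(Var("B"))), NodeSpec("B", Not(Var("A")))],
        name="toggle_switch",
    )
    cases.append(_case("toggle_switch", switch))

    ring = BooleanNetwork(
        [
            NodeSpec("A", Var("C")),
            NodeSpec("B", Var("A")),
            NodeSpec("C", Not(Var("B"))),
        ],
        name="frustrated_ring",
    )
    cases.append(_case("frustrated_ring", ring))

    driven = BooleanNetwork(
        [NodeSpec("A", Or([Var("u"), Var("A")])), NodeSpec("B", And([Var("A"), Var("B")]))],
        input_nodes=["u"],
        name="clamped_input",
    )
    cases.append(_case("clamped_input", driven, Scenario({"u": 1}, label="u_high")))

    cases.append(
        _case("clamped_toggle", toggle, Scenario(perturbations={"A": 1}, label="A_ki"))
    )
    return cases
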