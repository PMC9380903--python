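"""Boolean-network machinery: states, update schedules, attractors, basins.

A :class:`BooleanNetwork` has *internal* nodes, each carrying a logic rule,
and declared *input* nodes that appear only on rule right-hand sides.  The
network state is the bit vector of internal nodes; inputs are clamped per
:class:`Scenario` and therefore do not enlarge the state space.  With n
internal nodes the state space holds Omega = 2**n configurations.

Dynamics follow the classical parallel convention: at step t every *due*
node evaluates its rule on the pre-step state joined with the input clamps
(no within-step propagation).  Under the synchronous schedule every node is
due at every step; under the timed-asynchronous schedule node i is due when
``t % period_i == 0``, which keeps the dynamics deterministic while letting
fast species (metabolites) update more often than slow ones (transcription
and protein expression).  Knock-out/knock-in perturbations are clamps: a
perturbed node takes its clamp value at every step regardless of its rule.

Attractors of a deterministic finite system are fixed points or cycles.
:func:`enumerate_state_space` follows every one of the 2**n initial states
to its attractor with a bit-vectorised successor map and exact integer basin
accounting; :func:`find_attractor` is the scalar trajectory engine used for
single runs and as an internal cross-check.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .expr import BooleanExpression

logger = logging.getLogger(__name__)

__all__ = [
    "NODE_CLASSES",
    "DEFAULT_CLASS_PERIODS",
    "NodeSpec",
    "BooleanNetwork",
    "Scenario",
    "UpdateSchedule",
    "Attractor",
    "AttractorAtlas",
    "step",
    "find_attractor",
    "enumerate_state_space",
    "apply_perturbation",
    "NonterminationError",
    "StateSpaceTooLargeError",
]

#: Closed set of node classes, used to assign asynchronous update periods.
NODE_CLASSES = ("metabolite", "signaling", "transcription_factor", "expressed_protein")

#: Default update period (in steps) per node class: metabolite pools
#: equilibrate fastest, signalling complexes next, transcription and de-novo
#: protein expression slowest.
DEFAULT_CLASS_PERIODS = {
    "metabolite": 1,
    "signaling": 2,
    "transcription_factor": 4,
    "expressed_protein": 4,
}


class NonterminationError(RuntimeError):
    """A trajectory failed to recur within ``max_steps`` (signals a bug)."""


class StateSpaceTooLargeError(ValueError):
    """Exhaustive enumeration refused because 2**n exceeds the ceiling."""


@dataclass(frozen=True)
class NodeSpec:
    """An internal node: unique name, logic rule, and kinetic class."""

    name: str
    rule: BooleanExpression
    node_class: str = "signaling"

    def __post_init__(self):
        if not self.name:
            raise ValueError("node name must be nonempty")
        if self.node_class not in NODE_CLASSES:
            raise ValueError(
                f"node_class {self.node_class!r} not in {NODE_CLASSES}"
            )


class BooleanNetwork:
    """Named internal nodes with rules plus declared input nodes.

    Internal node order is significant: it defines bit positions in the
    packed integer encoding of states (bit i = i-th internal node) and the
    order of serialized bit strings.
    """

    def __init__(
        self,
        internal_nodes: Sequence[NodeSpec],
        input_nodes: Sequence[str] = (),
        name: str = "",
    ):
        self.internal_nodes = tuple(internal_nodes)
        self.input_nodes = tuple(input_nodes)
        self.name = name
        names = [spec.name for spec in self.internal_nodes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate internal node names")
        if len(set(self.input_nodes)) != len(self.input_nodes):
            raise ValueError("duplicate input node names")
        overlap = set(names) & set(self.input_nodes)
        if overlap:
            raise ValueError(f"names declared both internal and input: {sorted(overlap)}")
        self.names = tuple(names)
        self.index = {nm: i for i, nm in enumerate(names)}
        vocab = set(names) | set(self.input_nodes)
        for spec in self.internal_nodes:
            missing = spec.rule.leaves() - vocab
            if missing:
                raise ValueError(
                    f"rule for {spec.name!r} references undeclared names {sorted(missing)}"
                )

    @property
    def n(self) -> int:
        return len(self.internal_nodes)

    @property
    def omega(self) -> int:
        """Size of the internal state space, 2**n."""
        return 1 << self.n

    # -- state packing ----------------------------------------------------
    def encode(self, state) -> int:
        """Pack a state (mapping or bit sequence in node order) to an int."""
        if isinstance(state, Mapping):
            bits = [int(state[nm]) for nm in self.names]
        else:
            bits = [int(b) for b in state]
        if len(bits) != self.n or any(b not in (0, 1) for b in bits):
            raise ValueError("state must assign 0/1 to every internal node")
        code = 0
        for i, b in enumerate(bits):
            code |= b << i
        return code

    def decode(self, code: int) -> tuple[int, ...]:
        """Unpack an integer state code to a bit tuple in node order."""
        return tuple((code >> i) & 1 for i in range(self.n))

    def state_dict(self, state) -> dict[str, int]:
        if isinstance(state, int):
            state = self.decode(state)
        return dict(zip(self.names, (int(b) for b in state)))

    def __repr__(self):
        return (
            f"BooleanNetwork({self.name or 'unnamed'}: {self.n} internal, "
            f"{len(self.input_nodes)} inputs)"
        )


@dataclass(frozen=True)
class Scenario:
    """Input clamps (a total assignment over inputs) plus perturbation clamps.

    ``input_clamps`` encodes the extracellular context (cytokine milieu,
    nutrient levels); ``perturbations`` encodes knock-outs (clamp 0) and
    knock-ins (clamp 1) of internal nodes.
    """

    input_clamps: Mapping[str, int] = field(default_factory=dict)
    perturbations: Mapping[str, int] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "input_clamps", dict(self.input_clamps))
        object.__setattr__(self, "perturbations", dict(self.perturbations))
        for mapping in (self.input_clamps, self.perturbations):
            for key, value in mapping.items():
                if int(value) not in (0, 1):
                    raise ValueError(f"clamp for {key!r} must be 0 or 1, got {value!r}")
                mapping[key] = int(value)

    def validate(self, network: BooleanNetwork) -> None:
        missing = set(network.input_nodes) - set(self.input_clamps)
        if missing:
            raise ValueError(f"scenario does not clamp inputs {sorted(missing)}")
        extra = set(self.input_clamps) - set(network.input_nodes)
        if extra:
            raise ValueError(f"scenario clamps undeclared inputs {sorted(extra)}")
        bad = set(self.perturbations) - set(network.names)
        if bad:
            raise ValueError(f"perturbations target non-internal nodes {sorted(bad)}")


def apply_perturbation(scenario: Scenario, node: str, value: int, network: BooleanNetwork | None = None) -> Scenario:
    """Return a new scenario with ``node`` clamped to ``value`` (KO=0, KI=1).

    An existing clamp on the same node is overwritten with a logged warning
    (so a knock-in after a knock-out leaves the knock-in in force).  When a
    ``network`` is supplied the node must be one of its internal nodes;
    clamping a declared input is refused with a pointer to ``input_clamps``.
    """
    if int(value) not in (0, 1):
        raise ValueError(f"clamp value must be 0 or 1, got {value!r}")
    if node in scenario.input_clamps or (network is not None and node in network.input_nodes):
        raise ValueError(
            f"{node!r} is an input; set it through Scenario.input_clamps, not a perturbation"
        )
    if network is not None and node not in network.index:
        raise ValueError(f"unknown internal node {node!r}")
    perturbations = dict(scenario.perturbations)
    if node in perturbations and perturbations[node] != int(value):
        logger.warning(
            "overwriting existing clamp %s=%d with %d in scenario %r",
            node, perturbations[node], int(value), scenario.label,
        )
    perturbations[node] = int(value)
    return replace(scenario, perturbations=perturbations)


@dataclass(frozen=True)
class UpdateSchedule:
    """Synchronous or deterministic timed-asynchronous update schedule."""

    mode: str = "synchronous"
    periods: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("synchronous", "asynchronous"):
            raise ValueError(f"unknown schedule mode {self.mode!r}")
        object.__setattr__(self, "periods", dict(self.periods))
        for name, p in self.periods.items():
            if int(p) < 1:
                raise ValueError(f"period for {name!r} must be >= 1, got {p}")
            if self.mode == "synchronous" and int(p) != 1:
                raise ValueError("synchronous schedules require all periods == 1")
            self.periods[name] = int(p)

    @classmethod
    def synchronous(cls) -> "UpdateSchedule":
        return cls("synchronous")

    @classmethod
    def asynchronous(
        cls,
        network: BooleanNetwork,
        periods: Mapping[str, int] | None = None,
        class_periods: Mapping[str, int] | None = None,
    ) -> "UpdateSchedule":
        """Build a timed schedule from node classes, with optional overrides."""
        class_periods = dict(DEFAULT_CLASS_PERIODS, **(class_periods or {}))
        table = {spec.name: class_periods[spec.node_class] for spec in network.internal_nodes}
        table.update(periods or {})
        return cls("asynchronous", table)

    def period_of(self, name: str) -> int:
        return self.periods.get(name, 1)

    def is_due(self, name: str, t: int) -> bool:
        if t < 0:
            raise ValueError("t must be nonnegative")
        return self.mode == "synchronous" or t % self.period_of(name) == 0

    def phase_count(self, network: BooleanNetwork) -> int:
        """Least common multiple of all periods (1 for synchronous)."""
        if self.mode == "synchronous":
            return 1
        return math.lcm(*(self.period_of(nm) for nm in network.names)) if network.n else 1


def step(
    network: BooleanNetwork,
    state,
    scenario: Scenario,
    schedule: UpdateSchedule,
    t: int = 0,
) -> tuple[int, ...]:
    """One scenario-respecting update sweep at step index ``t``.

    Due, unperturbed nodes take their rule value computed on the pre-step
    state joined with the input clamps; perturbation-clamped nodes take
    their clamp value unconditionally; non-due nodes keep their value.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    if isinstance(state, int):
        bits = network.decode(state)
    else:
        bits = tuple(int(b) for b in state)
    if len(bits) != network.n:
        raise ValueError("state length does not match network")
    valuation = dict(zip(network.names, bits))
    valuation.update(scenario.input_clamps)
    out = []
    for i, spec in enumerate(network.internal_nodes):
        if spec.name in scenario.perturbations:
            out.append(scenario.perturbations[spec.name])
        elif schedule.is_due(spec.name, t):
            out.append(int(spec.rule.evaluate(valuation)) & 1)
        else:
            out.append(bits[i])
    return tuple(out)


# ---------------------------------------------------------------------------
# Attractors


def _min_rotation(seq: tuple, step: int = 1) -> tuple:
    """Lexicographically minimal rotation of a cyclic sequence.

    ``step`` restricts the candidate rotations to multiples of the schedule
    phase count: a timed-asynchronous attractor is a cycle over
    (state, phase) pairs, so two state sequences are the same attractor only
    if one is a phase-preserving rotation of the other.  With the sequence
    laid out from phase 0, those are exactly the rotations by multiples of
    the phase count.
    """
    best = seq
    for k in range(step, len(seq), step):
        rot = seq[k:] + seq[:k]
        if rot < best:
            best = rot
    return best


def _collapse(seq: Sequence) -> tuple:
    """Drop consecutive duplicates, treating the sequence as cyclic."""
    out = [s for i, s in enumerate(seq) if i == 0 or s != seq[i - 1]]
    if len(out) > 1 and out[-1] == out[0]:
        out.pop()
    return tuple(out)


@dataclass(frozen=True)
class Attractor:
    """A fixed point or cycle, with its exact basin size.

    ``states`` lists the distinct internal states visited (length 1 for a
    fixed point), as bit tuples in network node order.  ``canonical_key``
    is the rotation-invariant identity used to merge and compare
    attractors: the minimal rotation of the full per-step state sequence
    over one period of the schedule.
    """

    kind: str  # "fixed_point" | "cycle"
    states: tuple[tuple[int, ...], ...]
    basin_size: int = 0
    canonical_key: tuple = ()

    def __post_init__(self):
        if self.kind not in ("fixed_point", "cycle"):
            raise ValueError(f"bad attractor kind {self.kind!r}")
        if self.kind == "fixed_point" and len(self.states) != 1:
            raise ValueError("fixed_point attractors hold exactly one state")
        if not self.canonical_key:
            seq = tuple(self.states)
            object.__setattr__(self, "canonical_key", (self.kind, _min_rotation(seq)))

    @property
    def period(self) -> int:
        return len(self.states)


@dataclass
class AttractorAtlas:
    """All attractors of one (network, scenario, schedule) cell with basins."""

    network: BooleanNetwork
    scenario: Scenario
    schedule: UpdateSchedule
    attractors: list[Attractor]

    @property
    def omega(self) -> int:
        return self.network.omega

    def basin_total(self) -> int:
        return sum(a.basin_size for a in self.attractors)

    def validate(self) -> None:
        if self.basin_total() != self.omega:
            raise AssertionError(
                f"basin sizes sum to {self.basin_total()}, expected {self.omega}"
            )
        keys = [a.canonical_key for a in self.attractors]
        if len(set(keys)) != len(keys):
            raise AssertionError("duplicate attractors in atlas")
        # Attractors are disjoint as sets of (state, phase) pairs.  Under a
        # multi-phase schedule two attractors may pass through the same state
        # at different phases, so disjointness is checked on the full timed
        # sequence recorded in the canonical key.
        phases = self.schedule.phase_count(self.network)
        seen: set = set()
        for a in self.attractors:
            seq = a.canonical_key[1]
            for i, s in enumerate(seq):
                pair = (s, i % phases)
                if pair in seen:
                    raise AssertionError("two attractors share a (state, phase) pair")
                seen.add(pair)

    def fixed_points(self) -> list[Attractor]:
        return [a for a in self.attractors if a.kind == "fixed_point"]

    def cycles(self) -> list[Attractor]:
        return [a for a in self.attractors if a.kind == "cycle"]


def find_attractor(
    network: BooleanNetwork,
    initial,
    scenario: Scenario,
    schedule: UpdateSchedule,
    max_steps: int | None = None,
) -> Attractor:
    """Follow one trajectory until a (state, schedule-phase) pair recurs.

    Deterministic for both schedules.  The returned attractor carries
    ``basin_size=1`` (the single initial configuration followed).
    """
    scenario.validate(network)
    phases = schedule.phase_count(network)
    if max_steps is None:
        max_steps = 4 * network.omega * phases
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    state = tuple(int(b) for b in (network.decode(initial) if isinstance(initial, int) else initial))
    seen: dict[tuple[tuple[int, ...], int], int] = {}
    trajectory: list[tuple[int, ...]] = []
    for t in range(max_steps + 1):
        key = (state, t % phases)
        if key in seen:
            t0 = seen[key]
            cycle_seq = tuple(trajectory[t0:])
            # Align the sequence to start at schedule phase 0, then take the
            # minimal phase-preserving rotation as the attractor identity.
            shift = (-t0) % phases
            cycle_seq = cycle_seq[shift:] + cycle_seq[:shift]
            collapsed = _collapse(cycle_seq)
            kind = "fixed_point" if len(collapsed) == 1 else "cycle"
            canon = _min_rotation(cycle_seq, phases)
            return Attractor(
                kind=kind,
                states=_collapse(canon),
                basin_size=1,
                canonical_key=(kind, canon),
            )
        seen[key] = t
        trajectory.append(state)
        state = step(network, state, scenario, schedule, t)
    raise NonterminationError(
        f"no recurrence within {max_steps} steps; this should be impossible "
        "for a deterministic finite system and indicates a bug"
    )


# ---------------------------------------------------------------------------
# Exhaustive, bit-vectorised enumeration


def _phase_successors(
    network: BooleanNetwork, scenario: Scenario, schedule: UpdateSchedule
) -> list[np.ndarray]:
    """Packed successor map of every state, for each phase of the schedule."""
    n = network.n
    omega = 1 << n
    dtype = np.uint32 if n <= 31 else np.uint64
    codes = np.arange(omega, dtype=dtype)
    valuation: dict[str, object] = {
        spec.name: (codes >> np.uint8(i)) & 1
        for i, spec in enumerate(network.internal_nodes)
    }
    valuation.update(scenario.input_clamps)
    phases = schedule.phase_count(network)
    successors = []
    for t in range(phases):
        succ = np.zeros(omega, dtype=dtype)
        for i, spec in enumerate(network.internal_nodes):
            if spec.name in scenario.perturbations:
                bit = scenario.perturbations[spec.name]
            elif schedule.is_due(spec.name, t):
                bit = spec.rule.evaluate(valuation)
            else:
                bit = valuation[spec.name]
            if isinstance(bit, (int, np.integer)):
                if bit & 1:
                    succ |= dtype(1 << i)
            else:
                succ |= (bit & 1).astype(dtype) << np.uint8(i)
        successors.append(succ)
    return successors


def _terminal_cycles(successors: list[np.ndarray]):
    """Cycles of the phase-composed map plus per-initial-state attractor ids."""
    omega = successors[0].size
    period_map = successors[0]
    for succ in successors[1:]:
        period_map = succ[period_map]
    # Pointer doubling: after >= omega compound steps every state sits on its cycle.
    reach = period_map
    steps = 1
    while steps < omega:
        reach = reach[reach]
        steps <<= 1
    attr_id = np.full(omega, -1, dtype=np.int64)
    cycles: list[list[int]] = []
    for s in np.unique(reach).tolist():
        if attr_id[s] >= 0:
            continue
        cyc = [s]
        t = int(period_map[s])
        while t != s:
            cyc.append(t)
            t = int(period_map[t])
        for c in cyc:
            attr_id[c] = len(cycles)
        cycles.append(cyc)
    basins = np.bincount(attr_id[reach], minlength=len(cycles))
    return cycles, basins


def enumerate_state_space(
    network: BooleanNetwork,
    scenario: Scenario,
    schedule: UpdateSchedule | None = None,
    ceiling: int = 24,
) -> AttractorAtlas:
    """Follow all 2**n initial internal states to their attractors.

    Returns an :class:`AttractorAtlas` whose basin sizes are exact integer
    counts summing to 2**n.  Identical attractors (cycles compared as
    rotation-invariant sequences) are merged by construction since the
    engine works on the explicit successor map.  Networks with
    ``n > ceiling`` are refused; sample trajectories with
    :func:`find_attractor` instead for larger systems.
    """
    schedule = schedule or UpdateSchedule.synchronous()
    scenario.validate(network)
    if network.n > ceiling:
        raise StateSpaceTooLargeError(
            f"n={network.n} exceeds enumeration ceiling {ceiling}; "
            "raise the ceiling or sample trajectories instead"
        )
    successors = _phase_successors(network, scenario, schedule)
    phases = len(successors)
    cycles, basins = _terminal_cycles(successors)
    attractors = []
    for aid, cyc in enumerate(cycles):
        # Expand the phase-composed cycle into the per-step timed sequence.
        seq: list[int] = []
        for start in cyc:
            cur = start
            for t in range(phases):
                seq.append(cur)
                cur = int(successors[t][cur])
        states_seq = tuple(network.decode(c) for c in seq)
        collapsed = _collapse(states_seq)
        kind = "fixed_point" if len(collapsed) == 1 else "cycle"
        canon = _min_rotation(states_seq, phases)
        attractors.append(
            Attractor(
                kind=kind,
                states=_collapse(canon),
                basin_size=int(basins[aid]),
                canonical_key=(kind, canon),
            )
        )
    attractors.sort(key=lambda a: (-a.basin_size, a.canonical_key))
    atlas = AttractorAtlas(network, scenario, schedule, attractors)
    atlas.validate()
    return atlas
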