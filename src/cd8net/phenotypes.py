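"""Attractor phenotyping and basin-weighted phenotype frequencies.

Fixed-point attractors of the CD8+ T-cell network are read out as cell
phenotypes with Boolean identifier rules over marker nodes, on two axes:

* **stage** — Naive (no master regulator expressed), Effector
  (EOMES with a master regulator, FOXO1 off) or Memory (the same with
  FOXO1 on); FOXO1 separates effector from memory programmes.
* **lineage** — Tc1 (T-BET/IFN-γ), Tc2 (GATA3/IL-4), Tc17 (RORγT),
  TcReg (FOXP3/IL-10), or Tc0 when no master regulator is expressed.
  The four polarized-lineage identifiers are mutually exclusive: each
  requires a master regulator that the others negate.

The Naive and Tc0 identifiers are logically identical; they are the same
cell read on different axes, and reports never double-count them.  A memory
attractor cannot match a polarized-lineage identifier (those require FOXO1
off), so its lineage is additionally inferred from master-regulator
identity alone and reported with stage Memory.

Phenotype frequency is basin-weighted: f_k = 100 * y_k / Omega, where y_k
is the exact integer count of initial configurations whose trajectory ends
in an attractor called k, and Omega = 2**n is the state-space size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .expr import BooleanExpression, parse_rule
from .network import Attractor, AttractorAtlas

__all__ = [
    "PhenotypeRule",
    "PhenotypeCall",
    "FrequencyTable",
    "STAGE_LABELS",
    "LINEAGE_LABELS",
    "default_phenotype_rules",
    "classify_attractor",
    "classify_state",
    "phenotype_frequencies",
    "frequency_delta",
]

STAGE_LABELS = ("Naive", "Effector", "Memory")
LINEAGE_LABELS = ("Tc0", "Tc1", "Tc2", "Tc17", "TcReg")

#: Master transcription factor defining each polarized lineage.
MASTER_REGULATORS = {"TBET": "Tc1", "GATA3": "Tc2", "RORgT": "Tc17", "FOXP3": "TcReg"}

# Identifier rules over internal marker nodes.  "FOX03" in the published
# TcReg identifier is read as FOXP3 (the network has no FOXO3 node) and the
# "FOX01" spelling as FOXO1; see cd8.ALIASES.
_RULE_TEXT = {
    "Naive": "¬(EOMES ˅ TBET ˅ GATA3 ˅ RORgT ˅ FOXP3)",
    "Effector": "¬FOXO1 ˄ EOMES ˄ (TBET ˅ GATA3 ˅ RORgT ˅ FOXP3)",
    "Memory": "FOXO1 ˄ EOMES ˄ (TBET ˅ GATA3 ˅ RORgT ˅ FOXP3)",
    "Tc0": "¬(EOMES ˅ TBET ˅ GATA3 ˅ RORgT ˅ FOXP3)",
    "Tc1": "EOMES ˄ (TBET ˄ IFNg) ˄ ¬FOXO1 ˄ ¬(GATA3 ˅ RORgT ˅ FOXP3)",
    "Tc2": "EOMES ˄ (GATA3 ˄ IL4) ˄ ¬FOXO1 ˄ ¬(TBET ˅ RORgT ˅ FOXP3)",
    "Tc17": "EOMES ˄ RORgT ˄ ¬FOXO1 ˄ ¬(TBET ˅ GATA3 ˅ FOXP3)",
    "TcReg": "EOMES ˄ (FOXP3 ˄ IL10) ˄ ¬FOXO1 ˄ ¬(TBET ˅ GATA3 ˅ RORgT)",
}

#: Expressed-protein markers reported as flags on classified attractors.
_FLAG_NODES = ("GranzymeB", "Casp3", "GLUT1")


@dataclass(frozen=True)
class PhenotypeRule:
    """A phenotype label with its Boolean classifier over marker nodes."""

    label: str
    classifier: BooleanExpression

    def matches(self, state: Mapping[str, int]) -> bool:
        return bool(self.classifier.evaluate(state))


def default_phenotype_rules(vocabulary: Iterable[str] | None = None) -> dict[str, PhenotypeRule]:
    """The packaged stage and lineage identifier rules."""
    rules = {}
    for label, text in _RULE_TEXT.items():
        expr = parse_rule(text, vocabulary)
        rules[label] = PhenotypeRule(label, expr)
    return rules


@dataclass(frozen=True)
class PhenotypeCall:
    """Stage and lineage call for one attractor, plus marker flags.

    ``lineage`` is the strict identifier-rule call (memory attractors and
    cycles are ``unclassified`` on this axis); ``memory_lineage`` carries
    the master-regulator-based lineage of a Memory-stage attractor.
    ``classified`` records whether the attractor matched any identifier at
    all — the quantity behind full-state-space convergence statements.
    """

    stage: str  # Naive | Effector | Memory | none
    lineage: str  # Tc0 | Tc1 | Tc2 | Tc17 | TcReg | unclassified
    memory_lineage: str = "unclassified"
    flags: frozenset[str] = frozenset()

    @property
    def classified(self) -> bool:
        return self.stage != "none" or self.lineage != "unclassified"


def classify_state(state: Mapping[str, int], rules: Mapping[str, PhenotypeRule]) -> PhenotypeCall:
    """Classify a single fixed-point state dictionary."""
    stage = "none"
    for label in STAGE_LABELS:
        if rules[label].matches(state):
            stage = label
            break
    lineage = "unclassified"
    for label in ("Tc1", "Tc2", "Tc17", "TcReg"):
        if rules[label].matches(state):
            lineage = label
            break
    if lineage == "unclassified" and rules["Tc0"].matches(state):
        lineage = "Tc0"
    memory_lineage = "unclassified"
    if stage == "Memory":
        masters = [lin for tf, lin in MASTER_REGULATORS.items() if state.get(tf)]
        if len(masters) == 1:
            memory_lineage = masters[0]
    flags = frozenset(
        f"{node}_positive" for node in _FLAG_NODES if state.get(node)
    )
    return PhenotypeCall(stage, lineage, memory_lineage, flags)


def classify_attractor(attractor: Attractor, rules: Mapping[str, PhenotypeRule], names: Sequence[str]) -> PhenotypeCall:
    """Classify an attractor; cycles are unclassified with stage ``none``."""
    if attractor.kind != "fixed_point":
        return PhenotypeCall("none", "unclassified")
    state = dict(zip(names, attractor.states[0]))
    missing = {leaf for r in rules.values() for leaf in r.classifier.leaves()} - set(state)
    if missing:
        raise KeyError(f"classifier references nodes absent from the state: {sorted(missing)}")
    return classify_state(state, rules)


@dataclass
class FrequencyTable:
    """Basin-weighted phenotype frequencies f_k = 100 * y_k / Omega.

    Counts are exact integers; frequencies are derived on demand, so no
    floating-point accumulation ever touches the basins.  On the lineage
    axis the labels Tc0..TcReg plus ``unclassified`` partition Omega.
    """

    omega: int
    lineage_counts: dict[str, int]
    stage_counts: dict[str, int]
    classified_count: int
    cyclic_count: int
    flag_counts: dict[str, int] = field(default_factory=dict)
    label: str = ""

    def freq(self, label: str) -> float:
        """Lineage frequency in percent."""
        return 100.0 * self.lineage_counts.get(label, 0) / self.omega

    def stage_freq(self, label: str) -> float:
        return 100.0 * self.stage_counts.get(label, 0) / self.omega

    @property
    def memory_fraction(self) -> float:
        return self.stage_freq("Memory")

    @property
    def classified_fraction(self) -> float:
        """Percent of state-space mass ending in identifier-matched fixed points."""
        return 100.0 * self.classified_count / self.omega

    @property
    def cyclic_fraction(self) -> float:
        return 100.0 * self.cyclic_count / self.omega

    def flag_fraction(self, flag: str, lineage: str | None = None) -> float:
        key = f"{lineage}:{flag}" if lineage else flag
        return 100.0 * self.flag_counts.get(key, 0) / self.omega

    def modal_lineage(self) -> str:
        """The most frequent polarized lineage, or ``none`` if no lineage
        carries any basin mass."""
        best = max(LINEAGE_LABELS, key=lambda l: (self.lineage_counts.get(l, 0), l))
        return best if self.lineage_counts.get(best, 0) > 0 else "none"

    def as_dict(self) -> dict[str, float]:
        out = {f"f_{l}": self.freq(l) for l in LINEAGE_LABELS}
        out["f_unclassified"] = self.freq("unclassified")
        out.update({f"stage_{s}": self.stage_freq(s) for s in STAGE_LABELS})
        out["classified"] = self.classified_fraction
        out["cyclic"] = self.cyclic_fraction
        return out

    def __str__(self):
        parts = [f"{l}={self.freq(l):.2f}%" for l in LINEAGE_LABELS]
        parts.append(f"Memory={self.memory_fraction:.2f}%")
        parts.append(f"classified={self.classified_fraction:.2f}%")
        return f"FrequencyTable({self.label}: " + ", ".join(parts) + ")"


def phenotype_frequencies(
    atlas: AttractorAtlas, rules: Mapping[str, PhenotypeRule] | None = None
) -> FrequencyTable:
    """Aggregate an attractor atlas into a phenotype frequency table."""
    rules = rules or default_phenotype_rules()
    names = atlas.network.names
    lineage_counts = {l: 0 for l in (*LINEAGE_LABELS, "unclassified")}
    stage_counts = {s: 0 for s in (*STAGE_LABELS, "none")}
    flag_counts: dict[str, int] = {}
    classified = 0
    cyclic = 0
    for attractor in atlas.attractors:
        call = classify_attractor(attractor, rules, names)
        y = attractor.basin_size
        lineage_counts[call.lineage] += y
        stage_counts[call.stage] += y
        if call.classified:
            classified += y
        if attractor.kind == "cycle":
            cyclic += y
        for flag in call.flags:
            flag_counts[flag] = flag_counts.get(flag, 0) + y
            if call.lineage != "unclassified":
                key = f"{call.lineage}:{flag}"
                flag_counts[key] = flag_counts.get(key, 0) + y
    table = FrequencyTable(
        omega=atlas.omega,
        lineage_counts=lineage_counts,
        stage_counts=stage_counts,
        classified_count=classified,
        cyclic_count=cyclic,
        flag_counts=flag_counts,
        label=atlas.scenario.label,
    )
    total = sum(lineage_counts.values())
    if total != atlas.omega:
        raise AssertionError(f"lineage partition broken: {total} != {atlas.omega}")
    return table


def frequency_delta(table_a: FrequencyTable, table_b: FrequencyTable) -> dict[str, float]:
    """Signed per-label frequency differences a - b, in percentage points."""
    if table_a.omega != table_b.omega:
        raise ValueError("frequency tables span different state-space sizes")
    if set(table_a.lineage_counts) != set(table_b.lineage_counts):
        raise ValueError("frequency tables carry different label sets")
    out = {l: table_a.freq(l) - table_b.freq(l) for l in (*LINEAGE_LABELS, "unclassified")}
    out["Memory"] = table_a.memory_fraction - table_b.memory_fraction
    return out
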