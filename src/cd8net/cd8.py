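"""The 18-node CD8+ T-cell differentiation network, its contexts and checks.

The model couples cytokine signalling (IL-2/4/6/10/12/15, IFN-γ/I, TGF-β),
the lineage-determining transcription factors (T-BET, GATA3, RORγT, FOXP3,
EOMES, FOXO1) and a metabolic regulatory module (ROS, SOD, Akt, mTORC1,
mTORC2) with effector outputs (IFN-γ, IL-4, IL-10, Granzyme B, GLUT1,
BCL-2, Casp-3).  Eighteen regulated nodes define the 2**18 state space;
seventeen extracellular or context signals are inputs clamped per scenario.

Two rule variants ship:

* ``verbatim`` — the published rule table exactly as printed, read under the
  parser's stated precedence with unbalanced parentheses auto-closed at end
  of expression and misspelled tokens alias-normalised.  Several printed
  rows are visibly damaged (five rows have unbalanced parentheses), so this
  variant is kept as the auditable literal reading, not as the working model.
* ``reconciled`` (default) — the verbatim rules plus a small set of repairs:
  regrouped parentheses where the literal reading contradicts the model's
  documented qualitative behaviour, and reconstructed tails for rows whose
  text is truncated mid-group.  Every repair is a first-class
  :class:`Deviation` record, printable via the deviations manifest and
  testable individually.

Scenario presets encode the cytokine milieus and metabolic stressors of the
study: five polarizing contexts (none, IL-12+IFN-γ, IL-6+TGF-β, IL-4+IL-12,
IL-4), four single stressors (hyperglycemia, dyslipidemia, ceramide,
ethanol) and their diabetic combination (hyperglycemia + dyslipidemia +
ceramide).  All presets run in the presence of IL-15 unless stated
otherwise; the PD-1 context signal is present in the pro-inflammatory
(IL-12 + IFN-γ) presets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from .expr import parse_rule
from .network import BooleanNetwork, NodeSpec, Scenario, apply_perturbation

__all__ = [
    "NODE_ORDER",
    "INPUT_ORDER",
    "ALIASES",
    "Deviation",
    "deviations_manifest",
    "build_cd8_network",
    "PRESETS",
    "POLARIZING_PRESET",
    "STRESSOR_PRESETS",
    "make_scenario",
    "stat6_null_scenario",
    "CellSpec",
    "CalibrationAssertion",
    "calibration_suite",
]

#: Internal (regulated) nodes in published row order; bit i of a packed
#: state code is the i-th entry.
NODE_ORDER = (
    "TBET", "IFNg", "GATA3", "IL4", "RORgT", "IL10", "FOXP3", "FOXO1",
    "EOMES", "mTORC1", "mTORC2", "ROS", "Akt", "GLUT1", "GranzymeB",
    "SOD", "BCL2", "Casp3",
)

#: Display spellings for reports.
DISPLAY_NAMES = {
    "TBET": "T-BET", "IFNg": "IFN-γ", "GATA3": "GATA3", "IL4": "IL-4",
    "RORgT": "RORγT", "IL10": "IL-10", "FOXP3": "FOXP3", "FOXO1": "FOXO1",
    "EOMES": "EOMES", "mTORC1": "mTORC1", "mTORC2": "mTORC2", "ROS": "ROS",
    "Akt": "Akt", "GLUT1": "GLUT1", "GranzymeB": "Granzyme B", "SOD": "SOD",
    "BCL2": "BCL-2", "Casp3": "Casp-3",
}

#: Input (context) signals.  The published input list names twelve signals;
#: five further names appear only on rule right-hand sides (IL2s, IL15s,
#: PD1, aa, GFs) and are declared as inputs too — a name that is never a
#: rule target cannot be a state variable.
INPUT_ORDER = (
    "IL12s", "IL6s", "TGFb", "IL4s", "IL10s", "IFNgs", "IFNI",
    "Glucose", "FFAs", "Ceramide", "FasL", "EtOH",
    "IL2s", "IL15s", "PD1", "aa", "GFs",
)

#: Token normalisations applied by the rule parser: unicode glyph spellings
#: and recurring OCR-style typos of the printed table mapped to canonical
#: node names.
ALIASES = {
    "IFNγ": "IFNg", "IFN-γ": "IFNg", "IFNγs": "IFNgs", "IFN-γs": "IFNgs",
    "TGFβ": "TGFb", "TGF-β": "TGFb",
    "RORγT": "RORgT", "RORγt": "RORgT",
    "T-BET": "TBET", "IL-4": "IL4", "IL-10": "IL10",
    "F0X01": "FOXO1", "FOX01": "FOXO1", "FOX0": "FOXO1", "F0X0": "FOXO1",
    "FOX03": "FOXP3",
    "Et0H": "EtOH",
    "IFN1": "IFNI",
    "IL12": "IL12s",  # bare "IL12" appears once, in the mTORC1 row
    "IL1": "IL12s",
    "Granzyme": "GranzymeB", "GranzymeB": "GranzymeB", "Granzyme-B": "GranzymeB",
    "BCL-2": "BCL2", "Casp-3": "Casp3",
}

#: Kinetic class per node, used for timed-asynchronous update periods:
#: metabolite pools are fastest, then signalling complexes, then
#: transcription factors and newly expressed proteins.
NODE_CLASSES = {
    "ROS": "metabolite",
    "mTORC1": "signaling", "mTORC2": "signaling", "Akt": "signaling",
    "Casp3": "signaling",
    "TBET": "transcription_factor", "GATA3": "transcription_factor",
    "RORgT": "transcription_factor", "FOXP3": "transcription_factor",
    "FOXO1": "transcription_factor", "EOMES": "transcription_factor",
    "IFNg": "expressed_protein", "IL4": "expressed_protein",
    "IL10": "expressed_protein", "GLUT1": "expressed_protein",
    "GranzymeB": "expressed_protein", "SOD": "expressed_protein",
    "BCL2": "expressed_protein",
}

#: The published logic rules, exactly as printed (glyphs, typos, unbalanced
#: parentheses included).  Five rows open parentheses that never close —
#: their text is truncated — and are auto-closed when parsed verbatim.
VERBATIM_RULES = {
    "TBET": "((IFNγ ˅ (IL12s ˄¬ (IL6s ˅ IL4 ˅ IL10))) ˅ TBET) ˄¬ (IL4 ˅ GATA3 ˅ IL6s ˅ F0X01)",
    "IFNg": "((IFNγs ˅ IFNI ˅ ((IFNγ ˅ TBET ˅ EOMES) ˄ mTORC1 ˄¬ (GATA3 ˅ TGFβ))) ˄¬ IL6s ˅ IL4 ˅ IL10)",
    "GATA3": "((IL2s ˄ IL4) ˅ EOMES ˅ GATA3) ˄¬ (TBET ˅ TGFβ ˅ IL6s ˅ IFNγ",
    "IL4": "(IL4s ˅ (GATA3 ˄ (IL2s ˅ IL4) ˄¬ (TBET)) ˄¬ (IFNγ ˅ IL6s)",
    "RORgT": "(IL6s ˄ TGFβ ˄¬( TBET ˅ FOXP3 ˅ GATA3 ˅ FOX01)",
    "IL10": "(IL10s ˅ EOMES ˅ (IL10 ˄ (IFNγ ˅ IL6s ˅ TGFβ ˅ GATA3))) ˄ mTORC1",
    "FOXP3": "((IL2s ˅ IL12s) ˄ TGFβ ˅ FOXP3 ˅ IL4 ˅ (FOX01 ˄¬ (IL6s ˅ RORγT)",
    "FOXO1": "(ROS ˅ FOX01) ˄¬( mTORC1 ˅ mTORC2)",
    "EOMES": "(ROS ˅ EOMES ˅ IFN1 ˄ FOX01 ˄¬( mTORC2)",
    "mTORC1": "(aa ˅ ROS ˅ IL12 ˅ IL12s ˅ Akt) ˄¬ (mTORC2 ˄ PD1 ˄ IL15s)",
    "mTORC2": "(GFs ˅ ROS) ˄ ¬mTORC1",
    "ROS": "(Glucose ˅ FFAs ˅ Ceramide ˅ Et0H) ˄¬SOD",
    "Akt": "(IFNγ ˅ IL4 ˅ IL10 ˅ mTORC2)",
    "GLUT1": "Akt ˄ EOMES ˄ ¬FOX01",
    "GranzymeB": "TBET ˄ ¬(GATA3 ˅ RORγT ˅ FOXP3 ˅ FOX01)",
    "SOD": "ROS ˄ (FOX01) ˄ ¬(Ceramide)",
    "BCL2": "(FOX01) ˄ ¬ROS",
    "Casp3": "FasL ˄(ROS ˅ Casp3) ˄ ¬BCL2",
}

# Reconciled rule overrides are defined below, after the Deviation records
# that document them.


@dataclass(frozen=True)
class Deviation:
    """One documented difference between the printed and working rules."""

    node: str
    kind: str  # "alias" | "regroup" | "tail_reconstruction"
    applies_to: str  # "both" | "reconciled"
    description: str
    verbatim_reading: str = ""
    reconciled_reading: str = ""


# The reconciled readings below are frozen against the calibration suite;
# docs/methods.md gives the reasoning per row.  ASCII operator spellings are
# used for readability; the parser treats them identically to the glyphs.
RECONCILED_RULES: dict[str, str] = {
    "IFNg": "(IFNgs | IFNI | ((IFNg | TBET | EOMES) & mTORC1 & !(GATA3 | TGFb)))"
            " & !(IL6s | IL4 | IL10)",
    "GATA3": "((IL2s & IL4) | EOMES | GATA3)"
             " & !(TBET | TGFb | IL6s | IFNg | FOXP3)",
    "IL4": "(IL4s | (GATA3 & (IL2s | IL4) & !TBET)) & !(IFNg | IL6s)",
    "FOXP3": "((IL2s | IL12s) & (TGFb | FOXP3 | IL4))"
             " | (FOXO1 & !(IL6s | RORgT))",
    "EOMES": "(ROS | EOMES | (IFNI & FOXO1) | TBET | GATA3 | RORgT | FOXP3)"
             " & !mTORC2",
    "mTORC1": "(aa | ROS | IL12s | Akt) & !(PD1 & IL15s)",
}

DEVIATIONS: list[Deviation] = [
    # --- token normalisations (apply to both variants) -------------------
    Deviation("FOXO1", "alias", "both",
              "spellings 'F0X01'/'FOX01' normalised to FOXO1 wherever they "
              "appear (T-BET, RORγT, FOXP3, FOXO1, EOMES, GLUT1, Granzyme B, "
              "SOD and BCL-2 rows)"),
    Deviation("EOMES", "alias", "both",
              "'IFN1' in the EOMES row normalised to IFNI (type-I interferon "
              "input; the network declares no 'IFN1')"),
    Deviation("ROS", "alias", "both",
              "'Et0H' in the ROS row normalised to EtOH"),
    Deviation("mTORC1", "alias", "both",
              "bare 'IL12' in the mTORC1 row normalised to the IL12s input "
              "(no separate IL12 species is declared)"),
    Deviation("TcReg", "alias", "both",
              "'FOX03' in the TcReg identifier read as FOXP3 (the network "
              "has no FOXO3 node and TcReg is FOXP3-defined)"),
    # --- auto-closed truncations (apply to both variants) ----------------
    Deviation("GATA3", "auto_close", "both",
              "printed rule opens a parenthesis never closed; closed at end "
              "of expression"),
    Deviation("IL4", "auto_close", "both",
              "printed rule opens a parenthesis never closed; closed at end "
              "of expression"),
    Deviation("RORgT", "auto_close", "both",
              "printed rule opens a parenthesis never closed; closed at end "
              "of expression"),
    Deviation("FOXP3", "auto_close", "both",
              "printed rule is missing three closing parentheses; closed at "
              "end of expression"),
    Deviation("EOMES", "auto_close", "both",
              "printed rule opens a parenthesis never closed; closed at end "
              "of expression"),
    # --- reconciled repairs ---------------------------------------------
    Deviation(
        "IFNg", "regroup", "reconciled",
        "the inhibitory tail is grouped as a single NOT over IL6s, IL-4 and "
        "IL-10; the literal reading puts IL-4 and IL-10 as top-level OR "
        "terms, which would switch IFN-γ on under IL-4 alone and "
        "contradicts the Tc2 polarization behaviour",
        verbatim_reading="(((IFNgs | IFNI | X) & !IL6s) | IL4 | IL10)",
        reconciled_reading="(IFNgs | IFNI | X) & !(IL6s | IL4 | IL10)",
    ),
    Deviation(
        "IL4", "regroup", "reconciled",
        "the !(IFNg | IL6s) factor gates the whole rule rather than only "
        "the GATA3 branch, so exogenous IL-4 signalling is also silenced "
        "by IFN-γ; the literal reading lets IL4s bypass IFN-γ repression",
        verbatim_reading="IL4s | (GATA3 & (IL2s | IL4) & !TBET & !(IFNg | IL6s))",
        reconciled_reading="(IL4s | (GATA3 & (IL2s | IL4) & !TBET)) & !(IFNg | IL6s)",
    ),
    Deviation(
        "FOXP3", "regroup", "reconciled",
        "the cytokine term is read as (IL2s | IL12s) & (TGFb | FOXP3 | IL4); "
        "the literal reading exposes FOXP3 and IL4 as unconditional OR terms, "
        "which forces FOXP3 on under IL-4 alone and contradicts Tc2 "
        "polarization",
        verbatim_reading="((IL2s | IL12s) & TGFb) | FOXP3 | IL4 | (FOXO1 & !(IL6s | RORgT))",
        reconciled_reading="((IL2s | IL12s) & (TGFb | FOXP3 | IL4)) | (FOXO1 & !(IL6s | RORgT))",
    ),
    Deviation(
        "GATA3", "tail_reconstruction", "reconciled",
        "FOXP3 added to the truncated inhibitor group: without FOXP3 "
        "repression of GATA3, EOMES-driven GATA3 switches on in every "
        "TcReg-bound trajectory and the TcReg phenotype (which requires "
        "GATA3 off) is unreachable in the IL-4 + IL-12 context",
        verbatim_reading="... & !(TBET | TGFb | IL6s | IFNg)",
        reconciled_reading="... & !(TBET | TGFb | IL6s | IFNg | FOXP3)",
    ),
    Deviation(
        "EOMES", "tail_reconstruction", "reconciled",
        "the truncated row is completed so that the lineage master "
        "regulators drive EOMES and mTORC2 gates the whole rule: every "
        "effector/memory identifier requires EOMES, so without a "
        "master-regulator drive half the state space parks in "
        "master-on/EOMES-off attractors that match no identifier, "
        "contradicting the full classification of the inflammatory cells",
        verbatim_reading="ROS | EOMES | (IFNI & FOXO1 & !mTORC2)",
        reconciled_reading="(ROS | EOMES | (IFNI & FOXO1) | TBET | GATA3 | RORgT | FOXP3) & !mTORC2",
    ),
    Deviation(
        "mTORC1", "regroup", "reconciled",
        "the inhibitory complex is read as PD-1 with IL-15; as printed the "
        "suppression additionally requires mTORC2, which can only activate "
        "through ROS or growth factors, so mTORC1 could never switch off in "
        "unstressed cells, FOXO1 would stay off and no memory phenotype "
        "could exist in any cytokine context",
        verbatim_reading="(aa | ROS | IL12s | Akt) & !(mTORC2 & PD1 & IL15s)",
        reconciled_reading="(aa | ROS | IL12s | Akt) & !(PD1 & IL15s)",
    ),
]


def deviations_manifest(variant: str = "reconciled") -> list[Deviation]:
    """Deviation records in force for ``variant`` (aliases apply to both)."""
    if variant == "verbatim":
        return [d for d in DEVIATIONS if d.applies_to == "both"]
    if variant == "reconciled":
        return list(DEVIATIONS)
    raise ValueError(f"unknown rule variant {variant!r}")


def packaged_model_path(rule_variant: str = "reconciled"):
    """Path to the shipped BoolNet-style rule file for ``rule_variant``."""
    if rule_variant not in ("verbatim", "reconciled"):
        raise ValueError(f"unknown rule variant {rule_variant!r}")
    from importlib.resources import files

    return files("cd8net") / "data" / f"cd8_{rule_variant}.bnet"


def packaged_presets_path():
    """Path to the shipped scenario-preset config file."""
    from importlib.resources import files

    return files("cd8net") / "data" / "presets.yaml"


def build_cd8_network(rule_variant: str = "reconciled") -> BooleanNetwork:
    """Build the 18-node CD8+ T-cell network in the requested rule variant."""
    if rule_variant not in ("verbatim", "reconciled"):
        raise ValueError(f"unknown rule variant {rule_variant!r}")
    vocab = set(NODE_ORDER) | set(INPUT_ORDER)
    nodes = []
    for name in NODE_ORDER:
        text = VERBATIM_RULES[name]
        if rule_variant == "reconciled" and name in RECONCILED_RULES:
            text = RECONCILED_RULES[name]
        rule = parse_rule(text, vocab, aliases=ALIASES)
        nodes.append(NodeSpec(name, rule, NODE_CLASSES[name]))
    return BooleanNetwork(nodes, INPUT_ORDER, name=f"cd8-{rule_variant}")


# ---------------------------------------------------------------------------
# Scenario presets

#: Named input contexts (values not listed default to 0, except IL15s=1).
PRESETS: dict[str, dict[str, int]] = {
    "no_cytokines": {},
    "il12_ifng": {"IL12s": 1, "IFNgs": 1, "PD1": 1},
    "il6_tgfb": {"IL6s": 1, "TGFb": 1},
    "il4_il12": {"IL4s": 1, "IL12s": 1},
    "il4": {"IL4s": 1},
    "hyperglycemia": {"Glucose": 1},
    "dyslipidemia": {"FFAs": 1},
    "ceramide": {"Ceramide": 1},
    "ethanol": {"EtOH": 1},
    "diabetic": {"Glucose": 1, "FFAs": 1, "Ceramide": 1},
}

#: Figure-panel provenance of each preset.
PRESET_NOTES = {
    "no_cytokines": "baseline activated population, no polarizing cytokines",
    "il12_ifng": "IL-12 + IFN-γ pro-inflammatory polarization (PD-1 engaged)",
    "il6_tgfb": "IL-6 + TGF-β Tc17 polarization",
    "il4_il12": "IL-4 + IL-12 regulatory polarization",
    "il4": "IL-4 Tc2 polarization",
    "hyperglycemia": "high glucose",
    "dyslipidemia": "high free fatty acids",
    "ceramide": "high systemic ceramides",
    "ethanol": "chronic alcohol exposure",
    "diabetic": "type-II-diabetes context: hyperglycemia + dyslipidemia + ceramides",
}

#: Polarizing preset under which each phenotype is read out.
POLARIZING_PRESET = {
    "Tc0": "no_cytokines",
    "Tc1": "il12_ifng",
    "Tc2": "il4",
    "Tc17": "il6_tgfb",
    "TcReg": "il4_il12",
}

#: The metabolic stressor presets applied on top of polarizing contexts.
STRESSOR_PRESETS = ("hyperglycemia", "dyslipidemia", "ceramide", "ethanol", "diabetic")


def make_scenario(
    preset_name: str,
    extra_inputs: Mapping[str, int] | None = None,
    perturbations: Mapping[str, int] | None = None,
    label: str | None = None,
) -> Scenario:
    """Build a total-input scenario from a preset plus overrides.

    Every declared input is clamped: unnamed inputs default to 0 except
    IL15s, which defaults to 1 (simulations run in the presence of IL-15
    unless the condition states otherwise).
    """
    if preset_name not in PRESETS:
        raise ValueError(f"unknown preset {preset_name!r}; have {sorted(PRESETS)}")
    clamps = {name: 0 for name in INPUT_ORDER}
    clamps["IL15s"] = 1
    clamps.update(PRESETS[preset_name])
    for name, value in (extra_inputs or {}).items():
        if name not in clamps:
            raise ValueError(f"unknown input {name!r}")
        clamps[name] = int(value)
    perturbations = dict(perturbations or {})
    bad = set(perturbations) - set(NODE_ORDER)
    if bad:
        raise ValueError(f"perturbations target unknown nodes {sorted(bad)}")
    if label is None:
        label = preset_name
        extras = {k: v for k, v in (extra_inputs or {}).items()}
        if extras:
            label += "+" + ",".join(f"{k}={v}" for k, v in sorted(extras.items()))
        if perturbations:
            label += "+" + ",".join(
                f"{k}_{'ki' if v else 'ko'}" for k, v in sorted(perturbations.items())
            )
    return Scenario(input_clamps=clamps, perturbations=perturbations, label=label)


def stat6_null_scenario(base: Scenario) -> Scenario:
    """STAT6 knockout: suppress the IL-4/STAT6-responsive nodes.

    In this network the transcriptional response to IL-4 runs through STAT6
    into GATA3, autocrine IL-4 and IL-10 (all are STAT6 targets in type-2
    polarization), so a STAT6 null clamps the three to 0.  Idempotent.
    """
    out = apply_perturbation(base, "GATA3", 0)
    out = apply_perturbation(out, "IL4", 0)
    out = apply_perturbation(out, "IL10", 0)
    from dataclasses import replace

    if not base.label.endswith("+stat6_null"):
        out = replace(out, label=base.label + "+stat6_null")
    return out


# ---------------------------------------------------------------------------
# Calibration suite


@dataclass(frozen=True)
class CellSpec:
    """A simulation cell: preset plus input/perturbation overrides."""

    label: str
    preset: str
    extra_inputs: Mapping[str, int] = field(default_factory=dict)
    perturbations: Mapping[str, int] = field(default_factory=dict)

    def scenario(self) -> Scenario:
        return make_scenario(
            self.preset, self.extra_inputs, self.perturbations, label=self.label
        )


@dataclass(frozen=True)
class CalibrationAssertion:
    """A qualitative outcome the working model must reproduce.

    ``check`` receives a mapping from cell label to
    :class:`~cd8net.phenotypes.FrequencyTable` covering ``cells`` and
    returns True when the observation is reproduced.
    """

    name: str
    description: str
    provenance: str
    cells: tuple[CellSpec, ...]
    check: Callable[[Mapping[str, object]], bool]


def _cell(label, preset, extra=None, pert=None) -> CellSpec:
    return CellSpec(label, preset, dict(extra or {}), dict(pert or {}))


_BASE_CELLS = {
    "no_cytokines": _cell("no_cytokines", "no_cytokines"),
    "il12_ifng": _cell("il12_ifng", "il12_ifng"),
    "il6_tgfb": _cell("il6_tgfb", "il6_tgfb"),
    "il4_il12": _cell("il4_il12", "il4_il12"),
    "il4": _cell("il4", "il4"),
}

_EFFECTOR_LINEAGES = ("Tc0", "Tc1", "Tc2", "Tc17")


def _polarized_cell(lineage: str, stressor: str | None = None, pert=None) -> CellSpec:
    preset = POLARIZING_PRESET[lineage]
    extra = dict(PRESETS[stressor]) if stressor else {}
    label = preset + (f"+{stressor}" if stressor else "")
    if pert:
        label += "+" + ",".join(f"{k}_{'ki' if v else 'ko'}" for k, v in sorted(pert.items()))
    return _cell(label, preset, extra, pert)


def calibration_suite() -> list[CalibrationAssertion]:
    """The qualitative outcomes the model is calibrated against.

    Each assertion is decidable from frequency tables of its listed cells
    and carries the observation it encodes.  The same suite is evaluated
    under both update schedules.
    """
    suite: list[CalibrationAssertion] = []

    def add(name, description, provenance, cells, check):
        suite.append(CalibrationAssertion(name, description, provenance, tuple(cells), check))

    add(
        "tc0_baseline",
        "Without polarizing cytokines the population mainly keeps the Tc0 "
        "phenotype, with Tc1 and Tc17 also present",
        "an activated population of CD8+ T lymphocytes mainly preserves the "
        "phenotype Tc0, which then generates basal levels of the Tc1 "
        "phenotype, and finally gives rise to the Tc17 phenotype",
        [_BASE_CELLS["no_cytokines"]],
        lambda t: t["no_cytokines"].modal_lineage() == "Tc0"
        and t["no_cytokines"].freq("Tc1") > 0
        and t["no_cytokines"].freq("Tc17") > 0,
    )
    add(
        "tc1_vs_tc17_inflammatory",
        "IL-12 + IFN-γ raises Tc1 above Tc17",
        "In presence of IL-12 and IFN-γ, the Tc1 phenotype increases "
        "compared to the Tc17 phenotype",
        [_BASE_CELLS["il12_ifng"]],
        lambda t: t["il12_ifng"].freq("Tc1") > t["il12_ifng"].freq("Tc17"),
    )
    add(
        "tc17_induction",
        "IL-6 + TGF-β raises Tc17 above its unstimulated level",
        "The Tc17 phenotype increases when the population is stimulated "
        "with IL-6 and TGF-β",
        [_BASE_CELLS["il6_tgfb"], _BASE_CELLS["no_cytokines"]],
        lambda t: t["il6_tgfb"].freq("Tc17") > t["no_cytokines"].freq("Tc17"),
    )
    add(
        "tcreg_il4_il12",
        "IL-4 + IL-12 makes TcReg the modal phenotype",
        "IL-4 with IL-12 mainly produce CD8+ T regulatory cells (TcReg)",
        [_BASE_CELLS["il4_il12"]],
        lambda t: t["il4_il12"].modal_lineage() == "TcReg",
    )
    add(
        "tc2_il4",
        "IL-4 alone makes Tc2 the modal phenotype",
        "Adding IL-4 alone polarizes CD8+ T cells to Tc2 phenotype",
        [_BASE_CELLS["il4"]],
        lambda t: t["il4"].modal_lineage() == "Tc2",
    )
    add(
        "stat6_null_tc1_switch",
        "Under IL-4, a STAT6 null polarizes to Tc1 instead of Tc2",
        "in absence of STAT6 during stimulation with IL-4, CD8+ T cells are "
        "polarized towards the Tc1 phenotype instead of Tc2",
        [
            _cell("il4+stat6_null", "il4", pert={"GATA3": 0, "IL4": 0, "IL10": 0}),
        ],
        lambda t: t["il4+stat6_null"].freq("Tc1") > t["il4+stat6_null"].freq("Tc2"),
    )
    add(
        "il15_memory",
        "Removing IL-15 signalling minimizes memory generation in the "
        "pro-inflammatory context",
        "as a result of IL-15 signaling absence, during a pro-inflammatory "
        "context mediated by IFN-γ and IL-12, the generation of memory "
        "cells is minimized",
        [_cell("il12_ifng+IL15s=0", "il12_ifng", {"IL15s": 0}), _BASE_CELLS["il12_ifng"]],
        lambda t: t["il12_ifng+IL15s=0"].memory_fraction
        < t["il12_ifng"].memory_fraction,
    )
    add(
        "pd1_memory",
        "Removing PD-1 signalling reduces memory in the pro-inflammatory context",
        "The same was also reported during stimulation with IFN-γ and IL-12 "
        "in the absence of PD-1 signaling",
        [_cell("il12_ifng+PD1=0", "il12_ifng", {"PD1": 0}), _BASE_CELLS["il12_ifng"]],
        lambda t: t["il12_ifng+PD1=0"].memory_fraction < t["il12_ifng"].memory_fraction,
    )
    add(
        "ffa_tc1_downregulation",
        "Free fatty acids reduce Tc1 under IL-12 + IFN-γ",
        "the presence of free fatty acids (FFAs) downregulates the "
        "differentiation of Tc1 phenotype",
        [_cell("il12_ifng+FFAs=1", "il12_ifng", {"FFAs": 1}), _BASE_CELLS["il12_ifng"]],
        lambda t: t["il12_ifng+FFAs=1"].freq("Tc1") < t["il12_ifng"].freq("Tc1"),
    )
    add(
        "ethanol_memory",
        "Ethanol reduces memory under IL-12 + IFN-γ",
        "chronic consumption of alcohol reduces CD8+ T cell memory",
        [_cell("il12_ifng+EtOH=1", "il12_ifng", {"EtOH": 1}), _BASE_CELLS["il12_ifng"]],
        lambda t: t["il12_ifng+EtOH=1"].memory_fraction < t["il12_ifng"].memory_fraction,
    )

    stressor_cells = [
        _polarized_cell(lin, s)
        for s in STRESSOR_PRESETS
        for lin in _EFFECTOR_LINEAGES
    ]
    add(
        "stressors_abolish_effectors",
        "Each metabolic stressor and their diabetic combination zeroes "
        "Tc0, Tc1, Tc2 and Tc17 under the corresponding polarizing presets",
        "either hyperglycemia, dyslipidemia, high levels of ceramides or "
        "alcohol were able to abrogate the differentiation of CD8+ T cells "
        "to Tc0, Tc1, Tc2 and Tc17 phenotypes",
        stressor_cells,
        lambda t: all(
            t[_polarized_cell(lin, s).label].freq(lin) == 0
            for s in STRESSOR_PRESETS
            for lin in _EFFECTOR_LINEAGES
        ),
    )
    tcreg_cells = [_polarized_cell("TcReg", s) for s in STRESSOR_PRESETS]
    add(
        "tcreg_resistant",
        "TcReg frequency is unchanged by every metabolic stressor",
        "TcReg cells are resistant to nutritional impairment, such as "
        "hyperglycemia, dyslipidemia, or high levels of ceramides and ethanol",
        tcreg_cells + [_BASE_CELLS["il4_il12"]],
        lambda t: all(
            t[_polarized_cell("TcReg", s).label].freq("TcReg")
            == t["il4_il12"].freq("TcReg")
            for s in STRESSOR_PRESETS
        ),
    )

    diabetic_base = [_polarized_cell(lin, "diabetic") for lin in POLARIZING_PRESET]
    pert_cells = []
    for pert in ({"ROS": 0}, {"SOD": 1}, {"mTORC2": 0}, {"mTORC2": 1}):
        for lin in POLARIZING_PRESET:
            pert_cells.append(_polarized_cell(lin, "diabetic", pert))

    def _check_rescue(t):
        def eff_sum(pert=None):
            return sum(
                t[_polarized_cell(lin, "diabetic", pert).label].freq(lin)
                for lin in _EFFECTOR_LINEAGES
            )

        baseline = eff_sum()
        ros_ko = eff_sum({"ROS": 0})
        sod_ki = eff_sum({"SOD": 1})
        mtorc2_ko_all_zero = all(
            t[_polarized_cell(lin, "diabetic", {"mTORC2": 0}).label].freq(lin) == 0
            for lin in _EFFECTOR_LINEAGES
        )
        mtorc2_ki_all_present = all(
            t[_polarized_cell(lin, "diabetic", {"mTORC2": 1}).label].freq(lin) > 0
            for lin in POLARIZING_PRESET
        )
        return (
            ros_ko > baseline
            and sod_ki > baseline
            and mtorc2_ko_all_zero
            and mtorc2_ki_all_present
        )

    add(
        "metabolic_module_rescue",
        "In the diabetic context: ROS knockout or SOD knock-in partially "
        "restores effector phenotypes, mTORC2 knockout abolishes them all, "
        "and mTORC2 knock-in restores every lineage",
        "suppressing ROS was associated with an improvement ... total "
        "abrogation of such effector phenotypes was observed when we "
        "inhibited mTORC2 ... over-expression of mTORC2 restores all "
        "effector phenotypes of CD8+ T cells",
        diabetic_base + pert_cells,
        _check_rescue,
    )
    return suite
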