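"""Scripted simulation campaigns: validation panel, stressor and KO/KI screens.

Four campaigns reproduce the study's computational experiments:

* ``validation`` — the ten cytokine/mutant cells of the validation panel
  (five baseline polarizations and five mutant/condition cells), with the
  qualitative calibration assertions that concern them and the
  classified-fixed-point convergence fraction per cell.
* ``metabolic`` — the five metabolic stressor presets (hyperglycemia,
  dyslipidemia, ceramide, ethanol, diabetic) crossed with the five
  polarizing presets, plus the Granzyme-B-positive Tc1 readout under
  dyslipidemia.
* ``knockout`` / ``knockin`` — clamp screens over the metabolic regulatory
  module (SOD, Akt, ROS, mTORC1, mTORC2) in the diabetic context, with
  per-phenotype frequency deltas against the unperturbed diabetic baseline
  and a summary of total change per target.

Each campaign emits byte-reproducible frequency tables (exact integer basin
counts), per-assertion verdicts with their provenance quotes, and the
deviations manifest of the rule variant used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .cd8 import (
    PRESETS,
    POLARIZING_PRESET,
    STRESSOR_PRESETS,
    CellSpec,
    build_cd8_network,
    calibration_suite,
    deviations_manifest,
)
from .network import BooleanNetwork, UpdateSchedule, enumerate_state_space
from .phenotypes import (
    FrequencyTable,
    LINEAGE_LABELS,
    frequency_delta,
    phenotype_frequencies,
)

__all__ = [
    "PERTURBATION_TARGETS",
    "CampaignReport",
    "CampaignRunner",
    "run_validation_panel",
    "run_metabolic_screen",
    "run_perturbation_screen",
]

#: Metabolic regulatory module nodes screened by clamping.
PERTURBATION_TARGETS = ("SOD", "Akt", "ROS", "mTORC1", "mTORC2")

_EFFECTOR_LINEAGES = ("Tc0", "Tc1", "Tc2", "Tc17")

#: The ten validation-panel cells, in panel order.
VALIDATION_CELLS = (
    CellSpec("no_cytokines", "no_cytokines"),
    CellSpec("il12_ifng", "il12_ifng"),
    CellSpec("il6_tgfb", "il6_tgfb"),
    CellSpec("il4_il12", "il4_il12"),
    CellSpec("il4", "il4"),
    CellSpec("il4+stat6_null", "il4", perturbations={"GATA3": 0, "IL4": 0, "IL10": 0}),
    CellSpec("il12_ifng+IL15s=0", "il12_ifng", {"IL15s": 0}),
    CellSpec("il12_ifng+PD1=0", "il12_ifng", {"PD1": 0}),
    CellSpec("il12_ifng+FFAs=1", "il12_ifng", {"FFAs": 1}),
    CellSpec("il12_ifng+EtOH=1", "il12_ifng", {"EtOH": 1}),
)

#: Assertions evaluated by each campaign.
_CAMPAIGN_ASSERTIONS = {
    "validation": (
        "tc0_baseline", "tc1_vs_tc17_inflammatory", "tc17_induction",
        "tcreg_il4_il12", "tc2_il4", "stat6_null_tc1_switch", "il15_memory",
        "pd1_memory", "ffa_tc1_downregulation", "ethanol_memory",
    ),
    "metabolic": ("stressors_abolish_effectors", "tcreg_resistant"),
    "knockout": ("metabolic_module_rescue",),
    "knockin": ("metabolic_module_rescue",),
}


@dataclass
class AssertionVerdict:
    name: str
    passed: bool
    description: str
    provenance: str


@dataclass
class CampaignReport:
    """Frequency tables, verdicts and convergence for one campaign run."""

    name: str
    rule_variant: str
    schedule_mode: str
    tables: dict[str, FrequencyTable]
    verdicts: list[AssertionVerdict]
    convergence: dict[str, float]
    deltas: dict[str, dict[str, float]] = field(default_factory=dict)
    summary_change: dict[str, float] = field(default_factory=dict)
    extras: dict[str, float] = field(default_factory=dict)

    @property
    def all_passed(self) -> bool:
        return all(v.passed for v in self.verdicts)

    def to_markdown(self) -> str:
        lines = [f"# Campaign: {self.name}",
                 f"rule variant: {self.rule_variant}; schedule: {self.schedule_mode}",
                 "", "## Frequency tables (percent of state space)", ""]
        head = "| cell | " + " | ".join(LINEAGE_LABELS) + " | Memory | classified |"
        lines += [head, "|" + "---|" * (len(LINEAGE_LABELS) + 3)]
        for label, t in self.tables.items():
            row = [label] + [f"{t.freq(l):.2f}" for l in LINEAGE_LABELS]
            row += [f"{t.memory_fraction:.2f}", f"{t.classified_fraction:.2f}"]
            lines.append("| " + " | ".join(row) + " |")
        if self.summary_change:
            lines += ["", "## Total change per target (sum of |Δf| over phenotypes)", ""]
            for target, value in self.summary_change.items():
                lines.append(f"- {target}: {value:.2f}")
        lines += ["", "## Assertion verdicts", ""]
        for v in self.verdicts:
            mark = "PASS" if v.passed else "FAIL"
            lines.append(f"- **{mark}** `{v.name}`: {v.description}")
            lines.append(f"  - basis: \"{v.provenance}\"")
        ndev = len(deviations_manifest(self.rule_variant))
        lines += ["", f"(rule-variant deviations in force: {ndev}; "
                  "see `cd8net show-model` for the manifest)"]
        return "\n".join(lines) + "\n"

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stem = f"{self.name}_{self.schedule_mode}_{self.rule_variant}"
        payload = {
            "campaign": self.name,
            "rule_variant": self.rule_variant,
            "schedule": self.schedule_mode,
            "tables": {label: t.as_dict() for label, t in self.tables.items()},
            "convergence": self.convergence,
            "deltas": self.deltas,
            "summary_change": self.summary_change,
            "extras": self.extras,
            "verdicts": [
                {"name": v.name, "passed": v.passed, "basis": v.provenance}
                for v in self.verdicts
            ],
        }
        (outdir / f"{stem}.json").write_text(json.dumps(payload, indent=2))
        (outdir / f"{stem}.md").write_text(self.to_markdown())
        rows = ["cell," + ",".join(f"f_{l}" for l in LINEAGE_LABELS)
                + ",memory,classified"]
        for label, t in self.tables.items():
            rows.append(
                label + "," + ",".join(f"{t.freq(l):.6f}" for l in LINEAGE_LABELS)
                + f",{t.memory_fraction:.6f},{t.classified_fraction:.6f}"
            )
        (outdir / f"{stem}.csv").write_text("\n".join(rows) + "\n")


class CampaignRunner:
    """Shared network/schedule/table cache behind the campaign functions."""

    def __init__(self, rule_variant: str = "reconciled", schedule_mode: str = "synchronous"):
        self.rule_variant = rule_variant
        self.schedule_mode = schedule_mode
        self.network: BooleanNetwork = build_cd8_network(rule_variant)
        if schedule_mode == "synchronous":
            self.schedule = UpdateSchedule.synchronous()
        elif schedule_mode == "asynchronous":
            self.schedule = UpdateSchedule.asynchronous(self.network)
        else:
            raise ValueError(f"unknown schedule mode {schedule_mode!r}")
        self._cache: dict[str, FrequencyTable] = {}

    def table(self, cell: CellSpec) -> FrequencyTable:
        if cell.label not in self._cache:
            atlas = enumerate_state_space(self.network, cell.scenario(), self.schedule)
            self._cache[cell.label] = phenotype_frequencies(atlas)
        return self._cache[cell.label]

    def verdicts(self, assertion_names: Sequence[str]) -> list[AssertionVerdict]:
        out = []
        for assertion in calibration_suite():
            if assertion.name not in assertion_names:
                continue
            tables = {c.label: self.table(c) for c in assertion.cells}
            out.append(
                AssertionVerdict(
                    assertion.name, bool(assertion.check(tables)),
                    assertion.description, assertion.provenance,
                )
            )
        return out


def _polarized_cell(lineage, stressor=None, pert=None) -> CellSpec:
    preset = POLARIZING_PRESET[lineage]
    extra = dict(PRESETS[stressor]) if stressor else {}
    label = preset + (f"+{stressor}" if stressor else "")
    if pert:
        label += "+" + ",".join(
            f"{k}_{'ki' if v else 'ko'}" for k, v in sorted(pert.items())
        )
    return CellSpec(label, preset, extra, dict(pert or {}))


def run_validation_panel(
    schedule_mode: str = "synchronous", rule_variant: str = "reconciled"
) -> CampaignReport:
    """The ten-cell cytokine/mutant validation panel."""
    runner = CampaignRunner(rule_variant, schedule_mode)
    tables = {cell.label: runner.table(cell) for cell in VALIDATION_CELLS}
    return CampaignReport(
        name="validation",
        rule_variant=rule_variant,
        schedule_mode=schedule_mode,
        tables=tables,
        verdicts=runner.verdicts(_CAMPAIGN_ASSERTIONS["validation"]),
        convergence={l: t.classified_fraction for l, t in tables.items()},
    )


def run_metabolic_screen(
    schedule_mode: str = "synchronous", rule_variant: str = "reconciled"
) -> CampaignReport:
    """Stressor x polarizing-preset screen with the Granzyme-B Tc1 readout."""
    runner = CampaignRunner(rule_variant, schedule_mode)
    tables: dict[str, FrequencyTable] = {}
    deltas: dict[str, dict[str, float]] = {}
    for lineage in POLARIZING_PRESET:
        base = _polarized_cell(lineage)
        tables[base.label] = runner.table(base)
        for stressor in STRESSOR_PRESETS:
            cell = _polarized_cell(lineage, stressor)
            tables[cell.label] = runner.table(cell)
            deltas[cell.label] = frequency_delta(tables[cell.label], tables[base.label])
    gzb_base = runner.table(_polarized_cell("Tc1")).flag_fraction(
        "GranzymeB_positive", "Tc1"
    )
    gzb_ffa = runner.table(_polarized_cell("Tc1", "dyslipidemia")).flag_fraction(
        "GranzymeB_positive", "Tc1"
    )
    return CampaignReport(
        name="metabolic",
        rule_variant=rule_variant,
        schedule_mode=schedule_mode,
        tables=tables,
        verdicts=runner.verdicts(_CAMPAIGN_ASSERTIONS["metabolic"]),
        convergence={l: t.classified_fraction for l, t in tables.items()},
        deltas=deltas,
        extras={
            "granzymeB_tc1_baseline": gzb_base,
            "granzymeB_tc1_dyslipidemia": gzb_ffa,
        },
    )


def run_perturbation_screen(
    direction: str,
    targets: Sequence[str] = PERTURBATION_TARGETS,
    schedule_mode: str = "synchronous",
    rule_variant: str = "reconciled",
) -> CampaignReport:
    """Knock-out (clamp 0) or knock-in (clamp 1) screen in the diabetic context.

    For every target the five polarizing presets are re-run with the clamp on
    top of the diabetic stressor combination; deltas are reported against the
    unperturbed diabetic baseline, and ``summary_change`` gives the
    per-target sum of |Δf| over the five phenotype readouts.
    """
    if direction not in ("knockout", "knockin"):
        raise ValueError(f"direction must be 'knockout' or 'knockin', got {direction!r}")
    unknown = set(targets) - set(PERTURBATION_TARGETS)
    if unknown:
        raise ValueError(f"unknown perturbation targets {sorted(unknown)}")
    value = 0 if direction == "knockout" else 1
    runner = CampaignRunner(rule_variant, schedule_mode)
    tables: dict[str, FrequencyTable] = {}
    deltas: dict[str, dict[str, float]] = {}
    summary: dict[str, float] = {}
    baselines = {}
    for lineage in POLARIZING_PRESET:
        cell = _polarized_cell(lineage, "diabetic")
        baselines[lineage] = cell
        tables[cell.label] = runner.table(cell)
    for target in targets:
        total = 0.0
        for lineage in POLARIZING_PRESET:
            cell = _polarized_cell(lineage, "diabetic", {target: value})
            tables[cell.label] = runner.table(cell)
            delta = frequency_delta(
                tables[cell.label], tables[baselines[lineage].label]
            )
            deltas[cell.label] = delta
            total += abs(delta[lineage])
        summary[target] = total
    return CampaignReport(
        name=direction,
        rule_variant=rule_variant,
        schedule_mode=schedule_mode,
        tables=tables,
        verdicts=runner.verdicts(_CAMPAIGN_ASSERTIONS[direction]),
        convergence={l: t.classified_fraction for l, t in tables.items()},
        deltas=deltas,
        summary_change=summary,
    )
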