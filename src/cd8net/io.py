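"""File formats: BoolNet-style rule files, scenario configs, result tables.

Networks are stored in the plain-text ``targets, factors`` dialect used by
the BoolNet ecosystem::

    targets, factors
    A, B & !C
    u, u

A line whose factor is exactly its own name declares an input (a clamped
context signal rather than a state variable).  An optional ``#class:``
comment after a rule records the node's kinetic class.  Round-tripping a
network through write/read preserves rule logic exactly.

Scenario and schedule configuration travels in YAML (or JSON, a YAML
subset) with keys ``inputs``, ``perturbations``, ``schedule.mode`` and
``schedule.periods``.  Atlas and frequency exports are CSV/JSON, one row
per attractor or label, each file opened by a provenance header echoing the
package version and the configuration that produced it.
"""

from __future__ import annotations

import csv
import io as _io
import json
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__
from .expr import parse_rule
from .network import (
    Attractor,
    AttractorAtlas,
    BooleanNetwork,
    NodeSpec,
    Scenario,
    UpdateSchedule,
)
from .phenotypes import FrequencyTable, LINEAGE_LABELS, STAGE_LABELS

__all__ = [
    "read_network_file",
    "write_network_file",
    "read_scenario_config",
    "write_scenario_config",
    "atlas_records",
    "write_atlas",
    "write_frequencies",
]


def write_network_file(network: BooleanNetwork, path) -> None:
    """Write a network in the BoolNet-style ``targets, factors`` dialect."""
    lines = ["targets, factors"]
    for spec in network.internal_nodes:
        lines.append(f"{spec.name}, {spec.rule}  #class: {spec.node_class}")
    for name in network.input_nodes:
        lines.append(f"{name}, {name}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_network_file(path, name: str | None = None) -> BooleanNetwork:
    """Read a BoolNet-style rule file into a :class:`BooleanNetwork`.

    Parse repairs (auto-closed parentheses) are logged; unknown names in a
    rule raise with the offending identifier, and malformed lines raise
    with their line number.
    """
    path = Path(path)
    rows: list[tuple[str, str, str, int]] = []
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.lower().replace(" ", "") == "targets,factors":
            continue
        if "," not in line:
            raise ValueError(f"{path}:{lineno}: expected 'target, factors', got {line!r}")
        target, _, factors = line.partition(",")
        factors, _, comment = factors.partition("#")
        node_class = "signaling"
        if comment.strip().startswith("class:"):
            node_class = comment.strip()[len("class:"):].strip()
        rows.append((target.strip(), factors.strip(), node_class, lineno))
    if not rows:
        raise ValueError(f"{path}: no rules found")
    inputs = [t for t, f, _, _ in rows if f == t]
    internal_rows = [(t, f, c, ln) for t, f, c, ln in rows if f != t]
    vocab = {t for t, *_ in rows}
    nodes = []
    for target, factors, node_class, lineno in internal_rows:
        try:
            rule = parse_rule(factors, vocab)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        nodes.append(NodeSpec(target, rule, node_class))
    return BooleanNetwork(nodes, inputs, name=name or path.stem)


# ---------------------------------------------------------------------------
# Scenario / schedule configuration


def read_scenario_config(path, network: BooleanNetwork):
    """Read a YAML/JSON scenario + schedule config.

    Returns ``(scenario, schedule)``.  Recognised keys: ``inputs`` (mapping,
    required to cover the network's inputs unless a ``preset`` fills them),
    ``perturbations`` (mapping), ``label`` (string) and ``schedule`` with
    ``mode`` and optional ``periods``.
    """
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    clamps = {str(k): int(v) for k, v in (data.get("inputs") or {}).items()}
    perts = {str(k): int(v) for k, v in (data.get("perturbations") or {}).items()}
    scenario = Scenario(clamps, perts, label=str(data.get("label", Path(path).stem)))
    sched_data = data.get("schedule") or {}
    mode = sched_data.get("mode", "synchronous")
    if mode == "synchronous":
        schedule = UpdateSchedule.synchronous()
    else:
        schedule = UpdateSchedule.asynchronous(
            network, periods=sched_data.get("periods") or {}
        )
    scenario.validate(network)
    return scenario, schedule


def write_scenario_config(scenario: Scenario, schedule: UpdateSchedule, path) -> None:
    data = {
        "label": scenario.label,
        "inputs": dict(scenario.input_clamps),
        "perturbations": dict(scenario.perturbations),
        "schedule": {"mode": schedule.mode, "periods": dict(schedule.periods)},
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")


# ---------------------------------------------------------------------------
# Result export

_ATLAS_COLUMNS = ("kind", "period", "states", "basin_size", "basin_fraction")


def _bits(state: tuple[int, ...]) -> str:
    return "".join(str(b) for b in state)


def provenance_header(network: BooleanNetwork, scenario: Scenario | None = None,
                      schedule: UpdateSchedule | None = None, extra: Mapping | None = None) -> str:
    fields = {"package": f"cd8net {__version__}", "network": network.name,
              "n_internal": network.n, "node_order": ",".join(network.names)}
    if scenario is not None:
        fields["scenario"] = scenario.label
        fields["inputs"] = json.dumps(scenario.input_clamps, sort_keys=True)
        fields["perturbations"] = json.dumps(scenario.perturbations, sort_keys=True)
    if schedule is not None:
        fields["schedule"] = schedule.mode
        if schedule.periods:
            fields["periods"] = json.dumps(schedule.periods, sort_keys=True)
    for key, value in (extra or {}).items():
        fields[key] = value
    return "".join(f"# {k}: {v}\n" for k, v in fields.items())


def atlas_records(atlas: AttractorAtlas) -> list[dict]:
    """One record per attractor: kind, bit-string states, basin accounting."""
    records = []
    for a in atlas.attractors:
        records.append(
            {
                "kind": a.kind,
                "period": a.period,
                "states": "|".join(_bits(s) for s in a.states),
                "basin_size": a.basin_size,
                "basin_fraction": a.basin_size / atlas.omega,
            }
        )
    return records


def write_atlas(atlas: AttractorAtlas, path, fmt: str | None = None) -> None:
    """Write an atlas as CSV or JSON (inferred from the suffix by default)."""
    path = Path(path)
    fmt = fmt or (path.suffix.lstrip(".") or "csv")
    records = atlas_records(atlas)
    header = provenance_header(atlas.network, atlas.scenario, atlas.schedule)
    if fmt == "json":
        payload = {"provenance": header, "omega": atlas.omega, "attractors": records}
        path.write_text(json.dumps(payload, indent=2), encoding="utf-8")
        return
    buf = _io.StringIO()
    writer = csv.DictWriter(buf, fieldnames=_ATLAS_COLUMNS)
    writer.writeheader()
    writer.writerows(records)
    path.write_text(header + buf.getvalue(), encoding="utf-8")


def write_frequencies(table: FrequencyTable, path, network=None, scenario=None,
                      schedule=None, fmt: str | None = None) -> None:
    """Write a frequency table (label, y_k, f_k rows) as CSV or JSON."""
    path = Path(path)
    fmt = fmt or (path.suffix.lstrip(".") or "csv")
    rows = [
        {"axis": "lineage", "label": label, "y_k": table.lineage_counts.get(label, 0),
         "f_k": table.freq(label)}
        for label in (*LINEAGE_LABELS, "unclassified")
    ] + [
        {"axis": "stage", "label": label, "y_k": table.stage_counts.get(label, 0),
         "f_k": table.stage_freq(label)}
        for label in (*STAGE_LABELS, "none")
    ]
    header = ""
    if network is not None:
        header = provenance_header(network, scenario, schedule,
                                   extra={"omega": table.omega})
    if fmt == "json":
        payload = {"provenance": header, "omega": table.omega, "rows": rows,
                   "classified_fraction": table.classified_fraction,
                   "cyclic_fraction": table.cyclic_fraction}
        path.write_text(json.dumps(payload, indent=2), encoding="utf-8")
        return
    buf = _io.StringIO()
    writer = csv.DictWriter(buf, fieldnames=("axis", "label", "y_k", "f_k"))
    writer.writeheader()
    writer.writerows(rows)
    path.write_text(header + buf.getvalue(), encoding="utf-8")
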