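"""Readers and writers for on-disk artifacts.

Formats: delimited text for experiment tables and matrices (comma or tab,
sniffed from the header; ``#`` starts a comment), YAML for run
configuration, JSON for catalogs and reports, PNML for nets and DOT for
rendering.  All writers are deterministic byte-for-byte.

PNML dialect: standard place/transition PNML, with two extensions that
are documented in the README — a ``<capacity>`` child on places, and an
``<arctype>`` child on arcs whose text is ``read`` or ``inhibitory``.
Importing a foreign file with an unknown arc type falls back to a
standard arc with a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from xml.etree import ElementTree as ET

import yaml

from .assembly import (
    CatalogAlternative,
    CatalogColumn,
    SolutionCatalog,
)
from .control_logic import ControlFunction, ControlledReaction
from .decomposition import Caps, PInvariant
from .errors import ValidationError
from .petri_core import (
    INHIBITORY,
    INPUT,
    OUTPUT,
    READ,
    Arc,
    ExtendedPetriNet,
    Place,
)
from .timeseries import DifferenceVector, Experiment, StateMatrix

__all__ = [
    "RunConfig",
    "read_experiments",
    "write_experiments",
    "write_state_matrix",
    "write_difference_matrix",
    "write_catalog",
    "read_catalog",
    "catalog_table",
    "export_pnml",
    "import_pnml",
    "export_dot",
    "to_networkx",
]

_META_COLUMNS = ("experiment", "time", "terminal")


@dataclass
class RunConfig:
    """Everything a reconstruction run may be configured with."""

    capacities: dict = field(default_factory=dict)
    invariants: list = field(default_factory=list)  # weight vectors or name lists
    auto_invariants: bool = True
    max_candidates: int = 4096
    max_decompositions: int = 4096
    max_permutations: int = 40320
    qm_variable_cap: int = 24
    enumeration_limit: int | None = None
    merge_strict: bool = False
    seed: int = 0
    verbosity: int = 0

    def caps(self) -> Caps:
        return Caps(
            max_candidates=self.max_candidates,
            max_decompositions=self.max_decompositions,
            max_permutations=self.max_permutations,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=True, default_flow_style=False)
        )


# ---------------------------------------------------------------------------
# experiment tables
# ---------------------------------------------------------------------------

def _parse_table(text: str, source: str):
    lines = [l for l in text.splitlines() if l.strip()]
    terminal_flag = None
    rows = []
    header = None
    for line in lines:
        if line.lstrip().startswith("#"):
            body = line.lstrip().lstrip("#").strip().lower()
            if body.startswith("terminal"):
                value = body.split(":", 1)[1].strip() if ":" in body else "true"
                terminal_flag = value in ("1", "true", "yes")
            continue
        if header is None:
            delim = "\t" if "\t" in line else ","
            header = [c.strip() for c in line.split(delim)]
            continue
        rows.append([c.strip() for c in line.split(delim)])
    if header is None or not rows:
        raise ValidationError(f"{source}: empty table")
    for i, row in enumerate(rows):
        if len(row) != len(header):
            raise ValidationError(
                f"{source}, data row {i}: expected {len(header)} cells, got {len(row)}"
            )
    return header, rows, terminal_flag


def _to_int(cell: str, source: str, row: int, column: str) -> int:
    try:
        return int(cell)
    except ValueError:
        raise ValidationError(
            f"{source}, row {row}, column {column!r}: non-integer value {cell!r}"
        ) from None


def read_experiments(paths) -> list[Experiment]:
    """Load experiments from delimited text files.

    Either one file per experiment (the file stem is the experiment id; an
    optional ``#terminal`` comment line declares the final state terminal)
    or a single long-format file with an ``experiment`` id column.  A
    ``time`` column is optional; remaining header names are the components
    in declaration order.  A ``terminal`` column (0/1) may flag the end
    state of each experiment.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    paths = [Path(p) for p in paths]
    experiments: list[Experiment] = []
    for path in paths:
        header, rows, terminal_flag = _parse_table(path.read_text(), str(path))
        components = [c for c in header if c not in _META_COLUMNS]
        col = {name: k for k, name in enumerate(header)}
        if "experiment" in col:
            groups: dict[str, list] = {}
            order = []
            for i, row in enumerate(rows):
                exp_id = row[col["experiment"]]
                if exp_id not in groups:
                    groups[exp_id] = []
                    order.append(exp_id)
                groups[exp_id].append((i, row))
            for exp_id in order:
                series = []
                terminal = None
                for i, row in groups[exp_id]:
                    stamp = row[col["time"]] if "time" in col else len(series)
                    values = tuple(
                        _to_int(row[col[c]], str(path), i, c) for c in components
                    )
                    if "terminal" in col and row[col["terminal"]].strip():
                        terminal = bool(
                            _to_int(row[col["terminal"]], str(path), i, "terminal")
                        )
                    series.append((stamp, values))
                experiments.append(
                    Experiment(id=exp_id, series=series, terminal=terminal)
                )
        else:
            series = []
            for i, row in enumerate(rows):
                stamp = row[col["time"]] if "time" in col else i
                values = tuple(
                    _to_int(row[col[c]], str(path), i, c) for c in components
                )
                series.append((stamp, values))
            experiments.append(
                Experiment(id=path.stem, series=series, terminal=terminal_flag)
            )
    return experiments


def _components_of(path: Path) -> list[str]:
    header, _, _ = _parse_table(Path(path).read_text(), str(path))
    return header


def experiment_components(paths) -> list[str]:
    """Component names (declaration order) from the first input file."""
    if isinstance(paths, (str, Path)):
        paths = [paths]
    return [c for c in _components_of(Path(paths[0])) if c not in _META_COLUMNS]


def write_experiments(experiments, components, path) -> None:
    """Write experiments as one long-format TSV (lossless round trip)."""
    lines = ["\t".join(["experiment", "time", "terminal", *components])]
    for exp in experiments:
        for k, (stamp, values) in enumerate(exp.series):
            is_last = k == len(exp.series) - 1
            flag = ""
            if is_last and exp.terminal is not None:
                flag = "1" if exp.terminal else "0"
            lines.append(
                "\t".join([exp.id, str(stamp), flag, *map(str, values)])
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def write_state_matrix(sm: StateMatrix, path) -> None:
    """States as columns, components as rows (the published table layout)."""
    lines = []
    lines.append("\t".join(["Exp."] + [sm.segment_of(i) for i in range(sm.n_states)]))
    lines.append("\t".join(["Vector"] + [str(i) for i in range(sm.n_states)]))
    for j, comp in enumerate(sm.components):
        lines.append("\t".join([comp] + [str(s[j]) for s in sm.states]))
    lines.append(
        "\t".join(["Term.state"] + ["T" if t else "" for t in sm.terminal])
    )
    Path(path).write_text("\n".join(lines) + "\n")


def write_difference_matrix(diffs, sm: StateMatrix, path, witnesses_path=None) -> None:
    lines = []
    lines.append("\t".join(["Vector"] + [str(i + 1) for i in range(len(diffs))]))
    for j, comp in enumerate(sm.components):
        row = [comp]
        for d in diffs:
            e = d.entries[j]
            row.append(f"{e:+d}" if e else "")
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")
    if witnesses_path is not None:
        payload = [
            {"entries": list(d.entries), "witnesses": list(d.witnesses)}
            for d in diffs
        ]
        Path(witnesses_path).write_text(json.dumps(payload, indent=1) + "\n")


# ---------------------------------------------------------------------------
# catalog JSON
# ---------------------------------------------------------------------------

def _f_to_json(f: ControlFunction):
    return [[[p, bool(pos)] for p, pos in term] for term in f.terms]


def _f_from_json(data, components) -> ControlFunction:
    terms = [tuple((p, bool(pos)) for p, pos in term) for term in data]
    if not terms:
        return ControlFunction.always()
    return ControlFunction.of(terms, components)


def write_catalog(cat: SolutionCatalog, path) -> None:
    sm = cat.state_matrix
    payload = {
        "components": sm.components,
        "capacities": list(sm.capacities),
        "states": [list(s) for s in sm.states],
        "origin": [list(o) for o in sm.origin],
        "terminal": list(sm.terminal),
        "segments": [list(s) for s in sm.segments],
        "invariants": [
            {"weights": list(inv.weights), "values": list(inv.values)}
            for inv in cat.invariants
        ],
        "provenance": cat.provenance,
        "columns": [
            {
                "difference": list(col.difference.entries),
                "witnesses": list(col.difference.witnesses),
                "alternatives": [
                    {
                        "sequence": [
                            {
                                "r": list(cr.r),
                                "f": _f_to_json(cr.f),
                                "on": sorted(map(list, cr.on_states)),
                                "off": sorted(map(list, cr.off_states)),
                            }
                            for cr in alt.sequence
                        ]
                    }
                    for alt in col.alternatives
                ],
            }
            for col in cat.columns
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_catalog(path) -> SolutionCatalog:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path}: invalid catalog JSON ({exc})") from None
    sm = StateMatrix(
        components=list(data["components"]),
        capacities=tuple(data["capacities"]),
        states=[tuple(s) for s in data["states"]],
        origin=[tuple(o) for o in data["origin"]],
        terminal=list(data["terminal"]),
        segments=[(e, s, t) for e, s, t in data["segments"]],
    )
    invariants = [
        PInvariant(weights=tuple(i["weights"]), values=tuple(i["values"]))
        for i in data["invariants"]
    ]
    columns = []
    for cdata in data["columns"]:
        diff = DifferenceVector(
            entries=tuple(cdata["difference"]), witnesses=list(cdata["witnesses"])
        )
        alternatives = []
        for adata in cdata["alternatives"]:
            sequence = tuple(
                ControlledReaction(
                    r=tuple(e["r"]),
                    f=_f_from_json(e["f"], sm.components),
                    on_states=frozenset(map(tuple, e["on"])),
                    off_states=frozenset(map(tuple, e["off"])),
                )
                for e in adata["sequence"]
            )
            alternatives.append(CatalogAlternative(sequence=sequence))
        columns.append(CatalogColumn(difference=diff, alternatives=alternatives))
    return SolutionCatalog(
        columns=columns,
        state_matrix=sm,
        invariants=invariants,
        provenance=data.get("provenance", {}),
    )


def catalog_table(cat: SolutionCatalog) -> str:
    """Human-readable table: one column of controlled-reaction sequences
    per difference vector."""

    def sparse(v):
        return " ".join(
            f"{c}{e:+d}" for c, e in zip(cat.components, v) if e
        )

    out = []
    for k, col in enumerate(cat.columns):
        out.append(f"d{k + 1} = [{sparse(col.difference.entries)}]  "
                   f"witnesses {col.difference.witnesses}")
        for i, alt in enumerate(col.alternatives):
            steps = "; ".join(
                f"([{sparse(cr.r)}], {cr.f})" for cr in alt.sequence
            )
            out.append(f"  {i}: {steps}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# PNML
# ---------------------------------------------------------------------------

_PNML_NS = "http://www.pnml.org/version-2009/grammar/pnml"


def export_pnml(net: ExtendedPetriNet, path) -> None:
    root = ET.Element("pnml", xmlns=_PNML_NS)
    el_net = ET.SubElement(
        root, "net", id=net.name, type=f"{_PNML_NS}/ptnet"
    )
    page = ET.SubElement(el_net, "page", id="page0")
    for p in net.places:
        el = ET.SubElement(page, "place", id=p.name)
        name = ET.SubElement(ET.SubElement(el, "name"), "text")
        name.text = p.name
        cap = ET.SubElement(ET.SubElement(el, "capacity"), "text")
        cap.text = str(p.capacity)
    for t in net.transitions:
        ET.SubElement(page, "transition", id=t)
    k = 0
    for arc in net.arcs:
        if arc.kind == OUTPUT:
            source, target = arc.transition, arc.place
        else:
            source, target = arc.place, arc.transition
        el = ET.SubElement(page, "arc", id=f"a{k}", source=source, target=target)
        k += 1
        if arc.weight != 1:
            w = ET.SubElement(ET.SubElement(el, "inscription"), "text")
            w.text = str(arc.weight)
        if arc.kind in (READ, INHIBITORY):
            at = ET.SubElement(ET.SubElement(el, "arctype"), "text")
            at.text = arc.kind
    ET.indent(root)
    Path(path).write_bytes(ET.tostring(root, xml_declaration=True, encoding="utf-8"))


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def import_pnml(path) -> ExtendedPetriNet:
    try:
        root = ET.parse(Path(path)).getroot()
    except ET.ParseError as exc:
        raise ValidationError(f"{path}: not valid PNML ({exc})") from None
    el_net = None
    for el in root.iter():
        if _local(el.tag) == "net":
            el_net = el
            break
    if el_net is None:
        raise ValidationError(f"{path}: no <net> element")
    places, transitions, arcs = [], [], []
    place_ids, transition_ids = set(), set()
    raw_arcs = []
    for el in el_net.iter():
        tag = _local(el.tag)
        if tag == "place":
            pid = el.get("id")
            capacity = 1
            for child in el.iter():
                if _local(child.tag) == "capacity":
                    text = "".join(x.text or "" for x in child.iter() if x.text)
                    capacity = int(text)
            places.append(Place(name=pid, capacity=capacity))
            place_ids.add(pid)
        elif tag == "transition":
            transitions.append(el.get("id"))
            transition_ids.add(el.get("id"))
        elif tag == "arc":
            raw_arcs.append(el)
    for el in raw_arcs:
        source, target = el.get("source"), el.get("target")
        weight = 1
        arctype = None
        for child in el.iter():
            tag = _local(child.tag)
            if tag == "inscription":
                text = "".join(x.text or "" for x in child.iter() if x.text)
                weight = int(text)
            elif tag == "arctype":
                arctype = "".join(x.text or "" for x in child.iter() if x.text).strip()
        if source in place_ids and target in transition_ids:
            place, transition, kind = source, target, INPUT
        elif source in transition_ids and target in place_ids:
            place, transition, kind = target, source, OUTPUT
        else:
            raise ValidationError(
                f"{path}: arc {el.get('id')!r} does not connect a place with "
                f"a transition"
            )
        if arctype is not None:
            if arctype in (READ, INHIBITORY):
                if kind == OUTPUT:
                    raise ValidationError(
                        f"{path}: {arctype} arc must point from place to transition"
                    )
                kind = arctype
                weight = 1
            else:
                warnings.warn(
                    f"{path}: unknown arc type {arctype!r}; treating as a "
                    f"standard arc"
                )
        arcs.append(Arc(place=place, transition=transition, kind=kind, weight=weight))
    return ExtendedPetriNet(
        places=places, transitions=transitions, arcs=arcs,
        name=el_net.get("id", "net"),
    )


# ---------------------------------------------------------------------------
# DOT / networkx
# ---------------------------------------------------------------------------

def export_dot(net: ExtendedPetriNet, path=None) -> str:
    """GraphViz rendering: places are circles, transitions squares, read
    arcs double-headed, inhibitory arcs circle-headed."""
    lines = [f'digraph "{net.name}" {{', "  rankdir=LR;"]
    for p in net.places:
        cap = f"\\ncap={p.capacity}" if p.capacity != 1 else ""
        lines.append(f'  "{p.name}" [shape=circle label="{p.name}{cap}"];')
    for t in net.transitions:
        lines.append(f'  "{t}" [shape=box style=filled fillcolor=lightgrey];')
    for arc in net.arcs:
        label = f' [label="{arc.weight}"]' if arc.weight != 1 else ""
        if arc.kind == INPUT:
            lines.append(f'  "{arc.place}" -> "{arc.transition}"{label};')
        elif arc.kind == OUTPUT:
            lines.append(f'  "{arc.transition}" -> "{arc.place}"{label};')
        elif arc.kind == READ:
            lines.append(f'  "{arc.place}" -> "{arc.transition}" [dir=both];')
        else:
            lines.append(f'  "{arc.place}" -> "{arc.transition}" [arrowhead=odot];')
    lines.append("}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def to_networkx(net: ExtendedPetriNet):
    """Directed bipartite graph with typed nodes and arcs, suitable for
    isomorphism tests over labelled places."""
    import networkx as nx

    g = nx.MultiDiGraph()
    for p in net.places:
        g.add_node(("place", p.name), kind="place", label=p.name, capacity=p.capacity)
    for t in net.transitions:
        g.add_node(("transition", t), kind="transition", label="")
    for arc in net.arcs:
        p, t = ("place", arc.place), ("transition", arc.transition)
        if arc.kind == OUTPUT:
            g.add_edge(t, p, kind=arc.kind, weight=arc.weight)
        else:
            g.add_edge(p, t, kind=arc.kind, weight=arc.weight)
    return g
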