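"""Solution catalog and net composition.

The catalog is the implicit representation of *all* reconstructed nets:
one column per distinct difference vector, each column holding every
alternative controlled-reaction sequence that realises the difference and
survived intermediate-state validation and terminal-state classification.
Explicit extended Petri nets are composed by picking one alternative per
column; every composed net is verified by replaying the state matrix and
by checking deadness at every flagged terminal state.

Alternatives that differ only in the temporal order of the same controlled
reactions produce identical subnets; they are deduplicated, keeping the
canonically first ordering as the replay representative.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .control_logic import (
    ControlFunction,
    ControlledReaction,
    derive_controls,
    to_subnet,
)
from .decomposition import (
    Caps,
    PInvariant,
    Rejection,
    auto_pinvariants,
    candidate_reactions,
    decompositions,
    is_applicable,
    ordered_sequences,
    walk_intermediates,
)
from .errors import InfeasibleError, PetrirecError, ValidationError
from .petri_core import (
    Arc,
    ExtendedPetriNet,
    Place,
    enabled_transitions,
)
from .timeseries import DifferenceVector, StateMatrix, difference_matrix

__all__ = [
    "CatalogAlternative",
    "CatalogColumn",
    "SolutionCatalog",
    "ReconstructedNet",
    "ReplayReport",
    "EnumerationResult",
    "build_catalog",
    "compose_net",
    "enumerate_nets",
    "verify_replay",
    "wiring_signature",
]


@dataclass(frozen=True)
class CatalogAlternative:
    """One controlled-reaction sequence realising a difference vector."""

    sequence: tuple[ControlledReaction, ...]

    @property
    def key(self):
        """Order-insensitive identity: the multiset of (r, f) pairs."""
        return tuple(sorted(Counter((cr.r, cr.f.terms) for cr in self.sequence).items()))

    @property
    def n_transitions(self) -> int:
        return sum(max(1, len(cr.f.terms)) for cr in self.sequence)


@dataclass
class CatalogColumn:
    difference: DifferenceVector
    alternatives: list[CatalogAlternative]

    def __post_init__(self):
        for alt in self.alternatives:
            total = tuple(
                sum(col) for col in zip(*(cr.r for cr in alt.sequence))
            )
            if total != tuple(self.difference.entries):
                raise ValidationError(
                    f"alternative {alt} does not sum to {self.difference.entries}"
                )

    @property
    def is_ambiguous(self) -> bool:
        return len(self.alternatives) > 1

    def minimal_alternatives(self) -> list[int]:
        """Indices of the alternatives with the fewest transitions."""
        best = min(a.n_transitions for a in self.alternatives)
        return [i for i, a in enumerate(self.alternatives) if a.n_transitions == best]


@dataclass
class SolutionCatalog:
    """Implicit representation of every net consistent with the data."""

    columns: list[CatalogColumn]
    state_matrix: StateMatrix
    invariants: list[PInvariant]
    provenance: dict = field(default_factory=dict)

    @property
    def components(self) -> list[str]:
        return self.state_matrix.components

    @property
    def capacities(self) -> tuple[int, ...]:
        return self.state_matrix.capacities

    @property
    def n_nets(self) -> int:
        n = 1
        for col in self.columns:
            n *= len(col.alternatives)
        return n if self.columns else 0

    def ambiguous_columns(self) -> list[int]:
        return [i for i, c in enumerate(self.columns) if c.is_ambiguous]


@dataclass
class ReplayReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


@dataclass
class ReconstructedNet:
    net: ExtendedPetriNet
    selection: tuple[int, ...]
    report: ReplayReport
    transition_map: dict = field(default_factory=dict)  # (r, f.terms) -> [t ids]


def _sequence_alternatives(
    parts_ordering: tuple[tuple[int, ...], ...],
    witness_starts: Sequence[tuple[int, ...]],
    terminals: Sequence[tuple[int, ...]],
    capacities: Sequence[int],
    components: Sequence[str],
) -> list[CatalogAlternative]:
    """Alternatives arising from one ordering of one decomposition, or []
    if the ordering is invalid (out-of-bounds intermediate or group II)."""
    on_map: dict[tuple[int, ...], set] = {}
    for start in witness_starts:
        walked = walk_intermediates(start, parts_ordering, capacities)
        if isinstance(walked, Rejection):
            return []
        applied_at = (start,) + walked.intermediates[:-1]
        for part, state in zip(parts_ordering, applied_at):
            on_map.setdefault(part, set()).add(state)
    covers: dict[tuple[int, ...], list[ControlledReaction]] = {}
    for part, on in on_map.items():
        crs = derive_controls(part, on, terminals, capacities, components)
        if not crs:  # group II: the whole sequence is deleted
            return []
        covers[part] = crs
    unique_parts = sorted(on_map)
    alternatives = []
    for chosen in itertools.product(*(covers[p] for p in unique_parts)):
        by_part = dict(zip(unique_parts, chosen))
        alternatives.append(
            CatalogAlternative(
                sequence=tuple(by_part[p] for p in parts_ordering)
            )
        )
    return alternatives


def build_catalog(
    sm: StateMatrix,
    caps: Caps = Caps(),
    auto_invariants: bool = True,
    nominated_invariants: Iterable = (),
    provenance: dict | None = None,
) -> SolutionCatalog:
    """Run the full reconstruction pipeline on a compiled state matrix.

    Per difference vector: candidate reactions (invariant-filtered) →
    decompositions → orderings → intermediate-state validation against all
    witnesses → group classification → control derivation.  Only surviving
    sequences enter the column; an empty column aborts with
    :class:`InfeasibleError` naming the difference vector.
    """
    invariants = auto_pinvariants(
        sm, nominated=nominated_invariants, detect_pairs=auto_invariants
    )
    terminals = sm.terminal_states()
    capacities = sm.capacities
    columns = []
    for diff in difference_matrix(sm):
        witness_starts = [sm.states[i] for i in diff.witnesses]
        cands = candidate_reactions(diff, invariants, caps)
        alternatives: list[CatalogAlternative] = []
        seen_keys = set()
        for dec in decompositions(diff, cands, caps):
            for ordering in ordered_sequences(dec, caps):
                for alt in _sequence_alternatives(
                    ordering, witness_starts, terminals, capacities, sm.components
                ):
                    if alt.key in seen_keys:
                        continue
                    seen_keys.add(alt.key)
                    alternatives.append(alt)
        if not alternatives:
            raise InfeasibleError(diff.entries)
        columns.append(CatalogColumn(difference=diff, alternatives=alternatives))
    return SolutionCatalog(
        columns=columns,
        state_matrix=sm,
        invariants=invariants,
        provenance=provenance or {},
    )


def compose_net(
    cat: SolutionCatalog, selection: Sequence[int], name: str = "reconstructed"
) -> ReconstructedNet:
    """Compose an explicit net by picking one alternative per column.

    Identical ``(r, f)`` pairs selected in several columns merge into one
    transition set; reactions with equal vectors but different control
    functions stay distinct.  The composed net is replay-verified; a
    verification failure raises.
    """
    if len(selection) != len(cat.columns):
        raise ValidationError(
            f"selection has {len(selection)} entries for {len(cat.columns)} columns"
        )
    chosen: dict[tuple, ControlledReaction] = {}
    pooled_on: dict[tuple, set] = {}
    pooled_off: dict[tuple, set] = {}
    for col, idx in zip(cat.columns, selection):
        if not 0 <= idx < len(col.alternatives):
            raise ValidationError(
                f"selection index {idx} out of range for column "
                f"{col.difference.entries} with {len(col.alternatives)} alternatives"
            )
        for cr in col.alternatives[idx].sequence:
            key = (cr.r, cr.f.terms)
            chosen.setdefault(key, cr)
            pooled_on.setdefault(key, set()).update(cr.on_states)
            pooled_off.setdefault(key, set()).update(cr.off_states)

    index = {p: i for i, p in enumerate(cat.components)}
    for key, cr in chosen.items():
        bad_on = [x for x in pooled_on[key] if not cr.f.evaluate(x, index)]
        bad_off = [x for x in pooled_off[key] if cr.f.evaluate(x, index)]
        if bad_on or bad_off:
            raise PetrirecError(
                f"composition rejected: merged controlled reaction {cr.r} / "
                f"{cr.f} breaks separation on pooled states "
                f"(on violations: {bad_on}, off violations: {bad_off})"
            )

    places = [
        Place(name=p, capacity=c)
        for p, c in zip(cat.components, cat.capacities)
    ]
    transitions: list[str] = []
    arcs: list[Arc] = []
    transition_map: dict[tuple, list[str]] = {}
    for k, key in enumerate(sorted(chosen, key=lambda kv: (kv[0], kv[1]))):
        fragment = to_subnet(
            chosen[key], cat.components, cat.capacities, transition_prefix=f"t{k}"
        )
        transitions.extend(fragment.transitions)
        arcs.extend(fragment.arcs)
        transition_map[key] = list(fragment.transitions)
    net = ExtendedPetriNet(places=places, transitions=transitions, arcs=arcs, name=name)
    rnet = ReconstructedNet(
        net=net,
        selection=tuple(selection),
        report=ReplayReport(),
        transition_map=transition_map,
    )
    rnet.report = verify_replay(rnet, cat.state_matrix, cat)
    return rnet


@dataclass
class EnumerationResult:
    total: int
    nets: list[ReconstructedNet]
    duplicates: int = 0


def enumerate_nets(
    cat: SolutionCatalog, limit: int | None = None
) -> EnumerationResult:
    """Enumerate composed nets in canonical (mixed-radix) selection order.

    ``total`` is the product of the column alternative counts; nets that
    become identical after (r, f) merging are deduplicated and counted in
    ``duplicates``.  With ``limit=0`` only the count is computed.
    """
    total = cat.n_nets
    if limit == 0 or not cat.columns:
        return EnumerationResult(total=total, nets=[])
    sizes = [len(c.alternatives) for c in cat.columns]
    nets: list[ReconstructedNet] = []
    seen = set()
    duplicates = 0
    for selection in itertools.product(*(range(s) for s in sizes)):
        rnet = compose_net(cat, selection)
        sig = wiring_signature(rnet.net)
        if sig in seen:
            duplicates += 1
            continue
        seen.add(sig)
        nets.append(rnet)
        if limit is not None and len(nets) >= limit:
            break
    return EnumerationResult(total=total, nets=nets, duplicates=duplicates)


def verify_replay(
    rnet: ReconstructedNet, sm: StateMatrix, cat: SolutionCatalog | None = None
) -> ReplayReport:
    """Check a composed net against the state matrix.

    (a) For every consecutive state pair, the selected controlled-reaction
    sequence fires legally from the earlier to the later state; (b) at
    every flagged terminal state no transition of the net is enabled
    (otherwise the state would not be terminal).
    """
    report = ReplayReport()
    net = rnet.net
    index = {p: i for i, p in enumerate(sm.components)}
    if cat is not None:
        by_difference = {
            tuple(col.difference.entries): col.alternatives[sel]
            for col, sel in zip(cat.columns, rnet.selection)
        }
        for i, j in sm.consecutive_pairs():
            d = tuple(b - a for a, b in zip(sm.states[i], sm.states[j]))
            alt = by_difference.get(d)
            if alt is None:
                report.violations.append(
                    f"states #{i}->#{j}: no catalog column for difference {d}"
                )
                continue
            current = sm.states[i]
            for cr in alt.sequence:
                if not is_applicable(cr.r, current, sm.capacities):
                    report.violations.append(
                        f"states #{i}->#{j}: reaction {cr.r} not applicable at {current}"
                    )
                    break
                if not cr.f.evaluate(current, index):
                    report.violations.append(
                        f"states #{i}->#{j}: control {cr.f} blocks reaction "
                        f"{cr.r} at {current}"
                    )
                    break
                current = tuple(c + e for c, e in zip(current, cr.r))
            else:
                if current != sm.states[j]:
                    report.violations.append(
                        f"states #{i}->#{j}: sequence ends at {current}, "
                        f"expected {sm.states[j]}"
                    )
    for i in sm.terminal_indices():
        enabled = enabled_transitions(net, sm.states[i])
        if enabled:
            report.violations.append(
                f"terminal state #{i} enables transition(s) {enabled}"
            )
    return report


def wiring_signature(net: ExtendedPetriNet):
    """Canonical, transition-name-free identity of a net's wiring.

    Two nets over the same labelled places have equal signatures iff they
    are isomorphic under any renaming of transitions.
    """
    sigs = Counter()
    for t in net.transitions:
        sigs[
            (
                tuple(sorted(net.inputs(t).items())),
                tuple(sorted(net.outputs(t).items())),
                tuple(net.reads(t)),
                tuple(net.inhibitors(t)),
            )
        ] += 1
    return frozenset(sigs.items())
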