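"""Difference-vector decomposition into candidate reaction vectors.

Each difference vector is split exhaustively into the set of all reaction
vectors whose entries either equal or partially contribute to its entries;
every way of writing the difference as a multiset sum of such candidates
is enumerated, every ordering of every decomposition is generated, and the
chain of intermediate states is validated against the token bounds.

P-invariants (weighted token-conservation constraints detected in the data
or supplied by the user) act as a pre-filter: any candidate reaction that
would change a conserved weighted sum is removed before decomposition.

All enumeration is guarded by configurable caps; hitting a cap raises
:class:`~petrirec.errors.CapsExceededError`, never truncates silently.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from sympy.utilities.iterables import multiset_permutations

from .errors import CapsExceededError, ValidationError
from .timeseries import DifferenceVector, StateMatrix

__all__ = [
    "ReactionVector",
    "Decomposition",
    "OrderedSequence",
    "Rejection",
    "PInvariant",
    "Caps",
    "candidate_reactions",
    "decompositions",
    "ordered_sequences",
    "is_applicable",
    "walk_intermediates",
    "auto_pinvariants",
]

# a reaction vector is a plain tuple of signed ints; the alias documents intent
ReactionVector = tuple


@dataclass(frozen=True)
class Caps:
    """Combinatorial guards applied per difference vector."""

    max_candidates: int = 4096
    max_decompositions: int = 4096
    max_permutations: int = 40320  # 8!

    def __post_init__(self):
        for name in ("max_candidates", "max_decompositions", "max_permutations"):
            if getattr(self, name) < 1:
                raise ValidationError(f"cap {name} must be positive")


@dataclass
class Decomposition:
    """A multiset of reaction vectors summing exactly to ``parent``."""

    parts: tuple[tuple[int, ...], ...]  # sorted, may repeat
    parent: tuple[int, ...]

    def __post_init__(self):
        total = tuple(sum(col) for col in zip(*self.parts))
        if total != tuple(self.parent):
            raise ValidationError(
                f"decomposition parts {self.parts} do not sum to {self.parent}"
            )


@dataclass
class OrderedSequence:
    """One ordering of a decomposition applied at a concrete start state.

    ``intermediates[k]`` is the marking after applying the first ``k + 1``
    parts; the last entry equals ``start + sum(parts)``.
    """

    sequence: tuple[tuple[int, ...], ...]
    start: tuple[int, ...]
    intermediates: tuple[tuple[int, ...], ...]


@dataclass
class Rejection:
    """Why an ordered sequence was discarded: the first part whose prefix
    sum leaves the valid marking range."""

    step: int
    part: tuple[int, ...]
    marking: tuple[int, ...]
    place_index: int

    def __str__(self):
        return (
            f"step {self.step}: applying {self.part} at {self.marking} drives "
            f"place #{self.place_index} out of bounds"
        )


@dataclass
class PInvariant:
    """Non-negative weights whose weighted token sum is conserved.

    The conserved value is constant within each experiment segment; the
    per-segment values may differ because perturbed experiments start from
    different initial markings (a deletion mutant removes tokens from the
    conserved set).  ``values`` records the per-segment constants in
    segment order; ``value`` is the shared constant when all segments
    agree, else ``None``.
    """

    weights: tuple[int, ...]
    values: tuple[int, ...] = ()

    def __post_init__(self):
        if not any(self.weights):
            raise ValidationError("P-invariant weights must not all be zero")
        if any(w < 0 for w in self.weights):
            raise ValidationError("P-invariant weights must be non-negative")

    @property
    def value(self) -> int | None:
        return self.values[0] if len(set(self.values)) == 1 else None

    def dot(self, vector: Sequence[int]) -> int:
        return sum(w * v for w, v in zip(self.weights, vector))


def _sign(x: int) -> int:
    return (x > 0) - (x < 0)


def candidate_reactions(
    d: DifferenceVector | Sequence[int],
    invariants: Sequence[PInvariant] = (),
    caps: Caps = Caps(),
) -> list[tuple[int, ...]]:
    """All possible reaction vectors contributing to difference ``d``.

    Entry ``i`` of a candidate ranges over ``0, sign(d[i]), ..., d[i]``
    (partial magnitudes are admitted for multi-token differences; boolean
    data reduces this to ``{0, d[i]}``).  The zero vector is excluded, and
    any candidate that changes the weighted sum of a P-invariant is
    filtered out.  Output in lexicographic order.
    """
    entries = tuple(d.entries if isinstance(d, DifferenceVector) else d)
    if not any(entries):
        raise ValidationError("cannot decompose the zero difference vector")
    ranges = []
    for e in entries:
        step = _sign(e)
        ranges.append([0] if e == 0 else [step * k for k in range(abs(e) + 1)])
    n_total = 1
    for r in ranges:
        n_total *= len(r)
    if n_total - 1 > caps.max_candidates:
        raise CapsExceededError(
            "max_candidates", caps.max_candidates, n_total - 1, context=str(entries)
        )
    out = []
    for combo in itertools.product(*ranges):
        if not any(combo):
            continue
        if any(inv.dot(combo) != 0 for inv in invariants):
            continue
        out.append(tuple(combo))
    out.sort()
    return out


def decompositions(
    d: DifferenceVector | Sequence[int],
    candidates: Sequence[tuple[int, ...]],
    caps: Caps = Caps(),
) -> list[Decomposition]:
    """All multisets of ``candidates`` summing exactly to ``d``.

    Includes the singleton ``{d}`` whenever ``d`` survived the candidate
    filter.  Multisets are emitted with parts in non-decreasing
    lexicographic order, and the list of decompositions is itself
    canonically ordered (fewer parts first, then lexicographic).
    """
    entries = tuple(d.entries if isinstance(d, DifferenceVector) else d)
    cands = sorted(set(map(tuple, candidates)))
    results: list[tuple[tuple[int, ...], ...]] = []

    def compatible(remaining: tuple[int, ...]) -> bool:
        # every remaining entry must still be reachable by same-sign parts
        return all(r == 0 or _sign(r) == _sign(e) for r, e in zip(remaining, entries))

    def search(remaining: tuple[int, ...], start: int, chosen: list):
        if not any(remaining):
            results.append(tuple(chosen))
            if len(results) > caps.max_decompositions:
                raise CapsExceededError(
                    "max_decompositions",
                    caps.max_decompositions,
                    len(results),
                    context=str(entries),
                )
            return
        for k in range(start, len(cands)):
            c = cands[k]
            nxt = tuple(r - x for r, x in zip(remaining, c))
            if not compatible(nxt):
                continue
            chosen.append(c)
            search(nxt, k, chosen)  # k (not k+1): parts may repeat
            chosen.pop()

    search(entries, 0, [])
    results.sort(key=lambda parts: (len(parts), parts))
    return [Decomposition(parts=parts, parent=entries) for parts in results]


def ordered_sequences(
    dec: Decomposition, caps: Caps = Caps()
) -> list[tuple[tuple[int, ...], ...]]:
    """All distinct orderings (multiset permutations) of the parts."""
    parts = [list(p) for p in dec.parts]
    n_perm = 1
    for k in range(2, len(parts) + 1):
        n_perm *= k
    counts: dict[tuple, int] = {}
    for p in dec.parts:
        counts[p] = counts.get(p, 0) + 1
    for c in counts.values():
        for k in range(2, c + 1):
            n_perm //= k
    if n_perm > caps.max_permutations:
        raise CapsExceededError(
            "max_permutations", caps.max_permutations, n_perm, context=str(dec.parent)
        )
    return [tuple(map(tuple, perm)) for perm in multiset_permutations(parts)]


def is_applicable(
    r: Sequence[int], x: Sequence[int], capacities: Sequence[int]
) -> bool:
    """True iff applying ``r`` at state ``x`` stays within ``[0, capacity]``
    componentwise — the definition of a reaction being applicable."""
    if not len(r) == len(x) == len(capacities):
        raise ValidationError("reaction, state and capacities must have equal length")
    return all(0 <= xi + ri <= ci for ri, xi, ci in zip(r, x, capacities))


def walk_intermediates(
    start: Sequence[int],
    seq: Sequence[Sequence[int]],
    capacities: Sequence[int],
) -> OrderedSequence | Rejection:
    """Apply the parts of ``seq`` in order, computing every prefix state.

    Returns an :class:`OrderedSequence` when every prefix sum is a valid
    marking, else a :class:`Rejection` naming the violating step; rejected
    sequences are discarded from further analysis.
    """
    if not seq:
        raise ValidationError("walk_intermediates needs a nonempty sequence")
    state = tuple(start)
    intermediates = []
    for step, part in enumerate(seq):
        nxt = tuple(s + p for s, p in zip(state, part))
        for i, (v, c) in enumerate(zip(nxt, capacities)):
            if not 0 <= v <= c:
                return Rejection(
                    step=step, part=tuple(part), marking=state, place_index=i
                )
        intermediates.append(nxt)
        state = nxt
    return OrderedSequence(
        sequence=tuple(map(tuple, seq)),
        start=tuple(start),
        intermediates=tuple(intermediates),
    )


def auto_pinvariants(
    sm: StateMatrix,
    nominated: Iterable[Sequence[int] | Sequence[str]] = (),
    detect_pairs: bool = True,
) -> list[PInvariant]:
    """Detect 0/1-weight place-pair invariants and verify nominated ones.

    A pair (or nominated set) of places is an invariant when its unweighted
    token sum is constant within every experiment segment — equivalently,
    no observed difference vector changes the sum.  Per-segment values may
    differ (structural interventions change the conserved total).

    Nominated invariants are given as weight vectors or component-name
    lists; a nominated invariant violated by the data raises a validation
    error naming the offending state.
    """
    n = len(sm.components)
    found: list[PInvariant] = []

    def segment_values(weights: tuple[int, ...]) -> tuple[int, ...] | None:
        values = []
        for _, start, stop in sm.segments:
            sums = {
                sum(w * v for w, v in zip(weights, sm.states[i]))
                for i in range(start, stop)
            }
            if len(sums) != 1:
                return None
            values.append(sums.pop())
        return tuple(values)

    if sm.states and detect_pairs:
        for i, j in itertools.combinations(range(n), 2):
            weights = tuple(1 if k in (i, j) else 0 for k in range(n))
            values = segment_values(weights)
            if values is not None:
                found.append(PInvariant(weights=weights, values=values))

    for spec in nominated:
        spec = list(spec)
        if spec and isinstance(spec[0], str):
            unknown = set(spec) - set(sm.components)
            if unknown:
                raise ValidationError(
                    f"nominated invariant names unknown components: {sorted(unknown)}"
                )
            weights = tuple(1 if c in spec else 0 for c in sm.components)
        else:
            if len(spec) != n:
                raise ValidationError(
                    f"nominated invariant has {len(spec)} weights, expected {n}"
                )
            weights = tuple(int(w) for w in spec)
        values = segment_values(weights)
        if values is None:
            for exp_id, start, stop in sm.segments:
                base = sum(w * v for w, v in zip(weights, sm.states[start]))
                for i in range(start, stop):
                    s = sum(w * v for w, v in zip(weights, sm.states[i]))
                    if s != base:
                        raise ValidationError(
                            f"nominated invariant {weights} violated at state "
                            f"#{i} (experiment {exp_id!r}): weighted sum {s} != {base}"
                        )
        if all(pi.weights != weights for pi in found):
            found.append(PInvariant(weights=weights, values=values))
    return found
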