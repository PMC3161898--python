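"""Control-function derivation: terminal-state classification and exact
two-level boolean minimisation.

A reaction that is applied at some states but applicable at terminal
states needs a *control function*: a DNF over place presence/absence
literals that is 1 at every application state and 0 at every terminal
state where the reaction is applicable.  Every marking outside those two
sets is a don't-care, which preserves the nondeterminism of the Petri-net
semantics.

Reactions fall into three groups with respect to their terminal states:

* group I   — not applicable at any terminal state: always enabled, and by
  minimality no control arcs are attached;
* group II  — applied at a marking identical to a terminal-state marking:
  the control function would have to be 1 and 0 on the same marking, so no
  control exists and the reaction (its whole sequence) is deleted;
* group III — separable: control through read/inhibitory arcs is possible.

Minimisation follows the Quine-McCluskey discipline adapted to sparse
on/off sets with massive don't-care space: candidate terms are the prime
implicants with respect to the off-set (every literal of a term is needed
to exclude some off-state), and an exhaustive cover search returns ALL
covers with the minimum number of terms and, among those, the minimum
total literal count.  Each DNF term maps 1:1 to a transition; a positive
literal becomes a read arc and a negative literal an inhibitory arc.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .decomposition import is_applicable
from .errors import (
    MultiValuedControlError,
    NoSeparationError,
    ValidationError,
)
from .petri_core import (
    INHIBITORY,
    INPUT,
    OUTPUT,
    READ,
    Arc,
    ExtendedPetriNet,
    Place,
)

__all__ = [
    "Literal",
    "ControlFunction",
    "ControlledReaction",
    "GROUP_I",
    "GROUP_II",
    "GROUP_III",
    "classify",
    "minimize_boolean",
    "derive_controls",
    "to_subnet",
]

GROUP_I = "I"
GROUP_II = "II"
GROUP_III = "III"

# literal = (place name, polarity); positive polarity means ">= 1 token",
# negative means "no token".
Literal = tuple


@dataclass(frozen=True)
class ControlFunction:
    """Boolean condition in disjunctive normal form over place literals.

    ``terms`` is a tuple of conjunctive terms, each a tuple of
    ``(place, polarity)`` literals; the function is true at a marking iff
    some term has all its literals satisfied.  The constant-true function
    (no control arcs at all) is represented by an empty term tuple and
    reported by :attr:`is_always`.
    """

    terms: tuple[tuple[Literal, ...], ...] = ()

    @classmethod
    def always(cls) -> "ControlFunction":
        return cls(terms=())

    @classmethod
    def of(cls, terms: Iterable[Iterable[Literal]], places: Sequence[str]) -> "ControlFunction":
        """Build with canonical literal/term ordering (declaration order of
        ``places``, positive before negative)."""
        order = {p: i for i, p in enumerate(places)}
        canon_terms = []
        for term in terms:
            term = tuple(sorted(set(term), key=lambda l: (order[l[0]], not l[1])))
            seen_places = [l[0] for l in term]
            if len(set(seen_places)) != len(seen_places):
                raise ValidationError(f"term mentions a place twice: {term}")
            canon_terms.append(term)
        canon_terms.sort(key=lambda t: (len(t), [(order[p], not s) for p, s in t]))
        for a, b in itertools.permutations(canon_terms, 2):
            if set(a) < set(b):
                raise ValidationError(
                    f"redundant cover: term {b} is a superset of term {a}"
                )
        return cls(terms=tuple(canon_terms))

    @property
    def is_always(self) -> bool:
        return not self.terms

    def places(self) -> set[str]:
        return {p for term in self.terms for p, _ in term}

    def evaluate(self, marking: Sequence[int], place_index: dict[str, int]) -> bool:
        if self.is_always:
            return True
        for term in self.terms:
            ok = True
            for place, positive in term:
                tokens = marking[place_index[place]]
                if positive != (tokens >= 1):
                    ok = False
                    break
            if ok:
                return True
        return False

    def infix(self) -> str:
        """Human-readable form; NOT is written ``-`` as in the net diagrams."""
        if self.is_always:
            return "1"
        rendered = []
        for term in self.terms:
            lits = [p if positive else f"-{p}" for p, positive in term]
            rendered.append(" ∧ ".join(lits))
        if len(rendered) == 1:
            return rendered[0]
        return " ∨ ".join(f"({t})" if " " in t else t for t in rendered)

    def __str__(self):
        return self.infix()


@dataclass(frozen=True)
class ControlledReaction:
    """One catalog entry: a reaction vector paired with a control function.

    ``on_states``/``off_states`` keep the markings the control function was
    derived from, so the separation property can be re-asserted post hoc.
    """

    r: tuple[int, ...]
    f: ControlFunction
    on_states: frozenset = frozenset()
    off_states: frozenset = frozenset()


def classify(
    r: Sequence[int],
    on_states: Iterable[Sequence[int]],
    terminal_states: Iterable[Sequence[int]],
    capacities: Sequence[int],
) -> str:
    """Group label of reaction ``r`` with respect to the terminal states.

    ``on_states`` are the markings where the reaction is applied (observed
    states plus intermediate states of the sequence under evaluation).
    """
    on = {tuple(x) for x in on_states}
    if not on:
        raise ValidationError("classify needs a nonempty set of application states")
    applicable_terminals = {
        tuple(t) for t in terminal_states if is_applicable(r, t, capacities)
    }
    if not applicable_terminals:
        return GROUP_I
    if on & applicable_terminals:
        return GROUP_II
    return GROUP_III


def _literal_true(literal: Literal, marking, index) -> bool:
    place, positive = literal
    return positive == (marking[index[place]] >= 1)


def _minimal_hitting_sets(
    pool: list[Literal], kills: dict[Literal, frozenset], targets: frozenset
) -> list[frozenset]:
    """All minimal subsets of ``pool`` whose kill-sets cover ``targets``."""
    results: list[frozenset] = []

    def search(chosen: frozenset, covered: frozenset):
        if covered >= targets:
            for r in results:
                if r <= chosen:
                    return
            results[:] = [r for r in results if not chosen <= r] + [chosen]
            return
        # branch on the first uncovered target: any hitting set must
        # contain some literal that kills it
        missing = min(targets - covered)
        for lit in pool:
            if lit not in chosen and missing in kills[lit]:
                search(chosen | {lit}, covered | kills[lit])

    search(frozenset(), frozenset())
    # drop non-minimal leftovers (order of discovery may keep supersets)
    minimal = [
        s for s in results if not any(o < s for o in results)
    ]
    return minimal


def minimize_boolean(
    on: Iterable[Sequence[int]],
    off: Iterable[Sequence[int]],
    places: Sequence[str],
) -> list[ControlFunction]:
    """All minimum DNF covers separating ``on`` (value 1) from ``off``
    (value 0); every other marking is a don't-care.

    Optimality is lexicographic: fewest terms first, then fewest total
    literals; *all* optima are returned, canonically ordered.  An empty
    off-set yields the constant-true function.  Overlapping on/off sets
    raise :class:`NoSeparationError`.
    """
    on = sorted({tuple(x) for x in on})
    off = sorted({tuple(x) for x in off})
    if not on:
        raise ValidationError("minimize_boolean needs a nonempty on-set")
    overlap = set(on) & set(off)
    if overlap:
        raise NoSeparationError(
            f"no control function exists: marking(s) {sorted(overlap)} are both "
            f"on and off (the function cannot be 1 and 0 at identical marking)"
        )
    if not off:
        return [ControlFunction.always()]
    index = {p: i for i, p in enumerate(places)}
    off_ids = frozenset(range(len(off)))

    # Candidate terms: for every subset S of on-states, literals consistent
    # with all of S form the pool; minimal pool subsets excluding every
    # off-state are the prime terms covering (at least) S.
    terms: dict[frozenset, frozenset] = {}  # literals -> covered on-ids
    n_on = len(on)
    if n_on > 20:
        raise ValidationError(
            f"on-set of size {n_on} exceeds the exact-minimisation bound (20)"
        )
    for mask in range(1, 2 ** n_on):
        subset = [on[i] for i in range(n_on) if mask >> i & 1]
        pool = []
        kills: dict[Literal, frozenset] = {}
        for p in places:
            values = {s[index[p]] >= 1 for s in subset}
            if len(values) != 1:
                continue
            lit = (p, values.pop())
            killed = frozenset(
                j for j, o in enumerate(off) if not _literal_true(lit, o, index)
            )
            if killed:
                pool.append(lit)
                kills[lit] = killed
        if frozenset().union(*kills.values(), frozenset()) != off_ids:
            continue
        for lits in _minimal_hitting_sets(pool, kills, off_ids):
            if lits in terms:
                continue
            covered = frozenset(
                i
                for i, s in enumerate(on)
                if all(_literal_true(l, s, index) for l in lits)
            )
            terms[lits] = covered

    if not terms:
        raise NoSeparationError(
            "no implicant separates the on-set from the off-set"
        )
    term_list = sorted(terms.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
    all_on = frozenset(range(n_on))

    covers: list[tuple[frozenset, ...]] = []
    for k in range(1, n_on + 1):
        for combo in itertools.combinations(term_list, k):
            union = frozenset().union(*(cov for _, cov in combo))
            if union == all_on:
                covers.append(tuple(lits for lits, _ in combo))
        if covers:
            break
    if not covers:
        raise NoSeparationError("on-set cannot be covered by off-excluding terms")
    best_literals = min(sum(len(t) for t in c) for c in covers)
    optima = [c for c in covers if sum(len(t) for t in c) == best_literals]
    functions = [ControlFunction.of(c, places) for c in optima]
    functions.sort(key=lambda f: (len(f.terms), sum(map(len, f.terms)), f.terms))
    return functions


def derive_controls(
    r: Sequence[int],
    on_states: Iterable[Sequence[int]],
    terminal_states: Iterable[Sequence[int]],
    capacities: Sequence[int],
    places: Sequence[str],
) -> list[ControlledReaction]:
    """All controlled reactions ``(r, f)`` for reaction ``r``.

    Group I yields the single constant-true control; group II yields an
    empty list (the enclosing sequence must be deleted); group III yields
    one entry per minimum cover.  Separation is re-asserted on every
    returned entry.
    """
    r = tuple(r)
    on = {tuple(x) for x in on_states}
    group = classify(r, on, terminal_states, capacities)
    if group == GROUP_II:
        return []
    if group == GROUP_I:
        return [
            ControlledReaction(
                r=r, f=ControlFunction.always(), on_states=frozenset(on)
            )
        ]
    off = {
        tuple(t)
        for t in terminal_states
        if is_applicable(r, t, capacities)
    }
    if any(c > 1 for c in capacities):
        # presence/absence literals cannot express thresholds
        raise MultiValuedControlError(
            f"reaction {r}: control derivation over places with capacity > 1 "
            f"is not supported (presence/absence literals only)"
        )
    index = {p: i for i, p in enumerate(places)}
    out = []
    for f in minimize_boolean(on, off, places):
        assert all(f.evaluate(x, index) for x in on)
        assert not any(f.evaluate(x, index) for x in off)
        out.append(
            ControlledReaction(
                r=r, f=f, on_states=frozenset(on), off_states=frozenset(off)
            )
        )
    return out


def to_subnet(
    cr: ControlledReaction,
    places: Sequence[str],
    capacities: Sequence[int],
    transition_prefix: str = "t",
) -> ExtendedPetriNet:
    """Translate a controlled reaction into an extended-Petri-net fragment.

    One transition per DNF term (a constant-true control yields a single
    uncontrolled transition); every transition carries the standard arcs
    realising the reaction vector, plus one read arc per positive literal
    and one inhibitory arc per negative literal of its term.
    """
    place_objs = [Place(name=p, capacity=c) for p, c in zip(places, capacities)]
    terms = cr.f.terms if cr.f.terms else ((),)
    transitions = []
    arcs = []
    for k, term in enumerate(terms):
        t = transition_prefix if len(terms) == 1 else f"{transition_prefix}.{k}"
        transitions.append(t)
        for i, e in enumerate(cr.r):
            if e < 0:
                arcs.append(Arc(place=places[i], transition=t, kind=INPUT, weight=-e))
            elif e > 0:
                arcs.append(Arc(place=places[i], transition=t, kind=OUTPUT, weight=e))
        for place, positive in term:
            kind = READ if positive else INHIBITORY
            arcs.append(Arc(place=place, transition=t, kind=kind))
    return ExtendedPetriNet(
        places=place_objs, transitions=transitions, arcs=arcs, name=transition_prefix
    )
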