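"""Independent reference implementations used as test oracles.

Deliberately dumb: plain enumeration with no shared code paths with the
package's production algorithms.
"""

from __future__ import annotations

import itertools
from math import factorial


def sign(x):
    return (x > 0) - (x < 0)


def oracle_candidates(d):
    """All sign-compatible nonzero sub-vectors of d, by raw product."""
    ranges = []
    for e in d:
        if e == 0:
            ranges.append([0])
        elif e > 0:
            ranges.append(list(range(0, e + 1)))
        else:
            ranges.append(list(range(e, 1)))
    return sorted(v for v in itertools.product(*ranges) if any(v))


def oracle_decompositions(d, candidates):
    """All multisets of candidates summing to d, via bounded brute force."""
    total_moves = sum(abs(e) for e in d)
    cands = sorted(set(map(tuple, candidates)))
    found = set()
    for k in range(1, total_moves + 1):
        for combo in itertools.combinations_with_replacement(cands, k):
            if tuple(map(sum, zip(*combo))) == tuple(d):
                found.add(tuple(sorted(combo)))
    return sorted(found, key=lambda parts: (len(parts), parts))


def oracle_permutation_count(parts):
    """Multinomial coefficient for the multiset of parts."""
    n = factorial(len(parts))
    for p in set(parts):
        n //= factorial(list(parts).count(p))
    return n


def oracle_min_covers(on, off, places):
    """All minimum DNF covers (min terms, then min literals) separating
    on (1) from off (0), by exhaustive search over all DNFs by size.

    Returns a set of frozensets of literal-frozensets; the constant-true
    function is the singleton {frozenset()} when off is empty.  Only
    sensible for a handful of places.
    """
    on = sorted({tuple(x) for x in on})
    off = sorted({tuple(x) for x in off})
    if not off:
        # constant-true: the unique optimum, marked by the empty cover
        return {frozenset()}
    index = {p: i for i, p in enumerate(places)}

    def true_at(term, m):
        return all((m[index[p]] >= 1) == positive for p, positive in term)

    all_terms = []
    for r in range(1, len(places) + 1):
        for combo in itertools.combinations(places, r):
            for signs in itertools.product((True, False), repeat=r):
                all_terms.append(frozenset(zip(combo, signs)))
    # implicants that cover at least one on-state (others can never be part
    # of an optimal cover: dropping them keeps all optima and tames C(n, k))
    implicants = [
        t
        for t in all_terms
        if not any(true_at(t, o) for o in off)
        and any(true_at(t, s) for s in on)
    ]
    covers = set()
    for k in range(1, len(on) + 1):
        for combo in itertools.combinations(implicants, k):
            if all(any(true_at(t, s) for t in combo) for s in on):
                covers.add(frozenset(combo))
        if covers:
            break
    if not covers:
        return set()
    best = min(sum(len(t) for t in c) for c in covers)
    return {c for c in covers if sum(len(t) for t in c) == best}
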