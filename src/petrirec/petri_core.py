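"""Extended Petri net data model and token-game execution semantics.

An *extended* Petri net is a place/transition net whose transitions may, in
addition to weighted standard arcs, be connected to places through *read*
arcs (the place must hold at least one token for the transition to fire;
the marking of the place does not change) and *inhibitory* arcs (the place
must be empty).  Read and inhibitory arcs carry no weight beyond the
implicit threshold of one token.

Markings are plain tuples of non-negative integers, one entry per place in
declaration order.  Tuples keep markings hashable, which the reconstruction
stages rely on (markings are set members and dict keys throughout).

Dialect note: enabling is *capacity respecting* on the output side — a
transition whose firing would push a place above its capacity is treated
as disabled.  This matches the applicability test used during
reconstruction, where a successor state with "a negative or a too large
number of tokens per place" is invalid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import DisabledFiringError, UnknownTransitionError, ValidationError

__all__ = [
    "Place",
    "Arc",
    "INPUT",
    "OUTPUT",
    "READ",
    "INHIBITORY",
    "ARC_KINDS",
    "ExtendedPetriNet",
    "Trajectory",
    "is_enabled",
    "enabled_transitions",
    "fire",
    "reaction_vector_of",
    "simulate",
]

INPUT = "input"
OUTPUT = "output"
READ = "read"
INHIBITORY = "inhibitory"
ARC_KINDS = (INPUT, OUTPUT, READ, INHIBITORY)


@dataclass(frozen=True)
class Place:
    """A place: one measured component (or component state form).

    ``capacity`` is the maximum number of tokens the place may hold; for
    boolean data it is 1.
    """

    name: str
    capacity: int = 1

    def __post_init__(self):
        if self.capacity < 1:
            raise ValidationError(
                f"place {self.name!r}: capacity must be >= 1, got {self.capacity}"
            )


@dataclass(frozen=True)
class Arc:
    """A directed connection between one place and one transition.

    ``kind`` is one of ``input`` (place -> transition), ``output``
    (transition -> place), ``read`` or ``inhibitory`` (control arcs).
    Read/inhibitory arcs always have weight 1.
    """

    place: str
    transition: str
    kind: str
    weight: int = 1

    def __post_init__(self):
        if self.kind not in ARC_KINDS:
            raise ValidationError(f"unknown arc kind {self.kind!r}")
        if self.weight < 1:
            raise ValidationError(f"arc weight must be >= 1, got {self.weight}")
        if self.kind in (READ, INHIBITORY) and self.weight != 1:
            raise ValidationError(f"{self.kind} arcs have fixed weight 1")


@dataclass
class ExtendedPetriNet:
    """Places, transitions and arcs; the incidence matrix lives implicitly
    in the input/output arcs.

    Arcs always connect a place with a transition; uniqueness of the
    (place, transition, kind) triple is enforced.
    """

    places: list[Place]
    transitions: list[str]
    arcs: list[Arc]
    name: str = "net"

    # lookup tables, built once in __post_init__
    _index: dict = field(init=False, repr=False, default_factory=dict)
    _by_transition: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self):
        names = [p.name for p in self.places]
        if len(set(names)) != len(names):
            raise ValidationError("place names must be unique")
        if len(set(self.transitions)) != len(self.transitions):
            raise ValidationError("transition ids must be unique")
        self._index = {p.name: i for i, p in enumerate(self.places)}
        self._by_transition = {t: {k: {} for k in ARC_KINDS} for t in self.transitions}
        seen = set()
        for arc in self.arcs:
            if arc.place not in self._index:
                raise ValidationError(f"arc references unknown place {arc.place!r}")
            if arc.transition not in self._by_transition:
                raise ValidationError(
                    f"arc references unknown transition {arc.transition!r}"
                )
            key = (arc.place, arc.transition, arc.kind)
            if key in seen:
                raise ValidationError(f"duplicate arc {key}")
            seen.add(key)
            self._by_transition[arc.transition][arc.kind][arc.place] = arc.weight

    # -- structural accessors -------------------------------------------------

    @property
    def place_names(self) -> list[str]:
        return [p.name for p in self.places]

    @property
    def capacities(self) -> tuple[int, ...]:
        return tuple(p.capacity for p in self.places)

    def place_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise ValidationError(f"unknown place {name!r}") from None

    def _arcs_of(self, t: str, kind: str) -> dict[str, int]:
        try:
            return self._by_transition[t][kind]
        except KeyError:
            raise UnknownTransitionError(f"unknown transition {t!r}") from None

    def inputs(self, t: str) -> dict[str, int]:
        return dict(self._arcs_of(t, INPUT))

    def outputs(self, t: str) -> dict[str, int]:
        return dict(self._arcs_of(t, OUTPUT))

    def reads(self, t: str) -> list[str]:
        return sorted(self._arcs_of(t, READ))

    def inhibitors(self, t: str) -> list[str]:
        return sorted(self._arcs_of(t, INHIBITORY))

    def validate_marking(self, m: Sequence[int]) -> tuple[int, ...]:
        if len(m) != len(self.places):
            raise ValidationError(
                f"marking length {len(m)} != number of places {len(self.places)}"
            )
        for value, place in zip(m, self.places):
            if not isinstance(value, int):
                raise ValidationError(
                    f"marking of {place.name!r} must be an integer, got {value!r}"
                )
            if not 0 <= value <= place.capacity:
                raise ValidationError(
                    f"marking of {place.name!r} out of bounds: "
                    f"{value} not in [0, {place.capacity}]"
                )
        return tuple(m)


@dataclass
class Trajectory:
    """Result of :func:`simulate`: the visited markings, the fired
    transition ids (one fewer than markings) and whether the final marking
    is dead (no transition enabled)."""

    markings: list[tuple[int, ...]]
    fired: list[str]
    terminal: bool


def is_enabled(net: ExtendedPetriNet, t: str, m: Sequence[int]) -> bool:
    """True iff ``t`` may fire at marking ``m``.

    Requires: every input place holds at least the arc weight; firing would
    not push any place above its capacity; every read-arc place holds a
    token; every inhibitory-arc place is empty.
    """
    m = net.validate_marking(m)
    inputs = net._arcs_of(t, INPUT)
    outputs = net._arcs_of(t, OUTPUT)
    for place, w in inputs.items():
        if m[net._index[place]] < w:
            return False
    for place in set(inputs) | set(outputs):
        i = net._index[place]
        after = m[i] - inputs.get(place, 0) + outputs.get(place, 0)
        if not 0 <= after <= net.places[i].capacity:
            return False
    for place in net._arcs_of(t, READ):
        if m[net._index[place]] < 1:
            return False
    for place in net._arcs_of(t, INHIBITORY):
        if m[net._index[place]] != 0:
            return False
    return True


def enabled_transitions(net: ExtendedPetriNet, m: Sequence[int]) -> list[str]:
    """All transitions enabled at ``m``, in the net's declaration order."""
    return [t for t in net.transitions if is_enabled(net, t, m)]


def fire(net: ExtendedPetriNet, t: str, m: Sequence[int]) -> tuple[int, ...]:
    """Fire ``t`` at ``m`` and return the successor marking.

    Input-arc weights are removed, output-arc weights are added; places
    connected only through read or inhibitory arcs are untouched.  Firing a
    disabled transition raises :class:`DisabledFiringError`.
    """
    if not is_enabled(net, t, m):
        raise DisabledFiringError(t)
    result = list(m)
    for place, w in net._arcs_of(t, INPUT).items():
        result[net._index[place]] -= w
    for place, w in net._arcs_of(t, OUTPUT).items():
        result[net._index[place]] += w
    return tuple(result)


def reaction_vector_of(net: ExtendedPetriNet, t: str) -> tuple[int, ...]:
    """The incidence-matrix column of ``t``: output minus input weights per
    place.  Read and inhibitory arcs contribute nothing."""
    vec = [0] * len(net.places)
    for place, w in net._arcs_of(t, INPUT).items():
        vec[net._index[place]] -= w
    for place, w in net._arcs_of(t, OUTPUT).items():
        vec[net._index[place]] += w
    return tuple(vec)


def simulate(
    net: ExtendedPetriNet,
    m0: Sequence[int],
    policy: Iterable[str] | str = "deterministic",
    max_steps: int = 10_000,
) -> Trajectory:
    """Play the token game from ``m0``.

    ``policy`` is either an explicit sequence of transition ids, each of
    which must be enabled when its turn comes, or the string
    ``"deterministic"``: repeatedly fire the enabled transition with the
    lexicographically smallest id until the net is dead (used for fixtures
    and tests only — reconstruction never simulates with this chooser).

    The terminal flag of the returned trajectory is set iff the final
    marking enables no transition, i.e. the net entered a dead state.
    """
    m = net.validate_marking(m0)
    markings = [m]
    fired: list[str] = []
    if policy == "deterministic":
        for _ in range(max_steps):
            enabled = enabled_transitions(net, m)
            if not enabled:
                break
            t = min(enabled)
            m = fire(net, t, m)
            markings.append(m)
            fired.append(t)
    else:
        for step, t in enumerate(policy):
            if not is_enabled(net, t, m):
                raise DisabledFiringError(t, step=step)
            m = fire(net, t, m)
            markings.append(m)
            fired.append(t)
    terminal = not enabled_transitions(net, m)
    return Trajectory(markings=markings, fired=fired, terminal=terminal)
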