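"""Experiment ingestion, state-matrix compilation and difference vectors.

A reconstruction run starts from one time-series table per experiment
(wild-type or perturbed/mutant).  Compilation removes consecutive
duplicate measurements, concatenates the experiments into a single state
matrix with a global 0-based state numbering, flags terminal states, and
derives the duplicate-free difference-vector matrix.

Discretisation is deliberately the caller's job: values must already be
integers, anything else is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError

__all__ = [
    "Experiment",
    "StateMatrix",
    "DifferenceVector",
    "compile_state_matrix",
    "difference_matrix",
]


@dataclass
class Experiment:
    """One time-series data set over the shared component ordering.

    ``series`` is an ordered list of ``(time_stamp, values)`` pairs; time
    stamps are opaque labels (only order matters).  ``terminal`` may be set
    by the experimenter to declare that the series ends in a terminal
    (unchanging) state even without a repeated final measurement.
    """

    id: str
    series: list[tuple[object, tuple[int, ...]]]
    label: str = ""
    terminal: bool | None = None

    def __post_init__(self):
        if len(self.series) < 2:
            raise ValidationError(
                f"experiment {self.id!r}: need at least 2 time points, "
                f"got {len(self.series)}"
            )


@dataclass
class StateMatrix:
    """Compiled, concatenated, duplicate-free states of all experiments.

    ``states[i]`` is the i-th column of the matrix; ``origin[i]`` records
    the experiment id and the first raw time-point index that produced it;
    ``terminal[i]`` flags dead/unchanging end states; ``segments`` maps each
    experiment to its half-open global index range ``(start, stop)``.
    """

    components: list[str]
    capacities: tuple[int, ...]
    states: list[tuple[int, ...]]
    origin: list[tuple[str, int]]
    terminal: list[bool]
    segments: list[tuple[str, int, int]]

    @property
    def n_states(self) -> int:
        return len(self.states)

    def terminal_states(self) -> list[tuple[int, ...]]:
        return [s for s, t in zip(self.states, self.terminal) if t]

    def terminal_indices(self) -> list[int]:
        return [i for i, t in enumerate(self.terminal) if t]

    def segment_of(self, state_index: int) -> str:
        for exp_id, start, stop in self.segments:
            if start <= state_index < stop:
                return exp_id
        raise ValidationError(f"state index {state_index} out of range")

    def consecutive_pairs(self) -> list[tuple[int, int]]:
        """(i, i+1) index pairs within experiment segments only."""
        pairs = []
        for _, start, stop in self.segments:
            pairs.extend((i, i + 1) for i in range(start, stop - 1))
        return pairs


@dataclass
class DifferenceVector:
    """A distinct nonzero change between consecutive compiled states.

    ``witnesses`` lists every global state index ``i`` such that
    ``states[i+1] - states[i] == entries`` within one experiment segment.
    """

    entries: tuple[int, ...]
    witnesses: list[int] = field(default_factory=list)

    def __post_init__(self):
        if not any(self.entries):
            raise ValidationError("difference vector must not be the zero vector")


def _validate_experiments(
    experiments: Sequence[Experiment],
    components: Sequence[str] | None,
    capacities: Mapping[str, int] | None,
) -> tuple[list[str], tuple[int, ...]]:
    if not experiments:
        raise ValidationError("no experiments given")
    n = len(experiments[0].series[0][1])
    comps = list(components) if components is not None else [f"c{i}" for i in range(n)]
    if len(comps) != n:
        raise ValidationError(
            f"component list has {len(comps)} names but data rows have {n} values"
        )
    observed_max = [0] * n
    for exp in experiments:
        for row, (stamp, values) in enumerate(exp.series):
            if len(values) != n:
                raise ValidationError(
                    f"experiment {exp.id!r}, row {row} (t={stamp!r}): expected "
                    f"{n} values, got {len(values)}"
                )
            for j, v in enumerate(values):
                if not isinstance(v, int) or isinstance(v, bool):
                    raise ValidationError(
                        f"experiment {exp.id!r}, row {row}, column "
                        f"{comps[j]!r}: non-integer value {v!r} "
                        f"(discretise the data before loading it)"
                    )
                if v < 0:
                    raise ValidationError(
                        f"experiment {exp.id!r}, row {row}, column "
                        f"{comps[j]!r}: negative value {v}"
                    )
                observed_max[j] = max(observed_max[j], v)
    if capacities is None:
        caps = tuple(max(1, m) for m in observed_max)
    else:
        unknown = set(capacities) - set(comps)
        if unknown:
            raise ValidationError(f"capacities name unknown components: {sorted(unknown)}")
        caps = tuple(int(capacities.get(c, max(1, m))) for c, m in zip(comps, observed_max))
        for c, cap, m in zip(comps, caps, observed_max):
            if m > cap:
                raise ValidationError(
                    f"component {c!r}: observed value {m} exceeds declared capacity {cap}"
                )
    return comps, caps


def compile_state_matrix(
    experiments: Sequence[Experiment],
    components: Sequence[str] | None = None,
    capacities: Mapping[str, int] | None = None,
) -> StateMatrix:
    """Compile raw experiment tables into a :class:`StateMatrix`.

    Per experiment, consecutive duplicate measurements are collapsed (they
    carry no information about change); the experiments are then
    concatenated in input order under a single global state numbering.

    A compiled end state is flagged terminal when the raw series ended in
    at least two identical consecutive measurements (the observed system
    stopped changing) or when the experiment carries an explicit
    ``terminal=True`` declaration.  ``terminal=False`` suppresses the
    automatic flag.
    """
    comps, caps = _validate_experiments(experiments, components, capacities)
    states: list[tuple[int, ...]] = []
    origin: list[tuple[str, int]] = []
    terminal: list[bool] = []
    segments: list[tuple[str, int, int]] = []
    for exp in experiments:
        start = len(states)
        last = None
        repeated_end = False
        for row, (_, values) in enumerate(exp.series):
            values = tuple(values)
            if values == last:
                repeated_end = True
                continue
            repeated_end = False
            states.append(values)
            origin.append((exp.id, row))
            terminal.append(False)
            last = values
        is_terminal = exp.terminal if exp.terminal is not None else repeated_end
        terminal[-1] = bool(is_terminal)
        segments.append((exp.id, start, len(states)))
    return StateMatrix(
        components=comps,
        capacities=caps,
        states=states,
        origin=origin,
        terminal=terminal,
        segments=segments,
    )


def difference_matrix(sm: StateMatrix) -> list[DifferenceVector]:
    """All distinct nonzero consecutive differences, with witnesses.

    Differences are never computed across experiment boundaries; a change
    pattern observed in several experiments yields a single entry whose
    witnesses record every occurrence.  Output is ordered by first witness.
    """
    seen: dict[tuple[int, ...], DifferenceVector] = {}
    for i, j in sm.consecutive_pairs():
        entries = tuple(b - a for a, b in zip(sm.states[i], sm.states[j]))
        if not any(entries):
            # cannot happen on compiled input; guard for hand-built matrices
            continue
        if entries not in seen:
            seen[entries] = DifferenceVector(entries=entries, witnesses=[])
        seen[entries].witnesses.append(i)
    return sorted(seen.values(), key=lambda d: d.witnesses[0])
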