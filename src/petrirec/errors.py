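"""Exception hierarchy shared by all petrirec modules.

The CLI maps these onto process exit codes (see :mod:`petrirec.cli`):
validation problems exit 2, an unsatisfiable difference vector exits 3 and
a combinatorial-guard overflow exits 4.
"""


class PetrirecError(Exception):
    """Base class for all petrirec errors."""


class ValidationError(PetrirecError):
    """Malformed input: ragged rows, non-integer values, unknown names, ..."""


class UnknownTransitionError(ValidationError):
    """A transition id was used that does not belong to the net."""


class DisabledFiringError(PetrirecError):
    """An explicit firing sequence asked a disabled transition to fire."""

    def __init__(self, transition, step=None, message=None):
        self.transition = transition
        self.step = step
        if message is None:
            at = f" at step {step}" if step is not None else ""
            message = f"transition {transition!r} is not enabled{at}"
        super().__init__(message)


class CapsExceededError(PetrirecError):
    """A configurable combinatorial guard was hit.

    This is always a hard error, never a silent truncation: the offending
    difference vector and the guard that tripped are named.
    """

    def __init__(self, guard, limit, actual, context=""):
        self.guard = guard
        self.limit = limit
        self.actual = actual
        self.context = context
        where = f" while processing {context}" if context else ""
        super().__init__(
            f"guard {guard!r} exceeded{where}: {actual} > {limit}; "
            f"raise the cap in the run configuration to proceed"
        )


class InfeasibleError(PetrirecError):
    """No controlled-reaction sequence exists for some difference vector."""

    def __init__(self, difference, message=None):
        self.difference = difference
        super().__init__(
            message
            or f"reconstruction infeasible: no valid controlled-reaction "
            f"sequence realises difference vector {difference!r}"
        )


class NoSeparationError(PetrirecError):
    """on- and off-state sets intersect: no control function can exist."""


class MultiValuedControlError(PetrirecError):
    """Control derivation requested for places with capacity > 1.

    Control literals express presence (>= 1 token) or absence (0 tokens)
    only; threshold logic over multi-valued places is out of scope.
    """
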