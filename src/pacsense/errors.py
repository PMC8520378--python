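"""Exception hierarchy for pacsense.

All library errors derive from :class:`PacsenseError` so callers (and the
CLI) can catch one type at the boundary.
"""


class PacsenseError(Exception):
    """Base class for all pacsense errors."""


class UnsupportedBasisError(PacsenseError):
    """Requested sparse basis name (or variant) is not one of the built-ins."""


class InvalidSizeError(PacsenseError):
    """Transform size N is too small or otherwise invalid."""


class DimensionError(PacsenseError):
    """Shapes of signal / coefficients / operator do not agree."""


class InvalidThresholdError(PacsenseError):
    """Sparsity threshold c must be strictly positive."""


class InvalidKError(PacsenseError):
    """Sparsity level K outside the admissible range."""


class InvalidShapeError(PacsenseError):
    """Measurement matrix shape violates 1 <= M <= N."""


class InfeasibleKError(PacsenseError):
    """Greedy solver asked for more atoms than measurements."""


class InvalidPenaltyError(PacsenseError):
    """l1 penalty must be strictly positive."""


class InstanceTooLargeError(PacsenseError):
    """Exhaustive l0 search guarded against combinatorial blow-up."""


class UnsupportedKindError(PacsenseError):
    """Unknown synthetic test-signal kind."""


class OutOfWindowError(PacsenseError):
    """Phantom absorber pulse falls outside the simulated time window."""


class InvalidFactorError(PacsenseError):
    """Contrast enhancement factor must be >= 1."""


class SignalIOError(PacsenseError):
    """Signal file missing, empty, or malformed."""
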