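"""Exception hierarchy for rametipm."""


class RametIPMError(Exception):
    """Base class for all rametipm errors."""


class InvalidParameterError(RametIPMError, ValueError):
    """A vital-rate parameter is non-finite or violates its domain constraint."""


class InvariantViolationError(RametIPMError, ValueError):
    """A ramet table violates a per-record invariant.

    Carries the offending row numbers in ``rows`` (0-based positions in the
    table) and human-readable messages in ``violations``.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        self.rows = [r for r, _ in self.violations]
        msgs = "; ".join(f"row {r}: {m}" for r, m in self.violations)
        super().__init__(f"ramet table invariant violations: {msgs}")


class SchemaError(RametIPMError, ValueError):
    """A ramet CSV does not conform to the expected column schema."""


class SeparationError(RametIPMError, RuntimeError):
    """Logistic fit rejected: complete/quasi-complete separation or constant response."""


class DegenerateDataError(RametIPMError, ValueError):
    """Data insufficient or degenerate for the requested fit."""


class ConvergenceError(RametIPMError, RuntimeError):
    """An iterative fit or eigensolver failed to converge; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
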