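"""Exception hierarchy.

``ValidationError`` covers malformed inputs (bad tables, mismatched labels,
unknown residues); ``SingularSystemError`` covers numerically unsolvable
normal systems. CLI commands map the former to exit code 2 and the latter
to exit code 3.
"""


class TlpcaError(Exception):
    """Base class for all package errors."""


class ValidationError(TlpcaError, ValueError):
    """Input data violates a structural or domain constraint."""


class SingularSystemError(TlpcaError, ArithmeticError):
    """Every eigenvalue of a normal matrix fell below the inversion cutoff."""


class ConvergenceWarning(UserWarning):
    """The alternating fit stopped at the iteration cap without converging."""
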