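"""Exception hierarchy for topconnmf.

All errors raised deliberately by the package derive from
:class:`TopConNMFError` so callers can catch them with a single clause.
"""


class TopConNMFError(Exception):
    """Base class for all package errors."""


class InvalidRankError(TopConNMFError, ValueError):
    """Factorization rank outside ``1 <= k <= min(g, s)``."""


class DimensionError(TopConNMFError, ValueError):
    """Matrix shapes are incompatible for the requested operation."""


class DegenerateInputError(TopConNMFError, ValueError):
    """Input is structurally degenerate (e.g. k < 2 for correlations)."""


class TooFewFeaturesError(TopConNMFError, ValueError):
    """Not enough biomarker columns to form the requested clustering."""


class DegenerateClassError(TopConNMFError, ValueError):
    """A sample class or class-associated column set is empty."""


class ValidationError(TopConNMFError, ValueError):
    """Input data violates a contract (negative entries, bad labels...)."""


class JoinError(TopConNMFError, ValueError):
    """Sample identifiers cannot be matched between matrix and metadata."""
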