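"""Exception hierarchy.

Validation problems (bad specs, bad data files, dimension mismatches) raise
:class:`SpecificationError` or :class:`DataError`; numerical failures
(ill-conditioned or non-positive-definite matrices, degenerate blocks) raise
:class:`ConditioningError` or :class:`DegenerateBlockError`.  The CLI maps the
former to exit code 2 and the latter to exit code 3.
"""


class CCAError(Exception):
    """Base class for all package errors."""


class SpecificationError(CCAError, ValueError):
    """A model specification or parameter set violates its invariants."""


class DataError(CCAError, ValueError):
    """An input data table is unusable (missing columns, NA cells, N <= K)."""


class ConditioningError(CCAError, RuntimeError):
    """A matrix required to be positive-definite (within tolerance) is not."""


class DegenerateBlockError(CCAError, RuntimeError):
    """A block's weights or indicators are degenerate (zero variance/norm)."""


class FitTestError(CCAError, RuntimeError):
    """The bootstrap fit test could not produce a usable reference distribution."""
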