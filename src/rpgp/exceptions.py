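"""Exception hierarchy for rpgp.

All errors derive from :class:`RPGPError` so callers can catch the
package's failures with a single handler while still distinguishing
parse, validation, alignment and dimension problems.
"""


class RPGPError(Exception):
    """Base class for all rpgp errors."""


class ParseError(RPGPError, ValueError):
    """A data cell or token could not be parsed (names row/column)."""


class FormatError(RPGPError, ValueError):
    """Structural problem in an input file (ragged rows, bad header)."""


class ValidationError(RPGPError, ValueError):
    """An object violates a declared invariant (duplicate ids, NaNs, ...)."""


class AlignmentError(RPGPError, ValueError):
    """Sample identifiers of a matrix and a label vector do not line up."""


class DimensionError(RPGPError, ValueError):
    """Incompatible shapes (projection vs. matrix, k >= d, ...)."""


class EvaluationError(RPGPError, ValueError):
    """A program tree referenced a feature index outside the feature space."""
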