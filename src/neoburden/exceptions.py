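"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`NeoburdenError`, so callers (and the CLI) can distinguish
user/data errors from genuine bugs.  Plain ``ValueError`` is reserved for
invalid arguments to individual functions (bad threshold, empty input).
"""


class NeoburdenError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(NeoburdenError):
    """An input table or FASTA file violates the documented schema."""


class ReferenceMismatchError(NeoburdenError):
    """A mutation's reference residue does not match the proteome."""


class UnsupportedAlleleError(NeoburdenError):
    """The affinity predictor does not support the requested HLA allele."""


class InfeasibleMomentsError(NeoburdenError, ValueError):
    """Requested distribution moments are outside the feasible region."""


class InputInconsistencyError(NeoburdenError):
    """Duplicate keys with conflicting values in an input file."""


class DataIntegrityError(NeoburdenError):
    """Paired data arrived incomplete (e.g. mutant IC50 without wild-type)."""


class DegenerateRegressionError(NeoburdenError):
    """Regression requested on a constant predictor."""


class FitFailureError(NeoburdenError):
    """A model fit failed to converge."""
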