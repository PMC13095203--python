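"""Exception hierarchy shared by all clearseq modules.

Every error raised on a contract violation derives from :class:`ClearseqError`
so callers (and the CLI) can catch one base class and map it to a nonzero
exit code with the error name in the message.
"""


class ClearseqError(Exception):
    """Base class for all clearseq errors."""


# --- input / parsing -------------------------------------------------------

class DuplicateIdentifier(ClearseqError):
    """A gene, sample, or signature identifier occurs more than once."""


class MalformedMatrix(ClearseqError):
    """A matrix cell is negative, non-numeric, or missing."""


class EmptyInput(ClearseqError):
    """An operation received an empty matrix, vector, or file."""


class EmptySignature(ClearseqError):
    """A signature definition has no genes."""


class IOFailure(ClearseqError):
    """A file could not be read or written."""


# --- preprocessing ---------------------------------------------------------

class InvalidParameter(ClearseqError):
    """A configuration value is outside its valid range."""


class EmptyAfterFilter(ClearseqError):
    """A filtering step removed every gene or every sample."""


class DegenerateReference(ClearseqError):
    """No gene has all-positive counts; median-of-ratios reference undefined."""


class InsufficientBatch(ClearseqError):
    """A batch has too few samples for batch-effect estimation."""


class UnknownBatch(ClearseqError):
    """A sample carries a batch label absent from the fitted batch model."""


# --- scoring / classification ---------------------------------------------

class InsufficientSignatureCoverage(ClearseqError):
    """Too few signature genes are present in the expression matrix."""


class NonpositiveDenominator(ClearseqError):
    """A signature-ratio denominator is zero or negative."""


class MissingSignature(ClearseqError):
    """A required signature column is absent from the score matrix."""


class CohortTooSmall(ClearseqError):
    """Cohort-percentile mode was requested on too few samples."""


class IncompleteThresholds(ClearseqError):
    """Fixed-cutoff mode is missing one or more cutoff values."""


class SampleMismatch(ClearseqError):
    """Two label vectors do not cover the same sample set."""


# --- single-sample SVM -----------------------------------------------------

class DegenerateSample(ClearseqError):
    """A sample's values over the signature genes sum to <= 0."""


class DegenerateSplit(ClearseqError):
    """A class is absent from the training partition after splitting."""
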