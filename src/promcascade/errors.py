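"""Exception hierarchy shared across the package."""


class PromcascadeError(Exception):
    """Base class for all package-specific errors."""


class AlphabetError(PromcascadeError):
    """Sequence contains a character outside the ACGT alphabet (strict mode)."""


class LengthError(PromcascadeError):
    """Sequence too short to encode (fewer than 2 nucleotides)."""


class ShapeError(PromcascadeError):
    """Feature/sequence dimensions are inconsistent (mixed lengths, width mismatch)."""


class FormatError(PromcascadeError):
    """A table or file does not follow its documented format."""


class TooShortError(PromcascadeError):
    """An upstream or downstream region is shorter than the extraction window."""


class EmptyDatasetError(PromcascadeError):
    """No usable records remain after filtering."""


class DataError(PromcascadeError):
    """Training/evaluation data violates a precondition (e.g. single-class folds)."""


class ConfigError(PromcascadeError):
    """Invalid configuration (unknown algorithm, infeasible motif placement, ...)."""


class VersionError(PromcascadeError):
    """A model archive is incompatible or fails its integrity checks."""
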