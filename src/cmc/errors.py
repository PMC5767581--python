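"""Exception hierarchy for the CMC analysis pipeline."""


class CmcError(Exception):
    """Base class for all pipeline errors."""


class FormatError(CmcError):
    """A file does not conform to the expected on-disk format."""


class ClassificationError(CmcError):
    """A channel label cannot be mapped to a channel kind."""


class MontageError(CmcError):
    """Electrode montage is invalid (duplicates, too few electrodes, ...)."""


class UsageError(CmcError):
    """Invalid argument to an API entry point (unknown format, bad config)."""


class DesignError(CmcError):
    """Requested filter band cannot be realised."""


class LengthError(CmcError):
    """Signal too short for the requested operation."""


class RankError(CmcError):
    """Data matrix is rank deficient for the requested decomposition."""


class DegenerateSignalError(CmcError):
    """Signal carries no usable variance (all-zero or constant)."""


class PairingError(CmcError):
    """Two objects that must share a layout/grid do not."""


class ParameterError(CmcError):
    """Numerical parameter outside its admissible range."""


class BandError(CmcError):
    """Requested frequency band lies outside the available grid."""


class DofError(CmcError):
    """Degrees of freedom too small for the requested transform."""


class SingularityError(CmcError):
    """Operator construction hit a singular configuration."""


class EmptySetError(CmcError):
    """An operation produced or received an empty collection."""
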