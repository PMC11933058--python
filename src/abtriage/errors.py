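"""Exception hierarchy for the triage toolkit."""


class AbtriageError(Exception):
    """Base class for all toolkit-specific errors."""


class PairingError(AbtriageError):
    """A FASTA panel contains an id without exactly one VH and one VL."""


class AlphabetError(AbtriageError, ValueError):
    """A sequence contains a character outside the 20-letter amino-acid alphabet."""


class AnnotationError(AbtriageError):
    """CDR framework anchors could not be located on a chain."""


class AlignmentError(AbtriageError):
    """Too few alignable positions for a rigid superposition."""


class FormatError(AbtriageError):
    """An input file could not be parsed."""


class ConfigurationError(AbtriageError):
    """A required reference resource (database, distribution, model) is missing."""


class DegenerateDistributionError(AbtriageError, ValueError):
    """A reference distribution has zero spread and cannot yield a z-score."""


class GenerationError(AbtriageError):
    """A synthetic-fixture specification is internally inconsistent."""
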