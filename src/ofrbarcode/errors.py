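"""Exception hierarchy for ofrbarcode.

Every error raised by the library derives from :class:`OFRError` so callers
(and the CLI) can distinguish computational failures from usage mistakes.
"""


class OFRError(Exception):
    """Base class for all ofrbarcode errors."""


class ParseError(OFRError):
    """Malformed FASTA input."""


class LabelError(OFRError):
    """A FASTA header did not yield a species/accession pair."""


class DuplicateRecordError(OFRError):
    """The same (species, accession) pair appeared twice."""


class AlignmentError(OFRError):
    """An operation requiring an alignment got unequal-length sequences."""


class EmptyWindowError(OFRError):
    """No alignment column is covered by every record."""


class EmptySequenceError(OFRError):
    """A record became empty after gap removal."""


class GapError(OFRError):
    """A gapped sequence was passed to a gap-free operation."""


class TooShortError(OFRError):
    """Sequence shorter than the requested k-mer size."""


class ConfigError(OFRError):
    """Inconsistent parameters (e.g. mismatched k between profiles)."""


class InvalidLengthError(OFRError):
    """Average length too short to define a threshold."""


class UndefinedScoreError(OFRError):
    """No evaluable species pairs; percent resolution undefined."""


class UndefinedDistanceError(OFRError):
    """No comparable sites between two aligned sequences."""


class ScanError(OFRError):
    """Length scan cannot run (dataset shorter than one step)."""


class AuditError(OFRError):
    """Indel audit is missing required evidence."""


class ValidationError(OFRError):
    """Invalid simulation specification."""
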