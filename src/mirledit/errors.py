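"""Exception hierarchy for mirledit.

All errors derive from :class:`MirleditError` so callers can catch the
package's failures with a single except clause; each subclass maps to one
kind of contract violation (bad parameter, malformed input, unknown
reference, ...).
"""


class MirleditError(Exception):
    """Base class for all mirledit errors."""


class ParameterError(MirleditError, ValueError):
    """A function argument is outside its documented domain."""


class InputError(MirleditError, ValueError):
    """User-supplied data violates a structural contract (e.g. duplicate
    sample ids, p-values outside [0, 1])."""


class UnknownReferenceError(MirleditError, KeyError):
    """An edit, read or site refers to a pre-miRNA that is not in the
    reference set."""


class FastqParseError(MirleditError, ValueError):
    """A FASTQ record or quality string cannot be decoded (Sanger Phred+33)."""


class ClassificationError(MirleditError, ValueError):
    """A site position falls outside the hairpin plus the allowed 3' tail
    window and cannot be categorised."""


class CohortError(MirleditError, ValueError):
    """The cohort design is inconsistent with the level matrix, or a
    subgroup filter leaves an empty group."""
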