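"""Exception hierarchy.

All errors raised by the package derive from :class:`SeedRDError` so callers
can catch one type; the subclasses distinguish bad parameters, bad
configuration (sample sheets, library codes), malformed input files, and
profiles that cannot be normalized.
"""


class SeedRDError(Exception):
    """Base class for all seedrd errors."""


class ParameterError(SeedRDError, ValueError):
    """A numeric or structural argument is outside its valid domain."""


class ConfigurationError(SeedRDError, ValueError):
    """Sample sheet, cohort design, or library/priming configuration is invalid."""


class FormatError(SeedRDError, ValueError):
    """An input file violates its expected dialect (depth TSV, SAM, FASTA)."""


class UndefinedProfileError(SeedRDError, ValueError):
    """An all-zero depth vector has no normalized profile.

    Transcripts with no aligned reads in a sample must be removed by the
    presence filter before normalization.
    """


class QCWarning(UserWarning):
    """Quality-control condition that does not abort computation."""
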