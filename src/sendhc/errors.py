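"""Exception hierarchy for sendhc.

All package errors derive from :class:`SendhcError` so callers (and the CLI)
can catch one base class.
"""


class SendhcError(Exception):
    """Base class for all sendhc errors."""


class XptFormatError(SendhcError):
    """Malformed XPT transport file.

    Parameters
    ----------
    message : str
    offset : int, optional
        Byte offset at which the malformation was detected.
    """

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (byte offset {offset})"
        super().__init__(message)
        self.offset = offset


class UnsupportedFormatError(XptFormatError):
    """XPT v8/v9 or CPORT input; only transport v5 is supported."""


class EmptyLibraryError(XptFormatError):
    """Transport library contains zero datasets."""


class ValidationError(SendhcError):
    """A table or spec violates its declared invariants."""


class EmptyStudyError(SendhcError):
    """Study folder contains no XPT files."""


class StudyConsistencyError(SendhcError):
    """Domains within one study folder disagree on STUDYID."""


class AlreadyInitializedError(SendhcError):
    """Database already carries a SEND schema."""


class DuplicateStudyError(SendhcError):
    """STUDYID already present and replace not requested."""


class ClosedHandleError(SendhcError):
    """Operation attempted on a disconnected database handle."""


class InvalidRangeError(SendhcError):
    """Lower bound of a filter range exceeds the upper bound."""


class InvalidStudyDayError(SendhcError):
    """A --DY value of 0 was encountered; SEND study days skip day 0."""


class UnsupportedDomainError(SendhcError):
    """Requested domain has no subject identifier (or no table)."""


class WrongDomainError(SendhcError):
    """Aggregate function applied to findings from the wrong domain."""


class VocabError(SendhcError):
    """Controlled-terminology vocabulary problem (conflicts, unknown keys)."""
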