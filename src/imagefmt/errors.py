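"""Exception hierarchy.

Errors are split by how a caller should react:

* :class:`FormatError` — the input is corrupt or malformed for its format.
* :class:`UnsupportedDialectError` — the input belongs to a recognized format
  family but uses a variant this library deliberately does not decode
  (e.g. a compressed TIFF).
* :class:`CapabilityError` — a writer cannot represent the requested data
  (pixel type, shape, indexing) in its target format.
* :class:`UnsupportedOperationError` — the operation does not exist for the
  format at all (e.g. writing a read-only format).
"""


class ImageFmtError(Exception):
    """Base class for all errors raised by this package."""


class BoundsError(ImageFmtError, IndexError):
    """An index or region lies outside the valid range."""


class ValidationError(ImageFmtError, ValueError):
    """A model object violates one of its structural invariants."""


class FormatError(ImageFmtError):
    """An input file is corrupt or malformed for its claimed format."""


class UnsupportedDialectError(FormatError):
    """A recognized format family, but an unsupported variant of it."""


class CapabilityError(ImageFmtError):
    """A writer cannot represent the given data in its target format."""


class UnsupportedOperationError(ImageFmtError):
    """The requested operation is not defined for this format."""


class UnrecognizedFormatError(ImageFmtError):
    """No registered format claims the given source."""


class DuplicatePluginError(ImageFmtError):
    """A plugin identity is already registered in this context."""


class NoTranslatorError(ImageFmtError):
    """No direct or baseline-composite translator route exists."""


class TranslationTypeError(ImageFmtError, TypeError):
    """Metadata passed to a translator does not match its declared types."""


class PatternError(ImageFmtError, ValueError):
    """A multi-file pattern string does not follow the pattern grammar."""


class StitchError(ImageFmtError):
    """Constituent files of a pattern disagree on baseline metadata."""


class SourceIOError(ImageFmtError, IOError):
    """Payload bytes are missing, truncated, or unreadable."""


class FilterLookupError(ImageFmtError, KeyError):
    """A filter identity is not present in the filter stack."""
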