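"""Built-in format plugins and their translator suite.

Priorities space the formats at multiples of ten so third-party plugins can
interleave; the exchange container must outrank plain TIFF because both
match TIFF magic bytes, and detection consults the most specific format
first:

========== ========
synthetic  50
exchange   40
tiff       30
sciraw     20
pnm        10
========== ========

The translator inventory is hub-and-spoke around the baseline: every
format translates *to* the baseline, and every writable format has a
translator *from* it. The synthetic format is read-only, so it has no
inbound translator.
"""

from __future__ import annotations

from ..formats import BASELINE_TYPE
from ..translate import BaselineToFormatTranslator, ToBaselineTranslator
from .exchange import EXCHANGE_FORMAT
from .pnm import PNM_FORMAT
from .sciraw import SCIRAW_FORMAT
from .synthetic import SYNTHETIC_FORMAT
from .tiff import TIFF_FORMAT

__all__ = [
    "SYNTHETIC_FORMAT",
    "EXCHANGE_FORMAT",
    "TIFF_FORMAT",
    "SCIRAW_FORMAT",
    "PNM_FORMAT",
    "BUILTIN_FORMATS",
    "builtin_translators",
]

#: All built-in formats, most specific first.
BUILTIN_FORMATS = (
    SYNTHETIC_FORMAT,
    EXCHANGE_FORMAT,
    TIFF_FORMAT,
    SCIRAW_FORMAT,
    PNM_FORMAT,
)


class BaselineToSciraw(BaselineToFormatTranslator):
    """SCIRAW headers carry annotations and color tables, not calibration."""

    carries_open_table = True
    carries_indexed = True
    carries_calibration = False


class BaselineToExchange(BaselineToFormatTranslator):
    """The exchange schema is a superset of the baseline: lossless."""

    carries_open_table = True
    carries_indexed = True
    carries_calibration = True


class BaselineToTiff(BaselineToFormatTranslator):
    """Plain TIFF pages carry geometry and pixel type only."""


class BaselineToPnm(BaselineToFormatTranslator):
    """PNM headers carry geometry and pixel type only."""


_BASELINE_TO = {
    SCIRAW_FORMAT.meta_type: BaselineToSciraw,
    EXCHANGE_FORMAT.meta_type: BaselineToExchange,
    TIFF_FORMAT.meta_type: BaselineToTiff,
    PNM_FORMAT.meta_type: BaselineToPnm,
}


def builtin_translators():
    """Fresh instances of the built-in translator suite."""
    out = [ToBaselineTranslator(fmt.meta_type) for fmt in BUILTIN_FORMATS]
    out.extend(cls(meta_type) for meta_type, cls in _BASELINE_TO.items())
    return out
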