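"""Metadata-to-metadata translation.

Translators convert one metadata schema into another so that a dataset read
in any format can be written in any other. The topology is hub-and-spoke:
every format can express itself as the baseline
:class:`~imagefmt.model.ImageMetadata`, and every *writable* format has a
translator from the baseline; a request for a pair with no direct
translator is satisfied by composing the two baseline legs. Resolution is
priority-ordered, so registering a direct, higher-priority translator for a
specific pair overrides the composite route.

Translation may be lossy — a destination schema with no open key-value
table cannot carry annotations — but every dropped field is enumerated in
the returned :class:`TranslationReport` so callers can warn rather than
silently discard.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from .errors import BoundsError, NoTranslatorError, TranslationTypeError
from .formats import BASELINE_TYPE, DatasetMetadata, Format
from .model import ImageMetadata

__all__ = [
    "TranslationReport",
    "Translator",
    "CompositeTranslator",
    "TranslatorService",
    "to_image_metadata",
]


def to_image_metadata(meta: DatasetMetadata, image_index: int) -> ImageMetadata:
    """Express one image of any dataset as baseline metadata (a copy)."""
    return meta.get_image_metadata(image_index).copy()


@dataclass(frozen=True)
class TranslationReport:
    """Outcome of one translation: which source fields did not survive."""

    dropped_fields: tuple = ()

    @property
    def lossless(self) -> bool:
        return not self.dropped_fields

    def merged_with(self, other: "TranslationReport") -> "TranslationReport":
        seen = list(self.dropped_fields)
        seen.extend(f for f in other.dropped_fields if f not in seen)
        return TranslationReport(tuple(seen))


class Translator:
    """Unidirectional converter between two declared metadata types."""

    source_type: str = ""
    dest_type: str = ""
    priority: float = 0.0

    def translate(self, source: DatasetMetadata, dest: DatasetMetadata) -> TranslationReport:
        if source.meta_type != self.source_type:
            raise TranslationTypeError(
                f"translator expects source type {self.source_type!r}, "
                f"got {source.meta_type!r}"
            )
        if dest.meta_type != self.dest_type:
            raise TranslationTypeError(
                f"translator expects dest type {self.dest_type!r}, "
                f"got {dest.meta_type!r}"
            )
        return self._translate(source, dest)

    def _translate(self, source: DatasetMetadata, dest: DatasetMetadata) -> TranslationReport:
        raise NotImplementedError

    @property
    def identity(self) -> str:
        return f"{self.source_type}->{self.dest_type}"


class ToBaselineTranslator(Translator):
    """Generic spoke-to-hub leg: any format's metadata to the baseline.

    Baseline images are copied verbatim; format-private fields have no
    baseline representation and are reported as dropped. Private keys
    starting with an underscore are parser bookkeeping (byte offsets,
    directory handles), not metadata, and are not reported.
    """

    dest_type = BASELINE_TYPE

    def __init__(self, source_type: str, priority: float = 0.0):
        self.source_type = source_type
        self.priority = priority

    def _translate(self, source, dest):
        dest.images = [to_image_metadata(source, i) for i in range(source.image_count)]
        dest.source = source.source
        dropped = tuple(
            sorted(f"private.{k}" for k in source.private if not k.startswith("_"))
        )
        return TranslationReport(dropped)


class BaselineToFormatTranslator(Translator):
    """Generic hub-to-spoke leg, parameterized by what the spoke can carry.

    Subclasses (or instances) declare which baseline features the
    destination schema represents; everything else is stripped from the
    destination copy and enumerated in the report.
    """

    source_type = BASELINE_TYPE
    carries_calibration = False  # axis scale/unit
    carries_open_table = False   # the free key-value table
    carries_indexed = False      # indexed flag + color table
    carries_multi_image = True

    def __init__(self, dest_type: str, priority: float = 0.0):
        self.dest_type = dest_type
        self.priority = priority

    def _translate(self, source, dest):
        dropped = []
        dest.images = []
        dest.source = source.source
        for img in (source.get_image_metadata(i) for i in range(source.image_count)):
            out = img.copy()
            if not self.carries_open_table and out.table:
                dropped.extend(sorted(out.table))
                out.table = {}
            if not self.carries_calibration:
                new_axes = []
                for i, a in enumerate(out.axes):
                    if a.scale != 1.0:
                        dropped.append(f"axes[{i}].scale")
                    if a.unit != "":
                        dropped.append(f"axes[{i}].unit")
                    new_axes.append(replace(a, scale=1.0, unit=""))
                out.axes = tuple(new_axes)
            if not self.carries_indexed and out.indexed:
                dropped.append("color_table")
                out.indexed = False
                out.color_table = None
            dest.images.append(out)
        uniq = []
        for f in dropped:
            if f not in uniq:
                uniq.append(f)
        return TranslationReport(tuple(uniq))


class CompositeTranslator(Translator):
    """Two-leg route through the baseline when no direct translator exists."""

    def __init__(self, first: Translator, second: Translator):
        assert first.dest_type == BASELINE_TYPE and second.source_type == BASELINE_TYPE
        self.first = first
        self.second = second
        self.source_type = first.source_type
        self.dest_type = second.dest_type
        self.priority = min(first.priority, second.priority)

    def _translate(self, source, dest):
        hub = DatasetMetadata("baseline", BASELINE_TYPE, source=source.source)
        r1 = self.first.translate(source, hub)
        r2 = self.second.translate(hub, dest)
        return r1.merged_with(r2)


class TranslatorService:
    """Priority-ordered translator resolution with the baseline fallback."""

    def __init__(self, ctx):
        self._ctx = ctx
        self._instances: dict = {}

    def translators(self) -> list:
        from .plugins import PluginType

        out = []
        for desc in self._ctx.plugins_of_type(PluginType.TRANSLATOR):
            if desc.identity not in self._instances:
                self._instances[desc.identity] = desc.factory()
            out.append(self._instances[desc.identity])
        return out

    def _exact(self, source_type: str, dest_type: str) -> Optional[Translator]:
        for tr in self.translators():  # already in descending priority order
            if tr.source_type == source_type and tr.dest_type == dest_type:
                return tr
        return None

    def find_translator(self, source_type: str, dest_type: str) -> Translator:
        direct = self._exact(source_type, dest_type)
        if direct is not None:
            return direct
        first = self._exact(source_type, BASELINE_TYPE)
        second = self._exact(BASELINE_TYPE, dest_type)
        if first is not None and second is not None:
            return CompositeTranslator(first, second)
        raise NoTranslatorError(
            f"no translator route from {source_type!r} to {dest_type!r}"
        )

    def translate_to(self, source: DatasetMetadata, dest_format: Format):
        """Translate ``source`` for writing as ``dest_format``.

        Returns ``(dest_metadata, report)``; the destination metadata is
        freshly constructed and valid for the destination format's writer.
        """
        tr = self.find_translator(source.meta_type, dest_format.meta_type)
        dest = dest_format.new_metadata(source=source.source)
        report = tr.translate(source, dest)
        return dest, report
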