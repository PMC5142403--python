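"""Format component contracts and the detection service.

A :class:`Format` bundles the five components of image I/O:

* :class:`Checker` — decides whether a source belongs to the format, from
  the file name alone or (when allowed) by inspecting leading bytes;
* :class:`Parser` — builds :class:`DatasetMetadata` from a source's headers
  without touching pixel payloads;
* the *Metadata* itself (:class:`DatasetMetadata`, possibly with
  format-private fields), which every format can express as the baseline
  :class:`~imagefmt.model.ImageMetadata`;
* :class:`Reader` / :class:`Writer` — move pixel planes. Writers are
  optional; read-only formats simply omit one.

The :class:`FormatService` polls Checkers in descending plugin priority, so
the most specific format claims a source first (an exchange container must
outrank the plain TIFF format whose magic bytes it shares).
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import BinaryIO, Iterable, Optional, Sequence, Type

from . import model
from .errors import (
    BoundsError,
    CapabilityError,
    SourceIOError,
    UnrecognizedFormatError,
    UnsupportedOperationError,
    ValidationError,
)
from .model import ImageMetadata, Plane

log = logging.getLogger(__name__)

#: Metadata type identifier of the format-independent baseline.
BASELINE_TYPE = "baseline"

_PATTERN_TOKEN = re.compile(r"<(\d+)-(\d+)>")


@dataclass(frozen=True)
class SourceRef:
    """A named image source: a file path or a multi-file pattern locator."""

    locator: str

    @classmethod
    def coerce(cls, src) -> "SourceRef":
        if isinstance(src, SourceRef):
            return src
        return cls(str(src))

    @property
    def path(self) -> Path:
        return Path(self.locator)

    def exists(self) -> bool:
        return self.path.is_file()

    def size(self) -> int:
        try:
            return os.path.getsize(self.locator)
        except OSError as exc:
            raise SourceIOError(f"cannot stat {self.locator!r}: {exc}") from exc

    def open(self) -> BinaryIO:
        """Open the source for random-access binary reading."""
        return open(self.locator, "rb")

    def is_pattern(self) -> bool:
        return _PATTERN_TOKEN.search(self.locator) is not None

    def suffix_matches(self, suffixes: Iterable[str]) -> bool:
        low = self.locator.lower()
        return any(low.endswith(s.lower()) for s in suffixes)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.locator


@dataclass
class DatasetMetadata:
    """Format-specific metadata root: a source, its images, private fields.

    ``meta_type`` identifies the metadata schema for translator resolution;
    ``private`` holds format-specific fields that have no baseline
    representation (they surface in translation reports when dropped).
    """

    format_name: str
    meta_type: str
    source: Optional[str] = None
    images: list = field(default_factory=list)
    private: dict = field(default_factory=dict)

    @property
    def image_count(self) -> int:
        return len(self.images)

    def get_image_metadata(self, image_index: int) -> ImageMetadata:
        if not 0 <= image_index < len(self.images):
            raise BoundsError(
                f"image index {image_index} outside [0, {len(self.images)})"
            )
        return self.images[image_index]

    def validate_all(self) -> list:
        out = []
        for i, img in enumerate(self.images):
            out.extend(f"image {i}: {v}" for v in model.validate(img))
        return out


class Checker:
    """Default checker: filename-suffix match, plus optional magic bytes.

    With ``open_allowed=False`` the decision comes from the locator alone;
    with ``open_allowed=True`` an existing source may additionally be
    claimed by content (``_check_magic``). The source is never mutated.
    """

    def __init__(self, fmt: "Format"):
        self.format = fmt

    def is_format(self, src: SourceRef, open_allowed: bool = False) -> bool:
        if src.suffix_matches(self.format.suffixes):
            return True
        if open_allowed and not src.is_pattern():
            try:
                if not src.exists():
                    return False
                return self._check_magic(src)
            except (OSError, SourceIOError) as exc:
                log.warning("checker for %s could not read %s: %s",
                            self.format.name, src, exc)
                return False
        return False

    def _check_magic(self, src: SourceRef) -> bool:
        """Content inspection hook; the default format has no magic."""
        return False

    def _head(self, src: SourceRef, n: int) -> bytes:
        with src.open() as fh:
            return fh.read(n)


class Parser:
    """Builds DatasetMetadata from a source's header region only."""

    def __init__(self, fmt: "Format"):
        self.format = fmt

    def parse(self, src: SourceRef) -> DatasetMetadata:
        raise NotImplementedError


class Reader:
    """Reads pixel planes as described by parsed metadata.

    Subclasses implement ``_read_plane``; bounds checking, color-table
    attachment and region cropping are handled here.
    """

    def __init__(self, fmt: "Format", meta: DatasetMetadata, src: SourceRef):
        self.format = fmt
        self.metadata = meta
        self.source = src

    @property
    def image_count(self) -> int:
        return self.metadata.image_count

    def image_metadata(self, image_index: int) -> ImageMetadata:
        return self.metadata.get_image_metadata(image_index)

    def plane_count(self, image_index: int = 0) -> int:
        return model.plane_count(self.image_metadata(image_index))

    def open_plane(self, image_index: int, plane_index: int) -> Plane:
        img = self.image_metadata(image_index)
        n = model.plane_count(img)
        if not 0 <= plane_index < n:
            raise BoundsError(f"plane index {plane_index} outside [0, {n})")
        plane = self._read_plane(image_index, plane_index)
        if img.indexed and plane.color_table is None:
            plane.color_table = img.color_table
        return plane

    def open_region(self, image_index: int, plane_index: int,
                    bounds: Sequence) -> Plane:
        return self.open_plane(image_index, plane_index).crop(bounds)

    def _read_plane(self, image_index: int, plane_index: int) -> Plane:
        raise NotImplementedError


class Writer:
    """Writes planes to a destination; must be closed to finalize.

    Planes may arrive in any order; directory/header structures whose
    offsets depend on the full payload are emitted at :meth:`close`.
    Capability checks (unsupported pixel type or shape) happen eagerly at
    construction so callers fail before producing partial output.
    """

    def __init__(self, fmt: "Format", dest: SourceRef, meta: DatasetMetadata):
        self.format = fmt
        self.dest = dest
        self.metadata = meta
        self._planes: dict = {}
        self._closed = False
        violations = meta.validate_all()
        if violations:
            raise ValidationError(
                f"metadata invalid for writing: {'; '.join(violations)}"
            )
        self._check_capabilities(meta)

    def _check_capabilities(self, meta: DatasetMetadata) -> None:
        """Raise CapabilityError for data the format cannot represent."""

    def save_plane(self, image_index: int, plane_index: int, plane: Plane) -> None:
        if self._closed:
            raise SourceIOError("writer already closed")
        img = self.metadata.get_image_metadata(image_index)
        n = model.plane_count(img)
        if not 0 <= plane_index < n:
            raise BoundsError(f"plane index {plane_index} outside [0, {n})")
        self._planes[(image_index, plane_index)] = plane

    def close(self) -> None:
        if self._closed:
            return
        missing = [
            (i, p)
            for i in range(self.metadata.image_count)
            for p in range(model.plane_count(self.metadata.images[i]))
            if (i, p) not in self._planes
        ]
        if missing:
            raise SourceIOError(
                f"cannot finalize {self.dest}: missing planes {missing[:4]}"
                + ("..." if len(missing) > 4 else "")
            )
        self._finalize()
        self._closed = True

    def _finalize(self) -> None:
        raise NotImplementedError

    def __enter__(self) -> "Writer":
        return self

    def __exit__(self, exc_type, exc, tb) -> None:
        if exc_type is None:
            self.close()


@dataclass(frozen=True)
class Format:
    """A pluggable format: identity, suffixes, priority, component factories."""

    name: str
    suffixes: tuple
    priority: float
    meta_type: str
    checker_cls: Type[Checker] = Checker
    parser_cls: Type[Parser] = Parser
    reader_cls: Type[Reader] = Reader
    writer_cls: Optional[Type[Writer]] = None

    @property
    def has_writer(self) -> bool:
        return self.writer_cls is not None

    def make_checker(self) -> Checker:
        return self.checker_cls(self)

    def make_parser(self) -> Parser:
        return self.parser_cls(self)

    def make_reader(self, meta: DatasetMetadata, src: SourceRef) -> Reader:
        return self.reader_cls(self, meta, src)

    def make_writer(self, dest: SourceRef, meta: DatasetMetadata) -> Writer:
        if self.writer_cls is None:
            raise UnsupportedOperationError(f"format {self.name!r} has no writer")
        return self.writer_cls(self, dest, meta)

    def new_metadata(self, source: Optional[str] = None) -> DatasetMetadata:
        return DatasetMetadata(self.name, self.meta_type, source=source)


def checker_is_format(fmt: Format, src, open_allowed: bool = False) -> bool:
    """Convenience: run ``fmt``'s checker against a source."""
    return fmt.make_checker().is_format(SourceRef.coerce(src), open_allowed)


def parse(fmt: Format, src) -> DatasetMetadata:
    """Convenience: run ``fmt``'s parser against a source."""
    return fmt.make_parser().parse(SourceRef.coerce(src))


def write_dataset(fmt: Format, dest, meta: DatasetMetadata, planes) -> None:
    """Write a complete dataset: every (image, plane) index exactly once.

    ``planes`` yields ``(image_index, plane_index, Plane)`` triples in any
    order. Duplicate or missing indices are errors.
    """
    dest = SourceRef.coerce(dest)
    seen = set()
    with fmt.make_writer(dest, meta) as writer:
        for image_index, plane_index, plane in planes:
            key = (image_index, plane_index)
            if key in seen:
                raise ValidationError(f"plane {key} supplied more than once")
            seen.add(key)
            writer.save_plane(image_index, plane_index, plane)


class FormatService:
    """Resolves sources to formats by polling Checkers in priority order."""

    def __init__(self, ctx):
        self._ctx = ctx
        self._instances: dict = {}

    def _descriptors(self):
        from .plugins import PluginType

        return self._ctx.plugins_of_type(PluginType.FORMAT)

    def formats(self) -> list:
        """All registered formats, most specific (highest priority) first."""
        out = []
        for desc in self._descriptors():
            if desc.identity not in self._instances:
                self._instances[desc.identity] = desc.factory()
            out.append(self._instances[desc.identity])
        return out

    def get_format(self, name: str) -> Format:
        for fmt in self.formats():
            if fmt.name == name:
                return fmt
        raise UnrecognizedFormatError(f"no registered format named {name!r}")

    def find_format(self, src, open_allowed: bool = True) -> Format:
        src = SourceRef.coerce(src)
        consulted = []
        for fmt in self.formats():
            consulted.append(fmt.name)
            if fmt.make_checker().is_format(src, open_allowed):
                return fmt
        raise UnrecognizedFormatError(
            f"no format claims {src.locator!r} (consulted: {', '.join(consulted)})"
        )

    def parse(self, src, open_allowed: bool = True) -> DatasetMetadata:
        src = SourceRef.coerce(src)
        fmt = self.find_format(src, open_allowed)
        return fmt.make_parser().parse(src)

    def writable_format_for(self, dest, name: Optional[str] = None) -> Format:
        """Resolve the output format for ``dest`` by name or by suffix."""
        dest = SourceRef.coerce(dest)
        if name is not None:
            fmt = self.get_format(name)
        else:
            fmt = None
            for cand in self.formats():
                if dest.suffix_matches(cand.suffixes):
                    fmt = cand
                    break
            if fmt is None:
                raise UnrecognizedFormatError(
                    f"no registered format matches destination {dest.locator!r}"
                )
        if not fmt.has_writer:
            raise UnsupportedOperationError(f"format {fmt.name!r} has no writer")
        return fmt
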