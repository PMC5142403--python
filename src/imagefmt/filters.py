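"""Reader-wrapping filters: an ordered, individually toggleable chain.

Filters wrap a reader and modify the planes and apparent metadata flowing
through it. Each filter has a numeric priority; enabled filters are applied
over the base reader with the *highest* priority outermost, so the
channel-filling filter (priority 20) sees the dataset already composed by
the file stitcher (priority 10). Every filter can be toggled on or off per
stack; a fully disabled stack behaves exactly like the bare reader.

Two concrete filters are provided:

* :class:`ChannelFiller` — expands indexed-color planes into one plane per
  color-table component, inserting a CHANNEL axis as the first non-planar
  axis;
* :class:`FileStitcher` — presents the files of a numeric filename pattern
  (``img_<0-2>.sciraw``) as one dataset with an appended axis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from . import model
from .errors import (
    BoundsError,
    FilterLookupError,
    PatternError,
    SourceIOError,
    StitchError,
    ValidationError,
)
from .formats import DatasetMetadata, Format, Reader, SourceRef
from .model import CHANNEL, TIME, Axis, AxisType, ImageMetadata, Plane, Z

__all__ = [
    "FilePattern",
    "parse_file_pattern",
    "Filter",
    "ChannelFiller",
    "FileStitcher",
    "FilterStack",
    "expand_indexed",
    "stitched_metadata",
]

_TOKEN = re.compile(r"<(\d+)-(\d+)>")

STITCHED = AxisType.custom("STITCHED")


@dataclass(frozen=True)
class FilePattern:
    """A parsed numeric-range filename pattern ``prefix<a-b>suffix``."""

    prefix: str
    suffix: str
    start: int
    end: int
    width: int

    @property
    def count(self) -> int:
        return self.end - self.start + 1

    def name_at(self, i: int) -> str:
        if not self.start <= i <= self.end:
            raise BoundsError(f"pattern index {i} outside [{self.start}, {self.end}]")
        return f"{self.prefix}{str(i).zfill(self.width)}{self.suffix}"

    def names(self) -> list:
        return [self.name_at(i) for i in range(self.start, self.end + 1)]


def parse_file_pattern(locator: str) -> FilePattern:
    """Parse a locator containing exactly one ``<a-b>`` range token.

    The zero-pad width is the digit width of ``a``'s literal spelling, so
    ``t<08-10>.tif`` expands to ``t08, t09, t10``.
    """
    tokens = list(_TOKEN.finditer(locator))
    if len(tokens) != 1:
        raise PatternError(
            f"pattern {locator!r} must contain exactly one <a-b> token, "
            f"found {len(tokens)}"
        )
    tok = tokens[0]
    a, b = tok.group(1), tok.group(2)
    start, end = int(a), int(b)
    if start > end:
        raise PatternError(f"pattern {locator!r} has descending range {start} > {end}")
    return FilePattern(
        prefix=locator[: tok.start()],
        suffix=locator[tok.end() :],
        start=start,
        end=end,
        width=len(a),
    )


# ---------------------------------------------------------------------------
# metadata transforms (usable standalone, and by the filter classes)
# ---------------------------------------------------------------------------

def expand_indexed(meta: ImageMetadata) -> ImageMetadata:
    """Channel-filled view of ``meta``.

    Non-indexed metadata is returned as an unchanged copy. Indexed metadata
    becomes non-indexed with a CHANNEL axis of the color table's component
    count inserted as the first non-planar axis (an existing CHANNEL axis
    of length 1 in that slot is replaced); all other fields are preserved.
    """
    if not meta.indexed:
        return meta.copy()
    violations = model.validate(meta)
    if violations:
        raise ValidationError(
            f"cannot channel-fill invalid metadata: {'; '.join(violations)}"
        )
    c = meta.color_table.component_count
    planar = list(meta.planar_axes)
    rest = list(meta.nonplanar_axes)
    if rest and rest[0].type == CHANNEL and rest[0].length == 1:
        rest = rest[1:]
    if any(a.type == CHANNEL for a in planar + rest):
        raise ValidationError(
            "cannot channel-fill: a CHANNEL axis of length > 1 already exists"
        )
    out = meta.copy()
    out.axes = tuple(planar + [Axis(CHANNEL, c)] + rest)
    out.indexed = False
    out.color_table = None
    return out


def stitched_metadata(per_file: ImageMetadata, file_count: int) -> ImageMetadata:
    """Append the stitched axis: TIME if free, else Z, else custom STITCHED."""
    if file_count < 1:
        raise ValidationError("file_count must be >= 1")
    if per_file.axis_of_type(TIME) is None:
        ax = Axis(TIME, file_count)
    elif per_file.axis_of_type(Z) is None:
        ax = Axis(Z, file_count)
    else:
        ax = Axis(STITCHED, file_count)
    out = per_file.copy()
    out.axes = out.axes + (ax,)
    return out


def _baseline_mismatch(a: ImageMetadata, b: ImageMetadata) -> Optional[str]:
    """Name of the first baseline field on which two images differ."""
    if a.pixel_type is not b.pixel_type:
        return f"pixel_type ({a.pixel_type.code} != {b.pixel_type.code})"
    if a.indexed != b.indexed:
        return f"indexed ({a.indexed} != {b.indexed})"
    if a.planar_axis_count != b.planar_axis_count:
        return f"planar_axis_count ({a.planar_axis_count} != {b.planar_axis_count})"
    if len(a.axes) != len(b.axes):
        return f"axis count ({len(a.axes)} != {len(b.axes)})"
    for i, (ax, bx) in enumerate(zip(a.axes, b.axes)):
        if ax.type != bx.type:
            return f"axes[{i}].type ({ax.type.name} != {bx.type.name})"
        if ax.length != bx.length:
            return f"axes[{i}].length ({ax.length} != {bx.length})"
    return None


# ---------------------------------------------------------------------------
# filter classes
# ---------------------------------------------------------------------------

class Filter:
    """Base filter: a transparent reader wrapper.

    Subclasses override :attr:`metadata` and the plane accessors where they
    transform data; everything else delegates to the parent, so a filter is
    pass-through for datasets it does not apply to.
    """

    FILTER_ID = "identity"
    PRIORITY = 0.0

    def __init__(self, stack: "FilterStack", parent):
        self.stack = stack
        self.parent = parent

    @property
    def metadata(self) -> DatasetMetadata:
        return self.parent.metadata

    @property
    def image_count(self) -> int:
        return self.metadata.image_count

    def image_metadata(self, image_index: int) -> ImageMetadata:
        return self.metadata.get_image_metadata(image_index)

    def plane_count(self, image_index: int = 0) -> int:
        return model.plane_count(self.image_metadata(image_index))

    def open_plane(self, image_index: int, plane_index: int) -> Plane:
        return self.parent.open_plane(image_index, plane_index)

    def open_region(self, image_index: int, plane_index: int,
                    bounds: Sequence) -> Plane:
        return self.open_plane(image_index, plane_index).crop(bounds)


class ChannelFiller(Filter):
    """Expands indexed planes into per-component planes via the color table.

    With component count ``c``, transformed plane ``p`` maps to underlying
    plane ``p // c`` and component ``p % c``; every output sample is the
    color-table entry of the underlying index sample for that component.
    Non-indexed images pass through untouched.
    """

    FILTER_ID = "channel-filler"
    PRIORITY = 20.0

    @property
    def metadata(self) -> DatasetMetadata:
        src = self.parent.metadata
        out = replace(src)
        out.images = [expand_indexed(img) for img in src.images]
        out.private = dict(src.private)
        return out

    def open_plane(self, image_index: int, plane_index: int) -> Plane:
        under = self.parent.metadata.get_image_metadata(image_index)
        if not under.indexed:
            return self.parent.open_plane(image_index, plane_index)
        c = under.color_table.component_count
        n = model.plane_count(under) * c
        if not 0 <= plane_index < n:
            raise BoundsError(f"plane index {plane_index} outside [0, {n})")
        u, k = divmod(plane_index, c)
        raw = self.parent.open_plane(image_index, u)
        table = raw.color_table if raw.color_table is not None else under.color_table
        filled = table.values[k][raw.data.astype(np.int64)]
        filled = filled.astype(under.pixel_type.dtype, copy=False)
        return Plane(filled, raw.bounds, color_table=None)


class FileStitcher(Filter):
    """Unifies the files of a numeric filename pattern into one dataset.

    Every constituent file must parse to identical baseline metadata; the
    combined dataset gains one trailing axis of length ``file_count``. With
    per-file plane count ``p``, stitched plane ``i`` delegates to file
    ``i // p``, local plane ``i % p``. Without a pattern source the filter
    is pass-through.
    """

    FILTER_ID = "file-stitcher"
    PRIORITY = 10.0

    def __init__(self, stack: "FilterStack", parent):
        super().__init__(stack, parent)
        self._sources = None
        self._readers: dict = {0: parent}
        pattern = stack.pattern
        if pattern is None:
            return
        fmt = stack.format
        self._sources = [SourceRef(n) for n in pattern.names()]
        ref_meta = parent.metadata
        for k, src in enumerate(self._sources):
            if not src.exists():
                raise SourceIOError(
                    f"pattern file {src.locator!r} is missing from the range"
                )
            if k == 0:
                continue
            meta_k = fmt.make_parser().parse(src)
            if meta_k.image_count != ref_meta.image_count:
                raise StitchError(
                    f"file {k} has {meta_k.image_count} images, "
                    f"file 0 has {ref_meta.image_count}"
                )
            for i in range(ref_meta.image_count):
                diff = _baseline_mismatch(
                    ref_meta.get_image_metadata(i), meta_k.get_image_metadata(i)
                )
                if diff is not None:
                    raise StitchError(f"file {k}, image {i} differs in {diff}")

    @property
    def file_count(self) -> int:
        return 1 if self._sources is None else len(self._sources)

    @property
    def metadata(self) -> DatasetMetadata:
        src = self.parent.metadata
        if self._sources is None:
            return src
        out = replace(src)
        out.private = dict(src.private)
        out.images = [stitched_metadata(img, self.file_count) for img in src.images]
        out.source = self.stack.pattern_locator
        return out

    def _reader(self, file_index: int):
        if file_index not in self._readers:
            fmt = self.stack.format
            src = self._sources[file_index]
            meta = fmt.make_parser().parse(src)
            self._readers[file_index] = fmt.make_reader(meta, src)
        return self._readers[file_index]

    def open_plane(self, image_index: int, plane_index: int) -> Plane:
        if self._sources is None:
            return self.parent.open_plane(image_index, plane_index)
        per_file = model.plane_count(
            self.parent.metadata.get_image_metadata(image_index)
        )
        total = per_file * self.file_count
        if not 0 <= plane_index < total:
            raise BoundsError(f"plane index {plane_index} outside [0, {total})")
        file_index, local = divmod(plane_index, per_file)
        return self._reader(file_index).open_plane(image_index, local)


class FilterStack:
    """The per-reader chain of toggleable filters over a base reader.

    ``filter_specs`` is a list of ``(filter_id, priority, filter_class)``;
    enabled filters wrap the base in ascending priority order so the
    highest-priority filter ends up outermost.
    """

    def __init__(self, base: Reader, filter_specs, enabled=None,
                 pattern: Optional[FilePattern] = None,
                 fmt: Optional[Format] = None,
                 pattern_locator: Optional[str] = None):
        self.base = base
        self.pattern = pattern
        self.format = fmt if fmt is not None else base.format
        self.pattern_locator = pattern_locator
        self._specs = sorted(filter_specs, key=lambda s: s[1])
        known = {fid for fid, _, _ in self._specs}
        self._enabled = {fid: True for fid in known}
        for fid, state in (enabled or {}).items():
            if fid not in known:
                raise FilterLookupError(f"unknown filter {fid!r}")
            self._enabled[fid] = bool(state)
        self._rebuild()

    def _rebuild(self) -> None:
        head = self.base
        for fid, _, cls in self._specs:
            if self._enabled[fid]:
                head = cls(self, head)
        self.head = head

    # -- toggling --------------------------------------------------------
    def filter_ids(self) -> list:
        return [fid for fid, _, _ in self._specs]

    def is_enabled(self, filter_id: str) -> bool:
        if filter_id not in self._enabled:
            raise FilterLookupError(f"unknown filter {filter_id!r}")
        return self._enabled[filter_id]

    def set_enabled(self, filter_id: str, enabled: bool) -> None:
        if filter_id not in self._enabled:
            raise FilterLookupError(f"unknown filter {filter_id!r}")
        self._enabled[filter_id] = bool(enabled)
        self._rebuild()

    # -- reader interface ------------------------------------------------
    @property
    def metadata(self) -> DatasetMetadata:
        return self.head.metadata

    @property
    def image_count(self) -> int:
        return self.metadata.image_count

    def image_metadata(self, image_index: int) -> ImageMetadata:
        return self.metadata.get_image_metadata(image_index)

    def plane_count(self, image_index: int = 0) -> int:
        return model.plane_count(self.image_metadata(image_index))

    def open_plane(self, image_index: int, plane_index: int) -> Plane:
        return self.head.open_plane(image_index, plane_index)

    def open_region(self, image_index: int, plane_index: int,
                    bounds: Sequence) -> Plane:
        return self.head.open_region(image_index, plane_index, bounds)
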