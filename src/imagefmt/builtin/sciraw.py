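"""SCIRAW: raw little-endian pixels behind a human-readable text header.

The reference open format of this package: it can carry every pixel type,
any axis list, indexed color and the open key-value table, which makes it
the workhorse for round-trip testing of the whole read/write path.

Layout::

    SCIRAW/1.0
    name: img
    axes: X,Y,Z
    lengths: 16,16,4
    planarAxes: 2
    pixelType: uint8
    endian: little
    indexed: false
    meta.instrument: scope1
    <blank line>
    <planes in raster order, little-endian, first planar axis fastest>

Indexed images add a ``colorTable`` line holding
``components,length,v0,v1,...`` with values component-major. The parser
reads the header byte-by-byte and never touches the payload; payload size
is verified against the file length.
"""

from __future__ import annotations

import numpy as np

from .. import model
from ..errors import CapabilityError, FormatError, SourceIOError
from ..formats import (
    Checker,
    DatasetMetadata,
    Format,
    Parser,
    Reader,
    SourceRef,
    Writer,
)
from ..model import Axis, ColorTable, ImageMetadata, PixelType, Plane, axis_type

MAGIC = "SCIRAW/1.0"
_KNOWN_KEYS = {
    "name", "axes", "lengths", "planarAxes", "pixelType",
    "endian", "indexed", "colorTable",
}


def _read_text_line(fh, limit: int = 1 << 24) -> str:
    """Read one newline-terminated line a byte at a time (no read-ahead)."""
    out = bytearray()
    while True:
        b = fh.read(1)
        if not b:
            raise FormatError("unexpected end of file inside SCIRAW header")
        if b == b"\n":
            break
        out += b
        if len(out) > limit:
            raise FormatError("SCIRAW header line too long")
    return out.decode("utf-8")


def _plane_bytes(img: ImageMetadata) -> int:
    return img.plane_sample_count * img.pixel_type.bits_per_sample // 8


def _header_text(img: ImageMetadata) -> str:
    lines = [MAGIC]
    lines.append(f"name: {img.name}")
    lines.append("axes: " + ",".join(a.type.name for a in img.axes))
    lines.append("lengths: " + ",".join(str(a.length) for a in img.axes))
    lines.append(f"planarAxes: {img.planar_axis_count}")
    lines.append(f"pixelType: {img.pixel_type.code}")
    lines.append("endian: little")
    lines.append(f"indexed: {'true' if img.indexed else 'false'}")
    if img.indexed:
        t = img.color_table
        flat = ",".join(str(int(v)) for v in t.values.ravel())
        lines.append(f"colorTable: {t.component_count},{t.table_length},{flat}")
    for key in img.table:
        lines.append(f"meta.{key}: {img.table[key]}")
    return "\n".join(lines) + "\n\n"


class ScirawChecker(Checker):
    def _check_magic(self, src: SourceRef) -> bool:
        return self._head(src, 7) == b"SCIRAW/"


class ScirawParser(Parser):
    def parse(self, src: SourceRef) -> DatasetMetadata:
        with src.open() as fh:
            magic = _read_text_line(fh)
            if magic != MAGIC:
                if magic.startswith("SCIRAW/"):
                    raise FormatError(
                        f"unknown SCIRAW version {magic[7:]!r} (expected 1.0)"
                    )
                raise FormatError(f"bad SCIRAW magic line {magic!r}")
            fields = {}
            table = {}
            while True:
                line = _read_text_line(fh)
                if line == "":
                    break
                key, sep, value = line.partition(": ")
                if not sep:
                    raise FormatError(f"malformed SCIRAW header line {line!r}")
                if key.startswith("meta."):
                    table[key[5:]] = value
                elif key in _KNOWN_KEYS:
                    if key in fields:
                        raise FormatError(f"duplicate SCIRAW header key {key!r}")
                    fields[key] = value
                else:
                    raise FormatError(f"unknown SCIRAW header key {key!r}")
            data_offset = fh.tell()

        for required in ("axes", "lengths", "pixelType"):
            if required not in fields:
                raise FormatError(f"SCIRAW header missing required key {required!r}")

        types = [axis_type(n) for n in fields["axes"].split(",")]
        try:
            lengths = [int(v) for v in fields["lengths"].split(",")]
        except ValueError as exc:
            raise FormatError(f"bad lengths value {fields['lengths']!r}") from exc
        if len(types) != len(lengths):
            raise FormatError(
                f"axes/lengths arity mismatch in header: "
                f"{len(types)} axes, {len(lengths)} lengths"
            )
        for n in lengths:
            if n < 1:
                raise FormatError(f"axis length {n} must be positive")
        try:
            pixel_type = PixelType.from_code(fields["pixelType"])
        except Exception as exc:
            raise FormatError(str(exc)) from exc
        endian = fields.get("endian", "little")
        if endian != "little":
            raise FormatError(f"unsupported SCIRAW endian {endian!r}")
        indexed = fields.get("indexed", "false")
        if indexed not in ("true", "false"):
            raise FormatError(f"bad indexed value {indexed!r}")
        indexed = indexed == "true"
        try:
            planar = int(fields.get("planarAxes", "2"))
        except ValueError as exc:
            raise FormatError(f"bad planarAxes value {fields['planarAxes']!r}") from exc

        color_table = None
        if "colorTable" in fields:
            parts = fields["colorTable"].split(",")
            try:
                comp, length = int(parts[0]), int(parts[1])
                values = np.array([int(v) for v in parts[2:]], dtype=np.int64)
            except (ValueError, IndexError) as exc:
                raise FormatError("malformed colorTable header value") from exc
            if values.size != comp * length:
                raise FormatError(
                    f"colorTable promises {comp}x{length} samples, has {values.size}"
                )
            color_table = ColorTable(
                values.reshape(comp, length).astype(pixel_type.dtype)
            )
        if indexed and color_table is None:
            raise FormatError("indexed SCIRAW header lacks a colorTable")

        img = ImageMetadata(
            name=fields.get("name", ""),
            axes=tuple(Axis(t, n) for t, n in zip(types, lengths)),
            planar_axis_count=planar,
            pixel_type=pixel_type,
            indexed=indexed,
            color_table=color_table,
            table=table,
        )
        violations = model.validate(img)
        if violations:
            raise FormatError(f"invalid SCIRAW header: {'; '.join(violations)}")

        expected = model.plane_count(img) * _plane_bytes(img)
        if src.size() < data_offset + expected:
            raise SourceIOError(
                f"SCIRAW payload truncated: header promises {expected} bytes, "
                f"file has {src.size() - data_offset}"
            )

        meta = self.format.new_metadata(source=src.locator)
        meta.images = [img]
        meta.private["_data_offset"] = data_offset
        return meta


class ScirawReader(Reader):
    def _read_plane(self, image_index: int, plane_index: int) -> Plane:
        img = self.image_metadata(image_index)
        nbytes = _plane_bytes(img)
        offset = self.metadata.private["_data_offset"] + plane_index * nbytes
        with self.source.open() as fh:
            fh.seek(offset)
            raw = fh.read(nbytes)
        if len(raw) != nbytes:
            raise SourceIOError(
                f"short read: wanted {nbytes} bytes for plane {plane_index}, "
                f"got {len(raw)}"
            )
        le = img.pixel_type.dtype.newbyteorder("<")
        data = np.frombuffer(raw, dtype=le).astype(img.pixel_type.dtype, copy=False)
        return Plane(data, model.full_bounds(img))


class ScirawWriter(Writer):
    def _check_capabilities(self, meta: DatasetMetadata) -> None:
        if meta.image_count != 1:
            raise CapabilityError(
                f"SCIRAW stores exactly one image, got {meta.image_count}"
            )
        img = meta.images[0]
        for key, value in img.table.items():
            if "\n" in key or "\n" in value or ":" in key:
                raise CapabilityError(
                    f"metadata key {key!r} not representable in a SCIRAW header line"
                )

    def _finalize(self) -> None:
        img = self.metadata.images[0]
        le = img.pixel_type.dtype.newbyteorder("<")
        with open(self.dest.locator, "wb") as fh:
            fh.write(_header_text(img).encode("utf-8"))
            for p in range(model.plane_count(img)):
                plane = self._planes[(0, p)]
                fh.write(np.ascontiguousarray(plane.data, dtype=le).tobytes())


SCIRAW_FORMAT = Format(
    name="sciraw",
    suffixes=(".sciraw",),
    priority=20.0,
    meta_type="sciraw",
    checker_cls=ScirawChecker,
    parser_cls=ScirawParser,
    reader_cls=ScirawReader,
    writer_cls=ScirawWriter,
)
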