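"""Minimal baseline TIFF 6.0 codec: IFD chains, strips, uncompressed pages.

This is deliberately the smallest dialect that any mainstream TIFF reader
decodes: compression 1 (none), chunky planar configuration, gray or RGB
photometric interpretation, 8/16-bit samples. Reading handles both byte
orders and arbitrary strip layouts; writing emits little-endian files with
one IFD per page and a single strip per page.

The writer buffers the whole file and patches forward IFD offsets, since a
directory's position is only known after its page data is laid out.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import BinaryIO, List, Optional

from ..errors import FormatError, SourceIOError

# tag numbers (TIFF 6.0)
TAG_IMAGE_WIDTH = 256
TAG_IMAGE_LENGTH = 257
TAG_BITS_PER_SAMPLE = 258
TAG_COMPRESSION = 259
TAG_PHOTOMETRIC = 262
TAG_IMAGE_DESCRIPTION = 270
TAG_STRIP_OFFSETS = 273
TAG_SAMPLES_PER_PIXEL = 277
TAG_ROWS_PER_STRIP = 278
TAG_STRIP_BYTE_COUNTS = 279
TAG_PLANAR_CONFIGURATION = 284
TAG_SAMPLE_FORMAT = 339

TYPE_BYTE = 1
TYPE_ASCII = 2
TYPE_SHORT = 3
TYPE_LONG = 4
TYPE_RATIONAL = 5
_TYPE_SIZES = {TYPE_BYTE: 1, TYPE_ASCII: 1, TYPE_SHORT: 2, TYPE_LONG: 4, TYPE_RATIONAL: 8}
_MAGIC = 42


@dataclass
class TiffDirectory:
    """One parsed IFD: a tag-to-values map plus its file offset."""

    entries: dict
    offset: int

    def _values(self, tag: int, default=None):
        return self.entries.get(tag, default)

    def _scalar(self, tag: int, default=None):
        vals = self.entries.get(tag)
        if vals is None:
            return default
        if isinstance(vals, (str, bytes)):
            return vals
        return vals[0]

    @property
    def width(self) -> int:
        v = self._scalar(TAG_IMAGE_WIDTH)
        if v is None:
            raise FormatError("IFD missing required ImageWidth (tag 256)")
        return int(v)

    @property
    def length(self) -> int:
        v = self._scalar(TAG_IMAGE_LENGTH)
        if v is None:
            raise FormatError("IFD missing required ImageLength (tag 257)")
        return int(v)

    @property
    def bits_per_sample(self) -> tuple:
        return tuple(self._values(TAG_BITS_PER_SAMPLE, (1,)))

    @property
    def compression(self) -> int:
        return int(self._scalar(TAG_COMPRESSION, 1))

    @property
    def photometric(self) -> int:
        v = self._scalar(TAG_PHOTOMETRIC)
        if v is None:
            raise FormatError("IFD missing required PhotometricInterpretation (tag 262)")
        return int(v)

    @property
    def samples_per_pixel(self) -> int:
        return int(self._scalar(TAG_SAMPLES_PER_PIXEL, 1))

    @property
    def rows_per_strip(self) -> int:
        return int(self._scalar(TAG_ROWS_PER_STRIP, 2**32 - 1))

    @property
    def strip_offsets(self) -> tuple:
        v = self._values(TAG_STRIP_OFFSETS)
        if v is None:
            raise FormatError("IFD missing required StripOffsets (tag 273)")
        return tuple(v)

    @property
    def strip_byte_counts(self) -> tuple:
        v = self._values(TAG_STRIP_BYTE_COUNTS)
        if v is None:
            raise FormatError("IFD missing required StripByteCounts (tag 279)")
        return tuple(v)

    @property
    def planar_configuration(self) -> int:
        return int(self._scalar(TAG_PLANAR_CONFIGURATION, 1))

    @property
    def sample_format(self) -> tuple:
        return tuple(self._values(TAG_SAMPLE_FORMAT, (1,)))

    @property
    def description(self) -> Optional[str]:
        v = self._scalar(TAG_IMAGE_DESCRIPTION)
        if v is None:
            return None
        return v


def read_header(fh: BinaryIO):
    """Validate the byte-order mark and magic; return (endian, first offset)."""
    fh.seek(0)
    head = fh.read(8)
    if len(head) < 8:
        raise FormatError("file too short to be a TIFF")
    if head[:2] == b"II":
        endian = "<"
    elif head[:2] == b"MM":
        endian = ">"
    else:
        raise FormatError(f"bad TIFF byte-order mark {head[:2]!r}")
    (magic,) = struct.unpack(endian + "H", head[2:4])
    if magic != _MAGIC:
        raise FormatError(f"bad TIFF magic number {magic} (expected {_MAGIC})")
    (first,) = struct.unpack(endian + "I", head[4:8])
    return endian, first


def _read_entry(fh: BinaryIO, endian: str, raw: bytes):
    tag, typ, count = struct.unpack(endian + "HHI", raw[:8])
    size = _TYPE_SIZES.get(typ)
    if size is None:
        return tag, None  # unknown value type: tolerated and skipped
    total = size * count
    if total <= 4:
        payload = raw[8 : 8 + total]
    else:
        (off,) = struct.unpack(endian + "I", raw[8:12])
        here = fh.tell()
        fh.seek(off)
        payload = fh.read(total)
        fh.seek(here)
        if len(payload) != total:
            raise FormatError(f"tag {tag}: out-of-line value truncated")
    if typ == TYPE_ASCII:
        return tag, payload.split(b"\0", 1)[0].decode("utf-8", "replace")
    if typ == TYPE_BYTE:
        return tag, tuple(payload)
    if typ == TYPE_SHORT:
        return tag, struct.unpack(endian + "H" * count, payload)
    if typ == TYPE_LONG:
        return tag, struct.unpack(endian + "I" * count, payload)
    if typ == TYPE_RATIONAL:
        flat = struct.unpack(endian + "I" * (2 * count), payload)
        return tag, tuple(flat[i] / flat[i + 1] if flat[i + 1] else 0.0
                          for i in range(0, len(flat), 2))
    return tag, None


def read_directories(fh: BinaryIO, limit: int = 65536):
    """Follow the IFD chain; returns (endian, [TiffDirectory...]).

    The chain is cycle-checked: an offset seen twice (including an IFD
    pointing at itself) is a format error, not an infinite loop.
    """
    endian, offset = read_header(fh)
    dirs: List[TiffDirectory] = []
    seen = set()
    while offset != 0:
        if offset in seen:
            raise FormatError(f"cyclic IFD chain: offset {offset} repeats")
        seen.add(offset)
        if len(dirs) >= limit:
            raise FormatError("IFD chain longer than supported limit")
        fh.seek(offset)
        raw = fh.read(2)
        if len(raw) != 2:
            raise FormatError(f"truncated IFD at offset {offset}")
        (count,) = struct.unpack(endian + "H", raw)
        block = fh.read(12 * count + 4)
        if len(block) != 12 * count + 4:
            raise FormatError(f"truncated IFD entries at offset {offset}")
        entries = {}
        for i in range(count):
            tag, values = _read_entry(fh, endian, block[12 * i : 12 * i + 12])
            if values is not None:
                entries[tag] = values
        dirs.append(TiffDirectory(entries=entries, offset=offset))
        (offset,) = struct.unpack(endian + "I", block[-4:])
    if not dirs:
        raise FormatError("TIFF contains no image file directories")
    return endian, dirs


def read_strip_data(fh: BinaryIO, d: TiffDirectory) -> bytes:
    """Concatenate a page's strips in order (chunky configuration)."""
    out = bytearray()
    for off, cnt in zip(d.strip_offsets, d.strip_byte_counts):
        fh.seek(off)
        chunk = fh.read(cnt)
        if len(chunk) != cnt:
            raise SourceIOError(
                f"strip at offset {off} truncated ({len(chunk)} of {cnt} bytes)"
            )
        out += chunk
    return bytes(out)


def first_description(fh: BinaryIO) -> Optional[str]:
    """ImageDescription of the first IFD only (cheap content sniffing)."""
    endian, offset = read_header(fh)
    if offset == 0:
        return None
    fh.seek(offset)
    raw = fh.read(2)
    if len(raw) != 2:
        raise FormatError("truncated first IFD")
    (count,) = struct.unpack(endian + "H", raw)
    block = fh.read(12 * count)
    if len(block) != 12 * count:
        raise FormatError("truncated first IFD entries")
    for i in range(count):
        tag, values = _read_entry(fh, endian, block[12 * i : 12 * i + 12])
        if tag == TAG_IMAGE_DESCRIPTION and isinstance(values, str):
            return values
    return None


@dataclass
class PageSpec:
    """One page to serialize: dimensions, interpretation and raw samples.

    ``data`` holds the page's samples already interleaved (chunky) and in
    the file's byte order. ``bits`` is one entry per sample of a pixel.
    """

    width: int
    length: int
    bits: tuple
    photometric: int
    data: bytes
    samples_per_pixel: int = 1
    description: Optional[str] = None
    compression: int = 1


def write_tiff(dest: str, pages: List[PageSpec], endian: str = "<") -> None:
    """Serialize pages as a multi-page TIFF: one IFD and one strip each."""
    if not pages:
        raise ValueError("cannot write a TIFF with zero pages")
    order_mark = b"II" if endian == "<" else b"MM"
    buf = bytearray()
    buf += order_mark + struct.pack(endian + "H", _MAGIC)
    buf += struct.pack(endian + "I", 0)  # first IFD offset, patched below
    pointer_pos = 4

    for page in pages:
        if len(buf) % 2:
            buf += b"\0"
        data_off = len(buf)
        buf += page.data

        entries = []  # (tag, type, count, packed_payload)

        def add(tag, typ, values):
            if typ == TYPE_ASCII:
                payload = values.encode("utf-8") + b"\0"
                entries.append((tag, typ, len(payload), payload))
            else:
                fmt = "H" if typ == TYPE_SHORT else "I"
                payload = struct.pack(endian + fmt * len(values), *values)
                entries.append((tag, typ, len(values), payload))

        add(TAG_IMAGE_WIDTH, TYPE_LONG, (page.width,))
        add(TAG_IMAGE_LENGTH, TYPE_LONG, (page.length,))
        add(TAG_BITS_PER_SAMPLE, TYPE_SHORT, tuple(page.bits))
        add(TAG_COMPRESSION, TYPE_SHORT, (page.compression,))
        add(TAG_PHOTOMETRIC, TYPE_SHORT, (page.photometric,))
        if page.description is not None:
            add(TAG_IMAGE_DESCRIPTION, TYPE_ASCII, page.description)
        add(TAG_STRIP_OFFSETS, TYPE_LONG, (data_off,))
        add(TAG_SAMPLES_PER_PIXEL, TYPE_SHORT, (page.samples_per_pixel,))
        add(TAG_ROWS_PER_STRIP, TYPE_LONG, (page.length,))
        add(TAG_STRIP_BYTE_COUNTS, TYPE_LONG, (len(page.data),))

        entries.sort(key=lambda e: e[0])  # tags strictly ascending per TIFF 6.0
        if len(buf) % 2:
            buf += b"\0"
        ifd_off = len(buf)
        struct.pack_into(endian + "I", buf, pointer_pos, ifd_off)

        extra_off = ifd_off + 2 + 12 * len(entries) + 4
        extras = bytearray()
        buf += struct.pack(endian + "H", len(entries))
        for tag, typ, count, payload in entries:
            buf += struct.pack(endian + "HHI", tag, typ, count)
            if len(payload) <= 4:
                buf += payload + b"\0" * (4 - len(payload))
            else:
                pos = extra_off + len(extras)
                if pos % 2:
                    extras += b"\0"
                    pos += 1
                buf += struct.pack(endian + "I", pos)
                extras += payload
        pointer_pos = len(buf)
        buf += struct.pack(endian + "I", 0)
        buf += extras

    with open(dest, "wb") as fh:
        fh.write(buf)
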