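"""PGM/PPM (binary PNM): the interoperability format.

Reads the binary variants P5 (grayscale, maxval up to 65535, 16-bit
samples big-endian per the netpbm convention) and P6 (RGB, maxval 255).
The ASCII variants P2/P3 are recognized but deliberately not decoded. RGB
data is presented as three planes with a CHANNEL axis as the first
non-planar axis — the same convention used for RGB TIFF pages and for
channel-filled output, so one rule holds everywhere.

Writes P5 from uint8/uint16 X,Y images and P6 from uint8 X,Y,CHANNEL(3).
"""

from __future__ import annotations

import numpy as np

from .. import model
from ..errors import (
    CapabilityError,
    FormatError,
    SourceIOError,
    UnsupportedDialectError,
)
from ..formats import (
    Checker,
    DatasetMetadata,
    Format,
    Parser,
    Reader,
    SourceRef,
    Writer,
)
from ..model import CHANNEL, Axis, ImageMetadata, PixelType, Plane, X, Y

_WHITESPACE = b" \t\r\n\x0b\x0c"


def _next_token(fh) -> bytes:
    """Next header token, skipping whitespace and '#' comments, byte-wise."""
    tok = bytearray()
    while True:
        b = fh.read(1)
        if not b:
            if tok:
                return bytes(tok)
            raise FormatError("unexpected end of file in PNM header")
        if b == b"#" and not tok:
            while b and b != b"\n":
                b = fh.read(1)
            continue
        if b in _WHITESPACE:
            if tok:
                return bytes(tok)
            continue
        tok += b


def _next_int(fh, what: str) -> int:
    tok = _next_token(fh)
    try:
        return int(tok)
    except ValueError as exc:
        raise FormatError(f"bad PNM {what} token {tok!r}") from exc


class PnmChecker(Checker):
    def _check_magic(self, src: SourceRef) -> bool:
        return self._head(src, 2) in (b"P2", b"P3", b"P5", b"P6")


class PnmParser(Parser):
    def parse(self, src: SourceRef) -> DatasetMetadata:
        with src.open() as fh:
            magic = fh.read(2)
            if magic in (b"P2", b"P3"):
                raise UnsupportedDialectError(
                    f"ASCII PNM variant {magic.decode()} is not supported "
                    "(only binary P5/P6)"
                )
            if magic not in (b"P5", b"P6"):
                raise FormatError(f"bad PNM magic {magic!r}")
            width = _next_int(fh, "width")
            height = _next_int(fh, "height")
            maxval = _next_int(fh, "maxval")
            # exactly one whitespace byte separates maxval from the raster
            data_offset = fh.tell()

        if width < 1 or height < 1:
            raise FormatError(f"bad PNM dimensions {width}x{height}")
        if maxval < 1 or maxval > 65535:
            raise FormatError(f"PNM maxval {maxval} outside [1, 65535]")

        if magic == b"P5":
            pixel_type = PixelType.UINT8 if maxval < 256 else PixelType.UINT16
            axes = (Axis(X, width), Axis(Y, height))
            bytes_per = width * height * (1 if maxval < 256 else 2)
        else:
            if maxval != 255:
                raise UnsupportedDialectError(
                    f"P6 maxval {maxval} not supported (only 255)"
                )
            pixel_type = PixelType.UINT8
            axes = (Axis(X, width), Axis(Y, height), Axis(CHANNEL, 3))
            bytes_per = width * height * 3

        if src.size() < data_offset + bytes_per:
            raise SourceIOError(
                f"PNM raster truncated: header promises {bytes_per} bytes, "
                f"file has {src.size() - data_offset}"
            )

        img = ImageMetadata(
            name=src.path.stem,
            axes=axes,
            planar_axis_count=2,
            pixel_type=pixel_type,
        )
        meta = self.format.new_metadata(source=src.locator)
        meta.images = [img]
        meta.private["_data_offset"] = data_offset
        meta.private["_maxval"] = maxval
        meta.private["_variant"] = magic.decode()
        return meta


class PnmReader(Reader):
    def _read_plane(self, image_index: int, plane_index: int) -> Plane:
        img = self.image_metadata(image_index)
        offset = self.metadata.private["_data_offset"]
        variant = self.metadata.private["_variant"]
        w, h = img.planar_extents
        with self.source.open() as fh:
            fh.seek(offset)
            if variant == "P5":
                bpp = img.pixel_type.bits_per_sample // 8
                raw = fh.read(w * h * bpp)
                if len(raw) != w * h * bpp:
                    raise SourceIOError("short read in PNM raster")
                # netpbm stores 16-bit samples most significant byte first
                be = img.pixel_type.dtype.newbyteorder(">")
                data = np.frombuffer(raw, dtype=be).astype(
                    img.pixel_type.dtype, copy=False
                )
            else:
                raw = fh.read(w * h * 3)
                if len(raw) != w * h * 3:
                    raise SourceIOError("short read in PNM raster")
                interleaved = np.frombuffer(raw, dtype=np.uint8)
                data = np.ascontiguousarray(interleaved[plane_index::3])
        return Plane(data, model.full_bounds(img))


class PnmWriter(Writer):
    def _check_capabilities(self, meta: DatasetMetadata) -> None:
        if meta.image_count != 1:
            raise CapabilityError(f"PNM stores exactly one image, got {meta.image_count}")
        img = meta.images[0]
        if img.indexed:
            raise CapabilityError("PNM cannot store indexed-color images")
        types = tuple(a.type for a in img.axes)
        if img.planar_axis_count == 2 and types == (X, Y):
            if img.pixel_type not in (PixelType.UINT8, PixelType.UINT16):
                raise CapabilityError(
                    f"pixel type {img.pixel_type.code} not supported by PNM "
                    "(P5 gray is uint8/uint16)"
                )
        elif (
            img.planar_axis_count == 2
            and types == (X, Y, CHANNEL)
            and img.axes[2].length == 3
        ):
            if img.pixel_type is not PixelType.UINT8:
                raise CapabilityError(
                    f"pixel type {img.pixel_type.code} not supported by PNM "
                    "(P6 RGB is uint8)"
                )
        else:
            raise CapabilityError(
                "PNM stores X,Y gray or X,Y,CHANNEL(3) RGB images; got axes "
                + ",".join(f"{a.type.name}({a.length})" for a in img.axes)
            )

    def _finalize(self) -> None:
        img = self.metadata.images[0]
        w, h = img.planar_extents
        rgb = len(img.axes) == 3
        with open(self.dest.locator, "wb") as fh:
            if rgb:
                fh.write(b"P6\n%d %d\n255\n" % (w, h))
                chans = [self._planes[(0, k)].data for k in range(3)]
                interleaved = np.empty(w * h * 3, dtype=np.uint8)
                for k in range(3):
                    interleaved[k::3] = chans[k]
                fh.write(interleaved.tobytes())
            else:
                maxval = 255 if img.pixel_type is PixelType.UINT8 else 65535
                fh.write(b"P5\n%d %d\n%d\n" % (w, h, maxval))
                be = img.pixel_type.dtype.newbyteorder(">")
                fh.write(
                    np.ascontiguousarray(self._planes[(0, 0)].data, dtype=be).tobytes()
                )


PNM_FORMAT = Format(
    name="pnm",
    suffixes=(".pgm", ".ppm", ".pnm"),
    priority=10.0,
    meta_type="pnm",
    checker_cls=PnmChecker,
    parser_cls=PnmParser,
    reader_cls=PnmReader,
    writer_cls=PnmWriter,
)
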