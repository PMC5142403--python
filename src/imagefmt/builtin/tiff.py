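"""Baseline TIFF as a Format plugin.

Reading accepts both byte orders, any strip layout, gray (8/16-bit) and
RGB (8-bit chunky) pages; anything else in the wild TIFF zoo — compressed,
tiled, planar, palette — raises an unsupported-dialect error naming the
offending tag and value. A multi-page file maps pages to plane indices in
order and appears as a trailing TIME axis; an RGB page de-interleaves into
three planes behind a CHANNEL axis, the same convention as PPM.

Writing is little-endian, one page per plane, one strip per page,
uncompressed — minimal, but readable by every mainstream TIFF library.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .. import model
from ..errors import CapabilityError, FormatError, UnsupportedDialectError
from ..formats import (
    Checker,
    DatasetMetadata,
    Format,
    Parser,
    Reader,
    SourceRef,
    Writer,
)
from ..model import CHANNEL, TIME, Axis, ImageMetadata, PixelType, Plane, X, Y
from . import tiff_codec as codec
from .tiff_codec import PageSpec, TiffDirectory


def check_dialect(d: TiffDirectory) -> None:
    """Reject TIFF variants outside the supported baseline subset."""
    if d.compression != 1:
        raise UnsupportedDialectError(
            f"compression={d.compression} is not supported (tag 259; only 1 = none)"
        )
    if d.planar_configuration != 1:
        raise UnsupportedDialectError(
            f"planar configuration={d.planar_configuration} is not supported "
            "(tag 284; only 1 = chunky)"
        )
    if any(sf != 1 for sf in d.sample_format):
        raise UnsupportedDialectError(
            f"sample format={d.sample_format} is not supported "
            "(tag 339; only 1 = unsigned integer)"
        )
    phot = d.photometric
    if phot in (0, 1):
        if d.samples_per_pixel != 1 or d.bits_per_sample[0] not in (8, 16):
            raise UnsupportedDialectError(
                f"gray page with samples_per_pixel={d.samples_per_pixel}, "
                f"bits={d.bits_per_sample} is not supported"
            )
    elif phot == 2:
        if d.samples_per_pixel != 3 or d.bits_per_sample != (8, 8, 8):
            raise UnsupportedDialectError(
                f"RGB page with samples_per_pixel={d.samples_per_pixel}, "
                f"bits={d.bits_per_sample} is not supported (only 8,8,8)"
            )
    else:
        raise UnsupportedDialectError(
            f"photometric={phot} is not supported (tag 262; only 0, 1, 2)"
        )


def read_page_samples(src: SourceRef, endian: str, d: TiffDirectory) -> np.ndarray:
    """A page's full sample array (interleaved for RGB), native byte order."""
    with src.open() as fh:
        raw = codec.read_strip_data(fh, d)
    bits = d.bits_per_sample[0]
    expected = d.width * d.length * d.samples_per_pixel * bits // 8
    if len(raw) < expected:
        raise FormatError(
            f"page at offset {d.offset} has {len(raw)} strip bytes, "
            f"needs {expected}"
        )
    dtype = np.dtype(endian + ("u1" if bits == 8 else "u2"))
    arr = np.frombuffer(raw[:expected], dtype=dtype)
    return arr.astype(dtype.newbyteorder("="), copy=False)


class TiffChecker(Checker):
    def _check_magic(self, src: SourceRef) -> bool:
        head = self._head(src, 4)
        return head[:4] in (b"II*\0", b"MM\0*")


class TiffParser(Parser):
    def parse(self, src: SourceRef) -> DatasetMetadata:
        with src.open() as fh:
            endian, dirs = codec.read_directories(fh)
        for d in dirs:
            check_dialect(d)
            d.strip_offsets  # required-entry presence
            d.strip_byte_counts
        first = dirs[0]
        shape = (first.width, first.length, first.bits_per_sample, first.photometric)
        for d in dirs[1:]:
            if (d.width, d.length, d.bits_per_sample, d.photometric) != shape:
                raise FormatError(
                    "pages disagree on geometry: "
                    f"page 0 is {shape}, page at offset {d.offset} is "
                    f"{(d.width, d.length, d.bits_per_sample, d.photometric)}"
                )
        rgb = first.photometric == 2
        axes = [Axis(X, first.width), Axis(Y, first.length)]
        if rgb:
            axes.append(Axis(CHANNEL, 3))
        if len(dirs) > 1:
            axes.append(Axis(TIME, len(dirs)))
        pixel_type = PixelType.UINT8 if first.bits_per_sample[0] == 8 else PixelType.UINT16
        img = ImageMetadata(
            name=src.path.stem,
            axes=tuple(axes),
            planar_axis_count=2,
            pixel_type=pixel_type,
        )
        meta = self.format.new_metadata(source=src.locator)
        meta.images = [img]
        meta.private["_endian"] = endian
        meta.private["_directories"] = dirs
        meta.private["_rgb"] = rgb
        return meta


class TiffReader(Reader):
    def _read_plane(self, image_index: int, plane_index: int) -> Plane:
        img = self.image_metadata(image_index)
        dirs = self.metadata.private["_directories"]
        endian = self.metadata.private["_endian"]
        rgb = self.metadata.private["_rgb"]
        if rgb:
            page_index, channel = divmod(plane_index, 3)
        else:
            page_index, channel = plane_index, None
        d = dirs[page_index]
        arr = read_page_samples(self.source, endian, d)
        if rgb:
            arr = np.ascontiguousarray(arr[channel::3])
        data = arr.astype(img.pixel_type.dtype, copy=False)
        return Plane(data, model.full_bounds(img))


class TiffWriter(Writer):
    """Little-endian baseline writer; RGB is recombined from CHANNEL planes."""

    def _check_capabilities(self, meta: DatasetMetadata) -> None:
        if meta.image_count != 1:
            raise CapabilityError(
                f"plain TIFF stores exactly one image, got {meta.image_count}"
            )
        img = meta.images[0]
        if img.indexed:
            raise CapabilityError("plain TIFF writer cannot store indexed color")
        if img.pixel_type not in (PixelType.UINT8, PixelType.UINT16):
            raise CapabilityError(
                f"pixel type {img.pixel_type.code} not supported by the "
                "baseline TIFF writer (uint8/uint16 only)"
            )
        if img.planar_axis_count != 2 or tuple(
            a.type for a in img.planar_axes
        ) != (X, Y):
            raise CapabilityError("TIFF pages require X,Y planar axes")
        if self._rgb_layout(img) and img.pixel_type is not PixelType.UINT8:
            raise CapabilityError("RGB TIFF pages require uint8 samples")

    @staticmethod
    def _rgb_layout(img: ImageMetadata) -> bool:
        rest = img.nonplanar_axes
        return bool(rest) and rest[0].type == CHANNEL and rest[0].length == 3

    def _description_for_page(self, page_index: int) -> Optional[str]:
        return None

    def _finalize(self) -> None:
        img = self.metadata.images[0]
        w, h = img.planar_extents
        le = img.pixel_type.dtype.newbyteorder("<")
        bits = img.pixel_type.bits_per_sample
        pages = []
        if self._rgb_layout(img) and img.pixel_type is PixelType.UINT8:
            n_pages = model.plane_count(img) // 3
            for t in range(n_pages):
                interleaved = np.empty(w * h * 3, dtype=np.uint8)
                for k in range(3):
                    interleaved[k::3] = self._planes[(0, t * 3 + k)].data
                pages.append(
                    PageSpec(
                        width=w, length=h, bits=(8, 8, 8), photometric=2,
                        samples_per_pixel=3, data=interleaved.tobytes(),
                        description=self._description_for_page(t),
                    )
                )
        else:
            for p in range(model.plane_count(img)):
                data = np.ascontiguousarray(self._planes[(0, p)].data, dtype=le)
                pages.append(
                    PageSpec(
                        width=w, length=h, bits=(bits,), photometric=1,
                        samples_per_pixel=1, data=data.tobytes(),
                        description=self._description_for_page(p),
                    )
                )
        codec.write_tiff(self.dest.locator, pages, endian="<")


TIFF_FORMAT = Format(
    name="tiff",
    suffixes=(".tif", ".tiff"),
    priority=30.0,
    meta_type="tiff",
    checker_cls=TiffChecker,
    parser_cls=TiffParser,
    reader_cls=TiffReader,
    writer_cls=TiffWriter,
)
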