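"""The exchange container: baseline TIFF pages + an XML metadata document.

The open-exchange idea: pixels ride in a TIFF any standards-compliant
reader can decode, while the full N-dimensional metadata — typed calibrated
axes, pixel type, color table, free annotations — rides as an XML document
in the first page's ImageDescription entry, parseable by any XML reader.
Later pages' descriptions are ignored (first wins).

Schema (version 1)::

    <ImageSet version="1">
      <Image name="..." planarAxes="2">
        <Axis type="X" length="16" scale="1.0" unit=""/> ...
        <PixelType code="uint8"/>
        <ColorTable components="3" length="256">base64 of uint32-LE</ColorTable>
        <Meta key="instrument" value="scope1"/> ...
      </Image>
    </ImageSet>

Embedding then extracting is the identity on every metadata field. On
read, the XML is cross-checked against the carrying pages: planar axis
lengths must match page geometry and the declared plane count must match
the page count.
"""

from __future__ import annotations

import base64
import xml.etree.ElementTree as ET

import numpy as np

from .. import model
from ..errors import CapabilityError, FormatError
from ..formats import (
    Checker,
    DatasetMetadata,
    Format,
    Parser,
    Reader,
    SourceRef,
    Writer,
)
from ..model import Axis, ColorTable, ImageMetadata, PixelType, Plane, X, Y, axis_type
from . import tiff_codec as codec
from .tiff import check_dialect, read_page_samples
from .tiff_codec import PageSpec

SCHEMA_VERSION = "1"
ROOT_TAG = "ImageSet"
_MARKER = "<" + ROOT_TAG


def embed_xml(meta: DatasetMetadata) -> str:
    """Serialize a dataset's metadata as the exchange XML document."""
    root = ET.Element(ROOT_TAG, version=SCHEMA_VERSION)
    for img in meta.images:
        el = ET.SubElement(
            root, "Image", name=img.name, planarAxes=str(img.planar_axis_count)
        )
        for a in img.axes:
            ET.SubElement(
                el, "Axis",
                type=a.type.name, length=str(a.length),
                scale=repr(float(a.scale)), unit=a.unit,
            )
        ET.SubElement(el, "PixelType", code=img.pixel_type.code)
        if img.indexed:
            t = img.color_table
            ct = ET.SubElement(
                el, "ColorTable",
                components=str(t.component_count), length=str(t.table_length),
            )
            ct.text = base64.b64encode(
                t.values.astype("<u4").tobytes()
            ).decode("ascii")
        for key in img.table:
            ET.SubElement(el, "Meta", key=key, value=img.table[key])
    return ET.tostring(root, encoding="unicode")


def extract_xml(text: str) -> DatasetMetadata:
    """Parse an exchange XML document back into dataset metadata."""
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise FormatError(f"malformed exchange XML: {exc}") from exc
    if root.tag != ROOT_TAG:
        raise FormatError(f"exchange XML root is <{root.tag}>, expected <{ROOT_TAG}>")
    if root.get("version") != SCHEMA_VERSION:
        raise FormatError(
            f"exchange schema version {root.get('version')!r} "
            f"(expected {SCHEMA_VERSION!r})"
        )
    meta = DatasetMetadata("exchange", "exchange")
    for el in root.findall("Image"):
        axes = []
        for a in el.findall("Axis"):
            try:
                axes.append(
                    Axis(
                        axis_type(a.get("type", "")),
                        int(a.get("length", "0")),
                        float(a.get("scale", "1.0")),
                        a.get("unit", ""),
                    )
                )
            except (TypeError, ValueError) as exc:
                raise FormatError(f"bad Axis element: {exc}") from exc
        pt_el = el.find("PixelType")
        if pt_el is None:
            raise FormatError("Image element lacks a PixelType child")
        try:
            pixel_type = PixelType.from_code(pt_el.get("code", ""))
        except Exception as exc:
            raise FormatError(str(exc)) from exc
        color_table = None
        ct_el = el.find("ColorTable")
        if ct_el is not None:
            comp = int(ct_el.get("components", "0"))
            length = int(ct_el.get("length", "0"))
            try:
                raw = base64.b64decode(ct_el.text or "", validate=True)
            except Exception as exc:
                raise FormatError("bad ColorTable base64 payload") from exc
            values = np.frombuffer(raw, dtype="<u4")
            if values.size != comp * length:
                raise FormatError(
                    f"ColorTable promises {comp}x{length} samples, payload has "
                    f"{values.size}"
                )
            color_table = ColorTable(
                values.reshape(comp, length).astype(pixel_type.dtype)
            )
        table = {
            m.get("key", ""): m.get("value", "") for m in el.findall("Meta")
        }
        img = ImageMetadata(
            name=el.get("name", ""),
            axes=tuple(axes),
            planar_axis_count=int(el.get("planarAxes", "2")),
            pixel_type=pixel_type,
            indexed=color_table is not None,
            color_table=color_table,
            table=table,
        )
        violations = model.validate(img)
        if violations:
            raise FormatError(f"invalid exchange metadata: {'; '.join(violations)}")
        meta.images.append(img)
    if not meta.images:
        raise FormatError("exchange XML declares no images")
    return meta


class ExchangeChecker(Checker):
    """Claims TIFF files whose first page description is an ImageSet document."""

    def _check_magic(self, src: SourceRef) -> bool:
        with src.open() as fh:
            head = fh.read(4)
            if head[:4] not in (b"II*\0", b"MM\0*"):
                return False
            try:
                desc = codec.first_description(fh)
            except FormatError:
                return False
        return desc is not None and _MARKER in desc


class ExchangeParser(Parser):
    def parse(self, src: SourceRef) -> DatasetMetadata:
        with src.open() as fh:
            endian, dirs = codec.read_directories(fh)
        for d in dirs:
            check_dialect(d)
            if d.photometric == 2:
                raise FormatError(
                    "exchange containers carry gray pages only; "
                    "found an RGB page (channels are separate planes)"
                )
        desc = dirs[0].description
        if desc is None or _MARKER not in desc:
            raise FormatError(
                "first TIFF page carries no exchange XML document"
            )
        meta = extract_xml(desc)
        meta.source = src.locator

        # cross-check the XML against the carrying pages
        total = sum(model.plane_count(img) for img in meta.images)
        if total != len(dirs):
            raise FormatError(
                f"XML declares {total} planes but the TIFF has {len(dirs)} pages"
            )
        page = 0
        for img in meta.images:
            w = img.axes[0].length
            h = img.axes[1].length if img.planar_axis_count > 1 else 1
            xbits = img.pixel_type.bits_per_sample
            for _ in range(model.plane_count(img)):
                d = dirs[page]
                if d.width != w:
                    raise FormatError(
                        f"XML declares {img.axes[0].type.name}={w} but TIFF "
                        f"page width={d.width}"
                    )
                if d.length != h:
                    raise FormatError(
                        f"XML declares Y={h} but TIFF page length={d.length}"
                    )
                if d.bits_per_sample[0] != xbits:
                    raise FormatError(
                        f"XML declares pixel type {img.pixel_type.code} "
                        f"({xbits}-bit) but TIFF page bits={d.bits_per_sample[0]}"
                    )
                page += 1
        meta.private["_endian"] = endian
        meta.private["_directories"] = dirs
        return meta


class ExchangeReader(Reader):
    def _page_base(self, image_index: int) -> int:
        return sum(
            model.plane_count(self.metadata.images[i]) for i in range(image_index)
        )

    def _read_plane(self, image_index: int, plane_index: int) -> Plane:
        img = self.image_metadata(image_index)
        dirs = self.metadata.private["_directories"]
        endian = self.metadata.private["_endian"]
        d = dirs[self._page_base(image_index) + plane_index]
        arr = read_page_samples(self.source, endian, d)
        data = arr.astype(img.pixel_type.dtype, copy=False)
        return Plane(data, model.full_bounds(img))


class ExchangeWriter(Writer):
    """Gray pages in dataset order; the XML document on the first page."""

    def _check_capabilities(self, meta: DatasetMetadata) -> None:
        for i, img in enumerate(meta.images):
            if img.pixel_type not in (PixelType.UINT8, PixelType.UINT16):
                raise CapabilityError(
                    f"image {i}: pixel type {img.pixel_type.code} not supported "
                    "by the exchange container (uint8/uint16 pages)"
                )
            if img.planar_axis_count != 2 or tuple(
                a.type for a in img.planar_axes
            ) != (X, Y):
                raise CapabilityError(
                    f"image {i}: exchange pages require X,Y planar axes"
                )

    def _finalize(self) -> None:
        xml_text = embed_xml(self.metadata)
        pages = []
        for i, img in enumerate(self.metadata.images):
            w, h = img.planar_extents
            le = img.pixel_type.dtype.newbyteorder("<")
            bits = img.pixel_type.bits_per_sample
            for p in range(model.plane_count(img)):
                data = np.ascontiguousarray(self._planes[(i, p)].data, dtype=le)
                pages.append(
                    PageSpec(
                        width=w, length=h, bits=(bits,), photometric=1,
                        samples_per_pixel=1, data=data.tobytes(),
                        description=xml_text if not pages else None,
                    )
                )
        codec.write_tiff(self.dest.locator, pages, endian="<")


EXCHANGE_FORMAT = Format(
    name="exchange",
    suffixes=(".ex.tif", ".ex.tiff"),
    priority=40.0,
    meta_type="exchange",
    checker_cls=ExchangeChecker,
    parser_cls=ExchangeParser,
    reader_cls=ExchangeReader,
    writer_cls=ExchangeWriter,
)
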