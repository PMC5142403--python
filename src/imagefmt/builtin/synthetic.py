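"""The synthetic, zero-storage format (``.sim``).

A synthetic source stores nothing on disk: the locator itself encodes the
image ("name&axes=X,Y,Z&lengths=16,16,4&pixelType=uint16.sim") and every
pixel follows a closed-form law, making the format both a fixture
generator and an independent oracle for the rest of the framework.

The pixel law: for integral types, sample ``(x, y)`` of plane ``p`` equals
``(x + y + p) mod 2**min(bits, 16)``; float types carry the same value as a
real number. For indexed images that value is the color *index*, and table
component ``k`` at index ``v`` is ``(v + 17*k) mod 2**bits``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .. import model
from ..errors import FormatError
from ..formats import (
    Checker,
    DatasetMetadata,
    Format,
    Parser,
    Reader,
    SourceRef,
)
from ..model import (
    DEFAULT_AXIS_ORDER,
    Axis,
    ColorTable,
    ImageMetadata,
    PixelType,
    Plane,
    axis_type,
)

SUFFIX = ".sim"
_KNOWN_KEYS = {"axes", "lengths", "pixelType", "indexed", "tableComponents"}


@dataclass
class SyntheticSpec:
    """Parsed form of a synthetic locator; round-trips through its name."""

    name: str = "img"
    axes: tuple = ()
    pixel_type: PixelType = PixelType.UINT8
    indexed: bool = False
    table_components: int = 3

    def to_name(self) -> str:
        parts = [self.name]
        parts.append("axes=" + ",".join(a.type.name for a in self.axes))
        parts.append("lengths=" + ",".join(str(a.length) for a in self.axes))
        parts.append(f"pixelType={self.pixel_type.code}")
        if self.indexed:
            parts.append("indexed=true")
            parts.append(f"tableComponents={self.table_components}")
        return "&".join(parts) + SUFFIX

    @property
    def modulus(self) -> int:
        return 2 ** min(self.pixel_type.bits_per_sample, 16)

    def color_table(self) -> ColorTable:
        bits = self.pixel_type.bits_per_sample
        length = self.modulus
        v = np.arange(length, dtype=np.uint64)
        rows = [
            (v + 17 * k) % (2 ** np.uint64(bits))
            for k in range(self.table_components)
        ]
        values = np.stack(rows).astype(self.pixel_type.dtype)
        return ColorTable(values)

    def to_image_metadata(self) -> ImageMetadata:
        return ImageMetadata(
            name=self.name,
            axes=self.axes,
            planar_axis_count=min(2, len(self.axes)),
            pixel_type=self.pixel_type,
            indexed=self.indexed,
            color_table=self.color_table() if self.indexed else None,
        )


def synthetic_pixel(spec: SyntheticSpec, plane_index: int, x: int, y: int):
    """The closed-form pixel law (scalar form; the reader vectorizes it)."""
    value = (int(x) + int(y) + int(plane_index)) % spec.modulus
    return spec.pixel_type.dtype.type(value)


def parse_name(locator: str) -> SyntheticSpec:
    """Parse a ``.sim`` locator into a :class:`SyntheticSpec`.

    Defaults: axes X,Y; lengths 512,512; uint8; non-indexed; 3 table
    components. When only ``lengths`` is given, axis names default to the
    canonical X, Y, Z, CHANNEL, TIME prefix of matching arity.
    """
    base = locator.replace("\\", "/").rsplit("/", 1)[-1]
    if not base.endswith(SUFFIX):
        raise FormatError(f"synthetic locator {locator!r} must end with {SUFFIX}")
    body = base[: -len(SUFFIX)]
    tokens = body.split("&")
    name = tokens[0] or "img"
    kv = {}
    for tok in tokens[1:]:
        if "=" not in tok:
            raise FormatError(f"malformed synthetic token {tok!r} (expected key=value)")
        key, _, value = tok.partition("=")
        if key not in _KNOWN_KEYS:
            raise FormatError(f"unknown synthetic key {key!r}")
        if key in kv:
            raise FormatError(f"duplicate synthetic key {key!r}")
        kv[key] = value

    try:
        pixel_type = PixelType.from_code(kv.get("pixelType", "uint8"))
    except Exception as exc:
        raise FormatError(str(exc)) from exc

    if "lengths" in kv:
        try:
            lengths = [int(v) for v in kv["lengths"].split(",")]
        except ValueError as exc:
            raise FormatError(f"bad lengths {kv['lengths']!r}") from exc
    else:
        lengths = None

    if "axes" in kv:
        names = kv["axes"].split(",")
        types = [axis_type(n) for n in names]
        if lengths is None:
            lengths = [512] * len(types)
    else:
        if lengths is None:
            lengths = [512, 512]
        if len(lengths) > len(DEFAULT_AXIS_ORDER):
            raise FormatError(
                f"{len(lengths)} lengths exceed the {len(DEFAULT_AXIS_ORDER)} default axes"
            )
        types = list(DEFAULT_AXIS_ORDER[: len(lengths)])

    if len(types) != len(lengths):
        raise FormatError(
            f"axes/lengths arity mismatch: {len(types)} axes, {len(lengths)} lengths"
        )
    if not types:
        raise FormatError("synthetic image needs at least one axis")
    for n in lengths:
        if n < 1:
            raise FormatError(f"axis length {n} must be positive")

    indexed = kv.get("indexed", "false").lower()
    if indexed not in ("true", "false"):
        raise FormatError(f"indexed must be true/false, got {kv['indexed']!r}")
    indexed = indexed == "true"
    if indexed and not pixel_type.integral:
        raise FormatError(f"indexed synthetic image requires an integral pixel type")

    try:
        components = int(kv.get("tableComponents", "3"))
    except ValueError as exc:
        raise FormatError(f"bad tableComponents {kv['tableComponents']!r}") from exc
    if components < 1:
        raise FormatError("tableComponents must be >= 1")

    return SyntheticSpec(
        name=name,
        axes=tuple(Axis(t, n) for t, n in zip(types, lengths)),
        pixel_type=pixel_type,
        indexed=indexed,
        table_components=components,
    )


class SyntheticChecker(Checker):
    """Suffix-only: synthetic sources need not exist on disk."""


class SyntheticParser(Parser):
    def parse(self, src: SourceRef) -> DatasetMetadata:
        spec = parse_name(src.locator)
        meta = self.format.new_metadata(source=src.locator)
        meta.images = [spec.to_image_metadata()]
        meta.private["_spec"] = spec
        return meta


class SyntheticReader(Reader):
    def _read_plane(self, image_index: int, plane_index: int) -> Plane:
        spec: SyntheticSpec = self.metadata.private["_spec"]
        img = self.image_metadata(image_index)
        extents = img.planar_extents
        nx = extents[0]
        ny = extents[1] if len(extents) > 1 else 1
        xs = np.arange(nx, dtype=np.uint64)
        ys = np.arange(ny, dtype=np.uint64)
        vals = (np.add.outer(ys, xs) + np.uint64(plane_index)) % np.uint64(spec.modulus)
        data = vals.astype(img.pixel_type.dtype).ravel()
        return Plane(data, model.full_bounds(img))


SYNTHETIC_FORMAT = Format(
    name="synthetic",
    suffixes=(SUFFIX,),
    priority=50.0,
    meta_type="synthetic",
    checker_cls=SyntheticChecker,
    parser_cls=SyntheticParser,
    reader_cls=SyntheticReader,
    writer_cls=None,  # read-only by design: nothing to store
)
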