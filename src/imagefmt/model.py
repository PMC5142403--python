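"""Format-independent N-dimensional image model.

Every format expresses its metadata as :class:`ImageMetadata`: an ordered
list of typed, calibrated axes, a pixel type, an optional indexed-color
table, and an open key-value table. The first ``planar_axis_count`` axes
(normally X and Y) span a :class:`Plane`, the unit of pixel I/O; the
remaining axes are linearized into a plane index with the *first non-planar
axis varying fastest* (the common Z-then-channel-then-time ordering of
microscopy stacks, without hard-coding those axis names).

Conventions, stated once because every codec depends on them:

* coordinates are 0-based; regions are half-open ``(offset, extent)`` pairs;
* within a plane, the first planar axis varies fastest — for an X,Y plane
  the sample at ``(x, y)`` lives at buffer offset ``x + nx * y``;
* indexed planes store raw indices; expansion to components is exclusively
  the job of the channel-filling filter.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import BoundsError, ValidationError

__all__ = [
    "AxisType",
    "Axis",
    "PixelType",
    "ColorTable",
    "ImageMetadata",
    "Plane",
    "X",
    "Y",
    "Z",
    "CHANNEL",
    "TIME",
    "axis",
    "plane_count",
    "raster_to_position",
    "position_to_raster",
    "lookup_color",
    "validate",
]

_WELL_KNOWN = ("X", "Y", "Z", "CHANNEL", "TIME")


@dataclass(frozen=True)
class AxisType:
    """A dimensional axis role: one of the well-known set or a custom name."""

    name: str

    @property
    def is_well_known(self) -> bool:
        return self.name in _WELL_KNOWN

    @classmethod
    def custom(cls, name: str) -> "AxisType":
        """Create a custom axis type; the well-known names are reserved."""
        if name in _WELL_KNOWN:
            raise ValidationError(
                f"custom axis name {name!r} collides with a well-known axis type"
            )
        return cls(name)

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.name


X = AxisType("X")
Y = AxisType("Y")
Z = AxisType("Z")
CHANNEL = AxisType("CHANNEL")
TIME = AxisType("TIME")

#: Canonical ordering used when axis names are defaulted from a length list.
DEFAULT_AXIS_ORDER = (X, Y, Z, CHANNEL, TIME)


def axis_type(name: str) -> AxisType:
    """Return the well-known axis type of this name, or a custom one."""
    return AxisType(name) if name in _WELL_KNOWN else AxisType.custom(name)


@dataclass(frozen=True)
class Axis:
    """One dimension of an image: a type, a sample count and a calibration.

    ``scale`` is the physical size of one sample step along this axis and
    ``unit`` its unit string; they default to 1.0 and "" for uncalibrated
    data.
    """

    type: AxisType
    length: int
    scale: float = 1.0
    unit: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.length, (int, np.integer)) or self.length < 1:
            raise ValidationError(f"axis length must be a positive integer, got {self.length!r}")
        if not (math.isfinite(self.scale) and self.scale > 0):
            raise ValidationError(f"axis scale must be positive and finite, got {self.scale!r}")


def axis(type_: AxisType, length: int, scale: float = 1.0, unit: str = "") -> Axis:
    return Axis(type_, int(length), scale, unit)


class PixelType(enum.Enum):
    """Supported sample types, mirroring the numpy scalar types they map to."""

    UINT8 = ("uint8", 8, False, True)
    INT8 = ("int8", 8, True, True)
    UINT16 = ("uint16", 16, False, True)
    INT16 = ("int16", 16, True, True)
    UINT32 = ("uint32", 32, False, True)
    INT32 = ("int32", 32, True, True)
    FLOAT32 = ("float32", 32, True, False)
    FLOAT64 = ("float64", 64, True, False)

    def __init__(self, code: str, bits: int, signed: bool, integral: bool):
        self.code = code
        self.bits_per_sample = bits
        self.signed = signed
        self.integral = integral

    @property
    def dtype(self) -> np.dtype:
        """Native-endian numpy dtype for in-memory planes."""
        return np.dtype(self.code)

    @classmethod
    def from_code(cls, code: str) -> "PixelType":
        for pt in cls:
            if pt.code == code:
                return pt
        raise ValidationError(f"unknown pixel type code {code!r}")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PixelType.{self.name}"


@dataclass(frozen=True)
class ColorTable:
    """An indexed-color lookup table of shape (component_count, table_length).

    ``values`` keeps the dtype it was built with; that dtype bounds the
    output pixel-type range of the table.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValidationError(
                f"color table must be 2-D (components x length), got shape {arr.shape}"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValidationError("color table samples must be integers")
        object.__setattr__(self, "values", arr)

    @property
    def component_count(self) -> int:
        return int(self.values.shape[0])

    @property
    def table_length(self) -> int:
        return int(self.values.shape[1])

    def lookup(self, index_value: int) -> np.ndarray:
        """Samples (one per component) for an index; bounds-checked."""
        if not 0 <= int(index_value) < self.table_length:
            raise BoundsError(
                f"color index {index_value} outside table of length {self.table_length}"
            )
        return self.values[:, int(index_value)].copy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ColorTable):
            return NotImplemented
        return self.values.dtype == other.values.dtype and np.array_equal(
            self.values, other.values
        )

    def __hash__(self) -> int:  # pragma: no cover - unused
        return hash((self.values.shape, self.values.dtype.str))


def lookup_color(table: ColorTable, index_value: int) -> np.ndarray:
    """Resolve one color index to its per-component samples."""
    return table.lookup(index_value)


@dataclass
class ImageMetadata:
    """The format-independent baseline description of one image.

    Invariants (reported, not raised, by :func:`validate`):

    * ``1 <= planar_axis_count <= len(axes)``;
    * axis types are unique within the image;
    * ``indexed`` implies a color table is present and the pixel type is
      integral.
    """

    name: str = ""
    axes: tuple = ()
    planar_axis_count: int = 2
    pixel_type: PixelType = PixelType.UINT8
    indexed: bool = False
    color_table: Optional[ColorTable] = None
    table: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axes = tuple(self.axes)

    # -- axis views ------------------------------------------------------
    @property
    def planar_axes(self) -> tuple:
        return self.axes[: self.planar_axis_count]

    @property
    def nonplanar_axes(self) -> tuple:
        return self.axes[self.planar_axis_count :]

    @property
    def planar_extents(self) -> tuple:
        return tuple(a.length for a in self.planar_axes)

    @property
    def plane_sample_count(self) -> int:
        return int(np.prod([a.length for a in self.planar_axes], dtype=np.int64))

    @property
    def plane_count(self) -> int:
        return plane_count(self)

    def axis_of_type(self, type_: AxisType) -> Optional[Axis]:
        for a in self.axes:
            if a.type == type_:
                return a
        return None

    def copy(self) -> "ImageMetadata":
        """Independent copy; the axes tuple and color table are immutable."""
        return replace(self, table=dict(self.table))

    def validate(self) -> list:
        return validate(self)


def validate(meta: ImageMetadata) -> list:
    """Return a description of every violated invariant (empty if valid)."""
    violations = []
    if not meta.axes:
        violations.append("axes: image must have at least one axis")
    if meta.axes and not 1 <= meta.planar_axis_count <= len(meta.axes):
        violations.append(
            f"planar_axis_count: {meta.planar_axis_count} outside [1, {len(meta.axes)}]"
        )
    seen = set()
    for a in meta.axes:
        if a.type in seen:
            violations.append(f"axis uniqueness: duplicate axis type {a.type.name}")
        seen.add(a.type)
    if meta.indexed:
        if meta.color_table is None:
            violations.append("indexed: indexed image requires a color table")
        if not meta.pixel_type.integral:
            violations.append(
                f"indexed: pixel type {meta.pixel_type.code} is not integral"
            )
    elif meta.color_table is not None:
        violations.append("indexed: color table present on a non-indexed image")
    return violations


def plane_count(meta: ImageMetadata) -> int:
    """Number of planes: the product of all non-planar axis lengths (1 if none)."""
    return int(np.prod([a.length for a in meta.nonplanar_axes], dtype=np.int64))


def raster_to_position(meta: ImageMetadata, plane_index: int) -> tuple:
    """Decompose a plane index into non-planar coordinates, first axis fastest."""
    n = plane_count(meta)
    if not 0 <= plane_index < n:
        raise BoundsError(f"plane index {plane_index} outside [0, {n})")
    position = []
    rem = int(plane_index)
    for a in meta.nonplanar_axes:
        position.append(rem % a.length)
        rem //= a.length
    return tuple(position)


def position_to_raster(meta: ImageMetadata, position: Sequence[int]) -> int:
    """Linearize non-planar coordinates into a plane index (inverse of above)."""
    axes = meta.nonplanar_axes
    if len(position) != len(axes):
        raise BoundsError(
            f"position has {len(position)} coordinates for {len(axes)} non-planar axes"
        )
    index = 0
    stride = 1
    for coord, a in zip(position, axes):
        if not 0 <= int(coord) < a.length:
            raise BoundsError(
                f"coordinate {coord} outside axis {a.type.name} of length {a.length}"
            )
        index += int(coord) * stride
        stride *= a.length
    return index


@dataclass
class Plane:
    """One planar-axes pixel block.

    ``data`` is a flat sample buffer in native byte order, first planar axis
    fastest. Indexed planes hold raw indices and carry the color table.
    """

    data: np.ndarray
    bounds: tuple
    color_table: Optional[ColorTable] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).ravel()
        self.bounds = tuple((int(o), int(e)) for o, e in self.bounds)
        expected = int(np.prod([e for _, e in self.bounds], dtype=np.int64))
        if self.data.size != expected:
            raise ValidationError(
                f"plane buffer has {self.data.size} samples, bounds imply {expected}"
            )

    @property
    def extents(self) -> tuple:
        return tuple(e for _, e in self.bounds)

    def crop(self, bounds: Iterable) -> "Plane":
        """Sub-region of this plane; ``bounds`` are relative to this plane."""
        bounds = tuple((int(o), int(e)) for o, e in bounds)
        if len(bounds) != len(self.bounds):
            raise BoundsError(
                f"region has {len(bounds)} bounds for {len(self.bounds)} planar axes"
            )
        for (off, ext), full in zip(bounds, self.extents):
            if ext < 1 or off < 0 or off + ext > full:
                raise BoundsError(
                    f"region (offset={off}, extent={ext}) outside planar extent {full}"
                )
        # first axis fastest == C order with the axis sequence reversed
        shaped = self.data.reshape(self.extents[::-1])
        slices = tuple(slice(off, off + ext) for off, ext in bounds[::-1])
        cropped = shaped[slices]
        abs_bounds = tuple(
            (base_off + off, ext)
            for (off, ext), (base_off, _) in zip(bounds, self.bounds)
        )
        return Plane(np.ascontiguousarray(cropped).ravel(), abs_bounds, self.color_table)


def full_bounds(meta: ImageMetadata) -> tuple:
    """Zero-offset bounds covering the full planar extents of ``meta``."""
    return tuple((0, a.length) for a in meta.planar_axes)
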