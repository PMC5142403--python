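"""Shared fixtures: gateways, randomized dataset generators, and a scratch
packaging environment advertising an external format plugin."""

from __future__ import annotations

import textwrap

import numpy as np
import pytest

from imagefmt import (
    Axis,
    ColorTable,
    DatasetMetadata,
    ImageMetadata,
    PixelType,
    Plane,
    create_gateway,
)
from imagefmt.model import CHANNEL, TIME, X, Y, Z, full_bounds

pytest_plugins = ()


@pytest.fixture
def gw():
    return create_gateway()


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


# ---------------------------------------------------------------------------
# randomized dataset generation
# ---------------------------------------------------------------------------

def random_color_table(rng, pixel_type: PixelType, components=None) -> ColorTable:
    comp = int(components if components is not None else rng.integers(1, 5))
    length = int(rng.integers(2, 33))
    info = np.iinfo(pixel_type.dtype)
    values = rng.integers(info.min, int(info.max) + 1, size=(comp, length), dtype=np.int64)
    return ColorTable(values.astype(pixel_type.dtype))


def random_plane(img: ImageMetadata, rng) -> Plane:
    n = img.plane_sample_count
    if img.indexed:
        data = rng.integers(0, img.color_table.table_length, size=n).astype(
            img.pixel_type.dtype
        )
    elif img.pixel_type.integral:
        info = np.iinfo(img.pixel_type.dtype)
        data = rng.integers(info.min, int(info.max) + 1, size=n, dtype=np.int64).astype(
            img.pixel_type.dtype
        )
    else:
        data = (rng.standard_normal(n) * 100).astype(img.pixel_type.dtype)
    return Plane(data, full_bounds(img))


#: Pixel types each writable format can store.
WRITABLE_PIXEL_TYPES = {
    "sciraw": list(PixelType),
    "pnm": [PixelType.UINT8, PixelType.UINT16],
    "tiff": [PixelType.UINT8, PixelType.UINT16],
    "exchange": [PixelType.UINT8, PixelType.UINT16],
}


def random_roundtrip_metadata(fmt_name: str, pixel_type: PixelType, rng) -> ImageMetadata:
    """A random image layout within ``fmt_name``'s representable envelope."""
    w = int(rng.integers(1, 17))
    h = int(rng.integers(1, 17))
    axes = [Axis(X, w), Axis(Y, h)]
    indexed = False
    color_table = None
    if fmt_name == "sciraw":
        for t in (Z, CHANNEL, TIME):
            if rng.random() < 0.4:
                axes.append(Axis(t, int(rng.integers(1, 5))))
        if pixel_type.integral and rng.random() < 0.3:
            indexed = True
            color_table = random_color_table(rng, pixel_type)
    elif fmt_name == "pnm":
        if pixel_type is PixelType.UINT8 and rng.random() < 0.5:
            axes.append(Axis(CHANNEL, 3))
    elif fmt_name == "tiff":
        if pixel_type is PixelType.UINT8 and rng.random() < 0.5:
            axes.append(Axis(CHANNEL, 3))
        if rng.random() < 0.5:
            axes.append(Axis(TIME, int(rng.integers(2, 5))))
    elif fmt_name == "exchange":
        for t in (Z, CHANNEL, TIME):
            if rng.random() < 0.4:
                axes.append(Axis(t, int(rng.integers(1, 5))))
        if rng.random() < 0.5:
            axes[0] = Axis(X, w, scale=0.25, unit="um")
        if pixel_type.integral and rng.random() < 0.3:
            indexed = True
            color_table = random_color_table(rng, pixel_type)
    else:
        raise ValueError(fmt_name)
    return ImageMetadata(
        name="rt",
        axes=tuple(axes),
        planar_axis_count=2,
        pixel_type=pixel_type,
        indexed=indexed,
        color_table=color_table,
        table={"origin": "generated"} if fmt_name in ("sciraw", "exchange") else {},
    )


def dataset_for(fmt, img: ImageMetadata, source=None) -> DatasetMetadata:
    meta = fmt.new_metadata(source=source)
    meta.images = [img]
    return meta


def assert_baseline_equal(a: ImageMetadata, b: ImageMetadata, calibration=True):
    __tracebackhide__ = True
    assert a.pixel_type is b.pixel_type
    assert a.indexed == b.indexed
    assert len(a.axes) == len(b.axes)
    for ax, bx in zip(a.axes, b.axes):
        assert ax.type == bx.type
        assert ax.length == bx.length
        if calibration:
            assert ax.scale == bx.scale and ax.unit == bx.unit
    if a.indexed:
        assert a.color_table == b.color_table


# ---------------------------------------------------------------------------
# scratch packaging environment with an external plugin
# ---------------------------------------------------------------------------

EXT_MODULE = textwrap.dedent(
    """
    from imagefmt.formats import Checker, Format, Parser, Reader

    DEMO_FORMAT = Format(
        name="demo-ext",
        suffixes=(".demo",),
        priority=60.0,
        meta_type="demo-ext",
    )

    def broken_factory():
        raise RuntimeError("this plugin fails on construction")
    """
)


def install_external_plugin(tmp_path, monkeypatch, entry="demo = ext_demo_format:DEMO_FORMAT"):
    """Materialize a distribution advertising an entry point in the plugin
    group, visible to importlib.metadata via sys.path."""
    site = tmp_path / "site"
    site.mkdir(exist_ok=True)
    (site / "ext_demo_format.py").write_text(EXT_MODULE)
    dist = site / "extdemo-0.1.dist-info"
    dist.mkdir(exist_ok=True)
    (dist / "METADATA").write_text(
        "Metadata-Version: 2.1\nName: extdemo\nVersion: 0.1\n"
    )
    (dist / "entry_points.txt").write_text(f"[imagefmt.formats]\n{entry}\n")
    monkeypatch.syspath_prepend(str(site))
    return site


@pytest.fixture
def external_plugin(tmp_path, monkeypatch):
    return install_external_plugin(tmp_path, monkeypatch)
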