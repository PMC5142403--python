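"""Built-in formats: grammars, dialects, round trips, cross-validation."""

import struct

import numpy as np
import pytest

from imagefmt import PixelType, SourceRef, write_dataset
from imagefmt.builtin import tiff_codec as codec
from imagefmt.builtin.exchange import EXCHANGE_FORMAT, embed_xml, extract_xml
from imagefmt.builtin.synthetic import SyntheticSpec, parse_name, synthetic_pixel
from imagefmt.builtin.tiff_codec import PageSpec
from imagefmt.errors import FormatError, SourceIOError, UnsupportedDialectError
from imagefmt.formats import DatasetMetadata
from imagefmt.model import CHANNEL, TIME, Axis, ColorTable, ImageMetadata, X, Y, Z, full_bounds

from conftest import (
    WRITABLE_PIXEL_TYPES,
    assert_baseline_equal,
    dataset_for,
    random_color_table,
    random_plane,
    random_roundtrip_metadata,
)


class TestSyntheticGrammar:
    def test_explicit_axes_lengths_and_type(self):
        spec = parse_name("img&axes=X,Y,Z&lengths=16,16,4&pixelType=uint16.sim")
        assert [(a.type.name, a.length) for a in spec.axes] == [
            ("X", 16), ("Y", 16), ("Z", 4),
        ]
        assert spec.pixel_type is PixelType.UINT16

    def test_defaults(self):
        spec = parse_name("img.sim")
        assert [(a.type.name, a.length) for a in spec.axes] == [("X", 512), ("Y", 512)]
        assert spec.pixel_type is PixelType.UINT8 and not spec.indexed

    def test_lengths_only_take_canonical_axis_names(self):
        spec = parse_name("img&lengths=16,16,4.sim")
        assert [a.type.name for a in spec.axes] == ["X", "Y", "Z"]

    @pytest.mark.parametrize(
        "locator",
        [
            "img&axes=X,Y&lengths=16.sim",        # arity mismatch
            "img&bogus=1.sim",                     # unknown key
            "img&axes=X,Y&lengths=16,0.sim",       # non-positive length
            "img&pixelType=float32&indexed=true.sim",  # indexed needs integral
        ],
    )
    def test_malformed_names_rejected(self, locator):
        with pytest.raises(FormatError):
            parse_name(locator)


class TestSyntheticPixelLaw:
    def test_origin_is_zero(self):
        spec = parse_name("img.sim")
        assert synthetic_pixel(spec, 0, 0, 0) == 0

    def test_uint8_wraps_at_256(self):
        spec = parse_name("img&axes=X,Y&lengths=512,512.sim")
        assert synthetic_pixel(spec, 3, 10, 250) == 7

    def test_indexed_table_component_law(self):
        spec = parse_name("img&axes=X,Y&lengths=8,8&indexed=true.sim")
        table = spec.color_table()
        assert table.lookup(2)[1] == (2 + 17) % 256 == 19

    def test_reader_matches_closed_form_exhaustively(self, gw):
        locator = "o&axes=X,Y,Z&lengths=9,7,5&pixelType=uint16.sim"
        spec = parse_name(locator)
        stack = gw.open(locator)
        for p in range(5):
            plane = stack.open_plane(0, p).data.reshape(7, 9)
            for y in range(7):
                for x in range(9):
                    assert plane[y, x] == synthetic_pixel(spec, p, x, y)

    def test_float_planes_carry_the_same_values_as_reals(self, gw):
        stack = gw.open("f&axes=X,Y&lengths=4,4&pixelType=float64.sim")
        plane = stack.open_plane(0, 0)
        assert plane.data.dtype == np.float64
        assert plane.data.reshape(4, 4)[1, 2] == 3.0


class TestSciraw:
    def test_write_parse_round_trip_metadata(self, gw, tmp_path, rng):
        fmt = gw.formats.get_format("sciraw")
        img = ImageMetadata(
            name="cells",
            axes=(Axis(X, 6), Axis(Y, 5), Axis(Z, 3)),
            pixel_type=PixelType.INT16,
            table={"stage": "7", "note": "fixture with: colon"},
        )
        planes = [random_plane(img, rng) for _ in range(3)]
        path = str(tmp_path / "rt.sciraw")
        write_dataset(fmt, path, dataset_for(fmt, img),
                      [(0, p, pl) for p, pl in enumerate(planes)])
        back = fmt.make_parser().parse(SourceRef(path))
        assert_baseline_equal(img, back.images[0], calibration=False)
        assert back.images[0].name == "cells"
        assert back.images[0].table == img.table
        reader = fmt.make_reader(back, SourceRef(path))
        for p in range(3):
            assert np.array_equal(reader.open_plane(0, p).data, planes[p].data)

    def test_color_table_dump_round_trips(self, gw, tmp_path, rng):
        fmt = gw.formats.get_format("sciraw")
        img = ImageMetadata(
            name="ix", axes=(Axis(X, 4), Axis(Y, 4)),
            indexed=True, color_table=random_color_table(rng, PixelType.UINT8),
        )
        path = str(tmp_path / "ix.sciraw")
        write_dataset(fmt, path, dataset_for(fmt, img), [(0, 0, random_plane(img, rng))])
        assert b"colorTable:" in open(path, "rb").read().split(b"\n\n")[0]
        back = fmt.make_parser().parse(SourceRef(path))
        assert back.images[0].color_table == img.color_table

    def test_truncated_payload_is_io_error(self, gw, tmp_path):
        path = str(tmp_path / "t.sciraw")
        gw.convert("t&axes=X,Y&lengths=16,16.sim", path)
        data = open(path, "rb").read()
        open(path, "wb").write(data[:-1])
        fmt = gw.formats.get_format("sciraw")
        with pytest.raises(SourceIOError):
            fmt.make_parser().parse(SourceRef(path))

    def test_unknown_major_version_rejected(self, gw, tmp_path):
        path = tmp_path / "v.sciraw"
        path.write_bytes(b"SCIRAW/2.0\naxes: X,Y\nlengths: 2,2\npixelType: uint8\n\n" + b"\0" * 4)
        fmt = gw.formats.get_format("sciraw")
        with pytest.raises(FormatError) as err:
            fmt.make_parser().parse(SourceRef(str(path)))
        assert "version" in str(err.value)

    def test_negative_axis_length_rejected(self, gw, tmp_path):
        path = tmp_path / "n.sciraw"
        path.write_bytes(b"SCIRAW/1.0\naxes: X,Y\nlengths: 4,-4\npixelType: uint8\n\n")
        fmt = gw.formats.get_format("sciraw")
        with pytest.raises(FormatError):
            fmt.make_parser().parse(SourceRef(str(path)))


class TestPnm:
    def test_p5_layout_forced_by_header(self, gw, tmp_path):
        path = tmp_path / "a.pgm"
        path.write_bytes(b"P5\n2 2\n255\n" + bytes([1, 2, 3, 4]))
        stack = gw.open(str(path))
        assert list(stack.open_plane(0, 0).data) == [1, 2, 3, 4]
        img = stack.image_metadata(0)
        assert [(a.type.name, a.length) for a in img.axes] == [("X", 2), ("Y", 2)]

    def test_p6_channels_deinterleave(self, gw, tmp_path):
        path = tmp_path / "rgb.ppm"
        path.write_bytes(b"P6\n1 1\n255\n" + bytes([9, 8, 7]))
        stack = gw.open(str(path))
        assert stack.plane_count(0) == 3
        assert [int(stack.open_plane(0, k).data[0]) for k in range(3)] == [9, 8, 7]
        assert stack.image_metadata(0).axes[2].type == CHANNEL

    def test_header_comments_skipped(self, gw, tmp_path):
        path = tmp_path / "c.pgm"
        path.write_bytes(b"P5\n# a comment\n2 #inline\n2\n255\n" + bytes(4))
        assert gw.open(str(path)).image_metadata(0).axes[0].length == 2

    def test_ascii_variant_is_unsupported_dialect(self, gw, tmp_path):
        path = tmp_path / "a.pgm"
        path.write_bytes(b"P2\n2 2\n255\n1 2 3 4\n")
        fmt = gw.formats.get_format("pnm")
        with pytest.raises(UnsupportedDialectError):
            fmt.make_parser().parse(SourceRef(str(path)))

    def test_uint16_gray_round_trip_big_endian_on_disk(self, gw, tmp_path, rng):
        fmt = gw.formats.get_format("pnm")
        img = ImageMetadata(
            name="w", axes=(Axis(X, 3), Axis(Y, 2)), pixel_type=PixelType.UINT16
        )
        plane = random_plane(img, rng)
        path = str(tmp_path / "w.pgm")
        write_dataset(fmt, path, dataset_for(fmt, img), [(0, 0, plane)])
        raw = open(path, "rb").read()
        header, _, payload = raw.partition(b"65535\n")
        assert np.array_equal(
            np.frombuffer(payload, dtype=">u2").astype(np.uint16), plane.data
        )
        back = gw.open(path)
        assert back.image_metadata(0).pixel_type is PixelType.UINT16
        assert np.array_equal(back.open_plane(0, 0).data, plane.data)

    def test_written_pnm_readable_by_pillow(self, gw, tmp_path):
        from PIL import Image

        path = str(tmp_path / "p.pgm")
        gw.convert("p&axes=X,Y&lengths=8,6.sim", path)
        with Image.open(path) as im:
            arr = np.asarray(im)
        ours = gw.open(path).open_plane(0, 0).data.reshape(6, 8)
        assert np.array_equal(arr, ours)


class TestTiff:
    def test_multipage_gray_round_trip(self, gw, tmp_path, rng):
        fmt = gw.formats.get_format("tiff")
        img = ImageMetadata(
            name="t", axes=(Axis(X, 5), Axis(Y, 4), Axis(TIME, 3)),
            pixel_type=PixelType.UINT16,
        )
        planes = [random_plane(img, rng) for _ in range(3)]
        path = str(tmp_path / "m.tif")
        write_dataset(fmt, path, dataset_for(fmt, img),
                      [(0, p, pl) for p, pl in enumerate(planes)])
        back = gw.open(path)
        assert_baseline_equal(img, back.image_metadata(0), calibration=False)
        assert back.plane_count(0) == 3
        for p in range(3):
            assert np.array_equal(back.open_plane(0, p).data, planes[p].data)

    def test_rgb_pages_round_trip_channel_axis(self, gw, tmp_path, rng):
        fmt = gw.formats.get_format("tiff")
        img = ImageMetadata(
            name="rgb", axes=(Axis(X, 4), Axis(Y, 3), Axis(CHANNEL, 3)),
        )
        planes = [random_plane(img, rng) for _ in range(3)]
        path = str(tmp_path / "rgb.tif")
        write_dataset(fmt, path, dataset_for(fmt, img),
                      [(0, p, pl) for p, pl in enumerate(planes)])
        back = gw.open(path)
        assert back.image_metadata(0).axes[2].type == CHANNEL
        for p in range(3):
            assert np.array_equal(back.open_plane(0, p).data, planes[p].data)

    def test_big_endian_reads_identical_to_little_endian(self, gw, tmp_path, rng):
        data = rng.integers(0, 65536, size=20, dtype=np.int64).astype(np.uint16)
        for endian, path in (("<", "le.tif"), (">", "be.tif")):
            page = PageSpec(
                width=5, length=4, bits=(16,), photometric=1,
                data=data.astype(endian + "u2").tobytes(),
            )
            codec.write_tiff(str(tmp_path / path), [page], endian=endian)
        le = gw.open(str(tmp_path / "le.tif")).open_plane(0, 0).data
        be = gw.open(str(tmp_path / "be.tif")).open_plane(0, 0).data
        assert np.array_equal(le, be) and np.array_equal(le, data)

    def test_self_referential_ifd_chain_is_cyclic_error(self, gw, tmp_path):
        path = tmp_path / "cycle.tif"
        path.write_bytes(
            b"II*\0" + struct.pack("<I", 8) + struct.pack("<H", 0) + struct.pack("<I", 8)
        )
        fmt = gw.formats.get_format("tiff")
        with pytest.raises(FormatError) as err:
            fmt.make_parser().parse(SourceRef(str(path)))
        assert "cyclic" in str(err.value)

    def test_compressed_input_names_tag_and_value(self, gw, tmp_path):
        page = PageSpec(
            width=2, length=2, bits=(8,), photometric=1, data=bytes(4), compression=5
        )
        path = str(tmp_path / "lzw.tif")
        codec.write_tiff(path, [page])
        fmt = gw.formats.get_format("tiff")
        with pytest.raises(UnsupportedDialectError) as err:
            fmt.make_parser().parse(SourceRef(path))
        assert "compression=5" in str(err.value)

    def test_three_page_file_maps_pages_to_planes(self, gw, tmp_path):
        pages = [
            PageSpec(width=2, length=2, bits=(8,), photometric=1,
                     data=bytes([p] * 4))
            for p in range(3)
        ]
        path = str(tmp_path / "three.tif")
        codec.write_tiff(path, pages)
        stack = gw.open(path)
        assert stack.plane_count(0) == 3
        assert stack.image_metadata(0).axes[-1].length == 3
        assert [int(stack.open_plane(0, p).data[0]) for p in range(3)] == [0, 1, 2]

    def test_written_tiff_readable_by_tifffile_and_pillow(self, gw, tmp_path, rng):
        import tifffile
        from PIL import Image

        fmt = gw.formats.get_format("tiff")
        img = ImageMetadata(
            name="xv", axes=(Axis(X, 7), Axis(Y, 5), Axis(TIME, 2)),
            pixel_type=PixelType.UINT16,
        )
        planes = [random_plane(img, rng) for _ in range(2)]
        path = str(tmp_path / "xv.tif")
        write_dataset(fmt, path, dataset_for(fmt, img),
                      [(0, p, pl) for p, pl in enumerate(planes)])
        via_tifffile = tifffile.imread(path)
        assert via_tifffile.shape == (2, 5, 7)
        for p in range(2):
            assert np.array_equal(via_tifffile[p].ravel(), planes[p].data)
        with Image.open(path) as im:
            for p in range(2):
                im.seek(p)
                assert np.array_equal(np.asarray(im).ravel(), planes[p].data)


class TestExchange:
    def two_image_meta(self, rng):
        meta = DatasetMetadata("exchange", "exchange")
        meta.images = [
            ImageMetadata(
                name="first",
                axes=(Axis(X, 4, scale=0.25, unit="um"), Axis(Y, 3), Axis(Z, 2)),
                pixel_type=PixelType.UINT16,
                table={"instrument": "scope1"},
            ),
            ImageMetadata(
                name="second",
                axes=(Axis(X, 2), Axis(Y, 2)),
                pixel_type=PixelType.UINT8,
                indexed=True,
                color_table=random_color_table(rng, PixelType.UINT8, components=3),
            ),
        ]
        return meta

    def test_embed_extract_identity(self, rng):
        meta = self.two_image_meta(rng)
        back = extract_xml(embed_xml(meta))
        assert back.image_count == 2
        for a, b in zip(meta.images, back.images):
            assert_baseline_equal(a, b)
            assert a.name == b.name and a.table == b.table
            assert a.planar_axis_count == b.planar_axis_count

    def test_calibration_attribute_survives(self, rng):
        meta = self.two_image_meta(rng)
        back = extract_xml(embed_xml(meta))
        assert back.images[0].axes[0].scale == 0.25
        assert back.images[0].axes[0].unit == "um"

    def test_version_mismatch_rejected(self):
        with pytest.raises(FormatError):
            extract_xml('<ImageSet version="2"/>')
        with pytest.raises(FormatError):
            extract_xml('<NotImages version="1"/>')

    def test_two_image_dataset_write_read(self, gw, tmp_path, rng):
        meta = self.two_image_meta(rng)
        all_planes = [
            (i, p, random_plane(meta.images[i], rng))
            for i in range(2)
            for p in range(meta.images[i].plane_count)
        ]
        path = str(tmp_path / "two.ex.tif")
        write_dataset(EXCHANGE_FORMAT, path, meta, all_planes)
        assert gw.detect(path).name == "exchange"
        back = gw.open(path, fill_channels=False)
        assert back.image_count == 2
        for i in range(2):
            assert_baseline_equal(meta.images[i], back.image_metadata(i))
            assert back.image_metadata(i).table == meta.images[i].table
        for i, p, plane in all_planes:
            assert np.array_equal(back.open_plane(i, p).data, plane.data)

    def test_xml_page_geometry_mismatch_is_format_error(self, gw, tmp_path):
        img = ImageMetadata(name="bad", axes=(Axis(X, 16), Axis(Y, 4)))
        meta = DatasetMetadata("exchange", "exchange")
        meta.images = [img]
        xml = embed_xml(meta)
        page = PageSpec(
            width=32, length=4, bits=(8,), photometric=1,
            data=bytes(32 * 4), description=xml,
        )
        path = str(tmp_path / "bad.ex.tif")
        codec.write_tiff(path, [page])
        fmt = gw.formats.get_format("exchange")
        with pytest.raises(FormatError) as err:
            fmt.make_parser().parse(SourceRef(path))
        assert "16" in str(err.value) and "32" in str(err.value)

    def test_plain_tiff_is_not_claimed_by_exchange_checker(self, gw, tmp_path):
        path = str(tmp_path / "plain.tif")
        gw.convert("p&axes=X,Y&lengths=4,4.sim", path)
        fmt = gw.formats.get_format("exchange")
        assert not fmt.make_checker().is_format(SourceRef(path), open_allowed=True)


class TestCrossFormatConservation:
    def test_pixels_conserved_synthetic_to_sciraw_to_tiff_to_exchange(self, gw, tmp_path):
        spec = "c&axes=X,Y,Z&lengths=9,6,4&pixelType=uint16.sim"
        a = str(tmp_path / "c.sciraw")
        b = str(tmp_path / "c.tif")
        c = str(tmp_path / "c.ex.tif")
        gw.convert(spec, a)
        gw.convert(a, b)
        gw.convert(b, c)
        ref = gw.open(spec)
        out = gw.open(c)
        assert out.plane_count(0) == ref.plane_count(0) == 4
        for p in range(4):
            assert np.array_equal(out.open_plane(0, p).data, ref.open_plane(0, p).data)

    @pytest.mark.parametrize("fmt_name", ["sciraw", "pnm", "tiff", "exchange"])
    def test_randomized_write_read_round_trips(self, gw, tmp_path, rng, fmt_name):
        suffix = {"sciraw": ".sciraw", "pnm": ".pgm", "tiff": ".tif",
                  "exchange": ".ex.tif"}[fmt_name]
        fmt = gw.formats.get_format(fmt_name)
        for pixel_type in WRITABLE_PIXEL_TYPES[fmt_name]:
            for trial in range(4):
                img = random_roundtrip_metadata(fmt_name, pixel_type, rng)
                planes = [random_plane(img, rng) for _ in range(img.plane_count)]
                path = str(tmp_path / f"rt{pixel_type.code}{trial}{suffix}")
                write_dataset(fmt, path, dataset_for(fmt, img),
                              [(0, p, pl) for p, pl in enumerate(planes)])
                assert gw.detect(path).name == fmt_name
                back = gw.open(path, fill_channels=False, stitch=False)
                assert_baseline_equal(
                    img, back.image_metadata(0),
                    calibration=(fmt_name == "exchange"),
                )
                for p in range(img.plane_count):
                    assert np.array_equal(back.open_plane(0, p).data, planes[p].data)
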