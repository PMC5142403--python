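"""Filter chain: patterns, channel filling, stitching, toggling, order."""

import numpy as np
import pytest

from imagefmt import (
    PixelType,
    lookup_color,
    parse_file_pattern,
    write_dataset,
)
from imagefmt.errors import (
    BoundsError,
    FilterLookupError,
    PatternError,
    SourceIOError,
    StitchError,
)
from imagefmt.filters import expand_indexed, stitched_metadata
from imagefmt.model import CHANNEL, TIME, Axis, ImageMetadata, X, Y, Z, full_bounds

from conftest import dataset_for, random_color_table, random_plane


@pytest.fixture
def sciraw_series(gw, tmp_path, rng):
    """Three SCIRAW files of 4 planes each, with distinct random pixels."""
    fmt = gw.formats.get_format("sciraw")
    planes = {}
    for k in range(3):
        img = ImageMetadata(
            name="t", axes=(Axis(X, 6), Axis(Y, 5), Axis(Z, 4))
        )
        file_planes = [random_plane(img, rng) for _ in range(4)]
        planes[k] = file_planes
        write_dataset(
            fmt, str(tmp_path / f"img_{k}.sciraw"), dataset_for(fmt, img),
            [(0, p, pl) for p, pl in enumerate(file_planes)],
        )
    return str(tmp_path / "img_<0-2>.sciraw"), planes


class TestFilePattern:
    def test_basic_grammar(self):
        p = parse_file_pattern("img_<0-2>.sciraw")
        assert (p.prefix, p.suffix, p.start, p.end, p.width) == (
            "img_", ".sciraw", 0, 2, 1,
        )
        assert p.names() == ["img_0.sciraw", "img_1.sciraw", "img_2.sciraw"]

    def test_zero_padding_follows_literal_width(self):
        p = parse_file_pattern("t<08-10>.tif")
        assert p.width == 2
        assert p.names() == ["t08.tif", "t09.tif", "t10.tif"]

    @pytest.mark.parametrize(
        "locator", ["a<3-1>.tif", "plain.tif", "a<0-1>b<0-1>.tif"]
    )
    def test_malformed_patterns_rejected(self, locator):
        with pytest.raises(PatternError):
            parse_file_pattern(locator)


class TestChannelFillerMetadata:
    def test_non_indexed_input_unchanged(self):
        img = ImageMetadata(name="p", axes=(Axis(X, 4), Axis(Y, 4)))
        assert expand_indexed(img) == img

    def test_channel_axis_inserted_first_nonplanar(self, rng):
        img = ImageMetadata(
            axes=(Axis(X, 16), Axis(Y, 16), Axis(Z, 4)),
            indexed=True,
            color_table=random_color_table(rng, PixelType.UINT8, components=3),
        )
        out = expand_indexed(img)
        assert [(a.type.name, a.length) for a in out.axes] == [
            ("X", 16), ("Y", 16), ("CHANNEL", 3), ("Z", 4),
        ]
        assert not out.indexed and out.color_table is None
        assert img.plane_count == 4 and out.plane_count == 12

    def test_existing_length_one_channel_axis_replaced(self, rng):
        img = ImageMetadata(
            axes=(Axis(X, 8), Axis(Y, 8), Axis(CHANNEL, 1), Axis(Z, 2)),
            indexed=True,
            color_table=random_color_table(rng, PixelType.UINT8, components=3),
        )
        out = expand_indexed(img)
        assert [(a.type.name, a.length) for a in out.axes] == [
            ("X", 8), ("Y", 8), ("CHANNEL", 3), ("Z", 2),
        ]


class TestChannelFillerPlanes:
    SPEC = "i&axes=X,Y,Z&lengths=16,16,4&indexed=true.sim"

    def test_filled_planes_equal_per_pixel_table_lookup(self, gw):
        raw = gw.open(self.SPEC, fill_channels=False)
        filled = gw.open(self.SPEC, fill_channels=True)
        table = raw.image_metadata(0).color_table
        c = table.component_count
        assert filled.plane_count(0) == raw.plane_count(0) * c
        for u in range(raw.plane_count(0)):
            indices = raw.open_plane(0, u).data
            for k in range(c):
                expected = np.array(
                    [lookup_color(table, int(v))[k] for v in indices],
                    dtype=indices.dtype,
                )
                got = filled.open_plane(0, u * c + k).data
                assert np.array_equal(got, expected)

    def test_identity_grayscale_table_is_transparent(self, gw):
        spec = "g&axes=X,Y&lengths=8,8&indexed=true&tableComponents=1.sim"
        raw = gw.open(spec, fill_channels=False)
        filled = gw.open(spec, fill_channels=True)
        # synthetic single-component table is (v + 0*17) = v: the identity
        assert np.array_equal(filled.open_plane(0, 0).data, raw.open_plane(0, 0).data)

    def test_disabling_filter_restores_index_planes(self, gw):
        stack = gw.open(self.SPEC)
        assert stack.plane_count(0) == 12
        stack.set_enabled("channel-filler", False)
        assert stack.plane_count(0) == 4
        plane = stack.open_plane(0, 0)
        assert plane.color_table is not None
        stack.set_enabled("channel-filler", True)
        assert stack.plane_count(0) == 12

    def test_unknown_filter_id_is_lookup_error(self, gw):
        stack = gw.open(self.SPEC)
        with pytest.raises(FilterLookupError):
            stack.set_enabled("nope", True)


class TestStitcherMetadata:
    def test_time_axis_appended_when_absent(self):
        img = ImageMetadata(axes=(Axis(X, 16), Axis(Y, 16), Axis(Z, 4)))
        out = stitched_metadata(img, 3)
        assert [(a.type.name, a.length) for a in out.axes] == [
            ("X", 16), ("Y", 16), ("Z", 4), ("TIME", 3),
        ]

    def test_z_then_custom_fallback(self):
        img = ImageMetadata(axes=(Axis(X, 4), Axis(Y, 4), Axis(TIME, 2)))
        assert stitched_metadata(img, 2).axes[-1].type.name == "Z"
        img2 = ImageMetadata(
            axes=(Axis(X, 4), Axis(Y, 4), Axis(Z, 2), Axis(TIME, 2))
        )
        assert stitched_metadata(img2, 2).axes[-1].type.name == "STITCHED"


class TestStitcherPlanes:
    def test_stitched_reads_equal_per_file_reads(self, gw, sciraw_series):
        pattern, planes = sciraw_series
        stack = gw.open(pattern, stitch=True)
        assert stack.plane_count(0) == 12
        assert stack.image_metadata(0).axes[-1].type == TIME
        for i in range(12):
            k, local = divmod(i, 4)
            assert np.array_equal(
                stack.open_plane(0, i).data, planes[k][local].data
            )

    def test_plane_seven_resolves_to_file_one_local_three(self, gw, sciraw_series):
        pattern, planes = sciraw_series
        stack = gw.open(pattern)
        assert np.array_equal(stack.open_plane(0, 7).data, planes[1][3].data)

    def test_single_file_stitch_is_pixel_neutral(self, gw, tmp_path, rng):
        fmt = gw.formats.get_format("sciraw")
        img = ImageMetadata(name="s", axes=(Axis(X, 5), Axis(Y, 4), Axis(Z, 2)))
        file_planes = [random_plane(img, rng) for _ in range(2)]
        write_dataset(
            fmt, str(tmp_path / "solo_0.sciraw"), dataset_for(fmt, img),
            [(0, p, pl) for p, pl in enumerate(file_planes)],
        )
        stack = gw.open(str(tmp_path / "solo_<0-0>.sciraw"))
        assert [(a.type.name, a.length) for a in stack.image_metadata(0).axes] == [
            ("X", 5), ("Y", 4), ("Z", 2), ("TIME", 1),
        ]
        for p in range(2):
            assert np.array_equal(stack.open_plane(0, p).data, file_planes[p].data)

    def test_pixel_type_mismatch_is_stitch_error_naming_field(self, gw, tmp_path, rng):
        fmt = gw.formats.get_format("sciraw")
        for k, pt in enumerate([PixelType.UINT8, PixelType.UINT16]):
            img = ImageMetadata(name="m", axes=(Axis(X, 4), Axis(Y, 4)), pixel_type=pt)
            write_dataset(
                fmt, str(tmp_path / f"mix_{k}.sciraw"), dataset_for(fmt, img),
                [(0, 0, random_plane(img, rng))],
            )
        with pytest.raises(StitchError) as err:
            gw.open(str(tmp_path / "mix_<0-1>.sciraw"))
        assert "pixel_type" in str(err.value)

    def test_missing_file_in_range_is_io_error(self, gw, tmp_path, rng):
        fmt = gw.formats.get_format("sciraw")
        img = ImageMetadata(name="g", axes=(Axis(X, 4), Axis(Y, 4)))
        write_dataset(
            fmt, str(tmp_path / "gap_0.sciraw"), dataset_for(fmt, img),
            [(0, 0, random_plane(img, rng))],
        )
        with pytest.raises(SourceIOError):
            gw.open(str(tmp_path / "gap_<0-1>.sciraw"))

    def test_disabling_stitcher_reads_first_file_only(self, gw, sciraw_series):
        pattern, planes = sciraw_series
        stack = gw.open(pattern, stitch=False)
        assert stack.plane_count(0) == 4
        assert np.array_equal(stack.open_plane(0, 0).data, planes[0][0].data)


class TestStackComposition:
    def test_all_filters_disabled_equals_bare_reader(self, gw, sciraw_series):
        pattern, planes = sciraw_series
        stack = gw.open(pattern, fill_channels=False, stitch=False)
        base = stack.base
        assert stack.metadata == base.metadata
        for p in range(4):
            assert np.array_equal(
                stack.open_plane(0, p).data, base.open_plane(0, p).data
            )

    def test_toggle_twice_is_idempotent(self, gw, sciraw_series):
        pattern, _ = sciraw_series
        stack = gw.open(pattern)
        before = stack.plane_count(0)
        stack.set_enabled("file-stitcher", False)
        stack.set_enabled("file-stitcher", True)
        assert stack.plane_count(0) == before

    def test_channel_filler_applies_outside_stitcher(self, gw, tmp_path, rng):
        """Stitching composes the dataset before channel expansion, so the
        observed axis order is X, Y, CHANNEL, then the stitched TIME axis."""
        fmt = gw.formats.get_format("sciraw")
        table = random_color_table(rng, PixelType.UINT8, components=3)
        for k in range(2):
            img = ImageMetadata(
                name="ix", axes=(Axis(X, 4), Axis(Y, 4)),
                indexed=True, color_table=table,
            )
            write_dataset(
                fmt, str(tmp_path / f"ix_{k}.sciraw"), dataset_for(fmt, img),
                [(0, 0, random_plane(img, rng))],
            )
        stack = gw.open(str(tmp_path / "ix_<0-1>.sciraw"))
        assert [(a.type.name, a.length) for a in stack.image_metadata(0).axes] == [
            ("X", 4), ("Y", 4), ("CHANNEL", 3), ("TIME", 2),
        ]
        assert stack.plane_count(0) == 6
        # plane 4 = component 1 of stitched underlying plane 1 (file 1)
        raw = gw.open(str(tmp_path / "ix_<0-1>.sciraw"), fill_channels=False)
        indices = raw.open_plane(0, 1).data
        expected = table.values[1][indices]
        assert np.array_equal(stack.open_plane(0, 4).data, expected)
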