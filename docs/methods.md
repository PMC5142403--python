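# Methods

This note records the model behind `imagefmt`, the conventions every codec
depends on, the design choices made where the design was genuinely open,
and what the test suite does and does not demonstrate.

## The data model

An image is an ordered list of typed axes. The first `planar_axis_count`
axes (normally X and Y) span a *plane*, the unit of pixel I/O; the
remaining axes are linearized into a plane index. Two ordering conventions
are fixed once, because every reader, writer and filter depends on them:

* **Within a plane** the first planar axis varies fastest: for an X,Y
  plane the sample at `(x, y)` sits at buffer offset `x + nx*y`
  (row-major by y).
* **Across planes** the first non-planar axis varies fastest. For axes
  Z(2), CHANNEL(3), TIME(4) the index is `z + 2*c + 6*t` — the common
  microscopy ZCT-style ordering, expressed without privileging those
  particular axis names.

Coordinates are 0-based; regions are half-open `(offset, extent)` pairs.
Planar axes must be a prefix of the axis list; formats that store data in
another order (e.g. interleaved RGB) reorder at read time. Indexed-color
planes store raw indices and carry their color table; expansion to
components is exclusively the channel-filling filter's job, keeping every
plane single-component.

Pixel types are the eight numpy scalar types uint8…float64. Axis
calibration is a per-sample `scale` (default 1.0, must be positive) and a
free-text `unit` (default empty); no unit algebra is attempted.

## Priorities and resolution

Every plugin — format, translator, filter, service — carries one real
priority; all resolution order in the framework derives from it, with
lexicographic identity as a deterministic tie-break (the tie rule is a
local convention chosen for reproducibility, nothing deeper). Built-in
formats are spaced at multiples of ten (synthetic 50, exchange 40, TIFF
30, SCIRAW 20, PNM 10) so third parties can interleave. The spacing also
encodes a correctness constraint: the exchange container shares TIFF
magic bytes with plain TIFF, so its checker must be polled first —
"most specific format wins" falls out of the ordering rather than special
cases.

Checking is two-phase: with `open_allowed=False` the decision comes from
the locator alone (suffix), so nonexistent sources (the synthetic format)
and cheap batch scans work; with `open_allowed=True` content inspection
may additionally claim a file regardless of its suffix. An unreadable
source is a non-claim, never an exception.

Translator resolution is exact-type and single-fallback: the
highest-priority direct translator for `(source, dest)` wins; otherwise
the two baseline legs are composed. Multi-hop routing beyond the baseline
is deliberately out of scope — the hub-and-spoke topology keeps
resolution O(registered translators) and makes loss accounting exact.
Dropped fields are reported by name (`instrument`, `axes[0].scale`,
`color_table`); parser bookkeeping stored in format-private metadata
(byte offsets, directory handles, keys prefixed `_`) is not a metadata
field and is not reported.

Filters wrap the base reader in ascending priority order, so the
highest-priority filter is outermost: the ChannelFiller (20) operates on
the dataset already composed by the FileStitcher (10). The constants are
this package's choice; what matters and is tested is that the order is
priority-driven and observable (the stitched TIME axis appears after the
inserted CHANNEL axis through the full stack).

## The synthetic format as oracle

The synthetic format stores nothing: the locator encodes name, axes,
lengths, pixel type and indexing, and every sample follows
`(x + y + p) mod 2^min(bits,16)` (float types carry the same value as a
real). Indexed variants use that value as a color index with table
component `k` at index `v` equal to `(v + 17k) mod 2^bits`. Because the
law is closed-form, any pipeline built over the framework can be checked
pixel-for-pixel against an independent computation — this is how the
round-trip, filter and CLI tests obtain expected values without any
stored fixtures.

What synthetic data does *not* emulate: real headers with vendor quirks,
damaged or truncated files beyond the specific corruptions the tests
construct, large images (tests stay at desk scale, ≤ 32×32×8 exhaustive,
≤ 16×16 randomized), compression, and real acquisition metadata.
Passing tests demonstrate the architecture's contracts hold, not that any
particular vendor file decodes.

## Format dialects

* **SCIRAW** — one image per file; text header (`SCIRAW/1.0`, `key: value`
  lines, blank-line terminator) followed by raw little-endian planes. The
  header carries name, axes, planar count, pixel type, indexedness, a
  color-table dump and the open table; it does not carry axis calibration,
  so translation to SCIRAW reports `scale`/`unit` drops. The parser reads
  the header byte-by-byte (no buffered read-ahead), which lets tests
  *prove* parsing never touches the payload region; payload size is
  verified against the file length at parse time.
* **PGM/PPM** — binary P5 (gray, maxval ≤ 65535, 16-bit samples
  big-endian per netpbm) and P6 (RGB, maxval 255). ASCII P2/P3 are
  recognized but refused as an unsupported dialect. RGB is exposed as
  three planes behind a CHANNEL axis — the single RGB convention used
  across PNM, TIFF and channel-filled output.
* **TIFF** — own minimal baseline codec. Read: both byte orders, any
  strip layout, compression 1 only, photometric 0/1/2, chunky planar
  configuration, 8/16-bit gray or 8,8,8 RGB; IFD chains are cycle-checked.
  Write: little-endian, one page per plane, one strip per page,
  rows-per-strip = image length, tags strictly ascending — minimal but
  universally readable, which the suite verifies against tifffile and
  Pillow. Plain TIFF cannot name axes, so a multi-page file reads back
  with a trailing TIME axis; round-trip metadata fidelity therefore holds
  for the canonical shapes X,Y[,CHANNEL(3)][,TIME(n)], and the randomized
  round-trip generator draws from exactly that envelope. Pixel types
  outside uint8/uint16, and indexed color, are writer capability errors
  (the codec reads only unsigned sample format, so signed/palette
  variants are out of dialect).
* **Exchange** — TIFF carrier plus an `<ImageSet version="1">` XML
  document in the first page's ImageDescription (later descriptions are
  ignored, first wins). The XML carries everything the baseline model has
  — axes with calibration, pixel type, color table (base64 of uint32-LE),
  open table, multiple images — so baseline → exchange is lossless.
  Pixels are always gray pages (a CHANNEL axis is just another non-planar
  axis), and the parser cross-checks XML against carrier: planar lengths
  vs page geometry, declared plane count vs page count, pixel bits vs
  page bits, failing with both values named.

## Numerical and degenerate-input choices

Sample buffers are converted to native byte order at the read boundary;
writers serialize through explicit little-/big-endian dtypes, so
round-trip comparisons are bit-exact integer/float equality, never
approximate. Zero-extent regions, out-of-range plane indices and color
indices are bounds errors; malformed headers are format errors naming the
offending field; a writer missing planes at close refuses to finalize
rather than emit a truncated file. Validation of metadata invariants
returns violation descriptions as data (so tools can report them) and is
enforced eagerly only at the writer boundary.

## Scale of the shipped checks

The test suite and `scripts/acceptance.py` run entirely at desk scale on
one CPU: 50 randomized dimension configurations per writable format and
pixel type (~800 write/read round trips), 20 randomized synthetic specs
checked exhaustively against the pixel law, a 32×32×8 exhaustive
channel-filler check, 3×4-plane stitching, 50 randomized raster-arithmetic
axis sets against an enumeration oracle. These sizes were chosen so the
whole suite completes in seconds while still exercising every code path;
the properties verified are size-independent contracts, not asymptotic
claims.

## Known limitations

No compression codecs, BigTIFF, tiled TIFF, or floating-point TIFF; no
physical-units algebra; no multi-hop translator routing; one numeric range
token per file pattern; no streaming writes (writers buffer planes until
close, acceptable at the plane sizes this framework targets); plugin
unloading and hot reload are out of scope. The exchange XML schema is this
package's own; it demonstrates the open-exchange mechanism but is not an
implementation of any established community schema.
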