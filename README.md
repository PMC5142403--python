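# imagefmt

An extensible scientific image format I/O framework for Python.

Scientific imaging has no gold-standard file format: every instrument
family brings its own container, often proprietary, which makes sharing
and re-analysis painful. `imagefmt` addresses this the way the best image
I/O stacks do — not with one monolithic reader, but with an architecture:

* **Formats are decomposed into components.** A `Format` bundles a
  `Checker` (does this source belong to me?), a `Parser` (headers →
  metadata, never touching pixels), its `Metadata`, a `Reader` and an
  optional `Writer`. Writing a new format means implementing only the
  pieces that differ from the defaults.
* **A format-independent baseline.** Every format expresses itself as an
  `ImageMetadata`: ordered typed axes (X, Y, Z, CHANNEL, TIME or custom),
  each with length and physical calibration, a pixel type, indexed-color
  state, and an open key-value table. The unit of pixel I/O is the
  `Plane` — the block spanned by the planar axes (normally X,Y) at one
  position of the remaining axes, which are linearized with the first
  non-planar axis varying fastest.
* **Translators form a hub and spokes.** Metadata converts between
  format-specific schemas through translators resolved by priority; when
  no direct translator exists, the request routes through the baseline.
  Lossy conversions succeed but return a report enumerating every dropped
  field.
* **Filters compose reader behavior.** A priority-ordered, individually
  toggleable chain wraps any reader: the `ChannelFiller` expands
  indexed-color planes through the color table into per-channel planes,
  and the `FileStitcher` presents a numeric filename pattern
  (`img_<0-2>.sciraw`) as one dataset with an appended axis.
* **Everything is a plugin with a numeric priority.** Detection polls
  checkers from the most specific format down; third-party formats are
  discovered through the standard Python entry-point mechanism
  (group `imagefmt.formats`) with no code change to the framework.

Five formats are built in: a zero-storage **synthetic** format whose
pixels follow a closed-form law (the test oracle for everything else),
**SCIRAW** (raw pixels behind a readable text header, carries every pixel
type), **PGM/PPM**, baseline **TIFF** (own codec: both byte orders, any
strip layout, gray/RGB, uncompressed), and an **exchange** container that
stores pixels as baseline TIFF pages and the complete metadata as an XML
document in the first page's ImageDescription — decodable by any
standards-compliant TIFF and XML reader.

## Worked example

```python
import imagefmt

gw = imagefmt.create_gateway()

# a synthetic 16x16x4 stack; nothing is stored on disk
src = "cells&axes=X,Y,Z&lengths=16,16,4.sim"
stack = gw.open(src)
print(stack.image_metadata(0).axes)   # X(16), Y(16), Z(4)
print(stack.plane_count(0))           # 4
print(stack.open_plane(0, 3).data[:5])  # [3 4 5 6 7]  — law (x+y+p) mod 256

# convert to the exchange container and read it back
report = gw.convert(src, "cells.ex.tif")
print(report.lossless)                # True
print(gw.detect("cells.ex.tif").name) # 'exchange'
```

The same operations from the shell:

```sh
$ imagefmt formats
synthetic  priority=50     writer=no  suffixes=.sim
exchange   priority=40     writer=yes suffixes=.ex.tif,.ex.tiff
tiff       priority=30     writer=yes suffixes=.tif,.tiff
sciraw     priority=20     writer=yes suffixes=.sciraw
pnm        priority=10     writer=yes suffixes=.pgm,.ppm,.pnm

$ imagefmt info "cells&axes=X,Y,Z&lengths=16,16,4.sim"
source: cells&axes=X,Y,Z&lengths=16,16,4.sim
format: synthetic
images: 1
image 0: cells
  axis X: length=16
  axis Y: length=16
  axis Z: length=4
  pixel type: uint8
  planes: 4
  indexed: false

$ imagefmt convert "cells&axes=X,Y,Z&lengths=16,16,4.sim" cells.sciraw
wrote cells.sciraw
```

Exit statuses are stable for scripting: 0 success, 1 usage error,
2 format/detection error, 3 I/O error.

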