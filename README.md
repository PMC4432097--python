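# specplot

Static SVG charts for spectroscopy in the life sciences: pre-defined chart
types for mass spectra, 1D/2D NMR, IR and general time series, each following
the field's de-facto layout conventions; extremum-preserving per-pixel binning
so traces with tens of thousands of points render quickly; multi-series
overlays with legends and signal labels; a group-based annotation framework
with key/value tooltips; and an internal MDL Molfile (V2000) parser that draws
2D chemical structures directly into annotation callouts.

It is aimed at people building spectral resources — metabolomics and
proteomics databases, reference-spectrum collections, QC pipelines — who need
publication-clean, deterministic spectrum figures from peak lists or raw
traces without a browser in the loop.

## What it does

**Chart conventions.** Each chart type fixes axis direction, geometry and bin
mode the way its community expects: MS spectra draw impulse (stick) peaks over
an m/z axis with the intensity baseline at 0; 1D NMR draws a line trace with
the chemical-shift (ppm) axis running high-to-low left-to-right; IR draws
transmittance against a reversed wavenumber (cm⁻¹) axis; 2D NMR (HSQC-style)
draws cross peaks as points with both ppm axes reversed.

**Binning.** A trace with *n* points rendered into a plot of width *W* pixels
is reduced, per pixel-width bin, to the single original point with the
extremal intensity: the maximum for upward-peaked data (MS, NMR), the minimum
for IR, whose information lives in absorption valleys. Formally, with view
window [lo, hi) split into B = ⌊W / binwidth⌋ bins of width w = (hi−lo)/B, bin
*i* keeps

    argmax { y_j : lo + i·w ≤ x_j < lo + (i+1)·w }   (max mode; argmin for min mode)

with ties broken toward smaller x and the last bin closed at hi. No point is
invented or averaged, so peak positions stay exact for labels and annotation
lookup. Binning can be disabled or widened per dataset.

**Scales.** Linear and log10 domain→pixel maps with optional direction
reversal, exact endpoint mapping, closed-form inversion, and 1/2/5×10ᵏ
"nice" tick generation.

**Annotations.** A JSON table whose first two columns are a group name and an
x-domain lookup value; further columns are typed (`text`, `tooltip`,
`structure-url`). Annotations bind to the nearest data point in x (within
0.5% of the series extent by default) and render as labels and callout boxes
listing `<key>: <value>` lines; `structure-url` values resolve to molfiles and
are drawn as embedded 2D structures.

**Molfiles.** A fixed-column V2000 parser (counts line, atom/bond blocks,
`M  CHG` charges, `M  END` terminator; V3000 is rejected) and a minimal
skeletal depiction: one line per bond order, labeled heteroatoms with trimmed
bond ends, carbons as bare vertices.

## Worked example

Generate a seeded 60,000-point synthetic 1D NMR trace and render the 3–9 ppm
window:

```sh
specplot fixtures --kind nmr-trace --out-dir demo --seed 7 --n-points 60000
specplot render --type nmr1d --in demo/nmr-trace.json --out demo/nmr.svg \
    --xmin 3 --xmax 9 --legend --labels
```

The log reports what the pipeline did:

```
INFO loaded demo/nmr-trace.json as series series-1 (60000 points)
INFO series series-1: 710 of 60000 points in view
INFO wrote demo/nmr.svg
```

The unnamed series received the computed identifier `series-1`; the 60,000
input points were reduced to 710 — one per pixel of the 710-px-wide plot area
— before drawing. The same numbers are reachable from Python:

```python
from specplot import DataSet, parse_series, make_chart, ChartOptions, resolve_view
from specplot.binning import BinRequest, bin_series

s = parse_series(open("demo/nmr-trace.json").read())
ds = DataSet().add(s)
spec = make_chart("nmr1d")                      # line style, max binning, reversed ppm axis
xw, yw = resolve_view(spec, ChartOptions(x_window=(3.0, 9.0)), ds)
binned = bin_series(s.points, BinRequest(xw, 710, spec.bin_mode))
print(f"view x: {xw}  y: ({yw[0]:.3f}, {yw[1]:.3f})")
print(f"binned to {len(binned)} points")
top = max(binned, key=lambda p: p.y)
print(f"tallest visible signal at {top.x:.2f} ppm, intensity {top.y:.1f}")
```

which prints:

```
view x: (3.0, 9.0)  y: (-13.021, 259.702)
binned to 710 points
tallest visible signal at 3.23 ppm, intensity 247.3
```

The y window was rescaled to the data visible between 3 and 9 ppm (range-zoom
semantics, NMR convention) and padded by 5%. Because binning keeps original
points, the labeled signal at 3.23 ppm is an actual sample of the trace, not a
bin centroid.

Annotated MS charts work the same way; see `specplot render --help` for the
annotation flags and `docs/methods.md` for the full model description.

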