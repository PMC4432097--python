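# Methods

## Scope and model

specplot renders 2D Cartesian spectrum charts to standalone SVG 1.1 text. The
pipeline for every chart is: resolve the view window → build domain→pixel
scales → bin or filter each series against the window → emit geometry, legend,
labels, annotations, axes. All state lives in plain immutable values (a
`DataSet` of `DataSeries`, a `ChartSpec`, `ChartOptions`, a `StyleConfig`);
rendering is a pure function of them, which is what makes byte-identical
output a testable contract rather than an aspiration.

Interactivity is out of scope by design. The behaviours a browser viewer
implements with mouse gestures are mapped to declarative parameters: box/range
zoom becomes an explicit `x_window`/`y_window` (omitting it is the zoom
reset), legend-hover highlighting becomes a `highlight` option that dims the
other series to 30% opacity, and hover tooltips become statically rendered
callout boxes for the selected annotation group.

## Chart-type registry

The five chart types encode spectroscopy display conventions that are nowhere
written as numbers, so they are fixed here explicitly:

- **ms** — impulse sticks from a 0 baseline, m/z ascending, max-binning,
  box-zoom semantics. The 0 baseline is never padded away: resolving a view
  for non-negative MS data pins the lower y bound at 0.
- **nmr1d** — line trace, ppm axis reversed (high field right), max-binning,
  range-zoom semantics: a view window constrains x only and y is recomputed
  over the visible points.
- **nmr2d** — cross peaks as point markers, both ppm axes reversed, never
  binned (binning is defined along x for 1D traces only).
- **ir** — line trace, wavenumber axis reversed, **min**-binning: an IR
  transmittance trace sits near 1 and carries its signal in absorption
  valleys, so keeping per-bin minima preserves the bands. This commits the IR
  chart to transmittance-style display; absorbance data should be rendered as
  `timeseries` or inverted first.
- **timeseries** — line trace, both axes ascending, max-binning.

A derived y window is padded by 5% of the data span on each applicable side
(0.5 absolute when the span is zero), so peaks do not touch the frame.

## Binning

With window [lo, hi) and B bins of width w = (hi−lo)/B, a point x belongs to
bin ⌊(x−lo)/w⌋, clamped so that x = hi joins the last (closed) bin. Per
non-empty bin the original point with extremal y survives — no interpolation,
no averaging — with ties on y broken toward smaller x. Representatives keep
their original coordinates; this preserves exact peak positions for signal
labels and annotation anchoring, at the cost of the drawn trace skipping the
non-extremal envelope (a min–max dual envelope is deliberately not offered).

Consequences relied on by tests: the output is a subset of the input; the
global extremum inside the window always survives; the operation is
idempotent under a fixed request. The implementation vectorizes with
numpy (`lexsort` + `unique`); the test oracle re-derives every bin by
explicit boundary bisection and a linear scan, so agreement between the two
is meaningful. Binning runs against the rendered view window (not the full
extent), matching what a zoomed re-render needs.

Default bin width is one pixel — enough horizontal resolution to show the
shape of a trace. The chart type dictates min vs max; user configuration can
only disable binning or widen the bins.

## Scales and ticks

Linear and log10 scales map a domain interval onto a pixel interval with an
optional direction flip; reversal is also how the SVG y-down convention is
absorbed (an un-reversed data axis gets a flipped pixel range, so intensity
grows upward). Values outside the domain extrapolate; clipping is the
renderer's job, done by clamping emitted coordinates to the plot rectangle.
Endpoints map exactly; inversion is closed-form and round-trips to better
than 1e-9 relative error. Ticks are multiples of 1/2/5×10ᵏ chosen so the
count lands in [target/2, 2·target], preferring the step whose count is
nearest target+1; log scales use decade ticks, falling back to linear ticks
when the domain spans fewer than two decades. Only base-10 logarithms are
offered.

## Signal labels

Label candidates are strict local maxima (both neighbours strictly lower;
endpoints qualify against their single neighbour). Up to `max_signal_labels`
(default 10) are taken greedily by descending intensity, ties toward smaller
x, with a minimum x separation of 2% of the view window so labels do not
stack on a single multiplet. The label text is the peak's x value formatted
to the chart type's precision (m/z and ppm: 2 decimals; wavenumber: 0).

## Annotations

Annotation rows are column-ordered JSON lists `[group, x_lookup, payload...]`;
the payload schema (ordered names and kinds) is supplied separately, mirroring
a data-handler that is told the file structure before loading. Groups
partition rows in file order; one group is rendered per chart. Anchoring binds
each annotation to the series point minimizing |x − x_lookup| (bisection on
the sorted x values; ties toward smaller x) and accepts the match only within
a relative tolerance, default 0.5% of the series x extent — wide enough for
rounded lookup values like "113.00", narrow enough not to grab a neighbouring
peak. Unmatched annotations are logged and reported, never fatal. Annotations
bind to the first-loaded series of an overlay.

Tooltip columns render as `<key>: <value>` lines in a callout; `structure-url`
values pass through a pluggable resolver (default: local filesystem relative
to the annotation file) into the molfile parser and are drawn inside the
callout. A resolver or parse failure degrades to a placeholder line for that
column only.

## Molfile parsing and depiction

The V2000 reader is strict about structure and tolerant about content: fixed
columns for the counts line (atoms 1–3, bonds 4–6), atom block (x/y/z in
10-column fields, element in columns 32–34) and bond block; the z coordinate
is parsed and ignored; formal charges come from `M  CHG` property lines
(default 0 — the legacy atom-block charge column is ignored, as property-block
values supersede it in the format); parsing fails loudly on count/block
mismatch, out-of-range bond indices, a missing `M  END`, or a V3000 tag.
Stereo wedges, isotopes and S-groups are ignored territory.

Depiction normalizes coordinates — translate to the bounding-box origin,
scale uniformly to fit the target square with 10% padding, center the short
axis — so the drawing is invariant under translation and uniform scaling of
the input. Bond orders 1/2/3 draw as 1/2/3 parallel lines; the aromatic code
4 draws as a solid line plus an inner dashed parallel rather than attempting
kekulization, keeping rendering total on any parseable file. Heteroatoms and
charged atoms get centered labels with bond ends trimmed by a label radius
(capped at a third of the bond length so short bonds never invert); carbons
are bare vertices; implicit hydrogens are not drawn. Molecules whose atoms
all coincide (e.g. a molfile written without 2D coordinates) raise a
degenerate-geometry error: coordinate generation is a separate discipline
this package does not attempt.

## Input formats and determinism

Series JSON accepts a pair-list (`"points": [[x,y],...]`) or parallel arrays
(`"x"/"y"`, plus `"value"` for 2D point sets); both are one documented
canonical dialect chosen for testability. Points are sorted ascending by x on
ingestion. Unnamed series get computed identifiers `series-<k>` from a
per-dataset counter, deterministic in add order. Remote fetching is replaced
by local files plus a pluggable resolver hook; the library is offline.

Rendered output is byte-identical for identical inputs: coordinates are
formatted to 2 decimals, element order is fixed (background, series, labels,
legend, annotations, axes last), and text extents are estimated at 0.6 em per
character rather than measured from glyph metrics — golden files are
therefore only comparable against this implementation's own output.

## Synthetic data

The fixture generator emulates the gross shape of each instrument's output:
exponential-intensity centroided MS peak lists over m/z 50–500 with one
dominant base peak (an MS² fragmentation pattern); 60,000-point 1D NMR traces
over 0–10 ppm as sums of 12 Lorentzian lines (linewidths 0.004–0.02 ppm,
log-normal amplitudes) over a small Gaussian noise floor — the size regime
where per-pixel binning is the difference between a usable and an unusable
chart; IR transmittance over 400–4000 cm⁻¹ as a baseline near 0.98 minus
Gaussian absorption bands; HSQC-style cross-peak sets (¹H 0.5–9.5 ppm vs ¹³C
10–160 ppm); and hand-authored molfiles (ethanol, benzene, a uracil-like
pyrimidinedione ring, methane) plus deliberately corrupted variants.

What the generator does **not** emulate: phase and baseline artefacts,
solvent peaks, multiplet fine structure, isotope patterns, detector
saturation, or correlated noise. Passing tests therefore demonstrate the
geometry, reduction and bookkeeping contracts on realistically sized and
shaped data — not robustness to every artefact of real instrument output.

Test corpora sample series lengths log-uniformly over 1–100,000 points so
both tiny and large traces are covered at bounded runtime; the acceptance
checks use 1,000 such series (~9 million points).

## Numerical choices and edge cases

- Bin assignment uses floor division; a point mathematically on a bin
  boundary follows IEEE-754 evaluation of ⌊(x−lo)/w⌋, and the oracle's
  boundary-bisection route agrees on all tested corpora.
- Extents of an empty dataset are `None`; rendering one yields frame and axes
  over a unit window. A single-x series pads its window by ±0.5.
- Degenerate pixel ranges make `invert` fail rather than return garbage.
- Zero-area plot regions (margins ≥ canvas) raise a layout error before any
  geometry is attempted; the CLI never writes partial output.

## Known limitations

- No interactive output; no CSS restyling hooks in the emitted SVG.
- 1D annotation lookup only (no (x,y)-keyed annotations for 2D NMR).
- No mzML/JCAMP-DX readers; ingestion is the documented JSON dialect.
- Aromatic rings without explicit alternating bond orders display the
  dashed-parallel convention, not a kekulized ring.
- Estimated text metrics mean long labels can overflow their callout box in
  renderers whose fonts differ substantially from the 0.6 em/char estimate.
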