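"""Deterministic SVG assembly: frame, axes, series geometry, legend, callouts.

The output is a standalone SVG 1.1 document.  Determinism is a contract:
identical inputs must produce byte-identical text, so every coordinate is
formatted with fixed precision and elements are emitted in a fixed order —
background, series, signal labels, legend, annotations, axes last.

SVG's y axis points down; the y scale is built with its pixel range flipped so
intensity grows upward on screen.  Series geometry is clipped to the plot
rectangle by clamping pixel coordinates (points outside the x window are
already dropped by binning/filtering).
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Callable, Optional

from .annotations import AnnotationSet, AnchoredAnnotation, anchor, build_tooltip
from .binning import BinRequest, bin_series
from .charts import ChartOptions, ChartSpec, pick_signal_labels, resolve_view
from .datamodel import DataSeries, DataSet, Point
from .errors import LayoutError
from .molfile import depict
from .scales import Scale, ticks

__all__ = ["StyleConfig", "render_chart", "render_annotations"]

log = logging.getLogger("specplot")

# ColorBrewer Dark2: 8 distinguishable hues, assigned in series add order
_COLOR_CYCLE = (
    "#1b9e77", "#d95f02", "#7570b3", "#e7298a",
    "#66a61e", "#e6ab02", "#a6761d", "#666666",
)


@dataclass(frozen=True)
class StyleConfig:
    """Static styling, standing in for a user stylesheet."""

    font_family: str = "sans-serif"
    font_size: float = 11.0
    title_size: float = 14.0
    axis_color: str = "#333333"
    stroke_width: float = 1.0
    color_cycle: tuple = _COLOR_CYCLE
    background: str = "#ffffff"
    dim_opacity: float = 0.3  # non-highlighted series opacity
    point_radius: float = 2.5
    char_width_em: float = 0.6  # estimated glyph advance, em per character


def _fmt(v: float) -> str:
    return f"{v:.2f}"


def _clamp(v: float, lo: float, hi: float) -> float:
    return lo if v < lo else hi if v > hi else v


def _text(parent, x, y, s, style: StyleConfig, size=None, anchor_="start", color=None, **extra):
    t = ET.SubElement(
        parent,
        "text",
        {
            "x": _fmt(x),
            "y": _fmt(y),
            "font-family": style.font_family,
            "font-size": _fmt(size or style.font_size),
            "text-anchor": anchor_,
            "fill": color or style.axis_color,
            **extra,
        },
    )
    t.text = s
    return t


def _visible_points(series: DataSeries, xw, yw, is_2d: bool):
    if is_2d:
        return [p for p in series.points if xw[0] <= p.x <= xw[1] and yw[0] <= p.y <= yw[1]]
    return [p for p in series.points if xw[0] <= p.x <= xw[1]]


def render_chart(
    spec: ChartSpec,
    options: ChartOptions,
    ds: DataSet,
    ann: Optional[AnnotationSet] = None,
    style: Optional[StyleConfig] = None,
    ann_group: Optional[str] = None,
    ann_schema=None,
    resolver: Optional[Callable[[str], str]] = None,
) -> str:
    """Render a dataset to SVG text.

    Pipeline: resolve the view window, build scales, bin each series per the
    chart's bin mode, then emit geometry per render style (impulse: a vertical
    line per peak from the y baseline; line: one polyline per series; point:
    one circle per point), plus title, legend, signal labels, annotation
    callouts and axes.  An empty dataset yields frame and axes only.
    """
    style = style or StyleConfig()
    mt, mr, mb, ml = options.margins
    plot_w = options.width_px - ml - mr
    plot_h = options.height_px - mt - mb
    if plot_w <= 0 or plot_h <= 0:
        raise LayoutError(
            f"margins {options.margins} leave no plot area in "
            f"{options.width_px}x{options.height_px}px"
        )

    xw, yw = resolve_view(spec, options, ds)
    xscale = Scale("linear", xw, (ml, ml + plot_w), reversed=spec.x_reversed)
    # SVG y grows downward: an un-reversed data axis needs a flipped pixel map
    yscale = Scale("linear", yw, (mt, mt + plot_h), reversed=not spec.y_reversed)

    # bin / filter each series against the view window
    prepared: list[tuple[DataSeries, list[Point]]] = []
    n_bins = int(plot_w) // ds.bin_config.binwidth_px
    for s in ds.series:
        if s.is_2d or spec.bin_mode == "none" or not ds.bin_config.enabled:
            pts = _visible_points(s, xw, yw, s.is_2d and spec.type_id == "nmr2d")
        else:
            pts = bin_series(s.points, BinRequest(xw, max(n_bins, 1), spec.bin_mode))
        prepared.append((s, pts))
        log.info("series %s: %d of %d points in view", s.name, len(pts), len(s.points))

    root = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "version": "1.1",
            "width": str(options.width_px),
            "height": str(options.height_px),
            "viewBox": f"0 0 {options.width_px} {options.height_px}",
        },
    )
    ET.SubElement(
        root,
        "rect",
        {
            "x": "0",
            "y": "0",
            "width": str(options.width_px),
            "height": str(options.height_px),
            "fill": style.background,
        },
    )

    x0, x1 = ml, ml + plot_w
    y0, y1 = mt, mt + plot_h

    def cx(v: float) -> float:
        return _clamp(xscale.apply(v), x0, x1)

    def cy(v: float) -> float:
        return _clamp(yscale.apply(v), y0, y1)

    # --- series geometry ---------------------------------------------------
    series_root = ET.SubElement(root, "g", {"class": "series-root"})
    baseline_px = cy(0.0)
    for i, (s, pts) in enumerate(prepared):
        color = s.color or style.color_cycle[i % len(style.color_cycle)]
        attrs = {"id": f"series--{s.name}", "class": "series", "stroke": color}
        if options.highlight is not None and s.name != options.highlight:
            attrs["opacity"] = _fmt(style.dim_opacity)
        g = ET.SubElement(series_root, "g", attrs)
        if spec.render_style == "impulse":
            for p in pts:
                px = cx(p.x)
                ET.SubElement(
                    g,
                    "line",
                    {
                        "x1": _fmt(px),
                        "y1": _fmt(baseline_px),
                        "x2": _fmt(px),
                        "y2": _fmt(cy(p.y)),
                        "stroke-width": _fmt(style.stroke_width),
                    },
                )
        elif spec.render_style == "line":
            if pts:
                coords = " ".join(f"{_fmt(cx(p.x))},{_fmt(cy(p.y))}" for p in pts)
                ET.SubElement(
                    g,
                    "polyline",
                    {
                        "points": coords,
                        "fill": "none",
                        "stroke-width": _fmt(style.stroke_width),
                    },
                )
        else:  # point markers
            for p in pts:
                ET.SubElement(
                    g,
                    "circle",
                    {
                        "cx": _fmt(cx(p.x)),
                        "cy": _fmt(cy(p.y)),
                        "r": _fmt(style.point_radius),
                        "fill": color,
                        "stroke": "none",
                    },
                )

    # --- signal labels ------------------------------------------------------
    if options.signal_labels:
        lg = ET.SubElement(root, "g", {"class": "signal-labels"})
        for s, pts in prepared:
            if s.is_2d:
                continue
            for p in pick_signal_labels(pts, options.max_signal_labels, xw):
                _text(
                    lg,
                    cx(p.x),
                    _clamp(cy(p.y) - 4, y0 + style.font_size, y1),
                    f"{p.x:.{spec.label_precision}f}",
                    style,
                    size=style.font_size - 1,
                    anchor_="middle",
                )

    # --- legend -------------------------------------------------------------
    if options.legend and prepared:
        legend = ET.SubElement(root, "g", {"class": "legend"})
        longest = max(len(s.name or "") for s, _ in prepared)
        box_w = 24 + longest * style.char_width_em * style.font_size
        row_h = style.font_size + 6
        lx = x1 - box_w - 6
        ly = y0 + 6
        ET.SubElement(
            legend,
            "rect",
            {
                "x": _fmt(lx),
                "y": _fmt(ly),
                "width": _fmt(box_w),
                "height": _fmt(row_h * len(prepared) + 6),
                "fill": style.background,
                "stroke": style.axis_color,
                "stroke-width": "0.5",
            },
        )
        for i, (s, _) in enumerate(prepared):
            color = s.color or style.color_cycle[i % len(style.color_cycle)]
            yy = ly + 6 + row_h * i + style.font_size / 2
            entry = ET.SubElement(legend, "g", {"class": "legend-entry"})
            ET.SubElement(
                entry,
                "line",
                {
                    "x1": _fmt(lx + 4),
                    "y1": _fmt(yy),
                    "x2": _fmt(lx + 16),
                    "y2": _fmt(yy),
                    "stroke": color,
                    "stroke-width": "2.00",
                },
            )
            _text(entry, lx + 20, yy + style.font_size * 0.35, s.name or "", style)

    # --- annotations ----------------------------------------------------------
    if ann is not None and ann_group is not None and ann_schema is not None and prepared:
        target = prepared[0][0]  # annotations bind to the first (primary) series
        anchored, unmatched = anchor(ann, ann_group, target)
        for u in unmatched:
            log.info("annotation at x=%s in group %s unmatched", u.x_lookup, u.group)
        frag = render_annotations(
            anchored, xscale, yscale, style, spec,
            plot_rect=(x0, y0, x1, y1), schema=ann_schema, resolver=resolver,
        )
        root.append(frag)

    # --- axes (last, over everything) ----------------------------------------
    axes = ET.SubElement(root, "g", {"class": "axes"})
    ET.SubElement(
        axes,
        "line",
        {"x1": _fmt(x0), "y1": _fmt(y1), "x2": _fmt(x1), "y2": _fmt(y1),
         "stroke": style.axis_color, "stroke-width": "1.00"},
    )
    ET.SubElement(
        axes,
        "line",
        {"x1": _fmt(x0), "y1": _fmt(y0), "x2": _fmt(x0), "y2": _fmt(y1),
         "stroke": style.axis_color, "stroke-width": "1.00"},
    )
    for v, label in ticks(xscale, 8):
        px = xscale.apply(v)
        ET.SubElement(
            axes,
            "line",
            {"x1": _fmt(px), "y1": _fmt(y1), "x2": _fmt(px), "y2": _fmt(y1 + 5),
             "stroke": style.axis_color, "stroke-width": "1.00"},
        )
        _text(axes, px, y1 + 6 + style.font_size, label, style, anchor_="middle")
    for v, label in ticks(yscale, 5):
        py = yscale.apply(v)
        ET.SubElement(
            axes,
            "line",
            {"x1": _fmt(x0 - 5), "y1": _fmt(py), "x2": _fmt(x0), "y2": _fmt(py),
             "stroke": style.axis_color, "stroke-width": "1.00"},
        )
        _text(axes, x0 - 8, py + style.font_size * 0.35, label, style, anchor_="end")
    _text(
        axes, (x0 + x1) / 2, options.height_px - 8,
        options.x_label if options.x_label is not None else spec.x_label_default,
        style, anchor_="middle",
    )
    ylab = _text(
        axes, 0, 0,
        options.y_label if options.y_label is not None else spec.y_label_default,
        style, anchor_="middle",
    )
    ylab.set("transform", f"translate({_fmt(14)},{_fmt((y0 + y1) / 2)}) rotate(-90)")
    ylab.set("x", "0")
    ylab.set("y", "0")
    if options.title:
        _text(
            axes, (x0 + x1) / 2, mt / 2 + style.title_size / 2, options.title,
            style, size=style.title_size, anchor_="middle",
        )

    return (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        + ET.tostring(root, encoding="unicode")
        + "\n"
    )


def render_annotations(
    anchored: list[AnchoredAnnotation],
    xscale: Scale,
    yscale: Scale,
    style: StyleConfig,
    spec: ChartSpec,
    plot_rect: tuple[float, float, float, float],
    schema,
    resolver: Optional[Callable[[str], str]] = None,
) -> ET.Element:
    """Render anchored annotations as an SVG fragment.

    Text labels sit above-right of the anchor; tooltip/structure payloads
    become a callout box listing ``<key>: <value>`` lines with any molecule
    drawing embedded beneath.  Anchors outside the view window are skipped.
    """
    x0, y0, x1, y1 = plot_rect
    g = ET.Element("g", {"class": "annotations"})
    d0, d1 = xscale.domain
    mol_size = 90
    for aa in anchored:
        p = aa.point
        if not (d0 <= p.x <= d1):
            log.info("annotation anchor x=%s outside view window, skipped", p.x)
            continue
        px = _clamp(xscale.apply(p.x), x0, x1)
        py = _clamp(yscale.apply(p.y), y0, y1)
        item = ET.SubElement(g, "g", {"class": "annotation"})
        content = build_tooltip(aa.annotation, schema, resolver)
        # marker + text labels beside the point
        ET.SubElement(
            item,
            "circle",
            {"cx": _fmt(px), "cy": _fmt(py), "r": "3.00",
             "fill": "none", "stroke": style.axis_color, "stroke-width": "1.00"},
        )
        for k, label in enumerate(content.text_labels):
            _text(item, px + 6, py - 6 - k * (style.font_size + 2), label, style)
        # callout box for tooltip lines / structures
        callout_lines = content.lines
        if callout_lines or content.molecules:
            box_w = max(
                [style.char_width_em * style.font_size * len(s) for s in callout_lines]
                + ([mol_size] if content.molecules else [0])
            ) + 12
            box_h = 8 + (style.font_size + 4) * len(callout_lines) + (
                (mol_size + 6) * len(content.molecules)
            )
            bx = _clamp(px + 10, x0, max(x0, x1 - box_w))
            by = _clamp(py - box_h - 10, y0, max(y0, y1 - box_h))
            callout = ET.SubElement(item, "g", {"class": "callout"})
            ET.SubElement(
                callout,
                "rect",
                {"x": _fmt(bx), "y": _fmt(by), "width": _fmt(box_w), "height": _fmt(box_h),
                 "fill": "#fffff2", "stroke": style.axis_color, "stroke-width": "0.75"},
            )
            yy = by + 4 + style.font_size
            for line in callout_lines:
                _text(callout, bx + 6, yy, line, style)
                yy += style.font_size + 4
            for _, mol in content.molecules:
                mg = depict(mol, mol_size)
                mg.set("transform", f"translate({_fmt(bx + 6)},{_fmt(yy - style.font_size)})")
                callout.append(mg)
                yy += mol_size + 6
    return g
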