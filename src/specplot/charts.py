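"""Chart-type registry and view resolution.

Each spectroscopy has a de-facto layout standard and the registry encodes it:

======== ======== ========= ========== ============ =========================
type     style    bin mode  zoom       x direction  y direction
======== ======== ========= ========== ============ =========================
ms       impulse  max       box        ascending    ascending from 0 baseline
nmr1d    line     max       range      REVERSED     ascending
nmr2d    point    none      box        REVERSED     REVERSED
ir       line     min       box        REVERSED     ascending (transmittance)
timeseries line   max       box        ascending    ascending
======== ======== ========= ========== ============ =========================

NMR chemical shift (ppm) and IR wavenumber (cm^-1) axes run high-to-low
left-to-right by universal convention.  IR traces are binned by minimum
because transmittance signal lives in absorption valleys.

Interactive zooming becomes declarative here: a view window passed in
:class:`ChartOptions` restricts the axes; omitting it is the zoom reset.
Range-zoom chart types (1D NMR) take an x-window only and rescale y to the
visible data; box-zoom types accept independent x and y windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import Literal, Optional, Sequence

from .datamodel import DataSet, Point

__all__ = [
    "ChartSpec",
    "ChartOptions",
    "CHART_TYPES",
    "make_chart",
    "resolve_view",
    "pick_signal_labels",
]

ChartTypeId = Literal["ms", "nmr1d", "nmr2d", "ir", "timeseries"]


@dataclass(frozen=True)
class ChartSpec:
    type_id: str
    x_reversed: bool
    y_reversed: bool
    render_style: Literal["impulse", "line", "point"]
    bin_mode: Literal["min", "max", "none"]
    zoom_semantics: Literal["box", "range"]
    x_label_default: str
    y_label_default: str
    label_precision: int = 2  # decimals on tick and signal labels


_REGISTRY = {
    "ms": ChartSpec(
        "ms", False, False, "impulse", "max", "box", "m/z", "intensity", 2
    ),
    "nmr1d": ChartSpec(
        "nmr1d", True, False, "line", "max", "range", "chemical shift / ppm", "intensity", 2
    ),
    "nmr2d": ChartSpec(
        "nmr2d", True, True, "point", "none", "box", "F2 / ppm", "F1 / ppm", 2
    ),
    "ir": ChartSpec(
        "ir", True, False, "line", "min", "box", "wavenumber / cm-1", "transmittance", 0
    ),
    "timeseries": ChartSpec(
        "timeseries", False, False, "line", "max", "box", "time", "amplitude", 2
    ),
}
CHART_TYPES = MappingProxyType(_REGISTRY)


def make_chart(type_id: str) -> ChartSpec:
    """Look up the chart spec for a type; the registry is total and immutable."""
    try:
        return CHART_TYPES[type_id]
    except KeyError:
        raise ValueError(
            f"unknown chart type {type_id!r}; choose from {sorted(CHART_TYPES)}"
        ) from None


@dataclass(frozen=True)
class ChartOptions:
    """Per-render options, cascading over the chart-type defaults."""

    title: str = ""
    x_label: Optional[str] = None  # None -> chart-type default
    y_label: Optional[str] = None
    legend: bool = False
    margins: tuple[float, float, float, float] = (40.0, 30.0, 50.0, 60.0)  # t r b l
    signal_labels: bool = False
    max_signal_labels: int = 10
    width_px: int = 800
    height_px: int = 400
    x_window: Optional[tuple[float, float]] = None
    y_window: Optional[tuple[float, float]] = None
    highlight: Optional[str] = None

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("width_px and height_px must be positive")
        if any(m < 0 for m in self.margins):
            raise ValueError("margins must be non-negative")


_PAD = 0.05  # fractional y padding when the window is derived from data


def _padded_y(lo: float, hi: float, type_id: str) -> tuple[float, float]:
    span = hi - lo
    pad = _PAD * span if span > 0 else 0.5
    y0, y1 = lo - pad, hi + pad
    if type_id == "ms" and lo >= 0:
        y0 = 0.0  # impulse baseline: never pad the 0 away
    return y0, y1


def _visible_y(ds: DataSet, xw: tuple[float, float]) -> Optional[tuple[float, float]]:
    lo = hi = None
    for s in ds.series:
        for p in s.points:
            if xw[0] <= p.x <= xw[1]:
                lo = p.y if lo is None else min(lo, p.y)
                hi = p.y if hi is None else max(hi, p.y)
    return None if lo is None else (lo, hi)


def resolve_view(
    spec: ChartSpec, options: ChartOptions, ds: DataSet
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Resolve the rendered (x_window, y_window).

    No window -> full data extents, y padded 5% (the 0 baseline is kept for
    MS impulses).  Range-zoom types take an x window only; y is rescaled to
    the points visible in it.  Box-zoom types accept explicit x and y windows.
    An empty dataset resolves to the unit square so axes can still be drawn.
    """
    for w in (options.x_window, options.y_window):
        if w is not None and not (w[0] < w[1]):
            raise ValueError(f"view window must satisfy lo < hi, got {w}")
    if options.y_window is not None and spec.zoom_semantics == "range":
        raise ValueError(f"chart type {spec.type_id!r} is range-zoom: only an x window is accepted")

    xext, yext = ds.x_extent, ds.y_extent
    if xext is None:  # empty dataset
        return options.x_window or (0.0, 1.0), options.y_window or (0.0, 1.0)

    xw = options.x_window or (
        xext if xext[0] < xext[1] else (xext[0] - 0.5, xext[1] + 0.5)
    )
    if options.y_window is not None:
        yw = options.y_window
    else:
        if options.x_window is not None:
            vis = _visible_y(ds, xw)
            base = vis if vis is not None else yext
        else:
            base = yext
        yw = _padded_y(base[0], base[1], spec.type_id)
    return xw, yw


def pick_signal_labels(
    points: Sequence[Point],
    max_labels: int,
    x_window: Optional[tuple[float, float]] = None,
    min_sep_frac: float = 0.02,
) -> list[Point]:
    """Select up to ``max_labels`` prominent peaks to label.

    Candidates are strict local maxima (an interior point both of whose
    neighbours are strictly lower; an endpoint whose single neighbour is
    strictly lower; a lone point).  They are taken greedily by descending y —
    ties toward smaller x — subject to a minimum x separation of
    ``min_sep_frac`` of the window width.
    """
    if max_labels < 1:
        raise ValueError("max_labels must be >= 1")
    n = len(points)
    if n == 0:
        return []
    candidates = []
    for i, p in enumerate(points):
        left_lower = i == 0 or points[i - 1].y < p.y
        right_lower = i == n - 1 or points[i + 1].y < p.y
        if left_lower and right_lower:
            candidates.append(p)
    if x_window is None:
        x_window = (points[0].x, points[-1].x)
    min_sep = min_sep_frac * (x_window[1] - x_window[0])
    candidates.sort(key=lambda p: (-p.y, p.x))
    chosen: list[Point] = []
    for p in candidates:
        if len(chosen) >= max_labels:
            break
        if all(abs(p.x - q.x) >= min_sep for q in chosen):
            chosen.append(p)
    chosen.sort(key=lambda p: p.x)
    return chosen
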