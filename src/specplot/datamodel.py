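"""Series and dataset containers plus JSON ingestion.

The data handler pattern: a :class:`DataSet` owns every series bound to a
chart, keeps track of join extents, assigns computed identifiers to unnamed
series, and mediates all add/remove traffic.  A chart is bound to exactly one
dataset.

JSON schema
-----------
A series file is one JSON object in either of two equivalent forms::

    {"name": "spec-a", "points": [[x1, y1], [x2, y2], ...]}
    {"name": "spec-a", "x": [x1, x2, ...], "y": [y1, y2, ...]}

``name`` and ``color`` are optional.  For 2D point sets (``kind="points2d"``)
each point may carry a third element, the intensity::

    {"points": [[x1, y1, v1], ...]}       or parallel  {"x": [...], "y": [...], "value": [...]}

Points are sorted ascending by x on ingestion; the original file order is not
preserved (line rendering and binning require monotone x).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence

from .errors import ParseError, SchemaError, SeriesConflictError, SeriesNotFoundError

__all__ = [
    "Point",
    "Point2D",
    "DataSeries",
    "BinConfig",
    "DataSet",
    "parse_series",
    "serialize_series",
]

SeriesKind = Literal["peaks", "trace", "points2d"]


@dataclass(frozen=True)
class Point:
    """One x/y sample: x in domain units (m/z, ppm, cm^-1, time), y intensity."""

    x: float
    y: float


@dataclass(frozen=True)
class Point2D:
    """A 2D-NMR cross peak: x (F2, ppm), y (F1, ppm), optional intensity."""

    x: float
    y: float
    value: Optional[float] = None


@dataclass(frozen=True)
class DataSeries:
    """One named spectrum or trace; points are sorted ascending by x."""

    points: tuple
    name: Optional[str] = None
    color: Optional[str] = None
    kind: SeriesKind = "trace"

    @property
    def is_2d(self) -> bool:
        return self.kind == "points2d"

    def x_values(self) -> list[float]:
        return [p.x for p in self.points]

    def extents(self) -> tuple[Optional[tuple[float, float]], Optional[tuple[float, float]]]:
        """(x_extent, y_extent) of this series alone; (None, None) if empty."""
        if not self.points:
            return None, None
        xs = [p.x for p in self.points]
        ys = [p.y for p in self.points]
        return (min(xs), max(xs)), (min(ys), max(ys))


@dataclass(frozen=True)
class BinConfig:
    """User-tunable binning switches.

    The bin *mode* (min vs max) is dictated by the chart type, not here; users
    may only enable/disable binning and set the bin width in pixels.
    """

    enabled: bool = True
    binwidth_px: int = 1

    def __post_init__(self) -> None:
        if self.binwidth_px < 1:
            raise ValueError(f"binwidth_px must be >= 1, got {self.binwidth_px}")


def _check_finite(x: float, y: float, index: int) -> None:
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError(f"non-finite value at point index {index}: ({x!r}, {y!r})")


def _coerce_real(v, index: int) -> float:
    if isinstance(v, bool) or not isinstance(v, (int, float)):
        raise SchemaError(f"non-numeric value at point index {index}: {v!r}")
    return float(v)


def parse_series(json_text: str, kind: SeriesKind = "trace") -> DataSeries:
    """Parse one series from JSON text.

    Accepts the pair-list form (``"points"``) or the parallel-array form
    (``"x"``/``"y"``, plus ``"value"`` for 2D point sets).  Raises
    :class:`ParseError` with the byte offset for malformed JSON,
    :class:`SchemaError` for ragged arrays or wrong shapes, and
    ``ValueError`` naming the point index for non-finite values.
    """
    if kind not in ("peaks", "trace", "points2d"):
        raise ValueError(f"unknown series kind: {kind!r}")
    try:
        obj = json.loads(json_text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed JSON at byte offset {exc.pos}: {exc.msg}") from exc
    if not isinstance(obj, dict):
        raise SchemaError("series JSON must be an object")

    name = obj.get("name")
    if name is not None and not isinstance(name, str):
        raise SchemaError("'name' must be a string when present")
    color = obj.get("color")
    if color is not None and not isinstance(color, str):
        raise SchemaError("'color' must be a string when present")

    want_value = kind == "points2d"
    rows: list[tuple] = []
    if "points" in obj:
        pts = obj["points"]
        if not isinstance(pts, list):
            raise SchemaError("'points' must be a list of [x, y] pairs")
        for i, row in enumerate(pts):
            if not isinstance(row, list) or len(row) not in ((2, 3) if want_value else (2,)):
                raise SchemaError(
                    f"point {i} must be a pair [x, y]"
                    + (" or triple [x, y, value]" if want_value else "")
                )
            x = _coerce_real(row[0], i)
            y = _coerce_real(row[1], i)
            _check_finite(x, y, i)
            v = None
            if want_value and len(row) == 3 and row[2] is not None:
                v = _coerce_real(row[2], i)
            rows.append((x, y, v))
    elif "x" in obj or "y" in obj:
        xs = obj.get("x")
        ys = obj.get("y")
        if not isinstance(xs, list) or not isinstance(ys, list):
            raise SchemaError("parallel-array form requires both 'x' and 'y' lists")
        if len(xs) != len(ys):
            raise SchemaError(
                f"ragged parallel arrays: len(x)={len(xs)} != len(y)={len(ys)}"
            )
        vals = obj.get("value")
        if vals is not None:
            if not want_value:
                raise SchemaError("'value' array only valid for 2D point sets")
            if not isinstance(vals, list) or len(vals) != len(xs):
                raise SchemaError("'value' array length must match 'x'")
        for i, (xr, yr) in enumerate(zip(xs, ys)):
            x = _coerce_real(xr, i)
            y = _coerce_real(yr, i)
            _check_finite(x, y, i)
            v = _coerce_real(vals[i], i) if (vals is not None and vals[i] is not None) else None
            rows.append((x, y, v))
    else:
        raise SchemaError("series JSON needs either 'points' or parallel 'x'/'y' arrays")

    rows.sort(key=lambda r: r[0])
    if want_value:
        points = tuple(Point2D(x, y, v) for x, y, v in rows)
    else:
        points = tuple(Point(x, y) for x, y, _ in rows)
    return DataSeries(points=points, name=name, color=color, kind=kind)


def serialize_series(series: DataSeries) -> str:
    """Serialize a series back to canonical pair-list JSON (round-trip safe)."""
    obj: dict = {}
    if series.name is not None:
        obj["name"] = series.name
    if series.color is not None:
        obj["color"] = series.color
    if series.is_2d:
        obj["points"] = [
            [p.x, p.y] if p.value is None else [p.x, p.y, p.value] for p in series.points
        ]
    else:
        obj["points"] = [[p.x, p.y] for p in series.points]
    return json.dumps(obj, separators=(",", ":"), sort_keys=True)


def _union(
    a: Optional[tuple[float, float]], b: Optional[tuple[float, float]]
) -> Optional[tuple[float, float]]:
    if a is None:
        return b
    if b is None:
        return a
    return (min(a[0], b[0]), max(a[1], b[1]))


@dataclass(frozen=True)
class DataSet:
    """The data-handler state: bound series, bin config, extent bookkeeping.

    Instances are immutable; :meth:`add` and :meth:`remove` return new
    datasets.  Unnamed series receive computed identifiers ``series-<k>``
    from a per-dataset running counter, deterministic in add order.
    """

    series: tuple = ()
    bin_config: BinConfig = field(default_factory=BinConfig)
    _next_id: int = 1

    def names(self) -> list[str]:
        return [s.name for s in self.series]

    @property
    def x_extent(self) -> Optional[tuple[float, float]]:
        ext = None
        for s in self.series:
            ext = _union(ext, s.extents()[0])
        return ext

    @property
    def y_extent(self) -> Optional[tuple[float, float]]:
        ext = None
        for s in self.series:
            ext = _union(ext, s.extents()[1])
        return ext

    def add(self, s: DataSeries) -> "DataSet":
        """Append a series; assign ``series-<k>`` if it has no name."""
        counter = self._next_id
        if s.name is None:
            s = replace(s, name=f"series-{counter}")
        counter += 1
        if s.name in self.names():
            raise SeriesConflictError(f"series name already bound: {s.name!r}")
        return DataSet(self.series + (s,), self.bin_config, counter)

    def remove(self, name: str) -> "DataSet":
        """Remove the series with this name; extents shrink accordingly."""
        if name not in self.names():
            raise SeriesNotFoundError(f"no series named {name!r}")
        kept = tuple(s for s in self.series if s.name != name)
        return DataSet(kept, self.bin_config, self._next_id)

    def get(self, name: str) -> DataSeries:
        for s in self.series:
            if s.name == name:
                return s
        raise SeriesNotFoundError(f"no series named {name!r}")

    def with_bin_config(self, cfg: BinConfig) -> "DataSet":
        return DataSet(self.series, cfg, self._next_id)

    def __len__(self) -> int:
        return len(self.series)


def add_series(ds: DataSet, s: DataSeries) -> DataSet:
    """Functional alias for :meth:`DataSet.add`."""
    return ds.add(s)


def remove_series(ds: DataSet, name: str) -> DataSet:
    """Functional alias for :meth:`DataSet.remove`."""
    return ds.remove(name)
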