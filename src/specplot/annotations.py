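"""Group-based annotations: parsing, x-lookup anchoring, tooltip assembly.

An annotation file is a JSON list of rows.  The first two columns are fixed:
the *group* name and the *x lookup* value (the domain position the annotation
points at, e.g. an m/z).  The remaining columns are described by an
:class:`AnnotationSchema` supplied separately; each payload column is typed:

``text``
    drawn on the chart beside the anchored data point,
``tooltip``
    one ``<key>: <value>`` line in the rendered callout box,
``structure-url``
    a reference to an MDL Molfile, resolved through a pluggable resolver
    (defaulting to the local filesystem) and embedded as a molecule drawing.

Anchoring binds each annotation to the series point nearest its lookup value;
a match is accepted only within a relative tolerance of the series x extent
(default 0.5%), ties breaking toward smaller x.  Unmatched annotations are
reported, never fatal.
"""

from __future__ import annotations

import json
import math
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Optional, Sequence

from .datamodel import DataSeries, Point
from .errors import GroupNotFoundError, ParseError, SchemaError
from .molfile import Molecule, parse_molfile

__all__ = [
    "AnnotationSchema",
    "Annotation",
    "AnnotationSet",
    "AnchoredAnnotation",
    "TooltipContent",
    "parse_annotations",
    "serialize_annotations",
    "anchor",
    "build_tooltip",
    "local_file_resolver",
]

ColumnKind = Literal["text", "tooltip", "structure-url"]
_KINDS = ("text", "tooltip", "structure-url")


@dataclass(frozen=True)
class AnnotationSchema:
    """Ordered payload columns (name, kind) after the two mandatory ones."""

    columns: tuple

    def __post_init__(self) -> None:
        names = [c[0] for c in self.columns]
        if len(set(names)) != len(names):
            raise SchemaError(f"duplicate column names in schema: {names}")
        for name, kind in self.columns:
            if kind not in _KINDS:
                raise SchemaError(f"column {name!r} has unknown kind {kind!r}")

    def __len__(self) -> int:
        return len(self.columns)


@dataclass(frozen=True)
class Annotation:
    group: str
    x_lookup: float
    payload: tuple  # ordered (name, value) pairs, typed per schema


@dataclass(frozen=True)
class AnnotationSet:
    """Annotations partitioned by group, groups ordered by first appearance."""

    groups: tuple
    by_group: dict

    def group(self, name: str) -> list[Annotation]:
        if name not in self.by_group:
            raise GroupNotFoundError(f"no annotation group named {name!r}")
        return list(self.by_group[name])

    def __len__(self) -> int:
        return sum(len(v) for v in self.by_group.values())


def parse_annotations(json_text: str, schema: AnnotationSchema) -> AnnotationSet:
    """Parse annotation rows ``[group, x_lookup, payload...]`` against a schema."""
    try:
        rows = json.loads(json_text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed JSON at byte offset {exc.pos}: {exc.msg}") from exc
    if not isinstance(rows, list):
        raise SchemaError("annotation JSON must be a list of rows")

    groups: list[str] = []
    by_group: dict[str, list[Annotation]] = {}
    want = 2 + len(schema)
    for i, row in enumerate(rows):
        if not isinstance(row, list) or len(row) != want:
            got = len(row) if isinstance(row, list) else type(row).__name__
            raise SchemaError(f"row {i}: expected {want} values, got {got}")
        group = row[0]
        if not isinstance(group, str) or not group:
            raise SchemaError(f"row {i}: group must be a non-empty string")
        xl = row[1]
        if isinstance(xl, bool) or not isinstance(xl, (int, float)) or not math.isfinite(float(xl)):
            raise ValueError(f"row {i}: x_lookup must be a finite number, got {xl!r}")
        payload = []
        for (name, kind), value in zip(schema.columns, row[2:]):
            if kind == "structure-url":
                if not isinstance(value, str) or not value:
                    raise SchemaError(
                        f"row {i}: structure-url column {name!r} must be non-empty text"
                    )
                payload.append((name, value))
            else:
                payload.append((name, str(value)))
        ann = Annotation(group, float(xl), tuple(payload))
        if group not in by_group:
            groups.append(group)
            by_group[group] = []
        by_group[group].append(ann)
    return AnnotationSet(tuple(groups), by_group)


def serialize_annotations(aset: AnnotationSet) -> str:
    """Write an annotation set back to row JSON, preserving group file order."""
    rows = []
    for g in aset.groups:
        for a in aset.by_group[g]:
            rows.append([a.group, a.x_lookup, *[v for _, v in a.payload]])
    return json.dumps(rows, separators=(",", ":"))


@dataclass(frozen=True)
class AnchoredAnnotation:
    annotation: Annotation
    point: Point
    distance: float


def anchor(
    aset: AnnotationSet,
    group: str,
    series: DataSeries,
    rel_tolerance: float = 0.005,
) -> tuple[list[AnchoredAnnotation], list[Annotation]]:
    """Bind one group's annotations to their nearest series points.

    Returns ``(anchored, unmatched)``.  An annotation matches the point with
    minimal ``|x - x_lookup|`` (ties toward smaller x) and is accepted iff
    that distance is at most ``rel_tolerance`` times the series x-extent
    width.  Raises :class:`GroupNotFoundError` for an unknown group.
    """
    anns = aset.group(group)
    if not series.points:
        return [], list(anns)
    xs = [p.x for p in series.points]
    width = xs[-1] - xs[0]
    tol = rel_tolerance * width
    anchored: list[AnchoredAnnotation] = []
    unmatched: list[Annotation] = []
    for a in anns:
        i = bisect_left(xs, a.x_lookup)
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(xs):
                d = abs(xs[j] - a.x_lookup)
                # strict < keeps the earlier (smaller-x) point on ties
                if best is None or d < best[0]:
                    best = (d, j)
        d, j = best
        if d <= tol:
            anchored.append(AnchoredAnnotation(a, series.points[j], d))
        else:
            unmatched.append(a)
    return anchored, unmatched


def local_file_resolver(base_dir: Optional[str] = None) -> Callable[[str], str]:
    """Resolver treating structure URLs as local filesystem paths."""

    def resolve(url: str) -> str:
        path = Path(base_dir) / url if base_dir else Path(url)
        return path.read_text(encoding="utf-8")

    return resolve


@dataclass(frozen=True)
class TooltipContent:
    """Rendered payload of one annotation: text lines plus parsed molecules."""

    lines: tuple  # "<key>: <value>" strings, in column order
    molecules: tuple  # (column name, Molecule) for successfully resolved structures
    text_labels: tuple  # values of text-kind columns, drawn beside the anchor


def build_tooltip(
    a: Annotation,
    schema: AnnotationSchema,
    resolver: Optional[Callable[[str], str]] = None,
) -> TooltipContent:
    """Assemble the tooltip for one annotation.

    Text and tooltip columns become ``<key>: <value>`` lines; structure-url
    columns are resolved and parsed into molecules.  A resolver or parse
    failure degrades to an error placeholder line for that column only.
    """
    if resolver is None:
        resolver = local_file_resolver()
    lines: list[str] = []
    molecules: list[tuple[str, Molecule]] = []
    text_labels: list[str] = []
    for (name, kind), (_, value) in zip(schema.columns, a.payload):
        if kind == "structure-url":
            try:
                mol = parse_molfile(resolver(value))
                molecules.append((name, mol))
                lines.append(f"{name}: {mol.title or value}")
            except Exception as exc:  # graceful degradation, column-local
                lines.append(f"{name}: <unavailable: {exc.__class__.__name__}>")
        else:
            lines.append(f"{name}: {value}")
            if kind == "text":
                text_labels.append(str(value))
    return TooltipContent(tuple(lines), tuple(molecules), tuple(text_labels))
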