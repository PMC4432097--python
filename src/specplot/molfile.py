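"""MDL Molfile (V2000) parsing and 2D structure depiction to SVG.

Structural tooltip annotations reference molecule files; this module reads the
fixed-column V2000 dialect and draws the skeletal structure as an SVG group
that the renderer embeds in a callout.

V2000 layout: three header lines, a counts line (atom count in columns 1-3,
bond count in columns 4-6, ``V2000`` version tag), the atom block
(``x y z element`` in fixed columns), the bond block (``a1 a2 order``), then
property lines until ``M  END``.  Formal charges come from ``M  CHG`` lines
when present (the legacy charge column is ignored, matching the property-block
precedence of the format).  V3000 input is rejected loudly.

Depiction: coordinates are normalized (translated and uniformly scaled) to fit
a square with 10% padding, so the drawing is invariant under translation and
uniform scaling of the input coordinates.  Single/double/triple bonds map to
1/2/3 parallel lines; the "aromatic" bond code 4 draws as a solid line plus an
inner dashed parallel (no kekulization is attempted).  Heteroatoms and charged
atoms get centered element labels with bond ends trimmed back; carbons are
bare vertices.  Implicit hydrogens are not drawn.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import DegenerateGeometryError, MolfileDialectError, ParseError

__all__ = ["Atom", "Bond", "Molecule", "parse_molfile", "format_molfile", "depict"]


@dataclass(frozen=True)
class Atom:
    element: str
    x: float
    y: float
    charge: int = 0


@dataclass(frozen=True)
class Bond:
    a1: int  # 1-based atom indices
    a2: int
    order: int  # 1, 2, 3, or 4 (aromatic code)


@dataclass(frozen=True)
class Molecule:
    atoms: tuple
    bonds: tuple
    title: str = ""


def _float_field(line: str, start: int, end: int, what: str, lineno: int) -> float:
    try:
        return float(line[start:end])
    except ValueError:
        raise ParseError(f"line {lineno}: cannot read {what} from {line[start:end]!r}") from None


def _int_field(line: str, start: int, end: int, what: str, lineno: int) -> int:
    try:
        return int(line[start:end])
    except ValueError:
        raise ParseError(f"line {lineno}: cannot read {what} from {line[start:end]!r}") from None


def parse_molfile(text: str) -> Molecule:
    """Parse V2000 molfile text into a :class:`Molecule`.

    Raises :class:`ParseError` when the counts line disagrees with the actual
    block lengths, a bond index is out of range, or ``M  END`` is missing, and
    :class:`MolfileDialectError` for V3000 input.
    """
    lines = text.splitlines()
    if len(lines) < 4:
        raise ParseError("molfile too short: need 3 header lines and a counts line")
    title = lines[0].strip()
    counts = lines[3]
    if "V3000" in counts:
        raise MolfileDialectError("V3000 molfiles are not supported (V2000 only)")
    n_atoms = _int_field(counts, 0, 3, "atom count", 4)
    n_bonds = _int_field(counts, 3, 6, "bond count", 4)
    if n_atoms < 0 or n_bonds < 0:
        raise ParseError("counts line has negative counts")

    atom_lines = lines[4 : 4 + n_atoms]
    bond_lines = lines[4 + n_atoms : 4 + n_atoms + n_bonds]
    if len(atom_lines) < n_atoms or len(bond_lines) < n_bonds:
        raise ParseError(
            f"counts line promises {n_atoms} atoms / {n_bonds} bonds "
            f"but the file ends after {len(lines) - 4} block lines"
        )

    atoms: list[Atom] = []
    for i, line in enumerate(atom_lines):
        lineno = 5 + i
        x = _float_field(line, 0, 10, "x coordinate", lineno)
        y = _float_field(line, 10, 20, "y coordinate", lineno)
        _ = _float_field(line, 20, 30, "z coordinate", lineno)  # parsed, ignored
        element = line[31:34].strip()
        if not element:
            raise ParseError(f"line {lineno}: empty element symbol")
        if not (math.isfinite(x) and math.isfinite(y)):
            raise ParseError(f"line {lineno}: non-finite coordinates")
        atoms.append(Atom(element, x, y, 0))

    bonds: list[Bond] = []
    for i, line in enumerate(bond_lines):
        lineno = 5 + n_atoms + i
        a1 = _int_field(line, 0, 3, "bond atom 1", lineno)
        a2 = _int_field(line, 3, 6, "bond atom 2", lineno)
        order = _int_field(line, 6, 9, "bond order", lineno)
        if not (1 <= a1 <= n_atoms and 1 <= a2 <= n_atoms):
            raise ParseError(f"line {lineno}: bond index out of range ({a1}, {a2})")
        if a1 == a2:
            raise ParseError(f"line {lineno}: bond joins atom {a1} to itself")
        if order not in (1, 2, 3, 4):
            raise ParseError(f"line {lineno}: unsupported bond order {order}")
        bonds.append(Bond(a1, a2, order))

    # property block: only M  CHG handled; anything else skipped until M  END
    charges: dict[int, int] = {}
    terminated = False
    for line in lines[4 + n_atoms + n_bonds :]:
        if line.startswith("M  END"):
            terminated = True
            break
        if line.startswith("M  CHG"):
            parts = line.split()
            try:
                n_pairs = int(parts[2])
                entries = parts[3 : 3 + 2 * n_pairs]
                if len(entries) != 2 * n_pairs:
                    raise ValueError
                for j in range(n_pairs):
                    aidx, chg = int(entries[2 * j]), int(entries[2 * j + 1])
                    if not (1 <= aidx <= n_atoms):
                        raise ValueError
                    charges[aidx] = chg
            except (IndexError, ValueError):
                raise ParseError(f"malformed M  CHG line: {line!r}") from None
    if not terminated:
        raise ParseError("molfile not terminated by 'M  END'")

    if charges:
        atoms = [
            Atom(a.element, a.x, a.y, charges.get(i + 1, 0)) for i, a in enumerate(atoms)
        ]
    return Molecule(tuple(atoms), tuple(bonds), title)


def format_molfile(mol: Molecule) -> str:
    """Write a molecule back to V2000 text (fixed columns, ``M  END`` final)."""
    out = [mol.title, "", ""]
    out.append(
        f"{len(mol.atoms):3d}{len(mol.bonds):3d}  0  0  0  0  0  0  0  0999 V2000"
    )
    for a in mol.atoms:
        out.append(f"{a.x:10.4f}{a.y:10.4f}{0.0:10.4f} {a.element:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
    for b in mol.bonds:
        out.append(f"{b.a1:3d}{b.a2:3d}{b.order:3d}  0")
    charged = [(i + 1, a.charge) for i, a in enumerate(mol.atoms) if a.charge != 0]
    if charged:
        out.append(
            "M  CHG" + f"{len(charged):3d}" + "".join(f"{i:4d}{c:4d}" for i, c in charged)
        )
    out.append("M  END")
    return "\n".join(out) + "\n"


def _is_labeled(a: Atom) -> bool:
    return a.element != "C" or a.charge != 0


def _charge_suffix(charge: int) -> str:
    if charge == 0:
        return ""
    sign = "+" if charge > 0 else "-"
    mag = abs(charge)
    return sign if mag == 1 else f"{mag}{sign}"


def _fmt(v: float) -> str:
    return f"{v:.2f}"


def depict(mol: Molecule, size_px: int = 200) -> ET.Element:
    """Draw a molecule as an SVG ``<g>`` fragment fitting a size_px square.

    Raises :class:`DegenerateGeometryError` if all atoms share one coordinate
    (no meaningful 2D layout to scale).
    """
    if size_px <= 0:
        raise ValueError("size_px must be positive")
    if not mol.atoms:
        raise DegenerateGeometryError("molecule has no atoms")
    xs = [a.x for a in mol.atoms]
    ys = [a.y for a in mol.atoms]
    ex, ey = max(xs) - min(xs), max(ys) - min(ys)
    extent = max(ex, ey)
    if extent == 0:
        raise DegenerateGeometryError(
            "all atom coordinates coincide; molfile carries no 2D layout"
        )
    pad = 0.1 * size_px
    scale = (size_px - 2 * pad) / extent
    ox = pad + (size_px - 2 * pad - ex * scale) / 2 - min(xs) * scale
    oy = pad + (size_px - 2 * pad - ey * scale) / 2 - min(ys) * scale

    def to_px(a: Atom) -> tuple[float, float]:
        # SVG y points down; molfile y points up
        return a.x * scale + ox, size_px - (a.y * scale + oy)

    font_px = max(8.0, 0.07 * size_px)
    label_r = 0.55 * font_px  # trim radius around labeled atoms
    offset = max(1.2, 0.012 * size_px)  # half-gap between parallel bond lines

    g = ET.Element("g", {"class": "molecule"})
    pts = [to_px(a) for a in mol.atoms]

    for b in mol.bonds:
        (x1, y1), (x2, y2) = pts[b.a1 - 1], pts[b.a2 - 1]
        dx, dy = x2 - x1, y2 - y1
        length = math.hypot(dx, dy)
        if length == 0:
            continue
        ux, uy = dx / length, dy / length
        # trim ends that meet a labeled atom, but never past a third of the bond
        t1 = min(label_r, length / 3) if _is_labeled(mol.atoms[b.a1 - 1]) else 0.0
        t2 = min(label_r, length / 3) if _is_labeled(mol.atoms[b.a2 - 1]) else 0.0
        sx, sy = x1 + ux * t1, y1 + uy * t1
        ex2, ey2 = x2 - ux * t2, y2 - uy * t2
        px, py = -uy, ux  # unit perpendicular
        if b.order == 1:
            shifts = [0.0]
        elif b.order == 2:
            shifts = [-offset, offset]
        elif b.order == 3:
            shifts = [-2 * offset, 0.0, 2 * offset]
        else:  # aromatic code: solid line plus inner dashed parallel
            shifts = [0.0, 2 * offset]
        for k, sh in enumerate(shifts):
            attrs = {
                "x1": _fmt(sx + px * sh),
                "y1": _fmt(sy + py * sh),
                "x2": _fmt(ex2 + px * sh),
                "y2": _fmt(ey2 + py * sh),
                "stroke": "#222222",
                "stroke-width": _fmt(max(1.0, 0.008 * size_px)),
            }
            if b.order == 4 and k == 1:
                attrs["stroke-dasharray"] = "3,2"
            ET.SubElement(g, "line", attrs)

    for a, (x, y) in zip(mol.atoms, pts):
        if not _is_labeled(a):
            continue
        t = ET.SubElement(
            g,
            "text",
            {
                "x": _fmt(x),
                "y": _fmt(y),
                "text-anchor": "middle",
                "dominant-baseline": "central",
                "font-size": _fmt(font_px),
                "font-family": "sans-serif",
                "fill": "#222222",
            },
        )
        t.text = a.element + _charge_suffix(a.charge)
    return g
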