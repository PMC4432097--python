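"""Seeded synthetic fixture generation: spectra, point sets, molfiles.

These generators stand in for real repository spectra during testing and in
worked examples.  Each emulates the gross shape of its instrument's output:

- ``ms-peaks``: a centroided mass spectrum — discrete peaks at random m/z in
  [50, 500] with exponentially distributed intensities (most fragments weak,
  a few dominant), as in an MS2 fragmentation spectrum.
- ``nmr-trace``: a 1D NMR spectrum — a dense grid over 0-10 ppm carrying a sum
  of Lorentzian lines (the natural NMR lineshape) over a tiny noise floor;
  default 60,000 grid points, the regime where per-pixel binning matters.
- ``ir-trace``: an IR transmittance spectrum over 400-4000 cm^-1 — a baseline
  near 1 with Gaussian absorption dips, so the signal is in the valleys.
- ``nmr2d-points``: an HSQC-style cross-peak set (F2 1H ppm vs F1 13C ppm).
- ``molfile``: small hand-authored V2000 molecules (ethanol, benzene, a
  uracil-like ring) plus deliberately corrupted variants for parser tests.

All output is reproducible byte-for-byte from the seed; floats are rounded
before serialization so files are stable across platforms.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional

import numpy as np

from .molfile import Atom, Bond, Molecule, format_molfile

__all__ = [
    "make_ms_peaks",
    "make_nmr_trace",
    "make_ir_trace",
    "make_nmr2d_points",
    "make_molfiles",
    "generate_fixtures",
    "FIXTURE_KINDS",
]

FIXTURE_KINDS = ("ms-peaks", "nmr-trace", "ir-trace", "nmr2d-points", "molfile")


def _dump(obj) -> str:
    return json.dumps(obj, separators=(",", ":"), sort_keys=True)


def make_ms_peaks(seed: int, n: int = 40, name: Optional[str] = None) -> dict:
    """Centroided MS peak list: n peaks, m/z in [50, 500], exponential heights."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    mz = np.sort(rng.uniform(50.0, 500.0, size=n))
    inten = rng.exponential(scale=100.0, size=n) + 1.0
    inten[int(rng.integers(0, n))] *= 5.0  # one dominant base peak
    obj = {"points": [[round(float(x), 4), round(float(y), 4)] for x, y in zip(mz, inten)]}
    if name is not None:
        obj["name"] = name
    return obj


def make_nmr_trace(
    seed: int, n_points: int = 60000, n_lines: int = 12, name: Optional[str] = None
) -> dict:
    """1D NMR trace: Lorentzian lines on a dense 0-10 ppm grid."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, 10.0, n_points)
    y = np.zeros(n_points)
    centers = rng.uniform(0.5, 9.5, size=n_lines)
    gammas = rng.uniform(0.004, 0.02, size=n_lines)
    amps = rng.lognormal(mean=0.0, sigma=0.7, size=n_lines) * 100.0
    for c, g, a in zip(centers, gammas, amps):
        y += a * g**2 / ((x - c) ** 2 + g**2)
    y += rng.normal(0.0, 0.15, size=n_points)  # noise floor
    obj = {
        "x": [round(float(v), 6) for v in x],
        "y": [round(float(v), 5) for v in y],
    }
    if name is not None:
        obj["name"] = name
    return obj


def make_ir_trace(
    seed: int, n_points: int = 4000, n_bands: int = 10, name: Optional[str] = None
) -> dict:
    """IR transmittance trace: baseline near 1 with Gaussian absorption dips."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    rng = np.random.default_rng(seed)
    x = np.linspace(400.0, 4000.0, n_points)
    y = np.full(n_points, 0.98)
    centers = rng.uniform(500.0, 3800.0, size=n_bands)
    widths = rng.uniform(10.0, 60.0, size=n_bands)
    depths = rng.uniform(0.1, 0.7, size=n_bands)
    for c, w, d in zip(centers, widths, depths):
        y -= d * np.exp(-0.5 * ((x - c) / w) ** 2)
    y += rng.normal(0.0, 0.002, size=n_points)
    np.clip(y, 0.01, 1.0, out=y)
    obj = {
        "x": [round(float(v), 4) for v in x],
        "y": [round(float(v), 5) for v in y],
    }
    if name is not None:
        obj["name"] = name
    return obj


def make_nmr2d_points(seed: int, n_peaks: int = 25, name: Optional[str] = None) -> dict:
    """HSQC-style cross peaks: (1H ppm, 13C ppm, intensity) triples."""
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    rng = np.random.default_rng(seed)
    f2 = rng.uniform(0.5, 9.5, size=n_peaks)  # 1H
    f1 = rng.uniform(10.0, 160.0, size=n_peaks)  # 13C
    v = rng.exponential(scale=50.0, size=n_peaks) + 1.0
    pts = sorted(
        [round(float(a), 4), round(float(b), 3), round(float(c), 3)]
        for a, b, c in zip(f2, f1, v)
    )
    obj = {"points": pts}
    if name is not None:
        obj["name"] = name
    return obj


def _hexagon(radius: float = 1.0) -> list[tuple[float, float]]:
    return [
        (
            round(radius * math.cos(math.radians(90 - 60 * k)), 4),
            round(radius * math.sin(math.radians(90 - 60 * k)), 4),
        )
        for k in range(6)
    ]


ETHANOL = Molecule(
    atoms=(
        Atom("C", 0.0, 0.0),
        Atom("C", 1.299, 0.75),
        Atom("O", 2.5981, 0.0),
    ),
    bonds=(Bond(1, 2, 1), Bond(2, 3, 1)),
    title="ethanol",
)

BENZENE = Molecule(
    atoms=tuple(Atom("C", x, y) for x, y in _hexagon()),
    bonds=(
        Bond(1, 2, 2), Bond(2, 3, 1), Bond(3, 4, 2),
        Bond(4, 5, 1), Bond(5, 6, 2), Bond(6, 1, 1),
    ),
    title="benzene",
)

# pyrimidine-2,4-dione ring (the uracil core): 6-ring of N/C with two exo =O
_RING = _hexagon()
URACIL = Molecule(
    atoms=(
        Atom("N", *_RING[0]),
        Atom("C", *_RING[1]),
        Atom("N", *_RING[2]),
        Atom("C", *_RING[3]),
        Atom("C", *_RING[4]),
        Atom("C", *_RING[5]),
        Atom("O", round(_RING[1][0] * 2.0, 4), round(_RING[1][1] * 2.0, 4)),
        Atom("O", round(_RING[3][0] * 2.0, 4), round(_RING[3][1] * 2.0, 4)),
    ),
    bonds=(
        Bond(1, 2, 1), Bond(2, 3, 1), Bond(3, 4, 1),
        Bond(4, 5, 1), Bond(5, 6, 2), Bond(6, 1, 1),
        Bond(2, 7, 2), Bond(4, 8, 2),
    ),
    title="uracil-core",
)

METHANE = Molecule(atoms=(Atom("C", 0.0, 0.0),), bonds=(), title="methane")


def make_molfiles() -> dict[str, str]:
    """Valid molfile corpus plus corrupted variants keyed by file stem.

    ``*-corrupt-*`` entries must each raise the parser's documented error:
    truncation, a counts line disagreeing with the blocks, and a V3000 tag.
    """
    valid = {
        "ethanol": format_molfile(ETHANOL),
        "benzene": format_molfile(BENZENE),
        "uracil": format_molfile(URACIL),
        "methane": format_molfile(METHANE),
    }
    benzene_lines = valid["benzene"].splitlines()
    truncated = "\n".join(benzene_lines[: 4 + 3]) + "\n"  # promises 6 atoms, has 3
    bad_counts = valid["ethanol"].replace(
        "  3  2  0", "  5  2  0", 1
    )  # claims 5 atoms, file has 3
    v3000 = valid["ethanol"].replace("V2000", "V3000", 1)
    return {
        **valid,
        "corrupt-truncated": truncated,
        "corrupt-badcounts": bad_counts,
        "corrupt-v3000": v3000,
    }


def generate_fixtures(kind: str, out_dir, seed: int, **params) -> list[Path]:
    """Write fixture files of one kind to ``out_dir``; returns written paths.

    Output is byte-identical for equal (kind, seed, params).
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def write(name: str, text: str) -> None:
        p = out / name
        p.write_text(text, encoding="utf-8")
        written.append(p)

    if kind == "ms-peaks":
        write("ms-peaks.json", _dump(make_ms_peaks(seed, **params)) + "\n")
    elif kind == "nmr-trace":
        write("nmr-trace.json", _dump(make_nmr_trace(seed, **params)) + "\n")
    elif kind == "ir-trace":
        write("ir-trace.json", _dump(make_ir_trace(seed, **params)) + "\n")
    elif kind == "nmr2d-points":
        write("nmr2d-points.json", _dump(make_nmr2d_points(seed, **params)) + "\n")
    else:  # molfile corpus is deterministic by construction; seed unused
        for stem, text in make_molfiles().items():
            write(f"{stem}.mol", text)
    return written
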