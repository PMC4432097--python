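"""Domain-to-pixel coordinate mappings (the xScale/yScale contract).

A :class:`Scale` maps a data interval onto a pixel interval, linearly or on a
log10 transform, optionally reversed (used for NMR ppm and IR wavenumber axes,
which run right-to-left, and for the SVG y axis, which points down).

Values outside the domain extrapolate rather than error: zoom windows
routinely cut series, and clipping is the renderer's job.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

__all__ = ["Scale", "apply", "invert", "ticks"]


@dataclass(frozen=True)
class Scale:
    kind: Literal["linear", "log10"]
    domain: tuple[float, float]
    range_px: tuple[float, float]
    reversed: bool = False

    def __post_init__(self) -> None:
        d0, d1 = self.domain
        r0, r1 = self.range_px
        if self.kind not in ("linear", "log10"):
            raise ValueError(f"unknown scale kind: {self.kind!r}")
        if not (d0 < d1):
            raise ValueError(f"domain must satisfy d0 < d1, got {self.domain}")
        if self.kind == "log10" and d0 <= 0:
            raise ValueError(f"log10 domain must be positive, got {self.domain}")
        if not (r0 <= r1):
            raise ValueError(f"pixel range must satisfy r0 <= r1, got {self.range_px}")

    # convenience method forms
    def apply(self, v: float) -> float:
        return apply(self, v)

    def invert(self, px: float) -> float:
        return invert(self, px)

    def ticks(self, target_count: int = 6):
        return ticks(self, target_count)


def _fraction(scale: Scale, v: float) -> float:
    d0, d1 = scale.domain
    if scale.kind == "log10":
        if v <= 0:
            raise ValueError(f"log10 scale cannot map non-positive value {v!r}")
        return (math.log10(v) - math.log10(d0)) / (math.log10(d1) - math.log10(d0))
    return (v - d0) / (d1 - d0)


def apply(scale: Scale, v: float) -> float:
    """Map a domain value to a pixel coordinate (extrapolates outside)."""
    t = _fraction(scale, v)
    if scale.reversed:
        t = 1.0 - t
    r0, r1 = scale.range_px
    return r0 + t * (r1 - r0)


def invert(scale: Scale, px: float) -> float:
    """Map a pixel coordinate back to a domain value; inverse of :func:`apply`."""
    r0, r1 = scale.range_px
    if r0 == r1:
        raise ValueError("cannot invert a scale with a degenerate pixel range")
    t = (px - r0) / (r1 - r0)
    if scale.reversed:
        t = 1.0 - t
    d0, d1 = scale.domain
    if scale.kind == "log10":
        l0, l1 = math.log10(d0), math.log10(d1)
        return 10.0 ** (l0 + t * (l1 - l0))
    return d0 + t * (d1 - d0)


def _multiples_in(d0: float, d1: float, step: float) -> list[float]:
    first = math.ceil(d0 / step - 1e-9) * step
    vals = []
    k = 0
    v = first
    while v <= d1 + 1e-9 * step:
        vals.append(0.0 if abs(v) < 1e-12 * step else v)
        k += 1
        v = first + k * step
    return vals


def _linear_ticks(d0: float, d1: float, target: int) -> list[float]:
    """Nice 1/2/5 x 10^k multiples inside [d0, d1], count in [target/2, 2*target].

    Walks candidate steps from coarse to fine and stops at the first whose
    tick count reaches the lower bound; counts grow by at most ~2.5x per
    refinement, so the upper bound holds too.
    """
    span = d1 - d0
    lower = max(1, math.ceil(target / 2))
    exp = math.floor(math.log10(span)) + 1
    candidates: list[list[float]] = []
    done = False
    for _ in range(12):
        for mant in (5.0, 2.0, 1.0):
            step = mant * 10.0**exp
            vals = _multiples_in(d0, d1, step)
            candidates.append(vals)
            if len(vals) > 2 * target:
                done = True
                break
        if done:
            break
        exp -= 1
    in_band = [v for v in candidates if lower <= len(v) <= 2 * target]
    pool = in_band or candidates
    # closest to one-past-target (a span usually fits target+1 fenceposts)
    return min(pool, key=lambda v: abs(len(v) - (target + 1)))


def _format_tick(v: float) -> str:
    # %g trims trailing zeros but keeps enough digits for nice multiples
    return f"{v:.10g}"


def ticks(scale: Scale, target_count: int = 6) -> list[tuple[float, str]]:
    """Tick values at nice multiples of 1/2/5 x 10^k inside the domain.

    Returned in display order: ascending pixel position, so a reversed scale
    yields descending values.
    """
    if target_count < 1:
        raise ValueError("target_count must be >= 1")
    d0, d1 = scale.domain
    vals: list[float]
    if scale.kind == "log10":
        lo, hi = math.ceil(math.log10(d0) - 1e-12), math.floor(math.log10(d1) + 1e-12)
        vals = [10.0**k for k in range(lo, hi + 1)]
        if len(vals) < max(2, target_count // 2):
            # fewer than two decades: fall back to linear nice ticks
            vals = [v for v, _ in ticks(Scale("linear", scale.domain, scale.range_px), target_count)]
    else:
        vals = _linear_ticks(d0, d1, target_count)
    if scale.reversed:
        vals = vals[::-1]
    return [(v, _format_tick(v)) for v in vals]
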