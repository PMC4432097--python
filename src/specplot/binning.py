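"""Extremum-preserving per-pixel binning of dense traces.

Large spectra (an NMR trace can exceed 60,000 points) carry far more samples
than a chart has horizontal pixels.  Before rendering, each series is reduced
to at most one representative point per pixel-width bin: the view window is
partitioned into ``n_bins`` equal intervals and, within each non-empty bin,
the ORIGINAL point with the extremal intensity is kept — the maximum for
upward-peaked data (MS, NMR, time series) or the minimum for IR transmittance
traces, whose signal is absorption valleys.  No interpolation: every emitted
point is a member of the input, so exact peak positions survive for labels and
annotation lookup.

Bins are half-open ``[lo + i*w, lo + (i+1)*w)`` with the final bin closed at
``hi``; ties on extremal y break toward the smallest x.  Binning an
already-binned series with the same request is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .datamodel import BinConfig, DataSeries, DataSet, Point
from .errors import ContractError

__all__ = ["BinRequest", "bin_series", "bin_dataset"]

BinMode = Literal["min", "max"]


@dataclass(frozen=True)
class BinRequest:
    """One binning job: window [lo, hi) in domain units, bin count, mode."""

    x_window: tuple[float, float]
    n_bins: int
    mode: BinMode

    def __post_init__(self) -> None:
        lo, hi = self.x_window
        if not (lo < hi):
            raise ValueError(f"x_window must satisfy lo < hi, got {self.x_window}")
        if self.n_bins < 1:
            raise ValueError(f"n_bins must be >= 1, got {self.n_bins}")
        if self.mode not in ("min", "max"):
            raise ValueError(f"mode must be 'min' or 'max', got {self.mode!r}")


def bin_series(points: Sequence[Point], req: BinRequest) -> list[Point]:
    """Bin a sorted point list to at most one point per bin.

    Input must be sorted ascending by x (raises :class:`ContractError`
    otherwise).  Points outside the window are dropped; the point at exactly
    ``hi`` falls in the last bin.  Output is sorted by x and has at most
    ``req.n_bins`` points.
    """
    if not points:
        return []
    xs = np.asarray([p.x for p in points], dtype=np.float64)
    ys = np.asarray([p.y for p in points], dtype=np.float64)
    if np.any(np.diff(xs) < 0):
        raise ContractError("bin_series requires points sorted ascending by x")

    lo, hi = req.x_window
    width = (hi - lo) / req.n_bins
    inside = (xs >= lo) & (xs <= hi)  # x == hi joins the closed last bin
    if not np.any(inside):
        return []
    idx = np.nonzero(inside)[0]
    x_in, y_in = xs[idx], ys[idx]
    bins = np.floor((x_in - lo) / width).astype(np.int64)
    np.clip(bins, 0, req.n_bins - 1, out=bins)

    # order within each bin by extremal y first, then smallest x (tie-break);
    # lexsort's last key is primary
    ykey = -y_in if req.mode == "max" else y_in
    order = np.lexsort((x_in, ykey, bins))
    sorted_bins = bins[order]
    _, first = np.unique(sorted_bins, return_index=True)
    winners = idx[order[first]]
    winners.sort()  # ascending x since input is sorted
    return [points[i] for i in winners]


def bin_dataset(ds: DataSet, plot_width_px: int, mode: BinMode) -> DataSet:
    """Bin every 1D series in a dataset against its full x extent.

    ``n_bins = plot_width_px // binwidth_px``.  With binning disabled in the
    dataset's :class:`BinConfig`, series pass through unchanged.  2D point
    sets are never binned.
    """
    cfg = ds.bin_config
    if plot_width_px < cfg.binwidth_px:
        raise ValueError(
            f"plot width {plot_width_px}px is smaller than bin width {cfg.binwidth_px}px"
        )
    if not cfg.enabled:
        return ds
    extent = ds.x_extent
    if extent is None:
        return ds
    lo, hi = extent
    if lo == hi:  # single distinct x: nothing to reduce
        return ds
    n_bins = plot_width_px // cfg.binwidth_px
    req = BinRequest((lo, hi), n_bins, mode)
    out = DataSet((), cfg, ds._next_id)
    new_series = []
    for s in ds.series:
        if s.is_2d:
            new_series.append(s)
        else:
            new_series.append(
                DataSeries(tuple(bin_series(s.points, req)), s.name, s.color, s.kind)
            )
    return DataSet(tuple(new_series), cfg, ds._next_id)
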