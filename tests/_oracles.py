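"""Independent brute-force reference implementations used as test oracles.

These deliberately take a different algorithmic route from the library
(explicit boundary bisection and linear scans instead of vectorized floor
division) so agreement is meaningful.
"""

from bisect import bisect_left, bisect_right


def brute_force_bin(points, lo, hi, n_bins, mode):
    """Reference binning: assign each point to its bin by comparing against
    explicit bin boundaries, keep the per-bin extremum (ties: smaller x).

    Bins are [lo + i*w, lo + (i+1)*w), the last closed at hi.
    """
    w = (hi - lo) / n_bins
    inner_edges = [lo + i * w for i in range(1, n_bins)]
    best = {}
    for p in points:
        if p.x < lo or p.x > hi:
            continue
        b = bisect_right(inner_edges, p.x)  # 0 .. n_bins-1; x == hi lands last
        cur = best.get(b)
        if cur is None:
            best[b] = p
        elif mode == "max":
            if p.y > cur.y or (p.y == cur.y and p.x < cur.x):
                best[b] = p
        else:
            if p.y < cur.y or (p.y == cur.y and p.x < cur.x):
                best[b] = p
    return [best[b] for b in sorted(best)]


def nearest_x_scan(points, x_lookup):
    """Reference anchoring: full linear scan for the nearest x, ties to smaller x."""
    best = None
    for p in points:
        d = abs(p.x - x_lookup)
        if best is None or d < best[0]:
            best = (d, p)
    return best  # (distance, point) or None


def local_maxima_scan(points):
    """Reference peak finding: strict local maxima including endpoints."""
    n = len(points)
    out = []
    for i, p in enumerate(points):
        if (i == 0 or points[i - 1].y < p.y) and (i == n - 1 or points[i + 1].y < p.y):
            out.append(p)
    return out
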