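"""Penalized weighted least-squares segmentation and line fitting.

Single-channel segmentation minimizes

    sum_i (y_i - f(x_i))^2 / sigma_i^2  +  lambda * (number of segments)

over piecewise-linear fits with breakpoints on the probe grid, by exact
dynamic programming over probe indices.

The joint two-channel objective adds a shared-boundary discount and a
slope-coupling prior:

    sum_c [ wrss_c + lambda * k_c ]  -  delta * #shared_boundaries
        +  kappa * sum_aligned_pairs (slope_A - slope_B)^2

Boundary sharing is part of the fitted model structure, mirroring the
prior-probability view of using the same boundaries in both channels: a
*shared* boundary is one the optimizer declares common to both channels
(earning the delta discount), and an *aligned pair* is the segment pair
spanning two consecutive shared boundaries when each channel uses exactly
one segment there.  Intercepts are never coupled.  The coupling enters the
fit itself: for an aligned pair the two slopes are solved jointly from a
2x2 linear system, so as kappa -> infinity both slopes tend to the
precision-weighted mean slope.

The objective then decomposes over "blocks" delimited by consecutive
shared boundaries: inside a block each channel is segmented independently
(no coupling) unless both use a single segment (the coupled case).  An
outer DP over shared-boundary positions combined with per-channel inner
DPs over private boundaries is therefore exact, not an approximation; the
minimization runs over segmentations of both channels *and* over the
sharing structure.

Fits are deterministic; ties are broken toward fewer segments, then
leftmost boundaries (via DP iteration order with strict improvement).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import SegmentationParams
from .preprocess import NormalizedTrack

logger = logging.getLogger(__name__)

__all__ = [
    "Segment",
    "SegmentFit",
    "IntervalFit",
    "wls_line_fit",
    "segment_channel",
    "segment_joint",
    "fit_genome",
]

_INF = np.inf


@dataclass
class Segment:
    """One fitted line piece.  The line is y = intercept + slope * (x - x0)
    where x0 is the position of the segment's first probe."""

    channel: str
    start_idx: int   # probe indices, half-open
    end_idx: int
    slope: float     # log2 units per bp
    intercept: float  # log2 units at the first probe of the segment
    wrss: float
    x0: float = 0.0
    degenerate: bool = False

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * (np.asarray(x, dtype=float) - self.x0)


@dataclass
class SegmentFit:
    """Joint (or single-channel) fit over one probe index range."""

    x: np.ndarray
    segments: dict  # channel -> ordered list[Segment]
    boundaries: dict  # channel -> sorted interior probe indices
    shared: list  # boundaries present in both channels
    cost: float

    def segment_at(self, channel: str, idx: int, side: str) -> Segment:
        """Segment of ``channel`` adjacent to probe-index ``idx``:
        side='left' ends at idx (or covers it), side='right' starts at it."""
        for seg in self.segments[channel]:
            if side == "left" and seg.start_idx < idx <= seg.end_idx:
                return seg
            if side == "right" and seg.start_idx <= idx < seg.end_idx:
                return seg
        raise KeyError(f"no {side} segment at index {idx} in channel {channel}")


@dataclass
class IntervalFit:
    """Fit of one inter-site interval of the genome."""

    interval_id: int
    left_site: int | None
    right_site: int | None
    probe_start: int  # slice into the track's probe grid
    probe_end: int
    fit: SegmentFit


def wls_line_fit(x, y, w):
    """Closed-form weighted least squares line fit.

    Returns ``(slope, intercept, wrss)`` with the intercept evaluated at
    the first x value (the Segment convention).  Requires >= 2 points with
    distinct x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if x.size < 2:
        raise ValueError("wls_line_fit requires at least 2 points")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate fit: all x identical")
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    vxx = (w * (x - xbar) ** 2).sum()
    vxy = (w * (x - xbar) * (y - ybar)).sum()
    slope = vxy / vxx
    resid = y - (ybar + slope * (x - xbar))
    wrss = float((w * resid * resid).sum())
    intercept = ybar + slope * (x[0] - xbar)
    return float(slope), float(intercept), max(wrss, 0.0)


class _PrefixWLS:
    """All-pairs weighted line-fit statistics via prefix sums.

    For every half-open probe-index range [s, t) provides the centred
    moments, the optimal slope, and the weighted residual sum of squares in
    O(1) after O(n) setup (O(n^2) memory for the pair matrices).
    """

    def __init__(self, x: np.ndarray, y: np.ndarray, w: np.ndarray):
        n = x.size
        self.n = n
        self.x = x
        z = np.zeros(1)
        cw = np.concatenate([z, np.cumsum(w)])
        cwx = np.concatenate([z, np.cumsum(w * x)])
        cwy = np.concatenate([z, np.cumsum(w * y)])
        cwxx = np.concatenate([z, np.cumsum(w * x * x)])
        cwxy = np.concatenate([z, np.cumsum(w * x * y)])
        cwyy = np.concatenate([z, np.cumsum(w * y * y)])
        s = np.arange(n + 1)[:, None]
        t = np.arange(n + 1)[None, :]
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            SW = cw[t] - cw[s]
            SWX = cwx[t] - cwx[s]
            SWY = cwy[t] - cwy[s]
            self.xbar = SWX / SW
            self.ybar = SWY / SW
            self.vxx = (cwxx[t] - cwxx[s]) - SWX * SWX / SW
            self.vxy = (cwxy[t] - cwxy[s]) - SWX * SWY / SW
            self.vyy = (cwyy[t] - cwyy[s]) - SWY * SWY / SW
            self.slope = np.where(self.vxx > 0, self.vxy / np.maximum(self.vxx, 1e-300), 0.0)
            wrss = self.vyy - np.where(self.vxx > 0,
                                       self.vxy ** 2 / np.maximum(self.vxx, 1e-300), 0.0)
        self.wrss = np.maximum(np.nan_to_num(wrss, nan=_INF), 0.0)

    def fit(self, s: int, t: int, slope: float | None = None):
        """(slope, intercept-at-x[s], wrss) for range [s, t); a fixed slope
        may be imposed (used for coupled aligned pairs)."""
        if slope is None:
            slope = float(self.slope[s, t])
            wrss = float(self.wrss[s, t])
        else:
            wrss = float(self.vyy[s, t] - 2.0 * slope * self.vxy[s, t]
                         + slope * slope * self.vxx[s, t])
        intercept = float(self.ybar[s, t] + slope * (self.x[s] - self.xbar[s, t]))
        return slope, intercept, max(wrss, 0.0)


def _cost1(pre: _PrefixWLS, lam: float, min_probes: int) -> np.ndarray:
    """(n+1)x(n+1) matrix of single-segment costs wrss + lambda; inf where
    the range is shorter than min_probes."""
    n = pre.n
    c = pre.wrss + lam
    s = np.arange(n + 1)[:, None]
    t = np.arange(n + 1)[None, :]
    c[t - s < min_probes] = _INF
    return c


def _channel_tables(cost1: np.ndarray):
    """Per-channel inner DP over every range [s, t).

    Returns (any_cost, multi_cost, parent): any_cost[s, t] is the optimal
    segmentation cost of [s, t) (each segment paying its lambda through
    ``cost1``), multi_cost restricts to >= 2 segments, and parent[s, t] is
    the last interior breakpoint of the optimum (-1 for one segment).
    Ties prefer a single segment over a split, then the leftmost split.
    """
    n = cost1.shape[0] - 1
    any_cost = np.full((n + 1, n + 1), _INF)
    multi_cost = np.full((n + 1, n + 1), _INF)
    parent = np.full((n + 1, n + 1), -1, dtype=np.int64)
    for s in range(n):
        row_any = any_cost[s]
        for t in range(s + 1, n + 1):
            single = cost1[s, t]
            if t - s >= 2:
                vals = row_any[s + 1:t] + cost1[s + 1:t, t]
                j = int(np.argmin(vals))
                mc = float(vals[j])
            else:
                mc = _INF
            multi_cost[s, t] = mc
            if single <= mc:
                row_any[t] = single
            else:
                row_any[t] = mc
                parent[s, t] = s + 1 + j
    return any_cost, multi_cost, parent


def _coupled_pair(preA: _PrefixWLS, preB: _PrefixWLS, kappa: float):
    """Slopes and total wrss of the coupled aligned-pair fit for every
    range: minimize wrssA(mA) + wrssB(mB) + kappa (mA - mB)^2 jointly."""
    vxxA, vxyA, vyyA = preA.vxx, preA.vxy, preA.vyy
    vxxB, vxyB, vyyB = preB.vxx, preB.vxy, preB.vyy
    with np.errstate(divide="ignore", invalid="ignore"):
        det = (vxxA + kappa) * (vxxB + kappa) - kappa * kappa
        mA = ((vxxB + kappa) * vxyA + kappa * vxyB) / det
        mB = ((vxxA + kappa) * vxyB + kappa * vxyA) / det
        cost = (vyyA - 2 * mA * vxyA + mA * mA * vxxA
                + vyyB - 2 * mB * vxyB + mB * mB * vxxB
                + kappa * (mA - mB) ** 2)
    cost = np.nan_to_num(cost, nan=_INF)
    return mA, mB, np.maximum(cost, 0.0)


def _reconstruct_channel(pre: _PrefixWLS, parent: np.ndarray, s: int, t: int) -> list[tuple[int, int]]:
    """Segment ranges of the optimal single-channel segmentation of [s, t)."""
    u = parent[s, t]
    if u < 0:
        return [(s, t)]
    return _reconstruct_channel(pre, parent, s, u) + [(u, t)]


def _make_segments(channel: str, pre: _PrefixWLS, ranges, slope_override=None) -> list[Segment]:
    segs = []
    for (s, t) in ranges:
        slope, intercept, wrss = pre.fit(s, t, slope_override.get((s, t)) if slope_override else None)
        segs.append(Segment(channel, s, t, slope, intercept, wrss, x0=float(pre.x[s])))
    return segs


def segment_channel(x, y, w, lam: float, min_probes: int = 4) -> SegmentFit:
    """Optimal single-channel penalized segmentation by dynamic programming.

    Returns a SegmentFit whose cost is the global minimum of
    wrss + lambda * #segments over all breakpoint placements on the probe
    grid with segments of at least ``min_probes`` probes.  Instances with
    fewer than ``min_probes`` probes yield one degenerate flagged segment.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if lam <= 0:
        raise ValueError("lambda_seg must be positive")
    n = x.size
    if n < min_probes:
        seg = _degenerate_segment("A", x, y, w)
        return SegmentFit(x, {"A": [seg]}, {"A": []}, [], seg.wrss + lam)
    pre = _PrefixWLS(x, y, w)
    cost1 = _cost1(pre, lam, min_probes)
    C = np.full(n + 1, _INF)
    nseg = np.zeros(n + 1, dtype=np.int64)
    par = np.full(n + 1, -1, dtype=np.int64)
    C[0] = 0.0
    for t in range(min_probes, n + 1):
        for s in range(0, t - min_probes + 1):
            if C[s] == _INF or cost1[s, t] == _INF:
                continue
            c = C[s] + cost1[s, t]
            k = nseg[s] + 1
            if c < C[t] or (c == C[t] and k < nseg[t]):
                C[t], nseg[t], par[t] = c, k, s
    # walk back
    bounds = []
    t = n
    while t > 0:
        s = int(par[t])
        bounds.append(s)
        t = s
    ranges = []
    cuts = sorted(bounds) + [n]
    for i in range(len(cuts) - 1):
        ranges.append((cuts[i], cuts[i + 1]))
    segs = _make_segments("A", pre, ranges)
    interior = [r[0] for r in ranges[1:]]
    return SegmentFit(x, {"A": segs}, {"A": interior}, [], float(C[n]))


def _degenerate_segment(channel: str, x, y, w) -> Segment:
    if x.size >= 2 and np.ptp(x) > 0:
        slope, intercept, wrss = wls_line_fit(x, y, w)
    else:
        slope, intercept, wrss = 0.0, float(y[0]) if y.size else 0.0, 0.0
    return Segment(channel, 0, int(x.size), slope, intercept, wrss,
                   x0=float(x[0]) if x.size else 0.0, degenerate=True)


def segment_joint(x, y_a, y_b, w_a, w_b, lam: float, delta: float,
                  kappa: float, min_probes: int = 4) -> SegmentFit:
    """Exact joint two-channel segmentation (see module docstring).

    ``delta`` discounts each interior boundary shared by both channels
    (0 <= delta <= lambda); ``kappa`` couples the slopes of aligned
    segment pairs.
    """
    x = np.asarray(x, dtype=float)
    y_a = np.asarray(y_a, dtype=float)
    y_b = np.asarray(y_b, dtype=float)
    if not (x.size == y_a.size == y_b.size):
        raise ValueError("channels must share one probe grid")
    if not 0 <= delta <= lam:
        raise ValueError("delta_shared must satisfy 0 <= delta <= lambda")
    if kappa < 0:
        raise ValueError("kappa_slope must be >= 0")
    n = x.size
    if n < min_probes:
        sa = _degenerate_segment("A", x, y_a, np.asarray(w_a, dtype=float))
        sb = _degenerate_segment("B", x, y_b, np.asarray(w_b, dtype=float))
        return SegmentFit(x, {"A": [sa], "B": [sb]}, {"A": [], "B": []}, [],
                          sa.wrss + sb.wrss + 2 * lam)

    preA = _PrefixWLS(x, y_a, np.asarray(w_a, dtype=float))
    preB = _PrefixWLS(x, y_b, np.asarray(w_b, dtype=float))
    c1A = _cost1(preA, lam, min_probes)
    c1B = _cost1(preB, lam, min_probes)
    anyA, multiA, parA = _channel_tables(c1A)
    anyB, multiB, parB = _channel_tables(c1B)
    mA, mB, cpl_wrss = _coupled_pair(preA, preB, kappa)
    # block costs for the four private-structure cases; the coupled
    # single/single case pays 2 lambda like the uncoupled ones
    c11 = cpl_wrss + 2 * lam
    c11[np.arange(n + 1)[None, :] - np.arange(n + 1)[:, None] < min_probes] = _INF
    case_costs = [c11,
                  c1A + multiB,
                  multiA + c1B,
                  multiA + multiB]

    J = np.full(n + 1, _INF)
    parent = np.full(n + 1, -1, dtype=np.int64)
    case = np.full(n + 1, -1, dtype=np.int64)
    J[0] = 0.0
    for t in range(min_probes, n + 1):
        for s in range(0, t - min_probes + 1):
            if J[s] == _INF:
                continue
            for ci, cc in enumerate(case_costs):
                if cc[s, t] == _INF:
                    continue
                c = J[s] + cc[s, t] - (delta if t < n else 0.0)
                if c < J[t]:
                    J[t], parent[t], case[t] = c, s, ci
    if J[n] == _INF:
        raise ValueError("no feasible joint segmentation (check min_probes)")

    # reconstruct blocks right to left
    blocks = []
    t = n
    while t > 0:
        s = int(parent[t])
        blocks.append((s, t, int(case[t])))
        t = s
    blocks.reverse()

    segsA: list[Segment] = []
    segsB: list[Segment] = []
    slope_over_A: dict = {}
    slope_over_B: dict = {}
    for (s, t, ci) in blocks:
        if ci == 0:
            slope_over_A[(s, t)] = float(mA[s, t])
            slope_over_B[(s, t)] = float(mB[s, t])
            ra = rb = [(s, t)]
        elif ci == 1:
            ra = [(s, t)]
            rb = _reconstruct_channel(preB, parB, s, t)
        elif ci == 2:
            ra = _reconstruct_channel(preA, parA, s, t)
            rb = [(s, t)]
        else:
            ra = _reconstruct_channel(preA, parA, s, t)
            rb = _reconstruct_channel(preB, parB, s, t)
        segsA.extend(_make_segments("A", preA, ra, slope_over_A))
        segsB.extend(_make_segments("B", preB, rb, slope_over_B))

    bA = [seg.start_idx for seg in segsA[1:]]
    bB = [seg.start_idx for seg in segsB[1:]]
    # declared shared boundaries are the interior block edges; coincident
    # private boundaries (possible only in the multi/multi case) are kept
    # un-shared, as the optimizer chose that structure
    shared = sorted(t for (s, t, ci) in blocks if t < n)
    return SegmentFit(x, {"A": segsA, "B": segsB},
                      {"A": sorted(bA), "B": sorted(bB)}, shared, float(J[n]))


def fit_genome(track: NormalizedTrack, params: SegmentationParams) -> list[IntervalFit]:
    """Joint segmentation run independently within every inter-site
    interval (restriction sites are free boundaries where the profile
    legitimately resets).  Intervals with fewer than ``min_probes`` probes
    are skipped and logged."""
    fits: list[IntervalFit] = []
    sites = track.sites
    n_skipped = 0
    for iv in np.unique(track.interval_id):
        idx = np.flatnonzero(track.interval_id == iv)
        if idx.size < params.min_probes:
            n_skipped += 1
            logger.debug("interval %d skipped (%d probes)", iv, idx.size)
            continue
        lam, delta, kappa = params.resolve(idx.size)
        sl = idx[0]
        fit = segment_joint(track.position[idx], track.y_a[idx], track.y_b[idx],
                            1.0 / track.var_a[idx], 1.0 / track.var_b[idx],
                            lam, delta, kappa, params.min_probes)
        left = int(sites[iv - 1]) if 1 <= iv <= sites.size else None
        right = int(sites[iv]) if iv < sites.size else None
        fits.append(IntervalFit(int(iv), left, right, int(idx[0]),
                                int(idx[-1] + 1), fit))
    if n_skipped:
        logger.info("fit_genome: %d intervals skipped (< %d probes)",
                    n_skipped, params.min_probes)
    return fits


def segments_table(fits: list[IntervalFit], track: NormalizedTrack):
    """Flatten fitted segments for TSV export."""
    import pandas as pd

    rows = []
    for f in fits:
        for channel, segs in f.fit.segments.items():
            for seg in segs:
                rows.append({
                    "chrom": track.chrom,
                    "interval_start": f.left_site if f.left_site is not None else ".",
                    "interval_end": f.right_site if f.right_site is not None else ".",
                    "channel": channel,
                    "seg_start_probe": f.probe_start + seg.start_idx,
                    "seg_end_probe": f.probe_start + seg.end_idx,
                    "slope": seg.slope,
                    "intercept": seg.intercept,
                    "wrss": seg.wrss,
                })
    return pd.DataFrame(rows, columns=["chrom", "interval_start", "interval_end",
                                       "channel", "seg_start_probe", "seg_end_probe",
                                       "slope", "intercept", "wrss"])
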