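"""Probe filtering, two-channel normalization and variance estimation.

The normalization follows the standard two-color workflow: linear-scale
median matching of the two channels, log2 transform, then a rotation of the
log-log point cloud so that the channel-B-on-channel-A regression line is
the diagonal.  Per-probe variances combine the local co-linearity of the
log2 intensities (residual variance of a short windowed line fit inside the
same inter-site interval) with an intensity-dependent term.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PreprocessParams

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizedTrack",
    "filter_probes",
    "median_scale",
    "rotate_normalize",
    "estimate_variance",
    "assign_intervals",
    "build_track",
]

_PROBE_COLUMNS = {"probe_id", "chrom", "start", "end", "hit_count", "hit_length"}


@dataclass
class NormalizedTrack:
    """Per-probe normalized log2 intensities on the retained probe grid,
    sorted by genomic position within a chromosome."""

    chrom: str
    probe_id: np.ndarray
    position: np.ndarray   # probe start, bp
    probe_end: np.ndarray
    y_a: np.ndarray        # normalized log2, channel A (reference strain)
    y_b: np.ndarray
    var_a: np.ndarray
    var_b: np.ndarray
    interval_id: np.ndarray  # index of the flanking-site interval
    sites: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.position) <= 0):
            raise ValueError("probe positions must be strictly increasing")
        for v in (self.var_a, self.var_b):
            if np.any(~np.isfinite(v)) or np.any(v <= 0):
                raise ValueError("variances must be finite and positive")
        for y in (self.y_a, self.y_b):
            if np.any(~np.isfinite(y)):
                raise ValueError("log2 intensities must be finite")

    def __len__(self) -> int:
        return self.position.size


def filter_probes(mappings: pd.DataFrame) -> pd.DataFrame:
    """Retain probes with a single genomic hit of more than 50 bp.

    Multi-mapping probes (hit_count != 1) and probes whose best hit is
    50 bp or shorter are dropped.
    """
    missing = {"hit_count", "hit_length"} - set(mappings.columns)
    if missing:
        raise ValueError(f"probe mapping table missing columns: {sorted(missing)}")
    keep = (mappings["hit_count"] == 1) & (mappings["hit_length"] > 50)
    out = mappings.loc[keep].reset_index(drop=True)
    logger.info("probe filter: %d of %d retained", len(out), len(mappings))
    return out


def _log_median(values: np.ndarray) -> float:
    """Median on the log2 scale (geometric interpolation for even n), so
    that linear-scale and log-scale median matching agree exactly."""
    return float(np.median(np.log2(values)))


def median_scale(intensities_a: np.ndarray, intensities_b: np.ndarray) -> np.ndarray:
    """Scale channel B so its median equals channel A's median.

    Returns the scaled copy of ``intensities_b``; channel A is unchanged.
    """
    a = np.asarray(intensities_a, dtype=float)
    b = np.asarray(intensities_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("median_scale requires at least one probe per channel")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("intensities must be positive")
    factor = 2.0 ** (_log_median(a) - _log_median(b))
    return b * factor


def _rotation_angle(y_a: np.ndarray, y_b: np.ndarray) -> float:
    """Angle (radians) of the rotation about the centroid after which the
    OLS regression of B on A has slope exactly 1.

    Solves t^2 (Sxy + Syy) - t (Sxx - Syy + 2 Sxy) - (Sxy - Sxx) = 0 for
    t = tan(angle) and picks the smaller-magnitude root (continuity with
    the identity when the cloud is already diagonal).
    """
    xa = y_a - y_a.mean()
    xb = y_b - y_b.mean()
    sxx = float(xa @ xa)
    syy = float(xb @ xb)
    sxy = float(xa @ xb)
    a2 = sxy + syy
    a1 = -(sxx - syy + 2.0 * sxy)
    a0 = -(sxy - sxx)
    if abs(a2) < 1e-300:
        roots = [-a0 / a1] if a1 != 0 else [0.0]
    else:
        disc = a1 * a1 - 4.0 * a2 * a0
        if disc < 0:
            # no rotation of this cloud yields an OLS slope of exactly 1
            # (possible only for weakly correlated channels, which real
            # two-channel data is not); fall back to rotating the fitted
            # line itself onto the diagonal
            warnings.warn("channels too weakly correlated for exact "
                          "diagonal normalization; rotating fitted line only")
            slope = sxy / sxx
            return float(np.arctan(slope) - np.pi / 4.0)
        r = np.sqrt(disc)
        roots = [(-a1 + r) / (2 * a2), (-a1 - r) / (2 * a2)]
    # a root that rotates the cloud to vertical satisfies the condition
    # vacuously (0 == 0); keep only roots with nonvanishing predictor spread
    valid = []
    scale = sxx + syy
    for t in roots:
        c, s = 1.0 / np.sqrt(1 + t * t), t / np.sqrt(1 + t * t)
        sxx_rot = c * c * sxx - 2 * c * s * sxy + s * s * syy
        if sxx_rot > 1e-12 * scale:
            valid.append(t)
    if not valid:
        raise ValueError("no valid rotation (cloud degenerate in both channels)")
    return float(np.arctan(min(valid, key=abs)))


def rotate_normalize(y_a: np.ndarray, y_b: np.ndarray):
    """Rotate the (y_A, y_B) log2 cloud about its centroid so the B-on-A
    regression line becomes the diagonal, then align the channel medians.

    Refitting the same regression on the output gives slope 1 to machine
    precision, and the composite median-scale + rotate pipeline is exactly
    idempotent.  A degenerate predictor (zero variance in y_A) returns the
    inputs unchanged with a warning.
    """
    ya = np.asarray(y_a, dtype=float)
    yb = np.asarray(y_b, dtype=float)
    if ya.size < 2:
        raise ValueError("rotate_normalize requires at least 2 probes")
    if np.ptp(ya) == 0.0:
        warnings.warn("zero variance in channel A; rotation skipped")
        return ya.copy(), yb.copy()
    phi = _rotation_angle(ya, yb)
    c, s = np.cos(phi), np.sin(phi)
    ca, cb = ya.mean(), yb.mean()
    xa, xb = ya - ca, yb - cb
    out_a = c * xa - s * xb + ca
    out_b = s * xa + c * xb + cb
    out_b = out_b + (np.median(out_a) - np.median(out_b))
    return out_a, out_b


def assign_intervals(positions: np.ndarray, sites: np.ndarray) -> np.ndarray:
    """Index of the inter-site interval containing each position.

    Interval 0 precedes the first site; interval k lies between sites
    k-1 and k; interval len(sites) follows the last site.  With an empty
    site map the whole chromosome is one interval (id 0).
    """
    if sites is None or len(sites) == 0:
        warnings.warn("empty restriction map: treating chromosome as one interval")
        return np.zeros(len(positions), dtype=np.int64)
    return np.searchsorted(np.asarray(sites), np.asarray(positions), side="right")


def estimate_variance(positions: np.ndarray, y: np.ndarray,
                      interval_id: np.ndarray, params: PreprocessParams) -> np.ndarray:
    """Per-probe variance of the normalized log2 intensity.

    sigma_i^2 = alpha * (robust residual variance of a least-squares line
    over the window_k probes centred on i, clipped to probe i's inter-site
    interval) + beta / 2^y_i + sigma_floor^2.  The residual scale is the
    scaled median absolute deviation rather than the raw residual variance
    so that the isolated extreme probes produced by real structural changes
    (e.g. probes deleted from one genome) do not inflate the variance of --
    and thereby down-weight -- their own neighborhood.  Intervals with
    fewer than window_k probes fall back to an interval-wide fit.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    out = np.empty(n)
    half = params.window_k // 2
    for iv in np.unique(interval_id):
        idx = np.flatnonzero(interval_id == iv)
        xs, ys = x[idx], y[idx]
        m = idx.size
        if m < 3:
            out[idx] = 0.0
            continue
        k = min(params.window_k, m)
        xw = np.lib.stride_tricks.sliding_window_view(xs, k)
        yw = np.lib.stride_tricks.sliding_window_view(ys, k)
        xb = xw.mean(axis=1, keepdims=True)
        yb = yw.mean(axis=1, keepdims=True)
        vxx = ((xw - xb) ** 2).sum(axis=1, keepdims=True)
        slope = ((xw - xb) * (yw - yb)).sum(axis=1, keepdims=True) / np.maximum(vxx, 1e-300)
        resid = yw - (yb + slope * (xw - xb))
        mad = np.median(np.abs(resid - np.median(resid, axis=1, keepdims=True)), axis=1)
        resvar = (1.4826 * mad) ** 2 * k / (k - 2.0)  # dof correction for the line fit
        win = np.clip(np.arange(m) - half, 0, m - k)  # window centred on i, clipped
        out[idx] = resvar[win]
    return params.alpha * out + params.beta / np.power(2.0, y) + params.sigma_floor2


def build_track(probes: pd.DataFrame, intensities: pd.DataFrame,
                sites: np.ndarray, params: PreprocessParams,
                chrom: str | None = None) -> NormalizedTrack:
    """Full preprocessing pipeline: filter, join, median-scale, log2,
    rotate, estimate variances; returns the normalized probe grid."""
    missing = _PROBE_COLUMNS - set(probes.columns)
    if missing:
        raise ValueError(f"probe table missing columns: {sorted(missing)}")
    retained = filter_probes(probes)
    merged = retained.merge(intensities, on="probe_id", how="left", validate="1:1")
    if merged["intensity_A"].isna().any() or merged["intensity_B"].isna().any():
        examples = merged.loc[merged["intensity_A"].isna() | merged["intensity_B"].isna(),
                              "probe_id"].head(5).tolist()
        raise ValueError(f"probes missing intensity records, e.g. {examples}")
    if chrom is None:
        chroms = merged["chrom"].unique()
        if len(chroms) != 1:
            raise ValueError("build_track handles one chromosome at a time; "
                             f"got {list(chroms)}")
        chrom = str(chroms[0])
    else:
        merged = merged[merged["chrom"] == chrom]
    merged = merged.sort_values("start").reset_index(drop=True)

    a = merged["intensity_A"].to_numpy(dtype=float)
    b = merged["intensity_B"].to_numpy(dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("intensities must be positive for log transformation")
    b = median_scale(a, b)
    y_a, y_b = np.log2(a), np.log2(b)
    y_a, y_b = rotate_normalize(y_a, y_b)

    pos = merged["start"].to_numpy(dtype=np.int64)
    interval_id = assign_intervals(pos, sites)
    var_a = estimate_variance(pos, y_a, interval_id, params)
    var_b = estimate_variance(pos, y_b, interval_id, params)
    logger.info("normalized track: %d probes, %d intervals", len(merged),
                len(np.unique(interval_id)))
    return NormalizedTrack(
        chrom=chrom,
        probe_id=merged["probe_id"].to_numpy(),
        position=pos,
        probe_end=merged["end"].to_numpy(dtype=np.int64),
        y_a=y_a, y_b=y_b, var_a=var_a, var_b=var_b,
        interval_id=interval_id,
        sites=np.asarray(sites, dtype=np.int64) if sites is not None else np.array([], dtype=np.int64),
    )
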