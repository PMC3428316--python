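"""Boundary classification into indel signatures and evaluation.

A structural variant between the two genomes shows up in the fitted
segments as one of four boundary signatures:

``a_split_one_channel``
    A segment boundary exists in exactly one channel: that genome's probe
    distances jump while the other's do not.
``b_sign_flip``
    Both channels break and the between-channel difference changes sign
    across the boundary (typical of repeat-length changes).
``c_unequal_drop``
    Both channels break with steps of the same sign but clearly different
    magnitude (repeat or repetitive-element changes).
``d_new_site``
    One channel's fitted intensity rises sharply at the boundary while the
    other's does not: a restriction site present in only one genome, e.g.
    an insertion carrying the recognition sequence.

Steps are measured from the fitted lines at the midpoint between the two
probes flanking the boundary; a call's genomic interval is the gap between
those probes (the method cannot localize within a probe gap).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CallingParams
from .preprocess import NormalizedTrack
from .segmentation import IntervalFit, SegmentFit

logger = logging.getLogger(__name__)

__all__ = [
    "IndelCall",
    "EvalReport",
    "boundary_steps",
    "classify_boundary",
    "call_indels",
    "evaluate_calls",
]

CASES = ("a_split_one_channel", "b_sign_flip", "c_unequal_drop", "d_new_site")


@dataclass
class IndelCall:
    chrom: str
    start: int
    end: int
    case: str
    magnitude: float  # |step_B - step_A|, log2 units
    score: float      # magnitude / pooled per-probe sigma
    step_a: float
    step_b: float
    boundary_probe: int  # global probe index of the right flanking probe


@dataclass
class EvalReport:
    sensitivity: float
    n_true_positives: int
    n_false_positives: int
    n_truth: int
    n_truth_scored: int  # truth variants with |size| >= min_size
    truth_matched: pd.DataFrame = field(repr=False, default=None)

    def summary(self) -> str:
        return (f"sensitivity {self.sensitivity:.3f} "
                f"({self.n_true_positives} matched calls, "
                f"{self.n_false_positives} false positives, "
                f"{self.n_truth_scored}/{self.n_truth} truth variants scored)")


def _fitted_sides(fit: SegmentFit, channel: str, b: int):
    """(left segment, right segment) around interior boundary index b;
    identical when the channel is continuous across b."""
    left = fit.segment_at(channel, b, "left")
    right = fit.segment_at(channel, b, "right")
    return left, right


def boundary_steps(fit: SegmentFit, boundary: int) -> tuple[float, float]:
    """Signed per-channel fitted-value step across an interior boundary:
    right-limit minus left-limit of the fitted lines at the midpoint
    between the flanking probes.  Exactly 0.0 for a channel whose fit is
    one continuous segment there."""
    n = fit.x.size
    if not 0 < boundary < n:
        raise ValueError(f"boundary {boundary} at or outside the fitted range")
    x_mid = 0.5 * (fit.x[boundary - 1] + fit.x[boundary])
    steps = []
    for channel in ("A", "B"):
        if boundary in fit.boundaries[channel]:
            left, right = _fitted_sides(fit, channel, boundary)
            steps.append(float(right.predict(x_mid) - left.predict(x_mid)))
        else:
            steps.append(0.0)
    return tuple(steps)


def _diff_means(fit: SegmentFit, b: int, k: int = 2):
    """Mean fitted (B - A) over up to k probes on each side of boundary b,
    used by the sign-flip test to resist single-probe noise."""
    lo = max(b - k, 0)
    hi = min(b + k, fit.x.size)
    left_x = fit.x[lo:b]
    right_x = fit.x[b:hi]

    def fitted(channel, xs, side):
        seg = fit.segment_at(channel, b, side)
        return seg.predict(xs)

    d_left = float(np.mean(fitted("B", left_x, "left") - fitted("A", left_x, "left")))
    d_right = float(np.mean(fitted("B", right_x, "right") - fitted("A", right_x, "right")))
    return d_left, d_right


def classify_boundary(steps: tuple[float, float], shared: bool, tau: float,
                      rho: float, diffs: tuple[float, float] | None = None) -> str | None:
    """Assign one of the four signatures to a boundary, or None.

    ``steps`` are the (A, B) fitted steps; ``shared`` says whether the
    boundary exists in both channels; ``diffs`` are the mean fitted B - A
    values left/right of the boundary (for the sign-flip test).  Each
    boundary receives at most one label (first match in the order b, d, c
    for shared boundaries).
    """
    step_a, step_b = steps
    if not np.isfinite(step_a) or not np.isfinite(step_b):
        raise ValueError("steps must be finite")
    if not shared:
        step = step_b if step_a == 0.0 else step_a
        return "a_split_one_channel" if abs(step) >= tau else None
    dstep = step_b - step_a
    if abs(dstep) < tau:
        return None
    if diffs is not None and diffs[0] * diffs[1] < 0:
        return "b_sign_flip"
    hi, lo = max(step_a, step_b), min(step_a, step_b)
    if hi >= tau and lo < tau:
        return "d_new_site"
    if step_a * step_b > 0:
        big, small = max(abs(step_a), abs(step_b)), min(abs(step_a), abs(step_b))
        if small == 0.0 or big / small >= rho:
            return "c_unequal_drop"
    return None


def call_indels(fits: list[IntervalFit], track: NormalizedTrack,
                params: CallingParams, probe_spacing: int | None = None) -> list[IndelCall]:
    """Classify every interior fitted boundary genome-wide and emit calls.

    Adjacent calls of the same case within one probe spacing are merged,
    keeping the larger magnitude.
    """
    if probe_spacing is None:
        probe_spacing = int(np.median(np.diff(track.position))) if len(track) > 1 else 0
    calls: list[IndelCall] = []
    for ivfit in fits:
        fit = ivfit.fit
        bset = sorted(set(fit.boundaries["A"]) | set(fit.boundaries["B"]))
        for b in bset:
            steps = boundary_steps(fit, b)
            shared = b in fit.boundaries["A"] and b in fit.boundaries["B"]
            diffs = _diff_means(fit, b) if shared else None
            case = classify_boundary(steps, shared, params.tau, params.rho, diffs)
            if case is None:
                continue
            gb = ivfit.probe_start + b  # global probe index
            start = int(track.probe_end[gb - 1])
            end = int(track.position[gb])
            if end <= start:  # overlapping/abutting probes
                start, end = int(track.position[gb - 1]), int(track.position[gb]) + 1
            magnitude = abs(steps[1] - steps[0])
            pooled = float(np.sqrt(np.mean([track.var_a[gb - 1], track.var_a[gb],
                                            track.var_b[gb - 1], track.var_b[gb]])))
            calls.append(IndelCall(track.chrom, start, end, case, magnitude,
                                   magnitude / pooled, steps[0], steps[1], gb))
    calls.sort(key=lambda c: c.start)
    merged: list[IndelCall] = []
    for c in calls:
        if merged and c.case == merged[-1].case and c.start - merged[-1].end <= probe_spacing:
            best = max(merged[-1], c, key=lambda k: k.magnitude)
            merged[-1] = IndelCall(c.chrom, merged[-1].start, c.end, c.case,
                                   best.magnitude, best.score, best.step_a,
                                   best.step_b, best.boundary_probe)
        else:
            merged.append(c)
    logger.info("call_indels: %d boundaries -> %d calls", len(calls), len(merged))
    return merged


def _interval_distance(a_start, a_end, b_start, b_end) -> int:
    """Gap between two half-open intervals (0 when they overlap)."""
    return max(0, max(a_start, b_start) - min(a_end, b_end))


def evaluate_calls(calls: list[IndelCall] | pd.DataFrame, truth: pd.DataFrame,
                   tolerance: int, min_size: int) -> EvalReport:
    """Greedy one-to-one matching of calls to truth variants by interval
    distance; sensitivity is computed over truth variants with
    |size| >= min_size, false positives are calls matching no variant."""
    if isinstance(calls, pd.DataFrame):
        call_iv = list(zip(calls["start"].astype(int), calls["end"].astype(int)))
    else:
        call_iv = [(c.start, c.end) for c in calls]
    truth = truth.reset_index(drop=True)
    pairs = []
    for ci, (cs, ce) in enumerate(call_iv):
        for ti, t in truth.iterrows():
            d = _interval_distance(cs, ce, int(t["ref_start"]), int(t["ref_end"]))
            if d <= tolerance:
                pairs.append((d, ci, ti))
    pairs.sort()
    used_calls: set[int] = set()
    matched_truth: dict[int, int] = {}
    for d, ci, ti in pairs:
        if ci in used_calls or ti in matched_truth:
            continue
        used_calls.add(ci)
        matched_truth[ti] = ci
    truth = truth.copy()
    truth["matched"] = [i in matched_truth for i in range(len(truth))]
    scored = truth[truth["size"].abs() >= min_size]
    sens = float(scored["matched"].mean()) if len(scored) else 0.0
    return EvalReport(
        sensitivity=sens,
        n_true_positives=len(used_calls),
        n_false_positives=len(call_iv) - len(used_calls),
        n_truth=len(truth),
        n_truth_scored=len(scored),
        truth_matched=truth,
    )
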