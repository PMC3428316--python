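"""Independent brute-force oracles for the segmentation objective.

These deliberately avoid the package's prefix-sum machinery: segment fits
go through numpy's generic least-squares solver on explicit design
matrices, and the joint objective is evaluated by exhaustive enumeration
of both channels' boundary placements and of the shared/private structure
of coincident boundaries.
"""

from __future__ import annotations

import itertools

import numpy as np


def segmentations(n: int, min_probes: int):
    """All tuples of interior breakpoints splitting range(n) into segments
    of at least min_probes probes."""
    def rec(start):
        if n - start >= min_probes:
            yield ()
        for cut in range(start + min_probes, n - min_probes + 1):
            for rest in rec(cut):
                yield (cut,) + rest
    yield from rec(0)


def wls_fit_lstsq(x, y, w):
    """(slope, intercept-at-0, wrss) by scaled lstsq."""
    sw = np.sqrt(w)
    A = np.stack([x * sw, sw], axis=1)
    coef, _, _, _ = np.linalg.lstsq(A, y * sw, rcond=None)
    resid = y - (coef[0] * x + coef[1])
    return coef[0], coef[1], float((w * resid * resid).sum())


def _wrss_cache(x, y, w, min_probes):
    """wrss of the plain WLS fit for every feasible range [s, t)."""
    n = len(x)
    cache = {}
    for s in range(n):
        for t in range(s + min_probes, n + 1):
            cache[(s, t)] = wls_fit_lstsq(x[s:t], y[s:t], w[s:t])[2]
    return cache


def single_cost(x, y, w, bounds, lam, cache=None):
    edges = [0] + list(bounds) + [len(x)]
    total = 0.0
    for s, t in zip(edges[:-1], edges[1:]):
        wrss = cache[(s, t)] if cache is not None \
            else wls_fit_lstsq(x[s:t], y[s:t], w[s:t])[2]
        total += wrss + lam
    return total


def brute_single(x, y, w, lam, min_probes):
    cache = _wrss_cache(x, y, w, min_probes)
    return min(single_cost(x, y, w, b, lam, cache)
               for b in segmentations(len(x), min_probes))


def coupled_block_cost(x, ya, yb, wa, wb, kappa):
    """Joint fit of one aligned segment pair: minimize
    sum wa (ya - mA x - bA)^2 + sum wb (yb - mB x - bB)^2 + kappa (mA-mB)^2
    by solving the assembled 4x4 normal equations."""
    M = np.zeros((4, 4))
    r = np.zeros(4)
    M[0, 0] = (wa * x * x).sum() + kappa
    M[0, 1] = (wa * x).sum()
    M[0, 2] = -kappa
    M[1, 0] = M[0, 1]
    M[1, 1] = wa.sum()
    M[2, 2] = (wb * x * x).sum() + kappa
    M[2, 3] = (wb * x).sum()
    M[2, 0] = -kappa
    M[3, 2] = M[2, 3]
    M[3, 3] = wb.sum()
    r[0] = (wa * x * ya).sum()
    r[1] = (wa * ya).sum()
    r[2] = (wb * x * yb).sum()
    r[3] = (wb * yb).sum()
    mA, bA, mB, bB = np.linalg.solve(M, r)
    ra = ya - (mA * x + bA)
    rb = yb - (mB * x + bB)
    return float((wa * ra * ra).sum() + (wb * rb * rb).sum()
                 + kappa * (mA - mB) ** 2)


def joint_cost(x, ya, yb, wa, wb, ba, bb, lam, delta, kappa,
               cache_a=None, cache_b=None, cache_cpl=None):
    """Cost of one joint structure choice: boundary tuples ba/bb per
    channel, minimized over which coincident boundaries are declared
    shared (sharing earns the delta discount; a block where both channels
    have exactly one segment is an aligned, slope-coupled pair)."""
    n = len(x)
    coincident = sorted(set(ba) & set(bb))
    base = lam * (len(ba) + 1 + len(bb) + 1)
    best = np.inf
    for k in range(len(coincident) + 1):
        for S in itertools.combinations(coincident, k):
            edges = [0] + list(S) + [n]
            cost = base - delta * len(S)
            for s, t in zip(edges[:-1], edges[1:]):
                in_a = [c for c in ba if s < c < t]
                in_b = [c for c in bb if s < c < t]
                if not in_a and not in_b:
                    if cache_cpl is not None:
                        cost += cache_cpl[(s, t)]
                    else:
                        cost += coupled_block_cost(x[s:t], ya[s:t], yb[s:t],
                                                   wa[s:t], wb[s:t], kappa)
                else:
                    for bounds, y, w, cache in ((in_a, ya, wa, cache_a),
                                                (in_b, yb, wb, cache_b)):
                        sub = [0] + list(bounds) + [t]
                        sub[0] = s
                        for u, v in zip(sub[:-1], sub[1:]):
                            if cache is not None:
                                cost += cache[(u, v)]
                            else:
                                cost += wls_fit_lstsq(x[u:v], y[u:v], w[u:v])[2]
            best = min(best, cost)
    return best


def brute_joint(x, ya, yb, wa, wb, lam, delta, kappa, min_probes):
    n = len(x)
    segs = list(segmentations(n, min_probes))
    cache_a = _wrss_cache(x, ya, wa, min_probes)
    cache_b = _wrss_cache(x, yb, wb, min_probes)
    cache_cpl = {rng: coupled_block_cost(x[rng[0]:rng[1]], ya[rng[0]:rng[1]],
                                         yb[rng[0]:rng[1]], wa[rng[0]:rng[1]],
                                         wb[rng[0]:rng[1]], kappa)
                 for rng in cache_a}
    return min(joint_cost(x, ya, yb, wa, wb, ba, bb, lam, delta, kappa,
                          cache_a, cache_b, cache_cpl)
               for ba in segs for bb in segs)
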