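"""Numerical kernels for the cutpoint dynamic program.

The DP merges an ordered grid of candidate intervals of one continuous
variable into at most ``max_bins`` bins so as to maximize the (conditional)
mutual information with a fixed partner partition, minus a per-cutpoint
penalty.  Kernels are jitted with numba when available; the pure-numpy
fallbacks implement the same contract.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _build_gains(P, PU):
    """Gain matrix for all segments.

    P:  (C+1, M) prefix counts over partner cells (M = ru * ry)
    PU: (C+1, RU) prefix counts per conditioning stratum
    Returns H of shape (C+1, C+1); H[j, i] valid for j < i.
    """
    C1, M = P.shape
    RU = PU.shape[1]
    H = np.zeros((C1, C1))
    for i in range(1, C1):
        for j in range(i):
            acc = 0.0
            for s in range(M):
                c = P[i, s] - P[j, s]
                if c > 0.0:
                    acc += c * np.log(c)
            for u in range(RU):
                b = PU[i, u] - PU[j, u]
                if b > 0.0:
                    acc -= b * np.log(b)
            H[j, i] = acc
    return H


@njit(cache=True)
def _dp_partition(H, lam, max_bins):
    """Maximize sum of segment gains minus (B-1)*lam over partitions with at
    most ``max_bins`` bins.

    Returns (best_value, cuts) where cuts are the internal candidate-boundary
    indices of the optimal partition (empty for a single bin).
    """
    C1 = H.shape[0]
    C = C1 - 1  # number of candidate boundaries + ... positions 0..C
    B = min(max_bins, C)
    NEG = -1e300
    V = np.full((B + 1, C1), NEG)
    back = np.zeros((B + 1, C1), dtype=np.int64)
    for i in range(1, C1):
        V[1, i] = H[0, i]
    for b in range(2, B + 1):
        for i in range(b, C1):
            best = NEG
            arg = b - 1
            for j in range(b - 1, i):
                v = V[b - 1, j] + H[j, i]
                if v > best:
                    best = v
                    arg = j
            V[b, i] = best
            back[b, i] = arg
    best_val = V[1, C]
    best_b = 1
    for b in range(2, B + 1):
        v = V[b, C] - (b - 1) * lam
        if v > best_val + 1e-12:
            best_val = v
            best_b = b
    cuts = np.zeros(best_b - 1, dtype=np.int64)
    i = C
    for b in range(best_b, 1, -1):
        j = back[b, i]
        cuts[b - 2] = j
        i = j
    return best_val, cuts
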