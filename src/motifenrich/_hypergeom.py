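"""Vectorized hypergeometric upper-tail log-probabilities.

The one-sided Fisher tail P(overlap >= k) for a 2x2 table is needed at up to
~10^6 grid cells per motif (PASTAA's joint maximization), which rules out
elementwise library calls.  It is computed here from the log pmf at k
(gamma-function form) plus the standard forward term-ratio series

    pmf(v+1) / pmf(v) = (K - v)(N1 - v) / ((v + 1)(n - K - N1 + v + 1)),

accumulated in linear space with periodic renormalization; the series is
finite, monotone beyond the mode, and summed to machine precision.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln


def _log_binom(m: np.ndarray, k: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    k = np.asarray(k, dtype=float)
    with np.errstate(invalid="ignore"):
        out = gammaln(m + 1) - gammaln(k + 1) - gammaln(m - k + 1)
    return np.where((k < 0) | (k > m), -np.inf, out)


def logsf(k, n: int, K, N1) -> np.ndarray:
    """log P(X >= k) for X ~ Hypergeometric(n, K, N1), broadcast over arrays.

    ``n`` is the population size, ``K`` the number of marked items, ``N1``
    the draw size and ``k`` the observed overlap.  Exactly 0.0 at or below
    the lower support bound max(0, K + N1 - n) and -inf above min(K, N1).
    """
    k, K, N1 = np.broadcast_arrays(np.asarray(k, dtype=np.int64),
                                   np.asarray(K, dtype=np.int64),
                                   np.asarray(N1, dtype=np.int64))
    lower = np.maximum(0, K + N1 - n)
    vmax = np.minimum(K, N1)
    kk = np.clip(k, lower, vmax)
    lp = _log_binom(K, kk) + _log_binom(n - K, N1 - kk) - _log_binom(n, N1)

    # All convergence and renormalization decisions below are made cell by
    # cell, so a cell's result is a deterministic function of its own
    # (k, n, K, N1) regardless of what else is evaluated in the same batch;
    # fixed-threshold scores and maximization sweeps therefore agree exactly.
    # Converged cells are compacted out of the working arrays as the series
    # proceeds, which keeps large grids (PASTAA) affordable.
    shape = kk.shape
    out = np.array(lp, dtype=float).ravel()
    S_all = np.ones(out.shape)
    idx = np.arange(out.size)
    S = np.ones(out.size)
    term = np.ones(out.size)
    v = kk.astype(float).ravel()
    Kf = K.astype(float).ravel()
    Nf = N1.astype(float).ravel()
    steps = int(np.max(vmax - kk, initial=0))
    for _ in range(steps):
        ratio = np.maximum((Kf - v) * (Nf - v), 0.0) / ((v + 1.0) * (n - Kf - Nf + v + 1.0))
        term = term * ratio
        S = S + term
        v += 1.0
        # freeze cells past the mode whose remaining tail is negligible
        done = (ratio <= 1.0) & (term <= 1e-18 * S)
        if done.any():
            S_all[idx[done]] = S[done]
            keep = ~done
            idx, S, term, v, Kf, Nf = idx[keep], S[keep], term[keep], v[keep], Kf[keep], Nf[keep]
            if idx.size == 0:
                break
        big = S > 1e250  # renormalize before linear-space overflow
        if big.any():
            out[idx[big]] += np.log(S[big])
            term[big] /= S[big]
            S[big] = 1.0
    S_all[idx] = S
    out = (out + np.log(S_all)).reshape(shape)
    out = np.minimum(out, 0.0)
    out = np.where(k <= lower, 0.0, out)
    out = np.where(k > vmax, -np.inf, out)
    return out


def logsf_scalar(k: int, n: int, K: int, N1: int) -> float:
    return float(logsf(np.int64(k), n, np.int64(K), np.int64(N1)))
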