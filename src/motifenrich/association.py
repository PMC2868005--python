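"""Association functions F measuring motif-signal association.

Each function maps a mapped dataset (and, where applicable, thresholds t_x /
t_y on the affinity and transformed-signal scales) to a real value F; larger F
always means stronger *positive* association.  For the three statistical
tests (Fisher exact, multi-hypergeometric, rank-sum) F is the reciprocal of a
one-sided p-value; Clover and linear regression return non-statistical
scores; Spearman returns the rank correlation coefficient.

Because 1/p overflows double precision long before the tests lose resolution,
every p-value-based result also carries ``log10_f`` (= -log10 p), and the
partition-maximization layer compares in that domain.  The Clover score is
likewise computed in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp

from .affinity import AffinityKind, MappedDataset
from .errors import (
    DegenerateDataError,
    EmptyPositiveSetError,
    InputError,
    PartitionError,
)

_LN10 = math.log(10.0)
_LR_EPS = 1e-12  # mean-squared-error floor for exact linear fits
RANKSUM_EXACT_MAX_N = 20  # exact enumeration below, normal approximation above


class Method(str, Enum):
    FISHER = "fisher"
    MHG = "mhg"
    RANKSUM = "ranksum"
    CLOVER = "clover"
    LR = "lr"
    SPEARMAN = "spearman"


#: methods whose association function partitions on the signal Y
PARTITION_METHODS = (Method.FISHER, Method.MHG, Method.RANKSUM, Method.CLOVER)


@dataclass(frozen=True)
class AssociationResult:
    method: Method
    f_value: float
    p_value: float | None = None
    log10_f: float | None = None  # log10(F); set whenever F can leave double range
    t_x_used: float | None = None
    t_y_used: float | None = None
    n_positive: int = 0
    details: dict = field(default_factory=dict)

    @property
    def sort_key(self) -> float:
        """Comparable magnitude, overflow-safe: log10(F) when available."""
        return self.log10_f if self.log10_f is not None else self.f_value


def _from_logp(method: Method, logp: float, *, t_x=None, t_y=None, n_positive=0,
               details=None) -> AssociationResult:
    """Package a natural-log p-value as an AssociationResult with F = 1/p."""
    logp = min(logp, 0.0)
    p = math.exp(logp)
    with np.errstate(over="ignore"):
        f = math.inf if logp < -700 else 1.0 / p
    return AssociationResult(
        method=method, f_value=f, p_value=p, log10_f=-logp / _LN10,
        t_x_used=t_x, t_y_used=t_y, n_positive=n_positive, details=details or {},
    )


def _positive_mask(d: MappedDataset, t_y: float) -> np.ndarray:
    mask = d.y >= t_y
    if not np.any(mask):
        raise EmptyPositiveSetError(f"no points with Y >= {t_y}")
    return mask


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------

def hypergeom_logsf(k: int, n: int, K: int, n1: int) -> float:
    """log P(overlap >= k) for the 2x2 table (one-sided upper tail)."""
    from ._hypergeom import logsf_scalar

    return logsf_scalar(k, n, K, n1)


def fisher_association(d: MappedDataset, t_x: float, t_y: float) -> AssociationResult:
    """Fisher exact test on the 2x2 table induced by thresholds t_x and t_y.

    p is the one-sided hypergeometric upper-tail probability of observing at
    least the seen number of points with X >= t_x among those with Y >= t_y.
    """
    if len(d) < 2:
        raise InputError("need at least 2 points")
    pos = _positive_mask(d, t_y)
    n = len(d)
    K = int(np.sum(d.x >= t_x))
    n1 = int(np.sum(pos))
    k = int(np.sum(pos & (d.x >= t_x)))
    return _from_logp(Method.FISHER, hypergeom_logsf(k, n, K, n1),
                      t_x=t_x, t_y=t_y, n_positive=n1, details={"k": k, "K": K})


# ---------------------------------------------------------------------------
# multi-hypergeometric test
# ---------------------------------------------------------------------------

def mhg_logsf(category_counts: np.ndarray, n1: int, observed_total: int) -> float:
    """log P(total >= observed) when n1 points are drawn without replacement.

    ``category_counts[j]`` is the number of points with (capped) count j, for
    j = 0..c.  The draw yields category counts (k_0..k_c) with multivariate
    hypergeometric probability prod C(N_j, k_j) / C(n, n1); the tail is taken
    over the total matched count sum(j * k_j) >= observed, the natural
    extension of Fisher's one-sided enrichment tail.  Computed by a log-space
    sum over the grid of (k_1..k_c) vectors.
    """
    N = np.asarray(category_counts, dtype=np.int64)
    n = int(N.sum())
    c = len(N) - 1
    if not (1 <= n1 <= n):
        raise InputError("n1 must be in [1, n]")
    if observed_total <= 0:
        return 0.0

    def logC(m, k):
        k = np.asarray(k, dtype=float)
        out = gammaln(m + 1) - gammaln(k + 1) - gammaln(m - k + 1)
        return np.where((k < 0) | (k > m), -np.inf, out)

    # broadcastable grids over k_1..k_c
    axes = [np.arange(min(int(N[j]), n1) + 1) for j in range(1, c + 1)]
    grids = np.ix_(*axes) if c > 1 else (axes[0],)
    logw = 0.0
    total = 0
    ksum = 0
    for j, g in enumerate(grids, start=1):
        logw = logw + logC(int(N[j]), g)
        total = total + j * g
        ksum = ksum + g
    k0 = n1 - ksum
    logw = logw + logC(int(N[0]), k0)
    tail = np.where(total >= observed_total, logw, -np.inf)
    return float(logsumexp(tail.ravel()) - logC(n, n1))


class MhgNull:
    """Precomputed tail machinery for the c = 2 multi-hypergeometric null.

    For category counts (N_0, N_1, N_2) the tail over k_1 + 2 k_2 >= obs is
    rewritten as sum over k_2 of C(N_2, k_2) * S(max(0, obs - 2 k_2), n1 - k_2)
    with S(lo, s) = sum_{k_1 >= lo} C(N_1, k_1) C(N_0, s - k_1), a suffix sum
    precomputed once per dataset/motif; each threshold query then costs
    O(min(N_2, n1)).  The maximization sweep and fixed-threshold calls share
    one instance, so their values agree exactly.
    """

    def __init__(self, category_counts: np.ndarray):
        N = np.asarray(category_counts, dtype=np.int64)
        if len(N) != 3:
            raise InputError("MhgNull supports exactly 3 categories (c = 2)")
        self.N = N
        n = int(N.sum())
        self.n = n
        k1 = np.arange(min(int(N[1]), n) + 1)
        s = np.arange(n + 1)
        lp = _log_binom_vec(int(N[1]), k1)[:, None] + _log_binom_vec(
            int(N[0]), s[None, :] - k1[:, None]
        )
        colmax = np.max(lp, axis=0)
        colmax = np.where(np.isfinite(colmax), colmax, 0.0)
        with np.errstate(invalid="ignore"):
            lin = np.exp(lp - colmax[None, :])
        suff = np.cumsum(lin[::-1], axis=0)[::-1]
        with np.errstate(divide="ignore"):
            self._log_suffix = np.log(suff) + colmax[None, :]
        self._lc2 = _log_binom_vec(int(N[2]), np.arange(min(int(N[2]), n) + 1))
        self._lcn = _log_binom_vec(n, np.arange(n + 1))
        self._k1_max = len(k1) - 1

    def logsf(self, n1: int, observed_total: int) -> float:
        """log P(total matched count >= observed) drawing n1 of n points."""
        if not (1 <= n1 <= self.n):
            raise InputError("n1 must be in [1, n]")
        if observed_total <= 0:
            return 0.0
        k2 = np.arange(min(int(self.N[2]), n1) + 1)
        s = n1 - k2
        lo = np.maximum(0, observed_total - 2 * k2)
        reachable = lo <= self._k1_max
        terms = np.full(len(k2), -np.inf)
        idx = np.nonzero(reachable)[0]
        terms[idx] = self._lc2[k2[idx]] + self._log_suffix[lo[idx], s[idx]]
        return float(min(logsumexp(terms) - self._lcn[n1], 0.0))


def _log_binom_vec(m: int, k: np.ndarray) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    with np.errstate(invalid="ignore"):
        out = gammaln(m + 1) - gammaln(k + 1) - gammaln(m - k + 1)
    return np.where((k < 0) | (k > m), -np.inf, out)


def mhg_association(d: MappedDataset, t_y: float, c: int = 2) -> AssociationResult:
    """Multi-hypergeometric test on match counts capped to the range [0, c].

    X values must be integral (MC affinity); counts above c are set to c.
    t_x plays no role.  With c = 1 this reduces exactly to the Fisher exact
    test with t_x = 1.
    """
    if c < 1:
        raise InputError("c must be >= 1")
    if not np.allclose(d.x, np.round(d.x)):
        raise InputError("mHG requires integral affinities (MC)")
    pos = _positive_mask(d, t_y)
    xc = np.minimum(np.round(d.x).astype(np.int64), c)
    N = np.bincount(xc, minlength=c + 1)
    n1 = int(np.sum(pos))
    observed = int(np.sum(xc[pos]))
    if c == 1:
        # two categories: identical to the Fisher exact test with t_x = 1
        logp = hypergeom_logsf(observed, len(d), int(N[1]), n1)
    elif c == 2:
        logp = MhgNull(N).logsf(n1, observed)
    else:
        logp = mhg_logsf(N, n1, observed)
    return _from_logp(Method.MHG, logp, t_y=t_y, n_positive=n1,
                      details={"c": c, "observed_total": observed})


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

def _x_ranks(x: np.ndarray) -> np.ndarray:
    """Ranks with rank 1 = largest X; ties receive average ranks."""
    return stats.rankdata(-x, method="average")


def ranksum_logcdf_exact(ranks2: np.ndarray, n1: int, W2: float) -> float:
    """Exact log P(rank-sum <= W) by dynamic programming over doubled ranks.

    ``ranks2`` are the ranks multiplied by 2 (integers even with average-rank
    ties); ``W2`` is the doubled observed positive rank-sum.  Counts subsets
    of size n1 with doubled rank-sum <= W2.
    """
    r2 = np.rint(ranks2).astype(np.int64)
    n = len(r2)
    maxs = int(np.sort(r2)[-n1:].sum())
    W2i = int(math.floor(W2 + 1e-9))
    if W2i >= maxs:
        return 0.0
    # ways[j, s] = number of size-j subsets with doubled rank-sum s
    ways = np.zeros((n1 + 1, maxs + 1))
    ways[0, 0] = 1.0
    for r in r2:
        ways[1:, r:] += ways[:-1, :-r or None].copy() if r else ways[:-1, :]
    favourable = ways[n1, : min(W2i, maxs) + 1].sum()
    total = math.comb(n, n1)
    return math.log(favourable) - math.log(total)


def ranksum_logcdf_normal(n: int, n1: int, W: float, tie_term: float) -> float:
    """Normal approximation to log P(rank-sum <= W) with tie-corrected variance
    and a 0.5 continuity correction.  ``tie_term`` is sum(t^3 - t) over tie
    group sizes t."""
    n2 = n - n1
    mu = n1 * (n + 1) / 2.0
    var = n1 * n2 * (n + 1) / 12.0 - n1 * n2 * tie_term / (12.0 * n * (n - 1))
    if var <= 0:
        raise DegenerateDataError("rank-sum variance is zero (all X tied)")
    z = (W + 0.5 - mu) / math.sqrt(var)
    return float(stats.norm.logcdf(z))


def _tie_term(ranks: np.ndarray) -> float:
    _, counts = np.unique(ranks, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def ranksum_association(d: MappedDataset, t_y: float) -> AssociationResult:
    """Rank-sum test: are the positive set's affinities unusually large?

    Points are ranked by X with rank 1 = largest; the p-value is
    P(rank-sum of a random size-n1 subset <= observed rank-sum of the
    positive set).  Exact by enumeration for n <= 20, otherwise a normal
    approximation with tie correction and continuity correction.
    """
    pos = _positive_mask(d, t_y)
    n = len(d)
    n1 = int(np.sum(pos))
    if n1 == n:
        raise PartitionError("rank-sum requires a nonempty negative set")
    ranks = _x_ranks(d.x)
    W = float(np.sum(ranks[pos]))
    if n <= RANKSUM_EXACT_MAX_N:
        logp = ranksum_logcdf_exact(2 * ranks, n1, 2 * W)
    else:
        logp = ranksum_logcdf_normal(n, n1, W, _tie_term(ranks))
    return _from_logp(Method.RANKSUM, logp, t_y=t_y, n_positive=n1, details={"W": W})


# ---------------------------------------------------------------------------
# Clover score
# ---------------------------------------------------------------------------

def clover_log_scores(a: np.ndarray) -> np.ndarray:
    """Log Clover scores of every prefix of the affinity sequence ``a``.

    The Clover score of a positive set with affinities a_1..a_P is the mean
    over subset sizes j of the mean size-j subset product, i.e.
    (1/P) * sum_j e_j(a) / C(P, j) with e_j the j-th elementary symmetric
    polynomial.  The stable recursion d(i, j) = [j a_i d(i-1, j-1) +
    (i-j) d(i-1, j)] / i maintains d(i, j) = e_j(a_1..a_i)/C(i, j) point by
    point, so one pass yields the score of every prefix; it is evaluated in
    log space because subset products overflow doubles for large sets.
    Returns log scores for prefixes of length 1..len(a).
    """
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise InputError("Clover requires strictly positive affinities")
    P = len(a)
    la = np.log(a)
    ld = np.full(P + 1, -np.inf)
    ld[0] = 0.0
    out = np.empty(P)
    logi = np.log(np.arange(1, P + 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(1, P + 1):
            j = np.arange(1, i + 1)
            grow = logi[j - 1] + la[i - 1] + ld[0:i]        # choose point i
            keep = np.where(i - j > 0, np.log(np.maximum(i - j, 1)), -np.inf) + ld[1 : i + 1]
            ld[1 : i + 1] = np.logaddexp(grow, keep) - logi[i - 1]
            out[i - 1] = logsumexp(ld[1 : i + 1]) - logi[i - 1]
    return out


def clover_association(d: MappedDataset, t_y: float) -> AssociationResult:
    """Clover score: average motif affinity over all subsets of the positive set."""
    if d.affinity_kind not in (AffinityKind.AMA, AffinityKind.RMA):
        raise InputError("Clover requires the AMA affinity function")
    pos = _positive_mask(d, t_y)
    # process positives in descending-Y order so fixed-threshold calls agree
    # bit-for-bit with the incremental partition sweep
    order = np.argsort(-d.y, kind="stable")
    a = d.x[order][pos[order]]
    log_score = float(clover_log_scores(a)[-1])
    f = math.inf if log_score > 700 else math.exp(log_score)
    return AssociationResult(
        method=Method.CLOVER, f_value=f, log10_f=log_score / _LN10,
        t_y_used=t_y, n_positive=int(len(a)),
    )


# ---------------------------------------------------------------------------
# linear regression and Spearman
# ---------------------------------------------------------------------------

def _lr_stats(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and mean-squared residual of Y = mX + b."""
    xm = x - x.mean()
    sxx = float(np.dot(xm, xm))
    if sxx == 0.0:
        raise DegenerateDataError("linear regression requires non-constant X")
    ym = y - y.mean()
    m = float(np.dot(xm, ym)) / sxx
    resid = ym - m * xm
    return m, float(np.dot(resid, resid)) / len(x)


def lr_association(d: MappedDataset) -> AssociationResult:
    """Linear-regression association: F = sgn(m) / E.

    Y = mX + b is fitted by least squares over all points, with no partition,
    outlier removal or skewness check; E is the mean squared residual and
    sgn(m) is -1 for negative slopes, +1 otherwise.  Exact fits (E = 0) are
    capped at sgn(m)/1e-12 and flagged.
    """
    if len(d) < 3:
        raise InputError("linear regression needs at least 3 points")
    m, E = _lr_stats(d.x, d.y)
    sgn = -1.0 if m < 0 else 1.0
    exact = E < _LR_EPS
    f = sgn / max(E, _LR_EPS)
    return AssociationResult(
        method=Method.LR, f_value=f, n_positive=len(d),
        details={"slope": m, "mse": E, "exact_fit": exact},
    )


def spearman_association(d: MappedDataset) -> AssociationResult:
    """Spearman rank correlation of (X, Y); threshold-free on both axes."""
    if len(d) < 3:
        raise InputError("Spearman needs at least 3 points")
    if np.all(d.x == d.x[0]) or np.all(d.y == d.y[0]):
        raise DegenerateDataError("Spearman requires non-constant X and Y")
    rho = float(stats.spearmanr(d.x, d.y).statistic)
    return AssociationResult(method=Method.SPEARMAN, f_value=rho, n_positive=len(d))


# ---------------------------------------------------------------------------
# dispatch and permutation p-values
# ---------------------------------------------------------------------------

def negate_direction(d: MappedDataset, method: Method, *, t_x: float = 1.0,
                     c: int = 2) -> MappedDataset:
    """Reverse the affinity scale so the method's positive-association tail
    measures *negative* association on the original data.

    Exact identities: Fisher tests the depletion tail via the indicator of
    "no match at t_x" (upper tail on non-matches = lower tail on matches);
    mHG reverses the capped count scale (x -> c - x, mapping total >= obs
    onto total <= obs of the original); rank-sum reflects the ranks
    (x -> max x - x); Clover reverses the multiplicative scale (x -> 1/x).
    """
    if method is Method.FISHER:
        x = (d.x < t_x).astype(float)
    elif method is Method.MHG:
        x = c - np.minimum(np.round(d.x), c)
    elif method is Method.CLOVER:
        x = 1.0 / d.x
    elif method is Method.RANKSUM:
        x = float(d.x.max()) - d.x
    else:
        raise InputError(f"no affinity reversal defined for {method.value}")
    return MappedDataset(d.ids, x, d.y, d.affinity_kind, d.signal_kind)


def compute_association(
    d: MappedDataset,
    method: Method | str,
    *,
    t_x: float = 1.0,
    t_y: float | None = None,
    c: int = 2,
    direction: str = "positive",
) -> AssociationResult:
    """Evaluate one association function with its method-specific arguments.

    ``direction="negative"`` reports depletion instead of enrichment: the
    relevant tail or sign is negated, so large F then indicates strong
    *negative* association.
    """
    method = Method(method)
    if direction not in ("positive", "negative"):
        raise InputError("direction must be 'positive' or 'negative'")
    if direction == "negative":
        if method in (Method.LR, Method.SPEARMAN):
            res = compute_association(d, method, t_x=t_x, t_y=t_y, c=c)
            return AssociationResult(
                method=method, f_value=-res.f_value, p_value=res.p_value,
                log10_f=None, t_x_used=res.t_x_used, t_y_used=res.t_y_used,
                n_positive=res.n_positive,
                details={**res.details, "direction": "negative"},
            )
        d = negate_direction(d, method, t_x=t_x, c=c)
    if method in PARTITION_METHODS:
        if t_y is None:
            raise InputError(f"{method.value} requires a Y threshold t_y")
        if method is Method.FISHER:
            return fisher_association(d, t_x if direction == "positive" else 1.0, t_y)
        if method is Method.MHG:
            return mhg_association(d, t_y, c=c)
        if method is Method.RANKSUM:
            return ranksum_association(d, t_y)
        return clover_association(d, t_y)
    if method is Method.LR:
        return lr_association(d)
    return spearman_association(d)


def permutation_pvalue(
    d: MappedDataset,
    method: Method | str,
    n_perm: int,
    seed: int,
    **method_kwargs,
) -> float:
    """Permutation p-value of the observed F: permute Y against X.

    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm), with a seeded generator so
    identical seeds give identical p-values.  Comparisons use the
    overflow-safe sort key.
    """
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    observed = compute_association(d, method, **method_kwargs).sort_key
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = d.with_y(rng.permutation(d.y))
        if compute_association(perm, method, **method_kwargs).sort_key >= observed:
            hits += 1
    return (1 + hits) / (1 + n_perm)
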