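"""Association scores R: maximization of F over signal-partition thresholds.

Four scoring regimes are provided.  YFP evaluates F at one fixed threshold on
the raw signal; YCPM maximizes F over all thresholds admitting only points
with raw p-value <= b into the positive set; YUPM maximizes over every
distinct observed signal value; and the PASTAA-style score maximizes the
Fisher statistic jointly over top-i-by-affinity and top-j-by-signal cutoffs,
both capped (1000 sequences by default).

Thresholds in this module are stated on the *raw* p-value scale used in
ChIP-style signal files (e.g. t_y = 0.001 means the positive set is the
sequences with fluorescence p <= 0.001); they are converted internally to the
transformed Y scale of the mapped dataset.  Equal-Y points always land on the
same side of a partition, and among thresholds with equal F the one with the
smallest positive set is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from . import association as assoc
from ._hypergeom import logsf as hypergeom_logsf_grid
from .affinity import MappedDataset, SignalKind, transform_signal
from .association import AssociationResult, Method, _from_logp
from .errors import (
    DegenerateDataError,
    EmptyPositiveSetError,
    InputError,
    PartitionError,
)


class PartitionMode(str, Enum):
    NONE = "none"
    YFP = "yfp"
    YCPM = "ycpm"
    YUPM = "yupm"
    PASTAA = "pastaa"


@dataclass(frozen=True)
class PartitionSpec:
    """Configuration of the partition-maximization regime.

    ``t_y`` (YFP) and ``y_bound`` (YCPM) are raw-signal-scale thresholds;
    ``max_positive`` optionally caps the positive-set size for the
    maximization modes (the DRIM-style count constraint); the PASTAA maxima
    cap the top-by-X and top-by-Y cutoff grids.
    """

    mode: PartitionMode = PartitionMode.YFP
    t_y: float | None = None
    y_bound: float | None = None
    max_positive: int | None = None
    max_positive_x: int = 1000
    max_positive_y: int = 1000

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", PartitionMode(self.mode))
        if self.mode is PartitionMode.YFP and self.t_y is None:
            raise InputError("YFP requires a fixed threshold t_y")
        if self.mode is PartitionMode.YCPM and self.y_bound is None:
            raise InputError("YCPM requires an upper bound y_bound")
        if self.mode is PartitionMode.PASTAA and (self.max_positive_x < 1 or self.max_positive_y < 1):
            raise InputError("PASTAA maxima must be >= 1")


@dataclass(frozen=True)
class ScoredMotif:
    motif_id: str
    r: float | None = None
    best: AssociationResult | None = None
    skipped: bool = False
    reason: str | None = None

    @property
    def sort_key(self) -> float:
        if self.skipped or self.best is None:
            return -math.inf
        return self.best.sort_key


def _raw_to_y(t_raw: float, kind: SignalKind) -> float:
    """Convert a raw p-value threshold to the transformed Y scale."""
    if kind is SignalKind.RAW:
        return t_raw
    return transform_signal(t_raw, kind)


def candidate_thresholds(
    d: MappedDataset,
    bound: float | None = None,
    max_positive: int | None = None,
) -> np.ndarray:
    """Distinct observed Y values, descending, optionally constrained.

    Each candidate t yields a distinct nonempty positive set {Y >= t}.  With
    ``bound`` (raw p-value scale), only candidates whose positive set is
    confined to points with raw p <= bound are kept; with ``max_positive``,
    only candidates with positive-set size <= max_positive.
    """
    ts = np.unique(d.y)[::-1]  # descending
    if bound is not None:
        ts = ts[ts >= _raw_to_y(bound, d.signal_kind)]
    if max_positive is not None:
        sizes = np.array([np.sum(d.y >= t) for t in ts])
        ts = ts[sizes <= max_positive]
    return ts


def _skip(motif_id: str, reason: str) -> ScoredMotif:
    return ScoredMotif(motif_id=motif_id, skipped=True, reason=reason)


def score_yfp(
    d: MappedDataset,
    method: Method | str,
    t_y: float,
    *,
    motif_id: str = "",
    t_x: float = 1.0,
    c: int = 2,
) -> ScoredMotif:
    """Y-fixed-partition score: F at the single raw-scale threshold t_y."""
    ty = _raw_to_y(t_y, d.signal_kind)
    try:
        res = assoc.compute_association(d, method, t_x=t_x, t_y=ty, c=c)
    except (EmptyPositiveSetError, PartitionError, DegenerateDataError) as exc:
        return _skip(motif_id, str(exc))
    return ScoredMotif(motif_id=motif_id, r=res.f_value, best=res)


def _sweep(d: MappedDataset, method: Method, cands: np.ndarray,
           t_x: float, c: int) -> list[AssociationResult]:
    """Evaluate F at every candidate threshold, with vectorized fast paths.

    The fast paths reproduce the single-call functions operation for
    operation (same scipy kernels, same floating-point accumulation order),
    so a maximum found here equals an exhaustive sweep of individual calls
    exactly.
    """
    n = len(d)
    order = np.argsort(-d.y, kind="stable")
    y_sorted = d.y[order]
    x_sorted = d.x[order]
    # prefix size for each candidate threshold (ties grouped by value)
    m_of = np.searchsorted(-y_sorted, -cands, side="right")
    results: list[AssociationResult] = []

    if method is Method.FISHER:
        K = int(np.sum(d.x >= t_x))
        kcum = np.cumsum(x_sorted >= t_x)
        ks = kcum[m_of - 1]
        logps = hypergeom_logsf_grid(ks, n, np.full_like(ks, K), m_of.astype(np.int64))
        for t, m, k, logp in zip(cands, m_of, ks, logps):
            results.append(_from_logp(Method.FISHER, float(logp),
                                      t_x=t_x, t_y=float(t), n_positive=int(m),
                                      details={"k": int(k), "K": K}))
    elif method is Method.MHG:
        if not np.allclose(d.x, np.round(d.x)):
            raise InputError("mHG requires integral affinities (MC)")
        xc = np.minimum(np.round(d.x).astype(np.int64), c)
        Ncat = np.bincount(xc, minlength=c + 1)
        obs_cum = np.cumsum(np.minimum(np.round(x_sorted).astype(np.int64), c))
        if c == 1:
            null_logsf = lambda m, obs: assoc.hypergeom_logsf(obs, n, int(Ncat[1]), m)
        elif c == 2:
            table = assoc.MhgNull(Ncat)
            null_logsf = table.logsf
        else:
            null_logsf = lambda m, obs: assoc.mhg_logsf(Ncat, m, obs)
        for t, m in zip(cands, m_of):
            logp = null_logsf(int(m), int(obs_cum[m - 1]))
            results.append(_from_logp(Method.MHG, logp, t_y=float(t), n_positive=int(m),
                                      details={"c": c, "observed_total": int(obs_cum[m - 1])}))
    elif method is Method.RANKSUM:
        ranks = assoc._x_ranks(d.x)
        tie_term = assoc._tie_term(ranks)
        for t, m in zip(cands, m_of):
            if m == n:
                continue  # empty negative set: not an admissible partition
            # same masked summation as the fixed-threshold call, so a sweep
            # maximum equals the corresponding single evaluation exactly
            W = float(np.sum(ranks[d.y >= t]))
            if n <= assoc.RANKSUM_EXACT_MAX_N:
                logp = assoc.ranksum_logcdf_exact(2 * ranks, int(m), 2 * W)
            else:
                logp = assoc.ranksum_logcdf_normal(n, int(m), W, tie_term)
            results.append(_from_logp(Method.RANKSUM, logp, t_y=float(t),
                                      n_positive=int(m), details={"W": W}))
    elif method is Method.CLOVER:
        log_scores = assoc.clover_log_scores(x_sorted)  # prefix scores, Y-desc order
        for t, m in zip(cands, m_of):
            ls = float(log_scores[m - 1])
            f = math.inf if ls > 700 else math.exp(ls)
            results.append(AssociationResult(method=Method.CLOVER, f_value=f,
                                             log10_f=ls / math.log(10.0),
                                             t_y_used=float(t), n_positive=int(m)))
    else:
        raise InputError(f"method {method.value} does not use a Y partition")
    return results


def _best(results: list[AssociationResult], motif_id: str) -> ScoredMotif:
    """Maximum F; ties broken toward the smaller positive set."""
    best: AssociationResult | None = None
    for res in results:
        if best is None or res.sort_key > best.sort_key or (
            res.sort_key == best.sort_key and res.n_positive < best.n_positive
        ):
            best = res
    if best is None:
        return _skip(motif_id, "no admissible partition threshold")
    return ScoredMotif(motif_id=motif_id, r=best.f_value, best=best)


def score_ycpm(
    d: MappedDataset,
    method: Method | str,
    b: float,
    *,
    motif_id: str = "",
    t_x: float = 1.0,
    c: int = 2,
    max_positive: int | None = None,
) -> ScoredMotif:
    """Constrained partition maximization: max F over thresholds bounded by b.

    b is a raw p-value upper bound: the positive set may only contain points
    with raw p <= b.
    """
    method = Method(method)
    cands = candidate_thresholds(d, bound=b, max_positive=max_positive)
    if len(cands) == 0:
        return _skip(motif_id, f"no candidate threshold admissible under bound {b}")
    return _best(_sweep(d, method, cands, t_x, c), motif_id)


def score_yupm(
    d: MappedDataset,
    method: Method | str,
    *,
    motif_id: str = "",
    t_x: float = 1.0,
    c: int = 2,
    max_positive: int | None = None,
) -> ScoredMotif:
    """Unconstrained partition maximization: max F over all observed thresholds."""
    method = Method(method)
    cands = candidate_thresholds(d, max_positive=max_positive)
    if len(cands) == 0:
        return _skip(motif_id, "no candidate thresholds")
    return _best(_sweep(d, method, cands, t_x, c), motif_id)


def score_pastaa(
    d: MappedDataset,
    max_positive_x: int = 1000,
    max_positive_y: int = 1000,
    *,
    motif_id: str = "",
) -> ScoredMotif:
    """PASTAA-style joint X/Y constrained maximization of the Fisher statistic.

    Points are sorted by X descending and by Y descending (ties broken by
    input order, deterministically); for every pair (i, j) of cutoffs up to
    the caps, the hypergeometric upper-tail p of the overlap between the
    top-i-by-X and top-j-by-Y sets is computed on the full grid, and
    R = 1 / min p.  Overlap counts are maintained incrementally so the grid
    costs O(max_x * max_y).
    """
    n = len(d)
    if n < 2:
        raise InputError("need at least 2 points")
    if max_positive_x < 1 or max_positive_y < 1:
        raise InputError("PASTAA maxima must be >= 1")
    mx = min(max_positive_x, n)
    my = min(max_positive_y, n)
    order_x = np.argsort(-d.x, kind="stable")
    order_y = np.argsort(-d.y, kind="stable")
    y_rank = np.empty(n, dtype=np.int64)  # 1-based position in the Y ordering
    y_rank[order_y] = np.arange(1, n + 1)
    # overlap[i-1, j-1] = |top-i-by-X  intersect  top-j-by-Y|
    js = np.arange(1, my + 1)
    indic = (y_rank[order_x[:mx]][:, None] <= js[None, :])
    overlap = np.cumsum(indic, axis=0)
    iis = np.arange(1, mx + 1)
    logp = hypergeom_logsf_grid(overlap, n, np.broadcast_to(iis[:, None], overlap.shape),
                                np.broadcast_to(js[None, :], overlap.shape))
    flat = np.argmin(logp)  # row-major: smallest i, then smallest j, on ties
    bi, bj = divmod(int(flat), my)
    best_logp = float(logp[bi, bj])
    res = _from_logp(Method.FISHER, best_logp,
                     t_x=float(iis[bi]), t_y=float(js[bj]), n_positive=int(js[bj]),
                     details={"top_x": int(iis[bi]), "top_y": int(js[bj]),
                              "overlap": int(overlap[bi, bj])})
    return ScoredMotif(motif_id=motif_id, r=res.f_value, best=res)


def score_motif(
    d: MappedDataset,
    method: Method | str,
    spec: PartitionSpec,
    *,
    motif_id: str = "",
    t_x: float = 1.0,
    c: int = 2,
) -> ScoredMotif:
    """Score one mapped dataset under the partition regime in ``spec``."""
    method = Method(method)
    if spec.mode is PartitionMode.PASTAA:
        return score_pastaa(d, spec.max_positive_x, spec.max_positive_y, motif_id=motif_id)
    if spec.mode is PartitionMode.NONE:
        try:
            res = assoc.compute_association(d, method)
        except (DegenerateDataError, InputError) as exc:
            if isinstance(exc, InputError):
                raise
            return _skip(motif_id, str(exc))
        return ScoredMotif(motif_id=motif_id, r=res.f_value, best=res)
    if spec.mode is PartitionMode.YFP:
        return score_yfp(d, method, spec.t_y, motif_id=motif_id, t_x=t_x, c=c)
    if spec.mode is PartitionMode.YCPM:
        return score_ycpm(d, method, spec.y_bound, motif_id=motif_id, t_x=t_x, c=c,
                          max_positive=spec.max_positive)
    return score_yupm(d, method, motif_id=motif_id, t_x=t_x, c=c,
                      max_positive=spec.max_positive)
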