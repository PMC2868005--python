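"""Motif affinity functions: mapping sequences to per-sequence scores X_g.

Three affinity functions are provided.  MC (match-count) counts the
strand-positions whose PWM score has a match p-value <= t_m under the
zero-order background null.  AMA (average motif affinity) is the arithmetic
mean of the *likelihood ratio* (not its log) over all valid strand-positions
on both strands, approximating total occupancy.  RMA (relative motif
affinity) divides AMA by the maximum single-position likelihood ratio so its
range is [0, 1].

Windows containing any non-ACGT character are skipped entirely by every
affinity function; the AMA denominator counts only windows actually scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from . import scan
from .errors import EmptyDatasetError, InputError, UndefinedAffinityError
from .motifs import Motif, ScoreDistribution, integer_llr, reverse_complement

logger = logging.getLogger(__name__)


class AffinityKind(str, Enum):
    MC = "mc"
    AMA = "ama"
    RMA = "rma"


class SignalKind(str, Enum):
    RECIPROCAL_P = "reciprocal_p"
    NEGLOG_P = "neglog_p"
    RAW = "raw"


@dataclass(frozen=True)
class SequenceRecord:
    """A DNA sequence paired with its biological signal.

    ``raw_signal`` is typically a fluorescence p-value in (0, 1];
    ``transformed_signal`` is the larger-is-stronger value Y_g, populated once
    a signal transform has been applied.
    """

    id: str
    sequence: str
    raw_signal: float
    transformed_signal: float | None = None


@dataclass(frozen=True)
class MappedPoint:
    id: str
    x: float
    y: float


@dataclass
class MappedDataset:
    """The mapped dataset: one (X_g, Y_g) point per retained sequence."""

    ids: list[str]
    x: np.ndarray
    y: np.ndarray
    affinity_kind: AffinityKind
    signal_kind: SignalKind

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.ids) != len(self.x) or len(self.x) != len(self.y):
            raise InputError("ids, x and y must have equal lengths")
        if np.any(~np.isfinite(self.x)) or np.any(~np.isfinite(self.y)):
            raise InputError("mapped dataset must not contain missing values")
        if np.any(self.x < 0):
            raise InputError("affinities must be nonnegative")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def points(self) -> list[MappedPoint]:
        return [MappedPoint(i, float(a), float(b)) for i, a, b in zip(self.ids, self.x, self.y)]

    def with_y(self, y: np.ndarray) -> "MappedDataset":
        return MappedDataset(self.ids, self.x, np.asarray(y, dtype=float),
                             self.affinity_kind, self.signal_kind)


def transform_signal(p, kind: SignalKind | str):
    """Transform raw signals to the larger-is-stronger scale Y.

    ``reciprocal_p`` -> 1/p, ``neglog_p`` -> -log10(p), ``raw`` -> identity.
    Both p-value transforms are strictly decreasing in p, so thresholding
    Y >= t_y is equivalent to thresholding p <= t for the corresponding t.
    """
    kind = SignalKind(kind)
    arr = np.asarray(p, dtype=float)
    if kind is SignalKind.RAW:
        return arr if arr.ndim else float(arr)
    if np.any(arr <= 0) or np.any(arr > 1):
        raise InputError("p-values must lie in (0, 1]")
    out = 1.0 / arr if kind is SignalKind.RECIPROCAL_P else -np.log10(arr)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# single-sequence affinity functions
# ---------------------------------------------------------------------------

def _lr_window_means(codes: np.ndarray, motif: Motif) -> tuple[np.ndarray, np.ndarray]:
    """Per-row mean likelihood ratio over both strands and valid window count."""
    fwd, rev = scan.strand_scores(codes, motif, lambda m: m.llr)
    both = np.concatenate([fwd, rev], axis=1)  # log2 likelihood ratios
    valid = np.isfinite(both)
    nvalid = valid.sum(axis=1)
    with np.errstate(invalid="ignore"):
        lr = np.exp2(both)
    sums = np.where(valid, lr, 0.0).sum(axis=1)
    means = np.divide(sums, nvalid, out=np.full(len(sums), np.nan), where=nvalid > 0)
    return means, nvalid


def ama(seq: str, motif: Motif) -> float:
    """Average motif affinity: mean likelihood ratio over both strands."""
    means, nvalid = _lr_window_means(scan.encode(seq)[None, :], motif)
    if nvalid[0] == 0:
        raise UndefinedAffinityError(
            f"sequence has no valid window for motif {motif.id!r} (width {motif.width})"
        )
    return float(means[0])


def rma(seq: str, motif: Motif) -> float:
    """Relative motif affinity: AMA / max single-position likelihood ratio."""
    return ama(seq, motif) / motif.max_likelihood_ratio


def _match_counts(codes: np.ndarray, motif: Motif, t_m: float, dist: ScoreDistribution) -> np.ndarray:
    if not (0 < t_m <= 1):
        raise InputError(f"t_m must be in (0, 1], got {t_m}")
    smin = dist.score_threshold(t_m)
    illr = integer_llr(motif, dist.scale).astype(float)
    fwd = scan.window_scores(codes, illr)
    rev = scan.window_scores(codes, integer_llr(reverse_complement(motif), dist.scale).astype(float))
    both = np.concatenate([fwd, rev], axis=1)
    with np.errstate(invalid="ignore"):
        hits = (both >= smin) & np.isfinite(both)
    return hits.sum(axis=1)


def match_count(seq: str, motif: Motif, t_m: float, dist: ScoreDistribution) -> int:
    """Number of strand-positions (both strands) with match p-value <= t_m.

    Overlapping matches all count; sequences shorter than the motif return 0.
    """
    return int(_match_counts(scan.encode(seq)[None, :], motif, t_m, dist)[0])


# ---------------------------------------------------------------------------
# dataset mapping
# ---------------------------------------------------------------------------

def map_dataset(
    records: Sequence[SequenceRecord],
    motif: Motif,
    affinity_kind: AffinityKind | str,
    *,
    signal_kind: SignalKind | str = SignalKind.RECIPROCAL_P,
    t_m: float | None = None,
    dist: ScoreDistribution | None = None,
) -> MappedDataset:
    """Map sequence records to (X_g, Y_g) points for one motif.

    Records whose affinity is undefined (no valid window) are dropped with a
    warning; dropping everything raises :class:`EmptyDatasetError`.  For MC,
    ``t_m`` and a precomputed :class:`ScoreDistribution` are required.
    """
    affinity_kind = AffinityKind(affinity_kind)
    signal_kind = SignalKind(signal_kind)
    if not records:
        raise EmptyDatasetError("no records to map")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise InputError("sequence ids must be unique within a dataset")
    codes = scan.encode_batch([r.sequence for r in records])

    if affinity_kind is AffinityKind.MC:
        if t_m is None or dist is None:
            raise InputError("MC affinity requires t_m and a score distribution")
        x = _match_counts(codes, motif, t_m, dist).astype(float)
        keep = np.ones(len(records), dtype=bool)  # MC is defined (0) even with no window
    else:
        means, nvalid = _lr_window_means(codes, motif)
        keep = nvalid > 0
        x = means
        if affinity_kind is AffinityKind.RMA:
            x = x / motif.max_likelihood_ratio

    dropped = [ids[i] for i in np.nonzero(~keep)[0]]
    if dropped:
        logger.warning(
            "dropping %d record(s) with undefined affinity for motif %s: %s",
            len(dropped), motif.id, ", ".join(dropped[:5]) + ("..." if len(dropped) > 5 else ""),
        )
    if not np.any(keep):
        raise EmptyDatasetError(f"all records dropped for motif {motif.id!r}")
    raw = np.array([r.raw_signal for r in records])[keep]
    y = transform_signal(raw, signal_kind)
    return MappedDataset(
        ids=[i for i, k in zip(ids, keep) if k],
        x=x[keep],
        y=np.atleast_1d(y),
        affinity_kind=affinity_kind,
        signal_kind=signal_kind,
    )
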