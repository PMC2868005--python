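"""Evaluation harness: motif-library ranking and percentile rank accuracy.

A method is tested on a dataset by scoring every motif in a library with
identical settings and asking where the designated true motif's association
score ranks.  Scores are sorted in increasing order so the most positively
associated motif has rank N; percentile rank accuracy (PRA) maps that rank
affinely onto [0, 100] with 100 ideal.  Ties receive average ranks, so a
scorer returning a constant lands at PRA 50 in expectation rather than at
either extreme.  Datasets where the signal threshold produces an empty
positive set are skipped and excluded from aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .affinity import (
    AffinityKind,
    MappedDataset,
    SequenceRecord,
    SignalKind,
    map_dataset,
)
from .association import Method
from .errors import InputError
from .motifs import BackgroundModel, Motif, estimate_background, score_distribution
from .partition import PartitionMode, PartitionSpec, ScoredMotif, score_motif

#: default affinity function per method (Table-style pairings):
#: count-based tests use MC; subset/rank scores use AMA; regression uses RMA.
DEFAULT_AFFINITY: dict[Method, AffinityKind] = {
    Method.FISHER: AffinityKind.MC,
    Method.MHG: AffinityKind.MC,
    Method.RANKSUM: AffinityKind.AMA,
    Method.CLOVER: AffinityKind.AMA,
    Method.SPEARMAN: AffinityKind.AMA,
    Method.LR: AffinityKind.RMA,
}

#: default signal transform per method: reciprocal p everywhere except the
#: regression method, which uses -log10(p)
DEFAULT_SIGNAL: dict[Method, SignalKind] = {
    m: (SignalKind.NEGLOG_P if m is Method.LR else SignalKind.RECIPROCAL_P) for m in Method
}


@dataclass(frozen=True)
class ScanParams:
    """Scanning configuration shared by every motif in a ranking run."""

    t_m: float = 0.001
    t_x: float = 1.0
    c: int = 2
    scale: int = 1000
    affinity_kind: AffinityKind | None = None  # None -> method default
    signal_kind: SignalKind | None = None


@dataclass
class MotifRanking:
    dataset_id: str
    method: Method
    partition: PartitionSpec
    scores: dict[str, ScoredMotif]
    designated_id: str
    n_motifs: int = 0
    rank: float | None = None
    pra: float | None = None
    skipped: bool = False
    reason: str | None = None


def percentile_rank_accuracy(rank: float, n: int) -> float:
    """PRA = 100 (R_k - 1) / (N - 1): 0 at rank 1, 100 at rank N."""
    if n < 2:
        raise InputError("PRA requires a library of at least 2 motifs")
    if not (1 <= rank <= n):
        raise InputError(f"rank must lie in [1, {n}], got {rank}")
    return 100.0 * (rank - 1) / (n - 1)


def map_library(
    records: Sequence[SequenceRecord],
    library: Sequence[Motif],
    affinity_kind: AffinityKind,
    signal_kind: SignalKind,
    *,
    params: ScanParams = ScanParams(),
    background: BackgroundModel | None = None,
) -> dict[str, MappedDataset]:
    """Map one dataset against every motif in a library.

    Scanning dominates the cost of an evaluation, and the mapped datasets
    depend only on the affinity/signal pairing, so callers comparing several
    partition regimes (or Fisher vs mHG, which share MC) can map once and
    score many times.
    """
    if affinity_kind is AffinityKind.MC and background is None:
        background = estimate_background([r.sequence for r in records])
    mapped: dict[str, MappedDataset] = {}
    for motif in library:
        dist = None
        if affinity_kind is AffinityKind.MC:
            dist = score_distribution(motif, background, scale=params.scale)
        mapped[motif.id] = map_dataset(records, motif, affinity_kind,
                                       signal_kind=signal_kind, t_m=params.t_m, dist=dist)
    return mapped


def rank_from_mapped(
    mapped: dict[str, MappedDataset],
    method: Method | str,
    spec: PartitionSpec,
    *,
    designated_id: str,
    dataset_id: str = "dataset",
    params: ScanParams = ScanParams(),
) -> MotifRanking:
    """Rank pre-mapped motif datasets under one method and partition regime."""
    method = Method(method)
    ids = list(mapped.keys())
    if len(ids) < 2:
        raise InputError("library must contain at least 2 motifs")
    if designated_id not in ids:
        raise InputError(f"designated motif {designated_id!r} not in library")
    scores = {
        mid: score_motif(d, method, spec, motif_id=mid, t_x=params.t_x, c=params.c)
        for mid, d in mapped.items()
    }
    ranking = MotifRanking(dataset_id=dataset_id, method=method, partition=spec,
                           scores=scores, designated_id=designated_id,
                           n_motifs=len(ids))
    if any(s.skipped for s in scores.values()):
        ranking.skipped = True
        ranking.reason = next(s.reason for s in scores.values() if s.skipped)
        return ranking
    keys = np.array([scores[i].sort_key for i in ids])
    ranks = stats.rankdata(keys, method="average")  # ascending: best motif -> rank N
    ranking.rank = float(ranks[ids.index(designated_id)])
    ranking.pra = percentile_rank_accuracy(ranking.rank, len(ids))
    return ranking


def rank_library(
    records: Sequence[SequenceRecord],
    library: Sequence[Motif],
    method: Method | str,
    spec: PartitionSpec,
    *,
    designated_id: str,
    dataset_id: str = "dataset",
    params: ScanParams = ScanParams(),
    background: BackgroundModel | None = None,
) -> MotifRanking:
    """Score every motif in the library on one dataset and rank the true one.

    The affinity function and signal transform default to the method's
    standard pairing; MC scanning uses the exact score-distribution null
    under a background estimated from the dataset's own sequences unless one
    is supplied.  An empty positive set is a property of the signal
    partition, not of any motif, so skips are all-or-none per dataset.
    """
    method = Method(method)
    affinity_kind = params.affinity_kind or (
        AffinityKind.AMA if spec.mode is PartitionMode.PASTAA else DEFAULT_AFFINITY[method]
    )
    signal_kind = params.signal_kind or DEFAULT_SIGNAL[method]
    mapped = map_library(records, library, affinity_kind, signal_kind,
                         params=params, background=background)
    return rank_from_mapped(mapped, method, spec, designated_id=designated_id,
                            dataset_id=dataset_id, params=params)


def aggregate_pra(rankings: Iterable[MotifRanking]) -> tuple[float, float, float, int]:
    """Mean, median, standard error and count of PRA over retained datasets."""
    pras = np.array([r.pra for r in rankings if not r.skipped])
    if len(pras) == 0:
        raise InputError("all datasets were skipped; nothing to aggregate")
    se = float(np.std(pras, ddof=1) / np.sqrt(len(pras))) if len(pras) > 1 else 0.0
    return float(np.mean(pras)), float(np.median(pras)), se, int(len(pras))


@dataclass
class SweepResult:
    """Tidy per-cell results of a threshold sweep."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _spec_for(mode: PartitionMode, threshold: float) -> PartitionSpec:
    if mode is PartitionMode.YFP:
        return PartitionSpec(mode=mode, t_y=threshold)
    if mode is PartitionMode.YCPM:
        return PartitionSpec(mode=mode, y_bound=threshold)
    return PartitionSpec(mode=mode)


def threshold_sweep(
    datasets: Sequence[tuple[str, Sequence[SequenceRecord], str]],
    library: Sequence[Motif],
    methods: Sequence[Method | str],
    modes: Sequence[PartitionMode | str],
    thresholds: Sequence[float],
    *,
    params: ScanParams = ScanParams(),
) -> SweepResult:
    """Run rank_library over a (method, mode, threshold) grid of settings.

    ``datasets`` is a sequence of (dataset_id, records, designated_motif_id)
    triples.  For YFP the threshold is the fixed t_y; for YCPM it is the
    bound b; threshold-free modes ignore it (evaluated once per method).
    Each cell records the retained-dataset count alongside mean/median PRA,
    mirroring the shrinking dataset counts seen at strict thresholds.
    """
    if len(thresholds) == 0:
        raise InputError("threshold grid must be nonempty")
    rows = []
    for method in methods:
        method = Method(method)
        for mode in modes:
            mode = PartitionMode(mode)
            cell_thresholds = list(thresholds) if mode in (PartitionMode.YFP, PartitionMode.YCPM) else [np.nan]
            for t in cell_thresholds:
                spec = _spec_for(mode, t)
                rankings = [
                    rank_library(records, library, method, spec, designated_id=truth,
                                 dataset_id=ds_id, params=params)
                    for ds_id, records, truth in datasets
                ]
                retained = [r for r in rankings if not r.skipped]
                row = {"method": method.value, "mode": mode.value, "threshold": t,
                       "n_retained": len(retained), "mean_pra": np.nan,
                       "median_pra": np.nan, "se_pra": np.nan}
                if retained:
                    mean, median, se, _ = aggregate_pra(retained)
                    row.update(mean_pra=mean, median_pra=median, se_pra=se)
                rows.append(row)
    return SweepResult(table=pd.DataFrame(rows))
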