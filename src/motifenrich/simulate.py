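"""Seeded synthetic ChIP-chip-like datasets with planted motif occurrences.

The generator emulates the input a microarray binding experiment provides:
a few hundred intergenic-scale sequences, a minority "positive" subset
carrying planted motif sites and small fluorescence p-values, and a majority
of background sequences with uniform p-values.  Defaults mirror a scaled-down
yeast-intergenic study: 500 sequences of length 500, 50 positives with 1-3
sites each, and positive p-values 10^-U with U uniform on [3, 10], so the
positive signal spans the 1e-3 .. 1e-10 threshold range relevant to
partition-based enrichment methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .affinity import SequenceRecord
from .errors import InputError
from .motifs import ALPHABET, BackgroundModel, Motif

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def default_planted_motif() -> Motif:
    """An 8-bp yeast-TF-like planted motif (0.85 consensus base per column)."""
    consensus = "TGACTCAG"
    probs = np.full((len(consensus), 4), 0.05)
    for j, b in enumerate(consensus):
        probs[j, ALPHABET.index(b)] = 0.85
    return Motif(id="planted", probs=probs)


@dataclass(frozen=True)
class PlantedSite:
    seq_id: str
    start: int  # 1-based, inclusive
    strand: str  # '+' or '-'
    site: str  # sampled site sequence (motif orientation)


@dataclass
class SyntheticSpec:
    """Study conditions of one synthetic dataset."""

    n_sequences: int = 500
    seq_length: int = 500
    background: BackgroundModel = field(default_factory=BackgroundModel.uniform)
    motif: Motif = field(default_factory=default_planted_motif)
    n_positive: int = 50
    sites_per_positive: tuple[int, int] = (1, 3)
    u_range: tuple[float, float] = (3.0, 10.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_positive > self.n_sequences:
            raise InputError("n_positive must be <= n_sequences")
        lo, hi = self.sites_per_positive
        if not (1 <= lo <= hi):
            raise InputError("sites_per_positive must be an increasing range from >= 1")
        if self.u_range[0] < 1:
            raise InputError("u_min must be >= 1 so positive p-values are <= 0.1")
        if self.seq_length < self.motif.width * hi:
            raise InputError("seq_length too short for the requested site load")


def _sample_site(motif: Motif, rng: np.random.Generator) -> str:
    bases = [ALPHABET[rng.choice(4, p=motif.probs[j])] for j in range(motif.width)]
    return "".join(bases)


def _place_nonoverlapping(rng: np.random.Generator, length: int, w: int, k: int) -> list[int]:
    """k non-overlapping 0-based start positions for width-w sites."""
    for _ in range(1000):
        starts = sorted(rng.integers(0, length - w + 1, size=k).tolist())
        if all(b - a >= w for a, b in zip(starts, starts[1:])):
            return starts
    raise InputError("could not place sites without overlap; sequence too short")


def generate_dataset(spec: SyntheticSpec) -> tuple[list[SequenceRecord], list[PlantedSite]]:
    """Generate one dataset: records plus the ground truth of planted sites.

    Deterministic for a given spec and seed.  Exactly ``n_positive``
    sequences carry sites sampled from the motif's probability matrix,
    inserted at non-overlapping positions on a uniformly chosen strand;
    their p-values are 10^-U with U ~ Uniform(u_range).  All remaining
    content is i.i.d. from the background and negative p-values are
    Uniform(0, 1].
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, L, w = spec.n_sequences, spec.seq_length, spec.motif.width
    width_digits = max(4, len(str(n)))
    ids = [f"seq{i + 1:0{width_digits}d}" for i in range(n)]
    positives = set(rng.choice(n, size=spec.n_positive, replace=False).tolist())

    records: list[SequenceRecord] = []
    truth: list[PlantedSite] = []
    bases = np.array(list(ALPHABET))
    for i in range(n):
        seq = "".join(bases[rng.choice(4, size=L, p=spec.background.freqs)])
        if i in positives:
            k = int(rng.integers(spec.sites_per_positive[0], spec.sites_per_positive[1] + 1))
            chars = list(seq)
            for start in _place_nonoverlapping(rng, L, w, k):
                site = _sample_site(spec.motif, rng)
                strand = "+" if rng.random() < 0.5 else "-"
                chars[start : start + w] = site if strand == "+" else _revcomp(site)
                truth.append(PlantedSite(ids[i], start + 1, strand, site))
            seq = "".join(chars)
            u = rng.uniform(*spec.u_range)
            p = 10.0 ** (-u)
        else:
            p = 1.0 - rng.random()  # uniform on (0, 1]
        records.append(SequenceRecord(id=ids[i], sequence=seq, raw_signal=p))
    return records, truth


def generate_decoys(
    n: int, width: int = 8, concentration: float = 1.0, seed: int = 0
) -> list[Motif]:
    """Decoy motif library: columns drawn from a symmetric Dirichlet.

    Small ``concentration`` gives sharp, informative columns; large values
    approach uniform (uninformative) columns.  Column probabilities are
    floored at 1e-3 and renormalized so score supports stay bounded.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    if width < 4:
        raise InputError("width must be >= 4")
    rng = np.random.default_rng(seed)
    motifs: list[Motif] = []
    seen: set[bytes] = set()
    i = 0
    while len(motifs) < n:
        probs = rng.dirichlet(np.full(4, concentration), size=width)
        probs = np.maximum(probs, 1e-3)
        probs = probs / probs.sum(axis=1)[:, None]
        key = np.round(probs, 6).tobytes()
        if key in seen:
            continue
        seen.add(key)
        i += 1
        motifs.append(Motif(id=f"decoy{i:03d}", probs=probs))
    return motifs


def shuffle_motif(motif: Motif, seed: int = 0) -> Motif:
    """Column-shuffled decoy: permute column order, preserve column contents.

    For width >= 2 a non-identity permutation is enforced, so the shuffled
    motif has the same per-column information content but a different site
    preference.
    """
    if motif.width < 2:
        raise InputError("shuffle requires width >= 2")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(motif.width)
    while np.all(perm == np.arange(motif.width)):
        perm = rng.permutation(motif.width)
    return Motif(id=f"{motif.id}_shuffled", probs=motif.probs[perm].copy(),
                 n_sites=motif.n_sites)


def planted_library(
    n_decoys: int = 29, width: int = 8, concentration: float = 1.0, seed: int = 1
) -> list[Motif]:
    """The default evaluation library: the planted motif plus Dirichlet decoys."""
    return [default_planted_motif()] + generate_decoys(n_decoys, width=width,
                                                       concentration=concentration,
                                                       seed=seed)
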