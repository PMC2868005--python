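"""Position weight matrix motifs, scanning backgrounds and exact score nulls.

A motif is a position probability matrix (PPM) over the DNA alphabet A,C,G,T
together with its log-likelihood-ratio (LLR) form.  Following common motif
practice the LLR denominator is the *uniform* distribution (0.25 per base),
while the scanning null used for match p-values is a zero-order background
estimated from the scanned sequences.  Match p-values are obtained from the
exact distribution of the integer-discretized LLR score of a random w-mer
drawn i.i.d. from the background, computed by position-wise convolution.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import FormatError, InputError

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
# complement of base index i is 3 - i under the A,C,G,T ordering
_PROB_FLOOR = 1e-6  # floor applied when reading matrices containing zeros


def _as_prob_matrix(probs: np.ndarray) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
        raise InputError(f"probability matrix must be w x 4 with w >= 1, got {probs.shape}")
    if np.any(probs <= 0):
        raise InputError("probability matrix entries must be strictly positive")
    sums = probs.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise InputError("probability matrix rows must each sum to 1")
    # renormalize exactly so downstream invariants hold to 1e-9
    return probs / sums[:, None]


@dataclass(frozen=True)
class Motif:
    """A PWM motif: position probabilities plus derived LLR scores (base 2)."""

    id: str
    probs: np.ndarray  # w x 4, rows sum to 1, strictly positive
    n_sites: int | None = None
    llr: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        probs = _as_prob_matrix(self.probs)
        probs.setflags(write=False)
        object.__setattr__(self, "probs", probs)
        llr = np.log2(probs / 0.25)
        llr.setflags(write=False)
        object.__setattr__(self, "llr", llr)

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[a] for a in np.argmax(self.probs, axis=1))

    @property
    def max_likelihood_ratio(self) -> float:
        """Product over positions of the best single-base likelihood ratio."""
        return float(np.prod(self.probs.max(axis=1) / 0.25))

    def column_entropies(self) -> np.ndarray:
        p = self.probs
        return -(p * np.log2(p)).sum(axis=1)


@dataclass(frozen=True)
class BackgroundModel:
    """Zero-order (i.i.d. single nucleotide) background over A,C,G,T."""

    freqs: np.ndarray
    source: str = "uniform"

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        if freqs.shape != (4,):
            raise InputError("background must have exactly 4 frequencies (A,C,G,T)")
        if np.any(freqs <= 0) or abs(freqs.sum() - 1.0) > 1e-6:
            raise InputError("background frequencies must be positive and sum to 1")
        freqs = freqs / freqs.sum()
        freqs.setflags(write=False)
        object.__setattr__(self, "freqs", freqs)

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls(np.full(4, 0.25), source="uniform")


def build_motif_from_sites(
    sites: Sequence[str], pseudocount: float = 0.25, id: str = "motif"
) -> Motif:
    """Estimate a PPM from aligned binding sites with an additive pseudocount.

    ``probs[j][a] = (count(a at j) + pseudocount) / (n_sites + 4 * pseudocount)``;
    the pseudocount is spread uniformly over the four bases.  Sites must be
    equal-length strings over A,C,G,T (case-insensitive, no ambiguity codes).
    """
    if len(sites) == 0:
        raise InputError("at least one site is required")
    if pseudocount < 0:
        raise InputError("pseudocount must be nonnegative")
    upper = [s.upper() for s in sites]
    w = len(upper[0])
    if w < 1:
        raise InputError("sites must be non-empty")
    if any(len(s) != w for s in upper):
        raise InputError("all sites must have the same length")
    counts = np.zeros((w, 4))
    for s in upper:
        for j, b in enumerate(s):
            if b not in _BASE_INDEX:
                raise InputError(f"invalid character {b!r} in site {s!r} (only A,C,G,T allowed)")
            counts[j, _BASE_INDEX[b]] += 1
    n = len(upper)
    denom = n + 4.0 * pseudocount
    probs = (counts + pseudocount) / denom
    if np.any(probs <= 0):
        raise InputError("zero pseudocount with unobserved bases yields zero probabilities; use pseudocount > 0")
    return Motif(id=id, probs=probs, n_sites=n)


def reverse_complement(motif: Motif) -> Motif:
    """Reverse-complement a motif: reverse positions, complement bases."""
    # complement maps index a -> 3 - a under A,C,G,T, so flip both axes
    return Motif(id=motif.id, probs=motif.probs[::-1, ::-1].copy(), n_sites=motif.n_sites)


def complement_codes() -> np.ndarray:
    """Index map c -> complement(c) for encoded bases (4 = unknown maps to 4)."""
    return np.array([3, 2, 1, 0, 4], dtype=np.int8)


def estimate_background(sequences: Iterable[str], floor: float = 1e-4) -> BackgroundModel:
    """Zero-order background pooled over sequences and their reverse complements.

    Averaging both strands forces freq(A)=freq(T) and freq(C)=freq(G), matching
    double-stranded scanning.  Non-ACGT characters are excluded from the counts.
    Zero frequencies are floored at ``floor`` and the vector renormalized so
    degenerate inputs never produce -inf scores.
    """
    counts = np.zeros(4)
    any_seq = False
    for seq in sequences:
        any_seq = True
        s = seq.upper()
        for b, i in _BASE_INDEX.items():
            counts[i] += s.count(b)
    if not any_seq or counts.sum() == 0:
        raise InputError("sequences contain no A,C,G,T characters")
    counts = counts + counts[::-1]  # add reverse-complement strand counts
    freqs = counts / counts.sum()
    if np.any(freqs == 0):
        freqs = np.maximum(freqs, floor)
        freqs = freqs / freqs.sum()
    return BackgroundModel(freqs, source="estimated-from-sequences")


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact null distribution of the discretized LLR score of a random w-mer.

    Scores are integers on a grid of ``scale`` units per log2 unit: each LLR
    entry is multiplied by ``scale`` and rounded before the position-wise
    convolution, bounding the total rounding error at w/scale log2 units.
    ``pmf[i]`` is the probability of total score ``min_score + i`` under the
    background; the survival function gives the FIMO-style match p-value
    P(score >= s).  Both strands are scored against the same distribution,
    which is exact for strand-symmetric backgrounds (the only kind produced
    by :func:`estimate_background` or :meth:`BackgroundModel.uniform`).
    """

    motif_id: str
    scale: int
    min_score: int
    pmf: np.ndarray
    sf: np.ndarray = field(init=False, repr=False)  # sf[i] = P(score >= min_score + i)

    def __post_init__(self) -> None:
        pmf = np.asarray(self.pmf, dtype=float)
        pmf.setflags(write=False)
        object.__setattr__(self, "pmf", pmf)
        sf = np.cumsum(pmf[::-1])[::-1]
        sf.setflags(write=False)
        object.__setattr__(self, "sf", sf)

    @property
    def max_score(self) -> int:
        return self.min_score + len(self.pmf) - 1

    def pvalue(self, score: int | np.ndarray) -> np.ndarray:
        """Match p-value P(total score >= score), exactly 1 below the support."""
        idx = np.clip(np.asarray(score) - self.min_score, 0, len(self.pmf) - 1)
        p = self.sf[idx]
        return np.where(np.asarray(score) > self.max_score, 0.0, p)

    def score_threshold(self, t_m: float) -> int:
        """Smallest integer score whose p-value is <= t_m.

        A window matches at threshold ``t_m`` iff its integer score is >= the
        returned value.  Returns ``max_score + 1`` when no score passes.
        """
        if not (0 < t_m <= 1):
            raise InputError(f"t_m must be in (0, 1], got {t_m}")
        passing = np.nonzero(self.sf <= t_m)[0]
        if len(passing) == 0:
            return self.max_score + 1
        return self.min_score + int(passing[0])


def integer_llr(motif: Motif, scale: int) -> np.ndarray:
    """LLR matrix discretized to integer score units (``scale`` per log2)."""
    return np.rint(motif.llr * scale).astype(np.int64)


def score_distribution(
    motif: Motif, background: BackgroundModel, scale: int = 1000
) -> ScoreDistribution:
    """Exact pmf of the discretized w-mer score under the zero-order background."""
    if scale < 10:
        raise InputError("scale must be >= 10")
    illr = integer_llr(motif, scale)
    lo = int(illr.min(axis=1).sum())
    hi = int(illr.max(axis=1).sum())
    pmf = np.zeros(hi - lo + 1)
    # convolve one position at a time; offsets tracked against the running minimum
    cur = np.array([1.0])
    cur_lo = 0
    for j in range(motif.width):
        row = illr[j]
        rlo = int(row.min())
        new = np.zeros(len(cur) + int(row.max()) - rlo)
        for a in range(4):
            off = int(row[a]) - rlo
            new[off : off + len(cur)] += background.freqs[a] * cur
        cur = new
        cur_lo += rlo
    pmf[cur_lo - lo : cur_lo - lo + len(cur)] = cur
    return ScoreDistribution(motif_id=motif.id, scale=scale, min_score=lo, pmf=pmf)


# ---------------------------------------------------------------------------
# MEME minimal motif format I/O
# ---------------------------------------------------------------------------

_MATRIX_HEADER = re.compile(
    r"letter-probability matrix:(?:\s+alength=\s*(?P<alength>\d+))?"
    r"(?:\s+w=\s*(?P<w>\d+))?(?:\s+nsites=\s*(?P<nsites>\d+(?:\.\d+)?))?"
)


def read_motif_library(path: str | Path) -> list[Motif]:
    """Read a MEME minimal-format motif file.

    Accepts the usual layout: a ``MEME version`` line, optional ``ALPHABET=``
    and ``Background letter frequencies`` blocks, then one or more ``MOTIF``
    blocks each followed by a ``letter-probability matrix:`` header and w rows
    of four probabilities.  Rows not summing to ~1 (tolerance 0.01), duplicate
    motif ids, non-DNA alphabets and empty matrices raise :class:`FormatError`
    with the offending line number.  Zero entries are floored at 1e-6 and rows
    renormalized so the resulting motifs satisfy the strict-positivity
    invariant.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".fa", ".fasta"))
        if not files:
            raise FormatError(f"no .fa/.fasta site files in directory {path}")
        motifs = [read_sites_fasta(p) for p in files]
        ids = [m.id for m in motifs]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate motif ids among site files")
        return motifs
    lines = path.read_text().splitlines()
    motifs: list[Motif] = []
    seen: set[str] = set()
    i = 0
    n = len(lines)
    saw_version = False

    def finish(motif_id: str, rows: list[list[float]], header_line: int) -> None:
        if not rows:
            raise FormatError(f"motif {motif_id!r} has an empty letter-probability matrix", header_line)
        probs = np.array(rows)
        probs = np.maximum(probs, _PROB_FLOOR)
        probs = probs / probs.sum(axis=1)[:, None]
        motifs.append(Motif(id=motif_id, probs=probs, n_sites=nsites_holder[0]))

    nsites_holder: list[int | None] = [None]
    while i < n:
        line = lines[i].strip()
        i += 1
        if not line or line.startswith("#"):
            continue
        if line.upper().startswith("MEME VERSION"):
            saw_version = True
            continue
        if line.upper().startswith("ALPHABET"):
            alpha = line.split("=", 1)[-1].strip().replace(" ", "")
            if alpha.upper() not in ("ACGT", "DNA"):
                raise FormatError(f"unsupported alphabet {alpha!r} (only ACGT)", i)
            continue
        if line.lower().startswith("background letter frequencies") or line.lower().startswith("strands"):
            # background values may continue on the next line; skip bare number lines
            while i < n and re.fullmatch(r"[ACGTacgt0-9.eE+\-\s]+", lines[i].strip() or "x") and lines[i].strip():
                if lines[i].strip().upper().startswith(("MOTIF", "MEME", "ALPHABET")):
                    break
                i += 1
            continue
        if line.upper().startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise FormatError("MOTIF line without an identifier", i)
            motif_id = parts[1]
            if motif_id in seen:
                raise FormatError(f"duplicate motif id {motif_id!r}", i)
            seen.add(motif_id)
            # scan forward for the matrix header
            header_line = None
            width = None
            nsites_holder = [None]
            while i < n:
                sub = lines[i].strip()
                i += 1
                if not sub:
                    continue
                m = _MATRIX_HEADER.match(sub)
                if m:
                    header_line = i
                    if m.group("alength") and int(m.group("alength")) != 4:
                        raise FormatError("alength must be 4 for DNA motifs", i)
                    if m.group("w"):
                        width = int(m.group("w"))
                    if m.group("nsites"):
                        nsites_holder[0] = int(float(m.group("nsites")))
                    break
                if sub.upper().startswith("MOTIF"):
                    raise FormatError(f"motif {motif_id!r} has no letter-probability matrix", i)
            if header_line is None:
                raise FormatError(f"motif {motif_id!r} has no letter-probability matrix", i)
            rows: list[list[float]] = []
            while i < n:
                sub = lines[i].strip()
                if not sub or sub.upper().startswith(("MOTIF", "URL")):
                    break
                i += 1
                try:
                    vals = [float(v) for v in sub.split()]
                except ValueError as exc:
                    raise FormatError(f"unparseable matrix row in motif {motif_id!r}: {sub!r}", i) from exc
                if len(vals) != 4:
                    raise FormatError(f"matrix row must have 4 values in motif {motif_id!r}", i)
                if abs(sum(vals) - 1.0) > 0.01:
                    raise FormatError(
                        f"matrix row sums to {sum(vals):.4g} (expected 1) in motif {motif_id!r}", i
                    )
                rows.append(vals)
                if width is not None and len(rows) == width:
                    break
            if width is not None and len(rows) != width:
                raise FormatError(f"motif {motif_id!r} declares w={width} but has {len(rows)} rows", i)
            finish(motif_id, rows, header_line)
            continue
        # tolerate URL and other trailing annotation lines
        if line.upper().startswith("URL"):
            continue
    if not saw_version and not motifs:
        raise FormatError("not a MEME motif file (missing 'MEME version' line)", 1)
    if not motifs:
        raise FormatError("no MOTIF blocks found", n)
    return motifs


def write_motif_library(
    motifs: Sequence[Motif], path: str | Path, background: BackgroundModel | None = None
) -> None:
    """Write motifs in MEME minimal format (round-trip stable to 1e-6)."""
    ids = [m.id for m in motifs]
    if len(set(ids)) != len(ids):
        raise InputError("motif ids must be unique")
    bg = background.freqs if background is not None else np.full(4, 0.25)
    out = ["MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", ""]
    out.append("Background letter frequencies")
    out.append(" ".join(f"{b} {f:.6f}" for b, f in zip(ALPHABET, bg)))
    out.append("")
    for m in motifs:
        out.append(f"MOTIF {m.id}")
        nsites = m.n_sites if m.n_sites is not None else 20
        out.append(f"letter-probability matrix: alength= 4 w= {m.width} nsites= {nsites} E= 0")
        for row in m.probs:
            out.append(" ".join(f"{v:.6f}" for v in row))
        out.append("")
    Path(path).write_text("\n".join(out) + "\n")


def read_sites_fasta(path: str | Path, pseudocount: float = 0.25, id: str | None = None) -> Motif:
    """Build a motif from a FASTA file of equal-length aligned binding sites."""
    from Bio import SeqIO

    sites = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    if not sites:
        raise InputError(f"no sites found in {path}")
    return build_motif_from_sites(sites, pseudocount=pseudocount, id=id or Path(path).stem)
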