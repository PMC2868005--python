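"""Vectorized PWM scanning primitives.

Sequences are encoded as small integer arrays (A,C,G,T -> 0..3, anything else
-> 4) and all windows of a batch of sequences are scored in O(w) numpy
operations by summing shifted lookups into a (w x 5) weight matrix whose fifth
column is NaN, so any window touching a non-ACGT character scores NaN and is
treated as invalid.  Positions are 0-based half-open internally; user-facing
coordinates are 1-based inclusive.
"""

from __future__ import annotations

import numpy as np

from .motifs import Motif, reverse_complement

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (4 = non-ACGT)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_batch(seqs: list[str]) -> np.ndarray:
    """Encode sequences into a (n, max_len) matrix padded with code 4."""
    n = len(seqs)
    maxlen = max((len(s) for s in seqs), default=0)
    out = np.full((n, maxlen), 4, dtype=np.int8)
    for i, s in enumerate(seqs):
        if s:
            out[i, : len(s)] = encode(s)
    return out


def _extend_weights(weights: np.ndarray) -> np.ndarray:
    """Append a NaN column for the unknown-base code."""
    w = np.asarray(weights, dtype=float)
    ext = np.full((w.shape[0], 5), np.nan)
    ext[:, :4] = w
    return ext


def window_scores(codes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Score every length-w window of each row of ``codes``.

    ``weights`` is the motif's (w x 4) per-position score matrix.  Returns an
    (n, L - w + 1) array; windows containing non-ACGT characters (or padding)
    are NaN.  Returns an (n, 0) array when L < w.
    """
    codes = np.atleast_2d(codes)
    ext = _extend_weights(weights)
    w = ext.shape[0]
    n, L = codes.shape
    if L < w:
        return np.empty((n, 0))
    nwin = L - w + 1
    scores = np.zeros((n, nwin))
    idx = codes.astype(np.intp)
    for j in range(w):
        scores += ext[j, idx[:, j : j + nwin]]
    return scores


def strand_scores(codes: np.ndarray, motif: Motif, weights_of) -> tuple[np.ndarray, np.ndarray]:
    """Forward- and reverse-strand window scores for a batch.

    ``weights_of(motif)`` supplies the (w x 4) matrix to scan with.  The
    reverse strand is scored by scanning the forward sequence with the
    reverse-complement motif, which is equivalent to scoring each window's
    reverse complement with the motif itself.
    """
    fwd = window_scores(codes, weights_of(motif))
    rev = window_scores(codes, weights_of(reverse_complement(motif)))
    return fwd, rev
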