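"""File input/output: FASTA sequences, signal tables and fixture directories.

The sequence input is plain FASTA; the signal input is a two-column
tab-separated file mapping sequence id -> raw signal (typically a
fluorescence p-value), with an optional header and ``#`` comment lines.
Ids in the two files are matched exactly; a partial overlap is intersected
with a warning, and an overlap below 50% of either file is an error.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .affinity import SequenceRecord
from .errors import FormatError, InputError
from .simulate import PlantedSite

logger = logging.getLogger(__name__)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping (ids must be unique)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise FormatError(f"no sequences found in {path}")
    return seqs


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    bio = [BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def read_fasta_signals(path: str | Path) -> dict[str, float]:
    """Parse signals from FASTA headers: `>id <value> ...` (AME-compatible)."""
    signals: dict[str, float] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split()
        if len(parts) < 2:
            raise FormatError(f"no signal value in FASTA header for {rec.id!r}")
        try:
            signals[rec.id] = float(parts[1])
        except ValueError:
            raise FormatError(f"unparseable signal {parts[1]!r} in header for {rec.id!r}")
    if not signals:
        raise FormatError(f"no sequences found in {path}")
    return signals


def read_signal(path: str | Path) -> dict[str, float]:
    """Read the two-column tab-separated signal file: id <TAB> value."""
    signals: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError("expected two tab-separated columns", lineno)
        sid, val = parts[0].strip(), parts[1].strip()
        try:
            value = float(val)
        except ValueError:
            if lineno == 1:  # tolerate a header line
                continue
            raise FormatError(f"unparseable signal value {val!r}", lineno)
        if sid in signals:
            raise FormatError(f"duplicate id {sid!r}", lineno)
        signals[sid] = value
    if not signals:
        raise FormatError(f"no signal values found in {path}")
    return signals


def write_signal(records: Sequence[SequenceRecord], path: str | Path) -> None:
    lines = ["#sequence_id\tp_value"]
    lines += [f"{r.id}\t{r.raw_signal:.6g}" for r in records]
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth(truth: Sequence[PlantedSite], path: str | Path) -> None:
    lines = ["#seq_id\tstart_1based\tstrand\tsite_seq"]
    lines += [f"{t.seq_id}\t{t.start}\t{t.strand}\t{t.site}" for t in truth]
    Path(path).write_text("\n".join(lines) + "\n")


def combine_records(
    seqs: dict[str, str], signals: dict[str, float], *, min_overlap: float = 0.5
) -> list[SequenceRecord]:
    """Join sequences with signals on id; warn-and-intersect partial overlap."""
    common = [i for i in seqs if i in signals]
    if not common:
        raise InputError("sequence and signal files share no ids")
    frac = len(common) / max(len(seqs), len(signals))
    if frac < min_overlap:
        raise InputError(
            f"only {len(common)} ids shared between sequences ({len(seqs)}) and "
            f"signal ({len(signals)}); overlap below {min_overlap:.0%}"
        )
    if len(common) < len(seqs) or len(common) < len(signals):
        logger.warning("intersecting inputs: %d shared ids (%d sequences, %d signals)",
                       len(common), len(seqs), len(signals))
    return [SequenceRecord(id=i, sequence=seqs[i], raw_signal=signals[i]) for i in common]


def load_dataset(sequences_path: str | Path, signal_path: str | Path) -> list[SequenceRecord]:
    return combine_records(read_fasta(sequences_path), read_signal(signal_path))


def sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path: str | Path, params: dict, inputs: Sequence[str | Path] = ()) -> None:
    """Machine-readable run manifest: parameters plus input checksums."""
    manifest = {
        "parameters": params,
        "inputs": {str(p): sha256(p) for p in inputs if Path(p).exists()},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
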