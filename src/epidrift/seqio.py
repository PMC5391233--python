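"""Sequence encoding helpers and FASTA/FASTQ input/output.

Sequences are manipulated as numpy uint8 arrays of ASCII codes so that
per-base error injection, mismatch counting and overlap scoring are
vectorized. FASTA parsing goes through Biopython; FASTQ records are plain
4-line Phred+33 with constant qualities, written and read directly.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTNacgtn", b"TGCANtgcan"):
    _COMPLEMENT[_a] = _b


def encode(seq: str) -> np.ndarray:
    """ASCII-encode a nucleotide string as uint8."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return decode(_COMPLEMENT[encode(seq)][::-1])


def revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[arr][::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return int((encode(a) != encode(b)).sum())


def mismatch_positions(a: str, b: str) -> tuple[int, ...]:
    if len(a) != len(b):
        raise ValueError("mismatch positions require equal lengths")
    return tuple(int(i) for i in np.nonzero(encode(a) != encode(b))[0])


# ---------------------------------------------------------------------------
# FASTQ


def _open(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, str]]) -> int:
    """Write (id, sequence, quality) triples as 4-line FASTQ. Returns count."""
    n = 0
    with _open(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality) from a 4-line FASTQ file."""
    with _open(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            yield header[1:].rstrip("\n").split()[0], seq, qual


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> int:
    recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    return SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
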