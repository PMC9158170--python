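"""In-memory read sets and FASTA/FASTQ round-tripping.

Reads are held as a dense ``(n_reads, read_length)`` uint8 matrix of 2-bit base
codes (A=0, C=1, G=2, T=3; N and other ambiguity codes collapse to 4, which
never matches anything).  The dense layout is what the exact-match scanner in
:mod:`spliceprobe.quant` consumes directly; FASTQ/FASTA import/export goes
through Biopython.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode_seq(seq: str) -> np.ndarray:
    """Encode a DNA string into base codes (A,C,G,T -> 0..3; other -> 4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def decode_seq(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement on base codes; N (code 4) maps to itself."""
    out = codes[..., ::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


@dataclass
class ReadSet:
    """Fixed-length single-end reads for one sample."""

    codes: np.ndarray  # (n, read_length) uint8
    sample_id: str = "sample"
    ids: Sequence[str] | None = None  # default: "<sample_id>:<i>"

    def __post_init__(self) -> None:
        self.codes = np.ascontiguousarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a (n_reads, read_length) matrix")

    def __len__(self) -> int:
        return self.codes.shape[0]

    @property
    def read_length(self) -> int:
        return self.codes.shape[1]

    @property
    def total_nt(self) -> int:
        return self.codes.size

    def read_id(self, i: int) -> str:
        return self.ids[i] if self.ids is not None else f"{self.sample_id}:{i}"

    def sequences(self) -> list[str]:
        return [decode_seq(row) for row in self.codes]

    @classmethod
    def from_sequences(
        cls, seqs: Iterable[str], sample_id: str = "sample",
        ids: Sequence[str] | None = None,
    ) -> "ReadSet":
        seqs = list(seqs)
        if not seqs:
            raise ValueError("empty read set")
        lens = {len(s) for s in seqs}
        if len(lens) != 1:
            raise ValueError(f"reads must share one length, found {sorted(lens)}")
        codes = np.vstack([encode_seq(s) for s in seqs])
        return cls(codes, sample_id=sample_id, ids=ids)

    @classmethod
    def from_file(cls, path: str | Path, sample_id: str | None = None) -> "ReadSet":
        path = Path(path)
        fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
        ids, seqs = [], []
        for rec in SeqIO.parse(str(path), fmt):
            ids.append(rec.id)
            seqs.append(str(rec.seq))
        return cls.from_sequences(seqs, sample_id=sample_id or path.stem, ids=ids)

    def to_fastq(self, path: str | Path, quality_char: str = "I") -> None:
        """Write as FASTQ with a constant quality string."""
        with open(path, "w") as fh:
            qual = quality_char * self.read_length
            for i, row in enumerate(self.codes):
                fh.write(f"@{self.read_id(i)}\n{decode_seq(row)}\n+\n{qual}\n")

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, row in enumerate(self.codes):
                fh.write(f">{self.read_id(i)}\n{decode_seq(row)}\n")

    def reverse_complemented(self) -> "ReadSet":
        """A new read set with every read reverse-complemented (for invariance checks)."""
        return ReadSet(revcomp_codes(self.codes), sample_id=self.sample_id, ids=self.ids)
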