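"""Sequence I/O helpers: FASTA/FASTQ reading and writing, base encoding.

FASTA goes through Biopython's SeqIO; FASTQ through the fast
FastqGeneralIterator, wrapped so that malformed records are reported with
their record number.
"""
from __future__ import annotations

import os
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# base -> small integer; anything outside ACGT (notably N) maps to 4 and is
# treated as a mismatch / no-call downstream
BASE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    BASE_LUT[ord(_b)] = _i
    BASE_LUT[ord(_b.lower())] = _i

BASES = "ACGT"


class FastqFormatError(ValueError):
    """Raised for a malformed FASTQ record; carries the 1-based record number."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 (A=0 C=1 G=2 T=3, other=4)."""
    return BASE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a FASTA file into a list of (id, sequence) pairs."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | os.PathLike, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    """Write (id, sequence) pairs as FASTA, wrapped at `width` columns."""
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality) from a FASTQ file.

    Raises FastqFormatError naming the 1-based record number on malformed
    input.
    """
    n = 0
    with open(path) as fh:
        it = FastqGeneralIterator(fh)
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqFormatError(
                    f"malformed FASTQ record {n + 1} in {path}: {exc}"
                ) from exc
            n += 1
            yield rec


def write_fastq(path: str | os.PathLike, records: Iterable[tuple[str, str, str]]) -> None:
    """Write (id, sequence, quality) triples as 4-line Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
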