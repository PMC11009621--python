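"""TE consensus library: loading, validation and sequence annotation.

A library bundles the consensus sequences of TE families together with a
small set of single-copy genes used to normalize read coverage into haploid
copy numbers.  Homopolymer runs (e.g. the poly-A track of some LTR
retrotransposons) are annotated per family because coverage estimates are
curbed over them downstream.

Coordinates are 0-based half-open throughout; 1-based coordinates appear
only in exported human-readable tables.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .io_utils import read_fasta, write_fasta

VALID_BASES = set("ACGTN")

#: default minimum length for a homopolymer run to be treated as a
#: poly-A/poly-N curbing target
DEFAULT_POLY_MIN_LEN = 8


@dataclass
class TEConsensus:
    """Consensus sequence of one TE family.

    ltr_length is the length of the long terminal repeat for LTR
    retrotransposons (the two LTRs are identical at insertion time, so their
    divergence dates an insertion); orf_count is purely descriptive metadata.
    """

    family_id: str
    sequence: str
    ltr_length: int | None = None
    orf_count: int | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for family {self.family_id!r}")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"family {self.family_id!r} contains non-ACGTN characters: "
                f"{sorted(bad)}"
            )
        if self.ltr_length is not None:
            if not 0 < self.ltr_length < self.length / 2:
                raise ValueError(
                    f"family {self.family_id!r}: ltr_length {self.ltr_length} "
                    f"must lie in (0, length/2) for length {self.length}"
                )


@dataclass
class GeneSequence:
    """A single-copy gene used for coverage normalization."""

    name: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for gene {self.name!r}")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"gene {self.name!r} contains non-ACGTN characters: {sorted(bad)}"
            )


@dataclass
class TELibrary:
    """TE consensus sequences plus single-copy normalization genes."""

    families: list[TEConsensus]
    genes: list[GeneSequence] = field(default_factory=list)
    homopolymer_runs: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [f.family_id for f in self.families] + [g.name for g in self.genes]
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise ValueError(f"duplicate identifier {i!r} in library")
            seen.add(i)
        if not self.homopolymer_runs:
            self.homopolymer_runs = {
                f.family_id: find_homopolymer_runs(f.sequence, DEFAULT_POLY_MIN_LEN)
                for f in self.families
            }
        for fid, runs in self.homopolymer_runs.items():
            length = len(self.sequence_of(fid))
            prev_end = -1
            for start, end in runs:
                if not (0 <= start < end <= length):
                    raise ValueError(
                        f"homopolymer run [{start},{end}) outside [0,{length}) "
                        f"for {fid!r}"
                    )
                if start < prev_end:
                    raise ValueError(f"overlapping homopolymer runs for {fid!r}")
                prev_end = end

    # -- lookups ---------------------------------------------------------

    @property
    def family_ids(self) -> list[str]:
        return [f.family_id for f in self.families]

    @property
    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]

    @property
    def reference_ids(self) -> list[str]:
        """All reference identifiers, families first, then genes."""
        return self.family_ids + self.gene_names

    def family(self, family_id: str) -> TEConsensus:
        for f in self.families:
            if f.family_id == family_id:
                return f
        raise KeyError(f"unknown family {family_id!r}")

    def is_gene(self, ref_id: str) -> bool:
        return ref_id in self.gene_names

    def sequence_of(self, ref_id: str) -> str:
        for f in self.families:
            if f.family_id == ref_id:
                return f.sequence
        for g in self.genes:
            if g.name == ref_id:
                return g.sequence
        raise KeyError(f"unknown reference {ref_id!r}")

    # -- export ----------------------------------------------------------

    def write_fasta(self, te_path: str | os.PathLike, gene_path: str | os.PathLike) -> None:
        write_fasta(te_path, [(f.family_id, f.sequence) for f in self.families])
        write_fasta(gene_path, [(g.name, g.sequence) for g in self.genes])

    def manifest(self) -> pd.DataFrame:
        """Library manifest: one row per family (tab-separated on export)."""
        return pd.DataFrame(
            {
                "family_id": self.family_ids,
                "length": [f.length for f in self.families],
                "ltr_length": [f.ltr_length for f in self.families],
                "orf_count": [f.orf_count for f in self.families],
            }
        )

    def write_manifest(self, path: str | os.PathLike) -> None:
        self.manifest().to_csv(path, sep="\t", index=False)


def find_homopolymer_runs(seq: str, min_len: int) -> list[tuple[int, int]]:
    """Maximal single-base runs of length >= min_len, as sorted, non-
    overlapping 0-based half-open intervals."""
    if min_len < 2:
        raise ValueError(f"min_len must be >= 2, got {min_len}")
    runs: list[tuple[int, int]] = []
    n = len(seq)
    i = 0
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j))
        i = j
    return runs


def load_library(
    te_fasta: str | os.PathLike,
    gene_fasta: str | os.PathLike | None = None,
    ltr_lengths: Mapping[str, int] | None = None,
    orf_counts: Mapping[str, int] | None = None,
    poly_min_len: int = DEFAULT_POLY_MIN_LEN,
) -> TELibrary:
    """Load TE consensus and single-copy gene FASTA files into a TELibrary.

    Identifiers are preserved verbatim and sequences uppercased.  Duplicate
    identifiers, empty sequences and non-ACGTN characters are hard errors.
    ltr_lengths/orf_counts attach optional per-family metadata.
    """
    ltr_lengths = ltr_lengths or {}
    orf_counts = orf_counts or {}
    te_records = read_fasta(te_fasta)
    _check_duplicates(te_records, te_fasta)
    families = [
        TEConsensus(
            family_id=name,
            sequence=seq,
            ltr_length=ltr_lengths.get(name),
            orf_count=orf_counts.get(name),
        )
        for name, seq in te_records
    ]
    genes: list[GeneSequence] = []
    if gene_fasta is not None:
        gene_records = read_fasta(gene_fasta)
        _check_duplicates(gene_records, gene_fasta)
        genes = [GeneSequence(name, seq) for name, seq in gene_records]
    runs = {
        f.family_id: find_homopolymer_runs(f.sequence, poly_min_len) for f in families
    }
    return TELibrary(families=families, genes=genes, homopolymer_runs=runs)


def _check_duplicates(records: Sequence[tuple[str, str]], path) -> None:
    seen: set[str] = set()
    for name, _ in records:
        if name in seen:
            raise ValueError(f"duplicate identifier {name!r} in {path}")
        seen.add(name)
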