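"""Read trimming, alignment against the consensus library, SAM interop and
pileup construction.

The internal aligner is a deliberately small replacement for an external
short-read mapper, sufficient for the statistics this pipeline needs
(per-position coverage and base counts on consensus coordinates).  It is a
seed-and-extend, *ungapped* semi-global aligner: exact k-mer seeds locate
candidate diagonals over all families + genes and both strands; each
candidate is scored match +1 / mismatch -1 over the aligned span.  Reads may
overhang the reference ends (the overhang is soft-clipped, not scored).
Indels in reads are absorbed as mismatch runs or rejected by the identity
threshold; externally produced (gapped) alignments can be ingested from SAM
instead.

A read whose best score is attained on two or more references is
*ambiguous*: it is emitted once per tied reference and later contributes
coverage weight 1/k, kept separate from unambiguous coverage (mirroring the
dark/light distinction in coverage plots of TE abundance).
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

from .io_utils import encode, revcomp
from .te_library import TELibrary

DEFAULT_MIN_IDENTITY = 0.75
DEFAULT_SEED_K = 13
DEFAULT_MIN_ALIGNED = 30


@dataclass
class ReadAlignment:
    """Placement of one read on one library reference (0-based, consensus
    coordinates; `seq` is the read already oriented to the consensus
    strand)."""

    read_id: str
    family_id: str
    start: int
    strand: str  # "+" or "-"
    mismatches: int
    aligned_len: int
    is_ambiguous: bool = False
    n_tied: int = 1
    seq: str = ""
    q_start: int = 0  # offset of the aligned span within `seq`
    score: int = 0
    #: CIGAR (op, length) tuples for gapped records ingested from SAM;
    #: None for the internal (ungapped) aligner
    cigar: list[tuple[int, int]] | None = None

    @property
    def end(self) -> int:
        return self.start + self.aligned_len

    @property
    def divergence(self) -> float:
        return self.mismatches / self.aligned_len if self.aligned_len else 0.0


def trim_reads(
    reads: Iterable[tuple[str, str, str]], target_len: int
) -> Iterator[tuple[str, str, str]]:
    """Filter-or-trim: reads longer than target_len are cut to their first
    target_len bases; shorter reads are discarded."""
    if target_len <= 0:
        raise ValueError("target_len must be > 0")
    for name, seq, qual in reads:
        if len(seq) >= target_len:
            yield name, seq[:target_len], qual[:target_len]


class Aligner:
    """Seed-and-extend ungapped aligner over a TELibrary (families + genes)."""

    def __init__(
        self,
        library: TELibrary,
        min_identity: float = DEFAULT_MIN_IDENTITY,
        k: int = DEFAULT_SEED_K,
        min_aligned: int = DEFAULT_MIN_ALIGNED,
    ) -> None:
        if not 0 < min_identity <= 1:
            raise ValueError("min_identity must be in (0,1]")
        self.library = library
        self.min_identity = min_identity
        self.k = k
        self.min_aligned = min_aligned
        self.ref_ids = library.reference_ids
        self.ref_seqs = {r: library.sequence_of(r).upper() for r in self.ref_ids}
        self.ref_enc = {r: encode(s) for r, s in self.ref_seqs.items()}
        self.n_unaligned = 0
        self._index: dict[str, list[tuple[str, int]]] = {}
        for rid in self.ref_ids:
            s = self.ref_seqs[rid]
            for pos in range(len(s) - k + 1):
                self._index.setdefault(s[pos : pos + k], []).append((rid, pos))

    def _seed_offsets(self, read_len: int) -> list[int]:
        offs = list(range(0, read_len - self.k + 1, self.k))
        last = read_len - self.k
        if last >= 0 and last not in offs:
            offs.append(last)
        return offs

    def align_read(self, read_id: str, seq: str) -> list[ReadAlignment]:
        """Best semi-global placement(s) of one read.

        Returns [] for unmappable reads; one entry per tied reference with
        is_ambiguous set when the best score ties across >=2 references.
        """
        seq = seq.upper()
        entries: list[tuple[int, str, str, int, int, int, int, str]] = []
        # (score, ref, strand, start, alen, mm, q_start, oriented_seq)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            L = len(s)
            if L < max(self.k, self.min_aligned):
                continue
            q = encode(s)
            cands: set[tuple[str, int]] = set()
            for o in self._seed_offsets(L):
                for rid, pos in self._index.get(s[o : o + self.k], ()):
                    cands.add((rid, pos - o))
            for rid, d in cands:
                ref = self.ref_enc[rid]
                a = max(0, d)
                b = min(len(ref), d + L)
                alen = b - a
                if alen < self.min_aligned:
                    continue
                mm = int(np.count_nonzero(ref[a:b] != q[a - d : b - d]))
                if (alen - mm) / alen < self.min_identity:
                    continue
                score = alen - 2 * mm
                entries.append((score, rid, strand, a, alen, mm, a - d, s))
        if not entries:
            self.n_unaligned += 1
            return []
        best = max(e[0] for e in entries)
        winners = [e for e in entries if e[0] == best]
        per_ref: dict[str, tuple] = {}
        for e in winners:
            key = e[1]
            rank = (e[2] != "+", e[3])  # prefer + strand, then smallest start
            if key not in per_ref or rank < (per_ref[key][2] != "+", per_ref[key][3]):
                per_ref[key] = e
        n_tied = len(per_ref)
        out = []
        for rid in sorted(per_ref, key=self.ref_ids.index):
            score, _, strand, start, alen, mm, qs, s = per_ref[rid]
            out.append(
                ReadAlignment(
                    read_id=read_id,
                    family_id=rid,
                    start=start,
                    strand=strand,
                    mismatches=mm,
                    aligned_len=alen,
                    is_ambiguous=n_tied > 1,
                    n_tied=n_tied,
                    seq=s,
                    q_start=qs,
                    score=score,
                )
            )
        return out


def align_reads(
    reads: Iterable[tuple[str, str, str] | tuple[str, str]],
    library: TELibrary,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    **kwargs,
) -> list[ReadAlignment]:
    """Align a read set; returns the concatenated per-read placements."""
    aligner = Aligner(library, min_identity=min_identity, **kwargs)
    out: list[ReadAlignment] = []
    for rec in reads:
        out.extend(aligner.align_read(rec[0], rec[1]))
    return out


# ---------------------------------------------------------------------------
# SAM interoperability
# ---------------------------------------------------------------------------


def write_sam(
    alignments: Sequence[ReadAlignment], library: TELibrary, path: str | os.PathLike
) -> None:
    """Emit alignments as text SAM (soft clips for overhangs, AS/NM tags;
    the second and later members of an ambiguous group carry the secondary
    flag)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": rid, "LN": len(library.sequence_of(rid))}
            for rid in library.reference_ids
        ],
    }
    ref_index = {rid: i for i, rid in enumerate(library.reference_ids)}
    seen_primary: set[str] = set()
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for aln in alignments:
            rec = pysam.AlignedSegment(sam.header)
            rec.query_name = aln.read_id
            rec.reference_id = ref_index[aln.family_id]
            rec.reference_start = aln.start
            rec.mapping_quality = 0 if aln.is_ambiguous else 60
            flag = 0
            if aln.strand == "-":
                flag |= 16
            if aln.read_id in seen_primary:
                flag |= 256
            seen_primary.add(aln.read_id)
            rec.flag = flag
            cigar = []
            if aln.q_start:
                cigar.append((4, aln.q_start))
            cigar.append((0, aln.aligned_len))
            tail = len(aln.seq) - aln.q_start - aln.aligned_len
            if tail:
                cigar.append((4, tail))
            rec.cigartuples = cigar
            rec.query_sequence = aln.seq
            rec.set_tag("AS", aln.score)
            rec.set_tag("NM", aln.mismatches)
            sam.write(rec)


def ingest_sam(path: str | os.PathLike, library: TELibrary) -> list[ReadAlignment]:
    """Convert mapped SAM records into ReadAlignments.

    Secondary records whose alignment score equals the primary's mark the
    read ambiguous (tie semantics); unmapped records are skipped.  SAM
    references must be a subset of the library.
    """
    groups: dict[str, list] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        known = set(library.reference_ids)
        for ref in sam.references:
            if ref not in known:
                raise ValueError(f"SAM reference {ref!r} not in library")
        for rec in sam:
            if rec.is_unmapped:
                continue
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            alen = rec.query_alignment_length
            score = rec.get_tag("AS") if rec.has_tag("AS") else alen - 2 * nm
            groups.setdefault(rec.query_name, []).append(
                (
                    score,
                    rec.reference_name,
                    "-" if rec.is_reverse else "+",
                    rec.reference_start,
                    alen,
                    int(nm),
                    rec.query_alignment_start,
                    rec.query_sequence or "",
                    rec.cigartuples,
                )
            )
    out: list[ReadAlignment] = []
    order = {rid: i for i, rid in enumerate(library.reference_ids)}
    for read_id, recs in groups.items():
        best = max(r[0] for r in recs)
        winners = [r for r in recs if r[0] == best]
        refs = sorted({r[1] for r in winners}, key=order.get)
        n_tied = len(refs)
        by_ref = {}
        for r in winners:
            by_ref.setdefault(r[1], r)
        for rid in refs:
            score, _, strand, start, alen, nm, qs, seq, cig = by_ref[rid]
            gapped = cig is not None and any(op in (1, 2, 3) for op, _ in cig)
            out.append(
                ReadAlignment(
                    read_id=read_id,
                    family_id=rid,
                    start=start,
                    strand=strand,
                    mismatches=nm,
                    aligned_len=alen,
                    is_ambiguous=n_tied > 1,
                    n_tied=n_tied,
                    seq=seq,
                    q_start=qs,
                    score=int(score),
                    cigar=[tuple(t) for t in cig] if gapped else None,
                )
            )
    return out


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------


@dataclass
class RefPileup:
    """Per-reference pileup arrays over consensus positions."""

    cov_unambiguous: np.ndarray
    cov_ambiguous: np.ndarray
    bases: np.ndarray  # shape (4, L): A/C/G/T counts from unambiguous reads
    insertions: np.ndarray
    deletions: np.ndarray
    read_divergences: list[float] = field(default_factory=list)

    @property
    def total_coverage(self) -> np.ndarray:
        return self.cov_unambiguous + self.cov_ambiguous


@dataclass
class PileupMatrix:
    """Pileups for every library reference plus library-wide read totals."""

    refs: dict[str, RefPileup]
    total_mapped_reads: float = 0.0

    def __getitem__(self, ref_id: str) -> RefPileup:
        return self.refs[ref_id]

    def mean_divergence(self, ref_id: str) -> float:
        divs = self.refs[ref_id].read_divergences
        return float(np.mean(divs)) if divs else 0.0

    # -- serialization (tab-separated dump, one row per position) --------

    def write_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(f"#TOTAL_MAPPED\t{self.total_mapped_reads!r}\n")
            for rid, p in self.refs.items():
                divs = p.read_divergences
                mean_div = float(np.mean(divs)) if divs else 0.0
                fh.write(f"#DIVERGENCE\t{rid}\t{mean_div!r}\t{len(divs)}\n")
            fh.write("family\tpos\tcovU\tcovA\tA\tC\tG\tT\tins\tdel\n")
            for rid, p in self.refs.items():
                for i in range(len(p.cov_unambiguous)):
                    fh.write(
                        f"{rid}\t{i}\t{float(p.cov_unambiguous[i])!r}\t{float(p.cov_ambiguous[i])!r}\t"
                        f"{int(p.bases[0, i])}\t{int(p.bases[1, i])}\t"
                        f"{int(p.bases[2, i])}\t{int(p.bases[3, i])}\t"
                        f"{int(p.insertions[i])}\t{int(p.deletions[i])}\n"
                    )

    @classmethod
    def read_tsv(cls, path: str | os.PathLike) -> "PileupMatrix":
        total = 0.0
        div_info: dict[str, tuple[float, int]] = {}
        rows: dict[str, list[list[float]]] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("#TOTAL_MAPPED"):
                    total = float(line.split("\t")[1])
                    continue
                if line.startswith("#DIVERGENCE"):
                    _, rid, mean_div, n = line.rstrip("\n").split("\t")
                    div_info[rid] = (float(mean_div), int(n))
                    continue
                if line.startswith("family\t"):
                    continue
                parts = line.rstrip("\n").split("\t")
                rows.setdefault(parts[0], []).append([float(x) for x in parts[2:]])
        refs = {}
        for rid, data in rows.items():
            arr = np.asarray(data).T
            mean_div, n = div_info.get(rid, (0.0, 0))
            refs[rid] = RefPileup(
                cov_unambiguous=arr[0],
                cov_ambiguous=arr[1],
                bases=arr[2:6],
                insertions=arr[6],
                deletions=arr[7],
                read_divergences=[mean_div] * n,
            )
        return cls(refs=refs, total_mapped_reads=total)


def build_pileup(
    alignments: Sequence[ReadAlignment], library: TELibrary
) -> PileupMatrix:
    """Accumulate coverage, base and indel counts per consensus position.

    Unambiguous reads contribute 1 to cov_unambiguous and to the base counts
    of their (ACGT) bases; ambiguous reads contribute 1/k to cov_ambiguous of
    each of their k tied references and no base counts (the base identity of
    an ambiguously placed read is unreliable).  Per-read divergence is
    recorded for unambiguous reads.  Order-independent by construction.
    """
    refs = {}
    for rid in library.reference_ids:
        L = len(library.sequence_of(rid))
        refs[rid] = RefPileup(
            cov_unambiguous=np.zeros(L),
            cov_ambiguous=np.zeros(L),
            bases=np.zeros((4, L)),
            insertions=np.zeros(L),
            deletions=np.zeros(L),
        )
    total = 0.0
    for aln in alignments:
        if aln.family_id not in refs:
            raise KeyError(f"alignment references unknown family {aln.family_id!r}")
        p = refs[aln.family_id]
        if aln.is_ambiguous:
            ref_span = _reference_span(aln)
            p.cov_ambiguous[aln.start : aln.start + ref_span] += 1.0 / aln.n_tied
            total += 1.0 / aln.n_tied
        elif aln.cigar is None:
            seg = encode(aln.seq[aln.q_start : aln.q_start + aln.aligned_len])
            pos = np.arange(aln.start, aln.end)
            mask = seg < 4  # N bases carry no call
            p.cov_unambiguous[pos[mask]] += 1
            p.bases[seg[mask], pos[mask]] += 1
            p.read_divergences.append(aln.divergence)
            total += 1.0
        else:
            _accumulate_gapped(p, aln)
            p.read_divergences.append(aln.divergence)
            total += 1.0
    return PileupMatrix(refs=refs, total_mapped_reads=total)


def _reference_span(aln: ReadAlignment) -> int:
    if aln.cigar is None:
        return aln.aligned_len
    return sum(length for op, length in aln.cigar if op in (0, 2, 3, 7, 8))


def _accumulate_gapped(p: RefPileup, aln: ReadAlignment) -> None:
    """Walk a gapped CIGAR, adding coverage/base counts for match ops and
    counting insertion/deletion events at their reference positions."""
    enc = encode(aln.seq) if aln.seq else np.empty(0, dtype=np.uint8)
    rpos, qpos = aln.start, 0
    for op, length in aln.cigar:
        if op in (0, 7, 8):  # M / = / X
            seg = enc[qpos : qpos + length]
            pos = np.arange(rpos, rpos + length)
            mask = seg < 4
            p.cov_unambiguous[pos[mask]] += 1
            p.bases[seg[mask], pos[mask]] += 1
            rpos += length
            qpos += length
        elif op == 1:  # insertion relative to the consensus
            if rpos < len(p.insertions):
                p.insertions[rpos] += 1
            qpos += length
        elif op in (2, 3):  # deletion / skip
            p.deletions[rpos : rpos + length] += 1
            rpos += length
        elif op in (4,):  # soft clip
            qpos += length
        # hard clips (5) and pads (6) consume nothing we track
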