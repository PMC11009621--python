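"""Small-RNA preprocessing and piRNA ping-pong signatures.

piRNAs are 23-29 nt small RNAs that silence TEs.  The ping-pong
amplification cycle alternately cleaves sense and antisense TE transcripts
10 nt downstream of the partner's 5' end, so an active cycle leaves a
characteristic excess of sense/antisense read pairs whose 5' ends overlap by
exactly 10 nt.  Here overlap k counts the number of overlapping nucleotides
between the two 5' ends, so the canonical ping-pong peak sits at k = 10
(conventions in the literature differ by +-1; this one is pinned).

The signature statistic z10 is the z-score of the 10-nt overlap count
against the background overlaps k in {1..23} \\ {10} (23 = minimum piRNA
length bounds the possible overlap).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .align import Aligner
from .synthetic import DEFAULT_ADAPTER
from .te_library import TELibrary

MIN_LEN, MAX_LEN = 18, 36
KMAX = 23


@dataclass
class StrandCounts:
    """Per-position 5'-end counts of sense and antisense reads on one
    family's consensus (multi-mapping reads weighted 1/k)."""

    sense: np.ndarray
    antisense: np.ndarray
    length_hist: dict[int, float] = field(default_factory=dict)


@dataclass
class PingPongProfile:
    family_id: str
    overlap: np.ndarray  # overlap[k-1] = o(k), k = 1..KMAX
    z10: float | None
    length_hist: dict[int, float] = field(default_factory=dict)
    single_stranded: bool = False

    def o(self, k: int) -> float:
        return float(self.overlap[k - 1])


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def _adapter_start(seq: str, adapter: str, min_overlap: int) -> int | None:
    """Leftmost position where a prefix of the adapter matches the read 3'
    end with overlap >= min_overlap and <= 1 mismatch per 10 bases."""
    n = len(seq)
    for i in range(n - min_overlap + 1):
        ov = min(len(adapter), n - i)
        allowed = ov // 10
        mm = sum(a != b for a, b in zip(seq[i : i + ov], adapter[:ov]))
        if mm <= allowed:
            return i
    return None


def preprocess_smallrna(
    reads: Iterable[tuple[str, str, str]],
    adapter: str = DEFAULT_ADAPTER,
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
    min_overlap: int = 3,
) -> Iterator[tuple[str, str, str]]:
    """Remove the 3' sequencing adapter and keep reads of 18-36 nt.

    The read is cut at the first prefix-match of the adapter (minimum
    overlap 3 nt, at most 1 mismatch per 10 adapter bases); reads without an
    adapter hit are kept whole, then the length filter is applied.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    for name, seq, qual in reads:
        cut = _adapter_start(seq.upper(), adapter.upper(), min_overlap)
        if cut is not None:
            seq, qual = seq[:cut], qual[:cut]
        if min_len <= len(seq) <= max_len:
            yield name, seq, qual


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------


def map_smallrna(
    reads: Iterable[tuple[str, str, str]],
    library: TELibrary,
    min_identity: float = 0.9,
) -> dict[str, StrandCounts]:
    """Assign each read to its best-matching family and strand and record
    stranded 5'-end counts in consensus coordinates.

    For a sense (plus-strand) read the 5' end is the alignment start; for an
    antisense read it is alignment end - 1.  Multi-mapping reads contribute
    1/k to each tied family.
    """
    aligner = Aligner(library, min_identity=min_identity, k=13, min_aligned=MIN_LEN)
    counts = {
        rid: StrandCounts(
            sense=np.zeros(len(library.sequence_of(rid))),
            antisense=np.zeros(len(library.sequence_of(rid))),
        )
        for rid in library.reference_ids
    }
    for rec in reads:
        for aln in aligner.align_read(rec[0], rec[1]):
            w = 1.0 / aln.n_tied
            c = counts[aln.family_id]
            if aln.strand == "+":
                c.sense[aln.start] += w
            else:
                c.antisense[aln.end - 1] += w
            L = len(rec[1])
            if MIN_LEN <= L <= MAX_LEN:
                c.length_hist[L] = c.length_hist.get(L, 0.0) + w
    return counts


# ---------------------------------------------------------------------------
# signature
# ---------------------------------------------------------------------------


def pingpong_signature(
    counts: StrandCounts, family_id: str = "", kmax: int = KMAX
) -> PingPongProfile:
    """Overlap histogram o(k) and the z10 ping-pong statistic.

    o(k) = sum over positions p of sense5'(p) * antisense5'(p + k - 1);
    z10 = (o(10) - mean{o(k), k != 10}) / sd{o(k), k != 10}.  With reads on
    only one strand the profile is flagged and z10 undefined.
    """
    sense, anti = counts.sense, counts.antisense
    single = sense.sum() == 0 or anti.sum() == 0
    n = len(sense)
    overlap = np.zeros(kmax)
    for k in range(1, kmax + 1):
        overlap[k - 1] = float(np.dot(sense[: n - (k - 1)], anti[k - 1 :]))
    z10: float | None = None
    if not single:
        background = np.delete(overlap, 9)
        if np.count_nonzero(background) >= 2 and background.std(ddof=1) > 0:
            z10 = float((overlap[9] - background.mean()) / background.std(ddof=1))
    return PingPongProfile(
        family_id=family_id,
        overlap=overlap,
        z10=z10,
        length_hist=dict(counts.length_hist),
        single_stranded=single,
    )
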