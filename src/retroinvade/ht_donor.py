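"""Candidate horizontal-transfer donor scoring across genome assemblies.

A species that donated a TE to another by horizontal transfer should carry
insertions highly similar to the recipient's consensus sequence.  The
pipeline finds TE hits on each candidate assembly (internal local-alignment
hit finder, or ingested repeat-annotation tables in the standard
RepeatMasker .out dialect), merges fragmented matches, and computes per
(assembly, family) the similarity

    s = max(score_i) / max(score_all)

i.e. the best hit score in assembly i relative to the best hit score in any
assembly: 1 for the assembly carrying the most consensus-like insertion,
0 for assemblies without hits.  Full-length insertions can be extracted by
length window for external multiple alignment and tree inference, and LTR
insertions dated from the divergence of their two terminal repeats
(age = d / (2*rate): both LTRs are identical at insertion time and diverge
independently afterwards).
"""
from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io_utils import encode, read_fasta, revcomp
from .te_library import TELibrary

DEFAULT_MAX_GAP = 100  # bp, merge distance for fragmented hits
DEFAULT_MIN_SCORE = 30
SEED_K = 12
XDROP = 20


@dataclass
class RepeatHit:
    """A scored match of a TE family on an assembly contig (0-based
    half-open contig coordinates; consensus_span in family coordinates)."""

    assembly_id: str
    contig: str
    start: int
    end: int
    strand: str
    family_id: str
    score: float
    divergence: float
    consensus_span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"bad hit interval [{self.start},{self.end})")
        if not 0 <= self.divergence <= 1:
            raise ValueError(f"divergence {self.divergence} outside [0,1]")
        if self.score < 0:
            raise ValueError("negative hit score")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# RepeatMasker .out dialect
# ---------------------------------------------------------------------------


def parse_repeat_table(path: str | os.PathLike, assembly_id: str = "") -> list[RepeatHit]:
    """Parse the standard 15-column RepeatMasker .out layout (3 header
    lines).  Coordinates are converted to 0-based half-open, percent
    divergence to a fraction, and 'C' orientation to strand '-'."""
    hits: list[RepeatHit] = []
    if not assembly_id:
        assembly_id = os.path.splitext(os.path.basename(str(path)))[0]
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, start=1):
        if lineno <= 3 or not line.strip():
            continue
        parts = line.split()
        try:
            score = float(parts[0])
            div = float(parts[1]) / 100.0
            contig = parts[4]
            qbegin, qend = int(parts[5]), int(parts[6])
            orient = parts[8]
            family = parts[9]
            # repeat-position columns are "begin end (left)" for + hits and
            # "(left) end begin" for C (complement) hits
            if orient == "C":
                strand = "-"
                rend, rbegin = int(parts[12]), int(parts[13])
            else:
                strand = "+"
                rbegin, rend = int(parts[11]), int(parts[12])
            hits.append(
                RepeatHit(
                    assembly_id=assembly_id,
                    contig=contig,
                    start=qbegin - 1,
                    end=qend,
                    strand=strand,
                    family_id=family,
                    score=score,
                    divergence=div,
                    consensus_span=(rbegin - 1, rend),
                )
            )
        except (ValueError, IndexError) as exc:
            raise ValueError(f"malformed .out row at line {lineno} of {path}: {exc}")
    return hits


def write_repeat_table(hits: list[RepeatHit], path: str | os.PathLike) -> None:
    """Write hits back in the .out dialect (inverse of parse_repeat_table)."""
    with open(path, "w") as fh:
        fh.write(
            "   SW   perc perc perc  query     position in query    matching "
            "repeat       position in repeat\n"
            "score   div. del. ins.  sequence  begin end   (left)   repeat   "
            "class/family begin end (left)  ID\n\n"
        )
        for i, h in enumerate(hits, start=1):
            qs, qe = h.consensus_span
            if h.strand == "-":
                rep_cols = f"(0) {qe} {qs + 1}"
                orient = "C"
            else:
                rep_cols = f"{qs + 1} {qe} (0)"
                orient = "+"
            fh.write(
                f"{h.score:g} {h.divergence * 100:.2f} 0.00 0.00 {h.contig} "
                f"{h.start + 1} {h.end} (0) {orient} {h.family_id} "
                f"Unknown {rep_cols} {i}\n"
            )


# ---------------------------------------------------------------------------
# internal hit finder
# ---------------------------------------------------------------------------


def _load_assembly(assembly) -> dict[str, str]:
    if isinstance(assembly, dict):
        return assembly
    return dict(read_fasta(assembly))


def find_hits(
    assembly,
    library: TELibrary,
    min_score: float = DEFAULT_MIN_SCORE,
    assembly_id: str = "assembly",
    k: int = SEED_K,
    xdrop: float = XDROP,
) -> list[RepeatHit]:
    """Local ungapped hits of each family on each contig, both strands.

    Seed (k=12 exact match) and gapless extension, match +1 / mismatch -1
    with x-drop termination; hits below min_score are dropped.  Divergence
    is mismatches / alignment length.  `assembly` is a FASTA path or a
    {contig: sequence} dict.
    """
    contigs = _load_assembly(assembly)
    # seed index over both orientations of every family consensus
    index: dict[str, list[tuple[str, str, int]]] = {}
    targets: dict[tuple[str, str], np.ndarray] = {}
    for fam in library.families:
        for orient, seq in (("+", fam.sequence), ("-", revcomp(fam.sequence))):
            targets[(fam.family_id, orient)] = encode(seq)
            for pos in range(len(seq) - k + 1):
                index.setdefault(seq[pos : pos + k], []).append(
                    (fam.family_id, orient, pos)
                )
    hits: list[RepeatHit] = []
    for contig_name, cseq in contigs.items():
        cseq = cseq.upper()
        cenc = encode(cseq)
        seeds: dict[tuple[str, str, int], list[int]] = {}
        for p in range(len(cseq) - k + 1):
            for fam, orient, tpos in index.get(cseq[p : p + k], ()):
                seeds.setdefault((fam, orient, p - tpos), []).append(p)
        for (fam, orient, diag), positions in seeds.items():
            tenc = targets[(fam, orient)]
            a = max(0, diag)
            b = min(len(cenc), diag + len(tenc))
            if b - a < k:
                continue
            eq = cenc[a:b] == tenc[a - diag : b - diag]
            covered_to = a - 1
            for sp in sorted(positions):
                if sp <= covered_to:
                    continue
                h_start, h_end, score, mm = _xdrop_extend(
                    eq, sp - a, k, xdrop
                )
                covered_to = a + h_end - 1
                if score < min_score:
                    continue
                c_start, c_end = a + h_start, a + h_end
                t_start, t_end = c_start - diag, c_end - diag
                if orient == "+":
                    span = (t_start, t_end)
                    strand = "+"
                else:
                    L = len(tenc)
                    span = (L - t_end, L - t_start)
                    strand = "-"
                alen = h_end - h_start
                hits.append(
                    RepeatHit(
                        assembly_id=assembly_id,
                        contig=contig_name,
                        start=c_start,
                        end=c_end,
                        strand=strand,
                        family_id=fam,
                        score=float(score),
                        divergence=mm / alen,
                        consensus_span=span,
                    )
                )
    hits = _drop_contained(hits)
    hits.sort(key=lambda h: (h.contig, h.family_id, h.strand, h.start))
    return hits


def _drop_contained(hits: list[RepeatHit]) -> list[RepeatHit]:
    """Drop hits whose contig interval lies inside a higher-scoring hit of
    the same family on the same contig (self-repeats such as the two LTRs of
    one insertion spawn contained sub-hits)."""
    kept: list[RepeatHit] = []
    for h in sorted(hits, key=lambda x: -x.score):
        contained = any(
            k.contig == h.contig
            and k.family_id == h.family_id
            and k.start <= h.start
            and h.end <= k.end
            for k in kept
        )
        if not contained:
            kept.append(h)
    return kept


def _xdrop_extend(
    eq: np.ndarray, seed_start: int, k: int, xdrop: float
) -> tuple[int, int, float, int]:
    """Gapless x-drop extension of a seed along one diagonal.

    eq is the per-position match indicator along the diagonal; returns
    (start, end, score, mismatches) of the best-scoring extension interval
    containing the seed.
    """
    step = np.where(eq, 1.0, -1.0)
    # extend right from seed end
    best_r, run = 0.0, 0.0
    end = seed_start + k
    for j in range(seed_start + k, len(step)):
        run += step[j]
        if run > best_r:
            best_r = run
            end = j + 1
        elif best_r - run > xdrop:
            break
    # extend left from seed start
    best_l, run = 0.0, 0.0
    start = seed_start
    for j in range(seed_start - 1, -1, -1):
        run += step[j]
        if run > best_l:
            best_l = run
            start = j
        elif best_l - run > xdrop:
            break
    seed_score = float(step[seed_start : seed_start + k].sum())
    score = seed_score + best_l + best_r
    mm = int(np.count_nonzero(~eq[start:end]))
    return start, end, score, mm


# ---------------------------------------------------------------------------
# defragmentation
# ---------------------------------------------------------------------------


def defragment(
    hits: list[RepeatHit],
    max_gap: int = DEFAULT_MAX_GAP,
    require_colinear: bool = True,
) -> list[RepeatHit]:
    """Merge fragmented matches: hits on the same contig/family/strand whose
    genomic gap is <= max_gap (and, unless require_colinear=False, whose
    consensus spans advance in hit order -- this keeps tandem copies apart;
    a 50 bp span overlap is tolerated for ragged fragment ends).

    Merged score = sum of fragment scores; merged divergence =
    length-weighted mean.  Idempotent.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    span_tol = 50
    out: list[RepeatHit] = []
    key = lambda h: (h.assembly_id, h.contig, h.family_id, h.strand)
    groups: dict[tuple, list[RepeatHit]] = {}
    for h in hits:
        groups.setdefault(key(h), []).append(h)
    for _, group in sorted(groups.items()):
        group = sorted(group, key=lambda h: h.start)
        cur = group[0]
        cur_wdiv = cur.divergence * cur.length
        cur_len = cur.length
        for nxt in group[1:]:
            gap = nxt.start - cur.end
            colinear = True
            if require_colinear:
                if cur.strand == "+":
                    colinear = nxt.consensus_span[0] >= cur.consensus_span[1] - span_tol
                else:
                    colinear = nxt.consensus_span[1] <= cur.consensus_span[0] + span_tol
            if gap <= max_gap and colinear:
                cur = replace(
                    cur,
                    end=max(cur.end, nxt.end),
                    score=cur.score + nxt.score,
                    consensus_span=(
                        min(cur.consensus_span[0], nxt.consensus_span[0]),
                        max(cur.consensus_span[1], nxt.consensus_span[1]),
                    ),
                )
                cur_wdiv += nxt.divergence * nxt.length
                cur_len += nxt.length
                cur = replace(cur, divergence=cur_wdiv / cur_len)
            else:
                out.append(cur)
                cur = nxt
                cur_wdiv = cur.divergence * cur.length
                cur_len = cur.length
        out.append(cur)
    out.sort(key=lambda h: (h.assembly_id, h.contig, h.family_id, h.strand, h.start))
    return out


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------


@dataclass
class SimilarityTable:
    """Per (assembly, family) similarity s in [0,1]; NaN where a family has
    no hit in any assembly (s undefined there, not 0/0)."""

    s: pd.DataFrame  # assemblies x families
    best_assembly: dict[str, str | None]


def similarity_scores(hits_by_assembly: dict[str, list[RepeatHit]]) -> SimilarityTable:
    """s = max(score in assembly) / max(score in any assembly), per family.

    Assemblies without a hit for a family score 0; scale-invariant in the
    hit scores."""
    if not hits_by_assembly:
        raise ValueError("need at least one assembly")
    families = sorted({h.family_id for hits in hits_by_assembly.values() for h in hits})
    assemblies = list(hits_by_assembly)
    best = pd.DataFrame(0.0, index=assemblies, columns=families)
    for asm, hits in hits_by_assembly.items():
        for h in hits:
            if h.score > best.loc[asm, h.family_id]:
                best.loc[asm, h.family_id] = h.score
    global_max = best.max(axis=0)
    s = best.divide(global_max.where(global_max > 0), axis=1)
    best_assembly = {
        fam: (best[fam].idxmax() if global_max[fam] > 0 else None)
        for fam in families
    }
    return SimilarityTable(s=s, best_assembly=best_assembly)


def length_divergence_table(hits: list[RepeatHit]) -> pd.DataFrame:
    """One (family, length, divergence) row per hit; recent full-length
    insertions cluster near (consensus length, <1%), ancient remnants at
    (short, 20-30%)."""
    return pd.DataFrame(
        [
            {
                "assembly": h.assembly_id,
                "contig": h.contig,
                "family": h.family_id,
                "length": h.length,
                "divergence": h.divergence,
            }
            for h in hits
        ],
        columns=["assembly", "contig", "family", "length", "divergence"],
    )


# ---------------------------------------------------------------------------
# extraction and LTR dating
# ---------------------------------------------------------------------------


def extract_full_length(
    hits: list[RepeatHit],
    assembly,
    length_window: tuple[int, int],
) -> list[tuple[str, str]]:
    """Sequences of (defragmented) hits whose length falls inside the
    window, reverse-complemented to consensus orientation; ids encode
    assembly/contig/coordinates.  Ready for external multiple alignment."""
    lo, hi = length_window
    if lo >= hi:
        raise ValueError("length window lo must be < hi")
    contigs = _load_assembly(assembly)
    out = []
    for h in hits:
        if not lo <= h.length <= hi:
            continue
        if h.contig not in contigs or h.end > len(contigs[h.contig]):
            raise ValueError(
                f"hit {h.contig}:{h.start}-{h.end} outside contig bounds"
            )
        seq = contigs[h.contig][h.start : h.end]
        if h.strand == "-":
            seq = revcomp(seq)
        name = f"{h.assembly_id}:{h.contig}:{h.start}-{h.end}:{h.strand}:{h.family_id}"
        out.append((name, seq))
    return out


def ltr_age(insertion_seq: str, ltr_length: int, rate: float) -> float:
    """Insertion age in years from LTR-LTR divergence: age = d / (2*rate).

    d is the per-site mismatch fraction between the insertion's 5' and 3'
    terminal `ltr_length` stretches (gapless comparison); `rate` is the
    substitution rate per site per year.  The two LTRs are identical when
    the element inserts, so each accumulates d/2 substitutions.
    """
    if rate <= 0:
        raise ValueError("substitution rate must be > 0")
    if ltr_length <= 0 or 2 * ltr_length > len(insertion_seq):
        raise ValueError(
            f"cannot compare two {ltr_length} bp LTRs on a "
            f"{len(insertion_seq)} bp insertion"
        )
    five = insertion_seq[:ltr_length].upper()
    three = insertion_seq[-ltr_length:].upper()
    d = sum(a != b for a, b in zip(five, three)) / ltr_length
    return d / (2 * rate)
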