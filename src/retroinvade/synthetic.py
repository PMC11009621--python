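"""Synthetic ground-truth genomes, short-read samples, small-RNA sets and
donor-assembly panels.

The generator emulates the structure the analysis assumes in real data:

* per-sample haploid TE copy numbers between 0 and ~40;
* lineage-specific TE-internal SNPs whose frequencies differ between
  populations (each inserted copy draws each SNP independently with the
  lineage frequency);
* recent full-length insertions with little divergence to the consensus
  (<1%) next to old, highly diverged (20-30%) fragments -- remnants of
  ancient invasions;
* single-end reads of 50 or 100 bp with uniform substitution errors;
* 23-29 nt small RNAs, a configurable fraction of which form sense/antisense
  ping-pong pairs whose 5' ends overlap by exactly 10 nt.

Everything is deterministic given a seed; identical specs produce
byte-identical FASTA/FASTQ output.  Backbone sequence is i.i.d. uniform
ACGT so that it carries no accidental homology with the consensus library.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_utils import BASES, revcomp
from .te_library import GeneSequence, TEConsensus, TELibrary

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

# Each generator derives its RNG from (seed, role) so that reusing one seed
# across functions never replays the same stream (a genome backbone must not
# accidentally reproduce the library drawn with the same seed).
_ROLE_GENOME = 1
_ROLE_READS = 2
_ROLE_SMALLRNA = 3
_ROLE_PANEL = 4
_ROLE_LIBRARY = 5


def _rng(seed: int, role: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), role]))


# ---------------------------------------------------------------------------
# specs and truth
# ---------------------------------------------------------------------------


@dataclass
class DegradedSpec:
    """Old degraded fragments of a family: how many, how diverged, how long."""

    count: int
    divergence: float
    length_range: tuple[int, int]

    def __post_init__(self) -> None:
        if not 0 <= self.divergence < 1:
            raise ValueError(f"divergence must be in [0,1), got {self.divergence}")
        lo, hi = self.length_range
        if not 0 < lo <= hi:
            raise ValueError(f"bad length_range {self.length_range}")


@dataclass
class GenomeSpec:
    """Ground-truth description of one synthetic haploid genome sample."""

    backbone_length: int
    copy_number: dict[str, int] = field(default_factory=dict)
    #: per family: list of (consensus position, alt base, lineage frequency)
    lineage_snps: dict[str, list[tuple[int, str, float]]] = field(default_factory=dict)
    degraded: dict[str, DegradedSpec] = field(default_factory=dict)
    #: extra per-copy point-mutation rate for full-length copies
    copy_divergence: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for fam, n in self.copy_number.items():
            if n < 0:
                raise ValueError(f"negative copy number for {fam!r}")
        for fam, snps in self.lineage_snps.items():
            for pos, alt, freq in snps:
                if not 0 < freq <= 1:
                    raise ValueError(
                        f"lineage frequency must be in (0,1], got {freq} "
                        f"for {fam!r}:{pos}"
                    )
                if alt not in BASES:
                    raise ValueError(f"alt base {alt!r} for {fam!r}:{pos}")


@dataclass
class Insertion:
    """One realized insertion in the emitted genome (genome coordinates)."""

    family_id: str
    start: int
    end: int
    identity: float  # fraction identity to the consensus over the insert
    kind: str = "full"  # "full" | "degraded" | "gene"


@dataclass
class TruthTable:
    """Ground truth for one genome: copy numbers, realized SNP frequencies
    (fraction of full-length copies carrying the alt base) and insertion
    intervals."""

    copy_number: dict[str, int]
    snp_frequency: dict[tuple[str, int, str], float]
    insertions: list[Insertion]


# ---------------------------------------------------------------------------
# mutation helpers
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, length)])


def _mutate_exact(seq: str, n_mut: int, rng: np.random.Generator,
                  forbidden: set[int] | None = None) -> str:
    """Mutate exactly n_mut distinct positions to a different base."""
    allowed = [i for i in range(len(seq)) if not forbidden or i not in forbidden]
    if n_mut > len(allowed):
        n_mut = len(allowed)
    positions = rng.choice(len(allowed), size=n_mut, replace=False)
    out = list(seq)
    for idx in positions:
        p = allowed[idx]
        choices = [b for b in BASES if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out)


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------


def build_genome(spec: GenomeSpec, library: TELibrary) -> tuple[str, TruthTable]:
    """Emit a synthetic genome and its TruthTable.

    Each full-length TE copy is the consensus with lineage SNPs drawn
    independently at their lineage frequency, plus uniform point mutations at
    spec.copy_divergence (never on SNP positions, so realized SNP frequencies
    are exact counts over copies).  Degraded fragments are random consensus
    subsequences mutated to exactly the stated divergence.  Exactly one copy
    of each normalization gene is inserted.  Insertions never overlap: they
    are spliced into the backbone at distinct random points.
    """
    rng = _rng(spec.seed, _ROLE_GENOME)
    backbone = _random_seq(rng, spec.backbone_length)

    segments: list[tuple[str, str, float, str]] = []  # (family, seq, identity, kind)
    snp_carriers: dict[tuple[str, int, str], int] = {}

    for fam in sorted(spec.copy_number):
        cons = library.family(fam).sequence
        snps = spec.lineage_snps.get(fam, [])
        for pos, alt, _ in snps:
            if not 0 <= pos < len(cons):
                raise ValueError(f"SNP position {pos} outside consensus of {fam!r}")
            snp_carriers.setdefault((fam, pos, alt), 0)
        snp_positions = {pos for pos, _, _ in snps}
        for _copy in range(spec.copy_number[fam]):
            seq = list(cons)
            for pos, alt, freq in snps:
                if rng.random() < freq:
                    seq[pos] = alt
                    snp_carriers[(fam, pos, alt)] += 1
            copy_seq = "".join(seq)
            n_mut = rng.binomial(len(cons) - len(snp_positions), spec.copy_divergence)
            copy_seq = _mutate_exact(copy_seq, int(n_mut), rng, forbidden=snp_positions)
            ident = 1.0 - sum(a != b for a, b in zip(copy_seq, cons)) / len(cons)
            segments.append((fam, copy_seq, ident, "full"))

    for fam in sorted(spec.degraded):
        dspec = spec.degraded[fam]
        cons = library.family(fam).sequence
        for _frag in range(dspec.count):
            lo, hi = dspec.length_range
            hi = min(hi, len(cons))
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, len(cons) - length + 1))
            frag = cons[start : start + length]
            n_mut = int(round(dspec.divergence * length))
            frag = _mutate_exact(frag, n_mut, rng)
            segments.append((fam, frag, 1.0 - n_mut / length, "degraded"))

    for gene in library.genes:
        segments.append((gene.name, gene.sequence, 1.0, "gene"))

    # strand of each insertion
    strands = rng.integers(0, 2, len(segments))
    order = rng.permutation(len(segments))
    n_seg = len(segments)
    if n_seg > spec.backbone_length + 1:
        raise ValueError(
            f"cannot place {n_seg} insertions without overlap in a "
            f"{spec.backbone_length} bp backbone; use a larger backbone"
        )
    points = np.sort(rng.choice(spec.backbone_length + 1, size=n_seg, replace=False))

    pieces: list[str] = []
    insertions: list[Insertion] = []
    cursor = 0
    offset = 0
    for k, point in enumerate(points):
        pieces.append(backbone[cursor : int(point)])
        offset += int(point) - cursor
        cursor = int(point)
        fam, seq, ident, kind = segments[order[k]]
        emitted = revcomp(seq) if strands[order[k]] else seq
        pieces.append(emitted)
        insertions.append(Insertion(fam, offset, offset + len(seq), ident, kind))
        offset += len(seq)
    pieces.append(backbone[cursor:])
    genome = "".join(pieces)

    copy_number = {fam: spec.copy_number.get(fam, 0) for fam in library.family_ids}
    snp_frequency = {
        key: (carriers / spec.copy_number[key[0]] if spec.copy_number.get(key[0]) else 0.0)
        for key, carriers in snp_carriers.items()
    }
    truth = TruthTable(
        copy_number=copy_number,
        snp_frequency=snp_frequency,
        insertions=sorted(insertions, key=lambda i: i.start),
    )
    return genome, truth


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def simulate_reads(
    genome: str,
    coverage: float,
    read_len: int,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str, str]]:
    """Single-end reads at uniform random positions on either strand.

    Expected depth equals `coverage`; substitution errors at `error_rate`;
    base qualities constant 'I' (no stage of the pipeline uses qualities).
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if read_len > len(genome):
        raise ValueError("read_len exceeds genome length")
    rng = _rng(seed, _ROLE_READS)
    n_reads = int(round(coverage * len(genome) / read_len))
    starts = rng.integers(0, len(genome) - read_len + 1, n_reads)
    strands = rng.integers(0, 2, n_reads)
    qual = "I" * read_len
    reads: list[tuple[str, str, str]] = []
    for i in range(n_reads):
        s = int(starts[i])
        seq = genome[s : s + read_len]
        if error_rate > 0:
            n_err = rng.binomial(read_len, error_rate)
            if n_err:
                seq = _mutate_exact(seq, int(n_err), rng)
        if strands[i]:
            seq = revcomp(seq)
        reads.append((f"read_{i}", seq, qual))
    return reads


# ---------------------------------------------------------------------------
# small RNA simulation
# ---------------------------------------------------------------------------


def simulate_smallrna(
    family: TEConsensus,
    n_pairs: int,
    pingpong_fraction: float,
    adapter: str = DEFAULT_ADAPTER,
    seed: int = 0,
) -> list[tuple[str, str, str]]:
    """Simulate a small-RNA library from one TE family.

    Generates 2*n_pairs reads of 23-29 nt from both strands of the
    consensus.  A fraction `pingpong_fraction` of read pairs are
    sense/antisense ping-pong partners whose 5' ends overlap by exactly
    10 nt; the remainder are independent reads.  The 3' sequencing adapter is
    appended to every read (removed again by the small-RNA preprocessing
    stage).
    """
    if not 0 <= pingpong_fraction <= 1:
        raise ValueError("pingpong_fraction must be in [0,1]")
    rng = _rng(seed, _ROLE_SMALLRNA)
    cons = family.sequence
    n = len(cons)
    n_pp = int(round(pingpong_fraction * n_pairs))
    reads: list[tuple[str, str, str]] = []

    def emit(idx: int, insert: str) -> None:
        seq = insert + adapter
        reads.append((f"srna_{idx}", seq, "I" * len(seq)))

    idx = 0
    for _ in range(n_pp):
        ls = int(rng.integers(23, 30))
        la = int(rng.integers(23, 30))
        # sense 5' at p, antisense 5' at p + 9 => 10 nt 5'-overlap
        p_min = max(0, la - 10)
        p_max = n - ls
        p = int(rng.integers(p_min, p_max + 1))
        sense = cons[p : p + ls]
        anti = revcomp(cons[p + 10 - la : p + 10])
        emit(idx, sense)
        idx += 1
        emit(idx, anti)
        idx += 1
    for _ in range(n_pairs - n_pp):
        for _rep in range(2):
            length = int(rng.integers(23, 30))
            p = int(rng.integers(0, n - length + 1))
            insert = cons[p : p + length]
            if rng.integers(0, 2):
                insert = revcomp(insert)
            emit(idx, insert)
            idx += 1
    return reads


# ---------------------------------------------------------------------------
# donor-species panel
# ---------------------------------------------------------------------------


def build_species_panel(
    library: TELibrary,
    divergence_ladder: list[float],
    seed: int = 0,
    copies_per_family: int = 2,
    backbone_length: int = 8000,
) -> tuple[dict[str, dict[str, str]], dict]:
    """One synthetic assembly per ladder value.

    Each assembly carries `copies_per_family` insertions of every family,
    mutated to exactly that ladder divergence.  The 0-divergence assembly is
    the designated horizontal-transfer donor.  Returns
    ({assembly_id: {contig_id: sequence}}, truth) where truth records the
    donor id and the per-assembly divergence.
    """
    for v in divergence_ladder:
        if not 0 <= v < 1:
            raise ValueError(f"ladder value {v} outside [0,1)")
    rng = _rng(seed, _ROLE_PANEL)
    assemblies: dict[str, dict[str, str]] = {}
    truth: dict = {"divergence": {}, "donor": None}
    for i, div in enumerate(divergence_ladder):
        name = f"asm{i:02d}_div{int(round(div * 100)):02d}"
        backbone = _random_seq(rng, backbone_length)
        segments: list[str] = []
        for fam in library.families:
            for _ in range(copies_per_family):
                n_mut = int(round(div * fam.length))
                seq = _mutate_exact(fam.sequence, n_mut, rng)
                if rng.integers(0, 2):
                    seq = revcomp(seq)
                segments.append(seq)
        points = np.sort(
            rng.choice(backbone_length + 1, size=len(segments), replace=False)
        )
        pieces = []
        cursor = 0
        for k, point in enumerate(points):
            pieces.append(backbone[cursor : int(point)])
            pieces.append(segments[k])
            cursor = int(point)
        pieces.append(backbone[cursor:])
        assemblies[name] = {"contig1": "".join(pieces)}
        truth["divergence"][name] = div
        if div == 0:
            truth["donor"] = name
    return assemblies, truth


# ---------------------------------------------------------------------------
# demo library
# ---------------------------------------------------------------------------


def make_demo_library(
    n_families: int = 3,
    family_length: int = 1200,
    ltr_length: int = 150,
    n_genes: int = 3,
    gene_length: int = 800,
    polya_length: int = 12,
    seed: int = 0,
) -> TELibrary:
    """Random TE consensus library with LTR structure and a poly-A track.

    Families are LTR-retrotransposon-shaped: identical terminal repeats of
    `ltr_length` bp and an internal poly-A run of `polya_length` bp (the
    coverage-curbing target).  Gene names follow the standard normalization
    trio.
    """
    rng = _rng(seed, _ROLE_LIBRARY)
    families = []
    for i in range(n_families):
        ltr = _random_seq(rng, ltr_length)
        internal_len = family_length - 2 * ltr_length - polya_length
        internal = _random_seq(rng, internal_len)
        mid = internal_len // 2
        seq = ltr + internal[:mid] + "A" * polya_length + internal[mid:] + ltr
        families.append(
            TEConsensus(f"TEfam{i + 1}", seq, ltr_length=ltr_length, orf_count=2)
        )
    gene_names = ["rhino", "trafficjam", "rpl32", *(f"gene{i}" for i in range(4, 10))]
    genes = [
        GeneSequence(gene_names[i], _random_seq(rng, gene_length))
        for i in range(n_genes)
    ]
    return TELibrary(families=families, genes=genes)
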