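"""End-to-end synthetic study scenarios with known ground truth.

Each function builds one of the study designs the pipeline is meant to
handle -- a copy-number ladder, a dated invasion panel, a population
composition panel, ping-pong small-RNA sets, a donor divergence ladder, a
null group comparison -- runs the pipeline on it and returns the measured
quantities next to the truth.  Problem sizes are desk-scale by design: 1 kb
synthetic consensus sequences stand in for the ~7.5 kb elements so that a
full scenario runs in seconds to a couple of minutes on one CPU; the
statistical structure (coverage, copy numbers, divergences, read lengths)
is kept at the study's stated conditions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import abundance, align, composition, smallrna, synthetic
from .abundance import ClassifyThresholds, CopyNumberCall, TESnp
from .synthetic import DegradedSpec, GenomeSpec
from .te_library import TELibrary

# study conditions: coverage and read structure of the genomic analysis
COVERAGE = 20.0
READ_LEN = 100
ERROR_RATE = 0.01
COPY_LADDER = (0, 2, 5, 10, 20, 40)


def _sample_pileup(
    library: TELibrary,
    spec: GenomeSpec,
    coverage: float = COVERAGE,
    read_len: int = READ_LEN,
    error_rate: float = ERROR_RATE,
    read_seed: int = 1,
):
    genome, truth = synthetic.build_genome(spec, library)
    reads = synthetic.simulate_reads(genome, coverage, read_len, error_rate, read_seed)
    alignments = align.align_reads(reads, library)
    pileup = align.build_pileup(alignments, library)
    return pileup, truth, alignments


# ---------------------------------------------------------------------------
# copy-number recovery ladder
# ---------------------------------------------------------------------------


@dataclass
class CopyNumberRecovery:
    truth: dict[str, int]
    estimate: dict[str, float]
    calls: dict[str, CopyNumberCall]

    def relative_errors(self) -> dict[str, float]:
        return {
            fam: abs(self.estimate[fam] - n) / n
            for fam, n in self.truth.items()
            if n > 0
        }


def copy_number_recovery(
    seed: int,
    copy_numbers: tuple[int, ...] = COPY_LADDER,
    coverage: float = COVERAGE,
    read_len: int = READ_LEN,
    error_rate: float = ERROR_RATE,
) -> CopyNumberRecovery:
    """One genome carrying one family per ladder value (0..40 copies),
    sequenced at the study coverage; estimates vs planted truth.

    Consensus and gene lengths are kept at realistic kb scale (5 kb
    elements, 4 kb normalization genes) so that read-sampling noise on the
    coverage ratio stays well inside the 10% recovery margin.
    """
    library = synthetic.make_demo_library(
        n_families=len(copy_numbers),
        family_length=5000,
        ltr_length=400,
        gene_length=6000,
        seed=seed,
    )
    spec = GenomeSpec(
        backbone_length=30_000,
        copy_number={
            fam: n for fam, n in zip(library.family_ids, copy_numbers)
        },
        copy_divergence=0.005,
        seed=seed + 1,
    )
    pileup, truth, _ = _sample_pileup(
        library, spec, coverage, read_len, error_rate, read_seed=seed + 2
    )
    factor = abundance.normalization_factor(pileup, library)
    calls = {}
    for fam in library.families:
        call = abundance.copy_number(
            pileup,
            fam,
            factor,
            homopolymer_runs=library.homopolymer_runs[fam.family_id],
        )
        abundance.classify_family(call)
        calls[fam.family_id] = call
    return CopyNumberRecovery(
        truth=truth.copy_number,
        estimate={f: c.copies for f, c in calls.items()},
        calls=calls,
    )


# ---------------------------------------------------------------------------
# invasion timeline panel
# ---------------------------------------------------------------------------

#: 12-sample panel bracketing an invasion: all samples up to 1850 carry only
#: ancient degraded fragments, all samples from 1933 on carry recent
#: full-length copies, and the 1900 samples are mixed (the invasion is under
#: way), so the recovered interval must be (1850, 1933).
TIMELINE_YEARS = {
    "s01": 1800, "s02": 1800, "s03": 1820, "s04": 1850, "s05": 1850,
    "s06": 1900, "s07": 1900,
    "s08": 1933, "s09": 1933, "s10": 1933, "s11": 1950, "s12": 1960,
}
TIMELINE_RECENT = {"s07", "s08", "s09", "s10", "s11", "s12"}
TRUTH_INTERVAL = (1850, 1933)


def timeline_recovery(
    seed: int,
    coverage: float = 15.0,
    read_len: int = READ_LEN,
) -> tuple[dict, list[CopyNumberCall]]:
    """Recover the invasion interval of one family from a 12-sample panel
    with a planted invasion between 1850 and 1933."""
    library = synthetic.make_demo_library(
        n_families=1, family_length=1000, ltr_length=120, seed=seed
    )
    fam = library.families[0]
    calls: list[CopyNumberCall] = []
    for i, (sample, _year) in enumerate(sorted(TIMELINE_YEARS.items())):
        invaded = sample in TIMELINE_RECENT
        spec = GenomeSpec(
            backbone_length=12_000,
            copy_number={fam.family_id: 8 if invaded else 0},
            degraded={
                fam.family_id: DegradedSpec(
                    count=4, divergence=0.22, length_range=(200, 500)
                )
            },
            copy_divergence=0.005,
            seed=seed + 10 + i,
        )
        pileup, _, _ = _sample_pileup(
            library, spec, coverage, read_len, ERROR_RATE, read_seed=seed + 100 + i
        )
        factor = abundance.normalization_factor(pileup, library)
        call = abundance.copy_number(
            pileup,
            fam,
            factor,
            homopolymer_runs=library.homopolymer_runs[fam.family_id],
            sample_id=sample,
        )
        abundance.classify_family(call)
        calls.append(call)
    timeline = abundance.build_timeline(calls, TIMELINE_YEARS)
    return timeline, calls


# ---------------------------------------------------------------------------
# composition panel
# ---------------------------------------------------------------------------


def composition_panel(
    seed: int,
    n_per_pop: int = 8,
    populations: tuple[str, ...] = ("Zimbabwe", "Netherlands", "Ithaca"),
    target_pop: str = "Zimbabwe",
    copies: int = 20,
    n_shared: int = 24,
    n_private: int = 6,
) -> tuple[composition.AlleleFreqMatrix, list[tuple[int, str]]]:
    """Sample panel where one population carries private high-frequency
    lineage SNPs (a founder effect during the invasion); all populations
    share a background of common SNPs.

    Returns the (unfiltered) allele-frequency matrix and the planted private
    SNP sites.  Frequencies are realized truth frequencies over `copies`
    inserted copies per sample, i.e. they carry binomial sampling noise just
    as deep-coverage estimates would.
    """
    rng = np.random.default_rng(seed)
    library = synthetic.make_demo_library(
        n_families=1, family_length=1000, ltr_length=120, seed=seed
    )
    fam = library.families[0]
    cons = fam.sequence
    in_run = set()
    for start, end in library.homopolymer_runs[fam.family_id]:
        in_run.update(range(start, end))
    usable = [p for p in range(len(cons)) if p not in in_run]
    sites = rng.choice(len(usable), size=n_shared + n_private, replace=False)
    sites = [usable[i] for i in sites]

    def alt_of(pos: int) -> str:
        choices = [b for b in "ACGT" if b != cons[pos]]
        return choices[int(rng.integers(0, 3))]

    shared = [(p, alt_of(p), float(rng.uniform(0.25, 0.6))) for p in sites[:n_shared]]
    private_sites = [(p, alt_of(p)) for p in sites[n_shared:]]

    snp_calls: dict[str, list[TESnp]] = {}
    pops: dict[str, str] = {}
    idx = 0
    for pop in populations:
        for _ in range(n_per_pop):
            sample = f"{pop[:3]}{idx:02d}"
            idx += 1
            pops[sample] = pop
            lineage = list(shared)
            for p, alt in private_sites:
                freq = 0.7 if pop == target_pop else 0.04
                lineage.append((p, alt, freq))
            spec = GenomeSpec(
                backbone_length=2000,
                copy_number={fam.family_id: copies},
                lineage_snps={fam.family_id: lineage},
                copy_divergence=0.0,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            _, truth = synthetic.build_genome(spec, library)
            calls = [
                TESnp(
                    family_id=fam.family_id,
                    position=pos,
                    ref_base=cons[pos],
                    base_freqs={alt: f, cons[pos]: 1 - f},
                    coverage=copies,
                )
                for (fam_id, pos, alt), f in truth.snp_frequency.items()
                if f > 0
            ]
            snp_calls[sample] = calls
    matrix = composition.build_matrix(snp_calls, pops)
    return matrix, private_sites


# ---------------------------------------------------------------------------
# ping-pong
# ---------------------------------------------------------------------------


def pingpong_profile(
    seed: int, fraction: float, n_pairs: int = 1500
) -> smallrna.PingPongProfile:
    """Simulate, preprocess and map a small-RNA set with a planted ping-pong
    pair fraction; return the signature profile of the family."""
    library = synthetic.make_demo_library(
        n_families=1, family_length=1000, ltr_length=120, seed=seed
    )
    fam = library.families[0]
    raw = synthetic.simulate_smallrna(fam, n_pairs, fraction, seed=seed + 1)
    clean = list(smallrna.preprocess_smallrna(raw))
    counts = smallrna.map_smallrna(clean, library)
    return smallrna.pingpong_signature(counts[fam.family_id], fam.family_id)


def pingpong_null_rate(
    seed: int, n_reps: int = 100, n_pairs: int = 200, z_cut: float = 3.0
) -> float:
    """Fraction of independent-read (no ping-pong) replicates with
    |z10| < z_cut."""
    ok = 0
    defined = 0
    for rep in range(n_reps):
        prof = pingpong_profile(seed + 1000 * (rep + 1), fraction=0.0, n_pairs=n_pairs)
        if prof.z10 is None:
            continue
        defined += 1
        if abs(prof.z10) < z_cut:
            ok += 1
    if defined == 0:
        raise RuntimeError("z10 undefined in every replicate")
    return ok / defined


# ---------------------------------------------------------------------------
# donor ladder
# ---------------------------------------------------------------------------


def donor_ladder(
    seed: int, ladder: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3)
) -> tuple[list[str], "np.ndarray", dict]:
    """Similarity scores along a divergence ladder of candidate donor
    assemblies; returns (assembly order, per-family mean s in that order,
    truth)."""
    from . import ht_donor

    library = synthetic.make_demo_library(
        n_families=3, family_length=1000, ltr_length=120, seed=seed
    )
    assemblies, truth = synthetic.build_species_panel(
        library, list(ladder), seed=seed + 1
    )
    hits = {
        name: ht_donor.defragment(
            ht_donor.find_hits(contigs, library, assembly_id=name)
        )
        for name, contigs in assemblies.items()
    }
    table = ht_donor.similarity_scores(hits)
    order = [name for name in assemblies]  # ladder order by construction
    return order, table.s.loc[order], truth


# ---------------------------------------------------------------------------
# group-comparison calibration
# ---------------------------------------------------------------------------


def type_i_error_rate(
    seed: int,
    n_reps: int = 1000,
    n_a: int = 9,
    n_b: int = 16,
    alpha: float = 0.05,
) -> float:
    """Rejection rate of the Wilcoxon rank-sum comparison under the null
    (both year groups drawn from the same copy-number distribution), at the
    9-vs-16 design of the historical panel."""
    rng = np.random.default_rng(seed)
    rejected = 0
    for _ in range(n_reps):
        a = rng.normal(10.0, 2.0, n_a)
        b = rng.normal(10.0, 2.0, n_b)
        _, p = abundance.wilcoxon_rank_sum(a, b)
        if p <= alpha:
            rejected += 1
    return rejected / n_reps
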