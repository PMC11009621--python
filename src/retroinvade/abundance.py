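"""Copy-number estimation, SNP calling, rpm abundance, invasion-status
classification, timeline assembly and year-group comparison.

The central statistic is the haploid copy number of a TE family: the mean
per-position coverage of the family consensus divided by the mean coverage
of single-copy genes (e.g. TE coverage 121 over gene coverage 12 gives 10.1
copies per haploid genome).  Coverage over annotated homopolymer runs (the
poly-A track) is curbed to the median of the flanking sequence, since reads
from any A-rich region of the genome pile up there.

A family in a sample is classified as
  absent        -- copies below a minimum (default 0.2);
  degraded_only -- present, but patchy and/or highly diverged reads only:
                   remnants of an ancient invasion;
  recent        -- copies present at high consensus similarity across the
                   whole consensus (breadth >= 0.8, mean read divergence
                   <= 5%), the signature of a recent invasion.
The per-sample classifications across collection years then bracket the
invasion interval of each family.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import PileupMatrix, ReadAlignment
from .te_library import TEConsensus, TELibrary, find_homopolymer_runs

CURB_FLANK = 50  # bp of flanking coverage used to curb homopolymer runs


@dataclass
class ClassifyThresholds:
    """Declared thresholds behind the three-way invasion-status call (the
    analogous call on real data is usually made by eye; fixing numbers makes
    it reproducible)."""

    c_min: float = 0.2
    breadth_min: float = 0.8
    divergence_max: float = 0.05


@dataclass
class CopyNumberCall:
    family_id: str
    sample_id: str
    copies: float
    normalization_factor: float
    breadth: float
    mean_read_divergence: float
    status: str | None = None  # absent | degraded_only | recent


@dataclass
class TESnp:
    """A variant segregating among the dispersed copies of one TE family.

    Its frequency is the fraction of copies carrying the allele: 15 G and
    5 A reads at a site give G frequency 0.75.
    """

    family_id: str
    position: int
    ref_base: str
    base_freqs: dict[str, float] = field(default_factory=dict)
    coverage: float = 0.0

    @property
    def alt_freqs(self) -> dict[str, float]:
        return {b: f for b, f in self.base_freqs.items() if b != self.ref_base}


# ---------------------------------------------------------------------------
# copy number
# ---------------------------------------------------------------------------


def normalization_factor(pileup: PileupMatrix, library: TELibrary) -> float:
    """Mean per-position unambiguous coverage pooled across all
    normalization genes."""
    if not library.genes:
        raise ValueError("library has no normalization genes")
    cov_sum = 0.0
    n_pos = 0
    for gene in library.genes:
        cov = pileup[gene.name].cov_unambiguous
        cov_sum += float(cov.sum())
        n_pos += len(cov)
    if cov_sum == 0:
        raise ValueError(
            "no reads aligned to any normalization gene; copy numbers undefined"
        )
    return cov_sum / n_pos


def copy_number(
    pileup: PileupMatrix,
    family: TEConsensus,
    factor: float,
    curb_polyA: bool = True,
    homopolymer_runs: Sequence[tuple[int, int]] | None = None,
    sample_id: str = "",
) -> CopyNumberCall:
    """Haploid copy number: curbed mean total coverage / normalization
    factor, plus breadth and divergence diagnostics."""
    if factor <= 0:
        raise ValueError("normalization factor must be > 0")
    p = pileup[family.family_id]
    total = p.total_coverage.astype(float).copy()
    if curb_polyA:
        if homopolymer_runs is None:
            homopolymer_runs = find_homopolymer_runs(family.sequence, 8)
        for start, end in homopolymer_runs:
            flank = np.concatenate(
                [total[max(0, start - CURB_FLANK) : start], total[end : end + CURB_FLANK]]
            )
            if flank.size:
                total[start:end] = np.median(flank)
    uncurbed = p.total_coverage
    return CopyNumberCall(
        family_id=family.family_id,
        sample_id=sample_id,
        copies=float(total.mean()) / factor,
        normalization_factor=factor,
        breadth=float((uncurbed >= 1).mean()),
        mean_read_divergence=pileup.mean_divergence(family.family_id),
    )


def classify_family(
    call: CopyNumberCall, thresholds: ClassifyThresholds | None = None
) -> str:
    """Three-way invasion status; also stored on the call."""
    t = thresholds or ClassifyThresholds()
    if call.copies < t.c_min:
        status = "absent"
    elif (
        call.breadth >= t.breadth_min
        and call.mean_read_divergence <= t.divergence_max
    ):
        status = "recent"
    else:
        status = "degraded_only"
    call.status = status
    return status


# ---------------------------------------------------------------------------
# SNP calling
# ---------------------------------------------------------------------------


def call_snps(
    pileup: PileupMatrix,
    family: TEConsensus,
    min_cov: int = 10,
    min_freq: float = 0.1,
) -> list[TESnp]:
    """Sites with unambiguous coverage >= min_cov where a non-reference base
    reaches frequency >= min_freq.  Frequencies are base count / total base
    count at the site, over unambiguous reads only."""
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    if not 0 < min_freq < 0.5:
        raise ValueError("min_freq must be in (0, 0.5)")
    p = pileup[family.family_id]
    totals = p.bases.sum(axis=0)
    out: list[TESnp] = []
    candidate = np.nonzero(totals >= min_cov)[0]
    bases = "ACGT"
    ref = family.sequence
    for pos in candidate:
        counts = p.bases[:, pos]
        total = totals[pos]
        ref_base = ref[pos]
        ref_idx = bases.find(ref_base)
        alt_ok = any(
            counts[i] / total >= min_freq
            for i in range(4)
            if i != ref_idx and counts[i] > 0
        )
        if not alt_ok:
            continue
        freqs = {bases[i]: counts[i] / total for i in range(4) if counts[i] > 0}
        out.append(
            TESnp(
                family_id=family.family_id,
                position=int(pos),
                ref_base=ref_base,
                base_freqs=freqs,
                coverage=float(total),
            )
        )
    return out


# ---------------------------------------------------------------------------
# rpm and enrichment
# ---------------------------------------------------------------------------


def rpm_abundance(alignments: Sequence[ReadAlignment]) -> dict[str, float]:
    """Reads per million mapped reads, per reference; ambiguous reads count
    1/k toward each tied reference so totals are conserved."""
    counts: dict[str, float] = {}
    total = 0.0
    for aln in alignments:
        w = 1.0 / aln.n_tied
        counts[aln.family_id] = counts.get(aln.family_id, 0.0) + w
        total += w
    if total == 0:
        raise ValueError("zero mapped reads; rpm undefined")
    return {rid: c * 1e6 / total for rid, c in counts.items()}


def fold_enrichment(
    calls_a: Mapping[str, "CopyNumberCall | float"],
    calls_b: Mapping[str, "CopyNumberCall | float"],
    pseudocount: float = 0.1,
) -> dict[str, float]:
    """Per-family (copies_b + pseudocount) / (copies_a + pseudocount).

    The pseudocount keeps the ratio finite for families absent from the
    reference sample."""
    if set(calls_a) != set(calls_b):
        raise ValueError("fold_enrichment requires identical family sets")

    def val(x) -> float:
        return x.copies if isinstance(x, CopyNumberCall) else float(x)

    return {
        fam: (val(calls_b[fam]) + pseudocount) / (val(calls_a[fam]) + pseudocount)
        for fam in calls_a
    }


# ---------------------------------------------------------------------------
# timeline
# ---------------------------------------------------------------------------


def build_timeline(
    calls: Sequence[CopyNumberCall],
    years: Mapping[str, int],
) -> dict[str, tuple[float, float] | None]:
    """Per-family invasion interval (t_low, t_high) from classified calls.

    t_low is the latest collection year up to which every sample is
    non-recent; t_high the earliest year from which every sample on is
    recent.  Families recent everywhere get (-inf, earliest year); families
    absent everywhere get None.  The truth invasion year, if any, lies
    inside (t_low, t_high).
    """
    for call in calls:
        if call.status is None:
            raise ValueError(
                f"call {call.family_id}/{call.sample_id} not classified"
            )
        if call.sample_id not in years:
            raise ValueError(f"sample {call.sample_id!r} has no collection year")
    all_years = sorted({years[c.sample_id] for c in calls})
    if len(all_years) < 2:
        raise ValueError("need >=2 distinct collection years")
    out: dict[str, tuple[float, float] | None] = {}
    for fam in sorted({c.family_id for c in calls}):
        fam_calls = [c for c in calls if c.family_id == fam]
        if all(c.status == "absent" for c in fam_calls):
            out[fam] = None
            continue
        by_year: dict[int, list[str]] = {}
        for c in fam_calls:
            by_year.setdefault(years[c.sample_id], []).append(c.status)
        yrs = sorted(by_year)
        if all(s == "recent" for sl in by_year.values() for s in sl):
            out[fam] = (float("-inf"), float(yrs[0]))
            continue
        # earliest year from which on every sample is recent
        t_high = float("inf")
        for i in range(len(yrs) - 1, -1, -1):
            if all(s == "recent" for s in by_year[yrs[i]]):
                t_high = float(yrs[i])
            else:
                break
        # latest year up to which every sample is non-recent
        t_low = float("-inf")
        for y in yrs:
            if all(s != "recent" for s in by_year[y]):
                t_low = float(y)
            else:
                break
        out[fam] = (t_low, t_high)
    return out


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Exact p-value for combined n <= 25 without ties; normal approximation
    with tie correction otherwise.  Returns (W, p) with W the rank-sum
    statistic of the first sample (U + n1(n1+1)/2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 samples")
    n1 = len(x)
    if np.all(x == x[0]) and np.all(y == x[0]):
        return n1 * (n1 + 1) / 2 + n1 * len(y) / 2, 1.0
    has_ties = len(np.unique(np.concatenate([x, y]))) < n1 + len(y)
    method = "exact" if (n1 + len(y) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    w = float(res.statistic) + n1 * (n1 + 1) / 2
    return w, float(res.pvalue)


def compare_groups(
    copies: Mapping[str, Mapping[str, float]] | pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-family Wilcoxon rank-sum comparison of copy numbers between two
    sample groups (e.g. collection years).

    `copies` maps family -> {sample -> copies} (or an equivalent DataFrame
    with families as columns and samples as rows).  Benjamini-Hochberg
    adjusted p-values are added when fdr=True (no correction by default).
    """
    if isinstance(copies, pd.DataFrame):
        table = {fam: copies[fam].to_dict() for fam in copies.columns}
    else:
        table = {fam: dict(vals) for fam, vals in copies.items()}
    rows = []
    for fam in sorted(table):
        a = [table[fam][s] for s in group_a]
        b = [table[fam][s] for s in group_b]
        w, p = wilcoxon_rank_sum(a, b)
        rows.append({"family": fam, "W": w, "pvalue": p})
    df = pd.DataFrame(rows).set_index("family")
    if fdr and len(df):
        df["pvalue_bh"] = stats.false_discovery_control(df["pvalue"].to_numpy())
    return df
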