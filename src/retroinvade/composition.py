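"""Cross-sample TE-SNP allele-frequency matrices, composition PCA,
diagnostic-SNP detection and the diagnostic-SNP ablation experiment.

The allele frequency of a TE-internal SNP in one sample is the fraction of
that family's dispersed copies carrying the alt base; across samples these
frequencies describe the *composition* of the family.  Populations seeded by
slightly different TE variants (founder effects during an invasion) show up
as clusters in a PCA of the sample x SNP frequency matrix, driven by
diagnostic SNPs: SNPs abundant in one population but rare in all others.
Removing the diagnostic SNPs collapses the clustering; removing an equally
sized random SNP set does not.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .abundance import TESnp


def snp_key(family_id: str, position: int, alt: str) -> str:
    return f"{family_id}:{position}:{alt}"


def parse_key(key: str) -> tuple[str, int, str]:
    fam, pos, alt = key.rsplit(":", 2)
    return fam, int(pos), alt


@dataclass
class AlleleFreqMatrix:
    """Samples x SNP-key frequency matrix with population labels.

    frame: rows = samples, columns = "family:pos:alt" keys, entries =
    alt-allele frequency in [0,1], NaN for sites with no coverage in a
    sample.  `filters` records the provenance of applied filters.
    """

    frame: pd.DataFrame
    populations: pd.Series
    filters: list[str] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return list(self.frame.index)

    @property
    def keys(self) -> list[str]:
        return list(self.frame.columns)

    def write_tsv(self, path) -> None:
        out = self.frame.copy()
        out.insert(0, "population", self.populations.reindex(out.index))
        out.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def read_tsv(cls, path) -> "AlleleFreqMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample")
        df.index.name = None
        pops = df.pop("population")
        pops.name = None
        return cls(frame=df, populations=pops)


@dataclass
class PCAResult:
    coordinates: pd.DataFrame  # samples x components
    variance_explained: np.ndarray
    loadings: pd.DataFrame  # components x SNP keys


# ---------------------------------------------------------------------------
# matrix construction and filtering
# ---------------------------------------------------------------------------


def build_matrix(
    snp_calls: Mapping[str, Sequence[TESnp]],
    populations: Mapping[str, str],
    coverage: Mapping[str, Mapping[str, np.ndarray]] | None = None,
) -> AlleleFreqMatrix:
    """Union of SNP keys across samples; per sample the frequency of the alt
    base (0 when the site is covered but the alt absent; NaN when the
    optional per-sample coverage says the site is uncovered)."""
    sample_ids = list(snp_calls)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids")
    keys: dict[str, tuple[str, int, str]] = {}
    for sample, calls in snp_calls.items():
        for snp in calls:
            for alt in snp.alt_freqs:
                keys[snp_key(snp.family_id, snp.position, alt)] = (
                    snp.family_id,
                    snp.position,
                    alt,
                )
    cols = sorted(keys)
    data = np.zeros((len(sample_ids), len(cols)))
    for i, sample in enumerate(sample_ids):
        lookup = {
            (snp.family_id, snp.position): snp for snp in snp_calls[sample]
        }
        for j, col in enumerate(cols):
            fam, pos, alt = keys[col]
            snp = lookup.get((fam, pos))
            if snp is not None:
                data[i, j] = snp.base_freqs.get(alt, 0.0)
            elif coverage is not None:
                cov = coverage.get(sample, {}).get(fam)
                if cov is None or cov[pos] < 1:
                    data[i, j] = np.nan
    frame = pd.DataFrame(data, index=sample_ids, columns=cols)
    pops = pd.Series({s: populations[s] for s in sample_ids})
    return AlleleFreqMatrix(frame=frame, populations=pops)


def filter_matrix(m: AlleleFreqMatrix, min_samples: int = 3) -> AlleleFreqMatrix:
    """Keep biallelic SNPs seen in more than `min_samples` samples.

    Sites with more than one observed alt base (i.e. >2 alleles counting the
    reference) are dropped entirely; columns with nonzero frequency in
    <= min_samples samples are dropped.  Idempotent.
    """
    if min_samples < 0:
        raise ValueError("min_samples must be >= 0")
    by_site: dict[tuple[str, int], list[str]] = {}
    for col in m.frame.columns:
        fam, pos, _ = parse_key(col)
        by_site.setdefault((fam, pos), []).append(col)
    keep = []
    for site, cols in by_site.items():
        observed = [c for c in cols if (m.frame[c].fillna(0) > 0).any()]
        if len(observed) > 1:  # triallelic or worse
            continue
        for c in observed:
            if int((m.frame[c].fillna(0) > 0).sum()) > min_samples:
                keep.append(c)
    keep = sorted(keep)
    if not keep:
        warnings.warn("all SNP columns removed by filtering; empty matrix")
    return AlleleFreqMatrix(
        frame=m.frame[keep].copy(),
        populations=m.populations.copy(),
        filters=m.filters + [f"biallelic,min_samples>{min_samples}"],
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def composition_pca(m: AlleleFreqMatrix, standardize: bool = False) -> PCAResult:
    """PCA of the column-centered frequency matrix via SVD.

    Missing entries are imputed to the column mean.  Component signs are
    fixed by making each component's largest-magnitude loading positive.
    Frequencies are used raw by default; standardize=True divides columns by
    their standard deviation.
    """
    if m.frame.shape[0] < 3 or m.frame.shape[1] < 2:
        raise ValueError("PCA needs >=3 samples and >=2 SNP columns")
    X = m.frame.to_numpy(dtype=float).copy()
    col_mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    n_comp = min(X.shape[0] - 1, X.shape[1])
    if not np.any(X):
        # all rows identical: no variance, every coordinate is 0
        coords = pd.DataFrame(
            np.zeros((X.shape[0], n_comp)),
            index=m.frame.index,
            columns=[f"PC{i + 1}" for i in range(n_comp)],
        )
        loadings = pd.DataFrame(
            np.zeros((n_comp, X.shape[1])),
            index=coords.columns,
            columns=m.frame.columns,
        )
        return PCAResult(coords, np.zeros(n_comp), loadings)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    U, S, Vt = U[:, :n_comp], S[:n_comp], Vt[:n_comp]
    for i in range(n_comp):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    coords = pd.DataFrame(
        U * S,
        index=m.frame.index,
        columns=[f"PC{i + 1}" for i in range(n_comp)],
    )
    var = S**2 / (S**2).sum()
    loadings = pd.DataFrame(Vt, index=coords.columns, columns=m.frame.columns)
    return PCAResult(coords, var, loadings)


# ---------------------------------------------------------------------------
# diagnostic SNPs and ablation
# ---------------------------------------------------------------------------


def diagnostic_snps(
    m: AlleleFreqMatrix,
    target_pop: str,
    f_in: float = 0.3,
    f_out: float = 0.1,
) -> list[str]:
    """SNPs abundant (mean >= f_in) in the target population and rare
    (mean <= f_out) in every other population, sorted by descending
    inside-outside frequency gap."""
    pops = m.populations
    if target_pop not in set(pops):
        raise ValueError(f"unknown population {target_pop!r}")
    inside = m.frame.loc[pops[pops == target_pop].index]
    if len(inside) < 2:
        raise ValueError(f"population {target_pop!r} has fewer than 2 samples")
    other_pops = [p for p in pops.unique() if p != target_pop]
    mean_in = inside.fillna(0).mean(axis=0)
    out = []
    for col in m.frame.columns:
        if mean_in[col] < f_in:
            continue
        outside_means = [
            m.frame.loc[pops[pops == p].index, col].fillna(0).mean()
            for p in other_pops
        ]
        if all(om <= f_out for om in outside_means):
            gap = mean_in[col] - (max(outside_means) if outside_means else 0.0)
            out.append((gap, col))
    out.sort(key=lambda t: (-t[0], t[1]))
    return [col for _, col in out]


def ablate_and_pca(
    m: AlleleFreqMatrix, remove: Sequence[str], standardize: bool = False
) -> PCAResult:
    """PCA after removing a set of SNP columns (e.g. the diagnostic SNPs)."""
    missing = set(remove) - set(m.frame.columns)
    if missing:
        raise ValueError(f"cannot remove unknown SNP keys: {sorted(missing)}")
    keep = [c for c in m.frame.columns if c not in set(remove)]
    if not keep:
        raise ValueError("removal would empty the matrix")
    sub = AlleleFreqMatrix(
        frame=m.frame[keep].copy(),
        populations=m.populations.copy(),
        filters=m.filters + [f"ablated:{len(remove)}"],
    )
    return composition_pca(sub, standardize=standardize)
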