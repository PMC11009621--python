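"""Config-driven end-to-end runs with logging, tabular outputs and figures.

A run reads a YAML config naming the consensus library, the sample manifest
(sample id, reads, collection year, population label) and parameters, then
executes the requested stages in dependency order:

    align -> abundance -> {composition, timeline}; smallrna; donors

Every output is a tab-separated table with a header comment naming the
producing version and parameters, so that reruns with identical config and
seeds are byte-identical.  Figures are rendered separately from the tables
(`render_reports`) and can never corrupt them.
"""
from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, abundance, align, composition, smallrna, te_library
from . import ht_donor

log = logging.getLogger("retroinvade")

STAGE_ORDER = ["align", "abundance", "composition", "smallrna", "donors", "timeline"]

DEFAULT_PARAMS = {
    "trim_len": 100,
    "min_identity": 0.75,
    "seed_k": 13,
    "min_cov": 10,
    "min_freq": 0.1,
    "c_min": 0.2,
    "breadth_min": 0.8,
    "divergence_max": 0.05,
    "min_samples": 3,
    "f_in": 0.3,
    "f_out": 0.1,
    "defrag_gap": 100,
    "seed": 0,
    "target_pop": None,
    "smallrna_adapter": None,
}


@dataclass
class RunConfig:
    library: Path
    genes: Path
    samples: Path
    outdir: Path
    assemblies: list[Path] = field(default_factory=list)
    smallrna: Path | None = None  # manifest: sample_id <tab> fastq
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent
        resolve = lambda p: (base / p) if p and not os.path.isabs(p) else (Path(p) if p else None)
        params = dict(DEFAULT_PARAMS)
        params.update(raw.get("params", {}) or {})
        return cls(
            library=resolve(raw["library"]),
            genes=resolve(raw["genes"]),
            samples=resolve(raw["samples"]),
            outdir=resolve(raw["outdir"]),
            assemblies=[resolve(p) for p in raw.get("assemblies", []) or []],
            smallrna=resolve(raw.get("smallrna")),
            params=params,
        )

    def validate(self) -> None:
        for name in ("library", "genes", "samples"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"config path {name!r} does not exist: {p}")
        for key, value in self.params.items():
            if key in ("trim_len", "min_cov", "min_samples", "defrag_gap", "seed_k"):
                if value is not None and value <= 0 and key != "defrag_gap":
                    raise ValueError(f"parameter {key} must be positive, got {value}")
        if not 0 < self.params["min_identity"] <= 1:
            raise ValueError("min_identity must be in (0,1]")
        if not 0 < self.params["min_freq"] < 0.5:
            raise ValueError("min_freq must be in (0,0.5)")


def _read_manifest(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "reads", "year", "population"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample manifest missing columns: {sorted(missing)}")
    return df


def _write_table(df: pd.DataFrame, path: Path, params: dict, index=True) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# retroinvade {__version__} params="
            + json.dumps(params, sort_keys=True, default=str)
            + "\n"
        )
        df.to_csv(fh, sep="\t", index=index)


def _read_table(path: Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


class StageError(RuntimeError):
    pass


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> Path:
    """Execute the requested stages in dependency order.

    Partial outputs of a failing stage are removed; a stage whose inputs are
    missing (because an earlier stage was not run) raises a StageError
    naming the missing artifact.
    """
    config.validate()
    stages = [s for s in STAGE_ORDER if s in (stages or STAGE_ORDER)]
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.params
    library = te_library.load_library(config.library, config.genes)
    manifest = _read_manifest(config.samples)
    base = Path(config.samples).parent
    counts: dict = {}

    for stage in stages:
        created: list[Path] = []
        try:
            if stage == "align":
                _stage_align(config, library, manifest, base, outdir, created, counts)
            elif stage == "abundance":
                _stage_abundance(config, library, manifest, outdir, created, counts)
            elif stage == "timeline":
                _stage_timeline(config, manifest, outdir, created)
            elif stage == "composition":
                _stage_composition(config, library, manifest, outdir, created)
            elif stage == "smallrna":
                _stage_smallrna(config, library, base, outdir, created)
            elif stage == "donors":
                _stage_donors(config, library, outdir, created)
        except Exception:
            for p in created:
                if p.exists():
                    p.unlink()
            raise
        log.info("stage %s done", stage)

    manifest_out = {
        "version": __version__,
        "params": params,
        "stages": stages,
        "counts": counts,
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest_out, fh, indent=2, sort_keys=True, default=str)
    return outdir


# -- stages ---------------------------------------------------------------


def _stage_align(config, library, manifest, base, outdir, created, counts):
    from .io_utils import read_fastq

    params = config.params
    pdir = outdir / "pileups"
    pdir.mkdir(exist_ok=True)
    rpm_rows = []
    for _, row in manifest.iterrows():
        reads_path = base / row["reads"] if not os.path.isabs(row["reads"]) else Path(row["reads"])
        if str(reads_path).endswith(".sam"):
            alignments = align.ingest_sam(reads_path, library)
        else:
            reads = align.trim_reads(read_fastq(reads_path), params["trim_len"])
            alignments = align.align_reads(
                reads, library, min_identity=params["min_identity"], k=params["seed_k"]
            )
        pileup = align.build_pileup(alignments, library)
        out = pdir / f"{row['sample_id']}.pileup.tsv"
        pileup.write_tsv(out)
        created.append(out)
        counts[row["sample_id"]] = {
            "aligned_reads": pileup.total_mapped_reads,
        }
        for rid, rpm in abundance.rpm_abundance(alignments).items():
            rpm_rows.append(
                {"sample": row["sample_id"], "reference": rid, "rpm": rpm}
            )
    rpm_path = outdir / "rpm.tsv"
    _write_table(pd.DataFrame(rpm_rows), rpm_path, params, index=False)
    created.append(rpm_path)


def _require(path: Path, producer: str):
    if not path.exists():
        raise StageError(
            f"missing artifact {path.name!r}; run stage {producer!r} first"
        )
    return path


def _stage_abundance(config, library, manifest, outdir, created, counts):
    params = config.params
    pdir = _require(outdir / "pileups", "align")
    thresholds = abundance.ClassifyThresholds(
        c_min=params["c_min"],
        breadth_min=params["breadth_min"],
        divergence_max=params["divergence_max"],
    )
    rows = []
    sdir = outdir / "snps"
    sdir.mkdir(exist_ok=True)
    for _, row in manifest.iterrows():
        sample = row["sample_id"]
        pileup = align.PileupMatrix.read_tsv(
            _require(pdir / f"{sample}.pileup.tsv", "align")
        )
        factor = abundance.normalization_factor(pileup, library)
        snp_rows = []
        for fam in library.families:
            call = abundance.copy_number(
                pileup,
                fam,
                factor,
                homopolymer_runs=library.homopolymer_runs[fam.family_id],
                sample_id=sample,
            )
            abundance.classify_family(call, thresholds)
            rows.append(
                {
                    "sample": sample,
                    "family": fam.family_id,
                    "copies": round(call.copies, 4),
                    "breadth": round(call.breadth, 4),
                    "divergence": round(call.mean_read_divergence, 5),
                    "status": call.status,
                }
            )
            for snp in abundance.call_snps(
                pileup, fam, min_cov=params["min_cov"], min_freq=params["min_freq"]
            ):
                for alt, freq in snp.alt_freqs.items():
                    snp_rows.append(
                        {
                            "family": snp.family_id,
                            "pos": snp.position,
                            "ref": snp.ref_base,
                            "alt": alt,
                            "freq": round(freq, 5),
                            "coverage": snp.coverage,
                        }
                    )
        snp_path = sdir / f"{sample}.snps.tsv"
        _write_table(pd.DataFrame(snp_rows, columns=["family", "pos", "ref", "alt", "freq", "coverage"]), snp_path, params, index=False)
        created.append(snp_path)
    path = outdir / "copy_numbers.tsv"
    _write_table(pd.DataFrame(rows), path, params, index=False)
    created.append(path)


def _stage_timeline(config, manifest, outdir, created):
    params = config.params
    table = _read_table(_require(outdir / "copy_numbers.tsv", "abundance"))
    years = dict(zip(manifest["sample_id"], manifest["year"]))
    calls = [
        abundance.CopyNumberCall(
            family_id=r["family"],
            sample_id=r["sample"],
            copies=r["copies"],
            normalization_factor=1.0,
            breadth=r["breadth"],
            mean_read_divergence=r["divergence"],
            status=r["status"],
        )
        for _, r in table.iterrows()
    ]
    timeline = abundance.build_timeline(calls, years)
    rows = [
        {
            "family": fam,
            "t_low": interval[0] if interval else "",
            "t_high": interval[1] if interval else "",
            "detected": interval is not None,
        }
        for fam, interval in timeline.items()
    ]
    path = outdir / "timeline.tsv"
    _write_table(pd.DataFrame(rows), path, params, index=False)
    created.append(path)


def _stage_composition(config, library, manifest, outdir, created):
    params = config.params
    sdir = _require(outdir / "snps", "abundance")
    populations = dict(zip(manifest["sample_id"], manifest["population"]))
    snp_calls = {}
    for sample in manifest["sample_id"]:
        table = _read_table(_require(sdir / f"{sample}.snps.tsv", "abundance"))
        by_site: dict[tuple[str, int], abundance.TESnp] = {}
        for _, r in table.iterrows():
            key = (r["family"], int(r["pos"]))
            snp = by_site.get(key)
            if snp is None:
                snp = abundance.TESnp(
                    family_id=r["family"],
                    position=int(r["pos"]),
                    ref_base=r["ref"],
                    base_freqs={},
                    coverage=float(r["coverage"]),
                )
                by_site[key] = snp
            snp.base_freqs[r["alt"]] = float(r["freq"])
        for snp in by_site.values():
            snp.base_freqs.setdefault(
                snp.ref_base, max(0.0, 1.0 - sum(snp.base_freqs.values()))
            )
        snp_calls[sample] = list(by_site.values())
    matrix = composition.build_matrix(snp_calls, populations)
    filtered = composition.filter_matrix(matrix, min_samples=params["min_samples"])
    mpath = outdir / "allele_freq_matrix.tsv"
    filtered.write_tsv(mpath)
    created.append(mpath)
    if filtered.frame.shape[0] >= 3 and filtered.frame.shape[1] >= 2:
        pca = composition.composition_pca(filtered)
        coords = pca.coordinates.copy()
        coords.insert(0, "population", filtered.populations.reindex(coords.index))
        cpath = outdir / "pca_coords.tsv"
        _write_table(coords, cpath, params)
        created.append(cpath)
        vpath = outdir / "pca_variance.tsv"
        _write_table(
            pd.DataFrame(
                {"component": coords.columns[1:], "variance_explained": pca.variance_explained}
            ),
            vpath,
            params,
            index=False,
        )
        created.append(vpath)
        if params.get("target_pop"):
            diag = composition.diagnostic_snps(
                filtered,
                params["target_pop"],
                f_in=params["f_in"],
                f_out=params["f_out"],
            )
            dpath = outdir / f"diagnostic_{params['target_pop']}.tsv"
            _write_table(
                pd.DataFrame({"snp": diag}), dpath, params, index=False
            )
            created.append(dpath)
    else:
        log.warning("composition matrix too small for PCA; skipped")


def _stage_smallrna(config, library, base, outdir, created):
    from .io_utils import read_fastq
    from .synthetic import DEFAULT_ADAPTER

    params = config.params
    if config.smallrna is None:
        log.warning("no small-RNA manifest configured; stage skipped")
        return
    adapter = params.get("smallrna_adapter") or DEFAULT_ADAPTER
    srna = pd.read_csv(config.smallrna, sep="\t")
    rows, summary = [], []
    for _, row in srna.iterrows():
        path = base / row["reads"] if not os.path.isabs(row["reads"]) else Path(row["reads"])
        clean = smallrna.preprocess_smallrna(read_fastq(path), adapter=adapter)
        counts = smallrna.map_smallrna(clean, library)
        for fam in library.family_ids:
            profile = smallrna.pingpong_signature(counts[fam], fam)
            for kk in range(1, smallrna.KMAX + 1):
                rows.append(
                    {
                        "sample": row["sample_id"],
                        "family": fam,
                        "k": kk,
                        "o": profile.o(kk),
                    }
                )
            summary.append(
                {
                    "sample": row["sample_id"],
                    "family": fam,
                    "z10": "" if profile.z10 is None else round(profile.z10, 3),
                }
            )
    ppath = outdir / "pingpong.tsv"
    _write_table(pd.DataFrame(rows), ppath, params, index=False)
    created.append(ppath)
    spath = outdir / "pingpong_summary.tsv"
    _write_table(pd.DataFrame(summary), spath, params, index=False)
    created.append(spath)


def _stage_donors(config, library, outdir, created):
    params = config.params
    if not config.assemblies:
        log.warning("no assemblies configured; donors stage skipped")
        return
    hits_by_assembly = {}
    ld_rows = []
    for path in config.assemblies:
        name = Path(path).stem
        if str(path).endswith(".out"):
            hits = ht_donor.parse_repeat_table(path, assembly_id=name)
        else:
            hits = ht_donor.find_hits(str(path), library, assembly_id=name)
        hits = ht_donor.defragment(hits, max_gap=params["defrag_gap"])
        hits_by_assembly[name] = hits
        ld_rows.append(ht_donor.length_divergence_table(hits))
    table = ht_donor.similarity_scores(hits_by_assembly)
    spath = outdir / "similarity.tsv"
    _write_table(table.s, spath, params)
    created.append(spath)
    lpath = outdir / "length_divergence.tsv"
    _write_table(
        pd.concat(ld_rows, ignore_index=True) if ld_rows else pd.DataFrame(),
        lpath,
        params,
        index=False,
    )
    created.append(lpath)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

STATUS_COLORS = {"absent": "#c0392b", "degraded_only": "#f1c40f", "recent": "#27ae60"}


def render_reports(artifact_dir: str | os.PathLike) -> list[Path]:
    """Render one figure per available results table; missing tables are
    skipped with a warning and a plotting failure never touches the
    tables."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(artifact_dir)
    figures: list[Path] = []

    def fig_path(name: str) -> Path:
        return outdir / name

    # status grid + fold enrichment from copy numbers
    cn_path = outdir / "copy_numbers.tsv"
    if cn_path.exists():
        try:
            table = _read_table(cn_path)
            grid = table.pivot(index="family", columns="sample", values="status")
            fig, ax = plt.subplots(figsize=(1 + 0.5 * grid.shape[1], 1 + 0.4 * grid.shape[0]))
            colors = {"absent": 0, "degraded_only": 1, "recent": 2}
            img = grid.apply(lambda col: col.map(colors)).to_numpy(dtype=float)
            ax.imshow(img, cmap=matplotlib.colors.ListedColormap(list(STATUS_COLORS.values())), vmin=0, vmax=2, aspect="auto")
            ax.set_xticks(range(grid.shape[1]), grid.columns, rotation=90, fontsize=6)
            ax.set_yticks(range(grid.shape[0]), grid.index, fontsize=7)
            ax.set_title("invasion status per sample")
            fig.tight_layout()
            p = fig_path("status_grid.png")
            fig.savefig(p, dpi=120)
            plt.close(fig)
            figures.append(p)
        except Exception as exc:  # plots must never break the run
            log.warning("status grid rendering failed: %s", exc)
    else:
        log.warning("copy_numbers.tsv missing; status grid skipped")

    # coverage track of the first pileup
    pdir = outdir / "pileups"
    pileups = sorted(pdir.glob("*.pileup.tsv")) if pdir.exists() else []
    if pileups:
        try:
            pileup = align.PileupMatrix.read_tsv(pileups[0])
            fam = next(iter(pileup.refs))
            p0 = pileup[fam]
            fig, ax = plt.subplots(figsize=(8, 2.5))
            x = range(len(p0.cov_unambiguous))
            ax.fill_between(x, 0, p0.cov_unambiguous, color="0.3", label="unambiguous")
            ax.fill_between(
                x,
                p0.cov_unambiguous,
                p0.total_coverage,
                color="0.75",
                label="ambiguous",
            )
            ax.set_xlabel(f"{fam} consensus position")
            ax.set_ylabel("coverage")
            ax.legend(fontsize=7)
            fig.tight_layout()
            p = fig_path("coverage_track.png")
            fig.savefig(p, dpi=120)
            plt.close(fig)
            figures.append(p)
        except Exception as exc:
            log.warning("coverage track rendering failed: %s", exc)
    else:
        log.warning("no pileups found; coverage track skipped")

    # PCA scatter
    pca_path = outdir / "pca_coords.tsv"
    if pca_path.exists():
        try:
            coords = _read_table(pca_path, index_col=0)
            fig, ax = plt.subplots(figsize=(4, 4))
            for pop, sub in coords.groupby("population"):
                ax.scatter(sub["PC1"], sub["PC2"], label=pop, s=14)
            ax.set_xlabel("PC1")
            ax.set_ylabel("PC2")
            ax.legend(fontsize=7)
            fig.tight_layout()
            p = fig_path("pca.png")
            fig.savefig(p, dpi=120)
            plt.close(fig)
            figures.append(p)
        except Exception as exc:
            log.warning("PCA rendering failed: %s", exc)
    else:
        log.warning("pca_coords.tsv missing; PCA scatter skipped")

    # similarity bars
    sim_path = outdir / "similarity.tsv"
    if sim_path.exists():
        try:
            sim = _read_table(sim_path, index_col=0)
            fig, axes = plt.subplots(
                1, max(1, sim.shape[1]), figsize=(2.2 * max(1, sim.shape[1]), 2.5), squeeze=False
            )
            for ax, fam in zip(axes[0], sim.columns):
                ax.bar(range(len(sim)), sim[fam].fillna(0))
                ax.set_xticks(range(len(sim)), sim.index, rotation=90, fontsize=6)
                ax.set_title(fam, fontsize=8)
                ax.set_ylim(0, 1.05)
            fig.tight_layout()
            p = fig_path("similarity.png")
            fig.savefig(p, dpi=120)
            plt.close(fig)
            figures.append(p)
        except Exception as exc:
            log.warning("similarity rendering failed: %s", exc)
    else:
        log.warning("similarity.tsv missing; similarity bars skipped")
    return figures
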