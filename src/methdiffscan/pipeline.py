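"""End-to-end orchestration: import, unite, DMC/DMR/DMP testing, TSS
annotation, gene scoring, overlaps, integration and enrichment, driven by
a single YAML-serialisable configuration and recorded in a run manifest.

All intermediates are plain TSV/BED/JSON so every stage can be inspected
and resumed independently.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as mio
from . import diffmeth, features, scoring, integration

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and stage parameters for one pipeline run."""

    samples: dict[str, str]          # sample_id -> coverage file path
    design: str                      # design TSV
    annotation: str                  # annotation path
    outdir: str
    annotation_format: str = "bed12"
    expression: str | None = None
    gmt: str | None = None
    chrom_sizes: dict[str, int] | None = None
    seed: int = 0
    log_level: str = "INFO"
    resume: bool = False

    # stage parameters (defaults documented in docs/methods.md)
    min_coverage: int = 10
    max_coverage_percentile: float = 99.9
    q_max: float = 0.01
    min_abs_diff: float = 25.0
    tile_window: int = 1000
    promoter_flank: int = 1000
    hifreq_window: int = 10000
    hifreq_min_count: int = 5
    topdmc_max_dist: int = 10000
    topdmc_min_diff: float = 30.0
    summary_window: int = 10000
    min_dmcs: int = 2

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        paths = [self.design, self.annotation, *self.samples.values()]
        if self.expression:
            paths.append(self.expression)
        if self.gmt:
            paths.append(self.gmt)
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        if not 0 < self.q_max <= 1:
            raise ValueError("q_max must lie in (0, 1]")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if not 0 <= self.min_abs_diff <= 100:
            raise ValueError("min_abs_diff must lie in [0, 100]")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _infer_chrom_sizes(config, annotation, samples) -> dict[str, int]:
    if config.chrom_sizes:
        return dict(config.chrom_sizes)
    sizes: dict[str, int] = {}
    for df in samples.values():
        for chrom, mx in df.groupby("chrom")["pos"].max().items():
            sizes[chrom] = max(sizes.get(chrom, 0), int(mx))
    for rec in annotation.itertuples():
        sizes[rec.chrom] = max(sizes.get(rec.chrom, 0), int(rec.tx_end))
    return sizes


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {
        "tool": "methdiffscan", "version": __version__,
        "seed": config.seed, "parameters": {
            k: v for k, v in asdict(config).items()
            if k not in ("samples", "design", "annotation", "expression",
                         "gmt", "outdir")
        },
        "stages": [], "files": {},
    }

    def record(stage: str, n_records: int, *paths: Path):
        manifest["stages"].append({"stage": stage, "n_records": n_records,
                                   "status": "completed"})
        for p in paths:
            manifest["files"][p.name] = _sha256(p)

    try:
        # --- import ---
        samples = {name: mio.read_bismark_cov(path)
                   for name, path in config.samples.items()}
        design = mio.read_design(config.design)
        annotation = mio.read_annotation(config.annotation, config.annotation_format)
        record("import", sum(len(df) for df in samples.values()))
        chrom_sizes = _infer_chrom_sizes(config, annotation, samples)

        # --- unite ---
        matrix = diffmeth.unite(samples, design, config.min_coverage,
                                config.max_coverage_percentile)
        record("unite", matrix.n_loci)

        # --- sample QC (PCA) ---
        coords, varfrac = diffmeth.pca_samples(matrix.percent())
        pca_path = outdir / "pca.tsv"
        coords.assign(group=[design.groups[s] for s in coords.index]).to_csv(
            pca_path, sep="\t")
        manifest["pca_variance_fractions"] = [float(v) for v in varfrac[:5]]
        record("pca", len(coords), pca_path)

        thresholds = {"q_max": config.q_max, "min_abs_diff": config.min_abs_diff,
                      "seed": config.seed, "version": __version__}

        def test_and_call(mat):
            res = diffmeth.diff_test(mat)
            res["q_value"] = diffmeth.adjust_fdr(res["p_value"].to_numpy())
            return diffmeth.call_differential(res, config.q_max, config.min_abs_diff)

        # --- DMC / DMR / DMP ---
        dmc = test_and_call(matrix)
        dmc_path = outdir / "dmc.tsv"
        mio.write_results(dmc, dmc_path, "dmc", thresholds)
        dmc_called = diffmeth.called(dmc)
        if len(dmc_called):
            mio.write_bed(dmc_called, outdir / "dmc.bed")
        record("dmc", len(dmc_called), dmc_path)

        tiles = features.tile_genome(chrom_sizes, config.tile_window)
        dmr = test_and_call(features.aggregate_region_counts(matrix, tiles))
        dmr_path = outdir / "dmr.tsv"
        mio.write_results(dmr, dmr_path, "dmr", thresholds)
        record("dmr", len(diffmeth.called(dmr)), dmr_path)

        promoters = features.promoter_regions(annotation, config.promoter_flank,
                                              chrom_sizes)
        dmp = test_and_call(features.aggregate_region_counts(matrix, promoters))
        dmp_path = outdir / "dmp.tsv"
        mio.write_results(dmp, dmp_path, "dmp", thresholds)
        record("dmp", len(diffmeth.called(dmp)), dmp_path)

        # --- annotation of called loci ---
        dmc_assoc = features.nearest_tss(dmc_called, annotation)
        dmc_assoc["feature_class"] = features.classify_feature(
            dmc_assoc, annotation, promoters)
        assoc_path = outdir / "dmc_annotated.tsv"
        mio.write_results(dmc_assoc, assoc_path, "association", thresholds)
        if len(dmc_assoc):
            manifest["feature_proportions"] = features.feature_proportions(
                dmc_assoc, annotation, promoters)
        record("annotate", len(dmc_assoc), assoc_path)

        # --- gene scoring ---
        top_genes = scoring.top_dmc_genes(dmc_assoc, config.topdmc_max_dist,
                                          config.topdmc_min_diff)
        top_path = outdir / "top_dmc_genes.tsv"
        pd.DataFrame({"gene_id": sorted(top_genes)}).to_csv(top_path, sep="\t",
                                                            index=False)
        record("topdmc", len(top_genes), top_path)

        hifreq = scoring.high_frequency_genes(dmc_assoc, annotation,
                                              config.hifreq_window,
                                              config.hifreq_min_count)
        hifreq_path = outdir / "hifreq_genes.tsv"
        hifreq.drop(columns="members").to_csv(hifreq_path, sep="\t", index=False)
        record("hifreq", len(hifreq), hifreq_path)

        _counts, freq_summary = scoring.dmc_frequency_distribution(
            dmc_assoc, annotation, config.hifreq_window)
        _dists, dist_summary = scoring.tss_distance_distribution(dmc_assoc)
        manifest["dmc_frequency_summary"] = freq_summary
        manifest["tss_distance_summary"] = dist_summary

        chrom_counts = scoring.chromosome_direction_counts(dmc)
        chrom_path = outdir / "chromosome_counts.tsv"
        chrom_counts.to_csv(chrom_path, sep="\t")
        record("chromosome_counts", int(chrom_counts.to_numpy().sum()), chrom_path)

        # --- cross-category overlap (direction-aware) ---
        def called_genes(res):
            sub = diffmeth.called(res)
            if len(sub) == 0:
                return pd.DataFrame(columns=["gene_id", "direction"])
            assoc = features.nearest_tss(sub, annotation)
            return assoc[["gene_id", "direction"]]

        overlap = scoring.cross_category_overlap(
            dmc_assoc[["gene_id", "direction"]], called_genes(dmr),
            called_genes(dmp), direction_aware=True)
        overlap_path = outdir / "overlap.json"
        overlap_path.write_text(json.dumps(
            {k: sorted(v) for k, v in overlap.items()}, indent=2))
        record("overlap", sum(len(v) for v in overlap.values()), overlap_path)

        # --- integration ---
        if config.expression:
            expression = mio.read_expression(config.expression)
            summaries = integration.gene_meth_summaries(
                dmc_assoc, annotation, config.summary_window, config.min_dmcs)
            try:
                corr = integration.meth_expr_correlation(summaries, expression)
                manifest["meth_expr_correlation"] = {
                    "rho": corr.rho, "p_value": corr.p_value,
                    "n_genes": corr.n_genes}
                corr_path = outdir / "meth_expr_pairs.tsv"
                corr.table.to_csv(corr_path, sep="\t", index=False)
                record("integration", corr.n_genes, corr_path)
            except ValueError as exc:
                manifest["meth_expr_correlation"] = {"error": str(exc)}
                manifest["stages"].append({"stage": "integration",
                                           "n_records": 0, "status": "skipped"})

        # --- enrichment ---
        if config.gmt:
            term_map = integration.read_gmt(config.gmt)
            universe = _testable_universe(matrix, annotation, config.summary_window)
            study = top_genes & universe
            if study:
                enr = integration.enrichment_fisher(study, universe, term_map)
                enr_path = outdir / "enrichment.tsv"
                enr.to_csv(enr_path, sep="\t", index=False)
                record("enrichment", len(enr), enr_path)
            else:
                manifest["stages"].append({"stage": "enrichment",
                                           "n_records": 0, "status": "skipped"})
    except Exception as exc:
        manifest["stages"].append({"stage": "failed", "error": str(exc),
                                   "status": "failed"})
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    manifest["runtime_seconds"] = round(time.time() - t0, 3)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _testable_universe(matrix, annotation, window) -> set[str]:
    """Genes with at least one tested CpG inside TSS +/- window."""
    universe = set()
    for chrom, ann_sub in annotation.groupby("chrom", sort=False):
        pos = matrix.loci.loc[matrix.loci["chrom"] == chrom, "start"].to_numpy()
        if len(pos) == 0:
            continue
        for rec in ann_sub.itertuples():
            lo = np.searchsorted(pos, rec.tss - window, side="left")
            hi = np.searchsorted(pos, rec.tss + window, side="right")
            if hi > lo:
                universe.add(rec.gene_id)
    return universe
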