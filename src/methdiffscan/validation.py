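"""Reusable validation experiments on synthetic data.

Each experiment regenerates a dataset under the package's standard study
conditions (two groups of three samples, ~10x or ~30x coverage, bimodal
baseline methylation), runs the relevant pipeline stages, and returns
the measured quantities.  They back both the test suite and the
reproduction script; problem sizes are chosen so every experiment runs
in seconds to a few minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import diffmeth, features, scoring, integration
from .io import GroupDesign
from .simulate import (SimConfig, PlantedSite, PlantedCluster,
                       simulate_annotation, simulate_counts,
                       simulate_expression)


def _design(samples: dict) -> GroupDesign:
    return GroupDesign(
        {n: ("control" if n.startswith("control") else "case") for n in samples},
        reference="control",
    )


def _tested_results(config: SimConfig, min_coverage: int = 10):
    annotation = simulate_annotation(config)
    samples, truth = simulate_counts(config, annotation)
    matrix = diffmeth.unite(samples, _design(samples), min_coverage)
    results = diffmeth.diff_test(matrix)
    results["q_value"] = diffmeth.adjust_fdr(results["p_value"].to_numpy())
    return annotation, truth, matrix, results


def null_calibration(seed: int, n_tested: int = 20000) -> dict:
    """Type-I error of the site test on binomial-null data at ~10x coverage.

    Simulates CpGs at mean coverage 10 with no planted effects and no
    overdispersion until ``n_tested`` survive the >= 10x-in-all-samples
    filter, then measures the fraction of p-values below 0.05 and the
    percentage of sites called at BH q < 0.05.
    """
    config = SimConfig(
        seed=seed, n_chroms=3, chrom_length_bp=3_600_000, cpg_spacing_bp=10.0,
        n_transcripts=0, mean_coverage=10.0, dispersion=0.0,
    )
    _ann, _truth, _matrix, results = _tested_results(config, min_coverage=10)
    if len(results) < n_tested:
        raise RuntimeError(f"only {len(results)} sites survived the filter")
    sub = results.iloc[:n_tested]
    q = diffmeth.adjust_fdr(sub["p_value"].to_numpy())
    return {
        "n_tested": n_tested,
        "frac_p_below_0.05": float((sub["p_value"] < 0.05).mean()),
        "bh_called_percent": float((q < 0.05).mean() * 100.0),
    }


def dmc_recovery(seed: int, n_planted: int = 500, delta: float = 40.0,
                 q_max: float = 0.01, min_abs_diff: float = 25.0) -> dict:
    """Recall and observed FDR for planted single-CpG effects.

    ``n_planted`` sites with a ``delta``-point shift (half hyper, half
    hypo) among ~20,000 null CpGs; 3 vs 3 samples at ~30x coverage.
    """
    half = n_planted // 2
    config = SimConfig(
        seed=seed, n_chroms=3, chrom_length_bp=700_000, n_transcripts=0,
        mean_coverage=30.0,
        planted_dmc=([PlantedSite(delta, "hyper") for _ in range(half)]
                     + [PlantedSite(delta, "hypo") for _ in range(n_planted - half)]),
    )
    _ann, truth, _matrix, results = _tested_results(config)
    results = diffmeth.call_differential(results, q_max, min_abs_diff)
    called = diffmeth.called(results)
    called_keys = set(zip(called["chrom"], called["start"]))
    planted_keys = set(zip(truth["chrom"], truth["start"]))
    n_hit = len(called_keys & planted_keys)
    return {
        "n_planted": n_planted,
        "n_tested": len(results),
        "n_called": len(called_keys),
        "recall": n_hit / n_planted,
        "observed_fdr": ((len(called_keys) - n_hit) / len(called_keys)
                         if called_keys else 0.0),
    }


def hifreq_recovery(seed: int, n_clusters: int = 20, cluster_size: int = 6,
                    delta: float = 50.0, min_count: int = 5) -> dict:
    """High-frequency-gene detection with planted TSS-proximal DMC clusters."""
    config = SimConfig(
        seed=seed, n_chroms=3, chrom_length_bp=1_000_000, n_transcripts=60,
        mean_coverage=30.0,
        planted_hifreq=[PlantedCluster(cluster_size, delta, "hyper")
                        for _ in range(n_clusters)],
    )
    annotation, truth, _matrix, results = _tested_results(config)
    results = diffmeth.call_differential(results)
    assoc = features.nearest_tss(diffmeth.called(results), annotation)
    reported = scoring.high_frequency_genes(assoc, annotation,
                                            min_count=min_count)
    planted = set(truth.loc[truth["category"] == "HIFREQ", "transcript_id"])
    found = set(reported["transcript_id"])
    return {
        "n_planted": n_clusters,
        "n_recovered": len(planted & found),
        "n_reported": len(found),
    }


def hifreq_null(seed: int, min_count: int = 5) -> dict:
    """High-frequency-gene false reports on a fully null dataset."""
    config = SimConfig(
        seed=seed, n_chroms=3, chrom_length_bp=1_000_000, n_transcripts=60,
        mean_coverage=30.0,
    )
    annotation, _truth, _matrix, results = _tested_results(config)
    results = diffmeth.call_differential(results)
    assoc = features.nearest_tss(diffmeth.called(results), annotation)
    reported = scoring.high_frequency_genes(assoc, annotation,
                                            min_count=min_count)
    return {"n_reported": len(reported)}


def expression_coupling(seed: int, rho: float, n_genes: int = 15) -> float:
    """Sample Spearman rho between planted deltas and simulated log2FC."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    deltas = rng.uniform(20, 90, n_genes)
    directions = rng.choice(["hyper", "hypo"], n_genes)
    truth = pd.DataFrame({
        "category": "DMP", "chrom": "chr1", "start": 1, "end": 2,
        "transcript_id": [f"tx{i:04d}" for i in range(n_genes)],
        "gene_id": [f"g{i:04d}" for i in range(n_genes)],
        "delta_percent": deltas, "direction": directions, "n_sites": 1,
    })
    expr = simulate_expression(truth, pd.DataFrame(columns=["gene_id"]),
                               rho=rho, seed=seed)
    signed = np.where(truth["direction"] == "hyper", 1.0, -1.0) * deltas
    summaries = pd.DataFrame({"gene_id": truth["gene_id"], "n_dmcs": 2,
                              "mean_meth_diff": signed})
    return integration.meth_expr_correlation(summaries, expr).rho


def coverage_mode(seed: int, mean_coverage: float = 10.0) -> int:
    """Modal per-read-count coverage over >= 10,000 simulated CpGs."""
    config = SimConfig(seed=seed, n_chroms=1, chrom_length_bp=1_200_000,
                       n_transcripts=0, mean_coverage=mean_coverage)
    samples, _ = simulate_counts(config, simulate_annotation(config))
    cov = np.concatenate([(df["n_meth"] + df["n_unmeth"]).to_numpy()
                          for df in samples.values()])
    return int(np.bincount(cov).argmax())


def methylation_histogram(seed: int, bin_width: float = 2.0):
    """Pooled %methylation histogram (counts, edges) across all samples."""
    config = SimConfig(seed=seed, n_chroms=1, chrom_length_bp=1_200_000,
                       n_transcripts=0, mean_coverage=30.0)
    samples, _ = simulate_counts(config, simulate_annotation(config))
    pct = np.concatenate([
        100.0 * df["n_meth"] / (df["n_meth"] + df["n_unmeth"])
        for df in samples.values()
    ])
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    hist, _ = np.histogram(pct, bins=edges)
    return hist, edges
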