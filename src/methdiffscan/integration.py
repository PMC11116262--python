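"""Cross-omics stages: per-gene methylation summaries, Spearman
methylation-expression correlation, and Fisher-exact gene-set enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import UNASSIGNED


def gene_meth_summaries(dmcs: pd.DataFrame, annotation: pd.DataFrame,
                        window: int = 10000, min_dmcs: int = 2,
                        summary: str = "mean") -> pd.DataFrame:
    """Per-gene DMC count and summary methylation difference.

    A DMC belongs to a gene when it lies within TSS +/- window of any of
    the gene's transcripts; genes with fewer than ``min_dmcs`` member
    DMCs are omitted.  The summary of member differences is the
    unweighted mean by default (``summary="median"`` for the median).
    """
    if summary not in ("mean", "median"):
        raise ValueError(f"unknown summary {summary!r}")
    rows = []
    for gene_id, g_ann in annotation.groupby("gene_id", sort=False):
        member_idx: set[int] = set()
        for rec in g_ann.itertuples():
            sub = dmcs[dmcs["chrom"] == rec.chrom]
            if len(sub) == 0:
                continue
            inside = np.abs(sub["start"].to_numpy(dtype=np.int64) - int(rec.tss)) <= window
            member_idx.update(sub.index[inside])
        if len(member_idx) < min_dmcs:
            continue
        diffs = dmcs.loc[sorted(member_idx), "meth_diff"].to_numpy(dtype=float)
        value = float(np.mean(diffs) if summary == "mean" else np.median(diffs))
        rows.append(dict(gene_id=gene_id, n_dmcs=len(member_idx),
                         mean_meth_diff=value))
    return pd.DataFrame(rows, columns=["gene_id", "n_dmcs", "mean_meth_diff"])


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n_genes: int
    table: pd.DataFrame  # gene_id, mean_meth_diff, log2_fold_change


def meth_expr_correlation(summaries: pd.DataFrame, expression: pd.DataFrame,
                          de_only: bool = False) -> CorrelationResult:
    """Spearman correlation of per-gene methylation change vs log2FC.

    Computed over genes present in both tables (optionally restricted to
    genes flagged differentially expressed); tie-aware rho with the
    t-approximation p-value.  The paired table is returned for audit.
    """
    expr = expression[expression["de_flag"]] if de_only else expression
    table = summaries.merge(expr[["gene_id", "log2_fold_change"]], on="gene_id")
    if len(table) < 3:
        raise ValueError(
            f"insufficient paired genes for correlation (n={len(table)}, need >= 3)"
        )
    rho, p = stats.spearmanr(table["mean_meth_diff"], table["log2_fold_change"])
    return CorrelationResult(rho=float(rho), p_value=float(p),
                             n_genes=len(table),
                             table=table[["gene_id", "mean_meth_diff",
                                          "log2_fold_change"]])


def enrichment_fisher(study_genes: set, universe_genes: set,
                      term_map: dict[str, set]) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of a study set against terms.

    For each term the 2x2 table (in study / not) x (in term / not) over
    the universe is tested for over-representation; p-values are BH
    adjusted across the tested terms.  Terms with zero study hits are
    reported (p = 1) and flagged.
    """
    study = set(study_genes)
    universe = set(universe_genes)
    if not universe:
        raise ValueError("empty universe")
    if not term_map:
        raise ValueError("empty term map")
    if not study <= universe:
        raise ValueError("study set must be a subset of the universe")

    n, big_n = len(study), len(universe)
    rows = []
    for term_id, genes in term_map.items():
        term = set(genes) & universe
        big_k = len(term)
        k = len(term & study)
        table = [[k, big_k - k], [n - k, big_n - big_k - (n - k)]]
        odds, p = stats.fisher_exact(table, alternative="greater")
        rows.append(dict(term_id=term_id, k=k, K=big_k, n=n, N=big_n,
                         odds_ratio=float(odds), p_value=float(p),
                         zero_hit=k == 0))
    out = pd.DataFrame(rows)
    from .diffmeth import adjust_fdr
    out["p_adjusted"] = adjust_fdr(out["p_value"].to_numpy())
    return out[["term_id", "k", "K", "n", "N", "odds_ratio", "p_value",
                "p_adjusted", "zero_hit"]]


def read_gmt(path) -> dict[str, set]:
    """Read a GMT gene-set file: term, description, gene, gene, ..."""
    term_map: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            term_map[fields[0]] = set(fields[2:])
    return term_map


def write_gmt(term_map: dict[str, set], path) -> None:
    with open(path, "w") as fh:
        for term, genes in term_map.items():
            fh.write("\t".join([term, term] + sorted(genes)) + "\n")
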