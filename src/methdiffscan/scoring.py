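"""Gene-level DMC statistics: top-DMC genes, high-frequency DMC genes,
TSS-distance and per-transcript frequency distributions, chromosome
direction tallies, and set-overlap (Venn) reports.

Threshold semantics follow their definitions literally: a top DMC gene
requires a DMC with TSS distance strictly below 10 kb and an absolute
methylation difference strictly above 30 percentage points; a
high-frequency gene requires at least five DMCs inside the transcript's
TSS +/- 10 kb window (boundary inclusive).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import UNASSIGNED


def top_dmc_genes(dmcs: pd.DataFrame, max_dist: float = 10000,
                  min_abs_diff: float = 30.0) -> set[str]:
    """Genes with a DMC at |TSS distance| < max_dist and |diff| > min_abs_diff.

    Both inequalities are strict; ``dmcs`` must carry ``gene_id`` and
    ``distance_to_tss`` columns from TSS annotation.
    """
    keep = (
        (dmcs["distance_to_tss"].abs() < max_dist)
        & (dmcs["meth_diff"].abs() > min_abs_diff)
        & (dmcs["gene_id"] != UNASSIGNED)
    )
    return set(dmcs.loc[keep, "gene_id"])


def _dmcs_per_transcript(dmcs: pd.DataFrame, annotation: pd.DataFrame,
                         window: int, multi_assign: bool):
    """Yield (transcript row, member DataFrame) for transcripts with >= 1 DMC.

    With ``multi_assign`` every DMC counts toward every transcript whose
    TSS +/- window contains it; otherwise only toward its nearest
    transcript (the ``transcript_id`` column).
    """
    for chrom, ann_sub in annotation.groupby("chrom", sort=False):
        sub = dmcs[dmcs["chrom"] == chrom]
        if len(sub) == 0:
            continue
        pos = sub["start"].to_numpy(dtype=np.int64)
        for rec in ann_sub.itertuples():
            inside = np.abs(pos - int(rec.tss)) <= window
            if multi_assign:
                members = sub.loc[inside]
            else:
                members = sub.loc[inside & (sub["transcript_id"] == rec.transcript_id).to_numpy()]
            if len(members):
                yield rec, members


def _dominant_direction(diffs: np.ndarray) -> str:
    n_hyper = int((diffs > 0).sum())
    n_hypo = int((diffs < 0).sum())
    if n_hyper > n_hypo:
        return "hyper"
    if n_hypo > n_hyper:
        return "hypo"
    return "mixed"


def high_frequency_genes(dmcs: pd.DataFrame, annotation: pd.DataFrame,
                         window: int = 10000, min_count: int = 5,
                         multi_assign: bool = True) -> pd.DataFrame:
    """Transcripts carrying at least ``min_count`` DMCs in TSS +/- window.

    Returns one row per reported transcript with the member DMC list
    (position, meth_diff, direction) and the dominant direction (majority
    sign; exact ties are labelled ``mixed``).
    """
    rows = []
    for rec, members in _dmcs_per_transcript(dmcs, annotation, window, multi_assign):
        if len(members) < min_count:
            continue
        diffs = members["meth_diff"].to_numpy()
        rows.append(dict(
            transcript_id=rec.transcript_id, gene_id=rec.gene_id,
            dmc_count=len(members),
            dominant_direction=_dominant_direction(diffs),
            members=tuple(zip(members["start"].tolist(), diffs.tolist(),
                              members["direction"].tolist())),
        ))
    out = pd.DataFrame(rows, columns=["transcript_id", "gene_id", "dmc_count",
                                      "dominant_direction", "members"])
    return out.sort_values("dmc_count", ascending=False, kind="stable").reset_index(drop=True)


def dmc_frequency_distribution(dmcs: pd.DataFrame, annotation: pd.DataFrame,
                               window: int = 10000,
                               multi_assign: bool = True):
    """Per-transcript DMC counts (transcripts with >= 1 DMC) plus summary.

    Returns ``(counts, summary)`` where counts is a Series indexed by
    transcript_id and summary holds median and quartiles of the count
    vector.
    """
    counts = {
        rec.transcript_id: len(members)
        for rec, members in _dmcs_per_transcript(dmcs, annotation, window, multi_assign)
    }
    vec = pd.Series(counts, dtype=float, name="dmc_count")
    if len(vec):
        summary = {"median": float(vec.median()),
                   "q1": float(vec.quantile(0.25)),
                   "q3": float(vec.quantile(0.75)),
                   "n_transcripts": int(len(vec))}
    else:
        summary = {"median": np.nan, "q1": np.nan, "q3": np.nan, "n_transcripts": 0}
    return vec, summary


def tss_distance_distribution(dmcs: pd.DataFrame):
    """Absolute TSS distances of annotated DMCs plus median/IQR summary."""
    assigned = dmcs[dmcs["transcript_id"] != UNASSIGNED]
    dist = assigned["distance_to_tss"].abs().to_numpy(dtype=float)
    if len(dist):
        summary = {"median": float(np.median(dist)),
                   "q1": float(np.percentile(dist, 25)),
                   "q3": float(np.percentile(dist, 75)),
                   "n": int(len(dist))}
    else:
        summary = {"median": np.nan, "q1": np.nan, "q3": np.nan, "n": 0}
    return dist, summary


def chromosome_direction_counts(called: pd.DataFrame) -> pd.DataFrame:
    """Hyper and hypo counts per chromosome for a called locus set."""
    sub = called[called["direction"].isin(["hyper", "hypo"])]
    table = (sub.groupby(["chrom", "direction"]).size().unstack(fill_value=0)
             .reindex(columns=["hyper", "hypo"], fill_value=0))
    table.columns.name = None
    return table


@dataclass
class OverlapReport:
    """Full Venn partition of 2-4 named sets, with pairwise Jaccard indices."""

    set_names: list[str]
    partitions: dict[str, set] = field(default_factory=dict)
    jaccard: dict[tuple[str, str], float] = field(default_factory=dict)

    def cardinality(self, key: str) -> int:
        return len(self.partitions.get(key, set()))

    @property
    def center(self) -> set:
        return self.partitions.get("&".join(self.set_names), set())


def overlap_sets(named_sets: dict[str, set]) -> OverlapReport:
    """Partition the union of 2-4 named sets into exclusive Venn regions.

    Partition keys join the names of the sets an element belongs to with
    ``&`` (e.g. ``"A&C"``); each union member appears in exactly one
    partition.
    """
    if not 2 <= len(named_sets) <= 4:
        raise ValueError("overlap_sets expects between 2 and 4 sets")
    names = list(named_sets)
    report = OverlapReport(set_names=names)
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(named_sets[n] for n in combo))
            outside = set.union(set(), *(named_sets[n] for n in names if n not in combo))
            report.partitions["&".join(combo)] = inside - outside
    for a, b in itertools.combinations(names, 2):
        union = named_sets[a] | named_sets[b]
        report.jaccard[(a, b)] = (
            len(named_sets[a] & named_sets[b]) / len(union) if union else 0.0
        )
    return report


def _direction_pairs(category) -> set[tuple[str, str]]:
    """Normalize a category input to a set of (gene, direction) pairs."""
    if isinstance(category, pd.DataFrame):
        return set(zip(category["gene_id"], category["direction"]))
    if isinstance(category, dict):
        out = set()
        for gene, direction in category.items():
            if isinstance(direction, (set, frozenset, list, tuple)):
                out |= {(gene, d) for d in direction}
            else:
                out.add((gene, direction))
        return out
    return {(g, "any") for g in category}


def cross_category_overlap(dmc_genes, dmr_genes, dmp_genes,
                           direction_aware: bool = True) -> dict[str, set]:
    """Genes shared between the DMC / DMR / DMP categories.

    Inputs are gene->direction mappings (or DataFrames with ``gene_id``
    and ``direction``).  When ``direction_aware`` a gene matches across
    categories only if it shows the same trend (hyper with hyper, hypo
    with hypo) in every category of the combination.
    """
    cats = {"DMC": _direction_pairs(dmc_genes), "DMR": _direction_pairs(dmr_genes),
            "DMP": _direction_pairs(dmp_genes)}
    out: dict[str, set] = {}
    names = list(cats)
    for r in range(2, 4):
        for combo in itertools.combinations(names, r):
            if direction_aware:
                shared = set.intersection(*(cats[n] for n in combo))
                out["&".join(combo)] = {g for g, _d in shared}
            else:
                genes = [{g for g, _d in cats[n]} for n in combo]
                out["&".join(combo)] = set.intersection(*genes)
    return out
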