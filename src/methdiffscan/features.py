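"""Genome geometry: tiling, promoters, region aggregation, TSS annotation.

Coordinates are 1-based inclusive throughout.  Tiles are non-overlapping
1-kb windows anchored at k*W + 1 (so position 1,203,500 falls in the
window [1,203,001, 1,204,000]); promoters are TSS +/- 1 kb, clipped to
chromosome bounds.  Signed TSS distances follow transcript orientation:
negative means upstream of the TSS.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .diffmeth import UnitedMatrix

logger = logging.getLogger(__name__)

FEATURE_CLASSES = ["promoter", "exon", "intron", "intergenic"]

UNASSIGNED = "unassigned"


def tile_genome(chrom_sizes: dict[str, int], window: int = 1000) -> pd.DataFrame:
    """Partition each chromosome into consecutive fixed-width windows.

    Windows are [k*W + 1, (k+1)*W]; the last window is truncated at the
    chromosome end.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    rows = []
    for chrom, size in chrom_sizes.items():
        starts = np.arange(1, size + 1, window, dtype=np.int64)
        ends = np.minimum(starts + window - 1, size)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["chrom", "start", "end"])
    out["kind"] = "tile"
    out["owner"] = ""
    return out


def promoter_regions(annotation: pd.DataFrame, flank: int = 1000,
                     chrom_sizes: dict[str, int] | None = None,
                     deduplicate: bool = True) -> pd.DataFrame:
    """TSS +/- flank promoter windows, one per transcript.

    Clipped to [1, chromosome length] when sizes are given.  Identical
    intervals from isoforms sharing a TSS are deduplicated to the
    lexicographically smallest owner transcript (logged).
    """
    if len(annotation) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "kind", "owner", "gene_id"])
    tss = annotation["tss"].to_numpy(dtype=np.int64)
    start = np.maximum(1, tss - flank)
    end = tss + flank
    if chrom_sizes is not None:
        limits = annotation["chrom"].map(chrom_sizes).to_numpy()
        end = np.minimum(end, limits)
    out = pd.DataFrame(
        {
            "chrom": annotation["chrom"], "start": start, "end": end,
            "kind": "promoter", "owner": annotation["transcript_id"],
            "gene_id": annotation["gene_id"],
        }
    )
    if deduplicate:
        before = len(out)
        out = (out.sort_values("owner", kind="stable")
                  .drop_duplicates(subset=["chrom", "start", "end"], keep="first"))
        dropped = before - len(out)
        if dropped:
            logger.info("promoter_regions: deduplicated %d identical intervals", dropped)
    return out.sort_values(["chrom", "start", "owner"], kind="stable").reset_index(drop=True)


def aggregate_region_counts(matrix: UnitedMatrix,
                            regions: pd.DataFrame) -> UnitedMatrix:
    """Sum site counts into region-level counts per sample.

    Regions containing no covered CpG are dropped (logged).  Region rows
    retain ``kind``/``owner``/``gene_id`` columns when present.
    """
    loci = matrix.loci
    n_samples = len(matrix.samples)
    meth_out = np.zeros((len(regions), n_samples), dtype=np.int64)
    cov_out = np.zeros((len(regions), n_samples), dtype=np.int64)

    # per-chromosome prefix sums over position-sorted sites
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in loci.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["start"].to_numpy()
        cm = np.vstack([np.zeros(n_samples, dtype=np.int64),
                        np.cumsum(matrix.meth[idx], axis=0)])
        cc = np.vstack([np.zeros(n_samples, dtype=np.int64),
                        np.cumsum(matrix.cov[idx], axis=0)])
        by_chrom[chrom] = (pos, cm, cc)

    chroms = regions["chrom"].to_numpy()
    starts = regions["start"].to_numpy()
    ends = regions["end"].to_numpy()
    for i in range(len(regions)):
        entry = by_chrom.get(chroms[i])
        if entry is None:
            continue
        pos, cm, cc = entry
        lo = np.searchsorted(pos, starts[i], side="left")
        hi = np.searchsorted(pos, ends[i], side="right")
        if hi > lo:
            meth_out[i] = cm[hi] - cm[lo]
            cov_out[i] = cc[hi] - cc[lo]

    keep = (cov_out > 0).all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("aggregate_region_counts: dropped %d regions without "
                    "covered CpGs", dropped)
    region_loci = regions.loc[keep].reset_index(drop=True)
    return UnitedMatrix(
        loci=region_loci, meth=meth_out[keep], cov=cov_out[keep],
        samples=matrix.samples, design=matrix.design,
    )


def nearest_tss(loci: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Associate each locus with the transcript whose TSS is closest.

    Distance is signed in transcript orientation (negative = upstream of
    the TSS); for an interval locus the distance is the minimum over its
    bases (0 if it contains the TSS).  Equidistant ties go to the
    lexicographically smallest transcript id.  Loci on chromosomes
    absent from the annotation get the sentinel owner ``unassigned``.
    """
    out = loci.copy().reset_index(drop=True)
    n = len(out)
    tx_id = np.full(n, UNASSIGNED, dtype=object)
    gene_id = np.full(n, UNASSIGNED, dtype=object)
    dist = np.full(n, np.nan)

    ann_by_chrom = {c: sub.sort_values("transcript_id", kind="stable")
                    for c, sub in annotation.groupby("chrom", sort=False)}
    n_unassigned = 0
    for chrom, sub in out.groupby("chrom", sort=False):
        ann = ann_by_chrom.get(chrom)
        idx = sub.index.to_numpy()
        if ann is None or len(ann) == 0:
            n_unassigned += len(idx)
            continue
        tss = ann["tss"].to_numpy(dtype=np.int64)  # columns ordered by transcript_id
        strand_plus = (ann["strand"] == "+").to_numpy()
        a = sub["start"].to_numpy(dtype=np.int64)[:, None]
        b = sub["end"].to_numpy(dtype=np.int64)[:, None]
        t = tss[None, :]
        below = np.clip(a - t, 0, None)   # tss left of the interval
        above = np.clip(t - b, 0, None)   # tss right of the interval
        absdist = np.maximum(below, above)  # 0 iff a <= t <= b
        j = np.argmin(absdist, axis=1)  # first minimum = smallest transcript_id
        rows = np.arange(len(idx))
        edge = np.where(tss[j] < a[rows, 0], a[rows, 0],
                        np.where(tss[j] > b[rows, 0], b[rows, 0], tss[j]))
        signed = np.where(strand_plus[j], edge - tss[j], tss[j] - edge)
        tx_id[idx] = ann["transcript_id"].to_numpy()[j]
        gene_id[idx] = ann["gene_id"].to_numpy()[j]
        dist[idx] = signed
    if n_unassigned:
        logger.info("nearest_tss: %d loci on chromosomes absent from the "
                    "annotation", n_unassigned)
    out["transcript_id"] = tx_id
    out["gene_id"] = gene_id
    out["distance_to_tss"] = dist
    return out


def _build_trees(annotation: pd.DataFrame, promoters: pd.DataFrame):
    trees = {"promoter": {}, "exon": {}, "body": {}}

    def add(kind, chrom, s, e):
        trees[kind].setdefault(chrom, IntervalTree()).addi(s, e + 1)

    for rec in promoters.itertuples():
        add("promoter", rec.chrom, rec.start, rec.end)
    for rec in annotation.itertuples():
        add("body", rec.chrom, rec.tx_start, rec.tx_end)
        for s, e in rec.exons:
            add("exon", rec.chrom, s, e)
    return trees


def classify_feature(loci: pd.DataFrame, annotation: pd.DataFrame,
                     promoters: pd.DataFrame,
                     precedence: tuple = ("promoter", "exon", "intron")) -> pd.Series:
    """Assign each locus a single feature class by overlap with precedence.

    Default precedence promoter > exon > intron; anything else is
    intergenic.  Intron means inside a transcript body but overlapping no
    exon of any transcript.
    """
    trees = _build_trees(annotation, promoters)

    def overlaps(kind, chrom, s, e):
        tree = trees[kind].get(chrom)
        return bool(tree.overlap(s, e + 1)) if tree is not None else False

    classes = []
    for rec in loci.itertuples():
        label = "intergenic"
        for kind in precedence:
            hit = (overlaps("body", rec.chrom, rec.start, rec.end)
                   and not overlaps("exon", rec.chrom, rec.start, rec.end)
                   ) if kind == "intron" else overlaps(kind, rec.chrom, rec.start, rec.end)
            if hit:
                label = kind
                break
        classes.append(label)
    return pd.Series(classes, index=loci.index, name="feature_class")


def feature_proportions(loci: pd.DataFrame, annotation: pd.DataFrame,
                        promoters: pd.DataFrame) -> dict[str, float]:
    """Fraction of loci per feature class; always reports all four classes."""
    if len(loci) == 0:
        raise ValueError("cannot compute feature proportions of an empty locus set")
    classes = classify_feature(loci, annotation, promoters)
    counts = classes.value_counts()
    return {c: float(counts.get(c, 0)) / len(loci) for c in FEATURE_CLASSES}
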