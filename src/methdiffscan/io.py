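"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates held in memory are 1-based inclusive; BED-family
formats are converted at the I/O boundary (BED start = pos - 1).

Methylation calls are carried as pandas DataFrames with columns
``chrom, pos, n_meth, n_unmeth`` (one row per covered CpG).  Transcript
annotations are DataFrames with columns ``transcript_id, gene_id, chrom,
strand, tx_start, tx_end, exons, tss`` where ``exons`` is a tuple of
``(start, end)`` 1-based inclusive pairs and ``tss`` is the strand-aware
5' end (``tx_start`` on +, ``tx_end`` on -).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METH_COLUMNS = ["chrom", "pos", "n_meth", "n_unmeth"]

ANNOTATION_COLUMNS = [
    "transcript_id", "gene_id", "chrom", "strand",
    "tx_start", "tx_end", "exons", "tss",
]

EXPRESSION_COLUMNS = ["gene_id", "log2_fold_change", "adjusted_p", "de_flag"]

#: tolerance (percentage points) between the stored %meth field and the
#: value recomputed from the counts before a warning is raised
PERCENT_TOLERANCE = 0.5


@dataclass(frozen=True)
class GroupDesign:
    """Two-group sample design; ``reference`` is the control group."""

    groups: dict[str, str]  # sample_id -> group label
    reference: str

    def __post_init__(self) -> None:
        labels = set(self.groups.values())
        if len(labels) != 2:
            raise ValueError(
                f"design must contain exactly 2 groups, got {sorted(labels)}"
            )
        if self.reference not in labels:
            raise ValueError(f"reference group {self.reference!r} not in design")
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("sample ids must be unique")

    @property
    def case(self) -> str:
        """The non-reference (patient) group label."""
        return next(g for g in self.groups.values() if g != self.reference)

    def samples_of(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    @property
    def samples(self) -> list[str]:
        return list(self.groups)


def read_design(path) -> GroupDesign:
    """Read a TSV design table: columns sample_id, group, reference (0/1)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample_id", "group", "reference"}
    if not required.issubset(df.columns):
        raise ValueError(f"design table needs columns {sorted(required)}")
    ref_groups = df.loc[df["reference"].astype(bool), "group"].unique()
    if len(ref_groups) != 1:
        raise ValueError("exactly one group must be flagged as reference")
    return GroupDesign(
        groups=dict(zip(df["sample_id"], df["group"])), reference=ref_groups[0]
    )


def write_design(design: GroupDesign, path) -> None:
    rows = [
        {"sample_id": s, "group": g, "reference": int(g == design.reference)}
        for s, g in design.groups.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Bismark coverage files
# ---------------------------------------------------------------------------

def read_bismark_cov(path) -> pd.DataFrame:
    """Parse a Bismark-style coverage file into a methylation-call frame.

    The 6 tab-separated columns are chrom, start, end, %methylation,
    methylated count, unmethylated count.  Both the 1-based dialect
    (start == end) and the 0-based half-open dialect (end == start + 1)
    are accepted; the dialect is autodetected per file and must be
    consistent within it.

    Zero-coverage records are dropped; a stored %meth deviating from the
    counts by more than ``PERCENT_TOLERANCE`` points triggers a warning
    (the counts win).  Drop/mismatch tallies are attached as
    ``df.attrs['n_dropped_zero_coverage']`` / ``df.attrs['n_percent_mismatch']``
    and logged.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "pct", "n_meth", "n_unmeth"],
            dtype={"chrom": str},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed coverage file {path}: {exc}") from exc
    for col in ("start", "end", "n_meth", "n_unmeth"):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            lineno = int(bad[0]) + 1 if len(bad) else "?"
            raise ValueError(f"malformed value in column {col!r} of {path}, line {lineno}")

    if len(df) == 0:
        out = pd.DataFrame(columns=METH_COLUMNS)
        out.attrs["n_dropped_zero_coverage"] = 0
        out.attrs["n_percent_mismatch"] = 0
        return out

    one_based = (df["start"] == df["end"]).all()
    zero_based = (df["end"] == df["start"] + 1).all()
    if not (one_based or zero_based):
        bad = df.index[(df["start"] != df["end"]) & (df["end"] != df["start"] + 1)]
        raise ValueError(
            f"inconsistent coordinate dialect in {path} "
            f"(first odd record at line {int(bad[0]) + 1 if len(bad) else '?'})"
        )
    pos = df["end"] if zero_based and not one_based else df["start"]

    cov = df["n_meth"] + df["n_unmeth"]
    dropped = int((cov == 0).sum())
    if dropped:
        logger.info("%s: dropped %d zero-coverage records", path, dropped)

    keep = cov > 0
    recomputed = 100.0 * df.loc[keep, "n_meth"] / cov[keep]
    mismatch = int((np.abs(recomputed - df.loc[keep, "pct"]) > PERCENT_TOLERANCE).sum())
    if mismatch:
        warnings.warn(
            f"{path}: {mismatch} records where the stored %meth disagrees with "
            f"the counts by > {PERCENT_TOLERANCE} points; counts take precedence",
            stacklevel=2,
        )

    out = pd.DataFrame(
        {
            "chrom": df.loc[keep, "chrom"].to_numpy(),
            "pos": pos[keep].astype(np.int64).to_numpy(),
            "n_meth": df.loc[keep, "n_meth"].astype(np.int64).to_numpy(),
            "n_unmeth": df.loc[keep, "n_unmeth"].astype(np.int64).to_numpy(),
        }
    )
    out.attrs["n_dropped_zero_coverage"] = dropped
    out.attrs["n_percent_mismatch"] = mismatch
    return out


def write_bismark_cov(calls: pd.DataFrame, path) -> None:
    """Write calls in the 1-based coverage dialect (start == end == pos)."""
    cov = calls["n_meth"] + calls["n_unmeth"]
    pct = np.where(cov > 0, 100.0 * calls["n_meth"] / cov.replace(0, 1), 0.0)
    out = pd.DataFrame(
        {
            "chrom": calls["chrom"],
            "start": calls["pos"],
            "end": calls["pos"],
            "pct": np.round(pct, 6),
            "n_meth": calls["n_meth"],
            "n_unmeth": calls["n_unmeth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def destrand(calls: pd.DataFrame) -> pd.DataFrame:
    """Merge complementary-strand calls of a CpG dinucleotide.

    A record at position p+1 is folded onto a record at p (the + strand
    cytosine) when both exist, summing counts.  The merge is logged.
    """
    df = calls.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    merged = 0
    parts = []
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        is_minus_partner = np.zeros(len(sub), dtype=bool)
        is_minus_partner[1:] = pos[1:] == pos[:-1] + 1
        target = np.arange(len(sub))
        target[is_minus_partner] -= 1
        g = sub.groupby(target).agg(
            pos=("pos", "first"), n_meth=("n_meth", "sum"), n_unmeth=("n_unmeth", "sum")
        )
        g.insert(0, "chrom", chrom)
        merged += int(is_minus_partner.sum())
        parts.append(g)
    out = pd.concat(parts, ignore_index=True) if parts else df
    logger.info("destrand: merged %d minus-strand records", merged)
    out.attrs["n_merged"] = merged
    return out


# ---------------------------------------------------------------------------
# Transcript annotations
# ---------------------------------------------------------------------------

def _finalize_annotation(records: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(records, columns=ANNOTATION_COLUMNS)
    if len(df):
        bad = ~df["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError(
                f"transcript {df.loc[bad, 'transcript_id'].iloc[0]!r} has no "
                "strand; TSS is undefined"
            )
        df["tss"] = np.where(df["strand"] == "+", df["tx_start"], df["tx_end"])
        df = df.sort_values(["chrom", "tx_start", "transcript_id"], kind="stable")
    return df.reset_index(drop=True)


def read_annotation(path, fmt: str = "bed12") -> pd.DataFrame:
    """Read a transcript annotation from BED12 or GTF.

    Exons are sorted and must not overlap within a transcript.  BED12
    names of the form ``transcript|gene`` carry the gene id; otherwise
    gene_id defaults to the transcript id.
    """
    if fmt == "bed12":
        return _read_bed12(path)
    if fmt == "gtf":
        return _read_gtf(path)
    raise ValueError(f"unknown annotation format {fmt!r}")


def _read_bed12(path) -> pd.DataFrame:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 requires 12 fields")
            chrom, cstart, cend, name, _score, strand = f[:6]
            block_sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            block_starts = [int(x) for x in f[11].rstrip(",").split(",")]
            tx_start = int(cstart) + 1  # to 1-based inclusive
            tx_end = int(cend)
            exons = tuple(
                (tx_start + bs, tx_start + bs + sz - 1)
                for bs, sz in zip(block_starts, block_sizes)
            )
            _check_exons(exons, name, tx_start, tx_end)
            tid, _, gid = name.partition("|")
            records.append(
                dict(
                    transcript_id=tid, gene_id=gid or tid, chrom=chrom,
                    strand=strand, tx_start=tx_start, tx_end=tx_end,
                    exons=exons, tss=None,
                )
            )
    return _finalize_annotation(records)


def _read_gtf(path) -> pd.DataFrame:
    import gffutils

    try:
        with warnings.catch_warnings():
            # transcript features present alongside exons are expected here
            warnings.simplefilter("ignore", UserWarning)
            db = gffutils.create_db(str(path), ":memory:", force=True,
                                    keep_order=True,
                                    disable_infer_genes=True,
                                    merge_strategy="create_unique")
    except Exception as exc:
        raise ValueError(f"failed to parse GTF {path}: {exc}") from exc
    records = []
    for tx in db.features_of_type("transcript"):
        tid = tx.attributes.get("transcript_id", [tx.id])[0]
        gid = tx.attributes.get("gene_id", [tid])[0]
        exons = sorted((e.start, e.end)
                       for e in db.children(tx, featuretype="exon"))
        if not exons:
            exons = [(tx.start, tx.end)]
        tx_start = min(tx.start, exons[0][0])
        tx_end = max(tx.end, exons[-1][1])
        _check_exons(tuple(exons), tid, tx_start, tx_end)
        records.append(dict(
            transcript_id=tid, gene_id=gid, chrom=tx.seqid,
            strand=tx.strand if tx.strand in ("+", "-") else ".",
            tx_start=tx_start, tx_end=tx_end, exons=tuple(exons), tss=None,
        ))
    return _finalize_annotation(records)


def _check_exons(exons, tid, tx_start, tx_end) -> None:
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if s2 <= e1:
            raise ValueError(f"transcript {tid!r}: overlapping exons")
    if exons and (exons[0][0] < tx_start or exons[-1][1] > tx_end):
        raise ValueError(f"transcript {tid!r}: exon outside transcript body")


def write_bed12(annotation: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for rec in annotation.itertuples():
            cstart = rec.tx_start - 1
            sizes = ",".join(str(e - s + 1) for s, e in rec.exons)
            starts = ",".join(str(s - rec.tx_start) for s, _e in rec.exons)
            name = f"{rec.transcript_id}|{rec.gene_id}"
            fh.write(
                f"{rec.chrom}\t{cstart}\t{rec.tx_end}\t{name}\t0\t{rec.strand}"
                f"\t{cstart}\t{rec.tx_end}\t0\t{len(rec.exons)}\t{sizes}\t{starts}\n"
            )


def write_gtf(annotation: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for rec in annotation.itertuples():
            attrs = f'transcript_id "{rec.transcript_id}"; gene_id "{rec.gene_id}";'
            fh.write(
                f"{rec.chrom}\tmethdiffscan\ttranscript\t{rec.tx_start}\t{rec.tx_end}"
                f"\t.\t{rec.strand}\t.\t{attrs}\n"
            )
            for s, e in rec.exons:
                fh.write(
                    f"{rec.chrom}\tmethdiffscan\texon\t{s}\t{e}"
                    f"\t.\t{rec.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if not set(EXPRESSION_COLUMNS).issubset(df.columns):
        raise ValueError(f"expression table needs columns {EXPRESSION_COLUMNS}")
    df = df[EXPRESSION_COLUMNS].copy()
    df["de_flag"] = df["de_flag"].astype(bool)
    bad = ~df["adjusted_p"].between(0, 1)
    if bad.any():
        raise ValueError("adjusted_p outside [0, 1]")
    return df


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_results(results: pd.DataFrame, path, kind: str,
                  params: dict | None = None) -> None:
    """Write a result table as TSV with a parameter-recording header comment."""
    if kind not in ("dmc", "dmr", "dmp", "genes", "association", "summary"):
        raise ValueError(f"unknown result kind {kind!r}")
    with open(path, "w") as fh:
        fh.write(f"# methdiffscan result kind={kind}\n")
        for key, val in (params or {}).items():
            fh.write(f"# {key}={val}\n")
        results.to_csv(fh, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_bed(loci: pd.DataFrame, path, name_col: str | None = None) -> None:
    """Export loci (1-based inclusive start/end) as 0-based half-open BED."""
    with open(path, "w") as fh:
        for i, rec in enumerate(loci.itertuples()):
            name = getattr(rec, name_col) if name_col else f"locus_{i}"
            fh.write(f"{rec.chrom}\t{rec.start - 1}\t{rec.end}\t{name}\n")
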