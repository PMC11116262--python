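"""Synthetic WGBS dataset generator with a planted-effect ground truth.

The generator emulates the statistical structure of duodenal WGBS count
data: CpG sites spaced ~100 bp apart, read coverage distributed around a
~10x mode, and a bimodal per-site methylation-fraction profile with most
sites near 95-100% methylation and a smaller mode near 0-5%.  Two sample
groups (control and case) share per-site baseline methylation; planted
effects shift the case group by a configured percentage-point delta at
single CpGs, within 1-kb tiles, within TSS+/-1kb promoters, or as DMC
clusters inside a transcript's TSS+/-10kb neighbourhood.  Every planted
entity is recorded in a truth table, the ground truth for recovery tests.

Coverage follows a truncated negative binomial (Poisson-gamma); counts
are binomial at ``dispersion=0`` and beta-binomial otherwise.  Each stage
draws from its own RNG stream derived from the master seed, so adding a
stage does not perturb earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio

TILE_WINDOW = 1000
PROMOTER_FLANK = 1000
CLUSTER_WINDOW = 10000

TRUTH_COLUMNS = [
    "category", "chrom", "start", "end",
    "transcript_id", "gene_id", "delta_percent", "direction", "n_sites",
]


@dataclass(frozen=True)
class PlantedSite:
    """A single differentially methylated CpG to plant (DMC)."""

    delta_percent: float
    direction: str = "hyper"
    chrom: str | None = None  # None -> drawn at random
    pos: int | None = None


@dataclass(frozen=True)
class PlantedTile:
    """A 1-kb tile whose CpGs are all shifted (DMR)."""

    delta_percent: float
    direction: str = "hyper"
    chrom: str | None = None
    tile_index: int | None = None  # 0-based tile number on the chromosome


@dataclass(frozen=True)
class PlantedPromoter:
    """A TSS+/-1kb promoter whose CpGs are all shifted (DMP)."""

    delta_percent: float
    direction: str = "hyper"
    transcript_id: str | None = None


@dataclass(frozen=True)
class PlantedCluster:
    """A cluster of n shifted CpGs inside a transcript's TSS+/-10kb window."""

    n_dmcs: int
    delta_percent: float
    direction: str = "hyper"
    transcript_id: str | None = None


@dataclass
class SimConfig:
    """Full description of one synthetic dataset.

    ``baseline_mixture`` is a tuple of ``(weight, alpha, beta)`` Beta
    components for the per-site baseline methylation fraction; defaults
    put 75% of sites in a high mode (Beta(20,1), mean ~0.95) and 25% in a
    low mode (Beta(1,20)), reproducing the bimodal profile of duodenal
    tissue.  ``dispersion`` is the beta-binomial intra-class correlation
    (0 = pure binomial).  ``seed`` is mandatory.
    """

    seed: int
    n_chroms: int = 3
    chrom_length_bp: int = 1_000_000
    cpg_spacing_bp: float = 100.0
    n_transcripts: int = 100
    samples_per_group: int = 3
    mean_coverage: float = 10.0
    coverage_dispersion: float = 50.0  # NB size parameter; larger = closer to Poisson
    dispersion: float = 0.0
    baseline_mixture: tuple = ((0.75, 20.0, 1.0), (0.25, 1.0, 20.0))
    planted_dmc: list = field(default_factory=list)
    planted_dmr_tiles: list = field(default_factory=list)
    planted_dmp_promoters: list = field(default_factory=list)
    planted_hifreq: list = field(default_factory=list)
    expr_coupling_rho: float = 0.0
    case_label: str = "case"
    control_label: str = "control"

    def __post_init__(self) -> None:
        weights = [w for w, _a, _b in self.baseline_mixture]
        if any(not 0 <= w <= 1 for w in weights) or abs(sum(weights) - 1) > 1e-9:
            raise ValueError("baseline mixture weights must lie in [0,1] and sum to 1")
        for plan in (self.planted_dmc, self.planted_dmr_tiles,
                     self.planted_dmp_promoters, self.planted_hifreq):
            for p in plan:
                if not 0 < p.delta_percent <= 100:
                    raise ValueError("delta_percent must lie in (0, 100]")
                if p.direction not in ("hyper", "hypo"):
                    raise ValueError(f"unknown direction {p.direction!r}")
        for p in self.planted_hifreq:
            if p.n_dmcs < 1:
                raise ValueError("n_clustered_dmcs must be >= 1")
        if not 0 <= self.dispersion < 1:
            raise ValueError("dispersion must lie in [0, 1)")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length_bp for i in range(self.n_chroms)}


def _streams(config: SimConfig) -> dict[str, np.random.Generator]:
    names = ["annotation", "positions", "coverage", "baseline", "counts",
             "planting", "expression"]
    children = np.random.SeedSequence(config.seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def simulate_annotation(config: SimConfig) -> pd.DataFrame:
    """Place non-overlapping transcript bodies with random strands and exons."""
    rng = _streams(config)["annotation"]
    chroms = list(config.chrom_sizes)
    per_chrom = np.zeros(len(chroms), dtype=int)
    per_chrom[: config.n_transcripts % len(chroms)] += 1
    per_chrom += config.n_transcripts // len(chroms)

    records = []
    idx = 0
    for chrom, k in zip(chroms, per_chrom):
        if k == 0:
            continue
        lengths = rng.integers(2000, 10001, size=k)
        slack = config.chrom_length_bp - int(lengths.sum())
        if slack < k + 1:
            raise ValueError(
                f"cannot pack {k} transcript bodies of total length "
                f"{int(lengths.sum())} bp into {chrom} "
                f"({config.chrom_length_bp} bp); reduce n_transcripts"
            )
        gaps = rng.multinomial(slack - (k + 1), np.full(k + 1, 1 / (k + 1))) + 1
        start = 1
        for j in range(k):
            start += gaps[j]
            tx_start, tx_end = start, start + int(lengths[j]) - 1
            start = tx_end + 1
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(1, 4))
            exons = _split_exons(tx_start, tx_end, n_ex, rng)
            idx += 1
            records.append(
                dict(
                    transcript_id=f"tx{idx:05d}", gene_id=f"g{idx:05d}",
                    chrom=chrom, strand=strand, tx_start=tx_start,
                    tx_end=tx_end, exons=exons,
                    tss=tx_start if strand == "+" else tx_end,
                )
            )
    df = pd.DataFrame(records, columns=mio.ANNOTATION_COLUMNS)
    return df.sort_values(["chrom", "tx_start"], kind="stable").reset_index(drop=True)


def _split_exons(tx_start: int, tx_end: int, n_ex: int,
                 rng: np.random.Generator) -> tuple:
    length = tx_end - tx_start + 1
    if n_ex == 1 or length < 6 * n_ex:
        return ((tx_start, tx_end),)
    # pick intron midpoints, keep exons >= 2 bp; first/last exon pin the ends
    cuts = np.sort(rng.choice(np.arange(2, length - 2), size=2 * (n_ex - 1),
                              replace=False))
    exons = []
    lo = 0
    for i in range(n_ex - 1):
        exons.append((tx_start + lo, tx_start + int(cuts[2 * i]) - 1))
        lo = int(cuts[2 * i + 1])
    exons.append((tx_start + lo, tx_end))
    return tuple((s, e) for s, e in exons if e >= s)


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def _draw_coverage(rng, mean, size_param, shape) -> np.ndarray:
    p = size_param / (size_param + mean)
    cov = rng.negative_binomial(size_param, p, size=shape)
    while (cov == 0).any():  # truncate at >= 1
        zeros = cov == 0
        cov[zeros] = rng.negative_binomial(size_param, p, size=int(zeros.sum()))
    return cov


def _mixture_baseline(rng, mixture, n) -> np.ndarray:
    weights = np.array([w for w, _a, _b in mixture])
    comp = rng.choice(len(mixture), size=n, p=weights)
    p = np.empty(n)
    for i, (_w, a, b) in enumerate(mixture):
        mask = comp == i
        p[mask] = rng.beta(a, b, size=int(mask.sum()))
    return p


def simulate_counts(config: SimConfig,
                    annotation: pd.DataFrame) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Draw per-sample CpG counts and return them with the truth table.

    Control samples follow the per-site baseline; case samples are
    shifted by the planted delta at planted loci (proportions clamped to
    [0.001, 0.999]).  Planted hyper effects are seeded at lowly
    methylated CpGs and hypo effects at highly methylated ones, so the
    requested delta is realisable — mirroring where such shifts can occur
    biologically.
    """
    streams = _streams(config)
    pos_rng = streams["positions"]
    chrom_sizes = config.chrom_sizes

    chrom_arr, pos_arr = [], []
    for chrom, size in chrom_sizes.items():
        # geometric spacing with the configured mean, min 2 bp (CpG step)
        n_est = int(size / config.cpg_spacing_bp * 1.3) + 10
        steps = pos_rng.geometric(1 / max(config.cpg_spacing_bp - 1, 1), n_est) + 1
        pos = 1 + np.cumsum(steps)
        pos = pos[pos <= size]
        chrom_arr.append(np.full(len(pos), chrom))
        pos_arr.append(pos)
    chrom_all = np.concatenate(chrom_arr)
    pos_all = np.concatenate(pos_arr).astype(np.int64)

    chrom_all, pos_all, planted_delta, planted_dir, truth = _plant_effects(
        config, annotation, chrom_all, pos_all, streams["planting"]
    )
    n_sites = len(pos_all)
    n_samples = 2 * config.samples_per_group

    baseline = _mixture_baseline(streams["baseline"], config.baseline_mixture, n_sites)
    shifted = planted_delta != 0
    if shifted.any():
        # feasible baselines: hyper effects start low, hypo effects start high
        hyper = shifted & (planted_dir > 0)
        hypo = shifted & (planted_dir < 0)
        _w, a_hi, b_hi = max(config.baseline_mixture, key=lambda c: c[1] / (c[1] + c[2]) if c[1] + c[2] else 0)
        _w, a_lo, b_lo = min(config.baseline_mixture, key=lambda c: c[1] / (c[1] + c[2]) if c[1] + c[2] else 0)
        rng_b = streams["baseline"]
        baseline[hyper] = rng_b.beta(a_lo, b_lo, size=int(hyper.sum()))
        baseline[hypo] = rng_b.beta(a_hi, b_hi, size=int(hypo.sum()))

    p_control = np.clip(baseline, 1e-3, 1 - 1e-3)
    p_case = np.clip(baseline + planted_dir * planted_delta / 100.0, 1e-3, 1 - 1e-3)

    cov = _draw_coverage(streams["coverage"], config.mean_coverage,
                         config.coverage_dispersion, (n_sites, n_samples))
    cnt_rng = streams["counts"]
    p_site = np.column_stack(
        [np.repeat(p_control[:, None], config.samples_per_group, axis=1),
         np.repeat(p_case[:, None], config.samples_per_group, axis=1)]
    )
    if config.dispersion > 0:
        d = config.dispersion
        a = p_site * (1 - d) / d
        b = (1 - p_site) * (1 - d) / d
        p_site = cnt_rng.beta(a, b)
    meth = cnt_rng.binomial(cov, p_site)

    order = np.lexsort((pos_all, chrom_all))
    chrom_all, pos_all = chrom_all[order], pos_all[order]
    cov, meth = cov[order], meth[order]

    names = ([f"{config.control_label}_{i + 1}" for i in range(config.samples_per_group)]
             + [f"{config.case_label}_{i + 1}" for i in range(config.samples_per_group)])
    samples = {
        name: pd.DataFrame(
            {
                "chrom": chrom_all, "pos": pos_all,
                "n_meth": meth[:, j], "n_unmeth": cov[:, j] - meth[:, j],
            }
        )
        for j, name in enumerate(names)
    }
    return samples, truth


def _plant_effects(config, annotation, chrom_all, pos_all, rng):
    """Assign planted deltas to sites; inject cluster CpGs where needed."""
    truth_rows = []
    claimed = np.zeros(len(pos_all), dtype=bool)
    blocked = np.zeros(len(pos_all), dtype=bool)  # inside any planted region
    delta = np.zeros(len(pos_all))
    sign = np.zeros(len(pos_all))
    extra_chrom, extra_pos, extra_delta, extra_sign = [], [], [], []

    def in_interval(chrom, lo, hi):
        return (chrom_all == chrom) & (pos_all >= lo) & (pos_all <= hi)

    chroms = list(config.chrom_sizes)

    # --- tiles ---
    for tile in config.planted_dmr_tiles:
        chrom = tile.chrom or chroms[int(rng.integers(len(chroms)))]
        n_tiles = config.chrom_sizes[chrom] // TILE_WINDOW
        k = tile.tile_index if tile.tile_index is not None else int(rng.integers(n_tiles))
        lo, hi = k * TILE_WINDOW + 1, (k + 1) * TILE_WINDOW
        mask = in_interval(chrom, lo, hi)
        s = 1.0 if tile.direction == "hyper" else -1.0
        delta[mask], sign[mask], claimed[mask] = tile.delta_percent, s, True
        blocked |= mask
        truth_rows.append(dict(
            category="DMR", chrom=chrom, start=lo, end=hi, transcript_id="",
            gene_id="", delta_percent=tile.delta_percent,
            direction=tile.direction, n_sites=int(mask.sum()),
        ))

    # --- promoters ---
    used_tx: set[str] = set()
    for prom in config.planted_dmp_promoters:
        rec = _pick_transcript(annotation, prom.transcript_id, used_tx, rng)
        lo = max(1, int(rec.tss) - PROMOTER_FLANK)
        hi = min(config.chrom_sizes[rec.chrom], int(rec.tss) + PROMOTER_FLANK)
        footprint = in_interval(rec.chrom, lo, hi)
        mask = footprint & ~claimed
        s = 1.0 if prom.direction == "hyper" else -1.0
        delta[mask], sign[mask], claimed[mask] = prom.delta_percent, s, True
        blocked |= footprint
        truth_rows.append(dict(
            category="DMP", chrom=rec.chrom, start=lo, end=hi,
            transcript_id=rec.transcript_id, gene_id=rec.gene_id,
            delta_percent=prom.delta_percent, direction=prom.direction,
            n_sites=int(mask.sum()),
        ))

    # --- high-frequency clusters ---
    for clu in config.planted_hifreq:
        rec = _pick_transcript(annotation, clu.transcript_id, used_tx, rng)
        lo = max(1, int(rec.tss) - CLUSTER_WINDOW)
        hi = min(config.chrom_sizes[rec.chrom], int(rec.tss) + CLUSTER_WINDOW)
        footprint = in_interval(rec.chrom, lo, hi)
        blocked |= footprint
        avail = np.flatnonzero(footprint & ~claimed)
        s = 1.0 if clu.direction == "hyper" else -1.0
        take = avail[rng.permutation(len(avail))[: clu.n_dmcs]]
        delta[take], sign[take], claimed[take] = clu.delta_percent, s, True
        missing = clu.n_dmcs - len(take)
        if missing > 0:  # inject fresh CpGs into the window
            occupied = set(pos_all[chrom_all == rec.chrom].tolist())
            free = [p for p in range(lo, hi + 1) if p not in occupied]
            new = rng.choice(free, size=missing, replace=False)
            extra_chrom += [rec.chrom] * missing
            extra_pos += [int(p) for p in new]
            extra_delta += [clu.delta_percent] * missing
            extra_sign += [s] * missing
        truth_rows.append(dict(
            category="HIFREQ", chrom=rec.chrom, start=lo, end=hi,
            transcript_id=rec.transcript_id, gene_id=rec.gene_id,
            delta_percent=clu.delta_percent, direction=clu.direction,
            n_sites=clu.n_dmcs,
        ))

    # --- single DMCs, disjoint from everything planted above ---
    free_idx = np.flatnonzero(~claimed & ~blocked)
    rng.shuffle(free_idx)
    cursor = 0
    for site in config.planted_dmc:
        s = 1.0 if site.direction == "hyper" else -1.0
        if site.pos is not None:
            mask = (chrom_all == site.chrom) & (pos_all == site.pos)
            if not mask.any():
                raise ValueError(f"no CpG at {site.chrom}:{site.pos} to plant")
            i = int(np.flatnonzero(mask)[0])
        else:
            i = int(free_idx[cursor])
            cursor += 1
        delta[i], sign[i], claimed[i] = site.delta_percent, s, True
        truth_rows.append(dict(
            category="DMC", chrom=chrom_all[i], start=int(pos_all[i]),
            end=int(pos_all[i]), transcript_id="", gene_id="",
            delta_percent=site.delta_percent, direction=site.direction,
            n_sites=1,
        ))

    if extra_pos:
        chrom_all = np.concatenate([chrom_all, np.array(extra_chrom)])
        pos_all = np.concatenate([pos_all, np.array(extra_pos, dtype=np.int64)])
        delta = np.concatenate([delta, np.array(extra_delta)])
        sign = np.concatenate([sign, np.array(extra_sign)])

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return chrom_all, pos_all, delta, sign, truth


def _pick_transcript(annotation, transcript_id, used: set, rng):
    if len(annotation) == 0:
        raise ValueError("cannot plant transcript-anchored effects without annotation")
    if transcript_id is not None:
        rows = annotation[annotation["transcript_id"] == transcript_id]
        if len(rows) == 0:
            raise ValueError(f"transcript {transcript_id!r} not in annotation")
        used.add(transcript_id)
        return rows.iloc[0]
    avail = annotation[~annotation["transcript_id"].isin(used)]
    if len(avail) == 0:
        raise ValueError("no unused transcripts left for planting")
    rec = avail.iloc[int(rng.integers(len(avail)))]
    used.add(rec.transcript_id)
    return rec


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(truth: pd.DataFrame, annotation: pd.DataFrame,
                        rho: float, seed: int,
                        noise_sd: float = 0.0,
                        lfc_scale: float = 1.5) -> pd.DataFrame:
    """Generate per-gene log2 fold-changes coupled to planted TSS-proximal deltas.

    Genes owning a planted promoter or DMC-cluster effect receive a
    log2FC whose Spearman correlation with the signed planted delta
    approaches ``rho`` (via a Gaussian copula; the latent Pearson
    correlation is ``2 sin(pi rho / 6)``).  All other annotated genes get
    null-centred noise.
    """
    if not -1 <= rho <= 1:
        raise ValueError("|rho| must be <= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 17]))

    anchored = truth[truth["transcript_id"] != ""].copy() if len(truth) else truth
    rows = []
    if len(anchored):
        signed = np.where(anchored["direction"] == "hyper", 1.0, -1.0) * anchored["delta_percent"]
        per_gene = pd.Series(signed.to_numpy(), index=anchored["gene_id"].to_numpy())
        per_gene = per_gene.groupby(level=0).mean()
        d = per_gene.to_numpy(dtype=float)
        k = len(d)
        # rank-based coupling: ties in d broken by an independent jitter draw
        jitter = rng.normal(0, 1e-9, k)
        ranks = np.argsort(np.argsort(d + jitter)) + 1
        z = _norm_ppf(ranks / (k + 1))
        r = 2 * np.sin(np.pi * rho / 6)
        eps = rng.standard_normal(k)
        y = r * z + np.sqrt(max(0.0, 1 - r * r)) * eps
        if noise_sd > 0:
            y = y + rng.normal(0, noise_sd, k)
        lfc = y * lfc_scale
        padj = np.clip(2 * _norm_sf(np.abs(y) / 0.5), 1e-12, 1.0)
        for gid, l, p in zip(per_gene.index, lfc, padj):
            rows.append(dict(gene_id=gid, log2_fold_change=float(l),
                             adjusted_p=float(p), de_flag=bool(p < 0.05)))

    planted_genes = set(r["gene_id"] for r in rows)
    for gid in annotation["gene_id"]:
        if gid in planted_genes:
            continue
        l = float(rng.normal(0, 0.3))
        rows.append(dict(gene_id=gid, log2_fold_change=l,
                         adjusted_p=float(rng.uniform(0.05, 1.0)), de_flag=False))
    return pd.DataFrame(rows, columns=mio.EXPRESSION_COLUMNS)


def _norm_ppf(q):
    from scipy.stats import norm
    return norm.ppf(q)


def _norm_sf(x):
    from scipy.stats import norm
    return norm.sf(x)


# ---------------------------------------------------------------------------
# Dataset writer
# ---------------------------------------------------------------------------

def write_dataset(config: SimConfig, outdir) -> dict[str, Path]:
    """Simulate and write a complete dataset; returns the emitted paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation = simulate_annotation(config)
    samples, truth = simulate_counts(config, annotation)
    expression = simulate_expression(truth, annotation, config.expr_coupling_rho,
                                     config.seed)

    paths: dict[str, Path] = {}
    for name, calls in samples.items():
        p = outdir / f"{name}.cov"
        mio.write_bismark_cov(calls, p)
        paths[name] = p
    paths["annotation"] = outdir / "annotation.bed12"
    mio.write_bed12(annotation, paths["annotation"])
    design = mio.GroupDesign(
        groups={n: (config.control_label if n.startswith(config.control_label)
                    else config.case_label) for n in samples},
        reference=config.control_label,
    )
    paths["design"] = outdir / "design.tsv"
    mio.write_design(design, paths["design"])
    paths["truth"] = outdir / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["expression"] = outdir / "expression.tsv"
    expression.to_csv(paths["expression"], sep="\t", index=False)
    return paths
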