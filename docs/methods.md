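# Methods

## The differential test

Each locus is tested with a binomial logistic regression of methylated
read counts on the group indicator. Writing m_g and n_g for the pooled
methylated count and coverage of group g, the maximum-likelihood fit of
the group model assigns each group its pooled proportion p̂_g = m_g/n_g,
and the null model the overall proportion; the likelihood-ratio
statistic is therefore computed in closed form as the deviance
difference

    G = 2 Σ_cells O ln(O/E),   df = 1,

over the pooled 2×2 (methylated/unmethylated × group) table, with the
0·ln 0 = 0 convention. Complete separation (one group fully methylated,
the other fully unmethylated) yields the finite deviance limit rather
than an error. Because the samples enter only through their pooled
counts, the test is exchangeable under within-group sample permutations;
this and the equivalence with an explicitly fitted GLM are covered by
tests. The test assumes binomial counts within groups — replicate
overdispersion is not corrected, matching common practice for this
design; the data generator exposes a beta-binomial mode for stress
testing the consequences.

The methylation difference is reported in percentage points as the
coverage-weighted case-minus-control difference,
100·(m_case/n_case − m_ctrl/n_ctrl). An unweighted per-sample-mean
variant would weight shallow samples equally; coverage weighting was
chosen because it matches the quantity the test itself compares.

### Multiplicity and calling

P-values are converted to q-values by Benjamini–Hochberg step-up with a
stable sort, so tied p receive equal q. `adjust_fdr` accepts any
callable `p -> q` as an alternative procedure (e.g. a sliding-linear-
model implementation), preserving input order. Default call thresholds
are q ≤ 0.01 and |Δmeth| ≥ 25 points (both inclusive); they are
deliberately below the strict 30-point / 10-kb filters used later for
top-DMC gene selection, and are configurable everywhere.

### Filters before testing

`unite` keeps loci covered at ≥ `min_coverage` (default 10×) in **all**
samples and removes loci whose coverage exceeds the per-sample 99.9th
percentile in any sample, a standard guard against PCR-duplicate pileups.
Both tallies are logged. The upper filter uses each sample's own
coverage distribution; on toy inputs with a handful of loci it should be
disabled (`max_coverage_percentile=100`).

## Genome geometry

Internal coordinates are 1-based inclusive, so printed genomic windows
such as [1,203,001, 1,204,000] are directly representable; BED I/O
converts at the boundary. Tiles are consecutive non-overlapping windows
anchored at k·W+1 (W = 1000 by default), truncated at chromosome ends.
Promoters are TSS ± 1 kb, strand-aware (TSS = transcript start on +,
end on −), clipped to chromosome bounds, with identical isoform
intervals deduplicated to the lexicographically smallest owner.

Region counts are sums of contained site counts per sample (prefix sums
per chromosome); regions with no covered CpG are dropped and logged, and
aggregation conserves totals — checked by brute-force re-summation.

Nearest-TSS distance is signed in transcript orientation (negative =
upstream). For an interval locus the distance is the minimum over its
bases, 0 if it contains the TSS; min-edge was chosen over midpoint
because it is well defined for loci larger than the flank and matches
the intuition "how far must one travel to reach the TSS". Equidistant
ties resolve to the lexicographically smallest transcript id, making the
annotation deterministic. Feature classes are assigned with precedence
promoter > exon > intron > intergenic (configurable order); intron means
inside a transcript body but overlapping no exon of any transcript.

## Gene-level scores

Threshold semantics follow their verbal definitions literally: top DMC
genes use strict inequalities (|TSS distance| < 10,000 bp and
|Δmeth| > 30 points), high-frequency genes an inclusive one (≥ 5 DMCs
within TSS ± 10 kb, boundary included). DMCs are counted per transcript
with multi-assignment — a DMC inside two transcripts' windows counts for
both — because per-transcript counting implies it; nearest-only counting
is available by flag. Dominant direction is the majority sign of member
differences; exact ties are labelled `mixed` and never counted as hyper
or hypo. Venn partitions are computed exactly for 2–4 named sets
(members land in exactly one partition) with pairwise Jaccard indices;
cross-category overlaps (DMC/DMR/DMP) can require direction agreement.

## Methylation–expression integration

The per-gene methylation summary for correlation is the unweighted mean
of member DMC differences within TSS ± 10 kb of any of the gene's
transcripts, requiring ≥ 2 members (median available by flag; the window
matches the high-frequency framework for consistency). Correlation with
log2 fold-changes is tie-aware Spearman with the t-approximation
p-value; the paired table is emitted for audit. Enrichment is the
one-sided Fisher exact test of the study set against each term
restricted to the universe, BH-adjusted across terms; the default
universe is the set of genes with at least one *tested* CpG near a TSS,
because the background must reflect testability.

## The synthetic data generator

The generator emulates the structure of duodenal WGBS count data, not
reads: CpG positions with geometric spacing (mean 100 bp), coverage from
a negative binomial (Poisson-gamma, size 50) truncated at ≥ 1 whose mode
sits at the configured mean (default 10×, matching the empirical ~10×
profile), and per-site baseline methylation from a two-component Beta
mixture — weight 0.75 on Beta(20, 1) (high mode) and 0.25 on Beta(1, 20)
(low mode) — reproducing the bimodal %methylation histogram with its
major peak at 95–100 % and secondary peak at 0–5 %. Counts are binomial
given the site proportion; `dispersion` (beta-binomial intra-class
correlation) defaults to 0 because the downstream test assumes binomial
counts, and is exposed for overdispersion stress tests. Group sizes
default to 3 vs 3, the cohort scale the pipeline targets.

Planted effects shift the case group by a configured percentage-point
delta at single CpGs, whole 1-kb tiles, whole promoters, or as n-site
clusters inside a transcript's TSS ± 10 kb window (extra CpGs are
injected if the window holds too few). So that a requested delta is
realisable, hyper effects draw their baseline from the low mixture
component and hypo effects from the high component — mirroring where
such shifts can occur biologically (a 95 %-methylated CpG cannot gain 40
points); proportions are finally clamped to [0.001, 0.999]. Planted
categories are mutually disjoint, and every planted entity is recorded
once in the truth table. Each generation stage draws from its own RNG
stream spawned from the master seed, so identical configurations give
byte-identical outputs and adding a stage does not perturb earlier draws.

Expression tables couple per-gene log2 fold-changes to the signed
planted deltas through a Gaussian copula: the latent Pearson correlation
is set to 2·sin(πρ/6) so the *Spearman* correlation approaches the
requested ρ; unplanted genes get null-centred noise. At ρ = −1 with no
extra noise the ranks are exactly anti-monotone.

What the generator does **not** model: read-level artefacts (bisulfite
conversion failure, mapping bias, SNPs), non-CpG methylation, spatial
correlation of methylation along the genome beyond the planted regions,
cell-type mixture, and replicate overdispersion unless requested.
Passing recovery tests therefore demonstrates correctness of the
statistical machinery under the stated model, not robustness to those
real-data complications.

## Validation experiment sizes

The standard experiments (`methdiffscan.validation`) use problem sizes
chosen to estimate each quantity stably in seconds on one CPU: 20,000
tested null CpGs for calibration (drawn from ~1 M raw sites, since only
~2 % of sites at mean 10× pass a 10×-in-all-samples filter); 500 planted
sites among ~20k nulls at 30× over 10 seeds for recall/FDR; 20 planted
6-DMC clusters and 20 null seeds for high-frequency recovery and
specificity; 100 seeds at n = 15 genes for the expression-coupling
recovery. The p-value uniformity check uses a mid-range Beta(5, 5)
baseline: at the extreme bimodal baselines the test's null distribution
is visibly discrete at 10–30× coverage (the χ² approximation needs
adequate expected counts), while the aggregate type-I error remains
nominal under the bimodal profile — which is what the calibration
experiment measures.

## Numerical and degenerate-input choices

- 0·ln 0 = 0 throughout the deviance; the statistic is floored at 0
  against floating-point cancellation.
- Identical proportions give statistic exactly 0 and p = 1.
- `adjust_fdr` rejects NaN p-values outright rather than propagating.
- Zero-coverage records are dropped at parse time (counted and logged);
  a stored %meth disagreeing with its counts by > 0.5 points warns, and
  the counts win.
- Bismark coverage files may be 1-based (start == end) or 0-based
  half-open (end == start + 1); the dialect is autodetected per file and
  must be consistent within it.
- PCA centres each locus across samples and orders components by
  explained variance; a constant matrix is rejected (no variance).
- Empty locus sets are errors where a proportion would be undefined
  (feature proportions), and empty results elsewhere are valid empty
  tables.

## Known limitations

- No covariates or paired designs: the contrast is strictly two-group,
  df = 1.
- No overdispersion correction in the test; with strongly overdispersed
  replicates the FDR is anti-conservative (the generator's beta-binomial
  mode can quantify this).
- The sliding-linear-model FDR variant used by some pipelines is a
  plug-in slot, not an implementation, so q-values near the threshold
  may differ from pipelines using it.
- Interval queries use in-memory structures sized for desk-scale
  analyses (up to a few million CpGs), not for many-genome scans.
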