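"""Differential-methylation testing on united count matrices.

Each locus (a CpG site, a 1-kb tile, or a promoter) is tested by a
binomial logistic regression of the methylated fraction on the group
indicator.  With a single binary covariate the maximum-likelihood fit has
closed form (each group's fitted proportion is its pooled proportion), so
the likelihood-ratio statistic

    G = deviance(null) - deviance(group model)
      = 2 * sum_cells O * ln(O / E)

equals the G statistic of the pooled 2x2 (methylated/unmethylated x
group) table and is referred to a chi-square with 1 degree of freedom.
The methylation difference is reported in percentage points, signed as
case (patient) minus control, using coverage-weighted group percentages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GroupDesign

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["chrom", "start", "end", "meth_diff", "statistic", "df",
                  "p_value", "q_value", "direction"]


@dataclass
class UnitedMatrix:
    """Loci x samples methylation counts with an attached group design.

    ``loci`` has columns ``chrom, start, end`` (1-based inclusive; a CpG
    site has start == end).  ``meth`` and ``cov`` are (n_loci, n_samples)
    integer arrays aligned with ``samples``.
    """

    loci: pd.DataFrame
    meth: np.ndarray
    cov: np.ndarray
    samples: list[str]
    design: GroupDesign

    def __post_init__(self) -> None:
        if self.meth.shape != self.cov.shape:
            raise ValueError("meth and cov shapes differ")
        if self.meth.shape[1] != len(self.samples):
            raise ValueError("sample dimension mismatch")
        if (self.meth > self.cov).any():
            raise ValueError("methylated count exceeds coverage")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def group_columns(self, group: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.samples)
                         if self.design.groups[s] == group])

    def percent(self) -> pd.DataFrame:
        """Per-locus per-sample methylation percentages."""
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.meth / self.cov
        return pd.DataFrame(pct, columns=self.samples)


def unite(samples: dict[str, pd.DataFrame], design: GroupDesign,
          min_coverage: int = 10,
          max_coverage_percentile: float = 99.9) -> UnitedMatrix:
    """Intersect per-sample calls into a loci x samples count matrix.

    Keeps loci covered at >= ``min_coverage`` in every sample and drops
    loci whose coverage exceeds the per-sample ``max_coverage_percentile``
    cutoff in any sample (a PCR-duplicate guard).  Both filter tallies
    are logged.
    """
    missing = [s for s in design.samples if s not in samples]
    if missing:
        raise ValueError(f"samples missing from input: {missing}")
    order = design.samples

    frames = []
    for name in order:
        df = samples[name]
        f = df.set_index(["chrom", "pos"])[["n_meth", "n_unmeth"]]
        if f.index.duplicated().any():
            raise ValueError(f"duplicate positions in sample {name!r}")
        frames.append(f)
    joined = pd.concat(frames, axis=1, join="inner", keys=order)
    n_common = len(joined)
    if n_common == 0:
        raise ValueError(
            "no loci shared by all samples; consider lowering min_coverage "
            "or checking chromosome naming"
        )

    meth = np.column_stack([joined[(s, "n_meth")].to_numpy() for s in order])
    unmeth = np.column_stack([joined[(s, "n_unmeth")].to_numpy() for s in order])
    cov = meth + unmeth

    keep_min = (cov >= min_coverage).all(axis=1)
    # upper cutoff per sample from its own full coverage distribution
    cutoffs = np.array([
        np.percentile((samples[s]["n_meth"] + samples[s]["n_unmeth"]).to_numpy(),
                      max_coverage_percentile)
        for s in order
    ])
    keep_max = (cov <= cutoffs[None, :]).all(axis=1)
    keep = keep_min & keep_max
    logger.info(
        "unite: %d common loci; dropped %d below %dx, %d above the %.2f "
        "percentile", n_common, int((~keep_min).sum()), min_coverage,
        int((keep_min & ~keep_max).sum()), max_coverage_percentile,
    )
    if not keep.any():
        raise ValueError(
            f"no loci pass min_coverage={min_coverage} in all samples; "
            "consider lowering min_coverage"
        )

    idx = joined.index[keep]
    loci = pd.DataFrame(
        {
            "chrom": idx.get_level_values("chrom"),
            "start": idx.get_level_values("pos").astype(np.int64),
            "end": idx.get_level_values("pos").astype(np.int64),
        }
    )
    mat = UnitedMatrix(
        loci=loci.reset_index(drop=True), meth=meth[keep], cov=cov[keep],
        samples=list(order), design=design,
    )
    return _sort_matrix(mat)


def _sort_matrix(mat: UnitedMatrix) -> UnitedMatrix:
    order = np.lexsort((mat.loci["start"].to_numpy(), mat.loci["chrom"].to_numpy()))
    return UnitedMatrix(
        loci=mat.loci.iloc[order].reset_index(drop=True),
        meth=mat.meth[order], cov=mat.cov[order],
        samples=mat.samples, design=mat.design,
    )


def _g_statistic(m1, c1, m2, c2):
    """Vectorized pooled-table G statistic with the 0*ln(0) = 0 convention."""
    m1, c1 = np.asarray(m1, float), np.asarray(c1, float)
    m2, c2 = np.asarray(m2, float), np.asarray(c2, float)
    u1, u2 = c1 - m1, c2 - m2
    tot = c1 + c2
    mt, ut = m1 + m2, u1 + u2

    def term(o, e):
        with np.errstate(divide="ignore", invalid="ignore"):
            t = o * np.log(o / e)
        return np.where(o == 0, 0.0, t)

    g = 2.0 * (
        term(m1, c1 * mt / tot) + term(u1, c1 * ut / tot)
        + term(m2, c2 * mt / tot) + term(u2, c2 * ut / tot)
    )
    return np.maximum(g, 0.0)


def lrt_diff_test(meth_case, cov_case, meth_ctrl, cov_ctrl):
    """Binomial logistic-regression LRT for one locus.

    Parameters are per-sample methylated counts and coverages for the
    case and control groups.  Returns ``(statistic, p_value, meth_diff)``
    where ``meth_diff`` is the coverage-weighted case-minus-control
    difference in percentage points.  Complete separation yields the
    finite deviance limit, not an error.
    """
    meth_case, cov_case = np.atleast_1d(meth_case), np.atleast_1d(cov_case)
    meth_ctrl, cov_ctrl = np.atleast_1d(meth_ctrl), np.atleast_1d(cov_ctrl)
    if len(meth_case) == 0 or len(meth_ctrl) == 0:
        raise ValueError("both groups must contain at least one sample")
    if (np.concatenate([cov_case, cov_ctrl]) < 1).any():
        raise ValueError("every cell must have coverage >= 1")
    m1, c1 = float(meth_case.sum()), float(cov_case.sum())
    m2, c2 = float(meth_ctrl.sum()), float(cov_ctrl.sum())
    g = float(_g_statistic(m1, c1, m2, c2))
    p = float(stats.chi2.sf(g, df=1))
    diff = 100.0 * (m1 / c1 - m2 / c2)
    return g, p, diff


def diff_test(matrix: UnitedMatrix) -> pd.DataFrame:
    """Run the per-locus LRT across a united matrix (vectorized)."""
    case_cols = matrix.group_columns(matrix.design.case)
    ctrl_cols = matrix.group_columns(matrix.design.reference)
    if len(case_cols) == 0 or len(ctrl_cols) == 0:
        raise ValueError("both groups need at least one sample")
    m1 = matrix.meth[:, case_cols].sum(axis=1)
    c1 = matrix.cov[:, case_cols].sum(axis=1)
    m2 = matrix.meth[:, ctrl_cols].sum(axis=1)
    c2 = matrix.cov[:, ctrl_cols].sum(axis=1)
    g = _g_statistic(m1, c1, m2, c2)
    out = matrix.loci.copy()
    out["meth_diff"] = 100.0 * (m1 / c1 - m2 / c2)
    out["statistic"] = g
    out["df"] = 1
    out["p_value"] = stats.chi2.sf(g, df=1)
    out["q_value"] = np.nan
    out["direction"] = "ns"
    return out


def adjust_fdr(p_values, method="bh"):
    """FDR adjustment; default Benjamini-Hochberg step-up q-values.

    ``method`` may be ``"bh"`` or a callable implementing an alternative
    procedure (e.g. a SLIM plug-in) with signature ``p -> q``; output
    order always matches input order.
    """
    p = np.asarray(p_values, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if callable(method):
        q = np.asarray(method(p), dtype=float)
        if q.shape != p.shape:
            raise ValueError("FDR plug-in returned a wrong-shaped vector")
        return q
    if method != "bh":
        raise ValueError(f"unknown FDR method {method!r}")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def call_differential(results: pd.DataFrame, q_max: float = 0.01,
                      min_abs_diff: float = 25.0) -> pd.DataFrame:
    """Assign hyper / hypo / ns calls by q-value and absolute difference.

    A locus is called iff ``q <= q_max`` and ``|meth_diff| >= min_abs_diff``;
    direction follows the sign of the difference (case minus control).
    Returns a copy with the ``direction`` column filled.
    """
    if results["q_value"].isna().any():
        raise ValueError("q-values must be filled before calling; run adjust_fdr")
    out = results.copy()
    called = (out["q_value"] <= q_max) & (out["meth_diff"].abs() >= min_abs_diff)
    out["direction"] = np.where(
        called & (out["meth_diff"] > 0), "hyper",
        np.where(called & (out["meth_diff"] < 0), "hypo", "ns"),
    )
    return out


def called(results: pd.DataFrame) -> pd.DataFrame:
    """The subset of loci called differential (direction != ns)."""
    return results[results["direction"] != "ns"]


def pca_samples(percent_matrix: pd.DataFrame):
    """Locus-centred PCA of samples on the %methylation matrix.

    ``percent_matrix`` is loci x samples.  Returns ``(coords, varfrac)``:
    sample coordinates on the principal components (samples x PCs) and
    the fraction of variance each component explains, in decreasing
    order.
    """
    x = percent_matrix.to_numpy(dtype=float).T  # samples x loci
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 loci")
    xc = x - x.mean(axis=0, keepdims=True)
    if not np.any(xc):
        raise ValueError("constant matrix has no variance to decompose")
    u, s, _vt = np.linalg.svd(xc, full_matrices=False)
    coords = u * s
    varfrac = s**2 / (s**2).sum()
    n_pc = coords.shape[1]
    return (
        pd.DataFrame(coords, index=percent_matrix.columns,
                     columns=[f"PC{i + 1}" for i in range(n_pc)]),
        varfrac,
    )
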