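"""Normalization, contrast testing and the three selection filters.

The testing stage turns a raw count matrix into the differentially
expressed gene (DEG) universe in four steps:

1. median-of-ratios size factors and the normalized matrix;
2. a testability flag (enough nonzero observations to test at all) and a
   low-count filter (total normalized count over all samples must exceed a
   threshold, 48 by default);
3. negative-binomial Wald tests of the nine condition contrasts, with
   Benjamini-Hochberg adjustment per contrast; a gene is a DEG when its
   smallest adjusted p-value over the nine contrasts is at or below alpha
   (0.02 by default);
4. an annotation filter keeping genes whose best database hit has
   E-value <= 9e-4.

The negative-binomial model is mean mu, variance mu + a*mu^2 with a
per-gene dispersion ``a`` estimated by method of moments across the design
cells.  The Wald statistic for a contrast of two sample groups is the log2
ratio of normalized group means over its delta-method standard error,
referred to a standard normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import (
    NINE_CONTRASTS,
    AnnotationBundle,
    CountMatrix,
    SampleDesign,
)

__all__ = [
    "NormalizedMatrix",
    "size_factors",
    "normalize",
    "testable_flags",
    "low_count_filter",
    "estimate_dispersions",
    "nb_contrast_test",
    "contrast_table",
    "bh_adjust",
    "deg_selection",
    "annotation_filter",
    "filter_report",
    "DEFAULT_COUNT_TOTAL",
    "DEFAULT_DEG_ALPHA",
    "DEFAULT_ANNOT_EVALUE",
]

DEFAULT_COUNT_TOTAL = 48.0
DEFAULT_DEG_ALPHA = 0.02
DEFAULT_ANNOT_EVALUE = 9e-4

_MIN_DISPERSION = 1e-8


@dataclass(frozen=True)
class NormalizedMatrix:
    """Size-factor-scaled counts with the factors that produced them."""

    values: pd.DataFrame
    size_factors: pd.Series

    def __post_init__(self) -> None:
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be strictly positive")


def size_factors(counts: CountMatrix, zero_tolerant_fraction: float = 0.2) -> pd.Series:
    """Median-of-ratios size factors.

    Reference genes are those with no zero count; each sample's factor is
    the median over reference genes of count / geometric mean of that gene.
    When no zero-free gene exists, genes with zeros in at most
    ``zero_tolerant_fraction`` of samples are used instead, with zeros
    excluded from their geometric means; if that also fails, an error asks
    for a larger fixture.
    """
    v = counts.values.to_numpy(dtype=float)
    zero_free = (v > 0).all(axis=1)
    if zero_free.any():
        ref = v[zero_free]
        log_gm = np.log(ref).mean(axis=1)
        ratios = np.log(ref) - log_gm[:, None]
        factors = np.exp(np.median(ratios, axis=0))
    else:
        zero_frac = (v == 0).mean(axis=1)
        usable = zero_frac <= zero_tolerant_fraction
        if not usable.any():
            raise ValueError(
                "no gene with sufficiently few zero counts for the "
                "median-of-ratios method; supply a larger matrix or "
                f"raise zero_tolerant_fraction (> {zero_tolerant_fraction})"
            )
        ref = v[usable]
        with np.errstate(divide="ignore"):
            logs = np.where(ref > 0, np.log(ref), np.nan)
        log_gm = np.nanmean(logs, axis=1)
        ratios = logs - log_gm[:, None]
        factors = np.exp(np.nanmedian(ratios, axis=0))
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def normalize(counts: CountMatrix, factors: pd.Series | None = None) -> NormalizedMatrix:
    """Counts divided by their column's size factor."""
    if factors is None:
        factors = size_factors(counts)
    factors = factors.reindex(counts.sample_ids)
    if factors.isna().any():
        raise ValueError("size factors missing for some samples")
    return NormalizedMatrix(counts.values / factors, factors)


def testable_flags(counts: CountMatrix, min_nonzero_samples: int = 2) -> pd.Series:
    """True when a gene has enough nonzero observations to be tested.

    A gene that is zero everywhere, or nonzero in fewer than
    ``min_nonzero_samples`` samples, cannot support the contrast test.
    """
    nonzero = (counts.values > 0).sum(axis=1)
    return (nonzero >= min_nonzero_samples).rename("testable")


def low_count_filter(
    norm: NormalizedMatrix, threshold: float = DEFAULT_COUNT_TOTAL
) -> pd.Series:
    """True when the gene's total normalized count over all samples exceeds
    ``threshold`` (totals at or below the threshold are discarded)."""
    total = norm.values.sum(axis=1)
    return (total > threshold).rename("passed_count_filter")


def estimate_dispersions(
    norm: NormalizedMatrix, design: SampleDesign, prior_weight: float = 0.5
) -> pd.Series:
    """Per-gene method-of-moments dispersion pooled across the design cells.

    With cell means m_c and within-cell sample variances s2_c on normalized
    counts, the moment relation E[s2_c] = m_c + a * m_c**2 gives the
    through-origin estimator a = sum_c(s2_c - m_c) / sum_c(m_c**2), clipped
    below at 1e-8.  Pooling across cells keeps the estimate valid for genes
    whose mean differs between conditions.

    The per-gene estimate carries only ~one degree of freedom per cell, so
    it is shrunk toward the across-gene mean dispersion with weight
    ``prior_weight`` (0 disables shrinkage); without it the Wald test
    downstream is anticonservative for genes whose dispersion is
    underestimated by chance.
    """
    if not 0.0 <= prior_weight <= 1.0:
        raise ValueError("prior_weight must be in [0, 1]")
    cond = design.condition_labels()
    groups = norm.values.T.groupby(cond.reindex(norm.values.columns).to_numpy())
    cell_means = groups.mean().T  # genes x cells
    cell_vars = groups.var(ddof=1).T
    num = (cell_vars - cell_means).sum(axis=1)
    den = (cell_means**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = num / den
    alpha = alpha.fillna(_MIN_DISPERSION).clip(lower=_MIN_DISPERSION)
    if prior_weight > 0 and len(alpha) > 1:
        alpha = (1.0 - prior_weight) * alpha + prior_weight * alpha.mean()
    return alpha.rename("dispersion")


def nb_contrast_test(
    counts: CountMatrix,
    design: SampleDesign,
    contrast: tuple[str, str],
    norm: NormalizedMatrix | None = None,
    dispersions: pd.Series | None = None,
) -> pd.DataFrame:
    """Wald test of one condition contrast for every gene.

    Returns a frame with columns ``log2_fold_change`` (second condition
    over first) and ``p_raw``.  Genes with zero total count in both groups
    are untestable for the contrast: fold change 0, p 1.
    """
    if norm is None:
        norm = normalize(counts)
    if dispersions is None:
        dispersions = estimate_dispersions(norm, design)

    cond_a, cond_b = contrast
    samples_a = design.samples_in_condition(cond_a)
    samples_b = design.samples_in_condition(cond_b)
    if not samples_a or not samples_b:
        raise ValueError(f"contrast {contrast} references an empty condition")

    alpha = dispersions.to_numpy()
    sf = norm.size_factors

    def _group_stats(samples: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """Normalized group mean and the variance of its natural log."""
        sub = norm.values[samples].to_numpy()
        sfs = sf[samples].to_numpy()
        n = len(samples)
        q = sub.mean(axis=1)
        # Var(count_s / sf_s) = (mu_s + a mu_s^2) / sf_s^2 with mu_s = sf_s q
        var_norm = (sfs[None, :] * q[:, None] + alpha[:, None] * (sfs[None, :] * q[:, None]) ** 2) / sfs[None, :] ** 2
        var_qhat = var_norm.sum(axis=1) / n**2
        with np.errstate(divide="ignore", invalid="ignore"):
            var_log = var_qhat / q**2
        return q, var_log

    q_a, vlog_a = _group_stats(samples_a)
    q_b, vlog_b = _group_stats(samples_b)

    testable = (q_a > 0) & (q_b > 0)
    ln2 = np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc_all = np.log2(q_b / q_a)
        se = np.sqrt(vlog_a + vlog_b) / ln2
        z = np.where(se > 0, lfc_all / se, 0.0)
    p_all = 2.0 * stats.norm.sf(np.abs(z))

    lfc = np.where(testable, lfc_all, 0.0)
    p = np.where(testable, p_all, 1.0)
    # exact null: identical group means give statistic 0, p exactly 1
    p = np.where(testable & (q_a == q_b), 1.0, p)
    lfc = np.where(testable & (q_a == q_b), 0.0, lfc)

    return pd.DataFrame(
        {"log2_fold_change": lfc, "p_raw": np.clip(p, 0.0, 1.0)},
        index=counts.gene_ids,
    )


def bh_adjust(p_values: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjustment of a p-value vector."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return p_values
    if np.any((arr < 0) | (arr > 1) | np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    adj = multipletests(arr, method="fdr_bh")[1]
    if isinstance(p_values, pd.Series):
        return pd.Series(adj, index=p_values.index, name=p_values.name)
    return adj


def contrast_table(
    counts: CountMatrix,
    design: SampleDesign,
    contrasts: tuple[tuple[str, str], ...] = NINE_CONTRASTS,
    norm: NormalizedMatrix | None = None,
) -> pd.DataFrame:
    """Test every contrast and adjust p-values per contrast across genes.

    Returns a long-format frame with columns ``gene_id``, ``contrast``,
    ``log2_fold_change``, ``p_raw``, ``p_adj``.
    """
    if norm is None:
        norm = normalize(counts)
    dispersions = estimate_dispersions(norm, design)
    frames = []
    for cond_a, cond_b in contrasts:
        res = nb_contrast_test(
            counts, design, (cond_a, cond_b), norm=norm, dispersions=dispersions
        )
        res = res.copy()
        res["p_adj"] = bh_adjust(res["p_raw"].to_numpy())
        res["contrast"] = f"{cond_a}:{cond_b}"
        res.index.name = "gene_id"
        frames.append(res.reset_index())
    return pd.concat(frames, ignore_index=True)[
        ["gene_id", "contrast", "log2_fold_change", "p_raw", "p_adj"]
    ]


def deg_selection(
    contrasts: pd.DataFrame, alpha: float = DEFAULT_DEG_ALPHA
) -> pd.Series:
    """True when a gene's smallest adjusted p over the contrasts is <= alpha."""
    min_padj = contrasts.groupby("gene_id")["p_adj"].min()
    return (min_padj <= alpha).rename("passed_deg_filter")


def annotation_filter(
    genes: list[str],
    bundle: AnnotationBundle,
    evalue_max: float = DEFAULT_ANNOT_EVALUE,
) -> pd.Series:
    """True when the gene has a best hit with E-value <= ``evalue_max``."""
    flags = {
        g: (bundle.best_evalue(g) is not None and bundle.best_evalue(g) <= evalue_max)
        for g in genes
    }
    return pd.Series(flags, name="passed_annotation_filter")


def filter_report(
    counts: CountMatrix,
    design: SampleDesign,
    bundle: AnnotationBundle | None = None,
    count_threshold: float = DEFAULT_COUNT_TOTAL,
    deg_alpha: float = DEFAULT_DEG_ALPHA,
    evalue_max: float = DEFAULT_ANNOT_EVALUE,
) -> tuple[pd.DataFrame, pd.DataFrame, NormalizedMatrix]:
    """Run the full selection cascade.

    Returns (report, contrast table, normalized matrix).  The report has
    one row per gene with the testability flag, the total normalized count
    and count-filter flag, the minimum adjusted p and DEG flag, the best
    E-value and annotation flag, and ``selected`` combining all filters.
    Contrast tests are run only on genes that pass the testability and
    count filters, so downstream flags are False for the rest.
    """
    norm = normalize(counts)
    testable = testable_flags(counts)
    total = norm.values.sum(axis=1).rename("total_normalized_count")
    count_ok = low_count_filter(norm, count_threshold) & testable

    tested_genes = list(count_ok.index[count_ok])
    if tested_genes:
        sub_counts = CountMatrix(counts.values.loc[tested_genes])
        sub_norm = NormalizedMatrix(
            norm.values.loc[tested_genes], norm.size_factors
        )
        ct = contrast_table(sub_counts, design, norm=sub_norm)
        deg = deg_selection(ct, deg_alpha)
    else:
        ct = pd.DataFrame(
            columns=["gene_id", "contrast", "log2_fold_change", "p_raw", "p_adj"]
        )
        deg = pd.Series(dtype=bool)
    deg = deg.reindex(counts.gene_ids, fill_value=False)
    min_padj = (
        ct.groupby("gene_id")["p_adj"].min().reindex(counts.gene_ids)
        if len(ct)
        else pd.Series(np.nan, index=counts.gene_ids)
    )

    if bundle is not None:
        annot = annotation_filter(counts.gene_ids, bundle, evalue_max)
        best_ev = pd.Series(
            {g: bundle.best_evalue(g) for g in counts.gene_ids}, dtype=float
        )
    else:
        annot = pd.Series(True, index=counts.gene_ids)
        best_ev = pd.Series(np.nan, index=counts.gene_ids)

    report = pd.DataFrame(
        {
            "testable": testable,
            "total_normalized_count": total,
            "passed_count_filter": count_ok,
            "min_adj_p": min_padj,
            "passed_deg_filter": deg & count_ok,
            "best_evalue": best_ev,
            "passed_annotation_filter": annot,
        }
    )
    report["selected"] = (
        report["passed_deg_filter"] & report["passed_annotation_filter"]
    )
    report.index.name = "gene_id"
    return report, ct, norm
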