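"""The ANOVA cascade that partitions DEGs into LR, TCR and TLSR sets.

On log2-transformed normalized counts, a fixed-effects two-factor ANOVA
(line x treatment, time points and replicates pooled as within-cell
replication) is fitted per gene.  Genes whose expression varies with the
line but not the treatment form the Line Response (LR) set: constitutive
differences between the frost-tolerant and frost-sensitive lines.  Genes
varying with the treatment but not the line form the Temperature Common
Response (TCR): the shared chilling response.  Genes significant for both
factors form the Temperature Line-Specific Response (TLSR), the candidate
freezing-tolerance set.  Genes significant for neither are reported as NS.

The partition is computed as a simultaneous decision rule on the two
factor-level significance flags, which reproduces the arithmetic of the
serial subtract-and-retest procedure (total - LR fed to the treatment
stage, and so on) while keeping every decision reproducible from one
table.  Significance is Benjamini-Hochberg-adjusted p <= alpha per factor
across the DEG universe (alpha = 0.05 by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .de_testing import NormalizedMatrix, bh_adjust
from .io_formats import SampleDesign

__all__ = [
    "DEFAULT_ANOVA_ALPHA",
    "log_transform",
    "two_way_anova",
    "two_way_anova_table",
    "one_way_anova",
    "classify_cascade",
    "cascade_set_counts",
]

DEFAULT_ANOVA_ALPHA = 0.05

#: Smallest representable p-value, reported for zero-residual-variance
#: genes with a nonzero effect where the F ratio is formally infinite.
P_FLOOR = np.nextafter(0.0, 1.0)


def log_transform(norm: NormalizedMatrix | pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Elementwise log2(value + pseudocount)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    return np.log2(values + pseudocount)


def _balanced_two_way_ss(
    y: np.ndarray, a_codes: np.ndarray, b_codes: np.ndarray
) -> tuple[np.ndarray, ...]:
    """Sums of squares of the balanced two-factor layout, vectorized.

    ``y`` is genes x samples; ``a_codes``/``b_codes`` are integer level
    codes per sample.  Returns (ss_a, ss_b, ss_ab, ss_err, df tuple).
    """
    n_a = a_codes.max() + 1
    n_b = b_codes.max() + 1
    cell = a_codes * n_b + b_codes
    counts = np.bincount(cell, minlength=n_a * n_b)
    if counts.min() != counts.max():
        raise ValueError("unbalanced layout: unequal cell sizes")
    n_per_cell = counts[0]
    if n_per_cell < 2:
        raise ValueError("need >= 2 observations per cell for the error term")

    n_genes, n_samples = y.shape
    grand = y.mean(axis=1)

    def _level_means(codes: np.ndarray, n_levels: int) -> np.ndarray:
        sums = np.zeros((n_genes, n_levels))
        for lv in range(n_levels):
            sums[:, lv] = y[:, codes == lv].mean(axis=1)
        return sums

    mean_a = _level_means(a_codes, n_a)  # genes x n_a
    mean_b = _level_means(b_codes, n_b)
    mean_cell = np.zeros((n_genes, n_a * n_b))
    for c in range(n_a * n_b):
        mean_cell[:, c] = y[:, cell == c].mean(axis=1)

    per_a = n_samples // n_a
    per_b = n_samples // n_b
    ss_a = per_a * ((mean_a - grand[:, None]) ** 2).sum(axis=1)
    ss_b = per_b * ((mean_b - grand[:, None]) ** 2).sum(axis=1)

    cell_a = np.repeat(np.arange(n_a), n_b)
    cell_b = np.tile(np.arange(n_b), n_a)
    interaction = (
        mean_cell
        - mean_a[:, cell_a]
        - mean_b[:, cell_b]
        + grand[:, None]
    )
    ss_ab = n_per_cell * (interaction**2).sum(axis=1)

    resid = y - mean_cell[:, cell]
    ss_err = (resid**2).sum(axis=1)

    df = (n_a - 1, n_b - 1, (n_a - 1) * (n_b - 1), n_samples - n_a * n_b)
    return ss_a, ss_b, ss_ab, ss_err, df


def _f_and_p(ss: np.ndarray, df: int, ss_err: np.ndarray, df_err: int,
             tol: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    """F statistic and p with explicit handling of zero residual variance."""
    ms = ss / df
    mse = ss_err / df_err
    regular = mse > tol
    f = np.zeros_like(ms)
    f[regular] = ms[regular] / mse[regular]
    p = np.ones_like(ms)
    p[regular] = stats.f.sf(f[regular], df, df_err)
    degenerate_effect = ~regular & (ms > tol)
    p[degenerate_effect] = P_FLOOR
    f[degenerate_effect] = np.inf
    return f, p


def two_way_anova(
    expr: pd.Series | np.ndarray, design: SampleDesign,
    factor_a: str = "line", factor_b: str = "treatment",
) -> dict[str, float]:
    """Classical fixed-effects two-factor ANOVA for one gene.

    Returns F statistics, p-values and degrees of freedom for both main
    effects and their interaction.  A fully constant gene gives p = 1
    everywhere; zero within-cell variance with a nonzero effect gives the
    machine-minimum p (the F ratio is formally infinite).
    """
    table = two_way_anova_table(
        pd.DataFrame([np.asarray(expr, dtype=float)], index=["_g"],
                     columns=design.sample_ids),
        design, factor_a=factor_a, factor_b=factor_b,
    )
    return table.iloc[0].to_dict()


def two_way_anova_table(
    expr: pd.DataFrame, design: SampleDesign,
    factor_a: str = "line", factor_b: str = "treatment",
) -> pd.DataFrame:
    """Vectorized two-factor ANOVA over all genes (rows of ``expr``).

    ``expr`` columns must match the design's samples; replicates over any
    factors not named are pooled as within-cell replication.
    """
    y = expr[design.sample_ids].to_numpy(dtype=float)
    a_levels = design.factor(factor_a)
    b_levels = design.factor(factor_b)
    a_codes = pd.Categorical(a_levels).codes.astype(int)
    b_codes = pd.Categorical(b_levels).codes.astype(int)

    ss_a, ss_b, ss_ab, ss_err, (df_a, df_b, df_ab, df_err) = _balanced_two_way_ss(
        y, a_codes, b_codes
    )
    f_a, p_a = _f_and_p(ss_a, df_a, ss_err, df_err)
    f_b, p_b = _f_and_p(ss_b, df_b, ss_err, df_err)
    f_ab, p_ab = _f_and_p(ss_ab, df_ab, ss_err, df_err)

    return pd.DataFrame(
        {
            f"F_{factor_a}": f_a,
            f"p_{factor_a}": p_a,
            f"F_{factor_b}": f_b,
            f"p_{factor_b}": p_b,
            "F_interaction": f_ab,
            "p_interaction": p_ab,
            "df_effect": df_a,
            "df_error": df_err,
        },
        index=expr.index,
    )


def one_way_anova(expr: pd.Series | np.ndarray, grouping: pd.Series | np.ndarray) -> float:
    """Classical one-way F-test p-value for one gene.

    With two levels this equals the pooled-variance t-test via F = t**2.
    Zero residual variance with distinct group means gives the machine
    minimum; a fully constant response gives p = 1.
    """
    y = np.asarray(expr, dtype=float)
    g = np.asarray(grouping)
    uniq = np.unique(g)
    codes = np.searchsorted(uniq, g)
    n_levels = len(uniq)
    if n_levels < 2:
        raise ValueError("grouping needs at least 2 levels")
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 observations")

    grand = y.mean()
    ss_between = 0.0
    ss_within = 0.0
    for lv in range(n_levels):
        vals = y[codes == lv]
        ss_between += len(vals) * (vals.mean() - grand) ** 2
        ss_within += ((vals - vals.mean()) ** 2).sum()
    df_b = n_levels - 1
    df_w = len(y) - n_levels
    if ss_within <= 1e-12 * max(1.0, abs(grand)):
        return 1.0 if ss_between <= 1e-12 else float(P_FLOOR)
    f = (ss_between / df_b) / (ss_within / df_w)
    return float(stats.f.sf(f, df_b, df_w))


def classify_cascade(
    anova: pd.DataFrame,
    alpha: float = DEFAULT_ANOVA_ALPHA,
    adjust: bool = True,
    require_interaction_for_tlsr: bool = False,
) -> pd.DataFrame:
    """Partition the DEG universe from the two factor-level p-values.

    ``anova`` must carry columns ``p_line`` and ``p_treatment`` (and
    ``p_interaction`` when the interaction switch is used).  With
    s_line = (adjusted p_line <= alpha) and s_treat likewise:

    - LR   when s_line and not s_treat,
    - TCR  when s_treat and not s_line,
    - TLSR when both,
    - NS   when neither.

    Returns a frame with the adjusted p-values, the flags and ``set_label``.
    """
    for col in ("p_line", "p_treatment"):
        if col not in anova.columns:
            raise ValueError(f"missing ANOVA column {col!r}")
    out = anova.copy()
    if adjust:
        out["p_line_adj"] = bh_adjust(out["p_line"].to_numpy())
        out["p_treatment_adj"] = bh_adjust(out["p_treatment"].to_numpy())
        if "p_interaction" in out:
            out["p_interaction_adj"] = bh_adjust(out["p_interaction"].to_numpy())
    else:
        out["p_line_adj"] = out["p_line"]
        out["p_treatment_adj"] = out["p_treatment"]
        if "p_interaction" in out:
            out["p_interaction_adj"] = out["p_interaction"]

    s_line = out["p_line_adj"] <= alpha
    s_treat = out["p_treatment_adj"] <= alpha
    label = np.where(
        s_line & s_treat, "TLSR",
        np.where(s_line, "LR", np.where(s_treat, "TCR", "NS")),
    )
    if require_interaction_for_tlsr:
        if "p_interaction_adj" not in out:
            raise ValueError("interaction p-values required but absent")
        s_int = out["p_interaction_adj"] <= alpha
        label = np.where((label == "TLSR") & ~s_int, "TCR", label)

    out["significant_line"] = s_line
    out["significant_treatment"] = s_treat
    out["set_label"] = label
    return out


def cascade_set_counts(classification: pd.DataFrame | pd.Series) -> dict[str, int]:
    """Stage counts of the cascade, with the serial-subtraction identities.

    Accepts the classification frame (or just its ``set_label`` column) and
    returns the total, the three set sizes, the NS remainder, and the
    derived stage inputs: ``remaining_after_line`` = total - LR is the
    gene count entering the treatment stage, and after removing TCR the
    rest is TLSR plus NS.
    """
    labels = (
        classification["set_label"]
        if isinstance(classification, pd.DataFrame)
        else classification
    )
    n_total = int(len(labels))
    n = {k: int((labels == k).sum()) for k in ("LR", "TCR", "TLSR", "NS")}
    return {
        "n_total": n_total,
        "n_lr": n["LR"],
        "n_tcr": n["TCR"],
        "n_tlsr": n["TLSR"],
        "n_ns": n["NS"],
        "remaining_after_line": n_total - n["LR"],
        "remaining_after_treatment": n_total - n["LR"] - n["TCR"],
    }
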