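"""Hierarchical clustering of expression patterns into the eight subsets.

Each classified gene is reduced to its profile over the twelve
line x treatment x time condition means (log2 of normalized counts plus a
pseudocount), standardized to zero mean and unit variance, and clustered
by average linkage (UPGMA) on the Pearson correlation distance
d = 1 - r.  The tree is cut to a fixed number of clusters per set: 2 for
the Line Response, 2 for the Temperature Common Response, and 4 for the
Temperature Line-Specific Response.

Each cluster is then named by the sign pattern of its mean profile:

- line contrast: mean over Ch conditions minus mean over Te conditions;
- LT trend: mean of the LT T1/T2 conditions minus LT T0, averaged over
  the two lines.

LR clusters split into LRa (Ch up) and LRb (Te up); TCR clusters into
TCRa (down-regulated under LT) and TCRb (up-regulated); TLSR clusters into
the four quadrants TLSRa (Ch up, down under LT), TLSRb (Ch up, up),
TLSRc (Te up, down) and TLSRd (Te up, up).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .cascade_classifier import log_transform
from .de_testing import NormalizedMatrix
from .io_formats import CONDITION_ORDER, SampleDesign

__all__ = [
    "DEFAULT_K_PER_SET",
    "condition_means",
    "standardize",
    "hcl_average_pearson",
    "pattern_label",
    "assign_subsets",
]

#: Fixed number of pattern clusters per gene set.
DEFAULT_K_PER_SET = {"LR": 2, "TCR": 2, "TLSR": 4}

_CH_CONDITIONS = tuple(c for c in CONDITION_ORDER if c.startswith("Ch"))
_TE_CONDITIONS = tuple(c for c in CONDITION_ORDER if c.startswith("Te"))
_LT_T0 = ("ChLT0", "TeLT0")
_LT_LATE = ("ChLT1", "ChLT2", "TeLT1", "TeLT2")


class PatternTieError(ValueError):
    """A cluster's summary contrast is exactly zero; inspect it by hand."""


def condition_means(
    norm: NormalizedMatrix, design: SampleDesign, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-gene mean of log2(normalized + pseudocount) per condition.

    Columns follow the fixed display order: Ch before Te, N before LT,
    T0 < T1 < T2.
    """
    logged = log_transform(norm, pseudocount)
    cond = design.condition_labels().reindex(logged.columns)
    if cond.isna().any():
        raise ValueError("normalized matrix contains samples absent from design")
    means = logged.T.groupby(cond.to_numpy()).mean().T
    missing = [c for c in CONDITION_ORDER if c not in means.columns]
    if missing:
        raise ValueError(f"conditions without samples: {missing}")
    return means[list(CONDITION_ORDER)]


def standardize(profiles: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Row-wise centring and unit-variance scaling.

    Returns the standardized profiles and a boolean Series flagging
    constant profiles, which are left as zero rows and must be excluded
    from clustering.
    """
    arr = profiles.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    constant = (sd.ravel() == 0) | ~np.isfinite(sd.ravel())
    sd_safe = np.where(constant[:, None], 1.0, sd)
    out = (arr - mean) / sd_safe
    out[constant] = 0.0
    return (
        pd.DataFrame(out, index=profiles.index, columns=profiles.columns),
        pd.Series(constant, index=profiles.index, name="constant"),
    )


def pearson_distance_matrix(profiles: pd.DataFrame) -> np.ndarray:
    """Condensed 1 - Pearson-correlation distances between profile rows."""
    arr = profiles.to_numpy(dtype=float)
    arr = arr - arr.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(arr, axis=1)
    if (norms == 0).any():
        raise ValueError("constant profile has no defined correlation")
    r = (arr @ arr.T) / np.outer(norms, norms)
    d = 1.0 - np.clip(r, -1.0, 1.0)
    iu = np.triu_indices(len(arr), k=1)
    return np.maximum(d[iu], 0.0)


def hcl_average_pearson(profiles: pd.DataFrame, k: int) -> tuple[pd.Series, np.ndarray]:
    """Average-linkage (UPGMA) clustering on correlation distance.

    Returns cluster ids (renumbered 1..k by each cluster's smallest row
    position, for determinism) and the scipy-format linkage matrix.
    """
    n = len(profiles)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if n == 1:
        return (
            pd.Series([1], index=profiles.index, name="cluster_id"),
            np.empty((0, 4)),
        )
    condensed = pearson_distance_matrix(profiles)
    tree = linkage(condensed, method="average")
    raw = fcluster(tree, t=k, criterion="maxclust")
    # canonical numbering: cluster containing the first row is 1, etc.
    order: dict[int, int] = {}
    for cid in raw:
        if cid not in order:
            order[cid] = len(order) + 1
    ids = pd.Series([order[c] for c in raw], index=profiles.index, name="cluster_id")
    return ids, tree


def _summaries(mean_profile: pd.Series) -> tuple[float, float]:
    d_line = float(
        mean_profile[list(_CH_CONDITIONS)].mean()
        - mean_profile[list(_TE_CONDITIONS)].mean()
    )
    d_lt = float(
        mean_profile[list(_LT_LATE)].mean() - mean_profile[list(_LT_T0)].mean()
    )
    return d_line, d_lt


def pattern_label(mean_profile: pd.Series, set_label: str) -> str:
    """Subset name from a cluster's mean profile over the 12 conditions."""
    d_line, d_lt = _summaries(mean_profile)
    if set_label == "LR":
        if d_line == 0:
            raise PatternTieError("line contrast is exactly zero for an LR cluster")
        return "LRa" if d_line > 0 else "LRb"
    if set_label == "TCR":
        if d_lt == 0:
            raise PatternTieError("LT trend is exactly zero for a TCR cluster")
        return "TCRa" if d_lt < 0 else "TCRb"
    if set_label == "TLSR":
        if d_line == 0 or d_lt == 0:
            raise PatternTieError("zero summary contrast for a TLSR cluster")
        if d_line > 0:
            return "TLSRa" if d_lt < 0 else "TLSRb"
        return "TLSRc" if d_lt < 0 else "TLSRd"
    raise ValueError(f"set {set_label!r} has no pattern subsets")


def assign_subsets(
    norm: NormalizedMatrix,
    design: SampleDesign,
    classification: pd.DataFrame,
    k_per_set: dict[str, int] | None = None,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Cluster each gene set and name the resulting pattern subsets.

    Returns (assignment frame, linkage trees per set).  The frame has one
    row per classified LR/TCR/TLSR gene with ``set_label``, ``cluster_id``
    and ``subset_label``; constant-profile genes are flagged and left
    unlabelled.
    """
    k_per_set = dict(DEFAULT_K_PER_SET if k_per_set is None else k_per_set)
    profiles = condition_means(norm, design, pseudocount)
    std, constant = standardize(profiles)

    rows = []
    trees: dict[str, np.ndarray] = {}
    for set_label, k in k_per_set.items():
        genes = classification.index[classification["set_label"] == set_label]
        genes = [g for g in genes if g in std.index]
        missing = set(classification.index[classification["set_label"] == set_label]) - set(genes)
        if missing:
            raise ValueError(f"classified genes absent from matrix: {sorted(missing)}")
        usable = [g for g in genes if not constant[g]]
        for g in set(genes) - set(usable):
            rows.append(
                {"gene_id": g, "set_label": set_label, "cluster_id": 0,
                 "subset_label": None, "constant_profile": True}
            )
        if not usable:
            continue
        k_eff = min(k, len(usable))
        ids, tree = hcl_average_pearson(std.loc[usable], k_eff)
        trees[set_label] = tree
        for cid in range(1, k_eff + 1):
            members = ids.index[ids == cid]
            label = pattern_label(profiles.loc[members].mean(axis=0), set_label)
            for g in members:
                rows.append(
                    {"gene_id": g, "set_label": set_label, "cluster_id": cid,
                     "subset_label": label, "constant_profile": False}
                )
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "set_label", "cluster_id", "subset_label", "constant_profile"],
    ).set_index("gene_id")
    return out, trees


def write_linkage_tree(tree: np.ndarray, path) -> None:
    """Serialize a scipy linkage matrix as a merge list (child1, child2,
    height, size)."""
    frame = pd.DataFrame(tree, columns=["child1", "child2", "height", "size"])
    frame[["child1", "child2", "size"]] = frame[["child1", "child2", "size"]].astype(int)
    frame.to_csv(path, sep="\t", index=False)
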