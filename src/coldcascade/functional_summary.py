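"""Functional summary tables over the classified gene sets.

Joins the set/subset assignments with the annotation bundle to rebuild the
per-subset tallies a reader expects from this kind of study: numbers and
percentages of putative kinases and transcription factors (with the most
represented TF family), and counts of genes carrying any of the three
cold-related GO identifiers (response to cold GO:0009409, cold acclimation
GO:0009631, cellular response to cold GO:0070417).  GO-term
over-representation is a one-sided hypergeometric (urn) test with
Benjamini-Hochberg adjustment across terms.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .de_testing import bh_adjust
from .io_formats import AnnotationBundle
from .synthetic_data import COLD_GO_TERMS

__all__ = [
    "percentage",
    "summarize_sets",
    "cold_go_matrix",
    "hypergeom_enrichment",
    "most_represented_family",
]


def percentage(count: int, total: int, decimals: int = 2) -> float:
    """100 * count / total rounded to ``decimals``; 0.0 for an empty total."""
    if total == 0:
        return 0.0
    return round(100.0 * count / total, decimals)


def most_represented_family(
    genes: Iterable[str], family_map: Mapping[str, str]
) -> list[tuple[str, int]]:
    """The modal annotation family among ``genes``.

    Returns ``[(family, count)]``, or several pairs sorted alphabetically
    on ties, or an empty list when no gene is labelled.
    """
    counts: dict[str, int] = {}
    for g in genes:
        fam = family_map.get(g)
        if fam is not None:
            counts[fam] = counts.get(fam, 0) + 1
    if not counts:
        return []
    top = max(counts.values())
    return sorted((f, c) for f, c in counts.items() if c == top)


def _check_subset_coverage(subsets: pd.DataFrame, classification: pd.DataFrame) -> None:
    unknown = set(subsets.index) - set(classification.index)
    if unknown:
        raise ValueError(
            f"subset assignment contains unclassified genes: {sorted(unknown)[:5]}"
        )


def summarize_sets(
    classification: pd.DataFrame,
    subsets: pd.DataFrame,
    bundle: AnnotationBundle,
    cold_terms: Sequence[str] = COLD_GO_TERMS,
) -> pd.DataFrame:
    """Per-subset (and per-set total) annotation tallies.

    One row per pattern subset plus a total row per set, with gene counts,
    kinase and TF counts and percentages, the most represented TF family,
    and cold-GO counts split by term.  Percentages are recomputed from the
    counts at display time and stored unrounded alongside.
    """
    _check_subset_coverage(subsets, classification)
    rows = []
    labelled = subsets[subsets["subset_label"].notna()]
    for set_label in ("LR", "TCR", "TLSR"):
        set_rows = labelled[labelled["set_label"] == set_label]
        groups = [
            (subset, list(frame.index))
            for subset, frame in set_rows.groupby("subset_label", observed=True)
        ]
        groups.append((f"{set_label}_total", list(set_rows.index)))
        for name, genes in groups:
            n = len(genes)
            n_kin = sum(1 for g in genes if g in bundle.kinase_family)
            n_tf = sum(1 for g in genes if g in bundle.tf_family)
            per_term = {
                term: sum(1 for g in genes if term in bundle.go_terms.get(g, ()))
                for term in cold_terms
            }
            n_cold = sum(
                1
                for g in genes
                if bundle.go_terms.get(g, set()) & set(cold_terms)
            )
            top_tf = most_represented_family(genes, bundle.tf_family)
            rows.append(
                {
                    "set_label": set_label,
                    "subset": name,
                    "n_genes": n,
                    "n_kinases": n_kin,
                    "pct_kinases": percentage(n_kin, n, 1),
                    "n_tf": n_tf,
                    "pct_tf": percentage(n_tf, n, 2),
                    "top_tf_family": ";".join(f"{f}({c})" for f, c in top_tf),
                    **{f"n_{t}": c for t, c in per_term.items()},
                    "n_cold_go": n_cold,
                    "pct_cold_go": percentage(n_cold, n, 1),
                    "empty": n == 0,
                }
            )
    return pd.DataFrame(rows)


def cold_go_matrix(
    classification: pd.DataFrame,
    subsets: pd.DataFrame,
    bundle: AnnotationBundle,
    cold_terms: Sequence[str] = COLD_GO_TERMS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x subset incidence of cold-related GO annotation.

    Returns (incidence, totals): the incidence table has one row per
    cold-annotated classified gene with its subset and the terms it
    carries; totals has, per subset, the cold gene count and the ratio
    (percent of subset size, one decimal).
    """
    _check_subset_coverage(subsets, classification)
    cold_set = set(cold_terms)
    labelled = subsets[subsets["subset_label"].notna()]
    inc_rows = []
    for gene, row in labelled.iterrows():
        terms = bundle.go_terms.get(gene, set()) & cold_set
        if terms:
            inc_rows.append(
                {
                    "gene_id": gene,
                    "set_label": row["set_label"],
                    "subset_label": row["subset_label"],
                    "terms": ";".join(sorted(terms)),
                }
            )
    incidence = pd.DataFrame(
        inc_rows, columns=["gene_id", "set_label", "subset_label", "terms"]
    )

    tot_rows = []
    for subset, frame in labelled.groupby("subset_label", observed=True):
        genes = list(frame.index)
        n_cold = sum(
            1 for g in genes if bundle.go_terms.get(g, set()) & cold_set
        )
        tot_rows.append(
            {
                "subset_label": subset,
                "n_genes": len(genes),
                "n_cold": n_cold,
                "ratio_pct": percentage(n_cold, len(genes), 1),
            }
        )
    totals = pd.DataFrame(
        tot_rows, columns=["subset_label", "n_genes", "n_cold", "ratio_pct"]
    )
    return incidence, totals


def hypergeom_enrichment(
    subset_genes: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    background: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of each term.

    With background size M, term size K (after intersecting with the
    background), subset size n and overlap k, the p-value is
    P(X >= k) for X ~ Hypergeom(M, K, n).  BH adjustment is applied
    across terms.
    """
    bg = set(background)
    sub = set(subset_genes)
    if not sub <= bg:
        raise ValueError("subset genes must be contained in the background")
    M = len(bg)
    n = len(sub)
    rows = []
    for term, members in gene_sets.items():
        term_bg = set(members) & bg
        K = len(term_bg)
        k = len(term_bg & sub)
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        rows.append(
            {
                "term": term,
                "overlap": k,
                "term_size": K,
                "subset_size": n,
                "background_size": M,
                "p_value": min(p, 1.0),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["term", "overlap", "term_size", "subset_size", "background_size", "p_value"],
    )
    if len(table):
        table["p_adj"] = bh_adjust(table["p_value"].to_numpy())
    else:
        table["p_adj"] = np.array([], dtype=float)
    return table
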