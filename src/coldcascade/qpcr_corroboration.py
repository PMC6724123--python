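"""Corroboration of RNA-seq fold changes against an external qPCR study.

Unigenes are linked to the ESTs behind the qPCR assays through BLAST hits
passing three simultaneous thresholds (E-value <= 1e-25, alignment length
>= 200 bp, identity >= 95%); the RNA-seq sampling times T0/T1/T2 are paired
with the qPCR study's days T0/T6/T10.  Agreement between the paired log2
ratios is measured with the uncentered (cosine) correlation

    R = sum(x*y) / sqrt(sum(x^2) * sum(y^2)),

not Pearson's centred form; a switch offers the centred coefficient for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import BlastHitRecord
from .synthetic_data import QPCR_TIME_MAP

__all__ = [
    "DEFAULT_LINK_EVALUE",
    "DEFAULT_LINK_MIN_LENGTH",
    "DEFAULT_LINK_MIN_IDENTITY",
    "QpcrLink",
    "link_filter",
    "uncentered_correlation",
    "corroborate",
]

DEFAULT_LINK_EVALUE = 1e-25
DEFAULT_LINK_MIN_LENGTH = 200
DEFAULT_LINK_MIN_IDENTITY = 95.0


@dataclass(frozen=True)
class QpcrLink:
    """A unigene linked to a qPCR EST by a threshold-passing BLAST hit."""

    unigene: str
    est_id: str
    hit: BlastHitRecord


def link_filter(
    hits: list[BlastHitRecord],
    evalue_max: float = DEFAULT_LINK_EVALUE,
    min_length: int = DEFAULT_LINK_MIN_LENGTH,
    min_identity: float = DEFAULT_LINK_MIN_IDENTITY,
) -> list[QpcrLink]:
    """Keep hits passing all three link thresholds, best hit per pair.

    A hit passes when E-value <= ``evalue_max`` AND alignment length >=
    ``min_length`` AND percent identity >= ``min_identity``.  Among
    passing hits of the same (query, subject) pair, the one with the
    lowest E-value wins, ties broken by the highest bit score.
    """
    best: dict[tuple[str, str], BlastHitRecord] = {}
    for hit in hits:
        if (
            hit.evalue <= evalue_max
            and hit.alignment_length >= min_length
            and hit.percent_identity >= min_identity
        ):
            key = (hit.query_id, hit.subject_id)
            prev = best.get(key)
            if (
                prev is None
                or hit.evalue < prev.evalue
                or (hit.evalue == prev.evalue and hit.bit_score > prev.bit_score)
            ):
                best[key] = hit
    return [QpcrLink(q, s, h) for (q, s), h in sorted(best.items())]


def uncentered_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """R = sum(xy) / sqrt(sum(x^2) * sum(y^2)), the cosine form."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 paired observations")
    denom = np.sqrt((x**2).sum() * (y**2).sum())
    if denom == 0:
        raise ZeroDivisionError("a vector of zeros has no defined correlation")
    return float((x * y).sum() / denom)


def corroborate(
    rnaseq_ratios: pd.DataFrame,
    qpcr_ratios: pd.DataFrame,
    links: list[QpcrLink],
    time_map: dict[str, str] = QPCR_TIME_MAP,
    centered: bool = False,
) -> tuple[pd.DataFrame, float]:
    """Assemble paired log2 ratios through the links and compute R.

    Both ratio tables carry columns ``transcript``, ``timepoint``,
    ``log2_ratio``; RNA-seq transcripts are the link queries, qPCR
    transcripts the link subjects, and RNA-seq timepoints are translated
    through ``time_map`` before joining.  Returns the pair table
    (transcript, timepoint, x = qPCR, y = RNA-seq) and the correlation.
    """
    if not links:
        raise ValueError("no links between RNA-seq unigenes and qPCR ESTs")
    qpcr_idx = qpcr_ratios.set_index(["transcript", "timepoint"])["log2_ratio"]
    rows = []
    for link in links:
        sub = rnaseq_ratios[rnaseq_ratios["transcript"] == link.unigene]
        for _, r in sub.iterrows():
            mapped = time_map.get(r["timepoint"])
            if mapped is None:
                continue
            key = (link.est_id, mapped)
            if key in qpcr_idx.index:
                rows.append(
                    {
                        "transcript": link.unigene,
                        "est_id": link.est_id,
                        "timepoint": r["timepoint"],
                        "x_qpcr": float(qpcr_idx.loc[key]),
                        "y_rnaseq": float(r["log2_ratio"]),
                    }
                )
    pairs = pd.DataFrame(
        rows, columns=["transcript", "est_id", "timepoint", "x_qpcr", "y_rnaseq"]
    )
    if len(pairs) < 2:
        raise ValueError(f"only {len(pairs)} linked ratio pairs; need >= 2")
    x = pairs["x_qpcr"].to_numpy()
    y = pairs["y_rnaseq"].to_numpy()
    if centered:
        r = float(np.corrcoef(x, y)[0, 1])
    else:
        r = uncentered_correlation(x, y)
    return pairs, r
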