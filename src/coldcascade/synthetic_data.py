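"""Synthetic count matrices with planted expression archetypes.

The generator emulates the study layout this package targets: a 24-sample
full factorial (2 lines x 2 treatments x 3 times x 2 replicates) of
negative-binomial read counts.  Each gene is drawn from one of nine
archetypes that mirror the expression-pattern subsets the pipeline is meant
to recover:

===========  =========================  ==========================================
archetype    line offset (log2, Ch-Te)  low-temperature slope (log2 per time step)
===========  =========================  ==========================================
NULL         0                          0
LR_CH_UP     +offset                    0
LR_TE_UP     -offset                    0
TCR_DOWN     0                          -slope, identical in both lines
TCR_UP       0                          +slope, identical in both lines
TLSR_A       +offset                    -slope, line-specific magnitude
TLSR_B       +offset                    +slope, line-specific magnitude
TLSR_C       -offset                    -slope, line-specific magnitude
TLSR_D       -offset                    +slope, line-specific magnitude
===========  =========================  ==========================================

The slope acts only on low-temperature (LT) samples, with time coded
0, 1, 2 for T0, T1, T2; control (N) columns stay flat for every archetype.
For line-specific archetypes the frost-sensitive line receives the slope
scaled by ``te_slope_scale`` (< 1), so both lines move in the same direction
but with different amplitudes.  The line offset is split symmetrically
(+offset/2 to Ch, -offset/2 to Te) so the grand mean, and hence the
low-count filter, is archetype-independent.

Counts follow NB(mean = sf_s * base_mean * 2**eta, variance = mu + a*mu^2)
with a the dispersion, matching the model assumed by the testing stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import AnnotationBundle, CountMatrix, SampleDesign

__all__ = [
    "ARCHETYPES",
    "COLD_GO_TERMS",
    "SimulationConfig",
    "archetype_effects",
    "simulate_counts",
    "simulate_annotation",
    "simulate_qpcr",
]

ARCHETYPES = (
    "NULL",
    "LR_CH_UP",
    "LR_TE_UP",
    "TCR_DOWN",
    "TCR_UP",
    "TLSR_A",
    "TLSR_B",
    "TLSR_C",
    "TLSR_D",
)

#: GO identifiers for the cold response, cold acclimation and the cellular
#: response to cold, used by the functional summary stage.
COLD_GO_TERMS = ("GO:0009409", "GO:0009631", "GO:0070417")

_TF_FAMILIES = (
    "bHLH", "AP2-EREBP", "MYB", "C2H2", "WRKY", "NAC", "C3H",
    "C2C2-CO-like", "MADS", "bZIP",
)
_KINASE_FAMILIES = ("RLK-Pelle", "CAMK", "CMGC", "STE", "TKL", "CK1")

# sign of (line offset, LT slope); None = zero
_ARCHETYPE_SIGNS: dict[str, tuple[int, int, bool]] = {
    # (offset sign, slope sign, line_specific)
    "NULL": (0, 0, False),
    "LR_CH_UP": (+1, 0, False),
    "LR_TE_UP": (-1, 0, False),
    "TCR_DOWN": (0, -1, False),
    "TCR_UP": (0, +1, False),
    "TLSR_A": (+1, -1, True),
    "TLSR_B": (+1, +1, True),
    "TLSR_C": (-1, -1, True),
    "TLSR_D": (-1, +1, True),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-archetype count simulation.

    Defaults define the package's reference study conditions: 1000 null
    genes plus 100 genes per non-null archetype, base mean 100 counts,
    dispersion 0.05, a 1.5 log2 line offset and a 1.0 log2-per-step LT
    slope.
    """

    n_genes_per_archetype: Mapping[str, int] = field(
        default_factory=lambda: {
            "NULL": 1000,
            **{a: 100 for a in ARCHETYPES if a != "NULL"},
        }
    )
    base_mean: float = 100.0
    dispersion: float = 0.05
    effect_offset: float = 1.5
    effect_slope: float = 1.0
    te_slope_scale: float = 0.5
    library_size_factors: tuple[float, ...] | None = None
    seed: int = 42

    def __post_init__(self) -> None:
        if self.base_mean <= 0:
            raise ValueError("base_mean must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        for a in self.n_genes_per_archetype:
            if a not in ARCHETYPES:
                raise ValueError(f"unknown archetype {a!r}")
        if any(n < 0 for n in self.n_genes_per_archetype.values()):
            raise ValueError("archetype gene counts must be non-negative")
        if self.library_size_factors is not None and any(
            f <= 0 for f in self.library_size_factors
        ):
            raise ValueError("library size factors must be positive")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def archetype_effects(
    archetype: str, effect_offset: float, effect_slope: float
) -> tuple[float, float, bool]:
    """(line_offset, lt_slope, line_specific) for one archetype."""
    off_sign, slope_sign, line_specific = _ARCHETYPE_SIGNS[archetype]
    return (
        off_sign * abs(effect_offset),
        slope_sign * abs(effect_slope),
        line_specific,
    )


def _truth_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    idx = 0
    for archetype in ARCHETYPES:
        n = config.n_genes_per_archetype.get(archetype, 0)
        offset, slope, line_specific = archetype_effects(
            archetype, config.effect_offset, config.effect_slope
        )
        for _ in range(n):
            rows.append(
                {
                    "gene_id": f"g{idx:05d}",
                    "archetype": archetype,
                    "line_offset": offset,
                    "lt_slope": slope,
                    "line_specific": line_specific,
                }
            )
            idx += 1
    truth = pd.DataFrame(
        rows, columns=["gene_id", "archetype", "line_offset", "lt_slope", "line_specific"]
    )
    return truth.set_index("gene_id")


def expected_log2_effect(
    truth_row: pd.Series, line: str, treatment: str, time: str,
    te_slope_scale: float,
) -> float:
    """The planted log2 deviation from base mean for one gene in one condition."""
    step = {"T0": 0, "T1": 1, "T2": 2}[time]
    eta = truth_row["line_offset"] / 2.0 * (1.0 if line == "Ch" else -1.0)
    if treatment == "LT":
        slope = truth_row["lt_slope"]
        if truth_row["line_specific"] and line == "Te":
            slope = slope * te_slope_scale
        eta += slope * step
    return float(eta)


def simulate_counts(
    config: SimulationConfig, design: SampleDesign
) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw the planted-archetype count matrix for ``design``.

    Returns the count matrix and the truth table (gene -> archetype,
    line_offset, lt_slope, line_specific).  Identical config and design
    give identical output.
    """
    truth = _truth_table(config)
    n_genes = len(truth)
    n_samples = design.n_samples
    sf = (
        np.ones(n_samples)
        if config.library_size_factors is None
        else np.asarray(config.library_size_factors, dtype=float)
    )
    if len(sf) != n_samples:
        raise ValueError(
            f"{len(sf)} library size factors for {n_samples} samples"
        )

    # per-gene, per-sample log2 effect
    step = design.factor("time").map({"T0": 0, "T1": 1, "T2": 2}).to_numpy()
    is_ch = (design.factor("line") == "Ch").to_numpy()
    is_lt = (design.factor("treatment") == "LT").to_numpy()

    offset = truth["line_offset"].to_numpy()[:, None]
    slope = truth["lt_slope"].to_numpy()[:, None]
    line_specific = truth["line_specific"].to_numpy()[:, None]

    line_sign = np.where(is_ch, 0.5, -0.5)[None, :]
    slope_scale = np.where(
        line_specific & ~is_ch[None, :], config.te_slope_scale, 1.0
    )
    eta = offset * line_sign + slope * slope_scale * (step * is_lt)[None, :]
    mu = sf[None, :] * config.base_mean * np.exp2(eta)

    rng = np.random.default_rng(config.seed)
    # NB with variance mu + a*mu^2: shape n = 1/a, success prob n/(n+mu)
    n_param = 1.0 / config.dispersion
    counts = rng.negative_binomial(n_param, n_param / (n_param + mu))

    matrix = CountMatrix(
        pd.DataFrame(counts, index=truth.index, columns=design.sample_ids)
    )
    return matrix, truth


def simulate_annotation(
    truth: pd.DataFrame,
    annotated_fraction: float = 0.8,
    evalue_range: tuple[float, float] = (1e-10, 1e-1),
    tf_fraction: float = 0.05,
    kinase_fraction: float = 0.04,
    cold_go_fraction: float = 0.03,
    seed: int = 0,
) -> AnnotationBundle:
    """Draw annotation sidecars for the simulated genes.

    A fraction of genes receive a best hit whose E-value is log-uniform on
    ``evalue_range`` (which straddles the downstream annotation threshold,
    so the filter actually bites); independent fractions receive a
    transcription-factor family, a kinase family, and one cold-related GO
    identifier.
    """
    if truth.empty:
        raise ValueError("truth table is empty")
    for name, frac in (
        ("annotated_fraction", annotated_fraction),
        ("tf_fraction", tf_fraction),
        ("kinase_fraction", kinase_fraction),
        ("cold_go_fraction", cold_go_fraction),
    ):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {frac}")
    lo, hi = evalue_range
    if not (0 < lo <= hi):
        raise ValueError("evalue_range must satisfy 0 < low <= high")

    rng = np.random.default_rng(seed)
    genes = list(truth.index)
    n = len(genes)

    bundle = AnnotationBundle()
    hit_mask = rng.random(n) < annotated_fraction
    log_ev = rng.uniform(np.log10(lo), np.log10(hi), size=n)
    for i, gene in enumerate(genes):
        if hit_mask[i]:
            bundle.best_hit[gene] = (f"AT{i % 5 + 1}G{i:05d}", float(10.0 ** log_ev[i]))

    tf_mask = rng.random(n) < tf_fraction
    tf_fam = rng.choice(len(_TF_FAMILIES), size=n)
    kin_mask = rng.random(n) < kinase_fraction
    kin_fam = rng.choice(len(_KINASE_FAMILIES), size=n)
    # cold GO ids are heavily skewed toward the generic "response to cold"
    cold_mask = rng.random(n) < cold_go_fraction
    cold_term = rng.choice(len(COLD_GO_TERMS), size=n, p=(0.85, 0.10, 0.05))
    for i, gene in enumerate(genes):
        if tf_mask[i]:
            bundle.tf_family[gene] = _TF_FAMILIES[tf_fam[i]]
        if kin_mask[i]:
            bundle.kinase_family[gene] = _KINASE_FAMILIES[kin_fam[i]]
        terms: set[str] = set()
        if cold_mask[i]:
            terms.add(COLD_GO_TERMS[cold_term[i]])
        bundle.go_terms[gene] = terms
    return bundle


#: RNA-seq sampling times paired with the qPCR study's sampling days.
QPCR_TIME_MAP = {"T0": "T0", "T1": "T6", "T2": "T10"}


def simulate_qpcr(
    truth: pd.DataFrame,
    n_transcripts: int,
    noise_sd: float,
    seed: int = 0,
    te_slope_scale: float = 0.5,
) -> pd.DataFrame:
    """Paired RNA-seq / qPCR log2 ratios for a subset of responsive genes.

    Ratios are within-condition, relative to T0 under the LT treatment (the
    frost-tolerant line's profile).  The qPCR column equals the true ratio
    plus Gaussian noise with standard deviation ``noise_sd``; its timepoints
    carry the qPCR study's labels (T6, T10).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    non_null = truth[truth["archetype"] != "NULL"]
    if n_transcripts > len(non_null):
        raise ValueError(
            f"requested {n_transcripts} transcripts but only "
            f"{len(non_null)} non-null genes are available"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(non_null.index.to_numpy(), size=n_transcripts, replace=False)

    rows = []
    for gene in chosen:
        row = non_null.loc[gene]
        for rnaseq_time, qpcr_time, step in (("T1", "T6", 1), ("T2", "T10", 2)):
            true_ratio = float(row["lt_slope"]) * step
            rows.append(
                {
                    "transcript": gene,
                    "rnaseq_time": rnaseq_time,
                    "qpcr_time": qpcr_time,
                    "rnaseq_log2_ratio": true_ratio,
                    "qpcr_log2_ratio": true_ratio + rng.normal(0.0, noise_sd),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript",
            "rnaseq_time",
            "qpcr_time",
            "rnaseq_log2_ratio",
            "qpcr_log2_ratio",
        ],
    )
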