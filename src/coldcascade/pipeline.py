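"""End-to-end orchestration: simulate or load, test, classify, cluster,
summarize and corroborate, with a machine-readable run report.

Every stage writes its table to the output directory in the package's
tab-separated dialect, and the report records the gene count surviving
each filter together with the thresholds and the seed, so two runs with
the same configuration are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cascade_classifier import (
    DEFAULT_ANOVA_ALPHA,
    cascade_set_counts,
    classify_cascade,
    log_transform,
    two_way_anova_table,
)
from .de_testing import (
    DEFAULT_ANNOT_EVALUE,
    DEFAULT_COUNT_TOTAL,
    DEFAULT_DEG_ALPHA,
    filter_report,
)
from .functional_summary import cold_go_matrix, hypergeom_enrichment, summarize_sets
from .io_formats import (
    AnnotationBundle,
    CountMatrix,
    SampleDesign,
    read_best_hits,
    read_counts,
    read_design,
    read_gene_sets,
    read_two_column_map,
    write_best_hits,
    write_counts,
    write_design,
    write_two_column_map,
)
from .pattern_clustering import DEFAULT_K_PER_SET, assign_subsets, write_linkage_tree
from .qpcr_corroboration import uncentered_correlation
from .synthetic_data import (
    SimulationConfig,
    simulate_annotation,
    simulate_counts,
    simulate_qpcr,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``counts_path``/``design_path`` (plus optional annotation
    sidecars) point at existing tables, or ``simulate`` is true and the
    synthetic generator provides them.  All thresholds default to the
    pipeline's canonical values.
    """

    outdir: str = "coldcascade_run"
    simulate: bool = True
    seed: int = 42

    # input tables (used when simulate is false)
    counts_path: str | None = None
    design_path: str | None = None
    best_hits_path: str | None = None
    tf_path: str | None = None
    kinase_path: str | None = None
    go_sets_path: str | None = None

    # simulation settings
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    annotated_fraction: float = 0.8
    evalue_range: tuple[float, float] = (1e-10, 1e-1)
    qpcr_n_transcripts: int = 33
    qpcr_noise_sd: float = 0.75

    # thresholds
    count_total: float = DEFAULT_COUNT_TOTAL
    deg_alpha: float = DEFAULT_DEG_ALPHA
    annot_evalue: float = DEFAULT_ANNOT_EVALUE
    anova_alpha: float = DEFAULT_ANOVA_ALPHA
    k_per_set: dict = field(default_factory=lambda: dict(DEFAULT_K_PER_SET))

    def __post_init__(self) -> None:
        for name in ("count_total", "deg_alpha", "annot_evalue", "anova_alpha"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(k < 1 for k in self.k_per_set.values()):
            raise ValueError("cluster counts must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_raw:
            cfg.sim = SimulationConfig(**sim_raw)
        return cfg


def _load_inputs(config: RunConfig) -> tuple[
    CountMatrix, SampleDesign, AnnotationBundle, pd.DataFrame | None, pd.DataFrame | None
]:
    if config.simulate:
        design = SampleDesign.canonical()
        sim = config.sim.with_(seed=config.seed)
        counts, truth = simulate_counts(sim, design)
        bundle = simulate_annotation(
            truth,
            annotated_fraction=config.annotated_fraction,
            evalue_range=config.evalue_range,
            seed=config.seed + 1,
        )
        qpcr = simulate_qpcr(
            truth,
            n_transcripts=min(
                config.qpcr_n_transcripts,
                int((truth["archetype"] != "NULL").sum()),
            ),
            noise_sd=config.qpcr_noise_sd,
            seed=config.seed + 2,
            te_slope_scale=sim.te_slope_scale,
        )
        return counts, design, bundle, truth, qpcr

    if not (config.counts_path and config.design_path):
        raise ValueError("counts_path and design_path required when simulate is false")
    design = read_design(config.design_path)
    counts = read_counts(config.counts_path, design)
    bundle = AnnotationBundle()
    if config.best_hits_path:
        bundle.best_hit = read_best_hits(config.best_hits_path)
    if config.tf_path:
        bundle.tf_family = read_two_column_map(config.tf_path, "gene_id", "family")
    if config.kinase_path:
        bundle.kinase_family = read_two_column_map(config.kinase_path, "gene_id", "family")
    if config.go_sets_path:
        sets = read_gene_sets(config.go_sets_path)
        go_terms: dict[str, set[str]] = {}
        for term, members in sets.items():
            for g in members:
                go_terms.setdefault(g, set()).add(term)
        bundle.go_terms = go_terms
    return counts, design, bundle, None, None


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the machine-readable report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    counts, design, bundle, truth, qpcr = _load_inputs(config)
    write_design(design, outdir / "design.tsv")
    write_counts(counts, outdir / "counts.tsv")
    if truth is not None:
        truth.to_csv(outdir / "truth.tsv", sep="\t")
    if bundle.best_hit:
        write_best_hits(bundle.best_hit, outdir / "best_hits.tsv")
    if bundle.tf_family:
        write_two_column_map(bundle.tf_family, outdir / "tf_families.tsv", "gene_id", "family")
    if bundle.kinase_family:
        write_two_column_map(
            bundle.kinase_family, outdir / "kinase_families.tsv", "gene_id", "family"
        )

    # --- selection cascade
    report_table, contrasts, norm = filter_report(
        counts,
        design,
        bundle if (bundle.best_hit or not config.simulate) else None,
        count_threshold=config.count_total,
        deg_alpha=config.deg_alpha,
        evalue_max=config.annot_evalue,
    )
    report_table.to_csv(outdir / "filter_report.tsv", sep="\t")
    contrasts.to_csv(outdir / "contrasts.tsv", sep="\t", index=False)
    norm.size_factors.to_frame().to_csv(outdir / "size_factors.tsv", sep="\t")

    deg_genes = list(report_table.index[report_table["selected"]])

    # --- ANOVA cascade on the DEG universe
    logged = log_transform(norm)
    anova = two_way_anova_table(logged.loc[deg_genes], design)
    classification = classify_cascade(anova, alpha=config.anova_alpha)
    classification.to_csv(outdir / "classification.tsv", sep="\t")
    set_counts = cascade_set_counts(classification)

    # --- pattern clustering
    subsets, trees = assign_subsets(
        norm, design, classification, k_per_set=config.k_per_set
    )
    subsets.to_csv(outdir / "subsets.tsv", sep="\t")
    for set_label, tree in trees.items():
        write_linkage_tree(tree, outdir / f"linkage_{set_label}.tsv")

    # --- functional summary
    summary = summarize_sets(classification, subsets, bundle)
    summary.to_csv(outdir / "subset_summary.tsv", sep="\t", index=False)
    incidence, cold_totals = cold_go_matrix(classification, subsets, bundle)
    incidence.to_csv(outdir / "cold_go_incidence.tsv", sep="\t", index=False)
    cold_totals.to_csv(outdir / "cold_go_totals.tsv", sep="\t", index=False)

    go_map: dict[str, set[str]] = {}
    for g, terms in bundle.go_terms.items():
        for t in terms:
            go_map.setdefault(t, set()).add(g)
    background = [g for g in deg_genes if g in bundle.go_terms or g in bundle.best_hit]
    enrich_rows = []
    if go_map and background:
        for subset_label, frame in subsets.groupby("subset_label", observed=True):
            sub_genes = [g for g in frame.index if g in background]
            res = hypergeom_enrichment(sub_genes, go_map, background)
            res.insert(0, "subset_label", subset_label)
            enrich_rows.append(res)
    enrichment = (
        pd.concat(enrich_rows, ignore_index=True)
        if enrich_rows
        else pd.DataFrame(
            columns=["subset_label", "term", "overlap", "term_size",
                     "subset_size", "background_size", "p_value", "p_adj"]
        )
    )
    enrichment.to_csv(outdir / "go_enrichment.tsv", sep="\t", index=False)

    # --- qPCR corroboration (synthetic runs only: paired table from truth)
    corroboration: dict | None = None
    if qpcr is not None and len(qpcr):
        qpcr.to_csv(outdir / "qpcr_pairs.tsv", sep="\t", index=False)
        x = qpcr["qpcr_log2_ratio"].to_numpy()
        y = qpcr["rnaseq_log2_ratio"].to_numpy()
        corroboration = {
            "n_pairs": int(len(qpcr)),
            "n_transcripts": int(qpcr["transcript"].nunique()),
            "uncentered_r": uncentered_correlation(x, y),
        }

    report = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "count_total": config.count_total,
            "deg_alpha": config.deg_alpha,
            "annot_evalue": config.annot_evalue,
            "anova_alpha": config.anova_alpha,
        },
        "k_per_set": dict(config.k_per_set),
        "stage_counts": {
            "genes": int(len(report_table)),
            "testable": int(report_table["testable"].sum()),
            "passed_count_filter": int(report_table["passed_count_filter"].sum()),
            "passed_deg_filter": int(report_table["passed_deg_filter"].sum()),
            "selected_deg_universe": int(report_table["selected"].sum()),
            **set_counts,
            "subsets": {
                str(k): int(v)
                for k, v in subsets["subset_label"].value_counts().sort_index().items()
            },
        },
        "corroboration": corroboration,
    }
    # subtraction identities of the serial cascade, checked at run time
    sc = report["stage_counts"]
    assert sc["n_total"] - sc["n_lr"] == sc["remaining_after_line"]
    assert sc["remaining_after_line"] - sc["n_tcr"] == sc["n_tlsr"] + sc["n_ns"]

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(outdir / "report.txt", "w") as fh:
        fh.write(_format_report(report))
    return report


def _format_report(report: dict) -> str:
    sc = report["stage_counts"]
    lines = [
        f"coldcascade {report['version']} run (seed {report['seed']})",
        "",
        f"genes                      {sc['genes']}",
        f"  testable                 {sc['testable']}",
        f"  passed count filter      {sc['passed_count_filter']}",
        f"  passed DEG filter        {sc['passed_deg_filter']}",
        f"  DEG universe             {sc['selected_deg_universe']}",
        f"    LR                     {sc['n_lr']}",
        f"    remaining after LR     {sc['remaining_after_line']}",
        f"    TCR                    {sc['n_tcr']}",
        f"    TLSR                   {sc['n_tlsr']}",
        f"    NS                     {sc['n_ns']}",
        "",
        "subsets: "
        + ", ".join(f"{k}={v}" for k, v in sc["subsets"].items()),
    ]
    if report["corroboration"]:
        c = report["corroboration"]
        lines.append(
            f"qPCR corroboration: R = {c['uncentered_r']:.3f} over "
            f"{c['n_pairs']} pairs ({c['n_transcripts']} transcripts)"
        )
    return "\n".join(lines) + "\n"
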