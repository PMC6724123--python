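"""Tabular input/output for the cascade pipeline.

All tables are tab-delimited text with a single header row; lines starting
with ``#`` are comments.  Gene identifiers are opaque strings.  The module
holds the small set of domain containers shared by every downstream stage:
the factorial sample design, the raw count matrix, BLAST tabular hit
records, and the annotation bundle (best hits, transcription-factor and
kinase families, GO memberships).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "LINES",
    "TREATMENTS",
    "TIMES",
    "CONDITION_ORDER",
    "NINE_CONTRASTS",
    "SampleDesign",
    "CountMatrix",
    "BlastHitRecord",
    "AnnotationBundle",
    "ValidationError",
    "read_design",
    "write_design",
    "read_counts",
    "write_counts",
    "read_blast_tab",
    "read_gene_sets",
    "write_gene_sets",
    "read_two_column_map",
    "write_two_column_map",
    "read_best_hits",
    "write_best_hits",
    "read_qpcr_table",
    "write_qpcr_table",
]

LINES = ("Ch", "Te")
TREATMENTS = ("N", "LT")
TIMES = ("T0", "T1", "T2")

#: Single-letter treatment codes used inside condition names: ``ChLT0`` is
#: line Ch, treatment LT, time T0; ``ChNT0`` is the control at T0.
_TREATMENT_CODE = {"N": "N", "LT": "L"}

#: The twelve line x treatment x time conditions, in the display order used
#: throughout the pipeline (Ch before Te, N before LT, T0 < T1 < T2).
CONDITION_ORDER = tuple(
    f"{ln}{_TREATMENT_CODE[tr]}{tm}" for ln in LINES for tr in TREATMENTS for tm in TIMES
)

#: The nine condition contrasts tested for differential expression:
#: the inter-line contrast at T0 under control conditions, plus the T0-vs-T1
#: and T0-vs-T2 contrasts within each line x treatment series.
NINE_CONTRASTS = (
    ("ChNT0", "TeNT0"),
    ("ChNT0", "ChNT1"),
    ("ChNT0", "ChNT2"),
    ("ChLT0", "ChLT1"),
    ("ChLT0", "ChLT2"),
    ("TeNT0", "TeNT1"),
    ("TeNT0", "TeNT2"),
    ("TeLT0", "TeLT1"),
    ("TeLT0", "TeLT2"),
)


class ValidationError(ValueError):
    """An input table violated a structural invariant."""


def condition_label(line: str, treatment: str, time: str) -> str:
    """Condition name such as ``ChLT0`` from its three factor levels."""
    return f"{line}{_TREATMENT_CODE[treatment]}{time}"


@dataclass(frozen=True)
class SampleDesign:
    """The factor layout of the samples.

    ``table`` has one row per sample with columns ``sample_id``, ``line``,
    ``treatment``, ``time`` and ``replicate``.  The canonical design is the
    full factorial 2 lines x 2 treatments x 3 times x 2 replicates = 24
    samples.
    """

    table: pd.DataFrame

    REQUIRED_COLUMNS = ("sample_id", "line", "treatment", "time", "replicate")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED_COLUMNS if c not in t.columns]
        if missing:
            raise ValidationError(f"design table missing columns: {missing}")
        if t.empty:
            raise ValidationError("design table has no samples")
        dup = t["sample_id"][t["sample_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate sample_id: {sorted(set(dup))}")
        for col, levels in (("line", LINES), ("treatment", TREATMENTS), ("time", TIMES)):
            bad = ~t[col].isin(levels)
            if bad.any():
                row = int(t.index[bad][0])
                raise ValidationError(
                    f"unknown {col} level {t[col][bad].iloc[0]!r} in row {row} "
                    f"(sample {t['sample_id'][bad].iloc[0]!r}); allowed: {levels}"
                )
        if (t["replicate"].astype(int) < 1).any():
            raise ValidationError("replicate numbers must be positive integers")
        # balanced replication across occupied cells
        counts = t.groupby(["line", "treatment", "time"], observed=True).size()
        if counts.nunique() > 1:
            raise ValidationError(
                "unbalanced design: cells have unequal replicate counts "
                f"({dict(counts)})"
            )

    @classmethod
    def canonical(cls, n_replicates: int = 2) -> "SampleDesign":
        """The full-factorial 2 x 2 x 3 x ``n_replicates`` layout."""
        rows = [
            {
                "sample_id": f"{ln}_{tr}_{tm}_r{r}",
                "line": ln,
                "treatment": tr,
                "time": tm,
                "replicate": r,
            }
            for ln in LINES
            for tr in TREATMENTS
            for tm in TIMES
            for r in range(1, n_replicates + 1)
        ]
        return cls(pd.DataFrame(rows))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def n_samples(self) -> int:
        return len(self.table)

    def condition_labels(self) -> pd.Series:
        """Per-sample condition name (e.g. ``ChLT0``), indexed by sample_id."""
        t = self.table
        labels = [
            condition_label(ln, tr, tm)
            for ln, tr, tm in zip(t["line"], t["treatment"], t["time"])
        ]
        return pd.Series(labels, index=t["sample_id"].values, name="condition")

    def samples_in_condition(self, condition: str) -> list[str]:
        lab = self.condition_labels()
        return list(lab.index[lab == condition])

    def factor(self, name: str) -> pd.Series:
        """One factor column as a Series indexed by sample_id."""
        return pd.Series(
            self.table[name].values, index=self.table["sample_id"].values, name=name
        )


@dataclass(frozen=True)
class CountMatrix:
    """Integer read counts, genes x samples, column order fixed by a design."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            raise ValidationError("duplicate gene identifiers in count matrix")
        if v.columns.duplicated().any():
            raise ValidationError("duplicate sample identifiers in count matrix")
        if v.isna().any().any():
            gene, sample = _first_offending(v.isna())
            raise ValidationError(f"missing count at gene {gene!r}, sample {sample!r}")
        arr = v.to_numpy()
        if (arr < 0).any():
            gene, sample = _first_offending(v < 0)
            raise ValidationError(f"negative count at gene {gene!r}, sample {sample!r}")
        frac = arr != arr.astype(int)
        if frac.any():
            gene, sample = _first_offending(pd.DataFrame(frac, index=v.index, columns=v.columns))
            raise ValidationError(
                f"non-integer count at gene {gene!r}, sample {sample!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _first_offending(mask: pd.DataFrame) -> tuple[str, str]:
    stacked = mask.stack()
    gene, sample = stacked.index[stacked.argmax()]
    return str(gene), str(sample)


@dataclass(frozen=True)
class BlastHitRecord:
    """One line of 12-column tabular BLAST output (outfmt 6 order)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValidationError(
                f"percent identity {self.percent_identity} outside [0, 100] "
                f"for hit {self.query_id} vs {self.subject_id}"
            )
        if self.alignment_length <= 0:
            raise ValidationError("alignment length must be positive")
        if self.evalue < 0:
            raise ValidationError("E-value must be non-negative")


@dataclass
class AnnotationBundle:
    """Functional annotation sidecars joined to genes by identifier.

    ``best_hit`` maps gene -> (subject id, E-value) for its best database
    match; ``tf_family`` and ``kinase_family`` are partial maps to family
    names; ``go_terms`` maps gene -> set of GO identifiers (possibly empty).
    """

    best_hit: dict[str, tuple[str, float]] = field(default_factory=dict)
    tf_family: dict[str, str] = field(default_factory=dict)
    kinase_family: dict[str, str] = field(default_factory=dict)
    go_terms: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, (_, ev) in self.best_hit.items():
            if ev < 0 or math.isnan(ev):
                raise ValidationError(f"negative or NaN E-value for gene {gene!r}")

    def best_evalue(self, gene: str) -> float | None:
        hit = self.best_hit.get(gene)
        return None if hit is None else hit[1]


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kwargs)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"empty table: {path}") from exc


def read_design(path: str | Path) -> SampleDesign:
    """Read a sample design table (tab-separated, one row per sample)."""
    table = _read_table(path, dtype={"sample_id": str})
    return SampleDesign(table)


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path, design: SampleDesign) -> CountMatrix:
    """Read a gene x sample count table and align its columns to ``design``.

    Files may contain extra samples (a master matrix); these are dropped.
    A design sample missing from the file is an error.
    """
    table = _read_table(path, index_col=0)
    table.index = table.index.astype(str)
    missing = [s for s in design.sample_ids if s not in table.columns]
    if missing:
        raise ValidationError(f"samples in design but not in count file: {missing}")
    return CountMatrix(table[design.sample_ids])


def write_counts(counts: CountMatrix, path: str | Path, gene_column: str = "gene_id") -> None:
    out = counts.values.copy()
    out.index.name = gene_column
    out.to_csv(path, sep="\t")


_BLAST_FIELDS = (
    ("query_id", str),
    ("subject_id", str),
    ("percent_identity", float),
    ("alignment_length", int),
    ("mismatches", int),
    ("gap_opens", int),
    ("q_start", int),
    ("q_end", int),
    ("s_start", int),
    ("s_end", int),
    ("evalue", float),
    ("bit_score", float),
)


def read_blast_tab(path: str | Path) -> list[BlastHitRecord]:
    """Parse a standard 12-column tabular BLAST hit file; no filtering."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[BlastHitRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValidationError(
                    f"{path}:{lineno}: expected >= 12 tab-separated fields, "
                    f"got {len(parts)}"
                )
            kwargs = {}
            for (name, cast), value in zip(_BLAST_FIELDS, parts):
                try:
                    kwargs[name] = cast(value)
                except ValueError as exc:
                    raise ValidationError(
                        f"{path}:{lineno}: cannot parse field {name!r} "
                        f"from {value!r}"
                    ) from exc
            records.append(BlastHitRecord(**kwargs))
    return records


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT-style gene-set file: term id, description, members."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError(
                    f"{path}:{lineno}: expected term, description, members"
                )
            term = parts[0]
            if term in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate term id {term!r}")
            sets[term] = set(g for g in parts[2:] if g)
    return sets


def write_gene_sets(sets: Mapping[str, Iterable[str]], path: str | Path,
                    descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for term, members in sets.items():
            desc = (descriptions or {}).get(term, "")
            fh.write("\t".join([term, desc, *sorted(set(members))]) + "\n")


def read_two_column_map(path: str | Path, key: str, value: str) -> dict[str, str]:
    """Read a gene -> label table (e.g. TF or kinase families)."""
    table = _read_table(path, dtype=str)
    for col in (key, value):
        if col not in table.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    if table[key].duplicated().any():
        dups = sorted(set(table[key][table[key].duplicated()]))
        raise ValidationError(f"{path}: duplicate keys {dups}")
    return dict(zip(table[key], table[value]))


def write_two_column_map(mapping: Mapping[str, str], path: str | Path,
                         key: str, value: str) -> None:
    pd.DataFrame({key: list(mapping), value: list(mapping.values())}).to_csv(
        path, sep="\t", index=False
    )


def read_best_hits(path: str | Path) -> dict[str, tuple[str, float]]:
    """Read a best-hit table: gene_id, subject_id, evalue."""
    table = _read_table(path, dtype={"gene_id": str, "subject_id": str})
    for col in ("gene_id", "subject_id", "evalue"):
        if col not in table.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    if table["gene_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate gene ids")
    return {
        g: (s, float(e))
        for g, s, e in zip(table["gene_id"], table["subject_id"], table["evalue"])
    }


def write_best_hits(best_hit: Mapping[str, tuple[str, float]], path: str | Path) -> None:
    rows = [
        {"gene_id": g, "subject_id": s, "evalue": e}
        for g, (s, e) in best_hit.items()
    ]
    pd.DataFrame(rows, columns=["gene_id", "subject_id", "evalue"]).to_csv(
        path, sep="\t", index=False
    )


def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR ratio table: transcript, timepoint, log2_ratio."""
    table = _read_table(path, dtype={"transcript": str, "timepoint": str})
    for col in ("transcript", "timepoint", "log2_ratio"):
        if col not in table.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return table


def write_qpcr_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
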