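"""Readers and writers for the tab-delimited interchange tables.

All tables are UTF-8 tab-delimited text with a mandatory header row.
Reading validates the schema row by row and reports offending line numbers;
a table written by this module reads back identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "PipelineConfig",
    "read_observations",
    "write_observations",
    "read_annotations",
    "write_annotations",
    "read_table",
    "write_table",
    "read_config",
    "write_config",
    "write_report",
]

OBSERVATION_COLUMNS = [
    "peptide_sequence", "charge", "mz", "protein_accessions",
    "stage", "replicate", "slice", "xic",
]
ANNOTATION_COLUMNS = [
    "accession", "cterm_tail", "signalp", "targetp", "predotar",
    "phobius", "tmhmm_tm_count", "domain_labels",
]


class SchemaError(ValueError):
    """A table violates its schema; the message names the offending line."""


@dataclass
class PipelineConfig:
    """All pipeline thresholds, in one serialisable place.

    Defaults follow the published analysis settings: proteins need at least
    two specific peptides and presence in at least three biological
    replicates within one stage; peptides need at least two replicates;
    stage effects are called at p < 0.001; the dendrogram is cut at height
    1.1.
    """

    stages: list[str] = field(default_factory=lambda: ["9DAF", "13DAF", "19DAF"])
    min_specific_peptides: int = 2
    min_replicates_presence: int = 3
    min_peptide_replicates: int = 2
    p_threshold: float = 0.001
    cluster_cut: float = 1.1
    preferential_margin: float = 0.1
    mz_tolerance_ppm: float = 10.0
    distance: str = "correlation"  # or "euclidean_std"
    linkage: str = "complete"
    #: count 2+/3+ ions of one sequence as a single peptide for the
    #: two-specific-peptides rule
    merge_charge_states: bool = True
    fdr: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not self.stages:
            raise ValueError("stages must be non-empty")
        for name in ("min_specific_peptides", "min_replicates_presence",
                     "min_peptide_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0, 1]")
        if self.cluster_cut < 0:
            raise ValueError("cluster_cut must be >= 0")
        if self.distance not in ("correlation", "euclidean_std"):
            raise ValueError(f"unknown distance {self.distance!r}")


def read_config(path: str | Path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg


def write_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


def _read_tsv(path: str | Path, required: Iterable[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return df


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read a peptide observation table, enforcing row invariants.

    Raises :class:`SchemaError` naming the first offending line (1-based,
    counting the header as line 1) for non-numeric or non-positive XICs,
    empty protein fields, bad charges or bad slice indices.
    """
    df = _read_tsv(path, OBSERVATION_COLUMNS)

    def fail(mask: pd.Series, why: str) -> None:
        if mask.any():
            line = int(mask.idxmax()) + 2  # +1 header, +1 zero-base
            raise SchemaError(f"{path}: line {line}: {why}")

    for col, kind in [("charge", int), ("slice", int), ("replicate", int),
                      ("mz", float), ("xic", float)]:
        converted = pd.to_numeric(df[col], errors="coerce")
        fail(converted.isna(), f"non-numeric value in column {col!r}")
        df[col] = converted.astype(kind)
    fail(df["xic"] <= 0, "xic must be positive")
    fail(df["charge"] < 1, "charge must be >= 1")
    fail(df["slice"] < 1, "slice index must be >= 1")
    fail(df["protein_accessions"].str.strip() == "", "empty protein field")
    fail(df["peptide_sequence"].str.strip() == "", "empty peptide sequence")
    return df[OBSERVATION_COLUMNS]


def write_observations(df: pd.DataFrame, path: str | Path) -> None:
    df[OBSERVATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, ANNOTATION_COLUMNS)
    dup = df["accession"].duplicated()
    if dup.any():
        line = int(dup.idxmax()) + 2
        raise SchemaError(f"{path}: line {line}: duplicate accession")
    df["tmhmm_tm_count"] = pd.to_numeric(
        df["tmhmm_tm_count"], errors="coerce").fillna(-1).astype(int)
    return df[ANNOTATION_COLUMNS]


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    df[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Generic reader for report tables written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", keep_default_na=False,
                       na_values=["NA"])


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    """Write protein sequences as FASTA (60-column wrapped)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=acc, description="")
               for acc, s in sequences.items()]
    seqio_write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio.SeqIO import parse as seqio_parse

    return {rec.id: str(rec.seq) for rec in seqio_parse(str(path), "fasta")}


def split_accessions(field: str) -> frozenset[str]:
    """Parse a semicolon-separated accession field into a set."""
    return frozenset(a for a in field.split(";") if a)


def write_report(results, outdir: str | Path) -> list[Path]:
    """Write the pipeline's report files into ``outdir``.

    ``results`` is a :class:`cwpquant.pipeline.PipelineResult`. Emits the
    CWP list with functional classes, Venn cell counts, the ANOVA table,
    cluster assignments with preferential stages, the filter audit and the
    selection-exclusion log, all as tab-delimited text. Returns the paths
    written. Empty results produce headers-only files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in results.report_tables().items():
        p = outdir / f"{name}.tsv"
        write_table(df, p)
        written.append(p)
    return written
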