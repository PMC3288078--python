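"""Readers and writers for the on-disk formats the pipeline touches.

Formats: BED3 (peaks, CpG islands), tabular gene models, FASTA
(genome / promoter sequences), TSV (expression matrix, sample sheet,
feature table, summaries).  All coordinates are converted to 0-based
half-open at this boundary; readers reject malformed records instead of
silently repairing them (the only normalizations are the documented
self-merge of peak intervals and FASTA upper-casing, both logged).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .genomic_model import (
    Condition,
    GenomicInterval,
    Mark,
    PeakSet,
    Strand,
    TssRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ParseError",
    "read_bed",
    "write_bed",
    "read_gene_models",
    "write_gene_models",
    "read_fasta",
    "write_fasta",
    "read_expression",
    "write_expression",
    "write_feature_table",
    "read_feature_table",
]


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# BED

def read_bed(
    path: str | Path,
    mark: Mark = Mark.H3AC,
    condition: Condition = Condition.MINUS,
    label: str = "",
) -> PeakSet:
    """Read a BED3+ file into a canonicalized PeakSet.

    Only columns 1-3 are interpreted (peak callers emit divergent extra
    columns).  Intervals are 0-based half-open as in BED; overlapping
    records are self-merged with the merge count logged.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinates") from exc
            if start >= end or start < 0:
                raise ParseError(
                    f"{path}:{lineno}: invalid interval {fields[0]}:{start}-{end}"
                )
            intervals.append(GenomicInterval(fields[0], start, end))
    ps = PeakSet(mark=mark, condition=condition, intervals=intervals,
                 label=label or str(path))
    if ps.n_merged:
        logger.info("read_bed(%s): merged %d overlapping records", path, ps.n_merged)
    return ps


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              names: Iterable[str] | None = None) -> None:
    path = Path(path)
    names = list(names) if names is not None else None
    with path.open("w") as fh:
        for i, iv in enumerate(intervals):
            extra = f"\t{names[i]}" if names else ""
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}{extra}\n")


# ---------------------------------------------------------------------------
# Gene models

_GENE_COLUMNS = ["gene_id", "seq_id", "strand", "tss_pos", "exon_starts", "exon_ends"]


def read_gene_models(path: str | Path, dialect: str = "table") -> list[TssRecord]:
    """Read gene models into TssRecords (one per annotated TSS).

    The ``table`` dialect expects a header with columns
    gene_id, seq_id, strand, tss_pos (1-based), exon_starts, exon_ends
    (comma-separated 1-based inclusive pairs).  Genes with several rows
    yield several records sharing gene_id.
    """
    if dialect != "table":
        raise ValueError(f"unsupported gene-model dialect: {dialect!r}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _GENE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    records: list[TssRecord] = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        if row.strand not in ("+", "-"):
            raise ParseError(f"{path}:{lineno}: bad strand {row.strand!r}")
        exons: list[GenomicInterval] = []
        starts = str(row.exon_starts).strip()
        ends = str(row.exon_ends).strip()
        if starts and starts.lower() != "nan":
            s_list = [int(x) for x in starts.rstrip(",").split(",")]
            e_list = [int(x) for x in ends.rstrip(",").split(",")]
            if len(s_list) != len(e_list):
                raise ParseError(f"{path}:{lineno}: exon_starts/ends length mismatch")
            # 1-based inclusive -> 0-based half-open
            exons = [GenomicInterval(row.seq_id, s - 1, e) for s, e in zip(s_list, e_list)]
        records.append(
            TssRecord(
                gene_id=row.gene_id,
                seq_id=row.seq_id,
                tss_pos=int(row.tss_pos) - 1,
                strand=Strand(row.strand),
                exons=exons,
            )
        )
    return records


def write_gene_models(records: Iterable[TssRecord], path: str | Path) -> None:
    """Inverse of :func:`read_gene_models` (table dialect, 1-based output)."""
    rows = []
    for r in records:
        rows.append(
            {
                "gene_id": r.gene_id,
                "seq_id": r.seq_id,
                "strand": r.strand.value,
                "tss_pos": r.tss_pos + 1,
                "exon_starts": ",".join(str(e.start + 1) for e in r.exons),
                "exon_ends": ",".join(str(e.end) for e in r.exons),
            }
        )
    pd.DataFrame(rows, columns=_GENE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {seq_id: sequence}; sequences are upper-cased."""
    path = Path(path)
    seqs: dict[str, list[str]] = {}
    name: str | None = None
    lowered = 0
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                if name in seqs:
                    raise ParseError(f"{path}: duplicate sequence id {name!r}")
                seqs[name] = []
            else:
                if name is None:
                    raise ParseError(f"{path}: sequence data before first header")
                if line != line.upper():
                    lowered += 1
                seqs[name].append(line.upper())
    if lowered:
        logger.info("read_fasta(%s): upper-cased %d lines", path, lowered)
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with Path(path).open("w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Expression matrix

@dataclass
class ExpressionMatrix:
    """Gene x sample log2 expression with a sample -> condition map."""

    gene_ids: list[str]
    sample_labels: list[str]
    condition_of_sample: dict[str, Condition]
    values: np.ndarray  # shape (n_genes, n_samples), log2 scale
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_labels)):
            raise ValueError("values shape does not match gene/sample labels")
        for cond in Condition:
            n = sum(1 for c in self.condition_of_sample.values() if c is cond)
            if n < 2:
                raise ValueError(
                    f"condition {cond.value} has {n} samples; need >=2 for a t-test"
                )

    def samples_of(self, cond: Condition) -> list[int]:
        return [
            i
            for i, s in enumerate(self.sample_labels)
            if self.condition_of_sample[s] is cond
        ]


def read_expression(
    expr_path: str | Path,
    samples_path: str | Path,
    linear: bool = False,
) -> ExpressionMatrix:
    """Read an expression TSV plus its sample-sheet sidecar.

    The expression TSV has a header ``gene_id <tab> sample...``; the
    sample sheet has columns ``sample, condition`` with condition in
    {minus_LPS, plus_LPS}.  Values are assumed log2 unless ``linear``;
    then they must be positive and are log2-transformed on load.  Rows
    with missing values are dropped (count logged); duplicate gene_id
    rows are an error.
    """
    df = pd.read_csv(expr_path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{expr_path}: duplicated gene_id rows {dups[:5]}")
    n_before = len(df)
    df = df.dropna()
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("read_expression(%s): dropped %d rows with missing values",
                    expr_path, n_dropped)
    sheet = pd.read_csv(samples_path, sep="\t", dtype=str)
    if not {"sample", "condition"} <= set(sheet.columns):
        raise ParseError(f"{samples_path}: need columns sample, condition")
    cond_map = {r.sample: Condition(r.condition) for r in sheet.itertuples()}
    unknown = [s for s in df.columns if s not in cond_map]
    if unknown:
        raise ParseError(f"{expr_path}: samples missing from sample sheet: {unknown}")
    values = df.to_numpy(dtype=float)
    if linear:
        if (values <= 0).any():
            raise ParseError(f"{expr_path}: non-positive values under --linear")
        values = np.log2(values)
    return ExpressionMatrix(
        gene_ids=list(df.index),
        sample_labels=list(df.columns),
        condition_of_sample={s: cond_map[s] for s in df.columns},
        values=values,
        n_dropped=n_dropped,
    )


def write_expression(m: ExpressionMatrix, expr_path: str | Path,
                     samples_path: str | Path) -> None:
    df = pd.DataFrame(m.values, index=m.gene_ids, columns=m.sample_labels)
    df.index.name = "gene_id"
    df.to_csv(expr_path, sep="\t", float_format="%.6f")
    pd.DataFrame(
        {
            "sample": m.sample_labels,
            "condition": [m.condition_of_sample[s].value for s in m.sample_labels],
        }
    ).to_csv(samples_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Feature table (the integrated per-TSS output)

FEATURE_COLUMNS = [
    "gene_id",
    "tss_pos",
    "strand",
    "p_value",
    "fold_change",
    "de_call",
    "h3ac_common",
    "extension",
    "s5p_status",
    "sp1_status",
    "cpg",
    "tata",
    "group",
]


def _fmt_float(x: float | None) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{x:.4g}"


def write_feature_table(profiles: Iterable, path: str | Path) -> None:
    """Write TssFeatureProfiles as a TSV mirroring the per-TSS report layout."""
    with Path(path).open("w") as fh:
        fh.write("\t".join(FEATURE_COLUMNS) + "\n")
        for p in profiles:
            de = p.de
            fh.write(
                "\t".join(
                    [
                        p.gene_id,
                        str(p.tss.tss_pos),
                        p.tss.strand.value,
                        _fmt_float(de.p_value if de else None),
                        _fmt_float(de.fold_change if de else None),
                        de.call if de else "NA",
                        "YES" if p.h3ac_common else "NO",
                        p.extension,
                        p.s5p_status,
                        p.sp1_status,
                        "YES" if p.cpg else "NO",
                        "YES" if p.tata else "NO",
                        str(p.group),
                    ]
                )
                + "\n"
            )


def read_feature_table(path: str | Path) -> pd.DataFrame:
    # keep_default_na: "null" is a legitimate DE call, not a missing value
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing feature columns {missing}")
    return df
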