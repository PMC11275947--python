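"""Readers and writers for the genomic and tabular formats the pipeline touches.

All coordinates are 0-based half-open (BED-native) internally.  GTF input
(1-based inclusive) is converted on read.  Peak enrichment is taken from the
narrowPeak ``signalValue`` column (column 7) and treated as a uniform
per-base signal across the peak.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GenomicInterval",
    "GeneAnnotation",
    "ExpressionTable",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_gene_annotations",
    "write_gene_annotations_bed6",
    "read_expression_table",
    "write_expression_table",
    "write_predictions",
    "ParseError",
    "ValidationError",
]


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


class ValidationError(ValueError):
    """A parsed record violates an invariant (coordinates, strand, keys)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A signal-carrying interval: ``[start, end)`` on ``chrom``.

    ``signal`` is a non-negative per-base enrichment (uniform over the
    interval); ``strand`` is '+', '-' or '.' (unstranded).
    """

    chrom: str
    start: int
    end: int
    signal: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start coordinate: {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end ({self.end}) must be > start ({self.start})"
            )
        if self.signal < 0:
            raise ValidationError(f"negative signal: {self.signal}")
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene locus reduced to what featurization needs: TSS and strand.

    ``tss`` is 0-based; for a minus-strand gene it is the last base of the
    annotated interval (``end - 1`` in half-open coordinates).
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValidationError(f"negative TSS for {self.gene_id}")
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene strand must be '+' or '-', got {self.strand!r}"
            )


@dataclass
class ExpressionTable:
    """Expression values keyed by (gene_id, cell_line); assumed log-scaled."""

    records: dict[tuple[str, str], float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, key: tuple[str, str]) -> float:
        return self.records[key]

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.records

    @property
    def keys(self) -> set[tuple[str, str]]:
        return set(self.records)


def read_narrowpeak(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read an ENCODE narrowPeak (BED6+4) file into intervals.

    One interval per line; the per-base signal is column 7 (signalValue).
    Coordinates are kept 0-based half-open as in the file.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=10 tab-separated "
                    f"narrowPeak columns, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
                strand = fields[5] if fields[5] in ("+", "-", ".") else "."
                signal = float(fields[6])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, signal=signal, strand=strand)
                )
            except ValidationError as exc:
                raise ValidationError(
                    f"{path}: line {lineno}: {exc}"
                ) from exc
    return intervals


def write_narrowpeak(intervals: Iterable[GenomicInterval], path: str | os.PathLike) -> None:
    """Write intervals as narrowPeak; round-trips exactly through the reader."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak{i}\t0\t{iv.strand}\t"
                f"{iv.signal!r}\t-1\t-1\t{len(iv) // 2}\n"
            )


def read_gene_annotations(
    path: str | os.PathLike, format: str = "bed6"
) -> list[GeneAnnotation]:
    """Read gene annotations from BED6 or a minimal GTF (gene lines only).

    TSS convention: for '+' the interval start; for '-' the last covered
    base, i.e. ``end - 1`` half-open.  GTF 1-based starts are converted to
    0-based before the same rule applies.
    """
    if format not in ("bed6", "gtf"):
        raise ValueError(f"unknown annotation format: {format!r}")
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if format == "bed6":
                    if len(fields) < 6:
                        raise ParseError("expected 6 BED columns")
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    gene_id, strand = fields[3], fields[5]
                else:
                    if len(fields) < 9:
                        raise ParseError("expected 9 GTF columns")
                    if fields[2] != "gene":
                        continue
                    chrom = fields[0]
                    start = int(fields[3]) - 1  # GTF is 1-based inclusive
                    end = int(fields[4])
                    strand = fields[6]
                    gene_id = _gtf_gene_id(fields[8])
            except ParseError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if strand not in ("+", "-"):
                raise ValidationError(
                    f"{path}: line {lineno}: unknown strand {strand!r}"
                )
            if gene_id in seen:
                raise ValidationError(
                    f"{path}: line {lineno}: duplicate gene_id {gene_id!r}"
                )
            seen.add(gene_id)
            tss = start if strand == "+" else end - 1
            genes.append(GeneAnnotation(gene_id, chrom, strand, tss))
    return genes


def _gtf_gene_id(attributes: str) -> str:
    for chunk in attributes.split(";"):
        chunk = chunk.strip()
        if chunk.startswith("gene_id"):
            return chunk.split(None, 1)[1].strip().strip('"')
    raise ParseError("no gene_id attribute in GTF line")


def write_gene_annotations_bed6(
    genes: Iterable[GeneAnnotation], path: str | os.PathLike, gene_length: int = 1000
) -> None:
    """Write genes as BED6 so that re-reading reproduces each TSS exactly."""
    with open(path, "w") as fh:
        for g in genes:
            if g.strand == "+":
                start, end = g.tss, g.tss + gene_length
            else:
                start, end = max(0, g.tss + 1 - gene_length), g.tss + 1
            fh.write(f"{g.chrom}\t{start}\t{end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_expression_table(path: str | os.PathLike) -> ExpressionTable:
    """Read a TSV with header ``gene_id  cell_line  expression``."""
    df = pd.read_csv(
        path, sep="\t", dtype={"gene_id": str, "cell_line": str},
        float_precision="round_trip",
    )
    required = {"gene_id", "cell_line", "expression"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    expr = pd.to_numeric(df["expression"], errors="coerce")
    bad = df.index[expr.isna()]
    if len(bad):
        raise ParseError(
            f"{path}: non-numeric expression value at data row {bad[0] + 1}"
        )
    table = ExpressionTable()
    for gene_id, cell_line, value in zip(df["gene_id"], df["cell_line"], expr):
        key = (gene_id, cell_line)
        if key in table.records:
            raise ValidationError(f"{path}: duplicate key {key}")
        table.records[key] = float(value)
    return table


def write_expression_table(table: ExpressionTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcell_line\texpression\n")
        for (gene_id, cell_line), value in table.records.items():
            fh.write(f"{gene_id}\t{cell_line}\t{value!r}\n")


def write_predictions(
    records: Sequence[tuple[str, float, float]], path: str | os.PathLike
) -> None:
    """Write per-sample predictions as TSV: sample_id, y_true, y_pred, residual.

    The residual column is ``y_true - y_pred`` verbatim (the quantity the
    residual plots are drawn from).
    """
    with open(path, "w") as fh:
        fh.write("sample_id\ty_true\ty_pred\tresidual\n")
        for sample_id, y_true, y_pred in records:
            fh.write(f"{sample_id}\t{y_true!r}\t{y_pred!r}\t{y_true - y_pred!r}\n")
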