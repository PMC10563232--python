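"""Shared domain types and readers/writers for the pipeline's exchange formats.

Internal coordinates are 0-based half-open throughout; GTF input/output
converts at the boundary (GTF is 1-based inclusive).  TSV is the exchange
format for matrices, designs, edges and GO annotations (UTF-8, tab-delimited,
lines starting with ``#`` are ignored).  All writers sort on stable keys so a
rerun on identical inputs is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BIOTYPES = ("mRNA", "lncRNA", "unclassified", "miRNA_precursor")
VALID_UNITS = ("count", "FPKM", "TPM")
VALID_GROUPS = ("TPS", "MPS")


class GTFParseError(ValueError):
    """Raised for malformed GTF content; message names the offending line."""


@dataclass
class TranscriptModel:
    """A located transcript: genomic span plus exon structure.

    ``start``/``end`` and every exon are 0-based half-open base-pair
    intervals on ``chrom``.  Exons must be sorted, non-overlapping and lie
    within ``[start, end)``.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    biotype: str = "unclassified"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"{self.transcript_id}: start must be < end ({self.start}, {self.end})")
        if self.biotype not in VALID_BIOTYPES:
            raise ValueError(f"{self.transcript_id}: unknown biotype {self.biotype!r}")
        exons = tuple((int(a), int(b)) for a, b in self.exons)
        if not exons:
            raise ValueError(f"{self.transcript_id}: transcript needs at least one exon")
        prev_end = None
        for a, b in exons:
            if a >= b:
                raise ValueError(f"{self.transcript_id}: empty exon ({a}, {b})")
            if a < self.start or b > self.end:
                raise ValueError(
                    f"{self.transcript_id}: exon ({a}, {b}) outside transcript span "
                    f"[{self.start}, {self.end})"
                )
            if prev_end is not None and a < prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap or are unsorted at ({a}, {b})")
            prev_end = b
        self.exons = exons

    @property
    def length(self) -> int:
        """Transcript length = sum of exon lengths (bp)."""
        return sum(b - a for a, b in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def with_biotype(self, biotype: str) -> "TranscriptModel":
        return replace(self, biotype=biotype)


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Sort and merge overlapping/adjacent half-open intervals."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return tuple((a, b) for a, b in merged)


def _parse_gtf_attributes(block: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in block.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            raise GTFParseError(f"line {lineno}: malformed attribute {chunk!r}")
        key, value = parts
        attrs[key] = value.strip().strip('"')
    return attrs


def read_transcript_models(path: str | Path) -> list[TranscriptModel]:
    """Parse a GTF file into :class:`TranscriptModel` records.

    Only ``exon`` features (and optional ``transcript`` span declarations)
    are consumed.  Coordinates are converted from GTF 1-based inclusive to
    internal 0-based half-open.  Exons are merged per transcript and sorted.
    Duplicate transcript declarations, conflicting locations, or exons
    outside a declared transcript span are hard errors.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str, str]] = {}  # tid -> (gene, chrom, strand, biotype)
    declared_span: dict[str, tuple[int, int]] = {}
    order: list[str] = []

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GTFParseError(f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_block = fields
            if feature not in ("exon", "transcript"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GTFParseError(f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}") from None
            attrs = _parse_gtf_attributes(attr_block, lineno)
            if "transcript_id" not in attrs or "gene_id" not in attrs:
                raise GTFParseError(f"line {lineno}: missing transcript_id/gene_id attribute")
            tid = attrs["transcript_id"]
            biotype = attrs.get("biotype", attrs.get("transcript_biotype", "unclassified"))
            key = (attrs["gene_id"], chrom, strand, biotype)
            if tid in meta:
                if feature == "transcript":
                    if tid in declared_span:
                        raise GTFParseError(f"line {lineno}: duplicate transcript declaration for {tid!r}")
                if meta[tid] != key:
                    raise GTFParseError(f"line {lineno}: conflicting redefinition of transcript {tid!r}")
            else:
                meta[tid] = key
                order.append(tid)
            iv = (start1 - 1, end1)  # to 0-based half-open
            if feature == "transcript":
                declared_span[tid] = iv
            else:
                exons.setdefault(tid, []).append(iv)

    models = []
    for tid in order:
        gene_id, chrom, strand, biotype = meta[tid]
        if tid not in exons:
            raise GTFParseError(f"transcript {tid!r} has no exon features")
        merged = _merge_intervals(exons[tid])
        if tid in declared_span:
            span = declared_span[tid]
            if merged[0][0] < span[0] or merged[-1][1] > span[1]:
                raise ValueError(
                    f"transcript {tid!r}: exon outside declared transcript span "
                    f"[{span[0]}, {span[1]})"
                )
            start, end = span
        else:
            start, end = merged[0][0], merged[-1][1]
        models.append(
            TranscriptModel(
                transcript_id=tid, gene_id=gene_id, chrom=chrom, strand=strand,
                start=start, end=end, exons=merged, biotype=biotype,
            )
        )
    return models


def write_transcript_models(models: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write models as GTF (transcript + exon lines, 1-based inclusive)."""
    lines = []
    for m in sorted(models, key=lambda m: (m.chrom, m.start, m.transcript_id)):
        attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
        if m.biotype != "unclassified":
            attrs += f' biotype "{m.biotype}";'
        lines.append(
            f"{m.chrom}\tcernapipe\ttranscript\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t{attrs}"
        )
        for a, b in m.exons:
            lines.append(f"{m.chrom}\tcernapipe\texon\t{a + 1}\t{b}\t.\t{m.strand}\t.\t{attrs}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass
class ExpressionMatrix:
    """Features x samples expression values with a unit tag.

    ``data`` is a pandas DataFrame indexed by feature id with sample-id
    columns.  Values must be non-negative; ``unit='count'`` additionally
    requires integer-valued entries.
    """

    data: pd.DataFrame
    unit: str = "count"

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if values.size and (values < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.unit == "count" and values.size and not np.allclose(values, np.round(values)):
            raise ValueError("count matrices must be integer-valued")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def read_expression_matrix(path: str | Path, unit: str = "count") -> ExpressionMatrix:
    """Read a TSV (first column feature id, header row sample ids)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    numeric = pd.DataFrame(index=df.index)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(f"{path}: non-numeric value at feature {row!r}, sample {col!r}")
        numeric[col] = converted
    numeric.index.name = df.index.name
    return ExpressionMatrix(numeric.astype(float), unit=unit)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.data
    if matrix.unit == "count":
        df = df.round().astype(int)
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_design(path: str | Path) -> pd.DataFrame:
    """Read a sample design TSV with columns sample_id, group, replicate."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample_id", "group", "replicate"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: design requires columns {sorted(required)}")
    unknown = set(df["group"]) - set(VALID_GROUPS)
    if unknown:
        raise ValueError(f"{path}: unknown groups {sorted(unknown)}; expected {VALID_GROUPS}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    df["replicate"] = df["replicate"].astype(int)
    if (df["replicate"] < 1).any():
        raise ValueError(f"{path}: replicate numbers must be positive")
    return df


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False)


@dataclass
class GOAnnotationTable:
    """feature id -> set of GO term ids, plus optional term labels."""

    annotations: dict[str, frozenset[str]]
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fid, terms in self.annotations.items():
            if not terms:
                raise ValueError(f"feature {fid!r} has an empty GO term set")

    def terms(self) -> list[str]:
        out: set[str] = set()
        for t in self.annotations.values():
            out |= t
        return sorted(out)


def read_go_annotations(path: str | Path, term_names_path: str | Path | None = None) -> GOAnnotationTable:
    """Read ``feature_id<TAB>GO:A;GO:B`` lines (and optional term-name TSV)."""
    ann: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path} line {lineno}: expected feature_id<TAB>terms")
            fid, terms_s = parts[0], parts[1]
            terms = frozenset(t for t in terms_s.split(";") if t)
            if fid in ann:
                raise ValueError(f"{path} line {lineno}: duplicate feature {fid!r}")
            ann[fid] = terms
    names: dict[str, str] = {}
    if term_names_path is not None:
        with open(term_names_path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                term, name = line.split("\t", 1)
                names[term] = name
    return GOAnnotationTable(ann, names)


def write_go_annotations(table: GOAnnotationTable, path: str | Path,
                         term_names_path: str | Path | None = None) -> None:
    lines = [f"{fid}\t{';'.join(sorted(terms))}" for fid, terms in sorted(table.annotations.items())]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    if term_names_path is not None:
        tlines = [f"{t}\t{n}" for t, n in sorted(table.term_names.items())]
        Path(term_names_path).write_text("\n".join(tlines) + "\n", encoding="utf-8")


VALID_EDGE_TYPES = ("mirna_mrna", "mirna_lncrna", "lncrna_mrna")
VALID_EDGE_MODES = ("seed", "cis_overlap", "cis_nonoverlap", "trans")


@dataclass
class InteractionEdge:
    """A regulator -> target pair with mode-dependent scores.

    miRNA edges (``mirna_mrna``/``mirna_lncrna``) carry the alignment
    penalty, duplex energy/ratio and the target-site position; lncRNA edges
    (``lncrna_mrna``) carry the gating correlations and, for trans edges,
    the local duplex energy.
    """

    regulator_id: str
    target_id: str
    edge_type: str
    mode: str
    penalty_score: float | None = None
    energy: float | None = None
    energy_ratio: float | None = None
    spearman: float | None = None
    pearson: float | None = None
    site_position: int | None = None
    antisense: bool | None = None

    def __post_init__(self) -> None:
        if self.edge_type not in VALID_EDGE_TYPES:
            raise ValueError(f"unknown edge_type {self.edge_type!r}")
        if self.mode not in VALID_EDGE_MODES:
            raise ValueError(f"unknown mode {self.mode!r}")


_EDGE_COLUMNS = (
    "regulator", "target", "edge_type", "mode", "penalty_score", "energy",
    "energy_ratio", "spearman", "pearson", "site_position", "antisense",
)


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_edges(edges: Sequence[InteractionEdge], path: str | Path) -> None:
    """Write edges as TSV, deterministically sorted by (regulator, target)."""
    rows = sorted(edges, key=lambda e: (e.regulator_id, e.target_id, e.edge_type, e.mode))
    lines = ["\t".join(_EDGE_COLUMNS)]
    for e in rows:
        lines.append("\t".join(_fmt(v) for v in (
            e.regulator_id, e.target_id, e.edge_type, e.mode, e.penalty_score,
            e.energy, e.energy_ratio, e.spearman, e.pearson, e.site_position,
            e.antisense,
        )))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_edges(path: str | Path) -> list[InteractionEdge]:
    def _parse(value: str, caster):
        return None if value == "NA" else caster(value)

    edges = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _EDGE_COLUMNS:
            raise ValueError(f"{path}: unexpected edge header {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            edges.append(InteractionEdge(
                regulator_id=f[0], target_id=f[1], edge_type=f[2], mode=f[3],
                penalty_score=_parse(f[4], float), energy=_parse(f[5], float),
                energy_ratio=_parse(f[6], float), spearman=_parse(f[7], float),
                pearson=_parse(f[8], float), site_position=_parse(f[9], int),
                antisense=_parse(f[10], lambda v: v == "1"),
            ))
    return edges


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence dict (uppercased)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_json(obj, path: str | Path) -> None:
    """Deterministic JSON writer (sorted keys, fixed separators)."""
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n", encoding="utf-8")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text(encoding="utf-8"))
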