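"""Readers and writers for the external formats the pipeline touches.

All sequences are stored internally over the DNA alphabet (``U`` is converted
to ``T`` on read and restored on write when the source was RNA).  Internal
coordinates are 0-based half-open; human-facing TSV exports are 1-based
inclusive and say so in a header comment.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

ARM_VALUES = ("5p", "3p", "unknown")
NAMESPACES = ("GO:BP", "GO:MF", "GO:CC", "KEGG")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ConsistencyError(ValueError):
    """Cross-file records contradict each other."""


class SchemaError(ValueError):
    """A row does not conform to the declared table schema."""


def revcomp(sequence: str) -> str:
    """Reverse complement over the internal DNA alphabet."""
    return sequence.translate(_COMPLEMENT)[::-1]


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode, encoding="utf-8")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


@dataclass
class SeqRecord:
    """A named sequence; ``was_rna`` records the source alphabet."""

    id: str
    description: str = ""
    sequence: str = ""
    was_rna: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path) -> list[SeqRecord]:
    """Parse a FASTA file with strict validation.

    Sequences are upper-cased; ``U`` is converted to ``T`` and the record
    flagged ``was_rna``.  Malformed headers, empty sequences, illegal
    characters and duplicate ids raise :class:`FormatError` naming the line.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    current: list | None = None  # [id, description, chunks, header_lineno]

    def finish(cur) -> SeqRecord:
        rid, desc, chunks, lineno = cur
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"{path}: empty sequence for record {rid!r} (header at line {lineno})")
        was_rna = "U" in seq
        return SeqRecord(rid, desc, seq.replace("U", "T"), was_rna)

    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if current is not None:
                    records.append(finish(current))
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"{path}: malformed (empty) header at line {lineno}")
                parts = header.split(None, 1)
                rid = parts[0]
                if rid in seen:
                    raise FormatError(f"{path}: duplicate record id {rid!r} at line {lineno}")
                seen.add(rid)
                current = [rid, parts[1] if len(parts) > 1 else "", [], lineno]
            else:
                if current is None:
                    raise FormatError(f"{path}: sequence data before any header at line {lineno}")
                chunk = line.strip().upper()
                bad = set(chunk) - (DNA_ALPHABET | {"U"})
                if bad:
                    raise FormatError(
                        f"{path}: illegal character(s) {sorted(bad)} at line {lineno}"
                    )
                current[2].append(chunk)
    if current is not None:
        records.append(finish(current))
    return records


def write_fasta(path, records: Iterable[SeqRecord], width: int = 60) -> None:
    """Write FASTA; records flagged ``was_rna`` are restored to the RNA alphabet."""
    with _open_text(path, "wt") as handle:
        for rec in records:
            seq = rec.sequence.replace("T", "U") if rec.was_rna else rec.sequence
            header = f">{rec.id} {rec.description}".rstrip()
            handle.write(header + "\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------


@dataclass
class FastqRead:
    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.quality) != len(self.sequence):
            raise FormatError(
                f"read {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def read_fastq(path) -> Iterator[FastqRead]:
    """Stream 4-line FASTQ records (Phred+33) in file order."""
    with _open_text(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                seq = seq.upper()
                bad = set(seq) - DNA_ALPHABET
                if bad:
                    raise FormatError(f"{path}: illegal character(s) {sorted(bad)} in read {title!r}")
                yield FastqRead(title.split()[0], seq, qual)
        except ValueError as exc:  # Biopython signals malformed records
            if isinstance(exc, FormatError):
                raise
            raise FormatError(f"{path}: {exc}") from exc


def write_fastq(path, reads: Iterable[FastqRead]) -> None:
    with _open_text(path, "wt") as handle:
        for read in reads:
            handle.write(f"@{read.id}\n{read.sequence}\n+\n{read.quality}\n")


# ---------------------------------------------------------------------------
# miRBase-dialect references
# ---------------------------------------------------------------------------


@dataclass
class MatureAnnotation:
    """Placement of an annotated mature miRNA within its precursor."""

    precursor_id: str
    mature_id: str
    arm: str = "unknown"
    start: int = 0
    end: int = 0

    def __post_init__(self) -> None:
        if self.arm not in ARM_VALUES:
            raise ValueError(f"arm must be one of {ARM_VALUES}, got {self.arm!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.mature_id}: invalid coordinates [{self.start}, {self.end})"
            )


def read_mirbase_dialect(hairpin_path, mature_path, coords_path):
    """Load precursor/mature FASTA plus a coords TSV.

    The coords TSV has columns ``mature_id, precursor_id, start, end, arm``
    (0-based half-open).  Every mature sequence must equal the precursor
    substring at its coordinates (after U->T).  Matures absent from the
    coords file fall back to a unique exact substring search with arm
    ``unknown``; a non-unique or absent match is a consistency error.

    Returns ``(precursors, matures, annotations)``.
    """
    precursors = read_fasta(hairpin_path)
    matures = read_fasta(mature_path)
    prec_by_id = {p.id: p for p in precursors}
    mat_by_id = {m.id: m for m in matures}

    annotations: list[MatureAnnotation] = []
    annotated: set[str] = set()
    with _open_text(coords_path) as handle:
        header = None
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                expected = ["mature_id", "precursor_id", "start", "end", "arm"]
                if fields != expected:
                    raise FormatError(
                        f"{coords_path}: expected header {expected}, got {fields}"
                    )
                continue
            if len(fields) != 5:
                raise FormatError(f"{coords_path}: expected 5 columns at line {lineno}")
            mature_id, precursor_id, start_s, end_s, arm = fields
            ann = MatureAnnotation(precursor_id, mature_id, arm, int(start_s), int(end_s))
            if mature_id not in mat_by_id:
                raise ConsistencyError(
                    f"{coords_path}: mature id {mature_id!r} not present in {mature_path}"
                )
            if precursor_id not in prec_by_id:
                raise ConsistencyError(
                    f"{coords_path}: precursor id {precursor_id!r} not present in {hairpin_path}"
                )
            prec = prec_by_id[precursor_id]
            if ann.end > len(prec):
                raise ConsistencyError(
                    f"{mature_id}: coordinates [{ann.start}, {ann.end}) exceed "
                    f"precursor {precursor_id} length {len(prec)}"
                )
            if prec.sequence[ann.start : ann.end] != mat_by_id[mature_id].sequence:
                raise ConsistencyError(
                    f"mature {mature_id!r} does not match precursor {precursor_id!r} "
                    f"substring [{ann.start}, {ann.end})"
                )
            annotations.append(ann)
            annotated.add(mature_id)

    for mature in matures:
        if mature.id in annotated:
            continue
        hits = []
        for prec in precursors:
            start = prec.sequence.find(mature.sequence)
            while start != -1:
                hits.append((prec.id, start))
                start = prec.sequence.find(mature.sequence, start + 1)
        if len(hits) != 1:
            raise ConsistencyError(
                f"mature {mature.id!r} absent from coords and matched "
                f"{len(hits)} precursor positions (need exactly 1)"
            )
        prec_id, start = hits[0]
        annotations.append(
            MatureAnnotation(prec_id, mature.id, "unknown", start, start + len(mature.sequence))
        )

    return precursors, matures, annotations


def write_coords_tsv(path, annotations: Iterable[MatureAnnotation]) -> None:
    with _open_text(path, "wt") as handle:
        handle.write("mature_id\tprecursor_id\tstart\tend\tarm\n")
        for ann in annotations:
            handle.write(
                f"{ann.mature_id}\t{ann.precursor_id}\t{ann.start}\t{ann.end}\t{ann.arm}\n"
            )


# ---------------------------------------------------------------------------
# Annotation tables (gene -> term)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotationRow:
    gene_id: str
    term_id: str
    term_name: str
    namespace: str


def read_annotation_table(path) -> list[AnnotationRow]:
    """Read a TSV of gene->term annotations; (gene_id, term_id) must be unique."""
    rows: list[AnnotationRow] = []
    seen: set[tuple[str, str]] = set()
    with _open_text(path) as handle:
        header = None
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if fields[:4] != ["gene_id", "term_id", "term_name", "namespace"]:
                    raise FormatError(f"{path}: unexpected annotation header {fields}")
                continue
            gene_id, term_id, term_name, namespace = fields[:4]
            if namespace not in NAMESPACES:
                raise FormatError(
                    f"{path}: namespace {namespace!r} at line {lineno} not in {NAMESPACES}"
                )
            key = (gene_id, term_id)
            if key in seen:
                raise FormatError(f"{path}: duplicate (gene, term) pair {key} at line {lineno}")
            seen.add(key)
            rows.append(AnnotationRow(gene_id, term_id, term_name, namespace))
    return rows


def write_annotation_table(path, rows: Iterable[AnnotationRow]) -> None:
    with _open_text(path, "wt") as handle:
        handle.write("gene_id\tterm_id\tterm_name\tnamespace\n")
        for row in rows:
            handle.write(f"{row.gene_id}\t{row.term_id}\t{row.term_name}\t{row.namespace}\n")


# ---------------------------------------------------------------------------
# Generic TSV tables with schema
# ---------------------------------------------------------------------------

_KINDS = {"str": str, "int": int, "float": float}


def format_float(value) -> str:
    """Render a float with 6 significant digits; NaN renders as ``NA``."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    return f"{float(value):.6g}"


def write_tsv_table(path, rows: Sequence[dict], schema: Sequence[tuple[str, str]],
                    comment: str | None = None) -> None:
    """Write a schema-checked TSV table (header line, UTF-8, byte-stable).

    ``schema`` is a sequence of ``(column, kind)`` with kind in
    ``{"str", "int", "float"}``.  Floats are rendered with 6 significant
    digits; NaN floats render as ``NA``.
    """
    for column, kind in schema:
        if kind not in _KINDS:
            raise SchemaError(f"unknown kind {kind!r} for column {column!r}")
    with _open_text(path, "wt") as handle:
        if comment:
            handle.write(f"# {comment}\n")
        handle.write("\t".join(column for column, _ in schema) + "\n")
        for index, row in enumerate(rows):
            cells = []
            for column, kind in schema:
                if column not in row:
                    raise SchemaError(f"row {index}: missing column {column!r}")
                value = row[column]
                if kind == "float":
                    if value is not None and not isinstance(value, (int, float)):
                        raise SchemaError(f"row {index}: column {column!r} is not numeric")
                    cells.append(format_float(value))
                elif kind == "int":
                    if isinstance(value, bool) or not isinstance(value, int):
                        raise SchemaError(f"row {index}: column {column!r} is not an int")
                    cells.append(str(value))
                else:
                    cells.append(str(value))
            handle.write("\t".join(cells) + "\n")


def read_tsv_table(path, schema: Sequence[tuple[str, str]]) -> list[dict]:
    """Read a TSV written by :func:`write_tsv_table` back to row dicts."""
    rows: list[dict] = []
    columns = [column for column, _ in schema]
    kinds = dict(schema)
    with _open_text(path) as handle:
        header = None
        for raw in handle:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if fields != columns:
                    raise SchemaError(f"{path}: header {fields} != schema columns {columns}")
                continue
            row = {}
            for column, cell in zip(columns, fields):
                kind = kinds[column]
                if kind == "float":
                    row[column] = float("nan") if cell == "NA" else float(cell)
                elif kind == "int":
                    row[column] = int(cell)
                else:
                    row[column] = cell
            rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# Dot-bracket (Vienna-style) structure files
# ---------------------------------------------------------------------------


@dataclass
class DotBracketRecord:
    id: str
    sequence: str
    structure: str
    energy: float

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.sequence):
            raise FormatError(
                f"{self.id}: structure length {len(self.structure)} "
                f"!= sequence length {len(self.sequence)}"
            )
        depth = 0
        for char in self.structure:
            if char == "(":
                depth += 1
            elif char == ")":
                depth -= 1
                if depth < 0:
                    raise FormatError(f"{self.id}: unbalanced structure")
            elif char != ".":
                raise FormatError(f"{self.id}: illegal structure character {char!r}")
        if depth != 0:
            raise FormatError(f"{self.id}: unbalanced structure")


def read_dotbracket(path) -> list[DotBracketRecord]:
    """Read Vienna-style records: ``>id``, sequence line, ``structure (energy)``."""
    records: list[DotBracketRecord] = []
    with _open_text(path) as handle:
        lines = [line.rstrip("\n") for line in handle if line.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise FormatError(f"{path}: expected '>' header, got {lines[i]!r}")
        rid = lines[i][1:].split()[0]
        if i + 2 >= len(lines):
            raise FormatError(f"{path}: truncated record {rid!r}")
        sequence = lines[i + 1].strip().upper().replace("U", "T")
        struct_line = lines[i + 2].strip()
        if "(" in struct_line and struct_line.rstrip().endswith(")") and " " in struct_line:
            structure, _, energy_part = struct_line.rpartition(" ")
            energy = float(energy_part.strip("()").strip())
            structure = structure.strip()
        else:
            structure, energy = struct_line, 0.0
        records.append(DotBracketRecord(rid, sequence, structure, energy))
        i += 3
    return records


def write_dotbracket(path, records: Iterable[DotBracketRecord]) -> None:
    with _open_text(path, "wt") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n{rec.sequence}\n{rec.structure} ({rec.energy:.2f})\n")
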