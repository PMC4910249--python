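"""Reading and writing of the formats the pipeline touches.

FASTA/FASTQ ingestion (gzip-transparent) is delegated to Biopython; outputs
are unitig FASTA, GFA1 and a tab-separated mapping table.  All coordinates
in outputs are 0-based, half-open.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional

from Bio import SeqIO

from .errors import ParseError
from .graph import CompactedGraph
from .mapper import FORWARD, REVERSE, GraphMapping, Status

MAPPING_COLUMNS = ("read_id", "status", "orientation", "path", "start_offset", "mismatches")


@dataclass(frozen=True)
class ReadRecord:
    """One input sequence; qual, when present, matches the sequence length."""

    id: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(f"record {self.id!r}: quality/sequence length mismatch")


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _detect_format(path) -> Optional[str]:
    with _open_text(path) as handle:
        for line in handle:
            if line.strip():
                first = line[0]
                break
        else:
            return None  # empty file
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ParseError(f"{path}: cannot detect format from first character {first!r}")


def read_sequences(path, format: str = "auto") -> List[ReadRecord]:
    """Parse a FASTA/FASTQ file into uppercased records, in file order.

    Duplicate ids get a "/2", "/3", ... suffix.  Malformed records raise
    ParseError naming the offending line.
    """
    if format == "auto":
        format = _detect_format(path)
        if format is None:
            return []
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format: {format!r}")
    records: List[ReadRecord] = []
    seen: dict = {}
    lines_per_record = 4 if format == "fastq" else 2
    with _open_text(path) as handle:
        parser = SeqIO.parse(handle, format)
        while True:
            try:
                rec = next(parser, None)
            except ValueError as exc:
                line = len(records) * lines_per_record + 1
                raise ParseError(f"{path}: malformed {format} record near line {line}: {exc}") from exc
            if rec is None:
                break
            qual = None
            if format == "fastq":
                qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            name = rec.id
            seen[name] = seen.get(name, 0) + 1
            if seen[name] > 1:
                name = f"{name}/{seen[name]}"
            records.append(ReadRecord(id=name, seq=str(rec.seq).upper(), qual=qual))
    return records


def write_fasta(records: Iterable[ReadRecord], path) -> None:
    with _open_text(path, "wt") as out:
        for rec in records:
            out.write(f">{rec.id}\n{rec.seq}\n")


def write_fastq(records: Iterable[ReadRecord], path) -> None:
    with _open_text(path, "wt") as out:
        for rec in records:
            qual = rec.qual if rec.qual is not None else "I" * len(rec.seq)
            out.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")


def write_unitigs_fasta(graph: CompactedGraph, path) -> None:
    """One record per unitig, ascending id order."""
    with _open_text(path, "wt") as out:
        for u in graph:
            out.write(f">{u.id}\n{u.seq}\n")


def write_gfa(graph: CompactedGraph, path) -> None:
    """GFA1: S line per unitig, L line per directed (k-1)-overlap adjacency."""
    ov = graph.k - 1
    with _open_text(path, "wt") as out:
        out.write(f"H\tVN:Z:1.0\tkm:i:{graph.k}\n")
        for u in graph:
            out.write(f"S\t{u.id}\t{u.seq}\n")
        for u in graph:
            for vid in graph.neighbors(u.id, "out"):
                out.write(f"L\t{u.id}\t+\t{vid}\t+\t{ov}M\n")


def write_mappings(mappings: Iterable[GraphMapping], path) -> None:
    """Tab-separated mapping table, one row per read.

    Columns: read_id, status, orientation(+/-), path (comma-joined unitig
    ids), start_offset (0-based on the first unitig), mismatches.  The three
    last columns are empty for unmapped reads.
    """
    with _open_text(path, "wt") as out:
        out.write("# dbgmap mappings; coordinates are 0-based, half-open\n")
        out.write("#" + "\t".join(MAPPING_COLUMNS) + "\n")
        for m in mappings:
            orient = "+" if m.orientation == FORWARD else "-"
            if m.mapped:
                row = (m.read_id, m.status.value, orient, ",".join(m.walk), str(m.start_offset), str(m.mismatches))
            else:
                row = (m.read_id, m.status.value, orient, "", "", "")
            out.write("\t".join(row) + "\n")


def read_mappings(path) -> List[GraphMapping]:
    """Parse a table produced by :func:`write_mappings`."""
    mappings = []
    with _open_text(path) as handle:
        for line_no, line in enumerate(handle, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(MAPPING_COLUMNS):
                raise ParseError(f"{path}: line {line_no}: expected {len(MAPPING_COLUMNS)} columns")
            read_id, status, orient, walk, offset, mm = fields
            mappings.append(
                GraphMapping(
                    read_id=read_id,
                    status=Status(status),
                    orientation=FORWARD if orient == "+" else REVERSE,
                    walk=tuple(walk.split(",")) if walk else (),
                    start_offset=int(offset) if offset != "" else None,
                    mismatches=int(mm) if mm != "" else None,
                )
            )
    return mappings
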