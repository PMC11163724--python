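"""Readers and writers for splice-junction tables and GTF exon annotation.

Every in-memory coordinate in this package is 0-based half-open on the forward
genomic strand; all conversions from 1-based file formats happen here, at the
I/O boundary, and nowhere else.

Junction semantics: a :class:`SpliceJunction` describes one intron observed in
one sample — ``start`` is the first intronic base, ``end`` is one past the last
intronic base. A junction whose ``end`` equals an exon's ``start`` therefore
splices directly into that exon (and symmetrically for ``start`` == exon
``end``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from gffutils.feature import feature_from_line

from .errors import ParseError

JUNCTION_STRANDS = ("+", "-", ".")
EXON_STRANDS = ("+", "-")

#: STAR SJ.out.tab column 4 strand codes.
_STAR_STRAND = {"0": ".", "1": "+", "2": "-"}


@dataclass(frozen=True, slots=True)
class SpliceJunction:
    """One intron observation with unique-read support in a single sample."""

    chrom: str
    start: int  # 0-based first intronic base
    end: int  # 0-based exclusive, one past the last intronic base
    strand: str
    reads: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"junction start must be < end, got [{self.start}, {self.end})"
            )
        if self.reads < 0:
            raise ValueError(f"junction read count must be >= 0, got {self.reads}")
        if self.strand not in JUNCTION_STRANDS:
            raise ValueError(f"junction strand must be one of {JUNCTION_STRANDS}")

    @property
    def interval(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True, slots=True)
class ExonRecord:
    """One annotated exon (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    exon_id: str
    transcript_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"exon start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in EXON_STRANDS:
            raise ValueError(f"exon strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_star_sj(path: str | Path, sample_id: str) -> list[SpliceJunction]:
    """Read a STAR ``SJ.out.tab`` junction file.

    STAR reports 1-based inclusive intron coordinates and a numeric strand
    code (0 undefined, 1 '+', 2 '-'); column 7 is the unique-mapping read
    count. Coordinates are converted to 0-based half-open.
    """
    path = Path(path)
    junctions: list[SpliceJunction] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(
                    f"{path} line {lineno}: expected >= 9 tab-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                start1 = int(fields[1])
                end1 = int(fields[2])
                reads = int(fields[6])
            except ValueError as exc:
                raise ParseError(f"{path} line {lineno}: {exc}") from exc
            strand = _STAR_STRAND.get(fields[3])
            if strand is None:
                raise ParseError(
                    f"{path} line {lineno}: bad strand code {fields[3]!r}"
                )
            try:
                junctions.append(
                    SpliceJunction(
                        chrom=fields[0],
                        start=start1 - 1,
                        end=end1,  # 1-based inclusive == 0-based exclusive
                        strand=strand,
                        reads=reads,
                        sample_id=sample_id,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path} line {lineno}: {exc}") from exc
    if not junctions:
        warnings.warn(f"{path}: no junctions parsed", stacklevel=2)
    return junctions


def read_junction_bed(path: str | Path, sample_id: str) -> list[SpliceJunction]:
    """Read a 6-column junction BED (0-based half-open intron span).

    The score column is interpreted as the unique-read count; no coordinate
    shift is applied.
    """
    path = Path(path)
    junctions: list[SpliceJunction] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"{path} line {lineno}: expected 6 BED columns, got "
                    f"{len(fields)}"
                )
            try:
                start = int(fields[1])
                end = int(fields[2])
                reads = int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path} line {lineno}: {exc}") from exc
            try:
                junctions.append(
                    SpliceJunction(
                        chrom=fields[0],
                        start=start,
                        end=end,
                        strand=fields[5],
                        reads=reads,
                        sample_id=sample_id,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path} line {lineno}: {exc}") from exc
    if not junctions:
        warnings.warn(f"{path}: no junctions parsed", stacklevel=2)
    return junctions


def write_junction_bed(junctions: Iterable[SpliceJunction], path: str | Path) -> None:
    """Write junctions in the BED6 dialect read by :func:`read_junction_bed`."""
    with open(path, "w") as handle:
        for i, j in enumerate(junctions):
            name = f"j{i + 1}"
            handle.write(
                f"{j.chrom}\t{j.start}\t{j.end}\t{name}\t{j.reads}\t{j.strand}\n"
            )


def write_junction_tsv(junctions: Iterable[SpliceJunction], path: str | Path) -> None:
    """Write the normalized junction table (0-based half-open, with sample)."""
    with open(path, "w") as handle:
        handle.write("# coordinates: 0-based half-open intron span\n")
        handle.write("chrom\tstart\tend\tstrand\treads\tsample_id\n")
        for j in junctions:
            handle.write(
                f"{j.chrom}\t{j.start}\t{j.end}\t{j.strand}\t{j.reads}\t"
                f"{j.sample_id}\n"
            )


def read_exons_gtf(path: str | Path, feature: str = "exon") -> list[ExonRecord]:
    """Read exon records from a GTF/GFF file.

    Accepts both GTF (``key "value";``) and GFF (``key=value``) attribute
    dialects. 1-based inclusive coordinates are converted to 0-based
    half-open. A missing ``exon_id`` is synthesized deterministically as
    ``<transcript_id>_exon<ordinal>`` in file order. The reader is non-lossy:
    identical exon intervals shared by several transcripts all come through
    (deduplication is a downstream, explicit step; see
    :func:`unique_exon_intervals`).
    """
    path = Path(path)
    records: list[ExonRecord] = []
    per_transcript_count: dict[str, int] = {}
    saw_data = False
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            saw_data = True
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(
                    f"{path} line {lineno}: expected 9 GTF columns, got "
                    f"{len(fields)}"
                )
            if fields[2] != feature:
                continue
            strand = fields[6]
            if strand not in EXON_STRANDS:
                raise ParseError(
                    f"{path} line {lineno}: unknown strand symbol {strand!r}"
                )
            try:
                start1 = int(fields[3])
                end1 = int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path} line {lineno}: {exc}") from exc
            try:
                feat = feature_from_line(line.rstrip("\n"))
                attrs = feat.attributes
            except Exception as exc:  # gffutils raises assorted types
                raise ParseError(
                    f"{path} line {lineno}: bad attribute column ({exc})"
                ) from exc
            gene_id = _attr(attrs, "gene_id")
            if gene_id is None:
                raise ParseError(f"{path} line {lineno}: missing gene_id attribute")
            transcript_id = _attr(attrs, "transcript_id")
            if transcript_id is None:
                raise ParseError(
                    f"{path} line {lineno}: missing transcript_id attribute"
                )
            exon_id = _attr(attrs, "exon_id")
            if exon_id is None:
                ordinal = per_transcript_count.get(transcript_id, 0) + 1
                exon_id = f"{transcript_id}_exon{ordinal}"
            per_transcript_count[transcript_id] = (
                per_transcript_count.get(transcript_id, 0) + 1
            )
            try:
                records.append(
                    ExonRecord(
                        chrom=fields[0],
                        start=start1 - 1,
                        end=end1,
                        strand=strand,
                        gene_id=gene_id,
                        exon_id=exon_id,
                        transcript_id=transcript_id,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path} line {lineno}: {exc}") from exc
    if saw_data and not records:
        warnings.warn(f"{path}: no {feature!r} features found", stacklevel=2)
    return records


def _attr(attributes, key: str) -> str | None:
    values = attributes.get(key)
    if not values:
        return None
    return values[0] if isinstance(values, (list, tuple)) else str(values)


def unique_exon_intervals(exons: Iterable[ExonRecord]) -> list[ExonRecord]:
    """Deduplicate exons sharing an identical (chrom, start, end, strand).

    The first record for each interval (in input order) is kept, so the result
    is deterministic for a deterministic input ordering.
    """
    seen: set[tuple[str, int, int, str]] = set()
    unique: list[ExonRecord] = []
    for exon in exons:
        key = (exon.chrom, exon.start, exon.end, exon.strand)
        if key not in seen:
            seen.add(key)
            unique.append(exon)
    return unique
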