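"""Lift BED intervals from component coordinates to object coordinates.

After scaffolding, alignments made against the contigs (Hi-C read pairs,
typically) are still in contig coordinates.  Rather than re-aligning,
this module maps each BED interval through the AGP: find where the
contig span landed in its object, shift (and mirror, for ``-``-oriented
placements) the interval accordingly, and emit it under the object's
name.  BED is 0-based half-open and AGP 1-based inclusive; the
conversion happens in exactly two places — on entry to and exit from
:func:`transform_record` — so every off-by-one lives where a test can
pin it.

An interval overlapping a placement only partially is trimmed to the
overlap rather than dropped (keeping as much Hi-C signal as possible);
strict mode turns partial overlaps and intervals on unplaced components
into errors.  A component split across several placements yields one
output record per overlapped placement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, TextIO

from .agp import AgpDocument, ComponentRow
from .errors import AgpError, FileFormatError

logger = logging.getLogger("agptools")


@dataclass
class BedRecord:
    """One BED interval: 0-based half-open, extra columns preserved verbatim."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: str | None = None
    strand: str | None = None
    extra: list[str] = field(default_factory=list)

    def to_line(self) -> str:
        fields = [self.chrom, str(self.start), str(self.end)]
        for value in (self.name, self.score, self.strand):
            if value is None:
                break
            fields.append(value)
        fields.extend(self.extra)
        return "\t".join(fields)


class Placement(NamedTuple):
    """Where one component span sits in an object (all 1-based inclusive)."""

    object_name: str
    object_beg: int
    object_end: int
    component_beg: int
    component_end: int
    orientation: str


class PlacementIndex(dict):
    """component_id -> placements sorted by component_beg, non-overlapping."""


def build_index(doc: AgpDocument) -> PlacementIndex:
    """Index every component row of ``doc`` by component_id.

    Two placements of one component that overlap in component coordinates
    make the lift ambiguous and are an error here (plain :func:`validate`
    already warns about the component appearing in several objects).
    """
    index = PlacementIndex()
    for layout in doc.objects:
        for row in layout.rows:
            if isinstance(row, ComponentRow):
                index.setdefault(row.component_id, []).append(Placement(
                    layout.name, row.object_beg, row.object_end,
                    row.component_beg, row.component_end, row.orientation,
                ))
    for comp, placements in index.items():
        placements.sort(key=lambda p: p.component_beg)
        for a, b in zip(placements, placements[1:]):
            if b.component_beg <= a.component_end:
                raise AgpError(
                    f"overlapping placements of component {comp!r}: "
                    f"{a.component_beg}-{a.component_end} in "
                    f"{a.object_name!r} and {b.component_beg}-"
                    f"{b.component_end} in {b.object_name!r}"
                )
    return index


def transform_record(rec: BedRecord, index: PlacementIndex,
                     strict: bool = False) -> list[BedRecord]:
    """Map one BED record through the index; one output per placement hit.

    The interval is converted to 1-based inclusive, clipped to each
    overlapping placement's component span, mapped (``+``: constant
    shift; ``-``: mirrored through the placement), re-ordered so start
    precedes end, and converted back to BED.  The strand column, when
    present and directional, is toggled on ``-`` placements.
    """
    if rec.start < 0 or rec.end <= rec.start:
        raise AgpError(
            f"bad BED interval {rec.chrom}:{rec.start}-{rec.end} "
            "(need 0 <= start < end)"
        )
    placements = index.get(rec.chrom, [])
    beg1, end1 = rec.start + 1, rec.end  # 1-based inclusive
    out: list[BedRecord] = []
    for p in placements:
        lo = max(beg1, p.component_beg)
        hi = min(end1, p.component_end)
        if lo > hi:
            continue
        if strict and (lo, hi) != (beg1, end1):
            raise AgpError(
                f"interval {rec.chrom}:{rec.start}-{rec.end} extends outside "
                f"placement {p.component_beg}-{p.component_end} "
                f"in {p.object_name!r}"
            )
        if p.orientation == "-":
            o1 = p.object_end - (lo - p.component_beg)
            o2 = p.object_end - (hi - p.component_beg)
        else:
            o1 = p.object_beg + (lo - p.component_beg)
            o2 = p.object_beg + (hi - p.component_beg)
        if o1 > o2:
            o1, o2 = o2, o1
        strand = rec.strand
        if strand in ("+", "-") and p.orientation == "-":
            strand = "-" if strand == "+" else "+"
        out.append(replace(rec, chrom=p.object_name, start=o1 - 1, end=o2,
                           strand=strand, extra=list(rec.extra)))
    if not out and strict:
        raise AgpError(
            f"component {rec.chrom!r} has no placement in the AGP"
        )
    return out


def parse_bed_line(line: str, file_label: str = "<bed>",
                   lineno: int | None = None) -> BedRecord:
    """Parse one BED3+ line; track/browser header lines are rejected."""
    if line.startswith(("track", "browser")):
        raise FileFormatError(
            "track/browser lines are not supported; strip BED headers first",
            file_label, lineno,
        )
    fields = line.rstrip("\r\n").split("\t")
    if len(fields) < 3:
        raise FileFormatError(
            f"expected at least 3 tab-separated BED columns, got {len(fields)}",
            file_label, lineno,
        )
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise FileFormatError(
            f"BED start/end must be integers, got {fields[1]!r}, {fields[2]!r}",
            file_label, lineno,
        ) from None
    if start < 0 or end <= start:
        raise FileFormatError(
            f"bad BED interval {start}-{end} (need 0 <= start < end)",
            file_label, lineno,
        )
    name = fields[3] if len(fields) > 3 else None
    score = fields[4] if len(fields) > 4 else None
    strand = fields[5] if len(fields) > 5 else None
    if strand is not None and strand not in ("+", "-", "."):
        raise FileFormatError(
            f"BED strand must be '+', '-' or '.', got {strand!r}",
            file_label, lineno,
        )
    return BedRecord(fields[0], start, end, name, score, strand, fields[6:])


class TransformSummary(NamedTuple):
    n_in: int
    n_out: int
    n_unplaced: int
    n_split: int


def transform_stream(source: Iterable[str], index: PlacementIndex,
                     sink: TextIO, file_label: str = "<bed>",
                     strict: bool = False) -> TransformSummary:
    """Stream a BED file through the lift, record by record.

    Input order is preserved and the file is never held in memory — Hi-C
    alignment BEDs routinely run to hundreds of millions of lines.
    Returns counts of records read, written, dropped as unplaced, and
    split across multiple placements; unplaced drops are summarized in a
    single log line rather than one message each.
    """
    n_in = n_out = n_unplaced = n_split = 0
    for lineno, raw in enumerate(source, start=1):
        if not raw.strip():
            continue
        rec = parse_bed_line(raw, file_label, lineno)
        n_in += 1
        try:
            hits = transform_record(rec, index, strict=strict)
        except AgpError as exc:
            raise FileFormatError(str(exc), file_label, lineno) from None
        if not hits:
            n_unplaced += 1
            continue
        if len(hits) > 1:
            n_split += 1
        for hit in hits:
            sink.write(hit.to_line() + "\n")
            n_out += 1
    if n_unplaced:
        logger.warning(
            "%s: %d record(s) on components with no placement were dropped",
            file_label, n_unplaced,
        )
    return TransformSummary(n_in, n_out, n_unplaced, n_split)
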