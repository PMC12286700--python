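"""Materialize objects: components FASTA + AGP layout -> assembled FASTA.

Each output record is built by walking one object's rows in order: a
component row contributes the 1-based inclusive slice of its component
(reverse-complemented when the row is "-"-oriented), and a gap row
contributes a run of uppercase ``N`` of the gap's length.  Whole
components are held in memory — assembly is the one operation in this
package whose memory use scales with genome size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, TextIO

from .agp import AgpDocument, ComponentRow, GapRow
from .errors import AgpError, FileFormatError

logger = logging.getLogger("agptools")

# IUPAC nucleotide complement, upper and lower case.  U complements to A
# so RNA-alphabet input round-trips through DNA conventions.
_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "U": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
_TABLE = str.maketrans(
    {**_COMPLEMENT, **{k.lower(): v.lower() for k, v in _COMPLEMENT.items()}}
)
_VALID = frozenset(_COMPLEMENT) | frozenset(c.lower() for c in _COMPLEMENT)


@dataclass
class SequenceRecord:
    """A named sequence with an optional free-text description."""

    name: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string, case preserved per character.

    All IUPAC ambiguity codes are mapped to their complements (N stays N).
    A character outside the IUPAC alphabet raises :class:`AgpError`
    reporting its 0-based offset in the input.
    """
    for i, ch in enumerate(seq):
        if ch not in _VALID:
            raise AgpError(
                f"non-IUPAC character {ch!r} at offset {i} in sequence"
            )
    return seq.translate(_TABLE)[::-1]


def read_fasta(source: Iterable[str],
               file_label: str = "<fasta>") -> dict[str, SequenceRecord]:
    """Read FASTA into an ordered name -> record mapping.

    The record name is the header up to the first whitespace; the rest of
    the header line is kept as the description.  Duplicate names are an
    error carrying the line number of the second occurrence.
    """
    records: dict[str, SequenceRecord] = {}
    name: str | None = None
    desc = ""
    chunks: list[str] = []

    def flush() -> None:
        if name is not None:
            records[name] = SequenceRecord(name, "".join(chunks), desc)

    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\r\n")
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            if not header:
                raise FileFormatError("empty FASTA header", file_label, lineno)
            parts = header.split(None, 1)
            name = parts[0]
            desc = parts[1] if len(parts) > 1 else ""
            if name in records:
                raise FileFormatError(
                    f"duplicate sequence name {name!r}", file_label, lineno
                )
            chunks = []
        elif line.strip():
            if name is None:
                raise FileFormatError(
                    "sequence data before first FASTA header", file_label, lineno
                )
            chunks.append(line.strip())
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], sink: TextIO,
                line_width: int = 60) -> None:
    """Write records as FASTA wrapped at ``line_width`` columns.

    Descriptions are dropped on write: assembled objects are new
    sequences and inherit no annotation from their components.
    """
    if line_width < 1:
        raise AgpError(f"line_width must be positive, got {line_width}")
    for rec in records:
        sink.write(f">{rec.name}\n")
        seq = rec.sequence
        for i in range(0, len(seq), line_width):
            sink.write(seq[i:i + line_width] + "\n")


def load_fasta(path: str) -> dict[str, SequenceRecord]:
    """Read the FASTA file at ``path`` into a name -> record mapping."""
    with open(path) as fh:
        return read_fasta(fh, path)


def assemble(doc: AgpDocument,
             components: Mapping[str, SequenceRecord],
             keep_unplaced: bool = False) -> list[SequenceRecord]:
    """Build one assembled record per object, in document order.

    Rows with orientation ``?``, ``0``, or ``na`` are assembled as ``+``
    with a warning — the AGP records that the orientation is unknown, but
    a concrete sequence needs a concrete choice.  With ``keep_unplaced``,
    components never referenced by the AGP are appended unchanged after
    the assembled objects.
    """
    out: list[SequenceRecord] = []
    used: set[str] = set()
    for layout in doc.objects:
        pieces: list[str] = []
        for row in layout.rows:
            if isinstance(row, GapRow):
                pieces.append("N" * row.gap_length)
                continue
            rec = components.get(row.component_id)
            if rec is None:
                raise AgpError(
                    f"component {row.component_id!r} (object {layout.name!r}, "
                    f"part {row.part_number}) not found in components FASTA"
                )
            used.add(row.component_id)
            if not rec.sequence:
                raise AgpError(
                    f"component {row.component_id!r} has an empty sequence"
                )
            if row.component_end > len(rec.sequence):
                raise AgpError(
                    f"object {layout.name!r}, part {row.part_number}: "
                    f"component_end {row.component_end} exceeds length "
                    f"{len(rec.sequence)} of component {row.component_id!r}"
                )
            chunk = rec.sequence[row.component_beg - 1:row.component_end]
            orientation = row.orientation
            if orientation not in ("+", "-"):
                logger.warning(
                    "object %r, part %d: orientation %r assembled as '+'",
                    layout.name, row.part_number, orientation,
                )
                orientation = "+"
            if orientation == "-":
                chunk = reverse_complement(chunk)
            pieces.append(chunk)
        out.append(SequenceRecord(layout.name, "".join(pieces)))
    if keep_unplaced:
        for name, rec in components.items():
            if name not in used:
                out.append(rec)
    return out
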