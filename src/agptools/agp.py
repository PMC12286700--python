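"""Core AGP v2.1 data model: parsing, writing, validation, renumbering.

An AGP file is a 9-column tab-separated table in which each line places
either a span of a named component sequence (a contig, usually) or a gap
into a larger *object* (a scaffold or chromosome).  All AGP coordinates
are 1-based and inclusive, per the NCBI convention; that convention is
mirrored exactly in the in-memory model so that a parsed document can be
written back byte-for-byte (modulo tab normalization).  The only place
0-based coordinates appear in this package is the BED interface of
:mod:`agptools.transform`.

The unit every edit operates on is the :class:`ObjectLayout` — the ordered
rows of one output sequence.  A valid layout tiles the object exactly:
row k+1 begins at the base after row k ends, part numbers count 1..k, and
the layout neither begins nor ends with a gap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, TextIO, Union

from .errors import FileFormatError, InvariantError

logger = logging.getLogger("agptools")

COMPONENT_TYPES = frozenset("WADFGOP")
GAP_TYPES = frozenset("NU")
ORIENTATIONS = frozenset({"+", "-", "?", "0", "na"})

#: Unicode minus signs occasionally pasted into AGP files by word
#: processors; normalized to ASCII "-" on input.
_MINUS_VARIANTS = {"−", "–", "—"}


@dataclass
class ComponentRow:
    """One AGP line placing a span of a component into an object.

    ``object_beg``/``object_end`` and ``component_beg``/``component_end``
    are 1-based inclusive; the two spans must have equal length.
    ``orientation`` is one of ``+ - ? 0 na``; the three non-directional
    codes are preserved verbatim but treated as ``+`` (with a warning) by
    sequence-producing operations.
    """

    object_name: str
    object_beg: int
    object_end: int
    part_number: int
    component_type: str  # one of W A D F G O P
    component_id: str
    component_beg: int
    component_end: int
    orientation: str

    @property
    def length(self) -> int:
        return self.component_end - self.component_beg + 1

    def to_line(self) -> str:
        return "\t".join(
            str(x)
            for x in (
                self.object_name, self.object_beg, self.object_end,
                self.part_number, self.component_type, self.component_id,
                self.component_beg, self.component_end, self.orientation,
            )
        )


@dataclass
class GapRow:
    """One AGP line describing a gap inside an object.

    ``component_type`` is ``N`` (size known) or ``U`` (size unknown, by
    convention recorded as 100 bp).  ``linkage_evidence`` is a
    semicolon-separated list of controlled-vocabulary tokens naming the
    data that justified joining the flanking sequences.
    """

    object_name: str
    object_beg: int
    object_end: int
    part_number: int
    component_type: str  # N or U
    gap_length: int
    gap_type: str
    linkage: str  # yes or no
    linkage_evidence: str

    @property
    def length(self) -> int:
        return self.gap_length

    def to_line(self) -> str:
        return "\t".join(
            str(x)
            for x in (
                self.object_name, self.object_beg, self.object_end,
                self.part_number, self.component_type, self.gap_length,
                self.gap_type, self.linkage, self.linkage_evidence,
            )
        )


Row = Union[ComponentRow, GapRow]


@dataclass
class ObjectLayout:
    """Ordered rows of one output sequence; the unit all edits act on."""

    name: str
    rows: list[Row] = field(default_factory=list)

    def __iter__(self) -> Iterator[Row]:
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class AgpDocument:
    """An ordered collection of object layouts plus preserved header comments."""

    objects: list[ObjectLayout] = field(default_factory=list)
    header_comments: list[str] = field(default_factory=list)

    def __iter__(self) -> Iterator[ObjectLayout]:
        return iter(self.objects)

    def names(self) -> list[str]:
        return [o.name for o in self.objects]

    def get(self, name: str) -> ObjectLayout | None:
        for obj in self.objects:
            if obj.name == name:
                return obj
        return None


@dataclass
class ValidationIssue:
    """One problem found by :func:`validate`; severity ``error`` or ``warning``."""

    file_label: str
    message: str
    severity: str = "error"
    line_number: int | None = None

    def __str__(self) -> str:
        where = self.file_label
        if self.line_number is not None:
            where += f", line {self.line_number}"
        return f"{where}: {self.severity}: {self.message}"


# ---------------------------------------------------------------------------
# parsing


def _parse_int(token: str, what: str, label: str, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise FileFormatError(
            f"{what} must be an integer, got {token!r}", label, lineno
        ) from None


def _parse_row(fields: list[str], label: str, lineno: int) -> Row:
    object_name = fields[0]
    object_beg = _parse_int(fields[1], "object_beg", label, lineno)
    object_end = _parse_int(fields[2], "object_end", label, lineno)
    part_number = _parse_int(fields[3], "part_number", label, lineno)
    ctype = fields[4]
    if object_beg < 1 or object_end < object_beg:
        raise FileFormatError(
            f"bad object coordinates {object_beg}-{object_end}", label, lineno
        )
    if part_number < 1:
        raise FileFormatError(
            f"part_number must be >= 1, got {part_number}", label, lineno
        )
    if ctype in GAP_TYPES:
        gap_length = _parse_int(fields[5], "gap_length", label, lineno)
        if gap_length < 1:
            raise FileFormatError(
                f"gap_length must be positive, got {gap_length}", label, lineno
            )
        if object_end - object_beg + 1 != gap_length:
            raise FileFormatError(
                f"span mismatch: object span {object_end - object_beg + 1} "
                f"!= gap_length {gap_length}", label, lineno
            )
        linkage = fields[7]
        if linkage not in ("yes", "no"):
            raise FileFormatError(
                f"linkage must be 'yes' or 'no', got {linkage!r}", label, lineno
            )
        return GapRow(object_name, object_beg, object_end, part_number,
                      ctype, gap_length, fields[6], linkage, fields[8])
    if ctype in COMPONENT_TYPES:
        component_beg = _parse_int(fields[6], "component_beg", label, lineno)
        component_end = _parse_int(fields[7], "component_end", label, lineno)
        orientation = fields[8]
        if orientation in _MINUS_VARIANTS:
            orientation = "-"
        if orientation not in ORIENTATIONS:
            raise FileFormatError(
                f"unknown orientation {fields[8]!r}", label, lineno
            )
        if component_beg < 1 or component_end < component_beg:
            raise FileFormatError(
                f"bad component coordinates {component_beg}-{component_end}",
                label, lineno,
            )
        if object_end - object_beg != component_end - component_beg:
            raise FileFormatError(
                f"span mismatch: object span {object_end - object_beg + 1} "
                f"!= component span {component_end - component_beg + 1}",
                label, lineno,
            )
        return ComponentRow(object_name, object_beg, object_end, part_number,
                            ctype, fields[5], component_beg, component_end,
                            orientation)
    raise FileFormatError(f"unknown component_type {ctype!r}", label, lineno)


def parse_agp(source: Iterable[str], file_label: str = "<agp>") -> AgpDocument:
    """Parse an AGP v2.1 text stream into an :class:`AgpDocument`.

    Objects are returned in file order; rows of one object must be
    consecutive (an object name that reappears after another object
    intervened is an error, as are non-contiguous object coordinates and
    non-sequential part numbers).  ``#`` comment lines are preserved but
    only permitted before the first data line.  Every error carries
    ``file_label`` and the offending 1-based line number.
    """
    doc = AgpDocument()
    current: ObjectLayout | None = None
    finished: set[str] = set()
    seen_data = False
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            if seen_data:
                raise FileFormatError(
                    "comment lines are only allowed before the first data line",
                    file_label, lineno,
                )
            doc.header_comments.append(line)
            continue
        seen_data = True
        fields = line.split("\t")
        if len(fields) == 1:
            # tolerate space-separated toy input only if it yields 9 fields
            fields = line.split()
        if len(fields) != 9:
            raise FileFormatError(
                f"expected 9 tab-separated columns, got {len(fields)}",
                file_label, lineno,
            )
        row = _parse_row(fields, file_label, lineno)
        if current is None or row.object_name != current.name:
            if row.object_name in finished:
                raise FileFormatError(
                    f"object {row.object_name!r} reappears after other objects "
                    "(interleaved object names)", file_label, lineno,
                )
            if current is not None:
                finished.add(current.name)
            current = ObjectLayout(row.object_name)
            doc.objects.append(current)
            if row.object_beg != 1:
                raise FileFormatError(
                    f"first row of object {row.object_name!r} must start at 1, "
                    f"got {row.object_beg}", file_label, lineno,
                )
            if row.part_number != 1:
                raise FileFormatError(
                    f"first part_number of object {row.object_name!r} must be 1, "
                    f"got {row.part_number}", file_label, lineno,
                )
        else:
            prev = current.rows[-1]
            if row.object_beg != prev.object_end + 1:
                raise FileFormatError(
                    f"object {row.object_name!r} is not contiguous: row starts "
                    f"at {row.object_beg}, previous row ended at {prev.object_end}",
                    file_label, lineno,
                )
            if row.part_number != prev.part_number + 1:
                raise FileFormatError(
                    f"non-sequential part_number {row.part_number} after "
                    f"{prev.part_number} in object {row.object_name!r}",
                    file_label, lineno,
                )
        current.rows.append(row)
    return doc


def read_agp(path: str) -> AgpDocument:
    """Parse the AGP file at ``path`` (``"-"`` reads standard input)."""
    import sys

    if path == "-":
        return parse_agp(sys.stdin, "<stdin>")
    with open(path) as fh:
        return parse_agp(fh, path)


# ---------------------------------------------------------------------------
# writing


def _check_layout(layout: ObjectLayout) -> None:
    """Raise :class:`InvariantError` if a layout breaks the AGP invariants."""
    if not layout.rows:
        raise InvariantError(f"object {layout.name!r} has no rows")
    pos = 1
    for i, row in enumerate(layout.rows):
        if row.object_name != layout.name:
            raise InvariantError(
                f"row {i + 1} of object {layout.name!r} is named "
                f"{row.object_name!r}"
            )
        if row.part_number != i + 1:
            raise InvariantError(
                f"part_number gap in {layout.name!r}: row {i + 1} has "
                f"part_number {row.part_number}"
            )
        if row.object_beg != pos:
            raise InvariantError(
                f"object {layout.name!r} row {i + 1} starts at "
                f"{row.object_beg}, expected {pos}"
            )
        if row.object_end - row.object_beg + 1 != row.length:
            raise InvariantError(
                f"object {layout.name!r} row {i + 1}: object span does not "
                "match row length"
            )
        pos = row.object_end + 1


def write_agp(doc: AgpDocument, sink: TextIO) -> None:
    """Write ``doc`` as AGP text; inverse of :func:`parse_agp`.

    Raises :class:`InvariantError` (naming the object and row) rather than
    emitting an AGP that would not re-parse.
    """
    names = set()
    for layout in doc.objects:
        _check_layout(layout)
        if layout.name in names:
            raise InvariantError(f"duplicate object name {layout.name!r}")
        names.add(layout.name)
    for comment in doc.header_comments:
        sink.write(comment + "\n")
    for layout in doc.objects:
        for row in layout.rows:
            sink.write(row.to_line() + "\n")


def format_agp(doc: AgpDocument) -> str:
    """Return ``doc`` as AGP text (convenience wrapper over :func:`write_agp`)."""
    import io

    buf = io.StringIO()
    write_agp(doc, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# renumbering and validation


def renumber(layout: ObjectLayout) -> ObjectLayout:
    """Recompute object coordinates and part numbers from row lengths.

    Every edit operation reorders, inserts, or slices rows and then calls
    this to restore the AGP invariants: object coordinates become the
    cumulative sums of row lengths (component span for component rows,
    ``gap_length`` for gap rows), part numbers run 1..k, and every row's
    object name is set to ``layout.name``.
    """
    if not layout.rows:
        raise InvariantError(f"cannot renumber empty object {layout.name!r}")
    out: list[Row] = []
    pos = 1
    for k, row in enumerate(layout.rows, start=1):
        out.append(replace(
            row,
            object_name=layout.name,
            object_beg=pos,
            object_end=pos + row.length - 1,
            part_number=k,
        ))
        pos += row.length
    return ObjectLayout(layout.name, out)


def object_length(layout: ObjectLayout) -> int:
    """Total length of the object in bp (position of its last base)."""
    return layout.rows[-1].object_end


def validate(doc: AgpDocument, file_label: str = "<agp>") -> list[ValidationIssue]:
    """Collect every problem in ``doc`` without stopping at the first.

    Returns an empty list iff the document is fully valid.  Structural
    breakage (bad coordinates, part numbers, duplicate names) is reported
    at severity ``error``; conventions that do not make the document
    ambiguous — a U gap whose length is not the customary 100 bp, or a
    component placed in more than one object (legal AGP, but rejected at
    submission; see :mod:`agptools.sanitize`) — are ``warning``.
    """
    issues: list[ValidationIssue] = []

    def err(msg: str) -> None:
        issues.append(ValidationIssue(file_label, msg, "error"))

    def warn(msg: str) -> None:
        issues.append(ValidationIssue(file_label, msg, "warning"))

    seen_names: set[str] = set()
    component_objects: dict[str, list[str]] = {}
    for layout in doc.objects:
        if layout.name in seen_names:
            err(f"duplicate object name {layout.name!r}")
        seen_names.add(layout.name)
        if not layout.rows:
            err(f"object {layout.name!r} has no rows")
            continue
        try:
            _check_layout(layout)
        except InvariantError as exc:
            err(str(exc))
        if isinstance(layout.rows[0], GapRow):
            warn(f"object {layout.name!r} begins with a gap row")
        if isinstance(layout.rows[-1], GapRow):
            warn(f"object {layout.name!r} ends with a gap row")
        for row in layout.rows:
            if isinstance(row, GapRow):
                if row.component_type == "U" and row.gap_length != 100:
                    warn(
                        f"object {layout.name!r}: U gap of length "
                        f"{row.gap_length} (convention is 100)"
                    )
                if row.linkage == "no" and row.linkage_evidence != "na":
                    err(
                        f"object {layout.name!r}: gap with linkage=no must "
                        f"have linkage_evidence=na, got {row.linkage_evidence!r}"
                    )
            else:
                objs = component_objects.setdefault(row.component_id, [])
                if layout.name not in objs:
                    objs.append(layout.name)
    for comp, objs in component_objects.items():
        if len(objs) > 1:
            warn(
                f"component {comp!r} placed in multiple objects: "
                + ", ".join(repr(o) for o in objs)
            )
    return issues
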