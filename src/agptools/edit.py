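"""Layout edits: join, split, flip, remove, rename.

Each operation consumes an :class:`~agptools.agp.AgpDocument` plus a
parsed operations spec and returns a new document; inputs are never
mutated.  Every edit finishes by renumbering the layouts it touched, so
its output always satisfies the AGP invariants (contiguous object
coordinates, sequential part numbers, no leading or trailing gap rows).

Conventions chosen by this package (the format itself does not fix them):

* **Joins file** — one join per line; column 1 is a comma-separated list
  of object names, each optionally prefixed ``+`` or ``-`` for
  orientation; an optional tab-separated column 2 names the joined
  object (default: the first part's name).
* **Breakpoints** — breakpoint *b* means the left piece ends at object
  position *b* and the right piece begins at *b+1*.  A breakpoint inside
  a gap deletes that gap entirely: the gap recorded a join that is being
  undone, so it carries no evidence worth keeping, and the flanking
  components become the new object ends.
* **Split piece names** — ``<name>.1 .. <name>.k``, left to right.
* **Flip endpoints** — an endpoint strictly inside a gap snaps outward so
  the whole gap joins the inverted segment; an endpoint strictly inside a
  component row is an error (split first), not an implicit component
  split.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .agp import (
    AgpDocument,
    ComponentRow,
    GapRow,
    ObjectLayout,
    Row,
    object_length,
    renumber,
)
from .errors import AgpError, FileFormatError

logger = logging.getLogger("agptools")


# ---------------------------------------------------------------------------
# specs


@dataclass
class GapSpec:
    """Attributes for gap rows created by :func:`join`.

    Defaults (500 bp, type ``scaffold``, linked, evidence ``na``) describe
    a routine scaffolding join whose evidence the curator has not
    recorded.
    """

    gap_length: int = 500
    gap_type: str = "scaffold"
    linkage: str = "yes"
    linkage_evidence: str = "na"

    def __post_init__(self) -> None:
        if self.gap_length < 1:
            raise AgpError(f"gap length must be positive, got {self.gap_length}")
        if self.linkage not in ("yes", "no"):
            raise AgpError(f"linkage must be 'yes' or 'no', got {self.linkage!r}")
        if self.linkage == "no" and self.linkage_evidence != "na":
            raise AgpError(
                "a gap with linkage=no must have linkage_evidence=na, "
                f"got {self.linkage_evidence!r}"
            )

    def make_row(self) -> GapRow:
        # object coordinates and part number are placeholders; the edit
        # that inserts this row renumbers afterwards
        return GapRow("", 1, self.gap_length, 1, "N", self.gap_length,
                      self.gap_type, self.linkage, self.linkage_evidence)


@dataclass
class JoinSpec:
    """An ordered list of (object_name, orientation) to merge into one object."""

    parts: list[tuple[str, str]]
    new_name: str | None = None
    line_number: int | None = None
    file_label: str | None = None


@dataclass
class SplitSpec:
    """An object name plus ascending breakpoints in object coordinates."""

    object_name: str
    breakpoints: list[int]
    line_number: int | None = None
    file_label: str | None = None


@dataclass
class FlipSpec:
    """A segment [seg_start, seg_end] (1-based inclusive) to invert."""

    object_name: str
    seg_start: int
    seg_end: int
    line_number: int | None = None
    file_label: str | None = None


@dataclass
class RenameSpec:
    """Rename an object, optionally reverse-complementing its layout."""

    old_name: str
    new_name: str
    orientation: str = "+"
    line_number: int | None = None
    file_label: str | None = None


_MINUS = {"−", "–", "—"}


def _norm_minus(token: str) -> str:
    for m in _MINUS:
        token = token.replace(m, "-")
    return token


# ---------------------------------------------------------------------------
# operations-file parsers


def _data_lines(source: Iterable[str]):
    """Yield (lineno, stripped_line) for non-blank, non-comment lines."""
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        yield lineno, line


def parse_joins(source: Iterable[str],
                file_label: str = "<joins>") -> list[JoinSpec]:
    """Parse a joins file: one join per line (syntax in the module docstring)."""
    specs: list[JoinSpec] = []
    for lineno, line in _data_lines(source):
        fields = line.split("\t")
        if len(fields) > 2:
            raise FileFormatError(
                f"expected at most 2 tab-separated fields, got {len(fields)}",
                file_label, lineno,
            )
        new_name = fields[1].strip() if len(fields) == 2 else None
        if len(fields) == 2 and not new_name:
            raise FileFormatError("empty new-name field", file_label, lineno)
        parts: list[tuple[str, str]] = []
        for token in fields[0].split(","):
            token = _norm_minus(token.strip())
            orientation = "+"
            if token.startswith(("+", "-")):
                orientation = token[0]
                token = token[1:]
            if not token:
                raise FileFormatError(
                    "malformed join token (empty sequence name)",
                    file_label, lineno,
                )
            parts.append((token, orientation))
        if len(parts) < 2:
            raise FileFormatError(
                "need at least two sequences to join", file_label, lineno
            )
        specs.append(JoinSpec(parts, new_name, lineno, file_label))
    return specs


def parse_splits(source: Iterable[str],
                 file_label: str = "<splits>") -> list[SplitSpec]:
    """Parse a splits file: object name TAB comma-separated breakpoints."""
    specs: list[SplitSpec] = []
    for lineno, line in _data_lines(source):
        fields = line.split("\t")
        if len(fields) != 2:
            raise FileFormatError(
                f"expected 2 tab-separated fields, got {len(fields)}",
                file_label, lineno,
            )
        name = fields[0].strip()
        breakpoints: list[int] = []
        for token in fields[1].split(","):
            token = token.strip()
            try:
                breakpoints.append(int(token))
            except ValueError:
                raise FileFormatError(
                    f"breakpoint must be an integer, got {token!r}",
                    file_label, lineno,
                ) from None
        if breakpoints != sorted(breakpoints):
            logger.warning(
                "%s, line %d: breakpoints not in ascending order; sorting",
                file_label, lineno,
            )
            breakpoints.sort()
        specs.append(SplitSpec(name, breakpoints, lineno, file_label))
    return specs


def parse_flips(source: Iterable[str],
                file_label: str = "<flips>") -> list[FlipSpec]:
    """Parse a flips file: object name TAB segment start TAB segment end."""
    specs: list[FlipSpec] = []
    for lineno, line in _data_lines(source):
        fields = line.split("\t")
        if len(fields) != 3:
            raise FileFormatError(
                f"expected 3 tab-separated fields, got {len(fields)}",
                file_label, lineno,
            )
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise FileFormatError(
                f"segment coordinates must be integers, got "
                f"{fields[1]!r}, {fields[2]!r}", file_label, lineno,
            ) from None
        specs.append(FlipSpec(fields[0].strip(), start, end, lineno, file_label))
    return specs


def parse_removes(source: Iterable[str],
                  file_label: str = "<removes>") -> list[str]:
    """Parse a removes file: one object name per line."""
    names: list[str] = []
    for lineno, line in _data_lines(source):
        name = line.strip()
        if "\t" in name:
            raise FileFormatError(
                "expected one object name per line", file_label, lineno
            )
        names.append(name)
    return names


def parse_renames(source: Iterable[str],
                  file_label: str = "<renames>") -> list[RenameSpec]:
    """Parse a renames file: old name TAB new name TAB orientation."""
    specs: list[RenameSpec] = []
    for lineno, line in _data_lines(source):
        fields = line.split("\t")
        if len(fields) != 3:
            raise FileFormatError(
                f"expected 3 tab-separated fields, got {len(fields)}",
                file_label, lineno,
            )
        orientation = _norm_minus(fields[2].strip())
        if orientation not in ("+", "-"):
            raise FileFormatError(
                f"orientation must be '+' or '-', got {fields[2]!r}",
                file_label, lineno,
            )
        specs.append(RenameSpec(fields[0].strip(), fields[1].strip(),
                                orientation, lineno, file_label))
    return specs


# ---------------------------------------------------------------------------
# shared helpers


def _spec_error(message: str, spec) -> FileFormatError:
    return FileFormatError(message, spec.file_label, spec.line_number)


def _toggle(orientation: str, context: str) -> str:
    if orientation == "+":
        return "-"
    if orientation == "-":
        return "+"
    logger.warning(
        "%s: orientation %r has no defined reverse; using '-'",
        context, orientation,
    )
    return "-"


def _reversed_rows(rows: Sequence[Row], context: str) -> list[Row]:
    """Rows in reverse order with component orientations toggled."""
    out: list[Row] = []
    for row in reversed(rows):
        if isinstance(row, ComponentRow):
            out.append(replace(row, orientation=_toggle(row.orientation, context)))
        else:
            out.append(replace(row))
    return out


# ---------------------------------------------------------------------------
# join


def join(doc: AgpDocument, spec: JoinSpec,
         gap: GapSpec | None = None) -> AgpDocument:
    """Merge the listed objects into one, a new gap between each pair.

    ``-``-oriented parts contribute their rows reversed, with component
    orientations toggled.  The joined object is appended after the
    surviving objects and named ``spec.new_name``, or after the first
    part when no name was given.
    """
    gap = gap or GapSpec()
    part_names = [name for name, _ in spec.parts]
    if len(set(part_names)) != len(part_names):
        raise _spec_error("duplicate sequence name in join", spec)
    for name in part_names:
        if doc.get(name) is None:
            raise _spec_error(f"{name!r} not in AGP", spec)
    new_name = spec.new_name or part_names[0]
    survivors = [o for o in doc.objects if o.name not in part_names]
    if any(o.name == new_name for o in survivors):
        raise _spec_error(
            f"joined object name {new_name!r} collides with an existing object",
            spec,
        )
    rows: list[Row] = []
    for name, orientation in spec.parts:
        part = doc.get(name)
        if rows:
            rows.append(gap.make_row())
        if orientation == "-":
            rows.extend(_reversed_rows(part.rows, f"join of {name!r}"))
        else:
            rows.extend(replace(r) for r in part.rows)
    joined = renumber(ObjectLayout(new_name, rows))
    return AgpDocument(survivors + [joined], list(doc.header_comments))


def join_all(doc: AgpDocument, specs: Sequence[JoinSpec],
             gap: GapSpec | None = None) -> AgpDocument:
    for spec in specs:
        doc = join(doc, spec, gap)
    return doc


# ---------------------------------------------------------------------------
# split


def _cut_component(row: ComponentRow, b: int) -> tuple[ComponentRow, ComponentRow]:
    """Divide a component row at object position ``b`` (b stays left).

    For ``-``-oriented rows the component sub-spans are mirrored: the left
    object piece carries the *right* end of the component, because the
    object reads the component backwards.  This is forced by sequence
    conservation — each piece must assemble to the same bases as the
    corresponding stretch of the unsplit object.
    """
    offset = b - row.object_beg + 1  # bases going to the left piece
    if row.orientation == "-":
        left = replace(row, object_end=b,
                       component_beg=row.component_end - offset + 1)
        right = replace(row, object_beg=b + 1,
                        component_end=row.component_end - offset)
    else:
        left = replace(row, object_end=b,
                       component_end=row.component_beg + offset - 1)
        right = replace(row, object_beg=b + 1,
                        component_beg=row.component_beg + offset)
    return left, right


def split(doc: AgpDocument, spec: SplitSpec) -> AgpDocument:
    """Break one object at the given breakpoints into ``<name>.1..k`` pieces.

    Breakpoint *b*: left piece ends at object position *b*.  A breakpoint
    inside a gap removes the whole gap; several breakpoints inside one gap
    collapse to a single cut.  Pieces are trimmed so they never begin or
    end with a gap row, and replace the original object in place.
    """
    layout = doc.get(spec.object_name)
    if layout is None:
        raise _spec_error(f"{spec.object_name!r} not in AGP", spec)
    total = object_length(layout)
    for b in spec.breakpoints:
        if b < 1 or b >= total:
            raise _spec_error(
                f"breakpoint {b} outside object {spec.object_name!r} "
                f"(length {total}; must satisfy 1 <= b < length)", spec,
            )
    bps = deque(sorted(set(spec.breakpoints)))

    pieces: list[list[Row]] = []
    cur: list[Row] = []
    for row in layout.rows:
        pending: Row | None = replace(row)
        while bps and pending is not None and bps[0] <= pending.object_end:
            b = bps.popleft()
            if isinstance(pending, GapRow):
                # cut lands in a gap: delete the gap, cut between flanks
                pieces.append(cur)
                cur = []
                while bps and bps[0] <= pending.object_end:
                    bps.popleft()  # collapse further cuts in the same gap
                pending = None
            elif b == pending.object_end:
                cur.append(pending)
                pieces.append(cur)
                cur = []
                pending = None
            else:
                left, pending = _cut_component(pending, b)
                cur.append(left)
                pieces.append(cur)
                cur = []
        if pending is not None:
            cur.append(pending)
    pieces.append(cur)

    # trim dangling gaps; a piece reduced to nothing (gap-only) vanishes
    kept: list[list[Row]] = []
    for piece in pieces:
        while piece and isinstance(piece[0], GapRow):
            piece.pop(0)
        while piece and isinstance(piece[-1], GapRow):
            piece.pop()
        if piece:
            kept.append(piece)

    existing = {o.name for o in doc.objects if o.name != spec.object_name}
    new_layouts: list[ObjectLayout] = []
    for i, piece in enumerate(kept, start=1):
        name = f"{spec.object_name}.{i}"
        if name in existing:
            raise _spec_error(
                f"split piece name {name!r} collides with an existing object",
                spec,
            )
        new_layouts.append(renumber(ObjectLayout(name, piece)))

    objects: list[ObjectLayout] = []
    for obj in doc.objects:
        if obj.name == spec.object_name:
            objects.extend(new_layouts)
        else:
            objects.append(obj)
    return AgpDocument(objects, list(doc.header_comments))


def split_all(doc: AgpDocument, specs: Sequence[SplitSpec]) -> AgpDocument:
    for spec in specs:
        doc = split(doc, spec)
    return doc


# ---------------------------------------------------------------------------
# flip


def flip(doc: AgpDocument, spec: FlipSpec) -> AgpDocument:
    """Invert the segment [seg_start, seg_end] of one object.

    Endpoints inside a gap snap outward so the whole gap is inverted with
    the segment; endpoints strictly inside a component row are an error
    (split the component first).  Covered rows are reversed in order and
    component orientations toggled; everything outside the segment is
    untouched.
    """
    layout = doc.get(spec.object_name)
    if layout is None:
        raise _spec_error(f"{spec.object_name!r} not in AGP", spec)
    if spec.seg_start > spec.seg_end:
        raise _spec_error(
            f"segment start {spec.seg_start} > end {spec.seg_end}", spec
        )
    total = object_length(layout)
    if spec.seg_start < 1 or spec.seg_end > total:
        raise _spec_error(
            f"segment {spec.seg_start}-{spec.seg_end} outside object "
            f"{spec.object_name!r} (length {total})", spec,
        )

    start, end = spec.seg_start, spec.seg_end
    first = last = None
    for i, row in enumerate(layout.rows):
        if row.object_beg <= start <= row.object_end:
            if start != row.object_beg:
                if isinstance(row, ComponentRow):
                    raise _spec_error(
                        f"segment start {start} falls inside component "
                        f"{row.component_id!r} ({row.object_beg}-"
                        f"{row.object_end}); split the component first", spec,
                    )
                start = row.object_beg  # snap outward over the gap
            first = i
        if row.object_beg <= end <= row.object_end:
            if end != row.object_end:
                if isinstance(row, ComponentRow):
                    raise _spec_error(
                        f"segment end {end} falls inside component "
                        f"{row.component_id!r} ({row.object_beg}-"
                        f"{row.object_end}); split the component first", spec,
                    )
                end = row.object_end  # snap outward over the gap
            last = i

    rows = (list(layout.rows[:first])
            + _reversed_rows(layout.rows[first:last + 1],
                             f"flip of {spec.object_name!r}")
            + list(layout.rows[last + 1:]))
    flipped = renumber(ObjectLayout(layout.name, rows))
    objects = [flipped if o.name == layout.name else o for o in doc.objects]
    return AgpDocument(objects, list(doc.header_comments))


def flip_all(doc: AgpDocument, specs: Sequence[FlipSpec]) -> AgpDocument:
    for spec in specs:
        doc = flip(doc, spec)
    return doc


# ---------------------------------------------------------------------------
# remove and rename


def remove(doc: AgpDocument, names: Sequence[str]) -> AgpDocument:
    """Drop the listed objects; everything else keeps its order."""
    for name in names:
        if doc.get(name) is None:
            raise AgpError(f"{name!r} not in AGP")
    drop = set(names)
    return AgpDocument([o for o in doc.objects if o.name not in drop],
                       list(doc.header_comments))


def rename(doc: AgpDocument, specs: Sequence[RenameSpec]) -> AgpDocument:
    """Rename objects; a ``-`` orientation also reverse-complements the layout."""
    old_names = {o.name for o in doc.objects}
    mapping: dict[str, RenameSpec] = {}
    for spec in specs:
        if spec.old_name not in old_names:
            raise _spec_error(f"{spec.old_name!r} not in AGP", spec)
        if spec.old_name in mapping:
            raise _spec_error(f"{spec.old_name!r} renamed twice", spec)
        mapping[spec.old_name] = spec
    final = [mapping[o.name].new_name if o.name in mapping else o.name
             for o in doc.objects]
    dupes = {n for n in final if final.count(n) > 1}
    if dupes:
        raise FileFormatError(
            "rename would produce duplicate object name(s): "
            + ", ".join(sorted(repr(d) for d in dupes)),
            specs[0].file_label if specs else None,
        )
    objects: list[ObjectLayout] = []
    for obj in doc.objects:
        spec = mapping.get(obj.name)
        if spec is None:
            objects.append(obj)
            continue
        rows = list(obj.rows)
        if spec.orientation == "-":
            rows = _reversed_rows(rows, f"rename of {obj.name!r}")
        objects.append(renumber(ObjectLayout(spec.new_name, rows)))
    return AgpDocument(objects, list(doc.header_comments))
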