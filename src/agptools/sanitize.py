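"""Repair AGP constructs that NCBI's submission pipeline rejects.

Two constructs are perfectly valid AGP but fail assembly submission:

* ``minus_singleton`` — an object consisting of a single component row in
  reverse orientation.
* ``shared_component`` — one input component placed in two or more
  output objects (a contig split between scaffolds).

Both are repaired by rewriting component identity rather than layout, so
the assembled sequence of every object is bitwise unchanged — that
equality is the governing constraint of this module and is what its
tests assert.  A reverse-oriented singleton becomes a ``+`` placement of
a new ``<id>_rc`` component holding the reverse complement; a shared
component's placements become independent components ``<id>_1 ..
<id>_k`` (numbered in object order) with coordinates rebased to 1, and
any stretches of the original component used by no placement are kept as
``<id>_unplaced_<j>`` records so no sequence is silently lost.

When no components FASTA is supplied the AGP is still rewritten and the
rename map returned, but the caller must create the new sequence records
before the AGP is usable; a warning says so.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .agp import (
    AgpDocument,
    ComponentRow,
    ObjectLayout,
    ValidationIssue,
)
from .assembly import SequenceRecord, reverse_complement
from .errors import AgpError

logger = logging.getLogger("agptools")

RULE_MINUS_SINGLETON = "minus_singleton"
RULE_SHARED_COMPONENT = "shared_component"


@dataclass
class SanitizeReport:
    """Every change :func:`sanitize` made, for the curation record.

    ``fixes`` holds (object_name, rule_id, description) triples;
    ``component_renames`` maps each rewritten component usage
    (old_id, old_beg, old_end) to its replacement
    (new_id, new_beg, new_end).
    """

    fixes: list[tuple[str, str, str]] = field(default_factory=list)
    component_renames: dict[tuple[str, int, int], tuple[str, int, int]] = \
        field(default_factory=dict)

    def __bool__(self) -> bool:
        return bool(self.fixes)


def find_submission_issues(doc: AgpDocument) -> list[ValidationIssue]:
    """Flag minus-singleton objects and components shared between objects."""
    issues: list[ValidationIssue] = []
    component_objects: dict[str, list[str]] = {}
    for layout in doc.objects:
        rows = layout.rows
        if (len(rows) == 1 and isinstance(rows[0], ComponentRow)
                and rows[0].orientation == "-"):
            issues.append(ValidationIssue(
                "<agp>",
                f"object {layout.name!r} is a single reverse-oriented "
                f"component ({rows[0].component_id!r}); rejected at "
                f"submission ({RULE_MINUS_SINGLETON})",
                "error",
            ))
        for row in rows:
            if isinstance(row, ComponentRow):
                objs = component_objects.setdefault(row.component_id, [])
                if layout.name not in objs:
                    objs.append(layout.name)
    for comp, objs in component_objects.items():
        if len(objs) > 1:
            issues.append(ValidationIssue(
                "<agp>",
                f"component {comp!r} is split among multiple objects "
                f"({', '.join(repr(o) for o in objs)}); rejected at "
                f"submission ({RULE_SHARED_COMPONENT})",
                "error",
            ))
    return issues


def _get_record(records: dict[str, SequenceRecord] | None,
                name: str) -> SequenceRecord:
    assert records is not None
    rec = records.get(name)
    if rec is None:
        raise AgpError(
            f"component {name!r} needed by sanitize is missing from the "
            "components FASTA"
        )
    return rec


def sanitize(
    doc: AgpDocument,
    components: dict[str, SequenceRecord] | None = None,
) -> tuple[AgpDocument, list[SequenceRecord] | None, SanitizeReport]:
    """Rewrite ``doc`` (and, if given, its components) to be submittable.

    Returns the repaired document, the matching component records (or
    ``None`` when no FASTA was supplied), and a report of every change.
    Assembling the output against the output records yields exactly the
    same sequences as the input; :func:`find_submission_issues` on the
    output is always empty; running sanitize twice equals running it
    once.
    """
    report = SanitizeReport()
    objects = [ObjectLayout(o.name, [replace(r) for r in o.rows])
               for o in doc.objects]
    working = dict(components) if components is not None else None
    derived: dict[str, SequenceRecord] = {}
    remainder_names: set[str] = set()

    def new_id_ok(name: str) -> str:
        if (name in {r.component_id for o in objects for r in o.rows
                     if isinstance(r, ComponentRow)}
                or (working is not None and name in working)):
            raise AgpError(
                f"sanitize cannot rename: generated component id {name!r} "
                "already exists"
            )
        return name

    # --- shared components: split into independent per-placement components
    locations: dict[str, list[tuple[int, int]]] = {}
    for oi, layout in enumerate(objects):
        for ri, row in enumerate(layout.rows):
            if isinstance(row, ComponentRow):
                locations.setdefault(row.component_id, []).append((oi, ri))
    for comp_id, locs in locations.items():
        if len({objects[oi].name for oi, _ in locs}) < 2:
            continue
        used_spans: list[tuple[int, int]] = []
        for i, (oi, ri) in enumerate(locs, start=1):
            row = objects[oi].rows[ri]
            new_id = new_id_ok(f"{comp_id}_{i}")
            span = (row.component_beg, row.component_end)
            used_spans.append(span)
            objects[oi].rows[ri] = replace(
                row, component_id=new_id,
                component_beg=1, component_end=row.length,
            )
            report.component_renames[(comp_id, *span)] = (new_id, 1, row.length)
            report.fixes.append((
                objects[oi].name, RULE_SHARED_COMPONENT,
                f"placement {i} of {comp_id!r} ({span[0]}-{span[1]}) "
                f"renamed {new_id!r} (1-{row.length})",
            ))
            if working is not None:
                src = _get_record(working, comp_id)
                derived[new_id] = SequenceRecord(
                    new_id, src.sequence[span[0] - 1:span[1]]
                )
        if working is not None:
            src = _get_record(working, comp_id)
            pos, j = 1, 0
            for beg, end in sorted(used_spans):
                if beg > pos:
                    j += 1
                    name = new_id_ok(f"{comp_id}_unplaced_{j}")
                    derived[name] = SequenceRecord(
                        name, src.sequence[pos - 1:beg - 1]
                    )
                    remainder_names.add(name)
                pos = max(pos, end + 1)
            if pos <= len(src.sequence):
                j += 1
                name = new_id_ok(f"{comp_id}_unplaced_{j}")
                derived[name] = SequenceRecord(name, src.sequence[pos - 1:])
                remainder_names.add(name)
        if working is not None:
            working.update(derived)

    # --- minus singletons: bake the reverse complement into a new component
    for layout in objects:
        rows = layout.rows
        if not (len(rows) == 1 and isinstance(rows[0], ComponentRow)
                and rows[0].orientation == "-"):
            continue
        row = rows[0]
        new_id = new_id_ok(f"{row.component_id}_rc")
        span = (row.component_beg, row.component_end)
        rows[0] = replace(
            row, component_id=new_id, orientation="+",
            component_beg=1, component_end=row.length,
        )
        report.component_renames[(row.component_id, *span)] = \
            (new_id, 1, row.length)
        report.fixes.append((
            layout.name, RULE_MINUS_SINGLETON,
            f"reverse-oriented singleton {row.component_id!r} "
            f"({span[0]}-{span[1]}) replaced by {new_id!r} (+)",
        ))
        if working is not None:
            src = _get_record(working, row.component_id)
            seq = reverse_complement(src.sequence[span[0] - 1:span[1]])
            derived[new_id] = SequenceRecord(new_id, seq)
            working[new_id] = derived[new_id]

    out_doc = AgpDocument(objects, list(doc.header_comments))

    out_records: list[SequenceRecord] | None = None
    if components is not None:
        referenced_in = {r.component_id for o in doc.objects for r in o.rows
                         if isinstance(r, ComponentRow)}
        referenced_out = {r.component_id for o in objects for r in o.rows
                          if isinstance(r, ComponentRow)}
        out_records = []
        for name, rec in components.items():
            # drop originals whose every placement was rewritten; keep
            # records the input never referenced (user's unplaced contigs)
            if name in referenced_in and name not in referenced_out:
                continue
            out_records.append(rec)
        for name, rec in derived.items():
            if name in referenced_out or name in remainder_names:
                out_records.append(rec)
    elif report:
        logger.warning(
            "sanitize rewrote component ids but no components FASTA was "
            "given; create the renamed sequence records before using the AGP"
        )
    return out_doc, out_records, report
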