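"""Synthetic assemblies with known ground truth, for tests and demos.

:func:`generate_fixture` builds, from a single integer seed, a triple of
(truth scaffolds, component contigs, AGP layout) that is self-consistent
by construction: assembling the components through the AGP reproduces
the truth sequences exactly.  Reverse-oriented components are stored as
the reverse complement of their slice of the truth, so the assembly path
must undo the orientation correctly to reconstruct it — this makes the
triple a ground-truth oracle for every edit and transform property in
the test suite, with no external data needed.

The generator emulates the *structure* of a scaffolded assembly (ordered
oriented contigs alternating with sized gaps), not its biology: bases
are i.i.d. uniform, so there are no repeats, no GC skew, and no
misassemblies.  Tests passing on these fixtures demonstrate coordinate
and orientation bookkeeping, not robustness to messy real genomes.

:func:`corrupt_agp` does the opposite job: it plants exactly one known
defect of a chosen class at a known line, so error-handling tests can
assert that parsing fails with the right message at the right line.

All randomness flows from ``random.Random(seed)``; no OS entropy or
wall-clock input anywhere, so every fixture is bit-reproducible.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .agp import AgpDocument, ComponentRow, GapRow, ObjectLayout, format_agp, renumber
from .assembly import SequenceRecord, reverse_complement
from .errors import AgpError

CORRUPTION_MODES = ("bad_span", "bad_part", "overlap", "unknown_type",
                    "interleaved")


@dataclass
class FixtureParams:
    """Knobs of the synthetic assembly generator.

    Defaults give a small but structurally rich assembly: a handful of
    scaffolds of a few hundred bp to ~1 kb, one to six contigs each,
    gap sizes drawn from values scaffolders commonly emit, and roughly a
    third of contigs reverse-oriented (typical of Hi-C scaffolding,
    where input contig orientation is arbitrary).
    """

    seed: int = 0
    n_objects: int = 5
    object_length_range: tuple[int, int] = (200, 1000)
    components_per_object_range: tuple[int, int] = (1, 6)
    gap_length_choices: tuple[int, ...] = (100, 200, 500)
    p_minus: float = 0.3

    def __post_init__(self) -> None:
        if (self.n_objects < 1
                or self.object_length_range[0] < 1
                or self.object_length_range[0] > self.object_length_range[1]
                or self.components_per_object_range[0] < 1
                or (self.components_per_object_range[0]
                    > self.components_per_object_range[1])
                or not self.gap_length_choices
                or min(self.gap_length_choices) < 1
                or not 0.0 <= self.p_minus <= 1.0):
            raise AgpError("impossible fixture parameter ranges")


@dataclass
class Fixture:
    """A generated assembly: truth scaffolds, component contigs, AGP."""

    truth: list[SequenceRecord]
    components: dict[str, SequenceRecord]
    doc: AgpDocument
    params: FixtureParams = field(repr=False, default_factory=FixtureParams)


def generate_fixture(params: FixtureParams | None = None) -> Fixture:
    """Generate one self-consistent (truth, components, AGP) triple.

    Component lengths are drawn so each object's total sequence falls
    near ``object_length_range`` (each contig is uniform between range
    bounds divided by the contig count); gaps separate every adjacent
    contig pair.  Deterministic for a given ``params.seed``.
    """
    params = params or FixtureParams()
    rng = random.Random(params.seed)
    truth: list[SequenceRecord] = []
    components: dict[str, SequenceRecord] = {}
    doc = AgpDocument()
    ctg_serial = 0
    for i in range(1, params.n_objects + 1):
        name = f"scaffold_{i}"
        ncomp = rng.randint(*params.components_per_object_range)
        lo = max(1, params.object_length_range[0] // ncomp)
        hi = max(lo, params.object_length_range[1] // ncomp)
        rows: list[ComponentRow | GapRow] = []
        seq_parts: list[str] = []
        for k in range(ncomp):
            if k:
                gap = rng.choice(params.gap_length_choices)
                rows.append(GapRow(name, 1, gap, 1, "N", gap, "scaffold",
                                   "yes", "proximity_ligation"))
                seq_parts.append("N" * gap)
            ctg_serial += 1
            ctg_name = f"ctg_{ctg_serial}"
            length = rng.randint(lo, hi)
            seq = "".join(rng.choice("ACGT") for _ in range(length))
            orientation = "-" if rng.random() < params.p_minus else "+"
            # the truth carries the object-strand bases; the stored contig
            # is their reverse complement when the placement is "-"
            seq_parts.append(seq)
            stored = reverse_complement(seq) if orientation == "-" else seq
            components[ctg_name] = SequenceRecord(ctg_name, stored)
            rows.append(ComponentRow(name, 1, length, 1, "W", ctg_name,
                                     1, length, orientation))
        doc.objects.append(renumber(ObjectLayout(name, rows)))
        truth.append(SequenceRecord(name, "".join(seq_parts)))
    return Fixture(truth, components, doc, params)


@dataclass
class CorruptedAgp:
    """AGP text with one planted defect of class ``mode`` at ``line_number``."""

    text: str
    line_number: int
    mode: str


def _data_line_indices(lines: list[str]) -> list[int]:
    return [i for i, l in enumerate(lines) if l and not l.startswith("#")]


def corrupt_agp(doc: AgpDocument, mode: str, seed: int = 0) -> CorruptedAgp:
    """Emit ``doc`` as AGP text with exactly one seeded defect.

    Modes: ``bad_span`` (component span longer than object span),
    ``bad_part`` (part number out of sequence), ``overlap`` (a row
    starting before the previous one ended), ``unknown_type`` (component
    type code outside the AGP vocabulary), ``interleaved`` (an object's
    rows resuming after another object intervened).
    """
    if mode not in CORRUPTION_MODES:
        raise AgpError(f"unknown corruption mode {mode!r}")
    rng = random.Random(seed)
    lines = format_agp(doc).splitlines()
    data = _data_line_indices(lines)

    def fields_of(i: int) -> list[str]:
        return lines[i].split("\t")

    def component_lines() -> list[int]:
        return [i for i in data if fields_of(i)[4] not in ("N", "U")]

    def non_first_lines() -> list[int]:
        out = []
        prev_obj = None
        for i in data:
            obj = fields_of(i)[0]
            if obj == prev_obj:
                out.append(i)
            prev_obj = obj
        return out

    if mode == "bad_span":
        candidates = component_lines()
        if not candidates:
            raise AgpError("bad_span corruption needs a component row")
        i = rng.choice(candidates)
        f = fields_of(i)
        f[7] = str(int(f[7]) + 1)
        lines[i] = "\t".join(f)
        return CorruptedAgp("\n".join(lines) + "\n", i + 1, mode)
    if mode == "bad_part":
        candidates = non_first_lines()
        if not candidates:
            raise AgpError("bad_part corruption needs a multi-row object")
        i = rng.choice(candidates)
        f = fields_of(i)
        f[3] = str(int(f[3]) + 1)
        lines[i] = "\t".join(f)
        return CorruptedAgp("\n".join(lines) + "\n", i + 1, mode)
    if mode == "overlap":
        candidates = non_first_lines()
        if not candidates:
            raise AgpError("overlap corruption needs a multi-row object")
        i = rng.choice(candidates)
        f = fields_of(i)
        f[1] = str(int(f[1]) - 1)
        f[2] = str(int(f[2]) - 1)  # keep the span length legal
        lines[i] = "\t".join(f)
        return CorruptedAgp("\n".join(lines) + "\n", i + 1, mode)
    if mode == "unknown_type":
        i = rng.choice(data)
        f = fields_of(i)
        f[4] = "Z"
        lines[i] = "\t".join(f)
        return CorruptedAgp("\n".join(lines) + "\n", i + 1, mode)
    # interleaved: move the LAST row of a non-final multi-row object to the
    # end of the file — removing a final row leaves the object well-formed,
    # so the parser reaches the moved line and fails there
    last_obj = fields_of(data[-1])[0]
    object_last_line = {fields_of(i)[0]: i for i in data}
    candidates = [i for i in non_first_lines()
                  if fields_of(i)[0] != last_obj
                  and object_last_line[fields_of(i)[0]] == i]
    if not candidates:
        raise AgpError(
            "interleaved corruption needs two objects, the first multi-row"
        )
    i = rng.choice(candidates)
    moved = lines.pop(i)
    lines.append(moved)
    return CorruptedAgp("\n".join(lines) + "\n", len(lines), mode)


def main(argv: list[str] | None = None) -> int:
    """Developer CLI: write a fixture triple into a directory."""
    import argparse
    import os

    from .agp import write_agp
    from .assembly import write_fasta

    parser = argparse.ArgumentParser(
        prog="agptools-fixture",
        description="Emit a synthetic (truth.fa, components.fa, layout.agp) "
                    "fixture triple with known ground truth.",
    )
    parser.add_argument("outdir")
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n-objects", type=int, default=5)
    parser.add_argument("--p-minus", type=float, default=0.3)
    args = parser.parse_args(argv)
    fixture = generate_fixture(FixtureParams(
        seed=args.seed, n_objects=args.n_objects, p_minus=args.p_minus,
    ))
    os.makedirs(args.outdir, exist_ok=True)
    with open(os.path.join(args.outdir, "truth.fa"), "w") as fh:
        write_fasta(fixture.truth, fh)
    with open(os.path.join(args.outdir, "components.fa"), "w") as fh:
        write_fasta(fixture.components.values(), fh)
    with open(os.path.join(args.outdir, "layout.agp"), "w") as fh:
        write_agp(fixture.doc, fh)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
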