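# Methods

## The AGP model

An AGP v2.1 file is a 9-column tab-separated table.  Each line places
either a span of a *component* sequence (a contig, usually) or a gap
into an *object* (a scaffold or chromosome).  All AGP coordinates are
1-based inclusive.  The in-memory model mirrors the file exactly — a
`ComponentRow` or `GapRow` per line, grouped into `ObjectLayout`s, in an
`AgpDocument` — so that parse→write round-trips byte-for-byte (modulo
tab normalization).  A valid layout tiles its object: row *k+1* starts
one base after row *k* ends, part numbers run 1..k, and component rows
bound both ends.

Every edit is implemented as: rearrange/slice rows, then `renumber()` —
recompute object coordinates as cumulative sums of row lengths and
reassign part numbers.  This single choke point is why the contiguity
invariants survive arbitrary compositions of edits.

The two deliberate coordinate-convention sites are the entry and exit
of the BED transform (BED is 0-based half-open); nothing else in the
package converts coordinates, which keeps off-by-one surface minimal
and testable.

## Edit semantics and their free choices

The file format fixes what the five edits must mean but not every
detail; where the design was open we chose as follows.

* **Join** inserts one new gap row between consecutive parts
  (default 500 bp / `scaffold` / linkage `yes` / evidence `na` —
  a routine scaffolding join whose evidence the curator has not
  recorded; all four are CLI flags).  A `-`-oriented part contributes
  its rows reversed with component orientations toggled.  Joins-file
  micro-syntax (comma-separated names, optional `+`/`-` prefix,
  optional tab-separated new name) is this package's own convention.
* **Split** interprets breakpoint *b* as "left piece ends at object
  position *b*".  A breakpoint inside a gap deletes the whole gap: the
  gap recorded exactly the join being undone, so its length and
  evidence have no residual meaning.  Several breakpoints inside one
  gap collapse to one cut.  Pieces are trimmed so they never start or
  end with a gap, then named `<name>.1..k` left to right.  Splitting a
  `-`-oriented component mirrors the component sub-spans (the left
  object piece keeps the *right* end of the component) — forced by the
  requirement that each piece assemble to the same bases as the
  corresponding stretch of the unsplit object, and the easiest place
  in the package to write a sign error, hence pinned by sequence
  oracles at three different scales in the tests.
* **Flip** requires segment endpoints on row boundaries; an endpoint
  strictly inside a gap snaps outward so the whole gap joins the
  segment, while an endpoint inside a component is an error rather than
  an implicit split — explicit beats magic.  Flip is an involution for
  row-aligned segments.  One consequence of snapping: a segment that
  touches an object end and stops inside a gap can leave a gap row at
  the object edge after reversal; `validate()` flags this as a warning.
  We accept it rather than trim, because trimming would break both the
  involution and sequence-length conservation.
* **Rename** with orientation `-` flips the whole object, for imposing
  chromosome orientation conventions.
* Orientations `?`, `0`, `na` are parsed and preserved, but
  sequence-producing operations treat them as `+` (with a warning), and
  reversing operations turn them into `-` (with a warning): the AGP may
  record ignorance, but a concrete sequence needs a concrete choice.

## Assembly and liftover

`assemble()` concatenates, per object, the 1-based component slices
(reverse-complemented for `-` rows, via an IUPAC-complete, case-
preserving complement table) and `N`-runs for gaps.  Gap fill is
uppercase `N` regardless of gap type — the N/U distinction lives in
the AGP, not the FASTA.  Components are held fully in memory; assembly
is the one operation whose memory footprint scales with genome size.

`transform()` lifts BED intervals through a per-component placement
index.  For a `+` placement the map is a constant shift; for `-` it is
a mirror through the placement, with endpoints re-ordered and the
strand column (when present and directional) toggled.  Intervals
partially outside a placement are trimmed to the overlap rather than
dropped, maximizing retained Hi-C signal; `--strict` upgrades partial
overlaps and unplaced components to errors.  Records stream one line
at a time (Hi-C BEDs run to hundreds of millions of lines) and keep
input order.  The module's governing test is a sequence oracle: bases
of the assembled object under the lifted interval must equal the (rc
of the) component bases under the original interval, for thousands of
random intervals.

## Submission repair

Two constructs are valid AGP but rejected by assembly-database
submission pipelines: a single-component object in `-` orientation,
and one component placed in multiple objects.  `sanitize()` repairs
both by rewriting component identity, never layout: the singleton
becomes a `+` placement of a new `<id>_rc` record holding the reverse
complement; a shared component's placements become independent
components `<id>_1..k` rebased to coordinate 1, with unused stretches
kept as `<id>_unplaced_<j>` records.  The governing constraint —
assembled output identical, object by object, before and after — is
asserted directly, along with idempotence and an empty issue list on
the output.  Known limitation: a minus singleton that uses only part
of its component drops the unused remainder together with the original
record (only the shared-component path emits remainder records).
Without a components FASTA, the AGP is still rewritten and the rename
map returned, with a warning that the renamed records must be created.

## Synthetic fixtures

`generate_fixture()` builds, from one integer seed, a triple of truth
scaffolds, component contigs, and AGP that is self-consistent by
construction: `assemble(components, agp) == truth`.  Defaults — 5
objects of roughly 200–1000 bp, 1–6 contigs each, gap lengths drawn
from {100, 200, 500}, 30% of contigs reverse-oriented — give a small
assembly with the structural features that matter (multi-row objects,
minus strands, singletons) at sizes where the whole property suite
runs in seconds.  `-`-oriented contigs are stored reverse-complemented
relative to the truth, so any orientation bug breaks the equality.
The generator emulates structure, not biology: bases are i.i.d.
uniform, with no repeats, GC skew, or misassemblies, and every
component is placed exactly once and in full.  Passing tests therefore
demonstrate coordinate and orientation bookkeeping, not robustness to
messy real assemblies (split placements are exercised by hand-written
fixtures in the transform and sanitize tests).  All randomness flows
from `random.Random(seed)`; nothing reads the clock or OS entropy.

`corrupt_agp()` plants exactly one defect of a chosen class at a known
line (span mismatch, part-number skip, overlapping rows, unknown
component type, interleaved object), so error-handling tests can
assert that parsing fails with the right message at the right 1-based
line — the error contract every user-facing failure path follows.

## Error handling and CLI

All data errors are `AgpError`s; file-driven ones are
`FileFormatError`s carrying the file label and the first offending
line number.  The CLI maps usage errors to exit 1 and data errors to
exit 2 with a single stderr message, never a traceback.  Every
subcommand reads the AGP from a path or `-` and writes to `-o`/stdout,
so edits compose under shell pipes.

## Problem sizes

The default test suite (including the acceptance layer, which re-runs
the unit suite under coverage in a subprocess) finishes in well under a
minute on one CPU: fixture assemblies are a few kilobases, property
families run 10–100 seeds, and the liftover oracle checks 1000 random
intervals per fixture — sizes chosen because every property here is
exact (equality, not statistics), so small inputs lose no generality.
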