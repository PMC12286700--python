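# agptools

Edit AGP genome-assembly layout files during assembly curation.

The AGP format (A Golden Path) is the standard tab-separated
description of how component sequences — usually contigs — are
ordered, oriented, and gapped into larger objects such as scaffolds
and chromosomes; it is the submission format for the major assembly
databases, and scaffolders emit it.  Curating an assembly means
editing that layout: breaking misjoins, joining sequences that
long-range evidence links, inverting segments, dropping haplotigs and
contamination, and naming chromosomes.  Doing those edits on the AGP
instead of the FASTA is both cheaper and more faithful — inverting a
contig is a `+`→`-` on one line rather than a splice-and-reverse-
complement of a multi-megabase string — and leaves a reproducible
record: the operations files plus the inputs re-create the curated
assembly exactly.

This package provides those edits as a library and as one command,

```
agptools {join,split,flip,remove,rename,assemble,transform,sanitize}
```

plus the machinery around them: a strict AGP v2.1 parser/writer whose
errors point at the offending file and line, reconstruction of the
scaffold FASTA from contigs + AGP (`assemble`), strand-aware liftover
of BED intervals from contig to scaffold coordinates (`transform`, so
Hi-C alignments survive re-scaffolding without re-mapping), and repair
of the two layout constructs that submission pipelines reject
(`sanitize`).

## The model in brief

An AGP object is an ordered list of rows tiling positions `1..L`
(1-based, inclusive).  A component row places bases
`[component_beg, component_end]` of a named component at
`[object_beg, object_end]`, in orientation `+` or `-`; a gap row
contributes `gap_length` unknown bases with a typed reason and linkage
evidence.  Every edit here reduces to reordering/slicing rows followed
by renumbering (object coordinates = cumulative row lengths, part
numbers = 1..k), which is why each command's output is again a valid
AGP.  For a `-` placement the coordinate maps mirror: object position
`x` corresponds to component position
`component_end − (x − object_beg)`, the identity behind both
minus-strand splitting and strand-aware liftover.

## Worked example

A toy assembly: scaffold_1 is two contigs around a 100 bp gap (the
second contig reverse-oriented), scaffold_2 a single contig.

```
$ cat toy.agp
scaffold_1	1	8	1	W	ctg1	1	8	+
scaffold_1	9	108	2	N	100	scaffold	yes	proximity_ligation
scaffold_1	109	112	3	W	ctg2	1	4	-
scaffold_2	1	7	1	W	ctg3	1	7	+
$ cat toy.fa
>ctg1
AAAATTTT
>ctg2
CCAA
>ctg3
GATTACA
```

Join scaffold_2, reverse-complemented, onto scaffold_1:

```
$ echo 'scaffold_1,-scaffold_2' > joins.tsv
$ agptools join joins.tsv toy.agp
scaffold_1	1	8	1	W	ctg1	1	8	+
scaffold_1	9	108	2	N	100	scaffold	yes	proximity_ligation
scaffold_1	109	112	3	W	ctg2	1	4	-
scaffold_1	113	612	4	N	500	scaffold	yes	na
scaffold_1	613	619	5	W	ctg3	1	7	-
agptools: INFO: join: 2 object(s) in, 1 out
```

One 619 bp object: the original rows, a new 500 bp gap (size, type,
and evidence settable by flags), and ctg3 flipped to `-` because the
join listed it reversed.  Splitting inside a gap undoes such a join
and deletes the gap; splitting inside a contig divides its row:

```
$ printf 'scaffold_1\t110\n' > breaks.tsv
$ agptools split breaks.tsv toy.agp
scaffold_1.1	1	8	1	W	ctg1	1	8	+
scaffold_1.1	9	108	2	N	100	scaffold	yes	proximity_ligation
scaffold_1.1	109	110	3	W	ctg2	3	4	-
scaffold_1.2	1	2	1	W	ctg2	1	2	-
scaffold_2	1	7	1	W	ctg3	1	7	+
```

Breakpoint 110 falls two bases into the `-`-oriented ctg2, so the left
piece keeps component bases 3–4 and the right piece bases 1–2 — the
mirror that keeps every piece's sequence identical to the matching
stretch of the original scaffold.  Materialize and lift coordinates:

```
$ agptools assemble toy.fa toy.agp -o scaffolds.fa   # scaffold_1 =
#   AAAATTTT + 100*N + TTGG (112 bp): ctg2 enters reverse-complemented
$ printf 'ctg2\t0\t2\tm1\t0\t+\n' | agptools transform - toy.agp
scaffold_1	110	112	m1	0	-
```

The interval covering ctg2's first two bases (`CC`) lands on
scaffold_1's last two (`GG`), strand toggled — the liftover commutes
with assembly.

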