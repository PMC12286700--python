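"""Lift BED intervals from contig coordinates to scaffold coordinates.

After scaffolding, alignments made against contigs (e.g. Hi-C read
pairs) can be reused by mapping them through the AGP instead of
re-aligning.
"""

import io

from agptools import build_index, parse_agp, transform_stream

TOY = (
    "scaffold_1\t1\t8\t1\tW\tctg1\t1\t8\t+\n"
    "scaffold_1\t9\t108\t2\tN\t100\tscaffold\tyes\tproximity_ligation\n"
    "scaffold_1\t109\t112\t3\tW\tctg2\t1\t4\t-\n"
    "scaffold_2\t1\t7\t1\tW\tctg3\t1\t7\t+\n"
)
BED = (
    "ctg1\t0\t4\tread1\t0\t+\n"   # maps with a constant shift
    "ctg2\t0\t2\tread2\t0\t+\n"   # "-" placement: mirrored, strand toggled
    "ctg9\t0\t5\tread3\t0\t+\n"   # not placed anywhere: dropped, counted
)

doc = parse_agp(io.StringIO(TOY), "toy.agp")
out = io.StringIO()
summary = transform_stream(io.StringIO(BED), build_index(doc), out, "demo.bed")
print(out.getvalue(), end="")
print(f"records in={summary.n_in} out={summary.n_out} "
      f"unplaced={summary.n_unplaced} split={summary.n_split}")
# read2 lands on scaffold_1:110-112 with strand "-": the first two
# bases of ctg2 are the *last* two of the scaffold, reverse-complemented.
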