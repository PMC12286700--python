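"""Materialize scaffold sequences from contigs plus an AGP layout.

Each component row contributes its (possibly reverse-complemented)
slice; each gap row contributes a run of N.
"""

import io

from agptools import SequenceRecord, assemble, parse_agp

TOY = (
    "scaffold_1\t1\t8\t1\tW\tctg1\t1\t8\t+\n"
    "scaffold_1\t9\t108\t2\tN\t100\tscaffold\tyes\tproximity_ligation\n"
    "scaffold_1\t109\t112\t3\tW\tctg2\t1\t4\t-\n"
    "scaffold_2\t1\t7\t1\tW\tctg3\t1\t7\t+\n"
)
contigs = {
    "ctg1": SequenceRecord("ctg1", "AAAATTTT"),
    "ctg2": SequenceRecord("ctg2", "CCAA"),
    "ctg3": SequenceRecord("ctg3", "GATTACA"),
}

doc = parse_agp(io.StringIO(TOY), "toy.agp")
for rec in assemble(doc, contigs):
    shown = rec.sequence if len(rec) <= 20 else \
        f"{rec.sequence[:10]}...{rec.sequence[-6:]}"
    print(f"{rec.name}: {len(rec)} bp  {shown}")
# scaffold_1 is 8 + 100 + 4 = 112 bp and ends in TTGG: ctg2 is placed
# "-", so its bases CCAA enter reverse-complemented.
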