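"""Repair the two AGP constructs that assembly submission rejects.

A reverse-oriented single-component object, and a contig shared by two
scaffolds, are rewritten so every assembled sequence is unchanged.
"""

import io

from agptools import (
    SequenceRecord,
    assemble,
    find_submission_issues,
    format_agp,
    parse_agp,
    sanitize,
)

BAD = (
    "chrA\t1\t4\t1\tW\tctg1\t1\t4\t+\n"
    "chrB\t1\t4\t1\tW\tctg1\t5\t8\t+\n"   # ctg1 split between two objects
    "chrC\t1\t4\t1\tW\tctg2\t1\t4\t-\n"   # reverse-oriented singleton
)
contigs = {
    "ctg1": SequenceRecord("ctg1", "AACCGGTT"),
    "ctg2": SequenceRecord("ctg2", "GGCA"),
}

doc = parse_agp(io.StringIO(BAD), "bad.agp")
for issue in find_submission_issues(doc):
    print("issue:", issue.message)

before = {r.name: r.sequence for r in assemble(doc, contigs)}
fixed, records, report = sanitize(doc, contigs)
print("\nsanitized AGP:")
print(format_agp(fixed), end="")
print("\nnew component records:",
      ", ".join(f"{r.name}({len(r)} bp)" for r in records))
after = {r.name: r.sequence for r in assemble(fixed,
                                              {r.name: r for r in records})}
print("assembled sequences unchanged:", after == before)
print("remaining issues:", len(find_submission_issues(fixed)))
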