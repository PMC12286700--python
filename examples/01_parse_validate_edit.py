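"""Parse an AGP, validate it, and run the core layout edits.

Builds the toy two-scaffold assembly in memory, then joins, flips, and
splits it, printing the AGP after each step.
"""

import io

from agptools import (
    FlipSpec,
    JoinSpec,
    SplitSpec,
    flip,
    format_agp,
    join,
    parse_agp,
    split,
    validate,
)

TOY = (
    "scaffold_1\t1\t8\t1\tW\tctg1\t1\t8\t+\n"
    "scaffold_1\t9\t108\t2\tN\t100\tscaffold\tyes\tproximity_ligation\n"
    "scaffold_1\t109\t112\t3\tW\tctg2\t1\t4\t-\n"
    "scaffold_2\t1\t7\t1\tW\tctg3\t1\t7\t+\n"
)

doc = parse_agp(io.StringIO(TOY), "toy.agp")
print(f"parsed {len(doc.objects)} objects; "
      f"validation issues: {len(validate(doc))}")

joined = join(doc, JoinSpec([("scaffold_1", "+"), ("scaffold_2", "-")]))
print("\nafter joining scaffold_2 (reverse-complemented) onto scaffold_1:")
print(format_agp(joined), end="")
# one object: original rows, a new 500 bp default gap, ctg3 now "-"

flipped = flip(doc, FlipSpec("scaffold_2", 1, 7))
print("\nafter flipping all of scaffold_2 (a one-line change):")
print(format_agp(flipped), end="")

pieces = split(doc, SplitSpec("scaffold_1", [50]))
print("\nafter splitting scaffold_1 at position 50 (inside the gap,")
print("so the gap is deleted and two clean pieces remain):")
print(format_agp(pieces), end="")
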