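"""Generate a seeded synthetic assembly with known ground truth.

The generator emits (truth scaffolds, contigs, AGP) such that
assembling the contigs through the AGP reproduces the truth exactly —
the oracle behind the package's property tests.
"""

from agptools import assemble, object_length, validate
from agptools.fixtures import FixtureParams, generate_fixture

fx = generate_fixture(FixtureParams(seed=42, n_objects=3))

for layout in fx.doc.objects:
    n_comp = sum(1 for r in layout.rows if hasattr(r, "component_id"))
    print(f"{layout.name}: {object_length(layout)} bp, "
          f"{n_comp} contigs, {len(layout.rows) - n_comp} gaps")

print("validation issues:", len(validate(fx.doc)))
assembled = assemble(fx.doc, fx.components)
print("assemble(contigs, agp) == truth:",
      [r.sequence for r in assembled] == [r.sequence for r in fx.truth])
# deterministic: the same seed always yields byte-identical fixtures
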