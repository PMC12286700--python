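"""Shared fixtures: the canonical two-scaffold toy assembly.

``toy`` is the smallest assembly that exercises every structural feature
at once: a two-contig scaffold with one 100 bp gap (with the second
contig reverse-oriented) plus a single-contig scaffold.  Its component
sequences are short enough to check assembled output by eye:
scaffold_1 = AAAATTTT + 100*N + revcomp(CCAA)=TTGG, scaffold_2 = GATTACA.
"""

import io

import pytest

from agptools import SequenceRecord, parse_agp

TOY_AGP = (
    "scaffold_1\t1\t8\t1\tW\tctg1\t1\t8\t+\n"
    "scaffold_1\t9\t108\t2\tN\t100\tscaffold\tyes\tproximity_ligation\n"
    "scaffold_1\t109\t112\t3\tW\tctg2\t1\t4\t-\n"
    "scaffold_2\t1\t7\t1\tW\tctg3\t1\t7\t+\n"
)

TOY_FASTA = ">ctg1\nAAAATTTT\n>ctg2\nCCAA\n>ctg3\nGATTACA\n"

TOY_SCAFFOLD_1 = "AAAATTTT" + "N" * 100 + "TTGG"
TOY_SCAFFOLD_2 = "GATTACA"


@pytest.fixture
def toy():
    return parse_agp(io.StringIO(TOY_AGP), "toy.agp")


@pytest.fixture
def toy_components():
    return {
        "ctg1": SequenceRecord("ctg1", "AAAATTTT"),
        "ctg2": SequenceRecord("ctg2", "CCAA"),
        "ctg3": SequenceRecord("ctg3", "GATTACA"),
    }
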