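"""Edit operations: join, split, flip, remove, rename, and their parsers.

The deepest checks here are sequence-conservation oracles: every edit's
output, assembled against the same components, must relate to the
original assembled sequence in a predictable way (equality, reverse
complement, concatenation, or gap-stripped equality).
"""

import io
import logging

import pytest

from agptools import (
    AgpError,
    ComponentRow,
    FileFormatError,
    FlipSpec,
    GapRow,
    GapSpec,
    JoinSpec,
    RenameSpec,
    SplitSpec,
    assemble,
    flip,
    format_agp,
    join,
    object_length,
    parse_flips,
    parse_joins,
    parse_removes,
    parse_renames,
    parse_splits,
    remove,
    rename,
    reverse_complement,
    split,
    validate,
)
from agptools.fixtures import FixtureParams, generate_fixture


def parse(fn, text, label="ops.tsv"):
    return fn(io.StringIO(text), label)


def seqs(doc, components):
    return {r.name: r.sequence for r in assemble(doc, components)}


class TestJoin:
    def test_toy_join_with_reverse_part(self, toy):
        out = join(toy, JoinSpec([("scaffold_1", "+"), ("scaffold_2", "-")]))
        assert out.names() == ["scaffold_1"]
        rows = out.objects[0].rows
        assert len(rows) == 5
        assert (rows[0].component_id, rows[0].orientation) == ("ctg1", "+")
        assert rows[1].gap_length == 100  # original gap kept
        assert (rows[2].component_id, rows[2].orientation) == ("ctg2", "-")
        assert (rows[3].gap_length, rows[3].gap_type, rows[3].linkage,
                rows[3].linkage_evidence) == (500, "scaffold", "yes", "na")
        assert (rows[4].component_id, rows[4].orientation) == ("ctg3", "-")
        assert object_length(out.objects[0]) == 619

    def test_two_singletons_give_three_rows(self, toy):
        """Two contigs + one gap = the canonical three-line scaffold."""
        doc = split(toy, SplitSpec("scaffold_1", [50]))  # two singletons
        out = join(doc, JoinSpec([("scaffold_1.1", "+"), ("scaffold_1.2", "+")],
                                 new_name="merged"))
        assert len(out.get("merged").rows) == 3
        types = [type(r) for r in out.get("merged").rows]
        assert types == [ComponentRow, GapRow, ComponentRow]

    def test_join_sequence_oracle(self, toy, toy_components):
        before = seqs(toy, toy_components)
        out = join(toy, JoinSpec([("scaffold_1", "+"), ("scaffold_2", "-")]),
                   GapSpec(gap_length=10))
        after = seqs(out, toy_components)
        assert after["scaffold_1"] == (
            before["scaffold_1"] + "N" * 10
            + reverse_complement(before["scaffold_2"])
        )

    def test_new_name_and_order(self, toy):
        out = join(toy, JoinSpec([("scaffold_2", "+"), ("scaffold_1", "+")],
                                 new_name="chr1"))
        assert out.names() == ["chr1"]
        assert out.objects[0].rows[0].component_id == "ctg3"

    def test_untouched_objects_keep_order(self):
        fx = generate_fixture(FixtureParams(seed=3, n_objects=4))
        out = join(fx.doc, JoinSpec([("scaffold_2", "+"), ("scaffold_4", "-")]))
        assert out.names() == ["scaffold_1", "scaffold_3", "scaffold_2"]

    def test_join_errors(self, toy):
        with pytest.raises(FileFormatError, match="not in AGP"):
            join(toy, JoinSpec([("scaffold_1", "+"), ("nope", "+")],
                               line_number=4, file_label="j.tsv"))
        with pytest.raises(FileFormatError, match="duplicate sequence name"):
            join(toy, JoinSpec([("scaffold_1", "+"), ("scaffold_1", "-")]))
        fx = generate_fixture(FixtureParams(seed=1, n_objects=3))
        with pytest.raises(FileFormatError, match="collides"):
            join(fx.doc, JoinSpec([("scaffold_1", "+"), ("scaffold_2", "+")],
                                  new_name="scaffold_3"))
        # the error message carries the joins-file position
        try:
            join(toy, JoinSpec([("a", "+"), ("b", "+")], line_number=4,
                               file_label="j.tsv"))
        except FileFormatError as exc:
            assert exc.line_number == 4 and exc.file_label == "j.tsv"

    def test_gap_spec_validation(self):
        with pytest.raises(AgpError, match="positive"):
            GapSpec(gap_length=0)
        with pytest.raises(AgpError, match="linkage must be"):
            GapSpec(linkage="perhaps")
        with pytest.raises(AgpError, match="linkage=no"):
            GapSpec(linkage="no", linkage_evidence="map")


class TestParseJoins:
    def test_minus_prefix_and_default_orientation(self):
        (spec,) = parse(parse_joins, "scaffold_1,-scaffold_2\n")
        assert spec.parts == [("scaffold_1", "+"), ("scaffold_2", "-")]
        assert spec.new_name is None

    def test_new_name_field(self):
        (spec,) = parse(parse_joins, "a,b,+c\tchr1\n")
        assert spec.parts == [("a", "+"), ("b", "+"), ("c", "+")]
        assert spec.new_name == "chr1"

    def test_comments_and_blanks_skipped(self):
        specs = parse(parse_joins, "# note\n\na,b\n")
        assert len(specs) == 1 and specs[0].line_number == 3

    @pytest.mark.parametrize("text,match", [
        ("a\n", "at least two sequences"),
        ("a,,b\n", "empty sequence name"),
        ("a,b\t\n", "empty new-name"),
        ("a,b\tx\ty\n", "at most 2"),
    ])
    def test_malformed_lines(self, text, match):
        with pytest.raises(FileFormatError, match=match) as exc:
            parse(parse_joins, text)
        assert exc.value.line_number == 1


class TestSplit:
    def test_breakpoint_in_gap_deletes_gap(self, toy, toy_components):
        out = split(toy, SplitSpec("scaffold_1", [50]))
        assert out.names() == ["scaffold_1.1", "scaffold_1.2", "scaffold_2"]
        p1, p2 = out.objects[0], out.objects[1]
        assert [r.component_id for r in p1.rows] == ["ctg1"]
        assert [(r.component_id, r.orientation, r.component_beg,
                 r.component_end) for r in p2.rows] == [("ctg2", "-", 1, 4)]
        # pieces equal the gap-flanking substrings of the assembled original
        before = seqs(toy, toy_components)
        after = seqs(out, toy_components)
        assert after["scaffold_1.1"] == before["scaffold_1"][:8]
        assert after["scaffold_1.2"] == before["scaffold_1"][108:]

    def test_breakpoint_in_plus_component(self, toy, toy_components):
        out = split(toy, SplitSpec("scaffold_2", [3]))
        after = seqs(out, toy_components)
        assert after["scaffold_2.1"] == "GAT"
        assert after["scaffold_2.2"] == "TACA"
        assert after["scaffold_2.1"] + after["scaffold_2.2"] == "GATTACA"

    def test_breakpoint_in_minus_component_mirrors_span(self, toy,
                                                        toy_components):
        out = split(toy, SplitSpec("scaffold_1", [110]))
        last = out.get("scaffold_1.1").rows[-1]
        assert (last.component_id, last.component_beg, last.component_end,
                last.orientation) == ("ctg2", 3, 4, "-")
        (only,) = out.get("scaffold_1.2").rows
        assert (only.component_beg, only.component_end, only.orientation) == \
            (1, 2, "-")
        before = seqs(toy, toy_components)["scaffold_1"]
        after = seqs(out, toy_components)
        assert after["scaffold_1.1"] == before[:110]
        assert after["scaffold_1.2"] == before[110:]

    def test_multiple_breakpoints_in_one_gap_collapse(self, toy):
        out = split(toy, SplitSpec("scaffold_1", [20, 50, 90]))
        assert out.names() == ["scaffold_1.1", "scaffold_1.2", "scaffold_2"]

    def test_breakpoint_at_gap_edges_trims_dangling_gap(self, toy):
        # b=8: right piece would begin with the gap; b=108: left would end with it
        for b in (8, 108):
            out = split(toy, SplitSpec("scaffold_1", [b]))
            for name in ("scaffold_1.1", "scaffold_1.2"):
                rows = out.get(name).rows
                assert isinstance(rows[0], ComponentRow)
                assert isinstance(rows[-1], ComponentRow)

    def test_split_then_rejoin_roundtrip(self, toy, toy_components):
        out = split(toy, SplitSpec("scaffold_2", [2, 5]))
        assert out.names() == ["scaffold_1", "scaffold_2.1", "scaffold_2.2",
                               "scaffold_2.3"]
        after = seqs(out, toy_components)
        assert (after["scaffold_2.1"] + after["scaffold_2.2"]
                + after["scaffold_2.3"]) == "GATTACA"

    def test_split_errors(self, toy):
        with pytest.raises(FileFormatError, match="not in AGP"):
            split(toy, SplitSpec("nope", [5]))
        for b in (0, -3, 112, 200):
            with pytest.raises(FileFormatError, match="breakpoint"):
                split(toy, SplitSpec("scaffold_1", [b]))

    def test_piece_name_collision_rejected(self, toy):
        bad = rename(toy, [RenameSpec("scaffold_2", "scaffold_1.1", "+")])
        with pytest.raises(FileFormatError, match="collides"):
            split(bad, SplitSpec("scaffold_1", [50]))


class TestParseSplits:
    def test_simple_and_multi(self):
        specs = parse(parse_splits, "scaffold_1\t50\nchr2\t10,900,9000\n")
        assert specs[0].breakpoints == [50]
        assert specs[1].breakpoints == [10, 900, 9000]

    def test_unsorted_autosorted_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="agptools"):
            (spec,) = parse(parse_splits, "chr2\t900,10\n")
        assert spec.breakpoints == [10, 900]
        assert "sorting" in caplog.text

    @pytest.mark.parametrize("text,match", [
        ("chr2\t10,ten\n", "must be an integer"),
        ("chr2\n", "expected 2"),
        ("chr2\t5\textra\n", "expected 2"),
    ])
    def test_malformed(self, text, match):
        with pytest.raises(FileFormatError, match=match) as exc:
            parse(parse_splits, text)
        assert exc.value.line_number == 1


class TestFlip:
    def test_single_component_flip_changes_one_line(self, toy):
        before = format_agp(toy).splitlines()
        out = flip(toy, FlipSpec("scaffold_2", 1, 7))
        after = format_agp(out).splitlines()
        diffs = [i for i, (a, b) in enumerate(zip(before, after)) if a != b]
        assert len(diffs) == 1
        assert after[diffs[0]] == before[diffs[0]].replace("+", "-")

    def test_whole_object_flip_is_reverse_complement(self, toy,
                                                     toy_components):
        out = flip(toy, FlipSpec("scaffold_1", 1, 112))
        rows = out.objects[0].rows
        assert [(r.object_beg, r.object_end) for r in rows] == \
            [(1, 4), (5, 104), (105, 112)]
        assert (rows[0].component_id, rows[0].orientation) == ("ctg2", "+")
        assert (rows[2].component_id, rows[2].orientation) == ("ctg1", "-")
        before = seqs(toy, toy_components)["scaffold_1"]
        after = seqs(out, toy_components)["scaffold_1"]
        assert after == reverse_complement(before)

    def test_involution(self, toy):
        spec = FlipSpec("scaffold_1", 1, 112)
        assert flip(flip(toy, spec), spec) == toy

    def test_endpoint_in_gap_snaps_outward(self, toy):
        out = flip(toy, FlipSpec("scaffold_1", 50, 112))
        rows = out.objects[0].rows
        # segment grew to cover the whole gap: [9, 112]
        assert rows[0].component_id == "ctg1"
        assert (rows[1].component_id, rows[1].orientation) == ("ctg2", "+")
        assert isinstance(rows[2], GapRow)

    def test_endpoint_in_component_is_error(self, toy):
        with pytest.raises(FileFormatError, match="split the component first"):
            flip(toy, FlipSpec("scaffold_1", 3, 112))
        with pytest.raises(FileFormatError, match="split the component first"):
            flip(toy, FlipSpec("scaffold_1", 1, 110))

    def test_flip_errors(self, toy):
        with pytest.raises(FileFormatError, match="not in AGP"):
            flip(toy, FlipSpec("nope", 1, 5))
        with pytest.raises(FileFormatError, match="start .* > end"):
            flip(toy, FlipSpec("scaffold_1", 9, 5))
        with pytest.raises(FileFormatError, match="outside object"):
            flip(toy, FlipSpec("scaffold_1", 1, 200))

    def test_undirected_orientation_becomes_minus_with_warning(self, caplog):
        import agptools

        doc = agptools.parse_agp(io.StringIO(
            "s\t1\t4\t1\tW\tc\t1\t4\t?\n"), "q.agp")
        with caplog.at_level(logging.WARNING, logger="agptools"):
            out = flip(doc, FlipSpec("s", 1, 4))
        assert out.objects[0].rows[0].orientation == "-"
        assert "no defined reverse" in caplog.text


class TestParseFlips:
    def test_three_columns(self):
        (spec,) = parse(parse_flips, "scaffold_1\t5\t100\n")
        assert (spec.object_name, spec.seg_start, spec.seg_end) == \
            ("scaffold_1", 5, 100)

    @pytest.mark.parametrize("text,match", [
        ("s\t5\n", "expected 3"),
        ("s\tfive\t10\n", "must be integers"),
    ])
    def test_malformed(self, text, match):
        with pytest.raises(FileFormatError, match=match):
            parse(parse_flips, text)


class TestRemoveRename:
    def test_remove(self, toy):
        out = remove(toy, ["scaffold_2"])
        assert out.names() == ["scaffold_1"]

    def test_remove_nothing_is_identity(self, toy):
        assert remove(toy, []) == toy

    def test_remove_unknown(self, toy):
        with pytest.raises(AgpError, match="'scaffold_9' not in AGP"):
            remove(toy, ["scaffold_9"])

    def test_parse_removes(self):
        assert parse(parse_removes, "a\n\n# skip\nb\n") == ["a", "b"]
        with pytest.raises(FileFormatError, match="one object name"):
            parse(parse_removes, "a\tb\n")

    def test_rename_plus_keeps_rows(self, toy, toy_components):
        out = rename(toy, [RenameSpec("scaffold_1", "chr1", "+")])
        assert out.names() == ["chr1", "scaffold_2"]
        assert [r.component_id for r in out.get("chr1").rows
                if isinstance(r, ComponentRow)] == ["ctg1", "ctg2"]
        assert seqs(out, toy_components)["chr1"] == \
            seqs(toy, toy_components)["scaffold_1"]

    def test_rename_minus_equals_whole_object_flip(self, toy):
        out = rename(toy, [RenameSpec("scaffold_1", "chr1", "-")])
        flipped = flip(toy, FlipSpec("scaffold_1", 1, 112))
        expect = rename(flipped, [RenameSpec("scaffold_1", "chr1", "+")])
        assert out == expect

    def test_rename_errors(self, toy):
        with pytest.raises(FileFormatError, match="not in AGP"):
            rename(toy, [RenameSpec("nope", "chr1", "+")])
        with pytest.raises(FileFormatError, match="duplicate object name"):
            rename(toy, [RenameSpec("scaffold_1", "x", "+"),
                         RenameSpec("scaffold_2", "x", "+")])
        with pytest.raises(FileFormatError, match="renamed twice"):
            rename(toy, [RenameSpec("scaffold_1", "x", "+"),
                         RenameSpec("scaffold_1", "y", "+")])
        with pytest.raises(FileFormatError, match="duplicate object name"):
            rename(toy, [RenameSpec("scaffold_1", "scaffold_2", "+")])

    def test_parse_renames(self):
        (spec,) = parse(parse_renames, "scaffold_1\tchr1\t−\n")
        assert (spec.old_name, spec.new_name, spec.orientation) == \
            ("scaffold_1", "chr1", "-")
        with pytest.raises(FileFormatError, match="expected 3"):
            parse(parse_renames, "a\tb\n")
        with pytest.raises(FileFormatError, match="orientation"):
            parse(parse_renames, "a\tb\tboth\n")


class TestEditProperties:
    """Fuzzed invariants over generator fixtures with known ground truth."""

    @pytest.mark.parametrize("seed", range(15))
    def test_every_edit_output_validates_clean(self, seed):
        import random

        fx = generate_fixture(FixtureParams(seed=seed, n_objects=4))
        rng = random.Random(seed)
        doc = fx.doc
        names = doc.names()
        doc = join(doc, JoinSpec([(names[0], "+"), (names[2], "-")]))
        target = doc.objects[-1]
        b = rng.randint(1, object_length(target) - 1)
        doc = split(doc, SplitSpec(target.name, [b]))
        some = doc.objects[0]
        doc = flip(doc, FlipSpec(some.name, 1, object_length(some)))
        doc = rename(doc, [RenameSpec(doc.names()[-1], "chrZ", "-")])
        doc = remove(doc, [doc.names()[0]])
        assert [i for i in validate(doc) if i.severity == "error"] == []

    @pytest.mark.parametrize("seed", range(10))
    def test_split_conserves_sequence_outside_gaps(self, seed):
        import random

        fx = generate_fixture(FixtureParams(seed=seed, n_objects=3))
        rng = random.Random(seed + 1)
        layout = fx.doc.objects[rng.randrange(3)]
        L = object_length(layout)
        bps = sorted(rng.sample(range(1, L), min(3, L - 1)))
        out = split(fx.doc, SplitSpec(layout.name, bps))
        before = seqs(fx.doc, fx.components)[layout.name]
        pieces = [r.sequence for r in assemble(out, fx.components)
                  if r.name.startswith(layout.name + ".")]
        # gap runs may be dropped at split sites; compare gap-stripped content
        assert "".join(pieces).replace("N", "") == before.replace("N", "")

    @pytest.mark.parametrize("seed", range(10))
    def test_join_then_split_at_gap_midpoints_recovers_parts(self, seed):
        fx = generate_fixture(
            FixtureParams(seed=seed, n_objects=3, p_minus=0.0))
        names = fx.doc.names()
        gap = GapSpec(gap_length=333)
        joined = join(fx.doc, JoinSpec([(n, "+") for n in names],
                                       new_name="all"), gap)
        cuts = [row.object_beg + 166 for row in joined.get("all").rows
                if isinstance(row, GapRow) and row.gap_length == 333]
        back = split(joined, SplitSpec("all", cuts))
        recovered = [o for o in back.objects if o.name.startswith("all.")]
        assert len(recovered) == len(names)
        for orig_name, piece in zip(names, recovered):
            orig = fx.doc.get(orig_name)
            assert [(type(r).__name__, r.length) for r in orig.rows] == \
                [(type(r).__name__, r.length) for r in piece.rows]


class TestSplitEdgeShapes:
    def test_consecutive_gaps_trimmed_from_piece_tail(self):
        import agptools

        doc = agptools.parse_agp(io.StringIO(
            "s\t1\t4\t1\tW\tc1\t1\t4\t+\n"
            "s\t5\t14\t2\tN\t10\tscaffold\tyes\tna\n"
            "s\t15\t24\t3\tN\t10\tscaffold\tyes\tna\n"
            "s\t25\t28\t4\tW\tc2\t1\t4\t+\n"), "gg.agp")
        # cut inside the SECOND gap: the piece left of it would end with
        # the first gap, which must be trimmed too
        out = split(doc, SplitSpec("s", [20]))
        assert [r.component_id for r in out.get("s.1").rows] == ["c1"]
        assert [r.component_id for r in out.get("s.2").rows] == ["c2"]


class TestFlipEndSnap:
    def test_end_endpoint_in_gap_snaps_outward(self, toy):
        out = flip(toy, FlipSpec("scaffold_1", 1, 50))
        rows = out.objects[0].rows
        # segment grew to [1, 108]; the gap leads after reversal
        assert isinstance(rows[0], GapRow)
        assert (rows[1].component_id, rows[1].orientation) == ("ctg1", "-")
        assert (rows[2].component_id, rows[2].orientation) == ("ctg2", "-")
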