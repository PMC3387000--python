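"""Global alignment, family clustering, block finding and analog flagging."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from Bio.Align import substitution_matrices

from togascreen import make_genome_map, make_porin
from togascreen.porin_screen import CriterionVector
from togascreen.seqio import GeneLocus, ParseError, ProteinRecord
from togascreen.synteny import (
    SyntenyBlock,
    cluster_families,
    find_syntenic_blocks,
    flag_analogs,
    global_align,
)

B62 = substitution_matrices.load("BLOSUM62")


def _rec(seq, rid="x"):
    return ProteinRecord(id=rid, sequence=seq)


def brute_force_score(a, b, gap_open=11, gap_extend=1):
    """Exhaustive max over all gapped alignments (affine: open + (k-1)*ext)."""

    def gap_cost(prev, op):
        return gap_extend if prev == op else gap_open

    best = [-(10 ** 9)]

    def rec(i, j, prev, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + B62[a[i], b[j]])
        if i < len(a):
            rec(i + 1, j, "D", score - gap_cost(prev, "D"))
        if j < len(b):
            rec(i, j + 1, "I", score - gap_cost(prev, "I"))

    rec(0, 0, None, 0)
    return best[0]


class TestGlobalAlign:
    def test_identical_triplet_score(self):
        res = global_align(_rec("MKV", "a"), _rec("MKV", "b"))
        assert res.score == 14  # B62 diagonal: M=5, K=5, V=4
        assert res.identity == 1.0

    def test_empty_sequence_is_rejected_at_construction(self):
        with pytest.raises(ParseError):
            _rec("")

    def test_gapped_strings_recover_inputs(self):
        res = global_align(_rec("MKVLF", "a"), _rec("MVF", "b"))
        assert res.aligned_a.replace("-", "") == "MKVLF"
        assert res.aligned_b.replace("-", "") == "MVF"
        assert len(res.aligned_a) == len(res.aligned_b)

    def test_matches_brute_force_exhaustively_short(self):
        seqs = ["".join(p) for n in (1, 2) for p in itertools.product("ACDE", repeat=n)]
        for a, b in itertools.product(seqs, repeat=2):
            got = global_align(_rec(a, "a"), _rec(b, "b")).score
            assert got == brute_force_score(a, b), (a, b)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.text(alphabet="ACDE", min_size=1, max_size=6),
        st.text(alphabet="ACDE", min_size=1, max_size=6),
    )
    def test_matches_brute_force_sampled(self, a, b):
        assert global_align(_rec(a, "a"), _rec(b, "b")).score == brute_force_score(a, b)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.text(alphabet="ACDEFGHIKL", min_size=1, max_size=30),
        st.text(alphabet="ACDEFGHIKL", min_size=1, max_size=30),
    )
    def test_score_symmetry(self, a, b):
        assert (
            global_align(_rec(a, "a"), _rec(b, "b")).score
            == global_align(_rec(b, "b"), _rec(a, "a")).score
        )


class TestClusterFamilies:
    def test_identical_sequences_share_family(self):
        fam = cluster_families([_rec("MKVLFAE", "b"), _rec("MKVLFAE", "a")])
        assert fam["a"] == fam["b"] == "a"

    def test_unrelated_porins_split(self):
        a, _ = make_porin(11, record_id="a")
        b, _ = make_porin(222, record_id="b")
        assert global_align(a, b).identity < 0.30
        fam = cluster_families([a, b])
        assert fam["a"] != fam["b"]

    def test_single_linkage_chains(self):
        # a~b and b~c above threshold links all three even if a~c is not
        a = _rec("MKVLFAEMKVLFAE", "a")
        b = _rec("MKVLFAEWWWWWWW", "b")
        c = _rec("HHHHHHHWWWWWWW", "c")
        fam = cluster_families([a, b, c], identity_threshold=0.45)
        assert global_align(a, c).identity < 0.45
        assert fam["a"] == fam["b"] == fam["c"] == "a"

    def test_order_independence(self):
        records = [
            _rec("MKVLFAE", "r1"),
            _rec("MKVLFAE", "r2"),
            _rec("WWWWHHH", "r3"),
        ]
        fwd = cluster_families(records)
        rev = cluster_families(list(reversed(records)))
        assert fwd == rev


def _genome(families_strands, genome_id="g1"):
    return [
        GeneLocus(genome_id, f"{genome_id}_{i}", i, strand, fam)
        for i, (fam, strand) in enumerate(families_strands)
    ]


PATTERN = ("secG", "tyrS", "ompA", "ompB")


class TestFindBlocks:
    def test_direct_match(self):
        loci = _genome(
            [("x", "+"), ("secG", "+"), ("tyrS", "+"), ("ompA", "+"), ("ompB", "+"), ("y", "+")]
        )
        blocks = find_syntenic_blocks(loci, PATTERN)
        assert len(blocks) == 1
        assert blocks[0].analog_slot is None
        assert [l.family for l in blocks[0].loci] == list(PATTERN)

    def test_analog_slot_detected(self):
        loci = _genome([("secG", "+"), ("tyrS", "+"), ("ompA", "+"), ("hyp1", "+")])
        blocks = find_syntenic_blocks(loci, PATTERN)
        assert len(blocks) == 1
        assert blocks[0].analog_slot.family == "hyp1"

    def test_pattern_family_in_last_slot_is_not_an_analog(self):
        loci = _genome([("secG", "+"), ("tyrS", "+"), ("ompA", "+"), ("tyrS", "+")])
        assert find_syntenic_blocks(loci, PATTERN) == []

    def test_scattered_families_give_no_block(self):
        loci = _genome(
            [("secG", "+"), ("x", "+"), ("tyrS", "+"), ("y", "+"), ("ompA", "+"), ("z", "+"), ("ompB", "+")]
        )
        assert find_syntenic_blocks(loci, PATTERN) == []

    def test_mixed_strand_run_is_not_matched(self):
        loci = _genome([("secG", "+"), ("tyrS", "-"), ("ompA", "+"), ("ompB", "+")])
        assert find_syntenic_blocks(loci, PATTERN) == []

    def test_reverse_strand_block(self):
        loci = _genome([("ompB", "-"), ("ompA", "-"), ("tyrS", "-"), ("secG", "-")])
        blocks = find_syntenic_blocks(loci, PATTERN)
        assert len(blocks) == 1

    def test_invariance_under_genome_reversal(self):
        fams = [("a", "+"), ("secG", "+"), ("tyrS", "+"), ("ompA", "+"), ("ompB", "+"), ("b", "-")]
        loci = _genome(fams)
        flipped = [
            GeneLocus("g1", l.locus_tag, len(loci) - 1 - l.ordinal,
                      "+" if l.strand == "-" else "-", l.family)
            for l in loci
        ]
        fwd = find_syntenic_blocks(loci, PATTERN)
        rev = find_syntenic_blocks(flipped, PATTERN)
        assert len(fwd) == len(rev) == 1
        assert {l.locus_tag for l in fwd[0].loci} == {l.locus_tag for l in rev[0].loci}

    def test_gap_allowance(self):
        # four pattern loci with one missing gene between ompA and ompB:
        # strictly-consecutive matching rejects the run, one intervening
        # gene allowed accepts it
        spaced = [
            GeneLocus("g1", f"g1_{i}", o, "+", f)
            for i, (o, f) in enumerate([(0, "secG"), (1, "tyrS"), (2, "ompA"), (4, "ompB")])
        ]
        assert find_syntenic_blocks(spaced, PATTERN, max_gap=0) == []
        assert len(find_syntenic_blocks(spaced, PATTERN, max_gap=1)) == 1

    def test_interrupted_run_reports_analog_window_not_full_block(self):
        # [secG, tyrS, ompA, x, ompB] at gap 0: no full block (ompB is not
        # adjacent), but the first four genes form an analog-slot window
        loci = _genome(
            [("secG", "+"), ("tyrS", "+"), ("ompA", "+"), ("x", "+"), ("ompB", "+")]
        )
        blocks = find_syntenic_blocks(loci, PATTERN, max_gap=0)
        assert len(blocks) == 1
        assert blocks[0].analog_slot is not None
        assert blocks[0].analog_slot.family == "x"

    def test_empty_pattern_label_rejected(self):
        with pytest.raises(ValueError):
            find_syntenic_blocks([], ("secG", ""))


class TestFlagAnalogs:
    def _block_with_slot(self, tag="slot1"):
        loci = _genome([("secG", "+"), ("tyrS", "+"), ("ompA", "+"), ("hyp", "+")])
        slot = GeneLocus("g1", tag, 3, "+", "hyp")
        loci[3] = slot
        return SyntenyBlock("g1", tuple(loci), True, analog_slot=slot)

    def test_passing_slot_is_putative_analog(self):
        block = self._block_with_slot()
        vec = CriterionVector.from_flags(True, True, False, False, True)
        [(locus, verdict)] = flag_analogs([block], {"slot1": vec})
        assert verdict == "putative analog porin"

    def test_failing_cterm_is_unresolved(self):
        block = self._block_with_slot()
        vec = CriterionVector.from_flags(True, True, True, True, False)
        [(_, verdict)] = flag_analogs([block], {"slot1": vec})
        assert verdict == "unresolved"

    def test_no_analog_slots_gives_empty(self):
        loci = _genome([("secG", "+"), ("tyrS", "+"), ("ompA", "+"), ("ompB", "+")])
        block = SyntenyBlock("g1", tuple(loci), True)
        assert flag_analogs([block], {}) == []

    def test_missing_screen_result_is_an_error(self):
        block = self._block_with_slot()
        with pytest.raises(KeyError):
            flag_analogs([block], {})


class TestGenomeMapIntegration:
    def test_analog_block_flagged_end_to_end(self):
        from togascreen import make_reference_set, screen_proteome

        loci, records, truth = make_genome_map(1, with_analog=True)
        blocks = find_syntenic_blocks(loci)
        screened = {r.id: v for r, v in screen_proteome(records, make_reference_set(7))}
        [(locus, verdict)] = flag_analogs(blocks, screened)
        assert verdict == "putative analog porin"
        assert truth.labels[locus.locus_tag] == "analog_porin"
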