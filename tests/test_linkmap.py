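import collections
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xlquant.linkmap import (
    LinkAnnotation,
    ResiduePairKey,
    intra_inter_fractions,
    loop_distance,
    make_entrapment_fasta,
    read_fasta,
    to_residue_pairs,
    write_fasta,
    xifdr_input,
)
from xlquant.plink_io import CsmRecord


def cross_csm(acc_a, site_a, acc_b, site_b, title="t", pep_a="AKCDE", pos_a=2,
              pep_b="FGKHI", pos_b=3, extra_a=None):
    proteins_a = [(acc_a, site_a)]
    if extra_a:
        proteins_a.append(extra_a)
    return CsmRecord(
        spectrum_title=title, peptide_a=pep_a, peptide_b=pep_b,
        link_pos_a=pos_a, link_pos_b=pos_b,
        proteins_a=proteins_a, proteins_b=[(acc_b, site_b)],
        score=1e-5, link_type="cross",
    )


def loop_csm(acc, site_a, site_b, title="t"):
    lo, hi = sorted((site_a, site_b))
    length = hi - lo + 4
    return CsmRecord(
        spectrum_title=title, peptide_a="K" * length, peptide_b="",
        link_pos_a=2, link_pos_b=2 + hi - lo,
        proteins_a=[(acc, lo)], proteins_b=[(acc, hi)],
        score=1e-5, link_type="loop",
    )


class TestResiduePairKey:
    def test_canonical_ordering(self):
        key = ResiduePairKey.make("B", 5, "A", 9)
        assert (key.protein_a, key.pos_a) == ("A", 9)
        assert (key.protein_b, key.pos_b) == ("B", 5)

    def test_non_canonical_construction_rejected(self):
        with pytest.raises(ValueError, match="canonical"):
            ResiduePairKey("B", 1, "A", 1)

    def test_positions_one_based(self):
        with pytest.raises(ValueError, match="1-based"):
            ResiduePairKey.make("A", 0, "A", 5)

    def test_string_roundtrip(self):
        key = ResiduePairKey.make("P1", 104, "P2", 57)
        assert ResiduePairKey.from_string(key.as_string()) == key


class TestToResiduePairs:
    def test_site_arithmetic(self):
        # peptide starts at protein offset 100 (0-based), link pos 5 -> site 104
        fasta = {"P1": "X" * 100 + "AKCDKFGHI" + "X" * 20}
        # build a CSM whose claimed site matches: peptide AKCDKFGHI at offset 100,
        # link pos 5 -> protein site 105 (1-based: residue K at index 104)
        csm = CsmRecord(
            spectrum_title="t", peptide_a="AKCDKFGHI", peptide_b="AKCDKFGHI",
            link_pos_a=5, link_pos_b=2,
            proteins_a=[("P1", 105)], proteins_b=[("P1", 102)],
            score=0.1, link_type="cross",
        )
        (ann,) = to_residue_pairs([csm], fasta)
        assert (ann.key.pos_a, ann.key.pos_b) == (102, 105)

    def test_inconsistent_site_errors(self):
        fasta = {"P1": "AAAAAAAAAA"}
        csm = cross_csm("P1", 5, "P1", 8)
        with pytest.raises(ValueError, match="not found"):
            to_residue_pairs([csm], fasta)

    def test_swapped_sides_merge(self):
        a = cross_csm("P1", 10, "P2", 20, title="t1")
        b = cross_csm("P2", 20, "P1", 10, title="t2", pep_a="FGKHI", pos_a=3,
                      pep_b="AKCDE", pos_b=2)
        (ann,) = to_residue_pairs([a, b])
        assert ann.csm_count == 2
        assert ann.key == ResiduePairKey.make("P1", 10, "P2", 20)

    def test_shared_peptide_flagged(self):
        csm = cross_csm("P1", 10, "P2", 20, extra_a=("P9", 44))
        (ann,) = to_residue_pairs([csm])
        assert ann.shared_peptide

    def test_short_loops_excluded(self):
        csms = [loop_csm("P1", 10, 14), loop_csm("P1", 10, 15)]
        anns = to_residue_pairs(csms)
        assert len(anns) == 1
        assert anns[0].loop_seq_distance == 5
        assert anns[0].key.origin == "long_loop"

    def test_planted_fixture_recovery(self):
        rng = random.Random(4)
        planted = set()
        csms = []
        for i in range(50):
            sa, sb = rng.randint(1, 200), rng.randint(1, 200)
            if sa == sb:
                sb += 1
            acc_a, acc_b = f"P{rng.randint(1, 5)}", f"P{rng.randint(1, 5)}"
            key = ResiduePairKey.make(acc_a, sa, acc_b, sb)
            planted.add((key.protein_a, key.pos_a, key.protein_b, key.pos_b))
            csms.append(cross_csm(acc_a, sa, acc_b, sb, title=f"t{i}"))
        anns = to_residue_pairs(csms)
        recovered = {(a.key.protein_a, a.key.pos_a, a.key.protein_b, a.key.pos_b) for a in anns}
        assert recovered == planted
        assert sum(a.csm_count for a in anns) == 50

    def test_order_invariance(self):
        rng = random.Random(9)
        csms = [
            cross_csm(f"P{rng.randint(1, 3)}", rng.randint(1, 50),
                      f"P{rng.randint(1, 3)}", rng.randint(51, 99), title=f"t{i}")
            for i in range(30)
        ]
        ref = to_residue_pairs(csms)
        shuffled = csms[:]
        rng.shuffle(shuffled)
        alt = to_residue_pairs(shuffled)
        assert [(a.key, a.csm_count) for a in ref] == [(a.key, a.csm_count) for a in alt]

    def test_intra_inter_sum_to_100(self):
        csms = [cross_csm("P1", 1, "P1", 9), cross_csm("P1", 2, "P2", 9),
                cross_csm("P2", 3, "P3", 9)]
        pct_intra, pct_inter = intra_inter_fractions(to_residue_pairs(csms))
        assert pct_intra + pct_inter == pytest.approx(100.0)
        assert pct_intra == pytest.approx(100.0 / 3)


class TestLoopDistance:
    def test_distance_4_not_long(self):
        dist, is_long = loop_distance(loop_csm("P1", 10, 14))
        assert (dist, is_long) == (4, False)

    def test_distance_5_long(self):
        dist, is_long = loop_distance(loop_csm("P1", 10, 15))
        assert (dist, is_long) == (5, True)

    def test_degenerate_zero(self):
        csm = CsmRecord("t", "AKDE", "", 2, 2, [("P1", 7)], [("P1", 7)], 0.1, "loop")
        assert loop_distance(csm) == (0, False)

    def test_non_loop_rejected(self):
        with pytest.raises(ValueError, match="loop"):
            loop_distance(cross_csm("P1", 1, "P2", 2))


class TestEntrapmentFasta:
    def test_decoy_is_anagram(self):
        out = make_entrapment_fasta({"T1": "PEPTIDEK"}, seed=1)
        decoy = out["DECOY_T1"]
        assert len(decoy) == 8
        assert collections.Counter(decoy) == collections.Counter("PEPTIDEK")

    def test_entry_count(self):
        out = make_entrapment_fasta({"T1": "PEPTIDEK", "T2": "AAKRRK"}, seed=1)
        assert len(out) == 4

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="at least one"):
            make_entrapment_fasta({}, seed=1)

    def test_seed_determinism(self, tmp_path):
        targets = {"T1": "PEPTIDEKRRKAAK", "T2": "MKWVTFISLLLLFSSAYSK"}
        p1, p2, p3 = (tmp_path / n for n in ("a.fasta", "b.fasta", "c.fasta"))
        make_entrapment_fasta(targets, seed=7, path=p1)
        make_entrapment_fasta(targets, seed=7, path=p2)
        make_entrapment_fasta(targets, seed=8, path=p3)
        assert p1.read_bytes() == p2.read_bytes()
        assert p1.read_bytes() != p3.read_bytes()

    def test_tryptic_preservation_option(self):
        seq = "AKRPLKDER"
        out = make_entrapment_fasta({"T": seq}, seed=3, preserve_tryptic=True)
        decoy = out["DECOY_T"]
        assert [i for i, aa in enumerate(decoy) if aa in "KR"] == [
            i for i, aa in enumerate(seq) if aa in "KR"
        ]
        assert collections.Counter(decoy) == collections.Counter(seq)

    @settings(max_examples=25, deadline=None)
    @given(
        seqs=st.lists(
            st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=5, max_size=60),
            min_size=1, max_size=5, unique=True,
        ),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_multiset_preserved_property(self, seqs, seed):
        targets = {f"T{i}": s for i, s in enumerate(seqs)}
        out = make_entrapment_fasta(targets, seed=seed)
        for acc, seq in targets.items():
            assert collections.Counter(out["DECOY_" + acc]) == collections.Counter(seq)
            assert len(out["DECOY_" + acc]) == len(seq)

    def test_fasta_roundtrip(self, tmp_path):
        targets = {"T1": "PEPTIDEK" * 10, "T2": "MKWVTFISLK" * 8}
        path = tmp_path / "t.fasta"
        write_fasta(targets, path)
        assert read_fasta(path) == targets


class TestXifdrInput:
    def test_shared_filtered(self):
        csms = [cross_csm("P1", 1, "P2", 9, title=f"t{i}") for i in range(7)]
        csms += [cross_csm("P1", 2, "P2", 8, title=f"s{i}", extra_a=("P9", 40))
                 for i in range(3)]
        table = xifdr_input(csms, to_residue_pairs(csms))
        assert len(table) == 7

    def test_decoy_flags(self):
        csm = cross_csm("DECOY_P1", 1, "P2", 9)
        table = xifdr_input([csm])
        assert bool(table.iloc[0]["Decoy1"]) is True
        assert bool(table.iloc[0]["Decoy2"]) is False

    def test_exact_row_set(self):
        shared_titles = {"s0", "s1"}
        csms = [cross_csm("P1", 1, "P2", 9, title="t0"),
                cross_csm("P1", 3, "P3", 9, title="t1"),
                cross_csm("P1", 2, "P2", 8, title="s0", extra_a=("P9", 40)),
                cross_csm("P1", 4, "P2", 8, title="s1", extra_a=("P8", 41)),
                loop_csm("P1", 5, 15, title="l0")]
        table = xifdr_input(csms, to_residue_pairs(csms))
        assert set(table["SpectrumTitle"]) == {"t0", "t1"}
        assert not set(table["SpectrumTitle"]) & shared_titles
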