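import pytest
from hypothesis import given, strategies as st

import pepdisrupt as pd
from pepdisrupt.structures import Residue

from _oracles import interface_oracle

CDC37_Y4_D15 = "YSVWDHIEVSDD"
CDC37_L119_N130 = "LSKDGFSKSMVN"
CDC37P1 = "NYSVWDHIEVSDDLSKDGFSKSMVN"


def _residues(chain_id, numbers):
    return [Residue(chain_id=chain_id, number=n, name3="GLY", one_letter="G")
            for n in numbers]


class TestInterfaceResidues:
    def test_groove_peptide_fully_in_contact(self, toy_complex):
        got = pd.interface_residues(toy_complex, ["R"], "P")
        assert [r.number for r in got] == list(range(1, 13))

    def test_translated_ligand_out_of_contact(self, toy_complex):
        moved = toy_complex.copy()
        for res in moved.chain("P").residues:
            for atom in res.atoms:
                atom.position = atom.position + [0.0, 50.0, 0.0]
        assert pd.interface_residues(moved, ["R"], "P") == []

    def test_equals_all_pairs_oracle(self, jittered_frames):
        for frame in jittered_frames[:5]:
            for cutoff in (3.0, 5.0):
                got = [r.number for r in
                       pd.interface_residues(frame, ["R"], "P", cutoff)]
                assert got == interface_oracle(frame, ["R"], "P", cutoff)

    def test_unknown_chain(self, toy_complex):
        with pytest.raises(KeyError):
            pd.interface_residues(toy_complex, ["Z"], "P")


class TestContiguousStretches:
    def test_two_interface_stretches(self):
        numbers = list(range(4, 16)) + list(range(119, 131))
        spans = pd.contiguous_stretches(_residues("E", numbers))
        assert [(s.start, s.end) for s in spans] == [(4, 15), (119, 130)]

    def test_single_run(self):
        spans = pd.contiguous_stretches(_residues("A", [1, 2, 3]))
        assert [(s.start, s.end) for s in spans] == [(1, 3)]

    def test_gap_tolerance(self):
        spans = pd.contiguous_stretches(_residues("A", [1, 3]), max_gap=1)
        assert [(s.start, s.end) for s in spans] == [(1, 3)]
        spans = pd.contiguous_stretches(_residues("A", [1, 3]), max_gap=0)
        assert [(s.start, s.end) for s in spans] == [(1, 1), (3, 3)]

    def test_mixed_chains_rejected(self):
        with pytest.raises(ValueError):
            pd.contiguous_stretches(_residues("A", [1]) + _residues("B", [2]))


class TestExciseWindows:
    def test_window_count(self, toy_complex):
        spans = pd.contiguous_stretches(pd.interface_residues(toy_complex, ["R"], "P"))
        cands = pd.excise_windows(toy_complex, "P", spans, (5, 5))
        assert len(cands) == 12 - 5 + 1

    def test_full_span_window(self, toy_complex):
        spans = pd.contiguous_stretches(pd.interface_residues(toy_complex, ["R"], "P"))
        cands = pd.excise_windows(toy_complex, "P", spans, (12, 12))
        assert len(cands) == 1
        assert cands[0].sequence == spans[0].sequence == CDC37_L119_N130

    def test_windows_are_substrings_of_chain_sequence(self, toy_complex):
        spans = pd.contiguous_stretches(pd.interface_residues(toy_complex, ["R"], "P"))
        full = pd.chain_sequence(toy_complex, "P")
        for cand in pd.excise_windows(toy_complex, "P", spans, (3, 12)):
            assert cand.sequence in full

    def test_anchor_pose_copied_from_parent(self, toy_candidate, toy_complex):
        parent = toy_complex.chain("P").residues[0].atom("CA").position
        assert toy_candidate.anchor.residues[0].atom("CA").position == pytest.approx(
            parent, abs=0)

    def test_short_span_skipped_with_warning(self, toy_complex):
        short = pd.InterfaceSpan("P", 1, 3, "LSK")
        with pytest.warns(UserWarning, match="skipped"):
            cands = pd.excise_windows(toy_complex, "P", [short], (10, 12))
        assert cands == []

    def test_ranking_energy_ascending_ties_by_sequence(self, toy_complex):
        spans = pd.contiguous_stretches(pd.interface_residues(toy_complex, ["R"], "P"))
        ranked = pd.rank_candidates(pd.excise_windows(
            toy_complex, "P", spans, (10, 12), receptor_chains=["R"]))
        energies = [c.binding_energy for c in ranked]
        assert energies == sorted(energies)


class TestJoinAndPhosphomimetic:
    def test_join_reproduces_25mer_design(self):
        cand = pd.join_stretches(CDC37_Y4_D15, CDC37_L119_N130, "N",
                                 c_term_amide=True)
        assert cand.sequence == CDC37P1
        assert len(cand) == 25
        assert cand.c_term_amide

    def test_empty_extension_concatenates(self):
        cand = pd.join_stretches("AB", "CDE")
        assert cand.sequence == "ABCDE"

    def test_position_map_places_s13_at_index_11(self):
        spans = [pd.InterfaceSpan("E", 4, 15, CDC37_Y4_D15),
                 pd.InterfaceSpan("E", 119, 130, CDC37_L119_N130)]
        mapping = pd.build_position_map(spans, n_term_extension_len=1)
        assert mapping[13] == 11
        assert mapping[4] == 2
        assert mapping[119] == 14
        assert mapping[130] == 25

    @pytest.mark.parametrize("replacement, expected", [
        ("S", CDC37P1),
        ("D", "NYSVWDHIEVDDDLSKDGFSKSMVN"),
        ("E", "NYSVWDHIEVEDDLSKDGFSKSMVN"),
    ])
    def test_phosphomimetic_series(self, replacement, expected):
        spans = [pd.InterfaceSpan("E", 4, 15, CDC37_Y4_D15),
                 pd.InterfaceSpan("E", 119, 130, CDC37_L119_N130)]
        mapping = pd.build_position_map(spans, 1)
        assert pd.phosphomimetic(CDC37P1, 13, mapping, replacement) == expected

    def test_non_phosphorylatable_site_rejected(self):
        with pytest.raises(ValueError):
            pd.phosphomimetic("GAV", 2, {2: 2}, "D")

    @given(st.text(alphabet="ACDEFG", min_size=1, max_size=8),
           st.text(alphabet="HIKLMN", min_size=1, max_size=8),
           st.text(alphabet="PQRST", max_size=3))
    def test_join_length_additive(self, a, b, ext):
        assert len(pd.join_stretches(a, b, ext).sequence) == len(a) + len(b) + len(ext)

    def test_phosphomimetic_changes_hamming_by_at_most_one(self):
        spans = [pd.InterfaceSpan("E", 4, 15, CDC37_Y4_D15),
                 pd.InterfaceSpan("E", 119, 130, CDC37_L119_N130)]
        mapping = pd.build_position_map(spans, 1)
        for repl in "SDE":
            out = pd.phosphomimetic(CDC37P1, 13, mapping, repl)
            assert pd.hamming(CDC37P1, out) in (0, 1)
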