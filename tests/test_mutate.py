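import numpy as np
import pytest
from hypothesis import given, strategies as st

import pepdisrupt as pd
from pepdisrupt.mutate import _mutated_anchor

CDC37P4 = "LSKDGFSKSMVN"
CDC37P5 = "PSKDIFLKSMIN"
WEIGHTS = pd.EnergyWeights()


class TestConservation:
    def test_identical_sequences_fully_conserved(self):
        profile = pd.conservation_scores([("a", "LSKD"), ("b", "LSKD"),
                                          ("c", "LSKD")])
        assert np.allclose(profile.scores, 1.0)

    def test_single_sequence_alignment(self):
        profile = pd.conservation_scores([("ref", "GASGAS")])
        assert np.allclose(profile.scores, 1.0)

    def test_programmed_conservation_recovered(self):
        msa = pd.make_msa(CDC37P4, 1000, [0.8] * len(CDC37P4), seed=5)
        profile = pd.conservation_scores(msa)
        assert np.all(np.abs(profile.scores - 0.8) <= 0.04)

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            pd.conservation_scores([("a", "GAS"), ("b", "GA")])

    def test_entropy_alternative_available(self):
        profile = pd.conservation_scores(
            [("a", "AA"), ("b", "AC"), ("c", "AG")], method="entropy")
        assert profile[0] == pytest.approx(1.0)
        assert profile[1] < 1.0


class TestEnumerateVariants:
    def test_cartesian_product_count(self):
        variants = pd.enumerate_variants(
            "GAS", [1, 3], {1: "LIV", 3: "DEN"})
        assert len(variants) == 9
        assert len(set(variants)) == 9

    def test_empty_positions_return_input(self):
        assert pd.enumerate_variants("GAS", [], {}) == ["GAS"]

    def test_exhaustive_single_mutants_of_12mer(self):
        alphabet = sorted(set("ACDEFGHIKLMNPQRSTVWY"))
        count = 0
        for pos in range(1, 13):
            wt = CDC37P4[pos - 1]
            count += len(pd.enumerate_variants(
                CDC37P4, [pos], {pos: [a for a in alphabet if a != wt]}))
        assert count == 12 * 19

    def test_empty_allowed_set_rejected(self):
        with pytest.raises(ValueError):
            pd.enumerate_variants("GAS", [2], {2: ""})


class TestHamming:
    def test_p4_to_p5_is_four_mutations(self):
        assert pd.hamming(CDC37P4, CDC37P5) == 4

    def test_identity(self):
        assert pd.hamming(CDC37P4, CDC37P4) == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pd.hamming("GAS", "GA")

    @given(st.text(alphabet="ACDG", min_size=1, max_size=20).flatmap(
        lambda a: st.tuples(st.just(a),
                            st.text(alphabet="ACDG", min_size=len(a),
                                    max_size=len(a)))))
    def test_matches_positionwise_oracle(self, pair):
        a, b = pair
        assert pd.hamming(a, b) == sum(x != y for x, y in zip(a, b))


class TestOptimize:
    def test_zero_mutations_returns_input(self, toy_complex, toy_candidate):
        profile = pd.ConservationProfile([1.0] * 12)
        proposals, best = pd.optimize(
            toy_candidate, profile, toy_complex, max_mutations=0,
            lambda_steepness=0.0, receptor_chains=["R"])
        assert proposals == []
        assert best is toy_candidate

    def test_zero_conservation_proposes_nothing(self, toy_complex, toy_candidate):
        profile = pd.ConservationProfile([0.0] * 12)
        _, best = pd.optimize(
            toy_candidate, profile, toy_complex, max_mutations=2,
            lambda_steepness=0.0, receptor_chains=["R"])
        assert best.sequence == toy_candidate.sequence

    def test_beam_equals_exhaustive_single_mutant_search(self, toy_complex,
                                                         toy_candidate):
        """With beam width >= 19*L and one mutation allowed, the beam search
        must return the same best mutant as brute-force enumeration."""
        seq = toy_candidate.sequence
        profile = pd.ConservationProfile([1.0] * len(seq))
        allowed = {i + 1: [a for a in sorted(set("ACDEFGHIKLMNPQRSTVWY"))
                           if a != seq[i]]
                   for i in range(len(seq))}
        e0 = pd.score_pose(toy_complex, toy_candidate.anchor, WEIGHTS, ["R"])

        # independent exhaustive search over all 19*L single mutants
        best_exhaustive, best_obj = seq, 0.0
        for pos in range(1, len(seq) + 1):
            for aa in allowed[pos]:
                anchor = _mutated_anchor(toy_candidate.anchor, pos, aa)
                obj = e0 - pd.score_pose(toy_complex, anchor, WEIGHTS, ["R"])
                variant = seq[:pos - 1] + aa + seq[pos:]
                improves = obj > best_obj
                ties = (obj == best_obj and best_exhaustive != seq
                        and variant < best_exhaustive)
                if improves or ties:
                    best_exhaustive, best_obj = variant, obj

        _, best = pd.optimize(
            toy_candidate, profile, toy_complex, weights=WEIGHTS,
            beam_width=19 * len(seq), max_mutations=1,
            lambda_steepness=0.0, allowed=allowed, receptor_chains=["R"])
        assert best.sequence == best_exhaustive

    def test_designed_cavity_single_substitution(self, toy_complex, toy_candidate):
        """Restricting the search to hydrophobic-for-polar swaps at one
        position must recover exactly that substitution."""
        seq = toy_candidate.sequence  # LSKDGFSKSMVN
        profile = pd.ConservationProfile([1.0] * len(seq))
        allowed = {5: ["I"]}  # G5 -> I facing the hydrophobic groove
        proposals, best = pd.optimize(
            toy_candidate, profile, toy_complex, beam_width=5, max_mutations=1,
            lambda_steepness=0.0, allowed=allowed, receptor_chains=["R"])
        assert best.sequence == "LSKDIFSKSMVN"
        assert best.binding_energy < toy_candidate.binding_energy

    def test_objective_never_worse_than_input(self, toy_complex, toy_candidate):
        profile = pd.ConservationProfile([1.0] * 12)
        _, best = pd.optimize(
            toy_candidate, profile, toy_complex, beam_width=4, max_mutations=2,
            lambda_steepness=0.0, receptor_chains=["R"])
        assert best.binding_energy <= toy_candidate.binding_energy

    def test_deterministic_under_seed(self, toy_complex, toy_candidate):
        profile = pd.ConservationProfile([1.0] * 12)
        kwargs = dict(beam_width=3, max_mutations=2, seed=9,
                      rrt_params=pd.RRTParams(max_nodes=40, seed=0),
                      lambda_steepness=1.0, receptor_chains=["R"])
        _, a = pd.optimize(toy_candidate, profile, toy_complex, **kwargs)
        _, b = pd.optimize(toy_candidate, profile, toy_complex, **kwargs)
        assert a.sequence == b.sequence
        assert a.binding_energy == b.binding_energy
        assert a.funnel_steepness == b.funnel_steepness

    def test_candidate_without_anchor_rejected(self, toy_complex):
        cand = pd.PeptideCandidate(sequence="GASGASGASGAS")
        with pytest.raises(ValueError, match="anchor"):
            pd.optimize(cand, pd.ConservationProfile([1.0] * 12), toy_complex)


def test_blosum_allowed_substitutions():
    top = pd.allowed_substitutions("L", top_n=5)
    assert len(top) == 5
    assert "L" not in top
    assert "I" in top and "M" in top  # conservative replacements rank first
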