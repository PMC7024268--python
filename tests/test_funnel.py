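import numpy as np
import pytest

import pepdisrupt as pd
from pepdisrupt.funnel import BinderCall, RRTParams, _peptide_coords

from _oracles import score_oracle

WEIGHTS = pd.EnergyWeights()


def _translated(chain, shift):
    moved = pd.Chain(chain.id, [
        type(r)(chain_id=r.chain_id, number=r.number, name3=r.name3,
                icode=r.icode, one_letter=r.one_letter,
                modification=r.modification,
                atoms=[type(a)(a.name, a.element, a.position + shift)
                       for a in r.atoms])
        for r in chain.residues
    ])
    return moved


class TestScorePose:
    def test_distant_peptide_scores_zero(self, toy_complex, toy_candidate):
        far = _translated(toy_candidate.anchor, np.array([0.0, 50.0, 0.0]))
        assert pd.score_pose(toy_complex, far, WEIGHTS, ["R"]) == 0.0

    def test_energy_linear_in_hbond_weight(self, toy_complex):
        # E is linear in w_hbond with coefficient N_hbond: each satisfied
        # bond contributes exactly w_hbond to the total
        peptide = toy_complex.chain("P")
        n_hb = len(pd.detect_hbonds(toy_complex, {"R"}, {"P"}))
        e_a = pd.score_pose(toy_complex, peptide,
                            pd.EnergyWeights(w_hbond=-2.0), ["R"])
        e_b = pd.score_pose(toy_complex, peptide,
                            pd.EnergyWeights(w_hbond=-3.0), ["R"])
        assert e_b - e_a == pytest.approx(-1.0 * n_hb, abs=1e-12)

    def test_equals_brute_force_oracle(self, jittered_frames):
        for frame in jittered_frames[:5]:
            peptide = frame.chain("P")
            got = pd.score_pose(frame, peptide, WEIGHTS, ["R"])
            want = score_oracle(frame, ["R"], peptide, WEIGHTS)
            assert got == pytest.approx(want, abs=1e-9)

    def test_invariant_under_global_isometry(self, toy_complex):
        e0 = pd.score_pose(toy_complex, toy_complex.chain("P"), WEIGHTS, ["R"])
        moved = toy_complex.copy()
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0],
                        [0, 0, 1]])
        for res in moved.iter_residues():
            for atom in res.atoms:
                atom.position = rot @ atom.position + np.array([5.0, -3.0, 2.0])
        e1 = pd.score_pose(moved, moved.chain("P"), WEIGHTS, ["R"])
        assert abs(e1 - e0) < 1e-6

    def test_empty_peptide_rejected(self, toy_complex):
        with pytest.raises(ValueError):
            pd.score_pose(toy_complex, pd.Chain("Q", []), WEIGHTS, ["R"])

    def test_weight_signs_enforced(self):
        with pytest.raises(ValueError):
            pd.EnergyWeights(w_hbond=1.0)


class TestRRT:
    def test_vanishing_steps_keep_samples_at_anchor(self, toy_complex, toy_candidate):
        params = RRTParams(max_nodes=30, translation_step=1e-6,
                           rotation_step=1e-6, dihedral_step=1e-6, seed=1)
        samples = pd.rrt_explore(toy_complex, toy_candidate.anchor, params,
                                 receptor_chains=["R"])
        assert max(s.rmsd for s in samples) < 1e-4

    def test_coverage_reaches_exploration_radius(self, toy_complex, toy_candidate):
        params = RRTParams(max_nodes=200, seed=7)
        samples = pd.rrt_explore(toy_complex, toy_candidate.anchor, params,
                                 receptor_chains=["R"])
        assert max(s.rmsd for s in samples) >= 0.8 * params.rmsd_max

    def test_all_samples_inside_radius_and_clash_free(self, toy_complex, toy_candidate):
        params = RRTParams(max_nodes=150, seed=3)
        samples = pd.rrt_explore(toy_complex, toy_candidate.anchor, params,
                                 receptor_chains=["R"])
        rec = np.array([a.position for r in toy_complex.chain("R").residues
                        for a in r.atoms])
        for s in samples:
            assert s.rmsd <= params.rmsd_max + 1e-9
            dmin = np.min(np.linalg.norm(
                rec[None, :, :] - s.conformation[:, None, :], axis=2))
            assert dmin >= 2.5

    def test_reproducible_and_bounded(self, toy_complex, toy_candidate):
        params = RRTParams(max_nodes=80, seed=5)
        a = pd.rrt_explore(toy_complex, toy_candidate.anchor, params,
                           receptor_chains=["R"])
        b = pd.rrt_explore(toy_complex, toy_candidate.anchor, params,
                           receptor_chains=["R"])
        assert len(a) == len(b) <= params.max_nodes
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.conformation, sb.conformation)
            assert sa.energy == sb.energy

    def test_clashing_anchor_reported(self, toy_complex, toy_candidate):
        crashed = _translated(toy_candidate.anchor, np.array([0.0, 3.0, 0.0]))
        with pytest.raises(ValueError, match="clash"):
            pd.rrt_explore(toy_complex, crashed, RRTParams(max_nodes=10, seed=0),
                           receptor_chains=["R"])


class TestSteepness:
    def test_noise_free_slope_exact(self):
        samples = pd.make_funnel_samples(5.0, 0.0, 100, 3.0, seed=1)
        assert pd.funnel_steepness(samples).slope == pytest.approx(5.0, abs=1e-9)

    def test_noisy_slope_within_three_stderr(self):
        samples = pd.make_funnel_samples(6.36, 0.5, 500, 3.0, seed=2)
        from scipy import stats as sstats
        x = [s.rmsd for s in samples]
        y = [s.energy for s in samples]
        se = sstats.linregress(x, y).stderr
        assert pd.funnel_steepness(samples).slope == pytest.approx(6.36, abs=3 * se)

    def test_constant_energy_slope_zero(self):
        samples = [pd.FunnelSample(None, r, 1.5) for r in (0.0, 1.0, 2.0)]
        stats = pd.funnel_steepness(samples)
        assert stats.slope == pytest.approx(0.0, abs=1e-12)

    def test_order_invariance(self):
        samples = pd.make_funnel_samples(4.0, 0.3, 50, 2.0, seed=3)
        fwd = pd.funnel_steepness(samples).slope
        rev = pd.funnel_steepness(samples[::-1]).slope
        assert fwd == pytest.approx(rev, abs=1e-12)

    def test_degenerate_rmsd_rejected(self):
        samples = [pd.FunnelSample(None, 1.0, 0.0), pd.FunnelSample(None, 1.0, 2.0)]
        with pytest.raises(ValueError):
            pd.funnel_steepness(samples)

    def test_window_restricts_fit(self):
        inside = pd.make_funnel_samples(5.0, 0.0, 50, 2.0, seed=4)
        outlier = [pd.FunnelSample(None, 10.0, -100.0)]
        stats = pd.funnel_steepness(inside + outlier, rmsd_window=(0.0, 2.0))
        assert stats.slope == pytest.approx(5.0, abs=1e-9)
        assert stats.n_samples == 50


class TestBinderRule:
    @pytest.mark.parametrize("slope, length, expected", [
        (6.36, 12, BinderCall.BINDER),
        (11.68, 12, BinderCall.BINDER),
        (4.9, 12, BinderCall.NON_BINDER),
        (5.0, 12, BinderCall.NON_BINDER),   # strictly above five
        (6.36, 9, BinderCall.NOT_CALIBRATED),
        (6.36, 16, BinderCall.NOT_CALIBRATED),
    ])
    def test_slope_above_five_for_10_to_15_mers(self, slope, length, expected):
        assert pd.is_binder(slope, length) is expected

    def test_accepts_funnel_stats(self):
        stats = pd.FunnelStats(slope=6.36, intercept=0.0, r_squared=0.9, n_samples=10)
        assert bool(pd.is_binder(stats, 12))
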