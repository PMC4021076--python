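"""Parentage likelihoods, posteriors, MCMC-vs-enumeration, and scoring."""

import numpy as np
import pytest

from pedpower.demography import UNSAMPLED
from pedpower.markers import (
    ErrorModel,
    LocusModel,
    MarkerPanel,
    mendelian_offspring_codes,
    observe_codes,
    simulate_founder_codes,
)
from pedpower.parentage import (
    AssignmentPosterior,
    ChainSettings,
    UnsampledPrior,
    enumerate_posterior,
    likelihood_tensor,
    mcmc_assign,
    mismatch_prefilter,
    mismatch_tolerance_for,
    pair_likelihood,
    score_against_truth,
    threshold_assign,
)


def _locus(freqs, alleles=None):
    alleles = alleles or tuple("ABCDEFG"[: len(freqs)])
    return LocusModel("L1", alleles, np.array(freqs, dtype=float))


class TestPairLikelihood:
    def test_mendelian_exclusion_without_error(self, no_error):
        panel = MarkerPanel([_locus([0.5, 0.5])])
        ok = pair_likelihood({"L1": ("A", "B")}, {"L1": ("A", "A")},
                             {"L1": ("B", "B")}, panel, no_error)
        assert ok == pytest.approx(1.0)
        excluded = pair_likelihood({"L1": ("A", "A")}, {"L1": ("A", "A")},
                                   {"L1": ("B", "B")}, panel, no_error)
        assert excluded == 0.0

    def test_sampled_vs_unsampled_ratio(self, no_error):
        # offspring BB, candidate dam BB vs unsampled dam at p_B = 0.1:
        # likelihood ratio 1 : 0.1
        panel = MarkerPanel([_locus([0.9, 0.1])])
        cand = pair_likelihood({"L1": ("B", "B")}, {"L1": ("B", "B")}, None,
                               panel, no_error)
        unsamp = pair_likelihood({"L1": ("B", "B")}, None, None, panel, no_error)
        assert unsamp / cand == pytest.approx(0.1)

    def test_all_missing_gives_unit_likelihood(self, no_error):
        panel = MarkerPanel([_locus([0.5, 0.5]),
                             LocusModel("L2", ("A", "B"), np.array([0.7, 0.3]))])
        lk = pair_likelihood({"L1": None, "L2": None}, {"L1": ("A", "A")},
                             None, panel, no_error)
        assert lk == pytest.approx(1.0)

    def test_invariant_to_allele_relabelling_and_locus_order(self, no_error):
        lo1 = LocusModel("x", ("A", "B", "C"), np.array([0.5, 0.3, 0.2]))
        lo2 = LocusModel("y", ("Q", "R", "S"), np.array([0.5, 0.3, 0.2]))
        p12 = MarkerPanel([lo1, LocusModel("z", ("A", "B"), np.array([0.6, 0.4]))])
        p21 = MarkerPanel([LocusModel("z", ("A", "B"), np.array([0.6, 0.4])), lo2])
        err = ErrorModel(0.02, 0.004, 0.0)
        a = pair_likelihood({"x": ("A", "B"), "z": ("A", "A")},
                            {"x": ("A", "C"), "z": ("A", "B")}, None, p12, err)
        b = pair_likelihood({"y": ("Q", "R"), "z": ("A", "A")},
                            {"y": ("Q", "S"), "z": ("A", "B")}, None, p21, err)
        assert a == pytest.approx(b, rel=1e-12)


class TestMismatchPrefilter:
    def _codes(self, pairs):
        return np.array(pairs, dtype=np.int32)

    def test_three_mismatches_dropped_at_tolerance_two(self):
        off = self._codes([[0, 0], [0, 0], [0, 0], [0, 1]])
        cand = self._codes([[1, 1], [1, 1], [1, 1], [0, 1]])
        assert not mismatch_prefilter(off, cand, tolerance=2)
        assert mismatch_prefilter(off, cand, tolerance=3)

    def test_no_mismatch_kept_at_zero_tolerance(self):
        off = self._codes([[0, 1], [0, 0]])
        cand = self._codes([[1, 2], [0, 1]])
        assert mismatch_prefilter(off, cand, tolerance=0)

    def test_missing_calls_never_count(self):
        off = self._codes([[-1, -1], [0, 0]])
        cand = self._codes([[1, 1], [-1, -1]])
        assert mismatch_prefilter(off, cand, tolerance=0)

    def test_tolerance_rule_for_panel_sizes(self):
        assert mismatch_tolerance_for(14) == 2
        assert mismatch_tolerance_for(28) == 2
        assert mismatch_tolerance_for(50) == 3


def _toy_instance(rng, n_dams=2, n_sires=2, n_loci=3, n_off=3, error=None,
                  seed_panel=7):
    from pedpower.markers import build_synthetic_panel

    panel = build_synthetic_panel(n_loci, 4.0, 0.55, seed=seed_panel)
    error = error or ErrorModel(0.02, 0.004, 0.0)
    dams = simulate_founder_codes(panel, n_dams, rng)
    sires = simulate_founder_codes(panel, n_sires, rng)
    offs = mendelian_offspring_codes(
        dams[rng.integers(n_dams, size=n_off)],
        sires[rng.integers(n_sires, size=n_off)], rng)
    freqs = [l.freqs for l in panel.loci]
    L = likelihood_tensor(observe_codes(offs, panel, error, rng),
                          observe_codes(dams, panel, error, rng),
                          observe_codes(sires, panel, error, rng),
                          panel, freqs, error)
    off_ids = [f"o{i}" for i in range(n_off)]
    dam_ids = [f"d{i}" for i in range(n_dams)]
    sire_ids = [f"s{i}" for i in range(n_sires)]
    return off_ids, dam_ids, sire_ids, L


class TestEnumeratePosterior:
    def test_symmetric_candidates_split_mass(self):
        # two dams with identical genotypes, no unsampled mass
        L = np.zeros((1, 3, 1))
        L[0, 0, 0] = L[0, 1, 0] = 0.4
        post = enumerate_posterior(["o"], ["d1", "d2"], [], L, 1e-12, 1.0)
        assert post.dam_marginals[0, 0] == pytest.approx(0.5, abs=1e-9)
        assert post.dam_marginals[0, 1] == pytest.approx(0.5, abs=1e-9)

    def test_two_hypothesis_closed_form(self, no_error):
        # one compatible homozygous dam vs one expected unsampled dam at
        # p_B = 0.1: posterior(candidate) = 1/(1 + 0.1)
        panel = MarkerPanel([_locus([0.9, 0.1])])
        off = np.array([[[1, 1]]], dtype=np.int32)
        dam = np.array([[[1, 1]]], dtype=np.int32)
        L = likelihood_tensor(off, dam, np.empty((0, 1, 2), dtype=np.int32),
                              panel, [panel.loci[0].freqs], no_error)
        post = enumerate_posterior(["o"], ["d"], [], L, 1.0, 1.0)
        assert post.dam_marginals[0, 0] == pytest.approx(1 / 1.1, abs=1e-9)

    def test_unsampled_dominates_in_the_limit(self, no_error):
        panel = MarkerPanel([_locus([0.9, 0.1])])
        off = np.array([[[1, 1]]], dtype=np.int32)
        dam = np.array([[[1, 1]]], dtype=np.int32)
        L = likelihood_tensor(off, dam, np.empty((0, 1, 2), dtype=np.int32),
                              panel, [panel.loci[0].freqs], no_error)
        post = enumerate_posterior(["o"], ["d"], [], L, 1e9, 1.0)
        assert post.dam_marginals[0, 0] < 1e-6

    def test_marginals_normalise(self, rng):
        off_ids, dam_ids, sire_ids, L = _toy_instance(rng)
        post = enumerate_posterior(off_ids, dam_ids, sire_ids, L, 3.0, 5.0)
        np.testing.assert_allclose(post.dam_marginals.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(post.sire_marginals.sum(axis=1), 1.0, atol=1e-9)


class TestMcmcAssign:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_enumeration_oracle(self, seed):
        """Collapsed MCMC marginals match exact enumeration at the prior mean
        when the count prior is nearly a point mass (<= 4x4 candidates)."""
        rng = np.random.default_rng(seed)
        off_ids, dam_ids, sire_ids, L = _toy_instance(
            rng, n_dams=4, n_sires=4, n_loci=3, n_off=4, seed_panel=seed + 3)
        prior = UnsampledPrior(dam_mean=3.0, dam_sd=1e-3, sire_mean=5.0, sire_sd=1e-3)
        chain = ChainSettings(iterations=4000, burnin=1000, thin=5)
        post = mcmc_assign(off_ids, dam_ids, sire_ids, L, prior, chain, rng)
        exact = enumerate_posterior(off_ids, dam_ids, sire_ids, L, 3.0, 5.0)
        np.testing.assert_allclose(post.dam_marginals, exact.dam_marginals, atol=0.02)
        np.testing.assert_allclose(post.sire_marginals, exact.sire_marginals, atol=0.02)

    def test_zero_information_returns_prior_weights(self, rng):
        # all loci missing: posterior over dams equals the prior weights
        L = np.ones((2, 3, 2))
        prior = UnsampledPrior(dam_mean=2.0, dam_sd=1e-3, sire_mean=1.0, sire_sd=1e-3)
        chain = ChainSettings(iterations=3000, burnin=500, thin=5)
        post = mcmc_assign(["o1", "o2"], ["d1", "d2"], ["s1"], L, prior, chain, rng)
        # weights 1,1,2 over (d1, d2, UNSAMPLED)
        np.testing.assert_allclose(post.dam_marginals[0], [0.25, 0.25, 0.5], atol=0.02)

    def test_nonmixing_chain_warns(self, rng):
        off_ids, dam_ids, sire_ids, L = _toy_instance(rng)
        prior = UnsampledPrior(dam_mean=3.0, dam_sd=1e-6, sire_mean=5.0, sire_sd=1e6)
        chain = ChainSettings(iterations=2000, burnin=200, thin=5,
                              scale_dam=5000.0, scale_sire=1e-9)
        with pytest.warns(UserWarning, match="acceptance"):
            mcmc_assign(off_ids, dam_ids, sire_ids, L, prior, chain, rng)

    def test_invalid_chain_settings_rejected(self):
        with pytest.raises(ValueError):
            ChainSettings(iterations=100, burnin=200)


class TestThresholdAssign:
    def _post(self, marg):
        marg = np.asarray(marg, dtype=float)
        return AssignmentPosterior(
            offspring_ids=["o"], dam_ids=[f"d{i}" for i in range(marg.shape[1] - 1)],
            sire_ids=[], dam_marginals=marg, sire_marginals=np.ones((1, 1)),
        )

    def test_threshold_boundary_accepts_at_equality(self):
        post = self._post([[0.95, 0.04, 0.01]])
        assert threshold_assign(post, 0.95)["o"][0] == "d0"
        post = self._post([[0.94, 0.05, 0.01]])
        assert threshold_assign(post, 0.95)["o"][0] == UNSAMPLED

    def test_unsampled_never_emitted(self):
        post = self._post([[0.01, 0.01, 0.98]])
        assert threshold_assign(post, 0.5)["o"][0] == UNSAMPLED

    def test_lowering_threshold_never_removes_links(self, rng):
        off_ids, dam_ids, sire_ids, L = _toy_instance(rng, n_off=6)
        post = enumerate_posterior(off_ids, dam_ids, sire_ids, L, 2.0, 2.0)
        high = threshold_assign(post, 0.9)
        low = threshold_assign(post, 0.4)
        for o, (d, s) in high.items():
            if d != UNSAMPLED:
                assert low[o][0] == d
            if s != UNSAMPLED:
                assert low[o][1] == s


class TestScoring:
    def test_perfect_inference(self):
        truth = {"o1": ("d1", "s1"), "o2": ("d2", UNSAMPLED)}
        inferred = {"o1": ("d1", "s1"), "o2": ("d2", UNSAMPLED)}
        m = score_against_truth(inferred, truth)
        assert m.true_assignment_pct == 100.0
        assert m.false_assignment_pct == 0.0

    def test_empty_inference_zero_true_zero_false(self):
        truth = {"o1": ("d1", "s1")}
        m = score_against_truth({"o1": (UNSAMPLED, UNSAMPLED)}, truth)
        assert m.true_assignment_pct == 0.0
        assert m.false_assignment_pct == 0.0

    def test_one_of_two_links_wrong(self):
        truth = {"o1": ("d1", "s1")}
        m = score_against_truth({"o1": ("d1", "s2")}, truth)
        assert m.false_assignment_pct == 50.0

    def test_unanalysed_parent_not_assignable(self):
        truth = {"o1": ("d1", "s1"), "o2": ("d2", "s2")}
        inferred = {"o1": ("d1", UNSAMPLED), "o2": (UNSAMPLED, UNSAMPLED)}
        m = score_against_truth(inferred, truth, assignable_parents={"d1", "s1"})
        assert m.n_assignable == 2
        assert m.true_assignment_pct == 50.0

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            score_against_truth({}, {})


class TestMendelianConsistency:
    def test_emitted_links_consistent_without_error(self):
        """With e1 = e2 = 0, any link emitted at a high threshold is
        Mendelian-compatible at every co-scored locus."""
        from pedpower.markers import build_synthetic_panel
        from pedpower.parentage import mismatch_counts

        rng = np.random.default_rng(5)
        panel = build_synthetic_panel(8, 6.0, 0.65, seed=2)
        err = ErrorModel(0, 0, 0.2)
        dams = simulate_founder_codes(panel, 20, rng)
        sires = simulate_founder_codes(panel, 20, rng)
        offs = mendelian_offspring_codes(dams[rng.integers(20, size=30)],
                                         sires[rng.integers(20, size=30)], rng)
        freqs = [l.freqs for l in panel.loci]
        d_obs = observe_codes(dams, panel, err, rng)
        s_obs = observe_codes(sires, panel, err, rng)
        o_obs = observe_codes(offs, panel, err, rng)
        L = likelihood_tensor(o_obs, d_obs, s_obs, panel, freqs,
                              ErrorModel(0, 0, 0))
        post = enumerate_posterior([f"o{i}" for i in range(30)],
                                   [f"d{i}" for i in range(20)],
                                   [f"s{i}" for i in range(20)], L, 5.0, 5.0)
        links = threshold_assign(post, 0.8)
        mm_d = mismatch_counts(o_obs, d_obs)
        for i, (o, (d, s)) in enumerate(links.items()):
            if d != UNSAMPLED:
                assert mm_d[i, int(d[1:])] == 0
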