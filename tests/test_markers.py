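"""Marker panels, the genotyping-error model, diversity and exclusion statistics."""

import numpy as np
import pytest

from pedpower.markers import (
    ErrorModel,
    GenotypeTable,
    LocusModel,
    MarkerPanel,
    apply_error_and_missingness,
    build_synthetic_panel,
    combined_exclusion,
    diversity_summary,
    estimate_error_rates,
    exclusion_probability,
    genotype_pairs,
    hwe_probs,
    observation_matrix,
    observe_codes,
    simulate_founder_codes,
    simulate_offspring_genotype,
)


class TestLocusModel:
    def test_validation(self):
        with pytest.raises(ValueError):
            LocusModel("x", ("A",), np.array([1.0]))
        with pytest.raises(ValueError):
            LocusModel("x", ("A", "B"), np.array([0.7, 0.2]))
        with pytest.raises(ValueError):
            LocusModel("x", ("A", "B"), np.array([1.0, 0.0]))

    def test_he_and_pic_closed_forms(self, biallelic):
        assert biallelic.expected_heterozygosity() == pytest.approx(0.5)
        assert biallelic.pic() == pytest.approx(0.375)  # 1 - 2p^2q^2 - sum p^2 at p=q=0.5


class TestPanelSynthesis:
    def test_hits_summary_targets(self):
        panel = build_synthetic_panel(14, 12.0, 0.70, seed=1)
        assert abs(panel.mean_allele_number() - 12.0) <= 1.2
        assert abs(panel.mean_expected_heterozygosity() - 0.70) <= 0.05

    def test_biallelic_special_case(self):
        with pytest.warns(UserWarning):
            panel = build_synthetic_panel(1, 2.0, 0.5, seed=0)
        np.testing.assert_allclose(panel.loci[0].freqs, [0.5, 0.5], atol=1e-6)

    def test_deterministic_given_seed(self):
        a = build_synthetic_panel(5, 8.0, 0.6, seed=42)
        b = build_synthetic_panel(5, 8.0, 0.6, seed=42)
        for la, lb in zip(a.loci, b.loci):
            np.testing.assert_array_equal(la.freqs, lb.freqs)
            assert la.allele_ids == lb.allele_ids

    def test_infeasible_targets_rejected(self):
        with pytest.raises(ValueError):
            build_synthetic_panel(5, 12.0, 1.2, seed=0)
        with pytest.raises(ValueError):
            build_synthetic_panel(0, 12.0, 0.7, seed=0)


class TestOffspringSimulation:
    def test_forced_heterozygote(self, biallelic, rng):
        g = simulate_offspring_genotype(("A", "A"), ("B", "B"), biallelic, rng)
        assert g == ("A", "B")

    def test_mendelian_ratios(self, biallelic, rng):
        draws = [simulate_offspring_genotype(("A", "B"), ("A", "B"), biallelic, rng)
                 for _ in range(20000)]
        frac_aa = np.mean([g == ("A", "A") for g in draws])
        frac_ab = np.mean([g == ("A", "B") for g in draws])
        assert frac_aa == pytest.approx(0.25, abs=0.015)
        assert frac_ab == pytest.approx(0.5, abs=0.015)

    def test_null_parents_draw_hwe(self, skewed_biallelic, rng):
        draws = [simulate_offspring_genotype(None, None, skewed_biallelic, rng)
                 for _ in range(100000)]
        frac = {g: np.mean([d == g for d in draws])
                for g in [("A", "A"), ("A", "B"), ("B", "B")]}
        assert frac[("A", "A")] == pytest.approx(0.81, abs=0.01)
        assert frac[("A", "B")] == pytest.approx(0.18, abs=0.01)
        assert frac[("B", "B")] == pytest.approx(0.01, abs=0.005)

    def test_foreign_allele_rejected(self, biallelic, rng):
        with pytest.raises(ValueError):
            simulate_offspring_genotype(("A", "Z"), None, biallelic, rng)


class TestErrorModel:
    def test_rates_validated(self):
        with pytest.raises(ValueError):
            ErrorModel(e1=1.5)

    def test_boundary_dropout(self, biallelic, rng):
        err = ErrorModel(e1=1.0, e2=0.0, missing_rate=0.0)
        draws = [apply_error_and_missingness(("A", "B"), biallelic, err, rng)
                 for _ in range(5000)]
        assert set(draws) == {("A", "A"), ("B", "B")}
        assert np.mean([d == ("A", "A") for d in draws]) == pytest.approx(0.5, abs=0.03)

    def test_homozygote_immune_to_dropout(self, biallelic, rng):
        err = ErrorModel(e1=0.5, e2=0.0, missing_rate=0.0)
        assert all(
            apply_error_and_missingness(("A", "A"), biallelic, err, rng) == ("A", "A")
            for _ in range(200)
        )

    def test_heterozygote_retention_rate(self, biallelic, rng):
        err = ErrorModel(e1=0.02, e2=0.0, missing_rate=0.0)
        draws = [apply_error_and_missingness(("A", "B"), biallelic, err, rng)
                 for _ in range(100000)]
        assert np.mean([d == ("A", "B") for d in draws]) == pytest.approx(0.98, abs=0.004)

    @pytest.mark.parametrize("n_alleles", [2, 3, 4])
    def test_observation_density_normalises(self, n_alleles):
        err = ErrorModel(e1=0.1, e2=0.05, missing_rate=0.2)
        O = observation_matrix(n_alleles, err)
        np.testing.assert_allclose(O.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(O >= 0)

    def test_vectorised_observation_matches_density(self, small_panel, rng):
        """observe_codes (the simulator) and observation_matrix (the likelihood)
        describe the same process: empirical frequencies match the density."""
        err = ErrorModel(e1=0.3, e2=0.1, missing_rate=0.15)
        locus = small_panel.loci[1]
        true = np.tile(np.array([[0, 1]], dtype=np.int32), (200000, 1))[:, None, :]
        obs = observe_codes(true, MarkerPanel([locus]), err, rng)[:, 0, :]
        O = observation_matrix(locus.n_alleles, err)
        pairs = genotype_pairs(locus.n_alleles)
        g_true = int(np.flatnonzero((pairs == [0, 1]).all(axis=1))[0])
        for g, (a, b) in enumerate(pairs):
            emp = np.mean((obs[:, 0] == a) & (obs[:, 1] == b))
            assert emp == pytest.approx(O[g_true, g], abs=0.004)
        assert np.mean(obs[:, 0] < 0) == pytest.approx(err.missing_rate, abs=0.004)


class TestDiversitySummary:
    def _table(self, codes, n_alleles=2):
        codes = np.asarray(codes, dtype=np.int32)[:, None, :]
        labels = [tuple(f"{i + 1:03d}" for i in range(n_alleles))]
        return GenotypeTable([f"i{k}" for k in range(codes.shape[0])], ["L1"], labels, codes)

    def test_even_biallelic_closed_form(self, rng):
        locus = LocusModel("L1", ("001", "002"), np.array([0.5, 0.5]))
        codes = simulate_founder_codes(MarkerPanel([locus]), 50000, rng)
        t = GenotypeTable([str(i) for i in range(50000)], ["L1"], [locus.allele_ids], codes)
        s = diversity_summary(t)
        assert s.loc["L1", "He"] == pytest.approx(0.5, abs=0.01)
        assert s.loc["L1", "PIC"] == pytest.approx(0.375, abs=0.01)

    def test_monomorphic_observed(self):
        s = diversity_summary(self._table([[0, 0], [0, 0], [0, 0]]))
        assert s.loc["L1", "Ho"] == 0.0
        assert s.loc["L1", "He"] == 0.0

    def test_fully_heterozygous(self):
        s = diversity_summary(self._table([[0, 1], [0, 1]]))
        assert s.loc["L1", "Ho"] == 1.0

    def test_all_missing_flagged(self):
        s = diversity_summary(self._table([[-1, -1], [-1, -1]]))
        assert bool(s.loc["L1", "all_missing"])
        assert np.isnan(s.loc["L1", "Ho"])


def exclusion_oracle(freqs):
    """Brute-force enumeration over (offspring, candidate) genotype pairs:
    probability an unrelated HWE candidate shares no allele with an HWE-bred
    offspring."""
    freqs = np.asarray(freqs, float)
    K = freqs.size
    pairs = genotype_pairs(K)
    # offspring genotype distribution: child of two HWE parents is HWE
    off_probs = hwe_probs(freqs)
    cand_probs = hwe_probs(freqs)
    total = 0.0
    for go, (a, b) in enumerate(pairs):
        for gc, (c, d) in enumerate(pairs):
            if len({a, b} & {c, d}) == 0:
                total += off_probs[go] * cand_probs[gc]
    return total


class TestExclusion:
    def test_even_biallelic_value(self, biallelic):
        assert exclusion_probability(biallelic) == pytest.approx(0.125, abs=1e-12)

    def test_near_monomorphic_vanishes(self):
        locus = LocusModel("m", ("A", "B"), np.array([1 - 1e-9, 1e-9]))
        assert exclusion_probability(locus) == pytest.approx(0.0, abs=1e-8)

    def test_combined_independence_product(self, biallelic):
        panel = MarkerPanel([
            LocusModel("a", ("A", "B"), np.array([0.5, 0.5])),
            LocusModel("b", ("A", "B"), np.array([0.5, 0.5])),
        ])
        assert combined_exclusion(panel) == pytest.approx(1 - 0.875**2, abs=1e-12)

    @pytest.mark.parametrize("n_alleles", [2, 3, 4, 5])
    def test_matches_enumeration_oracle(self, n_alleles):
        rng = np.random.default_rng(n_alleles)
        for _ in range(20):
            freqs = rng.dirichlet(np.ones(n_alleles) * rng.uniform(0.3, 3.0))
            freqs = np.clip(freqs, 1e-6, None)
            freqs /= freqs.sum()
            locus = LocusModel("x", tuple("ABCDE"[:n_alleles]), freqs)
            assert exclusion_probability(locus) == pytest.approx(
                exclusion_oracle(freqs), abs=1e-12
            )


class TestErrorRateEstimation:
    def _replicates(self, panel, n_pairs, err, rng):
        true = simulate_founder_codes(panel, n_pairs, rng)
        reps = []
        for obs in (observe_codes(true, panel, err, rng),
                    observe_codes(true, panel, err, rng)):
            rows = []
            for i in range(n_pairs):
                rec = {}
                for j, locus in enumerate(panel.loci):
                    a, b = obs[i, j]
                    rec[locus.locus_id] = (
                        None if a < 0
                        else (locus.allele_ids[a], locus.allele_ids[b])
                    )
                rows.append(rec)
            reps.append(rows)
        return list(zip(reps[0], reps[1]))

    def test_identical_replicates_give_zero(self, small_panel, rng):
        true = simulate_founder_codes(small_panel, 400, rng)
        obs = observe_codes(true, small_panel, ErrorModel(0, 0, 0), rng)
        rows = []
        for i in range(400):
            rec = {loc.locus_id: tuple(loc.allele_ids[c] for c in obs[i, j])
                   for j, loc in enumerate(small_panel.loci)}
            rows.append(rec)
        est = estimate_error_rates(list(zip(rows, rows)), small_panel)
        assert est["e1"] < 0.01 and est["e2"] < 0.01

    def test_recovers_study_error_rates(self, rng):
        panel = build_synthetic_panel(14, 8.0, 0.7, seed=9)
        err = ErrorModel(e1=0.02, e2=0.004, missing_rate=0.05)
        pairs = self._replicates(panel, 1000, err, rng)
        est = estimate_error_rates(pairs, panel)
        lo1, hi1 = est["e1_ci"]
        lo2, hi2 = est["e2_ci"]
        assert lo1 <= 0.02 <= hi1
        assert lo2 <= 0.004 <= hi2
        assert est["e1"] == pytest.approx(0.02, abs=0.01)

    def test_single_mismatching_pair_degenerate(self, small_panel):
        a = {"L1": ("A", "A")}
        b = {"L1": ("B", "B")}
        est = estimate_error_rates([(a, b)], small_panel)
        assert 0.0 < est["e1"] < 1.0
        assert est["n_coscored"] == 1

    def test_no_coscored_loci_refused(self, small_panel):
        with pytest.raises(ValueError):
            estimate_error_rates([({"L1": None}, {"L1": ("A", "A")})], small_panel)


class TestEstimatorConsistency:
    def test_dropout_bias_shrinks_with_sample_size(self):
        """e1 estimates tighten around the truth as replicate pairs grow."""
        panel = build_synthetic_panel(8, 6.0, 0.65, seed=4)
        err = ErrorModel(e1=0.05, e2=0.004, missing_rate=0.0)
        helper = TestErrorRateEstimation()
        errs = []
        for k, n in enumerate((50, 500, 5000)):
            rng = np.random.default_rng(100 + k)
            est = estimate_error_rates(helper._replicates(panel, n, err, rng), panel)
            errs.append(abs(est["e1"] - 0.05))
        assert errs[2] < errs[0]
        assert errs[2] < 0.01


class TestDensityProperties:
    """Property-based checks of the observation model."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        n_alleles=st.integers(2, 5),
        e1=st.floats(0.0, 1.0),
        e2=st.floats(0.0, 1.0),
        m=st.floats(0.0, 0.95),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_density_rows_always_normalise(self, n_alleles, e1, e2, m):
        O = observation_matrix(n_alleles, ErrorModel(e1, e2, m))
        assert np.all(O >= -1e-15)
        np.testing.assert_allclose(O.sum(axis=1), 1.0, atol=1e-10)

    @given(
        seed=st.integers(0, 10_000),
        n_loci=st.integers(1, 6),
        he=st.floats(0.2, 0.85),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_panel_frequencies_always_valid(self, seed, n_loci, he):
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            panel = build_synthetic_panel(n_loci, 6.0, he, seed=seed)
        for locus in panel.loci:
            assert np.all(locus.freqs > 0)
            assert abs(locus.freqs.sum() - 1.0) < 1e-12
            assert locus.n_alleles >= 2
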