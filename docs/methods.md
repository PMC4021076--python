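# Methods

This note documents the models behind `pedpower`, the choices made where
the design was genuinely open, and what the simulations do and do not show
about real data.

## 1. Marker panels and the observation model

**Panel synthesis.** A panel is defined by per-locus allele-frequency
vectors. Real archival microsatellite panels are heterogeneous: a few
hypervariable loci (20+ alleles, He ≈ 0.9) carry most of the assignment
information, alongside several weakly informative loci. The generator
therefore draws allele counts per locus from a shifted negative binomial
(`K = 2 + NB(mean = target − 2, dispersion 0.7)`, capped at 45), draws
frequencies from a Dirichlet(0.8) of that size — so allele-rich loci are
naturally the high-diversity ones — and calibrates a single panel-wide
concentration exponent so the realised mean expected heterozygosity hits
the target exactly (bisection on `q ∝ p^λ`). With the defaults
(mean 12 alleles, He target 0.725) a 14-locus panel reproduces the
benchmark panel's printed summary moments simultaneously: mean allele
number ≈ 12, mean He ≈ 0.725, per-locus diversity spanning roughly
0.05–0.95, and a combined single-parent exclusion probability of
≈ 0.99995. The last moment matters most: assignment information is convex
in per-locus diversity, so two panels with the same mean He can differ
several-fold in power. An earlier design with near-constant per-locus
diversity matched He and PIC but fell an order of magnitude short of the
published exclusion probability and systematically under-predicted
assignment success.

**Observation density.** A true single-locus genotype is observed through
three stages: (i) missing with probability `m`; (ii) allelic dropout — a
heterozygote is scored as either constituent homozygote with probability
`e1/2` each (true homozygotes are immune); (iii) per-allele miscall — each
reported allele is independently replaced by one of the other `K − 1`
alleles uniformly with probability `e2`. The density is assembled exactly
as a (true genotype × observed genotype + missing) matrix whose rows sum
to one; simulation samples from it and the parentage likelihood integrates
over it, so data generation and inference share one error model. Defaults
`e1 = 0.02`, `e2 = 0.004` are the study's replicate-based estimates, and
`estimate_error_rates` re-derives such estimates by maximum likelihood
from repeat-genotyped individuals (latent true genotype integrated over
HWE; logit-scale Nelder–Mead with a soft box so degenerate inputs stay
interior; Wald CIs from a finite-difference Hessian).

**Missingness in the pipeline.** Aggregate missingness is ~11%, but
archival DNA quality varies strongly with specimen age, so missing calls
cluster within individuals. In the assignment pipeline each analysed
individual draws its own missing rate from a Beta with mean 0.11 and
concentration 1.2; individuals scoring fewer than half the panel are
replaced by fresh draws, because the analysed counts in the cohort table
already exclude such failures. The concentration was calibrated so that at
14 loci ~7.6% of raw draws fail the half-panel rule — the study's excluded
fraction — while the mean missing rate stays 11%. This matters: uniform
11% missingness overstates its cost to assignment roughly threefold at 14
loci, because in real data most analysed specimens are nearly complete and
a small minority are poor. Single-call operations (`apply_error_and_missingness`,
`observation_matrix`) default to homogeneous missingness; the likelihood
conditions on the observed missingness pattern either way, so inference is
unaffected by the choice — only simulated data are.

## 2. Demography

Ten cohorts (1977–1986) with the published census/sampled/analysed counts;
six parent–offspring pairs at a fixed four-year generation interval. Per
cohort pair:

* female fraction of the adult census ~ Uniform(0.55, 0.70);
* precocious male parr enlarge the male breeding pool by a Beta-distributed
  fraction (mean 0.17, concentration 12) and are never sampled;
* reproductive success per parent is negative binomial with dispersion
  0.25 (males) / 0.75 (females) — male success is more skewed and more
  males fail entirely (Bateman asymmetry); independent per-sex draws are
  pinned to the offspring-census total exactly (multinomial top-up,
  hypergeometric removal), then offspring slots are matched randomly
  (each offspring gets one dam and one sire, preserving per-parent counts);
* sampling is independent of the pedigree: the analysed count is drawn
  without replacement, split by sex so ~81% of sampled kelts are female.

Group labels for the RRS analysis scale the NB mean of the "high" group by
the fold difference with the totals held fixed, so "fold" is the ratio of
per-capita expected offspring between groups.

## 3. Parentage model

For each analysed offspring, one dam and one sire are drawn from (analysed
candidates of the right sex) + (a pooled UNSAMPLED category). Sampled
candidates have prior weight 1; the unsampled category has weight equal to
a latent count `U` per sex, with truncated-normal priors whose means come
from census arithmetic (unsampled females: mid-range sex ratio × census −
analysed females; unsampled males additionally inflated by the parr pool)
and deliberately broad SDs.

The pair likelihood at a locus is the bilinear form `t_d^T W t_s`:
`t_p` is the candidate's allele-transmission vector with its true genotype
integrated over the error-aware posterior given its observed genotype
(HWE prior; population frequencies if unscored or unsampled), and
`W[a,b] = P(observed offspring genotype | true genotype (a,b))`. Loci
multiply; missing offspring loci contribute a constant. Allele frequencies
are the empirical frequencies of the pooled analysed parent+offspring
sample (with a half-count floor). Candidates with more than the tolerated
number of allele-disjoint loci (2; 3 at 50 loci) are excluded up front.

**Inference.** Given `(U_dam, U_sire)`, offspring are conditionally
independent and their pair posteriors are exact categorical sums, so the
per-offspring indicators are collapsed analytically and a component-wise
Gaussian random walk (proposal SD = 0.5 / 0.1 × prior SD for dams/sires,
reflected at zero) samples the two counts — the per-offspring factor is
`Z_o(U)/((n_d + U_d)(n_s + U_s))` with `Z_o` linear in each count, so an
iteration costs O(offspring). Chain defaults: 13,000 iterations, 3,000
burn-in, thinning 10. Parent marginals are Rao–Blackwellised: because the
marginal numerators are linear in the opposite-sex count, averaging over
thinned draws reduces to four 1/Z-weighted moments. On enumerable
instances this matches exact enumeration to Monte-Carlo error (tested at
±0.02). A link is emitted when a specific sampled candidate's marginal
reaches the threshold (ties accept); the unsampled category is never
emitted. True-assignment % divides correct links by truth links whose
parent was analysed; false-assignment % divides wrong links by emitted
links (0/0 → 0).

## 4. RRS power

Each replicate builds one cohort pair's parental counts per sex, draws NB
reproductive success with the group fold applied, samples parents and
offspring at the empirical fractions (offspring allocated to parents by
multivariate hypergeometric draws, so sibship clustering propagates), and
retains each sampled true link with probability equal to the panel's mean
true-assignment rate (0.95-threshold rates; the acceptance script feeds
the rate it just computed). Fisher's exact test (two-sided) is applied to
[[sampled high-group parents, assigned high-group offspring], [low, low]];
a zero margin is recorded as non-significant. Power is the fraction of
replicates with p < α over ≥200 replicates; "combined" sums the six
per-pair tables within a replicate before testing. Common random numbers
across grid points make fold/ratio/rate contrasts paired. Because family
sizes are overdispersed, the observed null rejection rate can sit slightly
above the nominal α even though Fisher's test is conservative for
independent counts; it stays within Monte-Carlo range of α = 0.05.

## 5. Heritability power

`build_A` implements the tabular method; `synthesize_pedigree_like`
generates a pedigree hitting an empirical structure summary exactly
(maternal/paternal link counts, dual-parent offspring, half-sib family
counts with maximum sizes, full-sib families), with everything else
unrelated founders — the built-in `TABLE4_COMBINED` structure has 876
offspring, 297 maternal and 44 paternal links, 64 maternal families
(max 7) and 7 paternal families (max 6). Phenotypes: founder breeding
values ~ N(0, h²); non-founders take the parental mean (unknown parents
contribute 0, treated as unrelated non-inbred founders — adequate for
these shallow pedigrees) plus Mendelian-sampling noise with variance
h²(1 − n_known/4); residuals N(0, 1 − h²), so total variance is 1 and the
offspring–parent regression slope is h²/2.

REML profiles the restricted likelihood in λ = σ²_a/σ²_e after one
eigendecomposition of A (cached and shared across replicates): a 25-point
log-spaced grid on λ ∈ [10⁻⁴, 10²] followed by bounded Brent refinement;
the residual variance is closed-form. With A = I the ratio is not
identified; the fit pins h² to 0 and flags it. The σ²_a = 0 test uses the
boundary mixture ½χ²₀ + ½χ²₁ by default — known to be conservative on
sparse pedigrees — with a parametric-bootstrap null
(`lrt_h2_simulated_null`) available where exactness matters. Power curves
report the rejection fraction and the spread of ĥ² per h² value; a list of
pedigrees is fitted "combined" with a block-diagonal A and per-pedigree
intercepts.

## 6. Problem sizes and reproducibility

The shipped experiments run the six cohort pairs at 10–12 replicates per
marker number (the study used 100), 200 RRS replicates per grid point
(study: 1,000), and 50 phenotype replicates per h² value (study: 100);
Monte-Carlo SEs at these sizes are ~1–3 percentage points on the reported
rates, small against the comparison tolerances. Every stochastic stage
takes an explicit seed; per-replicate sub-seeds are spawned
deterministically (`SeedSequence(entropy, spawn_key)`), and demography is
re-used across marker numbers within a replicate so marker contrasts are
paired.

## 7. What the simulations do not capture

* Sampling is independent of reproductive success; if kelt sampling in
  fact conditions on successful spawning, real assignable-link fractions
  would be higher than simulated.
* Genotypes are in HWE with locus independence and temporally stable
  frequencies; null alleles, linkage, and cohort differentiation are not
  modelled.
* The allocation engine fixes error rates at their estimates rather than
  co-estimating them with the pedigree, and grandparent links would be
  derived by chaining single-generation assignments, not by joint
  multigenerational likelihoods.
* Groups in the RRS analysis are abstract labels; real dichotomies
  (sea-winter age, hatchery origin) may correlate with sampling or
  survival in ways the thinning model ignores.
* The heritability model is univariate with no maternal-effect component;
  phenotypes are complete and noise-free given h².
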