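# pedpower

Power analysis for molecular pedigree reconstruction in partially sampled
wild populations, modelled on a ten-cohort Atlantic salmon (*Salmo salar*)
river system with a total trapping census, archival scale samples, and a
four-year generation interval.

In systems like this, parent–offspring relationships can only be recovered
genetically, and three practical questions decide whether a pedigree-based
study is worth attempting **before** any genotyping is done:

1. **How many microsatellite loci are needed** to assign parents reliably,
   given partial sampling (12–51% of each cohort analysed), an unsampled
   pool of precocious mature male parr, and archival-DNA genotyping error?
2. **What difference in relative reproductive success (RRS)** between two
   groups of breeders is detectable from the assigned offspring counts?
3. **How heritable must a continuous trait be** for an animal model fitted
   to the partially resolved pedigree to detect it?

`pedpower` answers all three by simulation:

* **Markers** (`pedpower.markers`) — synthesizes microsatellite panels with
  a target mean allele number and mean expected heterozygosity (per-locus
  diversity varies widely, as in real panels), simulates Mendelian
  genotypes, and pushes them through an explicit observation model:
  allelic dropout `e1` (a heterozygote scored as either homozygote with
  probability `e1/2` each), per-allele miscall `e2`, and per-specimen
  missingness. The same density parameterises the assignment likelihood.
  Also: per-locus Ho/He/PIC, single-parent exclusion probability
  `Q = Σᵢ pᵢ²(1−pᵢ)² + Σ_{i≠j} pᵢpⱼ(1−pᵢ−pⱼ)²`, and maximum-likelihood
  `(e1, e2)` estimation from repeat-genotyped individuals.
* **Demography** (`pedpower.demography`) — the built-in cohort table
  (census 245–854 per year, 1977–1986), female-biased adult sex ratio
  (55–70%), a never-sampled parr pool (mean 17% of breeding males),
  per-sex negative-binomial reproductive skew (dispersion 0.25 males /
  0.75 females, totals pinned to the offspring census), random mating, and
  sex-biased kelt sampling (81% of samples female).
* **Parentage** (`pedpower.parentage`) — Bayesian categorical allocation:
  each offspring draws one dam and one sire from (analysed candidates +
  an UNSAMPLED category) whose prior weight is a latent count with a
  truncated-normal prior from census arithmetic; likelihoods integrate
  genotyping error on both sides; Mendelian mismatch pre-filtering;
  a collapsed Metropolis sampler over the unsampled counts with
  Rao–Blackwellised parent marginals; posterior-threshold link emission
  and truth-based scoring.
* **RRS power** (`pedpower.power_rrs`) — group-labelled breeders, an
  assignment-rate thinning standing in for the genotype pipeline, Fisher's
  exact test on the (sampled parents × assigned offspring) 2×2 table, and
  power surfaces over group ratio × fold difference, per cohort pair and
  pooled.
* **Heritability power** (`pedpower.power_h2`) — numerator relationship
  matrices (tabular method), pedigree synthesis matching empirical link
  and family-size structure, phenotype simulation with Mendelian-sampling
  variance, a hand-rolled REML animal model (1-D profile likelihood after
  eigendecomposition), boundary-corrected likelihood-ratio tests, and
  power curves over h².

## Worked example

```python
import numpy as np
import pedpower as pp

# a 14-locus panel like the study's Panel 1
panel = pp.build_synthetic_panel(n_loci=14, target_mean_alleles=12,
                                 target_mean_ho=0.725, seed=1)
print(round(panel.mean_allele_number(), 1),
      round(panel.mean_expected_heterozygosity(), 3),
      round(pp.combined_exclusion(panel), 6))
# 12.0 0.725 0.999938   -> ~12 alleles/locus, He 0.725, panel-wide
#                          exclusion probability ~0.99994

# the built-in cohort table
cfgs, pairs = pp.make_burrishoole_configs()
s = pp.cohort_table_summary(cfgs)
print(s["totals"]["census"], s["means"]["census"], s["means"]["pct_sampled_analysed"])
# 4885 488.5 92.5       -> total census, mean census, mean % of sampled
#                          fish successfully analysed

# marker-number experiment (one cohort pair, quick settings)
from pedpower.parentage import marker_number_experiment, summarise_marker_experiment
tab = marker_number_experiment(loci_grid=(14, 28), thresholds=(0.95,),
                               replicates=2, cohort_pairs=[(1981, 1985)], seed=1)
print(summarise_marker_experiment(tab)[["n_loci", "true_pct"]].round(1))
#    n_loci  true_pct
# 0      14      68.6
# 1      28      98.2
# -> at the stringent 0.95 posterior threshold, 14 loci recover ~2/3 of
#    the assignable true parental links in this well-sampled cohort pair,
#    28 loci nearly all of them
```

The CLI mirrors the library stages:

```bash
pedpower summary --seed 1 --out run/
pedpower marker-power --seed 1 --replicates 10 --out run/
pedpower rrs-power --seed 1 --out run/
pedpower h2-power --seed 1 --reps 50 --out run/
pedpower assign --genotypes G.tsv --dams dams.txt --sires sires.txt \
    --offspring offspring.txt --threshold 0.95
```

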