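"""Power to detect relative-reproductive-success (RRS) differences.

Two arbitrary parental groups ('high'/'low') within a cohort differ in
per-capita expected offspring by a fold factor. Reproductive success is
negative-binomial per sex (males far more skewed than females), totals are
pinned to the empirical offspring census, both cohorts are partially sampled
at the empirical fractions, and each sampled true parent-offspring link
survives genotyping/assignment with a probability equal to the mean
true-assignment rate of the marker panel in use (14 or 28 loci). The
observed group-by-count table (sampled parents x assigned offspring) is
tested with Fisher's exact test; power is the fraction of significant
replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .demography import (
    FEMALE_SAMPLE_SHARE,
    MALE_SAMPLE_SHARE,
    BURRISHOOLE_PAIRS,
    CohortConfig,
    make_burrishoole_configs,
)

__all__ = [
    "RRSExperiment",
    "ASSIGNMENT_RATES",
    "simulate_rrs_replicate",
    "fisher_exact_2x2",
    "power_surface",
    "DEFAULT_R_GRID",
]

DEFAULT_R_GRID = (0.01, 0.05, 0.15, 0.3, 0.5, 0.7, 0.85, 0.95, 0.99)

# mean true-assignment rates at the 0.95 posterior threshold, by panel size;
# produced by parentage.marker_number_experiment (see the acceptance script)
# and used here as link-retention probabilities.
ASSIGNMENT_RATES = {14: 0.67, 28: 0.952}


@dataclass(frozen=True)
class RRSExperiment:
    """Grid definition for an RRS power surface."""

    r_grid: tuple = DEFAULT_R_GRID
    fold_grid: tuple = (1.0, 1.5, 2.0, 2.5, 3.0)
    sexes: str = "F"  # 'F', 'M' or 'both'
    n_loci: int = 28
    assignment_rate: float = None  # default: ASSIGNMENT_RATES[n_loci]
    replicates: int = 1000
    alpha: float = 0.05
    cohort_pairs: tuple = tuple(BURRISHOOLE_PAIRS)

    def __post_init__(self) -> None:
        if any(not 0 < r < 1 for r in self.r_grid):
            raise ValueError("group ratios must lie in (0, 1)")
        if any(f < 1 for f in self.fold_grid):
            raise ValueError("fold differences must be >= 1")
        rate = self.rate
        if not 0.0 <= rate <= 1.0:
            raise ValueError("assignment_rate must lie in [0, 1]")
        if self.sexes not in ("F", "M", "both"):
            raise ValueError("sexes must be 'F', 'M' or 'both'")

    @property
    def rate(self) -> float:
        if self.assignment_rate is not None:
            return self.assignment_rate
        return ASSIGNMENT_RATES[self.n_loci]


def _one_sex_table(N_parents: int, n_parents_analysed: int, total_offspring: int,
                   n_off_analysed: int, dispersion: float, r: float, fold: float,
                   rate: float, rng) -> np.ndarray:
    """[parents analysed, offspring assigned] x [high, low] for one parent sex."""
    from .demography import _exact_total_nb

    n_high = int(round(r * N_parents))
    n_high = min(max(n_high, 1), N_parents - 1)
    group = np.zeros(N_parents, dtype=bool)
    group[:n_high] = True
    mu_low = total_offspring / (fold * n_high + (N_parents - n_high))
    mu = np.where(group, fold * mu_low, mu_low)
    counts = _exact_total_nb(mu, dispersion, total_offspring, rng)
    analysed = np.zeros(N_parents, dtype=bool)
    analysed[rng.choice(N_parents, size=min(n_parents_analysed, N_parents),
                        replace=False)] = True
    # which offspring are analysed: exact without-replacement sampling of the
    # offspring cohort, allocated over parents hypergeometrically
    n_off_analysed = min(n_off_analysed, total_offspring)
    off_analysed = rng.multivariate_hypergeometric(counts, n_off_analysed)
    assignable = np.where(analysed, off_analysed, 0)
    assigned = rng.binomial(assignable, rate)
    table = np.array([
        [int(analysed[group].sum()), int(assigned[group].sum())],
        [int(analysed[~group].sum()), int(assigned[~group].sum())],
    ])
    return table


def simulate_rrs_replicate(parent_cfg: CohortConfig, offspring_cfg: CohortConfig,
                           r: float, fold: float, rate: float, rng,
                           sexes: str = "F",
                           female_fraction: float = None) -> np.ndarray:
    """One replicate 2x2 table [[high parents, high assigned], [low, low]].

    For ``sexes='both'`` the female and male tables are summed (groups are
    labelled within each sex at the same ratio). The male breeding pool
    includes never-sampled parr; male sampling uses the male kelt share.
    """
    if female_fraction is None:
        lo, hi = parent_cfg.female_fraction_range
        female_fraction = rng.uniform(lo, hi)
    N_f = int(round(female_fraction * parent_cfg.census))
    N_m_anad = parent_cfg.census - N_f
    pm = parent_cfg.parr_fraction_mean
    n_parr = int(round(pm / (1 - pm) * N_m_anad)) if pm > 0 else 0
    share_f = FEMALE_SAMPLE_SHARE / (FEMALE_SAMPLE_SHARE + MALE_SAMPLE_SHARE)
    n_an_f = int(round(share_f * parent_cfg.n_analysed))
    n_an_m = parent_cfg.n_analysed - n_an_f
    total = offspring_cfg.census
    n_off_an = offspring_cfg.n_analysed
    table = np.zeros((2, 2), dtype=int)
    if sexes in ("F", "both"):
        table += _one_sex_table(N_f, n_an_f, total, n_off_an, 0.75, r, fold, rate, rng)
    if sexes in ("M", "both"):
        # analysed males sit inside the anadromous pool; parr enlarge the
        # breeding pool but can never be analysed, so cap analysed count
        t = _one_sex_table(N_m_anad + n_parr, min(n_an_m, N_m_anad), total,
                           n_off_an, 0.25, r, fold, rate, rng)
        table += t
    return table


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value; a zero margin returns p = 1
    (recorded as non-significant by convention)."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table entries must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def power_surface(experiment: RRSExperiment, seed: int = 0,
                  pooled: bool = True) -> pd.DataFrame:
    """Monte-Carlo power over the (r, fold) grid.

    Emits one row per grid point per cohort pair, plus (``pooled=True``) a
    'combined' row in which the six per-pair tables of each replicate are
    summed before testing. Common random numbers are used across grid
    points (the same per-(pair, replicate) seed), so power comparisons along
    fold, r or assignment-rate are paired.
    """
    configs, _ = make_burrishoole_configs()
    cfg = {c.cohort_year: c for c in configs}
    root = np.random.SeedSequence(seed)
    rows = []
    for r in experiment.r_grid:
        for fold in experiment.fold_grid:
            pvals = {pair: np.empty(experiment.replicates) for pair in experiment.cohort_pairs}
            pooled_p = np.empty(experiment.replicates)
            for rep in range(experiment.replicates):
                tables = []
                for pi, (py, oy) in enumerate(experiment.cohort_pairs):
                    rng = np.random.default_rng(
                        np.random.SeedSequence(entropy=root.entropy, spawn_key=(pi, rep))
                    )
                    t = simulate_rrs_replicate(cfg[py], cfg[oy], r, fold,
                                               experiment.rate, rng,
                                               sexes=experiment.sexes)
                    tables.append(t)
                    pvals[(py, oy)][rep] = fisher_exact_2x2(t)
                if pooled:
                    pooled_p[rep] = fisher_exact_2x2(np.sum(tables, axis=0))
            for pair in experiment.cohort_pairs:
                p = float(np.mean(pvals[pair] < experiment.alpha))
                rows.append(dict(r=r, fold=fold, sex=experiment.sexes,
                                 n_loci=experiment.n_loci,
                                 cohort_pair=f"{pair[0]}-{pair[1]}", power=p,
                                 se=float(np.sqrt(p * (1 - p) / experiment.replicates))))
            if pooled:
                p = float(np.mean(pooled_p < experiment.alpha))
                rows.append(dict(r=r, fold=fold, sex=experiment.sexes,
                                 n_loci=experiment.n_loci, cohort_pair="combined",
                                 power=p,
                                 se=float(np.sqrt(p * (1 - p) / experiment.replicates))))
    return pd.DataFrame(rows)
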