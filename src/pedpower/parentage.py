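"""Bayesian categorical parentage allocation with unsampled parents.

Model
-----
For each offspring in a cohort, exactly one dam and one sire are drawn from
(candidate analysed parents of the right sex) + (a pooled UNSAMPLED category).
A priori every sampled candidate has weight 1 and the unsampled category has
weight equal to the latent number of unsampled parents of that sex, which
carries a truncated-normal prior (mean/SD from census arithmetic). The
likelihood of a (dam, sire) pair at a locus sums over the offspring's true
genotype: Mendelian transmission from the candidates' true genotypes
(integrated over their own genotyping error, given their observed genotypes)
times the observation density of the offspring's observed genotype; unsampled
parents transmit population-frequency alleles. Loci multiply; missing loci
contribute a constant factor and carry no information.

Inference integrates the per-offspring pair indicator analytically (pairs are
conditionally independent given the unsampled counts), leaving a 2-D
Metropolis random walk on the unsampled dam/sire counts; parent marginals are
Rao-Blackwellised over the count draws. On instances small enough to
enumerate, this agrees with exact enumeration by construction up to
Monte-Carlo error in the counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demography import UNSAMPLED, unsampled_parent_prior
from .markers import (
    ErrorModel,
    MarkerPanel,
    build_synthetic_panel,
    genotype_pairs,
    mendelian_offspring_codes,
    observation_matrix,
    observe_codes,
    simulate_founder_codes,
    transmission_matrix,
)

__all__ = [
    "CandidateSet",
    "UnsampledPrior",
    "ChainSettings",
    "AssignmentPosterior",
    "AssignmentMetrics",
    "pair_likelihood",
    "mismatch_prefilter",
    "mismatch_counts",
    "likelihood_tensor",
    "enumerate_posterior",
    "mcmc_assign",
    "threshold_assign",
    "score_against_truth",
    "marker_number_experiment",
    "mismatch_tolerance_for",
    "DEFAULT_LOCI_GRID",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_LOCI_GRID = (5, 10, 14, 20, 28, 50)
DEFAULT_THRESHOLDS = (0.2, 0.4, 0.6, 0.8, 0.95)


@dataclass(frozen=True)
class CandidateSet:
    """Candidate analysed parents for one offspring (same cohort pair)."""

    offspring_id: str
    candidate_dams: tuple
    candidate_sires: tuple


@dataclass(frozen=True)
class UnsampledPrior:
    """Truncated-normal prior (counts) on unsampled dams and sires."""

    dam_mean: float
    dam_sd: float
    sire_mean: float
    sire_sd: float

    def __post_init__(self) -> None:
        if min(self.dam_mean, self.dam_sd, self.sire_mean, self.sire_sd) <= 0:
            raise ValueError("prior means and SDs must be > 0")


@dataclass(frozen=True)
class ChainSettings:
    """MCMC chain control; defaults follow the simulation protocol
    (13,000 iterations, 3,000 burn-in, thinning 10; random-walk scaling
    constants 0.5 / 0.1 for the unsampled dam / sire counts)."""

    iterations: int = 13_000
    burnin: int = 3_000
    thin: int = 10
    scale_dam: float = 0.5
    scale_sire: float = 0.1

    def __post_init__(self) -> None:
        if self.iterations <= self.burnin or self.burnin < 0 or self.thin < 1:
            raise ValueError("invalid chain settings")


@dataclass
class AssignmentPosterior:
    """Per-offspring posterior mass over candidates + UNSAMPLED, by parent sex."""

    offspring_ids: list
    dam_ids: list
    sire_ids: list
    dam_marginals: np.ndarray  # (n_off, n_dams + 1); last column = UNSAMPLED
    sire_marginals: np.ndarray
    count_draws: np.ndarray = None  # (n_draws, 2): unsampled dams, sires
    acceptance: dict = field(default_factory=dict)

    def _as_dict(self, marg, ids, off_id):
        i = self.offspring_ids.index(off_id)
        out = dict(zip(ids, marg[i, :-1]))
        out[UNSAMPLED] = marg[i, -1]
        return out

    def dam_posterior(self, off_id) -> dict:
        return self._as_dict(self.dam_marginals, self.dam_ids, off_id)

    def sire_posterior(self, off_id) -> dict:
        return self._as_dict(self.sire_marginals, self.sire_ids, off_id)


@dataclass
class AssignmentMetrics:
    true_assignment_pct: float
    false_assignment_pct: float
    n_assignable: int
    n_emitted: int
    n_correct: int


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------


def _pair_index_grid(n_alleles: int) -> np.ndarray:
    """Map (a, b) allele codes -> unordered genotype index."""
    gidx = np.empty((n_alleles, n_alleles), dtype=np.int64)
    for g, (a, b) in enumerate(genotype_pairs(n_alleles)):
        gidx[a, b] = gidx[b, a] = g
    return gidx


def _parent_transmission(obs_codes_j: np.ndarray, freqs: np.ndarray,
                         O: np.ndarray, T: np.ndarray, gidx: np.ndarray,
                         hwe: np.ndarray) -> np.ndarray:
    """Per-candidate allele transmission probabilities at one locus.

    Integrates each candidate's true genotype over its error-aware posterior
    given the observed genotype (HWE prior); a missing call falls back to the
    population frequencies.
    """
    n = obs_codes_j.shape[0]
    t = np.tile(freqs, (n, 1))
    scored = obs_codes_j[:, 0] >= 0
    if scored.any():
        g_obs = gidx[obs_codes_j[scored, 0], obs_codes_j[scored, 1]]
        post = hwe[None, :] * O[:, g_obs].T  # (n_scored, G)
        post /= post.sum(axis=1, keepdims=True)
        t[scored] = post @ T
    return t


def mismatch_counts(off_codes: np.ndarray, cand_codes: np.ndarray) -> np.ndarray:
    """Number of loci at which offspring and candidate share no allele.

    Opposing homozygotes and allele-disjoint heterozygotes both count; a
    missing call on either side never counts. Shapes (n_o, L, 2) and
    (n_c, L, 2) -> (n_o, n_c).
    """
    o = off_codes[:, None, :, :]  # (n_o, 1, L, 2)
    c = cand_codes[None, :, :, :]  # (1, n_c, L, 2)
    share = (
        (o[..., 0:1] == c) | (o[..., 1:2] == c)
    ).any(axis=-1)
    scored = (off_codes[:, None, :, 0] >= 0) & (cand_codes[None, :, :, 0] >= 0)
    return np.sum(scored & ~share, axis=-1)


def mismatch_prefilter(obs_offspring: np.ndarray, candidate: np.ndarray,
                       tolerance: int) -> bool:
    """Keep (True) or drop (False) one candidate for one offspring."""
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    n = mismatch_counts(obs_offspring[None], candidate[None])[0, 0]
    return bool(n <= tolerance)


def mismatch_tolerance_for(n_loci: int) -> int:
    """Pre-filter tolerance: two mismatching loci, three at 50+ loci."""
    return 3 if n_loci >= 50 else 2


def likelihood_tensor(off_codes: np.ndarray, dam_codes: np.ndarray,
                      sire_codes: np.ndarray, panel: MarkerPanel,
                      freqs_list, error: ErrorModel,
                      tolerance: int = None) -> np.ndarray:
    """Pair likelihoods L[o, d, s] over (dams + UNSAMPLED) x (sires + UNSAMPLED).

    Entries are normalised per offspring (constant factors drop out of every
    posterior). The last dam/sire index is the unsampled category (one
    hypothetical HWE parent). ``freqs_list`` gives the allele frequencies per
    locus used for transmission from unsampled parents and for candidate
    genotype integration (in practice: empirical frequencies of the pooled
    analysed cohorts). ``tolerance`` applies the Mendelian mismatch
    pre-filter; None disables it.
    """
    n_o, L, _ = off_codes.shape
    n_d = dam_codes.shape[0]
    n_s = sire_codes.shape[0]
    err = ErrorModel(e1=error.e1, e2=error.e2, missing_rate=0.0)
    out = np.ones((n_o, n_d + 1, n_s + 1))
    for j, locus in enumerate(panel.loci):
        K = locus.n_alleles
        freqs = np.asarray(freqs_list[j], dtype=float)
        O = observation_matrix(K, err)[:, :-1]  # (G, G)
        T = transmission_matrix(K)
        gidx = _pair_index_grid(K)
        pairs = genotype_pairs(K)
        hwe = freqs[pairs[:, 0]] * freqs[pairs[:, 1]]
        hwe[pairs[:, 0] != pairs[:, 1]] *= 2.0
        t_d = np.vstack([
            _parent_transmission(dam_codes[:, j, :], freqs, O, T, gidx, hwe),
            freqs[None, :],
        ])
        t_s = np.vstack([
            _parent_transmission(sire_codes[:, j, :], freqs, O, T, gidx, hwe),
            freqs[None, :],
        ])
        scored = off_codes[:, j, 0] >= 0
        if not scored.any():
            continue
        g_off = gidx[off_codes[scored, j, 0], off_codes[scored, j, 1]]
        w = O[:, g_off]  # (G, n_scored): P(obs | true)
        # W[o, a, b] = P(obs_o | true=(a,b)) as a K x K symmetric array
        W = np.zeros((int(scored.sum()), K, K))
        W[:, pairs[:, 0], pairs[:, 1]] = w.T
        W[:, pairs[:, 1], pairs[:, 0]] = w.T
        # L_j[o, d, s] = t_d[d] . W_o . t_s[s]
        A = np.einsum("oab,da->odb", W, t_d, optimize=True)
        Lj = np.einsum("odb,sb->ods", A, t_s, optimize=True)
        sub = out[scored]
        sub *= Lj
        norm = sub.max(axis=(1, 2), keepdims=True)
        norm[norm == 0] = 1.0
        out[scored] = sub / norm
    if tolerance is not None:
        mm_d = mismatch_counts(off_codes, dam_codes) > tolerance  # (n_o, n_d)
        mm_s = mismatch_counts(off_codes, sire_codes) > tolerance
        out[:, :n_d, :] *= ~mm_d[:, :, None]
        out[:, :, :n_s] *= ~mm_s[:, None, :]
    return out


def pair_likelihood(obs_offspring: dict, obs_dam: dict, obs_sire: dict,
                    panel: MarkerPanel, error: ErrorModel) -> float:
    """Likelihood of one (dam, sire) hypothesis for one offspring.

    Genotypes are dicts locus_id -> allele-label pair or None (missing);
    a None parent dict means 'unsampled' (population-frequency alleles).
    The value is conditional on the missingness pattern: missing offspring
    loci contribute a factor of 1.
    """
    err = ErrorModel(e1=error.e1, e2=error.e2, missing_rate=0.0)
    total = 1.0
    for locus in panel.loci:
        obs_o = (obs_offspring or {}).get(locus.locus_id)
        if obs_o is None:
            continue
        K = locus.n_alleles
        label_idx = {a: i for i, a in enumerate(locus.allele_ids)}
        O = observation_matrix(K, err)[:, :-1]
        T = transmission_matrix(K)
        gidx = _pair_index_grid(K)
        pairs = genotype_pairs(K)
        hwe = locus.freqs[pairs[:, 0]] * locus.freqs[pairs[:, 1]]
        hwe[pairs[:, 0] != pairs[:, 1]] *= 2.0

        def trans(obs_parent):
            g = (obs_parent or {}).get(locus.locus_id) if obs_parent is not None else None
            if obs_parent is None or g is None:
                return locus.freqs
            a, b = sorted(label_idx[x] for x in g)
            post = hwe * O[:, gidx[a, b]]
            post = post / post.sum()
            return post @ T

        t_d, t_s = trans(obs_dam), trans(obs_sire)
        a, b = sorted(label_idx[x] for x in obs_o)
        w = O[:, gidx[a, b]]
        W = np.zeros((K, K))
        W[pairs[:, 0], pairs[:, 1]] = w
        W[pairs[:, 1], pairs[:, 0]] = w
        total *= float(t_d @ W @ t_s)
    return total


# ---------------------------------------------------------------------------
# posterior computation
# ---------------------------------------------------------------------------


def _marginals_from_weights(L: np.ndarray, w_dam_u: float, w_sire_u: float):
    """Exact marginals for fixed unsampled-category weights."""
    n_d = L.shape[1] - 1
    n_s = L.shape[2] - 1
    w_d = np.ones(n_d + 1)
    w_d[-1] = w_dam_u
    w_s = np.ones(n_s + 1)
    w_s[-1] = w_sire_u
    joint = L * w_d[None, :, None] * w_s[None, None, :]
    Z = joint.sum(axis=(1, 2), keepdims=True)
    Z[Z == 0] = 1.0
    joint /= Z
    return joint.sum(axis=2), joint.sum(axis=1)


def enumerate_posterior(offspring_ids, dam_ids, sire_ids, L: np.ndarray,
                        n_unsampled_dams: float, n_unsampled_sires: float) -> AssignmentPosterior:
    """Exact posterior over (dam, sire) pairs for point unsampled counts.

    Serves as the small-instance oracle for the MCMC: the unsampled category
    gets prior weight equal to the count, each sampled candidate weight 1.
    """
    dam_m, sire_m = _marginals_from_weights(L, n_unsampled_dams, n_unsampled_sires)
    return AssignmentPosterior(
        offspring_ids=list(offspring_ids), dam_ids=list(dam_ids),
        sire_ids=list(sire_ids), dam_marginals=dam_m, sire_marginals=sire_m,
    )


def mcmc_assign(offspring_ids, dam_ids, sire_ids, L: np.ndarray,
                prior: UnsampledPrior, chain: ChainSettings, rng) -> AssignmentPosterior:
    """Posterior parent marginals + draws of the unsampled dam/sire counts.

    Collapsed Metropolis-within-Gibbs: the per-offspring pair indicator is
    summed out analytically, and a component-wise Gaussian random walk
    (proposal SD = scaling constant x prior SD, reflected at zero) samples
    the two count parameters. Marginals are averaged over the thinned,
    post-burn-in count draws (Rao-Blackwellised).
    """
    n_o, n_d1, n_s1 = L.shape
    n_d, n_s = n_d1 - 1, n_s1 - 1
    # sufficient reductions: Z_o(Ud, Us) = a + Ud*b + Us*c + Ud*Us*d
    a = L[:, :n_d, :n_s].sum(axis=(1, 2))
    b = L[:, n_d, :n_s].sum(axis=1)
    c = L[:, :n_d, n_s].sum(axis=1)
    d = L[:, n_d, n_s]

    def logpost(Ud, Us):
        Z = a + Ud * b + Us * c + Ud * Us * d
        if np.any(Z <= 0):
            return -np.inf
        # categorical prior over parents is normalised: each offspring's
        # pair weight carries 1/((n_d + Ud)(n_s + Us))
        lp = np.log(Z).sum() - n_o * (np.log(n_d + Ud) + np.log(n_s + Us))
        lp -= 0.5 * ((Ud - prior.dam_mean) / prior.dam_sd) ** 2
        lp -= 0.5 * ((Us - prior.sire_mean) / prior.sire_sd) ** 2
        return lp

    Ud, Us = prior.dam_mean, prior.sire_mean
    lp = logpost(Ud, Us)
    sd_d = chain.scale_dam * prior.dam_sd
    sd_s = chain.scale_sire * prior.sire_sd
    draws = []
    acc = np.zeros(2)
    steps = rng.normal(size=(chain.iterations, 2)) * np.array([sd_d, sd_s])
    unif = np.log(rng.random((chain.iterations, 2)))
    for it in range(chain.iterations):
        prop = abs(Ud + steps[it, 0])  # reflect at zero
        lp_new = logpost(prop, Us)
        if lp_new - lp > unif[it, 0]:
            Ud, lp = prop, lp_new
            acc[0] += 1
        prop = abs(Us + steps[it, 1])
        lp_new = logpost(Ud, prop)
        if lp_new - lp > unif[it, 1]:
            Us, lp = prop, lp_new
            acc[1] += 1
        if it >= chain.burnin and (it - chain.burnin) % chain.thin == 0:
            draws.append((Ud, Us))
    draws = np.asarray(draws)
    acc /= chain.iterations

    # Rao-Blackwellised marginals: numerators are linear in the opposite
    # count, so averaging 1/Z-weighted moments over draws is exact.
    Zmat = (a[None, :] + draws[:, 0:1] * b[None, :] + draws[:, 1:2] * c[None, :]
            + (draws[:, 0] * draws[:, 1])[:, None] * d[None, :])
    Zmat[Zmat <= 0] = np.inf
    inv = 1.0 / Zmat  # (n_draws, n_o)
    c0 = inv.mean(axis=0)
    c_us = (inv * draws[:, 1:2]).mean(axis=0)
    c_ud = (inv * draws[:, 0:1]).mean(axis=0)
    c_uds = (inv * (draws[:, 0] * draws[:, 1])[:, None]).mean(axis=0)

    S_ds = L[:, :n_d, :n_s].sum(axis=2)  # (n_o, n_d)
    S_du = L[:, :n_d, n_s]
    dam_m = np.empty((n_o, n_d + 1))
    dam_m[:, :n_d] = S_ds * c0[:, None] + S_du * c_us[:, None]
    dam_m[:, n_d] = b * c_ud + d * c_uds

    S_sd = L[:, :n_d, :n_s].sum(axis=1)  # (n_o, n_s)
    S_su = L[:, n_d, :n_s]
    sire_m = np.empty((n_o, n_s + 1))
    sire_m[:, :n_s] = S_sd * c0[:, None] + S_su * c_ud[:, None]
    sire_m[:, n_s] = c * c_us + d * c_uds

    # guard against all-zero rows (no information at all)
    for m in (dam_m, sire_m):
        rows = m.sum(axis=1)
        bad = rows <= 0
        m[bad] = 1.0 / m.shape[1]
        m[~bad] /= rows[~bad, None]

    accept = {"dam_counts": float(acc[0]), "sire_counts": float(acc[1])}
    if not (0.05 <= min(acc) and max(acc) <= 0.9):
        import warnings

        warnings.warn(
            f"MCMC acceptance rates outside [0.05, 0.9]: {accept}; "
            "consider retuning the scaling constants",
            stacklevel=2,
        )
    return AssignmentPosterior(
        offspring_ids=list(offspring_ids), dam_ids=list(dam_ids),
        sire_ids=list(sire_ids), dam_marginals=dam_m, sire_marginals=sire_m,
        count_draws=draws, acceptance=accept,
    )


# ---------------------------------------------------------------------------
# assignment and scoring
# ---------------------------------------------------------------------------


def threshold_assign(posterior: AssignmentPosterior, p_threshold: float) -> dict:
    """Emit offspring -> (dam, sire) links at a posterior threshold.

    A specific sampled candidate is linked iff its marginal posterior is
    >= the threshold (ties accept); the UNSAMPLED category is never emitted.
    """
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must lie in (0, 1)")
    out = {}
    dam_ids = np.asarray(posterior.dam_ids, dtype=object)
    sire_ids = np.asarray(posterior.sire_ids, dtype=object)
    for i, off in enumerate(posterior.offspring_ids):
        dam = UNSAMPLED
        if dam_ids.size:
            j = int(np.argmax(posterior.dam_marginals[i, :-1]))
            if posterior.dam_marginals[i, j] >= p_threshold:
                dam = dam_ids[j]
        sire = UNSAMPLED
        if sire_ids.size:
            j = int(np.argmax(posterior.sire_marginals[i, :-1]))
            if posterior.sire_marginals[i, j] >= p_threshold:
                sire = sire_ids[j]
        out[off] = (dam, sire)
    return out


def score_against_truth(inferred: dict, truth: dict,
                        assignable_parents=None) -> AssignmentMetrics:
    """True/false assignment percentages against a known pedigree.

    True % = correctly recovered links / links in the truth whose parent is
    assignable (was analysed); false % = wrong links / emitted links (0 by
    convention when nothing is emitted).
    """
    if not truth:
        raise ValueError("empty truth pedigree")
    n_assignable = n_correct = n_emitted = n_wrong = 0
    for off, (t_dam, t_sire) in truth.items():
        i_dam, i_sire = inferred.get(off, (UNSAMPLED, UNSAMPLED))
        for t_p, i_p in ((t_dam, i_dam), (t_sire, i_sire)):
            assignable = (t_p != UNSAMPLED and
                          (assignable_parents is None or t_p in assignable_parents))
            if assignable:
                n_assignable += 1
            if i_p != UNSAMPLED:
                n_emitted += 1
                if i_p == t_p:
                    n_correct += 1
                else:
                    n_wrong += 1
    if n_assignable == 0:
        raise ValueError("no assignable links in truth")
    return AssignmentMetrics(
        true_assignment_pct=100.0 * n_correct / n_assignable,
        false_assignment_pct=(100.0 * n_wrong / n_emitted) if n_emitted else 0.0,
        n_assignable=n_assignable,
        n_emitted=n_emitted,
        n_correct=n_correct,
    )


# ---------------------------------------------------------------------------
# full marker-number pipeline
# ---------------------------------------------------------------------------


def _empirical_freqs(codes: np.ndarray, panel: MarkerPanel):
    """Per-locus allele frequencies of the pooled analysed sample, with a
    small positive floor so no declared allele has zero mass."""
    out = []
    for j, locus in enumerate(panel.loci):
        col = codes[:, j, :].ravel()
        col = col[col >= 0]
        counts = np.bincount(col, minlength=locus.n_alleles).astype(float)
        counts += 0.5
        out.append(counts / counts.sum())
    return out


def assign_cohort_pair(pop, panel: MarkerPanel, sim_error: ErrorModel,
                       inference_error: ErrorModel, prior: UnsampledPrior,
                       chain: ChainSettings, tolerance: int, rng):
    """Simulate genotypes for one simulated cohort pair and run assignment.

    Returns (posterior, truth-restricted-to-analysed-offspring, analysed
    parent id set).
    """
    df = pop.individuals
    parent_mask = ~df["id"].isin(pop.pedigree.keys())
    parent_ids = df.loc[parent_mask, "id"].tolist()
    true_parent = dict(zip(parent_ids, range(len(parent_ids))))
    parent_codes = simulate_founder_codes(panel, len(parent_ids), rng)
    off_ids = list(pop.pedigree.keys())
    dam_rows = np.array([true_parent[pop.pedigree[o][0]] for o in off_ids])
    sire_rows = np.array([true_parent[pop.pedigree[o][1]] for o in off_ids])
    off_codes_true = mendelian_offspring_codes(
        parent_codes[dam_rows], parent_codes[sire_rows], rng
    )

    analysed = set(df.loc[df["analysed"], "id"])
    dam_ids = df.loc[parent_mask & df["analysed"] & (df["sex"] == "F"), "id"].tolist()
    sire_ids = df.loc[parent_mask & df["analysed"] & (df["sex"] == "M"), "id"].tolist()
    off_an = [o for o in off_ids if o in analysed]

    def observed(ids, codes_lookup):
        rows = np.array([codes_lookup[i] for i in ids], dtype=int)
        return rows

    def observe_analysed(true_codes):
        """Observation with per-specimen DNA quality; individuals scoring
        fewer than half the loci are replaced by a fresh passing draw, since
        the analysed counts already exclude such genotyping failures."""
        from .markers import MISSING_CONCENTRATION

        obs = observe_codes(true_codes, panel, sim_error, rng,
                            missing_concentration=MISSING_CONCENTRATION)
        min_scored = (panel.n_loci + 1) // 2
        for _ in range(100):
            bad = (obs[:, :, 0] >= 0).sum(axis=1) < min_scored
            if not bad.any():
                break
            obs[bad] = observe_codes(true_codes[bad], panel, sim_error, rng,
                                     missing_concentration=MISSING_CONCENTRATION)
        return obs

    dam_obs = observe_analysed(parent_codes[observed(dam_ids, true_parent)])
    sire_obs = observe_analysed(parent_codes[observed(sire_ids, true_parent)])
    off_index = {o: i for i, o in enumerate(off_ids)}
    off_obs = observe_analysed(off_codes_true[[off_index[o] for o in off_an]])

    pooled = np.concatenate([dam_obs, sire_obs, off_obs], axis=0)
    freqs = _empirical_freqs(pooled, panel)
    L = likelihood_tensor(off_obs, dam_obs, sire_obs, panel, freqs,
                          inference_error, tolerance=tolerance)
    post = mcmc_assign(off_an, dam_ids, sire_ids, L, prior, chain, rng)
    truth = {o: pop.pedigree[o] for o in off_an}
    return post, truth, analysed


def marker_number_experiment(
    loci_grid=DEFAULT_LOCI_GRID,
    thresholds=DEFAULT_THRESHOLDS,
    replicates: int = 100,
    cohort_pairs=None,
    seed: int = 0,
    error: ErrorModel = ErrorModel(e1=0.02, e2=0.004, missing_rate=0.11),
    include_error: bool = True,
    include_missing: bool = True,
    chain: ChainSettings = ChainSettings(),
    target_mean_alleles: float = 12.0,
    target_mean_ho: float = 0.725,
) -> pd.DataFrame:
    """Full pipeline power experiment over marker numbers and thresholds.

    For each cohort pair and replicate: simulate the demography once (shared
    across marker numbers, so marker-count contrasts are paired), then per
    marker number synthesize a fresh panel, simulate genotypes under the
    error model (optionally with error and/or missingness disabled in the
    *simulated data only* -- inference always assumes the stated error
    model), assign parentage, and score each posterior threshold against the
    truth. Returns a tidy DataFrame with one row per
    (cohort_pair, replicate, n_loci, threshold).
    """
    from .demography import make_burrishoole_configs, simulate_cohort_pair

    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    configs, pairs = make_burrishoole_configs()
    cfg_by_year = {c.cohort_year: c for c in configs}
    if cohort_pairs is None:
        cohort_pairs = pairs
    sim_base = ErrorModel(
        e1=error.e1 if include_error else 0.0,
        e2=error.e2 if include_error else 0.0,
        missing_rate=error.missing_rate if include_missing else 0.0,
    )
    inference_error = ErrorModel(e1=error.e1, e2=error.e2, missing_rate=0.0)
    root = np.random.SeedSequence(seed)
    rows = []
    for (py, oy) in cohort_pairs:
        p_cfg, o_cfg = cfg_by_year[py], cfg_by_year[oy]
        for rep in range(replicates):
            ss_dem, ss_gen = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(py, rep)
            ).spawn(2)
            pop = simulate_cohort_pair(p_cfg, o_cfg, np.random.default_rng(ss_dem))
            gen_children = ss_gen.spawn(len(loci_grid))
            df = pop.individuals
            n_dams_an = int(((df["sex"] == "F") & df["analysed"]
                             & ~df["id"].isin(pop.pedigree)).sum())
            n_sires_an = int(((df["sex"] == "M") & df["analysed"]
                              & ~df["id"].isin(pop.pedigree)).sum())
            pr = unsampled_parent_prior(p_cfg, n_dams_an, n_sires_an)
            prior = UnsampledPrior(**pr)
            for gi, n_loci in enumerate(loci_grid):
                rng = np.random.default_rng(gen_children[gi])
                panel = build_synthetic_panel(
                    n_loci, target_mean_alleles, target_mean_ho,
                    seed=int(rng.integers(2**31)),
                )
                post, truth, analysed = assign_cohort_pair(
                    pop, panel, sim_base, inference_error, prior, chain,
                    tolerance=mismatch_tolerance_for(n_loci), rng=rng,
                )
                for thr in thresholds:
                    inferred = threshold_assign(post, thr)
                    m = score_against_truth(inferred, truth, analysed)
                    rows.append(dict(
                        cohort_pair=f"{py}-{oy}", replicate=rep, n_loci=n_loci,
                        threshold=thr, true_pct=m.true_assignment_pct,
                        false_pct=m.false_assignment_pct,
                        n_assignable=m.n_assignable, n_emitted=m.n_emitted,
                    ))
    return pd.DataFrame(rows)


def summarise_marker_experiment(table: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD true and false assignment % per (n_loci, threshold), averaging
    the six cohort-pair means as the study protocol does."""
    per_pair = table.groupby(["n_loci", "threshold", "cohort_pair"])[
        ["true_pct", "false_pct"]
    ].mean()
    g = per_pair.groupby(["n_loci", "threshold"])
    out = g.mean()
    out[["true_sd", "false_sd"]] = g.std()[["true_pct", "false_pct"]]
    return out.reset_index()
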