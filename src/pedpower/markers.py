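"""Microsatellite marker panels, the genotyping-error process, and genotype simulation.

The genotyping model used throughout the package:

* a single-locus genotype is an unordered pair of alleles (A/B == B/A);
* with probability ``missing_rate`` the genotype is unscored;
* otherwise a heterozygote suffers *allelic dropout* with probability ``e1``,
  being reported as either homozygote with probability ``e1/2`` each
  (class-I error; a true homozygote is immune);
* independently, each reported allele is *miscalled* with probability ``e2``,
  being replaced by one of the other alleles of the locus uniformly at random
  (class-II error).

The same observation density parameterises both genotype simulation and the
parentage likelihood, so simulated data and inference share one error model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

MISSING = -1  # sentinel allele code for an unscored single-locus genotype

__all__ = [
    "MISSING",
    "ErrorModel",
    "LocusModel",
    "MarkerPanel",
    "GenotypeTable",
    "build_synthetic_panel",
    "simulate_offspring_genotype",
    "apply_error_and_missingness",
    "diversity_summary",
    "exclusion_probability",
    "combined_exclusion",
    "estimate_error_rates",
    "genotype_pairs",
    "observation_matrix",
    "transmission_matrix",
    "simulate_founder_codes",
    "mendelian_offspring_codes",
    "observe_codes",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ErrorModel:
    """Genotyping error rates: e1 = allelic dropout (per heterozygous
    single-locus genotype), e2 = stochastic miscall (per reported allele),
    missing_rate = probability a single-locus genotype is unscored."""

    e1: float = 0.0
    e2: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("e1", "e2", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} must lie in [0, 1]")


@dataclass(frozen=True)
class LocusModel:
    """One microsatellite locus: ordered allele labels and their frequencies."""

    locus_id: str
    allele_ids: tuple
    freqs: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "allele_ids", tuple(self.allele_ids))
        if len(self.allele_ids) < 2:
            raise ValueError(f"locus {self.locus_id}: need >= 2 alleles")
        if len(self.allele_ids) != freqs.size:
            raise ValueError(f"locus {self.locus_id}: allele/frequency length mismatch")
        if np.any(freqs <= 0):
            raise ValueError(f"locus {self.locus_id}: all frequencies must be > 0")
        if abs(freqs.sum() - 1.0) > 1e-12:
            raise ValueError(f"locus {self.locus_id}: frequencies must sum to 1")

    @property
    def n_alleles(self) -> int:
        return len(self.allele_ids)

    def expected_heterozygosity(self) -> float:
        return 1.0 - float(np.sum(self.freqs**2))

    def pic(self) -> float:
        p = self.freqs
        p2 = p**2
        cross = np.outer(p2, p2)
        off = (cross.sum() - np.sum(p2**2)) / 2.0
        return 1.0 - float(p2.sum()) - 2.0 * float(off)


@dataclass
class MarkerPanel:
    """A set of loci, optionally with locus-specific error models."""

    loci: list
    per_locus_error: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [loc.locus_id for loc in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus_ids in panel")
        if not self.loci:
            raise ValueError("panel must contain at least one locus")

    @property
    def locus_ids(self) -> list:
        return [loc.locus_id for loc in self.loci]

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def error_for(self, locus_id: str, default: ErrorModel) -> ErrorModel:
        return self.per_locus_error.get(locus_id, default)

    def mean_allele_number(self) -> float:
        return float(np.mean([loc.n_alleles for loc in self.loci]))

    def mean_expected_heterozygosity(self) -> float:
        return float(np.mean([loc.expected_heterozygosity() for loc in self.loci]))


class GenotypeTable:
    """Diploid multilocus genotypes for a set of individuals.

    Calls are stored as integer allele codes (indices into ``allele_labels``
    per locus) in an (n_individuals, n_loci, 2) array, sorted within the pair
    so that A/B and B/A are the same record; ``MISSING`` (-1) in both slots
    marks an unscored genotype.
    """

    def __init__(self, individuals, loci, allele_labels, codes):
        self.individuals = list(individuals)
        self.loci = list(loci)
        self.allele_labels = [tuple(a) for a in allele_labels]
        codes = np.asarray(codes, dtype=np.int32)
        if codes.shape != (len(self.individuals), len(self.loci), 2):
            raise ValueError("codes array has wrong shape")
        self.codes = np.sort(codes, axis=2)
        miss = np.any(self.codes < 0, axis=2)
        self.codes[miss] = MISSING
        self._index = {ind: i for i, ind in enumerate(self.individuals)}
        for j, labels in enumerate(self.allele_labels):
            hi = self.codes[:, j, :].max(initial=-1)
            if hi >= len(labels):
                raise ValueError(f"locus {self.loci[j]}: allele code {hi} has no label")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def genotype(self, individual, locus):
        """Return the allele-label pair, or None if missing."""
        i = self._index[individual]
        j = self.loci.index(locus)
        a, b = self.codes[i, j]
        if a == MISSING:
            return None
        labels = self.allele_labels[j]
        return (labels[a], labels[b])

    def missing_mask(self) -> np.ndarray:
        return self.codes[:, :, 0] == MISSING

    def allele_freqs(self, j: int) -> np.ndarray:
        """Observed allele frequencies at locus index j (non-missing calls)."""
        col = self.codes[:, j, :].ravel()
        col = col[col >= 0]
        if col.size == 0:
            raise ValueError(f"locus {self.loci[j]}: no scored genotypes")
        counts = np.bincount(col, minlength=len(self.allele_labels[j]))
        return counts / counts.sum()

    def subset(self, individuals) -> "GenotypeTable":
        idx = [self._index[i] for i in individuals]
        return GenotypeTable(individuals, self.loci, self.allele_labels, self.codes[idx])

    def to_dataframe(self) -> pd.DataFrame:
        data = {"id": self.individuals}
        for j, locus in enumerate(self.loci):
            labels = self.allele_labels[j]
            for k in (0, 1):
                col = [
                    labels[c] if c >= 0 else "0"
                    for c in self.codes[:, j, k]
                ]
                data[f"{locus}.{k + 1}"] = col
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# genotype-space helpers (shared with the parentage likelihood)
# ---------------------------------------------------------------------------


def genotype_pairs(n_alleles: int) -> np.ndarray:
    """All unordered diploid genotypes (a <= b) of a K-allele locus, shape (G, 2)."""
    a, b = np.triu_indices(n_alleles)
    return np.column_stack([a, b])


def hwe_probs(freqs: np.ndarray) -> np.ndarray:
    """HWE probability of each unordered genotype, aligned with genotype_pairs."""
    pairs = genotype_pairs(freqs.size)
    p = freqs[pairs[:, 0]] * freqs[pairs[:, 1]]
    p[pairs[:, 0] != pairs[:, 1]] *= 2.0
    return p


def _miscall_matrix(n_alleles: int, e2: float) -> np.ndarray:
    if n_alleles == 1:
        return np.ones((1, 1))
    M = np.full((n_alleles, n_alleles), e2 / (n_alleles - 1))
    np.fill_diagonal(M, 1.0 - e2)
    return M


def observation_matrix(n_alleles: int, error: ErrorModel) -> np.ndarray:
    """Observation density O[true_g, obs_g] over unordered genotypes.

    Columns 0..G-1 are observable genotypes, column G is missing; each row
    sums to 1. This is the exact density of the dropout+miscall+missingness
    process and is reused by the parentage likelihood.
    """
    pairs = genotype_pairs(n_alleles)
    G = pairs.shape[0]
    # dropout stage: distribution over intermediate genotypes
    gidx = -np.ones((n_alleles, n_alleles), dtype=int)
    for g, (a, b) in enumerate(pairs):
        gidx[a, b] = gidx[b, a] = g
    D = np.zeros((G, G))
    for g, (a, b) in enumerate(pairs):
        if a == b:
            D[g, g] = 1.0
        else:
            D[g, g] = 1.0 - error.e1
            D[g, gidx[a, a]] += error.e1 / 2.0
            D[g, gidx[b, b]] += error.e1 / 2.0
    # miscall stage on unordered pairs
    M = _miscall_matrix(n_alleles, error.e2)
    x, y = pairs[:, 0], pairs[:, 1]
    u, v = pairs[:, 0], pairs[:, 1]
    C = M[np.ix_(x, u)] * M[np.ix_(y, v)] + M[np.ix_(x, v)] * M[np.ix_(y, u)]
    same_obs = u == v
    C[:, same_obs] = M[np.ix_(x, u[same_obs])] * M[np.ix_(y, u[same_obs])]
    O = (1.0 - error.missing_rate) * (D @ C)
    out = np.zeros((G, G + 1))
    out[:, :G] = O
    out[:, G] = error.missing_rate
    return out


def transmission_matrix(n_alleles: int) -> np.ndarray:
    """T[true_g, allele] = probability a parent with true genotype g transmits allele."""
    pairs = genotype_pairs(n_alleles)
    T = np.zeros((pairs.shape[0], n_alleles))
    rows = np.arange(pairs.shape[0])
    np.add.at(T, (rows, pairs[:, 0]), 0.5)
    np.add.at(T, (rows, pairs[:, 1]), 0.5)
    return T


# ---------------------------------------------------------------------------
# panel synthesis
# ---------------------------------------------------------------------------


def _he_of_power(base: np.ndarray, lam: float) -> float:
    q = base**lam
    q /= q.sum()
    return 1.0 - float(np.sum(q**2))


def _freqs_for_he(base: np.ndarray, target_he: float) -> np.ndarray:
    """Power-interpolate a base frequency vector to hit a target He exactly.

    q(lam) ~ base**lam runs from uniform (lam=0, maximal He) towards a
    degenerate vector (He -> 0) as lam grows; He is monotone, so bisect.
    """
    lo, hi = 0.0, 1.0
    while _he_of_power(base, hi) > target_he and hi < 512:
        hi *= 2.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _he_of_power(base, mid) > target_he:
            lo = mid
        else:
            hi = mid
    q = base ** (0.5 * (lo + hi))
    q = np.clip(q / q.sum(), 1e-6, None)  # keep every allele representable
    return q / q.sum()


def build_synthetic_panel(
    n_loci: int,
    target_mean_alleles: float,
    target_mean_ho: float,
    seed: int,
    allele_count_dispersion: float = 0.7,
    dirichlet_alpha: float = 0.8,
) -> MarkerPanel:
    """Synthesize a microsatellite panel with given mean allele count and mean He.

    Emulates an empirical archival-scale microsatellite panel: allele counts
    per locus are broadly dispersed (shifted negative binomial around the
    target mean, giving a realistic span from near-biallelic loci to
    hypervariable ones with ~30 alleles), frequencies are Dirichlet draws so
    that allele-rich loci are naturally the high-heterozygosity, most
    informative ones, and a single panel-wide concentration parameter is
    calibrated so the realised mean expected heterozygosity hits the target.
    Per-locus diversity therefore varies widely around the panel mean, as in
    real panels. Deterministic given ``seed``.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if not 0.0 < target_mean_ho < 1.0:
        raise ValueError(f"target_mean_ho={target_mean_ho} must lie in (0, 1)")
    if target_mean_alleles < 2:
        raise ValueError("target_mean_alleles must be >= 2")
    if target_mean_ho >= 1.0 - 1.0 / target_mean_alleles:
        warnings.warn(
            "target He is infeasible at the target allele count for some loci; "
            "realised mean He will fall short",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    extra = target_mean_alleles - 2.0
    counts = np.full(n_loci, int(round(target_mean_alleles)))
    if extra > 0:
        k = allele_count_dispersion
        for _ in range(500):
            counts = 2 + rng.negative_binomial(k, k / (k + extra), size=n_loci)
            counts = np.minimum(counts, 45)
            if abs(counts.mean() - target_mean_alleles) <= 0.05 * target_mean_alleles:
                break
    bases = [rng.dirichlet(np.full(int(K), dirichlet_alpha)) for K in counts]
    bases = [np.clip(b, 1e-7, None) / np.clip(b, 1e-7, None).sum() for b in bases]

    def mean_he(lam: float) -> float:
        return float(np.mean([_he_of_power(b, lam) for b in bases]))

    # panel-wide concentration: lam=0 gives uniform loci (max He), larger lam
    # concentrates every locus; mean He is monotone decreasing, so bisect
    lo, hi = 0.0, 1.0
    while mean_he(hi) > target_mean_ho and hi < 256:
        hi *= 2.0
    if mean_he(0.0) < target_mean_ho:
        lam = 0.0
    else:
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if mean_he(mid) > target_mean_ho:
                lo = mid
            else:
                hi = mid
        lam = 0.5 * (lo + hi)
    loci = []
    for j, base in enumerate(bases):
        q = base**lam if lam > 0 else np.ones_like(base)
        q /= q.sum()
        q = np.clip(q, 1e-6, None)
        q /= q.sum()
        labels = tuple(f"{a + 1:03d}" for a in range(base.size))
        loci.append(LocusModel(locus_id=f"L{j + 1:02d}", allele_ids=labels, freqs=q))
    return MarkerPanel(loci=loci)


# ---------------------------------------------------------------------------
# single-genotype simulation primitives
# ---------------------------------------------------------------------------


def _label_to_code(locus: LocusModel, genotype) -> tuple:
    idx = {a: i for i, a in enumerate(locus.allele_ids)}
    try:
        return tuple(sorted(idx[a] for a in genotype))
    except KeyError as exc:
        raise ValueError(
            f"allele {exc.args[0]!r} not present in locus {locus.locus_id}"
        ) from None


def simulate_offspring_genotype(dam_true, sire_true, locus: LocusModel, rng) -> tuple:
    """Mendelian transmission at one locus; a null parent is an HWE draw.

    ``dam_true``/``sire_true`` are allele-label pairs or None; returns a sorted
    allele-label pair.
    """
    alleles = []
    for parent in (dam_true, sire_true):
        if parent is None:
            alleles.append(int(rng.choice(locus.n_alleles, p=locus.freqs)))
        else:
            code = _label_to_code(locus, parent)
            alleles.append(code[int(rng.integers(2))])
    a, b = sorted(alleles)
    return (locus.allele_ids[a], locus.allele_ids[b])


def apply_error_and_missingness(true_genotype, locus: LocusModel, error: ErrorModel, rng):
    """Push one true genotype through missingness, dropout and miscall.

    Returns a sorted allele-label pair, or None for a missing call.
    """
    if rng.random() < error.missing_rate:
        return None
    a, b = _label_to_code(locus, true_genotype)
    if a != b and rng.random() < error.e1:
        a = b = a if rng.random() < 0.5 else b
    K = locus.n_alleles
    out = []
    for x in (a, b):
        if K > 1 and rng.random() < error.e2:
            x = int(rng.choice([k for k in range(K) if k != x]))
        out.append(x)
    a, b = sorted(out)
    return (locus.allele_ids[a], locus.allele_ids[b])


# ---------------------------------------------------------------------------
# vectorised population-scale simulation (used by the pipeline)
# ---------------------------------------------------------------------------


def simulate_founder_codes(panel: MarkerPanel, n: int, rng) -> np.ndarray:
    """HWE genotypes for n founders over the panel, as a code array (n, L, 2)."""
    codes = np.empty((n, panel.n_loci, 2), dtype=np.int32)
    for j, locus in enumerate(panel.loci):
        codes[:, j, :] = rng.choice(locus.n_alleles, size=(n, 2), p=locus.freqs)
    return np.sort(codes, axis=2)


def mendelian_offspring_codes(dam_codes: np.ndarray, sire_codes: np.ndarray, rng) -> np.ndarray:
    """Independent assortment: each parent transmits one allele per locus."""
    n, L, _ = dam_codes.shape
    pick_d = rng.integers(2, size=(n, L))
    pick_s = rng.integers(2, size=(n, L))
    out = np.stack(
        [
            np.take_along_axis(dam_codes, pick_d[:, :, None], axis=2)[:, :, 0],
            np.take_along_axis(sire_codes, pick_s[:, :, None], axis=2)[:, :, 0],
        ],
        axis=2,
    ).astype(np.int32)
    return np.sort(out, axis=2)


# Beta concentration of per-individual missingness in the pipeline default:
# calibrated so that, at the study's mean missing rate (11%) and a 14-locus
# panel, ~7.6% of individuals fail the >= half-the-loci scoring rule --
# matching the study's excluded-individual fraction. Archival DNA quality
# varies per specimen, so missing calls cluster within individuals.
MISSING_CONCENTRATION = 1.2


def observe_codes(
    true_codes: np.ndarray, panel: MarkerPanel, error: ErrorModel, rng,
    missing_concentration: float = None,
) -> np.ndarray:
    """Apply the observation process to a whole code array at once.

    With ``missing_concentration`` set, each individual gets its own missing
    rate drawn from a Beta with mean ``error.missing_rate`` and the given
    concentration (modelling per-specimen DNA quality); otherwise missingness
    is homogeneous at the mean rate.
    """
    n, L, _ = true_codes.shape
    obs = true_codes.copy()
    # dropout on heterozygotes
    het = obs[:, :, 0] != obs[:, :, 1]
    drop = het & (rng.random((n, L)) < error.e1)
    keep_first = rng.random((n, L)) < 0.5
    a = np.where(keep_first, obs[:, :, 0], obs[:, :, 1])
    obs[drop, 0] = a[drop]
    obs[drop, 1] = a[drop]
    # per-allele miscall (locus-wise loop: allele counts differ)
    for j, locus in enumerate(panel.loci):
        K = locus.n_alleles
        if K < 2 or error.e2 == 0:
            continue
        for k in (0, 1):
            hit = rng.random(n) < error.e2
            if not hit.any():
                continue
            shift = rng.integers(1, K, size=int(hit.sum()))
            obs[hit, j, k] = (obs[hit, j, k] + shift) % K
    # missingness (optionally clustered within individuals)
    if missing_concentration and error.missing_rate > 0:
        a = error.missing_rate * missing_concentration
        b = (1.0 - error.missing_rate) * missing_concentration
        rates = rng.beta(a, b, size=n)[:, None]
    else:
        rates = error.missing_rate
    miss = rng.random((n, L)) < rates
    obs = np.sort(obs, axis=2)
    obs[miss] = MISSING
    return obs


# ---------------------------------------------------------------------------
# diversity and exclusion statistics
# ---------------------------------------------------------------------------


def _pic_from_freqs(p: np.ndarray) -> float:
    p2 = p**2
    cross = np.outer(p2, p2)
    off = (cross.sum() - np.sum(p2**2)) / 2.0
    return 1.0 - float(p2.sum()) - 2.0 * float(off)


def diversity_summary(table: GenotypeTable, panel: MarkerPanel = None) -> pd.DataFrame:
    """Per-locus Ho, He (1 - sum p^2), PIC, observed allele count and missingness.

    All-missing loci are flagged (``all_missing``) and carry NaN statistics;
    callers computing panel means should exclude them.
    """
    rows = []
    for j, locus in enumerate(table.loci):
        calls = table.codes[:, j, :]
        scored = calls[calls[:, 0] >= 0]
        missing_frac = 1.0 - scored.shape[0] / max(table.n_individuals, 1)
        if scored.shape[0] == 0:
            rows.append(
                dict(locus=locus, Ho=np.nan, He=np.nan, PIC=np.nan,
                     n_alleles=0, missing_frac=1.0, all_missing=True)
            )
            continue
        ho = float(np.mean(scored[:, 0] != scored[:, 1]))
        freqs = table.allele_freqs(j)
        nz = freqs[freqs > 0]
        he = 1.0 - float(np.sum(nz**2))
        rows.append(
            dict(locus=locus, Ho=ho, He=he, PIC=_pic_from_freqs(nz),
                 n_alleles=int(nz.size), missing_frac=missing_frac, all_missing=False)
        )
    return pd.DataFrame(rows).set_index("locus")


def exclusion_probability(locus: LocusModel) -> float:
    """Single-parent exclusion probability of one locus.

    Probability that a random unrelated candidate shares no allele with a
    random HWE offspring (no partner genotype known):

        Q = sum_i p_i^2 (1 - p_i)^2  +  sum_{i != j} p_i p_j (1 - p_i - p_j)^2
    """
    p = locus.freqs
    hom = np.sum(p**2 * (1.0 - p) ** 2)
    P = np.add.outer(p, p)
    het = np.outer(p, p) * (1.0 - P) ** 2
    np.fill_diagonal(het, 0.0)
    return float(hom + het.sum())


def combined_exclusion(panel: MarkerPanel) -> float:
    """Panel-wide exclusion probability assuming locus independence."""
    q = np.array([exclusion_probability(loc) for loc in panel.loci])
    return float(1.0 - np.prod(1.0 - q))


# ---------------------------------------------------------------------------
# error-rate estimation from replicate genotyping
# ---------------------------------------------------------------------------


def _replicate_loglik(e1: float, e2: float, panel: MarkerPanel, obs_pairs) -> float:
    """Log-likelihood of replicate pairs under a shared (e1, e2).

    obs_pairs: per locus index j, an (n_j, 2) array of observed genotype
    indices (into genotype_pairs) for the co-scored replicate pairs. The
    latent true genotype is integrated over HWE; missingness cancels out of
    the (e1, e2) likelihood because co-scored calls condition on non-missing.
    """
    err = ErrorModel(e1=e1, e2=e2, missing_rate=0.0)
    total = 0.0
    for j, locus in enumerate(panel.loci):
        pairs_j = obs_pairs.get(j)
        if pairs_j is None or len(pairs_j) == 0:
            continue
        O = observation_matrix(locus.n_alleles, err)[:, :-1]
        prior = hwe_probs(locus.freqs)
        # P(g1, g2) = sum_true prior * O[true, g1] * O[true, g2], evaluated
        # only at the observed genotype pairs (weighted by their counts)
        uniq, counts = np.unique(pairs_j, axis=0, return_counts=True)
        lk = np.einsum("t,tu,tu->u", prior, O[:, uniq[:, 0]], O[:, uniq[:, 1]])
        if np.any(lk <= 0):
            return -np.inf
        total += float(np.sum(counts * np.log(lk)))
    return total


def estimate_error_rates(replicate_pairs, panel: MarkerPanel) -> dict:
    """Maximum-likelihood (e1, e2) from repeat genotyping of the same individuals.

    ``replicate_pairs`` is a list of (genotype_row_a, genotype_row_b) where each
    row is a dict locus_id -> allele-label pair or None. Both replicates of a
    pair are modelled as independent observations of one latent HWE genotype
    under the shared error model. Returns point estimates, a pooled log-likelihood,
    approximate 95% Wald CIs, and the number of co-scored locus pairs.
    """
    locus_index = {loc.locus_id: j for j, loc in enumerate(panel.loci)}
    gidx_cache = {}
    obs_pairs: dict = {}
    n_coscored = 0
    for rec_a, rec_b in replicate_pairs:
        for locus_id, ga in rec_a.items():
            gb = rec_b.get(locus_id)
            if ga is None or gb is None or locus_id not in locus_index:
                continue
            j = locus_index[locus_id]
            locus = panel.loci[j]
            if j not in gidx_cache:
                pairs = genotype_pairs(locus.n_alleles)
                gidx_cache[j] = {
                    (locus.allele_ids[a], locus.allele_ids[b]): g
                    for g, (a, b) in enumerate(pairs)
                }
            key_a = tuple(sorted(ga))
            key_b = tuple(sorted(gb))
            obs_pairs.setdefault(j, []).append((gidx_cache[j][key_a], gidx_cache[j][key_b]))
            n_coscored += 1
    if n_coscored == 0:
        raise ValueError("no co-scored loci among replicate pairs; cannot estimate error rates")
    obs_pairs = {j: np.asarray(v, dtype=int) for j, v in obs_pairs.items()}

    def neg(x):
        # soft box on the logit scale keeps boundary cases (all-identical or
        # single-mismatch data) at finite interior estimates
        pen = float(np.sum(np.clip(np.abs(x) - 7.0, 0.0, None) ** 2)) * 100.0
        e1 = 1.0 / (1.0 + np.exp(-x[0]))
        e2 = 1.0 / (1.0 + np.exp(-x[1]))
        return -_replicate_loglik(e1, e2, panel, obs_pairs) + pen

    res = minimize(neg, x0=np.array([-3.5, -5.0]), method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    e1_hat = float(1.0 / (1.0 + np.exp(-res.x[0])))
    e2_hat = float(1.0 / (1.0 + np.exp(-res.x[1])))

    # Wald CIs on the logit scale from a finite-difference Hessian
    def ci(i):
        h = 1e-4
        x = res.x.copy()
        f0 = neg(x)
        x[i] += h
        fp = neg(x)
        x[i] -= 2 * h
        fm = neg(x)
        curv = (fp - 2 * f0 + fm) / h**2
        if not np.isfinite(curv) or curv <= 0:
            return (0.0, 1.0)
        se = 1.0 / np.sqrt(curv)
        lo, hi = res.x[i] - 1.96 * se, res.x[i] + 1.96 * se
        return (float(1 / (1 + np.exp(-lo))), float(1 / (1 + np.exp(-hi))))

    return {
        "e1": e1_hat,
        "e2": e2_hat,
        "e1_ci": ci(0),
        "e2_ci": ci(1),
        "loglik": -float(res.fun),
        "n_coscored": n_coscored,
    }
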