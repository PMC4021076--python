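"""Cohort demography simulation for a partially sampled wild salmon population.

Emulates the Burrishoole river-system study design: ten annual cohorts of
wild returning adults with known census and sampling counts, a four-year
generation interval linking six parent-offspring cohort pairs, a
female-biased adult sex ratio (55-70% female), an unsampled pool of
precocious mature male parr (mean 17% of breeding males), per-sex
negative-binomial reproductive skew (males more skewed than females), and
kelt sampling that is strongly female-biased (81.2% of samples female).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNSAMPLED = "*"  # sentinel parent id for an unassigned / unsampled parent

# female and male shares of sampled kelts (females dominate because male
# post-spawning mortality is higher)
FEMALE_SAMPLE_SHARE = 0.812
MALE_SAMPLE_SHARE = 0.178

GENERATION_YEARS = 4

__all__ = [
    "UNSAMPLED",
    "CohortConfig",
    "Individual",
    "RSModel",
    "Population",
    "make_burrishoole_configs",
    "BURRISHOOLE_PAIRS",
    "draw_reproductive_success",
    "mate_and_build_pedigree",
    "sample_population",
    "simulate_cohort_pair",
    "unsampled_parent_prior",
]


@dataclass(frozen=True)
class CohortConfig:
    """Census and sampling counts for one cohort of wild returning fish."""

    cohort_year: int
    census: int
    n_sampled: int
    n_analysed: int
    female_fraction_range: tuple = (0.55, 0.70)
    parr_fraction_mean: float = 0.17

    def __post_init__(self) -> None:
        if not self.n_analysed <= self.n_sampled <= self.census:
            raise ValueError(
                f"cohort {self.cohort_year}: need n_analysed <= n_sampled <= census"
            )
        lo, hi = self.female_fraction_range
        if not (0 <= lo <= hi <= 1 and 0 <= self.parr_fraction_mean <= 1):
            raise ValueError("fractions must lie in [0, 1]")


@dataclass
class Individual:
    """One fish. Precocious parr are male, breed in fresh water and are never
    sampled by the trap system; ``analysed`` implies ``sampled``."""

    id: str
    sex: str  # 'F' or 'M'
    origin: str  # 'anadromous' or 'parr'
    cohort_year: int
    group_label: str = "none"  # 'high' / 'low' / 'none'
    sampled: bool = False
    analysed: bool = False

    def __post_init__(self) -> None:
        if self.origin == "parr" and self.sex != "M":
            raise ValueError("parr individuals are male")
        if self.analysed and not self.sampled:
            raise ValueError("analysed implies sampled")


@dataclass(frozen=True)
class RSModel:
    """Per-sex negative-binomial reproductive success.

    ``dispersion_*`` are NB size parameters k (variance = mu + mu^2/k); the
    male value (0.25) is smaller than the female value (0.75), so male
    reproductive success is more skewed and more males fail to breed
    entirely. ``fold_difference`` scales the per-capita expectation of the
    'high' group relative to the 'low' group; ``high_group_ratio`` is the
    fraction of parents in the high group.
    """

    total_offspring: int
    dispersion_male: float = 0.25
    dispersion_female: float = 0.75
    fold_difference: float = 1.0
    high_group_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.dispersion_male <= 0 or self.dispersion_female <= 0:
            raise ValueError("dispersions must be > 0")
        if self.fold_difference < 1.0:
            raise ValueError("fold_difference must be >= 1 (swap group labels instead)")
        if not 0.0 < self.high_group_ratio < 1.0:
            raise ValueError("high_group_ratio must lie in (0, 1)")


@dataclass
class Population:
    """A parent cohort plus its offspring cohort and the true pedigree."""

    individuals: pd.DataFrame  # id, sex, origin, cohort_year, group_label, sampled, analysed
    pedigree: dict = field(default_factory=dict)  # offspring_id -> (dam_id, sire_id)

    def ids(self, **mask) -> list:
        df = self.individuals
        sel = np.ones(len(df), dtype=bool)
        for col, val in mask.items():
            sel &= (df[col] == val).to_numpy()
        return df.loc[sel, "id"].tolist()


# ---------------------------------------------------------------------------
# study-system constants
# ---------------------------------------------------------------------------

_BURRISHOOLE_ROWS = [
    (1977, 594, 169, 143),
    (1978, 400, 85, 68),
    (1979, 854, 303, 273),
    (1980, 628, 127, 124),
    (1981, 355, 158, 152),
    (1982, 392, 171, 150),
    (1983, 533, 227, 212),
    (1984, 245, 124, 124),
    (1985, 472, 223, 217),
    (1986, 412, 53, 52),
]

BURRISHOOLE_PAIRS = [
    (1977, 1981),
    (1978, 1982),
    (1979, 1983),
    (1980, 1984),
    (1981, 1985),
    (1982, 1986),
]


def make_burrishoole_configs():
    """The ten study cohorts (1977-1986) and the six parent-offspring pairs.

    Offspring cohorts lie four years after their parent cohort; 1977-1981-1985
    and 1978-1982-1986 form two three-generation chains.
    """
    configs = [CohortConfig(y, c, s, a) for (y, c, s, a) in _BURRISHOOLE_ROWS]
    return configs, list(BURRISHOOLE_PAIRS)


def unsampled_parent_prior(config: CohortConfig, n_analysed_dams: int, n_analysed_sires: int):
    """Prior means/SDs for the numbers of unsampled dams and sires of a cohort.

    Dams: females are 55-70% of the census; the prior mean is the midpoint
    count minus the analysed females, with SD three times the SD of the
    uniform female-count distribution (a deliberately broad random walk).
    Sires: anadromous males minus analysed males, inflated by a mean 17%
    parr share of the breeding males, with a very diffuse SD (equal to the
    mean) reflecting the unknown parr contribution.
    """
    lo, hi = config.female_fraction_range
    n_f = 0.5 * (lo + hi) * config.census
    dam_mean = max(n_f - n_analysed_dams, 1.0)
    dam_sd = 3.0 * (hi - lo) * config.census / np.sqrt(12.0)
    n_m = config.census - n_f
    parr = config.parr_fraction_mean / (1.0 - config.parr_fraction_mean) * n_m
    sire_mean = max(n_m - n_analysed_sires + parr, 1.0)
    sire_sd = max(sire_mean, 10.0)
    return {"dam_mean": dam_mean, "dam_sd": max(dam_sd, 1.0),
            "sire_mean": sire_mean, "sire_sd": sire_sd}


# ---------------------------------------------------------------------------
# reproductive success and mating
# ---------------------------------------------------------------------------


def _exact_total_nb(mu: np.ndarray, k: float, total: int, rng) -> np.ndarray:
    """NB draws with the given per-individual means, adjusted to sum exactly
    to ``total`` by multinomial re-allocation of the residual (additions
    proportional to mu, removals hypergeometric over existing offspring)."""
    p = k / (k + mu)
    counts = rng.negative_binomial(k, p).astype(np.int64)
    resid = total - int(counts.sum())
    if resid > 0:
        counts += rng.multinomial(resid, mu / mu.sum())
    elif resid < 0:
        removed = rng.multivariate_hypergeometric(counts, -resid)
        counts -= removed
    return counts


def draw_reproductive_success(parents: pd.DataFrame, model: RSModel, rng) -> dict:
    """Offspring counts per parent for one parental role (dam or sire side).

    ``parents`` needs columns id, sex, group_label; all rows must share a sex
    (each offspring has exactly one parent of each sex, so the two sides are
    drawn separately against the same offspring total). Group 'high' parents
    get ``fold_difference`` times the per-capita expectation of the others.
    """
    sexes = set(parents["sex"])
    if len(sexes) != 1:
        raise ValueError("draw_reproductive_success operates on a single sex at a time")
    sex = sexes.pop()
    k = model.dispersion_female if sex == "F" else model.dispersion_male
    n = len(parents)
    if n == 0:
        raise ValueError("need at least one parent")
    high = (parents["group_label"] == "high").to_numpy()
    n_high = int(high.sum())
    mu_low = model.total_offspring / (model.fold_difference * n_high + (n - n_high))
    mu = np.where(high, model.fold_difference * mu_low, mu_low)
    counts = _exact_total_nb(mu, k, model.total_offspring, rng)
    return dict(zip(parents["id"], (int(c) for c in counts)))


def mate_and_build_pedigree(dam_counts: dict, sire_counts: dict, rng,
                            offspring_prefix: str = "O", cohort_year: int = 0) -> dict:
    """Random bipartite matching of offspring slots to (dam, sire) pairs.

    Each parent appears in exactly as many pairs as its offspring count;
    dam-slot and sire-slot totals must agree.
    """
    t_d = sum(dam_counts.values())
    t_s = sum(sire_counts.values())
    if t_d != t_s:
        raise ValueError(f"dam offspring total {t_d} != sire offspring total {t_s}")
    dam_slots = np.repeat(list(dam_counts.keys()), list(dam_counts.values()))
    sire_slots = np.repeat(list(sire_counts.keys()), list(sire_counts.values()))
    rng.shuffle(dam_slots)
    rng.shuffle(sire_slots)
    width = max(len(str(t_d)), 3)
    return {
        f"{offspring_prefix}{cohort_year}_{i + 1:0{width}d}": (d, s)
        for i, (d, s) in enumerate(zip(dam_slots, sire_slots))
    }


def sample_population(individuals: pd.DataFrame, config: CohortConfig, rng,
                      female_share: float = FEMALE_SAMPLE_SHARE) -> pd.DataFrame:
    """Set sampled/analysed flags for one cohort per the empirical fractions.

    ``n_analysed`` fish are drawn without replacement from the anadromous
    pool, split by sex so that sampled kelts are ~81% female; parr are never
    trapped. Sampling is independent of the pedigree (no ascertainment).
    Returns the DataFrame with flags set (copy).
    """
    df = individuals.copy()
    df["sampled"] = False
    df["analysed"] = False
    anad = df["origin"] == "anadromous"
    females = np.flatnonzero(anad & (df["sex"] == "F"))
    males = np.flatnonzero(anad & (df["sex"] == "M"))
    share = female_share / (female_share + MALE_SAMPLE_SHARE)

    def pick(pool, n_s, n_a):
        n_s = min(n_s, pool.size)
        n_a = min(n_a, n_s)
        chosen = rng.choice(pool, size=n_s, replace=False)
        df.iloc[chosen, df.columns.get_loc("sampled")] = True
        df.iloc[chosen[:n_a], df.columns.get_loc("analysed")] = True

    n_f_s = int(round(share * config.n_sampled))
    n_f_a = int(round(share * config.n_analysed))
    pick(females, n_f_s, n_f_a)
    pick(males, config.n_sampled - n_f_s, config.n_analysed - n_f_a)
    # if one sex pool was exhausted, top up from the other so totals are met
    short = config.n_analysed - int(df["analysed"].sum())
    if short > 0:
        spare = np.flatnonzero(anad & ~df["sampled"].to_numpy())
        extra = rng.choice(spare, size=min(short, spare.size), replace=False)
        df.iloc[extra, df.columns.get_loc("sampled")] = True
        df.iloc[extra, df.columns.get_loc("analysed")] = True
    return df


def _build_parent_cohort(config: CohortConfig, rng, group_sexes=(),
                         high_group_ratio: float = 0.5,
                         parr_beta_concentration: float = 12.0) -> pd.DataFrame:
    lo, hi = config.female_fraction_range
    f = rng.uniform(lo, hi)
    n_f = int(round(f * config.census))
    n_m = config.census - n_f
    pm = config.parr_fraction_mean
    if pm > 0:
        a = pm * parr_beta_concentration
        b = (1.0 - pm) * parr_beta_concentration
        parr_frac = rng.beta(a, b)
    else:
        parr_frac = 0.0
    n_parr = int(round(parr_frac / (1.0 - parr_frac) * n_m))
    y = config.cohort_year
    rows = []
    for i in range(n_f):
        rows.append((f"P{y}_F{i + 1:04d}", "F", "anadromous", y))
    for i in range(n_m):
        rows.append((f"P{y}_M{i + 1:04d}", "M", "anadromous", y))
    for i in range(n_parr):
        rows.append((f"P{y}_parr{i + 1:04d}", "M", "parr", y))
    df = pd.DataFrame(rows, columns=["id", "sex", "origin", "cohort_year"])
    df["group_label"] = "none"
    for sex in group_sexes:
        idx = np.flatnonzero((df["sex"] == sex).to_numpy())
        n_high = int(round(high_group_ratio * idx.size))
        chosen = rng.choice(idx, size=idx.size, replace=False)
        df.iloc[chosen[:n_high], df.columns.get_loc("group_label")] = "high"
        df.iloc[chosen[n_high:], df.columns.get_loc("group_label")] = "low"
    return df


def simulate_cohort_pair(parent_cfg: CohortConfig, offspring_cfg: CohortConfig, rng,
                         rs_model: RSModel = None, group_sexes=(),
                         fold_difference: float = 1.0,
                         high_group_ratio: float = 0.5) -> Population:
    """Simulate one parent-offspring cohort pair with the true pedigree.

    The offspring cohort size is the offspring census; every offspring gets a
    dam from the parental females and a sire from the anadromous-male + parr
    pool, with per-sex NB reproductive skew. Both cohorts are then sampled at
    the empirical fractions (parr never).
    """
    parents = _build_parent_cohort(parent_cfg, rng, group_sexes=group_sexes,
                                   high_group_ratio=high_group_ratio)
    total = offspring_cfg.census
    if rs_model is None:
        rs_model = RSModel(total_offspring=total, fold_difference=fold_difference,
                           high_group_ratio=high_group_ratio)
    dams = parents[parents["sex"] == "F"]
    sires = parents[parents["sex"] == "M"]
    dam_counts = draw_reproductive_success(dams, rs_model, rng)
    sire_counts = draw_reproductive_success(sires, rs_model, rng)
    pedigree = mate_and_build_pedigree(dam_counts, sire_counts, rng,
                                       cohort_year=offspring_cfg.cohort_year)
    y = offspring_cfg.cohort_year
    sex_draw = rng.random(total) < 0.625  # offspring sex, female-biased as in adults
    off = pd.DataFrame({
        "id": list(pedigree.keys()),
        "sex": np.where(sex_draw, "F", "M"),
        "origin": "anadromous",
        "cohort_year": y,
        "group_label": "none",
    })
    parents = sample_population(parents, parent_cfg, rng)
    off = sample_population(off, offspring_cfg, rng)
    individuals = pd.concat([parents, off], ignore_index=True)
    return Population(individuals=individuals, pedigree=pedigree)
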