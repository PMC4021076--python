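"""File formats, run configuration and the stage-chaining pipeline.

Formats: genotype tables as TSV (two columns per locus, ``0``/blank =
missing) or GenePop (three-digit allele codes, ``000000`` = missing);
pedigrees as 3-column TSV with ``*`` for unknown parents; cohort tables as
TSV; run configuration as a flat YAML mapping. Every emitted table carries a
header comment naming the generating seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .demography import UNSAMPLED, CohortConfig, make_burrishoole_configs
from .markers import MISSING, GenotypeTable

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_pedigree",
    "write_pedigree",
    "read_cohort_table",
    "write_cohort_table",
    "cohort_table_summary",
    "RunConfig",
    "run_pipeline",
]


class ParseError(ValueError):
    pass


_MISSING_TOKENS = {"", "0", "0/0", "NA", "na", "."}


def _table_from_string_calls(individuals, loci, calls):
    """calls: dict (ind_row, locus_col) -> (a, b) string labels or None."""
    allele_labels = []
    label_idx = []
    for j in range(len(loci)):
        labels = sorted({a for (_, jj), g in calls.items() if jj == j and g
                         for a in g})
        allele_labels.append(labels)
        label_idx.append({a: i for i, a in enumerate(labels)})
        if not labels:
            allele_labels[-1] = ["001"]  # placeholder for an all-missing locus
    codes = np.full((len(individuals), len(loci), 2), MISSING, dtype=np.int32)
    for (i, j), g in calls.items():
        if g is None:
            continue
        codes[i, j, 0] = label_idx[j][g[0]]
        codes[i, j, 1] = label_idx[j][g[1]]
    return GenotypeTable(individuals, loci, allele_labels, codes)


def read_genotypes(path, dialect: str = "tsv") -> GenotypeTable:
    """Read a genotype table; ``dialect`` is 'tsv' or 'genepop'."""
    path = Path(path)
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "genepop":
        return _read_genepop(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_tsv(path: Path) -> GenotypeTable:
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    sep = "\t" if "\t" in lines[0] else ","
    header = lines[0].split(sep)
    if header[0].lower() != "id":
        raise ParseError(f"{path}:1: first column must be 'id'")
    cols = header[1:]
    if len(cols) % 2:
        raise ParseError(f"{path}:1: expected two columns per locus")
    loci = []
    for k in range(0, len(cols), 2):
        name = cols[k].rsplit(".", 1)[0]
        loci.append(name)
    individuals, calls = [], {}
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(sep)
        if len(parts) != len(header):
            raise ParseError(f"{path}:{ln}: expected {len(header)} fields, got {len(parts)}")
        i = len(individuals)
        individuals.append(parts[0])
        for j in range(len(loci)):
            a, b = parts[1 + 2 * j].strip(), parts[2 + 2 * j].strip()
            if a in _MISSING_TOKENS or b in _MISSING_TOKENS:
                calls[(i, j)] = None
            else:
                calls[(i, j)] = tuple(sorted((a, b)))
    return _table_from_string_calls(individuals, loci, calls)


def _read_genepop(path: Path) -> GenotypeTable:
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise ParseError(f"{path}: truncated GenePop file")
    loci = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        loci.extend(x.strip() for x in lines[i].split(",") if x.strip())
        i += 1
    if i == len(lines):
        raise ParseError(f"{path}: no 'Pop' line")
    individuals, calls = [], {}
    for ln in range(i + 1, len(lines)):
        line = lines[ln].strip()
        if not line:
            continue
        if line.lower() == "pop":
            continue  # additional populations are concatenated
        if "," not in line:
            raise ParseError(f"{path}:{ln + 1}: expected 'id , genotypes'")
        ind, geno = line.split(",", 1)
        row = len(individuals)
        individuals.append(ind.strip())
        fields = geno.split()
        if len(fields) != len(loci):
            raise ParseError(
                f"{path}:{ln + 1}: expected {len(loci)} genotypes, got {len(fields)}"
            )
        for j, f in enumerate(fields):
            if len(f) not in (4, 6):
                raise ParseError(f"{path}:{ln + 1}: malformed genotype {f!r}")
            half = len(f) // 2
            a, b = f[:half], f[half:]
            if int(a) == 0 or int(b) == 0:
                calls[(row, j)] = None
            else:
                calls[(row, j)] = tuple(sorted((a, b)))
    return _table_from_string_calls(individuals, loci, calls)


def write_genotypes(table: GenotypeTable, path, dialect: str = "tsv",
                    title: str = "pedpower genotypes") -> None:
    path = Path(path)
    if dialect == "tsv":
        df = table.to_dataframe()
        df.to_csv(path, sep="\t", index=False)
        return
    if dialect != "genepop":
        raise ValueError(f"unknown dialect {dialect!r}")
    with path.open("w") as fh:
        fh.write(title + "\n")
        for locus in table.loci:
            fh.write(locus + "\n")
        fh.write("Pop\n")
        for i, ind in enumerate(table.individuals):
            parts = []
            for j in range(len(table.loci)):
                a, b = table.codes[i, j]
                if a == MISSING:
                    parts.append("000000")
                else:
                    labels = table.allele_labels[j]
                    parts.append(f"{labels[a]}{labels[b]}")
            fh.write(f"{ind} ,  " + " ".join(parts) + "\n")


def read_pedigree(path) -> dict:
    """3-column TSV (id, dam, sire); '*' or blank = unknown parent."""
    ped = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0].lower() == "id":
            continue
        if len(parts) != 3:
            raise ParseError(f"{path}:{ln}: expected 3 tab-separated fields")
        dam = parts[1].strip() or UNSAMPLED
        sire = parts[2].strip() or UNSAMPLED
        ped[parts[0].strip()] = (dam, sire)
    return ped


def write_pedigree(ped: dict, path, seed=None) -> None:
    with Path(path).open("w") as fh:
        if seed is not None:
            fh.write(f"# generated by pedpower, seed={seed}\n")
        fh.write("id\tdam\tsire\n")
        for o, (d, s) in ped.items():
            fh.write(f"{o}\t{d}\t{s}\n")


def read_cohort_table(path):
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        CohortConfig(int(r.cohort_year), int(r.census), int(r.n_sampled), int(r.n_analysed))
        for r in df.itertuples()
    ]


def write_cohort_table(configs, path, seed=None) -> None:
    with Path(path).open("w") as fh:
        if seed is not None:
            fh.write(f"# pedpower cohort table (counts of fish), seed={seed}\n")
        fh.write("cohort_year\tcensus\tn_sampled\tn_analysed\n")
        for c in configs:
            fh.write(f"{c.cohort_year}\t{c.census}\t{c.n_sampled}\t{c.n_analysed}\n")


def cohort_table_summary(configs) -> dict:
    """Per-cohort analysed percentages plus column totals and means.

    Percentages are reported to one decimal: % of sampled fish analysed and
    overall % of the census analysed.
    """
    if not configs:
        raise ValueError("need at least one cohort")
    rows = []
    for c in configs:
        if c.census == 0:
            raise ValueError(f"cohort {c.cohort_year}: zero census")
        if c.n_sampled == 0:
            raise ValueError(f"cohort {c.cohort_year}: zero sampled count")
        rows.append(dict(
            cohort_year=c.cohort_year, census=c.census, n_sampled=c.n_sampled,
            n_analysed=c.n_analysed,
            pct_sampled_analysed=round(100.0 * c.n_analysed / c.n_sampled, 1),
            pct_overall_analysed=round(100.0 * c.n_analysed / c.census, 1),
        ))
    df = pd.DataFrame(rows)
    totals = {k: int(df[k].sum()) for k in ("census", "n_sampled", "n_analysed")}
    means = {
        "census": float(df["census"].mean()),
        "n_sampled": float(df["n_sampled"].mean()),
        "n_analysed": float(df["n_analysed"].mean()),
        "pct_sampled_analysed": round(float(df["pct_sampled_analysed"].mean()), 1),
        "pct_overall_analysed": round(float(df["pct_overall_analysed"].mean()), 1),
    }
    return {"per_cohort": df, "totals": totals, "means": means}


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RunConfig:
    """Flat configuration for a pipeline run (YAML-compatible subset)."""

    seed: int = 0
    cohort_table: str = "builtin:burrishoole"
    out_dir: str = "pedpower_run"
    stages: tuple = ("summary",)
    # marker / assignment settings
    n_loci: int = 14
    target_mean_alleles: float = 12.0
    target_mean_ho: float = 0.70
    e1: float = 0.02
    e2: float = 0.004
    missing_rate: float = 0.11
    threshold: float = 0.95
    iterations: int = 13_000
    burnin: int = 3_000
    thin: int = 10
    # experiment grids
    loci_grid: tuple = (14, 28)
    replicates: int = 10
    rrs_fold_grid: tuple = (1.0, 1.5, 2.0, 2.5, 3.0)
    rrs_r_grid: tuple = (0.5,)
    rrs_sexes: str = "F"
    rrs_replicates: int = 200
    h2_values: tuple = (0.0, 0.2, 0.4, 0.6, 0.8)
    h2_reps: int = 50

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "loci_grid", "rrs_fold_grid", "rrs_r_grid", "h2_values"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def cohorts(self):
        if self.cohort_table == "builtin:burrishoole":
            return make_burrishoole_configs()
        configs = read_cohort_table(self.cohort_table)
        years = {c.cohort_year for c in configs}
        pairs = [(c.cohort_year, c.cohort_year + 4) for c in configs
                 if c.cohort_year + 4 in years]
        return configs, pairs


def _write_df(df: pd.DataFrame, path: Path, seed: int, note: str) -> None:
    with path.open("w") as fh:
        fh.write(f"# pedpower: {note}; seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the requested stages and archive tables, logs and seeds.

    Re-running with the same config and seed reproduces every table
    byte-identically. A stage failure raises with the stage name attached.
    """
    import time

    from . import parentage, power_h2, power_rrs
    from .markers import ErrorModel

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(dataclasses.asdict(config)))
    configs, pairs = config.cohorts()
    log_lines = []
    for stage in config.stages:
        t0 = time.perf_counter()
        try:
            if stage == "summary":
                summ = cohort_table_summary(configs)
                _write_df(summ["per_cohort"], out / "cohort_summary.tsv",
                          config.seed, "per-cohort sampling summary (%, counts)")
            elif stage == "simulate-genotypes":
                _stage_simulate_genotypes(config, configs, pairs, out)
            elif stage == "marker-power":
                err = ErrorModel(config.e1, config.e2, config.missing_rate)
                table = parentage.marker_number_experiment(
                    loci_grid=config.loci_grid, replicates=config.replicates,
                    seed=config.seed, error=err,
                    chain=parentage.ChainSettings(config.iterations, config.burnin,
                                                  config.thin),
                )
                _write_df(table, out / "marker_power.tsv", config.seed,
                          "true/false assignment % per cohort pair and replicate")
                _write_df(parentage.summarise_marker_experiment(table),
                          out / "marker_power_summary.tsv", config.seed,
                          "mean assignment % over cohort pairs")
            elif stage == "rrs-power":
                exp = power_rrs.RRSExperiment(
                    r_grid=config.rrs_r_grid, fold_grid=config.rrs_fold_grid,
                    sexes=config.rrs_sexes, n_loci=config.n_loci,
                    replicates=config.rrs_replicates,
                )
                surf = power_rrs.power_surface(exp, seed=config.seed)
                _write_df(surf, out / "rrs_power.tsv", config.seed,
                          "RRS detection power (fraction significant)")
            elif stage == "h2-power":
                rng = np.random.default_rng(config.seed)
                ped = power_h2.synthesize_pedigree_like(power_h2.TABLE4_COMBINED, rng)
                grid = power_h2.H2Grid(values=config.h2_values, reps=config.h2_reps)
                curve = power_h2.h2_power_curve(ped, grid, seed=config.seed)
                _write_df(curve, out / "h2_power.tsv", config.seed,
                          "heritability detection power and estimate spread")
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        log_lines.append(f"{stage}\t{time.perf_counter() - t0:.2f}s")
    (out / "run.log").write_text(
        f"# seed={config.seed}\nstage\twall_clock\n" + "\n".join(log_lines) + "\n"
    )
    return out


def _stage_simulate_genotypes(config: RunConfig, configs, pairs, out: Path) -> None:
    from .demography import simulate_cohort_pair
    from .markers import (ErrorModel, build_synthetic_panel,
                          mendelian_offspring_codes, observe_codes,
                          simulate_founder_codes)

    rng = np.random.default_rng(config.seed)
    panel = build_synthetic_panel(config.n_loci, config.target_mean_alleles,
                                  config.target_mean_ho, seed=config.seed)
    cfg = {c.cohort_year: c for c in configs}
    py, oy = pairs[0]
    pop = simulate_cohort_pair(cfg[py], cfg[oy], rng)
    df = pop.individuals
    parent_ids = df.loc[~df["id"].isin(pop.pedigree), "id"].tolist()
    pc = simulate_founder_codes(panel, len(parent_ids), rng)
    pidx = {p: i for i, p in enumerate(parent_ids)}
    off_ids = list(pop.pedigree)
    oc = mendelian_offspring_codes(
        pc[[pidx[pop.pedigree[o][0]] for o in off_ids]],
        pc[[pidx[pop.pedigree[o][1]] for o in off_ids]], rng)
    analysed = df.loc[df["analysed"], "id"].tolist()
    codes = np.concatenate([pc, oc])
    ids = parent_ids + off_ids
    keep = [i for i, x in enumerate(ids) if x in set(analysed)]
    err = ErrorModel(config.e1, config.e2, config.missing_rate)
    obs = observe_codes(codes[keep], panel, err, rng)
    table = GenotypeTable([ids[i] for i in keep], panel.locus_ids,
                          [loc.allele_ids for loc in panel.loci], obs)
    write_genotypes(table, out / f"genotypes_{py}_{oy}.tsv")
    write_pedigree(pop.pedigree, out / f"true_pedigree_{py}_{oy}.tsv", seed=config.seed)
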