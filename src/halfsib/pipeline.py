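"""Config-driven end-to-end runner.

Simulates (or loads) a full reciprocal-transplant dataset on a factorial
breeding design, fits the per-subset quantitative-genetic models
(population x environment heritability/maternal/dominance summaries), the
pooled per-population plasticity models (reaction-norm slope beta and
h2_pl), and the survival workflow (full, interval-split and subgroup Cox
models plus cumulative-mortality curves), writing every table as CSV with
a machine-readable run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design as dz
from . import mcmc, quantgen, simulate, survival
from ._levels import ordered_levels

__all__ = ["RunConfig", "run_pipeline", "load_phenotypes", "default_config"]

log = logging.getLogger("halfsib")


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    seed: int
    outdir: str = "halfsib_out"
    # breeding design
    n_populations: int = 2
    blocks_per_population: int = 4
    sires_per_block: int = 8
    dams_per_block: int = 2
    population_labels: list = field(default_factory=lambda: ["REF", "ASH"])
    # allocations
    n_treatments: int = 2
    n_replicates: int = 3
    n_spatial_blocks: int = 6
    cross_failure_prob: dict | float = 0.0
    unit_shortfall_prob: float = 0.0
    drop_blocks: list = field(default_factory=list)
    # synthetic truth: trait name -> {family: gaussian|threshold, **VarianceTruth}
    traits: dict = field(
        default_factory=lambda: {"trait": {"family": "gaussian"}}
    )
    hazard: dict = field(default_factory=dict)
    embryo: dict = field(default_factory=lambda: {"n_initial_coef": 0.0})
    # model settings
    n_iter: int = 5000
    burn_in: int = 1000
    thin: int = 1
    prior_shape: float = 0.001
    prior_scale: float = 0.001
    parameter_expansion: bool = False
    # survival settings
    cutpoints: list = field(default_factory=lambda: [30.0])
    ties: str = "efron"
    time_transform: str = "km"
    # optional observed data instead of simulation
    phenotype_file: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def default_config(seed: int = 1, outdir: str = "halfsib_out") -> RunConfig:
    """The field-study-mimic configuration.

    2 populations x 4 breeding blocks x (8 sires x 2 dams) = 128 families;
    embryos in 2 water treatments x 3 replicate shelves (768 potential
    units); larvae in 6 spatial blocks per environment; two breeding
    blocks of the REF population withheld from the field stage.
    """
    return RunConfig(
        seed=seed,
        outdir=outdir,
        cross_failure_prob={"REF": 4 / 64},
        unit_shortfall_prob=0.02,
        drop_blocks=[["REF", 3], ["REF", 4]],
        traits={
            "trait": {"family": "gaussian"},
            "mortality": {
                "family": "threshold",
                "mu": -0.6,
                "sigma2_sire": 0.05,
                "sigma2_dam": 0.08,
                "sigma2_sire_dam": 0.04,
                "sigma2_block": 0.05,
            },
        },
        hazard={
            "baseline_rate": [0.004, 0.003],
            "log_hr_env": [0.2, 0.7],
            "log_hr_interaction": [0.0, -1.2],
        },
    )


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


def load_phenotypes(path, design: dz.BreedingDesign | None = None) -> pd.DataFrame:
    """Load and validate a long-format phenotype CSV.

    Required columns: individual_id, sire, dam, population, environment,
    spatial_block.  Optional: family, trait columns, time, event.
    """
    table = pd.read_csv(path)
    required = [
        "individual_id", "sire", "dam", "population", "environment",
        "spatial_block",
    ]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"phenotype file missing columns: {missing}")
    dup = table["individual_id"].duplicated()
    if dup.any():
        ids = table.loc[dup, "individual_id"].head(5).tolist()
        raise ValueError(f"duplicate individual ids: {ids}")
    if "time" in table.columns and (table["time"] < 0).any():
        bad = table.index[table["time"] < 0].tolist()[:5]
        raise ValueError(f"negative survival times at rows {bad}")
    if design is not None:
        known_s = set(design.sires["id"])
        known_d = set(design.dams["id"])
        orphans = table.loc[~table["sire"].isin(known_s), "individual_id"]
        orphans = pd.concat(
            [orphans, table.loc[~table["dam"].isin(known_d), "individual_id"]]
        )
        if len(orphans):
            raise ValueError(
                f"individuals reference unknown parents: {orphans.head(5).tolist()}"
            )
    if "family" not in table.columns:
        table["family"] = table["sire"] + "x" + table["dam"].str.rsplit("-", n=1).str[-1]
    return table


def simulate_stage(config: RunConfig) -> dict:
    """Build design + allocations and simulate all configured outcomes."""
    seeds = _child_seeds(config.seed, 8)
    design = dz.make_design(
        config.n_populations,
        config.blocks_per_population,
        config.sires_per_block,
        config.dams_per_block,
        population_labels=config.population_labels,
    )
    n_potential_units = design.n_families * config.n_treatments * config.n_replicates
    units = dz.allocate_embryo_units(
        design, config.n_treatments, config.n_replicates
    )
    units = simulate.sample_initial_counts(units, seeds[0])
    design_surviving, units = dz.apply_attrition(
        design,
        config.cross_failure_prob,
        config.unit_shortfall_prob,
        seeds[1],
        units=units,
    )
    field_design = design_surviving
    if config.drop_blocks:
        field_design = design_surviving.drop_blocks(
            [tuple(b) for b in config.drop_blocks]
        )
    placements = dz.allocate_field(
        field_design,
        config.n_spatial_blocks,
        seeds[2],
        units=units,
    )

    table = placements.copy()
    truths = {}
    for i, (trait, cfg) in enumerate(sorted(config.traits.items())):
        cfg = dict(cfg)
        fam = cfg.pop("family", "gaussian")
        truth = simulate.VarianceTruth(**cfg)
        truths[trait] = (fam, truth)
        if fam == "threshold":
            table = simulate.simulate_binary_trait(
                design, table, truth, seeds[3] + i, trait=trait
            )
        else:
            table = simulate.simulate_gaussian_trait(
                design, table, truth, seeds[3] + i, trait=trait
            )
    hz = simulate.HazardTruth(**{
        k: tuple(v) if isinstance(v, list) else v for k, v in config.hazard.items()
    })
    table = simulate.simulate_survival(table, hz, seeds[4])

    em = dict(config.embryo)
    coef = em.pop("n_initial_coef", 0.0)
    etruth = simulate.VarianceTruth(**em) if em else simulate.VarianceTruth(
        mu=0.5, sigma2_sire=0.1, sigma2_dam=0.2, sigma2_sire_dam=0.1,
        sigma2_block=0.0, sigma2_resid=0.3,
    )
    units = simulate.simulate_embryo_survival(units, etruth, coef, seeds[5])

    return {
        "design": design,
        "field_design": field_design,
        "units": units,
        "placements": placements,
        "phenotypes": table,
        "n_potential_units": n_potential_units,
        "truths": truths,
    }


def _model_kwargs(config: RunConfig, seed: int) -> dict:
    return dict(
        prior_shape=config.prior_shape,
        prior_scale=config.prior_scale,
        parameter_expansion=config.parameter_expansion,
        n_iter=config.n_iter,
        burn_in=config.burn_in,
        thin=config.thin,
        seed=seed,
    )


def fit_stage(config: RunConfig, table: pd.DataFrame, traits: dict) -> dict:
    """Per-subset causal decompositions and pooled plasticity fits."""
    seeds = _child_seeds(config.seed + 1, 2 + 4 * len(traits))
    t1_rows, t2_rows = [], []
    si = 2
    for trait, fam in sorted(traits.items()):
        for pop in sorted(table["population"].unique()):
            pop_tab = table[table["population"] == pop]
            # Table-1 analogue: per-environment subset fits
            for env in sorted(pop_tab["environment"].unique()):
                sub = pop_tab[pop_tab["environment"] == env]
                try:
                    m = mcmc.MixedModelGibbs(
                        response=trait,
                        response_family=fam,
                        fixed_terms=["intercept"],
                        random_terms=["sire", "dam", "sire:dam", "block"],
                        **_model_kwargs(config, seeds[si % len(seeds)]),
                    ).fit(sub)
                    summ = quantgen.summarize_derived(m.posterior_, "causal")
                    row = {"trait": trait, "population": pop, "environment": env,
                           "n": len(sub)}
                    for q in ("h2", "mat", "dom"):
                        row[q] = summ.loc[q, "mean"]
                        row[f"{q}_low"] = summ.loc[q, "hpdi_low"]
                        row[f"{q}_high"] = summ.loc[q, "hpdi_high"]
                    t1_rows.append(row)
                except Exception as exc:  # isolate per-subset failures
                    log.error("subset fit failed (%s, %s, %s): %s",
                              trait, pop, env, exc)
                si += 1
            # Table-2 analogue: pooled plasticity model per population
            try:
                m = mcmc.MixedModelGibbs(
                    response=trait,
                    response_family=fam,
                    fixed_terms=["intercept", "environment"],
                    random_terms=[
                        "sire", "dam", "sire:dam", "block",
                        "sire:env", "dam:env", "sire:dam:env",
                    ],
                    **_model_kwargs(config, seeds[si % len(seeds)]),
                ).fit(pop_tab)
                summ = quantgen.summarize_derived(m.posterior_, "plasticity")
                beta_col = [c for c in m.posterior_.names
                            if c.startswith("environment")][0]
                beta = m.posterior_[beta_col]
                blo, bhi = mcmc.hpdi(beta)
                row = {
                    "trait": trait, "population": pop, "n": len(pop_tab),
                    "beta": float(np.mean(beta)), "beta_low": blo,
                    "beta_high": bhi,
                    "beta_pmcmc": mcmc.pmcmc(beta),
                    "beta_significant": mcmc.pmcmc(beta) < 0.05,
                }
                for q in ("h2_pl", "mat_pl", "dom_pl"):
                    row[q] = summ.loc[q, "mean"]
                    row[f"{q}_low"] = summ.loc[q, "hpdi_low"]
                    row[f"{q}_high"] = summ.loc[q, "hpdi_high"]
                t2_rows.append(row)
            except Exception as exc:
                log.error("plasticity fit failed (%s, %s): %s", trait, pop, exc)
            si += 1
    return {
        "table1": pd.DataFrame(t1_rows),
        "table2": pd.DataFrame(t2_rows),
    }


def survival_stage(config: RunConfig, table: pd.DataFrame) -> dict:
    """Full, interval-split and subgroup Cox models + mortality curves."""
    records = table.copy()
    records["start"] = 0.0
    records = records.rename(columns={"time": "stop"})
    pops = ordered_levels(records["population"])
    envs = ordered_levels(records["environment"])
    records["pop_ind"] = (records["population"] == pops[-1]).astype(float)
    records["env_ind"] = (records["environment"] == envs[-1]).astype(float)
    records["popXenv"] = records["pop_ind"] * records["env_ind"]
    records["cluster"] = (
        records["environment"].astype(str) + "|"
        + records["spatial_block"].astype(str)
    )
    covs = ["pop_ind", "env_ind", "popXenv"]

    full = survival.CoxPH(covariates=covs, cluster="cluster", ties=config.ties)
    full.fit(records)
    full.schoenfeld_test(config.time_transform)

    split = survival.split_episodes(records, config.cutpoints)
    interval_fits = {}
    for label, grp in split.groupby("interval"):
        try:
            m = survival.CoxPH(
                covariates=covs, cluster="cluster", ties=config.ties
            ).fit(grp)
            m.schoenfeld_test(config.time_transform)
            interval_fits[label] = m
        except ValueError as exc:
            log.error("interval model %s failed: %s", label, exc)

    sub_rows = []
    bounds = [0.0] + list(config.cutpoints) + [float(records["stop"].max())]
    for env in envs:
        for a, b in zip(bounds[:-1], bounds[1:]):
            try:
                fitres = survival.subgroup_hazard(
                    records, env, (a, b), cluster="cluster", ties=config.ties
                )
                sub_rows.append({
                    "environment": env, "interval": f"({a:g},{b:g}]",
                    "hazard_ratio": fitres.hazard_ratios.iloc[0],
                    "hr_low": fitres.ci_low.iloc[0],
                    "hr_high": fitres.ci_high.iloc[0],
                    "p": fitres.p_values.iloc[0],
                    "n": fitres.n, "n_events": fitres.n_events,
                })
            except ValueError as exc:
                log.error("subgroup (%s, %g-%g) failed: %s", env, a, b, exc)
    curves = survival.cumulative_mortality(
        records, ["population", "environment"]
    )
    return {
        "full": full,
        "interval_fits": interval_fits,
        "subgroups": pd.DataFrame(sub_rows),
        "curves": curves,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate -> fit -> survival -> report; return the result bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    log.addHandler(fh)
    try:
        log.info("simulate stage (seed %d)", config.seed)
        sim = simulate_stage(config)
        table = sim["phenotypes"]
        if config.phenotype_file:
            table = load_phenotypes(config.phenotype_file, sim["design"])
        sim["design"].to_csv(outdir / "design")
        sim["units"].to_csv(outdir / "embryo_units.csv", index=False)
        sim["placements"].to_csv(outdir / "field_placements.csv", index=False)
        table.to_csv(outdir / "phenotypes.csv", index=False)

        traits = {t: fam for t, (fam, _) in sim["truths"].items()}
        log.info("fit stage: %d trait(s)", len(traits))
        fits = fit_stage(config, table, traits)
        fits["table1"].to_csv(outdir / "table1_components.csv", index=False)
        fits["table2"].to_csv(outdir / "table2_plasticity.csv", index=False)

        log.info("survival stage")
        surv = survival_stage(config, table)
        surv["full"].result().summary().to_csv(outdir / "cox_full.csv")
        surv["full"].schoenfeld_.to_csv(outdir / "cox_full_schoenfeld.csv")
        for label, m in surv["interval_fits"].items():
            safe = label.replace("(", "").replace("]", "").replace(",", "_")
            m.result().summary().to_csv(outdir / f"cox_interval_{safe}.csv")
        surv["subgroups"].to_csv(outdir / "cox_subgroups.csv", index=False)
        surv["curves"].to_csv(outdir / "mortality_curves.csv", index=False)

        import halfsib

        manifest = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "versions": {
                "halfsib": halfsib.__version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "n_families": int(sim["design"].n_families),
            "n_potential_embryo_units": int(sim["n_potential_units"]),
            "n_realized_embryo_units": int(len(sim["units"])),
            "n_field_individuals": int(len(table)),
        }
        with open(outdir / "manifest.json", "w") as fhj:
            json.dump(manifest, fhj, indent=2, sort_keys=True)
        config.to_yaml(outdir / "config.yaml")
        return {"sim": sim, "fits": fits, "survival": surv, "manifest": manifest}
    finally:
        log.removeHandler(fh)
        fh.close()
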