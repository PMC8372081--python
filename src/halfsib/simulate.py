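"""Synthetic phenotypes and survival outcomes on a factorial breeding design.

The generators draw every random effect of the quantitative-genetic model
(sire, dam, sire:dam, spatial block, environment interactions, residual)
from zero-mean normals at user-chosen variances, so that the true causal
components — V_A = 4*sigma2_sire, V_M = sigma2_dam - sigma2_sire,
V_D = 4*sigma2_sire:dam, and the plasticity numerator 4*sigma2_sire_x_env —
are known exactly and every downstream estimator can be validated without
external data.

Genotype-by-environment structure is parameterized as main effect plus an
independent interaction deviation per (parent, environment) cell; for two
environments this is equivalent to correlated environment-specific effects
with sigma2_SxE = (1 - r) * sigma2_S,env-specific.

Survival times come from a piecewise-exponential law, the canonical
generating model for Cox proportional-hazards data: interval-specific
baseline rates times exp(linear predictor), censored at the end of study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from ._levels import indicator_level

__all__ = [
    "VarianceTruth",
    "HazardTruth",
    "simulate_gaussian_trait",
    "simulate_binary_trait",
    "simulate_embryo_survival",
    "simulate_survival",
    "sample_initial_counts",
]


@dataclass
class VarianceTruth:
    """Generating parameters for one trait (trait units / units squared).

    Defaults describe a field-realistic trait on a standardized scale:
    total phenotypic variance near 1 with narrow-sense heritability
    4*0.075/1.0 = 0.3, moderate maternal and dominance contributions, and
    modest genotype-by-environment variance.
    """

    mu: float = 0.0
    beta_env: float = 0.0
    sigma2_sire: float = 0.075
    sigma2_dam: float = 0.125
    sigma2_sire_dam: float = 0.05
    sigma2_block: float = 0.05
    sigma2_resid: float = 0.70
    sigma2_sireXenv: float = 0.0
    sigma2_damXenv: float = 0.0
    sigma2_sire_damXenv: float = 0.0

    def validate(self) -> None:
        for name in (
            "sigma2_sire",
            "sigma2_dam",
            "sigma2_sire_dam",
            "sigma2_block",
            "sigma2_resid",
            "sigma2_sireXenv",
            "sigma2_damXenv",
            "sigma2_sire_damXenv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class HazardTruth:
    """Piecewise-exponential generating parameters (rates in events/day).

    ``baseline_rate`` and the log hazard ratios may be scalars (constant
    over time) or sequences with one value per interval defined by
    ``cutpoints`` (len(cutpoints) + 1 intervals).  Defaults mimic a
    ~100-day larval study with a day-30 hazard change-point.
    """

    baseline_rate: float | tuple = 0.004
    log_hr_pop: float | tuple = 0.0
    log_hr_env: float | tuple = 0.0
    log_hr_interaction: float | tuple = 0.0
    cutpoints: tuple = (30.0,)
    censor_time: float = 104.0
    block_frailty_sd: float = 0.0

    def validate(self) -> None:
        if np.any(np.asarray(self.baseline_rate, float) < 0):
            raise ValueError("baseline_rate must be >= 0")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be > 0")
        cps = np.asarray(self.cutpoints, float)
        if len(cps) and (np.any(np.diff(cps) <= 0) or cps[0] <= 0):
            raise ValueError("cutpoints must be positive and strictly increasing")

    def per_interval(self, name: str) -> np.ndarray:
        n_int = len(self.cutpoints) + 1
        v = np.asarray(getattr(self, name), float)
        if v.ndim == 0:
            return np.full(n_int, float(v))
        if len(v) != n_int:
            raise ValueError(f"{name} must have {n_int} per-interval values")
        return v


def _group_effects(rng, keys: pd.Series, sigma2: float) -> np.ndarray:
    """Draw one N(0, sigma2) effect per unique key, mapped back to rows."""
    codes, uniques = pd.factorize(keys, sort=True)
    return rng.normal(0.0, np.sqrt(sigma2), size=len(uniques))[codes]


def _latent_liability(
    design,
    placements: pd.DataFrame,
    truth: VarianceTruth,
    rng: np.random.Generator,
    sigma2_resid: float,
) -> np.ndarray:
    envs = placements["environment"].unique()
    env_ind = (
        (placements["environment"] == indicator_level(envs)).to_numpy(float)
        if len(envs) > 1
        else 0.0
    )

    y = truth.mu + truth.beta_env * env_ind
    y = y + _group_effects(rng, placements["sire"], truth.sigma2_sire)
    y = y + _group_effects(rng, placements["dam"], truth.sigma2_dam)
    y = y + _group_effects(rng, placements["family"], truth.sigma2_sire_dam)
    env = placements["environment"].astype(str)
    y = y + _group_effects(rng, placements["sire"] + "|" + env, truth.sigma2_sireXenv)
    y = y + _group_effects(rng, placements["dam"] + "|" + env, truth.sigma2_damXenv)
    y = y + _group_effects(
        rng, placements["family"] + "|" + env, truth.sigma2_sire_damXenv
    )
    block = env + "|" + placements["spatial_block"].astype(str)
    y = y + _group_effects(rng, block, truth.sigma2_block)
    y = y + rng.normal(0.0, np.sqrt(sigma2_resid), size=len(placements))
    return np.asarray(y, float)


def simulate_gaussian_trait(
    design,
    placements: pd.DataFrame,
    truth: VarianceTruth,
    seed: int,
    trait: str = "trait",
) -> pd.DataFrame:
    """Add a Gaussian trait column to a copy of ``placements``.

    y = mu + beta_env * I(env = high) + sire + dam + sire:dam
        + sire x env + dam x env + sire:dam x env + block + residual,
    every effect an independent zero-mean normal at its stated variance.
    """
    truth.validate()
    rng = np.random.default_rng(seed)
    out = placements.copy()
    out[trait] = _latent_liability(design, placements, truth, rng, truth.sigma2_resid)
    return out


def simulate_binary_trait(
    design,
    placements: pd.DataFrame,
    truth: VarianceTruth,
    seed: int,
    trait: str = "binary_trait",
) -> pd.DataFrame:
    """Threshold (liability) trait: outcome 1 iff latent liability > 0.

    The liability is generated exactly as the Gaussian trait but with the
    residual variance fixed at 1, the probit-scale identifiability
    convention of threshold models.
    """
    truth.validate()
    rng = np.random.default_rng(seed)
    out = placements.copy()
    liab = _latent_liability(design, placements, truth, rng, sigma2_resid=1.0)
    out[trait] = (liab > 0).astype(int)
    return out


def sample_initial_counts(
    units: pd.DataFrame, seed: int, low: int = 8, high: int = 60
) -> pd.DataFrame:
    """Randomize per-unit initial embryo counts uniformly on [low, high]."""
    rng = np.random.default_rng(seed)
    out = units.copy()
    out["n_initial"] = rng.integers(low, high + 1, size=len(out))
    return out


def simulate_embryo_survival(
    units: pd.DataFrame,
    truth: VarianceTruth,
    n_initial_coef: float,
    seed: int,
) -> pd.DataFrame:
    """Fill ``n_survived`` ~ Binomial(n_initial, p) per embryonic unit.

    logit(p) = mu + n_initial_coef * n_initial + sire + dam + family
               + unit effect, with the unit effect drawn at
    ``truth.sigma2_resid`` (one rearing container = one overdispersion
    unit).
    """
    truth.validate()
    if (units["n_initial"] <= 0).any():
        raise ValueError("all units must have n_initial > 0")
    rng = np.random.default_rng(seed)
    out = units.copy()
    n_init = out["n_initial"].to_numpy(float)
    eta = truth.mu + n_initial_coef * n_init
    eta = eta + _group_effects(rng, out["sire"], truth.sigma2_sire)
    eta = eta + _group_effects(rng, out["dam"], truth.sigma2_dam)
    eta = eta + _group_effects(rng, out["family"], truth.sigma2_sire_dam)
    eta = eta + rng.normal(0.0, np.sqrt(truth.sigma2_resid), size=len(out))
    p = expit(eta)
    out["n_survived"] = rng.binomial(out["n_initial"].to_numpy(int), p)
    return out


def simulate_survival(
    placements: pd.DataFrame,
    truth: HazardTruth,
    seed: int,
) -> pd.DataFrame:
    """Draw (time, event) per individual from a piecewise-exponential law.

    The hazard on interval m is ``baseline_rate[m] * exp(eta_m)`` where the
    linear predictor uses population, environment and interaction
    indicators (high level = last label alphabetically, i.e. ASH in the
    REF/ASH layout) plus an optional per-spatial-block log-normal frailty.
    Times past ``censor_time`` are censored (event = 0).
    """
    truth.validate()
    rng = np.random.default_rng(seed)
    n = len(placements)
    pops = placements["population"].unique()
    envs = placements["environment"].unique()
    pop_ind = np.zeros(n)
    if len(pops) > 1:
        pop_ind = (placements["population"] == indicator_level(pops)).to_numpy(float)
    env_ind = np.zeros(n)
    if len(envs) > 1:
        env_ind = (placements["environment"] == indicator_level(envs)).to_numpy(float)

    frailty = np.zeros(n)
    if truth.block_frailty_sd > 0:
        block = placements["environment"].astype(str) + "|" + placements[
            "spatial_block"
        ].astype(str)
        frailty = _group_effects(rng, block, truth.block_frailty_sd**2)

    rates = truth.per_interval("baseline_rate")
    b_pop = truth.per_interval("log_hr_pop")
    b_env = truth.per_interval("log_hr_env")
    b_int = truth.per_interval("log_hr_interaction")
    bounds = np.concatenate([[0.0], np.asarray(truth.cutpoints, float), [np.inf]])

    time = np.full(n, truth.censor_time)
    event = np.zeros(n, dtype=int)
    alive = np.ones(n, dtype=bool)
    for m in range(len(rates)):
        if not alive.any():
            break
        eta = b_pop[m] * pop_ind + b_env[m] * env_ind + b_int[m] * pop_ind * env_ind
        h = rates[m] * np.exp(eta + frailty)
        lo, hi = bounds[m], bounds[m + 1]
        # exponential waiting time within the interval; memoryless restart at lo
        with np.errstate(divide="ignore"):
            wait = rng.exponential(1.0, size=n) / np.where(h > 0, h, np.nan)
        t_event = lo + wait
        dies_here = alive & np.isfinite(t_event) & (t_event <= hi) & (
            t_event <= truth.censor_time
        )
        time[dies_here] = t_event[dies_here]
        event[dies_here] = 1
        alive &= ~dies_here

    out = placements.copy()
    out["time"] = time
    out["event"] = event
    return out
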