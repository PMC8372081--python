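"""Bayesian hierarchical mixed models by Gibbs sampling.

The model is the classical Gaussian variance-component LMM

    y = X beta + sum_t Z_t u_t + e,   u_t ~ N(0, sigma2_t I),  e ~ N(0, sigma2_e I)

with a flat prior on the fixed effects and independent inverse-gamma priors
on every variance.  All full conditionals are conjugate:

* beta | rest          ~ multivariate normal (generalized least squares form)
* u_t levels | rest    ~ independent normals (shrinkage toward zero)
* sigma2_t | u_t       ~ inverse-gamma
* sigma2_e | residuals ~ inverse-gamma

Binary (threshold / liability) traits are handled by the Albert-Chib
augmentation: a latent Gaussian liability is drawn from its truncated
normal full conditional, the residual variance is fixed at 1 for
identifiability, and the Gaussian machinery runs on the liabilities.
Binomial success/failure counts are expanded to Bernoulli rows sharing a
unit-level random effect and fitted through the same threshold sampler
(probit link).

Optional parameter expansion (a redundant multiplicative working scalar
with a standard-normal prior per random term) improves mixing when a
variance is near zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from sklearn.base import BaseEstimator

from ._levels import ordered_levels

__all__ = [
    "ModelSpec",
    "PosteriorSamples",
    "MixedModelGibbs",
    "fit_gaussian",
    "fit_threshold",
    "fit_binomial_counts",
    "expand_binomial_counts",
    "hpdi",
    "pmcmc",
    "effective_sample_size",
]

#: grouping-key builders for the supported random terms
_RANDOM_TERMS = {
    "sire": lambda df: df["sire"].astype(str),
    "dam": lambda df: df["dam"].astype(str),
    "sire:dam": lambda df: df["family"].astype(str),
    "block": lambda df: df["environment"].astype(str)
    + "|"
    + df["spatial_block"].astype(str),
    "sire:env": lambda df: df["sire"].astype(str) + "|" + df["environment"].astype(str),
    "dam:env": lambda df: df["dam"].astype(str) + "|" + df["environment"].astype(str),
    "sire:dam:env": lambda df: df["family"].astype(str)
    + "|"
    + df["environment"].astype(str),
    "unit": lambda df: df["unit"].astype(str),
}


def hpdi(draws, prob: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(prob * n)`` sorted draws.

    Ties between equally short windows are broken toward the lowest start.
    """
    x = np.sort(np.asarray(draws, float))
    n = len(x)
    if n < 2:
        raise ValueError("hpdi needs at least 2 draws")
    if not 0.0 < prob < 1.0:
        raise ValueError("prob must be in (0, 1)")
    k = int(np.ceil(prob * n))
    k = min(max(k, 1), n)
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def pmcmc(draws) -> float:
    """Two-sided MCMC tail probability that the quantity crosses zero.

    ``2 * min(frac <= 0, frac > 0)``, floored at ``2 / n``.
    """
    x = np.asarray(draws, float)
    n = len(x)
    if n < 2:
        raise ValueError("pmcmc needs at least 2 draws")
    p = 2.0 * min(np.mean(x <= 0), np.mean(x > 0))
    return float(max(p, 2.0 / n))


def effective_sample_size(draws) -> float:
    """ESS via Geyer's initial positive sequence on the autocorrelation."""
    x = np.asarray(draws, float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    x = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    # sum consecutive pairs while they stay positive
    tau = 1.0
    for k in range(1, n - 1, 2):
        pair = rho[k] + rho[k + 1] if k + 1 < n else rho[k]
        if pair < 0:
            break
        tau += 2.0 * pair
    return float(min(n, n / max(tau, 1e-12)))


@dataclass
class ModelSpec:
    """Specification of one hierarchical model fit."""

    response: str
    response_family: str = "gaussian"  # gaussian | threshold | binomial_counts
    fixed_terms: list = dc_field(default_factory=lambda: ["intercept"])
    random_terms: list = dc_field(
        default_factory=lambda: ["sire", "dam", "sire:dam", "block"]
    )
    prior_shape: float = 0.001
    prior_scale: float = 0.001
    parameter_expansion: bool = False
    n_iter: int = 5000
    burn_in: int = 1000
    thin: int = 1
    seed: int = 0

    def validate(self) -> None:
        if not self.n_iter > self.burn_in >= 0:
            raise ValueError("need n_iter > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.response_family not in ("gaussian", "threshold", "binomial_counts"):
            raise ValueError(f"unknown family {self.response_family!r}")
        for t in self.random_terms:
            if t not in _RANDOM_TERMS:
                raise ValueError(f"unknown random term {t!r}")


class PosteriorSamples:
    """Retained MCMC draws of fixed effects and variance components."""

    def __init__(self, draws: pd.DataFrame, spec: ModelSpec | None = None):
        self.draws = draws
        self.spec = spec

    @property
    def names(self) -> list[str]:
        return list(self.draws.columns)

    def __len__(self) -> int:
        return len(self.draws)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.draws[name].to_numpy()

    def mean(self) -> pd.Series:
        return self.draws.mean()

    def hpdi(self, prob: float = 0.95) -> pd.DataFrame:
        rows = {c: hpdi(self.draws[c], prob) for c in self.draws.columns}
        return pd.DataFrame(rows, index=["low", "high"]).T

    def ess(self) -> pd.Series:
        return pd.Series(
            {c: effective_sample_size(self.draws[c]) for c in self.draws.columns}
        )

    def summary(self, prob: float = 0.95) -> pd.DataFrame:
        hp = self.hpdi(prob)
        return pd.DataFrame(
            {
                "mean": self.draws.mean(),
                "sd": self.draws.std(),
                "hpdi_low": hp["low"],
                "hpdi_high": hp["high"],
                "pmcmc": {c: pmcmc(self.draws[c]) for c in self.draws.columns},
                "ess": self.ess(),
            }
        )

    def to_csv(self, path) -> None:
        self.draws.to_csv(path, index=False)


def _build_fixed(table: pd.DataFrame, fixed_terms) -> tuple[np.ndarray, list]:
    cols, names = [], []
    for term in fixed_terms:
        if term == "intercept":
            cols.append(np.ones(len(table)))
            names.append("intercept")
        elif term == "environment":
            envs = ordered_levels(table["environment"])
            if len(envs) < 2:
                raise ValueError("environment term requires >= 2 levels")
            cols.append((table["environment"] == envs[-1]).to_numpy(float))
            names.append(f"environment[{envs[-1]}]")
        else:
            if term not in table.columns:
                raise ValueError(f"unknown fixed term {term!r}")
            cols.append(table[term].to_numpy(float))
            names.append(term)
    return np.column_stack(cols), names


def expand_binomial_counts(units: pd.DataFrame) -> pd.DataFrame:
    """Expand per-unit success/failure counts into Bernoulli rows.

    Each embryonic unit contributes ``n_initial`` rows with outcome 1 for
    survivors and 0 for deaths, all sharing one ``unit`` identifier so a
    unit-level random effect can absorb overdispersion.
    """
    if (units["n_survived"] > units["n_initial"]).any():
        raise ValueError("n_survived exceeds n_initial in some units")
    reps = units["n_initial"].to_numpy(int)
    out = units.loc[units.index.repeat(reps)].reset_index(drop=True)
    surv = units["n_survived"].to_numpy(int)
    y = np.concatenate([
        np.r_[np.ones(s, int), np.zeros(n - s, int)] for s, n in zip(surv, reps)
    ])
    out["survived"] = y
    out["unit"] = (
        out["family"].astype(str)
        + "|"
        + out.get("treatment", pd.Series("", index=out.index)).astype(str)
        + "|"
        + out.get("replicate", pd.Series(0, index=out.index)).astype(str)
    )
    return out


class MixedModelGibbs(BaseEstimator):
    """Variance-component mixed model fitted by conjugate Gibbs sampling.

    Scikit-learn style estimator: hyperparameters mirror
    :class:`ModelSpec`; :meth:`fit` takes a long-format phenotype
    DataFrame and exposes ``posterior_`` (a :class:`PosteriorSamples`),
    ``summary_`` and ``ess_``.

    Parameters
    ----------
    response : str
        Column to model (binary 0/1 for ``family="threshold"``).
    response_family : {"gaussian", "threshold", "binomial_counts"}
    fixed_terms : list of str
        ``"intercept"``, ``"environment"`` (indicator of the second
        environment level) and/or numeric covariate column names.
    random_terms : list of str
        Subset of ``{"sire", "dam", "sire:dam", "block", "sire:env",
        "dam:env", "sire:dam:env", "unit"}``.
    prior_shape, prior_scale : float
        Inverse-gamma hyperparameters per variance (default 0.001/0.001,
        weak and close to noninformative).
    parameter_expansion : bool
        Redundant multiplicative reparameterization for better mixing
        near zero variance.
    """

    def __init__(
        self,
        response: str = "trait",
        response_family: str = "gaussian",
        fixed_terms=("intercept",),
        random_terms=("sire", "dam", "sire:dam", "block"),
        prior_shape: float = 0.001,
        prior_scale: float = 0.001,
        parameter_expansion: bool = False,
        n_iter: int = 5000,
        burn_in: int = 1000,
        thin: int = 1,
        seed: int = 0,
    ):
        self.response = response
        self.response_family = response_family
        self.fixed_terms = fixed_terms
        self.random_terms = random_terms
        self.prior_shape = prior_shape
        self.prior_scale = prior_scale
        self.parameter_expansion = parameter_expansion
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            response=self.response,
            response_family=self.response_family,
            fixed_terms=list(self.fixed_terms),
            random_terms=list(self.random_terms),
            prior_shape=self.prior_shape,
            prior_scale=self.prior_scale,
            parameter_expansion=self.parameter_expansion,
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=self.seed,
        )

    def fit(self, table: pd.DataFrame, y=None) -> "MixedModelGibbs":
        spec = self._spec()
        spec.validate()
        if len(table) == 0:
            raise ValueError("empty table")
        if spec.response_family == "binomial_counts":
            table = expand_binomial_counts(table)
            response = "survived"
        else:
            response = spec.response
        if response not in table.columns:
            raise ValueError(f"response column {response!r} missing")
        yvec = table[response].to_numpy(float)
        if np.isnan(yvec).all():
            raise ValueError("response is all-missing")
        keep = ~np.isnan(yvec)
        table = table.loc[keep].reset_index(drop=True)
        yvec = yvec[keep]

        threshold = spec.response_family in ("threshold", "binomial_counts")
        if threshold:
            uniq = np.unique(yvec)
            if not np.all(np.isin(uniq, [0.0, 1.0])):
                raise ValueError("threshold response must be binary 0/1")
            if len(uniq) == 1:
                warnings.warn(
                    "response is constant (complete separation); intercept "
                    "posterior will drift to the prior boundary",
                    UserWarning,
                )
        elif np.var(yvec) == 0:
            warnings.warn("constant response: no information on variances", UserWarning)

        X, fixed_names = _build_fixed(table, spec.fixed_terms)
        n, p = X.shape
        XtX = X.T @ X
        XtX_inv = np.linalg.pinv(XtX)
        chol_fixed = np.linalg.cholesky(XtX_inv + 1e-12 * np.eye(p))

        codes, counts = [], []
        for term in spec.random_terms:
            key = _RANDOM_TERMS[term](table)
            c, uniques = pd.factorize(key, sort=True)
            codes.append(np.asarray(c))
            counts.append(np.bincount(c, minlength=len(uniques)).astype(float))

        rng = np.random.default_rng(spec.seed)
        a0, b0 = spec.prior_shape, spec.prior_scale
        n_terms = len(spec.random_terms)

        beta = np.zeros(p)
        us = [np.zeros(len(c)) for c in counts]
        sig2 = np.full(n_terms, 0.1)
        sig2_e = 1.0
        liab = yvec.copy()
        if threshold:
            liab = np.where(yvec > 0, 0.5, -0.5)
            sig2_e = 1.0

        n_keep = (spec.n_iter - spec.burn_in + spec.thin - 1) // spec.thin
        var_names = [f"var_{t}" for t in spec.random_terms]
        out = np.empty((n_keep, p + n_terms + 1))
        kept = 0

        fitted_random = np.zeros(n)
        for t in range(n_terms):
            fitted_random += us[t][codes[t]]

        for it in range(spec.n_iter):
            ywork = liab
            # --- fixed effects: beta | rest ~ N(bhat, sig2_e (X'X)^-1)
            resid_f = ywork - fitted_random
            bhat = XtX_inv @ (X.T @ resid_f)
            beta = bhat + np.sqrt(sig2_e) * (chol_fixed @ rng.standard_normal(p))
            xb = X @ beta

            # --- random effect vectors, one term at a time
            r = ywork - xb - fitted_random
            for t in range(n_terms):
                r_t = r + us[t][codes[t]]  # partial residuals for this term
                ssum = np.bincount(codes[t], weights=r_t, minlength=len(counts[t]))
                prec = counts[t] / sig2_e + 1.0 / sig2[t]
                mean = (ssum / sig2_e) / prec
                us[t] = mean + rng.standard_normal(len(prec)) / np.sqrt(prec)
                if spec.parameter_expansion:
                    # redundant scalar alpha ~ N(0,1) prior, regressed on Z u
                    cvec = us[t][codes[t]]
                    cc = float(cvec @ cvec)
                    va = 1.0 / (cc / sig2_e + 1.0)
                    ma = va * float(cvec @ r_t) / sig2_e
                    alpha = ma + np.sqrt(va) * rng.standard_normal()
                    utilde2 = float(us[t] @ us[t])
                    s2t = 1.0 / rng.gamma(a0 + 0.5 * len(us[t]), 1.0 / (b0 + 0.5 * utilde2))
                    us[t] = alpha * us[t]
                    sig2[t] = max(alpha * alpha * s2t, 1e-300)
                else:
                    ssq = float(us[t] @ us[t])
                    sig2[t] = 1.0 / rng.gamma(
                        a0 + 0.5 * len(us[t]), 1.0 / (b0 + 0.5 * ssq)
                    )
                r = r_t - us[t][codes[t]]

            fitted_random = ywork - xb - r

            # --- residual variance (Gaussian only; threshold fixes it at 1)
            if not threshold:
                sse = float(r @ r)
                sig2_e = 1.0 / rng.gamma(a0 + 0.5 * n, 1.0 / (b0 + 0.5 * sse))
            else:
                # --- latent liabilities: truncated normal around the mean
                mu_liab = xb + fitted_random
                u = rng.random(n)
                lo = ndtr(-mu_liab)  # P(liab <= 0)
                # y=1: sample from upper tail; y=0: lower tail
                q = np.where(yvec > 0, lo + u * (1 - lo), u * lo)
                q = np.clip(q, 1e-12, 1 - 1e-12)
                liab = mu_liab + ndtri(q)

            if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
                out[kept, :p] = beta
                out[kept, p : p + n_terms] = sig2
                out[kept, -1] = sig2_e
                kept += 1

        draws = pd.DataFrame(
            out[:kept], columns=fixed_names + var_names + ["var_resid"]
        )
        if threshold:
            draws["var_resid"] = 1.0
        self.posterior_ = PosteriorSamples(draws, spec)
        self.param_names_ = list(draws.columns)
        self.summary_ = self.posterior_.summary()
        self.ess_ = self.summary_["ess"]
        low_ess = self.ess_[self.ess_ < 200]
        if len(low_ess):
            warnings.warn(
                "low effective sample size (<200) for: "
                + ", ".join(f"{k} ({v:.0f})" for k, v in low_ess.items()),
                UserWarning,
            )
        return self


def fit_gaussian(table: pd.DataFrame, spec: ModelSpec) -> PosteriorSamples:
    """Fit a Gaussian variance-component model; returns the posterior draws."""
    spec = ModelSpec(**{**spec.__dict__, "response_family": "gaussian"})
    model = MixedModelGibbs(**spec.__dict__).fit(table)
    return model.posterior_


def fit_threshold(table: pd.DataFrame, spec: ModelSpec) -> PosteriorSamples:
    """Fit a probit threshold (liability) model to a binary response."""
    spec = ModelSpec(**{**spec.__dict__, "response_family": "threshold"})
    model = MixedModelGibbs(**spec.__dict__).fit(table)
    return model.posterior_


def fit_binomial_counts(units: pd.DataFrame, spec: ModelSpec) -> PosteriorSamples:
    """Fit per-unit success/failure counts via Bernoulli expansion + probit."""
    spec = ModelSpec(**{**spec.__dict__, "response_family": "binomial_counts"})
    model = MixedModelGibbs(**spec.__dict__).fit(units)
    return model.posterior_
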