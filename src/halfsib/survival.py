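"""Cox proportional-hazards workflow for counting-process survival records.

Covers the full field-study analysis path: Efron/Breslow partial
likelihood maximized by Newton-Raphson, cluster-sandwich (robust)
standard errors for spatial-block clustering, Grambsch-Therneau tests of
proportionality on scaled Schoenfeld residuals, episode splitting at
fixed cutpoints so hazard ratios can differ by time interval, per-stratum
subgroup hazard ratios, and Kaplan-Meier cumulative-mortality curves.

Records use half-open intervals (start, stop]: an individual is at risk
at time t iff start < t <= stop, so a death exactly at a cutpoint day
belongs to the earlier interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._levels import indicator_level

__all__ = [
    "CoxFit",
    "CoxPH",
    "fit_cox",
    "schoenfeld_test",
    "split_episodes",
    "subgroup_hazard",
    "cumulative_mortality",
]


@dataclass
class CoxFit:
    """Point estimates and diagnostics from one Cox model fit."""

    beta: pd.Series
    se_model: pd.Series
    se_robust: pd.Series | None
    hazard_ratios: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    p_values: pd.Series
    loglik: float
    n: int
    n_events: int
    schoenfeld: pd.DataFrame | None = None

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.beta,
                "se": self.se_model,
                "se_robust": self.se_robust,
                "HR": self.hazard_ratios,
                "HR_low": self.ci_low,
                "HR_high": self.ci_high,
                "p": self.p_values,
            }
        )


def _validate_records(records: pd.DataFrame, covariates, cluster):
    req = {"start", "stop", "event"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if (records["start"] >= records["stop"]).any():
        raise ValueError("need start < stop on every row")
    if not records["event"].isin([0, 1]).all():
        raise ValueError("event must be 0/1")
    for c in covariates:
        if c not in records.columns:
            raise ValueError(f"unknown covariate {c!r}")
        if records[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant")
    if cluster is not None and cluster not in records.columns:
        raise ValueError(f"unknown cluster column {cluster!r}")
    if records["event"].sum() < 1:
        raise ValueError("no events in the data; cannot fit a Cox model")


def _risk_sums(start, stop, event, w, X):
    """Weighted risk-set and death-set sums at every distinct event time.

    The risk set at t is {i : start_i < t <= stop_i}, so each sum over it
    is a suffix sum over rows ordered by stop minus a suffix sum over rows
    ordered by start — O(n log n) overall instead of O(n) per event time.
    Returns (times, d, s0r, s1r, s2r, s0d, s1d, s2d) with s2* flattened to
    (n_times, p, p).
    """
    n, p = X.shape
    wX = w[:, None] * X
    wXX = wX[:, :, None] * X[:, None, :]  # n x p x p
    times = np.unique(stop[event == 1])

    def suffix(by, arr):
        order = np.argsort(by, kind="stable")
        sorted_by = by[order]
        csum = np.cumsum(arr[order][::-1], axis=0)[::-1]
        idx = np.searchsorted(sorted_by, times, side="left")
        pad = np.zeros((1,) + arr.shape[1:])
        csum = np.concatenate([csum, pad], axis=0)
        return csum[idx]

    # sum over stop >= t  minus  sum over start >= t
    s0r = suffix(stop, w[:, None])[:, 0] - suffix(start, w[:, None])[:, 0]
    s1r = suffix(stop, wX) - suffix(start, wX)
    s2r = suffix(stop, wXX) - suffix(start, wXX)

    ev = event == 1
    order = np.argsort(stop[ev], kind="stable")
    dstop = stop[ev][order]
    dw, dwX, dwXX = w[ev][order], wX[ev][order], wXX[ev][order]
    bounds = np.searchsorted(dstop, times, side="left")
    d = np.diff(np.r_[bounds, len(dstop)])
    s0d = np.add.reduceat(dw, bounds)
    s1d = np.add.reduceat(dwX, bounds, axis=0)
    s2d = np.add.reduceat(dwXX, bounds, axis=0)
    return times, d, s0r, s1r, s2r, s0d, s1d, s2d


def _efron_terms(start, stop, event, X, beta, ties):
    """Log partial likelihood, gradient and information at beta."""
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # guards overflow; cancels in all ratios
    w = np.exp(eta)
    times, d, s0r, s1r, s2r, s0d, s1d, s2d = _risk_sums(start, stop, event, w, X)

    # expand one (phi, m) term per tied death: frac = l/d, l = 0..d-1
    rep = np.repeat(np.arange(len(times)), d)
    if ties == "efron":
        frac = np.concatenate([np.arange(k) / k for k in d])
    else:
        frac = np.zeros(int(d.sum()))
    phi = s0r[rep] - frac * s0d[rep]
    num1 = s1r[rep] - frac[:, None] * s1d[rep]
    m = num1 / phi[:, None]
    loglik = float(eta[event == 1].sum() - np.log(phi).sum())
    grad = X[event == 1].sum(axis=0) - m.sum(axis=0)
    s2 = (s2r[rep] - frac[:, None, None] * s2d[rep]) / phi[:, None, None]
    info = s2.sum(axis=0) - np.einsum("ij,ik->jk", m, m)
    return loglik, grad, info


def _score_residuals(start, stop, event, X, beta):
    """Per-row score residuals with Breslow baseline increments.

    U_i = delta_i (x_i - xbar(t_i))
          - w_i [ x_i Lambda0(start_i, stop_i] - B(start_i, stop_i] ]
    where Lambda0 accumulates d_t / S0(t) and B accumulates xbar(t) dLambda0.
    """
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()
    w = np.exp(eta)
    times, d, s0r, s1r, _, _, _, _ = _risk_sums(start, stop, event, w, X)
    xbar = s1r / s0r[:, None]
    dlam = d / s0r
    cumlam = np.r_[0.0, np.cumsum(dlam)]
    cumB = np.vstack([np.zeros(p), np.cumsum(xbar * dlam[:, None], axis=0)])

    # events within (start_i, stop_i]: times index in (lo_i, hi_i]
    lo = np.searchsorted(times, start, side="right")
    hi = np.searchsorted(times, stop, side="right")
    lam_i = cumlam[hi] - cumlam[lo]
    B_i = cumB[hi] - cumB[lo]
    U = -w[:, None] * (X * lam_i[:, None] - B_i)
    ev = event == 1
    t_idx = np.searchsorted(times, stop[ev])
    U[ev] += X[ev] - xbar[t_idx]
    return U


def _km_transform(start, stop, event):
    """Left-continuous Kaplan-Meier mortality just before each event time."""
    w = np.ones(len(stop))
    times, d, nrisk, _, _, _, _, _ = _risk_sums(
        start, stop, event, w, np.zeros((len(stop), 1))
    )
    surv = np.cumprod(1.0 - d / nrisk)
    g = np.r_[1.0, surv[:-1]]  # S(t-)
    return times, 1.0 - g


class CoxPH(BaseEstimator):
    """Cox proportional-hazards model on (start, stop] counting-process data.

    Scikit-learn style estimator.  ``fit`` takes a records DataFrame with
    columns ``start, stop, event``, the named covariate columns and an
    optional cluster column; fitted attributes carry trailing
    underscores (``coef_``, ``se_robust_``, ``hazard_ratios_`` ...).

    Parameters
    ----------
    covariates : list of str
        Covariate columns (numeric; encode indicators beforehand).
    cluster : str or None
        Column defining clusters for the sandwich variance (e.g. spatial
        block).  When None, rows sharing an ``id`` column are clustered
        together if present, else each row is its own cluster.
    ties : {"efron", "breslow"}
        Tie correction for the partial likelihood (Efron by default).
    """

    def __init__(
        self,
        covariates=("population",),
        cluster: str | None = None,
        ties: str = "efron",
        alpha: float = 0.05,
        max_iter: int = 50,
        gtol: float = 1e-8,
    ):
        self.covariates = covariates
        self.cluster = cluster
        self.ties = ties
        self.alpha = alpha
        self.max_iter = max_iter
        self.gtol = gtol

    def fit(self, records: pd.DataFrame, y=None) -> "CoxPH":
        covs = list(self.covariates)
        if self.ties not in ("efron", "breslow"):
            raise ValueError("ties must be 'efron' or 'breslow'")
        _validate_records(records, covs, self.cluster)
        records = records.reset_index(drop=True)
        start = records["start"].to_numpy(float)
        stop = records["stop"].to_numpy(float)
        event = records["event"].to_numpy(int)
        X = records[covs].to_numpy(float)
        n, p = X.shape

        beta = np.zeros(p)
        loglik, grad, info = _efron_terms(start, stop, event, X, beta, self.ties)
        for _ in range(self.max_iter):
            if np.linalg.norm(grad) < self.gtol:
                break
            step = np.linalg.solve(info + 1e-12 * np.eye(p), grad)
            # step halving keeps the likelihood monotone
            for _h in range(30):
                cand = beta + step
                ll_new, g_new, i_new = _efron_terms(
                    start, stop, event, X, cand, self.ties
                )
                if ll_new >= loglik - 1e-12:
                    break
                step *= 0.5
            beta, loglik, grad, info = cand, ll_new, g_new, i_new
        self.converged_ = bool(np.linalg.norm(grad) < self.gtol)
        if np.abs(beta).max() > 15:
            warnings.warn(
                "monotone partial likelihood (separation?): |beta| very large",
                UserWarning,
            )

        info_inv = np.linalg.inv(info + 1e-12 * np.eye(p))
        se_model = np.sqrt(np.diag(info_inv))

        U = _score_residuals(start, stop, event, X, beta)
        if self.cluster is not None:
            groups = records[self.cluster]
        elif "id" in records.columns:
            groups = records["id"]
        else:
            groups = pd.Series(np.arange(n))
        G = pd.DataFrame(U).groupby(groups.to_numpy()).sum().to_numpy()
        robust = info_inv @ (G.T @ G) @ info_inv
        se_robust = np.sqrt(np.diag(robust))

        se_wald = se_robust if self.cluster is not None else se_model
        z = beta / se_wald
        crit = stats.norm.ppf(1 - self.alpha / 2)

        idx = pd.Index(covs)
        self.coef_ = pd.Series(beta, index=idx)
        self.se_model_ = pd.Series(se_model, index=idx)
        self.se_robust_ = pd.Series(se_robust, index=idx)
        self.hazard_ratios_ = pd.Series(np.exp(beta), index=idx)
        self.ci_low_ = pd.Series(np.exp(beta - crit * se_wald), index=idx)
        self.ci_high_ = pd.Series(np.exp(beta + crit * se_wald), index=idx)
        self.p_values_ = pd.Series(2 * stats.norm.sf(np.abs(z)), index=idx)
        self.loglik_ = float(loglik)
        self.information_ = info
        self.n_ = n
        self.n_events_ = int(event.sum())
        self._data = (start, stop, event, X)
        return self

    def schoenfeld_test(self, time_transform: str = "km") -> pd.DataFrame:
        """Grambsch-Therneau proportionality test on scaled Schoenfeld residuals.

        Correlation-type score test of the residuals against transformed
        event times; returns per-covariate rows plus a GLOBAL row, each
        with ``chi2, df, p``.
        """
        start, stop, event, X = self._data
        p = X.shape[1]
        d_total = int(event.sum())
        if d_total < 2:
            raise ValueError("need >= 2 events for the proportionality test")
        if d_total <= p:
            raise ValueError("fewer events than covariates")
        eta = X @ self.coef_.to_numpy()
        eta = eta - eta.max()
        w = np.exp(eta)

        times, _, s0r, s1r, _, _, _, _ = _risk_sums(start, stop, event, w, X)
        if time_transform == "km":
            _, gmap = _km_transform(start, stop, event)
        elif time_transform == "identity":
            gmap = times
        elif time_transform == "rank":
            gmap = np.arange(1, len(times) + 1, dtype=float)
        else:
            raise ValueError("time_transform must be 'km', 'identity' or 'rank'")

        ev = event == 1
        t_idx = np.searchsorted(times, stop[ev])
        xbar = s1r / s0r[:, None]
        S = X[ev] - xbar[t_idx]  # d_total x p Schoenfeld residuals
        g = gmap[t_idx].astype(float)
        z = g - g.mean()
        zz = float(z @ z)

        info_inv = np.linalg.inv(self.information_ + 1e-12 * np.eye(p))
        u = S.T @ z
        rows = []
        iu = info_inv @ u
        for j, name in enumerate(self.coef_.index):
            chi2 = d_total * iu[j] ** 2 / (info_inv[j, j] * zz)
            rows.append(
                {"covariate": name, "chi2": chi2, "df": 1,
                 "p": float(stats.chi2.sf(chi2, 1))}
            )
        chi2_g = d_total * float(u @ iu) / zz
        rows.append(
            {"covariate": "GLOBAL", "chi2": chi2_g, "df": p,
             "p": float(stats.chi2.sf(chi2_g, p))}
        )
        self.schoenfeld_ = pd.DataFrame(rows).set_index("covariate")
        return self.schoenfeld_

    def result(self) -> CoxFit:
        return CoxFit(
            beta=self.coef_,
            se_model=self.se_model_,
            se_robust=self.se_robust_,
            hazard_ratios=self.hazard_ratios_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            p_values=self.p_values_,
            loglik=self.loglik_,
            n=self.n_,
            n_events=self.n_events_,
            schoenfeld=getattr(self, "schoenfeld_", None),
        )


def fit_cox(
    records: pd.DataFrame,
    covariates,
    cluster: str | None = None,
    ties: str = "efron",
) -> CoxFit:
    """Fit a Cox model and return a :class:`CoxFit` (functional wrapper)."""
    model = CoxPH(covariates=covariates, cluster=cluster, ties=ties).fit(records)
    model.schoenfeld_test()
    return model.result()


def schoenfeld_test(
    records: pd.DataFrame,
    covariates,
    cluster: str | None = None,
    ties: str = "efron",
    time_transform: str = "km",
) -> pd.DataFrame:
    """Fit + proportionality test in one call."""
    model = CoxPH(covariates=covariates, cluster=cluster, ties=ties).fit(records)
    return model.schoenfeld_test(time_transform)


def split_episodes(records: pd.DataFrame, cutpoints) -> pd.DataFrame:
    """Partition each record at the cutpoints into counting-process rows.

    The event flag moves to the terminal row only; total follow-up time
    and event count are conserved exactly.  An ``interval`` column labels
    each row with the time window it falls in (``(0,30]``-style).
    """
    cps = np.asarray(sorted(cutpoints), float)
    if len(cps) and (cps[0] <= 0 or np.any(np.diff(cps) <= 0)):
        raise ValueError("cutpoints must be positive and strictly increasing")
    rows = []
    for rec in records.to_dict("records"):
        s, e = float(rec["start"]), float(rec["stop"])
        bounds = [s] + [c for c in cps if s < c < e] + [e]
        for a, b in zip(bounds[:-1], bounds[1:]):
            r = dict(rec)
            r["start"], r["stop"] = a, b
            r["event"] = int(rec["event"]) if b == e else 0
            k = int(np.searchsorted(cps, b, side="left"))
            lo = 0.0 if k == 0 else cps[k - 1]
            hi = cps[k] if k < len(cps) else np.inf
            r["interval"] = f"({lo:g},{hi:g}]"
            rows.append(r)
    return pd.DataFrame(rows)


def subgroup_hazard(
    records: pd.DataFrame,
    environment: str,
    interval: tuple[float, float],
    cluster: str | None = "spatial_block",
    population_col: str = "population",
    ties: str = "efron",
) -> CoxFit:
    """Hazard ratio of the second vs first population within one stratum.

    Restricts to one rearing environment and one (t0, t1] time window,
    then fits population as the sole covariate with spatial-block
    clustering.  Individuals whose follow-up ends before t0 drop out;
    events after t1 are censored at t1.
    """
    t0, t1 = interval
    sub = records[records["environment"] == environment].copy()
    sub = sub[sub["stop"] > t0]
    sub["start"] = np.maximum(sub["start"], t0)
    sub["event"] = np.where(sub["stop"] <= t1, sub["event"], 0)
    sub["stop"] = np.minimum(sub["stop"], t1)
    if sub["event"].sum() < 1:
        raise ValueError(
            f"no events in environment {environment!r} on ({t0}, {t1}]"
        )
    sub["pop_ind"] = (
        sub[population_col] == indicator_level(sub[population_col])
    ).astype(float)
    model = CoxPH(covariates=["pop_ind"], cluster=cluster, ties=ties).fit(sub)
    return model.result()


def cumulative_mortality(records: pd.DataFrame, group_keys) -> pd.DataFrame:
    """1 - Kaplan-Meier survivor function per group, at event times.

    Uses lifelines' Kaplan-Meier estimator with late entry so pre-split
    and post-split records give identical curves.  Returns a long table
    ``(group columns, time, cum_mortality)``.
    """
    from lifelines import KaplanMeierFitter

    if len(records) == 0:
        raise ValueError("no records")
    out = []
    for keys, grp in records.groupby(list(group_keys)):
        kmf = KaplanMeierFitter()
        kmf.fit(
            grp["stop"], grp["event"], entry=grp["start"],
            timeline=np.unique(grp["stop"]),
        )
        sf = kmf.survival_function_.iloc[:, 0]
        for t, s in sf.items():
            row = dict(zip(group_keys, keys if isinstance(keys, tuple) else (keys,)))
            row["time"] = float(t)
            row["cum_mortality"] = float(1.0 - s)
            out.append(row)
    return pd.DataFrame(out)
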