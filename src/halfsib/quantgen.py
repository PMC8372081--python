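"""Causal decomposition of observational variance components.

In a factorial half-sib/full-sib design the observational components map
onto causal ones as

    sigma2_sire     = 1/4 V_A
    sigma2_dam      = 1/4 V_A + V_M
    sigma2_sire:dam = 1/4 V_D
    sigma2_resid    = 1/2 V_A + 3/4 V_D + V_E
    V_P = sigma2_sire + sigma2_dam + sigma2_sire:dam + sigma2_block + sigma2_resid

giving narrow-sense heritability h2 = V_A / V_P, the maternal-effect
fraction mat = V_M / V_P and the dominance fraction dom = V_D / V_P.
The heritability of plasticity uses the environment-interaction terms:
h2_pl = 4 sigma2_SxE / sigma2_P, mat_pl = (sigma2_DxE - sigma2_SxE) /
sigma2_P, dom_pl = 4 sigma2_SDxE / sigma2_P.

Transforms are applied per posterior draw and summarized as
mean-of-transforms with highest-posterior-density intervals; derived V_M
and V_E can go negative on individual draws and are reported raw with a
flag rather than truncated (truncation would bias the ratio posteriors
upward).

``anova_moments`` is an independent method-of-moments oracle: expected
mean squares of the crossed sire x dam ANOVA with replication, pooled
over breeding blocks. It requires a balanced design and exists to
cross-check the Gibbs sampler, not to replace it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mcmc import PosteriorSamples, hpdi

__all__ = [
    "VarianceComponents",
    "CausalComponents",
    "PlasticityEstimates",
    "causal_components",
    "variance_from_causal",
    "plasticity_components",
    "summarize_derived",
    "anova_moments",
]


@dataclass
class VarianceComponents:
    sigma2_sire: float
    sigma2_dam: float
    sigma2_sire_dam: float
    sigma2_block: float = 0.0
    sigma2_resid: float = 0.0
    sigma2_sireXenv: float | None = None
    sigma2_damXenv: float | None = None
    sigma2_sire_damXenv: float | None = None

    def validate(self) -> None:
        for name in ("sigma2_sire", "sigma2_dam", "sigma2_sire_dam",
                     "sigma2_block", "sigma2_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class CausalComponents:
    V_A: float
    V_M: float
    V_D: float
    V_E: float
    V_P: float
    h2: float
    mat: float
    dom: float
    negative_V_M: bool = False
    negative_V_E: bool = False


@dataclass
class PlasticityEstimates:
    h2_pl: float
    mat_pl: float
    dom_pl: float
    beta_env: float | None = None


def causal_components(vc: VarianceComponents) -> CausalComponents:
    """Map observational variance components to causal ones.

    Negative derived V_M or V_E (possible whenever sigma2_dam <
    sigma2_sire, or for noisy draws) are returned as-is and flagged.
    """
    vc.validate()
    V_A = 4.0 * vc.sigma2_sire
    V_M = vc.sigma2_dam - vc.sigma2_sire
    V_D = 4.0 * vc.sigma2_sire_dam
    V_E = vc.sigma2_resid - 2.0 * vc.sigma2_sire - 3.0 * vc.sigma2_sire_dam
    V_P = (
        vc.sigma2_sire
        + vc.sigma2_dam
        + vc.sigma2_sire_dam
        + vc.sigma2_block
        + vc.sigma2_resid
    )
    return CausalComponents(
        V_A=V_A,
        V_M=V_M,
        V_D=V_D,
        V_E=V_E,
        V_P=V_P,
        h2=V_A / V_P,
        mat=V_M / V_P,
        dom=V_D / V_P,
        negative_V_M=V_M < 0,
        negative_V_E=V_E < 0,
    )


def variance_from_causal(
    V_A: float, V_M: float, V_D: float, V_E: float, sigma2_block: float = 0.0
) -> VarianceComponents:
    """Inverse map: causal components to observational ones (for round trips)."""
    return VarianceComponents(
        sigma2_sire=V_A / 4.0,
        sigma2_dam=V_A / 4.0 + V_M,
        sigma2_sire_dam=V_D / 4.0,
        sigma2_block=sigma2_block,
        sigma2_resid=V_A / 2.0 + 0.75 * V_D + V_E,
    )


def plasticity_components(
    vc: VarianceComponents, sigma2_P: float, beta_env: float | None = None
) -> PlasticityEstimates:
    """Heritability (and analogues) of plasticity from interaction variances."""
    if sigma2_P <= 0:
        raise ValueError("sigma2_P must be > 0")
    for name in ("sigma2_sireXenv", "sigma2_damXenv", "sigma2_sire_damXenv"):
        if getattr(vc, name) is None:
            raise ValueError(f"{name} missing: fit the pooled plasticity model")
    return PlasticityEstimates(
        h2_pl=4.0 * vc.sigma2_sireXenv / sigma2_P,
        mat_pl=(vc.sigma2_damXenv - vc.sigma2_sireXenv) / sigma2_P,
        dom_pl=4.0 * vc.sigma2_sire_damXenv / sigma2_P,
        beta_env=beta_env,
    )


#: posterior draw column -> VarianceComponents field
_DRAW_COLS = {
    "var_sire": "sigma2_sire",
    "var_dam": "sigma2_dam",
    "var_sire:dam": "sigma2_sire_dam",
    "var_block": "sigma2_block",
    "var_resid": "sigma2_resid",
    "var_sire:env": "sigma2_sireXenv",
    "var_dam:env": "sigma2_damXenv",
    "var_sire:dam:env": "sigma2_sire_damXenv",
}


def summarize_derived(
    samples: PosteriorSamples,
    transform: str = "causal",
    prob: float = 0.95,
) -> pd.DataFrame:
    """Posterior mean + HPDI of derived quantities, draw by draw.

    The transform is applied to every retained draw and the summaries are
    computed on the transformed draws (mean-of-transforms, never
    transform-of-means — ratios are Jensen-sensitive).

    Returns a table with one row per derived quantity and columns
    ``mean, hpdi_low, hpdi_high, frac_negative``.
    """
    draws = samples.draws
    need = ["var_sire", "var_dam", "var_sire:dam", "var_resid"]
    if transform == "plasticity":
        need += ["var_sire:env", "var_dam:env", "var_sire:dam:env"]
    missing = [c for c in need if c not in draws.columns]
    if missing:
        raise ValueError(f"posterior lacks components: {missing}")

    s = draws["var_sire"].to_numpy()
    d = draws["var_dam"].to_numpy()
    sd = draws["var_sire:dam"].to_numpy()
    blk = draws.get("var_block", pd.Series(0.0, index=draws.index)).to_numpy()
    res = draws["var_resid"].to_numpy()

    if transform == "causal":
        V_A = 4 * s
        V_M = d - s
        V_D = 4 * sd
        V_E = res - 2 * s - 3 * sd
        V_P = s + d + sd + blk + res
        derived = {
            "V_A": V_A,
            "V_M": V_M,
            "V_D": V_D,
            "V_E": V_E,
            "V_P": V_P,
            "h2": V_A / V_P,
            "mat": V_M / V_P,
            "dom": V_D / V_P,
        }
    elif transform == "plasticity":
        sE = draws["var_sire:env"].to_numpy()
        dE = draws["var_dam:env"].to_numpy()
        sdE = draws["var_sire:dam:env"].to_numpy()
        # total phenotypic variance of the pooled model: all components
        V_P = s + d + sd + blk + res + sE + dE + sdE
        derived = {
            "h2_pl": 4 * sE / V_P,
            "mat_pl": (dE - sE) / V_P,
            "dom_pl": 4 * sdE / V_P,
            "sigma2_P": V_P,
        }
    else:
        raise ValueError(f"unknown transform {transform!r}")

    rows = []
    for name, x in derived.items():
        if np.ptp(x) == 0:
            lo = hi = float(x[0])
        else:
            lo, hi = hpdi(x, prob)
        rows.append(
            {
                "quantity": name,
                "mean": float(np.mean(x)),
                "hpdi_low": lo,
                "hpdi_high": hi,
                "frac_negative": float(np.mean(x < 0)),
            }
        )
    return pd.DataFrame(rows).set_index("quantity")


def anova_moments(table: pd.DataFrame, response: str = "trait") -> VarianceComponents:
    """Method-of-moments variance components from pooled expected mean squares.

    Within each breeding block the design must be a complete s x d cross
    with a constant number n >= 2 of offspring per family.  Sums of
    squares are pooled over blocks (sires and dams are nested in blocks):

        sigma2_sire:dam = (MS_SD - MS_W) / n
        sigma2_sire     = (MS_S  - MS_SD) / (n d)
        sigma2_dam      = (MS_D  - MS_SD) / (n s)

    Estimates may be negative; they are returned raw.
    """
    df = table[["population", "sire", "dam", "family", response]].dropna()
    fam_counts = df.groupby("family").size()
    n_off = fam_counts.iloc[0]
    if fam_counts.nunique() != 1:
        raise ValueError(
            "unbalanced design (unequal offspring per family); "
            "use the MCMC fitter for unbalanced data"
        )
    if n_off < 2:
        raise ValueError("need >= 2 offspring per family (within-family MS undefined)")

    blocks = df.groupby("sire")["dam"].agg(lambda x: tuple(sorted(set(x))))
    ss_s = ss_d = ss_sd = ss_w = 0.0
    df_s = df_d = df_sd = df_w = 0
    seen_shape = None
    # group sires sharing a dam set = one breeding block
    for dams, sire_grp in blocks.groupby(blocks):
        sires = list(sire_grp.index)
        s_n, d_n = len(sires), len(dams)
        if seen_shape is None:
            seen_shape = (s_n, d_n)
        elif seen_shape != (s_n, d_n):
            raise ValueError(
                "unbalanced design (blocks differ in sire/dam counts); "
                "use the MCMC fitter for unbalanced data"
            )
        sub = df[df["sire"].isin(sires)]
        if len(sub) != s_n * d_n * n_off:
            raise ValueError(
                "incomplete cross within a block; use the MCMC fitter"
            )
        y = sub[response].to_numpy(float)
        grand = y.mean()
        cell = sub.groupby(["sire", "dam"])[response].mean().unstack()
        sire_m = cell.mean(axis=1).to_numpy()
        dam_m = cell.mean(axis=0).to_numpy()
        cells = cell.to_numpy()
        ss_s += d_n * n_off * np.sum((sire_m - grand) ** 2)
        ss_d += s_n * n_off * np.sum((dam_m - grand) ** 2)
        inter = cells - sire_m[:, None] - dam_m[None, :] + grand
        ss_sd += n_off * np.sum(inter**2)
        cell_mean_per_row = sub.groupby(["sire", "dam"])[response].transform("mean")
        ss_w += np.sum((sub[response] - cell_mean_per_row) ** 2)
        df_s += s_n - 1
        df_d += d_n - 1
        df_sd += (s_n - 1) * (d_n - 1)
        df_w += s_n * d_n * (n_off - 1)

    ms_s, ms_d = ss_s / df_s, ss_d / df_d
    ms_sd, ms_w = ss_sd / df_sd, ss_w / df_w
    s_n, d_n = seen_shape
    return VarianceComponents(
        sigma2_sire=(ms_s - ms_sd) / (n_off * d_n),
        sigma2_dam=(ms_d - ms_sd) / (n_off * s_n),
        sigma2_sire_dam=(ms_sd - ms_w) / n_off,
        sigma2_block=0.0,
        sigma2_resid=ms_w,
    )
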