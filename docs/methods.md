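# Methods

## The breeding design and what it identifies

The package models an NC-II factorial mating design: within each breeding
block, every sire is crossed with every dam, so offspring form paternal
half-sib, maternal half-sib and full-sib families. Under the standard
quantitative-genetic covariance structure (half-sibs share ¼V_A; full sibs
share ½V_A + ¼V_D plus maternal effects), the observational variance
components of the mixed model map onto causal components as

    σ²_sire     = ¼ V_A
    σ²_dam      = ¼ V_A + V_M
    σ²_sire:dam = ¼ V_D
    σ²_resid    = ½ V_A + ¾ V_D + V_E
    V_P         = σ²_sire + σ²_dam + σ²_sire:dam + σ²_block + σ²_resid

with h² = V_A/V_P, mat = V_M/V_P, dom = V_D/V_P. The canonical layout is
2 populations × 4 blocks × (8 sires × 2 dams) = 128 full-sib families:
many sires per block maximizes power for V_A at the cost of precision on
the dam (maternal) component — dam-derived quantities carry wide intervals
by construction, and the package reports them with HPDIs rather than
pretending otherwise.

Genotype-by-environment structure is parameterized as main effect plus an
independent interaction deviation per (parent, environment) cell. For two
environments this is equivalent to correlated environment-specific effects
(σ²_S×E = (1−r)·σ²_S,env). The heritability of plasticity is
h²_pl = 4σ²_S×E/σ²_P, with mat_pl = (σ²_D×E − σ²_S×E)/σ²_P and
dom_pl = 4σ²_SD×E/σ²_P. The denominator σ²_P is taken from the pooled
cross-environment model and includes *all* of its variance components
(main, interaction, block, residual) — the most inclusive reading where
the convention is ambiguous; it is computed per draw inside
`summarize_derived`, so a different convention is a one-line change on the
returned draws.

Block variance enters V_P but never a causal numerator: spatial block is an
environmental stratum, not a genetic one.

## Gibbs sampler

`MixedModelGibbs` fits y = Xβ + Σ_t Z_t u_t + e with flat priors on β and
independent inverse-gamma(0.001, 0.001) priors on every variance — weak
enough that at the design sizes used here the data dominate. All full
conditionals are conjugate (normal for β and each random-effect vector,
inverse-gamma for each variance), and group-indexed `bincount`
accumulation makes a 5,000-iteration chain on ~800 observations take well
under a second. Optional parameter expansion (a redundant multiplicative
scalar with a standard-normal prior per term) is exposed for chains that
mix poorly near a zero variance; the default is the plain conjugate
sampler, which the recovery and coverage checks show is adequate at these
sizes.

Binary traits use Albert–Chib probit augmentation: latent liabilities are
drawn from truncated normals via the inverse-CDF, the Gaussian machinery
runs on the liabilities, and the residual variance is fixed at 1 (the
threshold-model identifiability convention). Binomial success/failure
counts per rearing unit are expanded to Bernoulli rows sharing a
unit-level random effect and fitted through the same sampler. This is a
probit, not logit, treatment of the count model: probit augmentation is
exactly conjugate, and liability-scale variance ratios are comparable to
logit-scale ones after the usual ~(π²/3 vs 1) residual-scale adjustment;
the choice is deliberate and surfaced here rather than hidden.

Posterior summaries: HPDI is the shortest contiguous window containing
⌈prob·n⌉ sorted draws (lowest start on ties); pMCMC is
2·min(frac ≤ 0, frac > 0) floored at 2/n; ESS uses Geyer's initial
positive-sequence estimator. Fits warn when any parameter's ESS drops
below 200. Derived quantities (h², h²_pl, …) are always transformed per
draw and summarized afterwards — mean-of-transforms, never
transform-of-means, because ratios are Jensen-sensitive. Negative derived
V_M or V_E draws are reported raw with a `frac_negative` flag; truncating
them at zero would bias the ratio posteriors upward.

`anova_moments` is the independent oracle: pooled expected mean squares of
the within-block crossed sire × dam ANOVA, σ̂²_SD = (MS_SD − MS_W)/n,
σ̂²_S = (MS_S − MS_SD)/(nd), σ̂²_D = (MS_D − MS_SD)/(ns). It requires
balance, may return negative estimates (reported raw), and exists to
cross-check the sampler, never to replace it on real (unbalanced) data.

## Survival workflow

`CoxPH` maximizes the Efron (default) or Breslow partial likelihood by
Newton–Raphson with step halving, to gradient norm < 1e-8. Records are
counting-process rows with half-open (start, stop] intervals; the risk set
at t is {start < t ≤ stop}, so a death exactly on a cutpoint day belongs
to the earlier interval. Risk-set sums are computed as suffix sums over
stop-ordered minus start-ordered rows (O(n log n) per evaluation), which
is what makes 500-replicate calibration experiments cheap.

Spatial-block clustering is handled by the sandwich variance on
cluster-aggregated score residuals, not by a frailty term. Score residuals
use Breslow-form baseline increments even under Efron point estimates —
the same light-ties simplification R's `survival` documents; Monte-Carlo
calibration confirms the resulting tests hold their level, and on untied
data the robust SEs match `lifelines` to machine precision.

The proportionality diagnostic is the Grambsch–Therneau correlation test
of Schoenfeld residuals against transformed event times, with the V(t) ≈
Ī/d approximation: per covariate χ²_j = d([Ī⁻¹u]_j)²/([Ī⁻¹]_jj Σz²),
global χ² = d·u'Ī⁻¹u/Σz², where u = Σ(g_k − ḡ)s_k. The default time
transform is the left-continuous Kaplan–Meier mortality (1 − S(t−));
identity and rank are exposed. Under proportional hazards the test's
type-I error calibrates to 0.05 ± 0.02 at n = 700.

`split_episodes` partitions each record at fixed cutpoints, the event flag
moving to the terminal row; person-time and event counts are conserved
exactly (tested on randomized fixtures). `subgroup_hazard` restricts to
one environment and one interval and fits population as the sole covariate
with block clustering — the hazard ratio then reads directly as "focal
population's mortality risk relative to the reference in that environment
and window". Cumulative mortality curves are 1 − KM via `lifelines` with
late entry, so split and unsplit records give identical curves.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical structure* of a two-population
reciprocal-transplant field study: the factorial pedigree, embryonic
units in 2 water treatments × 3 replicate shelves (768 potential units),
individually reared larvae in 6 spatial blocks per environment with the
rearing environment equal to the embryonic water source, stochastic
attrition (whole-cross failures, per-unit shortfalls, optionally whole
breeding blocks withheld from the field stage), Gaussian/liability traits
built from independent normal effects at stated variances, binomial embryo
survival with a per-embryo count covariate, and piecewise-exponential
survival times with a hazard change-point and end-of-study censoring.

Because the source study estimates rather than simulates, no generating
effect sizes exist to copy; defaults were chosen once as field-realistic:
trait variance components summing to σ²_P ≈ 1 with h² = 0.3-scale additive
variance, maternal and dominance fractions of similar magnitude, baseline
hazards of a few events per thousand animal-days with a day-30 change and
~104-day censoring, giving survival fractions in the 55–75% range typical
of larval cohorts. What the generators do *not* emulate: selection and
viability culling before measurement, non-normal effect distributions,
temporal trends within intervals other than the change-point, shared-
container competition, or correlated maternal-environmental transfer.
Passing tests therefore demonstrate that the estimators recover the truth
*under the model's own assumptions* at the study's design size — they
bound estimator error, not model misspecification on real field data.

## Numerical choices and problem sizes

- Chains: 5,000 iterations, 1,000 burn-in, thin 1 for headline checks —
  enough for ESS of several hundred on variance components at these sizes.
- Recovery experiments: 20 replicates per h² ∈ {0.1, 0.3, 0.5} for bias
  (tolerance ±0.15, reflecting the sampling variance of a 128-family
  design), 50 replicates for 95%-HPDI coverage (threshold 85%).
- Oracle agreement: 15 replicate datasets, criterion |mean difference| <
  3 Monte-Carlo SEs per component.
- Schoenfeld calibration: 500 simulations at n = 700, ~70% events.
- Degenerate inputs: constant responses warn (zero-information), all-0/1
  binary responses warn (separation) but the chain remains proper because
  the prior does; Cox fits with |β| > 15 warn of monotone likelihood;
  `anova_moments` refuses single-replicate or unbalanced layouts and
  points to the MCMC fitter.
- Seeding: one user seed per run; the pipeline spawns per-stage child
  seeds via `numpy.random.SeedSequence`, so stages can be rerun in
  isolation and reruns are byte-identical.

## Known limitations

- The dam side of an 8-sire × 2-dam block is weakly informative; maternal
  components have wide HPDIs and their point estimates shrink noticeably
  under the prior in small subsets. This mirrors the design, not a sampler
  defect.
- Environment-specific genetic variances come from per-environment subset
  fits; the pooled plasticity model assumes a common residual variance
  across environments.
- The binomial-count model is probit, not logit; odds-scale covariate
  effects from logit fits are not directly comparable without rescaling.
- No epistatic variance, genotype–environment covariance, or
  cross-environment genetic correlation matrices; no frailty survival
  models or time-varying covariates beyond episode splitting.
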