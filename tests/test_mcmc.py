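"""Gibbs sampler: posterior summaries, conjugacy, determinism, warnings."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import halfsib as hs
from halfsib.mcmc import effective_sample_size, expand_binomial_counts


def iid_table(n, seed, mu=0.0, sd=1.0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "individual_id": np.arange(n).astype(str),
            "family": "f0",
            "sire": np.repeat([f"S{i}" for i in range(10)], n // 10),
            "dam": "D0",
            "population": "REF",
            "environment": "REF",
            "spatial_block": 1,
            "trait": rng.normal(mu, sd, n),
        }
    )


class TestHpdi:
    def test_uniform_integer_window(self):
        lo, hi = hs.hpdi(np.arange(1, 101), 0.95)
        assert hi - lo == 94 and lo == 1.0

    def test_constant_draws_zero_width(self):
        assert hs.hpdi(np.full(50, 3.3), 0.95) == (3.3, 3.3)

    def test_normal_matches_central_interval(self):
        x = np.random.default_rng(0).normal(size=100_000)
        lo, hi = hs.hpdi(x, 0.95)
        assert abs(lo + 1.96) < 0.03 and abs(hi - 1.96) < 0.03
        assert abs((lo + hi) / 2) < 0.03  # symmetric about the mean

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            hs.hpdi([1.0], 0.95)


class TestPmcmc:
    def test_floor_at_two_over_n(self):
        assert hs.pmcmc(np.arange(1, 101)) == 2 / 100

    def test_symmetric_near_one(self):
        x = np.r_[np.arange(-50, 0), np.arange(1, 51)]
        assert hs.pmcmc(x) == 1.0

    def test_unit_shifted_normal_tail(self):
        x = np.random.default_rng(1).normal(1, 1, 100_000)
        assert abs(hs.pmcmc(x) - 2 * stats.norm.cdf(-1)) < 0.01


def test_flat_prior_matches_least_squares():
    """No random structure: posterior mean of beta ~ OLS solution."""
    rng = np.random.default_rng(2)
    n = 500
    tab = iid_table(n, 2)
    tab["cov"] = rng.normal(size=n)
    tab["trait"] = 1.0 + 0.5 * tab["cov"] + rng.normal(0, 1, n)
    m = hs.MixedModelGibbs(
        response="trait",
        fixed_terms=["intercept", "cov"],
        random_terms=["sire"],  # true variance 0
        n_iter=3000,
        burn_in=500,
        seed=3,
    ).fit(tab)
    X = np.column_stack([np.ones(n), tab["cov"]])
    ols = np.linalg.lstsq(X, tab["trait"], rcond=None)[0]
    post = m.posterior_.mean()
    assert abs(post["intercept"] - ols[0]) < 0.05
    assert abs(post["cov"] - ols[1]) < 0.05
    # residual variance ~ 1, dummy sire variance near zero
    assert abs(post["var_resid"] - 1.0) < 0.1
    assert post["var_sire"] < 0.05


def test_seed_determinism_and_chain_invariance():
    tab = iid_table(400, 5)
    kw = dict(response="trait", random_terms=["sire"], burn_in=500)
    a = hs.MixedModelGibbs(n_iter=2500, seed=7, **kw).fit(tab)
    b = hs.MixedModelGibbs(n_iter=2500, seed=7, **kw).fit(tab)
    pd.testing.assert_frame_equal(a.posterior_.draws, b.posterior_.draws)
    # doubling the chain moves the posterior mean < 2 MC standard errors
    c = hs.MixedModelGibbs(n_iter=4500, seed=8, **kw).fit(tab)
    for par in ("intercept", "var_resid"):
        x = a.posterior_[par]
        mcse = x.std() / np.sqrt(effective_sample_size(x))
        assert abs(x.mean() - c.posterior_[par].mean()) < 4 * mcse


def test_thinning_and_retained_count():
    tab = iid_table(100, 1)
    m = hs.MixedModelGibbs(
        response="trait", random_terms=["sire"], n_iter=1000, burn_in=200,
        thin=4, seed=0,
    ).fit(tab)
    assert len(m.posterior_) == 200


def test_posterior_variances_nonnegative():
    tab = iid_table(200, 3)
    m = hs.MixedModelGibbs(
        response="trait", random_terms=["sire"], n_iter=1500, burn_in=300, seed=1
    ).fit(tab)
    assert (m.posterior_.draws[["var_sire", "var_resid"]] > 0).all().all()


def test_constant_response_warns():
    tab = iid_table(100, 1)
    tab["trait"] = 2.0
    with pytest.warns(UserWarning, match="constant"):
        hs.MixedModelGibbs(
            response="trait", random_terms=["sire"], n_iter=400, burn_in=100,
            seed=0,
        ).fit(tab)


def test_specification_errors():
    tab = iid_table(50, 1)
    with pytest.raises(ValueError, match="empty"):
        hs.MixedModelGibbs(response="trait").fit(tab.iloc[:0])
    with pytest.raises(ValueError, match="unknown random term"):
        hs.MixedModelGibbs(response="trait", random_terms=["clutch"]).fit(tab)
    with pytest.raises(ValueError, match="missing"):
        hs.MixedModelGibbs(response="nope").fit(tab)
    with pytest.raises(ValueError):
        hs.MixedModelGibbs(response="trait", n_iter=100, burn_in=200).fit(tab)


class TestThreshold:
    def test_balanced_prevalence_centers_intercept(self):
        tab = iid_table(600, 4)
        tab["y"] = (np.arange(600) % 2).astype(int)
        m = hs.MixedModelGibbs(
            response="y", response_family="threshold", random_terms=["sire"],
            n_iter=2500, burn_in=500, seed=2,
        ).fit(tab)
        assert abs(m.posterior_.mean()["intercept"]) < 0.15
        assert (m.posterior_["var_resid"] == 1.0).all()

    def test_nonbinary_rejected(self):
        tab = iid_table(50, 1)
        tab["y"] = np.arange(50)
        with pytest.raises(ValueError, match="binary"):
            hs.MixedModelGibbs(response="y", response_family="threshold").fit(tab)

    def test_all_zero_warns_and_drives_intercept_negative(self):
        tab = iid_table(200, 1)
        tab["y"] = 0
        with pytest.warns(UserWarning, match="separation"):
            m = hs.MixedModelGibbs(
                response="y", response_family="threshold", random_terms=["sire"],
                n_iter=800, burn_in=200, seed=0,
            ).fit(tab)
        assert m.posterior_.mean()["intercept"] < -1.0
        assert np.isfinite(m.posterior_.draws.to_numpy()).all()


class TestBinomialCounts:
    def make_units(self, n_units, n_initial, frac, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "family": [f"f{i % 8}" for i in range(n_units)],
                "sire": [f"S{i % 8}" for i in range(n_units)],
                "dam": [f"D{i % 4}" for i in range(n_units)],
                "population": "REF",
                "treatment": "REF",
                "replicate": np.arange(n_units),
                "n_initial": n_initial,
                "n_survived": rng.binomial(n_initial, frac, n_units),
            }
        )

    def test_expansion_bookkeeping(self):
        units = self.make_units(10, 20, 0.5)
        rows = expand_binomial_counts(units)
        assert len(rows) == 200
        assert rows.groupby("unit")["survived"].sum().sum() == units["n_survived"].sum()

    def test_all_survive_gives_probability_near_one(self):
        units = self.make_units(30, 25, 1.0)
        units["n_survived"] = units["n_initial"]
        with pytest.warns(UserWarning):
            m = hs.MixedModelGibbs(
                response="n_survived", response_family="binomial_counts",
                random_terms=["unit"], n_iter=1200, burn_in=300, seed=1,
            ).fit(units)
        assert stats.norm.cdf(m.posterior_.mean()["intercept"]) > 0.98

    def test_survived_cannot_exceed_initial(self):
        units = self.make_units(5, 10, 0.5)
        units.loc[0, "n_survived"] = 11
        with pytest.raises(ValueError, match="exceeds"):
            expand_binomial_counts(units)


def test_ess_sane_on_white_noise():
    x = np.random.default_rng(0).normal(size=4000)
    assert effective_sample_size(x) > 2500
    # strongly autocorrelated chain has far fewer effective draws
    ar = np.add.accumulate(x) / np.sqrt(np.arange(1, 4001))
    assert effective_sample_size(ar) < 500
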