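"""Cox partial likelihood, robust variance, diagnostics, episode splitting."""

import numpy as np
import pandas as pd
import pytest

import halfsib as hs
from halfsib.survival import _efron_terms

from conftest import exp_survival_frame


class TestFit:
    def test_two_group_hazard_ratio_recovery(self):
        df = exp_survival_frame(1000, rate=0.02, hr=2.0, censor=80, seed=0)
        fit = hs.fit_cox(df, ["x"])
        assert 1.8 < fit.hazard_ratios["x"] < 2.2
        assert fit.ci_low["x"] < 2.0 < fit.ci_high["x"]

    def test_gradient_vanishes_and_information_pd(self):
        df = exp_survival_frame(400, rate=0.03, hr=1.5, censor=60, seed=1)
        m = hs.CoxPH(covariates=["x"]).fit(df)
        start = df["start"].to_numpy()
        stop = df["stop"].to_numpy()
        ev = df["event"].to_numpy()
        X = df[["x"]].to_numpy(float)
        _, grad, info = _efron_terms(start, stop, ev, X, m.coef_.to_numpy(), "efron")
        assert np.linalg.norm(grad) < 1e-8
        assert np.all(np.linalg.eigvalsh(info) > 0)

    def test_log_half_maps_to_hr_half(self):
        """beta = ln(0.5): the focal population dies at half the rate."""
        assert np.isclose(np.exp(np.log(0.5)), 0.5)
        df = exp_survival_frame(2000, rate=0.03, hr=0.5, censor=80, seed=3)
        fit = hs.fit_cox(df, ["x"])
        assert 0.42 < fit.hazard_ratios["x"] < 0.58

    def test_efron_equals_breslow_without_ties(self):
        df = exp_survival_frame(300, rate=0.03, hr=1.5, censor=60, seed=2)
        df["stop"] += np.random.default_rng(0).uniform(0, 1e-6, len(df))  # de-tie
        a = hs.CoxPH(covariates=["x"], ties="efron").fit(df)
        b = hs.CoxPH(covariates=["x"], ties="breslow").fit(df)
        assert np.allclose(a.coef_, b.coef_, atol=1e-7)

    def test_matches_lifelines(self):
        from lifelines import CoxPHFitter

        df = exp_survival_frame(500, rate=0.02, hr=1.8, censor=70, seed=4)
        m = hs.CoxPH(covariates=["x"], cluster="blk").fit(df)
        cf = CoxPHFitter().fit(
            df[["stop", "event", "x", "blk"]], "stop", "event",
            robust=True, cluster_col="blk",
        )
        assert np.allclose(m.coef_["x"], cf.params_["x"], atol=1e-5)
        assert np.allclose(m.se_robust_["x"], cf.summary["se(coef)"]["x"], rtol=0.05)

    def test_error_paths(self):
        df = exp_survival_frame(100, rate=0.02, hr=1.0, censor=50, seed=5)
        no_events = df.assign(event=0)
        with pytest.raises(ValueError, match="no events"):
            hs.CoxPH(covariates=["x"]).fit(no_events)
        with pytest.raises(ValueError, match="constant"):
            hs.CoxPH(covariates=["x"]).fit(df.assign(x=1.0))
        with pytest.raises(ValueError, match="start < stop"):
            hs.CoxPH(covariates=["x"]).fit(df.assign(start=df["stop"]))

    def test_separation_warns(self):
        # group 1 all dies early, group 0 all censored: monotone likelihood
        df = pd.DataFrame(
            {
                "start": 0.0,
                "stop": np.r_[np.linspace(1, 5, 30), np.full(30, 50.0)],
                "event": np.r_[np.ones(30, int), np.zeros(30, int)],
                "x": np.r_[np.ones(30), np.zeros(30)],
            }
        )
        with pytest.warns(UserWarning, match="separation"):
            hs.CoxPH(covariates=["x"]).fit(df)

    def test_cluster_robust_se_exceeds_model_se_with_frailty(self):
        """Shared block frailty inflates the sandwich SE above the naive one."""
        rng = np.random.default_rng(7)
        n, nblk = 800, 16
        blk = np.arange(n) % nblk
        frail = rng.normal(0, 0.8, nblk)[blk]
        x = (np.arange(n) % 2).astype(float)
        t = rng.exponential(1 / (0.02 * np.exp(0.4 * x + frail)))
        df = pd.DataFrame(
            {
                "start": 0.0, "stop": np.minimum(t, 60),
                "event": (t <= 60).astype(int), "x": x, "blk": blk,
            }
        )
        m = hs.CoxPH(covariates=["x"], cluster="blk").fit(df)
        assert m.se_robust_["x"] > m.se_model_["x"]


class TestSchoenfeld:
    def test_residuals_sum_to_zero_at_optimum(self):
        df = exp_survival_frame(300, rate=0.03, hr=1.5, censor=60, seed=6)
        m = hs.CoxPH(covariates=["x"]).fit(df)
        start, stop = df["start"].to_numpy(), df["stop"].to_numpy()
        ev, X = df["event"].to_numpy(), df[["x"]].to_numpy(float)
        _, grad, _ = _efron_terms(start, stop, ev, X, m.coef_.to_numpy(), "breslow")
        # sum of Schoenfeld residuals = Breslow score at beta-hat ~ 0
        assert np.abs(grad).max() < 1e-4

    def test_detects_reversing_hazard(self):
        """Sign-reversing HR at day 30 is flagged at n=700."""
        rng = np.random.default_rng(8)
        n = 700
        x = (np.arange(n) % 2).astype(float)
        truth = hs.HazardTruth(
            baseline_rate=0.02, log_hr_pop=(0.8, -0.8), cutpoints=(30.0,),
            censor_time=90.0,
        )
        p = pd.DataFrame(
            {
                "individual_id": np.arange(n).astype(str),
                "family": "f", "sire": "s", "dam": "d",
                "population": np.where(x > 0, "ASH", "REF"),
                "environment": "REF", "spatial_block": 1, "container": 1,
            }
        )
        tab = hs.simulate_survival(p, truth, seed=9)
        rec = tab.rename(columns={"time": "stop"}).assign(start=0.0, x=x)
        m = hs.CoxPH(covariates=["x"]).fit(rec)
        assert m.schoenfeld_test("km").loc["x", "p"] < 0.01

    def test_transform_validation_and_event_requirement(self):
        df = exp_survival_frame(200, rate=0.03, hr=1.5, censor=60, seed=10)
        m = hs.CoxPH(covariates=["x"]).fit(df)
        with pytest.raises(ValueError, match="time_transform"):
            m.schoenfeld_test("sqrt")
        tiny = df.head(40).copy()
        tiny["event"] = 0
        tiny.loc[tiny.index[0], "event"] = 1
        m2_data = tiny
        with pytest.raises(ValueError):
            hs.CoxPH(covariates=["x"]).fit(m2_data).schoenfeld_test()


class TestSplitEpisodes:
    def test_definition_examples(self):
        rec = pd.DataFrame(
            {
                "id": ["a", "b", "c"],
                "start": [0.0, 0.0, 0.0],
                "stop": [40.0, 20.0, 104.0],
                "event": [1, 1, 0],
            }
        )
        sp = hs.split_episodes(rec, [30.0])
        a = sp[sp["id"] == "a"]
        assert len(a) == 2
        assert a.iloc[0][["start", "stop", "event"]].tolist() == [0.0, 30.0, 0]
        assert a.iloc[1][["start", "stop", "event"]].tolist() == [30.0, 40.0, 1]
        b = sp[sp["id"] == "b"]
        assert len(b) == 1 and b.iloc[0]["event"] == 1
        c = sp[sp["id"] == "c"]
        assert len(c) == 2 and (c["event"] == 0).all()
        assert c.iloc[1]["stop"] == 104.0

    def test_conservation_on_random_fixtures(self):
        rng = np.random.default_rng(11)
        for trial in range(20):
            n = 50
            stop = rng.uniform(1, 120, n)
            rec = pd.DataFrame(
                {
                    "id": np.arange(n), "start": 0.0, "stop": stop,
                    "event": rng.integers(0, 2, n),
                }
            )
            cuts = np.sort(rng.uniform(5, 100, rng.integers(1, 4)))
            sp = hs.split_episodes(rec, cuts)
            assert np.isclose(
                (sp["stop"] - sp["start"]).sum(), rec["stop"].sum(), atol=1e-9
            )
            assert sp["event"].sum() == rec["event"].sum()
            # the terminal row of each individual carries the event flag
            last = sp.sort_values("stop").groupby("id").tail(1)
            assert last.set_index("id")["event"].sort_index().equals(
                rec.set_index("id")["event"].sort_index()
            )

    def test_bad_cutpoints(self):
        rec = pd.DataFrame({"start": [0.0], "stop": [10.0], "event": [1]})
        with pytest.raises(ValueError):
            hs.split_episodes(rec, [-5.0])


@pytest.fixture(scope="module")
def interaction_records(paper_design):
    units = hs.allocate_embryo_units(paper_design, 2, 3)
    p = hs.allocate_field(paper_design, 6, seed=0, units=units)
    truth = hs.HazardTruth(
        baseline_rate=(0.006, 0.004),
        log_hr_env=(0.2, 0.5),
        log_hr_interaction=(0.0, np.log(0.3)),
        cutpoints=(30.0,),
        censor_time=104.0,
    )
    tab = hs.simulate_survival(p, truth, seed=12)
    return tab.rename(columns={"time": "stop"}).assign(start=0.0)


class TestSubgroup:
    def test_recovers_late_interval_interaction(self, interaction_records):
        fit = hs.subgroup_hazard(interaction_records, "ASH", (30.0, 104.0))
        assert 0.2 < fit.hazard_ratios.iloc[0] < 0.45
        null_fit = hs.subgroup_hazard(interaction_records, "REF", (30.0, 104.0))
        assert null_fit.ci_low.iloc[0] < 1.0 < null_fit.ci_high.iloc[0]

    def test_no_event_stratum_errors(self, interaction_records):
        rec = interaction_records.assign(event=0)
        with pytest.raises(ValueError, match="no events"):
            hs.subgroup_hazard(rec, "ASH", (30.0, 104.0))

    def test_cutpoint_sensitivity_is_smooth(self, interaction_records):
        """Nearby splits around the true day-30 change give similar HRs."""
        hrs = [
            hs.subgroup_hazard(
                interaction_records, "ASH", (c, 104.0)
            ).hazard_ratios.iloc[0]
            for c in (21.0, 30.0, 35.0, 45.0)
        ]
        # all splits agree qualitatively (protective effect), and moving the
        # cutpoint by a few days never jumps the estimate
        assert all(hr < 1 for hr in hrs)
        ratios = [max(a, b) / min(a, b) for a, b in zip(hrs, hrs[1:])]
        assert max(ratios) < 1.6


class TestCumulativeMortality:
    def test_degenerate_curves(self):
        rec = pd.DataFrame(
            {
                "start": 0.0, "stop": [5.0, 6.0, 7.0], "event": 0,
                "population": "REF",
            }
        )
        c = hs.cumulative_mortality(rec, ["population"])
        assert (c["cum_mortality"] == 0).all()
        rec2 = rec.assign(stop=1.0, event=1)
        c2 = hs.cumulative_mortality(rec2, ["population"])
        assert c2["cum_mortality"].iloc[-1] == 1.0
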