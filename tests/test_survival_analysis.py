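import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from gliomorph.survival_analysis import (
    AnalysisConfig,
    AnalysisError,
    analysis_report,
    build_episodes,
    concordance_index,
    cox_fit,
    group_compare,
    km_curves,
    normality_screen,
    proportionality_check,
    spearman,
)
from gliomorph.synthetic_cohort import CohortSpec, generate_cohort


class TestNormalityScreen:
    def test_lognormal_rejected(self):
        rng = np.random.default_rng(0)
        out = normality_screen(np.exp(rng.standard_normal(5000)))
        assert out["normal"] is False
        assert out["p"] < 0.05

    def test_normal_accepted(self):
        rng = np.random.default_rng(1)
        out = normality_screen(rng.standard_normal(5000))
        assert out["normal"] is True

    def test_too_few_raises(self):
        with pytest.raises(AnalysisError):
            normality_screen([1.0, 2.0])

    def test_constant_raises(self):
        with pytest.raises(AnalysisError, match="zero variance"):
            normality_screen([3.0] * 10)


class TestGroupCompare:
    def test_identical_samples_p_near_one(self):
        v = list(range(10)) * 2
        g = ["a"] * 10 + ["b"] * 10
        out = group_compare(v, g)
        assert out["test"] == "mann_whitney"
        assert out["p"] > 0.99

    def test_exact_separated_samples(self):
        # U = 0; exact two-sided p for n=3,3 is 2/C(6,3) = 0.1
        out = group_compare([1, 2, 3, 101, 102, 103], ["a"] * 3 + ["b"] * 3)
        assert out["statistic"] == 0.0 or out["statistic"] == 9.0
        assert out["p"] == pytest.approx(0.1)

    def test_three_groups_kruskal(self):
        v = [1, 2, 3, 4, 5, 6, 7, 8, 9]
        g = ["a", "a", "a", "b", "b", "b", "c", "c", "c"]
        out = group_compare(v, g)
        assert out["test"] == "kruskal_wallis"
        assert set(out["group_medians"]) == {"a", "b", "c"}

    def test_single_group_raises(self):
        with pytest.raises(AnalysisError):
            group_compare([1, 2, 3], ["a", "a", "a"])


class TestSpearman:
    def test_monotone_increasing(self):
        out = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert out["rs"] == pytest.approx(1.0)

    def test_monotone_decreasing(self):
        out = spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert out["rs"] == pytest.approx(-1.0)

    def test_hand_ranked_oracle(self):
        x = [1, 2, 3, 4, 5]
        y = [5, 6, 7, 8, 7]
        # independent oracle: Pearson correlation of mid-ranks
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y)["rs"] == pytest.approx(expected, abs=1e-12)

    def test_constant_raises(self):
        with pytest.raises(AnalysisError, match="constant"):
            spearman([1, 1, 1], [1, 2, 3])


class TestBuildEpisodes:
    def _cohort(self, rows):
        return pd.DataFrame(
            rows, columns=["case_id", "survival_days", "event", "kps_post"]
        )

    def test_early_event_single_episode(self):
        ep = build_episodes(self._cohort([("a", 100.0, True, 80)]))
        assert len(ep) == 1
        row = ep.iloc[0]
        assert (row["start"], row["stop"]) == (0.0, 100.0)
        assert row["event"] and row["kps_early"] == 80 and row["kps_late"] == 0

    def test_censored_late_two_episodes(self):
        ep = build_episodes(self._cohort([("a", 400.0, False, 70)]))
        expected = pd.DataFrame(
            {
                "case_id": ["a", "a"],
                "kps_post": [70, 70],
                "start": [0.0, 300.0],
                "stop": [300.0, 400.0],
                "event": [False, False],
                "kps_early": [70.0, 0.0],
                "kps_late": [0.0, 70.0],
            }
        )
        pd.testing.assert_frame_equal(ep, expected, check_like=True)

    def test_event_exactly_at_split(self):
        ep = build_episodes(self._cohort([("a", 300.0, True, 90)]))
        assert len(ep) == 1
        assert ep.iloc[0]["event"]
        assert ep.iloc[0]["stop"] == 300.0

    def test_followup_and_events_conserved(self):
        cohort = generate_cohort(CohortSpec(n=300, seed=4))
        ep = build_episodes(cohort)
        total = (ep["stop"] - ep["start"]).groupby(ep["case_id"]).sum()
        merged = cohort.set_index("case_id")["survival_days"]
        pd.testing.assert_series_equal(
            total.sort_index(), merged.sort_index(), check_names=False
        )
        assert ep["event"].sum() == cohort["event"].sum()
        # events only in last episode per case
        last = ep.groupby("case_id").tail(1)
        assert last["event"].sum() == ep["event"].sum()

    def test_negative_times_raise(self):
        with pytest.raises(AnalysisError, match="negative"):
            build_episodes(self._cohort([("a", -1.0, True, 80)]))


def exact_partial_likelihood(beta, times, events, x):
    """Independent brute-force log partial likelihood (no ties)."""
    ll = 0.0
    for i in np.flatnonzero(events):
        at_risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[at_risk])))
    return ll


def tiny_instances():
    """All <=5-subject binary-covariate instances with interior MLE."""
    out = []
    for n in (3, 4, 5):
        times = np.arange(1.0, n + 1.0)
        for groups in itertools.product([0, 1], repeat=n):
            g = np.array(groups, dtype=float)
            if g.min() == g.max():
                continue
            for censor_last in (False, True):
                events = np.ones(n, dtype=bool)
                if censor_last:
                    events[-1] = False
                if events.sum() < 2:
                    continue
                res = optimize.minimize_scalar(
                    lambda b: -exact_partial_likelihood(b, times, events, g),
                    bounds=(-12, 12), method="bounded",
                )
                if abs(res.x) < 6.0:  # interior maximum: no separation
                    out.append((times, events, g, res.x))
    return out


class TestCoxFit:
    def test_brute_force_oracle_equivalence(self):
        instances = tiny_instances()
        assert len(instances) >= 20
        for times, events, g, beta_star in instances:
            df = pd.DataFrame(
                {"survival_days": times, "event": events, "x": g}
            )
            fit = cox_fit(df, ["x"])
            assert fit.table.loc["x", "coef"] == pytest.approx(
                beta_star, abs=1e-4
            )

    def test_breslow_equals_efron_without_ties(self):
        df = pd.DataFrame(
            {
                "survival_days": [1.0, 2.0, 3.0, 4.0, 5.0],
                "event": [True, True, True, True, False],
                "x": [1.0, 0.0, 1.0, 0.0, 0.0],
            }
        )
        fe = cox_fit(df, ["x"], ties="efron")
        fb = cox_fit(df, ["x"], ties="breslow")
        assert fe.table.loc["x", "coef"] == pytest.approx(
            fb.table.loc["x", "coef"], abs=1e-8
        )

    def test_single_episode_table_equals_cohort(self):
        cohort = generate_cohort(CohortSpec(n=300, seed=9))
        as_episodes = cohort.assign(
            start=0.0, stop=cohort["survival_days"]
        ).drop(columns=["survival_days"])
        f1 = cox_fit(cohort, ["si", "age"])
        f2 = cox_fit(as_episodes, ["si", "age"])
        np.testing.assert_allclose(f1.params, f2.params, atol=1e-8)
        assert f1.c_index == pytest.approx(f2.c_index, abs=1e-12)

    def test_null_coverage(self):
        """CI covers 1.0 for an independent predictor in >=17/20 replicates."""
        covered = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 500
            df = pd.DataFrame(
                {
                    "survival_days": rng.exponential(300.0, n),
                    "event": np.ones(n, dtype=bool),
                    "x": rng.standard_normal(n),
                }
            )
            t = cox_fit(df, ["x"]).table
            if t.loc["x", "ci95_low"] <= 1.0 <= t.loc["x", "ci95_high"]:
                covered += 1
        assert covered >= 17

    def test_constant_predictor_raises(self):
        df = pd.DataFrame(
            {"survival_days": [1.0, 2.0, 3.0], "event": [True, True, True],
             "x": [1.0, 1.0, 1.0]}
        )
        with pytest.raises(AnalysisError, match="constant"):
            cox_fit(df, ["x"])

    def test_too_few_events_raises(self):
        df = pd.DataFrame(
            {"survival_days": [1.0, 2.0, 3.0], "event": [True, False, False],
             "x": [1.0, 0.0, 1.0]}
        )
        with pytest.raises(AnalysisError, match="events"):
            cox_fit(df, ["x"])

    def test_generating_si_hr_recovered(self):
        cohort = generate_cohort(CohortSpec(n=2000, seed=77))
        ep = build_episodes(cohort)
        fit = cox_fit(
            ep,
            ["si", "volume_ml", "mgmt_methylated", "age", "kps_early",
             "kps_late", "eor_fraction"],
        )
        assert 1.9 <= fit.table.loc["si", "hr"] <= 2.6
        assert fit.n_used == 2000
        assert fit.c_index > 0.5

    def test_aic_improves_with_true_predictor(self):
        spec = CohortSpec(
            n=1000, seed=13, log_hr={"sex_male": np.log(2.0)},
            accrual_window_days=1e7,
        )
        cohort = generate_cohort(spec)
        with_pred = cox_fit(cohort, ["sex_male"])
        # null comparison: -2*logPL at beta=0 (no parameters)
        null_fit = cox_fit(cohort.assign(noise=np.random.default_rng(0)
                                         .standard_normal(len(cohort))),
                           ["noise"])
        assert with_pred.aic < null_fit.aic


class TestConcordance:
    def test_agrees_with_lifelines_on_plain_data(self):
        from lifelines.utils import concordance_index as ll_ci

        rng = np.random.default_rng(5)
        n = 300
        t = rng.exponential(100.0, n)
        e = rng.random(n) < 0.7
        lp = rng.standard_normal(n)
        ours = concordance_index(t, lp, e)
        theirs = ll_ci(t, -lp, e)
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_above_half_for_informative_predictor(self):
        cohort = generate_cohort(CohortSpec(n=1000, seed=6))
        fit = cox_fit(cohort, ["si", "age", "kps_post"])
        fresh = generate_cohort(CohortSpec(n=2000, seed=7))
        X = fresh[["si", "age", "kps_post"]].to_numpy(dtype=float)
        lp = (X - X.mean(axis=0)) @ fit.params
        c = concordance_index(
            fresh["survival_days"].to_numpy(), lp,
            fresh["event"].to_numpy(bool),
        )
        assert c > 0.55


class TestProportionalityCheck:
    FULL = ["si", "volume_ml", "mgmt_methylated", "age", "kps_post",
            "eor_fraction"]
    FULL_SPLIT = ["si", "volume_ml", "mgmt_methylated", "age", "kps_early",
                  "kps_late", "eor_fraction"]

    def test_constant_hazard_not_flagged(self):
        # the fitted model must match the generator: omitting generating
        # covariates induces genuine non-proportionality in the others
        cohort = generate_cohort(CohortSpec(n=1000, seed=15))
        fit = cox_fit(cohort, self.FULL)
        ph = proportionality_check(fit)
        assert not ph.loc["si", "violated"]
        assert not ph.loc["kps_post", "violated"]

    def test_decaying_kps_flagged_then_fixed_by_split(self):
        cohort = generate_cohort(
            CohortSpec(n=1500, seed=16, kps_effect_ends_day=300.0)
        )
        unsplit = cox_fit(cohort, self.FULL)
        assert proportionality_check(unsplit).loc["kps_post", "violated"]
        ep = build_episodes(cohort)
        split = cox_fit(ep, self.FULL_SPLIT)
        ph = proportionality_check(split)
        assert not ph.loc["kps_early", "violated"]
        assert not ph.loc["kps_late", "violated"]


class TestKMCurves:
    def test_no_censoring_steps_equal_empirical(self):
        n = 8
        df = pd.DataFrame(
            {
                "survival_days": np.arange(1.0, n + 1.0),
                "event": np.ones(n, dtype=bool),
            }
        )
        curves, _ = km_curves(df, "all")
        c = curves[0]
        # after the k-th event, survival is 1 - k/n exactly
        for k, t in enumerate(np.arange(1.0, n + 1.0), start=1):
            s = c.survival[c.times == t]
            assert s[0] == pytest.approx(1.0 - k / n, abs=1e-12)

    def test_two_identical_groups_null_logrank(self):
        rng = np.random.default_rng(17)
        t = rng.exponential(100.0, 1000)
        df = pd.DataFrame(
            {
                "survival_days": np.concatenate([t, t]),
                "event": np.ones(2000, dtype=bool),
            }
        )
        _, p = km_curves(df, "custom",
                         custom_groups=["a"] * 1000 + ["b"] * 1000)
        assert p > 0.5

    def test_exponential_median(self):
        lam = 1.0 / 400.0
        rng = np.random.default_rng(18)
        df = pd.DataFrame(
            {
                "survival_days": rng.exponential(1.0 / lam, 5000),
                "event": np.ones(5000, dtype=bool),
            }
        )
        curves, _ = km_curves(df, "all")
        assert curves[0].median_days == pytest.approx(np.log(2) / lam, rel=0.05)

    def test_survival_monotone_from_one(self):
        cohort = generate_cohort(CohortSpec(n=500, seed=19))
        curves, _ = km_curves(cohort, "median_split_si")
        for c in curves:
            assert c.survival[0] <= 1.0 + 1e-12
            assert (np.diff(c.survival) <= 1e-12).all()

    def test_stratum_without_events_raises(self):
        with pytest.raises(AnalysisError, match="no events"):
            km_curves(
                pd.DataFrame(
                    {"survival_days": [1.0, 2.0], "event": [True, False]}
                ),
                "custom",
                custom_groups=["a", "b"],
            )


@pytest.fixture(scope="module")
def report():
    cohort = generate_cohort(CohortSpec(n=400, seed=23))
    return analysis_report(cohort), cohort


class TestAnalysisReport:

    def test_two_multivariable_models_seven_predictors(self, report):
        rep, _ = report
        assert set(rep["multivariable"]) == {"csa_model", "si_model"}
        for name, fit in rep["multivariable"].items():
            assert len(fit.table) == 7
            assert "kps_early" in fit.table.index
            assert "kps_late" in fit.table.index

    def test_descriptive_keys(self, report):
        rep, cohort = report
        assert rep["descriptive"]["volume_ml"]["median"] == pytest.approx(
            cohort["volume_ml"].median()
        )
        assert "survival_months" in rep["descriptive"]

    def test_row_order_invariance(self, report):
        rep, cohort = report
        shuffled = cohort.sample(frac=1.0, random_state=99).reset_index(drop=True)
        rep2 = analysis_report(shuffled)
        for name in ("csa_model", "si_model"):
            pd.testing.assert_frame_equal(
                rep["multivariable"][name].table,
                rep2["multivariable"][name].table,
            )
        assert rep["univariable_cox"].equals(rep2["univariable_cox"])

    def test_degenerate_cohort_raises(self):
        cohort = generate_cohort(CohortSpec(n=2, seed=1))
        with pytest.raises(AnalysisError):
            analysis_report(cohort)

    def test_missing_column_raises(self):
        cohort = generate_cohort(CohortSpec(n=100, seed=2)).drop(columns=["mgmt"])
        with pytest.raises(AnalysisError, match="mgmt"):
            analysis_report(cohort)
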