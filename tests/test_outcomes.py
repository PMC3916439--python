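import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ms_claims_rwe import (
    OutcomeEstimate,
    baseline_table,
    crude_arr,
    fit_relapse_probability,
    fit_relapse_rate,
    km_time_to_first_relapse,
    proportion_chi2,
    sensitivity_adjusted,
)

from oracles import logrank_oracle


def simulate_matched(
    n_pairs=200,
    rr=1.0,
    base_rate=0.5,
    seed=0,
    logistic=False,
    alpha=0.6,
    symptoms=False,
):
    """Matched-style outcome data with known structure (no claims pipeline)."""
    rng = np.random.default_rng(seed)
    rows = []
    for pid in range(n_pairs):
        arm_first = rng.integers(0, 2)
        for k in range(2):
            arm = arm_first if k == 0 else 1 - arm_first
            years = rng.uniform(0.4, 1.0)
            mu = base_rate * (rr if arm else 1.0) * years
            if alpha > 0:
                g = rng.gamma(1.0 / alpha, alpha)
            else:
                g = 1.0
            count = rng.poisson(mu * g)
            rows.append(
                {
                    "member_id": f"p{pid}_{arm}",
                    "pair_id": pid,
                    "arm": arm,
                    "years": years,
                    "relapse_count": count,
                    "relapse_any": int(count > 0),
                }
            )
    df = pd.DataFrame(rows)
    if symptoms:
        for c in ("symptom_headache", "symptom_visual"):
            df[c] = rng.integers(0, 2, len(df))
    return df


class TestLogisticGEE:
    def test_single_cluster_independence_equals_mle(self):
        """With one member per cluster and independence working correlation,
        GEE point estimates equal ordinary logistic ML to 4 decimals."""
        df = simulate_matched(n_pairs=150, rr=0.5, seed=1)
        df["pair_id"] = np.arange(len(df))  # break the pairing
        gee = fit_relapse_probability(df, cov_struct=sm.cov_struct.Independence())
        X = sm.add_constant(df[["arm"]].astype(float))
        mle = sm.Logit(
            df["relapse_any"], X, offset=np.log(df["years"])
        ).fit(disp=0)
        assert gee.estimate == pytest.approx(np.exp(mle.params["arm"]), abs=1e-4)

    def test_equal_offsets_shift_only_the_intercept(self):
        df = simulate_matched(n_pairs=150, rr=0.5, seed=2)
        df["years"] = 1.0  # log-offset 0 for everyone
        with_offset = fit_relapse_probability(df)
        without = fit_relapse_probability(df, offset=False)
        assert with_offset.estimate == pytest.approx(without.estimate, rel=1e-6)

    def test_zero_event_arm_is_not_identifiable(self):
        df = simulate_matched(n_pairs=50, seed=3)
        df.loc[df["arm"] == 1, ["relapse_count", "relapse_any"]] = 0
        with pytest.raises(ValueError, match="zero relapse events"):
            fit_relapse_probability(df)

    def test_null_simulation_coverage(self):
        """Arms identical by construction: the OR CI should cover 1 in at
        least 93 of 100 simulations at 132 pairs."""
        cover = 0
        for seed in range(100):
            df = simulate_matched(n_pairs=132, rr=1.0, base_rate=0.4, seed=seed)
            est = fit_relapse_probability(df)
            cover += est.ci_lower <= 1.0 <= est.ci_upper
        assert cover >= 93

    def test_report_format(self):
        est = OutcomeEstimate("odds_ratio", 0.41, 0.21, 0.80, 0.0091, "GEE", 132, 132)
        assert est.format() == "OR, 0.41; 95% CI, 0.21-0.80; p = 0.0091"


class TestRateModel:
    def test_poisson_limit_matches_poisson_glm(self):
        """Poisson-generated counts: dispersion collapses to ~0 and the GEE
        rate ratio matches a Poisson fit within 1%."""
        df = simulate_matched(n_pairs=400, rr=0.5, alpha=0.0, seed=4)
        est, arr, alpha = fit_relapse_rate(df)
        assert alpha < 0.05
        X = sm.add_constant(df[["arm"]].astype(float))
        pois = sm.GLM(
            df["relapse_count"], X, family=sm.families.Poisson(),
            offset=np.log(df["years"]),
        ).fit()
        assert est.estimate == pytest.approx(np.exp(pois.params["arm"]), rel=0.01)

    def test_known_rate_ratio_recovered(self):
        df = simulate_matched(n_pairs=600, rr=0.38, base_rate=0.5, seed=5)
        est, arr, _ = fit_relapse_rate(df)
        assert est.ci_lower <= 0.38 <= est.ci_upper
        assert arr["fingolimod"] / arr["GA"] == pytest.approx(est.estimate, rel=1e-6)

    def test_all_zero_counts_error(self):
        df = simulate_matched(n_pairs=30, seed=6)
        df["relapse_count"] = 0
        df["relapse_any"] = 0
        with pytest.raises(ValueError, match="zero"):
            fit_relapse_rate(df)

    def test_model_arr_matches_crude_arr_without_covariates(self):
        """On covariate-free data the marginal NB model reproduces the
        empirical rate within 2%."""
        df = simulate_matched(n_pairs=500, rr=0.4, alpha=0.0, seed=7)
        _, arr_model, _ = fit_relapse_rate(df)
        arms = df.set_index("member_id")["arm"].map({1: "fingolimod", 0: "GA"})
        crude = crude_arr(
            df.set_index("member_id")["relapse_count"],
            df.set_index("member_id")["years"] * 360.0,
            arms,
        )
        for arm in ("fingolimod", "GA"):
            assert arr_model[arm] == pytest.approx(crude[arm], rel=0.02)


class TestCrudeARR:
    def test_zero_episodes(self):
        counts = pd.Series([0, 0], index=["a", "b"])
        days = pd.Series([360, 180], index=["a", "b"])
        arms = pd.Series(["GA", "GA"], index=["a", "b"])
        assert crude_arr(counts, days, arms)["GA"] == 0.0

    def test_half_year_doubles_rate(self):
        counts = pd.Series([2], index=["a"])
        days = pd.Series([180], index=["a"])
        arms = pd.Series(["GA"], index=["a"])
        assert crude_arr(counts, days, arms)["GA"] == pytest.approx(4.0)

    def test_full_windows_equal_mean_count(self):
        rng = np.random.default_rng(8)
        counts = pd.Series(rng.poisson(0.5, 50))
        days = pd.Series(np.full(50, 360))
        arms = pd.Series(["GA"] * 50)
        assert crude_arr(counts, days, arms)["GA"] == pytest.approx(counts.mean())


class TestKaplanMeier:
    def test_identical_arms_statistic_zero(self):
        df = pd.DataFrame(
            {
                "time": [50, 100, 200, 50, 100, 200],
                "event": [1, 0, 1, 1, 0, 1],
                "arm": [1, 1, 1, 0, 0, 0],
            }
        )
        _, chi2, p = km_time_to_first_relapse(df)
        assert chi2 == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_logrank(self):
        # arm A events at days 5 and 10; arm B censored at 10:
        # O_A = 2, E_A = 2/3 + 1/2, V = 2/9 + 1/4 -> chi2 = 0.8333^2/0.4722
        df = pd.DataFrame(
            {"time": [5, 10, 10], "event": [1, 1, 0], "arm": [1, 1, 0]}
        )
        _, chi2, p = km_time_to_first_relapse(df)
        assert chi2 == pytest.approx((2 - 7 / 6) ** 2 / (2 / 9 + 1 / 4), rel=1e-6)
        assert chi2 == pytest.approx(
            logrank_oracle([5, 10], [1, 1], [10], [0]), rel=1e-9
        )

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(
            {
                "time": rng.integers(1, 360, 80),
                "event": rng.integers(0, 2, 80),
                "arm": [1] * 40 + [0] * 40,
            }
        )
        _, chi2a, pa = km_time_to_first_relapse(df)
        df2 = df.assign(arm=1 - df["arm"])
        _, chi2b, pb = km_time_to_first_relapse(df2)
        assert chi2a == pytest.approx(chi2b)
        assert pa == pytest.approx(pb)

    def test_matches_oracle_on_random_data(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            na, nb = rng.integers(3, 25, 2)
            ta = rng.integers(1, 300, na)
            tb = rng.integers(1, 300, nb)
            ea = rng.integers(0, 2, na)
            eb = rng.integers(0, 2, nb)
            if ea.sum() + eb.sum() == 0:
                continue
            df = pd.DataFrame(
                {
                    "time": np.r_[ta, tb],
                    "event": np.r_[ea, eb],
                    "arm": [1] * na + [0] * nb,
                }
            )
            _, chi2, _ = km_time_to_first_relapse(df)
            assert chi2 == pytest.approx(
                logrank_oracle(ta, ea, tb, eb), rel=1e-6, abs=1e-9
            )


class TestBaselineTable:
    def test_identical_arms_p_one(self):
        cov = pd.DataFrame(
            {
                "symptom_fatigue": [True, False] * 10,
                "age": list(range(20)),
            },
            index=[f"m{i}" for i in range(20)],
        )
        treat = pd.Series([1, 0] * 10, index=cov.index)
        # arms see identical fatigue distributions
        cov["symptom_fatigue"] = [True] * 5 + [False] * 5 + [True] * 5 + [False] * 5
        treat = pd.Series([1] * 10 + [0] * 10, index=cov.index)
        table = baseline_table(cov, treat, continuous=("age",))
        row = table[table["variable"] == "symptom_fatigue"].iloc[0]
        assert row["p_value"] == pytest.approx(1.0)

    def test_printed_two_by_two_reconstruction(self):
        """17/132 vs 33/132 with relapses reproduces the published p=0.0120."""
        chi2, p = proportion_chi2(17, 132, 33, 132)
        assert round(p, 4) == 0.0120

    def test_constant_covariate_skipped_with_note(self):
        cov = pd.DataFrame(
            {"symptom_bowel": [False] * 10, "age": np.arange(10.0)},
            index=[f"m{i}" for i in range(10)],
        )
        treat = pd.Series([1] * 5 + [0] * 5, index=cov.index)
        table = baseline_table(cov, treat, continuous=("age",))
        row = table[table["variable"] == "symptom_bowel"]
        assert (row["note"] == "constant; test skipped").all()


class TestSensitivity:
    def test_independent_symptoms_leave_estimates_unchanged(self):
        df = simulate_matched(n_pairs=400, rr=0.4, seed=13, symptoms=True)
        base_or = fit_relapse_probability(df)
        base_rr, _, _ = fit_relapse_rate(df)
        adj = sensitivity_adjusted(
            df, symptoms=["symptom_headache", "symptom_visual"]
        )
        assert adj["odds_ratio"].estimate == pytest.approx(base_or.estimate, rel=0.15)
        assert adj["rate_ratio"].estimate == pytest.approx(base_rr.estimate, rel=0.15)

    def test_all_zero_symptoms_reduce_to_main_model(self):
        df = simulate_matched(n_pairs=200, rr=0.5, seed=14)
        df["symptom_headache"] = 0
        with pytest.warns(UserWarning, match="constant"):
            adj = sensitivity_adjusted(df, symptoms=["symptom_headache"])
        base = fit_relapse_probability(df)
        assert adj["odds_ratio"].estimate == pytest.approx(base.estimate, rel=1e-6)
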