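"""Effect estimation on the matched cohort.

Models follow the study's analysis plan:

* probability of any relapse while persistent — logistic GEE with an
  exchangeable working correlation within matched pairs, robust (sandwich)
  variance, and the log of years on therapy as an offset in the linear
  predictor (an unusual construction for a logit model, reproduced as
  specified; a no-offset variant is reported alongside);
* relapse count while persistent — negative-binomial GEE with the same
  clustering and a log-years offset; the NB dispersion is profiled by maximum
  likelihood on the pooled data and then held fixed in the GEE;
* crude annualized relapse rates (episodes per person-year, 360-day years);
* Kaplan-Meier time to first relapse while persistent with a two-sample
  log-rank test;
* a baseline table with chi-square tests (categorical) and Wilcoxon rank-sum
  tests (continuous);
* sensitivity re-adjustment adding the symptom covariates left out of the
  propensity model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

SENSITIVITY_SYMPTOMS = [
    "symptom_headache",
    "symptom_muscle_weakness",
    "symptom_visual",
    "symptom_bladder",
    "symptom_dizziness",
    "symptom_respiration",
    "symptom_walking",
]


@dataclass
class OutcomeEstimate:
    """Effect measure with 95% CI, p-value and model metadata."""

    measure: str  # odds_ratio | rate_ratio | arr | proportion
    estimate: float
    ci_lower: float
    ci_upper: float
    p_value: float
    model: str
    n_treated: int
    n_control: int

    @property
    def relative_reduction_pct(self) -> float:
        """Percent reduction implied by a ratio measure (1 - ratio) * 100."""
        return (1.0 - self.estimate) * 100.0

    def format(self) -> str:
        label = {"odds_ratio": "OR", "rate_ratio": "RR"}.get(self.measure, self.measure)
        return (
            f"{label}, {self.estimate:.2f}; 95% CI, {self.ci_lower:.2f}-{self.ci_upper:.2f}; "
            f"p = {self.p_value:.4f}"
        )


def _prepare(matched: pd.DataFrame):
    df = matched.copy()
    zero = df["years"] <= 0
    n_zero = int(zero.sum())
    if n_zero:
        warnings.warn(
            f"excluding {n_zero} member(s) with zero persistent time from the "
            "offset model",
            UserWarning,
            stacklevel=3,
        )
        df = df[~zero]
    return df, n_zero


def _gee(df, endog_col, family, extra_covariates=(), offset=True, cov_struct=None):
    cols = ["arm"] + [c for c in extra_covariates]
    X = sm.add_constant(df[cols].astype(float), has_constant="add")
    keep = [c for c in X.columns if c == "const" or X[c].nunique() > 1]
    dropped = [c for c in X.columns if c not in keep]
    if dropped:
        warnings.warn(f"dropping collinear/constant covariates: {dropped}", UserWarning,
                      stacklevel=3)
    X = X[keep]
    model = sm.GEE(
        df[endog_col].astype(float),
        X,
        groups=df["pair_id"].values,
        family=family,
        cov_struct=cov_struct or sm.cov_struct.Exchangeable(),
        offset=np.log(df["years"].astype(float)) if offset else None,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(maxiter=100)


def _estimate_from(res, df, measure, model_label):
    coef = res.params["arm"]
    se = res.bse["arm"]
    z = stats.norm.ppf(0.975)
    p = 2 * stats.norm.sf(abs(coef / se)) if se > 0 else np.nan
    return OutcomeEstimate(
        measure=measure,
        estimate=float(np.exp(coef)),
        ci_lower=float(np.exp(coef - z * se)),
        ci_upper=float(np.exp(coef + z * se)),
        p_value=float(p),
        model=model_label,
        n_treated=int((df["arm"] == 1).sum()),
        n_control=int((df["arm"] == 0).sum()),
    )


def fit_relapse_probability(
    matched: pd.DataFrame,
    extra_covariates=(),
    offset: bool = True,
    cov_struct=None,
) -> OutcomeEstimate:
    """Odds ratio (fingolimod vs GA) of any relapse while persistent.

    ``matched`` needs columns ``relapse_any`` (0/1), ``arm`` (1 = fingolimod),
    ``years`` (> 0, persistent time in 360-day years) and ``pair_id``.
    Raises when either arm has no events (the OR is not identifiable).
    """
    df, _ = _prepare(matched)
    events = df.groupby("arm")["relapse_any"].sum()
    if (events == 0).any() or len(events) < 2:
        raise ValueError(
            "odds ratio not identifiable: an arm has zero relapse events"
        )
    res = _gee(
        df, "relapse_any", sm.families.Binomial(), extra_covariates, offset, cov_struct
    )
    label = "GEE logistic" + (" (log-years offset)" if offset else " (no offset)")
    if extra_covariates:
        label += " + symptoms"
    return _estimate_from(res, df, "odds_ratio", label)


def estimate_nb_dispersion(matched: pd.DataFrame, extra_covariates=()) -> float:
    """NB2 dispersion (alpha) by maximum likelihood on the pooled data."""
    df, _ = _prepare(matched)
    cols = ["arm"] + list(extra_covariates)
    X = sm.add_constant(df[cols].astype(float), has_constant="add")
    with warnings.catch_warnings(), np.errstate(over="ignore", invalid="ignore"):
        warnings.simplefilter("ignore")
        try:
            res = sm.NegativeBinomial(
                df["relapse_count"].astype(float),
                X,
                offset=np.log(df["years"].astype(float)),
            ).fit(disp=0, maxiter=200)
            alpha = float(res.params[-1])
            if not np.isfinite(alpha):
                raise ValueError
        except Exception:
            alpha = 0.0
    return max(alpha, 1e-8)


def fit_relapse_rate(
    matched: pd.DataFrame,
    extra_covariates=(),
    cov_struct=None,
    year_days: int = 360,
):
    """Rate ratio (fingolimod vs GA) of relapses while persistent, plus the
    model-based annualized relapse rate per arm.

    The NB dispersion is estimated by ML on the pooled data, then fixed in a
    pair-clustered GEE. Returns ``(OutcomeEstimate, {"fingolimod": arr,
    "GA": arr}, alpha)``.
    """
    df, _ = _prepare(matched)
    if df["relapse_count"].sum() == 0:
        raise ValueError("all relapse counts are zero; the rate model is degenerate")
    alpha = estimate_nb_dispersion(df, extra_covariates)
    res = _gee(
        df,
        "relapse_count",
        sm.families.NegativeBinomial(alpha=alpha),
        extra_covariates,
        True,
        cov_struct,
    )
    label = "GEE negative binomial"
    if extra_covariates:
        label += " + symptoms"
    est = _estimate_from(res, df, "rate_ratio", label)
    # model-predicted rate at one year; covariates (if any) at their means
    lin = {"const": 1.0, "arm": 0.0}
    for c in extra_covariates:
        if c in res.params.index:
            lin[c] = float(df[c].astype(float).mean())
    base = sum(res.params[k] * v for k, v in lin.items() if k in res.params.index)
    arr = {
        "GA": float(np.exp(base)),
        "fingolimod": float(np.exp(base + res.params["arm"])),
    }
    return est, arr, alpha


def crude_arr(
    counts: pd.Series, days_persistent: pd.Series, arms: pd.Series, year_days: int = 360
) -> dict:
    """Crude annualized relapse rate per arm: total episodes over total
    person-time, person-time in ``year_days``-day years."""
    out = {}
    for arm in sorted(arms.unique()):
        mask = arms == arm
        person_years = days_persistent[mask].sum() / year_days
        out[arm] = float(counts[mask].sum() / person_years) if person_years > 0 else 0.0
    return out


@dataclass
class SurvivalCurve:
    arm: str
    timeline: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float


def km_time_to_first_relapse(matched: pd.DataFrame):
    """Kaplan-Meier time to first relapse while persistent, by arm.

    ``matched`` needs ``time`` (days, event or censoring), ``event`` (1 =
    relapse) and ``arm``. Returns ``(curves, chi2, p)`` with the two-sample
    log-rank statistic (1 df).
    """
    curves = {}
    for arm, grp in matched.groupby("arm"):
        kmf = KaplanMeierFitter()
        kmf.fit(grp["time"], event_observed=grp["event"])
        ev = kmf.event_table
        curves[arm] = SurvivalCurve(
            arm=str(arm),
            timeline=kmf.survival_function_.index.values.astype(float),
            survival=kmf.survival_function_.iloc[:, 0].values,
            at_risk=ev["at_risk"].values.astype(int),
            median=float(kmf.median_survival_time_),
        )
    arms = sorted(matched["arm"].unique())
    if len(arms) != 2:
        raise ValueError("log-rank comparison needs exactly two arms")
    a, b = (matched[matched["arm"] == arm] for arm in arms)
    lr = logrank_test(a["time"], b["time"], a["event"], b["event"])
    return curves, float(lr.test_statistic), float(lr.p_value)


def baseline_table(
    covariates: pd.DataFrame,
    treatment: pd.Series,
    categorical=None,
    continuous=("age", "pre_index_total_cost", "pre_index_relapse_count"),
) -> pd.DataFrame:
    """Baseline characteristics with between-arm tests.

    Categorical rows report n (%) per arm with an (uncorrected) chi-square
    p-value; continuous rows report mean +/- SD and median with a Wilcoxon
    rank-sum p-value. Degenerate rows are footnoted rather than dropped.
    """
    t = treatment.astype(int)
    g1 = covariates[t == 1]
    g0 = covariates[t == 0]
    if categorical is None:
        categorical = [
            c
            for c in covariates.columns
            if c not in continuous
            and (covariates[c].dtype == bool or covariates[c].dtype == object)
        ]
    rows = []
    for var in categorical:
        levels = sorted(covariates[var].astype(str).unique())
        table = np.array(
            [
                [(g1[var].astype(str) == lv).sum() for lv in levels],
                [(g0[var].astype(str) == lv).sum() for lv in levels],
            ]
        )
        note = ""
        if len(levels) < 2:
            p = np.nan
            note = "constant; test skipped"
        else:
            chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
            if (expected < 1).any():
                note = "expected cell count < 1; chi-square unreliable"
        for j, lv in enumerate(levels):
            if covariates[var].dtype == bool and lv == "False":
                continue
            rows.append(
                {
                    "variable": var,
                    "level": lv,
                    "treated": f"{table[0, j]} ({100 * table[0, j] / max(len(g1), 1):.1f}%)",
                    "control": f"{table[1, j]} ({100 * table[1, j] / max(len(g0), 1):.1f}%)",
                    "p_value": p,
                    "test": "chi-square",
                    "note": note,
                }
            )
    for var in continuous:
        if var not in covariates.columns:
            continue
        x1, x0 = g1[var].astype(float), g0[var].astype(float)
        if covariates[var].nunique() <= 1:
            p, note = np.nan, "constant; test skipped"
        else:
            p = float(stats.ranksums(x1, x0).pvalue)
            note = ""
        rows.append(
            {
                "variable": var,
                "level": "",
                "treated": f"{x1.mean():.2f}+/-{x1.std(ddof=1):.2f} (median {x1.median():.1f})",
                "control": f"{x0.mean():.2f}+/-{x0.std(ddof=1):.2f} (median {x0.median():.1f})",
                "p_value": p,
                "test": "wilcoxon rank-sum",
                "note": note,
            }
        )
    return pd.DataFrame(rows)


def proportion_chi2(n_event_t: int, n_t: int, n_event_c: int, n_c: int):
    """Uncorrected chi-square comparing two proportions (2x2)."""
    table = np.array(
        [[n_event_t, n_t - n_event_t], [n_event_c, n_c - n_event_c]]
    )
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def sensitivity_adjusted(
    matched: pd.DataFrame, symptoms=None
) -> dict:
    """Refit both GEE models with the extra symptom covariates.

    Returns ``{"odds_ratio": OutcomeEstimate, "rate_ratio": OutcomeEstimate}``.
    Collinear or constant symptom columns are dropped with a warning.
    """
    symptoms = list(symptoms or SENSITIVITY_SYMPTOMS)
    present = [c for c in symptoms if c in matched.columns]
    or_est = fit_relapse_probability(matched, extra_covariates=present)
    rr_est, _, _ = fit_relapse_rate(matched, extra_covariates=present)
    return {"odds_ratio": or_est, "rate_ratio": rr_est}
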