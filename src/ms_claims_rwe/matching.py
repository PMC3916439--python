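"""Propensity model, stratified 1:1 nearest-neighbor matching, balance.

The propensity score is the fitted probability of receiving fingolimod given
baseline covariates (logistic regression). Matching is 1:1 greedy nearest
neighbor without replacement on the probability scale, performed *within
strata of the pre-index relapse count* (bins 0, 1, 2, >=3) with a caliper
(default +/-0.01 in the fitted probability). Treated members are processed
in seeded random order; ties among equidistant controls break to the lowest
member id for reproducibility. Unmatched members are reported, never
silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

# Final covariate list of the study's propensity model.
DEFAULT_VARIABLES = [
    "age",
    "gender",
    "region",
    "plan_type",
    "prescriber_specialty",
    "charlson_score",
    "dalfampridine_use",
    "relapse_within_90d_pre",
    "pre_index_total_cost",
    "symptom_numbness",
    "symptom_fatigue",
    "symptom_bowel",
    "comorbidity_depression",
    "comorbidity_diabetes",
]

CATEGORICAL = ("gender", "region", "plan_type", "payer_type", "prescriber_specialty")


@dataclass
class PropensityFit:
    variables: list
    params: pd.Series
    scores: pd.Series  # member_id -> fitted P(fingolimod)
    converged: bool
    penalized: bool = False
    dropped: list = field(default_factory=list)
    model_result: object = None


def build_design(covariates: pd.DataFrame, variables=None) -> pd.DataFrame:
    """Numeric design matrix: dummies for categoricals, floats elsewhere.

    Dollar-scale costs are rescaled to units of $10,000 so the optimizer works
    on comparable magnitudes.
    """
    variables = list(variables or DEFAULT_VARIABLES)
    X = pd.DataFrame(index=covariates.index)
    for var in variables:
        col = covariates[var]
        if var in CATEGORICAL or col.dtype == object:
            dummies = pd.get_dummies(col.astype(str), prefix=var, drop_first=True)
            for c in dummies.columns:
                X[c] = dummies[c].astype(float)
        elif var == "pre_index_total_cost":
            X[var] = col.astype(float) / 1e4
        else:
            X[var] = col.astype(float)
    return X


def fit_propensity(
    covariates: pd.DataFrame,
    treatment: pd.Series,
    variables=None,
    selection_mode: str = "fixed",
    entry_p: float = 0.15,
    stay_p: float = 0.15,
) -> PropensityFit:
    """Fit the treatment-assignment logistic model and score every member.

    ``covariates`` must be indexed by member_id; ``treatment`` is 1 for
    fingolimod. ``selection_mode='stepwise'`` performs forward selection with
    likelihood-ratio entry/stay thresholds; the default fits the fixed final
    variable list.
    """
    y = treatment.astype(float)
    if y.nunique() < 2:
        raise ValueError("both treatment arms must be present to fit a propensity model")
    variables = list(variables or DEFAULT_VARIABLES)
    if selection_mode == "stepwise":
        variables = _forward_select(covariates, y, variables, entry_p)
    X = build_design(covariates, variables)

    dropped = [c for c in X.columns if X[c].nunique() <= 1]
    if dropped:
        warnings.warn(
            f"dropping constant design columns: {dropped}", UserWarning, stacklevel=2
        )
        X = X.drop(columns=dropped)
    X = sm.add_constant(X, has_constant="add")

    penalized = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", True))
            if not converged or not np.isfinite(res.params).all():
                raise ValueError("non-finite or non-converged fit")
        except Exception:
            res = sm.Logit(y, X).fit_regularized(alpha=1.0, disp=0, maxiter=500)
            converged, penalized = True, True
            warnings.warn(
                "propensity model showed separation/non-convergence; "
                "falling back to an L1-penalized fit",
                UserWarning,
                stacklevel=2,
            )
    scores = pd.Series(np.asarray(res.predict(X)), index=covariates.index).clip(
        1e-9, 1 - 1e-9
    )
    return PropensityFit(
        variables=variables,
        params=res.params,
        scores=scores,
        converged=converged,
        penalized=penalized,
        dropped=dropped,
        model_result=res,
    )


def _forward_select(covariates, y, candidates, entry_p):
    from scipy import stats

    chosen: list = []
    base_ll = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0).llf
    remaining = list(candidates)
    while remaining:
        best = None
        for var in remaining:
            X = sm.add_constant(build_design(covariates, chosen + [var]), has_constant="add")
            X = X.loc[:, X.nunique() > 1] if X.shape[1] > 1 else X
            try:
                res = sm.Logit(y, X).fit(disp=0, maxiter=100)
            except Exception:
                continue
            df = X.shape[1] - 1 - len(
                sm.add_constant(build_design(covariates, chosen), has_constant="add").columns
            ) + 1
            lr = 2 * (res.llf - base_ll)
            p = stats.chi2.sf(max(lr, 0.0), max(df, 1))
            if best is None or p < best[0]:
                best = (p, var, res.llf)
        if best is None or best[0] >= entry_p:
            break
        chosen.append(best[1])
        base_ll = best[2]
        remaining.remove(best[1])
    return chosen


# -- matching -----------------------------------------------------------------

def relapse_count_strata(counts: pd.Series, top_bin: int = 3) -> pd.Series:
    """Pre-index relapse-count strata: 0, 1, 2, >=3 (labelled by floor)."""
    return counts.clip(upper=top_bin).astype(int)


@dataclass
class MatchResult:
    pairs: pd.DataFrame  # treated_id, control_id, stratum, score_t, score_c, distance
    unmatched_treated: list
    unmatched_controls: list
    caliper: float


def match_nearest_neighbor(
    scores: pd.Series,
    treatment: pd.Series,
    strata: pd.Series,
    caliper: float = 0.01,
    seed: int = 0,
) -> MatchResult:
    """Stratified greedy 1:1 nearest-neighbor matching without replacement.

    Within each stratum, treated members are visited in seeded random order;
    each takes the unused control with the smallest absolute score difference
    provided it is within the caliper.
    """
    rng = np.random.default_rng(seed)
    rows = []
    unmatched_t: list = []
    unmatched_c: list = []
    for stratum in sorted(strata.unique()):
        in_stratum = strata.index[strata == stratum]
        treated = [m for m in in_stratum if treatment[m] == 1]
        controls = [m for m in in_stratum if treatment[m] == 0]
        order = rng.permutation(len(treated))
        # controls sorted by (score, id) so ties break to the lowest id
        avail = sorted(controls, key=lambda m: (scores[m], m))
        avail_scores = [scores[m] for m in avail]
        used = np.zeros(len(avail), dtype=bool)
        for k in order:
            t = treated[k]
            st = scores[t]
            best_j, best_d = None, None
            j = int(np.searchsorted(avail_scores, st))
            for direction in (-1, 1):
                jj = j - 1 if direction == -1 else j
                while 0 <= jj < len(avail):
                    if not used[jj]:
                        dist = abs(avail_scores[jj] - st)
                        if best_d is None or dist < best_d - 1e-15 or (
                            abs(dist - best_d) <= 1e-15 and avail[jj] < avail[best_j]
                        ):
                            best_j, best_d = jj, dist
                        break
                    jj += direction
            # the nearest unused neighbor on each side is enough: scores are
            # sorted, so anything further out is at least as distant
            if best_j is not None and best_d <= caliper + 1e-12:
                used[best_j] = True
                rows.append(
                    (
                        t,
                        avail[best_j],
                        stratum,
                        float(st),
                        float(avail_scores[best_j]),
                        float(best_d),
                    )
                )
            else:
                unmatched_t.append(t)
        unmatched_c.extend(m for m, u in zip(avail, used) if not u)
    pairs = pd.DataFrame(
        rows,
        columns=["treated_id", "control_id", "stratum", "score_treated", "score_control", "distance"],
    ).sort_values(["stratum", "treated_id"]).reset_index(drop=True)
    pairs["pair_id"] = np.arange(len(pairs))
    return MatchResult(pairs, sorted(unmatched_t), sorted(unmatched_c), caliper)


def standardized_mean_difference(x_t: np.ndarray, x_c: np.ndarray) -> float:
    """SMD with the pooled-variance denominator; 0 when moments coincide."""
    m_t, m_c = np.mean(x_t), np.mean(x_c)
    v_t = np.var(x_t, ddof=1) if len(x_t) > 1 else 0.0
    v_c = np.var(x_c, ddof=1) if len(x_c) > 1 else 0.0
    denom = np.sqrt((v_t + v_c) / 2.0)
    if denom == 0:
        return 0.0
    return float((m_t - m_c) / denom)


def assess_balance(
    covariates: pd.DataFrame,
    treatment: pd.Series,
    pairs: pd.DataFrame,
    variables=None,
) -> pd.DataFrame:
    """Per-covariate SMD before and after matching.

    Categoricals are expanded to indicator columns; binary covariates use the
    proportion-based SMD (a special case of the pooled formula).
    """
    X = build_design(covariates, variables or DEFAULT_VARIABLES)
    t_all = treatment.astype(int)
    matched_t = list(pairs["treated_id"])
    matched_c = list(pairs["control_id"])
    rows = []
    for col in X.columns:
        x = X[col]
        before = standardized_mean_difference(
            x[t_all == 1].values, x[t_all == 0].values
        )
        after = (
            standardized_mean_difference(
                x.loc[matched_t].values, x.loc[matched_c].values
            )
            if len(pairs)
            else np.nan
        )
        rows.append((col, before, after))
    report = pd.DataFrame(rows, columns=["covariate", "smd_before", "smd_after"])
    report.attrs["n_before"] = (int((t_all == 1).sum()), int((t_all == 0).sum()))
    report.attrs["n_after"] = (len(matched_t), len(matched_c))
    return report
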