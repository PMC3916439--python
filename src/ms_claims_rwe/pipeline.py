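"""End-to-end study runs: simulate → select → detect → persist → match → fit.

A :class:`StudyConfig` fully determines a run (together with its seed); the
report embeds the config hash so every number is reproducible from config +
seed alone. Each stage is also callable on its own through the stage modules.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .claims import ClaimsBundle, validate_bundle
from .cohort import (
    apply_selection_criteria,
    attrition_percentage,
    baseline_covariates,
    index_events_table,
)
from .matching import (
    assess_balance,
    fit_propensity,
    match_nearest_neighbor,
    relapse_count_strata,
)
from .outcomes import (
    SENSITIVITY_SYMPTOMS,
    crude_arr,
    fit_relapse_probability,
    fit_relapse_rate,
    km_time_to_first_relapse,
    baseline_table,
    proportion_chi2,
    sensitivity_adjusted,
)
from .persistence import persistence_table, summarize_persistence
from .relapse import RelapseDetector, episode_counts
from .simulate import SimulationConfig, generate_bundle


@dataclass
class StudyConfig:
    """All stage parameters of a study run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0
    index_window: tuple = ("2010-10-01", "2012-03-31")
    pre_days: int = 360
    horizon: int = 360
    switch_gap_max_days: int = 90
    persistence_gap_days: int = 60
    collapse_days: int = 30
    collapse_mode: str = "anchor"
    steroid_window_days: int = 7
    symmetric_steroid: bool = False
    caliper: float = 0.01
    year_days: int = 360
    admin_coverage_days: int = 28
    propensity_selection: str = "fixed"
    make_plots: bool = False

    def __post_init__(self):
        # one seed drives both the generator and the matcher
        self.simulation.seed = self.seed
        self.simulation.index_window = tuple(self.index_window)
        self.simulation.pre_days = self.pre_days
        self.simulation.horizon = self.horizon

    def to_mapping(self) -> dict:
        m = asdict(self)
        m["simulation"] = self.simulation.to_mapping()
        m["index_window"] = list(self.index_window)
        return m

    @classmethod
    def from_mapping(cls, m: dict) -> "StudyConfig":
        m = dict(m)
        if "simulation" in m:
            m["simulation"] = SimulationConfig.from_mapping(m["simulation"])
        if "index_window" in m:
            m["index_window"] = tuple(m["index_window"])
        return cls(**m)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_mapping(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_mapping(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    config: StudyConfig
    attrition: pd.DataFrame
    baseline: pd.DataFrame
    balance: pd.DataFrame
    persistence_summary: pd.DataFrame
    matched_data: pd.DataFrame
    pairs: pd.DataFrame
    estimates: dict
    summary: dict

    @property
    def provenance(self) -> dict:
        return {
            "seed": self.config.seed,
            "config_hash": self.config.config_hash,
            "version": __version__,
            "design_constants": {
                "pre_days": self.config.pre_days,
                "horizon": self.config.horizon,
                "switch_gap_max_days": self.config.switch_gap_max_days,
                "persistence_gap_days": self.config.persistence_gap_days,
                "collapse_days": self.config.collapse_days,
                "steroid_window_days": self.config.steroid_window_days,
                "caliper": self.config.caliper,
                "year_days": self.config.year_days,
            },
        }


def analyze_bundle(
    bundle: ClaimsBundle, config: StudyConfig, full: bool = True
) -> StudyReport:
    """Run every analysis stage on an existing bundle.

    ``full=False`` fits only the two primary effect models (used in large
    replicate simulations), skipping the descriptive tables, the
    Kaplan-Meier comparison and the sensitivity refits.
    """
    validation = validate_bundle(bundle)
    index_events = index_events_table(
        bundle, config.index_window, config.switch_gap_max_days
    )
    cohort, attrition = apply_selection_criteria(
        bundle, index_events, config.pre_days, config.horizon, validation
    )
    summary: dict = {
        "n_identified": int(attrition["n_remaining"].iloc[0]),
        "n_cohort": len(cohort),
        "attrition_pct": attrition_percentage(attrition),
    }
    estimates: dict = {}
    empty = pd.DataFrame()
    if len(cohort) == 0:
        return StudyReport(
            config, attrition, empty, empty, empty, empty, empty, estimates, summary
        )

    detector = RelapseDetector(bundle)
    idx_dates = cohort.set_index("member_id")["index_date"]
    det_kw = dict(
        steroid_window_days=config.steroid_window_days,
        symmetric_steroid=config.symmetric_steroid,
        collapse_days=config.collapse_days,
        collapse_mode=config.collapse_mode,
    )
    pre_eps = detector.episodes(idx_dates, (-config.pre_days, -1), **det_kw)
    post_eps = detector.episodes(idx_dates, (0, config.horizon - 1), **det_kw)

    covariates = baseline_covariates(bundle, cohort, pre_eps, config.pre_days).set_index(
        "member_id"
    )
    persistence = persistence_table(
        bundle,
        cohort,
        config.persistence_gap_days,
        config.horizon,
        config.admin_coverage_days,
    ).set_index("member_id")

    treatment = (cohort.set_index("member_id")["index_dmt"] == "fingolimod").astype(int)
    arms = cohort.set_index("member_id")["index_dmt"]

    fit = fit_propensity(
        covariates.loc[treatment.index],
        treatment,
        selection_mode=config.propensity_selection,
    )
    strata = relapse_count_strata(covariates["pre_index_relapse_count"])
    match = match_nearest_neighbor(
        fit.scores, treatment, strata, config.caliper, seed=config.seed
    )
    pairs = match.pairs
    balance = assess_balance(covariates, treatment, pairs)
    summary["n_pairs"] = len(pairs)
    summary["n_matched"] = 2 * len(pairs)

    matched_ids = list(pairs["treated_id"]) + list(pairs["control_id"])
    pair_of = dict(
        zip(
            matched_ids,
            list(pairs["pair_id"]) + list(pairs["pair_id"]),
        )
    )
    end_day = persistence["end_day"]
    post_counts = episode_counts(post_eps, matched_ids, persistence_end=end_day)
    pre_counts = covariates["pre_index_relapse_count"]

    first_onset = (
        post_eps.groupby("member_id")["onset_day"].min()
        if len(post_eps)
        else pd.Series(dtype=float)
    )
    md = pd.DataFrame(index=pd.Index(matched_ids, name="member_id"))
    md["arm"] = treatment.reindex(md.index)
    md["pair_id"] = [pair_of[m] for m in md.index]
    md["days_persistent"] = persistence["days_persistent"].reindex(md.index)
    md["years"] = md["days_persistent"] / config.year_days
    md["relapse_count"] = post_counts.reindex(md.index)
    md["relapse_any"] = (md["relapse_count"] > 0).astype(int)
    fo = first_onset.reindex(md.index)
    has_event = fo.notna() & (fo <= md["days_persistent"] - 1)
    md["event"] = has_event.astype(int)
    md["time"] = np.where(has_event, fo + 1, md["days_persistent"]).astype(float)
    for c in SENSITIVITY_SYMPTOMS:
        md[c] = covariates[c].reindex(md.index).astype(int)
    md["pre_relapse_count"] = pre_counts.reindex(md.index)
    matched_data = md.reset_index()

    persistence_summary = summarize_persistence(
        persistence.reset_index()[
            persistence.reset_index()["member_id"].isin(matched_ids)
        ],
        arms,
        config.horizon,
    )
    baseline = (
        baseline_table(
            covariates.loc[matched_ids].assign(
                pre_index_relapse_count=pre_counts.reindex(matched_ids)
            ),
            treatment.reindex(matched_ids),
        )
        if full
        else pd.DataFrame()
    )

    # crude annualized relapse rates, pre (full window) and post (persistent)
    matched_arms = arms.reindex(matched_ids)
    pre_full = pd.Series(config.pre_days, index=pd.Index(matched_ids), dtype=float)
    summary["arr_pre"] = crude_arr(
        pre_counts.reindex(matched_ids), pre_full, matched_arms, config.year_days
    )
    summary["arr_post_crude"] = crude_arr(
        post_counts.reindex(matched_ids),
        md["days_persistent"],
        matched_arms,
        config.year_days,
    )
    for arm in ("fingolimod", "GA"):
        mask = matched_arms == arm
        n = int(mask.sum())
        with_rel = int((md["relapse_any"][mask.values] > 0).sum()) if n else 0
        summary[f"relapse_proportion_{arm}"] = 100.0 * with_rel / n if n else np.nan
    t_mask = (matched_arms == "fingolimod").values
    if len(md):
        chi2, p = proportion_chi2(
            int(md["relapse_any"][t_mask].sum()),
            int(t_mask.sum()),
            int(md["relapse_any"][~t_mask].sum()),
            int((~t_mask).sum()),
        )
        summary["relapse_proportion_chi2"] = chi2
        summary["relapse_proportion_p"] = p

    if len(md) and md["relapse_any"].groupby(md["arm"]).sum().gt(0).all():
        estimates["odds_ratio"] = fit_relapse_probability(matched_data)
        rr, arr_model, alpha = fit_relapse_rate(matched_data, year_days=config.year_days)
        estimates["rate_ratio"] = rr
        summary["arr_post_model"] = arr_model
        summary["nb_dispersion"] = alpha
        if full:
            estimates["odds_ratio_no_offset"] = fit_relapse_probability(
                matched_data, offset=False
            )
            curves, lr_chi2, lr_p = km_time_to_first_relapse(matched_data)
            summary["logrank_chi2"] = lr_chi2
            summary["logrank_p"] = lr_p
            summary["km_median_days"] = {
                ("fingolimod" if arm == 1 else "GA"): c.median
                for arm, c in curves.items()
            }
            try:
                sens = sensitivity_adjusted(matched_data)
                estimates["odds_ratio_adjusted"] = sens["odds_ratio"]
                estimates["rate_ratio_adjusted"] = sens["rate_ratio"]
            except ValueError as exc:  # degenerate symptom design
                warnings.warn(
                    f"sensitivity refit skipped: {exc}", UserWarning, stacklevel=2
                )

    return StudyReport(
        config,
        attrition,
        baseline,
        balance,
        persistence_summary,
        matched_data,
        pairs,
        estimates,
        summary,
    )


def run_study(config: StudyConfig, full: bool = True):
    """Simulate a bundle under the config and analyze it end to end."""
    bundle, truth = generate_bundle(config.simulation)
    report = analyze_bundle(bundle, config, full=full)
    return report, bundle, truth


def write_report(report: StudyReport, out_dir) -> dict:
    """Write delimited tables plus a machine-readable summary.

    File contents are a pure function of (config, seed): no timestamps.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("attrition", report.attrition),
        ("baseline_table", report.baseline),
        ("balance", report.balance),
        ("persistence_summary", report.persistence_summary),
        ("matched_data", report.matched_data),
        ("pairs", report.pairs),
    ):
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path

    summary = dict(report.summary)
    if "attrition_pct" in summary and len(report.attrition):
        initial = int(report.attrition["n_remaining"].iloc[0])
        summary["attrition_excluded_n"] = initial - summary.get("n_cohort", 0)
    summary["estimates"] = {
        name: {
            "measure": est.measure,
            "estimate": est.estimate,
            "ci_lower": est.ci_lower,
            "ci_upper": est.ci_upper,
            "p_value": est.p_value,
            "relative_reduction_pct": est.relative_reduction_pct,
            "model": est.model,
            "n_treated": est.n_treated,
            "n_control": est.n_control,
        }
        for name, est in report.estimates.items()
    }
    summary["provenance"] = report.provenance
    path = out / "summary.json"
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    paths["summary"] = path

    if report.config.make_plots and len(report.matched_data):
        paths["km_plot"] = _km_plot(report, out / "km_time_to_relapse.svg")
    return paths


def _km_plot(report: StudyReport, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from lifelines import KaplanMeierFitter

    fig, ax = plt.subplots(figsize=(6, 4))
    for arm, label in ((1, "fingolimod"), (0, "GA")):
        grp = report.matched_data[report.matched_data["arm"] == arm]
        if len(grp) == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(grp["time"], event_observed=grp["event"], label=label)
        kmf.plot_survival_function(ax=ax)
    ax.set_xlabel("days since index switch")
    ax.set_ylabel("relapse-free proportion while persistent")
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)
    return path
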