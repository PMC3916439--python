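"""Synthetic claims generator.

Emulates the population the study design assumes: members with an interferon
history who switch to fingolimod or glatiramer acetate at an index date
inside a configurable index window, relapses drawn from a per-member Poisson
process with gamma frailty (so counts are marginally negative-binomial),
inpatient/outpatient relapse manifestation with nearby corticosteroid
claims, confounded treatment assignment, exponential treatment stop times
per arm, and configurable noise claims.

Every downstream stage can therefore be tested against known ground truth:
the generator returns both the claims bundle and a per-member truth table
(arm, frailty, true relapse days, true stop day, covariate flags).

Randomness flows from one seed; per-member sub-streams are spawned from it,
so adding members never perturbs existing members' draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .claims import ClaimsBundle, format_enrollment
from .dictionaries import CodeDictionary

# Covariate prevalences in the pooled matched sample (study baseline table).
DEFAULT_PREVALENCES = {
    "numbness": 0.197,
    "fatigue": 0.333,
    "bowel": 0.080,
    "headache": 0.200,
    "muscle_weakness": 0.140,
    "visual": 0.144,
    "bladder": 0.102,
    "dizziness": 0.070,
    "respiration": 0.055,
    "walking": 0.182,
    "depression": 0.235,
    "diabetes": 0.072,
    "dyslipidemia": 0.262,
    "tobacco": 0.068,
    "cvd": 0.061,
    "dalfampridine": 0.080,
}

# Log-odds of choosing fingolimod over GA, applied to the true covariates
# (scaled by confounding_strength). Signs follow the baseline-table
# imbalances the study reports.
DEFAULT_ASSIGNMENT_COEFS = {
    "intercept": -0.10,
    "pre_relapse_count": 0.35,
    "relapse_within_90d": 0.25,
    "fatigue": 0.30,
    "depression": -0.30,
    "diabetes": -0.40,
    "dalfampridine": 0.50,
    "headache": -0.25,
    "visual": -0.30,
    "muscle_weakness": -0.25,
}

REGIONS = (("northeast", 0.20), ("midwest", 0.25), ("south", 0.35), ("west", 0.20))
PLAN_TYPES = (("HMO", 0.30), ("PPO", 0.45), ("POS", 0.15), ("other", 0.10))
PAYER_TYPES = (("commercial", 0.80), ("self_insured", 0.20))
SPECIALTIES = (("neurology", 0.70), ("other", 0.30))

PATHOLOGIES = (
    "missing_days_supply",
    "enrollment_gap",
    "underage",
    "preindex_index_dmt",
    "missing_gender",
    "invalid_enrollment",
)


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Rates are per 360 days. Discontinuation hazards are per day, calibrated so
    survival of index-therapy exposure at day 300 matches the study's
    persistence proportions at the 360-day horizon (with 30-day fills, a stop
    after day 300 is indistinguishable from persistence under the 60-day gap
    rule).
    """

    n_members: int = 600
    seed: int = 0
    index_window: tuple = ("2010-10-01", "2012-03-31")
    pre_days: int = 360
    horizon: int = 360
    enrollment_pad_days: int = 30
    pre_index_relapse_rate: float = 0.47
    ga_post_relapse_rate: float = 0.51
    true_rate_ratio: float = 0.38
    frailty_shape: float = 1.5
    inpatient_fraction: float = 0.10
    steroid_capture_prob: float = 0.95
    oral_steroid_fraction: float = 0.80
    steroid_delay_max: int = 7
    confounding_strength: float = 1.0
    disc_hazard_fingolimod: float = -math.log(0.735) / 300.0
    disc_hazard_ga: float = -math.log(0.629) / 300.0
    switch_fraction: float = 0.15
    fill_days_supply: int = 30
    ifn_gap_max: int = 85
    female_fraction: float = 0.75
    nonms_visit_rate: float = 2.0
    steroid_noise_rate: float = 0.10
    ms_visit_noise_rate: float = 0.50
    covariate_prevalence: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    assignment_coefs: dict = field(default_factory=lambda: dict(DEFAULT_ASSIGNMENT_COEFS))

    def validate(self) -> None:
        probs = [
            self.inpatient_fraction,
            self.steroid_capture_prob,
            self.oral_steroid_fraction,
            self.switch_fraction,
            self.female_fraction,
            *self.covariate_prevalence.values(),
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        rates = [
            self.pre_index_relapse_rate,
            self.ga_post_relapse_rate,
            self.true_rate_ratio,
            self.disc_hazard_fingolimod,
            self.disc_hazard_ga,
            self.nonms_visit_rate,
            self.steroid_noise_rate,
            self.ms_visit_noise_rate,
        ]
        if any(r < 0 for r in rates):
            raise ValueError("rates must be non-negative")
        if self.n_members < 0:
            raise ValueError("n_members must be non-negative")
        if self.frailty_shape <= 0:
            raise ValueError("frailty_shape must be positive")

    def to_mapping(self) -> dict:
        m = asdict(self)
        m["index_window"] = list(self.index_window)
        return m

    @classmethod
    def from_mapping(cls, m: dict) -> "SimulationConfig":
        m = dict(m)
        if "index_window" in m:
            m["index_window"] = tuple(m["index_window"])
        return cls(**m)


@dataclass
class GroundTruth:
    """Per-member generative truth plus a config echo."""

    table: pd.DataFrame
    config: SimulationConfig

    def relapse_days(self, member_id: str, period: str = "post") -> list:
        col = f"{period}_relapse_days"
        raw = self.table.set_index("member_id").loc[member_id, col]
        return [int(x) for x in raw.split()] if raw else []


def _choice(rng, options):
    labels = [o for o, _ in options]
    probs = [p for _, p in options]
    return labels[int(rng.choice(len(labels), p=probs))]


def true_episode_onsets(days, collapse_days: int = 30) -> list:
    """Collapse true relapse days into episode onsets (fixed-anchor rule)."""
    onsets = []
    for d in sorted(days):
        if not onsets or d - onsets[-1] > collapse_days:
            onsets.append(int(d))
    return onsets


def generate_bundle(config: SimulationConfig, dictionaries: CodeDictionary | None = None):
    """Draw a full claims bundle plus ground truth from the configuration.

    Identical seed + config yields a byte-identical bundle. The emitted
    population passes cohort selection cleanly unless pathologies are
    injected afterwards.
    """
    config.validate()
    d = dictionaries or CodeDictionary.default()
    ifn_ndcs = d.ndc_codes("IFN")
    ga_ndc = d.ndc_codes("GA")[0]
    fingo_ndc = d.ndc_codes("fingolimod")[0]
    natalizumab_ndc = d.ndc_codes("natalizumab")[0]
    dalf_ndc = d.ndc_codes("dalfampridine")[0]
    oral_steroid_ndc = d.ndc_codes("oral_corticosteroid")[0]
    iv_steroid_proc = d.procedure_codes("iv_corticosteroid")[0]
    symptom_code = {k: v[0] for k, v in d.symptoms.items()}
    comorb_code = {k: v[0] for k, v in d.comorbidities.items()}

    window_start = np.datetime64(config.index_window[0], "D").astype(np.int64)
    window_end = np.datetime64(config.index_window[1], "D").astype(np.int64)
    n_index_days = int(window_end - window_start) + 1

    cov_names = list(DEFAULT_PREVALENCES)
    prev = config.covariate_prevalence
    coefs = config.assignment_coefs

    members_rows = []
    medical_rows = []
    pharmacy_rows = []
    truth_rows = []
    mc = rxc = 0  # claim id counters

    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_members)
    for i in range(config.n_members):
        rng = np.random.default_rng(children[i])
        mid = f"M{i:06d}"

        flags = {name: bool(rng.random() < prev.get(name, 0.0)) for name in cov_names}
        age = int(np.clip(round(rng.normal(46.0, 10.0)), 19, 80))
        gender = "F" if rng.random() < config.female_fraction else "M"
        region = _choice(rng, REGIONS)
        plan = _choice(rng, PLAN_TYPES)
        payer = _choice(rng, PAYER_TYPES)
        specialty = _choice(rng, SPECIALTIES)
        index_day = int(window_start + rng.integers(0, n_index_days))
        index_year = (
            np.datetime64(index_day, "D").astype("datetime64[Y]").astype(int) + 1970
        )
        birth_year = int(index_year - age)

        frailty = float(rng.gamma(config.frailty_shape, 1.0 / config.frailty_shape))
        n_pre = int(rng.poisson(config.pre_index_relapse_rate * frailty))
        pre_days = sorted(int(x) for x in rng.integers(-config.pre_days, 0, size=n_pre))
        relapse_90 = any(dd >= -90 for dd in pre_days)

        lp = float(coefs.get("intercept", 0.0))
        contrib = (
            coefs.get("pre_relapse_count", 0.0) * n_pre
            + coefs.get("relapse_within_90d", 0.0) * relapse_90
        )
        for name in cov_names:
            contrib += coefs.get(name, 0.0) * flags[name]
        lp += config.confounding_strength * contrib
        p_fingo = 1.0 / (1.0 + math.exp(-lp))
        arm = "fingolimod" if rng.random() < p_fingo else "GA"

        hazard = (
            config.disc_hazard_fingolimod if arm == "fingolimod" else config.disc_hazard_ga
        )
        stop_day = float(rng.exponential(1.0 / hazard)) if hazard > 0 else math.inf
        wants_switch = bool(rng.random() < config.switch_fraction)

        post_rate = config.ga_post_relapse_rate * (
            config.true_rate_ratio if arm == "fingolimod" else 1.0
        )
        n_post = int(rng.poisson(post_rate * frailty * (config.horizon / 360.0)))
        post_days = sorted(int(x) for x in rng.integers(0, config.horizon, size=n_post))

        enroll_start = index_day - config.pre_days - config.enrollment_pad_days
        enroll_end = index_day + config.horizon + config.enrollment_pad_days - 1
        members_rows.append(
            (
                mid,
                birth_year,
                gender,
                region,
                plan,
                payer,
                format_enrollment(
                    [
                        (
                            pd.Timestamp(np.datetime64(enroll_start, "D")),
                            pd.Timestamp(np.datetime64(enroll_end, "D")),
                        )
                    ]
                ),
            )
        )

        def med(day, setting, dxs, procs="", paid=150.0):
            nonlocal mc
            mc += 1
            medical_rows.append(
                (f"MC{mc:08d}", mid, index_day + day, setting, dxs, procs, specialty, paid)
            )

        def rx(day, ndc, supply, paid):
            nonlocal rxc
            rxc += 1
            pharmacy_rows.append(
                (f"RX{rxc:08d}", mid, index_day + day, ndc, supply, paid)
            )

        # interferon history ending 1..ifn_gap_max days before the switch
        ifn_ndc = ifn_ndcs[int(rng.integers(0, len(ifn_ndcs)))]
        last_ifn = -int(rng.integers(1, config.ifn_gap_max + 1))
        day = last_ifn
        while day >= -config.pre_days:
            rx(day, ifn_ndc, config.fill_days_supply, round(float(rng.normal(2800, 250)), 2))
            day -= config.fill_days_supply

        # index-DMT fills until the true stop day
        index_ndc = fingo_ndc if arm == "fingolimod" else ga_ndc
        fill_paid = 4200.0 if arm == "fingolimod" else 3100.0
        for fd in range(0, config.horizon, config.fill_days_supply):
            if fd >= stop_day:
                break
            rx(fd, index_ndc, config.fill_days_supply, fill_paid)

        # switch to natalizumab for a fraction of stoppers
        switch_day = None
        if wants_switch and stop_day <= config.horizon:
            cand = int(math.ceil(stop_day)) + int(rng.integers(1, 20))
            if 0 < cand < config.horizon:
                switch_day = cand
                rx(switch_day, natalizumab_ndc, 28, 5200.0)

        # relapse manifestation (pre and post)
        for rd in pre_days + post_days:
            u_inpat = rng.random()
            u_capture = rng.random()
            delay = int(rng.integers(0, config.steroid_delay_max + 1))
            u_oral = rng.random()
            if u_inpat < config.inpatient_fraction:
                med(rd, "inpatient", "340", paid=round(float(rng.lognormal(8.6, 0.4)), 2))
            else:
                med(rd, "outpatient", "340", paid=round(float(rng.lognormal(5.6, 0.4)), 2))
                if u_capture < config.steroid_capture_prob:
                    if u_oral < config.oral_steroid_fraction:
                        rx(rd + delay, oral_steroid_ndc, 7, 25.0)
                    else:
                        med(rd + delay, "outpatient", "V5889", iv_steroid_proc, paid=220.0)

        # one routine MS visit guarantees the MS-diagnosis criterion; placed
        # away from relapse days so it can never manufacture a relapse event
        taboo = pre_days + post_days
        start = int(rng.integers(-config.pre_days, config.horizon))
        routine_day = None
        for k in range(config.pre_days + config.horizon):
            cand = -config.pre_days + (
                (start + config.pre_days + k) % (config.pre_days + config.horizon)
            )
            if all(abs(cand - t) > config.steroid_delay_max + 1 for t in taboo):
                routine_day = cand
                break
        if routine_day is not None:
            med(routine_day, "outpatient", "340", paid=180.0)

        # baseline symptom/comorbidity claims and dalfampridine use
        for name in cov_names:
            if not flags[name]:
                continue
            cday = -int(rng.integers(1, config.pre_days + 1))
            if name == "dalfampridine":
                rx(cday, dalf_ndc, 30, 650.0)
            else:
                code = symptom_code.get(name) or comorb_code.get(name)
                med(cday, "outpatient", code, paid=round(float(rng.lognormal(5.0, 0.3)), 2))

        # noise claims
        span_years = (config.pre_days + config.horizon) / 360.0
        for _ in range(int(rng.poisson(config.nonms_visit_rate * span_years))):
            nd = int(rng.integers(-config.pre_days, config.horizon))
            med(nd, "outpatient", "4659", paid=90.0)
        for _ in range(int(rng.poisson(config.ms_visit_noise_rate * span_years))):
            nd = int(rng.integers(-config.pre_days, config.horizon))
            med(nd, "outpatient", "340", paid=110.0)
        for _ in range(int(rng.poisson(config.steroid_noise_rate * span_years))):
            nd = int(rng.integers(-config.pre_days, config.horizon))
            rx(nd, oral_steroid_ndc, 7, 25.0)

        truth_rows.append(
            (
                mid,
                arm,
                index_day,
                frailty,
                p_fingo,
                round(stop_day, 3) if math.isfinite(stop_day) else np.inf,
                switch_day if switch_day is not None else np.nan,
                " ".join(str(x) for x in pre_days),
                " ".join(str(x) for x in post_days),
                n_pre,
                relapse_90,
                age,
                gender,
                *[flags[name] for name in cov_names],
            )
        )

    members = pd.DataFrame(
        members_rows,
        columns=[
            "member_id",
            "birth_year",
            "gender",
            "region",
            "plan_type",
            "payer_type",
            "enrollment",
        ],
    )
    medical = pd.DataFrame(
        medical_rows,
        columns=[
            "claim_id",
            "member_id",
            "service_date",
            "setting",
            "diagnoses",
            "procedures",
            "provider_specialty",
            "paid_amount",
        ],
    )
    pharmacy = pd.DataFrame(
        pharmacy_rows,
        columns=["claim_id", "member_id", "fill_date", "ndc", "days_supply", "paid_amount"],
    )
    for df, col in ((medical, "service_date"), (pharmacy, "fill_date")):
        if len(df):
            df[col] = pd.to_datetime(df[col].values.astype("datetime64[D]"))
        else:
            df[col] = pd.to_datetime(df[col])
    if len(pharmacy):
        pharmacy["days_supply"] = pharmacy["days_supply"].astype(float)

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "member_id",
            "arm",
            "index_day",
            "frailty",
            "true_p_fingolimod",
            "stop_day",
            "switch_day",
            "pre_relapse_days",
            "post_relapse_days",
            "n_pre_relapses",
            "relapse_within_90d",
            "age",
            "gender",
            *cov_names,
        ],
    )
    if len(truth):
        truth["index_date"] = pd.to_datetime(truth["index_day"].values.astype("datetime64[D]"))
    else:
        truth["index_date"] = pd.to_datetime(truth["index_day"])

    bundle = ClaimsBundle(members, medical, pharmacy, d)
    return bundle, GroundTruth(truth, config)


def inject_pathologies(bundle: ClaimsBundle, spec: dict) -> ClaimsBundle:
    """Deterministically corrupt chosen members to exercise attrition paths.

    ``spec`` maps a pathology name (see :data:`PATHOLOGIES`) to a list of
    member ids. Unknown names and absent members raise.
    """
    known = set(bundle.member_ids)
    for name, mids in spec.items():
        if name not in PATHOLOGIES:
            raise KeyError(f"unknown pathology {name!r}")
        for mid in mids:
            if mid not in known:
                raise ValueError(f"member {mid!r} not in bundle")

    out = bundle.copy()
    d = out.dictionaries
    index_ndcs = set(d.ndc_codes("fingolimod")) | set(d.ndc_codes("GA"))

    for mid in spec.get("missing_days_supply", []):
        mask = (out.pharmacy["member_id"] == mid) & (
            out.pharmacy["ndc"].astype(str).isin(index_ndcs)
        )
        out.pharmacy.loc[mask, "days_supply"] = np.nan

    for mid in spec.get("enrollment_gap", []):
        row = out.members.index[out.members["member_id"] == mid][0]
        spans = str(out.members.loc[row, "enrollment"]).split(";")
        start_s, _, end_s = spans[0].partition(":")
        start, end = pd.Timestamp(start_s), pd.Timestamp(end_s)
        hole = start + pd.Timedelta(days=290)
        out.members.loc[row, "enrollment"] = format_enrollment(
            [(start, hole - pd.Timedelta(days=1)), (hole + pd.Timedelta(days=2), end)]
        )

    for mid in spec.get("underage", []):
        row = out.members.index[out.members["member_id"] == mid][0]
        ref_year = (
            out.calendar_end.year if out.calendar_end is not None else 2012
        )
        out.members.loc[row, "birth_year"] = ref_year - 16

    for mid in spec.get("preindex_index_dmt", []):
        rxm = out.pharmacy[
            (out.pharmacy["member_id"] == mid)
            & (out.pharmacy["ndc"].astype(str).isin(index_ndcs))
        ]
        if len(rxm) == 0:
            raise ValueError(f"member {mid!r} has no index-DMT fills")
        first = rxm.sort_values("fill_date").iloc[0]
        new = first.copy()
        new["claim_id"] = f"{first['claim_id']}P"
        new["fill_date"] = first["fill_date"] - pd.Timedelta(days=100)
        out.pharmacy = pd.concat(
            [out.pharmacy, new.to_frame().T], ignore_index=True
        )
        out.pharmacy["fill_date"] = pd.to_datetime(out.pharmacy["fill_date"])
        out.pharmacy["days_supply"] = out.pharmacy["days_supply"].astype(float)
        out.pharmacy["paid_amount"] = out.pharmacy["paid_amount"].astype(float)

    for mid in spec.get("missing_gender", []):
        out.members.loc[out.members["member_id"] == mid, "gender"] = ""

    for mid in spec.get("invalid_enrollment", []):
        out.members.loc[out.members["member_id"] == mid, "enrollment"] = (
            "2012-01-01:2011-01-01"
        )

    return out
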