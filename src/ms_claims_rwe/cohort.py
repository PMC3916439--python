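"""Index-switch identification, selection criteria and baseline covariates.

The index event is the first fingolimod or glatiramer acetate initiation
inside the index window whose nearest preceding interferon claim is at most
90 days earlier; that switch defines day 0 of all study windows and is the
only switch assessed. Selection then applies, in order: switch evidence,
continuous enrollment over the full pre+post window, at least one MS
diagnosis claim within the study window, age >= 18 at index; followed by the
exclusions: index DMT in the pre-index period, missing/zero days supply on
index-therapy fills, and data-quality flags. The attrition table conserves
counts: initial n = final n + sum(excluded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .claims import ClaimsBundle, parse_enrollment, validate_bundle
from .dictionaries import CodeDictionary, SYMPTOM_NAMES, COMORBIDITY_NAMES


@dataclass
class IndexEvent:
    member_id: str
    index_date: pd.Timestamp
    index_dmt: str
    last_ifn_date: pd.Timestamp
    switch_gap_days: int


def _dmt_claims(member_pharmacy, member_medical, dictionaries):
    """Dated, classified DMT claims for one member, sorted by (date, class)."""
    claims = []
    for _, row in member_pharmacy.iterrows():
        cls = dictionaries.classify_ndc(row["ndc"])
        if cls is not None:
            claims.append((row["fill_date"], cls))
    for _, row in member_medical.iterrows():
        for code in str(row.get("procedures", "") or "").split(";"):
            if code:
                cls = dictionaries.classify_procedure(code)
                if cls in ("IFN", "GA", "natalizumab"):
                    claims.append((row["service_date"], cls))
    claims.sort(key=lambda t: (t[0], t[1]))
    return claims


def find_index_switch(
    member_pharmacy: pd.DataFrame,
    member_medical: pd.DataFrame,
    dictionaries: CodeDictionary,
    index_window,
    max_gap_days: int = 90,
) -> IndexEvent | None:
    """First qualifying IFN → fingolimod/GA switch inside the index window."""
    lo, hi = pd.Timestamp(index_window[0]), pd.Timestamp(index_window[1])
    claims = _dmt_claims(member_pharmacy, member_medical, dictionaries)
    ifn_dates = [dt for dt, cls in claims if cls == "IFN"]
    for dt, cls in claims:
        if cls not in ("fingolimod", "GA") or not (lo <= dt <= hi):
            continue
        prior_ifn = [x for x in ifn_dates if x <= dt]
        if not prior_ifn:
            continue
        gap = (dt - max(prior_ifn)).days
        if 0 <= gap <= max_gap_days:
            mid = (
                member_pharmacy["member_id"].iloc[0]
                if len(member_pharmacy)
                else member_medical["member_id"].iloc[0]
            )
            return IndexEvent(mid, dt, cls, max(prior_ifn), gap)
    return None


def index_events_table(
    bundle: ClaimsBundle, index_window, max_gap_days: int = 90
) -> pd.DataFrame:
    """Index events for every member of the bundle (row-order independent)."""
    d = bundle.dictionaries
    lo = np.datetime64(pd.Timestamp(index_window[0]), "D").astype(np.int64)
    hi = np.datetime64(pd.Timestamp(index_window[1]), "D").astype(np.int64)

    events = {}  # member -> list of (day, class)
    rx = bundle.pharmacy.reset_index(drop=True)
    if len(rx):
        cls = rx["ndc"].astype(str).map(d.classify_ndc)
        days = rx["fill_date"].values.astype("datetime64[D]").astype(np.int64)
        for mid, day, c in zip(rx["member_id"].values, days, cls.values):
            if c is not None:
                events.setdefault(mid, []).append((int(day), c))
    med = bundle.medical.reset_index(drop=True)
    if len(med):
        lookup = {}
        for c in ("IFN", "GA", "natalizumab", "fingolimod"):
            for code in d.procedure_codes(c):
                lookup[code] = c
        if lookup:
            exploded = med["procedures"].astype(str).str.split(";").explode()
            mapped = exploded.map(lookup).dropna()
            if len(mapped):
                days = med["service_date"].values.astype("datetime64[D]").astype(np.int64)
                for pos, c in mapped.groupby(level=0).first().items():
                    events.setdefault(med["member_id"].iloc[pos], []).append(
                        (int(days[pos]), c)
                    )

    rows = []
    for mid in bundle.members["member_id"]:
        claims = sorted(events.get(mid, []))
        ifn_days = [day for day, c in claims if c == "IFN"]
        for day, c in claims:
            if c not in ("fingolimod", "GA") or not (lo <= day <= hi):
                continue
            prior = [x for x in ifn_days if x <= day]
            if not prior:
                continue
            gap = day - max(prior)
            if gap <= max_gap_days:
                rows.append((mid, day, c, max(prior), gap))
                break
    df = pd.DataFrame(
        rows,
        columns=["member_id", "index_day", "index_dmt", "last_ifn_day", "switch_gap_days"],
    )
    df["index_date"] = pd.to_datetime(df["index_day"].values.astype("datetime64[D]"))
    df["last_ifn_date"] = pd.to_datetime(df["last_ifn_day"].values.astype("datetime64[D]"))
    return df


SELECTION_CRITERIA = [
    "no qualifying IFN switch in index window",
    "not continuously enrolled 360 days pre/post index",
    "no MS diagnosis claim within 360 days of index",
    "aged under 18 at index",
    "index DMT received in pre-index period",
    "missing days supply on index therapy",
    "data quality issues",
]


def apply_selection_criteria(
    bundle: ClaimsBundle,
    index_events: pd.DataFrame,
    pre_days: int = 360,
    horizon: int = 360,
    validation=None,
):
    """Apply inclusion/exclusion criteria in study order.

    Returns ``(cohort, attrition)`` where ``cohort`` is the surviving subset
    of ``index_events`` and ``attrition`` is an ordered table of
    ``(criterion, n_remaining, n_excluded)`` conserving the initial count.
    """
    if validation is None:
        validation = validate_bundle(bundle)
    flagged = validation.flagged_members
    members = bundle.members.set_index("member_id")
    birth_year = members["birth_year"].to_dict()
    enrollment = members["enrollment"].to_dict()
    ev = index_events.set_index("member_id")
    ev_idx_day = ev["index_day"].to_dict()
    ev_dmt = ev["index_dmt"].to_dict()
    d = bundle.dictionaries

    med = bundle.medical.reset_index(drop=True)
    med_days = (
        med["service_date"].values.astype("datetime64[D]").astype(np.int64)
        if len(med)
        else np.array([], dtype=np.int64)
    )
    if len(med):
        ms_any = (
            med["diagnoses"]
            .astype(str)
            .str.replace(".", "", regex=False)
            .str.split(";")
            .explode()
            .str.startswith(tuple(d.ms_prefixes))
            .groupby(level=0)
            .any()
            .values
        )
    else:
        ms_any = np.array([], dtype=bool)
    ms_days_by_member = {}
    for mid, day in zip(med["member_id"].values[ms_any] if len(med) else [], med_days[ms_any] if len(med) else []):
        ms_days_by_member.setdefault(mid, []).append(day)

    rx = bundle.pharmacy.reset_index(drop=True)
    if len(rx):
        rx_cls = rx["ndc"].astype(str).map(d.classify_ndc).values
        rx_days = rx["fill_date"].values.astype("datetime64[D]").astype(np.int64)
        rx_mid = rx["member_id"].values
        rx_supply = rx["days_supply"].values
    else:
        rx_cls = rx_days = rx_mid = rx_supply = np.array([])
    index_fills_by_member = {}
    for j in range(len(rx_mid)):
        if rx_cls[j] in ("fingolimod", "GA"):
            index_fills_by_member.setdefault(rx_mid[j], []).append(
                (int(rx_days[j]), rx_cls[j], rx_supply[j])
            )

    proc_index_by_member = {}
    if len(med):
        lookup = {}
        for c in ("fingolimod", "GA"):
            for code in d.procedure_codes(c):
                lookup[code] = c
        if lookup:
            exploded = med["procedures"].astype(str).str.split(";").explode()
            mapped = exploded.map(lookup).dropna()
            for pos, c in mapped.groupby(level=0).first().items():
                proc_index_by_member.setdefault(med["member_id"].iloc[pos], []).append(
                    (int(med_days[pos]), c)
                )

    n0 = len(bundle.members)
    remaining = list(bundle.members["member_id"])
    attrition_rows = [("members with IFN-to-fingolimod/GA switch claims", n0, 0)]

    def apply(label, keep_fn):
        nonlocal remaining
        kept = [m for m in remaining if keep_fn(m)]
        attrition_rows.append((label, len(kept), len(remaining) - len(kept)))
        remaining = kept

    has_event = set(ev.index)
    apply(SELECTION_CRITERIA[0], lambda m: m in has_event)

    def continuous(m):
        idx = int(ev_idx_day[m])
        lo = pd.Timestamp(np.datetime64(idx - pre_days, "D"))
        hi = pd.Timestamp(np.datetime64(idx + horizon - 1, "D"))
        try:
            spans = parse_enrollment(enrollment[m])
        except (ValueError, TypeError):
            return False
        return any(s <= lo and e >= hi for s, e in spans)

    apply(SELECTION_CRITERIA[1], continuous)

    def has_ms_dx(m):
        idx = int(ev_idx_day[m])
        return any(
            -pre_days <= day - idx <= horizon - 1
            for day in ms_days_by_member.get(m, [])
        )

    apply(SELECTION_CRITERIA[2], has_ms_dx)

    def adult(m):
        by = birth_year[m]
        if pd.isna(by):
            return True  # caught by data-quality screening below
        year = pd.Timestamp(np.datetime64(int(ev_idx_day[m]), "D")).year
        return year - int(by) >= 18

    apply(SELECTION_CRITERIA[3], adult)

    def no_preindex_dmt(m):
        idx = int(ev_idx_day[m])
        cls = ev_dmt[m]
        for day, c, _ in index_fills_by_member.get(m, []):
            if c == cls and day < idx:
                return False
        for day, c in proc_index_by_member.get(m, []):
            if c == cls and day < idx:
                return False
        return True

    apply(SELECTION_CRITERIA[4], no_preindex_dmt)

    def supply_complete(m):
        idx = int(ev_idx_day[m])
        cls = ev_dmt[m]
        for day, c, supply in index_fills_by_member.get(m, []):
            if c == cls and day >= idx and (pd.isna(supply) or supply == 0):
                return False
        return True

    apply(SELECTION_CRITERIA[5], supply_complete)
    apply(SELECTION_CRITERIA[6], lambda m: m not in flagged)

    cohort = index_events[index_events["member_id"].isin(remaining)].reset_index(drop=True)
    attrition = pd.DataFrame(
        attrition_rows, columns=["criterion", "n_remaining", "n_excluded"]
    )
    return cohort, attrition


def attrition_percentage(attrition: pd.DataFrame) -> float:
    """Share of initially identified members excluded, in percent."""
    initial = int(attrition["n_remaining"].iloc[0])
    final = int(attrition["n_remaining"].iloc[-1])
    return 100.0 * (initial - final) / initial if initial else 0.0


# -- baseline covariates ------------------------------------------------------

def baseline_covariates(
    bundle: ClaimsBundle,
    cohort: pd.DataFrame,
    pre_episodes: pd.DataFrame,
    pre_days: int = 360,
) -> pd.DataFrame:
    """Pre-index covariate vector per cohort member.

    Symptom/comorbidity flags come from diagnosis prefix sets over pre-index
    claims; the Charlson score sums the weights of distinct categories
    present; costs sum all pre-index paid amounts; relapse covariates come
    from the supplied pre-index relapse episodes.
    """
    d = bundle.dictionaries
    idx_day = cohort.set_index("member_id")["index_day"]
    mids = cohort["member_id"]

    med = bundle.medical[bundle.medical["member_id"].isin(set(mids))].copy()
    if len(med):
        med["day"] = (
            med["service_date"].values.astype("datetime64[D]").astype(np.int64)
            - med["member_id"].map(idx_day).values
        )
        pre = med[(med["day"] >= -pre_days) & (med["day"] <= -1)]
    else:
        pre = med
    out = pd.DataFrame(index=pd.Index(mids, name="member_id"))

    if len(pre):
        exploded = (
            pre[["member_id", "diagnoses"]]
            .assign(
                diagnoses=pre["diagnoses"]
                .astype(str)
                .str.replace(".", "", regex=False)
                .str.split(";")
            )
            .explode("diagnoses")
        )
        tokens = exploded["diagnoses"].astype(str)
        token_member = exploded["member_id"].values

        def members_with(prefixes):
            if not prefixes:
                return set()
            return set(token_member[tokens.str.startswith(tuple(prefixes)).values])

        for name in SYMPTOM_NAMES:
            out[f"symptom_{name}"] = out.index.isin(members_with(d.symptoms.get(name, ())))
        for name in COMORBIDITY_NAMES:
            out[f"comorbidity_{name}"] = out.index.isin(
                members_with(d.comorbidities.get(name, ()))
            )
        charlson = pd.Series(0, index=out.index, dtype=int)
        for cat in d.charlson:
            present = out.index.isin(members_with(cat.prefixes))
            charlson += np.where(present, cat.weight, 0)
        out["charlson_score"] = charlson
        med_cost = pre.groupby("member_id")["paid_amount"].sum()
    else:
        for name in SYMPTOM_NAMES:
            out[f"symptom_{name}"] = False
        for name in COMORBIDITY_NAMES:
            out[f"comorbidity_{name}"] = False
        out["charlson_score"] = 0
        med_cost = pd.Series(dtype=float)

    rx = bundle.pharmacy[bundle.pharmacy["member_id"].isin(set(mids))].copy()
    if len(rx):
        rx["day"] = (
            rx["fill_date"].values.astype("datetime64[D]").astype(np.int64)
            - rx["member_id"].map(idx_day).values
        )
        rx_pre = rx[(rx["day"] >= -pre_days) & (rx["day"] <= -1)]
        dalf = set(d.ndc_codes("dalfampridine"))
        dalf_members = set(rx_pre[rx_pre["ndc"].astype(str).isin(dalf)]["member_id"])
        rx_cost = rx_pre.groupby("member_id")["paid_amount"].sum()
    else:
        dalf_members = set()
        rx_cost = pd.Series(dtype=float)
    out["dalfampridine_use"] = out.index.isin(dalf_members)
    out["pre_index_total_cost"] = (
        med_cost.reindex(out.index, fill_value=0.0)
        + rx_cost.reindex(out.index, fill_value=0.0)
    )

    # demographics
    members = bundle.members.set_index("member_id")
    index_year = pd.Series(
        [pd.Timestamp(np.datetime64(int(v), "D")).year for v in idx_day.reindex(out.index)],
        index=out.index,
    )
    out["age"] = (index_year - members["birth_year"].reindex(out.index)).astype(float)
    for col in ("gender", "region", "plan_type", "payer_type"):
        out[col] = members[col].reindex(out.index)

    if len(med):
        counts = (
            med.groupby(["member_id", "provider_specialty"], sort=False)
            .size()
            .reset_index(name="n")
            # most frequent specialty; ties break to the lexicographically first
            .sort_values(["member_id", "n", "provider_specialty"], ascending=[True, False, True])
        )
        specialty = counts.drop_duplicates("member_id").set_index("member_id")[
            "provider_specialty"
        ]
    else:
        specialty = pd.Series(dtype=object)
    out["prescriber_specialty"] = specialty.reindex(out.index, fill_value="unknown")

    # relapse history from detected pre-index episodes
    if len(pre_episodes):
        counts = pre_episodes.groupby("member_id").size()
        recent = pre_episodes[pre_episodes["onset_day"] >= -90].groupby("member_id").size()
    else:
        counts = recent = pd.Series(dtype=int)
    out["pre_index_relapse_count"] = counts.reindex(out.index, fill_value=0).astype(int)
    out["relapse_within_90d_pre"] = (
        recent.reindex(out.index, fill_value=0) > 0
    )
    return out.reset_index()


def compute_baseline_covariates(
    member_id: str,
    bundle: ClaimsBundle,
    index_event: IndexEvent,
    pre_episodes: pd.DataFrame,
    pre_days: int = 360,
) -> pd.Series:
    """Covariate vector for a single member (see :func:`baseline_covariates`)."""
    cohort = pd.DataFrame(
        {
            "member_id": [member_id],
            "index_day": [
                np.datetime64(index_event.index_date, "D").astype(np.int64)
            ],
            "index_dmt": [index_event.index_dmt],
        }
    )
    eps = (
        pre_episodes[pre_episodes["member_id"] == member_id]
        if len(pre_episodes)
        else pre_episodes
    )
    return baseline_covariates(bundle, cohort, eps, pre_days).iloc[0]
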