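"""Claims-based MS relapse detection.

The algorithm identifies two kinds of relapse manifestation in claims:

* **inpatient** — an inpatient claim with a *primary* ICD-9-CM diagnosis of
  MS (code 340);
* **outpatient** — an outpatient visit carrying an MS diagnosis (any
  position) together with an oral corticosteroid fill or an intravenous
  corticosteroid administration within the steroid window (default: the 7
  days starting at the visit), unless any claim on the visit date carries a
  primary exclusionary diagnosis (asthma, gout, rheumatoid arthritis,
  uveitis by default — steroids given for another indication).

Events within the same 30-day period are collapsed into a single episode:
the earliest unassigned event anchors an episode and every event within
``collapse_days`` of the anchor joins it (a ``rolling`` chain mode is
available). An episode is inpatient if any constituent event is inpatient.

All windows are inclusive integer day offsets from the member's index date.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .claims import ClaimsBundle
from .dictionaries import CodeDictionary

INPATIENT = "inpatient"
OUTPATIENT = "outpatient"


@dataclass
class RelapseEvent:
    member_id: str
    day: int
    kind: str
    claim_id: str | None = None
    steroid_claim_id: str | None = None


@dataclass
class RelapseEpisode:
    member_id: str
    onset_day: int
    kind: str
    events: list = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return len(self.events)


# -- pure-array kernels (shared by the per-member API and the bundle driver) --

def _steroid_qualifies(visit_day, steroid_days, window_days, symmetric):
    lo = visit_day - window_days if symmetric else visit_day
    hi = visit_day + window_days
    i = np.searchsorted(steroid_days, lo, side="left")
    return i < len(steroid_days) and steroid_days[i] <= hi


def _outpatient_event_days(
    visit_days, steroid_days, exclusion_days, steroid_window_days, symmetric
):
    steroid_days = np.sort(np.asarray(steroid_days))
    excl = set(int(d) for d in exclusion_days)
    out = []
    for d in visit_days:
        d = int(d)
        if d in excl:
            continue
        if _steroid_qualifies(d, steroid_days, steroid_window_days, symmetric):
            out.append(d)
    return out


def collapse_day_array(days, kinds, collapse_days=30, mode="anchor"):
    """Collapse sorted event days into episodes.

    ``anchor`` mode (default): the earliest unassigned event opens an episode
    and every event within ``collapse_days`` of that anchor joins it.
    ``rolling`` mode chains: an event joins the open episode when it is within
    ``collapse_days`` of the *previous* event.

    Returns a list of ``(onset_day, kind, member_indices)``.
    """
    order = np.argsort(days, kind="stable")
    days = np.asarray(days)[order]
    kinds = np.asarray(kinds)[order]
    episodes = []
    i = 0
    n = len(days)
    while i < n:
        anchor = days[i]
        j = i + 1
        last = anchor
        while j < n:
            ref = last if mode == "rolling" else anchor
            if days[j] - ref <= collapse_days:
                last = days[j]
                j += 1
            else:
                break
        kind = INPATIENT if (kinds[i:j] == INPATIENT).any() else OUTPATIENT
        episodes.append((int(anchor), kind, order[i:j].tolist()))
        i = j
    return episodes


# -- per-member API -----------------------------------------------------------

def _member_frames(member_claims, index_date):
    med = member_claims.copy()
    med["day"] = (med["service_date"] - index_date).dt.days
    primary = (
        med["diagnoses"].astype(str).str.split(";").str[0].str.replace(".", "", regex=False)
    )
    med["_primary"] = primary
    return med


def detect_inpatient_events(
    member_claims: pd.DataFrame,
    dictionaries: CodeDictionary,
    index_date,
    window,
) -> list[RelapseEvent]:
    """One event per inpatient claim with primary MS diagnosis inside the window."""
    med = _member_frames(member_claims, index_date)
    lo, hi = window
    events = []
    for _, row in med.iterrows():
        if (
            row["setting"] == INPATIENT
            and dictionaries.is_ms(row["_primary"])
            and lo <= row["day"] <= hi
        ):
            events.append(
                RelapseEvent(row["member_id"], int(row["day"]), INPATIENT, row["claim_id"])
            )
    return sorted(events, key=lambda e: e.day)


def detect_outpatient_events(
    member_claims: pd.DataFrame,
    pharmacy_claims: pd.DataFrame,
    dictionaries: CodeDictionary,
    index_date,
    window,
    steroid_window_days: int = 7,
    symmetric_steroid: bool = False,
) -> list[RelapseEvent]:
    """Outpatient MS-diagnosis visits with qualifying corticosteroid use.

    A steroid claim is an oral corticosteroid NDC fill or an IV corticosteroid
    procedure. Visits sharing a date with any claim whose primary diagnosis is
    exclusionary are rejected.
    """
    med = _member_frames(member_claims, index_date)
    lo, hi = window

    steroid = []
    for _, row in pharmacy_claims.iterrows():
        if dictionaries.classify_ndc(row["ndc"]) == "oral_corticosteroid":
            steroid.append(((row["fill_date"] - index_date).days, row["claim_id"]))
    for _, row in med.iterrows():
        for code in str(row.get("procedures", "") or "").split(";"):
            if code and dictionaries.classify_procedure(code) == "iv_corticosteroid":
                steroid.append((int(row["day"]), row["claim_id"]))
                break
    steroid.sort()
    steroid_days = np.array([d for d, _ in steroid], dtype=int)

    exclusion_days = {
        int(row["day"])
        for _, row in med.iterrows()
        if dictionaries.is_exclusionary(row["_primary"])
    }

    events = []
    for _, row in med.iterrows():
        if row["setting"] != OUTPATIENT or not (lo <= row["day"] <= hi):
            continue
        codes = str(row["diagnoses"]).split(";")
        if not any(dictionaries.is_ms(c) for c in codes):
            continue
        day = int(row["day"])
        if day in exclusion_days:
            continue
        if _steroid_qualifies(day, steroid_days, steroid_window_days, symmetric_steroid):
            i = np.searchsorted(
                steroid_days, day - steroid_window_days if symmetric_steroid else day
            )
            events.append(
                RelapseEvent(
                    row["member_id"], day, OUTPATIENT, row["claim_id"], steroid[i][1]
                )
            )
    return sorted(events, key=lambda e: e.day)


def collapse_events(
    events: list[RelapseEvent], collapse_days: int = 30, mode: str = "anchor"
) -> list[RelapseEpisode]:
    """Merge events within the same ``collapse_days`` period into episodes."""
    if not events:
        return []
    days = [e.day for e in events]
    kinds = [e.kind for e in events]
    episodes = []
    for onset, kind, idx in collapse_day_array(days, kinds, collapse_days, mode):
        episodes.append(
            RelapseEpisode(events[0].member_id, onset, kind, [events[i] for i in idx])
        )
    return episodes


def count_relapses(
    episodes: list[RelapseEpisode], window, persistence_end_day: int | None = None
):
    """Count episodes with onset inside the window (and, when a persistence
    result is supplied, with onset on or before its end day)."""
    lo, hi = window
    kept = [e for e in episodes if lo <= e.onset_day <= hi]
    if persistence_end_day is not None:
        kept = [e for e in kept if e.onset_day <= persistence_end_day]
    return len(kept), kept


# -- bundle-level driver ------------------------------------------------------

class RelapseDetector:
    """Vectorized detector over a whole bundle.

    Precomputes per-member claim-day arrays once; :meth:`episodes` then
    evaluates any window against any member→index-date map. Results are
    independent of claim row order.
    """

    def __init__(self, bundle: ClaimsBundle):
        d = bundle.dictionaries
        med = bundle.medical.reset_index(drop=True)
        n = len(med)
        if n:
            dxs = med["diagnoses"].astype(str).str.replace(".", "", regex=False)
            split = dxs.str.split(";")
            primary = split.str[0]
            ms_pref = tuple(d.ms_prefixes)
            excl_pref = tuple(d.exclusionary_primary)
            primary_ms = primary.str.startswith(ms_pref)
            primary_excl = (
                primary.str.startswith(excl_pref) if excl_pref else pd.Series(False, index=med.index)
            )
            exploded = split.explode()
            any_ms = (
                exploded.str.startswith(ms_pref).groupby(level=0).any().reindex(med.index, fill_value=False)
            )
            iv_codes = set(d.procedure_codes("iv_corticosteroid"))
            if iv_codes:
                proc = med["procedures"].astype(str).str.split(";").explode()
                iv = proc.isin(iv_codes).groupby(level=0).any().reindex(med.index, fill_value=False)
            else:
                iv = pd.Series(False, index=med.index)
            day = med["service_date"].values.astype("datetime64[D]").astype(np.int64)
            inpat = (med["setting"] == INPATIENT).values
            mids = med["member_id"].values
            self._inpat_ms = _group_days(mids, day, (inpat & primary_ms.values))
            self._outpat_ms = _group_days(mids, day, (~inpat & any_ms.values))
            self._excl = _group_days(mids, day, primary_excl.values)
            iv_days = _group_days(mids, day, iv.values)
        else:
            self._inpat_ms = self._outpat_ms = self._excl = {}
            iv_days = {}

        rx = bundle.pharmacy.reset_index(drop=True)
        if len(rx):
            oral = set(d.ndc_codes("oral_corticosteroid"))
            is_oral = rx["ndc"].astype(str).isin(oral).values
            fday = rx["fill_date"].values.astype("datetime64[D]").astype(np.int64)
            oral_days = _group_days(rx["member_id"].values, fday, is_oral)
        else:
            oral_days = {}
        self._steroid = {}
        for mid in set(iv_days) | set(oral_days):
            self._steroid[mid] = np.sort(
                np.concatenate(
                    [iv_days.get(mid, _EMPTY), oral_days.get(mid, _EMPTY)]
                )
            )

    def episodes(
        self,
        index_dates: pd.Series,
        window,
        steroid_window_days: int = 7,
        symmetric_steroid: bool = False,
        collapse_days: int = 30,
        collapse_mode: str = "anchor",
    ) -> pd.DataFrame:
        """Detected relapse episodes per member.

        ``index_dates`` maps member_id → index date. Returns a DataFrame with
        columns ``member_id, onset_day, kind, n_events, has_inpatient,
        has_outpatient`` (one row per episode; members without episodes are
        absent).
        """
        lo, hi = window
        idx_days = index_dates.astype("datetime64[ns]").values.astype("datetime64[D]").astype(np.int64)
        rows = []
        for mid, idx_day in zip(index_dates.index, idx_days):
            inpat = self._inpat_ms.get(mid, _EMPTY) - idx_day
            outpat = self._outpat_ms.get(mid, _EMPTY) - idx_day
            inpat = inpat[(inpat >= lo) & (inpat <= hi)]
            outpat = outpat[(outpat >= lo) & (outpat <= hi)]
            ev_days = list(inpat)
            ev_kinds = [INPATIENT] * len(inpat)
            if len(outpat):
                steroid = self._steroid.get(mid, _EMPTY) - idx_day
                excl = self._excl.get(mid, _EMPTY) - idx_day
                out_days = _outpatient_event_days(
                    np.unique(outpat), steroid, excl, steroid_window_days, symmetric_steroid
                )
                ev_days.extend(out_days)
                ev_kinds.extend([OUTPATIENT] * len(out_days))
            if not ev_days:
                continue
            kinds_arr = np.array(ev_kinds)
            for onset, kind, idxs in collapse_day_array(
                ev_days, ev_kinds, collapse_days, collapse_mode
            ):
                member_kinds = kinds_arr[idxs]
                rows.append(
                    (
                        mid,
                        onset,
                        kind,
                        len(idxs),
                        bool((member_kinds == INPATIENT).any()),
                        bool((member_kinds == OUTPATIENT).any()),
                    )
                )
        return pd.DataFrame(
            rows,
            columns=[
                "member_id",
                "onset_day",
                "kind",
                "n_events",
                "has_inpatient",
                "has_outpatient",
            ],
        )


_EMPTY = np.array([], dtype=np.int64)


def _group_days(member_ids, days, mask) -> dict:
    out: dict = {}
    if not mask.any():
        return out
    mids = member_ids[mask]
    ds = days[mask]
    order = np.argsort(mids, kind="stable")
    mids = mids[order]
    ds = ds[order]
    boundaries = np.flatnonzero(np.r_[True, mids[1:] != mids[:-1]])
    for start, stop in zip(boundaries, np.r_[boundaries[1:], len(mids)]):
        out[mids[start]] = np.sort(ds[start:stop])
    return out


def episode_counts(
    episodes: pd.DataFrame, member_ids, persistence_end: pd.Series | None = None
) -> pd.Series:
    """Per-member episode counts (0 for members without episodes).

    When ``persistence_end`` (member_id → last persistent day offset) is
    given, only episodes with onset on or before that day are counted.
    """
    ep = episodes
    if persistence_end is not None and len(ep):
        end = ep["member_id"].map(persistence_end)
        ep = ep[ep["onset_day"] <= end]
    counts = ep.groupby("member_id").size() if len(ep) else pd.Series(dtype=int)
    return counts.reindex(member_ids, fill_value=0).astype(int)
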