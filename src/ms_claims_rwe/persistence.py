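"""Index-therapy exposure and persistence.

Pharmacy fills (with days supply) and clinic administrations (fixed coverage
per administration) accumulate into a coverage timeline under a stockpiling
policy: an early refill queues behind remaining supply, so coverage extends
end-to-end. The *runout day* is the first uncovered day after the last
accumulated supply.

Persistence ends at the first of:

* **discontinuation** — a gap in exposure of at least ``gap_days`` (default
  60) following the runout day: the next fill arrives ``>= gap_days`` after
  runout, or no fill arrives and the horizon is ``>= gap_days`` past runout.
  Days persistent = the runout offset (the count of covered days).
* **switch** — a claim for a different DMT of interest (IFN, GA, fingolimod,
  natalizumab) before the discontinuation gap completes; days persistent =
  the switch-claim day (persistence ends the day before).
* **censoring** at the horizon (default 360 days).

All days are integer offsets from the index date (day 0 = index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DISCONTINUED = "discontinued"
SWITCHED = "switched"
CENSORED = "censored"


@dataclass
class ExposureEpisode:
    """Coverage segments [start, end) built from index-therapy claims."""

    member_id: str
    segments: list  # list of (start_day, end_day_exclusive)

    @property
    def runout_day(self) -> int:
        """First uncovered day after all supply is exhausted."""
        return self.segments[-1][1] if self.segments else 0

    @property
    def runouts(self) -> list:
        return [end for _, end in self.segments]


@dataclass
class PersistenceResult:
    member_id: str
    days_persistent: int
    reason: str
    switch_to: str | None = None

    @property
    def end_day(self) -> int:
        """Last persistent day as an offset from index (index + days − 1)."""
        return self.days_persistent - 1


def build_exposure(
    member_id,
    fill_days,
    days_supply,
    admin_days=(),
    admin_coverage_days: int = 28,
    stockpile: bool = True,
) -> ExposureEpisode:
    """Accumulate index-DMT fills/administrations into coverage segments.

    ``fill_days``/``days_supply`` are aligned arrays for pharmacy fills;
    ``admin_days`` are clinic administrations, each covering
    ``admin_coverage_days``. A missing days supply is an error here — such
    members are excluded upstream.
    """
    supplies = list(zip(fill_days, days_supply)) + [
        (d, admin_coverage_days) for d in admin_days
    ]
    if any(s is None or (isinstance(s, float) and np.isnan(s)) for _, s in supplies):
        raise ValueError(f"member {member_id}: fill with missing days supply")
    supplies.sort(key=lambda t: t[0])
    segments = []
    for day, supply in supplies:
        day, supply = int(day), int(supply)
        if supply <= 0:
            raise ValueError(f"member {member_id}: fill with missing days supply")
        if segments and day < segments[-1][1]:
            if stockpile:
                # queue the refill behind remaining supply
                start = segments[-1][1]
            else:
                # truncate: coverage restarts at the fill
                segments[-1] = (segments[-1][0], day)
                start = day
        else:
            start = day
        if segments and start == segments[-1][1]:
            segments[-1] = (segments[-1][0], start + supply)
        else:
            segments.append((start, start + supply))
    return ExposureEpisode(member_id, segments)


def find_persistence_end(
    exposure: ExposureEpisode,
    other_dmt_claims=(),
    gap_days: int = 60,
    horizon: int = 360,
) -> PersistenceResult:
    """Determine how and when persistence with the index DMT ended.

    ``other_dmt_claims`` is an iterable of ``(day, drug_class)`` for claims of
    DMTs other than the index DMT, day > 0. The earliest applicable reason
    wins; a switch claim arriving before a discontinuation gap completes takes
    precedence over the discontinuation.
    """
    segments = exposure.segments
    disc_runout = None
    if not segments and horizon >= gap_days:
        disc_runout = 0
    for i, (_, end) in enumerate(segments):
        nxt = segments[i + 1][0] if i + 1 < len(segments) else None
        if nxt is None:
            if horizon - end >= gap_days:
                disc_runout = end
            break
        if nxt - end >= gap_days:
            disc_runout = end
            break

    switches = sorted((int(d), c) for d, c in other_dmt_claims if 0 < int(d) <= horizon)
    for day, cls in switches:
        # a switch only counts while the member has not already discontinued
        if disc_runout is None or day < disc_runout + gap_days:
            if day >= horizon:
                break
            return PersistenceResult(
                exposure.member_id, min(day, horizon), SWITCHED, switch_to=cls
            )
        break

    if disc_runout is not None and disc_runout < horizon:
        return PersistenceResult(exposure.member_id, disc_runout, DISCONTINUED)
    return PersistenceResult(exposure.member_id, horizon, CENSORED)


def persistence_table(
    bundle,
    index_events: pd.DataFrame,
    gap_days: int = 60,
    horizon: int = 360,
    admin_coverage_days: int = 28,
    stockpile: bool = True,
) -> pd.DataFrame:
    """Per-member persistence results for a cohort.

    ``index_events`` needs columns ``member_id, index_date, index_dmt``.
    Returns ``member_id, days_persistent, reason, switch_to, end_day``.
    """
    d = bundle.dictionaries
    rx = bundle.pharmacy.reset_index(drop=True)
    if len(rx):
        ndc_class = rx["ndc"].astype(str).map(d.classify_ndc).to_numpy()
        rx_day = rx["fill_date"].values.astype("datetime64[D]").astype(np.int64)
        rx_supply = rx["days_supply"].to_numpy()
    else:
        ndc_class = np.array([], dtype=object)
        rx_day = np.array([], dtype=np.int64)
        rx_supply = np.array([])

    med = bundle.medical.reset_index(drop=True)
    proc_class = np.full(len(med), None, dtype=object)
    if len(med):
        lookup = {}
        for cls in ("IFN", "GA", "natalizumab"):
            for code in d.procedure_codes(cls):
                lookup[code] = cls
        if lookup:
            exploded = med["procedures"].astype(str).str.split(";").explode()
            mapped = exploded.map(lookup).dropna()
            if len(mapped):
                first = mapped.groupby(level=0).first()
                proc_class[first.index.to_numpy()] = first.to_numpy()
        med_day = med["service_date"].values.astype("datetime64[D]").astype(np.int64)
    else:
        med_day = np.array([], dtype=np.int64)

    dmt_classes = set(("IFN", "GA", "fingolimod", "natalizumab"))
    rows = []
    rx_groups = rx.groupby("member_id").indices if len(rx) else {}
    med_has_proc = np.flatnonzero(proc_class != None)  # noqa: E711
    med_groups = (
        pd.Series(med_has_proc)
        .groupby(med["member_id"].to_numpy()[med_has_proc])
        .apply(list)
        .to_dict()
        if len(med_has_proc)
        else {}
    )
    ev_mids = index_events["member_id"].to_numpy()
    ev_idx_days = (
        index_events["index_date"].values.astype("datetime64[D]").astype(np.int64)
    )
    ev_dmts = index_events["index_dmt"].to_numpy()
    for mid, idx_day, index_dmt in zip(ev_mids, ev_idx_days, ev_dmts):
        fill_days, supplies, others = [], [], []
        for i in rx_groups.get(mid, ()):
            cls = ndc_class[i]
            if cls is None:
                continue
            day = int(rx_day[i] - idx_day)
            if cls == index_dmt and day >= 0:
                fill_days.append(day)
                supplies.append(rx_supply[i])
            elif cls in dmt_classes and cls != index_dmt and day > 0:
                others.append((day, cls))
        admin_days = []
        for i in med_groups.get(mid, ()):
            cls = proc_class[i]
            day = int(med_day[i] - idx_day)
            if cls == index_dmt and day >= 0:
                admin_days.append(day)
            elif cls != index_dmt and day > 0:
                others.append((day, cls))
        exposure = build_exposure(
            mid, fill_days, supplies, admin_days, admin_coverage_days, stockpile
        )
        res = find_persistence_end(exposure, others, gap_days, horizon)
        rows.append(
            (mid, res.days_persistent, res.reason, res.switch_to, res.end_day)
        )
    return pd.DataFrame(
        rows, columns=["member_id", "days_persistent", "reason", "switch_to", "end_day"]
    )


def summarize_persistence(results: pd.DataFrame, arms: pd.Series, horizon: int = 360):
    """Arm-level persistence summary: proportion persistent at the horizon
    (reason == censored) and mean ± SD of days persistent."""
    df = results.copy()
    df["arm"] = df["member_id"].map(arms)
    out = []
    for arm, grp in df.groupby("arm"):
        out.append(
            {
                "arm": arm,
                "n": len(grp),
                "proportion_persistent": float((grp["reason"] == CENSORED).mean()),
                "mean_days": float(grp["days_persistent"].mean()),
                "sd_days": float(grp["days_persistent"].std(ddof=1)) if len(grp) > 1 else 0.0,
                "median_days": float(grp["days_persistent"].median()),
            }
        )
    return pd.DataFrame(out)
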