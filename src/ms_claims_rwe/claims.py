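"""Claims data schema, delimited-text I/O and data-quality validation.

The bundle holds three linked tables as pandas DataFrames:

* ``members`` — one row per health-plan member: ``member_id``, ``birth_year``,
  ``gender`` (F/M), ``region``, ``plan_type``, ``payer_type`` and
  ``enrollment`` (semicolon-joined closed date intervals
  ``YYYY-MM-DD:YYYY-MM-DD``).
* ``medical`` — medical claims: ``claim_id``, ``member_id``, ``service_date``,
  ``setting`` (inpatient/outpatient), ``diagnoses`` (semicolon-joined ICD-9-CM
  codes, position 1 = primary), ``procedures`` (semicolon-joined, may be
  empty), ``provider_specialty``, ``paid_amount``.
* ``pharmacy`` — pharmacy claims: ``claim_id``, ``member_id``, ``fill_date``,
  ``ndc``, ``days_supply`` (NaN when missing — distinct from zero) and
  ``paid_amount``.

Dates are ISO-8601 externally; analysis stages convert to integer day offsets
from each member's index date.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dictionaries import CodeDictionary

MEMBER_COLUMNS = [
    "member_id",
    "birth_year",
    "gender",
    "region",
    "plan_type",
    "payer_type",
    "enrollment",
]
MEDICAL_COLUMNS = [
    "claim_id",
    "member_id",
    "service_date",
    "setting",
    "diagnoses",
    "procedures",
    "provider_specialty",
    "paid_amount",
]
PHARMACY_COLUMNS = [
    "claim_id",
    "member_id",
    "fill_date",
    "ndc",
    "days_supply",
    "paid_amount",
]


class SchemaError(ValueError):
    """A required column is missing or a table is unusable."""


def parse_enrollment(spec: str) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Parse ``start:end;start:end`` into ordered closed intervals.

    Administrative 1-day boundary joins (next start == previous end + 1 day)
    are merged, so downstream continuity checks see one span.
    """
    if spec is None or (isinstance(spec, float) and np.isnan(spec)) or spec == "":
        return []
    spans = []
    for part in str(spec).split(";"):
        start_s, _, end_s = part.partition(":")
        spans.append((pd.Timestamp(start_s), pd.Timestamp(end_s)))
    spans.sort(key=lambda se: se[0])
    merged = [spans[0]]
    for start, end in spans[1:]:
        last_start, last_end = merged[-1]
        if start <= last_end + pd.Timedelta(days=1):
            merged[-1] = (last_start, max(last_end, end))
        else:
            merged.append((start, end))
    return merged


def format_enrollment(spans) -> str:
    return ";".join(f"{s.date()}:{e.date()}" for s, e in spans)


@dataclass
class ClaimsBundle:
    """The linked claims universe every analysis stage consumes."""

    members: pd.DataFrame
    medical: pd.DataFrame
    pharmacy: pd.DataFrame
    dictionaries: CodeDictionary
    calendar_start: pd.Timestamp | None = None
    calendar_end: pd.Timestamp | None = None

    def __post_init__(self):
        if self.calendar_start is None or self.calendar_end is None:
            dates = []
            if len(self.medical):
                dates.append(self.medical["service_date"].min())
                dates.append(self.medical["service_date"].max())
            if len(self.pharmacy):
                dates.append(self.pharmacy["fill_date"].min())
                dates.append(self.pharmacy["fill_date"].max())
            if dates:
                self.calendar_start = self.calendar_start or min(dates)
                self.calendar_end = self.calendar_end or max(dates)

    @property
    def member_ids(self) -> pd.Index:
        return pd.Index(self.members["member_id"])

    def copy(self) -> "ClaimsBundle":
        return ClaimsBundle(
            self.members.copy(),
            self.medical.copy(),
            self.pharmacy.copy(),
            self.dictionaries,
            self.calendar_start,
            self.calendar_end,
        )


@dataclass
class RejectReport:
    """Rows dropped at load time, with the reason — never silently discarded."""

    rows: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["table", "row", "reason"])
    )

    def add(self, table: str, row_index: int, reason: str) -> None:
        self.rows.loc[len(self.rows)] = [table, int(row_index), reason]

    def __len__(self) -> int:
        return len(self.rows)


def _require_columns(df: pd.DataFrame, required, table: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{table} table is missing required column {col!r}")


def _read_table(path, sep):
    return pd.read_csv(
        path, sep=sep, engine="python" if sep is None else "c", dtype=str,
        keep_default_na=False,
    )


def read_claims_bundle(
    member_path,
    medical_path,
    pharmacy_path,
    dictionary_path=None,
    sep: str | None = None,
):
    """Load the three claim tables plus dictionaries into a linked bundle.

    ``sep=None`` autodetects the delimiter (CSV/TSV). Unparseable rows are
    collected into the returned :class:`RejectReport`, not silently dropped.

    Returns ``(bundle, rejects)``.
    """
    dictionaries = (
        CodeDictionary.from_yaml(dictionary_path)
        if dictionary_path is not None
        else CodeDictionary.default()
    )
    rejects = RejectReport()

    members_raw = _read_table(member_path, sep)
    _require_columns(members_raw, MEMBER_COLUMNS, "member")
    if len(members_raw) == 0:
        raise SchemaError("member table is empty")
    keep = []
    for i, row in members_raw.iterrows():
        if row["member_id"] == "":
            rejects.add("member", i, "missing member_id")
            continue
        keep.append(i)
    members = members_raw.loc[keep, MEMBER_COLUMNS].reset_index(drop=True)
    members["birth_year"] = pd.to_numeric(members["birth_year"], errors="coerce")
    known = set(members["member_id"])

    medical_raw = _read_table(medical_path, sep)
    _require_columns(medical_raw, MEDICAL_COLUMNS, "medical")
    dates = pd.to_datetime(medical_raw["service_date"], errors="coerce")
    keep = []
    for i, row in medical_raw.iterrows():
        if row["member_id"] not in known:
            rejects.add("medical", i, "unknown member_id")
        elif row["diagnoses"].strip(";") == "":
            rejects.add("medical", i, "empty diagnosis field")
        elif pd.isna(dates.iloc[i]):
            rejects.add("medical", i, "unparseable service_date")
        elif row["setting"] not in ("inpatient", "outpatient"):
            rejects.add("medical", i, "invalid setting")
        else:
            keep.append(i)
    medical = medical_raw.loc[keep, MEDICAL_COLUMNS].reset_index(drop=True)
    medical["service_date"] = pd.to_datetime(medical["service_date"])
    medical["paid_amount"] = pd.to_numeric(
        medical["paid_amount"], errors="coerce"
    ).fillna(0.0)

    pharmacy_raw = _read_table(pharmacy_path, sep)
    _require_columns(pharmacy_raw, PHARMACY_COLUMNS, "pharmacy")
    dates = pd.to_datetime(pharmacy_raw["fill_date"], errors="coerce")
    supply_raw = pharmacy_raw["days_supply"]
    supply = pd.to_numeric(supply_raw.where(supply_raw != ""), errors="coerce")
    keep = []
    for i, row in pharmacy_raw.iterrows():
        if row["member_id"] not in known:
            rejects.add("pharmacy", i, "unknown member_id")
        elif pd.isna(dates.iloc[i]):
            rejects.add("pharmacy", i, "unparseable fill_date")
        elif not np.isnan(supply.iloc[i]) and supply.iloc[i] < 0:
            rejects.add("pharmacy", i, "negative days_supply")
        else:
            keep.append(i)
    pharmacy = pharmacy_raw.loc[keep, PHARMACY_COLUMNS].reset_index(drop=True)
    pharmacy["fill_date"] = pd.to_datetime(pharmacy["fill_date"])
    # NaN marks a missing days supply; 0 is a recorded zero — kept distinct.
    pharmacy["days_supply"] = pd.to_numeric(
        pharmacy["days_supply"].where(pharmacy["days_supply"] != ""), errors="coerce"
    )
    pharmacy["paid_amount"] = pd.to_numeric(
        pharmacy["paid_amount"], errors="coerce"
    ).fillna(0.0)

    return ClaimsBundle(members, medical, pharmacy, dictionaries), rejects


def write_bundle(bundle: ClaimsBundle, out_dir, sep: str = ",") -> dict:
    """Write the bundle to canonical delimited text; returns written paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "member": out / "members.csv",
        "medical": out / "medical_claims.csv",
        "pharmacy": out / "pharmacy_claims.csv",
        "dictionary": out / "dictionaries.yaml",
    }
    members = bundle.members.copy()
    members["birth_year"] = members["birth_year"].astype("Int64")
    members.to_csv(paths["member"], sep=sep, index=False)
    medical = bundle.medical.copy()
    medical["service_date"] = medical["service_date"].dt.strftime("%Y-%m-%d")
    medical.to_csv(paths["medical"], sep=sep, index=False, float_format="%.2f")
    pharmacy = bundle.pharmacy.copy()
    pharmacy["fill_date"] = pharmacy["fill_date"].dt.strftime("%Y-%m-%d")
    pharmacy["days_supply"] = pharmacy["days_supply"].map(
        lambda v: "" if pd.isna(v) else str(int(v))
    )
    pharmacy.to_csv(paths["pharmacy"], sep=sep, index=False, float_format="%.2f")
    bundle.dictionaries.to_yaml(paths["dictionary"])
    return paths


# -- validation ---------------------------------------------------------------

VALIDATION_ISSUES = (
    "invalid_enrollment",
    "missing_age",
    "missing_gender",
    "claim_outside_enrollment",
)


@dataclass
class ValidationReport:
    """Per-member data-quality violations; report-only, never raises."""

    issues: pd.DataFrame

    @property
    def flagged_members(self) -> set:
        return set(self.issues["member_id"])

    def __len__(self) -> int:
        return len(self.issues)


def validate_bundle(bundle: ClaimsBundle) -> ValidationReport:
    """Data-quality screen gating study entry.

    Flags members with invalid enrollment spans (end before start, overlap),
    missing/invalid age or gender, or claims dated outside every enrollment
    span.
    """
    records = []
    spans_by_member = {}
    for mid, enrollment, birth_year, gender in zip(
        bundle.members["member_id"].to_numpy(),
        bundle.members["enrollment"].to_numpy(),
        bundle.members["birth_year"].to_numpy(),
        bundle.members["gender"].to_numpy(),
    ):
        ok = True
        try:
            raw = (
                [
                    (
                        np.datetime64(p.partition(":")[0], "D").astype(np.int64),
                        np.datetime64(p.partition(":")[2], "D").astype(np.int64),
                    )
                    for p in str(enrollment).split(";")
                ]
                if enrollment
                else []
            )
        except (ValueError, TypeError):
            raw, ok = [], False
        if not raw:
            ok = False
        for start, end in raw:
            if end < start:
                ok = False
        raw.sort()
        for (s1, e1), (s2, e2) in zip(raw, raw[1:]):
            if s2 <= e1:
                ok = False
        if not ok:
            records.append((mid, "invalid_enrollment"))
        spans_by_member[mid] = raw if ok else []
        if pd.isna(birth_year) or not (1900 <= float(birth_year) <= 2020):
            records.append((mid, "missing_age"))
        if gender not in ("F", "M"):
            records.append((mid, "missing_gender"))

    outside = set()
    for df, date_col in ((bundle.medical, "service_date"), (bundle.pharmacy, "fill_date")):
        if not len(df):
            continue
        days = df[date_col].values.astype("datetime64[D]").astype(np.int64)
        mids = df["member_id"].to_numpy()
        order = np.argsort(mids, kind="stable")
        mids_s, days_s = mids[order], days[order]
        starts = np.flatnonzero(np.r_[True, mids_s[1:] != mids_s[:-1]])
        for start, stop in zip(starts, np.r_[starts[1:], len(mids_s)]):
            mid = mids_s[start]
            spans = spans_by_member.get(mid, [])
            if not spans or mid in outside:
                continue
            chunk = days_s[start:stop]
            covered = np.zeros(len(chunk), dtype=bool)
            for s, e in spans:
                covered |= (chunk >= s) & (chunk <= e)
            if not covered.all():
                outside.add(mid)
    records.extend((mid, "claim_outside_enrollment") for mid in sorted(outside))

    issues = pd.DataFrame(records, columns=["member_id", "issue"])
    return ValidationReport(issues.sort_values(["member_id", "issue"]).reset_index(drop=True))


def classify_claim(claim, dictionaries: CodeDictionary) -> str | None:
    """Drug class of a single claim row: NDC lookup for pharmacy claims,
    procedure lookup for medical claims; ``None`` when nothing matches."""
    if "ndc" in claim and not pd.isna(claim.get("ndc")):
        return dictionaries.classify_ndc(claim["ndc"])
    procs = str(claim.get("procedures", "") or "")
    for code in procs.split(";"):
        if code:
            cls = dictionaries.classify_procedure(code)
            if cls is not None:
                return cls
    return None
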