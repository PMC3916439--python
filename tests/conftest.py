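from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ms_claims_rwe import CodeDictionary, ClaimsBundle, SimulationConfig, generate_bundle

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# Reference date used by hand-built fixtures; inside the default index window.
BASE = pd.Timestamp("2011-01-15")


def D(day: int) -> pd.Timestamp:
    return BASE + pd.Timedelta(days=int(day))


def mk_member(mid, birth_year=1970, gender="F", enrollment=(-400, 400), **kw):
    lo, hi = enrollment
    return {
        "member_id": mid,
        "birth_year": birth_year,
        "gender": gender,
        "region": kw.get("region", "midwest"),
        "plan_type": kw.get("plan_type", "PPO"),
        "payer_type": kw.get("payer_type", "commercial"),
        "enrollment": f"{D(lo).date()}:{D(hi).date()}",
    }


def mk_med(cid, mid, day, setting="outpatient", dx="340", procs="", specialty="neurology", paid=100.0):
    return {
        "claim_id": cid,
        "member_id": mid,
        "service_date": D(day),
        "setting": setting,
        "diagnoses": dx,
        "procedures": procs,
        "provider_specialty": specialty,
        "paid_amount": paid,
    }


def mk_rx(cid, mid, day, ndc, supply=30, paid=100.0):
    return {
        "claim_id": cid,
        "member_id": mid,
        "fill_date": D(day),
        "ndc": ndc,
        "days_supply": float(supply) if supply is not None else np.nan,
        "paid_amount": paid,
    }


def toy_bundle(members, medical=(), pharmacy=(), dictionaries=None) -> ClaimsBundle:
    d = dictionaries or CodeDictionary.default()
    mdf = pd.DataFrame(members)
    meddf = pd.DataFrame(
        list(medical),
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
    rxdf = pd.DataFrame(
        list(pharmacy),
        columns=["claim_id", "member_id", "fill_date", "ndc", "days_supply", "paid_amount"],
    )
    meddf["service_date"] = pd.to_datetime(meddf["service_date"])
    rxdf["fill_date"] = pd.to_datetime(rxdf["fill_date"])
    return ClaimsBundle(mdf, meddf, rxdf, d)


@pytest.fixture(scope="session")
def dictionaries() -> CodeDictionary:
    return CodeDictionary.default()


@pytest.fixture(scope="session")
def codes(dictionaries):
    """Convenient single codes per drug class."""
    return {
        "IFN": dictionaries.ndc_codes("IFN")[0],
        "GA": dictionaries.ndc_codes("GA")[0],
        "fingolimod": dictionaries.ndc_codes("fingolimod")[0],
        "natalizumab": dictionaries.ndc_codes("natalizumab")[0],
        "dalfampridine": dictionaries.ndc_codes("dalfampridine")[0],
        "oral_steroid": dictionaries.ndc_codes("oral_corticosteroid")[0],
        "iv_steroid_proc": dictionaries.procedure_codes("iv_corticosteroid")[0],
        "ifn_proc": dictionaries.procedure_codes("IFN")[0],
    }


@pytest.fixture(scope="session")
def small_bundle():
    """A clean generated bundle shared by read-only tests."""
    cfg = SimulationConfig(n_members=40, seed=7)
    return generate_bundle(cfg)
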