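import numpy as np
import pandas as pd
import pytest

from ms_claims_rwe import (
    IndexEvent,
    SimulationConfig,
    apply_selection_criteria,
    attrition_percentage,
    baseline_covariates,
    compute_baseline_covariates,
    find_index_switch,
    generate_bundle,
    index_events_table,
    inject_pathologies,
)
from ms_claims_rwe.cohort import SELECTION_CRITERIA

from conftest import BASE, D, mk_med, mk_member, mk_rx, toy_bundle


def switch_oracle(dmt_claims, window, max_gap=90):
    """Exhaustive scan: all (candidate, prior-IFN) combinations in date
    order; the first candidate with a qualifying gap wins."""
    lo, hi = window
    for day, cls in sorted(dmt_claims):
        if cls not in ("fingolimod", "GA") or not (lo <= day <= hi):
            continue
        priors = [d for d, c in dmt_claims if c == "IFN" and d <= day]
        if priors and day - max(priors) <= max_gap:
            return day, cls
    return None


class TestIndexSwitch:
    def test_simple_switch(self, dictionaries, codes):
        b = toy_bundle(
            [mk_member("m1")],
            pharmacy=[
                mk_rx("r1", "m1", -20, codes["IFN"]),
                mk_rx("r2", "m1", 0, codes["GA"]),
            ],
        )
        ev = find_index_switch(
            b.pharmacy, b.medical, dictionaries, (D(-30), D(30))
        )
        assert ev.index_dmt == "GA"
        assert ev.switch_gap_days == 20
        assert ev.index_date == BASE

    def test_gap_over_ninety_days_disqualifies(self, dictionaries, codes):
        b = toy_bundle(
            [mk_member("m1")],
            pharmacy=[
                mk_rx("r1", "m1", -120, codes["IFN"]),
                mk_rx("r2", "m1", 0, codes["fingolimod"]),
            ],
        )
        assert (
            find_index_switch(b.pharmacy, b.medical, dictionaries, (D(-30), D(30)))
            is None
        )

    def test_first_qualifying_candidate_wins(self, dictionaries, codes):
        b = toy_bundle(
            [mk_member("m1")],
            pharmacy=[
                mk_rx("r1", "m1", -20, codes["IFN"]),
                mk_rx("r2", "m1", 0, codes["GA"]),
                mk_rx("r3", "m1", 40, codes["GA"]),
            ],
        )
        ev = find_index_switch(b.pharmacy, b.medical, dictionaries, (D(-30), D(60)))
        assert ev.index_date == BASE  # day 0, not day 40

    def test_matches_exhaustive_oracle_on_random_claim_streams(
        self, dictionaries, codes
    ):
        rng = np.random.default_rng(8)
        classes = ["IFN", "GA", "fingolimod", "natalizumab"]
        ndc = {c: codes[c] for c in classes}
        for trial in range(300):
            n = rng.integers(1, 8)
            claims = [
                (int(rng.integers(-200, 200)), classes[rng.integers(0, 4)])
                for _ in range(n)
            ]
            b = toy_bundle(
                [mk_member("m1")],
                pharmacy=[
                    mk_rx(f"r{i}", "m1", day, ndc[cls])
                    for i, (day, cls) in enumerate(claims)
                ],
            )
            got = find_index_switch(
                b.pharmacy, b.medical, dictionaries, (D(-100), D(100))
            )
            want = switch_oracle(claims, (-100, 100))
            if want is None:
                assert got is None
            else:
                assert ((got.index_date - BASE).days, got.index_dmt) == want

    def test_row_order_does_not_matter(self, dictionaries, codes):
        rows = [
            mk_rx("r1", "m1", -20, codes["IFN"]),
            mk_rx("r2", "m1", 0, codes["GA"]),
            mk_rx("r3", "m1", 40, codes["fingolimod"]),
        ]
        b1 = toy_bundle([mk_member("m1")], pharmacy=rows)
        b2 = toy_bundle([mk_member("m1")], pharmacy=rows[::-1])
        e1 = find_index_switch(b1.pharmacy, b1.medical, dictionaries, (D(-30), D(60)))
        e2 = find_index_switch(b2.pharmacy, b2.medical, dictionaries, (D(-30), D(60)))
        assert (e1.index_date, e1.index_dmt) == (e2.index_date, e2.index_dmt)


class TestSelection:
    def test_injected_pathologies_hit_their_criteria(self):
        cfg = SimulationConfig(n_members=20, seed=23)
        bundle, _ = generate_bundle(cfg)
        bad = inject_pathologies(
            bundle,
            {
                "missing_days_supply": ["M000002"],
                "underage": ["M000005"],
                "enrollment_gap": ["M000009"],
            },
        )
        events = index_events_table(bad, cfg.index_window)
        cohort, attrition = apply_selection_criteria(bad, events)
        assert len(cohort) == 17
        att = attrition.set_index("criterion")["n_excluded"]
        assert att[SELECTION_CRITERIA[1]] == 1  # enrollment gap
        assert att[SELECTION_CRITERIA[3]] == 1  # underage
        assert att[SELECTION_CRITERIA[5]] == 1  # missing days supply

    def test_one_day_enrollment_hole_is_strict(self, codes):
        m = mk_member("m1")
        # hole at day -100 only
        m["enrollment"] = (
            f"{D(-400).date()}:{D(-101).date()};{D(-99).date()}:{D(400).date()}"
        )
        b = toy_bundle(
            [m, mk_member("m2")],
            medical=[mk_med("c1", "m1", 5), mk_med("c2", "m2", 5)],
            pharmacy=[
                mk_rx("r1", "m1", -20, codes["IFN"]),
                mk_rx("r2", "m1", 0, codes["GA"]),
                mk_rx("r3", "m2", -20, codes["IFN"]),
                mk_rx("r4", "m2", 0, codes["GA"]),
            ],
        )
        events = index_events_table(b, (D(-30), D(30)))
        cohort, attrition = apply_selection_criteria(b, events)
        assert list(cohort["member_id"]) == ["m2"]
        assert attrition.set_index("criterion")["n_excluded"][SELECTION_CRITERIA[1]] == 1

    def test_clean_bundle_has_zero_exclusions_after_switch_row(self):
        cfg = SimulationConfig(n_members=15, seed=29)
        bundle, _ = generate_bundle(cfg)
        events = index_events_table(bundle, cfg.index_window)
        _, attrition = apply_selection_criteria(bundle, events)
        assert (attrition["n_excluded"].iloc[1:] == 0).all()

    def test_attrition_conserves_counts(self):
        cfg = SimulationConfig(n_members=30, seed=31)
        bundle, _ = generate_bundle(cfg)
        bad = inject_pathologies(
            bundle,
            {
                "missing_gender": ["M000001"],
                "underage": ["M000002"],
                "preindex_index_dmt": ["M000003"],
                "invalid_enrollment": ["M000004"],
            },
        )
        events = index_events_table(bad, cfg.index_window)
        cohort, attrition = apply_selection_criteria(bad, events)
        initial = attrition["n_remaining"].iloc[0]
        assert initial == 30
        assert attrition["n_excluded"].sum() == initial - len(cohort)
        assert (attrition["n_remaining"].diff().dropna() <= 0).all()

    def test_preindex_index_dmt_excluded(self):
        cfg = SimulationConfig(n_members=10, seed=37)
        bundle, _ = generate_bundle(cfg)
        bad = inject_pathologies(bundle, {"preindex_index_dmt": ["M000006"]})
        events = index_events_table(bad, cfg.index_window)
        cohort, attrition = apply_selection_criteria(bad, events)
        assert "M000006" not in set(cohort["member_id"])
        assert attrition.set_index("criterion")["n_excluded"][SELECTION_CRITERIA[4]] == 1

    def test_attrition_percentage(self):
        att = pd.DataFrame(
            {
                "criterion": ["identified", "a", "b"],
                "n_remaining": [952, 500, 264],
                "n_excluded": [0, 452, 236],
            }
        )
        assert attrition_percentage(att) == pytest.approx(72.27, abs=0.01)


class TestCovariates:
    def _bundle(self, codes, medical=(), pharmacy=()):
        return toy_bundle([mk_member("m1", birth_year=1968)], medical, pharmacy)

    def _event(self):
        return IndexEvent("m1", BASE, "fingolimod", BASE - pd.Timedelta(days=20), 20)

    def test_no_preindex_claims_gives_zeros(self, codes):
        b = self._bundle(codes)
        empty_eps = pd.DataFrame(columns=["member_id", "onset_day", "kind"])
        cov = compute_baseline_covariates("m1", b, self._event(), empty_eps)
        assert cov["charlson_score"] == 0
        assert cov["pre_index_total_cost"] == 0
        assert cov["pre_index_relapse_count"] == 0
        assert not cov["symptom_fatigue"]
        assert cov["age"] == 2011 - 1968

    def test_diabetes_claim_sets_flag_and_charlson(self, codes):
        b = self._bundle(
            codes, medical=[mk_med("c1", "m1", -40, dx="25000", paid=80.0)]
        )
        empty_eps = pd.DataFrame(columns=["member_id", "onset_day", "kind"])
        cov = compute_baseline_covariates("m1", b, self._event(), empty_eps)
        assert cov["comorbidity_diabetes"]
        assert cov["charlson_score"] >= 1
        assert cov["pre_index_total_cost"] == 80.0

    def test_dalfampridine_fill_sets_flag(self, codes):
        b = self._bundle(
            codes, pharmacy=[mk_rx("r1", "m1", -30, codes["dalfampridine"])]
        )
        empty_eps = pd.DataFrame(columns=["member_id", "onset_day", "kind"])
        cov = compute_baseline_covariates("m1", b, self._event(), empty_eps)
        assert cov["dalfampridine_use"]

    def test_relapse_history_covariates(self, codes):
        b = self._bundle(codes)
        eps = pd.DataFrame(
            {
                "member_id": ["m1", "m1"],
                "onset_day": [-300, -50],
                "kind": ["outpatient", "outpatient"],
            }
        )
        cov = compute_baseline_covariates("m1", b, self._event(), eps)
        assert cov["pre_index_relapse_count"] == 2
        assert cov["relapse_within_90d_pre"]

    def test_vectorized_covariates_match_truth_flags(self):
        """Generator truth flags are recovered from the emitted claims."""
        cfg = SimulationConfig(n_members=80, seed=41)
        bundle, truth = generate_bundle(cfg)
        events = index_events_table(bundle, cfg.index_window)
        empty_eps = pd.DataFrame(columns=["member_id", "onset_day", "kind"])
        cov = baseline_covariates(bundle, events, empty_eps).set_index("member_id")
        t = truth.table.set_index("member_id")
        for name in ("fatigue", "headache", "numbness"):
            assert (cov[f"symptom_{name}"] == t[name]).all(), name
        for name in ("depression", "diabetes", "dyslipidemia"):
            assert (cov[f"comorbidity_{name}"] == t[name]).all(), name
        assert (cov["dalfampridine_use"] == t["dalfampridine"]).all()
        assert (cov["age"] == t["age"]).all()
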