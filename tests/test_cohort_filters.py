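"""Unit tests for cohort construction from raw lab records."""

import numpy as np
import pandas as pd
import pytest

from egfr_reflim.cohort_filters import (
    LAB_COLUMNS,
    URINALYSIS_LIMITS,
    build_cohort,
    first_submission_per_patient,
    stable_pairs,
    urinalysis_pass,
)
from egfr_reflim.egfr_models import fas


def make_records(rows):
    """Rows: (pid, sex, date, age, scr, protein, blood, leuko, glucose, sender)."""
    frame = pd.DataFrame(rows, columns=LAB_COLUMNS)
    frame["specimen_date"] = pd.to_datetime(frame["specimen_date"])
    return frame


def record(pid="A", sex="male", date="2020-01-01", age=50.0, scr=0.9,
           protein=1.0, blood=0.001, leuko=5.0, glucose=5.0, sender="practice"):
    return (pid, sex, date, age, scr, protein, blood, leuko, glucose, sender)


class TestUrinalysisPass:
    def test_all_inconspicuous(self):
        rec = make_records([record(protein=5.0, blood=0.010, leuko=10, glucose=15.0)])
        assert urinalysis_pass(rec).tolist() == [True]

    def test_boundary_is_exclusive(self):
        rec = make_records([record(protein=10.0, blood=0.010, leuko=10, glucose=15.0)])
        assert urinalysis_pass(rec).tolist() == [False]

    def test_single_field_boundary_sweep(self):
        """Each field at its limit fails alone; just below it passes."""
        limits = URINALYSIS_LIMITS
        below = {
            "u_protein_mgdl": 9.9, "u_blood_mgdl": 0.0149,
            "u_leuko_per_ul": 24, "u_glucose_mgdl": 19.9,
        }
        for col in limits:
            vals = dict(below)
            vals[col] = limits[col]
            rec = make_records([record(
                protein=vals["u_protein_mgdl"], blood=vals["u_blood_mgdl"],
                leuko=vals["u_leuko_per_ul"], glucose=vals["u_glucose_mgdl"])])
            verdict = urinalysis_pass(rec)
            # brute-force oracle: all four strict inequalities
            expected = all(vals[c] < limits[c] for c in limits)
            assert verdict.tolist() == [expected], col

    def test_missing_field_is_na(self):
        rec = make_records([record(protein=np.nan)])
        assert urinalysis_pass(rec).isna().tolist() == [True]


class TestFirstSubmission:
    def test_earliest_kept(self):
        rec = make_records([
            record(date="2020-03-01", scr=1.0),
            record(date="2020-01-01", scr=1.2),
            record(date="2020-06-01", scr=0.8),
        ])
        out = first_submission_per_patient(rec)
        assert len(out) == 1
        assert out["scr_mgdl"].iloc[0] == 1.2

    def test_empty_input(self):
        rec = make_records([])
        assert first_submission_per_patient(rec).empty

    def test_tie_break_lower_creatinine(self):
        rec = make_records([
            record(date="2020-01-01", scr=1.4),
            record(date="2020-01-01", scr=1.1),
        ])
        assert first_submission_per_patient(rec)["scr_mgdl"].iloc[0] == 1.1

    def test_matches_brute_force_group_min(self):
        rng = np.random.default_rng(42)
        rows = [
            record(pid=f"P{rng.integers(10)}",
                   date=pd.Timestamp("2020-01-01") + pd.Timedelta(days=int(d)),
                   scr=float(rng.uniform(0.5, 2.0)))
            for d in rng.integers(0, 365, 30)
        ]
        rec = make_records(rows).reset_index(drop=True)
        out = first_submission_per_patient(rec)
        assert len(out) == rec["patient_id"].nunique()
        for pid, grp in rec.groupby("patient_id"):
            expected_date = grp["specimen_date"].min()
            got = out[out["patient_id"] == pid].iloc[0]
            assert got["specimen_date"] == expected_date


class TestStablePairs:
    def pair_records(self, scr1, scr2, days, age=50.0):
        return make_records([
            record(date="2020-01-01", scr=scr1, age=age),
            record(date=pd.Timestamp("2020-01-01") + pd.Timedelta(days=days),
                   scr=scr2, age=age + days / 365.25),
        ])

    def test_small_change_kept(self):
        # eGFR 107.3 -> ~113.6, +5.9% over half a year
        out = stable_pairs(self.pair_records(0.90, 0.85, 183), "fas")
        assert len(out) == 1
        age2 = 50.0 + 183 / 365.25
        assert out["pct_change"].iloc[0] == pytest.approx(
            (fas(0.85, age2, "male") - fas(0.90, 50.0, "male"))
            / fas(0.90, 50.0, "male") * 100
        )

    def test_large_change_excluded(self):
        out = stable_pairs(self.pair_records(0.90, 0.70, 183), "fas")
        assert out.empty  # +28% eGFR rise violates +-10%

    def test_short_interval_excluded(self):
        out = stable_pairs(self.pair_records(0.90, 0.88, 36), "fas")
        assert out.empty  # ~0.1 y < 0.25 y window

    def test_singleton_patients_emit_nothing(self):
        out = stable_pairs(make_records([record()]), "fas")
        assert out.empty

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        rows = []
        for p in range(20):
            for d in rng.integers(0, 900, rng.integers(1, 5)):
                rows.append(record(
                    pid=f"P{p}",
                    date=pd.Timestamp("2018-01-01") + pd.Timedelta(days=int(d)),
                    scr=float(rng.uniform(0.6, 1.6)),
                    age=45.0 + d / 365.25))
        rec = make_records(rows)
        shuffled = rec.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = stable_pairs(rec, "fas").sort_values("patient_id").reset_index(drop=True)
        b = stable_pairs(shuffled, "fas").sort_values("patient_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_tightening_tolerance_is_monotone(self):
        rng = np.random.default_rng(3)
        rows = []
        for p in range(100):
            for d in (0, int(rng.integers(100, 700))):
                rows.append(record(
                    pid=f"P{p}",
                    date=pd.Timestamp("2019-01-01") + pd.Timedelta(days=d),
                    scr=float(rng.uniform(0.7, 1.3)),
                    age=50 + d / 365.25))
        rec = make_records(rows)
        n10 = len(stable_pairs(rec, "fas", max_abs_pct=10.0))
        n5 = len(stable_pairs(rec, "fas", max_abs_pct=5.0))
        assert n5 <= n10

    def test_emitted_pairs_satisfy_window_postconditions(self):
        rng = np.random.default_rng(4)
        rows = []
        for p in range(150):
            for d in rng.integers(0, 1200, rng.integers(2, 6)):
                rows.append(record(
                    pid=f"P{p}",
                    date=pd.Timestamp("2017-06-01") + pd.Timedelta(days=int(d)),
                    scr=float(rng.lognormal(0, 0.25)),
                    age=40 + d / 365.25))
        out = stable_pairs(make_records(rows), "fas", 0.25, 3.0, 10.0)
        assert not out.empty
        assert (out["delta_t_years"] >= 0.25).all()
        assert (out["delta_t_years"] <= 3.0).all()
        assert (out["pct_change"].abs() <= 10.0).all()


class TestBuildCohort:
    @pytest.fixture()
    def mixed_records(self):
        rng = np.random.default_rng(11)
        rows = []
        senders = ["practice", "hospital", "nephrology", "dialysis"]
        for p in range(100):
            sender = senders[rng.integers(4)]
            age = float(rng.uniform(30, 84))
            clean = rng.random() < 0.7
            n_visits = int(rng.integers(1, 4))
            for v in range(n_visits):
                days = int(v * rng.integers(120, 400))
                rows.append(record(
                    pid=f"P{p}", sender=sender,
                    date=pd.Timestamp("2020-01-01") + pd.Timedelta(days=days),
                    age=age + days / 365.25,
                    scr=float(rng.lognormal(-0.05, 0.2)),
                    protein=1.0 if clean else 15.0,
                ))
        return make_records(rows)

    def test_model1_membership_equals_brute_force(self, mixed_records):
        cohort = build_cohort(mixed_records, "model1", "fas")
        # record-by-record re-filter
        ok = mixed_records[
            (mixed_records["sender_type"] == "practice")
            & (mixed_records["u_protein_mgdl"] < 10.0)
            & (mixed_records["u_blood_mgdl"] < 0.015)
            & (mixed_records["u_leuko_per_ul"] < 25)
            & (mixed_records["u_glucose_mgdl"] < 20.0)
            & mixed_records["age_at_specimen"].between(30, 85)
        ]
        expected = set(
            ok.sort_values(["patient_id", "specimen_date", "scr_mgdl"])
            .groupby("patient_id").head(1)["patient_id"]
        )
        assert set(cohort["patient_id"]) == expected

    def test_model2_subset_of_eligible_multivisit_patients(self, mixed_records):
        m1 = build_cohort(mixed_records, "model1", "fas")
        m2 = build_cohort(mixed_records, "model2", "fas")
        assert set(m2["patient_id"]) <= set(m1["patient_id"])

    def test_dialysis_sender_in_validation1_never_model1(self):
        rec = make_records([record(pid="D1", sender="dialysis")])
        assert build_cohort(rec, "model1", "fas").empty
        val1 = build_cohort(rec, "validation1", "fas")
        assert val1["patient_id"].tolist() == ["D1"]

    def test_null_urinalysis_excluded_from_model_kept_in_validation(self):
        rec = make_records([record(protein=np.nan)])
        assert build_cohort(rec, "model1", "fas").empty
        assert len(build_cohort(rec, "validation1", "fas")) == 1

    def test_empty_cohort_warns_not_crashes(self, caplog):
        rec = make_records([record(sender="hospital")])
        with caplog.at_level("WARNING"):
            out = build_cohort(rec, "model1", "fas")
        assert out.empty
        assert any("empty" in m for m in caplog.messages)

    def test_unknown_spec_rejected(self, mixed_records):
        with pytest.raises(ValueError, match="unknown cohort spec"):
            build_cohort(mixed_records, "model3", "fas")

    def test_paired_cohort_uses_later_measurement(self):
        rec = make_records([
            record(date="2020-01-01", scr=0.90, age=50.0),
            record(date="2020-07-01", scr=0.92, age=50.5),
        ])
        out = build_cohort(rec, "model2", "fas")
        assert len(out) == 1
        assert out["scr_mgdl"].iloc[0] == 0.92
        assert out["age"].iloc[0] == 50  # floored age at later measurement
        assert out["egfr"].iloc[0] == pytest.approx(fas(0.92, 50.5, "male"))
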