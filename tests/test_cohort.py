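"""Cohort data model: BMI cleaning, exclusion cascade, filters, summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icucausal.cohort import (
    Cohort,
    apply_exclusion_cascade,
    clean_bmi,
    complete_case_filter,
    derive_anthropometrics,
    derive_obesity,
    summarize_baseline,
)
from icucausal.errors import ConfigError, InvalidRecordError

from conftest import make_admissions_frame

NA = float("nan")


class TestCleanBmi:
    @pytest.mark.parametrize("height,weight,expected", [
        (1.70, 86.7, 30.0),        # plausible value passes through
        (1.70, 26.0, NA),          # 9.0 kg/m^2 -> implausibly low -> missing
        (1.00, 85.0, NA),          # 85 kg/m^2 -> implausibly high -> missing
        (NA, 70.0, NA),            # missing input propagates
        (1.70, NA, NA),
        (NA, NA, NA),
    ])
    def test_derivation_and_implausibility(self, height, weight, expected):
        out = clean_bmi(height, weight)
        if math.isnan(expected):
            assert math.isnan(out)
        else:
            assert out == pytest.approx(expected, rel=1e-9)

    def test_boundaries_are_inclusive(self):
        assert clean_bmi(1.0, 10.0) == pytest.approx(10.0)
        assert clean_bmi(1.0, 80.0) == pytest.approx(80.0)
        assert math.isnan(clean_bmi(1.0, 80.01))
        assert math.isnan(clean_bmi(1.0, 9.99))

    def test_nonpositive_height_is_invalid(self):
        with pytest.raises(InvalidRecordError):
            clean_bmi(0.0, 70.0)
        with pytest.raises(InvalidRecordError):
            clean_bmi(-1.7, 70.0)


class TestDeriveObesity:
    @pytest.mark.parametrize("bmi,cutoff,expected", [
        (30.0, 30.0, True),
        (29.99, 30.0, False),
        (25.0, 25.0, True),
        (34.99, 35.0, False),
    ])
    def test_threshold(self, bmi, cutoff, expected):
        assert derive_obesity(bmi, cutoff) is expected

    def test_missing_propagates(self):
        assert derive_obesity(NA) is pd.NA

    @given(bmi=st.floats(10, 80), lo=st.floats(15, 45), hi=st.floats(15, 45))
    @settings(max_examples=50, deadline=None)
    def test_antitone_in_cutoff(self, bmi, lo, hi):
        lo, hi = min(lo, hi), max(lo, hi)
        # a stricter cutoff can only turn exposure off
        assert derive_obesity(bmi, hi) <= derive_obesity(bmi, lo)

    def test_vectorized_derivation_matches_scalar(self):
        df = pd.DataFrame({
            "height": [1.70, 1.70, np.nan, 1.60, 1.80],
            "weight": [86.7, 26.0, 70.0, 95.0, np.nan],
        })
        out = derive_anthropometrics(df)
        for i in range(len(df)):
            scalar = clean_bmi(df.loc[i, "height"], df.loc[i, "weight"])
            if math.isnan(scalar):
                assert math.isnan(out.loc[i, "bmi"])
                assert out.loc[i, "obesity"] is pd.NA
            else:
                assert out.loc[i, "bmi"] == pytest.approx(scalar, rel=1e-9)
                assert bool(out.loc[i, "obesity"]) == (scalar >= 30)


class TestExclusionCascade:
    def test_study_flow_counts(self):
        # stage-count fixture built to the published flow diagram
        df = make_admissions_frame(n_clean=6557, n_weight_related=55,
                                   n_repeat=1762, n_low_saps=2063,
                                   n_missing_saps=807, seed=1)
        assert len(df) == 11244
        out = apply_exclusion_cascade(Cohort(df))
        removed = [s["n_removed"] for s in out.provenance]
        assert removed == [55, 1762, 2063, 807]
        assert len(out) == 6557

    def test_empty_cohort(self):
        df = make_admissions_frame(n_clean=0)
        out = apply_exclusion_cascade(Cohort(df))
        assert len(out) == 0
        assert [s["n_removed"] for s in out.provenance] == [0, 0, 0, 0]

    def test_matches_bruteforce_filter_and_telescopes(self):
        rng = np.random.default_rng(11)
        df = make_admissions_frame(n_clean=200, n_weight_related=30,
                                   n_repeat=90, n_low_saps=120,
                                   n_missing_saps=60, seed=11)
        df = df.sample(frac=1.0, random_state=5).reset_index(drop=True)
        out = apply_exclusion_cascade(Cohort(df))

        # independent single-pass brute-force re-filter in the same order
        keep = []
        counts = [0, 0, 0, 0]
        for _, r in df.iterrows():
            if r["admission_reason_weight_related"] is True:
                counts[0] += 1
            elif r["admission_seq"] > 1:
                counts[1] += 1
            elif not pd.isna(r["saps2"]) and r["saps2"] < 32:
                counts[2] += 1
            elif pd.isna(r["saps2"]):
                counts[3] += 1
            else:
                keep.append(r["admission_id"])
        assert [s["n_removed"] for s in out.provenance] == counts
        assert list(out.data["admission_id"]) == keep
        assert len(df) - sum(counts) == len(out)

    def test_idempotent(self):
        df = make_admissions_frame(n_clean=80, n_weight_related=5, n_repeat=9,
                                   n_low_saps=12, n_missing_saps=4, seed=2)
        once = apply_exclusion_cascade(Cohort(df))
        twice = apply_exclusion_cascade(once)
        assert len(twice) == len(once)
        assert all(s["n_removed"] == 0 for s in twice.provenance[-4:])


class TestCompleteCaseFilter:
    def test_counts_match_row_scan(self):
        df = make_admissions_frame(n_clean=10, seed=3)
        df["age"] = [60.0, np.nan, 55.0, 70.0, np.nan, 40.0, 61.0, 59.0, 66.0, 71.0]
        df["sex"] = ["male", "female", None, "male", "female",
                     "male", "male", None, "female", "male"]
        cohort = Cohort(df)
        sub, n_discarded = complete_case_filter(cohort, ["age", "sex"])
        expected_kept = sum(
            1 for i in range(10)
            if not pd.isna(df.loc[i, "age"]) and df.loc[i, "sex"] is not None)
        assert len(sub) == expected_kept
        assert n_discarded == 10 - expected_kept
        assert sub.data[["age", "sex"]].notna().all().all()

    def test_no_missing_is_identity(self):
        df = make_admissions_frame(n_clean=15, seed=4)
        sub, n_discarded = complete_case_filter(Cohort(df), ["saps2"])
        assert n_discarded == 0
        assert list(sub.data["admission_id"]) == list(df["admission_id"])

    def test_unknown_field_is_config_error(self):
        df = make_admissions_frame(n_clean=5)
        with pytest.raises(ConfigError):
            complete_case_filter(Cohort(df), ["no_such_field"])


class TestBaselineSummary:
    def _toy_cohort(self, n=400, seed=9):
        rng = np.random.default_rng(seed)
        obesity = pd.array(rng.random(n) < 0.2, dtype="boolean")
        obesity[rng.choice(n, 10, replace=False)] = pd.NA
        df = pd.DataFrame({
            "admission_id": [f"B{i}" for i in range(n)],
            "obesity": obesity,
            "age": rng.normal(64, 15, n),
            "smoking": rng.choice(
                np.asarray(["never", "ex_gt1y", "ex_lt1y", "current"],
                           dtype=object), n),
            "hospital_death": pd.array(rng.random(n) < 0.15, dtype="boolean"),
        })
        df.loc[rng.choice(n, 15, replace=False), "smoking"] = None
        return Cohort(df)

    def test_level_counts_sum_to_group_size_and_pcts_to_100(self):
        cohort = self._toy_cohort()
        tabs = summarize_baseline(cohort, continuous=["age"],
                                  categorical=["smoking"])
        cat = tabs["categorical"]
        for (var, grp), sub in cat.groupby(["variable", "group"]):
            size = {"total": len(cohort),
                    "unexposed": int((cohort.data["obesity"] == False).sum()),  # noqa: E712
                    "exposed": int((cohort.data["obesity"] == True).sum()),  # noqa: E712
                    }[grp]
            assert sub["count"].sum() == size
            assert sub["pct"].sum() == pytest.approx(100.0, abs=0.1)

    def test_constant_column_statistics(self):
        cohort = self._toy_cohort()
        cohort.data["calendar_time"] = 1.5
        tabs = summarize_baseline(cohort, continuous=["calendar_time"],
                                  categorical=[])
        cont = tabs["continuous"]
        assert (cont["sd"] == 0).all()
        assert (cont["q1"] == cont["median"]).all()
        assert (cont["median"] == cont["q3"]).all()

    def test_exposure_prevalence_matches_group_sizes(self):
        # group sizes as published: 5121 unexposed, 1192 exposed, 244 unknown
        n = 6557
        obesity = pd.array([False] * 5121 + [True] * 1192 + [None] * 244,
                           dtype="boolean")
        df = pd.DataFrame({"admission_id": [f"C{i}" for i in range(n)],
                           "obesity": obesity,
                           "age": np.linspace(20, 90, n)})
        tabs = summarize_baseline(Cohort(df), continuous=["age"], categorical=[])
        cont = tabs["continuous"].set_index("group")
        assert cont.loc["unexposed", "n"] == 5121
        assert cont.loc["exposed", "n"] == 1192
        prevalence = 1192 / (5121 + 1192)
        assert 100 * prevalence == pytest.approx(18.9, abs=0.05)


class TestCohortIO:
    def test_csv_roundtrip_preserves_missingness(self, tmp_path):
        df = make_admissions_frame(n_clean=20, n_missing_saps=5, seed=6)
        cohort = Cohort(df)
        cohort.log("unit_test", 0, len(df))
        path = tmp_path / "cohort.csv"
        cohort.to_csv(path)
        back = Cohort.from_csv(path)
        assert len(back) == len(cohort)
        assert back.data["saps2"].isna().sum() == df["saps2"].isna().sum()
        assert back.provenance[-1]["stage"] == "unit_test"

    def test_duplicate_admission_ids_rejected(self):
        df = make_admissions_frame(n_clean=4)
        df.loc[1, "admission_id"] = df.loc[0, "admission_id"]
        with pytest.raises(InvalidRecordError):
            Cohort(df)
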