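"""Patient schema, imaging quantities, and cohort CSV round-trips."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ichecon.cohort_model import (
    PatientRecord,
    ScanMeasurement,
    ValidationError,
    abc2_volume,
    expansion_flag,
    read_cohort,
    summarize_cohort,
    write_cohort,
)


def make_patient(**overrides) -> PatientRecord:
    base = dict(
        patient_id="p1",
        age=70,
        sex="male",
        premorbid_mrs=0,
        antithrombotic="none",
        gcs=12,
        nihss=10,
        location="basal_ganglia",
        ivh=False,
        onset_to_admission_h=6.0,
        triage_to_image_min=19.0,
        volume_initial_ml=35.0,
        volume_control_ml=37.0,
        control_interval_h=12.0,
        brainstem_dysfunction=False,
        rescue_surgery=False,
        evd=False,
        los_icu_d=2.0,
        los_stroke_unit_d=2.0,
        los_total_d=15.0,
        discharge_destination="rehabilitation",
        mrs_discharge=4,
        mrs_midterm=3,
        survived_30d=True,
    )
    base.update(overrides)
    return PatientRecord(**base)


class TestImagingQuantities:
    @pytest.mark.parametrize(
        "a,b,c,expected",
        [
            (6, 5, 4, 60.0),
            (0, 5, 4, 0.0),
            (7.2, 4.1, 3.0, 44.28),  # 7.2*4.1*3.0/2, hand-multiplied
        ],
    )
    def test_abc2_values(self, a, b, c, expected):
        assert abc2_volume(ScanMeasurement(a, b, c)) == pytest.approx(expected)

    def test_abc2_rejects_negative_and_nonfinite(self):
        with pytest.raises(ValidationError):
            ScanMeasurement(-1.0, 2.0, 3.0)
        with pytest.raises(ValidationError):
            ScanMeasurement(float("nan"), 2.0, 3.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        dims=st.tuples(*[st.floats(0, 50, allow_nan=False)] * 3),
        scale=st.floats(0.1, 10, allow_nan=False),
    )
    def test_abc2_symmetric_and_degree3_homogeneous(self, dims, scale):
        a, b, c = dims
        v = abc2_volume(ScanMeasurement(a, b, c))
        assert abc2_volume(ScanMeasurement(c, a, b)) == pytest.approx(v)
        assert abc2_volume(
            ScanMeasurement(scale * a, scale * b, scale * c)
        ) == pytest.approx(scale**3 * v, rel=1e-12)

    @pytest.mark.parametrize(
        "initial,control,expected",
        [
            (35, 41, True),  # growth 6 > 5
            (35, 40, False),  # boundary: exactly 5 is not expansion
            (60, 55, False),  # shrinkage
        ],
    )
    def test_expansion_threshold_is_strict(self, initial, control, expected):
        assert expansion_flag(initial, control) is expected

    def test_expansion_missing_control_is_indeterminate(self):
        assert expansion_flag(35, None) is None

    @settings(derandomize=True, max_examples=50)
    @given(
        v=st.floats(0, 200, allow_nan=False),
        bump=st.floats(0, 50, allow_nan=False),
    )
    def test_expansion_never_fires_on_identity_and_is_monotone(self, v, bump):
        assert expansion_flag(v, v) is False
        # monotone in the control volume
        if expansion_flag(v, v + bump):
            assert expansion_flag(v, v + bump + 1.0)


class TestRecordInvariants:
    def test_valid_record_constructs(self):
        assert make_patient().age == 70

    @pytest.mark.parametrize(
        "overrides,field_in_message",
        [
            (dict(mrs_discharge=7), "mrs_discharge"),
            (dict(gcs=2), "gcs"),
            (dict(nihss=43), "nihss"),
            (dict(age=17), "age"),
            (dict(sex="other"), "sex"),
            (dict(los_icu_d=10.0, los_total_d=5.0), "los_total_d"),
            (dict(discharge_destination="death"), "discharge_destination"),
            (dict(mrs_discharge=6), "discharge_destination"),
            (dict(survived_30d=False, mrs_midterm=3), "mrs_midterm"),
        ],
    )
    def test_invalid_records_name_the_offending_field(self, overrides, field_in_message):
        with pytest.raises(ValidationError, match=field_in_message):
            make_patient(**overrides)

    def test_death_requires_mrs6_and_vice_versa(self):
        rec = make_patient(
            discharge_destination="death", mrs_discharge=6, mrs_midterm=6, survived_30d=False
        )
        assert rec.discharge_destination == "death"


class TestCohortIO:
    def test_round_trip_is_identity(self, tmp_path):
        records = [
            make_patient(patient_id="a"),
            make_patient(patient_id="b", volume_control_ml=None, control_interval_h=None),
            make_patient(
                patient_id="c",
                discharge_destination="death",
                mrs_discharge=6,
                mrs_midterm=6,
                survived_30d=False,
                triage_to_image_min=19.337,
            ),
        ]
        path = tmp_path / "cohort.csv"
        write_cohort(records, path)
        back = read_cohort(path)
        assert back == records
        # write∘read is also the identity at the byte level
        path2 = tmp_path / "cohort2.csv"
        write_cohort(back, path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_out_of_range_cell_names_row_and_field(self, tmp_path):
        path = tmp_path / "bad.csv"
        write_cohort([make_patient()], path)
        text = path.read_text().replace(",3,true", ",7,true")  # mrs_midterm 3 -> 7
        path.write_text(text)
        with pytest.raises(ValidationError, match="row 2.*mrs_midterm"):
            read_cohort(path)

    def test_unknown_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        write_cohort([make_patient()], path)
        path.write_text(path.read_text().replace("patient_id", "subject"))
        with pytest.raises(ValidationError, match="subject"):
            read_cohort(path)

    def test_violated_los_invariant_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        rec = make_patient(los_icu_d=10.0, los_stroke_unit_d=0.0, los_total_d=15.0)
        write_cohort([rec], path)
        path.write_text(path.read_text().replace("15.0,rehabilitation", "5.0,rehabilitation"))
        with pytest.raises(ValidationError, match="row 2"):
            read_cohort(path)


class TestSummary:
    def test_all_male_toy_cohort(self):
        recs = [make_patient(patient_id=f"p{i}") for i in range(4)]
        assert summarize_cohort(recs)["male_frac"] == 1.0

    def test_single_patient_mean_sd(self):
        s = summarize_cohort([make_patient(age=70)])
        assert s["age_mean"] == 70
        assert s["age_sd"] == 0.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            summarize_cohort([])

    def test_default_synthetic_cohort_male_fraction(self, default_cohort):
        """n=137 cohort male fraction inside the 99% binomial CI of 0.591."""
        s = summarize_cohort(default_cohort)
        lo, hi = stats.binom.interval(0.99, 137, 0.591)
        assert lo / 137 <= s["male_frac"] <= hi / 137

    def test_summary_is_deterministic(self, default_cohort):
        a = summarize_cohort(default_cohort)
        b = summarize_cohort(list(default_cohort))
        assert a == b
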