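"""Generator calibration, copula coupling, and frozen arm fixtures."""

import numpy as np
import pytest
from scipy import stats

from ichecon.cohort_model import ValidationError
from ichecon.synthetic_cohort import (
    ArmResourceSummary,
    CohortGenParams,
    arm_summary_from_cohort,
    available_arms,
    generate_cohort,
    literature_arm,
    pseudo_cohort_from_summary,
)
from tests.test_cohort_model import make_patient


class TestGenerator:
    def test_same_seed_same_cohort(self):
        p = CohortGenParams.default()
        p.n = 50
        assert generate_cohort(p) == generate_cohort(p)

    def test_different_seed_different_cohort(self):
        a = CohortGenParams.default()
        b = CohortGenParams.default()
        a.n = b.n = 50
        b.seed = 99
        assert generate_cohort(a) != generate_cohort(b)

    def test_n_zero_gives_empty_cohort(self):
        p = CohortGenParams.default()
        p.n = 0
        assert generate_cohort(p) == []

    def test_invalid_probability_vector_rejected_before_sampling(self):
        with pytest.raises(ValidationError):
            CohortGenParams(location_probs=(0.5, 0.5, 0.5, 0.5))
        with pytest.raises(ValidationError):
            CohortGenParams(male_frac=1.5)

    def test_all_records_satisfy_invariants(self, big_cohort):
        # PatientRecord validates in __post_init__; re-validate explicitly
        for rec in big_cohort[:500]:
            rec.validate()

    def test_marginals_match_calibration_at_n5000(self, big_cohort):
        """>= 6 marginals inside their 99% Monte-Carlo CIs at n = 5000."""
        n = len(big_cohort)
        z99 = stats.norm.ppf(0.995)

        def binom_ok(frac, p):
            se = np.sqrt(p * (1 - p) / n)
            return abs(frac - p) <= z99 * se

        male = np.mean([r.sex == "male" for r in big_cohort])
        assert binom_ok(male, 0.591)

        ivh = np.mean([r.ivh for r in big_cohort])
        assert binom_ok(ivh, 0.38)

        rescue = np.mean([r.rescue_surgery for r in big_cohort])
        assert binom_ok(rescue, 0.131)

        evd = np.mean([r.evd for r in big_cohort])
        assert binom_ok(evd, 0.146)

        bg = np.mean([r.location == "basal_ganglia" for r in big_cohort])
        assert binom_ok(bg, 73 / 137)

        ages = np.array([r.age for r in big_cohort], dtype=float)
        # truncation to [18, 100] barely moves the mean; allow the CI + 0.5 y
        assert abs(ages.mean() - 69.0) <= z99 * 15.1 / np.sqrt(n) + 0.5

        vols = np.array([r.volume_initial_ml for r in big_cohort])
        assert abs(vols.mean() - 35.0) <= z99 * 42.0 / np.sqrt(n)

        mrs6 = np.mean([r.mrs_discharge == 6 for r in big_cohort])
        assert binom_ok(mrs6, 44 / 137)

    def test_zero_coupling_gives_independent_severity_fields(self):
        p = CohortGenParams.default()
        p.n = 5000
        p.severity_coupling = 0.0
        p.seed = 7
        cohort = generate_cohort(p)
        vol = [r.volume_initial_ml for r in cohort]
        nihss = [r.nihss for r in cohort]
        rho, pval = stats.spearmanr(vol, nihss)
        assert pval > 0.01  # not significantly different from 0

    def test_full_coupling_gives_strong_rank_correlation(self):
        p = CohortGenParams.default()
        p.n = 5000
        p.severity_coupling = 1.0
        p.seed = 7
        cohort = generate_cohort(p)
        vol = [r.volume_initial_ml for r in cohort]
        nihss = [r.nihss for r in cohort]
        rho, _ = stats.spearmanr(vol, nihss)
        assert rho > 0.5


class TestArmFixtures:
    def test_unknown_arm_lists_available(self):
        with pytest.raises(KeyError, match="mistie3_intervention"):
            literature_arm("nope")

    def test_available_arms(self):
        assert set(available_arms()) == {
            "mistie3_intervention",
            "kellner_intervention",
            "catheter_control",
            "endoscopic_control",
        }

    def test_kellner_fixture_matches_published_cells(self, arms):
        k = arms["kellner_intervention"]
        assert k.rehab_discharge_frac == 0.93
        assert k.or_minutes == 150
        assert k.mrs_midterm_counts == (1, 9, 19, 17, 25, 13, 16)
        assert k.mortality_30d_frac == 9 / 100
        assert k.icu_days == 8.5 and k.ward_days == 8.5  # cost-line reading
        assert k.icu_days_alt == 9.0 and k.ward_days_alt == 8.0  # reported LoS

    def test_mistie_fixture_matches_published_cells(self, arms):
        m = arms["mistie3_intervention"]
        assert m.icu_days == 10 and m.ward_days == 45
        assert m.or_minutes == 60
        assert sum(m.mrs_midterm_counts) == 249
        assert m.mrs_midterm_counts == (1, 15, 30, 64, 60, 31, 48)
        assert m.rehab_discharge_frac is None  # not reported
        assert m.mortality_30d_frac == 24 / 255

    def test_control_fixtures_use_exact_cohort_fractions(self, arms):
        assert arms["catheter_control"].surgery_prob == 5 / 17
        assert arms["catheter_control"].rehab_discharge_frac == 12 / 17
        assert arms["endoscopic_control"].surgery_prob == 10 / 59
        assert arms["endoscopic_control"].rehab_discharge_frac == 33 / 59

    def test_cost_line_los_flag_switches_kellner_days(self, arms):
        k = arms["kellner_intervention"]
        alt = k.with_cost_line_los(use_cost_line=False)
        assert (alt.icu_days, alt.ward_days) == (9.0, 8.0)
        assert k.with_cost_line_los(use_cost_line=True) is k


class TestArmSummaryFromCohort:
    def test_rescue_fraction(self):
        recs = [
            make_patient(patient_id="a", rescue_surgery=True),
            make_patient(patient_id="b"),
        ]
        assert arm_summary_from_cohort(recs).surgery_prob == 0.5

    def test_ward_days_from_single_patient(self):
        rec = make_patient(los_total_d=24.0, los_icu_d=4.0, los_stroke_unit_d=2.0)
        assert arm_summary_from_cohort([rec]).ward_days == 18.0

    def test_all_midterm_missing_flags_incomplete(self):
        recs = [make_patient(patient_id=str(i), mrs_midterm=None) for i in range(3)]
        s = arm_summary_from_cohort(recs)
        assert s.mrs_midterm_counts == (0,) * 7
        assert s.mrs_midterm_complete is False

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            arm_summary_from_cohort([])


class TestPseudoCohort:
    @pytest.mark.parametrize(
        "arm_name", ["catheter_control", "endoscopic_control", "kellner_intervention"]
    )
    def test_reconstituted_aggregates_match_summary(self, arms, arm_name):
        summary = arms[arm_name]
        cohort = pseudo_cohort_from_summary(summary)
        assert len(cohort) == summary.n
        back = arm_summary_from_cohort(
            cohort,
            interventional=summary.surgery_prob == 1.0,
            or_minutes=summary.or_minutes,
        )
        assert back.surgery_prob == pytest.approx(summary.surgery_prob, abs=0.5 / summary.n)
        assert back.icu_days == pytest.approx(summary.icu_days)
        assert back.ward_days == pytest.approx(summary.ward_days)
        assert back.mrs_midterm_counts == summary.mrs_midterm_counts
        assert back.mortality_30d_frac == pytest.approx(
            summary.mortality_30d_frac, abs=0.5 / summary.n
        )

    def test_arm_invariants_enforced(self):
        with pytest.raises(ValidationError):
            ArmResourceSummary(
                name="bad",
                n=10,
                or_minutes=60,
                surgery_prob=1.0,
                icu_days=1,
                stroke_unit_days=0,
                ward_days=1,
                rehab_discharge_frac=None,
                mortality_30d_frac=0.1,
                mrs_midterm_counts=(5, 5, 5, 0, 0, 0, 0),  # sums to 15 > n
                navigation_used=False,
                specific_material_cost_key=None,
            )
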