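"""Trial-eligibility rule engine: defaults, screening, and oracle equivalence."""

import dataclasses

import pytest

from ichecon.cohort_model import ValidationError
from ichecon.eligibility import (
    BUILTIN_TRIALS,
    Criterion,
    TrialRuleSet,
    builtin_ruleset,
    evaluate_patient,
    load_ruleset,
    save_ruleset,
    screen_cohort,
)
from ichecon.synthetic_cohort import CohortGenParams, generate_cohort
from tests.test_cohort_model import make_patient


class TestBuiltinRulesets:
    def test_mistie3_volume_threshold(self):
        rules = builtin_ruleset("mistie3")
        vols = [c for c in rules.inclusion if c.field == "volume_initial_ml"]
        assert vols and vols[0].op == "ge" and vols[0].value == 30.0

    def test_dist_window_is_8h(self):
        rules = builtin_ruleset("dist")
        windows = [c for c in rules.inclusion if c.field == "onset_to_admission_h"]
        assert windows and windows[0].value == 8.0

    def test_study_selection_premorbid_cutoff(self):
        rules = builtin_ruleset("study_selection")
        pm = [c for c in rules.inclusion if c.field == "premorbid_mrs"]
        assert pm and pm[0].op == "le" and pm[0].value == 3

    def test_unknown_trial_rejected(self):
        with pytest.raises(KeyError, match="mistie3"):
            builtin_ruleset("mistie4")

    def test_rule_referencing_unknown_field_fails_at_construction(self):
        with pytest.raises(ValidationError, match="unknown field"):
            Criterion(field="haematoma_vol", op="ge", value=30)


class TestEvaluatePatient:
    def test_small_volume_fails_mistie_volume_rule(self):
        patient = make_patient(volume_initial_ml=25.0, premorbid_mrs=0)
        res = evaluate_patient(builtin_ruleset("mistie3"), patient)
        assert not res.eligible
        assert any("30 ml" in label for label in res.failed)

    def test_premorbid_mrs3_fails_both_mis_trials(self):
        patient = make_patient(premorbid_mrs=3)
        for trial in ("mistie3", "dist"):
            res = evaluate_patient(builtin_ruleset(trial), patient)
            assert not res.eligible
            assert any("premorbid" in label for label in res.failed)

    def test_textbook_dist_candidate_is_eligible(self):
        patient = make_patient(
            volume_initial_ml=12.0,
            onset_to_admission_h=6.0,
            premorbid_mrs=1,
            nihss=8,
            gcs=12,
            location="basal_ganglia",
            brainstem_dysfunction=False,
        )
        res = evaluate_patient(builtin_ruleset("dist"), patient)
        assert res.eligible and not res.failed and not res.indeterminate

    def test_missing_control_scan_is_indeterminate_for_mistie_stability(self):
        patient = make_patient(
            volume_initial_ml=60.0,
            volume_control_ml=None,
            control_interval_h=None,
            premorbid_mrs=0,
            onset_to_admission_h=6.0,
        )
        res = evaluate_patient(builtin_ruleset("mistie3"), patient)
        assert not res.eligible  # conservative default
        assert any("stable" in label for label in res.indeterminate)
        # optimistic policy lets the indeterminate criterion through
        res_opt = evaluate_patient(builtin_ruleset("mistie3"), patient, missing_policy="optimistic")
        assert res_opt.eligible

    def test_eligible_patients_carry_no_labels(self, default_cohort):
        rules = builtin_ruleset("dist")
        for rec in default_cohort:
            res = evaluate_patient(rules, rec)
            if res.eligible:
                assert not res.failed and not res.indeterminate
            else:
                assert res.failed or res.indeterminate


class TestScreenCohort:
    def test_trivial_rule_set_accepts_everyone(self, default_cohort):
        rules = TrialRuleSet(
            trial="pass_all",
            inclusion=[Criterion(field="age", op="ge", value=18, label="adult")],
        )
        report = screen_cohort(rules, default_cohort[:10])
        assert report.proportion == 1.0

    def test_unsatisfiable_rule_rejects_everyone(self, default_cohort):
        rules = TrialRuleSet(
            trial="impossible",
            inclusion=[Criterion(field="volume_initial_ml", op="ge", value=1e6)],
        )
        assert screen_cohort(rules, default_cohort[:10]).proportion == 0.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            screen_cohort(builtin_ruleset("dist"), [])

    def test_default_synthetic_cohort_dist_proportion_plausible(self, default_cohort):
        """DIST eligibility on the calibrated 137-patient cohort lands in a
        wide Monte-Carlo range around the published 43%."""
        report = screen_cohort(builtin_ruleset("dist"), default_cohort)
        assert 0.2 <= report.proportion <= 0.7

    def test_eligible_set_subset_of_input(self, default_cohort):
        report = screen_cohort(builtin_ruleset("mistie3"), default_cohort)
        assert report.n_eligible <= report.n_screened == len(default_cohort)


def brute_force_eligible(rules: TrialRuleSet, patient) -> bool:
    """Independent re-check: each criterion evaluated one by one."""
    for crit in rules.inclusion:
        status = crit.check(patient)
        if status is None or status is False:
            return False
    for crit in rules.exclusion:
        status = crit.check(patient)
        if status is None or status is True:
            return False
    return True


class TestProperties:
    def test_oracle_equivalence_on_random_patients(self):
        params = CohortGenParams.default()
        params.n = 1000
        params.seed = 321
        cohort = generate_cohort(params)
        for trial in BUILTIN_TRIALS:
            rules = builtin_ruleset(trial)
            for rec in cohort:
                assert evaluate_patient(rules, rec).eligible == brute_force_eligible(rules, rec)

    def test_relaxing_a_threshold_never_shrinks_the_eligible_set(self, default_cohort):
        base = builtin_ruleset("dist")
        eligible_base = {
            r.patient_id
            for r, res in zip(
                default_cohort, screen_cohort(base, default_cohort).per_patient
            )
            if res.eligible
        }
        relaxed_inclusion = [
            dataclasses.replace(c, value=5.0) if c.field == "volume_initial_ml" else c
            for c in base.inclusion
        ]
        relaxed = TrialRuleSet(trial="dist_relaxed", inclusion=relaxed_inclusion, exclusion=base.exclusion)
        eligible_relaxed = {
            r.patient_id
            for r, res in zip(
                default_cohort, screen_cohort(relaxed, default_cohort).per_patient
            )
            if res.eligible
        }
        assert eligible_base <= eligible_relaxed

    def test_ruleset_file_round_trip(self, tmp_path):
        rules = builtin_ruleset("mistie3")
        path = tmp_path / "mistie3.json"
        save_ruleset(rules, path)
        back = load_ruleset(path)
        assert back.trial == rules.trial
        assert [(c.field, c.op, c.value) for c in back.inclusion] == [
            (c.field, c.op, c.value) for c in rules.inclusion
        ]
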