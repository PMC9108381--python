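"""Declarative trial-eligibility screening for ICH surgical trials.

A :class:`TrialRuleSet` expresses one trial's inclusion/exclusion
criteria as data — field, operator, threshold — so that the active rules
are auditable and overridable by configuration rather than buried in
code. Built-in defaults are shipped for the study-selection filter and
for the four minimally-invasive-surgery trials screened in the analysis:

* MISTIE III — catheter aspiration + thrombolysis; volume ≥ 30 ml,
  hematoma stability on a repeat scan ≥ 6 h apart (growth < 5 ml),
  72 h window, premorbid mRS ≤ 1, GCS ≤ 14 or NIHSS ≥ 6, intact brainstem.
* DIST — endoscopic evacuation; volume ≥ 10 ml, 8 h window, premorbid
  mRS ≤ 2, NIHSS ≥ 2, intact brainstem.
* ENRICH — lobar or anterior-basal-ganglia hematomas 30–80 ml, GCS 5–14.
* INVEST — deep hematomas 20–80 ml, NIHSS ≥ 6.

The defaults are reconstructions from the trials' published protocols;
where a protocol detail is ambiguous the choice is documented and can be
replaced via a rule-set config file.

Criteria that touch a missing field (e.g. no control scan for the
stability rule) are *indeterminate*; under the default conservative
policy an indeterminate criterion renders the patient ineligible, with
the reason recorded — never silently passed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

from .cohort_model import EXPANSION_THRESHOLD_ML, PatientRecord, ValidationError

__all__ = [
    "Criterion",
    "TrialRuleSet",
    "EligibilityResult",
    "ScreeningReport",
    "evaluate_patient",
    "screen_cohort",
    "builtin_ruleset",
    "load_ruleset",
    "save_ruleset",
    "BUILTIN_TRIALS",
]

_MISSING = object()

_OPS: dict[str, Callable] = {
    "ge": lambda v, t: v >= t,
    "gt": lambda v, t: v > t,
    "le": lambda v, t: v <= t,
    "lt": lambda v, t: v < t,
    "eq": lambda v, t: v == t,
    "in_set": lambda v, t: v in t,
    "is_true": lambda v, t: v is True,
    "is_false": lambda v, t: v is False,
    "not_missing": lambda v, t: True,  # missing is intercepted upstream
}


def _derived_supratentorial(p: PatientRecord):
    return p.location != "brainstem"


def _derived_deep_location(p: PatientRecord):
    return p.location == "basal_ganglia"


def _derived_lobar_or_deep(p: PatientRecord):
    return p.location in ("cortical", "subcortical", "basal_ganglia")


def _derived_mild_presentation(p: PatientRecord):
    """Too mild for MISTIE-style severity floor: GCS 15 and NIHSS < 6."""
    return p.gcs > 14 and p.nihss < 6


def _derived_hematoma_stable_6h(p: PatientRecord):
    """Stability requisite: repeat scan >= 6 h apart showing growth < 5 ml.

    Missing control imaging (or interval) makes the criterion
    indeterminate rather than false.
    """
    if p.volume_control_ml is None or p.control_interval_h is None:
        return None
    if p.control_interval_h < 6.0:
        return None  # repeat scan too early to establish stability
    return (p.volume_control_ml - p.volume_initial_ml) < EXPANSION_THRESHOLD_ML


_DERIVED: dict[str, Callable[[PatientRecord], object]] = {
    "supratentorial": _derived_supratentorial,
    "deep_location": _derived_deep_location,
    "lobar_or_deep_location": _derived_lobar_or_deep,
    "mild_presentation": _derived_mild_presentation,
    "hematoma_stable_6h": _derived_hematoma_stable_6h,
}

_RECORD_FIELDS = frozenset(PatientRecord.__dataclass_fields__)


@dataclass(frozen=True)
class Criterion:
    """One declarative rule: ``field op value``, with a human-readable label."""

    field: str
    op: str
    value: object = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ValidationError(f"criterion {self.label!r}: unknown op {self.op!r}")
        if self.field not in _RECORD_FIELDS and self.field not in _DERIVED:
            raise ValidationError(
                f"criterion {self.label!r}: unknown field {self.field!r} "
                f"(not a patient field or derived quantity)"
            )
        if self.op == "in_set" and not isinstance(self.value, (set, frozenset, list, tuple)):
            raise ValidationError(f"criterion {self.label!r}: in_set needs a collection value")

    def check(self, patient: PatientRecord) -> bool | None:
        """True/False, or None when the referenced value is missing."""
        value = (
            _DERIVED[self.field](patient)
            if self.field in _DERIVED
            else getattr(patient, self.field)
        )
        if value is None:
            return False if self.op == "not_missing" else None
        return bool(_OPS[self.op](value, self.value))


@dataclass
class TrialRuleSet:
    """Inclusion and exclusion criteria for one trial.

    A patient is eligible iff every inclusion criterion holds and every
    exclusion criterion fails.
    """

    trial: str
    inclusion: list[Criterion]
    exclusion: list[Criterion] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.inclusion:
            raise ValidationError(f"ruleset {self.trial!r}: inclusion list must be nonempty")


@dataclass
class EligibilityResult:
    eligible: bool
    failed: list[str]
    indeterminate: list[str]


@dataclass
class ScreeningReport:
    trial: str
    n_screened: int
    n_eligible: int
    proportion: float
    per_patient: list[EligibilityResult]


def evaluate_patient(
    rules: TrialRuleSet,
    patient: PatientRecord,
    missing_policy: str = "conservative",
) -> EligibilityResult:
    """Screen one patient against a rule set.

    ``missing_policy`` — "conservative" (default): indeterminate criteria
    make the patient ineligible; "optimistic": indeterminate criteria are
    recorded but do not block eligibility (sensitivity analysis).
    """
    if missing_policy not in ("conservative", "optimistic"):
        raise ValidationError(f"unknown missing_policy {missing_policy!r}")
    failed: list[str] = []
    indeterminate: list[str] = []
    for crit in rules.inclusion:
        res = crit.check(patient)
        if res is None:
            indeterminate.append(crit.label or f"{crit.field} {crit.op} {crit.value}")
        elif not res:
            failed.append(crit.label or f"{crit.field} {crit.op} {crit.value}")
    for crit in rules.exclusion:
        res = crit.check(patient)
        if res is None:
            indeterminate.append(crit.label or f"exclusion: {crit.field} {crit.op} {crit.value}")
        elif res:
            failed.append(crit.label or f"exclusion: {crit.field} {crit.op} {crit.value}")
    eligible = not failed and (missing_policy == "optimistic" or not indeterminate)
    return EligibilityResult(eligible=eligible, failed=failed, indeterminate=indeterminate)


def screen_cohort(
    rules: TrialRuleSet,
    records: Sequence[PatientRecord],
    missing_policy: str = "conservative",
) -> ScreeningReport:
    """Screen a whole cohort; eligible set is always a subset of the input."""
    if not records:
        raise ValidationError("cannot screen an empty cohort")
    per_patient = [evaluate_patient(rules, r, missing_policy) for r in records]
    n_eligible = sum(r.eligible for r in per_patient)
    return ScreeningReport(
        trial=rules.trial,
        n_screened=len(records),
        n_eligible=n_eligible,
        proportion=n_eligible / len(records),
        per_patient=per_patient,
    )


def _c(field, op, value=None, label="") -> Criterion:
    return Criterion(field=field, op=op, value=value, label=label)


def builtin_ruleset(trial: str) -> TrialRuleSet:
    """Shipped default rule set for a known trial key."""
    if trial == "study_selection":
        return TrialRuleSet(
            trial="study_selection",
            inclusion=[
                _c("supratentorial", "is_true", label="supratentorial hematoma"),
                _c("onset_to_admission_h", "le", 48.0, label="admission within 48 h of onset"),
                _c("premorbid_mrs", "le", 3, label="premorbid mRS <= 3"),
            ],
        )
    if trial == "mistie3":
        return TrialRuleSet(
            trial="mistie3",
            inclusion=[
                _c("supratentorial", "is_true", label="supratentorial hematoma"),
                _c("volume_initial_ml", "ge", 30.0, label="hematoma volume >= 30 ml"),
                _c(
                    "hematoma_stable_6h",
                    "is_true",
                    label="hematoma stable on repeat imaging >= 6 h apart (growth < 5 ml)",
                ),
                _c("onset_to_admission_h", "le", 72.0, label="within 72 h treatment window"),
                _c("premorbid_mrs", "le", 1, label="premorbid mRS <= 1"),
            ],
            exclusion=[
                _c(
                    "brainstem_dysfunction",
                    "is_true",
                    label="irreversible impaired brainstem function",
                ),
                _c(
                    "mild_presentation",
                    "is_true",
                    label="too mild: GCS 15 and NIHSS < 6",
                ),
            ],
        )
    if trial == "dist":
        return TrialRuleSet(
            trial="dist",
            inclusion=[
                _c("supratentorial", "is_true", label="supratentorial hematoma"),
                _c("volume_initial_ml", "ge", 10.0, label="hematoma volume >= 10 ml"),
                _c("onset_to_admission_h", "le", 8.0, label="within 8 h of symptom onset"),
                _c("premorbid_mrs", "le", 2, label="premorbid mRS <= 2"),
                _c("nihss", "ge", 2, label="NIHSS >= 2"),
            ],
            exclusion=[
                _c(
                    "brainstem_dysfunction",
                    "is_true",
                    label="irreversible impaired brainstem function",
                ),
            ],
        )
    if trial == "enrich":
        return TrialRuleSet(
            trial="enrich",
            inclusion=[
                _c(
                    "lobar_or_deep_location",
                    "is_true",
                    label="lobar or anterior basal ganglia hematoma",
                ),
                _c("volume_initial_ml", "ge", 30.0, label="hematoma volume >= 30 ml"),
                _c("volume_initial_ml", "le", 80.0, label="hematoma volume <= 80 ml"),
                _c("gcs", "ge", 5, label="GCS >= 5"),
                _c("gcs", "le", 14, label="GCS <= 14"),
                _c("onset_to_admission_h", "le", 24.0, label="within 24 h of onset"),
                _c("premorbid_mrs", "le", 1, label="premorbid mRS <= 1"),
            ],
            exclusion=[
                _c(
                    "brainstem_dysfunction",
                    "is_true",
                    label="irreversible impaired brainstem function",
                ),
            ],
        )
    if trial == "invest":
        return TrialRuleSet(
            trial="invest",
            inclusion=[
                _c("deep_location", "is_true", label="deep (basal ganglia) hematoma"),
                _c("volume_initial_ml", "ge", 20.0, label="hematoma volume >= 20 ml"),
                _c("volume_initial_ml", "le", 80.0, label="hematoma volume <= 80 ml"),
                _c("nihss", "ge", 6, label="NIHSS >= 6"),
                _c("onset_to_admission_h", "le", 24.0, label="within 24 h of onset"),
                _c("premorbid_mrs", "le", 2, label="premorbid mRS <= 2"),
            ],
            exclusion=[
                _c(
                    "brainstem_dysfunction",
                    "is_true",
                    label="irreversible impaired brainstem function",
                ),
            ],
        )
    raise KeyError(
        f"unknown trial {trial!r}; built-ins: {', '.join(BUILTIN_TRIALS)}"
    )


BUILTIN_TRIALS = ("study_selection", "mistie3", "dist", "enrich", "invest")


def load_ruleset(path: str | Path) -> TrialRuleSet:
    """Load a rule set from a JSON/YAML file (fields: trial, inclusion, exclusion)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix in (".yaml", ".yml"):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)

    def parse(items):
        out = []
        for d in items or []:
            value = d.get("value")
            if isinstance(value, list):
                value = tuple(value)
            out.append(Criterion(field=d["field"], op=d["op"], value=value, label=d.get("label", "")))
        return out

    return TrialRuleSet(
        trial=raw["trial"], inclusion=parse(raw.get("inclusion")), exclusion=parse(raw.get("exclusion"))
    )


def save_ruleset(rules: TrialRuleSet, path: str | Path) -> None:
    def dump(crits):
        return [
            {
                "field": c.field,
                "op": c.op,
                "value": list(c.value) if isinstance(c.value, (set, frozenset, tuple)) else c.value,
                "label": c.label,
            }
            for c in crits
        ]

    Path(path).write_text(
        json.dumps(
            {"trial": rules.trial, "inclusion": dump(rules.inclusion), "exclusion": dump(rules.exclusion)},
            indent=2,
        )
        + "\n",
        encoding="utf-8",
    )
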