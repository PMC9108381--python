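"""Patient-level data model for a spontaneous ICH cohort.

One :class:`PatientRecord` holds what the costing and outcome stages need
for a single admitted patient: demographics, admission severity (GCS,
NIHSS), imaging-derived hematoma quantities, resource use (lengths of
stay, rescue surgery, EVD) and functional outcomes on the modified Rankin
Scale (mRS, 0 = no symptoms … 6 = death).

The module also implements the two bedside imaging quantities used for
trial screening: the ABC/2 ellipsoid volume approximation and the
hematoma-expansion flag (growth of more than 5 ml between the initial and
the control scan).

Cohorts travel as plain CSV (one row per patient, header = field names,
empty string = missing); :func:`read_cohort` validates every row against
the record invariants so downstream stages can assume clean input.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PatientRecord",
    "ScanMeasurement",
    "ValidationError",
    "abc2_volume",
    "expansion_flag",
    "read_cohort",
    "write_cohort",
    "summarize_cohort",
    "SEXES",
    "ANTITHROMBOTICS",
    "LOCATIONS",
    "DESTINATIONS",
]

SEXES = frozenset({"male", "female"})
ANTITHROMBOTICS = frozenset(
    {"none", "oral_anticoagulant", "heparin", "antiplatelet", "combination"}
)
LOCATIONS = frozenset({"basal_ganglia", "subcortical", "cortical", "brainstem"})
DESTINATIONS = frozenset({"home", "rehabilitation", "death"})

EXPANSION_THRESHOLD_ML = 5.0  # growth strictly above this flags expansion


class ValidationError(ValueError):
    """A record or file failed schema/invariant validation."""


@dataclass(frozen=True)
class ScanMeasurement:
    """Three orthogonal hematoma diameters (cm) measured on CT/MRI."""

    a_cm: float
    b_cm: float
    c_cm: float

    def __post_init__(self) -> None:
        for name in ("a_cm", "b_cm", "c_cm"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(
                    f"ScanMeasurement.{name} must be finite and >= 0, got {v!r}"
                )


def abc2_volume(scan: ScanMeasurement) -> float:
    """Hematoma volume in ml via the ABC/2 ellipsoid approximation.

    A, B, C are the three orthogonal diameters in cm; the returned
    A*B*C/2 is in cm^3 == ml.
    """
    return scan.a_cm * scan.b_cm * scan.c_cm / 2.0


def expansion_flag(
    volume_initial_ml: float, volume_control_ml: float | None
) -> bool | None:
    """True iff the control scan shows growth of strictly more than 5 ml.

    Returns ``None`` (indeterminate) when the control volume is missing —
    an absent follow-up scan is never silently read as "stable".
    """
    if volume_control_ml is None:
        return None
    if volume_initial_ml < 0 or volume_control_ml < 0:
        raise ValidationError("hematoma volumes must be >= 0")
    return (volume_control_ml - volume_initial_ml) > EXPANSION_THRESHOLD_ML


@dataclass
class PatientRecord:
    """One admitted ICH patient.

    ``volume_control_ml``, ``control_interval_h``, ``mrs_discharge`` and
    ``mrs_midterm`` may be ``None`` (missing); everything else is
    mandatory. Invariants are enforced at construction.
    """

    patient_id: str
    age: int
    sex: str
    premorbid_mrs: int
    antithrombotic: str
    gcs: int
    nihss: int
    location: str
    ivh: bool
    onset_to_admission_h: float
    triage_to_image_min: float
    volume_initial_ml: float
    volume_control_ml: float | None
    control_interval_h: float | None
    brainstem_dysfunction: bool
    rescue_surgery: bool
    evd: bool
    los_icu_d: float
    los_stroke_unit_d: float
    los_total_d: float
    discharge_destination: str
    mrs_discharge: int | None
    mrs_midterm: int | None
    survived_30d: bool

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        err = lambda f, msg: ValidationError(  # noqa: E731
            f"patient {self.patient_id!r}: field {f!r} {msg}"
        )
        if not isinstance(self.patient_id, str) or not self.patient_id:
            raise ValidationError("patient_id must be a non-empty string")
        if not (isinstance(self.age, int) and self.age >= 18):
            raise err("age", f"must be an integer >= 18, got {self.age!r}")
        if self.sex not in SEXES:
            raise err("sex", f"must be one of {sorted(SEXES)}, got {self.sex!r}")
        if not (isinstance(self.premorbid_mrs, int) and 0 <= self.premorbid_mrs <= 5):
            raise err("premorbid_mrs", f"must be an integer 0-5, got {self.premorbid_mrs!r}")
        if self.antithrombotic not in ANTITHROMBOTICS:
            raise err(
                "antithrombotic",
                f"must be one of {sorted(ANTITHROMBOTICS)}, got {self.antithrombotic!r}",
            )
        if not (isinstance(self.gcs, int) and 3 <= self.gcs <= 15):
            raise err("gcs", f"must be an integer 3-15, got {self.gcs!r}")
        if not (isinstance(self.nihss, int) and 0 <= self.nihss <= 42):
            raise err("nihss", f"must be an integer 0-42, got {self.nihss!r}")
        if self.location not in LOCATIONS:
            raise err("location", f"must be one of {sorted(LOCATIONS)}, got {self.location!r}")
        for f in ("ivh", "brainstem_dysfunction", "rescue_surgery", "evd", "survived_30d"):
            if not isinstance(getattr(self, f), bool):
                raise err(f, f"must be boolean, got {getattr(self, f)!r}")
        for f in (
            "onset_to_admission_h",
            "triage_to_image_min",
            "volume_initial_ml",
            "los_icu_d",
            "los_stroke_unit_d",
            "los_total_d",
        ):
            v = getattr(self, f)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v >= 0):
                raise err(f, f"must be finite and >= 0, got {v!r}")
        for f in ("volume_control_ml", "control_interval_h"):
            v = getattr(self, f)
            if v is not None and not (math.isfinite(v) and v >= 0):
                raise err(f, f"must be finite and >= 0 or missing, got {v!r}")
        for f in ("mrs_discharge", "mrs_midterm"):
            v = getattr(self, f)
            if v is not None and not (isinstance(v, int) and 0 <= v <= 6):
                raise err(f, f"must be an integer 0-6 or missing, got {v!r}")
        if self.discharge_destination not in DESTINATIONS:
            raise err(
                "discharge_destination",
                f"must be one of {sorted(DESTINATIONS)}, got {self.discharge_destination!r}",
            )
        # cross-field invariants
        if self.los_icu_d + self.los_stroke_unit_d > self.los_total_d + 1e-9:
            raise err(
                "los_total_d",
                f"ICU + Stroke Unit stay ({self.los_icu_d} + {self.los_stroke_unit_d}) "
                f"exceeds total stay ({self.los_total_d})",
            )
        if (self.discharge_destination == "death") != (self.mrs_discharge == 6):
            raise err(
                "discharge_destination",
                "death at discharge must coincide with mRS 6 at discharge "
                f"(destination={self.discharge_destination!r}, mrs_discharge={self.mrs_discharge!r})",
            )
        if not self.survived_30d and self.mrs_midterm not in (None, 6):
            raise err(
                "mrs_midterm",
                f"patient dead at 30 days cannot have midterm mRS {self.mrs_midterm}",
            )


FIELD_NAMES: tuple[str, ...] = tuple(f.name for f in dc_fields(PatientRecord))

_INT_FIELDS = {"age", "premorbid_mrs", "gcs", "nihss"}
_OPT_INT_FIELDS = {"mrs_discharge", "mrs_midterm"}
_BOOL_FIELDS = {"ivh", "brainstem_dysfunction", "rescue_surgery", "evd", "survived_30d"}
_FLOAT_FIELDS = {
    "onset_to_admission_h",
    "triage_to_image_min",
    "volume_initial_ml",
    "los_icu_d",
    "los_stroke_unit_d",
    "los_total_d",
}
_OPT_FLOAT_FIELDS = {"volume_control_ml", "control_interval_h"}


def _parse_cell(field: str, raw: str, row: int):
    raw = raw.strip()
    if raw == "":
        if field in _OPT_INT_FIELDS | _OPT_FLOAT_FIELDS:
            return None
        raise ValidationError(f"row {row}: field {field!r} is mandatory but empty")
    try:
        if field in _INT_FIELDS | _OPT_INT_FIELDS:
            return int(raw)
        if field in _FLOAT_FIELDS | _OPT_FLOAT_FIELDS:
            return float(raw)
        if field in _BOOL_FIELDS:
            low = raw.lower()
            if low in ("true", "1"):
                return True
            if low in ("false", "0"):
                return False
            raise ValueError(f"not a boolean: {raw!r}")
    except ValueError as exc:
        raise ValidationError(f"row {row}: field {field!r}: {exc}") from exc
    return raw


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Read and validate a cohort CSV; raise naming row and field on error."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty file") from None
        if tuple(header) != FIELD_NAMES:
            unknown = set(header) - set(FIELD_NAMES)
            missing = set(FIELD_NAMES) - set(header)
            raise ValidationError(
                f"{path}: header mismatch (unknown columns: {sorted(unknown)}, "
                f"missing columns: {sorted(missing)})"
            )
        records: list[PatientRecord] = []
        for i, row in enumerate(reader, start=2):
            if len(row) != len(FIELD_NAMES):
                raise ValidationError(
                    f"{path}: row {i}: expected {len(FIELD_NAMES)} cells, got {len(row)}"
                )
            kwargs = {f: _parse_cell(f, cell, i) for f, cell in zip(FIELD_NAMES, row)}
            try:
                records.append(PatientRecord(**kwargs))
            except ValidationError as exc:
                raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return records


def write_cohort(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write records to CSV (UTF-8, '.' decimal, empty string = missing)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(FIELD_NAMES)
        for rec in records:
            writer.writerow([_format_cell(getattr(rec, f)) for f in FIELD_NAMES])


def summarize_cohort(records: Sequence[PatientRecord]) -> dict:
    """Marginal summary of a cohort (counts, means/SDs, medians/ranges).

    Mirrors the usual baseline-characteristics table layout: n, sex
    fraction, mean (SD) age and hematoma volume, categorical counts and
    median (range) admission times. Deterministic given the input.
    """
    if not records:
        raise ValidationError("cannot summarize an empty cohort")
    n = len(records)
    age = np.array([r.age for r in records], dtype=float)
    vol = np.array([r.volume_initial_ml for r in records], dtype=float)
    tti = np.array([r.triage_to_image_min for r in records], dtype=float)
    nihss = np.array([r.nihss for r in records], dtype=float)

    def counts(field: str, values: Iterable) -> dict:
        vals = [getattr(r, field) for r in records]
        return {v: sum(x == v for x in vals) for v in values}

    mrs_disc = [r.mrs_discharge for r in records if r.mrs_discharge is not None]
    expansion = [expansion_flag(r.volume_initial_ml, r.volume_control_ml) for r in records]
    return {
        "n": n,
        "male_frac": sum(r.sex == "male" for r in records) / n,
        "age_mean": float(age.mean()),
        "age_sd": float(age.std(ddof=1)) if n > 1 else 0.0,
        "volume_mean": float(vol.mean()),
        "volume_sd": float(vol.std(ddof=1)) if n > 1 else 0.0,
        "nihss_median": float(np.median(nihss)),
        "nihss_range": (float(nihss.min()), float(nihss.max())),
        "triage_to_image_median_min": float(np.median(tti)),
        "triage_to_image_range_min": (float(tti.min()), float(tti.max())),
        "premorbid_mrs_counts": counts("premorbid_mrs", range(6)),
        "location_counts": counts("location", sorted(LOCATIONS)),
        "antithrombotic_counts": counts("antithrombotic", sorted(ANTITHROMBOTICS)),
        "ivh_frac": sum(r.ivh for r in records) / n,
        "expansion_frac_of_controlled": (
            sum(e is True for e in expansion) / max(1, sum(e is not None for e in expansion))
        ),
        "control_imaging_frac": sum(e is not None for e in expansion) / n,
        "rescue_surgery_frac": sum(r.rescue_surgery for r in records) / n,
        "evd_frac": sum(r.evd for r in records) / n,
        "los_icu_mean_d": float(np.mean([r.los_icu_d for r in records])),
        "los_stroke_unit_mean_d": float(np.mean([r.los_stroke_unit_d for r in records])),
        "los_total_mean_d": float(np.mean([r.los_total_d for r in records])),
        "discharge_counts": counts("discharge_destination", sorted(DESTINATIONS)),
        "mrs_discharge_counts": {k: sum(m == k for m in mrs_disc) for k in range(7)},
        "mortality_discharge_frac": sum(r.discharge_destination == "death" for r in records) / n,
        "survival_30d_frac": sum(r.survived_30d for r in records) / n,
    }
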