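"""Tariff-based per-patient costing of ICH treatment strategies.

Every cost is a sum of public-tariff line items (2020/2021 price year,
EUR): a per-minute operating-room rate plus the surgical pack,
neuronavigation and technique-specific material where used; per-diem ICU
/ Stroke-Unit / general-ward stays; and an optional social term for the
fraction of patients discharged to a rehabilitation facility (per-diem
over a 3-month horizon).

Under conservative management surgery is a *rescue* craniotomy performed
only on deteriorating patients, so its subtotal is weighted by the
cohort's rescue-surgery probability; an interventional arm carries its
surgery subtotal in full. The operating-room line in the source cost
tables is the subtotal of the per-minute, pack, navigation and material
lines beneath it — the only reading under which the published totals
reconcile — so it is never added as a separate charge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .cohort_model import PatientRecord, ValidationError
from .synthetic_cohort import ArmResourceSummary

__all__ = [
    "TariffTable",
    "CostBreakdown",
    "CostPolicy",
    "surgery_subtotal",
    "conservative_arm_cost",
    "mis_arm_cost",
    "social_cost",
    "ward_days",
    "cost_per_patient",
]


@dataclass(frozen=True)
class TariffTable:
    """Unit costs (EUR) from the institutional public health tariff."""

    or_rate_per_min: float
    surgical_pack: float
    navigation: float
    specific_material: dict[str, float]
    icu_per_diem: float
    stroke_unit_per_diem: float
    ward_per_diem: float
    rehab_per_diem: float
    rehab_horizon_days: float

    def __post_init__(self) -> None:
        for f in (
            "or_rate_per_min",
            "surgical_pack",
            "navigation",
            "icu_per_diem",
            "stroke_unit_per_diem",
            "ward_per_diem",
            "rehab_per_diem",
            "rehab_horizon_days",
        ):
            if getattr(self, f) < 0:
                raise ValidationError(f"tariff {f} must be >= 0")
        if any(v < 0 for v in self.specific_material.values()):
            raise ValidationError("specific material costs must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "TariffTable":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        raw.pop("_comment", None)
        return cls(**raw)

    @classmethod
    def default(cls) -> "TariffTable":
        with resources.files("ichecon.fixtures").joinpath("tariff_default.json").open(
            encoding="utf-8"
        ) as fh:
            raw = json.load(fh)
        raw.pop("_comment", None)
        return cls(**raw)


@dataclass(frozen=True)
class CostBreakdown:
    """Per-patient cost line items (EUR) for one arm.

    ``surgery_weighted`` equals ``surgery_subtotal`` for interventional
    arms and ``surgery_prob x surgery_subtotal`` for conservative arms.
    ``social``/``total_with_social`` are ``None`` when the arm's
    rehabilitation-discharge fraction is unreported.
    """

    surgery_subtotal: float
    surgery_weighted: float
    icu: float
    stroke_unit: float
    ward: float
    hospital_total: float
    social: float | None = None
    total_with_social: float | None = None

    def __post_init__(self) -> None:
        parts = (self.surgery_weighted, self.icu, self.stroke_unit, self.ward)
        if any(p < 0 for p in parts) or self.surgery_subtotal < 0:
            raise ValidationError("cost components must be >= 0")
        if abs(self.hospital_total - sum(parts)) > 1e-6:
            raise ValidationError(
                f"hospital_total {self.hospital_total} != component sum {sum(parts)}"
            )
        if self.social is not None:
            if self.social < 0:
                raise ValidationError("social cost must be >= 0")
            if (
                self.total_with_social is None
                or abs(self.total_with_social - (self.hospital_total + self.social)) > 1e-6
            ):
                raise ValidationError("total_with_social != hospital_total + social")

    def as_dict(self) -> dict:
        return {
            "surgery_subtotal": self.surgery_subtotal,
            "surgery_weighted": self.surgery_weighted,
            "icu": self.icu,
            "stroke_unit": self.stroke_unit,
            "ward": self.ward,
            "hospital_total": self.hospital_total,
            "social": self.social,
            "total_with_social": self.total_with_social,
        }


def surgery_subtotal(
    minutes: float,
    tariff: TariffTable,
    use_navigation: bool = False,
    material_key: str | None = None,
) -> float:
    """OR time x per-minute rate + surgical pack (+ navigation, + material)."""
    if minutes < 0:
        raise ValidationError("surgery minutes must be >= 0")
    total = minutes * tariff.or_rate_per_min + tariff.surgical_pack
    if use_navigation:
        total += tariff.navigation
    if material_key is not None:
        try:
            total += tariff.specific_material[material_key]
        except KeyError:
            raise KeyError(
                f"unknown specific material {material_key!r}; tariff lists: "
                f"{', '.join(sorted(tariff.specific_material))}"
            ) from None
    return total


def social_cost(rehab_frac: float | None, tariff: TariffTable) -> float:
    """Rehabilitation-facility cost: fraction x per-diem x horizon days."""
    if rehab_frac is None:
        raise ValidationError(
            "rehabilitation-discharge fraction is missing; social cost undefined"
        )
    if not 0.0 <= rehab_frac <= 1.0:
        raise ValidationError(f"rehab_frac must lie in [0, 1], got {rehab_frac}")
    return rehab_frac * tariff.rehab_per_diem * tariff.rehab_horizon_days


def ward_days(los_total: float, los_icu: float, los_stroke_unit: float) -> float:
    """General-ward days: total stay minus ICU and Stroke-Unit days, floored at 0."""
    if min(los_total, los_icu, los_stroke_unit) < 0:
        raise ValidationError("lengths of stay must be >= 0")
    return max(0.0, los_total - los_icu - los_stroke_unit)


def _stay_costs(summary: ArmResourceSummary, tariff: TariffTable) -> tuple[float, float, float]:
    if min(summary.icu_days, summary.stroke_unit_days, summary.ward_days) < 0:
        raise ValidationError("stay days must be >= 0")
    return (
        summary.icu_days * tariff.icu_per_diem,
        summary.stroke_unit_days * tariff.stroke_unit_per_diem,
        summary.ward_days * tariff.ward_per_diem,
    )


def _breakdown(
    subtotal: float, weighted: float, summary: ArmResourceSummary, tariff: TariffTable
) -> CostBreakdown:
    icu, su, ward = _stay_costs(summary, tariff)
    hospital = weighted + icu + su + ward
    social = total_social = None
    if summary.rehab_discharge_frac is not None:
        social = social_cost(summary.rehab_discharge_frac, tariff)
        total_social = hospital + social
    return CostBreakdown(
        surgery_subtotal=subtotal,
        surgery_weighted=weighted,
        icu=icu,
        stroke_unit=su,
        ward=ward,
        hospital_total=hospital,
        social=social,
        total_with_social=total_social,
    )


def conservative_arm_cost(summary: ArmResourceSummary, tariff: TariffTable) -> CostBreakdown:
    """Cost of conservative management with rescue-surgery weighting.

    The rescue craniotomy subtotal enters multiplied by the arm's
    rescue-surgery probability; stays enter at their full per-diems.
    """
    if not 0.0 <= summary.surgery_prob <= 1.0:
        raise ValidationError("surgery_prob must lie in [0, 1]")
    subtotal = surgery_subtotal(
        summary.or_minutes, tariff, summary.navigation_used, summary.specific_material_cost_key
    )
    return _breakdown(subtotal, summary.surgery_prob * subtotal, summary, tariff)


def mis_arm_cost(summary: ArmResourceSummary, tariff: TariffTable) -> CostBreakdown:
    """Cost of a minimally-invasive interventional arm (every patient operated)."""
    if summary.surgery_prob != 1.0:
        raise ValidationError(
            f"interventional arm must have surgery_prob 1, got {summary.surgery_prob}"
        )
    subtotal = surgery_subtotal(
        summary.or_minutes, tariff, summary.navigation_used, summary.specific_material_cost_key
    )
    return _breakdown(subtotal, subtotal, summary, tariff)


@dataclass(frozen=True)
class CostPolicy:
    """Surgery parameters applied when costing individual patients.

    For a conservative cohort this describes the rescue craniotomy
    (patient records carry no surgery duration of their own); for an
    interventional policy every patient is operated.
    """

    surgery_minutes: float = 130.0
    use_navigation: bool = False
    material_key: str | None = None
    interventional: bool = False


def cost_per_patient(
    record: PatientRecord, tariff: TariffTable, policy: CostPolicy = CostPolicy()
) -> CostBreakdown:
    """Line-item cost of one patient's own resource use.

    The mean of this over a cohort equals :func:`conservative_arm_cost`
    of the cohort's aggregated summary (surgery weighted by the observed
    rescue fraction, stays by their means) — the vectorized and the
    per-patient paths are mutually checking oracles.
    """
    subtotal = surgery_subtotal(
        policy.surgery_minutes, tariff, policy.use_navigation, policy.material_key
    )
    operated = policy.interventional or record.rescue_surgery
    weighted = subtotal if operated else 0.0
    icu = record.los_icu_d * tariff.icu_per_diem
    su = record.los_stroke_unit_d * tariff.stroke_unit_per_diem
    ward = ward_days(record.los_total_d, record.los_icu_d, record.los_stroke_unit_d) * tariff.ward_per_diem
    hospital = weighted + icu + su + ward
    social = (
        tariff.rehab_per_diem * tariff.rehab_horizon_days
        if record.discharge_destination == "rehabilitation"
        else 0.0
    )
    return CostBreakdown(
        surgery_subtotal=subtotal,
        surgery_weighted=weighted,
        icu=icu,
        stroke_unit=su,
        ward=ward,
        hospital_total=hospital,
        social=social,
        total_with_social=hospital + social,
    )
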