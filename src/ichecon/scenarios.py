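"""Packaged reference scenario: the published-operand comparison.

Builds, from the frozen arm fixtures and default tariff alone, the two
deterministic strategy comparisons of the analysis:

* catheter technique — MISTIE III interventional arm vs the
  conservative-management catheter-candidate subgroup;
* endoscopic technique — Kellner 2020 endoscopic arm vs the
  conservative-management endoscopic-candidate subgroup.

Arm QALYs here are the *published group values* (0.09 / 0.32 for the
catheter pair, 0.234 / 0.365 for the endoscopic pair), which were
derived by the source analysis from midterm mRS through the Whynes
utility regression; that regression's coefficients are not packaged, so
these group values enter the economics directly as inputs rather than
being re-derived from a utility map. Everything else — costs, ICER, net
health benefit, required effect size — is recomputed from tariff line
items at run time.
"""

from __future__ import annotations

from dataclasses import dataclass

from .costing import (
    CostBreakdown,
    CostPolicy,
    TariffTable,
    conservative_arm_cost,
    mis_arm_cost,
)
from .econ import DEFAULT_LAMBDA, EconComparison, compare
from .synthetic_cohort import ArmResourceSummary, literature_arm

__all__ = [
    "TECHNIQUES",
    "PUBLISHED_GROUP_QALYS",
    "ReferenceComparison",
    "reference_comparison",
    "reference_cohort_policy",
]

TECHNIQUES = ("catheter", "endoscopic")

# published group QALYs (1-year horizon, Whynes-based mRS mapping)
PUBLISHED_GROUP_QALYS: dict[str, float] = {
    "catheter_control": 0.09,
    "mistie3_intervention": 0.32,
    "endoscopic_control": 0.234,
    "kellner_intervention": 0.365,
}

_ARMS: dict[str, tuple[str, str]] = {
    "catheter": ("mistie3_intervention", "catheter_control"),
    "endoscopic": ("kellner_intervention", "endoscopic_control"),
}


@dataclass(frozen=True)
class ReferenceComparison:
    """Deterministic comparison plus the two cost breakdowns behind it."""

    technique: str
    mis_arm: ArmResourceSummary
    conv_arm: ArmResourceSummary
    mis_cost: CostBreakdown
    conv_cost: CostBreakdown
    comparison: EconComparison

    def as_dict(self) -> dict:
        return {
            "technique": self.technique,
            "mis_arm": self.mis_arm.name,
            "conv_arm": self.conv_arm.name,
            "mis_cost": self.mis_cost.as_dict(),
            "conv_cost": self.conv_cost.as_dict(),
            "comparison": self.comparison.as_dict(),
        }


def reference_comparison(
    technique: str,
    tariff: TariffTable | None = None,
    lam: float = DEFAULT_LAMBDA,
    include_social: bool = False,
) -> ReferenceComparison:
    """Recompute one technique's comparison from packaged fixtures.

    With ``include_social`` the cost operands additionally carry the
    3-month rehabilitation-facility term (unavailable for MISTIE III,
    whose rehabilitation-discharge fraction is unreported).
    """
    if technique not in _ARMS:
        raise KeyError(f"unknown technique {technique!r}; choose from {TECHNIQUES}")
    tariff = tariff or TariffTable.default()
    mis_name, conv_name = _ARMS[technique]
    mis_arm = literature_arm(mis_name)
    conv_arm = literature_arm(conv_name)
    mis_cost = mis_arm_cost(mis_arm, tariff)
    conv_cost = conservative_arm_cost(conv_arm, tariff)
    if include_social:
        if mis_cost.total_with_social is None:
            raise ValueError(
                f"arm {mis_name!r} has no social-cost term (rehabilitation "
                "fraction unreported); cannot compare with social costs"
            )
        cost_mis, cost_conv = mis_cost.total_with_social, conv_cost.total_with_social
    else:
        cost_mis, cost_conv = mis_cost.hospital_total, conv_cost.hospital_total
    comparison = compare(
        cost_mis=cost_mis,
        cost_conv=cost_conv,
        qaly_mis=PUBLISHED_GROUP_QALYS[mis_name],
        qaly_conv=PUBLISHED_GROUP_QALYS[conv_name],
        lam=lam,
        name=technique,
    )
    return ReferenceComparison(
        technique=technique,
        mis_arm=mis_arm,
        conv_arm=conv_arm,
        mis_cost=mis_cost,
        conv_cost=conv_cost,
        comparison=comparison,
    )


def reference_cohort_policy(technique: str) -> CostPolicy:
    """Rescue-craniotomy cost policy matching each control subgroup."""
    if technique not in _ARMS:
        raise KeyError(f"unknown technique {technique!r}; choose from {TECHNIQUES}")
    conv = literature_arm(_ARMS[technique][1])
    return CostPolicy(
        surgery_minutes=conv.or_minutes,
        use_navigation=conv.navigation_used,
        material_key=conv.specific_material_cost_key,
        interventional=False,
    )
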