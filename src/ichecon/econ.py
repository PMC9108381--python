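"""Deterministic cost-utility comparison of two treatment strategies.

Given the mean per-patient cost and QALY of a minimally invasive
strategy (MIS) and of conventional management, this module computes

* the incremental cost-effectiveness ratio ICER = ΔC/ΔE,
* the cost-utility-plane quadrant of (ΔE, ΔC),
* net health benefit NHB = ΔE - ΔC/λ and net monetary benefit
  NMB = λ·ΔE - ΔC at a willingness-to-pay threshold λ (€/QALY), and
* the MIS-arm QALY that would be required for the ICER to hit λ exactly
  (the threshold or "required effect size" analysis).

A non-positive ΔE never yields a signed ICER number — the ratio is
meaningless there; dominance tags and the quadrant carry the
interpretation instead, with :func:`unsafe_icer` available where a raw
ratio is wanted for plotting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .cohort_model import ValidationError

__all__ = [
    "EconComparison",
    "DEFAULT_LAMBDA",
    "icer",
    "unsafe_icer",
    "quadrant",
    "nhb",
    "nmb",
    "required_qaly_at_threshold",
    "compare",
]

DEFAULT_LAMBDA = 30_000.0  # €/QALY; the locally accepted threshold

DOMINANT = "dominant"
DOMINATED = "dominated"
INDETERMINATE = "indeterminate"
SOUTHWEST_TRADEOFF = "southwest_tradeoff"


def _require_finite(*values: float) -> None:
    if any(not math.isfinite(v) for v in values):
        raise ValidationError("inputs must be finite")


def icer(
    cost_mis: float, cost_conv: float, qaly_mis: float, qaly_conv: float
) -> float | str:
    """ΔC/ΔE when ΔE > 0 and ΔC >= 0; a dominance tag otherwise.

    Tags: ``dominant`` (cheaper and more effective), ``dominated``
    (costlier and less effective), ``indeterminate`` (ΔE = 0),
    ``southwest_tradeoff`` (cheaper but less effective — savings per QALY
    forgone, not a cost per QALY gained).
    """
    _require_finite(cost_mis, cost_conv, qaly_mis, qaly_conv)
    dc = cost_mis - cost_conv
    de = qaly_mis - qaly_conv
    if de == 0.0:
        return INDETERMINATE
    if de > 0.0:
        return DOMINANT if dc < 0.0 else dc / de
    return DOMINATED if dc > 0.0 else SOUTHWEST_TRADEOFF


def unsafe_icer(cost_mis: float, cost_conv: float, qaly_mis: float, qaly_conv: float) -> float:
    """Raw ΔC/ΔE regardless of sign; for plotting only. Requires ΔE != 0."""
    _require_finite(cost_mis, cost_conv, qaly_mis, qaly_conv)
    de = qaly_mis - qaly_conv
    if de == 0.0:
        raise ValidationError("ΔE is zero; the ratio is undefined")
    return (cost_mis - cost_conv) / de


def quadrant(delta_cost: float, delta_qaly: float) -> str:
    """Cost-utility-plane quadrant of (ΔE, ΔC); ``axis`` when either is 0."""
    _require_finite(delta_cost, delta_qaly)
    if delta_cost == 0.0 or delta_qaly == 0.0:
        return "axis"
    if delta_qaly > 0.0:
        return "NE" if delta_cost > 0.0 else "SE"
    return "NW" if delta_cost > 0.0 else "SW"


def nhb(delta_cost: float, delta_qaly: float, lam: float = DEFAULT_LAMBDA) -> float:
    """Net health benefit ΔE - ΔC/λ, in QALYs."""
    _require_finite(delta_cost, delta_qaly)
    if lam <= 0:
        raise ValidationError(f"willingness-to-pay must be > 0, got {lam}")
    return delta_qaly - delta_cost / lam


def nmb(delta_cost: float, delta_qaly: float, lam: float = DEFAULT_LAMBDA) -> float:
    """Net monetary benefit λ·ΔE - ΔC, in EUR; identically λ times the NHB."""
    _require_finite(delta_cost, delta_qaly)
    if lam <= 0:
        raise ValidationError(f"willingness-to-pay must be > 0, got {lam}")
    return lam * delta_qaly - delta_cost


def required_qaly_at_threshold(
    delta_cost: float, qaly_conv: float, lam: float = DEFAULT_LAMBDA
) -> float:
    """MIS-arm QALY at which the ICER equals λ exactly: q_conv + ΔC/λ."""
    _require_finite(delta_cost, qaly_conv)
    if lam <= 0:
        raise ValidationError(f"willingness-to-pay must be > 0, got {lam}")
    return qaly_conv + delta_cost / lam


@dataclass(frozen=True)
class EconComparison:
    """Full deterministic comparison of one MIS strategy vs conventional care."""

    name: str
    cost_mis: float
    cost_conv: float
    qaly_mis: float
    qaly_conv: float
    delta_cost: float
    delta_qaly: float
    icer: float | str
    quadrant: str
    lam: float
    nhb: float
    nmb: float
    required_qaly_mis: float

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "cost_mis": self.cost_mis,
            "cost_conv": self.cost_conv,
            "qaly_mis": self.qaly_mis,
            "qaly_conv": self.qaly_conv,
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "quadrant": self.quadrant,
            "lambda": self.lam,
            "nhb": self.nhb,
            "nmb": self.nmb,
            "required_qaly_mis": self.required_qaly_mis,
        }


def compare(
    cost_mis: float,
    cost_conv: float,
    qaly_mis: float,
    qaly_conv: float,
    lam: float = DEFAULT_LAMBDA,
    name: str = "comparison",
) -> EconComparison:
    dc = cost_mis - cost_conv
    de = qaly_mis - qaly_conv
    return EconComparison(
        name=name,
        cost_mis=cost_mis,
        cost_conv=cost_conv,
        qaly_mis=qaly_mis,
        qaly_conv=qaly_conv,
        delta_cost=dc,
        delta_qaly=de,
        icer=icer(cost_mis, cost_conv, qaly_mis, qaly_conv),
        quadrant=quadrant(dc, de),
        lam=lam,
        nhb=nhb(dc, de, lam),
        nmb=nmb(dc, de, lam),
        required_qaly_mis=required_qaly_at_threshold(dc, qaly_conv, lam),
    )
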