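"""Modified Rankin Scale outcomes mapped to utilities and QALYs.

Effectiveness is expressed in quality-adjusted life years over a fixed
1-year horizon: each surviving patient contributes the utility attached
to their midterm mRS level times the horizon; death (mRS 6) contributes
exactly zero. No discounting or half-cycle correction is applied at this
horizon.

Two utility presets ship:

* ``linear`` — u(mRS) = (6 - mRS)/6, a transparent equal-spacing map
  useful for property checks and sensitivity analyses.
* ``whynes`` — a named but *unpopulated* slot for the regression-based
  mRS→utility mapping of Whynes et al.; the coefficients are not
  redistributable here, so the user supplies the 7 values from that
  publication (or any other elicited tariff) via config.

Arm-level QALYs published by source studies can also be passed straight
into the economic comparison without re-deriving them from a map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

from .cohort_model import ValidationError

__all__ = [
    "UtilityMap",
    "EffectSummary",
    "utility_of_mrs",
    "arm_qaly",
    "good_outcome_frac",
    "survival_frac_30d",
    "effect_summary",
]


@dataclass(frozen=True)
class UtilityMap:
    """Seven utilities indexed by mRS 0-6; u[6] (death) must be exactly 0."""

    u: tuple[float, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        if len(self.u) != 7:
            raise ValidationError("utility map needs exactly 7 entries (mRS 0-6)")
        if self.u[6] != 0.0:
            raise ValidationError(f"u[6] (death) must be exactly 0, got {self.u[6]}")
        if any(not -1.0 <= v <= 1.0 for v in self.u):
            raise ValidationError("utilities must lie in [-1, 1]")
        if any(self.u[i] < self.u[i + 1] for i in range(6)):
            warnings.warn(
                f"utility map {self.name!r} is not non-increasing in mRS",
                stacklevel=3,
            )

    @classmethod
    def linear(cls) -> "UtilityMap":
        return cls(u=tuple((6 - k) / 6 for k in range(7)), name="linear")

    @classmethod
    def whynes(cls, values: Sequence[float]) -> "UtilityMap":
        """The Whynes-style regression map; user supplies the published values."""
        return cls(u=tuple(float(v) for v in values), name="whynes")


@dataclass(frozen=True)
class EffectSummary:
    """Arm-level effectiveness: mean QALY, good-outcome and survival fractions."""

    mean_qaly: float
    good_outcome_frac: float
    survival_30d_frac: float
    n_evaluable: int
    horizon_years: float = 1.0


def utility_of_mrs(umap: UtilityMap, mrs: int) -> float:
    if not (isinstance(mrs, int) and 0 <= mrs <= 6):
        raise ValidationError(f"mRS must be an integer 0-6, got {mrs!r}")
    return umap.u[mrs]


def arm_qaly(
    mrs_counts: Sequence[int],
    umap: UtilityMap,
    horizon_years: float = 1.0,
    denominator_policy: str = "evaluable",
    n_enrolled: int | None = None,
) -> float:
    """Mean QALY of an arm from its midterm mRS count vector.

    ``denominator_policy`` — "evaluable" (default): divide by the counted
    patients, deaths included at utility 0; "enrolled": divide by
    ``n_enrolled``, treating unevaluated patients as zero-contribution.
    """
    if len(mrs_counts) != 7 or any(c < 0 for c in mrs_counts):
        raise ValidationError("mrs_counts must be 7 nonnegative counts")
    total = sum(mrs_counts)
    if denominator_policy == "evaluable":
        denom = total
    elif denominator_policy == "enrolled":
        if n_enrolled is None:
            raise ValidationError("denominator_policy='enrolled' needs n_enrolled")
        denom = n_enrolled
    else:
        raise ValidationError(f"unknown denominator_policy {denominator_policy!r}")
    if denom <= 0:
        raise ValidationError("QALY denominator must be > 0")
    weighted = sum(c * u for c, u in zip(mrs_counts, umap.u))
    return weighted * horizon_years / denom


def good_outcome_frac(mrs_counts: Sequence[int], cutoff: int = 3) -> float:
    """Fraction with a favorable functional outcome (mRS <= cutoff)."""
    if len(mrs_counts) != 7 or any(c < 0 for c in mrs_counts):
        raise ValidationError("mrs_counts must be 7 nonnegative counts")
    if not 0 <= cutoff <= 6:
        raise ValidationError("cutoff must lie in 0-6")
    total = sum(mrs_counts)
    if total == 0:
        raise ValidationError("mrs_counts sum to zero")
    return sum(mrs_counts[: cutoff + 1]) / total


def survival_frac_30d(deaths_30d: int, n: int) -> float:
    if n <= 0:
        raise ValidationError("n must be > 0")
    if not 0 <= deaths_30d <= n:
        raise ValidationError("deaths must lie in [0, n]")
    return 1.0 - deaths_30d / n


def effect_summary(
    mrs_counts: Sequence[int],
    mortality_30d_frac: float,
    umap: UtilityMap,
    horizon_years: float = 1.0,
) -> EffectSummary:
    """Bundle the three effectiveness measures for one arm."""
    return EffectSummary(
        mean_qaly=arm_qaly(mrs_counts, umap, horizon_years),
        good_outcome_frac=good_outcome_frac(mrs_counts),
        survival_30d_frac=1.0 - mortality_30d_frac,
        n_evaluable=int(sum(mrs_counts)),
        horizon_years=horizon_years,
    )
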