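"""Probabilistic sensitivity analysis for the cost-utility comparison.

Uncertainty is propagated by Monte-Carlo replication of the incremental
pair (ΔC, ΔE):

* the conservative (cohort) arm is resampled by nonparametric bootstrap
  of patients, so each replicate's mean cost and mean QALY move jointly
  with the patients drawn;
* the published interventional arm is resampled parametrically — the
  midterm mRS count vector through a Dirichlet(counts + 1) draw (the +1
  prior keeps zero cells alive), ICU/ward stays through moment-matched
  gamma distributions, and operating-room minutes through a normal
  truncated at zero. An SD of zero makes the corresponding quantity a
  point mass, and ``literature_resampling="none"`` freezes the whole arm
  at its point estimates.

Replicates feed the cost-utility plane export and the
cost-effectiveness acceptability curve (CEAC): the probability, at each
willingness-to-pay λ, that the intervention has strictly positive net
monetary benefit. A replicate sitting exactly at NMB = 0 counts as NOT
cost-effective, so the step behaviour of degenerate curves is
unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .cohort_model import PatientRecord, ValidationError
from .costing import CostPolicy, TariffTable, cost_per_patient, surgery_subtotal
from .econ import quadrant
from .qaly import UtilityMap, arm_qaly
from .synthetic_cohort import ArmResourceSummary

__all__ = [
    "PSAConfig",
    "CEACCurve",
    "run_psa",
    "ceac",
    "wtp_at_probability",
    "plane_export",
    "plot_plane",
    "plot_ceac",
]


def _default_lambda_grid() -> tuple[float, ...]:
    return tuple(float(x) for x in range(0, 150_001, 1_000))


@dataclass
class PSAConfig:
    """Replication settings for the probabilistic sensitivity analysis."""

    n_replicates: int = 5_000
    seed: int = 0
    cohort_resampling: str = "nonparametric_bootstrap"
    literature_resampling: str = "dirichlet_mrs+gamma_los+normal_cost"
    lambda_grid: tuple[float, ...] = field(default_factory=_default_lambda_grid)
    horizon_years: float = 1.0
    include_social: bool = False
    dirichlet_prior: float = 1.0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.cohort_resampling != "nonparametric_bootstrap":
            raise ValidationError(
                f"unknown cohort_resampling {self.cohort_resampling!r}"
            )
        if self.literature_resampling not in (
            "dirichlet_mrs+gamma_los+normal_cost",
            "none",
        ):
            raise ValidationError(
                f"unknown literature_resampling {self.literature_resampling!r}"
            )
        grid = np.asarray(self.lambda_grid, dtype=float)
        if grid.size == 0:
            raise ValidationError("lambda_grid must be nonempty")
        if np.any(grid < 0):
            raise ValidationError("lambda_grid values must be >= 0")
        if np.any(np.diff(grid) <= 0):
            raise ValidationError("lambda_grid must be strictly increasing")
        if self.dirichlet_prior < 0:
            raise ValidationError("dirichlet_prior must be >= 0")


@dataclass
class CEACCurve:
    """Acceptability probabilities on an ascending willingness-to-pay grid."""

    points: list[tuple[float, float]]
    n_replicates: int

    def __post_init__(self) -> None:
        lams = [p[0] for p in self.points]
        probs = [p[1] for p in self.points]
        if any(np.diff(lams) <= 0):
            raise ValidationError("CEAC lambdas must be strictly ascending")
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValidationError("CEAC probabilities must lie in [0, 1]")


def _gamma_draw(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    if mean <= 0 or sd <= 0:
        return np.full(size, max(mean, 0.0))
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return rng.gamma(shape, scale, size=size)


def _truncnorm_draw(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    if sd <= 0:
        return np.full(size, max(mean, 0.0))
    a = (0.0 - mean) / sd
    u = rng.uniform(size=size)
    return stats.truncnorm.ppf(u, a, np.inf, loc=mean, scale=sd)


def run_psa(
    cohort_records: Sequence[PatientRecord],
    literature_arm: ArmResourceSummary,
    tariff: TariffTable,
    utility_map: UtilityMap,
    config: PSAConfig,
    cohort_policy: CostPolicy = CostPolicy(),
) -> np.ndarray:
    """Monte-Carlo replicates of (ΔC, ΔE) = MIS minus conventional.

    Returns an array of shape (n_replicates, 2), bit-reproducible for a
    given (inputs, config.seed).
    """
    if not cohort_records:
        raise ValidationError("cohort arm must contain at least one patient")
    if cohort_policy.interventional:
        raise ValidationError("the bootstrapped cohort arm must be the conservative arm")
    n = len(cohort_records)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    R = config.n_replicates
    resample_lit = config.literature_resampling != "none"

    # per-patient cost and utility, computed once; the bootstrap then
    # resamples these jointly
    costs = np.empty(n)
    utilities = np.full(n, np.nan)  # NaN = midterm mRS missing
    for i, rec in enumerate(cohort_records):
        cb = cost_per_patient(rec, tariff, cohort_policy)
        costs[i] = cb.total_with_social if config.include_social else cb.hospital_total
        if rec.mrs_midterm is not None:
            utilities[i] = utility_map.u[rec.mrs_midterm] * config.horizon_years

    lit = literature_arm
    lit_counts = np.asarray(lit.mrs_midterm_counts, dtype=float)
    if lit_counts.sum() <= 0:
        raise ValidationError("literature arm has no evaluable midterm outcomes")
    u_vec = np.asarray(utility_map.u)
    lit_social = 0.0
    if config.include_social:
        if lit.rehab_discharge_frac is None:
            raise ValidationError(
                f"arm {lit.name!r} has no rehabilitation-discharge fraction; "
                "social costs cannot be included"
            )
        lit_social = lit.rehab_discharge_frac * tariff.rehab_per_diem * tariff.rehab_horizon_days

    if resample_lit:
        alpha = lit_counts + config.dirichlet_prior
        if np.any(alpha <= 0):
            raise ValidationError(
                "Dirichlet resampling needs every mRS cell positive; "
                "use a positive dirichlet_prior for arms with empty cells"
            )
        lit_probs = rng.dirichlet(alpha, size=R)
        lit_minutes = _truncnorm_draw(rng, lit.or_minutes, lit.or_minutes_sd, R)
        lit_icu = _gamma_draw(rng, lit.icu_days, lit.icu_days_sd, R)
        lit_ward = _gamma_draw(rng, lit.ward_days, lit.ward_days_sd, R)
    else:
        lit_probs = np.tile(lit_counts / lit_counts.sum(), (R, 1))
        lit_minutes = np.full(R, lit.or_minutes)
        lit_icu = np.full(R, lit.icu_days)
        lit_ward = np.full(R, lit.ward_days)

    lit_qaly = lit_probs @ u_vec * config.horizon_years
    lit_surgery = np.array(
        [
            surgery_subtotal(m, tariff, lit.navigation_used, lit.specific_material_cost_key)
            for m in lit_minutes
        ]
    )
    lit_cost = (
        lit_surgery
        + lit_icu * tariff.icu_per_diem
        + lit.stroke_unit_days * tariff.stroke_unit_per_diem
        + lit_ward * tariff.ward_per_diem
        + lit_social
    )

    out = np.empty((R, 2))
    for r in range(R):
        idx = rng.integers(0, n, size=n)
        conv_cost = costs[idx].mean()
        util = utilities[idx]
        util = util[~np.isnan(util)]
        # a resample with no evaluable outcome keeps the point estimate
        conv_qaly = util.mean() if util.size else np.nanmean(utilities)
        out[r, 0] = lit_cost[r] - conv_cost
        out[r, 1] = lit_qaly[r] - conv_qaly
    return out


def ceac(replicates: np.ndarray, lambda_grid: Sequence[float]) -> CEACCurve:
    """Acceptability curve: P(λ·ΔE - ΔC > 0) at each grid λ."""
    reps = np.asarray(replicates, dtype=float)
    if reps.size == 0:
        raise ValidationError("need at least one replicate")
    grid = np.asarray(lambda_grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("lambda grid must be nonempty")
    if np.any(np.diff(grid) <= 0):
        raise ValidationError("lambda grid must be strictly increasing")
    dc, de = reps[:, 0], reps[:, 1]
    points = [
        (float(lam), float(np.mean(lam * de - dc > 0.0))) for lam in grid
    ]
    return CEACCurve(points=points, n_replicates=len(reps))


def wtp_at_probability(curve: CEACCurve, p: float) -> float | None:
    """Smallest λ (linear interpolation) where acceptability reaches p.

    Returns ``None`` when the curve never attains p on its grid.
    """
    if not 0.0 < p < 1.0:
        raise ValidationError("p must lie strictly between 0 and 1")
    if not curve.points:
        raise ValidationError("curve has no points")
    prev_lam, prev_prob = curve.points[0]
    if prev_prob >= p:
        return prev_lam
    for lam, prob in curve.points[1:]:
        if prob >= p:
            if prob == prev_prob:
                return lam
            frac = (p - prev_prob) / (prob - prev_prob)
            return prev_lam + frac * (lam - prev_lam)
        prev_lam, prev_prob = lam, prob
    return None


def plane_export(replicates: np.ndarray, lam: float):
    """Cost-utility-plane table: one row per replicate, with quadrant and flag."""
    import pandas as pd

    reps = np.asarray(replicates, dtype=float)
    if reps.size == 0:
        raise ValidationError("need at least one replicate")
    dc, de = reps[:, 0], reps[:, 1]
    return pd.DataFrame(
        {
            "delta_qaly": de,
            "delta_cost": dc,
            "quadrant": [quadrant(c, e) for c, e in zip(dc, de)],
            "cost_effective_flag": lam * de - dc > 0.0,
        }
    )


def plot_plane(replicates_by_name: dict[str, np.ndarray], lam: float, path) -> None:
    """Incremental cost-utility scatter with the willingness-to-pay ray."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    colors = {"catheter": "tab:red", "endoscopic": "tab:blue"}
    for i, (name, reps) in enumerate(replicates_by_name.items()):
        reps = np.asarray(reps)
        ax.scatter(
            reps[:, 1],
            reps[:, 0],
            s=6,
            alpha=0.4,
            label=name,
            color=colors.get(name, f"C{i}"),
        )
    xmax = max(abs(ax.get_xlim()[0]), abs(ax.get_xlim()[1]))
    xs = np.linspace(-xmax, xmax, 3)
    ax.plot(xs, lam * xs, color="red", lw=1, label=f"λ = €{lam:,.0f}/QALY")
    ax.axhline(0, color="grey", lw=0.6)
    ax.axvline(0, color="grey", lw=0.6)
    ax.set_xlabel("incremental effectiveness (QALY)")
    ax.set_ylabel("incremental cost (€)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(curves_by_name: dict[str, CEACCurve], path) -> None:
    """Cost-effectiveness acceptability curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, curve in curves_by_name.items():
        lams = [pt[0] for pt in curve.points]
        probs = [pt[1] for pt in curve.points]
        ax.plot(lams, probs, label=name)
    ax.axhline(0.5, color="grey", lw=0.6, ls="--")
    ax.set_xlabel("willingness-to-pay (€/QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(0, 1)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
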