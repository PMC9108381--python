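# Methods

## Scope and model structure

The package implements a two-strategy cost-utility comparison over a
1-year horizon for patients with spontaneous supratentorial ICH:
conservative management versus one of two minimally invasive evacuation
techniques (catheter + thrombolysis; neuroendoscopic aspiration). It is a
decision-analytic cost-utility model, not a trial analysis: effectiveness
for the interventional arms comes from published trial reports (MISTIE III;
Kellner 2020), costs for all arms from one institution's public tariff,
and the conventional comparators are the registry subgroups that would
have been trial-eligible. There is no multi-year extrapolation, no
discounting and no half-cycle correction — at a 1-year horizon these
would be second-order relative to the uncertainty in effectiveness.

Stages are composable and individually tested: patient schema and imaging
quantities (`cohort_model`), synthetic cohorts and arm fixtures
(`synthetic_cohort`), trial screening (`eligibility`), tariff costing
(`costing`), utilities and QALYs (`qaly`), deterministic comparison
(`econ`), and probabilistic sensitivity analysis (`psa`).

## Costing

All costs are EUR, 2020/2021 price year, full floating precision
internally, rounded to cents only at presentation.

| parameter | default | unit |
|---|---|---|
| OR rate | 5 | €/min |
| surgical pack | 1,150 | € |
| neuronavigation | 862 | € |
| catheter material / endoscope consumables | 200 / 7,000 | € |
| ICU / Stroke Unit / ward per-diem | 1,175.9 / 707.4 / 419 | €/day |
| rehabilitation per-diem × horizon | 97.8 × 90 | €/day × days |

Structural choices:

* **The OR line is a subtotal.** The published cost tables print an
  "operating room" figure above its per-minute/pack/navigation/material
  components; the totals only reconcile when that figure is the subtotal
  of the lines beneath it, so the model never adds it separately.
* **Rescue weighting uses exact fractions.** The conservative arms weight
  the rescue craniotomy subtotal by the exact cohort fractions 5/17 and
  10/59 rather than the rounded percentages printed next to them (the
  printed €529.2 weighted line is itself 1,800 × 0.294). Recomputed arm
  totals land within 0.004–0.016% of the printed cells; the residuals are
  table-rounding artifacts, which is why the reproduction tolerance on
  cost totals is 0.1%.
* **Ward days are the remainder** `max(0, total − ICU − Stroke Unit)`;
  with validated records the floor never binds, which is what makes the
  per-patient and summary-level costing paths agree exactly (a tested
  oracle equivalence at 1e-6 €).
* **Kellner stay days.** The published report gives LoS medians (ICU 9,
  hospital 17) but its own cost lines use 8.5/8.5; the fixture carries
  both, defaults to the cost-line values, and exposes
  `with_cost_line_los(False)` to switch.
* The MISTIE III rehabilitation-discharge fraction is unreported, so that
  arm has no social term; requesting one raises rather than assuming 0.

## Utilities and QALYs

`arm_qaly` is `Σ counts[k]·u[k]·horizon / denominator` over midterm mRS
counts. The default denominator is the evaluable patients (deaths
included at u = 0), matching how the source arms report "data available
from N patients"; an `enrolled` policy divides by the full arm size
instead. Presets: `linear` (u = (6 − mRS)/6), a transparent map used for
property tests and the PSA; and `whynes`, a named slot for the
regression-based mRS→utility mapping the source analysis cites, whose
coefficients the user must supply (they are not reprinted here). The
published group QALYs (0.09 / 0.32 / 0.234 / 0.365) are therefore treated
as *inputs* to the economic comparison (`scenarios.PUBLISHED_GROUP_QALYS`),
not quantities the package re-derives; no packaged utility map reproduces
them, and the source text's phrase about multiplying survival time "by
the mRS" is read as shorthand for the utility attached to that mRS —
taken literally it would contradict both the cited utility model and the
printed group values. Both readings remain expressible via custom maps.

## Economics

ICER is reported as a signed number only in the economically meaningful
region (ΔE > 0, ΔC ≥ 0). Otherwise dominance tags carry the
interpretation: `dominant` (ΔC < 0, ΔE > 0), `dominated` (ΔC > 0,
ΔE < 0), `indeterminate` (ΔE = 0), `southwest_tradeoff` (ΔC ≤ 0,
ΔE < 0 — savings per QALY forgone, a different quantity). `unsafe_icer`
returns the raw ratio for plotting. λ defaults to €30,000/QALY, the
locally accepted threshold; the required-effect-size analysis inverts the
ICER at λ: `q_required = q_conv + ΔC/λ`, with the round-trip
`icer(..., q_required, q_conv) = λ` tested to 1e-9 relative.

## Synthetic cohort generator

The generator emulates the *marginal* distributions of the registry's
baseline and resource tables: age truncated-normal on [18, 100]
(69 ± 15.1 y); hematoma volume log-normal re-parameterized to mean 35 /
SD 42 ml (a normal would go negative); ICU / Stroke-Unit / total stays
gamma matched by moments (2 ± 7.8, 2 ± 2.6, 15 ± 20.8 days); categorical
mixes (sex, premorbid mRS, GCS bands with integer-uniform fill inside a
band, NIHSS as a rounded truncated normal with median 12 on 0–36,
location, antithrombotics, discharge mRS) at the published counts; and
Bernoulli rates for IVH (0.38), control imaging (0.679), expansion
(0.336), rescue surgery (0.131), EVD (0.146). Onset-to-admission is
log-normal (median 5 h, σ = 1) truncated at the 48 h study window;
triage-to-image log-normal matched to the published median of 19 min.

Dependence is a Gaussian copula: one latent standard-normal severity per
patient is mixed into each severity-linked field's uniform with weight
`severity_coupling` (default 0.6 — the source implies but never
quantifies coupling; 0 yields independence, 1 comonotonicity, both
tested). GCS couples negatively; volume, NIHSS, stays, discharge mRS,
rescue, EVD, IVH and brainstem dysfunction positively. Each field draws
from its own seeded substream in a fixed append-only order, so adding
fields later never perturbs existing cohorts.

Derived fields keep records internally consistent rather than marginally
exact: discharge destination is death iff discharge mRS = 6, else
rehabilitation for mRS 3–5 and home for 0–2 (reproducing the published
home/rehabilitation/death split to within one patient); total stay is
floored at ICU + Stroke-Unit; midterm mRS improves one level with
probability 0.5, moves to death with probability 0.05, and is missing
with probability 0.1 among survivors; 80% of in-hospital deaths are
assigned to the first 30 days.

What the generator does **not** emulate: joint distributions beyond the
single-factor copula, site/temporal effects, informative missingness, or
the registry's actual patients. Consequently the published eligibility
counts (17/59/24/11 of 137) are emulation targets only — screening the
default synthetic cohort lands near them (e.g. ~12% MISTIE III, ~46%
DIST at seed 0) but this is calibration, not reproduction, and tests
assert only a wide Monte-Carlo band plus structural properties
(monotonicity under threshold relaxation, brute-force oracle agreement).

## Eligibility rules

Rule sets are data: `(field, op, value, label)` triples over patient
fields and derived quantities (`supratentorial`, `hematoma_stable_6h`,
`mild_presentation`, location groupings). The shipped defaults encode
volume ≥ 30 ml, stability on repeat imaging ≥ 6 h apart (growth < 5 ml),
72 h window and premorbid mRS ≤ 1 for MISTIE III; volume ≥ 10 ml, 8 h
window, premorbid mRS ≤ 2, NIHSS ≥ 2 for DIST; 30–80 ml lobar/anterior
basal ganglia with GCS 5–14 for ENRICH; 20–80 ml deep with NIHSS ≥ 6 for
INVEST; all with an intact-brainstem exclusion, all overridable by config
files, and the screening report prints the active rules so divergence
from any protocol detail is auditable. Premorbid-mRS cutoffs for the two
MIS trials follow the candidate columns of the baseline table (no mRS ≥ 2
among MISTIE candidates, none ≥ 3 among DIST candidates). The 72 h
MISTIE window is applied to onset-to-admission, the only onset-anchored
time the record carries. Criteria touching missing fields are
indeterminate; the default policy counts them as ineligible-with-reason,
with an `optimistic` policy for sensitivity analysis. Expansion is
strictly `Δ > 5 ml`, so a 5.0 ml change is stable.

## Probabilistic sensitivity analysis

Each replicate pairs a nonparametric bootstrap of the conservative
cohort (per-patient cost and utility resampled jointly, so their
correlation is preserved) with parametric resampling of the published
arm: mRS probabilities ~ Dirichlet(counts + 1), ICU/ward days ~ gamma
matched to mean and an SD read off the published ranges (range/4),
OR minutes ~ normal truncated at 0. The +1 prior keeps empty mRS cells
alive; it slightly shrinks the resampled outcome distribution toward
uniform, so the bootstrap-consistency test uses a zero prior on the
Kellner arm (all cells positive) where the scheme is exactly unbiased.
`literature_resampling="none"` freezes the published arm at its point
estimates, which is also how the degenerate all-replicates-identical
behaviour is exercised. Summary-level conservative arms enter the
bootstrap through `pseudo_cohort_from_summary`, a deterministic synthetic
reconstruction whose aggregates reproduce the summary.

Cost-effectiveness is strict: NMB > 0, so a replicate exactly on the
threshold ray counts as not cost-effective and the CEAC of a point mass
steps just above its ICER. `wtp_at_probability` interpolates linearly
between grid points and returns an explicit "not reached" (`None`) when
the curve never attains the requested probability. The λ grid defaults
to 0–150,000 in 1,000-€ steps (λ = 0 is allowed; the CEAC value there is
the probability of cost saving).

The source analysis does not state how its replicate cloud was
generated, nor its replicate count; this scheme is the package's own
construction. Its published 50% crossings (€62,000 catheter, €69,000
endoscopic) are therefore qualitative calibration checks only — the
packaged scenarios land in the same order of magnitude (≈ €85,000 and
€74,000 with the linear utility map at 5,000 replicates, seed 0) with
≥ 99% of replicates in the north-east quadrant, but exact agreement or
the catheter-below-endoscopic ordering is not expected and not asserted.

## Problem sizes and determinism

Default runs use the registry-sized cohort (n = 137), 5,000 PSA
replicates, and the packaged arm sizes (17/59/100/255). Calibration and
independence tests use n = 5,000 cohorts with CI-based tolerances;
bootstrap consistency uses 2,000 replicates at a 2-Monte-Carlo-SE
tolerance. Every stochastic component takes an explicit integer seed
(spawned into per-field/per-stage substreams), and identical
seed + configuration reproduces outputs byte-for-byte. Property tests run
derandomized.

## Known limitations

* Single-center tariffs and a middle-income European setting: absolute
  EUR figures do not transport to other systems (the λ = $50,000/$150,000
  bands are exposed only as alternative configuration values, with no
  currency conversion).
* Outcome horizons are mixed by construction (registry mRS at 3 months,
  Kellner at 180 days, MISTIE III at 365 days); the record schema stores
  one `mrs_midterm` and leaves the time point to run metadata.
* The abstract-level ICER figures circulating for this comparison
  (€76,533.13 / €60,703.89) cannot be reconciled with the printed cost
  and QALY operands; the package reproduces the Results-section values
  (€82,335.17 / €75,047.40) and treats those as canonical.
* Passing tests show the pipeline's arithmetic and the synthetic
  calibration are right; they cannot validate the clinical realism of
  the registry, the transferability of the trial arms, or the utility
  mapping, all of which are inputs.
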