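# Methods

This note documents the model implemented in `gcsim`, the conventions
chosen where a state-transition microsimulation leaves genuine design
freedom, what the synthetic-data generator does and does not emulate,
and the package's known limitations.

## Model structure

A discrete-time individual-level state-transition model with 1-month
cycles and a 120-month horizon. Health states: NED (post-prostatectomy,
no evidence of disease), BCR (biochemical recurrence), MET (metastatic
disease), and two absorbing death states (prostate-cancer death from
MET only; other-cause death from any living state). Permitted
transitions: NED → {BCR, MET, death}; BCR → {NED (salvage success),
MET, death}; MET → {death}.

Progression probabilities are monthly and depend on treatment history:
an `untreated` block and a `treated` block, each holding
`bcr_from_ned`, `met_from_ned`, `met_from_bcr`. Receiving adjuvant or
salvage therapy moves a patient permanently onto the treated block;
this single switch *is* the model's treatment effect, applying the same
proportional benefit regardless of the patient's risk level. Death from
prostate cancer is a single monthly probability conditional on MET.
Other-cause death comes from an age-indexed annual life table converted
to monthly probabilities; the simulated patient's age advances monthly
and the lookup changes at integer-age boundaries, clamped to the
table's last row.

### Treatment process

* At entry, an adjuvant decision is drawn from the policy row for the
  arm (usual care, or GC-low/GC-high selected by whether the patient's
  5-year metastasis risk exceeds the 6% threshold — strictly: exactly
  6% is low). Modalities: observation, radiation (RT), hormone therapy
  (HT), or both.
* Patients observed adjuvantly face a salvage decision at their *first*
  BCR, drawn from the salvage policy row. An active salvage course
  allows monthly "redistribution" back to NED with probability
  `salvage_success_monthly`; once the course ends, a patient still in
  BCR stays there (no second salvage).
* Previously treated patients entering BCR or MET start 24 months of
  recurrence hormone therapy; any running course is stopped.
* Complications: while a modality is active, a monthly onset
  probability per treatment type (radiation, hormone); an incurred
  complication lasts the remainder of the treatment course that caused
  it unless the config gives a fixed duration.

### Utilities and outcomes

Cycle utility = health-state utility × active-treatment utility (RT,
HT, or RT+HT) × product of active complication utilities; all utilities
lie in (0, 1]. QALYs accrue as utility/12 per month, undiscounted
(there are no costs in the model, and the horizon is short). LY = months
alive / 12. Reported event outcomes: BCR-free survival at 5/10 years
(alive *and* recurrence-free — standard recurrence-free survival) and
MET-or-death at 5/10 years (death from any cause; a
prostate-cancer-only variant is available).

### Timing conventions (fixed, documented, not half-cycle corrected)

* Utility accrues for the cycle, then the transition at its end takes
  effect: death drawn in cycle k leaves k months of LY, so a constant
  monthly death probability p gives E[months] = (1/p)(1 − (1−p)^120).
* Within a cycle at most one transition fires, drawn in the fixed order
  other-cause death → prostate-cancer death → MET onset → BCR onset →
  salvage redistribution. The ordering bias is O(p²) per month with
  monthly probabilities ≪ 1.
* Treatment and complication clocks tick at cycle end, only if they
  were running at cycle start; a course started by this cycle's
  transition contributes from the next cycle and runs its full length.

### Random numbers and pairing

All uniforms for a cohort run are pre-drawn into per-(patient, month)
channels — one per event type — plus one uniform per treatment
decision. Draws are addressed by counter, never consumed conditionally,
so two arms evaluated on the same draw set share every uniform whose
meaning is arm-independent: identical arms produce identical
trajectories (paired deltas exactly zero), and between-arm comparisons
are variance-reduced common-random-number estimates. Comparisons use a
single bootstrap sample of 10,000 patients drawn with replacement
(sized so the QALY 95% CI half-width stays below 0.1), paired t-tests
for LY/QALY, McNemar's test for binary outcomes (χ² without continuity
correction; exact binomial below 25 discordant pairs), and Wald
binomial intervals — the normal-approximation interval reproduces
published interval widths at this sample size.

Two execution routes share these semantics exactly: a scalar
reference route (`step_cycle` / `simulate_patient`, readable, yields
full trajectories) and a vectorized cohort route (`simulate_cohort`)
used for bootstrap and calibration; a test asserts they are
bit-identical on shared draws.

## Individualization and its calibration error

`R_model`, the population model's 5-year metastasis risk, is estimated
by simulating 200,000 patients under usual care with other-cause death
disabled (so the calibrated quantity is disease-specific, comparable to
a classifier risk score; both choices are configurable). Patient *i* is
individualized by multiplying all six monthly BCR/MET-onset
probabilities by `r_i / R_model`, clipped to [0, 1]; if the two NED-exit
probabilities then exceed 1 jointly they are renormalized so the stay
probability is non-negative (never triggered in the observed risk
range). A hazard-scaling mode (scaling −log(1−p) instead) is available
for sensitivity work.

Proportional scaling of monthly probabilities does **not** reproduce
`r_i` exactly as the realized 5-year incidence: metastasis reached via
the BCR state requires two scaled events, so that pathway scales
roughly quadratically in the ratio. Measured against the shipped
parameter set, realized incidence under-shoots `r_i` below `R_model`
(about −20% relative at r = 0.02) and over-shoots above it (about +21%
at the top of the observed range), with exact agreement at
`r_i = R_model` by construction. The calibration tests assert this
characterized envelope (25–30% relative) rather than exact tracking;
the proportionality assumption itself is the modeling choice being
implemented, and sensitivity analyses probe its parameters.

## Shipped parameters

The package ships a complete, validated fixture configuration
(`src/gcsim/data/default_params.yaml`) with magnitudes plausible for
the post-prostatectomy setting, **not** transcribed from any published
input table:

| parameter | default | rationale |
|---|---|---|
| untreated BCR/MET-from-NED/MET-from-BCR (monthly) | 0.0105 / 0.0012 / 0.0055 | ≈47% untreated 5-y BCR risk; ≈8% model 5-y MET risk |
| treated block | 0.0050 / 0.0007 / 0.0035 | roughly halved hazards under treatment |
| prostate-cancer death from MET | 0.020/mo | multi-year metastatic survival |
| salvage success (redistribution) | 0.12/mo | ≈50–60% success over a salvage course |
| complication onset (RT / HT) | 0.05 / 0.03 per active month | occasional, course-limited toxicity |
| utilities NED/BCR/MET | 0.92 / 0.83 / 0.45 | time-trade-off magnitudes by disease stage |
| treatment utilities RT/HT/RT+HT | 0.90 / 0.85 / 0.78 | multiplicative decrements while on therapy |
| complication utilities RT/HT | 0.85 / 0.88 | |
| durations (months) | RT 2; adjuvant HT 6; salvage HT 6; recurrence HT 24 | recurrence HT fixed at two years |
| risk threshold | 0.06 (strict >) | decision threshold between GC-low/high rows |

Conversions between period probabilities use the constant-hazard
identity m = 1 − (1 − p)^(1/T). The life table is a *synthetic*
stylized Gompertz male table, q(x) = 5.0·10⁻⁵·e^(0.0875x) for ages
40–100, anchored to recent US male all-cause magnitudes; substitute a
national table CSV (`age, annual_qx`) for applied work. The policy
table sends ~45% of usual-care patients to adjuvant therapy, treats
GC-high patients more aggressively (75% adjuvant therapy, 90% salvage)
and GC-low patients more conservatively (15% / 45%), matching the
direction of published physician-recommendation shifts under classifier
results. `generate_param_fixture(seed)` jitters this baseline
(probabilities ×U(0.9, 1.1), utilities ×U(0.97, 1.03)) for
property-style testing across parameter sets.

## Synthetic cohorts

`generate_cohort` draws ages from a normal truncated to 40–90 years
(keeping life-table lookups plausible) and risks from a beta
distribution — support [0, 1], right-skewed, and exactly identified by
the two published constraints (mean, fraction above the 6% threshold)
via root-finding on the shape parameter; an unattainable pair raises an
explicit calibration error. Per-patient 95% CI bounds are placed at a
configurable ±40% relative width (the CI columns are carried through
the schema but do not enter the base analyses).

`reference_cohort` additionally pins the published validation-cohort
margins exactly: the case/control composition (68 cases + 148 controls
so that control weight 5 expands 216 → 808 records), the weighted
high-risk counts (335/808 = 41.46%; 63/139 = 45.32%), the weighted mean
risk (0.076 / 0.071, by an affine rescale of the above-threshold risks
about the threshold), and the risk range (extreme records pinned to
0.0095–0.48 / 0.0097–0.32). These are synthetic stand-ins: they match
the deposited data's published *margins*, not its joint distribution —
in particular any real age–risk correlation, per-patient CI widths,
and within-class risk shape are not reproduced. Tests passing on these
cohorts therefore validate the pipeline's mechanics and calibration
behavior, not conclusions about the original patients.

## Sensitivity analyses

* **One-way (tornado):** each probability/utility parameter varied
  ±10% (clipped to valid ranges), rerun on the base master seed so
  deltas are exact CRN contrasts; output ordered by |ΔQALY|. `R_model`
  is held at its base-case value across scenarios — perturbations
  measure outcome sensitivity at fixed individualization, not model
  recalibration.
* **Probabilistic:** all swept parameters drawn from beta
  distributions, moments matched so the ±10% range is a 95% interval
  (sd = 0.1·m/1.96); infeasible moments raise a named error; inner
  comparisons run at a reduced sample size of 2,000 per draw to keep
  draws × simulations tractable (a scaled-down inner loop, reported
  as such).
* **Aggressiveness:** the guided-care rows' observation share shifted
  by ±20 absolute points, clamped to [0, 1], with remaining mass
  redistributed over treatments preserving their ratios.

## Problem sizes

Defaults chosen for precision at reasonable cost on a single CPU:
calibration 200,000 × 60 cycles; comparisons 10,000 × 120 × 2 arms
(QALY CI half-width ≤ 0.1 by design); one-way sweeps 5,000 per
scenario; PSA 100–200 draws × 2,000. The vectorized route simulates a
10,000-patient paired comparison in under a second; the full
reproduction script runs in roughly half a minute.

## Known limitations

* The classifier is assumed perfectly accurate: the risk score is taken
  as the true 5-year metastasis probability (its published
  discrimination is imperfect), and per-patient risk CIs are unused by
  default.
* Proportional individualization has the characterized nonlinear
  calibration error above; it is the implemented assumption, not a fit.
* Treatment effects are history-switch proportional effects, identical
  across risk levels; no dose, fractionation, or sequencing detail.
* No costs, no discounting, population-average utilities only.
* The shipped parameter set and life table are plausible fixtures;
  quantitative conclusions for a real setting require substituting
  setting-specific inputs.
* Event ordering and accrual conventions are fixed (documented above);
  alternative conventions would shift results by O(monthly p²).
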