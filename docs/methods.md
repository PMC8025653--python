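# Methods

This note documents the models, rules and numerical choices behind the
package, the reasoning for the design decisions that were genuinely
open, and what the synthetic-data generators do and do not emulate.

## Units and data policy

Internal units are hours, ng/ml and mg per kg body weight. AUC values
are converted to µg·hr/ml exactly once, in the report layer. The lower
limit of quantitation (LLOQ) is 2.0 ng/ml by default; measurements below
it are flagged and excluded from every computation — they are never
imputed to 0 or LLOQ/2, and no pre-dose zero record is fabricated, so an
IM profile's AUC starts at the first quantifiable sample (5 min
nominal), slightly undercounting the onset triangle. A value exactly at
the LLOQ is treated as quantifiable (it is by definition quantitated); a
strict-`>` mode exists because the boundary convention cannot be settled
from group-level reports, and the choice is echoed in every run log.

## Non-compartmental analysis

* **Extrema.** Cmax/Tmax and Clast/Tlast are read directly from the
  quantifiable data; a tie in the maximum resolves to the earliest time.
* **Areas.** Per segment [t₁, t₂]: linear trapezoid when C₂ ≥ C₁,
  logarithmic when decreasing:

      AUC  = (C₁ − C₂)/k,                    k = ln(C₁/C₂)/Δt
      AUMC = (t₁C₁ − t₂C₂)/k + (C₁ − C₂)/k²

  A zero concentration inside a decreasing segment falls back to the
  linear rule (the logarithm is undefined). On any strictly decreasing
  segment the log area is bounded above by the linear area (convexity of
  exponential decay); this is enforced as a property test.
* **Terminal slope.** λz is −slope of OLS on (t, ln C) over a contiguous
  terminal window of ≥ 3 points strictly after Tmax. The default
  `best_fit` rule examines all such windows ending at Tlast and keeps
  the highest adjusted R²; differences below 10⁻⁴ count as ties and
  resolve toward the longer window (the convention of standard NCA
  software — a deterministic rule is required for reproducibility). A
  manual time-window override exists. Windows with non-negative slope
  are rejected; if none declines, estimation fails loudly rather than
  returning a half-life.
* **Extrapolation.** AUCinf = AUClast + Clast/λz;
  AUMCinf = AUMClast + Clast·Tlast/λz + Clast/λz². The extrapolated
  fraction (AUCinf − AUClast)/AUCinf is reported per animal.
* **IV-only parameters.** CL = Dose/AUCinf (ml/hr/kg), MRT =
  AUMCinf/AUCinf, Vss = CL·MRT. The AUMC log-segment form above is the
  standard moment formula; Vss = CL·MRT is the conventional definition —
  both are stated here as inferences because group-level reports never
  print AUMC.
* **Bioavailability.** Group-level F uses group-mean AUCs (this is the
  form that the published 92.2% and 107% ratios reproduce exactly);
  per-animal F against the IV group's mean dose-corrected AUC is also
  computed, since the published 81.4% at the double dose differs from
  the rounded-group-mean ratio (81.5%) in the last digit, suggesting
  unrounded or per-animal computation upstream. That one-digit gap is
  irreducible from group means and is documented rather than patched.

## Dose proportionality and comparisons

The power model ln AUCinf = β0 + β1 ln Dose is fitted by weighted least
squares (statsmodels WLS) with per-observation weight 1/Dose, AUC on the
ng·hr/ml scale (the scale on which the published intercept ≈ 7.14 is
meaningful), and 95% confidence limits. Residual diagnostics (mean
residual, Shapiro–Wilk p) are returned. The default fit uses per-animal
AUCs; a group-mean fit on the three published means gives slope 0.7995
(weighted) / 0.8038 (unweighted), consistent with the published
per-animal slope 0.8102 — the published β0/β1/R² themselves are not
reproducible without the unpublished per-animal AUCs. Two-sample
comparisons use Student's t with pooled variance ("Student's"
conventionally implies pooled); a Welch flag is provided.

## Field-trial rules and non-inferiority

Scores are integers 0–3 for depression and respiratory signs;
temperatures are °C within a 35–43 plausibility band.

* enrolment: depression ≥ 2 AND respiratory ≥ 2 AND T > 40.0;
* removal: (depression = 3 OR respiratory = 3) AND T ≥ 40.0 — the
  threshold is inclusive per the operational follow-up rule (an abstract
  summary elsewhere says strictly >; the operational section governs,
  and the threshold is configurable);
* day-10 failure: (depression ≥ 1 AND T > 40.0) OR (respiratory ≥ 1 AND
  T > 40.0) — temperature is conjoined with each sign, resolving an
  ambiguous one-line precedence in a table footnote by the fully
  parenthesized rule text; a febrile day-10 animal with both scores 0 is
  a success under the literal rule;
* dichotomization: score ≤ 1 acceptable; T ≤ 40.0 acceptable.

SRD-confirmed removals stay in every denominator and count as failures
(overall) and not-acceptable (each sign) — the published per-sign
denominators (150/151) confirm they remain in the analysis. Non-SRD
removals are excluded entirely. Sites are pooled.

The two-proportion CI uses the pooled proportion p̄ = (x₁+x₂)/(n₁+n₂)
and the fixed quantile 1.960 (the 3-decimal convention of the trial's
published formula; the difference from Φ⁻¹(0.975) is ~4·10⁻⁵ and far
below reporting precision). Decisions use unrounded values; proportions
round to whole percent and CI limits to 2 decimals only at the report
layer, with half-away-from-zero rounding. A degenerate p̄ ∈ {0, 1}
yields a zero-width CI plus a warning instead of an error.

## Synthetic PK study

**Disposition.** Two-compartment linear kinetics: a one-compartment
model cannot jointly satisfy the target clearance (1.03 L/hr/kg),
steady-state volume (39.2 L/kg) and 76 hr terminal half-life
(0.693·39.2/1.03 ≈ 26 hr), so two compartments are the minimal adequate
structure. Macro parameters (CL, V1, Q, V2) map to micro rates
k10 = CL/V1, k12 = Q/V1, k21 = Q/V2 with eigenvalues α, β from the
standard quadratic. Three constraints (CL, Vss = V1+V2, β) leave one
free choice; V1 = 2.0 L/kg was set so the post-peak decline is fast
enough (α ≈ 0.77/hr) that the observed Tmax stays in the 5–15 min
window under assay-level noise, giving defaults CL = 1.03, V1 = 2.0,
Q = 0.509, V2 = 37.2 (t½β = 76.2 hr). IV bolus profiles are
bi-exponential closed forms; IM adds first-order absorption
(ka = 28/hr, tri-exponential), with coincident rate constants handled
by an infinitesimal perturbation rather than failure.

**Known infidelity.** With CL, Vss and t½ pinned, a two-compartment
model over-predicts the IM peak: simulated Cmax at 6 mg/kg is
~2.4 µg/ml versus the observed ~0.96 µg/ml. Matching the peak as well
would need an additional very fast distribution phase (a third
compartment) or a slower absorption that would violate the observed
Tmax. The generator therefore prioritizes exposure, timing and the
terminal phase; simulated Cmax magnitudes should not be compared to
observed ones.

**Bioavailability.** The apparent IM bioavailable fraction is per-dose
by default — 1.07, 0.922, 0.814 at 3, 6, 12 mg/kg — reproducing the
observed dose-dependent exposure (group-mean AUCinf 3.12/5.37/9.48
µg·hr/ml versus observed 3.15/5.43/9.60) and the ≈ 0.81
dose-proportionality slope. The 3 mg/kg value exceeding 1 is an
apparent, estimation-borne quantity, not a physical fraction. Setting
`f_im_by_dose=None` gives an idealized dose-linear study (flat fraction
0.92), used to verify that the power-model slope returns 1 under true
proportionality.

**Variability.** Between-animal variability is log-normal
(median-preserving) with CV 0.15 on CL, V1, Q, V2 — bracketing the
reported group SD/mean ratios (~12–25%) — and CV 0.25 on ka. Residual
error is multiplicative log-normal with CV 0.05, anchored to the assay
quality-control recovery SD (±5%). Sampling follows the study schedule:
5, 10, 15, 30 min; 1, 2, 3, 6, 10, 24 hr; days 2–10 (19 samples).
Concentrations below the LLOQ keep their value but are flagged. All
draws flow from one seeded generator; identical seeds give byte-identical
tables.

Consequences of this design that the tests rely on: the day-10 samples
sit near the LLOQ, so the extrapolated AUC fraction averages ~5% for the
IV group and ~4–9% across IM groups (observed group-level values:
4.1/7.9/5.5/2.6%); the 3 mg/kg group straddles 10% at the level of
individual animals, exactly as its observed 7.9% mean with ~22% AUC CV
implies the real study's animals did.

## Synthetic field trial

Animals are allocated 1:1 in randomized blocks of two within site
(default six sites, 152 per arm). Each animal has a latent Bernoulli
outcome (default success probabilities 0.967/0.934, the observed
proportions). A latent failure exits early through the removal rule
with probability 0.5 (roughly the observed share of failures that were
removals); non-SRD exits occur with probability 0.013 and leave the
analysis. Emission distributions per latent state (categorical scores,
Gaussian temperature) generate the day-10 record, rejection-sampled so
the day-10 classifier reproduces the latent state exactly — hence the
observed success proportion is exactly binomial around the configured
probability. Enrolment-day records are constrained to the inclusion
rule, exit-day records to the removal rule, and intermediate days are
interpolated severities clipped so that no on-study animal ever meets
the removal rule. Temperatures are generated at 1-decimal resolution so
classification before and after serialization can never disagree.

The trial generator does not model site effects, within-animal score
autocorrelation beyond the linear trend, or any link between simulated
drug exposure and clinical outcome (the two studies are presented and
analyzed separately). Passing tests therefore demonstrate correctness
of scoring, accounting and the interval/decision machinery — not
clinical realism of daily score trajectories.

## Numerical and reporting choices

* Rounding is half-away-from-zero, applied only at the report layer:
  3 significant figures for PK summaries, whole percent and 2-decimal
  CI limits for the trial table.
* Reports are pure functions of (inputs, configuration): no timestamps;
  identical inputs give identical bytes. Run logs echo every threshold
  that affects a decision (LLOQ and its boundary mode, λz windows
  chosen per animal, excluded BLOQ counts, margin, t-test variant).
* CLI exit codes: 0 success, 2 input/validation error, 3 estimation
  error.

## Simulation sizes

Monte-Carlo checks use: 500 replicates for power-model CI coverage
(18 animals each); 10,000 replicates for the non-inferiority operating
characteristics at n = 150/arm; 400 full trial replicates for the
trial-simulator calibration in the acceptance script (1,000 in the test
suite); dense grids of ~10⁴ points for the closed-form NCA checks.

## Known limitations

* Absolute PK parameter values (per-animal AUC, Cmax, T½ distributions)
  are validated against closed forms and the simulator, not against the
  study's raw data, which were never published; the original λz window
  selections are likewise unknown, so published group means are
  approximate context, not bit-targets.
* The power-model R² on simulated data reflects the configured noise,
  not the published 0.8277.
* No sparse-sampling NCA, infusion dosing, multiple-dose accumulation,
  urine data, per-site stratified trial analysis, or bioequivalence-style
  TOST.
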