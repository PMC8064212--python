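# Methods

## The index

The amino-acid composition index (AACI) scores how far a diet's essential
amino-acid *mix* departs from a human requirement pattern (HRAAP). With
reference levels `p_i` and tryptophan as the denominator amino acid,

```
beta_i = p_i / p_trp
q_i    = | (intake_i / intake_trp) / beta_i - 1 |
AACI   = sum_{i=1..11} q_i
```

The eleven scored amino acids are the nine essential ones plus the two
conditionally essential (cysteine, tyrosine); tryptophan is among the eleven
and its own term is identically zero, included in the sum for fidelity to the
printed formula. Properties that follow directly and are asserted by tests:
AACI is zero exactly when the diet is pattern-proportional, invariant to
rescaling all intakes by a common factor (so the intake unit is irrelevant as
long as it is consistent), non-negative, and each component grows
monotonically as one amino acid moves away from its pattern-proportional
point. Both deficiency and excess score positive — the index measures
*imbalance*, not adequacy.

### Reference pattern

The packaged default is the WHO/FAO/UNU 2007 adult requirement pattern in
mg/g protein: Ile 30, Leu 59, Lys 45, Met 16, Cys 6, Phe 25, Tyr 13, Thr 23,
Trp 6, Val 39, His 15. The 2007 report gives the sulphur and aromatic amino
acids partly as class totals (SAA 22, AAA 38); the Met/Cys and Phe/Tyr splits
used here are documented assumptions, and any user pattern in the same
two-column CSV schema can be substituted. Every run records the pattern (and
its file hash) in the provenance manifest, because the index's numeric values
— including tertile cutpoints — depend on it.

### Tertiles

Cutpoints are linear-interpolation sample quantiles at 1/3 and 2/3; intervals
are `(-inf, c1], (c1, c2], (c2, inf)`, so ties at a cutpoint fall low,
matching the conventional `<c1 / c1–c2 / >c2` labelling. Explicit cutpoints
can be supplied to reproduce published boundaries. Fewer than three distinct
values, or quantiles that coincide (up to floating jitter), are refused as a
degenerate exposure.

## FFQ processing and inclusion

Daily intake of nutrient x is `sum_items freq/day * portion_g * per100g[x] / 100`.
Frequencies recorded per week or month are converted with factors 7 and
30.44. Inclusion criteria (age 20–74, energy 500–4500 kcal/day,
diabetes-free baseline, optionally complete serum panel) are applied in that
fixed order, each excluded subject counted once under the first failed
criterion, so exclusion ledgers are deterministic and conserve the input
count.

## Association models

Incident T2DM is ascertained as self-report OR treatment OR fasting glucose
≥ 7.0 mmol/L OR 2-h OGTT glucose ≥ 11.1 mmol/L (thresholds inclusive;
missing components never qualify; a subject with all four missing is
indeterminate). Tertile models are logistic regressions with the lowest
tertile as reference under four nested covariate sets:

* model1: age, sex
* model2: + BMI, education, smoking, drinking, exercise
* model3: + energy, protein, fiber, saturated fat, overall diet quality
* model4: + HOMA-IR, TC, TG, HDL-C, LDL-C

The ladder is configuration, not constants; every report names the
covariates used. Exponentiated coefficients are odds ratios; output labels
them "rr" following the reporting convention for cumulative-incidence cohort
analyses, and the documentation is explicit that they are ORs. The p for
trend refits the model with the ordinal category score (1, 2, 3) as a single
linear term — the dominant convention; per-category medians would be an easy
variant but is not implemented. Missing data are handled by listwise deletion
with logged counts; no imputation. Standardized linear models z-score
exposure and outcome within the analysis sample, making the exposure
coefficient invariant to affine rescaling of either variable. Across the 18
serum amino acids, raw p-values are reported without multiplicity
correction (flagged here deliberately: with 18 outcomes and 3–4 models,
expect ~1 false positive per ladder at the 0.05 level).

## Mediation

The parallel-mediator decomposition uses product-of-coefficients: one
covariate-adjusted linear model per mediator for the a-paths, a single
outcome model containing the exposure and all mediators jointly for the
b-paths and the direct effect, and an outcome model without mediators for
the total effect. Percent mediated is `100 * a_i * b_i / beta_tot`, with the
total the signed sum — inconsistent (suppression) components are reported
negative, and a protective mediator depressed by a harmful exposure
(negative a, negative b) correctly contributes a positive percentage.

For the binary outcome the default is a probit model with coefficients
standardized on the latent-index scale (divide by
`sqrt(var(X beta_hat) + v)`, v = 1 for probit, pi^2/3 for logit), the
convention of SEM software for binary endpoints; a logit link and a linear
(z-scored outcome) link are configuration. With the linear link the
decomposition `beta_tot = direct + sum a_i b_i` is an exact algebraic
identity (asserted to 1e-8); under the latent links it holds approximately
because the reduced and full models have different latent scales.

Model fitting inside this module is self-contained: OLS via normal
equations and Newton-scoring IRLS for logit/probit (tolerance 1e-10 on the
step, max 100 iterations, linear predictor clipped at ±35). This keeps a
bootstrap replicate at a few matrix solves, so percentile intervals
(2.5/97.5, default 1,000 case-resamples, seed-deterministic) are cheap.
Replicates whose resample has no cases (or no non-cases) are dropped and
counted, with a warning above 10%; `n_bootstrap=1` degenerates the CI to the
point estimate. Near-collinear mediators (correlation-matrix condition
number > 1e4) trigger a warning; a total effect below 1e-10 in magnitude
makes percentages undefined (NA with a warning) rather than exploding.

## Synthetic cohorts

The generator produces data with exactly the structure the analysis assumes,
plus known ground truth:

* **Intakes**: `intake_i = protein_g * p_i * exp(eps_i)`,
  `eps_i ~ N(0, deviation_scale^2)` per amino acid. `deviation_scale = 0`
  gives AACI ≡ 0 (tested: downstream association stages then refuse the
  degenerate exposure). The default 0.3 puts the mean AACI near 3.5,
  matching the magnitude of published tertile boundaries (~3.3–3.6).
* **Covariates**: age N(48, 10) truncated to 20–74, energy N(2300, 850)
  truncated to 500–4500 kcal/day, BMI N(25, 3.5), male fraction 0.33 — the
  magnitudes of an urban Chinese adult cohort. Truncation is by rejection
  sampling, so bounds are respected exactly.
* **Serum**: on the standardized scale `z_j = gamma_j z(AACI) + sqrt(1-gamma_j^2) e_j`,
  then mapped to typical μmol/L means/SDs. Default slopes are positive for
  valine, isoleucine, glutamic acid, phenylalanine and negative for glycine
  and histidine — the consistently associated panel — and zero elsewhere.
* **Outcome**: `P(case) = logistic(b0 + theta_d z(AACI) + sum_j theta_j z(serum_j))`
  over the three mediators (valine, glutamic acid, histidine). The direct
  effect is derived from `target_total_percent_mediated` (default 30%, i.e.
  10% per mediator with the default slopes); `b0 = -2.8` yields ~8–9%
  cumulative incidence. The implied latent decomposition (`GroundTruth`) is
  stored with every dataset. Glucose values are drawn from case/non-case
  conditional ranges straddling the 7.0/11.1 mmol/L thresholds, so
  threshold ascertainment reproduces the sampled flags exactly. The default
  effect sizes put the y*-standardized total effect near 0.49 — the scale of
  published standardized totals for this design (~0.27–0.51) — which makes
  the tertile odds ratios steeper than typical published ladders; the
  generator prioritises a well-identified mediation decomposition over
  matching every marginal at once.
* **FFQ**: a 30-item, 13-group synthetic composition table in which each
  item's amino acids follow the reference pattern scaled by protein content
  with per-item lognormal distortion; rice items are strongly lysine- and
  threonine-poor, as cereal proteins are, so raising the rice share raises
  the AACI (tested as a Monte-Carlo sign check).

Randomness: one `SeedSequence` per dataset, spawned into fixed per-stage
child streams (intakes, serum, outcome, covariates, FFQ), so any stage can
be regenerated in isolation and full datasets are bit-reproducible given the
seed.

What the generator does **not** emulate: food-consumption correlation
structure (items are drawn independently given group), measurement error in
the FFQ, confounding between covariates and diet (covariates are independent
of the exposure, so adjusted and crude estimates coincide in expectation),
exposure–mediator interaction, and longitudinal dropout. Passing recovery
tests therefore demonstrates correctness of the estimators under the model's
assumptions, not robustness to their violation in real cohorts.

## Problem sizes in the shipped checks

Recovery and calibration checks use 200 replicates of n = 2,000 with 200
bootstrap resamples (mediation CI coverage), 500 replicates of n = 2,000
(null uniformity of the trend p-value), and single cohorts of n = 20,000
(point recovery of slopes and standardized effects). These sizes put
Monte-Carlo error well inside the asserted tolerances while keeping the full
suite around a minute or two on one CPU.

## Known limitations

* The latent-scale standardization ties percent-mediated estimates to the
  chosen link; logit and probit agree closely (tested within ~5 points) but
  are not identical, and the linear-probability link attenuates mediated
  fractions for rare binary outcomes — it is kept for its exact
  decomposition identity, not for binary-outcome inference.
* Wald intervals and p-values throughout; no exact or profile methods for
  sparse categories (a category with zero cases is reported non-estimable).
* No survival modelling: incidence is treated as cumulative over follow-up,
  matching the design this package mirrors, not time-to-event data.
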