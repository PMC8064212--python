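# aaci

Scoring and cohort analysis for the **dietary amino-acid composition index
(AACI)** — a measure of how closely a diet's essential-amino-acid mix adheres
to the human requirement amino-acid pattern (HRAAP, WHO 2007) — and for the
epidemiological question it was built for: is a poorly balanced amino-acid
mix associated with incident type 2 diabetes, and how much of that
association runs through serum amino acids?

Intended users: nutritional epidemiologists with FFQ-derived intakes (or a
pre-computed amino-acid intake table), a serum amino-acid panel, and
glycaemic outcomes.

## The index and the analysis

With reference levels `p_i` and tryptophan as the denominator,

```
beta_i = p_i / p_trp
q_i    = | (intake_i / intake_trp) / beta_i  -  1 |
AACI   = sum over the 11 scored amino acids of q_i
```

AACI = 0 means the diet is exactly pattern-proportional; both deficiency and
excess of any amino acid relative to the pattern raise it. The index is
invariant to the total amount eaten (only ratios to tryptophan enter), so it
isolates composition from quantity.

On top of the score the package provides the full analysis pipeline:

* **FFQ → intakes**: frequency × portion × per-100 g composition, with
  inclusion filtering (age 20–74, energy 500–4500 kcal/day, diabetes-free
  baseline) and a deterministic exclusion ledger;
* **Tertile association**: logistic models of incident T2DM (ascertained as
  self-report / treatment / fasting glucose ≥ 7.0 / 2-h glucose ≥ 11.1
  mmol/L) across AACI tertiles under four nested covariate models, with a
  p for trend; standardized linear models of AACI against each of 18 serum
  amino acids and HbA1c; serum-amino-acid quartile models; food-group
  correlations;
* **Mediation**: a parallel three-mediator product-of-coefficients
  decomposition (default mediators: serum valine, glutamic acid, histidine)
  with probit/logit latent-scale standardization for the binary outcome,
  per-mediator and total percent mediated, and seed-deterministic percentile
  bootstrap CIs;
* **Synthetic cohorts**: a generator with known ground truth (injected serum
  slopes, direct and mediated effects, target percent mediated) used as the
  test surface for every stage.

## Worked example

```python
import aaci

# a synthetic cohort with known ground truth (30% total mediation injected)
cohort, truth = aaci.simulate_cohort(aaci.SimulationConfig(n_subjects=4000, seed=7))
cohort, cuts = aaci.score_and_cut(cohort, cohort["aaci"])

ladder = aaci.ModelLadder(models={"model1": ["age", "sex"]})
assoc = aaci.fit_tertile_logistic(cohort, ladder)["model1"]
print(assoc.table.round(3).to_string(index=False), f"p_trend {assoc.p_trend:.2e}")

med = aaci.bootstrap_mediation(
    cohort,
    aaci.MediationSpec(outcome_link="probit", n_bootstrap=500, seed=7,
                       covariates=("age", "sex", "bmi")),
)
print(med.summary())
```

prints (tertile cutpoints 2.561 / 3.615 for this draw):

```
category    n  cases    rr  ci_low  ci_high   p
      T1 1334     34 1.000     NaN      NaN NaN
      T2 1333     81 2.475   1.646    3.721 0.0
      T3 1333    263 9.394   6.513   13.550 0.0  p_trend 1.16e-43
Parallel mediation: aaci -> t2dm_incident (probit outcome link, n=4000)
  total effect beta_tot = +0.4647  95% CI (0.4228, 0.5001)
  direct  effect        = +0.3257
  aaci --a=+0.2988--> serum_valine --b=+0.1600--> t2dm_incident: indirect +0.0478 (10.3% of total)
  aaci --a=+0.2801--> serum_glutamic_acid --b=+0.1997--> t2dm_incident: indirect +0.0560 (12.0% of total)
  aaci --a=-0.2882--> serum_histidine --b=-0.1219--> t2dm_incident: indirect +0.0351 (7.6% of total)
  total mediated: 29.9%
```

Reading it: risk rises monotonically across tertiles of the index ("rr" are
odds ratios from the logistic model, labelled per the field's reporting
convention); the standardized total effect of the index on diabetes is
0.46, of which 29.9% is carried by the three serum mediators — valine and
glutamic acid as risk-raising paths, histidine as a protective mediator
depressed by a poor amino-acid mix (negative a-path × negative b-path =
positive mediated share). The generator injected 30%.

A command-line interface wraps the same functions:

```
aaci simulate --n 2000 --seed 1 --out sim/
aaci score --intakes intakes.csv --out scored.csv
aaci mediate --cohort sim/cohort.csv --out mediation.json --link probit
aaci run --config run.yaml
```

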