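# Methods

## The scores

### NRF family

A nutrient-rich foods (NRF) index summarises nutrient density per reference
amount — 100 g of edible portion or 100 kcal of energy. For a profile with
`n` nutrients to encourage and two to limit (written NRFn.2), two subscores
are formed from amounts `a_i` expressed per reference amount:

```
NRn  = Σ_{i ∈ encourage} min(a_i / DV_i, cap) · 100        (cap = 100 %DV)
LIM  = Σ_{j ∈ {sat fat, Na}} (a_j / MRV_j) · 100           (uncapped)
```

and combined by one of three algorithms:

```
sum    NRFn.2 = NRn − LIM
mean   NRFn.2 = NRn/n − LIM/2
ratio  NRFn.2 = NRn/LIM            (undefined at LIM = 0)
```

The built-in nutrient sets are NRF6.2 (protein, fibre, vitamin A, vitamin C,
Ca, Fe), NRF9.2 (adding vitamin E, K, Mg) and NRF11.2 (adding vitamin B12,
Zn); crossing the three sets with the three algorithms and the two reference
amounts yields the 18-variant grid that `variant_grid()` returns.

Design choices the formulas do not fix:

- **%DV cap.** Contributions to NRn are capped at 100 %DV per nutrient
  (configurable via `cap_percent_dv`). The cap prevents a single fortified
  or concentrated nutrient from dominating a food's score; uncapped scoring
  is one flag away for sensitivity analysis.
- **LIM is uncapped** — it is a penalty, and intakes beyond the maximal
  reference value should keep hurting the score.
- **`mean` divides LIM by 2**, the number of limit nutrients used here (not
  the 3 of older profiles that also limited added sugar).
- **`ratio` raises `UndefinedRatioError` at LIM = 0** instead of returning a
  sentinel; silent infinities would corrupt downstream regressions. Callers
  decide whether to drop such foods.
- **Saturated-fat MRV** comes from an acceptable-macronutrient-distribution
  fraction (0.10 of energy) converted with the 9 kcal/g Atwater factor. By
  default the conversion uses a fixed 2000 kcal reference so that food-level
  scores are person-independent; a per-person energy can be supplied.
- **Diet-level scoring** (the default for participants) pools the day's
  nutrients and expresses them per 100 kcal (or 100 g) of the whole diet,
  then applies the formulas once. An energy-weighted mean of per-food scores
  is provided as an alternative mode; the two agree exactly on single-food
  diets and diverge on mixed diets because capping is nonlinear.

### NAR and MAR

Nutrient adequacy of a participant's mean daily intake is summarised over a
fixed ten-nutrient panel (energy, protein, vitamin A, vitamin C, Ca, Fe, P,
thiamin, riboflavin, niacin):

```
NAR_i = min(intake_i / DRI_i, 1)         MAR = 100 · mean_i(NAR_i)
```

MAR is reported on the 0–100 percent scale (a 0–1 toggle exists). Energy is
treated like every other panel nutrient, capped at 1. Truncation makes MAR
insensitive to intakes above the reference — it measures adequacy, not
excess.

## Reference values

Daily values live in `data/chinese_dri_2013.csv` (columns `nutrient_id,
unit, sex, age_min, age_max, value, basis`), never in code. The bundled
table carries adult Chinese dietary reference intakes — RNI where available,
AI otherwise (fibre, vitamin E, K), the sodium maximal reference value
(2000 mg) and the saturated-fat AMDR fraction. Strata are closed age
intervals per sex ("any" matches both); construction rejects overlapping
strata, and lookups outside the declared coverage raise
`MissingReferenceError` naming the nutrient and stratum. Canonical units are
fixed per nutrient (g, mg, µg RAE, µg, kcal) so score denominators can never
mix units.

## Intake aggregation and screening

Recall records (participant, day, food, grams) are joined against the food
composition table (amounts per 100 g); per-day totals are averaged
**unweighted** over the participant's recall days. Energy plausibility uses
the conventional screens — retain 800–4200 kcal/d for men, 500–3500 kcal/d
for women — applied to the mean daily energy; the bounds are configuration,
and the exclusion report lists each removed participant with the violated
bound. The partition is exhaustive and disjoint by construction.

## Anthropometry

BMI classes are contiguous half-open intervals with inclusive lower bounds:
underweight [0, 18.5), normal [18.5, 24), overweight [24, 28), obese
[28, ∞), following the Working Group on Obesity in China. "Overweight" as an
outcome means BMI ≥ 24 including obesity. Central obesity is waist
circumference ≥ 85 cm (men) / ≥ 80 cm (women), or waist-hip ratio ≥ 0.90 /
≥ 0.85; all cut-offs are applied inclusively.

## Validation statistics

- **Index selection.** Each NRF variant's diet-level score is regressed
  against MAR by OLS on identical rows (optionally with covariates: age,
  sex, BMI, smoking, life pressure, grip strength, sedentary time, family
  size), and the variant with the highest adjusted
  R² = 1 − (1 − R²)(n − 1)/(n − p − 1) is selected; ties break by listed
  order. Singular designs raise a collinearity error naming the
  near-duplicate columns.
- **Quartiles.** Cut points are the sample 25th/50th/75th percentiles with
  linear interpolation between closest ranks; a value equal to a cut point
  is assigned downward. Fewer than four distinct values is a degenerate
  distribution, an error. The definition is exposed because odds ratios can
  shift with tie handling.
- **Kruskal–Wallis** uses the tie-corrected H with a chi-square reference on
  k − 1 degrees of freedom (delegated to `scipy.stats.kruskal`); a
  zero-variance input returns H = 0 by convention.
- **Quartile logistic models.** Q2–Q4 indicators with Q1 as reference;
  model 1 is crude, model 2 adds age (continuous), sex and education band
  (3 levels), model 3 adds income band (3), physical-activity band (4) and
  nap frequency (continuous). Categorical covariates are reference-coded
  with the lowest band as reference. OR = exp(β) with Wald 95% CIs,
  exp(β ± 1.96·SE). Perfect separation or non-convergence raises
  `ConvergenceError`; an empty quartile-outcome cell warns and yields a wide
  interval rather than failing.

## The synthetic cohort

The generator produces the inputs the pipeline needs with the statistical
structure the analysis assumes — it targets structure, not culinary realism.

- **Food supply.** `n_foods` foods across ten groups (all groups guaranteed
  present when `n_foods ≥ 10`). A fraction `frac_nutrient_dense` (default
  0.5) are nutrient-dense: energy density lognormal around 80 kcal/100 g and
  encouraged-nutrient densities around 10 %DV per 100 kcal, with low
  saturated fat and sodium per 100 kcal. Energy-dense foods centre on
  330 kcal/100 g and 2.5 %DV per 100 kcal with high limit-nutrient
  densities. Per-food, per-nutrient lognormal noise (σ = 0.9) keeps the
  nutrient sets of the different NRF variants from being collinear across
  diets.
- **Diet selection.** Each participant has a standard-normal latent
  diet-quality trait `z`. Food weights are a softmax of a base popularity,
  `0.9 · z` times the food's density direction, and idiosyncratic
  participant-food noise (σ = 1.0); the idiosyncratic term gives diets the
  multidimensional variation real cohorts have. Each of the two recall days
  samples a subset of foods (availability probability 0.6, at least three
  foods/day) with lognormal gram noise, then rescales grams to hit a per-day
  energy target (sex-specific, truncated inside the plausibility bounds with
  margin; day-to-day coefficient of variation `recall_noise_cv` = 0.25).
- **Planted exclusions.** A fraction `outlier_fraction` (default 0.067) of
  participants get both days' energy targets strictly outside their sex's
  bounds (half high, half low), so the exclusion count is exactly
  recoverable.
- **Overweight outcome.** P(overweight) = expit(α + β·z). β is root-found
  (Brent) so that the expected Q4-vs-Q1 odds ratio across quartiles of the
  *realised* NRF9.2 sum/100 kcal score equals `latent_effect_or` (default
  0.61), with α nested-solved to hold prevalence at 0.42. Calibrating
  against realised score quartiles rather than `z` itself absorbs the
  attenuation that recall noise and idiosyncratic preferences would
  otherwise introduce. BMI, and then weight/height/waist/hip, are drawn
  consistent with the flag, so central-obesity outcomes share the same
  adiposity pathway (the generator does not model independent fat
  distribution).
- **MAR link.** `generate_mar_link` makes the computed MAR follow
  `intercept + slope · standardised(driver) + N(0, mar_noise_sd)` (defaults
  72, 8, 5 on the percent scale), truncated to what the untouched panel
  nutrients allow. Only phosphorus, thiamin, riboflavin and niacin — panel
  nutrients outside every NRF variant — are rescaled, by a per-participant
  factor found with vectorised bisection on the piecewise-linear capped sum.
  Scaling any shared nutrient would feed back into the scores being
  validated and make the selection experiment circular; the driver can be
  the latent trait or any realised score.

All randomness flows from a single seed through named `SeedSequence`
substreams (foods, latent, prefs, grams, outcome, anthro, covariates, mar),
so outputs are byte-identical across runs and platforms and single stages
can be regenerated stably.

### What passing tests do and do not show

Recovery tests show the pipeline is consistent: planted odds ratios are
covered by their confidence intervals at nominal rates, the generating index
variant wins the adjusted-R² comparison, planted exclusions are recovered
exactly, and null effects stay null. They do not show that real recall data
satisfy the generator's assumptions — no correlated measurement error,
no under-reporting by adiposity, one-dimensional adiposity, independent
covariates — so field use still needs substantive validation.

## Problem sizes and numerics

Monte-Carlo checks use 100 replicates at n = 1000 (null calibration), 100 at
n = 2000 (odds-ratio recovery), 50 at the default n = 656 (index-selection
recovery) and 1000 simulations for the Kruskal–Wallis type-I rate; the whole
suite runs in about a minute on one CPU. Root-finding uses Brent's method on
[−12, 12] (logistic slope) and bisection with 80 iterations on log-scale
[−30, 30] (MAR link). Degenerate inputs fail loudly: zero-energy foods or
diets, non-positive reference values, constant score vectors, single-group
rank tests and separated logistic fits all raise typed errors rather than
propagating NaNs.

## Known limitations

- Usual-intake deattenuation across recall days is out of scope; two-day
  means are taken as-is.
- The saturated-fat MRV uses the fixed 2000 kcal reference for diet-level
  LIM as well; a per-person-energy mode would change LIM by the ratio of
  energies.
- The generator's central-obesity outcomes are driven by the same latent
  pathway as BMI, so it cannot emulate cohorts where diet quality relates to
  BMI but not to fat distribution.
- Bands and prevalences of the simulated covariates are plausible but not
  estimated from any survey.
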