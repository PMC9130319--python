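# Methods

## The model

The analysis targets the joint association of a polygenic risk score (PRS)
and smoking with disease incidence in a prospective cohort. For
participant *i* with covariate vector `x_i`, the hazard is assumed
proportional,

    h_i(t) = h0(t) · exp(x_i' β),

and β is estimated by maximising the Cox partial likelihood. The PRS is
the additive score `S_i = Σ_j w_j g_ij` over a panel of independent common
variants (dosage `g_ij` of the effect allele, external per-allele log
effect `w_j`), z-standardised over the analysis cohort (sample SD, n−1)
and categorised by empirical quintiles: lowest = low, 2–4 = intermediate,
highest = high genetic risk. Smoking enters either as status
(never/former/current) or as lifetime pack-year categories
(0 / 0.1–19.9 / 20–39.9 / ≥40, edges left-closed at 20 and 40).

### Cox fitter

`fit_cox` maximises the Efron (default) or Breslow partial likelihood by
Newton–Raphson with step-halving. Risk-set sums S0, S1, S2 are accumulated
over unique event times in decreasing order; the Efron correction
subtracts `l/d` fractions of the tied-set sums for a group of `d` tied
events. Convergence requires a relative log-likelihood change below 1e-9
or a gradient max-norm below 1e-6 within 50 iterations; the covariance is
the inverse observed information at the optimum. Collinear designs raise
an error naming the aliased column; apparently monotone likelihoods
(|β| > 15, as under complete separation) are flagged as divergent, never
silent. An optional `strata` column fits stratum-specific baselines by
summing per-stratum likelihood contributions.

The score (Rao) test at β = 0 is exposed; on two-group data without tied
event times it equals the log-rank chi-square, which the tests verify to
1e-8.

### Secondary statistics

* **Trend test** — the ordered category is refit as a single continuous
  covariate scored 0, 1, 2, …; its Wald p is "P for trend".
* **Interaction test** — likelihood-ratio comparison of the adjusted model
  with and without all products of the two terms' design columns
  (default construction: continuous z-PRS × category dummies; a
  categorical×categorical variant follows by listing both terms as
  categorical). The LRT was preferred over the Wald test for stability
  with sparse cells.
* **Proportional hazards** — Grambsch–Therneau score test on scaled
  Schoenfeld residuals against a time transform (default: one minus the
  pooled Kaplan–Meier survival), using the average risk-set covariance
  I(β̂)/d; per-term and global chi-squares. Residual risk-set means use
  Breslow-style averaging at ties. The construction reproduces
  `survival::cox.zph` (R) to three significant figures on shared data.
* **Restricted cubic splines** — truncated-power basis constrained to
  linearity beyond the boundary knots, normalised by the squared knot
  span; knots at Harrell's conventional quantiles (4 knots:
  5/35/65/95th percentiles). Four knots are the default; the count was a
  free choice and 3–5 are supported.
* **Discrimination** — ROC AUC by the Mann–Whitney U statistic with ties
  counted one half, computed in-sample on end-of-follow-up case status
  against a model's linear predictor (no cross-validation; an optimistic
  estimate, stated as such). Harrell's censoring-aware concordance is
  provided as a labelled alternative.
* **Post-hoc power** — Schoenfeld's approximation
  `Φ(|log HR|·√(d·p·(1−p)) − z_{1−α/2})` for d events and exposed
  fraction p, validated against log-rank simulation within 3 percentage
  points.

### Attributable fractions

Two classical estimators are implemented and always labelled, because they
answer the elimination counterfactual from different inputs: Miettinen's
case-load form (exposure distribution among cases + possibly adjusted
hazard ratios; the default for cohort-internal estimates) and Levin's
multi-category prevalence form (population distribution + hazard ratios;
required for external standardisation to survey prevalences). The
generalized impact fraction handles arbitrary counterfactual shifts and
reduces exactly to the Levin form when the counterfactual moves all mass
to the reference level — an identity the tests assert exactly.

Published inputs give fixed reference values the suite pins down: the
case-load form on the printed case counts (254/718/715) with hazard
ratios (1, 5.33, 14.54) evaluates to 0.740, the Levin form on the printed
cohort counts to 0.712, and the quit-scenario impact fraction (current →
former) to 0.261. These are direct-formula evaluations; the corresponding
published covariate-adjusted estimate (76.4%) used an unstated adjusted
estimator that the two implemented forms bracket but are not claimed to
reproduce.

Confidence intervals come from a parametric bootstrap: log hazard ratios
drawn from N(β̂, Cov̂), exposure proportions from a Dirichlet at the
observed counts, percentile interval over (default) 1000 replicates,
deterministic given the seed. No analytic variance is attempted because
the estimators mix regression and multinomial uncertainty.

## The synthetic cohort generator

The generator emulates the statistical structure of a large European
biobank lung-cancer analysis, and its defaults are the study conditions
used throughout the tests:

| quantity | default | basis |
|---|---|---|
| smoking mix (never/former/current) | 221073/90727/33994 of 345,794 (63.9/26.2/9.8%) | published baseline table |
| pack-years (ever-smokers) | log-normal, meanlog 2.97, sdlog 0.70 | fits the published light/intermediate/heavy split (≈18.5/11.8/5.5% of the cohort) |
| true hazard ratios | 1.16 per SD of PRS; 5.33 former; 14.54 current; 1.08/yr age; 1.28 male | published adjusted estimates |
| baseline hazard λ₀ | 1.6e-4 /person-year (2e-4 in covariate-free recovery studies) | yields ≈0.5% events over follow-up |
| censoring | administrative horizon U(5.9, 8.5) years + exponential dropout 0.001/yr | median observed follow-up ≈7.2 years (IQR ≈6.5–7.8) |
| variant panel | 33 synthetic independent loci, HWE genotypes | emulates the published 33-SNP panel, whose supplementary table is not redistributable |

Event times are exact inverse-transform draws from the exponential
proportional-hazards model, so closed-form oracles exist: with event rate
λ, dropout μ and horizon C ~ U(a, b),
`P(event) = λ/(λ+μ) · (1 − E[e^{−(λ+μ)C}])`. The generator embeds the
config actually used, making parameter-recovery studies self-describing.

What the generator deliberately does **not** emulate: linkage
disequilibrium between loci (the panel-selection rule assumes independent
variants, so LD labels are an input, not simulated); competing mortality;
registry coding; relatedness between participants (the corresponding
exclusion operates on a supplied flag); confounding between smoking and
covariates (independent draws by default; couplings are configurable,
including a per-variant genotype→smoking-propensity shift emulating loci
associated with both disease and smoking behaviour). Passing tests
therefore demonstrate statistical correctness of the machinery under the
assumed model, not robustness to the messiness of real registry data.

Because the default truth drives the hazard through smoking *status*, the
pack-year categories inherit only the status contrast and show no
dose-response gradient; analyses that need the published pack-year
gradient (1, 3.04, 8.61, 17.80) set those categories as the generative
truth instead, as the acceptance script does for its pack-year axis.

## Calibration studies (sizes and design)

All replication studies run on one desk CPU:

* **Parameter recovery** — 200 cohorts of n = 20,000 at λ₀ = 2e-4 with
  truth (1.16, 5.33, 14.54) and no covariate effects (≈100 events each);
  95% Wald intervals must cover each truth in 95% ± 4% of replicates.
* **Interaction null calibration** — 500 cohorts of n = 5,000 at
  λ₀ = 2e-3 (≈250 events each, enough for the χ² reference to hold) with
  real main effects and no generative product term; LRT p-values must
  pass a Kolmogorov–Smirnov uniformity test at α = 0.001.
* **Bootstrap coverage** — 200 cohorts of n = 20,000 at λ₀ = 2e-4; the
  bootstrap 95% interval for the Levin PAF must cover the closed-form
  generative attributable fraction in 95% ± 4% of replicates. At these
  event rates the rate-based estimand and the event-probability truth
  differ by ≈0.001, negligible against interval width.
* **Acceptance run** — one cohort at the emulated study scale
  (n = 345,794, ≈1700 events), full battery, plus a second cohort with
  pack-year truth for the dose-response axis.

## Numerical and design choices

* Sample (n−1) SD for z-scoring; quintile ties broken by stable rank
  order on (value, position) so group sizes never deviate from n/5 by
  more than one.
* Missing genotypes imputed as 2·eaf (the HWE mean) by default;
  palindromic A/T–C/G variants excluded by default since strand is
  unresolvable without metadata; both behaviours are flags.
* Efron ties by default, Breslow for cross-checks.
* Exclusion filters apply in a fixed documented order (missing
  covariates → prior-cancer flag → relatedness flag → early events →
  never-smoker/pack-year mismatch) so audit counts are reproducible.
* Joint genetic×smoking analyses code a single 9- or 12-level categorical
  with the low-genetic/never (or no-pack-years) cell as reference, per
  the reference-cell phrasing of the emulated analysis.
* Time-on-study is the only timescale; age-as-timescale (delayed entry)
  is not implemented. Frailty models for relatedness and Fine–Gray
  competing-risk models are out of scope.
* Reports are written with shortest-round-trip float formatting, making
  repeated runs byte-identical and file round-trips exact.

## Known limitations

* The packaged variant panel and external (survey-like) smoking
  distributions are synthetic placeholders; results produced with them
  characterise the machinery, not any real population.
* The AUC is in-sample; with ~30 scored variants the optimism is small
  but nonzero.
* The case-load PAF inherits whatever confounding control the supplied
  hazard ratios carry; the Levin form with adjusted hazard ratios is a
  common but inexact hybrid, which is one reason both are always
  reported.
* Wald intervals underlying recovery studies are asymptotic; with very
  few events per cell (deep stratifications of small cohorts) fits are
  flagged as divergent rather than reported.
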