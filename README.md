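# prscox

Polygenic risk scoring and Cox-based cohort analysis of gene-by-smoking
effects on cancer incidence, with attributable-fraction estimation and a
matched synthetic-cohort simulator.

## What this is for

Prospective biobank studies routinely ask how a polygenic risk score (PRS)
and a dominant environmental exposure — here, smoking — jointly shape the
incidence of a disease such as lung cancer. `prscox` packages that entire
analysis as tested, reusable components:

* **PRS construction** — select one independent common variant per locus
  (largest development-cohort *n*, then smallest *p*), harmonise genotype
  files (VCF or PLINK-RAW) to effect alleles with strand-flip and
  palindromic-SNP handling, score additively
  `S_i = Σ_j w_j g_ij`, z-standardise, and cut into quintile-based
  low / intermediate / high genetic-risk categories.
* **Survival modelling** — a Newton–Raphson Cox partial-likelihood fitter
  with Efron (default) and Breslow tie handling, Wald hazard ratios,
  ordinal trend tests, likelihood-ratio gene–environment interaction
  tests, Grambsch–Therneau Schoenfeld-residual proportional-hazards
  diagnostics, restricted cubic splines, Kaplan–Meier cumulative
  incidence, ROC AUC, incidence rates per 1000 person-years, and a
  Schoenfeld-approximation post-hoc power calculator.
* **Attributable fractions** — Miettinen's case-load form
  `PAF = Σ_k p_ck (HR_k − 1)/HR_k`, Levin's prevalence form
  `PAF = (Σ_k p_k HR_k − 1)/(Σ_k p_k HR_k)` (supporting external
  standardisation to survey smoking prevalences), the generalized impact
  fraction for arbitrary counterfactual exposure shifts, genetic-risk-
  stratified PAFs, and parametric-bootstrap confidence intervals.
* **A synthetic-cohort generator** — Hardy–Weinberg genotypes at
  independent loci, a configurable never/former/current smoking mix with
  log-normal pack-years, covariates, and exponential proportional-hazards
  event times `T_i = −log U_i / (λ₀ e^{η_i})` with administrative plus
  dropout censoring, so every downstream stage is testable, with known
  truth, without restricted data.
* **A pipeline and CLI** — exclusion filters with an audit log, the full
  model battery (marginal, joint 3×3 / 3×4 categories, stratified),
  deterministic TSV/JSON reports, and `prscox simulate/score/fit/paf/
  report/all` subcommands.

## Worked example

```python
import prscox as px
from prscox.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    simulation=px.SimulationConfig(n_participants=50_000, seed=1),
    seed=1, n_boot=500,
)
bundle = run_pipeline(cfg)
```

With the default generator (63.9/26.2/9.8% never/former/current smokers,
true hazard ratios 1.16 per SD of PRS, 5.33 former, 14.54 current, ~0.5%
events over a ~7.2-year median follow-up) this prints, via the report
tables:

```
n analysed 49910 events 247
HR per SD PRS: 1.32 (1.16-1.49)
HR former: 5.34 (3.80-7.50)
HR current: 13.35 (9.45-18.86)
interaction p (PRS x status): 0.404
case-load PAF: 69.4% (63.4-74.6)
quit-scenario GIF: 23.1% (15.5-30.3)
AUC combined: 0.821
```

Read: each standard deviation of polygenic risk multiplies the lung-cancer
hazard by ~1.3 here (the generative value 1.16 sits inside the interval;
at this cohort size a single draw is still noisy), current smoking
multiplies it by ~13, there is no evidence of PRS-by-smoking interaction
(none was generated), about 69% of the simulated cases are attributable to
smoking, and a scenario in which all current smokers quit (becoming former
smokers) would have averted ~23% of cases.

The same battery runs from files instead of a simulation:

```bash
prscox simulate --n 20000 --seed 7 --outdir run/
prscox score --weights run/weights.tsv --genotypes run/genotypes.vcf --out run/scores.tsv
prscox paf --phenotypes run/phenotypes.csv --out run/paf.json
prscox report --outdir run/report --n 20000 --seed 7
```

## Layout

```
src/prscox/
  prs.py        variant selection, harmonisation, scoring, categorisation
  synthetic.py  cohort generator and closed-form event-probability oracle
  survival.py   Cox fitter and all survival statistics
  paf.py        attributable and impact fractions with bootstrap CIs
  pipeline.py   exclusions, model battery, report bundle
  io.py         weight-table / VCF / PLINK-RAW / phenotype / exposure I/O
  cli.py        click command-line interface
docs/methods.md model, assumptions, calibration studies, limitations
```

The packaged 33-variant weight table and the external smoking
distributions are synthetic emulations (documented as such); no restricted
data are included or required.
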