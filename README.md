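# qofsmoke

Estimate smoking prevalence in general-practice populations from published
QOF (Quality and Outcomes Framework) pay-for-performance indicator data,
aggregate practice estimates to local-authority districts, quantify
agreement with survey-based area estimates, and assess the contribution of
the prevalence estimate to negative binomial models of premature CHD
mortality. A synthetic-data module generates QOF-like registries with
known ground truth so every stage is testable offline, including
missing-data bias and parameter-recovery studies.

The core manipulation: the denominator of the cessation-offer indicator
counts recorded current smokers, the denominator of the status-recording
indicator approximates the eligible 15+ population, so their ratio
estimates practice smoking prevalence (e.g. 1129/3721 = 30.3%).

## Modules

| Module | Role |
| --- | --- |
| `qofsmoke.qof_io` | Read/validate/filter long-format indicator extracts, postcode lookups, survey tables; indicator-code history per year |
| `qofsmoke.estimators` | Practice-level prevalence, underlying achievement, chronic-condition share; list-based fallback variant |
| `qofsmoke.aggregation` | Postcode-based district assignment; pooled-count (default) and mean-of-prevalence aggregation |
| `qofsmoke.agreement_stats` | Pearson r, Lin's concordance coefficient, Bland-Altman limits of agreement, chronic-to-general calibration regression with outlier pruning, year-pair concordance |
| `qofsmoke.mortality_model` | NB2 negative binomial regression (IRRs, Wald 95% CIs), with/without-covariate comparison and LR test |
| `qofsmoke.synthetic_data` | Deterministic registry/survey/mortality/multiyear generators with ground truth |
| `qofsmoke.pipeline` | File-based orchestration of simulate → estimate → aggregate → agree → model with a JSON report |
| `qofsmoke.datasets` | Shipped reference tables: five-practice worked example and the 16-district reference |

## Command line

```bash
# synthetic scenario with known truth
qofsmoke simulate --seed 1 --n-practices 215 --n-districts 16 --outdir sim/

# practice-level estimates from a long-format extract
qofsmoke estimate --input sim/registry.csv --out estimates.csv

# district aggregation (pooled counts by default)
qofsmoke aggregate --input sim/registry.csv --lookup sim/lookup.csv --out districts.csv

# agreement statistics for a paired table (id, first, second)
qofsmoke agree --pairs pairs.csv --out agree --plot

# negative binomial IRR table, with/without an added covariate
qofsmoke model --data sim/covariates.csv --covariates deprivation \
    --add smoking_pp --offset log-exposure --out irr.csv

# the full pipeline, reproducible under a seed
qofsmoke run --seed 1 --outdir run/
```

`qofsmoke run` writes per-stage CSVs and a deterministic `report.json`
(estimate distribution summary, district table, agreement summaries,
calibration fit, IRR comparison, and a log of skipped stages).

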