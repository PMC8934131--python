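# sbmodel

A proportional multi-state life table model of the health and economic
impact of reducing population sitting time. The pipeline translates
categorical sitting-time exposure (low `< 4 h/day`, moderate `4–8 h`, high
`> 8 h`) into disease-incidence changes via potential impact fractions
(PIFs), propagates them through a four-state illness–death engine for five
chronic diseases (type 2 diabetes, stroke, breast, colorectal and
endometrial cancer), and reports HALYs gained, deaths averted, incident
cases prevented and healthcare cost offsets — deterministically or with
second-order Monte-Carlo uncertainty (95% percentile intervals).

## Layout

| module | role |
| --- | --- |
| `sbmodel.exposure` | exposure table (proportions + category means per sex × age band), prevalence shifts, within-category sitting reductions |
| `sbmodel.evidence` | REML random-effects meta-analysis of study RRs, I², RR sampling distributions, pooled RR table |
| `sbmodel.pif` | categorical PIF, relative-risk shift along a piecewise log-linear dose–response, PIF Monte Carlo |
| `sbmodel.disease_model` | four-state illness–death consistency engine (exact matrix exponential per one-year interval) |
| `sbmodel.lifetable` | proportional multi-state life table: cohort survivorship, HALY/death/case/cost outputs |
| `sbmodel.scenarios` | four built-in scenarios, coverage mixtures, bisection threshold analysis |
| `sbmodel.uncertainty` | draw-indexed, reproducible Monte-Carlo layer |
| `sbmodel.synthetic_data` | internally consistent synthetic input bundles (population, epi, costs, study effects) |
| `sbmodel.cli` | `sbmodel` command-line interface |

Packaged fixtures `sbmodel/data/table2_exposure.csv` (survey sitting-time
exposure) and `table3_rr.csv` (pooled relative risks) are the only real
data; everything else is generated synthetically because the original
sources are not redistributable.

## CLI

```sh
sbmodel synth --seed 1 --out bundle/                 # synthetic CSV bundle
sbmodel simulate --bundle bundle/ --scenario 1 --out results/
sbmodel simulate --bundle bundle/ --scenario 4 --draws 2000 --seed 7 --out results_mc/
sbmodel pif --bundle bundle/ --scenario 2 --out pifs.csv
sbmodel meta --studies bundle/study_effects.csv --out pooled.csv
sbmodel threshold --bundle bundle/ --target-halys 500 --out threshold.json
```

Built-in scenarios: 1 — everyone moves to the low category; 2 — 30% of the
high group moves to moderate; 3 — 30% of the moderate group moves to low;
4 — a 36.3 min/day sitting reduction in the moderate and high groups
(relative-risk shift). `--coverage` scales the affected fraction of the
target population; `--horizon`/`--discount` control accrual. Every run
writes a manifest (seed, parameters, input hashes) for reproducibility.
Exit codes: 0 success, 2 validation error, 3 numerical failure.

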