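# ncdproj

Comparative-risk scenario analysis for premature mortality from
non-communicable diseases (NCDs). The package computes the unconditional
probability of dying between exact ages 30 and 70 (40q30) from registry-style
death counts, projects mortality and six risk-factor exposures to a horizon
year, converts counterfactual exposure scenarios into avoidable deaths via
population attributable / potential impact fractions, flags SDG 3.4
achievement (one-third reduction in 40q30) by sex and sub-national unit, and
quantifies the life-expectancy impact of eliminating causes of death with
cause-deleted life tables.

Because the motivating data sources (a national death registry and stepwise
risk-factor surveys) are not public, a first-class synthetic-data module
generates calibrated, seeded stand-ins with known ground truth, so every
downstream stage is testable by parameter recovery.

## Modules

| module | contents |
| --- | --- |
| `ncdproj.synthetic` | registry / survey / relative-risk / covariate generators with ground truth |
| `ncdproj.upod` | age-specific rates, 5q from 5m conversion, 40q30, bootstrap uncertainty |
| `ncdproj.projection` | Bayesian model averaging (exact enumeration and MC3), spatiotemporal interpolation of sparse survey rounds, GP smoothing, spline covariate extrapolation, log-linear mortality projection with province shrinkage |
| `ncdproj.riskpaf` | Levin and continuous-distribution PAF/PIF, multiplicative joint fractions, TMREL definitions |
| `ncdproj.scenarios` | WHO-target / TMREL / baseline counterfactuals, avoidable deaths, adjusted 40q30, SDG 3.4 flags |
| `ncdproj.lifetable` | abridged life tables, temporary life expectancy 30-70, cause deletion |
| `ncdproj.io`, `ncdproj.pipeline`, `ncdproj.cli` | CSV dialects, validation, end-to-end orchestration, CLI |

## CLI

```sh
ncdproj simulate --out data/ --seed 1            # synthetic input bundle
ncdproj upod --deaths data/registry.csv --out upod.csv --draws 500
ncdproj project --deaths data/registry.csv --exposures data/exposures.csv \
    --horizon 2030 --out proj/
ncdproj scenario --preset who2015 --exposures proj/exposures_projected.csv \
    --deaths horizon_deaths.csv --rr data/rr.csv --out results/
ncdproj lifetable --rates rates.csv --out lt.csv
ncdproj run --out run1/ --scenario who2015 --seed 1 --provinces 31
```

`run` executes the whole workflow (simulate, project, scenario, report) and
writes deterministic CSVs plus `metadata.json` recording the seed and a
config hash; a rerun with the same configuration is byte-identical.

Scenario presets: `who2010`, `who2015` (the six global monitoring-framework
risk targets against the 2010/2015 baseline), `tmrel` (all risks at their
theoretical-minimum exposure), `baseline` (null scenario).

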