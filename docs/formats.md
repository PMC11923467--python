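# File formats

## Trial records (CSV)

UTF-8, comma-separated, one header row naming every schema variable. Rows
may appear in any order; datasets are sorted by the recruitment index on
read. Values:

| kind        | representation                                  |
|-------------|-------------------------------------------------|
| continuous  | decimal number (full precision on write)         |
| event-time  | non-negative decimal number                      |
| binary      | one of the two declared level strings            |
| categorical | one of the declared level strings                |
| recruitment-index | unique integer, defines accrual order      |

Missing/empty values are rejected.

## Schema descriptor (YAML)

```yaml
variables:
  - {name: order, kind: continuous, role: recruitment-index}
  - {name: site,  kind: categorical, role: stratum, levels: [A, B]}
  - {name: arm,   kind: binary, role: treatment, levels: [control, treated]}
  - {name: age,   kind: continuous, role: covariate}
  - {name: event, kind: binary, role: event-indicator, levels: ["0", "1"]}
  - {name: time,  kind: event-time, role: outcome, event_indicator: event}
```

Rules: exactly one `recruitment-index`; at most one `treatment` (binary;
second level = treated arm); strata must be discrete; every `event-time`
names its paired binary `event-indicator`.

## Analysis spec (YAML)

```yaml
family: cox            # mean-difference | adjusted-linear | logistic |
                       # binary-robust | cox | survival-prob-difference |
                       # descriptive-mean
outcome: time
covariates: [age]      # optional
horizon: 5.0           # survival-prob-difference only
alpha: 0.05
```

## Simulation config (YAML)

Fields of `SimulationConfig` verbatim; see `trialrescue.simulate`. Example:

```yaml
n: 200
beta: 0.5
p_treat: 0.5
outcome_family: gaussian   # gaussian | bernoulli-logit | exponential-ph
sd: 1.0
delta: 0.0
seed: 3
strata:
  - {name: site, levels: [A, B], probs: [0.6, 0.4]}
covariates:
  - {name: age, kind: continuous, params: [60, 8], coefficient: 0.01}
```

## Sweep report

`sweep.csv`: one row per (generator, r) plus `full` and `reduced` baseline
rows — estimate, SE, CI, the four replicability metrics, mean Hellinger
fidelity, and a status/reason pair for failure rows. `manifest.json` echoes
the configuration and lists failures.
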