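# oaphen

Validation pipeline for knee-osteoarthritis case-identification algorithms in
longitudinal coded primary-care records.

The package implements the full validation workflow around a published study
design: eligibility and exclusion filtering of coded records, eight temporal
code-count algorithms (plus imaging-restricted variants), rule-based
gold-standard adjudication from imaging-report findings and questionnaire
pain data, and PPV/sensitivity estimation with 95% Wald confidence intervals.
Because the original data cannot be shared, a synthetic-data module provides
both a stochastic cohort generator matching the published sample
characteristics and deterministic fixtures that reproduce every published
validation-table row and the published exclusion attrition exactly.

## Layout

| module | role |
| --- | --- |
| `oaphen.model` | domain types (patients, coded events, imaging reports, questionnaires, code sets) |
| `oaphen.io` | CSV readers/writers and YAML code-set configuration |
| `oaphen.rules` | eligibility, exclusions, index dates, and the temporal rule engine |
| `oaphen.gold` | gold-standard adjudication from imaging findings + pain answers |
| `oaphen.stats` | 2x2 contingency, PPV, sensitivity, Wald CIs, cohort summary |
| `oaphen.synth` | synthetic cohort generator and deterministic row/exclusion fixtures |
| `oaphen.pipeline` / `oaphen.cli` | end-to-end orchestration and the `oaphen` CLI |

Default code sets (`src/oaphen/data/codesets.yaml`, the documented knee-pain
Read codes plus clearly marked placeholder lists) and algorithm definitions
(`src/oaphen/data/algorithms.yaml`) ship with the package and can be
overridden per run.

## CLI

```sh
# synthetic cohort (four CSV tables) from default or custom parameters
oaphen generate --n 500 --seed 7 --out cohort/

# deterministic reproduction fixtures
oaphen fixtures --table exclusion --out fixtures/exclusion
oaphen fixtures --table 2 --out fixtures/table2

# stage by stage
oaphen classify --cohort cohort/ --out decisions.csv
oaphen adjudicate --cohort cohort/ --out gold_standard.csv
oaphen validate --decisions decisions.csv --gold gold_standard.csv --out validation.csv
oaphen report --validation validation.csv

# everything at once from a YAML config (generator or cohort_dir source)
oaphen run --config run.yaml

# recompute every published table cell from the shipped fixtures;
# exits non-zero on any mismatch
oaphen reproduce-paper
```

A `run.yaml` looks like:

```yaml
out_dir: out/
generator: {n_patients: 500, seed: 7}
# or instead of generator:
# cohort_dir: cohort/
codesets: null      # optional override paths
algorithms: null
```

## Notes

* Dates are ISO calendar dates; all temporal arithmetic is in whole days
  (6 months = 183 days, 12 months = 365, 2 years = 730; configurable).
* "One code" algorithms mean *exactly* one code of that category in the whole
  record; two-code rules require a separation of at least 7 days.
* Rounding is half-away-from-zero to one decimal, matching the published
  tables; undefined estimates (empty denominators) are reported as missing.
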