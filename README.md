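# udsamp

Simulation and statistical analysis of uncertainty-driven sampling
experiments: participants learn novel object labels, judge which labels
they know, choose a limited number of objects to hear again, and are then
tested (with binary confidence ratings). The package provides

- **`udsamp.simulate`** — a generative simulator of the full experiment
  (logit-normal latent knowledge, judgement with configurable
  overconfidence, Plackett–Luce weighted sampling without replacement,
  test accuracy with a sampling boost, confidence, and familiar/unfamiliar
  control judgements), deterministic per participant given a master seed;
- **`udsamp.glmm`** — logistic mixed models with crossed random effects
  (random intercepts and slopes) fitted by Laplace-approximate maximum
  likelihood, with Wald tests and likelihood-ratio tests;
- **`udsamp.beta`** — beta regression (logit link) for proportions;
- **`udsamp.bootstrap`** — parametric bootstrap percentile intervals for
  estimates and fitted values;
- **`udsamp.analyses`** — the analysis stages: control-trial exclusion
  scoring, the two-column (sampled, not-sampled) response matrix, overall
  accuracy vs the 1/6 chance level, confidence–accuracy, preferential
  sampling with a within-participant permutation test, the
  chance-corrected sampling score with beta regression, two
  sampling-proportion accuracy models, and the sampling × judgement
  interaction model;
- **`udsamp.pipeline` / `udsamp.cli`** — an end-to-end runner producing
  per-group report CSVs and a combined summary.

## CLI

```sh
# simulate data with built-in group presets
udsamp simulate --preset adult --preset 5yo --n-per-group 50 --seed 1 \
    --out data/

# run every analysis per group and write a report bundle
udsamp analyze --records data/records.csv --controls data/controls.csv \
    --seed 1 --n-perm 1000 --n-boot 1000 --out reports/

# re-render the human-readable summary
udsamp report --bundle reports/

# replicated simulate+analyze: naive-Wald vs permutation rejection rates
udsamp power --preset adult --w 0.0 --n-reps 100 --n-perm 100 --seed 2 \
    --out power.csv
```

Input CSVs are UTF-8, comma-separated, with the documented headers
(`records.csv`: participant_id, age_group, object_id, knowledge_judgement,
times_sampled, test_correct, confidence_rating; `controls.csv`:
participant_id, item_id, item_class, judged_known). Externally deposited
data must be renamed onto this schema first; `udsamp simulate` writes a
`column_mapping.yaml` template for that purpose.

## Library example

```python
from udsamp.simulate import preset_config, simulate_experiment
from udsamp import analyses

cfg = preset_config(groups=("adult",), n_per_group=50, seed=7)
records, controls = simulate_experiment(cfg)
scores, included = analyses.score_controls_and_exclude(controls)
records = analyses.apply_exclusions(records, included)
report = analyses.run_preferential_sampling(records, "adult",
                                            n_perm=1000, seed=7)
print(report.tests["judgement_permutation"].p_value)
```
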