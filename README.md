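# glossperm

A tested, reusable analysis pipeline for a two-alternative gloss
discrimination experiment with neural-perturbation conditions:

- **`stimulus_design`** — the 7-level gloss parameter ladder in (c, d) space
  (equal c spacing, Δc/Δd held at 1.78), seeded spherical-harmonics shape
  families at 5 complexity levels, the 210-condition factorial task grid
  (7 gloss levels × 5 shapes × 3 illuminations × stimulation on/off), and the
  35-image + 7-shuffled-image selectivity stimulus set.
- **`synthetic_data`** — ground-truth generators: Poisson spike counts for
  multiunit sites (with an optional luminance confound in which
  shuffled-image responses track gloss level), Bernoulli choice sessions
  driven by a logistic psychometric truth (stimulation offset shift, muscimol
  slope-multiplier profile, geometric attenuation over repeated injections),
  and JSON ground-truth manifests.
- **`neural_selectivity`** — baseline-subtracted response rates, one-way
  ANOVA across gloss levels (minimum 5 repeats enforced), optimal-shape
  selection, tuning correlations, and the shuffled-image-controlled
  gloss-selectivity classification with glossy/matte preference signs.
- **`psychometrics`** — choice aggregation into per-level proportions and
  least-squares fitting of `y = 1/(1+exp(-a(x-b)))` via a batched, damped
  Gauss-Newton solver (validated against scipy `curve_fit`), plus the
  fit-quality exclusion rule.
- **`perturbation_stats`** — the 30-samples-per-level permutation test
  (15/15 re-splits, refit both pseudo-groups, 2.5%-tail criterion on Δa and
  Δb), shift-direction classification, the muscimol slope-change time course
  at 0.5/18/42 h, and the repeated-injection attenuation summary.
- **`pipeline` / `cli`** — end-to-end orchestration with a JSON `RunConfig`
  (every stochastic step seeded; outputs carry config hashes) and the
  `glossperm` command-line tool.

## CLI

```sh
glossperm design --c-min 0.029 --c-max 0.119 --cd-ratio 1.78 --seed 0 --out out/design
glossperm simulate microstim --seed 1 --out out/sim      # also: muscimol | units
glossperm fit --in out/sim/trials.tsv --group-by stimulation --out out/fits
glossperm permtest --in out/sim/trials.tsv --n-perm 10000 --seed 1 --out out/perm.json
glossperm classify --in out/units/spikes.tsv --alpha 0.05 --out out/cls
glossperm timecourse --in out/mus/trials.tsv --n-perm 10000 --seed 1 --out out/tc.tsv
glossperm pipeline microstim --config config.json --out-dir out/run
```

All tables are TSV; configs and manifests are JSON. Exit codes: 0 ok,
1 validation error, 2 runtime error.

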