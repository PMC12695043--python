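# treefx

Honest causal-tree subgroup discovery for two-arm randomized trials, with
the downstream subgroup statistics and a synthetic trial generator.

The package re-implements, as a tested reusable pipeline, a post-hoc
heterogeneous-treatment-effect analysis of a small two-arm trial whose
outcome is the change in percent-predicted FVC (ΔppFVC) from baseline to a
target week:

- **`treefx.trial_data`** — patient-level table model, CSV I/O, a
  28-covariate baseline catalog (8 binary + 20 continuous),
  last-observation-carried-forward (LOCF) imputation of the target-week
  ppFVC, and ΔppFVC construction.
- **`treefx.causal_tree`** — honest causal tree: splitting by an expected
  mean-squared-error criterion for the within-leaf treatment effect with a
  per-arm minimum terminal-node size (default 5), weakest-link
  cost-complexity path, and 5-fold cross-validated pruning using a
  transformed-outcome squared-error risk normalized by the root-only risk.
  Leaf effects are estimated full-sample by default (`honest_half`
  split-sample estimation is available).
- **`treefx.subgroup_inference`** — per-leaf treatment contrasts with Welch
  95% CIs, Fisher exact (probability-sum, two-sided) and Wilcoxon rank-sum
  arm comparisons, Mantel (χ² = (N−1)r²) and linear-regression trend tests
  across ordered leaves, Pearson correlations, and characteristic-table
  builders.
- **`treefx.synthetic_trial`** — generator of trials with planted
  threshold-defined effects: a high-CRP region, a low-CRP/high-KL-6 region
  and a double-low region, each with its own treatment effect and
  control-arm drift; zero-inflated CRP and right-skewed KL-6 marginals on
  rounded measurement grids.
- **`treefx.cli` / `treefx.report`** — command-line entry points and
  report-bundle assembly (tree JSON, rule text, characteristic tables,
  per-leaf contrasts, run log).

## CLI

```sh
# simulate a trial (defaults: n=48, 25/23 allocation, planted effects)
treefx simulate --seed 1 --n 48 --out trial.csv

# fit the CV-pruned causal tree
treefx fit --data trial.csv --outcome-week 24 --min-per-arm 5 --folds 5 \
    --estimate-mode full_sample --seed 1 --tree-out tree.json

# tables + rules + per-leaf contrasts for a fitted tree
treefx report --data trial.csv --tree tree.json --out-dir results/

# end-to-end (simulate or load, fit, report)
treefx run --sim-n 2000 --sim-seed 1 --seed 1 --out-dir results/
```

Exit codes: 0 success, 2 validation error, 3 fit error.  `simulate`
accepts a flat key-value YAML config whose keys mirror
`SimulationConfig` fields (`n`, `treat_frac`, `crp_cut`, `kl6_cut`,
`leaf_effects`, `control_means`, `noise_sd`, `missing_frac`, `seed`).

## CSV dialect

UTF-8, comma-separated, header row, `NA` for missing.  Columns:
`patient_id`, `arm` (0 control / 1 active), `ppfvc_w<k>` per visit week
`k` (week 0 required), then one column per catalog covariate (see
`treefx.covariate_catalog()`).  The writer emits the identical dialect
with shortest round-trip float formatting, so write→load is
value-identical.
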