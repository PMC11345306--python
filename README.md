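# gaitvar

Longitudinal gait-instability analysis for growing dogs at risk of hip
dysplasia (HD).

Puppies followed from 12 weeks to 15 months with a sensor-based gait
analysis system yield serial measurements of kinematic gait features
(step length, extension angles, acceleration/gyroscope amplitudes,
left-right symmetry indices). `gaitvar` quantifies how *unsteadily* each
dog walks during growth and tests whether dogs later diagnosed with HD
were already more variable: for every dog $d$ and feature $f$ the
day-averaged trajectory is detrended with per-dog ordinary least squares
against age $t$ (days), and the instability score is the mean squared
residual

$$\mathrm{MSE}_{d,f} = \tfrac{1}{n}\textstyle\sum_k \mathrm{res}_k^2,
\qquad \mathrm{res}_k = y_k - (\hat a + \hat b\,t_k),$$

compared between healthy and HD dogs with a two-sided pooled t-test at
α = 0.05 after Shapiro-Wilk normality checks. Per-dog detrending absorbs
breed and body-size differences; lateralized features are mirrored onto
the pathological limb before grouping.

The package provides:

- `gaitvar.io` — CSV readers/writers for run-level measurements, dog
  metadata and the feature catalogue, with strict validation;
- `gaitvar.preprocess` — plausibility filters (fixed category bounds,
  e.g. step lengths outside (0.1, 0.6] m; age > 450 d), whole-day
  exclusion, per-day run averaging, and the ≥4-measurement-days dog
  filter;
- `gaitvar.instability` — the per-dog OLS detrending, MSE score and
  pathological-side mirroring;
- `gaitvar.group_stats` — group comparison, summary-statistic t-tests for
  verifying published tables, box-whisker exports with significance
  stars;
- `gaitvar.synthetic` — a cohort simulator reproducing the study
  structure (44 dogs, 14 HD, monthly-then-bimonthly visit schedule, 1–3
  runs/day, HD-inflated dispersion, injected implausible values with a
  truth table), so the whole pipeline is testable without clinical data;
- a `gaitvar` command-line interface.

See `docs/methods.md` for the model, its assumptions and the calibration
choices.

## Worked example

Simulate a cohort, analyse it, and print the report:

```bash
gaitvar simulate --out-dir sim --seed 7 --implausible-rate 0.03
# wrote 22008 runs for 44 dogs to sim
gaitvar analyze --runs sim/runs.csv --dogs sim/dogs.csv \
    --features sim/features.csv --out-dir out
# analysed 44 dogs (0 removed by the 4-day rule); 24 features compared; outputs in out
gaitvar report --out-dir out
```

The report lists, per side-aligned feature, the group MSE means ± SD and
the pooled t-test p-value (excerpt):

```
feature                           healthy             HD          p
extension_l                   2.172±1.140    1.592±0.815   9.53e-02 ns
extension_r                   1.975±0.996    2.889±1.458   1.91e-02 *
max_acc_amp_r                 1.995±1.060    3.162±0.971   1.15e-03 **
```

`extension_r` is the pathological-limb extension group (healthy dogs use
the right-side convention; left-affected HD dogs are mirrored into it):
the HD group's mean instability is higher and the difference is
significant, while the contralateral `extension_l` shows no effect — the
built-in negative control. `out/` also contains `exclusions.csv` (every
filtered day with its reason), `instability.csv` (per dog × feature MSE),
`results.csv`, `boxplot_data.csv`, `boxplot.png` and a `manifest.json`
whose stage counts reconcile exactly with the files.

When only published group summaries are available, the identical pooled
test runs from summary statistics:

```bash
gaitvar summary-ttest 2.03 0.74 30 2.91 1.10 14
# t = -3.1339, p = 3.1e-03
```

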