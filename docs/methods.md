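# Methods

## The problem

Canine hip dysplasia (HD) is a polygenic developmental malformation of the
hip joint, finally diagnosed radiographically around 15 months of age. The
working hypothesis behind this package is that dogs developing HD walk with
a *more variable* gait during growth: individual visits scatter more widely
around the dog's own growth trend than they do in healthy littermates.
`gaitvar` implements the complete statistical pipeline for testing that
hypothesis on serial IMU-derived gait features, together with a synthetic
cohort generator so every stage is testable without access to clinical
data (the original cohort's raw measurements were never deposited;
only group-level summaries are available, shipped in
`gaitvar/data/reference_group_stats.csv`).

## The instability score

For each dog $d$ and each gait feature $f$, the day-averaged values
$y_k$ at ages $t_k$ (days) are detrended with per-dog ordinary least
squares,

$$y_k = a + b\,t_k + \mathrm{res}_k ,$$

and the instability score is the mean squared residual

$$\mathrm{MSE}_{d,f} = \frac{1}{n}\sum_{k=1}^{n}\mathrm{res}_k^2 .$$

Detrending per dog absorbs breed, body size and individual growth rate, so
the score isolates visit-to-visit unsteadiness. Points to note:

- **Divisor $n$, not $n-2$.** The score is defined as the plain mean of
  squared deviations and is only ever compared between groups, so the
  missing degrees-of-freedom correction cancels. For i.i.d. noise of
  variance $\sigma^2$ around a true line, $E[\mathrm{MSE}] =
  \sigma^2 (n-2)/n$ (0.8 $\sigma^2$ at $n=10$) — this identity is the
  Monte-Carlo oracle used in the tests. The unbiased variant (divisor
  $n-2$) is available via `ddof_correction=True`.
- **Minimum series length 3.** A 2-point fit is exact and would contribute
  a tautological MSE of 0, biasing a dog toward "stable"; shorter series
  are skipped and logged, never silently dropped.
- The fit is the closed-form centred normal-equations solution; it is
  cross-checked in the test suite against an explicit
  $X^\top X\beta = X^\top y$ solver and against `scipy.stats.linregress`
  at 1e-10 relative tolerance.

## Side alignment (mirroring)

Lateralized features are expressed relative to the pathological limb
before grouping: for a dog whose pathological side differs from the
reference side, a left/right feature is replaced by its contralateral
counterpart, and a diagonal symmetry feature (e.g. right femur vs left
humerus) by its mirrored pair; axial features never change. Healthy dogs
have no pathological side and adopt a configurable reference side
(default `right` — the convention is not fixed by the underlying study
design, so it is exposed as a parameter; on symmetric cohorts the group
results are side-invariant). Mirroring is an involution, which the
catalogue validator enforces (`symmetry_pair` must be symmetric) and the
tests exercise. The shipped catalogue therefore contains both orientations
of every lateralized and diagonal-symmetry feature, although descriptive
tables usually print only one.

## Preprocessing

Raw input is run-level: up to 3 consecutive 20 m walking trials per
examination day. The stages, in order:

1. **Plausibility filter.** The upstream feature-extraction software
   occasionally emits artefacts (typically doubled step frequencies,
   yielding e.g. 2 m step lengths). Values are checked against fixed
   category bounds — a value is implausible iff `value > upper` or
   `value <= lower`: energies (200, 0], step lengths (0.6 m, 0.1 m],
   withers height (0.6 m, 0.15 m] — plus a global age cut-off at 450 days.
   Features outside these categories are never value-flagged but are still
   age-checked.
2. **Whole-day exclusion.** One flagged value voids the *entire* session:
   all features, all runs of that dog-day. Because the artefact originates
   in the session's feature extraction, the whole day is suspect.
3. **Day averaging.** Remaining runs are averaged per (dog, day, feature).
4. **Dog filter.** Dogs with fewer than `min_days` (default 4) distinct
   surviving measurement days are excluded entirely, including dogs that
   lost every day to the filters. The count uses distinct dates across
   features, not per-feature series lengths.

The stage satisfies a conservation identity (rows in = rows out + rows on
excluded days + rows of removed dogs), is idempotent, and is invariant to
input row order; all three are tested.

## Group comparison

Per side-aligned feature, the healthy and HD MSE distributions are
compared with a two-sided **pooled-variance Student t-test**
(df = $n_1+n_2-2$) at $\alpha = 0.05$, after a Shapiro-Wilk normality
check in each group. Design choices:

- Pooled rather than Welch, because the pooled form reproduces the
  published reference p-value for the extension feature
  ($p = 3.1\times10^{-3}$ from summaries 2.03/0.74 ($n=30$) vs 2.91/1.10
  ($n=14$)) while Welch does not; Welch remains available
  (`equal_var=False`).
- A failed normality check attaches a warning to the comparison but does
  not switch to a nonparametric test, matching the published analysis.
- No multiple-testing correction by default (none was applied in the
  original 13-feature analysis); Bonferroni/Holm are available via
  `p_adjust` (delegated to `statsmodels`).
- `t_from_summary` computes the identical test from group summary
  statistics alone and is algebraically equal to the raw-data route
  (property-tested); it is the only way to re-verify published tables
  when raw data are unavailable.
- Boxplot quartiles use linear interpolation and Tukey 1.5·IQR whiskers
  (the common defaults; no convention was prescribed).

MSE scores are scaled chi-square-like, not Gaussian, so the t-test is an
approximation; the null calibration below shows its realised type-I error
at these group sizes stays near the nominal 5%.

## The synthetic cohort generator

The generator's defaults are the study conditions: 44 dogs (14 HD, sides
assigned left/right with equal probability; breed mix 37:11:6 Australian
Shepherd : Golden Retriever : Rottweiler by largest-remainder
apportionment), examined on the deterministic schedule 84, 112, 140, 168,
196, 256, 316, 376, 436 days (monthly to 28 weeks, then bimonthly), with
1–3 runs per day (probabilities 0.2/0.3/0.5, so $E[1/k] \approx 0.517$).

Each feature value is

$$v = a_f + \text{breed offset} + b_f t + \varepsilon_{\text{visit}} +
\varepsilon_{\text{run}},\qquad
\varepsilon_{\text{visit}}\sim N(0,\sigma^2_{\text{group}}),\;
\varepsilon_{\text{run}}\sim N(0,\text{run\_sd}^2).$$

Gaussian homoscedastic-within-group noise is the simplest structure
consistent with the t-test the pipeline itself applies. HD dogs carry
$\sigma_{\text{hd}}$ on the features of their pathological limb and on
group-sensitive axial features; everything else uses
$\sigma_{\text{healthy}}$ — so after side alignment, exactly the
pathological-limb feature groups separate, and the contralateral groups
act as built-in negative controls.

**Calibration.** Default noise SDs are back-computed from the published
MSE group means via $\sigma = \sqrt{\mathrm{mse}\cdot n/(n-2)}$ at $n=9$
visits (e.g. extension: $\sigma_{\text{healthy}}=1.62$,
$\sigma_{\text{hd}}=1.93$, giving pipeline MSE means near 2.03/2.91).
Two deliberate exceptions: the published step-length MSE scale (0.03 m²,
i.e. ~0.17 m RMS residuals) is physically incompatible with the
(0.1, 0.6] m plausibility bounds — noise at that scale would constantly
trip the filter — so the simulated step-length noise is a realistic
0.02–0.028 m SD instead; withers height is simulated as a slowly growing
body measurement with millimetre noise and no group effect. Run noise
defaults to 10% of the visit noise. All trend intercepts/slopes are
plausible stand-ins, not estimates of the real cohort's parameters.

**Injected artefacts.** Each dog-day is independently hit with probability
`implausible_rate`; one run value of a bounded-category feature that day
is overwritten with an out-of-bounds value (step length 2 m, energy 250,
withers 0.7 m), and every injection is recorded in a truth table. This
makes filter testing exact: the excluded day set must equal the injected
day set, and the dogs removed by the ≥4-day rule must equal the dogs the
truth table predicts.

**What the generator does not emulate:** visit-schedule irregularity and
dropout, non-Gaussian or heteroscedastic measurement noise, growth-phase
nonlinearity (real gait features plateau), correlated noise across
features and across consecutive runs, and severity grades of HD. Passing
tests therefore demonstrate that the pipeline is correct and calibrated
under its own model assumptions — not that the clinical effect would
reproduce in new data.

## Calibration checks and problem sizes

`scripts/acceptance.py` recomputes, from scratch at a given seed:

- the summary-statistic re-tests of the published reference table
  (extension p-value; count of pathological-limb features with p < 0.01;
  count of features with HD mean > healthy mean);
- the OLS oracle error over 1000 random series and the Monte-Carlo
  $E[\mathrm{MSE}]$ identity at $n=10$, $\sigma=1$ (10⁴ replicates);
- the full-pipeline type-I error over equal-dispersion cohorts
  (400 by default in the script; 2000 in the test suite). The null
  cohorts use a reduced catalogue — one unbounded lateralized feature
  pair plus one bounded pair so the exclusion filter stays in the loop —
  since per-feature type-I error does not depend on catalogue width;
- filter completeness at injection rate 0.6 (recall, false exclusions,
  dog-removal prediction mismatches);
- a default-cohort analysis (44 dogs analysed; extension MSE group means).

## Known limitations

- With only group summaries published, the raw-data route can never be
  validated against the original cohort; only the summary-statistic route
  is anchored to published numbers.
- Some published p-values are not reproducible from their own printed
  summaries under either pooled or Welch assumptions; the package asserts
  only the reproducible anchor (extension) and the p < 0.01 headline.
- The t-test on MSE scores ignores their skew; a permutation or
  rank-based option would be a natural extension but is deliberately out
  of scope to stay faithful to the reference analysis.
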