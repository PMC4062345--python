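# Methods

## Study design being modeled

The pipeline targets a daily-sampling qPCR experiment in a light–dark
entrained animal: tissue collected at nine zeitgeber times over one 24-h
cycle — ZT0, 3, 6, 9, 12, 15, 18, 20 and 24 by default, with a strictly
3-hourly variant (ZT21 in place of ZT20) available as a second preset —
with n = 6 biological replicates per timepoint. ZT0 and ZT24 are sampled
from distinct animals at the same circadian phase and are treated as
independent samples at t = 0 and t = 24; since the fitted cosine has a
24-h period this places them at an identical phase, which is intended.

## Quantification model

Amplification efficiency `E` per gene is estimated from a five-point
2-fold dilution series by OLS of Ct on log10(relative concentration):
`E = 10^(−1/slope)` (slope must be negative; a warning is emitted outside
the practical 1.6–2.1 range). Relative quantity is efficiency-corrected,
`RQ(g, s) = E_g^(Ct_cal(g) − Ct(g, s))`, with the calibrator `Ct_cal(g)`
fixed to the gene's minimum observed Ct so that RQ = 1 at the
most-expressed sample. The calibrator is an arbitrary per-gene constant:
every downstream statistic (cosinor P and acrophase, omnibus p, Pearson
r) is invariant to a per-gene rescaling, so the choice cannot affect any
conclusion; it only fixes the reporting scale. Missing Ct propagates to
missing RQ; nothing is imputed.

Reference-gene stability follows the geNorm algorithm: pairwise variation
`V_jk` is the SD over samples of `log2(RQ_j/RQ_k)` (sample SD, ddof = 1),
`M_j` is the mean of `V_jk` over partners, and the highest-M gene is
excluded iteratively until two remain; those two are the selected pair.
Ties on M are broken deterministically by excluding the lexically last
name, so all-identical candidates select the lexically first pair.
Normalized expression divides each target RQ by the geometric mean of the
selected references in the same sample, which cancels any per-sample
loading factor exactly. Only the selected references are removed from the
output; an unselected candidate remains in the matrix as an ordinary gene.

## Cosinor model and rhythmicity call

The fitted waveform is `y(t) = M + A·cos(2πt/P − φ)` with the period P
fixed (24 h by default; no period estimation is attempted). Rewriting with
`β_c = A·cos φ`, `β_s = A·sin φ` makes the fit OLS on
`[1, cos ωt, sin ωt]`; then `A = √(β_c² + β_s²)`, `φ = atan2(β_s, β_c)`
mapped to [0, 2π), and the acrophase in hours is `φ·P/2π`. The fit uses
replicate-level observations by default (`collapse_means=True` fits
per-timepoint means instead; the choice is exposed because either
convention is defensible, and it is recorded in the fit's `n_obs`).

`SE(A)` uses the delta method on the OLS coefficient covariance Σ of
(β_c, β_s): with gradient `g = (β_c, β_s)/A`, `SE(A)² = gᵀΣg`. The
significance statistic is the amplitude noise/signal ratio
`P = SE(A)/A` — smaller is a better-determined oscillation. The SE
estimator is validated by simulation: across 2000 fits at the default
design, the mean delta-method SE agrees with the Monte-Carlo SD of the
fitted amplitude within a few percent (see `scripts/acceptance.py`,
`se_calibration_ratio`).

A gene is called **daily rhythmic** iff `P < 0.3` AND the omnibus
time-of-day test gives p < 0.05. Both inequalities are strict; boundary
values are non-rhythmic. The 0.3 threshold is the conventional
noise/signal cut-off for this statistic and is a parameter
(`p_ns_threshold`), as is the omnibus alpha. No multiple-testing
correction is applied, and no post-hoc pairwise comparisons enter the
decision.

The omnibus test is one-way ANOVA when the parametric assumptions hold,
judged by per-timepoint Shapiro–Wilk (pooled decision: any group with
p < 0.05 fails — a deliberately conservative pooling) and Brown–Forsythe
equal variance (Levene centered at the median), both at α = 0.05;
otherwise Kruskal–Wallis. Timepoint groups with fewer than two
observations are dropped with a warning.

### Numerical choices

- OLS on a constant series returns an amplitude at the 1e-16 rounding
  level rather than exactly zero; amplitudes below 1e-12 of the data
  scale are treated as exactly flat: amplitude reported as 0, P = +inf,
  `amplitude_zero` flag set.
- A fit needs ≥ 4 observations at ≥ 3 distinct phases (mod P); otherwise
  the design matrix is rank deficient and the fit is rejected. In a
  whole-matrix screen such genes are reported as unfit, not fatal.
- All-identical data makes both omnibus branches degenerate; the
  Kruskal–Wallis path returns p = 1 by contract (no variation is no
  evidence of a time effect).
- Per-group Shapiro–Wilk is undefined for a constant group; such a group
  fails the normality gate and routes to Kruskal–Wallis.

## Correlation screen

Pearson r between two genes, by default over per-timepoint mean profiles
(n = number of timepoints, matching how a single r per pair over the
daily cycle is usually reported); sample-matched `replicates` mode is
available and the mode is recorded in the output. Pairs are retained when
|r| exceeds the threshold (default 0.5) and at least one member is
rhythmic. Magnitude categories are computed on |r| so negative pairs are
classified by strength too: moderate for 0.5 < |r| < 0.70 and strong for
|r| ≥ 0.70 (the published category wording leaves [0.69, 0.70)
unassigned; it is resolved to the strong side's complement, i.e. moderate
ends where strong begins). Zero-variance profiles make r undefined and
raise an error. No correlation p-values, lags or network inference.

## Synthetic-data generator

`generate_expression` produces
`value(g, s) = f_s · (M_g + A_g·cos(2πt_s/24 − φ_g) + ε)` with
`ε ~ N(0, noise_sd_g)` and a shared per-sample factor
`f_s = exp(N(0, sample_factor_sd))`. The additive term models biological
and assay scatter on the normalized-expression scale; the multiplicative
factor models per-sample loading/RT variation — exactly the artifact that
reference-gene normalization removes, which makes geNorm and
normalization testable. Real qPCR data has more structure the generator
does not emulate (heteroscedastic Ct noise, plate effects, inhibitors,
primer-dimer artifacts), so green tests demonstrate correctness of the
algorithms under the stated model, not robustness to every laboratory
failure mode.

Values are floored at 1e-6 before any log/Ct conversion (clip count
flagged in the output); non-positive expression yields a missing Ct.
`generate_ct_table` inverts the quantification model,
`Ct = ct0 − log_E(expression)` with optional Gaussian Ct noise, so that
quantification with the true efficiencies recovers expression ratios
exactly when noise is off (verified to ~1e-15 in tests).
`generate_dilution_series` produces noiseless (or noisy) standard-curve
rows whose fitted efficiency equals the specified one exactly.

All randomness flows through `numpy.random.default_rng(seed)` with a
fixed draw order, so identical specs and seed give bit-identical outputs.

### Bundled demo study

The demo (`qrhythm simulate`, and `demo_design`) mirrors the target
study: 16 clock-gene-like targets — eight with amplitude-to-noise ratio
between about 2.2 and 3.6 at the acrophases of the genes they are named
after, and eight flat or near-flat — plus three candidate references, two
stable (noise SD 0.3, no oscillation) and one deliberately unstable
(noise SD 1.5 with a 1.5-unit oscillation), a per-sample log-factor SD of
0.2, and gene-specific efficiencies in 1.85–1.97. Mesors are set to 10 so
that noise SD 1 corresponds to ~10% CV, a realistic scale for normalized
qPCR data.

## Pipeline and reproducibility

`run_pipeline` composes quantify → normalize → rhythm screen →
correlation screen from a single validated config (YAML round-trip is
lossless), writes every stage output as CSV/JSON, and emits
`manifest.json` with a SHA-256 of every output file, the config hash and
the package version. The pipeline is deterministic: identical inputs
produce byte-identical outputs. Stage failures abort with the stage name
and the offending gene or file.

`reclassify_table1` re-applies the `P < 0.3` rule to a packaged
transcription of a published 16-row clock-gene table (gene, acrophase,
P). That table does not print the omnibus column, so the check exercises
the P-threshold arm of the call only.

## Problem sizes

Simulation-backed checks use 500 fits for parameter recovery, 2000 for SE
calibration and null calibration, 1000 seeds for the geNorm exclusion
rate, and 20 instances for the grid-oracle comparison — sizes at which
the Monte-Carlo error of each checked quantity is comfortably below its
assertion tolerance.

## Known limitations

- Single-harmonic, fixed-period cosinor only: no period estimation,
  multi-component fits, or nonparametric rhythm statistics.
- The noise/signal P is not a p-value; its 0.3 threshold is a screening
  convention, and the omnibus gate is what bounds the false-call rate
  (≤ ~5% on null genes, verified by simulation).
- qPCR controls (no-template, minus-RT) are assumed already applied; the
  Ct table is taken as pre-censored.
- Single-plate model: no inter-plate calibrators.
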