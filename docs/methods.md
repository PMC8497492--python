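# Methods

This note documents the models, defaults, and numerical choices behind
`hrmclock`, and what the synthetic data does and does not establish.

## MS-HRM background

MS-HRM quantifies the average methylation of a short amplicon. Bisulfite
treatment converts unmethylated cytosines to uracil (read as T) while
methylated CpG cytosines survive; after PCR, the amplicon derived from a
methylated template retains its C/G content and melts at a higher
temperature. A sample of intermediate methylation amplifies into a mixture
of the two homoduplex species, and its melt profile interpolates between the
two pure transitions. Every plate carries a standard series of known
methylation ratios (0, 5, 10, 15, 25, 40, 50, 75, 100 %) prepared from
fully unmethylated and fully methylated control DNA, which anchors the
quantification; in the emulated assay every reaction is run in duplicate.

## Melt simulator

Each duplex species melts as a two-state transition: helix fraction
`θ(T) = 1/(1 + exp((T − Tm)/w))` with midpoint `Tm` and width `w` (°C).
The noiseless signal is `post(T) + (pre(T) − post(T))·θ_mix(T)` where `pre`
and `post` are linearly drifting baselines (slopes are expressed as
non-negative downward drifts, fluorescence/°C, so the noiseless curve is
non-increasing) and `θ_mix` is the two-species mixture. Gaussian noise of
standard deviation `noise_sd` is added per acquisition point.

Defaults: temperature grid 65→95 °C in 0.25 °C steps (an export-like
decimation of the instrument's continuous acquisition), signal amplitude
100, baseline drifts 0.20 and 0.05 /°C, noise 0.1 (0.1 % of amplitude,
HRM-grade signal-to-noise). Melt midpoints: 76/80 °C for the ELOVL2-like
marker (4 °C gap) and 74/77 °C for the RALYL-like marker (3 °C gap), widths
1.2 and 1.1 °C, placed so the markers' normalization windows
(66–68 & 84.5–85 °C; 67–68 & 82–83 °C) bracket the transitions.
Heteroduplexes are not modelled: with fully converted templates, MS-HRM
signal is dominated by the two homoduplexes, and the two-state mixture is
the simplest model in which Df increases strictly with methylation.

The mixture weight of the high-Tm species at methylation M is
`b·M/(b·M + (100 − M))` with amplification bias `b` (default 1). At `b = 1`
the curve is pointwise linear in M, which makes the calibration coefficient
`a = 1`; `b ≠ 1` deliberately induces calibration nonlinearity, and `b`
maps one-to-one onto the fitted `a`.

## Cohort generator

Ages are uniform on the cohort's range (the real age distribution is not
modelled). Sex and health labels are assigned in exact study proportions
(cat preset: n = 79, ages 0.41–21.04 y, 43 F : 36 M, 41 CKD; leopard preset:
n = 11, ages 2.25–14.67 y, 4 F : 7 M, 1 CKD). Per marker, true methylation
is `baseline + slope·age + offsets + N(0, sd)`, clamped to [0, 100]; each
sample gets two wells per marker and the plate carries a duplicated
standard series per marker.

Marker defaults were chosen analytically from the target marker–age
correlation r via `r = slope·sd(age)/√(slope²·sd(age)² + sd_res²)`:

| preset | marker | baseline % | slope %/y | residual sd % | CKD extra sd % |
|---|---|---|---|---|---|
| cat | ELOVL2 | 30 | 2.0 | 11 | +4 |
| cat | RALYL | 25 | 1.8 | 10 | +4 |
| leopard | ELOVL2 | 30 | 1.4 | 3.2 | +2 |
| leopard | RALYL | 25 | 1.26 | 3.0 | +2 |

With uniform cat ages (sd ≈ 5.96 y) these give r ≈ 0.65–0.70 per marker;
the leopard settings give r ≈ 0.8 at n = 11. Sex and CKD offsets on mean
methylation default to 0; disease instead acts through a wider residual sd
(+4 points for CKD cats), the simplest mechanism that degrades clock
accuracy for the diseased subgroup without shifting its mean. The leopard
slopes are 70 % of the cat's: a between-species shift in the
methylation–age coupling that makes a cat-trained clock systematically
underestimate leopard ages under direct transfer.

What the simulator does **not** emulate: heteroduplex melting, bisulfite
conversion inefficiency, PCR stochasticity and plate/batch effects,
non-uniform age distributions, and any real relationship between sex or
breed and methylation. Passing tests therefore demonstrate that the
pipeline recovers what the generative model plants — calibration
coefficients, methylation values, age signal, subgroup error structure —
not that the specific accuracy numbers would be reproduced on instrument
data.

## Melt processing

Normalization fits a least-squares line to each window and rescales to
`100·(F − post)/(pre − post)`; it errors if a window holds fewer than two
grid points or if the fitted pre-line does not exceed the post-line across
the analysis interval. Because the rescaling is a ratio of fitted lines it
is exactly idempotent only when the window contents are linear; noise or
transition tails inside a window perturb re-normalization slightly (this is
inherent to the two-line definition, not an implementation artifact).

Difference curves are taken against the plate's 0 % standard (duplicates
averaged pointwise), after resampling onto the baseline's grid by linear
interpolation when grids differ. Two modes are provided, and recorded in
every output row: `derivative` (default) subtracts −dN/dT curves, matching
a first-derivative reading of the assay; `fluorescence` subtracts the
normalized signals, the conventional HRM difference plot. Both rank a
standard series identically, and the calibration layer consumes either.
Derivatives use `np.gradient` (central differences, one-sided at the ends)
after a centered moving average (odd width, default 5 points) because
derivative differencing amplifies acquisition noise. The Df search is
restricted to the open interval between the windows to keep line-fit edge
artifacts out of the statistic; argmax ties break to the lower temperature.

## Calibration

The standard-curve model `a·M/(100 − M) = Df/(Df_max − Df)` is fitted in
its forward form `Df(M) = Df_max·a·M/(a·M + 100 − M)` by least squares on
the Df scale (`scipy.optimize.least_squares`, Levenberg–Marquardt,
tolerances 1e-12). `Df_max` is fixed at the observed 100 %-standard Df
(mean over duplicates) rather than co-estimated, because the model defines
it as an observation; 100 % points are excluded from the residuals they
would trivially zero. Positivity of `a` is enforced by optimising log a
from a₀ = 1. Inversion uses the closed form `M = 100·q/(a + q)` with
`q = Df/(Df_max − Df)`; sample Df values outside [0, Df_max] — routine
under instrument noise — clamp to 0/100 and are flagged, never raised.
Replicates are combined after inversion ("mean-of-M", default) or before
("mean-of-Df"); the two differ exactly when `a ≠ 1`. Calibration is
per marker × plate; single-plate inputs default to one plate.

Estimator precision: with 2 %-of-Df_max Gaussian noise on a duplicated
nine-level series, the fitted `a` lands within 10 % of truth in ≈98 % of
replicates (≈89 % with single wells — duplicate standards matter).

## The clock

ε-insensitive SVR with RBF kernel, γ fixed at 0.5 on features standardized
to zero mean/unit variance (standardization parameters are frozen at
training time and reused for all predictions, including cross-species
transfer). Tuning grids default to cost ∈ {2⁻¹ … 2⁶} and
ε ∈ {0.01, 0.05, 0.1, 0.2, 0.5, 1}, searched exhaustively by seeded
10-fold cross-validated MSE with ties broken toward smaller cost then
smaller ε. The default protocol tunes once on the full data and then runs
LOOCV at fixed hyperparameters; the statistically stricter variant that
retunes inside each fold is available (`loocv_variant: tune-in-fold`) and
generally yields slightly larger MAD. Ages are used untransformed (years).
Models serialize to JSON (hyperparameters, standardization, training
arrays) and are refitted deterministically on load, keeping artifacts
plain-text.

Species-specific refitting retunes (cost, ε) on the new species' data —
the "reset the model settings" protocol — which on simulated leopards
improves mean MAD over direct transfer (≈1.7 vs ≈2.2 y over 20 cohorts)
while direct transfer shows the expected systematic underestimation.

## Deviation analysis

OLS of (predicted − chronological) age on chronological age, sex
(treatment-coded, reference F) and health (reference healthy), via
statsmodels. All 2³ covariate subsets are fitted and ranked by AICc
computed with K = number of coefficients + 1 (the residual variance is
counted, the convention of likelihood-based selection on linear models);
near-ties within 1e-9 resolve to the smaller model with a warning.
LOOCV predictions are the default response (the error being diagnosed is
the validated one). Note that AIC-family selection admits a spurious null
covariate with probability ≈ P(χ²₁ > 2) ≈ 0.16 independent of n, so
exact-subset recovery plateaus near 70 % for one planted term; recovery
claims in the tests are therefore majority statements, not near-certainty.
A constant response leaves R² undefined and is flagged as NaN.

## Degenerate inputs and edge behaviour

- Melt curves require ≥ 10 strictly increasing temperatures.
- Plates must carry 0 % and 100 % standards per marker; orphan wells and
  duplicate well assignments are schema errors naming the offending rows.
- Constant feature columns in the clock warn and proceed with unit scale.
- Single-level categorical covariates make the deviation design
  rank-deficient and raise.
- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; identical seeds reproduce every output file
  byte-for-byte.

## Problem sizes used in checks

The automated checks run at desk scale: 500-replicate calibration
Monte-Carlo; single 79-sample cohorts for full-pipeline runs; 50-seed
ensembles for LOOCV-vs-training and subgroup comparisons (ground-truth
methylation is used directly there, skipping melt synthesis, since the
melt → Df → calibration chain is validated separately); 20-seed ensembles
for cross-species transfer; 60-replicate AICc selection runs.

## Known limitations

- Df scaling follows this package's normalization contract; absolute Df
  values from instrument software may differ by an affine factor, which the
  affine-invariance of the processing chain absorbs.
- No per-CpG resolution: the method measures region-average methylation.
- No confidence intervals on individual age predictions.
- Cross-plate calibration pooling is not implemented beyond keying fits by
  (marker, plate).
- The simulator's realism targets are the standard-series behaviour and the
  marker–age correlation strengths only.
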