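# hrmclock

Estimating the age of an animal from a blood sample is a recurring need in
veterinary practice and wildlife management, and DNA methylation at a small
number of age-associated gene regions (e.g. *ELOVL2*, *RALYL*) is one of the
most reliable molecular age markers. `hrmclock` implements the full analysis
chain of a methylation-sensitive high-resolution melting (MS-HRM) epigenetic
clock, from raw instrument melt traces to age predictions and error
diagnostics, together with a simulator that generates realistic melt curves
and age-structured cohorts so the entire chain can be exercised and tested
without any instrument data.

It is written for researchers running MS-HRM age assays (felid cohorts are
the motivating case: a domestic-cat-like cohort of 79 animals and a
snow-leopard-like cohort of 11), and for anyone who wants a tested,
scriptable reference implementation of the method.

## The method

1. **Melt-curve normalization.** Each well's fluorescence trace F(T) is
   rescaled between straight lines fitted to a pre-melt and a post-melt
   temperature window (e.g. 66–68 °C and 84.5–85 °C for *ELOVL2*):
   `N(T) = 100 · (F − post)/(pre − post)`. The result is invariant to affine
   distortions of the raw signal.
2. **Difference curves and the Df statistic.** The normalized curve (by
   default its negative first derivative, −dN/dT) is subtracted from that of
   the plate's 0%-methylated standard; the maximum absolute difference in
   the inter-window interval is the well's **Df value**.
3. **Calibration.** The plate's standard series (0, 5, 10, 15, 25, 40, 50,
   75, 100 % methylation) is fitted with the one-parameter model

       a·M/(100 − M) = Df/(Df_max − Df)

   where Df_max is the observed Df of the 100 % standard and `a` captures
   amplification bias between methylated and unmethylated templates (at
   a = 1, Df = Df_max·M/100 exactly). Sample Df values are inverted through
   the fitted curve to percent methylation; duplicates are averaged.
4. **The clock.** Age is regressed on the per-marker methylation
   percentages with ε-insensitive support vector regression (RBF kernel,
   γ = 0.5 on standardized features); cost and ε are tuned by seeded
   10-fold grid search, the model is validated by leave-one-out
   cross-validation (LOOCV), and accuracy is summarised as the mean
   absolute deviation (MAD, years). Relative age (age divided by the oldest
   study individual's age) supports cross-species comparison, and a fitted
   clock can be transferred unchanged to a second species.
5. **Deviation sources.** The per-sample error (predicted − chronological
   age) is modelled by OLS on age, sex, and health condition (reference
   levels: female, healthy), with exhaustive all-subsets AICc model
   selection.

## Worked example

Simulate a cat-like cohort (79 animals, two markers, duplicate wells, the
nine-level standard series on the same plate) and run the whole pipeline:

```bash
hrmclock simulate --preset cat --seed 1 --outdir demo
# wrote 352 curves for n=79 cat cohort to demo
hrmclock run-all --melt demo/melt.csv --sheet demo/sheet.csv --seed 1 --outdir demo/results
# {"mad_years": 2.5866669321990674, "cost": 8.0, "epsilon": 0.01, "gamma": 0.5}
```

The run prints the LOOCV MAD of the tuned clock — here the clock predicts
age to within about 2.6 years on average — and the hyperparameters the grid
search selected. `demo/results/` then holds every intermediate table:

- `calibration.csv` — the fitted standard curves, e.g. `a = 0.927`
  (ELOVL2) and `a = 1.000` (RALYL) with `Df_max ≈ 18.8`: both markers are
  close to the linear-mixing limit `a = 1`, as expected when amplification
  is unbiased.
- `correlations.csv` — Pearson r of methylation vs age per marker
  (`0.673` and `0.649` here), the screening step before model building.
- `predictions_loocv.csv` — per-sample held-out predictions with absolute
  and relative ages.
- `deviation_coefficients.csv` / `deviation_ranking.csv` — the best OLS
  model of the prediction error (here `{age}` with an age slope of
  `−0.31` y/y: older animals are relatively underestimated) and the full
  AICc ranking of all eight covariate subsets.

The same stages are available individually (`process`, `calibrate`,
`quantify`, `clock-fit`, `clock-predict`, `clock-loocv`, `deviation`) and as
library functions (`hrmclock.melt.process_plate`,
`hrmclock.calibration.fit_standard_curve`, `hrmclock.clock.loocv`, ...).
File formats are plain CSV (long-format melt traces; a documented
sample-sheet schema), JSON for models and summaries, and FASTA for marker
sequences. See `docs/methods.md` for the model details, simulator design,
and numerical choices.

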