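# Methods

This note documents the models and procedures implemented in `plotspec`, the
assumptions behind them, the tunable parameters that matter, and the design
choices made where the design was genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Pipeline model

The pipeline treats a plot trial as a chain of well-posed sub-problems:

1. **Radiometric calibration.** The sensor model is R_b = a_b · DN_b per band
   b, with no intercept — dark current and path radiance are assumed removed
   upstream by the flight-processing software, which is the operating regime
   of the camera class this targets. Slopes are estimated by zero-intercept
   least squares over reference panels, which makes a single panel
   sufficient (the ratio is then forced) and multiple panels a genuine
   regression with per-band residual RMS as the fit diagnostic. Panel DN is
   the arithmetic mean over pixels whose centers fall in a 0.2 m × 0.2 m
   square centered on the panel, avoiding boundary-mixing pixels. Calibrated
   reflectance above `clip_max` (default 1.0) is clipped with a logged count
   rather than failing: noisy bright panels can slightly exceed 1, and
   silent propagation would corrupt downstream indices.

2. **Soil masking.** Canopy pixels are `VARI > t`. The automatic threshold
   is Otsu's between-class-variance maximizer on a 256-bin histogram of the
   valid VARI values (delegated to scikit-image; a brute-force oracle backs
   it in the tests). A fixed threshold can be supplied instead. The mask is
   applied uniformly at every stage. Pixels where |G + R − B| < 1e-6 are
   nodata. Otsu's split is only guaranteed to separate soil from canopy
   exactly when the histogram is two-cluster; with strong between-plot vigor
   variation the canopy mode spreads and the split can land inside it, which
   is why the exact-recovery check in the acceptance suite uses a
   homogeneous-canopy scene while the realistic-contrast check asserts
   IoU ≥ 0.95 instead.

3. **Index extraction.** Per-pixel index rasters are averaged over canopy
   pixels inside each plot polygon buffered inward by 0.25 m (standard
   plot-trial practice against boundary mixing). The aggregation order is
   **mean-of-index**, not index-of-mean-reflectance; the two differ because
   the formulas are nonlinear ratios, and a regression test pins the choice.
   A plot with zero qualifying pixels at a stage is flagged explicitly
   (`empty_zones`), never silently NaN. Denominators within 1e-6 of zero are
   nodata.

4. **Traits.** Yield is kept in kg/ha (a g/m² → kg/ha converter exists for
   harvested-sample data; it takes the sampled area explicitly rather than
   guessing row-spacing conventions). NPFP = GY/Ni and
   aNUE = (GY − GY_N0)/Ni are computed only for Ni > 0 and raise errors at
   Ni = 0 rather than returning zeros. The GY_N0 control for each fertilized
   plot is the N0 plot of the same variety and replicate (default), or the
   variety's mean over N0 plots (`pairing="variety-mean"`). aNUE may be
   negative; no floor is imposed.

5. **Screening.** Pearson r with two-sided t-distribution p-values per
   (index, stage) cell; NUE screens use fertilized plots only. No
   multiple-testing correction is applied across the matrix — the screen is
   exploratory ranking, not inference. The stage-robustness score ranks
   indices per stage by |r| (average ranks on ties) and combines
   `w·mean-rank + (1−w)·max-rank` across stages, lower is better, `w = 0.5`
   by default. This weighted mean/max rank-sum is a reconstruction of the
   rank-aggregation idea for date-robust index selection; the exact
   published weighting it stands in for is not publicly specified, so only
   the reconstruction's own properties (permutation invariance, reduction to
   mean-rank at w=1, invariance to monotone index rescaling) are asserted.
   |r| rather than signed r drives the ranking because repRVI and mNDblue
   correlate negatively by construction.

6. **Modeling.** Four families on plot-level `index@stage` features:
   - *LR* — OLS on exactly one feature;
   - *MLR* — OLS on all supplied features, with rank-deficiency reported as
     a collinearity error naming the offending columns;
   - *SMLR* — bidirectional stepwise search minimizing Gaussian AIC
     `n·ln(RSS/n) + 2(k+1)`, starting from the full model, applying the
     single add/drop move with the largest AIC decrease until none improves;
     deterministic, ties break toward the earliest candidate (drops before
     adds, column order);
   - *PLSR* — scikit-learn NIPALS partial least squares (`scale=False`;
     scaling is owned by the evaluation protocol), component count fixed or
     chosen by seeded 5-fold cross-validation minimizing mean fold RMSE,
     folds stratified by N level, smaller count breaking ties.

   The evaluation protocol: within each N-level stratum, round(⅔·size)
   plots to training (half-up rounding — exact 6/3 at stratum size 9),
   remainder to test; features z-scored on the training set only; 20
   repeats with split seeds `base_seed+k`, so all families see identical
   partitions; mean and sd of train/test R², RMSE, MAE reported. R² is the
   squared sample Pearson correlation between observed and predicted —
   the convention of the R modeling stack this protocol mirrors (the
   sum-of-squares form printed in some write-ups of it is dimensionally
   inconsistent as typeset). A constant observed or predicted vector makes
   R² undefined (NaN with a warning); RMSE/MAE are always returned.

## The scene simulator

No field imagery is distributed with the trial design this package targets,
so `plotspec.scene` generates it. The generative chain is deliberately the
*minimal* model that produces every problem the pipeline solves:

- **Design**: 4 N levels (0/100/200/300 kg/ha) × 3 varieties × 3 replicates
  = 36 plots of 2 m × 8 m on a regular grid with 0.5 m spacing, N levels as
  full rows (split-plot layout), plus four 0.5 m gray reference panels
  (reflectance 0.06/0.22/0.44/0.64 across bands) in a calibration strip.
- **Latent vigor**: `0.15 + 0.65·(N/300)^0.8 + variety offset ± N(0, 0.04)`,
  clipped to [0.02, 1]. The saturating power law encodes diminishing returns
  to N; variety offsets (±0.02) are small because variety effects in such
  trials are mostly non-significant, keeping the variance N-dominated.
- **Canopy endmember spectrum**: linear in vigor per band — blue and red
  darken with vigor (chlorophyll absorption), red edge and NIR brighten
  (canopy structure): e.g. red 0.08 − 0.05·v, NIR 0.32 + 0.20·v. Soil is
  fixed at (0.10, 0.16, 0.22, 0.26, 0.30). These produce canopy VARI ≈ +0.4
  vs soil VARI ≈ −0.2, the separation the masking step exploits.
- **Cover**: per stage, `base_s + gain_s·v` (base rising from 0.15 at
  jointing to ~0.5 mid-season), capped at 0.98. At 1.5 cm GSD most pixels
  are nearly pure canopy or soil, so the per-pixel canopy fraction is
  Bernoulli(cover) pushed to ~0 or ~1 with half-Gaussian sub-pixel mixing
  (sd 0.06). The true mask is `fraction > 0.5`, an unambiguous target.
- **Reflectance and DN**: linear canopy/soil mixture per band, additive
  Gaussian reflectance noise (sd 0.004), clipped to [0,1]; panels overwrite
  their footprint exactly; DN = R/a_b + N(0, 15 DN), rounded into uint16.
  True slopes (1.8–2.6)·10⁻⁵ put the brightest panel near DN 30 000, well
  inside 16-bit range. Quantization is treated as one of the noise sources:
  `quantize_dn=False` gives the noiseless limit in which calibration must
  invert the imaging model to float precision.
- **Yield**: `2800 + 7000·vigor + N(0, 250)` kg/ha, floored at 0 — about
  3.8 t/ha unfertilized to 8.5–9 t/ha at 300 kg N/ha, a realistic range for
  high-input winter wheat, with NPFP and aNUE decreasing in N as field
  trials show.

**What the simulator does *not* emulate** — and hence what passing tests do
not show about real data: radiative-transfer canopy optics (no BRDF, shadow,
specular or view-angle effects), photogrammetric image formation
(orthomosaicking residuals, vignetting, exposure variation), spatial
autocorrelation of soil and canopy, ears vs leaves as distinct classes,
weather- or stress-driven decoupling of canopy signal from yield, and any
nonlinearity or saturation in the VI–trait link. Because the canopy–yield
link is linear with controlled noise, plot-level VI–yield correlations come
out near |r| ≈ 0.99 and model R² near 1 — far above the 0.6–0.85 typical of
field data. Structural properties (signs, orderings, identities, counts,
recovery of known parameters) are the simulation's targets, not the field
study's headline numbers, which are not reproducible without the original
(undeposited) imagery.

Desk-scale runs use a coarser GSD (5–8 cm) since every component is
resolution-independent; the default configuration keeps the full 1.5 cm
resolution (raster 2467 × 1600) and runs end-to-end in about a minute.

## Numerical choices

- Pixel membership everywhere is *pixel-center-in-polygon* on world
  coordinates with half-open cells; boundary centers are excluded (strict
  containment). Rendering buffers are float64: float32 reflectance would cap
  slope-recovery accuracy at ~10⁻⁸ relative.
- ELM fit requires strictly positive finite slopes; an all-zero DN band is a
  degenerate-fit error.
- `RSS` is floored at 10⁻³⁰⁰ inside the AIC to keep exact interpolation
  finite-ordered rather than NaN.
- Stratified-split rounding is half-up (`floor(f·n + 0.5)`).
- All randomness flows from explicit integer seeds (`numpy.random.
  default_rng`); per-stage render seeds derive from the scene seed as
  `seed + 1000·(stage index + 1)`; repeat k of the evaluation uses
  `base_seed + k`. Fixed seeds give bit-identical rasters, tables and
  manifest hashes.

## Known limitations

- The zero-intercept calibration cannot represent additive offsets (haze,
  dark current); imagery with uncorrected offsets will bias reflectance low
  or high at the dark end.
- Otsu masking assumes a bimodal VARI histogram; scenes that are nearly all
  canopy (or all soil) need a fixed threshold.
- The stepwise search is greedy; it bounds the full and empty models' AIC
  but is not guaranteed to find the global AIC minimum over all subsets.
- With 36 plots, test sets hold 12 plots (9 for NUE traits): per-repeat test
  metrics are noisy, which is exactly why the protocol averages 20 seeded
  repeats and why single-repeat numbers should not be quoted.
- The trait module assumes one yield value per plot; sub-plot sampling
  variability is upstream of this package (the converter handles one sample
  at a time).
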