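# Methods

## The synthetic data model

Real calibration studies of grape ripeness measure diffuse reflectance on
intact berries and pair each spectrum with destructive reference chemistry.
Since no such dataset ships with this package, all quantitative claims are
made on synthetic spectra with known ground truth. The generative model is

    clean_i(λ) = B(λ) + Σ_k link_k(c_ik) · Σ_b A_kb · exp(−(λ − μ_kb)² / 2σ_kb²)
    obs_i(λ)   = m_i · clean_i(λ) + o_i + p_i(λ) + ε_i(λ)

with `B(λ)` a fixed logistic baseline (low reflectance in the
pigment-absorbing visible region rising to a NIR plateau), Gaussian
absorption bands `(μ, σ, A)` per constituent, `link` either identity or the
square, log-normal multiplicative scatter `m_i`, Gaussian offset `o_i`, a
random low-order polynomial baseline `p_i` and i.i.d. channel noise `ε`.
Concentrations are uniform over each constituent's range, coupled across
constituents through a shared "maturity" latent factor (Gaussian copula,
correlation 0.5) to mimic the coordinated change of sugars, acids and
phenolics during ripening.

Default study-scale conditions: 192 samples on a 1507-point grid over
400–1100 nm; six constituents named for the quality indicators with two
bands each, placed in the visible pigment region and the 800–960 nm
sugar/phenolic region; plausible veraison-to-maturity concentration ranges
(pH 2.5–3.8, TSS 8–25 °Brix, TA 5–18 g/L, RS 40–200 g/L, TPCN 1.5–12 and
TPCD 20–90 mg GAE/g). Band amplitudes are scaled so a full-range
concentration swing moves reflectance by 0.07–0.15 units; artifact
magnitudes are scatter sd 0.1 (log scale), offset sd 0.02, baseline
polynomial coefficient sds (0.02, 0.01, 0.005) and channel noise sd 0.003.
The across-sample signal spread at band centers is therefore an order of
magnitude above the noise floor (SNR well above 10), which is the regime a
working Vis–NIR instrument operates in.

What the generator deliberately does not emulate: radiative-transfer
physics, instrument response and wavelength-dependent noise, temperature
and water-activity effects, and nonlinear band overlap chemistry. Passing
tests on this data demonstrate that the pipeline recovers known structure
under the distortions its preprocessing stage targets — not that any
particular field dataset will reach the same accuracy.

## Preprocessing definitions

The six operators follow chemometrics convention; the field's method names
rarely come with printed formulas, so the exact contracts are fixed here:

- **SNV**: per row, subtract the mean and divide by the sample sd (n−1).
  Errors on constant rows.
- **MSC**: regress each row on `[1, reference]` by least squares and return
  `(row − a)/b`; the reference is the training-set mean spectrum
  (leakage-safe). Slopes below 1e−12 error.
- **SG / FD**: Savitzky–Golay smoothing / first derivative, window 11,
  polyorder 2 by default; same-length output with polynomial edge fits
  (`mode="interp"`), so downstream wavelength bookkeeping never shifts. FD
  divides by the median grid step — units are reflectance per nm.
- **DT**: per row, subtract its least-squares polynomial in wavelength
  (order 2 default), computed on a rescaled wavelength axis for
  conditioning.
- **SS**: column z-score using training means and sample sds; zero-variance
  columns error by name.

Only MSC and SS learn anything from the training set; the rest are
row-wise, which the tests exploit (removing or permuting test rows cannot
change any output).

## Partitioning and wavelength selection

SPXY normalizes the spectral and response distance matrices by their maxima
before summing, so the split is invariant to rescaling either space. The
training size is `round(0.7·N)` (134 of 192) and every argmax tie breaks to
the lowest index, making splits fully deterministic. Distances are computed
on raw spectra: the split is made once per indicator, before the
preprocessing sweep, so every preprocessing sees the same partition.

The selector couples two mechanisms. Candidate subsets come from a classic
successive-projections chain — a purely X-driven, collinearity-minimizing
ordering started at the column most correlated with y. Subset size is then
scored by Monte-Carlo cross-validation: 80 resampled 10-fold assignments,
inner model MLR (PLS1 available), RMSECV averaged per size, minimum wins
with ties to the smaller size (an absolute tie slack of 1e−12 keeps
exact-fit plateaus from resolving to larger subsets). Under-determined
inner fits score +inf and are logged. `force_size=50` reproduces the
protocol of fixing 50 wavelengths per indicator regardless of where the
minimum falls.

## Regression engines

- **PLS** wraps the NIPALS PLS1 implementation of scikit-learn
  (`scale=False`: mean-centering only). The latent-variable count is chosen
  by 5-fold CV RMSE over 1..min(n_train, n_vars); by default the grid is
  capped at 20 components, ample for spectra of this kind — pass
  `max_components=None` for the uncapped sweep, `forced_components` to pin
  the count. Coefficients are exposed per wavelength for influence-band
  plots (top 25% / middle 50% / bottom 25% by |coefficient|).
- **SVR** wraps scikit-learn's `SVR` inside `RandomizedSearchCV` with the
  fixed grid (C, γ, kernel as in the README), exactly 10 draws, 5-fold CV,
  RMSE scoring, seeded. `scale`/`auto` are the usual kernel-coefficient
  heuristics 1/(p·var(X)) and 1/p.
- **CNN** is a from-scratch numpy implementation (no deep-learning
  framework dependency): forward and backward passes are hand-derived per
  layer and verified against finite differences in the test suite. The
  architecture is fixed (three conv/BN/ReLU blocks with w2/s1 max-pools,
  adaptive max-pool to length 1, FC 64→32→1 with dropout 0.2). Training
  uses MSE loss, Adam at lr 1e−3, batch size 16, 500 epochs by default (100
  in the fast grid profile), no weight decay or early stopping. Inputs are
  z-scored per wavelength and the target is z-scored too, both on training
  statistics only and inverted at prediction time — the target scaling
  keeps one optimizer setting stable across indicators whose units span
  three orders of magnitude. Per-epoch MSE is recorded on the calibration
  set and, when supplied, on the held-out set; held-out data never touch
  the weights, the optimizer or the stopping decision. All randomness
  (init, shuffling, dropout) flows from one seeded generator, so training
  is bit-reproducible. The layer chain needs at least 15 input wavelengths;
  shorter inputs error with that minimum.

The pooling windows of size 2 with stride 1 (shrinking each map by a single
sample) are unusual but implemented exactly as specified by the
architecture this package reproduces.

## Metrics

`compute_metrics` evaluates R² against the evaluated set's own mean (the
literal reading of the formula; a train-mean variant would give slightly
different prediction R²). RPD uses the n−1 standard deviation, which makes
the identity RPD = √(n/((n−1)(1−R²))) exact — the suite asserts it to
1e−9. A perfect fit reports RPD as +inf rather than erroring so exact
synthetic fits survive the grid.

## Grid orchestration and numerical choices

The grid runner isolates failures per cell, records chosen
hyperparameters, selected wavelengths, test-set predictions and CNN loss
histories, and serializes deterministically (sorted JSON keys) so reruns
are byte-comparable. By default SPA runs per (indicator, preprocessing)
cell; `spa_preprocessing` restricts it to one designated method when a
single "optimal" preprocessing is known. Winner selection maximizes
prediction R² with RPD, then RMSEP, then model simplicity (PLS < SVR <
CNN) as tie-breaks — the rule is explicit because published studies
usually state only the outcome.

Problem sizes in the shipped tests and the acceptance script are chosen
for desk-scale runs: study-scale 192 × 1507 data for the linear recovery
checks (seconds per seed), reduced grids (≈40–60 samples, 60–80
wavelengths, few CNN epochs) for orchestration tests, and n = 160 spectra
of length 50 for the CNN convergence check. The CNN convergence criterion
is evaluated on the recorded loss history (the minimum over the first 500
epochs): with dropout permanently on, the loss fluctuates around its floor
rather than descending monotonically.

## Known limitations

- Synthetic concentration ranges are plausible rather than matched to any
  published distribution; absolute RMSE values are therefore not comparable
  to field studies, only the relative behavior of the pipeline is.
- The SPA scoring stage assumes the inner MLR is well-posed up to
  `max_vars`; heavily undersized training sets score +inf for large
  subsets, which the curve exposes.
- The CNN is CPU-only and deliberately shallow; it is the correct
  architecture at these data sizes but will underperform deeper models on
  large multi-season datasets.
- SPXY on raw (rather than preprocessed) spectra is a fixed choice; both
  conventions exist in the literature, and the split function accepts any
  matrix if the other convention is wanted.
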