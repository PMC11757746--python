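# Methods

## Calibration model

The calibration is an intercept-free multiple linear regression from a
min-max-normalized transmittance spectrum to the degree of substitution
(DS).  Its assumptions, and where they come from, are:

- **Linearity.**  Band absorbance grows (or shrinks) roughly linearly with
  DS (Beer–Lambert behaviour of the ester C=O, C–H and C–O bands and the
  consumed O–H band), and over the instrument's dynamic range the
  transmittance change is close enough to linear for a single weight per
  wavenumber to capture it.
- **No intercept.**  A sample with zero absorbance everywhere carries no
  ester signal; forcing the fit through the origin encodes this and removes
  the one free hyper-parameter the model class would otherwise have.
- **Underdetermined regime.**  Calibration sets are small (S ≈ 16) against
  M = 1750 wavenumbers.  `fit_mlr` therefore solves the least-squares
  problem with an SVD (`scipy.linalg.lstsq`, LAPACK `gelsd`) and returns the
  minimum-Euclidean-norm solution; the rank cutoff is the LAPACK default
  (machine epsilon × max(S, M) × largest singular value) and is recorded in
  the model provenance.  The training residual is the orthogonal-projection
  residual, and adding an uninformative (zero) column never changes
  predictions.
- **Physical non-negativity.**  DS ∈ [0, 3]; a ReLU is applied to the model
  output at prediction time only.  It is never part of the training
  objective, so the fitted weights remain an ordinary least-squares
  solution.

## Normalization and regions

Min-max normalization is applied per sample over the *full* measured grid,
before any region restriction, and regions are never re-normalized — models
fit on different regions therefore see values on an identical scale.
Normalization is idempotent and invariant to per-sample affine rescaling of
the raw signal (instrument gain/offset), which is exactly why the method
needs no manual baseline correction.

Region bounds are half-open `[low, high)` on the grid values.  The interval
convention is an implementation choice (the literature writes strict
inequalities on both sides); half-open intervals compose without gap or
overlap at the 1500 cm⁻¹ fingerprint boundary, and a grid point at exactly
1500 cm⁻¹ belongs to the non-fingerprint region.

## Feature selection

Each wavenumber is scored by the sample Pearson correlation ρᵢ of its column
with DS and ranked by Fᵢ = ρᵢ²/(1−ρᵢ²)·(S−2).  Conventions:

- The (S−2) factor uses the **sample count**, matching the univariate
  F-test for regression; F is unbounded above, monotone in |ρ|, and +∞ when
  ρᵢ² = 1 (such a feature ranks first).  Descriptions of F as a 0–1 score
  that circulate in the application literature are inconsistent with this
  formula; the formula is what is implemented.
- Constant columns get ρ = 0 and hence F = 0: zero variance carries no DS
  information and such features are never selected before any varying one.
- Ties in F break toward the smaller index, making selection deterministic.
- During cross-validation, selection is refitted **inside each training
  fold** by default (`selection_scope="per_fold"`), so test rows never
  influence the selected set.  `selection_scope="global"` (select once on
  all data) is provided for comparison because published protocols often
  leave the scope unstated; it is the leaky variant and not the default.
- Selecting all M features is normalized to "no selection" so that an
  n = M sweep point reproduces the unselected cross-validation bit for bit
  (a column-subset copy would otherwise change BLAS summation order and
  perturb the last float bits).

## Cross-validation

Repeated k-fold with reshuffled assignment: repetition r shuffles the sample
indices with `numpy.random.default_rng(base_seed + r)` and splits them into
k folds whose sizes differ by at most one.  The seed schedule makes every
run bit-reproducible from one integer and lets any single repetition be
re-run in isolation.  Errors are reported at three aggregation levels —
per fold, pooled within a repetition, and pooled over all N·k test
predictions — because fold-level and pooled MAEs answer different questions
(spread across chance splits vs overall accuracy).  With equal fold sizes
the mean fold MAE and the mean pooled-per-repetition MAE coincide.

Fold MRE is reported as NaN when a fold's reference DS contains an exact
zero (the standalone `mre` raises instead); unreachable with the default
synthetic DS range.

Box statistics use linear interpolation between order statistics for the
quartiles (the common plotting default) and Tukey whiskers: the farthest
data points within 1.5·IQR beyond Q1/Q3, with points beyond listed as
outliers.

## Synthetic data generator

Each sample is a sum of Gaussian absorbance bands A(ν) = Σₚ (dₚ + sₚ·DS)
exp(−(ν−cₚ)²/2wₚ²) plus a per-sample random cubic baseline (scaled to
`baseline_amplitude`, default 0.01 absorbance) and i.i.d. Gaussian noise
(`noise_sd`, default 0.002 absorbance), converted to transmittance via
T = 10^(−A).  Defaults: a 400–4000 cm⁻¹ grid with 1750 points (the feature
count of the real instrument data the method was developed on) and DS drawn
uniformly from [0.41, 2.96], the range of the 16-sample cellulose acetate
reference series; this also keeps reference DS strictly positive, so MRE is
always defined.  One `SeedSequence` per dataset spawns per-sample
substreams, so datasets are bit-reproducible from a single integer.

The default band set mimics acetylation chemistry: C=O (1740 cm⁻¹), acetyl
C–H bending (1375), ester C–O (1230) and aliphatic C–H stretch (2900) grow
with DS; the broad O–H stretch (3400) shrinks; pyranose-ring skeletal bands
(1040, 900, 600) are DS-independent.  Two deliberate choices deserve note:

- **Beer–Lambert nonlinearity.**  The 10^(−A) map keeps DS → spectrum only
  approximately linear, so the regression faces realistic mild nonlinearity
  rather than data rigged to its own model class.
- **DS-independent normalization anchors.**  The 1040 cm⁻¹ band is the
  deepest band at every DS (as in real cellulose acetate spectra, where it
  dominates the series throughout), and the absorption-free window supplies
  the row maximum.  Min-max normalization divides by (max − min); when
  either anchor moved with DS the normalization itself would inject a
  rational nonlinearity that no linear model can remove, and the noiseless
  held-out error would plateau near 2.5·10⁻⁴ DS units.  With fixed anchors
  the normalized features are exponentials in DS, the linear model
  calibrates them essentially exactly, and the noiseless pipeline recovers
  held-out DS to ~10⁻¹⁴ — which is what the parameter-recovery test
  asserts (< 10⁻⁶).

The ground-truth "informative" wavenumbers are those where the DS
sensitivity |dA/dDS| = Σₚ|sₚ|·gaussianₚ(ν) reaches a threshold; the
principled default threshold is the **noise floor** `noise_sd / sd(DS)`
(signal across the sampled DS spread exceeds one noise standard deviation),
exposed as `noise_floor_threshold`.

What the generator does *not* emulate: Lorentzian/Voigt line shapes, ATR
penetration-depth (wavelength-dependent intensity) effects, instrument line
shape, water-vapour/CO₂ artefacts, ester-type variation, or any
instrument-to-instrument transfer.  A green synthetic test therefore
establishes that the pipeline machinery is correct and that the method works
under its own assumptions — not that a specific real-world accuracy will be
reached; synthetic error numbers are not comparable to published values on
instrument data.

## Numerical and interface conventions

- Spectra are canonicalized to strictly increasing wavenumbers; files
  stored descending are reversed and the original orientation recorded.
- Dataset alignment interpolates linearly onto the grid of the first
  manifest entry and refuses to extrapolate (explicit error instead).
- Model JSON round-trips weights bit-exactly (full-precision decimal
  serialization).
- Prediction accepts either the model's full training grid (restricting to
  the selected columns internally) or the already-restricted grid; grids
  must match to 1e-9 relative.
- `min_max_normalize` is idempotent: an already-normalized set is returned
  unchanged rather than raising.

## Known limitations

- Per-fold feature selection at very small S is itself noisy: at high noise
  levels (noise_sd ≳ 0.02 absorbance at S = 16) the selected sets become
  unstable across folds and selection can *increase* the cross-validated
  error relative to the full spectrum.  The overfitting-reduction benefit is
  a regime, not a law.
- The JCAMP-DX reader supports AFFN-encoded `XYDATA=(X++(Y..Y))` and
  `XYPOINTS` blocks only; compressed ASDF forms (SQZ/DIF/DUP) are rejected
  with a parse error rather than being silently misread.
- No stratified or grouped folds; extreme random splits (e.g. training only
  on low DS) are part of the reported CV spread by design.
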