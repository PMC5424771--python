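# Methods

## The problem

Resting-state functional connectivity between two hemodynamic channels
(fNIRS, and equally fMRI) is conventionally summarized by the Pearson
correlation of the two time courses and a p-value computed as if the
samples were independent. Two properties of real optical brain recordings
break both numbers:

1. **Serial correlation.** The vascular impulse response is slow (~8-12 s),
   so a channel sampled at ≥0.1 Hz is strongly autocorrelated. Two
   *independent* channels filtered through the same kind of slow response
   then show large spurious correlations (the Granger-Newbold effect): the
   nominal n samples carry far fewer effective degrees of freedom than n.
2. **Motion artifacts.** Probe movement produces transient, heavy-tailed
   noise roughly an order of magnitude larger than the signal, often at the
   same instants in many channels. A handful of shared spikes has enormous
   leverage on a product-moment correlation and can push an estimate from
   0.5 to 0.9 — or dilute it when the artifacts are unshared.

The package implements the two corresponding corrections — autoregressive
prewhitening and robust bivariate preweighted regression — and a wavelet
(frequency-domain) analogue, together with the Monte-Carlo harness that
quantifies false-discovery rates (FDR), ROC performance, and p-value
calibration of each estimator.

## Estimators

All pairwise estimators are exposed through `PairCorrelation(a, b,
method=...)` whose `fit()` returns a `CorrelationResult`:

- **COR** — Pearson correlation, p from the t transform with dof = n − 2.
- **LPF-COR** — zero-phase 4th-order Butterworth low-pass (default
  0.1 Hz) on both channels, then COR. Included because band-limiting is
  the traditional preprocessing; it does not fix the dof problem.
- **AR-COR** — each channel is fitted with an AR(P) model, P chosen by
  BIC over 0..max_order, and the Pearson correlation is computed between
  the innovations, with dof = (innovations length) − 2.
- **W-COR** — robust bidirectional regression with joint bivariate
  preweighting on the raw channels.
- **AR-W-COR** — the full procedure: prewhiten, preweight, robust
  bidirectional regression.

### AR prewhitening

The AR model `y_t = Σ a_i y_{t−i} + e_t` is estimated by conditional least
squares on the lagged design matrix after mean-centering (no intercept).
Nested residual sums for all candidate orders come from one thin QR
factorization of the max-order design, all candidates scored on the common
rows `t > max_order` so BIC values are comparable; the winner
(`BIC = n ln(RSS/n) + P ln n`) is refit on its own rows, so the innovations
have length n − P (the first P samples are conditioned on, not
zero-padded — padding would itself create startup outliers). Each channel
of a pair gets its own order; the two innovations series are aligned at
their final samples and trimmed to the common length.

`max_order` defaults to `min(ceil(10·fs), 40)`: the autocorrelation
induced by the hemodynamic response spans a roughly fixed ~10-s window, so
the order needed scales with the sample rate; the cap keeps the design
well-conditioned and the fit affordable. At 4-5 Hz, BIC typically selects
orders 10-20. Above ~4 Hz the truncation leaves a small residual serial
correlation (the innovations' Bartlett variance-inflation factor is ~1.07
at 4 Hz), which is why the prewhitened null FDR sits near 5-7% rather than
exactly 5% there.

### Robust bivariate preweighting

After whitening, motion artifacts survive as isolated outliers,
co-occurring across channels. The joint magnitude `r_t = sqrt(a_t² + b_t²)`
is studentized against the bulk, `u_t = (r_t − median r) / σ` with
`σ = 1.4826·MAD(r)`, and weighted by the square root of Tukey's bisquare,

    S(u) = 1 − (u/κ)²  for |u| < κ,  else 0,     κ = 4.685.

Centering at the median matters: the magnitude r_t is strictly positive
with a nonzero typical value, so standardizing without centering would put
the entire clean bulk near u ≈ 1.8 and shrink genuine correlations
severely. The weights are computed once (non-iteratively) and held fixed.

**Known bias.** Even centered, a smooth redescending weight of the *joint*
magnitude shrinks genuine correlation, because the largest joint
magnitudes carry a disproportionate share of the covariance: at ρ = 0.5
the population value of the preweighted estimator is ≈ 0.44 (measured by
direct large-sample evaluation; the residual-only robust fit is unbiased).
Under the null there is nothing to shrink, so false-discovery control and
calibration are unaffected; users comparing effect sizes across estimators
should be aware of the ~10% attenuation at moderate correlations.

### Bidirectional robust regression

Correlation is expressed through regression: regressing B on A gives a
slope whose product with σ_A/σ_B (MAD-based scales) estimates R_{A→B}, and
conversely. Each direction is solved by iteratively reweighted least
squares: residuals are standardized by `1.4826·MAD`, converted to
square-root-bisquare weights, multiplied by the fixed preweights, and the
weighted fit (weights applied to both sides of the design) is repeated
until the maximum relative coefficient change falls below 1e−6 (cap 50
iterations, flagged if hit). The combined magnitude is
`|R| = sqrt(R_{A→B} · R_{B→A})` — algebraically equal to |Pearson r| when
all weights are one. If the two directions disagree in sign (which happens
only when the correlation is indistinguishable from zero), the sign of the
direction with the larger |t| is used and the result flagged.

### p-values for the robust estimators

The effective degrees of freedom of a *weighted* correlation are not
`Σw − 2`: downweighting large-magnitude samples suppresses exactly the
high-variance cross products, so the null variance of the weighted
statistic is *smaller* than 1/n (empirically dof ≈ 1.5·n at n = 3000).
Two inference routes are used:

- **W-COR (plug-in):** `V = Σ q² x² y² / (Σ q x² · Σ q y²)` with q the
  squared combined weights; dof = 1/V and the usual t transform. This is
  empirically exact for the preweighted statistic, and deliberately makes
  no correction for serial correlation — on colored (unwhitened) data
  W-COR's p-values inflate the FDR just as the naive test does, which is
  the behaviour the FDR experiments are designed to expose.
- **AR-W-COR (blockwise sign-flip null, default):** the full estimator is
  re-run on 99 seeded wild/Rademacher replicas in which one innovations
  channel is multiplied by random ±1 signs, constant within blocks whose
  length equals the mean selected AR order, and `p = (k+1)/(N+1)` ranks
  the observed magnitude among the replicas. Sign-flipping preserves both
  channels' variance profiles *and their alignment in time* — exactly the
  structure a motion-contaminated null carries, since HRF-smeared
  artifacts leave co-occurring variance bursts that the preweight cannot
  fully zero — while destroying any cross-channel correlation; it is
  distribution-preserving for symmetric, cross-channel-independent
  innovations with any heteroscedasticity pattern. The blocks preserve the
  short-range serial structure of the deconvolution residue (the whitening
  filter's memory). Alternatives were evaluated and rejected on measured
  null calibration: full permutation and circular shifts destroy the
  artifact-time alignment and reject 9-12% of null pairs at α = 0.05
  under the standard motion model, and a studentized shift statistic is
  worse still; the block sign-flip null rejects 6-7% with motion and 3-6%
  without, with p-values passing Kolmogorov-Smirnov uniformity. It also
  automatically absorbs the extra slope variance the IRLS loops add
  (~25% beyond the conditional-on-weights formula, which is what makes
  the plug-in alone anti-conservative here). The replicas are computed by
  a vectorized closed-form IRLS (`batch_robust_magnitude`), verified
  against the scalar pipeline to machine precision.

A consequence adopted deliberately: reported `dof` can exceed n − 2.

## Wavelet coherence

`WaveletCoherence(a, b, prewhiten=...)` computes Morlet (ω₀ = 6) squared
coherence

    R²_n(s) = |S(W^AB/s)|² / ( S(|W^A|²/s) · S(|W^B|²/s) )

with the cross-spectrum `W^AB = W^A conj(W^B)`. The CWT is computed by
frequency-domain convolution with zero padding to the next power of two;
scales run dyadically from s₀ = 2/fs at 12 voices per octave up to the
record length. Smoothing follows the standard toolbox convention: in time,
a unit-mass Gaussian of SD equal to the scale (applied cyclically via
FFT); across scale, a normalized boxcar spanning 0.6 octaves. The 1/s
normalization sits inside the smoothing operators. Without smoothing the
ratio is identically 1; with it, coherence is bounded in [0, 1] by
Cauchy-Schwarz. The cone of influence uses the Morlet e-folding time
`sqrt(2)·s`; summary statistics exclude points inside it.

The scalar statistic (mean squared coherence outside the cone) and its
surrogate p-value are this package's construction: surrogates are
independent pairs with matched spectra — AR-matched (order ≤ 20) for raw
inputs, white with matched variance for prewhitened inputs — and
`p = (k+1)/(N+1)`. For ROC experiments the statistic itself is the
decision variable; a monotone p-transform would give the identical curve
at a fraction of the cost.

## Synthetic data and experiments

`simulate_neural_pair` draws bivariate standard-normal "neural" pairs with
correlation ρ; `canonical_hrf` builds the double-gamma hemodynamic kernel
(positive lobe peaking at 6 s, undershoot peaking at 16 s with ratio 1/6,
32-s support, peak-normalized); `hemodynamic_convolve` applies it causally
and truncates to the input length. `inject_motion` adds zero-mean Gaussian
noise with variance `var_scale ×` the channel's base variance to
`round(fraction·n)` samples — defaults 5% of samples at 10× variance, the
same time points in both channels but independent values (switches expose
the unshared-times and identical-values variants). Motion is injected into
the neural signal *before* convolution, mirroring how subject movement
precedes the optical measurement chain.

What the generator emulates: the two noise properties of real school-age
pediatric recordings that matter for inference — serially correlated
(colored) noise and heavy-tailed co-occurring outliers. What it does not:
cardiac/respiratory oscillations, global superficial (scalp) physiology
shared across channels, slow drifts, or spatially structured artifact
topographies. Passing these tests therefore demonstrates control of
serial-correlation and outlier-driven false discovery, not removal of
global systemic confounds, which require separate preprocessing (e.g.
short-separation regression).

`run_fdr_experiment` sweeps sample rates (default grid 0.1-4 Hz; the
kernel needs ≥2 taps, i.e. fs ≥ 1/16 Hz, and AR orders above 40 — needed
beyond ~4-10 Hz — are out of budget by design), generating `n_reps`
(default 2000) null pairs per rate, and reports the fraction of p-values
below α = 0.05 with binomial standard errors. Per-replicate seeds derive
deterministically from the master seed via `SeedSequence([seed, fs_index,
rep])`, so every estimator sees identical data within a replicate and the
whole report is bit-reproducible. `run_roc_experiment` generates half
correlated, half null pairs at 4 Hz, sweeps each estimator's decision
score into an ROC curve (trapezoidal AUC), and builds calibration curves
(empirical null rejection rate vs nominal level) from the null half for
the estimators with closed-form p-values.

The ROC positive-class correlation defaults to ρ = 0.15 in the
experiments' CLI. At n = 3000 and 4 Hz the naive null sd of r is ≈ 0.09,
so ρ = 0.5 separates the classes completely (every AUC = 1.0) and nothing
can be compared; ρ = 0.15 places the problem in the informative regime
where prewhitening visibly improves the AUC (naive ≈ 0.75-0.8 vs ≈ 1.0
prewhitened, a ~20-25% reduction for the unwhitened estimator).

## Numerical choices and degenerate inputs

- Zero MAD anywhere (constant signals, perfect fits) falls back to unit
  weights with a warning rather than failing; residual scales below
  1e−10 of the data scale are treated as exact fits.
- BIC candidates with numerically zero RSS are floored at 1e−12 of the
  total sum of squares.
- Coherence values are clipped to [0, 1] (they exceed 1 only by
  floating-point noise ≤ 1e−9).
- `|R|` is clipped to 1; `correlation_pvalue(±1) = 0`.
- Sample rates must match exactly between paired channels; no resampling
  is attempted.

## Problem sizes used in validation

The validation suite runs the study conditions at sizes chosen to keep
Monte-Carlo error meaningfully below the acceptance bands: 2000 replicates
for the naive-FDR quantities (binomial SE ≈ 1.1 points at 50%), 1000 for
the prewhitened FDR (SE ≈ 0.7 points), 500 for the motion, calibration and
ROC experiments, with n = 3000 samples per channel throughout.

## Known limitations

- The preweighted estimators shrink genuine correlations by ~10% at
  ρ ≈ 0.5 (see above); no Fisher-consistency correction is applied.
- Above ~4 Hz the capped AR order leaves mild FDR inflation (6-8%); a
  higher cap restores calibration at rapidly growing cost.
- Permutation p-values are discrete at resolution 1/(N+1) (default 0.01).
- The wavelet surrogate test assumes the AR fit captures the null
  spectrum; strongly nonstationary inputs violate this.
- Granger-style lagged cross-terms, partial correlations, and >2-channel
  joint models are out of scope.
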