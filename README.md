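# robustfc

Robust, autoregressively prewhitened connectivity estimators for slow
hemodynamic time series (fNIRS resting-state recordings and similar),
with a Monte-Carlo harness that measures the false-discovery rates, ROC
performance and p-value calibration of each estimator.

## Why

Resting-state functional connectivity is usually the Pearson correlation
between two channels with a p-value that assumes independent samples.
Hemodynamic signals violate that assumption twice over:

- the vascular response is slow (~8-12 s), so samples are strongly
  serially correlated — two *independent* channels show large spurious
  correlations, and the naive test rejects on roughly half of truly null
  pairs at typical sample rates;
- motion artifacts are heavy-tailed outliers an order of magnitude larger
  than the signal, often shared across channels, with enough leverage to
  push a correlation of 0.5 up to 0.9 or dilute it toward 0.

The remedy implemented here: fit each channel with an autoregressive model
(order chosen by BIC, up to `min(10·fs, 40)`), carry the analysis out on
the whitened innovations, downweight co-occurring outliers with a
square-root Tukey bisquare weight of the studentized joint magnitude
`r_t = sqrt(A_t² + B_t²)` (κ = 4.685, scale 1.4826·MAD), and estimate
correlation through bidirectional iteratively-reweighted regression,

    R_{A→B} = slope(B~A)·σ_A/σ_B,   |R| = sqrt(R_{A→B}·R_{B→A}),

which reduces exactly to |Pearson r| when all weights are one. A Morlet
wavelet-coherence estimator (with the same prewhitening option) covers the
frequency-resolved analogue.

## Worked example

Two simulated channels with true correlation 0.5, HRF-convolved at 1 Hz,
with shared 10x-variance motion artifacts on 5% of samples:

```python
from robustfc import (PairCorrelation, canonical_hrf, hemodynamic_convolve,
                      inject_motion, simulate_neural_pair)

a, b = simulate_neural_pair(3000, 0.5, seed=7, fs=1.0)
hrf = canonical_hrf(1.0)
a, b = hemodynamic_convolve(a, hrf), hemodynamic_convolve(b, hrf)
a, b = inject_motion((a, b), 0.05, 10.0, shared_times=True,
                     identical_values=True, seed=8)

print(PairCorrelation(a, b, method="COR").fit().summary())
print(PairCorrelation(a, b, method="AR-W-COR", seed=1).fit().summary())
```

```
Pair correlation (COR)
========================================
channels        : A ~ B
r               :  0.6825
R(A->B), R(B->A):  0.6825,  0.6825
effective dof   : 2998.0
p-value         : 0
samples used    : 3000

Pair correlation (AR-W-COR)
========================================
channels        : A ~ B
r               :  0.5457
R(A->B), R(B->A):  0.5460,  0.5454
effective dof   : 2414.3
p-value         : 0.01
samples used    : 2987
```

The shared artifacts inflate the naive estimate from 0.5 to 0.68 (with a
meaningless p-value computed on 2998 "independent" samples); the robust
prewhitened estimator stays near the true value and reports a permutation
p-value computed on exchangeable innovations. Note also the naive
estimator's false-discovery behaviour on *null* data: at 1 Hz roughly 40%
of independent HRF-convolved pairs come out "significant" at p < 0.05.

The same estimators run from the shell on a delimited channel table, and
the validation experiments are scriptable:

```sh
robustfc connectivity channels.csv --fs 4 --method AR-W-COR --fdr-correct --out results/
robustfc simulate-fdr --fs-grid 0.1,1,4 --estimators COR,AR-COR --n-reps 500 --seed 1 --out fdr/
robustfc simulate-roc --rho 0.15 --n-reps 500 --seed 1 --out roc/
```

## Library layout

| module | contents |
| --- | --- |
| `robustfc.prewhiten` | AR fitting, BIC order selection, innovations filtering |
| `robustfc.robust` | MAD scale, bisquare weights, joint preweighting, IRLS |
| `robustfc.correlation` | `PairCorrelation` model, the five estimators, p-values |
| `robustfc.coherence` | `WaveletCoherence` model, Morlet CWT, smoothing, surrogates |
| `robustfc.simulate` | synthetic generator, FDR / ROC / calibration experiments |
| `robustfc.io`, `robustfc.cli` | tables, connectivity matrices, command line |

See `docs/methods.md` for the statistical details, parameter defaults and
known limitations.

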