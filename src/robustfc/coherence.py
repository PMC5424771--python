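"""Morlet wavelet squared coherence with time/scale smoothing, and its
AR-prewhitened variant.

Coherence is the scale-resolved analogue of squared correlation:

    R_n^2(s) = |S(W_n^AB(s)/s)|^2 / ( S(|W_n^A(s)|^2/s) * S(|W_n^B(s)|^2/s) )

where W^A, W^B are continuous Morlet wavelet transforms, W^AB = W^A conj(W^B)
is the cross-spectrum, and S is smoothing in time (Gaussian of standard
deviation equal to the scale) followed by smoothing across scale (boxcar of
0.6 octaves).  Without smoothing the ratio is identically 1; the smoothing
windows set the effective number of independent cross-spectral estimates.

Like plain correlation, coherence between two slow hemodynamic signals is
biased by shared spectral coloring; prewhitening both channels with their
fitted AR models before the transform removes that coloring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import lfilter

from .prewhiten import fit_ar, max_order_bound, prewhiten_pair
from .timeseries import TimeSeries

__all__ = [
    "CoherenceMap",
    "CoherenceResult",
    "WaveletCoherence",
    "morlet_scales",
    "morlet_cwt",
    "smooth_wavelet",
    "wavelet_coherence",
    "ar_wavelet_coherence",
    "coherence_statistic",
]

#: Morlet center frequency (non-dimensional); 6 balances time/frequency
#: localization and makes scale ~ Fourier period.
OMEGA0 = 6.0
#: Voices per octave.
DJ = 1.0 / 12.0
#: Scale-smoothing decorrelation length in octaves.
SCALE_DECORRELATION = 0.6
#: Fourier period per unit scale for the Morlet at omega0 = 6.
FOURIER_FACTOR = 4.0 * np.pi / (OMEGA0 + np.sqrt(2.0 + OMEGA0**2))
#: e-folding time of the Morlet envelope, in units of scale.
EFOLD = np.sqrt(2.0)


@dataclass(frozen=True)
class CoherenceMap:
    """Smoothed wavelet squared coherence over time x scale.

    Attributes
    ----------
    coherence : ndarray, shape (n_times, n_scales)
        Squared coherence in [0, 1].
    scales : ndarray
        Wavelet scales in seconds, strictly increasing.
    freqs : ndarray
        Equivalent Fourier frequencies in Hz.
    coi : ndarray, shape (n_times,)
        Cone-of-influence boundary: the largest scale unaffected by edge
        effects at each time point.
    cross_spectrum : ndarray, shape (n_times, n_scales), complex
        Smoothed cross-spectrum S(W^AB / s).
    fs : float
        Sampling rate of the inputs in Hz.
    """

    coherence: np.ndarray
    scales: np.ndarray
    freqs: np.ndarray
    coi: np.ndarray
    cross_spectrum: np.ndarray
    fs: float
    whitened: bool = False
    inputs: tuple | None = None

    def outside_coi(self) -> np.ndarray:
        """Boolean mask (n_times, n_scales) of points outside the cone."""
        return self.scales[None, :] <= self.coi[:, None]


@dataclass(frozen=True)
class CoherenceResult:
    """Scalar coherence summary with a surrogate Monte-Carlo p-value."""

    statistic: float
    pvalue: float
    n_surrogates: int
    map: CoherenceMap

    def summary(self) -> str:
        return (
            "Wavelet coherence"
            + (" (AR-prewhitened)" if self.map.whitened else "")
            + "\n"
            + "=" * 40
            + f"\nmean squared coherence : {self.statistic:.4f}"
            + f"\nsurrogate p-value      : {self.pvalue:.4f} "
            + f"({self.n_surrogates} surrogates)"
        )


def morlet_scales(n: int, fs: float) -> np.ndarray:
    """Dyadic scale grid: s0 = 2/fs up to the record length, 12 voices/octave."""
    dt = 1.0 / fs
    s0 = 2.0 * dt
    max_scale = n * dt / FOURIER_FACTOR  # period <= record length
    if max_scale < s0:
        raise ValueError("record too short for any resolvable scale")
    j = int(np.floor(np.log2(max_scale / s0) / DJ))
    return s0 * 2.0 ** (DJ * np.arange(j + 1))


def morlet_cwt(y: TimeSeries, scales: np.ndarray) -> np.ndarray:
    """Continuous wavelet transform with the analytic Morlet mother wavelet.

    Computed by frequency-domain convolution with zero padding to the next
    power of two.  Returns complex coefficients of shape (n_scales, n).
    Scales whose Fourier period exceeds the record length are rejected.
    """
    x = y.values - y.values.mean()
    n = x.size
    if n < 32:
        raise ValueError("need at least 32 samples for the wavelet transform")
    dt = 1.0 / y.fs
    scales = np.asarray(scales, dtype=float)
    bad = scales * FOURIER_FACTOR > n * dt
    if np.any(bad):
        raise ValueError(
            f"{bad.sum()} scale(s) exceed the record length; largest usable "
            f"scale is {n * dt / FOURIER_FACTOR:.3g} s"
        )
    npad = int(2 ** np.ceil(np.log2(2 * n)))
    xhat = np.fft.fft(x, npad)
    omega = 2.0 * np.pi * np.fft.fftfreq(npad, d=dt)
    heaviside = omega > 0
    out = np.empty((scales.size, n), dtype=complex)
    norm = np.pi**-0.25 * np.sqrt(2.0 * np.pi / dt)
    for i, s in enumerate(scales):
        psi_hat = np.zeros(npad)
        psi_hat[heaviside] = (
            norm * np.sqrt(s) * np.exp(-0.5 * (s * omega[heaviside] - OMEGA0) ** 2)
        )
        out[i] = np.fft.ifft(xhat * psi_hat)[:n]
    return out


def smooth_wavelet(w: np.ndarray, scales: np.ndarray, fs: float) -> np.ndarray:
    """Time then scale smoothing of a wavelet matrix (n_scales, n).

    Time smoothing convolves each scale row with a unit-mass Gaussian of
    standard deviation equal to that scale (cyclic, via FFT); scale
    smoothing is a normalized boxcar spanning 0.6 octaves.
    """
    w = np.asarray(w)
    scales = np.asarray(scales, dtype=float)
    if w.shape[0] != scales.size:
        raise ValueError("matrix rows must match the number of scales")
    n = w.shape[1]
    dt = 1.0 / fs
    omega = 2.0 * np.pi * np.fft.fftfreq(n, d=dt)
    what = np.fft.fft(w, axis=1)
    # Gaussian in time of SD = s  <=>  multiply spectrum by exp(-s^2 w^2 / 2)
    gain = np.exp(-0.5 * (scales[:, None] * omega[None, :]) ** 2)
    out = np.fft.ifft(what * gain, axis=1)
    if not np.iscomplexobj(w):
        out = out.real
    width = max(1, int(round(SCALE_DECORRELATION / DJ)))
    return uniform_filter1d(out, size=width, axis=0, mode="nearest")


def _coherence_from_transforms(
    wa: np.ndarray, wb: np.ndarray, scales: np.ndarray, n: int, fs: float,
    whitened: bool, inputs: tuple,
) -> CoherenceMap:
    inv_s = 1.0 / scales[:, None]
    sa = smooth_wavelet(np.abs(wa) ** 2 * inv_s, scales, fs)
    sb = smooth_wavelet(np.abs(wb) ** 2 * inv_s, scales, fs)
    sab = smooth_wavelet(wa * np.conj(wb) * inv_s, scales, fs)
    denom = sa * sb
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.abs(sab) ** 2 / denom
    coh[~np.isfinite(coh)] = 0.0
    coh = np.clip(coh, 0.0, 1.0)
    dt = 1.0 / fs
    dist = np.minimum(np.arange(n), np.arange(n)[::-1])
    coi = dist * dt / EFOLD
    freqs = 1.0 / (FOURIER_FACTOR * scales)
    return CoherenceMap(
        coherence=coh.T, scales=scales, freqs=freqs, coi=coi,
        cross_spectrum=sab.T, fs=fs, whitened=whitened, inputs=inputs,
    )


def wavelet_coherence(
    a: TimeSeries, b: TimeSeries, scales: np.ndarray | None = None
) -> CoherenceMap:
    """Smoothed Morlet wavelet squared coherence between two channels."""
    if len(a) != len(b):
        raise ValueError("channels must have equal length")
    if a.fs != b.fs:
        raise ValueError("channels must share a sampling rate")
    if np.ptp(a.values) == 0 or np.ptp(b.values) == 0:
        raise ValueError("constant channel has no wavelet spectrum")
    if scales is None:
        scales = morlet_scales(len(a), a.fs)
    wa = morlet_cwt(a, scales)
    wb = morlet_cwt(b, scales)
    return _coherence_from_transforms(
        wa, wb, np.asarray(scales, float), len(a), a.fs, False, (a, b)
    )


def ar_wavelet_coherence(
    a: TimeSeries, b: TimeSeries, max_order: int | None = None
) -> CoherenceMap:
    """Wavelet coherence between AR-prewhitened innovations of both channels."""
    aw, bw = prewhiten_pair(a, b, max_order)
    m = wavelet_coherence(aw, bw)
    return CoherenceMap(
        coherence=m.coherence, scales=m.scales, freqs=m.freqs, coi=m.coi,
        cross_spectrum=m.cross_spectrum, fs=m.fs, whitened=True,
        inputs=(aw, bw),
    )


def _ar_surrogate(ts: TimeSeries, rng: np.random.Generator,
                  model=None) -> TimeSeries:
    """Series with the same AR spectrum as ``ts`` but fresh Gaussian innovations."""
    n = len(ts)
    if model is None or model.order == 0:
        std = ts.values.std()
        return ts.with_values(rng.standard_normal(n) * (std if std > 0 else 1.0))
    burn = 5 * model.order
    noise = rng.standard_normal(n + burn) * np.sqrt(model.noise_variance)
    sim = lfilter([1.0], np.concatenate([[1.0], -model.coeffs]), noise)
    return ts.with_values(sim[burn:])


def coherence_statistic(
    map: CoherenceMap, n_surrogates: int = 99, seed: int | None = None
) -> CoherenceResult:
    """Scalar coherence summary with a surrogate-based p-value.

    The statistic is the mean squared coherence over all time-scale points
    outside the cone of influence.  Its null distribution is estimated from
    ``n_surrogates`` independent surrogate pairs with matched spectra:
    AR-matched surrogates for raw inputs, white surrogates when the map was
    built from prewhitened innovations.  p = (k + 1) / (N + 1) where k
    surrogate statistics meet or exceed the observed one.
    """
    if n_surrogates < 19:
        raise ValueError("need at least 19 surrogates for a p-value")
    if map.inputs is None:
        raise ValueError("map does not carry its input series")
    mask = map.outside_coi()
    if not mask.any():
        raise ValueError("all time-scale points lie inside the cone of influence")
    observed = float(map.coherence[mask].mean())

    a, b = map.inputs
    rng = np.random.default_rng(seed)
    if map.whitened:
        model_a = model_b = None
    else:
        cap = min(max_order_bound(a.fs), 20)
        cap = min(cap, (len(a) - 1) // 3)
        model_a = fit_ar(a, cap)
        model_b = fit_ar(b, cap)
    count = 0
    for _ in range(n_surrogates):
        sa = _ar_surrogate(a, rng, model_a)
        sb = _ar_surrogate(b, rng, model_b)
        m = wavelet_coherence(sa, sb, scales=map.scales)
        if float(m.coherence[mask].mean()) >= observed:
            count += 1
    pvalue = (count + 1) / (n_surrogates + 1)
    return CoherenceResult(observed, pvalue, n_surrogates, map)


class WaveletCoherence:
    """Wavelet-coherence model for one channel pair (statsmodels-style).

    Parameters
    ----------
    a, b : TimeSeries
    prewhiten : bool
        Whiten each channel with its BIC-selected AR model before the
        transform (the AR-wCOH estimator).
    max_order : int, optional
        AR order cap when prewhitening.
    """

    def __init__(self, a: TimeSeries, b: TimeSeries, prewhiten: bool = False,
                 max_order: int | None = None):
        self.a = a
        self.b = b
        self.prewhiten = prewhiten
        self.max_order = max_order

    def fit(self) -> CoherenceMap:
        if self.prewhiten:
            return ar_wavelet_coherence(self.a, self.b, self.max_order)
        return wavelet_coherence(self.a, self.b)

    def test(self, n_surrogates: int = 99, seed: int | None = None) -> CoherenceResult:
        """Fit and test the mean coherence against matched surrogates."""
        return coherence_statistic(self.fit(), n_surrogates, seed)
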