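import numpy as np
import pytest
from scipy import stats

from robustfc import (
    TimeSeries,
    WaveletCoherence,
    ar_wavelet_coherence,
    coherence_statistic,
    wavelet_coherence,
)
from robustfc.coherence import FOURIER_FACTOR, morlet_cwt, morlet_scales, smooth_wavelet

from conftest import child_seed


@pytest.fixture
def scales():
    return morlet_scales(1024, 4.0)


class TestMorletCwt:
    def test_zero_signal_zero_coefficients(self, scales):
        y = TimeSeries(np.zeros(1024), 4.0)
        # zero signal is constant, bypass the variance check via direct cwt
        w = morlet_cwt(y, scales)
        assert np.allclose(w, 0.0)

    def test_sinusoid_localized_at_matching_scale(self, scales):
        fs, f0 = 4.0, 0.25
        t = np.arange(1024) / fs
        y = TimeSeries(np.sin(2 * np.pi * f0 * t), fs)
        w = morlet_cwt(y, scales)
        power = (np.abs(w) ** 2).mean(axis=1)
        f_peak = 1.0 / (FOURIER_FACTOR * scales[np.argmax(power)])
        # within one voice (12 voices/octave)
        assert abs(np.log2(f_peak / f0)) < 1.0 / 12 + 1e-9

    def test_linearity(self, rng, scales):
        fs = 4.0
        a = TimeSeries(rng.standard_normal(1024), fs)
        b = TimeSeries(rng.standard_normal(1024), fs)
        ab = TimeSeries(a.values + b.values, fs)
        w = morlet_cwt(ab, scales)
        assert np.allclose(w, morlet_cwt(a, scales) + morlet_cwt(b, scales), atol=1e-9)

    def test_overlong_scale_rejected(self, rng):
        y = TimeSeries(rng.standard_normal(128), 4.0)
        with pytest.raises(ValueError, match="scale"):
            morlet_cwt(y, np.array([1000.0]))


class TestSmoothing:
    def test_constant_matrix_preserved(self, scales):
        m = np.full((scales.size, 256), 3.7)
        out = smooth_wavelet(m, scales, 4.0)
        assert out == pytest.approx(m, rel=1e-9)

    def test_impulse_mass_preserved(self, scales):
        m = np.zeros((scales.size, 256))
        m[:, 128] = 1.0
        out = smooth_wavelet(m, scales, 4.0)
        assert out.sum(axis=1) == pytest.approx(np.ones(scales.size), rel=0.01)

    def test_nonnegativity_preserved(self, rng, scales):
        m = rng.random((scales.size, 256))
        assert np.all(smooth_wavelet(m, scales, 4.0) >= -1e-12)


class TestWaveletCoherence:
    def test_self_coherence_is_one(self, rng):
        a = TimeSeries(rng.standard_normal(512), 4.0)
        m = wavelet_coherence(a, a)
        assert m.coherence == pytest.approx(np.ones_like(m.coherence), abs=1e-9)

    def test_bounded_and_symmetric(self, rng):
        a = TimeSeries(rng.standard_normal(512), 4.0)
        b = TimeSeries(rng.standard_normal(512), 4.0)
        m1 = wavelet_coherence(a, b)
        assert np.all(m1.coherence >= 0) and np.all(m1.coherence <= 1)
        m2 = wavelet_coherence(b, a)
        assert m1.coherence == pytest.approx(m2.coherence, abs=1e-9)

    def test_scales_increasing_with_frequencies(self, rng):
        a = TimeSeries(rng.standard_normal(512), 4.0)
        m = wavelet_coherence(a, a)
        assert np.all(np.diff(m.scales) > 0)
        assert np.all(np.diff(m.freqs) < 0)

    def test_shared_band_limited_signal_detected(self):
        """Coherence concentrates at the scale of a shared sinusoid."""
        fs, f0, n = 4.0, 0.25, 1024
        t = np.arange(n) / fs
        hits = 0
        n_reps = 20
        for rep in range(n_reps):
            rng = np.random.default_rng(child_seed(31, rep))
            sig = np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
            a = TimeSeries(sig + rng.standard_normal(n), fs)
            b = TimeSeries(sig + rng.standard_normal(n), fs)
            m = wavelet_coherence(a, b)
            at = np.argmin(np.abs(m.freqs - f0))
            away = np.argmin(np.abs(m.freqs - f0 / 4))  # two octaves off
            mask = m.outside_coi()
            c_at = m.coherence[mask[:, at], at].mean()
            c_away = m.coherence[mask[:, away], away].mean()
            hits += c_at > c_away
        assert hits >= 0.9 * n_reps

    def test_constant_channel_rejected(self, rng):
        a = TimeSeries(np.ones(512), 4.0)
        b = TimeSeries(rng.standard_normal(512), 4.0)
        with pytest.raises(ValueError):
            wavelet_coherence(a, b)


class TestArWaveletCoherence:
    def test_identical_inputs_full_coherence(self, rng):
        a = TimeSeries(rng.standard_normal(600), 4.0)
        m = ar_wavelet_coherence(a, a)
        assert m.coherence == pytest.approx(np.ones_like(m.coherence), abs=1e-9)
        assert m.whitened

    def test_near_identity_on_white_inputs(self, rng):
        """Whitening is a near-no-op on white noise, so whitened and raw
        coherence statistics agree within Monte-Carlo error."""
        d = []
        for rep in range(10):
            r = np.random.default_rng(child_seed(37, rep))
            a = TimeSeries(r.standard_normal(512), 4.0)
            b = TimeSeries(r.standard_normal(512), 4.0)
            m_raw = wavelet_coherence(a, b)
            m_w = ar_wavelet_coherence(a, b)
            s_raw = m_raw.coherence[m_raw.outside_coi()].mean()
            s_w = m_w.coherence[m_w.outside_coi()].mean()
            d.append(s_w - s_raw)
        assert abs(np.mean(d)) < 0.02


class TestCoherenceStatistic:
    def test_identical_inputs_minimal_pvalue(self, rng):
        a = TimeSeries(rng.standard_normal(400), 4.0)
        res = coherence_statistic(wavelet_coherence(a, a), n_surrogates=19, seed=0)
        assert res.statistic == pytest.approx(1.0, abs=1e-9)
        assert res.pvalue == pytest.approx(1 / 20)

    def test_too_few_surrogates_rejected(self, rng):
        a = TimeSeries(rng.standard_normal(400), 4.0)
        with pytest.raises(ValueError):
            coherence_statistic(wavelet_coherence(a, a), n_surrogates=5)

    def test_null_pvalues_valid(self):
        """Surrogate p-values on independent white pairs are (sub)uniform."""
        ps = []
        for rep in range(60):
            r = np.random.default_rng(child_seed(41, rep))
            a = TimeSeries(r.standard_normal(256), 4.0)
            b = TimeSeries(r.standard_normal(256), 4.0)
            res = coherence_statistic(
                wavelet_coherence(a, b), n_surrogates=19, seed=child_seed(42, rep)
            )
            ps.append(res.pvalue)
        ps = np.asarray(ps)
        assert np.mean(ps <= 0.05) <= 0.12  # level roughly held
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_power_against_shared_signal(self):
        fs, n = 4.0, 256
        t = np.arange(n) / fs
        rej = 0
        for rep in range(20):
            r = np.random.default_rng(child_seed(43, rep))
            sig = np.sin(2 * np.pi * 0.25 * t + r.uniform(0, 2 * np.pi))
            a = TimeSeries(2 * sig + r.standard_normal(n), fs)
            b = TimeSeries(2 * sig + r.standard_normal(n), fs)
            res = coherence_statistic(
                wavelet_coherence(a, b), n_surrogates=19, seed=child_seed(44, rep)
            )
            rej += res.pvalue <= 0.05
        assert rej / 20 > 0.5


class TestWaveletCoherenceModel:
    def test_fit_and_test_roundtrip(self, rng):
        a = TimeSeries(rng.standard_normal(400), 4.0)
        b = TimeSeries(rng.standard_normal(400), 4.0)
        res = WaveletCoherence(a, b).test(n_surrogates=19, seed=1)
        assert 0 <= res.statistic <= 1
        assert 0 < res.pvalue <= 1
        assert "coherence" in res.summary()
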