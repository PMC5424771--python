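import numpy as np
import pandas as pd
import pytest

from robustfc import (
    SimulationConfig,
    TimeSeries,
    calibration_curve,
    canonical_hrf,
    hemodynamic_convolve,
    inject_motion,
    run_fdr_experiment,
    run_roc_experiment,
    simulate_neural_pair,
)

from conftest import child_seed


class TestCanonicalHrf:
    def test_shape_at_1hz(self):
        hrf = canonical_hrf(1.0)
        assert hrf.taps.size == 32
        assert int(np.argmax(hrf.taps)) == 6
        assert hrf.taps.max() == pytest.approx(1.0)

    def test_sign_pattern(self):
        hrf = canonical_hrf(2.0)
        t = np.arange(hrf.taps.size) / hrf.fs
        assert np.all(hrf.taps[(t > 0.5) & (t < 10)] > 0)
        assert np.any(hrf.taps[(t > 12) & (t < 25)] < 0)

    def test_too_low_rate_rejected(self):
        with pytest.raises(ValueError):
            canonical_hrf(0.01)


class TestSimulateNeuralPair:
    def test_null_sample_correlation_bounded(self):
        a, b = simulate_neural_pair(3000, 0.0, seed=5)
        r = np.corrcoef(a.values, b.values)[0, 1]
        assert abs(r) < 3 / np.sqrt(3000)

    def test_target_correlation_achieved(self):
        a, b = simulate_neural_pair(3000, 0.5, seed=6)
        r = np.corrcoef(a.values, b.values)[0, 1]
        assert r == pytest.approx(0.5, abs=0.05)

    def test_bit_reproducible(self):
        a1, b1 = simulate_neural_pair(500, 0.3, seed=7)
        a2, b2 = simulate_neural_pair(500, 0.3, seed=7)
        assert np.array_equal(a1.values, a2.values)
        assert np.array_equal(b1.values, b2.values)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            simulate_neural_pair(100, 1.0, seed=0)


class TestHemodynamicConvolve:
    def test_impulse_reproduces_kernel(self):
        hrf = canonical_hrf(1.0)
        x = np.zeros(100)
        x[0] = 1.0
        out = hemodynamic_convolve(TimeSeries(x, 1.0), hrf)
        assert out.values[:32] == pytest.approx(hrf.taps, abs=1e-9)
        assert out.values[32:] == pytest.approx(np.zeros(68), abs=1e-9)

    def test_output_strongly_autocorrelated(self):
        hrf = canonical_hrf(1.0)
        a, _ = simulate_neural_pair(3000, 0.0, seed=8)
        h = hemodynamic_convolve(a, hrf).values
        h = h - h.mean()
        assert h[:-1] @ h[1:] / (h @ h) > 0.9

    def test_zero_in_zero_out(self):
        hrf = canonical_hrf(1.0)
        out = hemodynamic_convolve(TimeSeries(np.zeros(64), 1.0), hrf)
        assert np.all(out.values == 0)

    def test_rate_mismatch_rejected(self):
        hrf = canonical_hrf(1.0)
        with pytest.raises(ValueError, match="mismatch"):
            hemodynamic_convolve(TimeSeries(np.zeros(64), 2.0), hrf)


class TestInjectMotion:
    def test_zero_fraction_is_noop(self):
        pair = simulate_neural_pair(500, 0.0, seed=9)
        out = inject_motion(pair, 0.0, 10.0, seed=1)
        assert out[0] is pair[0] and out[1] is pair[1]

    def test_variance_mixture(self):
        """5% artifacts at 10x variance raise total variance to ~1.5."""
        ratios = []
        for rep in range(300):
            a, b = simulate_neural_pair(1000, 0.0, seed=child_seed(51, rep))
            am, _ = inject_motion((a, b), 0.05, 10.0, seed=child_seed(52, rep))
            ratios.append(am.values.var() / a.values.var())
        assert np.mean(ratios) == pytest.approx(1.5, abs=0.05)

    def test_shared_times_same_indices(self):
        a, b = simulate_neural_pair(500, 0.0, seed=10)
        am, bm = inject_motion((a, b), 0.1, 10.0, shared_times=True, seed=2)
        assert np.array_equal(am.values != a.values, bm.values != b.values)

    def test_identical_values_proportional(self):
        a, b = simulate_neural_pair(500, 0.0, seed=11)
        am, bm = inject_motion(
            (a, b), 0.1, 10.0, shared_times=True, identical_values=True, seed=3
        )
        da, db = am.values - a.values, bm.values - b.values
        idx = da != 0
        # same standard-normal draws scaled by each channel's own base std
        assert da[idx] / np.sqrt(10 * a.values.var()) == pytest.approx(
            db[idx] / np.sqrt(10 * b.values.var())
        )

    def test_invalid_fraction_rejected(self):
        pair = simulate_neural_pair(100, 0.0, seed=12)
        with pytest.raises(ValueError):
            inject_motion(pair, 1.0, 10.0, seed=0)


class TestFdrExperiment:
    def test_unknown_estimator_rejected(self):
        c = SimulationConfig(n_reps=2, fs_grid=(1.0,))
        with pytest.raises(ValueError, match="unknown estimator"):
            run_fdr_experiment(c, ["NOPE"])

    def test_alpha_one_rejects_everything(self):
        c = SimulationConfig(n_reps=5, n_samples=400, fs_grid=(1.0,), alpha=0.9999)
        rep = run_fdr_experiment(c, ["COR"])
        assert float(rep.fdr_table.iloc[0, 0]) == 1.0

    def test_report_reproducible_from_seed(self):
        c = SimulationConfig(n_reps=10, n_samples=500, fs_grid=(0.5, 1.0), seed=77)
        r1 = run_fdr_experiment(c, ["COR", "AR-COR"])
        r2 = run_fdr_experiment(c, ["COR", "AR-COR"])
        pd.testing.assert_frame_equal(r1.fdr_table, r2.fdr_table)

    def test_unconvolved_nulls_hold_nominal_level(self):
        """Negative control: raw i.i.d. pairs give ~5% false discovery."""
        c = SimulationConfig(n_reps=200, fs_grid=(1.0,), seed=3)
        rep = run_fdr_experiment(c, ["COR"], convolve=False)
        assert float(rep.fdr_table.iloc[0, 0]) == pytest.approx(0.05, abs=0.04)

    def test_convolved_nulls_inflate_naive_fdr(self):
        c = SimulationConfig(n_reps=100, fs_grid=(1.0,), seed=4)
        rep = run_fdr_experiment(c, ["COR"])
        assert float(rep.fdr_table.iloc[0, 0]) > 0.25

    def test_fdr_monotone_in_sample_rate(self):
        """Serial correlation grows with fs, so naive FDR is non-decreasing
        over 0.1-4 Hz (one inversion within 2 binomial SEs allowed)."""
        c = SimulationConfig(n_reps=150, fs_grid=(0.1, 0.5, 1.0, 4.0), seed=5)
        rep = run_fdr_experiment(c, ["COR"])
        f = rep.fdr_table.loc["COR"].to_numpy(float)
        se = rep.fdr_se.loc["COR"].to_numpy(float)
        diffs = np.diff(f)
        bad = diffs < 0
        tol = 2 * np.hypot(se[:-1], se[1:])
        assert bad.sum() <= 1
        assert np.all(diffs >= -tol)


@pytest.fixture(scope="module")
def roc_report():
    c = SimulationConfig(n_reps=60, n_samples=1000, rho=0.3, seed=21)
    return run_roc_experiment(c, ["COR", "AR-COR"], fs=2.0)


class TestRocExperiment:

    def test_class_counts_balanced(self, roc_report):
        # by construction half the pairs are positives; AUC well above chance
        assert roc_report.config.n_reps % 2 == 0
        assert roc_report.roc["AR-COR"]["auc"] > 0.7

    def test_roc_curve_monotone(self, roc_report):
        for curve in roc_report.roc.values():
            assert np.all(np.diff(curve["fpr"]) >= 0)
            assert np.all(np.diff(curve["tpr"]) >= 0)
            assert 0 <= curve["auc"] <= 1

    def test_calibration_table_shape(self, roc_report):
        cal = roc_report.calibration["COR"]
        assert set(cal.columns) == {"nominal", "actual"}
        assert np.all(np.diff(cal["actual"]) >= 0)

    def test_odd_reps_rejected(self):
        c = SimulationConfig(n_reps=7, rho=0.3)
        with pytest.raises(ValueError):
            run_roc_experiment(c, ["COR"])


class TestCalibrationCurve:
    def test_uniform_pvalues_on_diagonal(self, rng):
        p = rng.uniform(size=5000)
        grid = np.linspace(0.05, 0.95, 10)
        curve = calibration_curve(p, grid)
        assert curve["actual"].to_numpy() == pytest.approx(grid, abs=0.03)

    def test_monotone_nondecreasing(self, rng):
        curve = calibration_curve(rng.beta(0.5, 3, 500), np.linspace(0.01, 0.99, 50))
        assert np.all(np.diff(curve["actual"]) >= 0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            calibration_curve([], [0.05])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            calibration_curve([1.5], [0.05])


class TestExperimentReportIO:
    def test_save_writes_tables_and_manifest(self, tmp_path):
        c = SimulationConfig(n_reps=4, n_samples=400, fs_grid=(1.0,), seed=1)
        rep = run_fdr_experiment(c, ["COR"])
        rep.save(tmp_path)
        assert (tmp_path / "fdr_table.csv").exists()
        assert (tmp_path / "manifest.json").exists()
        loaded = pd.read_csv(tmp_path / "fdr_table.csv", index_col=0)
        assert loaded.loc["COR"].iloc[0] == float(rep.fdr_table.iloc[0, 0])
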