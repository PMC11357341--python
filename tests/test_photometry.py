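"""Photometry preprocessing: trimming, bleach-fit recovery, robust scaling,
filtering, ΔF/F algebra, z-score invariants and QC rules."""
import numpy as np
import pytest

from photolick.photometry import (
    ControlFitError,
    PhotometryRecording,
    censor_shared_artifacts,
    compute_dff,
    fit_biexponential,
    lowpass,
    process_recording,
    qc_recording,
    ransac_scale,
    read_photometry_csv,
    trim_frames,
    write_photometry_csv,
    zscore_session,
)
from photolick.synthetic import simulate_session


def _recording(n=1000, fs=15.0):
    t = np.arange(n) / fs
    f415 = 2.0 * np.exp(-t / 30.0) + 10.0
    return PhotometryRecording("left", t, f415, 2.0 * f415, fs)


class TestTrimFrames:
    def test_drops_first_n_and_rezeros(self):
        rec = _recording(1000)
        out = trim_frames(rec, 300)
        assert out.n_frames == 700
        assert out.time[0] == 0.0
        assert out.meta["clock_offset"] == pytest.approx(300 / 15.0)
        assert np.array_equal(out.F415, rec.F415[300:])

    def test_zero_is_identity(self):
        rec = _recording(1000)
        assert trim_frames(rec, 0) is rec

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError, match="cannot trim"):
            trim_frames(_recording(200), 300)


class TestBiexponentialFit:
    def test_noiseless_recovery(self):
        t = np.arange(0, 3600.0, 1 / 15.0)
        f = 1.0 * np.exp(-t / 30.0) + 0.5 * np.exp(-t / 600.0) + 0.1
        fit = fit_biexponential(t, f)
        assert fit.converged
        assert fit.A1 == pytest.approx(1.0, rel=1e-3)
        assert fit.tau1 == pytest.approx(30.0, rel=1e-3)
        assert fit.A2 == pytest.approx(0.5, rel=1e-3)
        assert fit.tau2 == pytest.approx(600.0, rel=1e-3)
        assert fit.C == pytest.approx(0.1, rel=1e-3)
        assert fit.r_squared > 0.999999

    def test_tau_ordering_invariant(self):
        t = np.arange(0, 1200.0, 1 / 15.0)
        f = 0.5 * np.exp(-t / 500.0) + 1.0 * np.exp(-t / 20.0) + 5.0
        fit = fit_biexponential(t, f)
        assert 0 < fit.tau1 <= fit.tau2

    def test_constant_trace_degenerates_to_offset(self):
        t = np.arange(0, 600.0, 1 / 15.0)
        f = np.full_like(t, 7.5)
        fit = fit_biexponential(t, f)
        assert fit.A1 + fit.A2 < 1e-6
        assert fit.C == pytest.approx(7.5, rel=1e-6)
        # the scaled pipeline stays well-defined through the offset
        assert np.all(fit.curve > 0)

    def test_noisy_recovery_median_error(self):
        errs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            t = np.arange(0, 3600.0, 1 / 15.0)
            clean = 1.0 * np.exp(-t / 30.0) + 0.5 * np.exp(-t / 600.0) + 0.1
            f = clean + rng.normal(0, 0.016, len(t))  # 1 % of initial brightness
            fit = fit_biexponential(t, f)
            errs.append(max(abs(fit.tau1 - 30) / 30, abs(fit.tau2 - 600) / 600))
        assert np.median(errs) < 0.10


class TestRansacScale:
    def test_exact_line(self):
        x = 2.0 * np.exp(-np.linspace(0, 600, 5000) / 200.0) + 10.0
        y = 2.0 * x + 1.0
        sc = ransac_scale(x, y, seed=0)
        assert sc.slope == pytest.approx(2.0, abs=1e-9)
        assert sc.intercept == pytest.approx(1.0, abs=1e-7)
        assert sc.inlier_mask.all()
        assert np.allclose(sc.scaled_fit, y)

    def test_contaminated_slope_within_two_percent(self):
        rng = np.random.default_rng(0)
        x = 2.0 * np.exp(-np.linspace(0, 600, 10000) / 200.0) + 10.0
        y = 2.0 * x + 1.0 + rng.normal(0, 0.05, x.size)
        bad = rng.choice(x.size, size=x.size // 10, replace=False)
        y[bad] += 5.0
        sc = ransac_scale(x, y, seed=1)
        assert sc.slope == pytest.approx(2.0, rel=0.02)
        # the displaced frames are mostly outliers
        assert np.mean(sc.inlier_mask[bad]) < 0.1

    def test_seed_determinism(self):
        rng = np.random.default_rng(4)
        x = np.linspace(1, 10, 2000)
        y = 3.0 * x + rng.normal(0, 0.5, x.size)
        a = ransac_scale(x, y, seed=99)
        b = ransac_scale(x, y, seed=99)
        assert np.array_equal(a.inlier_mask, b.inlier_mask)
        assert a.slope == b.slope

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            ransac_scale(np.ones(100), np.arange(100.0), seed=0)


class TestLowpass:
    def test_dc_gain_unity(self):
        out = lowpass(np.full(3000, 4.2), 15.0)
        assert np.allclose(out, 4.2, atol=1e-9)

    def test_passband_preserved(self):
        fs = 30.0
        t = np.arange(0, 60, 1 / fs)
        x = np.sin(2 * np.pi * 1.0 * t)
        out = lowpass(x, fs)
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        assert np.max(np.abs(out[mid])) == pytest.approx(1.0, rel=0.01)

    def test_stopband_attenuated(self):
        fs = 30.0
        t = np.arange(0, 60, 1 / fs)
        x = np.sin(2 * np.pi * 12.0 * t)
        out = lowpass(x, fs)
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        assert np.max(np.abs(out[mid])) < 0.20

    def test_unsupported_rate_skips_with_warning(self):
        x = np.sin(np.arange(100.0))
        with pytest.warns(UserWarning, match="cannot support"):
            out = lowpass(x, frame_rate=10.0, cutoff=6.0)
        assert np.array_equal(out, x)


class TestDffAndZscore:
    def test_identity_inputs(self):
        f = np.linspace(5, 6, 100)
        assert np.allclose(compute_dff(f, f, "ratio"), 1.0)
        assert np.allclose(compute_dff(f, f, "subtract"), 0.0)

    def test_modes_differ_by_one(self):
        rng = np.random.default_rng(1)
        f = rng.uniform(5, 10, 500)
        fit = rng.uniform(4, 9, 500)
        assert np.allclose(
            compute_dff(f, fit, "ratio") - compute_dff(f, fit, "subtract"), 1.0
        )

    def test_nonpositive_control_raises(self):
        with pytest.raises(ControlFitError, match="nonpositive"):
            compute_dff(np.ones(10), np.linspace(-1, 1, 10))

    def test_zscore_invariants(self):
        rng = np.random.default_rng(2)
        x = rng.normal(3.0, 2.0, 10_000)
        z = zscore_session(x)
        assert abs(z.mean()) < 1e-9
        assert abs(z.std() - 1.0) < 1e-9

    def test_zscore_affine_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=5000)
        assert np.allclose(zscore_session(x), zscore_session(3.5 * x + 11.0), atol=1e-12)

    def test_ratio_and_subtract_give_identical_zdff(self):
        rng = np.random.default_rng(4)
        f = rng.uniform(5, 10, 5000)
        fit = rng.uniform(4, 9, 5000)
        za = zscore_session(compute_dff(f, fit, "ratio"))
        zb = zscore_session(compute_dff(f, fit, "subtract"))
        assert np.allclose(za, zb, atol=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            zscore_session(np.ones(100))


class TestQC:
    def _fit(self, r2):
        curve = np.linspace(10, 5, 100)
        return type("F", (), {"converged": True, "r_squared": r2, "curve": curve})()

    def _scaled(self, frac):
        mask = np.zeros(100, dtype=bool)
        mask[: int(100 * frac)] = True
        return type("S", (), {"inlier_mask": mask, "inlier_fraction": frac,
                              "scaled_fit": np.linspace(20, 10, 100)})()

    def test_poor_bleach_fit_flagged(self):
        res = qc_recording(self._fit(0.2), self._scaled(0.9),
                           np.random.default_rng(0).normal(size=100), 15.0)
        assert not res.passed and "poor bleach fit" in res.reasons

    def test_nonpositive_control_flagged(self):
        res = qc_recording(self._fit(0.95), self._scaled(0.9), None, 15.0)
        assert not res.passed and "nonpositive control fit" in res.reasons

    def test_low_inlier_fraction_flagged(self):
        res = qc_recording(self._fit(0.95), self._scaled(0.2),
                           np.random.default_rng(0).normal(size=100), 15.0)
        assert not res.passed and "excessive motion artifacts" in res.reasons

    def test_sustained_excursion_flagged(self):
        rng = np.random.default_rng(0)
        dff = rng.normal(0, 1e-3, 3000) + 1.0
        dff[1000:1020] += 2.0  # ~12 z for ~1.3 s at 15 Hz
        res = qc_recording(self._fit(0.95), self._scaled(0.9), dff, 15.0)
        assert not res.passed and "excessive excursions" in res.reasons

    def test_clean_synthetic_session_passes(self, small_config):
        left, _, _, _ = simulate_session(small_config)
        trace, _ = process_recording(left, seed=3, n_trim=300)
        assert trace.qc.passed, trace.qc.reasons


class TestPipelineComposition:
    def test_process_recording_equals_manual_stage_chain(self, small_config):
        """The preprocessing entry point is exactly the documented stage
        order: trim -> fit -> censor -> RANSAC -> lowpass -> ΔF/F -> z."""
        left, _, _, _ = simulate_session(small_config)
        seed = 42
        trace, diag = process_recording(left, seed=seed)

        trimmed = trim_frames(left, 300)
        fit = fit_biexponential(trimmed.time, trimmed.F415)
        f470, _ = censor_shared_artifacts(trimmed.F415, fit.curve, trimmed.F470)
        scaled = ransac_scale(fit.curve, f470, seed)
        filt = lowpass(f470, left.frame_rate, 6.0)
        dff = compute_dff(filt, scaled.scaled_fit, "ratio")
        zdff = zscore_session(dff)
        assert np.array_equal(trace.dff, dff)
        assert np.array_equal(trace.zdff, zdff)
        assert diag["fit"].tau2 == fit.tau2

    def test_censoring_suppresses_shared_boxcars(self):
        """A large channel-shared artifact is flagged from the isosbestic
        residual and interpolated out of the 470 channel."""
        rng = np.random.default_rng(8)
        t = np.arange(0, 600, 1 / 15.0)
        bleach = 3.0 * np.exp(-t / 60.0) + 10.0
        motion = np.zeros_like(t)
        motion[3000:3015] = 2.0
        f415 = bleach + motion + rng.normal(0, 0.3, t.size)
        f470 = 2.0 * bleach + motion + rng.normal(0, 0.3, t.size)
        from photolick.photometry import fit_biexponential as fitb

        fit = fitb(t, f415)
        out, mask = censor_shared_artifacts(f415, fit.curve, f470)
        assert mask[3000:3015].mean() > 0.9
        resid = out - 2.0 * fit.curve
        assert np.abs(resid[3000:3015]).max() < 1.5


class TestIO:
    def test_csv_roundtrip(self, small_config, tmp_path):
        left, _, _, _ = simulate_session(small_config)
        path = tmp_path / "phot.csv"
        write_photometry_csv([left], path)
        (back,) = read_photometry_csv(path)
        assert back.fiber_side == "left"
        assert back.frame_rate == left.frame_rate
        assert np.allclose(back.F415, left.F415, atol=1e-6)
        assert np.allclose(back.F470, left.F470, atol=1e-6)
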