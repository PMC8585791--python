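"""Temporal preprocessing: filtering, nuisance regression, censoring, QC."""

import numpy as np
import pytest

import contrafc as cf
from contrafc.preprocess import _censor_statistic


def _sinusoid_run(freq_hz, n_frames=400, tr=2.07, n_rois=3, amplitude=1.0):
    t = np.arange(n_frames) * tr
    series = amplitude * np.sin(2 * np.pi * freq_hz * t)
    data = np.tile(series[:, None], (1, n_rois))
    return cf.make_run(data, tr_seconds=tr, run_id=f"sin{freq_hz}")


def _rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


class TestLowpassFilter:
    def test_constant_series_unchanged(self):
        run = cf.make_run(np.full((100, 4), 7.3), tr_seconds=2.07)
        out = cf.lowpass_filter(run, cf.PreprocessParams())
        assert np.allclose(out.data, 7.3, atol=1e-10)

    def test_stopband_sinusoid_attenuated(self):
        """A 0.2 Hz oscillation lies above the 0.1 Hz cutoff and must be
        suppressed below 5% of its input RMS (Fourier-checked)."""
        run = _sinusoid_run(0.2)
        out = cf.lowpass_filter(run, cf.PreprocessParams())
        assert _rms(out.data) < 0.05 * _rms(run.data)
        # spectral oracle: the 0.2 Hz Fourier line itself is attenuated
        spectrum_in = np.abs(np.fft.rfft(run.data[:, 0]))
        spectrum_out = np.abs(np.fft.rfft(out.data[:, 0]))
        freqs = np.fft.rfftfreq(run.n_frames, run.tr_seconds)
        line = np.argmin(np.abs(freqs - 0.2))
        assert spectrum_out[line] < 0.05 * spectrum_in[line]

    def test_passband_sinusoid_preserved(self):
        run = _sinusoid_run(0.01)
        out = cf.lowpass_filter(run, cf.PreprocessParams())
        assert _rms(out.data) >= 0.95 * _rms(run.data)
        spectrum_in = np.abs(np.fft.rfft(run.data[:, 0]))
        spectrum_out = np.abs(np.fft.rfft(out.data[:, 0]))
        freqs = np.fft.rfftfreq(run.n_frames, run.tr_seconds)
        line = np.argmin(np.abs(freqs - 0.01))
        assert spectrum_out[line] >= 0.95 * spectrum_in[line]

    def test_cutoff_at_or_above_nyquist_rejected(self):
        run = _sinusoid_run(0.01, tr=2.07)
        params = cf.PreprocessParams(lowpass_cutoff_hz=0.25)  # nyquist 0.2415
        with pytest.raises(cf.ParameterError, match="Nyquist"):
            cf.lowpass_filter(run, params)

    def test_too_few_frames_rejected(self):
        run = cf.make_run(np.random.default_rng(0).normal(size=(10, 2)),
                          tr_seconds=2.07)
        with pytest.raises(cf.ParameterError, match="frames"):
            cf.lowpass_filter(run, cf.PreprocessParams())

    def test_mask_and_shape_unchanged(self):
        mask = np.ones(400, dtype=bool)
        mask[5] = False
        run = cf.make_run(np.random.default_rng(0).normal(size=(400, 3)),
                          tr_seconds=2.07, censor_mask=mask)
        out = cf.lowpass_filter(run, cf.PreprocessParams())
        assert out.data.shape == run.data.shape
        assert np.array_equal(out.censor_mask, mask)


class TestNuisanceRegressors:
    def test_intercept_plus_global(self):
        run = cf.make_run(np.arange(30.0).reshape(10, 3), tr_seconds=2.0)
        X = cf.build_nuisance_regressors(run)
        assert X.shape == (10, 2)
        assert np.allclose(X[:, 0], 1.0)
        assert np.allclose(X[:, 1], run.data.mean(axis=1))

    def test_global_equals_common_series(self):
        series = np.sin(np.linspace(0, 3, 10))
        run = cf.make_run(np.tile(series[:, None], (1, 5)), tr_seconds=2.0)
        X = cf.build_nuisance_regressors(run)
        assert np.allclose(X[:, 1], series)

    def test_external_column_order(self, rng):
        run = cf.make_run(rng.normal(size=(10, 3)), tr_seconds=2.0)
        external = rng.normal(size=(10, 3))
        X = cf.build_nuisance_regressors(run, external=external)
        assert X.shape == (10, 5)
        assert np.allclose(X[:, 2:], external)

    def test_frame_count_mismatch(self, rng):
        run = cf.make_run(rng.normal(size=(10, 3)), tr_seconds=2.0)
        with pytest.raises(cf.ValidationError, match="frames"):
            cf.build_nuisance_regressors(run, external=rng.normal(size=(8, 2)))


class TestNuisanceRegress:
    def test_series_equal_to_regressor_vanishes(self, rng):
        g = rng.normal(size=50)
        run = cf.make_run(np.column_stack([g, 2.0 * g + 1.0]), tr_seconds=2.0)
        X = np.column_stack([np.ones(50), g])
        out = cf.nuisance_regress(run, X)
        assert np.allclose(out.data, 0.0, atol=1e-10)

    def test_orthogonal_series_only_demeaned(self, rng):
        gc = rng.normal(size=200)
        gc = gc - gc.mean()
        s = rng.normal(size=200)
        s = s - s.mean()
        s = s - (s @ gc) / (gc @ gc) * gc  # orthogonal to gc, still centred
        run = cf.make_run(s[:, None], tr_seconds=2.0)
        X = np.column_stack([np.ones(200), gc])
        out = cf.nuisance_regress(run, X)
        assert np.allclose(out.data[:, 0], s, atol=1e-10)

    def test_recovers_signal_mixed_with_global(self, rng):
        """s + 2g with g regressed out leaves a residual correlating > 0.99
        with s; oracle = direct normal-equations OLS."""
        n = 2000
        g = rng.normal(size=n)
        s = rng.normal(size=n)
        data = (s + 2.0 * g)[:, None]
        run = cf.make_run(data, tr_seconds=2.0)
        X = np.column_stack([np.ones(n), g])
        out = cf.nuisance_regress(run, X)
        r = np.corrcoef(out.data[:, 0], s)[0, 1]
        assert r > 0.99
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ data)
        assert np.allclose(out.data, data - X @ beta_oracle, atol=1e-8)

    def test_fit_uses_retained_frames_but_predicts_all(self, rng):
        n = 100
        g = rng.normal(size=n)
        mask = np.ones(n, dtype=bool)
        mask[:10] = False
        data = np.tile((3.0 * g)[:, None], (1, 2))
        data[:10] += 50.0  # corrupted frames must not influence the fit
        run = cf.make_run(data, tr_seconds=2.0, censor_mask=mask)
        X = np.column_stack([np.ones(n), g])
        out = cf.nuisance_regress(run, X)
        assert np.allclose(out.data[mask], 0.0, atol=1e-10)
        assert np.allclose(out.data[~mask], 50.0, atol=1e-10)

    def test_rank_deficiency_rejected(self, rng):
        run = cf.make_run(rng.normal(size=(20, 2)), tr_seconds=2.0)
        X = np.column_stack([np.ones(20), np.ones(20)])
        with pytest.raises(cf.ValidationError, match="rank"):
            cf.nuisance_regress(run, X)

    def test_too_few_retained_frames_rejected(self, rng):
        mask = np.zeros(20, dtype=bool)
        mask[:2] = True
        run = cf.make_run(rng.normal(size=(20, 2)), tr_seconds=2.0,
                          censor_mask=mask)
        X = np.column_stack([np.ones(20), np.arange(20.0)])
        with pytest.raises(cf.ValidationError, match="retained"):
            cf.nuisance_regress(run, X)


class TestCensorFrames:
    def test_constant_run_censors_nothing(self):
        run = cf.make_run(np.full((50, 4), 100.0), tr_seconds=2.0)
        out = cf.censor_frames(run, cf.PreprocessParams())
        assert out.censor_mask.all()

    def test_level_shift_of_ten_percent_rms_censored(self):
        """Baseline ~100 a.u.; every ROI jumps by 10 a.u. at one frame and
        stays — a 10% change against a 0.5% threshold censors exactly that
        frame (hand computation: RMS ratio 0.10 > 0.005)."""
        data = np.full((60, 5), 100.0)
        data[30:] += 10.0
        run = cf.make_run(data, tr_seconds=2.0)
        frame_rms, grand_rms = _censor_statistic(data)
        assert frame_rms[29] / grand_rms == pytest.approx(10.0 / grand_rms)
        assert 10.0 / grand_rms > 0.005
        out = cf.censor_frames(run, cf.PreprocessParams())
        assert np.flatnonzero(~out.censor_mask).tolist() == [30]

    def test_single_frame_spike_censors_spike_and_recovery(self):
        data = np.full((60, 5), 100.0)
        data[30] += 10.0
        run = cf.make_run(data, tr_seconds=2.0)
        out = cf.censor_frames(run, cf.PreprocessParams())
        assert np.flatnonzero(~out.censor_mask).tolist() == [30, 31]

    def test_huge_threshold_censors_nothing(self, rng):
        run = cf.make_run(100 + rng.normal(size=(50, 4)), tr_seconds=2.0)
        params = cf.PreprocessParams(censor_threshold_fraction=1e6)
        assert cf.censor_frames(run, params).censor_mask.all()

    def test_frame_zero_never_censored(self, rng):
        data = 100 + rng.normal(size=(50, 4))
        data[0] += 1000.0
        run = cf.make_run(data, tr_seconds=2.0)
        out = cf.censor_frames(run, cf.PreprocessParams(
            censor_threshold_fraction=1e6))
        assert out.censor_mask[0]

    @pytest.mark.parametrize("thresholds", [(0.001, 0.005), (0.005, 0.05),
                                            (0.0001, 10.0)])
    def test_monotone_in_threshold(self, rng, thresholds):
        lo, hi = thresholds
        data = 100 + rng.normal(size=(200, 10))
        data[rng.integers(1, 199, size=8)] += 5.0
        run = cf.make_run(data, tr_seconds=2.0)
        n_lo = (~cf.censor_frames(
            run, cf.PreprocessParams(censor_threshold_fraction=lo)
        ).censor_mask).sum()
        n_hi = (~cf.censor_frames(
            run, cf.PreprocessParams(censor_threshold_fraction=hi)
        ).censor_mask).sum()
        assert n_hi <= n_lo

    def test_conjunction_with_existing_mask(self):
        data = np.full((10, 2), 100.0)
        mask = np.ones(10, dtype=bool)
        mask[3] = False
        run = cf.make_run(data, tr_seconds=2.0, censor_mask=mask)
        out = cf.censor_frames(run, cf.PreprocessParams())
        assert not out.censor_mask[3]

    def test_single_frame_rejected(self):
        run = cf.make_run(np.ones((1, 3)), tr_seconds=2.0)
        with pytest.raises(cf.ValidationError):
            cf.censor_frames(run, cf.PreprocessParams())


class TestQC:
    @pytest.mark.parametrize("n_censored,max_frac,passed", [
        (10, 0.5, True),    # fraction 0.05
        (150, 0.5, False),  # fraction 0.75
        (150, 1.0, True),   # threshold 1.0 always passes
    ])
    def test_verdicts(self, n_censored, max_frac, passed):
        mask = np.ones(200, dtype=bool)
        mask[:n_censored] = False
        run = cf.make_run(np.ones((200, 2)), tr_seconds=2.0, censor_mask=mask)
        verdict = cf.qc_exclude_run(
            run, cf.PreprocessParams(max_censored_fraction=max_frac))
        assert verdict.passed is passed
        assert verdict.censored_fraction == pytest.approx(n_censored / 200)


class TestChain:
    def test_shapes_preserved_end_to_end(self, rng):
        run = cf.make_run(100 + 0.2 * rng.normal(size=(200, 6)),
                          tr_seconds=2.07)
        out, verdict = cf.preprocess_run(run, cf.PreprocessParams())
        assert out.data.shape == run.data.shape
        assert out.censor_mask.shape == run.censor_mask.shape
        assert verdict.passed

    def test_denoising_stages_stable_under_reapplication(self):
        """Filtering + nuisance regression re-applied to their own output
        leave it essentially unchanged: the zero-phase filter is
        near-identity on already-band-limited content, residuals are
        orthogonal to the design, and the spent global regressor is exactly
        null after the first pass (so it is dropped, not refit).  The filter
        is not a strict projection, so the bound is relative to the input's
        fluctuation amplitude, not machine precision."""
        t = np.arange(300) * 2.07
        base = np.sin(2 * np.pi * 0.008 * t)
        slow = np.cos(2 * np.pi * 0.003 * t)
        data = 100.0 + np.column_stack(
            [base * (1 + 0.2 * k) + 0.3 * slow * (1 - 0.1 * k)
             for k in range(4)]
        )
        params = cf.PreprocessParams()

        def denoise(run):
            filtered = cf.lowpass_filter(run, params)
            X = cf.build_nuisance_regressors(filtered)
            return cf.nuisance_regress(filtered, X)

        first = denoise(cf.make_run(data, tr_seconds=2.07))
        second = denoise(first)
        fluctuation_rms = float(np.sqrt(((data - data.mean(0)) ** 2).mean()))
        assert np.abs(second.data - first.data).max() < 0.01 * fluctuation_rms

    def test_censor_mask_stable_on_recensoring(self, rng):
        """Censoring its own output with the same threshold removes no
        further frames (the statistic is recomputed on the same data)."""
        data = 100 + 0.2 * rng.normal(size=(200, 6))
        data[50] += 10.0
        run = cf.make_run(data, tr_seconds=2.07)
        params = cf.PreprocessParams()
        once = cf.censor_frames(run, params)
        twice = cf.censor_frames(once, params)
        assert np.array_equal(once.censor_mask, twice.censor_mask)

    def test_censor_on_filtered_option(self, rng):
        data = 100 + 0.2 * rng.normal(size=(200, 6))
        data[90] += 10.0
        run = cf.make_run(data, tr_seconds=2.07)
        raw_out, _ = cf.preprocess_run(run, cf.PreprocessParams(censor_on="raw"))
        assert not raw_out.censor_mask[90]
        filt_out, _ = cf.preprocess_run(
            run, cf.PreprocessParams(censor_on="filtered"))
        # filtering smears the spike; the raw statistic is the sharper detector
        assert (~raw_out.censor_mask).sum() >= 1
        assert filt_out.data.shape == run.data.shape
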