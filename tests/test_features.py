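import numpy as np
import pytest
from scipy.signal import get_window

import tremorkit as tk
from tremorkit.features import (
    LOG_EPS,
    SpectralEstimate,
    SpectralSettings,
    hos_params,
    psd_params,
    spectral_estimate,
)

RAW = SpectralSettings(detrend=None)


def welch_oracle(x, fs, nperseg, detrend=None):
    """Independent Welch PSD: windowed periodograms averaged by hand."""
    from scipy.signal import detrend as _detrend

    hop = nperseg // 2
    w = get_window("hann", nperseg, fftbins=True)
    scale = 1.0 / (fs * np.sum(w**2))
    psds = []
    for i in range((len(x) - nperseg) // hop + 1):
        seg = x[i * hop: i * hop + nperseg]
        if detrend:
            seg = _detrend(seg, type=detrend)
        X = np.fft.rfft(w * seg)
        p = scale * np.abs(X) ** 2
        p[1:-1] *= 2.0  # one-sided (even nperseg)
        psds.append(p)
    return np.fft.rfftfreq(nperseg, 1 / fs), np.mean(psds, axis=0)


def bisp_diag_oracle(x, fs, nperseg):
    """Segment-averaged |X(f)^2 X*(2f)| computed directly."""
    hop = nperseg // 2
    w = get_window("hann", nperseg, fftbins=True)
    kd = np.arange(nperseg // 4 + 1)
    acc = []
    for i in range((len(x) - nperseg) // hop + 1):
        X = np.fft.fft(w * x[i * hop: i * hop + nperseg])
        acc.append(X[kd] ** 2 * np.conj(X[2 * kd]))
    return np.abs(np.mean(acc, axis=0))


def trisp_diag_oracle(x, fs, nperseg):
    hop = nperseg // 2
    w = get_window("hann", nperseg, fftbins=True)
    kd = np.arange(nperseg // 6 + 1)
    acc = []
    for i in range((len(x) - nperseg) // hop + 1):
        X = np.fft.fft(w * x[i * hop: i * hop + nperseg])
        acc.append(X[kd] ** 3 * np.conj(X[3 * kd]))
    return np.abs(np.mean(acc, axis=0))


class TestEstimatePsd:
    def test_zero_series_gives_zero_psd(self):
        est = tk.estimate_psd(np.zeros(1024), 100.0, RAW)
        assert np.all(est.psd == 0.0)

    def test_sinusoid_peak_bin(self):
        t = np.arange(2048) / 100.0
        est = tk.estimate_psd(np.sin(2 * np.pi * 5.0 * t), 100.0)
        assert est.freqs[np.argmax(est.psd)] == pytest.approx(5.0, abs=100 / 256)

    def test_white_noise_parseval(self):
        """Integrated PSD matches the sample variance within 5%."""
        x = np.random.default_rng(8).standard_normal(2**14)
        est = tk.estimate_psd(x, 100.0, RAW)
        df = est.freqs[1] - est.freqs[0]
        assert np.sum(est.psd) * df == pytest.approx(np.var(x), rel=0.05)

    def test_matches_hand_rolled_welch(self):
        x = np.random.default_rng(9).standard_normal(1000)
        est = tk.estimate_psd(x, 100.0, SpectralSettings(detrend="linear"))
        f, p = welch_oracle(x, 100.0, 256, detrend="linear")
        assert np.allclose(est.psd, p, rtol=1e-10, atol=1e-15)
        assert np.allclose(est.freqs, f)

    def test_short_series_error_names_minimum(self):
        with pytest.raises(ValueError, match="256"):
            tk.estimate_psd(np.zeros(100), 100.0)


class TestPsdParams:
    def _est(self, freqs, psd):
        est = SpectralEstimate(settings=RAW, fs=100.0)
        est.freqs, est.psd = np.asarray(freqs, float), np.asarray(psd, float)
        return est

    def test_single_bin_spectrum(self):
        f0 = 5.0
        freqs = np.arange(0, 50.5, 0.5)
        psd = np.zeros_like(freqs)
        psd[freqs == f0] = 3.0
        p = psd_params(self._est(freqs, psd))
        assert p[0] == 3.0
        assert p[1] == f0          # frequency of the max
        assert p[2] == f0          # m1 of a degenerate distribution
        assert p[3] == f0**2       # m2
        assert p[4] == f0**4       # m4
        assert tuple(p[5:8]) == (1, 1, 1)
        assert p[8] == f0**5       # m5

    def test_flat_spectrum_first_moment_is_half_nyquist(self):
        freqs = np.linspace(0, 50, 129)
        p = psd_params(self._est(freqs, np.ones(129)))
        assert p[2] == pytest.approx(25.0, abs=0.5)

    def test_all_zero_psd_convention(self):
        p = psd_params(self._est(np.linspace(0, 50, 65), np.zeros(65)))
        assert np.all(p == 0.0)

    def test_random_spectrum_matches_direct_summation(self):
        rng = np.random.default_rng(10)
        freqs = np.linspace(0, 50, 129)
        psd = rng.random(129) ** 2
        p = psd_params(self._est(freqs, psd))
        norm = psd / psd.sum()
        assert p[2] == pytest.approx(np.sum(freqs * norm), abs=1e-12)
        assert p[3] == pytest.approx(np.sum(freqs**2 * norm), rel=1e-12)
        assert p[4] == pytest.approx(np.sum(freqs**4 * norm), rel=1e-12)
        assert p[8] == pytest.approx(np.sum(freqs**5 * norm), rel=1e-12)
        for j, lvl in enumerate((0.0072, 0.0242, 0.953)):
            assert p[5 + j] == np.sum(psd > lvl * psd.max())


class TestHigherOrderSpectra:
    def test_zero_series_zero_diagonals(self):
        est = spectral_estimate(np.zeros(1024), 100.0, RAW)
        assert np.all(est.bisp_diag == 0.0)
        assert np.all(est.trisp_diag == 0.0)

    def test_bispectrum_tiny_case_matches_triple_product(self):
        """Single 16-sample segment equals the direct X(f)X(f)X*(2f) product."""
        x = np.random.default_rng(11).standard_normal(16)
        st = SpectralSettings(nperseg=16, detrend=None)
        est = tk.bispectrum_diag(np.tile(x, 2), 100.0, st)
        # guard: first segment of the tiled series is x itself
        oracle = bisp_diag_oracle(np.tile(x, 2), 100.0, 16)
        assert np.allclose(est.bisp_diag, oracle, atol=1e-10)

    def test_trispectrum_tiny_case_matches_quadruple_product(self):
        x = np.random.default_rng(12).standard_normal(32)
        st = SpectralSettings(nperseg=16, detrend=None)
        est = tk.trispectrum_diag(x, 100.0, st)
        assert np.allclose(est.trisp_diag, trisp_diag_oracle(x, 100.0, 16), atol=1e-10)

    def test_segment_averaged_estimates_match_oracles(self):
        x = np.random.default_rng(13).standard_normal(2000)
        est = spectral_estimate(x, 100.0, RAW)
        assert np.allclose(est.bisp_diag, bisp_diag_oracle(x, 100.0, 256),
                           rtol=1e-10, atol=1e-12)
        assert np.allclose(est.trisp_diag, trisp_diag_oracle(x, 100.0, 256),
                           rtol=1e-10, atol=1e-12)

    def test_quadratic_phase_coupling_peaks_on_diagonal(self):
        """A phase-coupled (f0, f0, 2f0) triad lifts |B(f0, f0)| >= 10x the
        background median."""
        rng = np.random.default_rng(14)
        t = np.arange(4096) / 100.0
        f0, phi = 10.0, rng.uniform(0, 2 * np.pi)
        x = (np.cos(2 * np.pi * f0 * t + phi)
             + 0.7 * np.cos(2 * np.pi * 2 * f0 * t + 2 * phi)
             + 0.3 * rng.standard_normal(t.size))
        est = tk.bispectrum_diag(x, 100.0, RAW)
        k0 = np.argmin(np.abs(est.bisp_freqs - f0))
        background = np.delete(est.bisp_diag, [k0 - 1, k0, k0 + 1])
        assert est.bisp_diag[k0] >= 10.0 * np.median(background)

    def test_homogeneity_under_amplitude_scaling(self):
        """Scaling the series by c scales p1 by c^2, p10 by c^3, p17 by c^4."""
        x = np.random.default_rng(15).standard_normal(1024)
        c = 3.0
        est1 = spectral_estimate(x, 100.0, RAW)
        estc = spectral_estimate(c * x, 100.0, RAW)
        p1, pc = (np.concatenate([psd_params(e), hos_params(e)])
                  for e in (est1, estc))
        assert pc[0] == pytest.approx(c**2 * p1[0], rel=1e-10)
        assert pc[9] == pytest.approx(c**3 * p1[9], rel=1e-10)
        assert pc[16] == pytest.approx(c**4 * p1[16], rel=1e-10)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="512"):
            tk.bispectrum_diag(np.zeros(300), 100.0)
        with pytest.raises(ValueError, match="512"):
            tk.trispectrum_diag(np.zeros(300), 100.0)


class TestHosParams:
    def _est(self, bd, bfull, mask, td):
        est = SpectralEstimate(settings=RAW, fs=100.0)
        est.bisp_freqs = np.linspace(0, 25, len(bd))
        est.bisp_diag = np.asarray(bd, float)
        est.bisp_mag = np.asarray(bfull, float)
        est.bisp_mask = mask
        est.trisp_freqs = np.linspace(0, 50 / 3, len(td))
        est.trisp_diag = np.asarray(td, float)
        return est

    def _random_est(self, seed):
        rng = np.random.default_rng(seed)
        nb, nt, nfull = 65, 43, 129
        k = np.arange(nfull)
        mask = (k[None, :] <= k[:, None]) & (k[:, None] + k[None, :] <= nfull - 1)
        bfull = rng.random((nfull, nfull)) * mask
        return self._est(rng.random(nb), bfull, mask, rng.random(nt))

    def test_all_zero_spectra_convention(self):
        nfull = 9
        k = np.arange(nfull)
        mask = (k[None, :] <= k[:, None]) & (k[:, None] + k[None, :] <= nfull - 1)
        est = self._est(np.zeros(5), np.zeros((nfull, nfull)), mask, np.zeros(3))
        assert np.all(hos_params(est) == 0.0)

    def test_single_bin_bispectrum_diagonal(self):
        est = self._random_est(16)
        est.bisp_diag = np.zeros(65)
        i0 = 20
        est.bisp_diag[i0] = 2.0
        p = hos_params(est)
        assert p[4] == est.bisp_freqs[i0]     # p14: first moment
        assert p[12] == 1 and p[13] == 1      # p22, p23 threshold counts

    def test_every_parameter_matches_direct_summation(self):
        est = self._random_est(17)
        p = hos_params(est)
        bd, bf = est.bisp_diag, est.bisp_freqs
        td, tf = est.trisp_diag, est.trisp_freqs
        ball = est.bisp_mag[est.bisp_mask]

        def mom(f, w, k):
            return np.sum(f**k * w) / np.sum(w)

        expected = [
            np.sum(bd), np.sum(ball),
            np.sum(np.log(bd + LOG_EPS)), np.sum(np.log(ball + LOG_EPS)),
            mom(bf, bd, 1), mom(bf, bd, 2), mom(bf, np.log(bd + LOG_EPS), 1),
            np.max(td), np.sum(td) / td.size,
            mom(tf, td, 1), mom(tf, td, 2), mom(tf, td, 3),
            np.sum(bd > 0.0029 * bd.max()), np.sum(bd > 0.043 * bd.max()),
            np.sum(td > 0.0015 * td.max()), np.sum(td > 5.6e-8 * td.max()),
            mom(tf, td, 5),
        ]
        assert np.allclose(p, expected, rtol=1e-12, atol=1e-12)


class TestExtractFeatures:
    def test_vector_has_26_values(self, pd_recording, rest_pattern):
        fv = tk.extract_features(pd_recording, rest_pattern)
        assert fv.values.shape == (26,)
        assert np.all(np.isfinite(fv.values))

    def test_constant_recording_at_target_is_all_zero(self):
        pat = tk.make_pattern(2)
        n = 1024
        rec = tk.Recording("c", 2, "right", 100.0, np.arange(n) / 100.0,
                           np.zeros((n, 3)))
        fv = tk.extract_features(rec, pat)
        assert np.all(fv.values == 0.0)

    def test_deterministic_across_runs(self, rest_pattern):
        spec = tk.TremorModelSpec("ET", 7.0, 0.0015, seed=21)
        a = tk.extract_features(tk.simulate_recording(rest_pattern, spec, 10.0),
                                rest_pattern)
        b = tk.extract_features(tk.simulate_recording(rest_pattern, spec, 10.0),
                                rest_pattern)
        assert np.array_equal(a.values, b.values)

    def test_wrong_length_vector_rejected(self):
        with pytest.raises(ValueError, match="26"):
            tk.FeatureVector(values=np.zeros(9))


class TestSpectrogram:
    def test_stationary_sinusoid_has_constant_ridge(self):
        t = np.arange(4096) / 100.0
        f, tt, S = tk.spectrogram(np.sin(2 * np.pi * 8.0 * t), 100.0, 256)
        ridge = f[np.argmax(S, axis=0)]
        interior = (tt > 2.0) & (tt < t[-1] - 2.0)
        assert np.allclose(ridge[interior], 8.0, atol=100 / 256)

    def test_zero_series_is_zero(self):
        _, _, S = tk.spectrogram(np.zeros(1024), 100.0, 256)
        assert np.all(S == 0.0)

    def test_chirp_ridge_tracks_instantaneous_frequency(self):
        from scipy.signal import chirp

        fs, T = 100.0, 40.0
        t = np.arange(int(fs * T)) / fs
        x = chirp(t, f0=2.0, t1=T, f1=20.0)
        f, tt, S = tk.spectrogram(x, fs, 256)
        ridge = f[np.argmax(S, axis=0)]
        interior = (tt > 3.0) & (tt < T - 3.0)
        expected = 2.0 + (20.0 - 2.0) * tt[interior] / T
        assert np.all(np.abs(ridge[interior] - expected) <= fs / 256 + 1e-9)
        d = np.diff(ridge[interior])
        assert np.all(d >= -1e-9)  # monotone non-decreasing ridge

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError, match="window_len"):
            tk.spectrogram(np.zeros(100), 100.0, 256)
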