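import numpy as np
import pytest

from foldear.audio_io import AudioSegment
from foldear.spectrograms import (
    CQTConfig,
    MelConfig,
    STFTConfig,
    Spectrogram,
    _LUT,
    bilinear_resize,
    cqt,
    hann,
    mel_filterbank,
    mel_scale,
    mel_spectrogram,
    render_image,
    stft,
)


def naive_stft_frame(x_frame, window):
    """Direct O(N^2) evaluation of the windowed DFT of one frame."""
    n = x_frame.size
    xw = x_frame * window
    k = np.arange(n // 2 + 1)
    nn = np.arange(n)
    basis = np.exp(-2j * np.pi * np.outer(k, nn) / n)
    return np.abs(basis @ xw)


class TestSTFT:
    def test_zero_signal_all_zero(self):
        seg = AudioSegment(np.zeros(4096), 16_000)
        assert np.all(stft(seg).values == 0)

    def test_row_count_is_one_sided(self):
        seg = AudioSegment(np.ones(4096) * 0.1, 16_000)
        assert stft(seg, STFTConfig(N=2048)).values.shape[0] == 1025

    def test_too_short_signal_raises(self):
        with pytest.raises(ValueError, match="zero-pad"):
            stft(AudioSegment(np.ones(100) * 0.1, 16_000))

    def test_bin_centered_sine_matches_naive_dft(self, rng):
        sr, n = 16_000, 2048
        f = 100 * sr / n  # exactly bin 100
        t = np.arange(3 * n) / sr
        x = np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        seg = AudioSegment(x, sr)
        spec = stft(seg, STFTConfig(N=n, hop=512))
        assert np.all(spec.values.argmax(axis=0) == 100)
        w = hann(n)
        for tau in (0, 1):
            frame = x[tau * 512 : tau * 512 + n]
            oracle = naive_stft_frame(frame, w)
            np.testing.assert_allclose(spec.values[:, tau], oracle, rtol=1e-8, atol=1e-10)

    def test_bin_centered_sine_dominates_by_20db(self):
        sr, n = 16_000, 2048
        t = np.arange(4 * n) / sr
        seg = AudioSegment(np.sin(2 * np.pi * (200 * sr / n) * t), sr)
        spec = stft(seg, STFTConfig(N=n, hop=512)).values
        interior = spec[:, 1:-1]
        peak = interior[200]
        # the Hann main lobe spans the two adjacent bins; outside it the
        # tone must dominate everything by >= 20 dB in interior frames
        others = np.delete(interior, [199, 200, 201], axis=0).max(axis=0)
        assert np.all(20 * np.log10(peak / others) >= 20)


class TestCQT:
    def test_octave_span(self):
        assert CQTConfig(total_bins=200, bins_per_octave=32).octave_span == 6.25

    def test_one_octave_doubles_frequency(self):
        cfg = CQTConfig()
        assert cfg.bin_frequencies()[32] == pytest.approx(44.1)

    def test_constant_q_property(self):
        cfg = CQTConfig()
        sr = 16_000
        nk = cfg.kernel_lengths(sr)
        q_eff = nk * cfg.bin_frequencies() / sr
        # ceil rounding only ever increases N_k by < 1 sample
        assert np.all(q_eff >= cfg.quality_factor - 1e-9)
        assert np.all(q_eff <= cfg.quality_factor + cfg.bin_frequencies() / sr + 1e-9)

    def test_nyquist_violation_names_offending_bin(self):
        cfg = CQTConfig(total_bins=400, bins_per_octave=32)  # 12.5 octaves from 22.05 Hz
        seg = AudioSegment(np.ones(16_000) * 0.1, 16_000)
        with pytest.raises(ValueError, match=r"bin \d+ at .* Nyquist"):
            cqt(seg, cfg)

    def test_pure_tone_matches_per_bin_oracle(self, rng):
        sr = 16_000
        cfg = CQTConfig(hop=512)
        freqs = cfg.bin_frequencies()
        k_mid = 150
        t = np.arange(2 * sr) / sr
        x = np.sin(2 * np.pi * freqs[k_mid] * t + rng.uniform(0, 2 * np.pi))
        seg = AudioSegment(x, sr)
        spec = cqt(seg, cfg)
        assert spec.values.shape == (200, (x.size - 1) // 512 + 1)
        mid_frame = spec.values.shape[1] // 2
        assert abs(int(spec.values[:, mid_frame].argmax()) - k_mid) <= 1

        # direct evaluation of the definition for a handful of bins/frames
        nominal = cfg.kernel_lengths(sr)
        padded = np.concatenate([x, np.zeros(int(min(nominal.max(), x.size)))])
        for k in (40, 120, k_mid, 199):
            lk = int(min(nominal[k], x.size))
            n = np.arange(lk)
            kern = hann(lk) * np.exp(-2j * np.pi * cfg.quality_factor * n / int(nominal[k]))
            for tau in (0, mid_frame):
                val = np.abs(np.sum(padded[tau * 512 : tau * 512 + lk] * kern)) / lk
                assert spec.values[k, tau] == pytest.approx(val, rel=1e-6, abs=1e-12)

    def test_determinism(self, rng):
        x = rng.standard_normal(16_000) * 0.1
        seg = AudioSegment(x, 16_000)
        a = cqt(seg).values
        b = cqt(AudioSegment(x.copy(), 16_000)).values
        np.testing.assert_array_equal(a, b)


class TestMel:
    def test_mel_scale_closed_form(self):
        assert mel_scale(0.0) == 0.0
        assert mel_scale(700.0) == pytest.approx(2595 * np.log10(2), rel=1e-12)
        with pytest.raises(ValueError):
            mel_scale(-1.0)

    def test_mel_scale_strictly_increasing(self):
        grid = np.linspace(0, 8000, 500)
        assert np.all(np.diff(mel_scale(grid)) > 0)

    def test_zero_signal_zero_matrix(self):
        seg = AudioSegment(np.zeros(4096), 16_000)
        assert np.all(mel_spectrogram(seg).values == 0)

    def test_filterbank_covers_interior_bins(self):
        fb = mel_filterbank(128, 2048, 16_000)
        freqs = np.fft.rfftfreq(2048, d=1 / 16_000)
        interior = (freqs > freqs[1]) & (freqs < 8000 - freqs[1])
        assert np.all(fb.sum(axis=0)[interior] > 0)

    def test_matches_matrix_product_oracle(self, rng):
        x = rng.standard_normal(8192) * 0.2
        seg = AudioSegment(x, 16_000)
        cfg = MelConfig(n_mels=64)
        out = mel_spectrogram(seg, cfg).values
        stft_mag = stft(seg, STFTConfig(N=cfg.N, hop=cfg.hop)).values
        fb = mel_filterbank(64, cfg.N, 16_000)
        np.testing.assert_allclose(out, fb @ stft_mag, rtol=1e-8, atol=1e-12)


class TestRenderImage:
    def _spec(self, values):
        values = np.asarray(values, dtype=float)
        return Spectrogram(
            values=values,
            bin_frequencies=np.arange(values.shape[0], dtype=float),
            frame_times=np.arange(values.shape[1], dtype=float),
            kind="stft",
        )

    def test_constant_spectrogram_maps_to_lut_top(self):
        img = render_image(self._spec(np.full((40, 30), 3.7)))
        assert np.allclose(img.pixels, _LUT[255], atol=1e-12)

    def test_identity_resize_at_native_size(self, rng):
        vals = rng.random((100, 100)) + 0.1
        img = render_image(self._spec(vals))
        # independent step-by-step oracle without any resampling
        db = 20 * np.log10(vals + 1e-10)
        db = np.clip(db, db.max() - 80, db.max())
        norm = (db - db.min()) / (db.max() - db.min())
        oracle = _LUT[np.round(norm * 255).astype(int)]
        np.testing.assert_allclose(img.pixels, oracle, atol=1e-6)

    def test_full_chain_matches_step_by_step_oracle(self, rng):
        vals = rng.random((64, 37)) * 5
        img = render_image(self._spec(vals))
        db = 20 * np.log10(vals + 1e-10)
        db = np.clip(db, db.max() - 80, db.max())
        norm = (db - db.min()) / (db.max() - db.min())
        rgb = _LUT[np.round(norm * 255).astype(int)]
        # brute-force bilinear resize, half-pixel centers
        oracle = np.empty((100, 100, 3))
        h, w = 64, 37
        for i in range(100):
            for j in range(100):
                sy = min(max((i + 0.5) * h / 100 - 0.5, 0), h - 1)
                sx = min(max((j + 0.5) * w / 100 - 0.5, 0), w - 1)
                y0, x0 = int(sy), int(sx)
                y1, x1 = min(y0 + 1, h - 1), min(x0 + 1, w - 1)
                fy, fx = sy - y0, sx - x0
                oracle[i, j] = (
                    rgb[y0, x0] * (1 - fy) * (1 - fx)
                    + rgb[y0, x1] * (1 - fy) * fx
                    + rgb[y1, x0] * fy * (1 - fx)
                    + rgb[y1, x1] * fy * fx
                )
        np.testing.assert_allclose(img.pixels, oracle, atol=1e-6)

    def test_invariant_to_global_gain(self, rng):
        vals = rng.random((50, 40)) + 0.01
        a = render_image(self._spec(vals)).pixels
        b = render_image(self._spec(vals * 137.0)).pixels
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_bilinear_resize_identity(self, rng):
        img = rng.random((100, 100, 3))
        np.testing.assert_allclose(bilinear_resize(img, 100, 100), img, atol=1e-12)
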