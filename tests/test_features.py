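"""Feature estimators: spectra, band means, differential entropy, asymmetry families."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegscape.errors import ConfigurationError
from eegscape.features import (BandScheme, FeatureVector, band_variance, dasm,
                               dcau, de, extract_all, mas, psd, rasm, spectrum)
from eegscape.preprocess import Epoch
from tests.conftest import band_limited_gaussian

FS, N = 250.0, 500


def _epoch(x, cls=1):
    return Epoch(samples=x, class_id=cls, subject_id=0, video_instance=1, epoch_index=0)


def _sine_epoch(freq, amp=1.0, n_ch=29):
    t = np.arange(N) / FS
    return _epoch(np.tile(amp * np.sin(2 * np.pi * freq * t), (n_ch, 1)))


def _hann_line_amplitude(f0, amp, freqs):
    """Independent oracle: amplitude spectrum of a finite Hann-tapered sine.

    Direct evaluation of the windowed DFT sum, no FFT involved.
    """
    n = N
    t = np.arange(n) / FS
    w = np.hanning(n)
    out = []
    for f in freqs:
        c = np.sum(amp * np.sin(2 * np.pi * f0 * t) * w * np.exp(-2j * np.pi * f * t))
        out.append(2 * np.abs(c) / w.sum())
    return np.array(out)


class TestSpectrum:
    def test_unit_sine_peaks_at_one(self):
        freqs, amp, _ = spectrum(_sine_epoch(10.0))
        assert amp[0, np.argmin(np.abs(freqs - 10.0))] == pytest.approx(1.0, rel=0.02)

    def test_zero_epoch_gives_zero_spectra(self):
        freqs, amp, power = spectrum(_epoch(np.zeros((29, N))))
        assert not amp.any() and not power.any()

    def test_parseval(self):
        """Integrated periodogram equals variance (in expectation; averaged over channels)."""
        x = np.random.default_rng(0).standard_normal((2000, N))
        freqs, _, power = spectrum(_epoch(x))
        ratio = power.sum(axis=-1) * (freqs[1] - freqs[0]) / x.var(axis=-1)
        assert ratio.mean() == pytest.approx(1.0, abs=0.01)


class TestMAS:
    def test_matches_hann_line_oracle(self):
        bands = BandScheme()
        freqs = np.fft.rfftfreq(N, 1 / FS)
        mask = bands.bin_mask("alpha", freqs)
        expected = np.log(_hann_line_amplitude(10.0, 1.0, freqs[mask]).mean())
        got = mas(_sine_epoch(10.0), "alpha")
        np.testing.assert_allclose(got.values, expected, rtol=1e-6)

    def test_scaling_shifts_by_log_c(self):
        ep = _epoch(band_limited_gaussian(1, 29, 8, 12, 2.0))
        base = mas(ep, "alpha").values
        scaled = mas(_epoch(3.0 * ep.samples), "alpha").values
        np.testing.assert_allclose(scaled - base, np.log(3.0), atol=1e-12)

    def test_dimension(self):
        assert mas(_sine_epoch(10.0), "alpha").dim == 29


class TestPSD:
    def test_white_noise_log_density(self):
        sigma2 = 4.0
        vals = []
        for i in range(400):
            x = np.random.default_rng(i).standard_normal((4, N)) * np.sqrt(sigma2)
            vals.append(np.exp(psd(_epoch(x[:1].repeat(29, 0)), "beta").values))
        # mean density of white noise = sigma^2 / (fs/2)
        assert np.mean(vals) == pytest.approx(sigma2 / (FS / 2), rel=0.05)

    def test_scaling_shifts_by_two_log_c(self):
        ep = _epoch(band_limited_gaussian(2, 29, 14, 28, 1.0))
        shift = psd(_epoch(2.0 * ep.samples), "beta").values - psd(ep, "beta").values
        np.testing.assert_allclose(shift, 2 * np.log(2.0), atol=1e-12)


class TestDE:
    def test_gaussian_conformance_exact_for_in_band_signal(self):
        """Conditioned band-limited Gaussian: DE equals 1/2 ln(2 pi e sigma^2) exactly."""
        sigma = 3.0
        target = 0.5 * np.log(2 * np.pi * np.e * sigma ** 2)
        for seed in range(20):
            ep = _epoch(band_limited_gaussian(seed, 29, 9, 11.5, sigma))
            np.testing.assert_allclose(de(ep, "alpha").values, target, atol=1e-10)

    def test_zero_de_at_reference_variance(self):
        ep = _epoch(band_limited_gaussian(0, 29, 33, 67, 1.0))
        bv = band_variance(ep, "gamma")
        rescaled = _epoch(ep.samples / np.sqrt(bv * 2 * np.pi * np.e)[:, None])
        np.testing.assert_allclose(de(rescaled, "gamma").values, 0.0, atol=1e-10)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(c=st.floats(0.1, 50.0), seed=st.integers(0, 100))
    def test_scaling_identity(self, c, seed):
        ep = _epoch(band_limited_gaussian(seed, 5, 14, 28, 1.0).repeat(6, 0)[:29])
        shift = de(_epoch(c * ep.samples), "beta").values - de(ep, "beta").values
        np.testing.assert_allclose(shift, np.log(c), atol=1e-9)

    def test_filter_backend_close_to_projection(self):
        ep = _epoch(band_limited_gaussian(3, 29, 9, 11.5, 2.0))
        proj = band_variance(ep, "alpha", backend="projection")
        filt = band_variance(ep, "alpha", backend="filter")
        np.testing.assert_allclose(filt / proj, 1.0, atol=0.15)

    def test_de_is_affine_in_log_band_power(self):
        """For Gaussian signals DE and log band power differ by a constant."""
        des, logp = [], []
        for i in range(200):
            ep = _epoch(band_limited_gaussian(i, 1, 31, 69).repeat(29, 0))
            des.append(de(ep, "gamma").values[0])
            logp.append(np.log(band_variance(ep, "gamma")[0]))
        r = np.corrcoef(des, logp)[0, 1]
        assert r > 0.99
        np.testing.assert_allclose(np.array(des) - 0.5 * np.array(logp),
                                   0.5 * np.log(2 * np.pi * np.e), atol=1e-9)


class TestAsymmetryFamilies:
    def _mirror_swap(self, ep, montage):
        pos = {ch: i for i, ch in enumerate(montage.feature_channels)}
        x = ep.samples.copy()
        for l, r in montage.lr_pairs:
            x[[pos[l], pos[r]]] = x[[pos[r], pos[l]]]
        return _epoch(x)

    def test_dasm_antisymmetry_and_rasm_reciprocity(self, montage):
        ep = _epoch(band_limited_gaussian(7, 29, 14, 28, None))
        d = de(ep, "beta")
        d_sw = de(self._mirror_swap(ep, montage), "beta")
        np.testing.assert_allclose(dasm(d_sw, montage).values,
                                   -dasm(d, montage).values, atol=1e-12)
        np.testing.assert_allclose(rasm(d_sw, montage).values,
                                   1.0 / rasm(d, montage).values, atol=1e-12)

    def test_symmetric_epoch_gives_null_asymmetry(self, montage):
        pos = {ch: i for i, ch in enumerate(montage.feature_channels)}
        x = band_limited_gaussian(8, 29, 8, 12, 2.0)
        for l, r in montage.lr_pairs:
            x[pos[r]] = x[pos[l]]
        d = de(_epoch(x), "alpha")
        np.testing.assert_allclose(dasm(d, montage).values, 0.0, atol=1e-12)
        np.testing.assert_allclose(rasm(d, montage).values, 1.0, atol=1e-12)

    def test_dcau_frontal_scaling_shift(self, montage):
        pos = {ch: i for i, ch in enumerate(montage.feature_channels)}
        x = np.tile(band_limited_gaussian(9, 1, 14, 28, 2.0), (29, 1))
        d0 = de(_epoch(x), "beta")
        np.testing.assert_allclose(dcau(d0, montage).values, 0.0, atol=1e-12)
        c = 2.5
        x2 = x.copy()
        for f, _ in montage.fp_pairs:
            x2[pos[f]] *= c
        shift = dcau(de(_epoch(x2), "beta"), montage).values - dcau(d0, montage).values
        np.testing.assert_allclose(shift, np.log(c), atol=1e-10)

    def test_rasm_zero_denominator_flagged(self, montage):
        vals = np.ones(29)
        pos = {ch: i for i, ch in enumerate(montage.feature_channels)}
        vals[pos[montage.lr_pairs[0][1]]] = 1e-9  # denominator below sentinel threshold
        fv = FeatureVector("DE", "alpha", vals)
        out = rasm(fv, montage)
        assert np.isnan(out.values[0]) and np.isfinite(out.values[1:]).all()


class TestExtractAll:
    def test_dimensions_match_published_table(self, montage):
        eps = [_epoch(band_limited_gaussian(i, 29, 1, 70), cls=1 + i % 7) for i in range(6)]
        T = extract_all(eps, montage)
        dims = {"MAS": 29, "PSD": 29, "DE": 29, "DASM": 13, "RASM": 13, "DCAU": 11}
        for fam, d in dims.items():
            for b in ("delta", "theta", "alpha", "beta", "gamma"):
                assert T.values[(fam, b)].shape == (6, d)
            assert T.values[(fam, "total")].shape == (6, 5 * d)

    def test_total_is_ordered_concatenation(self, montage):
        eps = [_epoch(band_limited_gaussian(i, 29, 1, 70)) for i in range(3)]
        T = extract_all(eps, montage)
        manual = np.hstack([T.values[("DE", b)]
                            for b in ("delta", "theta", "alpha", "beta", "gamma")])
        np.testing.assert_array_equal(T.values[("DE", "total")], manual)

    def test_empty_input_gives_empty_tensor(self, montage):
        T = extract_all([], montage)
        assert T.n_epochs == 0
        assert T.values[("DE", "gamma")].shape == (0, 29)

    def test_band_energy_additivity(self, montage):
        """Per-band projection variances sum to the 1-70 Hz total variance."""
        ep = _epoch(band_limited_gaussian(11, 29, 1, 70))
        total = sum(band_variance(ep, b) for b in ("delta", "theta", "alpha", "beta", "gamma"))
        wide = band_variance(ep, "wide", BandScheme(bands={"wide": (1.0, 70.0)}))
        np.testing.assert_allclose(total, wide, rtol=1e-10)

    def test_wrong_dimension_is_constructor_error(self):
        with pytest.raises(ConfigurationError, match="dim"):
            FeatureVector("DASM", "alpha", np.zeros(12))
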