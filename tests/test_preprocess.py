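"""Preprocessing contracts: re-referencing, detrend, resample, filter, ICA, epoching."""

import numpy as np
import pytest

from eegscape.errors import ConfigurationError
from eegscape.montage import default_montage
from eegscape.preprocess import (Epoch, Recording, bandpass, detrend,
                                 remove_artifacts, rereference_mastoid,
                                 resample_to, segment)
from eegscape.simulate import NoiseModel, default_signatures, generate_subject
from tests.test_simulate import _short_schedule


def _rec(data, rate=250.0, labels=None, annotations=()):
    m = default_montage()
    labels = labels if labels is not None else list(m.electrodes)
    return Recording(samples=data, rate_hz=rate, channel_labels=labels,
                     annotations=list(annotations))


def test_rereference_subtracts_known_mastoid_offset(montage):
    rng = np.random.default_rng(0)
    n = 1000
    data = rng.standard_normal((32, n))
    i_l = montage.electrodes.index("TP9")
    i_r = montage.electrodes.index("TP10")
    offset = 0.5 * (data[i_l] + data[i_r])
    out = rereference_mastoid(_rec(data), montage)
    assert len(out.channel_labels) == 30
    for ch in out.channel_labels:
        np.testing.assert_allclose(
            out.samples[out.channel_labels.index(ch)],
            data[montage.electrodes.index(ch)] - offset, atol=1e-12)
    # zero mastoids: unchanged; channels equal to mastoids: all-zero
    data2 = rng.standard_normal((32, n))
    data2[i_l] = data2[i_r] = 0.0
    out2 = rereference_mastoid(_rec(data2), montage)
    np.testing.assert_allclose(out2.samples[0], data2[montage.electrodes.index(out2.channel_labels[0])])
    data3 = np.tile(rng.standard_normal(n), (32, 1))
    np.testing.assert_allclose(rereference_mastoid(_rec(data3), montage).samples, 0.0, atol=1e-12)


def test_rereference_missing_mastoid_errors(montage):
    labels = [ch for ch in montage.electrodes if ch != "TP9"]
    rec = _rec(np.zeros((31, 100)), labels=labels)
    with pytest.raises(ConfigurationError, match="TP9"):
        rereference_mastoid(rec, montage)


def test_detrend_removes_exactly_the_linear_component():
    n = 1000
    t = np.linspace(0, 1, n)
    sine = np.sin(2 * np.pi * 10 * t)
    data = np.vstack([3.0 * t + 1.0, sine + 5.0 * t])
    out = detrend(_rec(data, labels=["Fp1", "Fp2"]))
    np.testing.assert_allclose(out.samples[0], 0.0, atol=1e-10)
    # sine + ramp: residual is the sine minus its own tiny fitted trend
    np.testing.assert_allclose(out.samples[1], sine - np.polyval(
        np.polyfit(t, sine, 1), t), atol=1e-10)


def test_resample_preserves_sinusoid_and_halves_count():
    n = 5000
    t = np.arange(n) / 500.0
    data = np.sin(2 * np.pi * 10 * t)[None, :]
    rec = _rec(data, rate=500.0, labels=["Cz"])
    out = resample_to(rec, 250.0)
    assert out.samples.shape[1] == n // 2
    interior = slice(100, -100)  # polyphase edges excluded
    expected = np.sin(2 * np.pi * 10 * np.arange(n // 2) / 250.0)
    np.testing.assert_allclose(out.samples[0][interior], expected[interior], atol=0.01)
    assert resample_to(rec, 500.0) is rec
    with pytest.raises(ConfigurationError):
        resample_to(out, 500.0)


def test_bandpass_attenuation_and_passband():
    n = 5000
    t = np.arange(n) / 250.0
    rec = _rec(np.vstack([np.sin(2 * np.pi * 100 * t),
                          np.sin(2 * np.pi * 10 * t),
                          np.full(n, 3.0)]), labels=["Fp1", "Fp2", "Cz"])
    out = bandpass(rec, 0.5, 70.0)
    interior = slice(500, -500)
    stop_ratio = np.abs(out.samples[0][interior]).max()
    pass_ratio = np.abs(out.samples[1][interior]).max()
    assert 20 * np.log10(stop_ratio) < -20        # >=20 dB down at 100 Hz
    assert abs(20 * np.log10(pass_ratio)) < 1.0   # <1 dB ripple at 10 Hz
    assert np.abs(out.samples[2][interior]).max() < 0.05  # DC removed
    with pytest.raises(ConfigurationError):
        bandpass(rec, 0.5, 130.0)


def _blinky_pair(montage, blink_rate):
    """Short session generated with and without blinks, preprocessed to 250 Hz."""
    sched = _short_schedule(duration=10.0, rest=4.0)
    sigs = default_signatures(montage, effect_size=0.0)
    noise = NoiseModel(blink_rate_per_min=blink_rate, line_amp_uv=0.0)
    rec = generate_subject(sched, sigs, noise, montage, rate_hz=250.0, seed=3)
    rec = rereference_mastoid(rec, montage)
    return bandpass(rec, 0.5, 70.0)


def _lowfreq_frontal_power(rec, montage):
    from scipy import signal as sps
    fp1 = rec.samples[rec.channel_labels.index("Fp1")]
    f, p = sps.welch(fp1, fs=rec.rate_hz, nperseg=1024)
    return np.trapezoid(p[(f >= 0.5) & (f < 4)], f[(f >= 0.5) & (f < 4)])


def test_ica_removes_most_blink_power(montage):
    clean = _blinky_pair(montage, 0.0)
    dirty = _blinky_pair(montage, 20.0)
    repaired = remove_artifacts(dirty, method="ica", montage=montage, seed=0)
    p_clean = _lowfreq_frontal_power(clean, montage)
    p_dirty = _lowfreq_frontal_power(dirty, montage)
    p_rep = _lowfreq_frontal_power(repaired, montage)
    assert p_dirty > 2 * p_clean, "blinks should dominate frontal delta power"
    reduction = 1 - (p_rep - p_clean) / (p_dirty - p_clean)
    assert reduction >= 0.7


def test_artifact_none_is_identity_and_blink_free_ica_preserves_spectra(montage):
    clean = _blinky_pair(montage, 0.0)
    assert remove_artifacts(clean, method="none") is clean
    repaired = remove_artifacts(clean, method="ica", montage=montage, seed=0)
    from scipy import signal as sps
    for idx in (0, 10, 20):
        f, p0 = sps.welch(clean.samples[idx], fs=250.0, nperseg=1024)
        _, p1 = sps.welch(repaired.samples[idx], fs=250.0, nperseg=1024)
        band = (f >= 1) & (f <= 70)
        assert np.trapezoid(p1[band], f[band]) == pytest.approx(
            np.trapezoid(p0[band], f[band]), rel=0.10)
    with pytest.raises(ConfigurationError):
        remove_artifacts(clean, method="bogus")


def test_regression_reduces_frontal_blink_power(montage):
    clean = _blinky_pair(montage, 0.0)
    dirty = _blinky_pair(montage, 20.0)
    repaired = remove_artifacts(dirty, method="regression", montage=montage)
    assert _lowfreq_frontal_power(repaired, montage) < _lowfreq_frontal_power(dirty, montage)


class TestSegment:
    def _session(self, montage, n_blocks=14, block_s=40.0, amp=1.0, seed=0):
        rng = np.random.default_rng(seed)
        total = int((n_blocks * block_s + 10) * 250)
        labels = [ch for ch in montage.electrodes if ch not in montage.reference_labels]
        data = amp * rng.standard_normal((len(labels), total))
        ann = [(5.0 + i * block_s, block_s, 1 + i % 7) for i in range(n_blocks)]
        return Recording(samples=data, rate_hz=250.0, channel_labels=labels,
                         annotations=ann)

    def test_clean_block_yields_twenty_epochs(self, montage):
        rec = self._session(montage, n_blocks=1)
        eps = segment(rec, montage, reject_uv=100.0)
        assert len(eps) == 20
        assert all(e.samples.shape == (29, 500) for e in eps)

    def test_full_clean_session_yields_280(self, montage):
        eps = segment(self._session(montage), montage)
        assert len(eps) == 280
        # video_instance tracks the repeat number of each class
        first_cls = eps[0].class_id
        instances = {e.video_instance for e in eps if e.class_id == first_cls}
        assert instances == {1, 2}

    def test_spike_rejects_exactly_one_window(self, montage):
        rec = self._session(montage, n_blocks=1)
        rec.samples[0, int(5.0 * 250) + 700] = 150.0  # inside window 1
        eps = segment(rec, montage, reject_uv=100.0)
        assert len(eps) == 19

    def test_short_block_warns_and_yields_nothing(self, montage):
        rec = self._session(montage, n_blocks=1)
        rec.annotations = [(5.0, 1.0, 3)]
        with pytest.warns(UserWarning, match="shorter"):
            assert segment(rec, montage) == []

    def test_rejection_monotonicity(self, montage):
        rec = self._session(montage, n_blocks=3, amp=40.0)
        counts = [len(segment(rec, montage, reject_uv=r)) for r in (200, 120, 90, 60)]
        assert counts == sorted(counts, reverse=True)

    def test_wrong_rate_is_configuration_error(self, montage):
        rec = self._session(montage)
        rec.rate_hz = 500.0
        with pytest.raises(ConfigurationError, match="250"):
            segment(rec, montage)


def test_detrend_and_rereference_commute_on_trend_free_references(montage):
    rng = np.random.default_rng(4)
    data = rng.standard_normal((32, 2000))
    data += np.linspace(0, 5, 2000)[None, :] * rng.uniform(0.5, 1.5, (32, 1))
    i_l = montage.electrodes.index("TP9")
    i_r = montage.electrodes.index("TP10")
    for i in (i_l, i_r):  # strip the references' own linear trend
        data[i] = np.asarray(detrend(_rec(data[i][None, :], labels=["Cz"])).samples[0])
    a = detrend(rereference_mastoid(_rec(data), montage))
    b = rereference_mastoid(detrend(_rec(data)), montage)
    np.testing.assert_allclose(a.samples, b.samples, atol=1e-9)
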