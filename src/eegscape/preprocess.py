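"""Preprocessing: raw recording -> clean, labelled 2-s epochs.

Canonical stage order: mastoid re-reference -> linear detrend -> resample to
250 Hz -> 0.5-70 Hz zero-phase band-pass -> artifact removal (ICA or blink
regression) -> segmentation of each 40-s stimulus block into contiguous 2-s
windows with amplitude-based rejection.  A clean 40-s block yields 20
epochs; a clean 14-block session yields 280.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps
from scipy.stats import kurtosis

from eegscape.errors import ConfigurationError
from eegscape.montage import Montage, default_montage

TARGET_RATE_HZ = 250.0
EPOCH_S = 2.0


@dataclass
class Recording:
    """Continuous multichannel EEG in uV with stimulus annotations.

    ``samples`` is channels x time; ``annotations`` holds
    (onset_s, duration_s, class_id) per stimulus block, in seconds relative
    to the start of the record (resampling preserves them).
    """

    samples: np.ndarray
    rate_hz: float
    channel_labels: list[str]
    annotations: list[tuple[float, float, int]] = field(default_factory=list)
    subject_id: int = 0

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError("row count must equal number of channel labels")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        span = self.samples.shape[1] / self.rate_hz
        for on, dur, _ in self.annotations:
            if on < 0 or on + dur > span + 1e-6:
                raise ValueError(f"annotation ({on}, {dur}) outside record span {span:.3f}s")

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.rate_hz


@dataclass
class Epoch:
    """One labelled 2-s feature-channel segment (29 x 500 at 250 Hz)."""

    samples: np.ndarray
    class_id: int
    subject_id: int
    video_instance: int
    epoch_index: int


def rereference_mastoid(rec: Recording, montage: Montage | None = None) -> Recording:
    """Subtract the mastoid average 0.5*(TP9+TP10) from every channel; drop the references."""
    montage = montage or default_montage()
    left, right = montage.reference_labels
    for ref in (left, right):
        if ref not in rec.channel_labels:
            raise ConfigurationError(f"reference channel {ref} missing from recording")
    i_l = rec.channel_labels.index(left)
    i_r = rec.channel_labels.index(right)
    ref = 0.5 * (rec.samples[i_l] + rec.samples[i_r])
    keep = [i for i, ch in enumerate(rec.channel_labels) if ch not in (left, right)]
    out = rec.samples[keep] - ref[None, :]
    return replace(rec, samples=out,
                   channel_labels=[rec.channel_labels[i] for i in keep])


def detrend(rec: Recording) -> Recording:
    """Remove the per-channel least-squares linear trend (mean and slope)."""
    return replace(rec, samples=sps.detrend(rec.samples, axis=-1, type="linear"))


def resample_to(rec: Recording, target_hz: float = TARGET_RATE_HZ) -> Recording:
    """Anti-aliased polyphase downsampling; annotations stay in seconds."""
    if rec.rate_hz < target_hz:
        raise ConfigurationError("upsampling is out of scope")
    if rec.rate_hz == target_hz:
        return rec
    frac = Fraction(target_hz / rec.rate_hz).limit_denominator(1000)
    out = sps.resample_poly(rec.samples, frac.numerator, frac.denominator, axis=-1)
    return replace(rec, samples=out, rate_hz=float(target_hz))


def bandpass(rec: Recording, lo: float = 0.5, hi: float = 70.0) -> Recording:
    """Zero-phase 4th-order Butterworth band-pass (applied forward-backward)."""
    nyq = rec.rate_hz / 2.0
    if hi >= nyq:
        raise ConfigurationError(f"upper edge {hi} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=rec.rate_hz, output="sos")
    return replace(rec, samples=sps.sosfiltfilt(sos, rec.samples, axis=-1))


def _blink_reference(rec: Recording, montage: Montage) -> np.ndarray:
    """Low-frequency frontopolar average: a blink reference trace."""
    fp = [ch for ch in rec.channel_labels
          if montage.coords.get(ch, (0, 0))[1] >= 0.9]
    if not fp:  # fall back to most anterior available channel
        ys = [montage.coords.get(ch, (0, -2))[1] for ch in rec.channel_labels]
        fp = [rec.channel_labels[int(np.argmax(ys))]]
    idx = [rec.channel_labels.index(ch) for ch in fp]
    trace = rec.samples[idx].mean(axis=0)
    sos = sps.butter(4, 4.0, btype="lowpass", fs=rec.rate_hz, output="sos")
    return sps.sosfiltfilt(sos, trace)


def remove_artifacts(rec: Recording, method: str = "ica",
                     montage: Montage | None = None, n_components: int | None = None,
                     seed: int = 0, loading_ratio: float = 2.0,
                     kurtosis_min: float = 3.0, fit_decim: int = 4) -> Recording:
    """Suppress ocular artifacts.

    method="ica": FastICA decomposition; components are rejected when their
    mixing topography is frontally dominated (frontopolar loading more than
    ``loading_ratio`` times the channel average) and their time course has
    transient excess kurtosis above ``kurtosis_min`` — the canonical blink
    signature.  The record is reconstructed without the rejected components.

    method="regression": the low-passed (<4 Hz) frontopolar average is
    regressed out of every channel.

    method="none": identity.

    The ICA unmixing matrix is fit on every ``fit_decim``-th sample (the
    sources are stationary over the session, so decimation changes the
    estimate only marginally) and then applied to the full record.
    """
    montage = montage or default_montage()
    if method == "none":
        return rec
    if method == "regression":
        ref = _blink_reference(rec, montage)
        denom = float(ref @ ref)
        if denom == 0:
            return rec
        beta = rec.samples @ ref / denom
        return replace(rec, samples=rec.samples - beta[:, None] * ref[None, :])
    if method != "ica":
        raise ConfigurationError(f"unknown artifact method {method!r}")

    from sklearn.decomposition import FastICA

    n_ch = rec.samples.shape[0]
    k = n_components or n_ch
    if k > n_ch:
        raise ConfigurationError(f"{k} ICA components requested with only {n_ch} channels")
    X = rec.samples.T  # time x channels
    ica = FastICA(n_components=k, random_state=int(seed), whiten="unit-variance",
                  max_iter=500, tol=1e-4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # FastICA convergence warnings on benign data
        ica.fit(X[::max(int(fit_decim), 1)])
        S = ica.transform(X)
    mixing = ica.mixing_  # channels x components

    frontal = montage.frontal_loading()
    w_front = np.array([frontal[montage.electrodes.index(ch)]
                        if ch in montage.electrodes else 0.0
                        for ch in rec.channel_labels])
    load = np.abs(mixing)
    fp_load = (load * w_front[:, None]).sum(axis=0) / max(w_front.sum(), 1e-12)
    mean_load = load.mean(axis=0)
    kurt = kurtosis(S, axis=0, fisher=True)
    bad = (fp_load > loading_ratio * mean_load) & (kurt > kurtosis_min)

    S_clean = S.copy()
    S_clean[:, bad] = 0.0
    recon = S_clean @ mixing.T + ica.mean_[None, :]
    return replace(rec, samples=recon.T)


def segment(rec: Recording, montage: Montage | None = None, window_s: float = EPOCH_S,
            reject_uv: float = 100.0) -> list[Epoch]:
    """Cut non-overlapping 2-s windows from each annotated stimulus block.

    Windows are cut from block onset forward; a trailing partial window is
    discarded; any window containing a sample with \\|x\\| > reject_uv is
    rejected.  Epochs carry the block's class label, the repeat number of
    that class within the session (video_instance in {1, 2}) and a running
    epoch index.  Only the montage's 29 feature channels are kept, in
    montage order.
    """
    montage = montage or default_montage()
    if abs(rec.rate_hz - TARGET_RATE_HZ) > 1e-9:
        raise ConfigurationError(f"segment expects {TARGET_RATE_HZ:g} Hz input, got {rec.rate_hz:g}")
    try:
        idx = [rec.channel_labels.index(ch) for ch in montage.feature_channels]
    except ValueError as e:
        raise ConfigurationError(f"feature channel missing from recording: {e}")

    n_win = int(round(window_s * rec.rate_hz))
    epochs: list[Epoch] = []
    seen: dict[int, int] = {}
    epoch_index = 0
    for on, dur, cls in sorted(rec.annotations, key=lambda a: a[0]):
        seen[cls] = seen.get(cls, 0) + 1
        instance = seen[cls]
        i0 = int(round(on * rec.rate_hz))
        n_full = int(np.floor(dur * rec.rate_hz + 1e-9)) // n_win
        if n_full == 0:
            warnings.warn(f"block at {on:.1f}s shorter than the {window_s:.0f}s window; skipped")
            continue
        for w in range(n_full):
            a = i0 + w * n_win
            win = rec.samples[np.ix_(idx, range(a, a + n_win))]
            if np.max(np.abs(win)) > reject_uv:
                continue
            epochs.append(Epoch(samples=win, class_id=int(cls),
                                subject_id=rec.subject_id,
                                video_instance=instance, epoch_index=epoch_index))
            epoch_index += 1
    return epochs


def preprocess_recording(rec: Recording, montage: Montage | None = None,
                         artifact_method: str = "ica", reject_uv: float = 100.0,
                         lo_hz: float = 0.5, hi_hz: float = 70.0,
                         seed: int = 0) -> list[Epoch]:
    """Full canonical pipeline: rereference -> detrend -> resample -> bandpass -> artifacts -> segment."""
    montage = montage or default_montage()
    rec = rereference_mastoid(rec, montage)
    rec = detrend(rec)
    rec = resample_to(rec, TARGET_RATE_HZ)
    rec = bandpass(rec, lo_hz, hi_hz)
    rec = remove_artifacts(rec, method=artifact_method, montage=montage, seed=seed)
    return segment(rec, montage, reject_uv=reject_uv)
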