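"""Synthetic stimulus-locked EEG with controllable class-discriminative band power.

The generator emulates a landscape-perception viewing session: 14 stimulus
blocks of 40 s (7 landscape classes, each repeated twice, in seeded random
order) separated by 60 s rests, recorded on a 32-channel 10-20 cap.  Each
landscape class modulates the power of the narrowband oscillatory components
per channel and band through a :class:`ClassSignature`; the default
signatures load the discriminative signal into the gamma and beta bands,
with a small left-right gain differential, so high-frequency bands carry
most of the decodable information.

Signal model (per channel, summed):

* pink 1/f^alpha Gaussian background, synthesized by spectral shaping;
* five narrowband oscillations (band-pass-shaped Gaussian noise, one
  independent generator per band) whose amplitude inside a stimulus block
  is scaled by the block's class signature;
* a 50 Hz line-noise sinusoid common to all channels;
* eye blinks: 400 ms raised-cosine transients at Poisson-distributed times,
  projected onto a frontally weighted topography.

Everything is deterministic given (seed, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.fft import irfft, rfftfreq

from eegscape.errors import ConfigurationError
from eegscape.montage import Montage, default_montage

N_CLASSES = 7
CLASS_NAMES = {
    1: "forest", 2: "wetland", 3: "grassland", 4: "desert",
    5: "water", 6: "farmland", 7: "city",
}

#: Frequency bands (Hz); the canonical delta/theta/alpha/beta/gamma split.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 70.0),
}

#: Baseline RMS amplitude (uV) of each narrowband oscillation at rest.
DEFAULT_BAND_RMS_UV: dict[str, float] = {
    "delta": 5.0, "theta": 4.0, "alpha": 6.0, "beta": 3.0, "gamma": 2.0,
}


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered stimulus blocks of one viewing session.

    ``blocks`` is a list of (class_id, onset_s, duration_s); blocks are
    non-overlapping, separated by ``rest_duration_s`` of rest, and each of
    the 7 classes appears exactly twice (14 blocks).
    """

    blocks: tuple[tuple[int, float, float], ...]
    rest_duration_s: float
    randomized: bool
    seed: int
    lead_in_s: float = 5.0
    lead_out_s: float = 5.0

    @property
    def total_duration_s(self) -> float:
        last_cls, last_on, last_dur = self.blocks[-1]
        return last_on + last_dur + self.lead_out_s


@dataclass(frozen=True)
class ClassSignature:
    """Multiplicative per-band, per-channel power scaling for one class.

    ``band_gains[band]`` is a strictly positive power gain per montage
    electrode, applied to that band's oscillation inside the class's
    stimulus blocks.  ``effect_size == 0`` collapses all signatures to the
    identity (the null model).
    """

    class_id: int
    band_gains: dict[str, np.ndarray]
    asymmetry: float
    effect_size: float

    def __post_init__(self):
        for band, g in self.band_gains.items():
            if np.any(np.asarray(g) <= 0):
                raise ConfigurationError(f"non-positive gain in band {band} for class {self.class_id}")


@dataclass(frozen=True)
class NoiseModel:
    """Background and artifact parameters of the generator.

    alpha is the 1/f^alpha background exponent; powers/amplitudes in uV
    units; blink_rate in events per minute.
    """

    alpha: float = 1.0
    background_power_uv2: float = 64.0
    line_freq_hz: float = 50.0
    line_amp_uv: float = 2.0
    blink_rate_per_min: float = 10.0
    blink_amp_uv: float = 150.0
    blink_duration_s: float = 0.4

    def __post_init__(self):
        if min(self.background_power_uv2, self.line_amp_uv,
               self.blink_rate_per_min, self.blink_amp_uv) < 0:
            raise ConfigurationError("noise amplitudes must be non-negative")


def make_schedule(seed: int, block_duration_s: float = 40.0,
                  rest_duration_s: float = 60.0, lead_in_s: float = 5.0) -> StimulusSchedule:
    """Seeded random session schedule: 7 classes x 2 repeats = 14 blocks.

    The class order is a seeded permutation of the multiset {1..7} x 2;
    consecutive blocks are separated by ``rest_duration_s`` of rest.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(np.repeat(np.arange(1, N_CLASSES + 1), 2))
    blocks = []
    t = lead_in_s
    for cls in order:
        blocks.append((int(cls), float(t), float(block_duration_s)))
        t += block_duration_s + rest_duration_s
    return StimulusSchedule(blocks=tuple(blocks), rest_duration_s=rest_duration_s,
                            randomized=True, seed=int(seed), lead_in_s=lead_in_s)


def default_signatures(montage: Montage | None = None, effect_size: float = 1.0,
                       asymmetry: float = 0.1) -> list[ClassSignature]:
    """Gamma/beta-loaded class signatures with a small left-right differential.

    Gamma power gains are log-spaced across classes (exp(effect_size * u_k),
    u_k uniform on [-1, 1]); beta gains use the reversed ordering at 60% of
    the log-effect, so both high-frequency bands discriminate but not
    redundantly.  A left-right differential of +/- asymmetry * effect_size
    (log scale) rides on the gamma gains.  effect_size = 0 gives the exact
    null model.
    """
    montage = montage or default_montage()
    x = np.array([montage.coords[ch][0] for ch in montage.electrodes])
    side = np.sign(x)  # -1 left, +1 right, 0 midline
    u = np.linspace(-1.0, 1.0, N_CLASSES)
    out = []
    for k in range(1, N_CLASSES + 1):
        gains = {band: np.ones(len(montage.electrodes)) for band in BANDS}
        g_gamma = np.exp(effect_size * u[k - 1])
        g_beta = np.exp(0.6 * effect_size * u[::-1][k - 1])
        lr = np.exp(-asymmetry * effect_size * u[k - 1] * side)  # left up, right down for u>0
        gains["gamma"] = g_gamma * lr
        gains["beta"] = np.full(len(montage.electrodes), g_beta)
        out.append(ClassSignature(class_id=k, band_gains=gains,
                                  asymmetry=asymmetry, effect_size=effect_size))
    return out


def _shaped_noise(rng: np.random.Generator, n_ch: int, n: int, rate_hz: float,
                  shape_fn) -> np.ndarray:
    """Gaussian noise with the given one-sided amplitude shaping, unit RMS per channel.

    Synthesized directly in the frequency domain: independent complex
    Gaussian spectrum coefficients scaled by the shaping function, one
    inverse FFT — statistically identical to filtering white noise, at half
    the FFT cost.
    """
    f = rfftfreq(n, d=1.0 / rate_hz)
    nf = len(f)
    shape = shape_fn(f)
    nz = shape > 0
    spec = np.zeros((n_ch, nf), dtype=complex)
    k = int(nz.sum())
    spec[:, nz] = (rng.standard_normal((n_ch, k)) + 1j * rng.standard_normal((n_ch, k))) \
        * shape[nz][None, :]
    spec[:, 0] = spec[:, 0].real  # DC and (even-n) Nyquist bins must be real
    if n % 2 == 0:
        spec[:, -1] = spec[:, -1].real
    x = irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _pink_shape(alpha: float):
    def shape(f):
        a = np.zeros_like(f)
        a[f > 0] = f[f > 0] ** (-alpha / 2.0)
        return a
    return shape


def _band_shape(lo: float, hi: float, transition_hz: float = 0.5):
    """Band mask with raised-cosine edges to limit temporal ringing."""
    def shape(f):
        a = np.zeros_like(f)
        a[(f >= lo) & (f <= hi)] = 1.0
        for edge, sgn in ((lo, -1), (hi, +1)):
            t = (f - edge) * sgn
            m = (t > 0) & (t < transition_hz)
            a[m] = 0.5 * (1 + np.cos(np.pi * t[m] / transition_hz))
        return a
    return shape


def blink_times(noise: NoiseModel, duration_s: float, seed) -> np.ndarray:
    """Deterministic Poisson blink onsets (s) for a session; the generator uses exactly these."""
    rng = np.random.default_rng([_as_seed(seed), 3])
    n_events = rng.poisson(noise.blink_rate_per_min * duration_s / 60.0)
    t = np.sort(rng.uniform(0.0, max(duration_s - noise.blink_duration_s, 0.0), n_events))
    return t


def _as_seed(seed) -> int:
    s = int(seed)
    if s < 0:
        raise ConfigurationError("seeds must be non-negative")
    return s


def generate_subject(schedule: StimulusSchedule, signatures: list[ClassSignature],
                     noise: NoiseModel, montage: Montage | None = None,
                     rate_hz: float = 500.0, seed: int = 0,
                     band_rms_uv: dict[str, float] | None = None,
                     gain_jitter: float = 0.1, subject_id: int = 0):
    """Synthesize one full-session Recording for one subject.

    Within each stimulus block the expected power of band b on channel c is
    ``baseline_power * signature.band_gains[b][c]``; rests carry baseline
    statistics.  Per-subject variability is modelled as a log-domain jitter
    of the gains (gain ** (1 + u), u ~ U(-gain_jitter, +gain_jitter)), which
    leaves the null model (all gains 1) exactly invariant.

    Returns a :class:`eegscape.preprocess.Recording` whose annotations carry
    (onset_s, duration_s, class_id) for every stimulus block.
    """
    from eegscape.preprocess import Recording  # deferred: avoids import cycle

    montage = montage or default_montage()
    if rate_hz < 250:
        raise ConfigurationError("generation rate must be >= 250 Hz")
    sig_by_class = {s.class_id: s for s in signatures}
    missing = [k for k in range(1, N_CLASSES + 1) if k not in sig_by_class]
    if missing:
        raise ConfigurationError(f"missing class signatures for classes {missing}")
    band_rms = dict(DEFAULT_BAND_RMS_UV if band_rms_uv is None else band_rms_uv)

    n_ch = len(montage.electrodes)
    n = int(round(schedule.total_duration_s * rate_hz))
    seed = _as_seed(seed)

    # independent deterministic streams per component
    rng_bg = np.random.default_rng([seed, 0])
    rng_band = {b: np.random.default_rng([seed, 1, i]) for i, b in enumerate(BANDS)}
    rng_misc = np.random.default_rng([seed, 2])
    rng_jit = np.random.default_rng([seed, 4])

    data = np.zeros((n_ch, n))
    if noise.background_power_uv2 > 0:
        data += _shaped_noise(rng_bg, n_ch, n, rate_hz, _pink_shape(noise.alpha)) \
            * np.sqrt(noise.background_power_uv2)

    # per-subject log-domain gain jitter, one draw per (class, band)
    jit = {(k, b): 1.0 + rng_jit.uniform(-gain_jitter, gain_jitter)
           for k in range(1, N_CLASSES + 1) for b in BANDS}

    block_slices = [(cls, int(round(on * rate_hz)), int(round((on + dur) * rate_hz)))
                    for cls, on, dur in schedule.blocks]

    for band, (lo, hi) in BANDS.items():
        if band_rms.get(band, 0.0) <= 0:
            continue
        osc = _shaped_noise(rng_band[band], n_ch, n, rate_hz, _band_shape(lo, hi))
        osc *= band_rms[band]
        for cls, i0, i1 in block_slices:
            power_gain = sig_by_class[cls].band_gains[band] ** jit[(cls, band)]
            osc[:, i0:i1] *= np.sqrt(power_gain)[:, None]
        data += osc
        del osc

    if noise.line_amp_uv > 0:
        t = np.arange(n) / rate_hz
        phase = rng_misc.uniform(0, 2 * np.pi)
        data += noise.line_amp_uv * np.sin(2 * np.pi * noise.line_freq_hz * t + phase)[None, :]

    if noise.blink_rate_per_min > 0 and noise.blink_amp_uv > 0:
        loading = montage.frontal_loading()
        n_tpl = int(round(noise.blink_duration_s * rate_hz))
        tpl = 0.5 * (1 - np.cos(2 * np.pi * np.arange(n_tpl) / n_tpl))
        for t0 in blink_times(noise, schedule.total_duration_s, seed):
            i0 = int(round(t0 * rate_hz))
            seg = tpl[: n - i0]
            data[:, i0:i0 + len(seg)] += noise.blink_amp_uv * loading[:, None] * seg[None, :]

    annotations = [(on, dur, cls) for cls, on, dur in schedule.blocks]
    return Recording(samples=data, rate_hz=float(rate_hz),
                     channel_labels=list(montage.electrodes),
                     annotations=annotations, subject_id=subject_id)


def generate_dataset(n_subjects: int, base_seed: int = 0, montage: Montage | None = None,
                     signatures: list[ClassSignature] | None = None,
                     noise: NoiseModel | None = None, rate_hz: float = 500.0,
                     **kwargs) -> list:
    """One Recording per subject; schedules and signals independently seeded.

    Subject ``i`` uses schedule seed ``base_seed + i`` and an independent
    signal stream, so re-running with the same ``base_seed`` is bit-identical
    while subjects differ from one another.
    """
    if n_subjects < 1:
        raise ConfigurationError("n_subjects must be >= 1")
    montage = montage or default_montage()
    signatures = signatures if signatures is not None else default_signatures(montage)
    noise = noise or NoiseModel()
    out = []
    for i in range(n_subjects):
        sched = make_schedule(_as_seed(base_seed) + i)
        rec = generate_subject(sched, signatures, noise, montage, rate_hz=rate_hz,
                               seed=_as_seed(base_seed) * 1000 + i, subject_id=i,
                               **kwargs)
        out.append(rec)
    return out
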