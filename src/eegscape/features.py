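"""Six feature families per epoch per frequency band.

Frequency-domain families (29 values per band, one per feature channel):

* MAS — natural log of the mean one-sided FFT amplitude over the band's
  bins (Hann taper, taper-gain corrected);
* PSD — natural log of the mean periodogram density over the band's bins;
* DE  — differential entropy of the band-limited signal under the Gaussian
  model, 0.5 * ln(2*pi*e*sigma_b^2); the band variance sigma_b^2 is taken
  from the epoch's periodogram by default (a Butterworth time-domain
  backend is available, see :func:`band_variance`).

Spatial-domain families, derived from the per-band DE vector:

* DASM (13) — DE(left) - DE(right) over the mirror pairs;
* RASM (13) — DE(left) / DE(right);
* DCAU (11) — DE(frontal) - DE(posterior) over the caudal pairs.

The synthetic "total" band is the ordered concatenation of the five
per-band vectors, so per-family total dimensions are 145/145/145/65/65/55.

Band bins are half-open [lo, hi), except the gamma upper edge which is
inclusive at 70 Hz, so adjacent bands never double-count a bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal as sps

from eegscape.errors import ConfigurationError
from eegscape.montage import Montage, default_montage
from eegscape.preprocess import Epoch, TARGET_RATE_HZ

FAMILIES = ("MAS", "PSD", "DE", "DASM", "RASM", "DCAU")
BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")

#: Sentinel threshold: RASM denominators with |DE| below this are flagged NaN.
RASM_DENOM_EPS = 1e-6

_LOG2PIE = float(np.log(2 * np.pi * np.e))


@dataclass(frozen=True)
class BandScheme:
    """The five canonical bands plus the concatenated "total" pseudo-band."""

    bands: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "delta": (1.0, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 13.0),
        "beta": (13.0, 30.0), "gamma": (30.0, 70.0),
    })

    def __post_init__(self):
        prev_hi = None
        for name, (lo, hi) in self.bands.items():
            if lo >= hi:
                raise ConfigurationError(f"band {name}: lo must be < hi")
            if prev_hi is not None and lo < prev_hi:
                raise ConfigurationError(f"band {name} overlaps the previous band")
            prev_hi = hi

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.bands)

    def edges(self, band: str) -> tuple[float, float]:
        if band not in self.bands:
            raise ConfigurationError(f"unknown band {band!r}")
        return self.bands[band]

    def bin_mask(self, band: str, freqs: np.ndarray) -> np.ndarray:
        """Half-open [lo, hi) bin selection; the last band's upper edge is inclusive."""
        lo, hi = self.edges(band)
        last = band == list(self.bands)[-1]
        return (freqs >= lo) & ((freqs <= hi) if last else (freqs < hi))


@dataclass(frozen=True)
class FeatureVector:
    family: str
    band: str
    values: np.ndarray

    def __post_init__(self):
        expected = {"MAS": 29, "PSD": 29, "DE": 29, "DASM": 13, "RASM": 13, "DCAU": 11}
        n = expected[self.family] * (5 if self.band == "total" else 1)
        if len(self.values) != n:
            raise ConfigurationError(
                f"{self.family}/{self.band} has dim {len(self.values)}, expected {n}")

    @property
    def dim(self) -> int:
        return len(self.values)


def spectrum(epoch: Epoch, rate_hz: float = TARGET_RATE_HZ):
    """One-sided Hann-tapered amplitude and power spectra on a 0.5 Hz grid.

    Returns (freqs, amplitude, power_density).  Amplitude is gain-corrected
    so a unit sinusoid on a grid frequency peaks at 1.0; power is the
    periodogram density (uV^2/Hz) whose integral matches signal variance.
    """
    x = np.asarray(epoch.samples, dtype=float)
    n = x.shape[-1]
    w = np.hanning(n)
    X = np.fft.rfft(x * w, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    amp = 2.0 * np.abs(X) / w.sum()
    amp[..., 0] /= 2.0
    if n % 2 == 0:
        amp[..., -1] /= 2.0
    f2, power = sps.periodogram(x, fs=rate_hz, window="hann", axis=-1)
    assert np.allclose(f2, freqs)
    return freqs, amp, power


def _band_mean(values: np.ndarray, freqs: np.ndarray, bands: BandScheme, band: str) -> np.ndarray:
    mask = bands.bin_mask(band, freqs)
    if not mask.any():
        raise ConfigurationError(f"band {band} selects no frequency bins")
    return values[..., mask].mean(axis=-1)


def mas(epoch: Epoch, band: str, bands: BandScheme | None = None) -> FeatureVector:
    """Log mean amplitude spectrum over the band, per channel."""
    bands = bands or BandScheme()
    freqs, amp, _ = spectrum(epoch)
    return FeatureVector("MAS", band, np.log(np.maximum(_band_mean(amp, freqs, bands, band), 1e-300)))


def psd(epoch: Epoch, band: str, bands: BandScheme | None = None) -> FeatureVector:
    """Log mean periodogram density over the band, per channel."""
    bands = bands or BandScheme()
    freqs, _, power = spectrum(epoch)
    return FeatureVector("PSD", band, np.log(np.maximum(_band_mean(power, freqs, bands, band), 1e-300)))


@lru_cache(maxsize=32)
def _band_sos(lo: float, hi: float, rate_hz: float):
    return sps.butter(4, [lo, hi], btype="bandpass", fs=rate_hz, output="sos")


def band_variance(epoch: Epoch, band: str, bands: BandScheme | None = None,
                  backend: str = "projection", rate_hz: float = TARGET_RATE_HZ) -> np.ndarray:
    """Per-channel variance of the band-limited signal within the epoch.

    backend="projection" (default): variance of the orthogonal projection of
    the epoch onto the band's discrete Fourier subspace — equivalently the
    un-tapered periodogram summed over the band's bins times the bin width.
    This is an ideal zero-phase brick-wall band-pass evaluated exactly
    within the epoch: for a signal wholly inside the band it recovers the
    realized band variance with no loss, at the price of rectangular-window
    sidelobe leakage from strong out-of-band components.

    backend="hann": Hann-periodogram band sum; trades a few percent of
    narrowband variance (taper dispersion) for strong sidelobe suppression.

    backend="filter": variance after a zero-phase 4th-order Butterworth
    band-pass applied within the epoch (odd-reflection padding, padlen 100
    samples).  On 500-sample epochs this keeps only ~93-97% of the band
    variance (edge transients for narrow bands, passband droop for wide
    ones).
    """
    bands = bands or BandScheme()
    x = np.asarray(epoch.samples, dtype=float)
    if backend in ("projection", "hann"):
        window = "boxcar" if backend == "projection" else "hann"
        freqs, power = sps.periodogram(x, fs=rate_hz, window=window, axis=-1)
        mask = bands.bin_mask(band, freqs)
        if not mask.any():
            raise ConfigurationError(f"band {band} selects no frequency bins")
        return power[..., mask].sum(axis=-1) * (freqs[1] - freqs[0])
    if backend == "filter":
        lo, hi = bands.edges(band)
        sos = _band_sos(lo, hi, rate_hz)
        padlen = min(100, x.shape[-1] - 1)
        return sps.sosfiltfilt(sos, x, axis=-1, padlen=padlen).var(axis=-1)
    raise ConfigurationError(f"unknown DE backend {backend!r}")


def de(epoch: Epoch, band: str, bands: BandScheme | None = None,
       backend: str = "projection", rate_hz: float = TARGET_RATE_HZ) -> FeatureVector:
    """Differential entropy 0.5*ln(2*pi*e*sigma_b^2) of the band-limited signal.

    Under the Gaussian model the differential entropy of a signal with
    band variance sigma_b^2 is 0.5*ln(2*pi*e*sigma_b^2); sigma_b^2 comes
    from :func:`band_variance` (see its backend notes).  A zero-variance
    channel yields -inf.
    """
    var = band_variance(epoch, band, bands, backend=backend, rate_hz=rate_hz)
    with np.errstate(divide="ignore"):
        vals = 0.5 * (_LOG2PIE + np.log(var))
    return FeatureVector("DE", band, vals)


def _pair_indices(montage: Montage, pairs) -> tuple[np.ndarray, np.ndarray]:
    pos = {ch: i for i, ch in enumerate(montage.feature_channels)}
    try:
        a = np.array([pos[p[0]] for p in pairs])
        b = np.array([pos[p[1]] for p in pairs])
    except KeyError as e:
        raise ConfigurationError(f"pair member {e} not in feature channels")
    return a, b


def dasm(de_full: FeatureVector, montage: Montage | None = None) -> FeatureVector:
    """Differential asymmetry: DE(left) - DE(right) over the 13 mirror pairs."""
    montage = montage or default_montage()
    left, right = _pair_indices(montage, montage.lr_pairs)
    return FeatureVector("DASM", de_full.band, de_full.values[left] - de_full.values[right])


def rasm(de_full: FeatureVector, montage: Montage | None = None) -> FeatureVector:
    """Rational asymmetry: DE(left) / DE(right); near-zero denominators flagged NaN."""
    montage = montage or default_montage()
    left, right = _pair_indices(montage, montage.lr_pairs)
    den = de_full.values[right]
    vals = np.where(np.abs(den) < RASM_DENOM_EPS, np.nan, de_full.values[left] / den)
    return FeatureVector("RASM", de_full.band, vals)


def dcau(de_full: FeatureVector, montage: Montage | None = None) -> FeatureVector:
    """Differential caudality: DE(frontal) - DE(posterior) over the 11 caudal pairs."""
    montage = montage or default_montage()
    front, post = _pair_indices(montage, montage.fp_pairs)
    return FeatureVector("DCAU", de_full.band, de_full.values[front] - de_full.values[post])


@dataclass
class FeatureTensor:
    """All feature vectors of one subject, keyed by (family, band).

    ``values[(family, band)]`` is an (n_epochs x dim) array aligned with
    ``index`` (one row per retained epoch: epoch_index, class_id,
    video_instance).  "total" entries are the ordered concatenation of the
    five per-band blocks.
    """

    subject_id: int
    index: pd.DataFrame
    values: dict[tuple[str, str], np.ndarray]
    metadata: dict = field(default_factory=dict)

    @property
    def n_epochs(self) -> int:
        return len(self.index)

    def slice(self, family: str, band: str) -> tuple[np.ndarray, np.ndarray]:
        """(X, y) design for one (family, band) cell; rows with NaN sentinels dropped."""
        key = (family, band)
        if key not in self.values:
            raise KeyError(f"no slice for family={family!r} band={band!r}")
        X = self.values[key]
        y = self.index["class_id"].to_numpy()
        ok = np.isfinite(X).all(axis=1)
        if not ok.any():
            raise ValueError(f"all rows of {family}/{band} carry sentinel values")
        return X[ok], y[ok]


def extract_all(epochs: list[Epoch], montage: Montage | None = None,
                bands: BandScheme | None = None, de_backend: str = "projection") -> FeatureTensor:
    """Compute all six families over the five bands plus total for one subject's epochs."""
    montage = montage or default_montage()
    bands = bands or BandScheme()
    band_names = bands.names

    n = len(epochs)
    subject_id = epochs[0].subject_id if epochs else -1
    per_band: dict[tuple[str, str], list[np.ndarray]] = {
        (fam, b): [] for fam in FAMILIES for b in band_names}

    for ep in epochs:
        freqs, amp, power = spectrum(ep)
        for b in band_names:
            per_band[("MAS", b)].append(np.log(np.maximum(_band_mean(amp, freqs, bands, b), 1e-300)))
            per_band[("PSD", b)].append(np.log(np.maximum(_band_mean(power, freqs, bands, b), 1e-300)))
            de_b = de(ep, b, bands, backend=de_backend)
            per_band[("DE", b)].append(de_b.values)
            per_band[("DASM", b)].append(dasm(de_b, montage).values)
            per_band[("RASM", b)].append(rasm(de_b, montage).values)
            per_band[("DCAU", b)].append(dcau(de_b, montage).values)

    values: dict[tuple[str, str], np.ndarray] = {}
    dims = {"MAS": 29, "PSD": 29, "DE": 29, "DASM": 13, "RASM": 13, "DCAU": 11}
    for fam in FAMILIES:
        for b in band_names:
            arr = (np.vstack(per_band[(fam, b)]) if n
                   else np.empty((0, dims[fam])))
            if arr.shape[1] != dims[fam]:
                raise ConfigurationError(f"{fam}/{b} dimension {arr.shape[1]} != {dims[fam]}")
            values[(fam, b)] = arr
        values[(fam, "total")] = np.hstack([values[(fam, b)] for b in band_names]) \
            if n else np.empty((0, dims[fam] * len(band_names)))

    index = pd.DataFrame({
        "epoch_index": [ep.epoch_index for ep in epochs],
        "class_id": [ep.class_id for ep in epochs],
        "video_instance": [ep.video_instance for ep in epochs],
    })
    metadata = {
        "log_base": "e",
        "spectrum": "single Hann periodogram per 2 s epoch",
        "de_backend": de_backend,
        "band_bin_convention": "[lo, hi) except gamma upper edge inclusive",
        "total_band": "ordered concatenation delta|theta|alpha|beta|gamma",
    }
    return FeatureTensor(subject_id=subject_id, index=index, values=values, metadata=metadata)
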