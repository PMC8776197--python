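"""Shared fixtures: montage, band-limited Gaussian epoch factory, small sessions."""

from __future__ import annotations

import numpy as np
import pytest
from numpy.fft import irfft, rfftfreq

from eegscape.montage import default_montage
from eegscape.preprocess import Epoch

FS = 250.0
N = 500


@pytest.fixture(scope="session")
def montage():
    return default_montage()


def band_limited_gaussian(seed, n_ch, lo, hi, sigma=None, n=N, fs=FS):
    """Gaussian noise strictly inside [lo, hi] on the epoch's frequency grid.

    With ``sigma`` given, each channel is conditioned to exact sample
    standard deviation sigma (a spherical Gaussian draw), so the realized
    band variance is known exactly.
    """
    f = rfftfreq(n, 1.0 / fs)
    mask = (f >= lo) & (f <= hi)
    rng = np.random.default_rng(seed)
    spec = np.zeros((n_ch, len(f)), dtype=complex)
    spec[:, mask] = rng.standard_normal((n_ch, mask.sum())) \
        + 1j * rng.standard_normal((n_ch, mask.sum()))
    x = irfft(spec, n=n, axis=-1)
    if sigma is not None:
        x *= sigma / x.std(axis=-1, keepdims=True)
    return x


@pytest.fixture
def epoch_factory():
    def make(seed=0, lo=9.0, hi=11.5, sigma=3.0, n_ch=29, cls=1):
        return Epoch(samples=band_limited_gaussian(seed, n_ch, lo, hi, sigma),
                     class_id=cls, subject_id=0, video_instance=1, epoch_index=0)
    return make
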