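"""Spectral baseline feature vectors.

For a segment of duration Delta, each channel's discrete Fourier power is
taken at frequencies strictly between 0 and 100 Hz (DC excluded), floored,
and log-transformed; the vector is the mean across channels of the
per-channel log power.  The dimension depends only on Delta and the
sampling rate (frequency spacing 1/Delta).
"""

from __future__ import annotations

import warnings

import numpy as np

from .io import FeatureSet, Recording, StateInterval
from .surrogates import SurrogateSpec

FMAX_HZ = 100.0
POWER_FLOOR_REL = 1e-20


def fft_vector_freqs(n_samples: int, fs: float, fmax_hz: float = FMAX_HZ) -> np.ndarray:
    """Fourier frequencies kept in an FFT vector: 0 < f < fmax."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    return freqs[(freqs > 0) & (freqs < fmax_hz)]


def make_fft_vector(
    segment: np.ndarray,
    fs: float,
    fmax_hz: float = FMAX_HZ,
    log_of_mean: bool = False,
) -> np.ndarray:
    """Log-power vector below ``fmax_hz`` averaged across channels.

    ``log_of_mean=True`` switches to log of the channel-mean power instead
    of the default mean of per-channel log power.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 2 or segment.shape[1] < 4:
        raise ValueError("segment must be channels x samples with >= 4 samples")
    freqs = np.fft.rfftfreq(segment.shape[1], 1.0 / fs)
    keep = (freqs > 0) & (freqs < fmax_hz)
    power = np.abs(np.fft.rfft(segment, axis=1)[:, keep]) ** 2
    peak = power.max()
    if peak == 0:
        warnings.warn("all-zero segment: power floor engaged", stacklevel=2)
        peak = 1.0
    floored = np.maximum(power, POWER_FLOOR_REL * peak)
    if log_of_mean:
        return np.log(floored.mean(axis=0))
    return np.log(floored).mean(axis=0)


def make_fft_vectors(
    rec: Recording,
    intervals: list[StateInterval],
    window_s: float,
    n_per_interval: int = 500,
    surrogate: SurrogateSpec | None = None,
    seed: int = 0,
    fmax_hz: float = FMAX_HZ,
) -> FeatureSet:
    """Labeled FFT FeatureSet over equally spaced segments per interval."""
    from .ds_features import featurize_segments

    vectors, labels = featurize_segments(
        rec,
        intervals,
        window_s,
        n_per_interval,
        lambda seg: make_fft_vector(seg, rec.fs, fmax_hz),
        surrogate=surrogate,
        seed=seed,
    )
    return FeatureSet(
        vectors,
        labels,
        window_s,
        source="fft",
        surrogate=surrogate.kind if surrogate else "none",
        seed=seed,
    )
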