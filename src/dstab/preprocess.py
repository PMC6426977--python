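"""Zero-phase ideal (brick-wall) notch and bandpass filtering.

The filter operates by masking Fourier coefficients directly: coefficients
outside the passband, and inside each notch band, are zeroed; everything
retained is untouched.  This is exactly zero-phase and idempotent (the mask
is a projection), at the price of no transition band.  Line-noise removal at
50/100/150 Hz and a 5-500 Hz passband are the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Recording


class FilterSpecError(ValueError):
    pass


@dataclass
class FilterSpec:
    """Brick-wall filter description.

    notch_hz : centers of excluded line-noise bands (Hz)
    notch_halfwidth_hz : half-width of each excluded band (Hz)
    band_lo_hz, band_hi_hz : passband edges (Hz), inclusive
    """

    notch_hz: tuple[float, ...] = (50.0, 100.0, 150.0)
    notch_halfwidth_hz: float = 1.0
    band_lo_hz: float = 5.0
    band_hi_hz: float = 500.0

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        if not (0 < self.band_lo_hz < self.band_hi_hz):
            raise FilterSpecError("need 0 < band_lo < band_hi")
        if self.band_hi_hz > nyq:
            raise FilterSpecError(
                f"band_hi {self.band_hi_hz} Hz above Nyquist {nyq} Hz"
            )
        if self.notch_halfwidth_hz <= 0:
            raise FilterSpecError("notch half-width must be positive")
        for c in self.notch_hz:
            if not (0 < c < nyq):
                raise FilterSpecError(f"notch center {c} Hz outside (0, {nyq})")

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        """Boolean keep-mask over nonnegative Fourier frequencies."""
        keep = (freqs >= self.band_lo_hz) & (freqs <= self.band_hi_hz)
        for c in self.notch_hz:
            keep &= np.abs(freqs - c) > self.notch_halfwidth_hz
        return keep


def ideal_filter(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """Apply the brick-wall mask to every channel; returns a new Recording.

    Zero phase shift holds by construction: retained coefficients are
    passed through unchanged, so no phase is introduced anywhere.
    """
    if spec is None:
        spec = FilterSpec()
    if rec.n_samples < 4:
        raise ValueError("need at least 4 samples to filter")
    spec.validate(rec.fs)
    freqs = np.fft.rfftfreq(rec.n_samples, rec.dt)
    keep = spec.mask(freqs)
    coeffs = np.fft.rfft(rec.data, axis=1)
    coeffs[:, ~keep] = 0.0
    out = np.fft.irfft(coeffs, n=rec.n_samples, axis=1)
    meta = dict(rec.meta)
    meta["filter"] = {
        "notch_hz": list(spec.notch_hz),
        "notch_halfwidth_hz": spec.notch_halfwidth_hz,
        "band_hz": [spec.band_lo_hz, spec.band_hi_hz],
    }
    return Recording(out, rec.fs, list(rec.channel_ids), meta)
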