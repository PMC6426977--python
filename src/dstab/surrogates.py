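"""Surrogate procedures that destroy cross-channel structure.

Three controls, each preserving a different local property:

* ``phase`` — per-channel Fourier phase randomization; keeps each channel's
  power spectrum (hence autocorrelation) exactly, scrambles cross-channel
  phase relations.
* ``stagger`` — each channel circularly shifted forward by an independent
  random lag drawn fresh every time a segment is selected; keeps
  single-channel statistics, desynchronizes channels locally.
* ``global_stagger`` — the same per-channel lags, drawn once per
  experiment, applied to every segment.

Stagger lags come from a flat distribution of width 100*sqrt(12) ms
(standard deviation 100 ms); global-stagger lags from a flat distribution
of width 500 ms.  Shifts are circular, so the per-channel sample multiset
and spectrum are preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

STAGGER_WIDTH_S = 0.1 * np.sqrt(12.0)  # uniform width giving 100 ms std
GLOBAL_STAGGER_WIDTH_S = 0.5


@dataclass
class SurrogateSpec:
    """Which surrogate to apply and with what width.

    ``width_s`` defaults depend on kind: 0.1*sqrt(12) s for ``stagger``,
    0.5 s for ``global_stagger``; unused for ``phase``.
    """

    kind: str  # "phase" | "stagger" | "global_stagger"
    width_s: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("phase", "stagger", "global_stagger"):
            raise ValueError(f"unknown surrogate kind {self.kind!r}")
        if self.width_s is None:
            self.width_s = (
                STAGGER_WIDTH_S if self.kind == "stagger" else GLOBAL_STAGGER_WIDTH_S
            )
        if self.kind != "phase" and not self.width_s > 0:
            raise ValueError("stagger width must be positive")


def phase_surrogate(segment: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Randomize Fourier phases per channel, preserving each power spectrum.

    DC (and the Nyquist coefficient for even lengths) keep their phase so
    the inverse transform is exactly real.
    """
    segment = np.asarray(segment, dtype=float)
    n_ch, n = segment.shape
    if n < 4:
        raise ValueError("need at least 4 samples")
    coeffs = np.fft.rfft(segment, axis=1)
    n_bins = coeffs.shape[1]
    lo, hi = 1, n_bins - 1 if n % 2 == 0 else n_bins
    theta = rng.uniform(0.0, 2.0 * np.pi, size=(n_ch, hi - lo))
    coeffs[:, lo:hi] = np.abs(coeffs[:, lo:hi]) * np.exp(1j * theta)
    return np.fft.irfft(coeffs, n=n, axis=1)


def draw_stagger_lags(
    n_channels: int, fs: float, width_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Integer lags, one per channel, uniform on [0, width_s * fs)."""
    width_samples = int(round(width_s * fs))
    if width_samples < 1:
        raise ValueError(f"stagger width {width_s} s is below one sample at fs={fs}")
    return rng.integers(0, width_samples, size=n_channels)


def apply_lags(segment: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Circularly shift each channel forward in time by its lag."""
    segment = np.asarray(segment)
    out = np.empty_like(segment)
    for c, lag in enumerate(np.asarray(lags, dtype=int)):
        out[c] = np.roll(segment[c], lag)
    return out


def stagger_surrogate(
    segment: np.ndarray,
    fs: float,
    rng: np.random.Generator,
    width_s: float = STAGGER_WIDTH_S,
) -> np.ndarray:
    """Fresh independent circular shifts per channel (local staggering)."""
    lags = draw_stagger_lags(segment.shape[0], fs, width_s, rng)
    return apply_lags(segment, lags)


def global_stagger_lags(
    n_channels: int,
    fs: float,
    seed: int,
    width_s: float = GLOBAL_STAGGER_WIDTH_S,
) -> np.ndarray:
    """Per-experiment fixed lag vector, deterministic given the seed."""
    rng = np.random.default_rng(seed)
    return draw_stagger_lags(n_channels, fs, width_s, rng)
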