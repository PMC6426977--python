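"""Dynamical-stability (DS) feature vectors.

For a data segment of duration Delta (>= 0.5 s), ten equally spaced VAR(1)
models are fitted on delta = 0.5 s sub-windows (overlapping when
Delta < 5 s, tiling exactly at Delta = 5 s).  The pooled eigenmodes of the
ten fits are histogrammed on a fixed 20 x 20 grid spanning growth rates
tau in [-250, 25] 1/s (linear) and frequencies f in [4, 256] Hz
(logarithmic, base 2).  Flattening the grid row-major over tau rows
(frequency varying fastest) yields a 400-dimensional count vector; modes
outside the grid are dropped and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import FeatureSet, InfeasibleError, Recording, StateInterval, extract_segment_starts
from .modes import ModeSet, eig_modes, pool_modes
from .surrogates import (
    SurrogateSpec,
    apply_lags,
    global_stagger_lags,
    phase_surrogate,
    stagger_surrogate,
)
from .varfit import fit_var1

SUBWINDOW_S = 0.5
N_SUBWINDOW_FITS = 10


@dataclass(frozen=True)
class DSGrid:
    """The fixed coarse-graining grid for eigenmode distributions."""

    tau_min: float = -250.0
    tau_max: float = 25.0
    f_min: float = 4.0
    f_max: float = 256.0
    n_tau_bins: int = 20
    n_f_bins: int = 20

    @property
    def dim(self) -> int:
        return self.n_tau_bins * self.n_f_bins

    @property
    def tau_edges(self) -> np.ndarray:
        return np.linspace(self.tau_min, self.tau_max, self.n_tau_bins + 1)

    @property
    def log2f_edges(self) -> np.ndarray:
        return np.linspace(
            np.log2(self.f_min), np.log2(self.f_max), self.n_f_bins + 1
        )

    @property
    def f_edges(self) -> np.ndarray:
        return 2.0 ** self.log2f_edges


@dataclass
class DSVector:
    """One flattened eigenmode histogram with bookkeeping counts."""

    counts: np.ndarray
    n_modes_total: int
    n_modes_in_range: int
    segment_start_s: float = 0.0
    window_s: float = float("nan")
    surrogate: str = "none"

    def __post_init__(self) -> None:
        assert self.counts.sum() == self.n_modes_in_range <= self.n_modes_total


def subwindow_starts(
    segment_start_s: float,
    window_s: float,
    delta_s: float = SUBWINDOW_S,
    k: int = N_SUBWINDOW_FITS,
) -> np.ndarray:
    """``k`` equally spaced sub-window starts covering the segment.

    The first sub-window begins at the segment start and the last ends at
    the segment end; at ``window_s == delta_s`` all starts coincide.
    """
    if window_s < delta_s - 1e-12:
        raise InfeasibleError(
            f"segment of {window_s} s cannot hold a {delta_s} s sub-window"
        )
    if k == 1:
        return np.array([segment_start_s])
    return np.linspace(segment_start_s, segment_start_s + window_s - delta_s, k)


def bin_modes(
    modesets: list[ModeSet] | tuple[np.ndarray, np.ndarray],
    grid: DSGrid | None = None,
) -> DSVector:
    """Histogram pooled eigenmodes on the DS grid and flatten to a vector.

    Accepts either a list of fitted :class:`ModeSet` objects or a
    pre-pooled ``(tau, f)`` array pair.  Bins are half-open ``[lo, hi)``
    with the final bin closed at the top edge; each in-range mode
    increments exactly one cell.  Modes with rho = 0 (tau = -inf) never
    enter the pool.
    """
    if grid is None:
        grid = DSGrid()
    if isinstance(modesets, tuple):
        tau, f = modesets
        tau = np.asarray(tau, dtype=float)
        f = np.asarray(f, dtype=float)
    else:
        tau, f = pool_modes(modesets)
    with np.errstate(divide="ignore"):
        log2f = np.log2(np.maximum(f, 0.0))  # f = 0 -> -inf, safely out of range
    hist, _, _ = np.histogram2d(
        tau, log2f, bins=[grid.tau_edges, grid.log2f_edges]
    )
    counts = hist.astype(int).ravel()  # row-major: tau rows, f fastest
    return DSVector(
        counts=counts,
        n_modes_total=int(tau.size),
        n_modes_in_range=int(counts.sum()),
    )


def _surrogate_segment(
    segment: np.ndarray,
    fs: float,
    spec: SurrogateSpec | None,
    rng: np.random.Generator,
    fixed_lags: np.ndarray | None,
) -> np.ndarray:
    if spec is None:
        return segment
    if spec.kind == "phase":
        return phase_surrogate(segment, rng)
    if spec.kind == "stagger":
        return stagger_surrogate(segment, fs, rng, spec.width_s)
    return apply_lags(segment, fixed_lags)


def featurize_segments(
    rec: Recording,
    intervals: list[StateInterval],
    window_s: float,
    n_per_interval: int,
    vector_fn,
    surrogate: SurrogateSpec | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Shared segment-extraction/surrogation loop for DS and FFT vectors.

    ``vector_fn(segment) -> 1-D array`` maps a (possibly surrogated)
    channels x samples segment to a feature vector.
    """
    rng = np.random.default_rng(seed)
    fixed_lags = None
    if surrogate is not None and surrogate.kind == "global_stagger":
        fixed_lags = global_stagger_lags(
            rec.n_channels, rec.fs, seed=seed, width_s=surrogate.width_s
        )
    rows, labels = [], []
    for interval in intervals:
        for start in extract_segment_starts(interval, window_s, n_per_interval):
            seg = rec.segment(start, window_s)
            seg = _surrogate_segment(seg, rec.fs, surrogate, rng, fixed_lags)
            rows.append(vector_fn(seg))
            labels.append(interval.label)
    return np.array(rows), np.array(labels, dtype=object)


def ds_vector_from_segment(
    segment: np.ndarray,
    fs: float,
    grid: DSGrid | None = None,
    delta_s: float = SUBWINDOW_S,
    k_fits: int = N_SUBWINDOW_FITS,
    include_intercept: bool = True,
    normalize: bool = False,
) -> np.ndarray:
    """DS vector for one raw segment: k sub-window fits, pooled, binned."""
    if grid is None:
        grid = DSGrid()
    n = segment.shape[1]
    dt = 1.0 / fs
    window_s = n / fs
    n_sub = int(round(delta_s * fs))
    modesets = []
    for off in subwindow_starts(0.0, window_s, delta_s, k_fits):
        i0 = int(round(off * fs))
        sub = segment[:, i0 : i0 + n_sub]
        model = fit_var1(sub, dt=dt, include_intercept=include_intercept)
        modesets.append(eig_modes(model, dt))
    vec = bin_modes(modesets, grid).counts.astype(float)
    if normalize:
        total = vec.sum()
        if total > 0:
            vec = vec / total
    return vec


def make_ds_vectors(
    rec: Recording,
    intervals: list[StateInterval],
    window_s: float,
    n_per_interval: int = 500,
    surrogate: SurrogateSpec | None = None,
    seed: int = 0,
    grid: DSGrid | None = None,
    include_intercept: bool = True,
    normalize: bool = False,
) -> FeatureSet:
    """Build a labeled DS FeatureSet from a recording and its intervals.

    Per interval, ``n_per_interval`` equally spaced segments of duration
    ``window_s`` are drawn from the trimmed interval (overlap permitted),
    surrogated if requested, and reduced to 400-dimensional DS vectors.
    """
    vectors, labels = featurize_segments(
        rec,
        intervals,
        window_s,
        n_per_interval,
        lambda seg: ds_vector_from_segment(
            seg, rec.fs, grid, include_intercept=include_intercept, normalize=normalize
        ),
        surrogate=surrogate,
        seed=seed,
    )
    return FeatureSet(
        vectors,
        labels,
        window_s,
        source="ds",
        surrogate=surrogate.kind if surrogate else "none",
        seed=seed,
    )
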