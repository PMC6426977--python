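"""Least-squares estimation of first-order vector autoregressions.

The model is y_{n+1} = A y_n + c + u_n with white-noise innovations u_n.
A short window of N-channel data yields (n_samples - 1) regression
equations; A (and optionally the intercept c) is the minimum-norm
least-squares solution, computed through the SVD-backed solver so that
rank-deficient windows still return a well-defined estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


class DegenerateFitWarning(UserWarning):
    """Regressor matrix was rank deficient; minimum-norm solution returned."""


@dataclass
class VARModel:
    """Estimated VAR(1) coefficients for one data window.

    ``A`` is the N x N propagator whose eigenvalues carry the dynamical
    stability of the window; the intercept is a nuisance parameter and is
    never used downstream.
    """

    A: np.ndarray
    intercept: np.ndarray
    window_start_s: float = 0.0
    window_len_s: float = float("nan")
    n_samples_used: int = 0
    residual_norm: float = float("nan")
    rank: int = -1
    degenerate: bool = False

    @property
    def n_channels(self) -> int:
        return self.A.shape[0]


def fit_var1(
    segment: np.ndarray,
    dt: float = 1e-3,
    include_intercept: bool = True,
    rcond: float = 1e-10,
    window_start_s: float = 0.0,
) -> VARModel:
    """Fit a VAR(1) to a channels x samples window.

    Parameters
    ----------
    segment : ndarray, shape (n_channels, n_samples)
        Data window; ``n_samples`` transitions minus one become regression
        equations, so ``n_samples >= n_channels + 2`` is required for an
        overdetermined system.
    include_intercept : bool
        Fit a constant term alongside A (default).  Eigenvalue analysis
        uses A only either way.
    rcond : float
        Relative singular-value cutoff for rank decisions.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 2:
        raise ValueError("segment must be channels x samples")
    n_ch, n_samp = segment.shape
    if n_samp < n_ch + 2:
        raise ValueError(
            f"window of {n_samp} samples too short for {n_ch} channels "
            f"(need >= {n_ch + 2})"
        )
    if not np.all(np.isfinite(segment)):
        raise ValueError("segment contains non-finite values")

    x = segment[:, :-1]  # regressors, one column per transition
    y = segment[:, 1:]
    if include_intercept:
        x = np.vstack([x, np.ones(x.shape[1])])
    n_params = x.shape[0]

    coef, _, rank, _ = np.linalg.lstsq(x.T, y.T, rcond=rcond)
    degenerate = rank < n_params
    if degenerate:
        warnings.warn(
            f"rank-deficient regressors (rank {rank} < {n_params}); "
            "minimum-norm solution returned",
            DegenerateFitWarning,
            stacklevel=2,
        )
    coef = coef.T  # (n_ch, n_params)
    a = coef[:, :n_ch]
    c = coef[:, n_ch] if include_intercept else np.zeros(n_ch)
    resid = y - coef @ x
    return VARModel(
        A=a,
        intercept=c,
        window_start_s=window_start_s,
        window_len_s=n_samp * dt,
        n_samples_used=n_samp,
        residual_norm=float(np.linalg.norm(resid)),
        rank=int(rank),
        degenerate=degenerate,
    )
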