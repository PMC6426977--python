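"""Track stabilization over time with the Kolmogorov-Smirnov distance.

A reference distribution of damping timescales (tau values pooled from
consecutive short VAR(1) fits in an initial awake window) is compared
against the tau distribution at each subsequent timestamp.  The two-sample
KS statistic — the supremum gap between empirical CDFs — rises when the
dynamics stabilize (tau mass moves away from the reference), giving a
running index of departure from the awake baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import Recording
from .modes import eig_modes
from .varfit import fit_var1

SUBWINDOW_S = 0.5


def ks_statistic(sample_a, sample_b) -> float:
    """Two-sample Kolmogorov-Smirnov statistic sup_x |F_a(x) - F_b(x)|."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    return float(stats.ks_2samp(a, b).statistic)


@dataclass
class KSSeries:
    """KS distance from the reference tau distribution per timestamp."""

    times_s: np.ndarray
    ks: np.ndarray
    reference: tuple[float, float]  # (start_s, len_s) of the reference window
    meta: dict = field(default_factory=dict)


def pooled_taus(
    rec: Recording,
    start_s: float,
    n_fits: int,
    delta_s: float = SUBWINDOW_S,
    include_intercept: bool = True,
) -> np.ndarray:
    """Finite tau values pooled over consecutive delta-length fits."""
    taus = []
    for i in range(n_fits):
        seg = rec.segment(start_s + i * delta_s, delta_s)
        model = fit_var1(seg, dt=rec.dt, include_intercept=include_intercept)
        tau = eig_modes(model, rec.dt).tau
        taus.append(tau[np.isfinite(tau)])
    return np.concatenate(taus)


def track_stability(
    rec: Recording,
    reference_window: tuple[float, float],
    step_s: float,
    pool_fits: int = 20,
    delta_s: float = SUBWINDOW_S,
    include_intercept: bool = True,
) -> KSSeries:
    """KS time-course of the damping-timescale distribution.

    Parameters
    ----------
    reference_window : (start_s, len_s)
        Initial awake window; its consecutive delta-length fits define the
        reference tau distribution.
    step_s : float
        Spacing between successive tracked timestamps.
    pool_fits : int
        Consecutive delta-length fits pooled per timestamp (default 20,
        i.e. 10 s of data).
    """
    ref_start, ref_len = reference_window
    n_ref = max(1, int(round(ref_len / delta_s)))
    ref_taus = pooled_taus(rec, ref_start, n_ref, delta_s, include_intercept)

    span = pool_fits * delta_s
    if rec.duration_s < ref_start + ref_len + step_s:
        raise ValueError("recording shorter than reference window plus one step")
    times, values = [], []
    t = 0.0
    while t + span <= rec.duration_s + 1e-9:
        taus = pooled_taus(rec, t, pool_fits, delta_s, include_intercept)
        times.append(t + span / 2.0)
        values.append(ks_statistic(ref_taus, taus))
        t += step_s
    return KSSeries(
        times_s=np.array(times),
        ks=np.array(values),
        reference=(ref_start, ref_len),
        meta={"pool_fits": pool_fits, "delta_s": delta_s, "step_s": step_s},
    )
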