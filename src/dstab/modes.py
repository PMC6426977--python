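"""Map VAR(1) eigenvalues to dynamical modes in physical coordinates.

Each eigenvalue lambda_j = rho_j * exp(i * phi_j) of the propagator A
defines a mode with

    frequency    f_j   = |phi_j| / (2 * pi * dt)      [Hz]
    growth rate  tau_j = log(rho_j) / dt              [1/s]

tau < 0 means the mode is damped, tau = 0 marginally stable, tau > 0
unstable.  The natural logarithm is used.  Complex eigenvalues come in
conjugate pairs mapping to the same (f, tau): both members are retained, so
each oscillatory mode contributes two entries at a nonnegative frequency.
Zero eigenvalues (nilpotent directions) carry tau = -inf and are excluded
from any distribution built downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .varfit import VARModel


@dataclass(frozen=True)
class Mode:
    """One eigenmode in both eigenvalue and physical coordinates."""

    rho: float
    phi: float
    f: float
    tau: float


@dataclass
class ModeSet:
    """All N modes of one fitted window, as parallel arrays."""

    rho: np.ndarray
    phi: np.ndarray
    f: np.ndarray
    tau: np.ndarray
    window_start_s: float = 0.0

    def __len__(self) -> int:
        return len(self.rho)

    def __getitem__(self, j: int) -> Mode:
        return Mode(self.rho[j], self.phi[j], self.f[j], self.tau[j])

    @property
    def n_zero(self) -> int:
        """Number of rho = 0 modes (excluded from distributions)."""
        return int(np.sum(self.rho == 0))

    def finite(self) -> tuple[np.ndarray, np.ndarray]:
        """(tau, f) arrays of modes with finite tau (rho > 0)."""
        keep = np.isfinite(self.tau)
        return self.tau[keep], self.f[keep]


def eig_modes(model: VARModel | np.ndarray, dt: float) -> ModeSet:
    """Eigen-decompose a fitted propagator into (f, tau) modes.

    Accepts either a :class:`~dstab.varfit.VARModel` or a raw square matrix.
    """
    if isinstance(model, VARModel):
        a = model.A
        start = model.window_start_s
    else:
        a = np.asarray(model, dtype=float)
        start = 0.0
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("propagator must be square")
    if not np.all(np.isfinite(a)):
        raise ValueError("propagator contains non-finite entries")
    lam = np.linalg.eigvals(a)
    if not np.all(np.isfinite(lam)):
        raise ArithmeticError("eigenvalue computation returned non-finite values")
    rho = np.abs(lam)
    phi = np.angle(lam)
    f = np.abs(phi) / (2.0 * np.pi * dt)
    with np.errstate(divide="ignore"):
        tau = np.log(rho) / dt  # rho = 0 -> -inf sentinel
    return ModeSet(rho=rho, phi=phi, f=f, tau=tau, window_start_s=start)


def pool_modes(modesets: list[ModeSet]) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate finite (tau, f) pairs from several fitted windows."""
    if not modesets:
        raise ValueError("no mode sets to pool")
    taus, fs = zip(*(ms.finite() for ms in modesets))
    return np.concatenate(taus), np.concatenate(fs)
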