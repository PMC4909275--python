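"""Wave-shape estimation by functional linear regression.

With demodulated amplitude ``A~`` and phase ``phi~`` in hand, the model

    f(t) = A(t) [ alpha_0 + sum_{l=1..D} alpha_l cos(2 pi l phi(t))
                                        + beta_l sin(2 pi l phi(t)) ]

is linear in the shape coefficients.  Stacking the regressors

    c_0(k) = A~(k),  c_l(k) = A~(k) cos(2 pi l phi~(k)),
    d_l(k) = A~(k) sin(2 pi l phi~(k))

as the rows of a (2D+1) x N design matrix, ordinary least squares of the
recorded samples Y on those rows yields the *spectral pulse signature*
(SPS) ``gamma~ = (alpha~_0, alpha~_1..alpha~_D, beta~_1..beta~_D)`` — an
estimate of the wave-shape Fourier coefficients that is unaffected by
heart-rate variability, because the non-linear phase has been absorbed
into the regressors.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import PulseSignal, WaveShape, make_wave_shape
from .ridge import Demodulation

__all__ = ["DesignMatrix", "SPSVector", "build_design", "fit_sps",
           "reconstruct_signal", "harmonic_power", "sps_to_shape",
           "normalize_sps", "sps_to_wave_shape", "ConditioningError"]


class ConditioningError(np.linalg.LinAlgError):
    """Raised when the normal matrix of the regression is singular."""


@dataclass(frozen=True)
class DesignMatrix:
    """Functional regressors, shape (2D+1, N); row 0 is the amplitude trace."""

    c: np.ndarray
    D: int
    dt: float

    def __post_init__(self):
        if self.c.shape[0] != 2 * self.D + 1:
            raise ValueError("design must have 2D+1 rows")

    @property
    def n(self) -> int:
        return self.c.shape[1]


@dataclass(frozen=True)
class SPSVector:
    """Spectral pulse signature (alpha~_0, alpha~_1..D, beta~_1..D)."""

    gamma: np.ndarray
    D: int

    def __post_init__(self):
        g = np.asarray(self.gamma, dtype=float)
        object.__setattr__(self, "gamma", g)
        if g.shape != (2 * self.D + 1,):
            raise ValueError("gamma must have length 2D+1")
        if not np.all(np.isfinite(g)):
            raise ValueError("gamma must be finite")

    @property
    def alpha(self) -> np.ndarray:
        return self.gamma[: self.D + 1]

    @property
    def beta(self) -> np.ndarray:
        return self.gamma[self.D + 1:]

    @property
    def energy(self) -> float:
        return float(self.alpha[0] ** 2
                     + 0.5 * (self.alpha[1:] ** 2 + self.beta ** 2).sum())


def build_design(demod: Demodulation, D: int = 6) -> DesignMatrix:
    """Construct the (2D+1) x N functional design from a demodulation."""
    if D < 1:
        raise ValueError("D must be >= 1")
    A = demod.A
    phi = demod.phase
    N = A.size
    if N <= 2 * (2 * D + 1):
        raise ValueError(f"N={N} too small for 2D+1={2 * D + 1} parameters")
    ell = np.arange(1, D + 1)
    arg = 2.0 * np.pi * ell[:, None] * phi[None, :]
    c = np.empty((2 * D + 1, N))
    c[0] = A
    c[1:D + 1] = A[None, :] * np.cos(arg)
    c[D + 1:] = A[None, :] * np.sin(arg)
    dt = float(demod.times[1] - demod.times[0]) if demod.times.size > 1 else 1.0
    return DesignMatrix(c=c, D=D, dt=dt)


def fit_sps(Y: PulseSignal | np.ndarray, design: DesignMatrix,
            cond_warn: float = 1e8) -> SPSVector:
    """Least-squares SPS estimate: gamma~ = (Y c^T)(c c^T)^-1.

    Solved through a rank-revealing least-squares factorization rather than
    by inverting the normal matrix; mathematically identical when c c^T is
    invertible.  Warns above condition number ``cond_warn`` and raises
    :class:`ConditioningError` when the design is rank-deficient.
    """
    y = Y.samples if isinstance(Y, PulseSignal) else np.asarray(Y, float)
    if y.size != design.n:
        raise ValueError("signal and design lengths differ")
    C = design.c
    G = C @ C.T
    cond = np.linalg.cond(G)
    if not np.isfinite(cond) or cond > 1e15:
        raise ConditioningError(
            "design is numerically singular (constant phase?)")
    if cond > cond_warn:
        warnings.warn(f"ill-conditioned design (cond={cond:.3g})",
                      RuntimeWarning, stacklevel=2)
    gamma, _, rank, _ = np.linalg.lstsq(C.T, y, rcond=None)
    if rank < C.shape[0]:
        raise ConditioningError("rank-deficient design")
    return SPSVector(gamma=gamma, D=design.D)


def reconstruct_signal(sps: SPSVector, design: DesignMatrix) -> np.ndarray:
    """Fitted oscillatory signal ``f~ = gamma~^T c``."""
    if sps.D != design.D:
        raise ValueError("SPS and design have different harmonic cutoffs")
    return sps.gamma @ design.c


def harmonic_power(sps: SPSVector) -> np.ndarray:
    """Estimated power spectrum of the shape: p_l = (alpha_l^2 + beta_l^2)/4.

    This equals ``a_l^2 = |s-hat(l)|^2``; the harmonic phase information the
    SPS retains is deliberately discarded here.
    """
    return (sps.alpha[1:] ** 2 + sps.beta ** 2) / 4.0


def sps_to_shape(sps: SPSVector, n_grid: int = 256) -> np.ndarray:
    """Sample the estimated wave shape on a uniform unit-period grid."""
    if n_grid < 2 * sps.D + 1:
        raise ValueError("n_grid too small to resolve the harmonics")
    u = np.arange(n_grid) / n_grid
    ell = np.arange(1, sps.D + 1)
    arg = 2.0 * np.pi * np.outer(u, ell)
    return (sps.alpha[0] + np.cos(arg) @ sps.alpha[1:]
            + np.sin(arg) @ sps.beta)


def normalize_sps(sps: SPSVector) -> SPSVector:
    """Rescale to unit shape energy (removes the AM/shape amplitude gauge)."""
    e = sps.energy
    if e == 0:
        raise ValueError("cannot normalize a zero SPS")
    return SPSVector(gamma=sps.gamma / np.sqrt(e), D=sps.D)


def sps_to_wave_shape(sps: SPSVector) -> WaveShape:
    """View the SPS as a wave-shape function (for evaluation/comparison)."""
    return make_wave_shape(sps.alpha, sps.beta, normalize=False)
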