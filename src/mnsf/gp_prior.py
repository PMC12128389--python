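"""Gaussian-process prior: kernel, affine mean, and sparse conditioning.

The spatial prior on each log-scale factor is a GP with an affine mean
``mu(x) = beta0 + beta1 . x`` and an exponential (Matern-1/2) covariance

    k(a, b) = amplitude * exp(-||a - b|| / lengthscale)

The sparse approximation conditions the factor at observed spots on its values
``U`` at a set of inducing locations ``Z`` through the usual Gaussian
conditional (Schur complement):

    F | U ~ N( mu(X) + Kxu Kuu^{-1} (U - mu(Z)),  Kxx - Kxu Kuu^{-1} Kux )
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist

__all__ = [
    "KernelParams",
    "InducingSet",
    "ConditionalGaussian",
    "kernel_value",
    "cross_covariance",
    "gp_mean",
    "conditional_factor",
    "sample_conditional",
]

DEFAULT_JITTER = 1e-6


@dataclass
class KernelParams:
    """Exponential-kernel hyperparameters (both strictly positive)."""

    amplitude: float
    lengthscale: float

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.lengthscale <= 0:
            raise ValueError("amplitude and lengthscale must be > 0")


@dataclass
class InducingSet:
    """Inducing locations, optionally with their indices into the spot list."""

    Z: np.ndarray
    indices: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim != 2 or self.Z.shape[1] != 2:
            raise ValueError("inducing locations must be an n x 2 matrix")
        if self.Z.shape[0] < 1:
            raise ValueError("need at least one inducing point")
        if self.indices is not None:
            self.indices = np.asarray(self.indices, dtype=int)

    @property
    def n_points(self) -> int:
        return self.Z.shape[0]


@dataclass
class ConditionalGaussian:
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ValueError("cov must be square and match mean length")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("cov must be symmetric within 1e-8")


def _as_points(X: np.ndarray, name: str) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != 2:
        raise ValueError(f"{name} must have exactly 2 columns (2-D locations)")
    return X


def kernel_value(a: np.ndarray, b: np.ndarray, params: KernelParams) -> float:
    """``amplitude * exp(-||a-b|| / lengthscale)`` for two 2-D points."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != (2,) or b.shape != (2,):
        raise ValueError("kernel_value expects 2-D points")
    d = float(np.sqrt(np.sum((a - b) ** 2)))
    return params.amplitude * float(np.exp(-d / params.lengthscale))


def cross_covariance(
    X1: np.ndarray, X2: np.ndarray, params: KernelParams
) -> np.ndarray:
    """Kernel matrix with entry (i, j) = k(X1[i], X2[j])."""
    X1 = _as_points(X1, "X1")
    X2 = _as_points(X2, "X2")
    D = cdist(X1, X2)
    return params.amplitude * np.exp(-D / params.lengthscale)


def gp_mean(X: np.ndarray, beta0: float, beta1: np.ndarray) -> np.ndarray:
    """Affine GP mean ``beta0 + X @ beta1`` evaluated at each row of X."""
    X = _as_points(X, "X")
    beta1 = np.asarray(beta1, dtype=float).ravel()
    if beta1.shape != (2,):
        raise ValueError("beta1 must be a 2-vector")
    return beta0 + X @ beta1


def conditional_factor(
    U: np.ndarray,
    Z: InducingSet | np.ndarray,
    X: np.ndarray,
    kparams: KernelParams,
    beta0: float,
    beta1: np.ndarray,
    jitter: float = DEFAULT_JITTER,
) -> ConditionalGaussian:
    """Gaussian conditional of the factor at ``X`` given values ``U`` at ``Z``.

    ``jitter`` (scaled by the kernel amplitude) is added to the diagonal of
    ``Kuu`` before solving.
    """
    Zm = Z.Z if isinstance(Z, InducingSet) else _as_points(Z, "Z")
    X = _as_points(X, "X")
    U = np.asarray(U, dtype=float).ravel()
    if U.shape[0] != Zm.shape[0]:
        raise ValueError("U must have one value per inducing point")

    Kuu = cross_covariance(Zm, Zm, kparams)
    Kuu[np.diag_indices_from(Kuu)] += jitter * kparams.amplitude
    Kxu = cross_covariance(X, Zm, kparams)
    Kxx = cross_covariance(X, X, kparams)
    try:
        cf = cho_factor(Kuu, lower=True)
    except np.linalg.LinAlgError as err:  # pragma: no cover - diagnostic path
        raise np.linalg.LinAlgError(
            f"inducing-point covariance not positive definite even with "
            f"jitter={jitter:g} (n={Zm.shape[0]})"
        ) from err

    delta = U - gp_mean(Zm, beta0, beta1)
    mean = gp_mean(X, beta0, beta1) + Kxu @ cho_solve(cf, delta)
    cov = Kxx - Kxu @ cho_solve(cf, Kxu.T)
    cov = 0.5 * (cov + cov.T)
    return ConditionalGaussian(mean=mean, cov=cov)


def sample_conditional(
    cg: ConditionalGaussian, n_draws: int, seed: int, jitter: float = 1e-10
) -> np.ndarray:
    """Draw ``n_draws`` reproducible samples from N(mean, cov + jitter*I)."""
    rng = np.random.default_rng(seed)
    n = cg.mean.size
    cov = cg.cov + jitter * np.eye(n)
    eigmin = float(np.min(np.linalg.eigvalsh(cov)))
    if eigmin < -1e-6:
        raise np.linalg.LinAlgError(
            f"covariance is not PSD within tolerance (min eigenvalue {eigmin:g})"
        )
    # clip tiny negative eigenvalues from round-off
    if eigmin < 0:
        cov += (-eigmin + 1e-12) * np.eye(n)
    L = np.linalg.cholesky(cov)
    eps = rng.standard_normal((n_draws, n))
    return cg.mean[None, :] + eps @ L.T
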