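"""Data containers and observation-layer math for multi-sample spatial factorization.

The observation model is shared by all variants: counts for gene ``g`` at spot
``i`` of sample ``m`` are negative-binomial with mean

    mu_{mgi} = sz_{mi} * sum_l W[g, l] * exp(F_m[i, l])

where ``W`` (genes x factors, non-negative) is shared across samples and the
log-scale factors ``F_m`` are sample-specific.  The NB is parameterized by mean
``mu`` and shape ``phi`` with variance ``mu + mu**2 / phi``, so the Poisson
model is recovered as ``phi -> inf``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln, xlogy

__all__ = [
    "SampleData",
    "ModelParams",
    "FactorMatrix",
    "validate_dataset",
    "linear_predictor",
    "nb_log_likelihood",
    "poisson_deviance",
    "pnmf_log_prior",
]


@dataclass
class SampleData:
    """Counts, spot coordinates and size factors for a single sample.

    Parameters
    ----------
    counts
        Integer matrix, spots x genes, entries >= 0.
    coords
        Real matrix, spots x 2, in arbitrary physical units.
    size_factors
        Strictly positive per-spot normalizers; if omitted, all ones.
    sample_id
        Identifier used in outputs and error messages.
    labels
        Optional per-spot categorical annotation (e.g. cortical layer).
    spot_ids
        Optional per-spot identifiers (barcodes); generated if omitted.
    gene_ids
        Optional ordered gene list; must agree across samples of a dataset.
    """

    counts: np.ndarray
    coords: np.ndarray
    size_factors: Optional[np.ndarray] = None
    sample_id: str = "sample"
    labels: Optional[np.ndarray] = None
    spot_ids: Optional[np.ndarray] = None
    gene_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError(f"{self.sample_id}: counts must be 2-D (spots x genes)")
        if np.any(self.counts < 0):
            raise ValueError(f"{self.sample_id}: counts must be non-negative")
        if not np.allclose(self.counts, np.round(self.counts)):
            raise ValueError(f"{self.sample_id}: counts must be integers")
        self.counts = self.counts.astype(np.int64)

        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(f"{self.sample_id}: coords must have exactly 2 columns")
        if self.coords.shape[0] != self.counts.shape[0]:
            raise ValueError(f"{self.sample_id}: coords/counts spot mismatch")

        if self.size_factors is None:
            self.size_factors = np.ones(self.counts.shape[0])
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        if self.size_factors.shape != (self.counts.shape[0],):
            raise ValueError(f"{self.sample_id}: size_factors length mismatch")
        if np.any(self.size_factors <= 0):
            raise ValueError(f"{self.sample_id}: size_factors must be > 0")

        if self.spot_ids is None:
            self.spot_ids = np.array(
                [f"{self.sample_id}_spot{i}" for i in range(self.counts.shape[0])]
            )
        else:
            self.spot_ids = np.asarray(self.spot_ids)
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.counts.shape[0]:
                raise ValueError(f"{self.sample_id}: labels length mismatch")
        if self.gene_ids is not None:
            self.gene_ids = np.asarray(self.gene_ids)
            if self.gene_ids.shape[0] != self.counts.shape[1]:
                raise ValueError(f"{self.sample_id}: gene_ids length mismatch")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


def validate_dataset(samples: Sequence[SampleData]) -> None:
    """Check that all samples share the same ordered gene axis."""
    if len(samples) == 0:
        raise ValueError("dataset must contain at least one sample")
    n_genes = samples[0].n_genes
    ref_ids = samples[0].gene_ids
    for s in samples[1:]:
        if s.n_genes != n_genes:
            raise ValueError(
                f"gene axis mismatch: {s.sample_id} has {s.n_genes} genes, "
                f"expected {n_genes}"
            )
        if ref_ids is not None and s.gene_ids is not None:
            if not np.array_equal(ref_ids, s.gene_ids):
                raise ValueError(f"gene id order differs in {s.sample_id}")


@dataclass
class FactorMatrix:
    """Latent factors on the log scale; ``exp(values)`` is the non-negative usage."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("factor matrix must be 2-D (spots x factors)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("factor matrix must be finite")

    @property
    def usage(self) -> np.ndarray:
        """Factors on the non-negative (exp) scale."""
        return np.exp(self.values)


@dataclass
class ModelParams:
    """Shared loadings plus per-sample, per-factor GP hyperparameters.

    ``W`` is genes x factors and non-negative at all times.  Kernel amplitude,
    lengthscale, mean intercept/slope and NB dispersion are arrays indexed by
    (sample, factor) — dispersion by sample only.
    """

    W: np.ndarray
    dispersion: np.ndarray  # (M,)
    kernel_amplitude: np.ndarray  # (M, L)
    kernel_lengthscale: np.ndarray  # (M, L)
    mean_intercept: np.ndarray  # (M, L)
    mean_slope: np.ndarray  # (M, L, 2)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2:
            raise ValueError("W must be 2-D (genes x factors)")
        if np.any(self.W < 0):
            raise ValueError("W must be non-negative")
        for name in ("dispersion", "kernel_amplitude", "kernel_lengthscale"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if np.any(arr <= 0):
                raise ValueError(f"{name} must be strictly positive")
        self.mean_intercept = np.asarray(self.mean_intercept, dtype=float)
        self.mean_slope = np.asarray(self.mean_slope, dtype=float)

    @property
    def n_factors(self) -> int:
        return self.W.shape[1]

    @property
    def n_samples(self) -> int:
        return self.dispersion.shape[0]


def linear_predictor(
    W: np.ndarray, F: FactorMatrix | np.ndarray, size_factors: np.ndarray
) -> np.ndarray:
    """NB mean matrix: ``mu[i, g] = sz[i] * sum_l W[g, l] * exp(F[i, l])``.

    Homogeneous of degree one in both ``W`` and ``size_factors``.
    """
    Fv = F.values if isinstance(F, FactorMatrix) else np.asarray(F, dtype=float)
    W = np.asarray(W, dtype=float)
    size_factors = np.asarray(size_factors, dtype=float)
    if np.any(W < 0):
        raise ValueError("W must be non-negative")
    if W.ndim != 2 or Fv.ndim != 2 or W.shape[1] != Fv.shape[1]:
        raise ValueError(
            f"shape mismatch: W {W.shape} vs F {Fv.shape} (factor axes must agree)"
        )
    if size_factors.shape != (Fv.shape[0],):
        raise ValueError("size_factors length must equal the number of spots")
    return size_factors[:, None] * (np.exp(Fv) @ W.T)


def nb_log_likelihood(Y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """Sum of NB log-pmf over all entries, mean/shape parameterization.

    ``Var = mu + mu**2 / phi``; as ``phi -> inf`` this approaches the Poisson
    log-likelihood.
    """
    Y = np.asarray(Y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if phi <= 0:
        raise ValueError("dispersion phi must be > 0")
    if np.any(mu <= 0):
        raise ValueError("NB mean must be strictly positive")
    lp = (
        gammaln(Y + phi)
        - gammaln(phi)
        - gammaln(Y + 1.0)
        + phi * np.log(phi / (phi + mu))
        + Y * np.log(mu / (phi + mu))
    )
    return float(np.sum(lp))


def poisson_deviance(Y: np.ndarray, mu: np.ndarray) -> float:
    """Poisson deviance ``2 * sum[y*log(y/mu) - (y - mu)]`` with 0*log(0) = 0."""
    Y = np.asarray(Y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("predicted means must be strictly positive")
    dev = 2.0 * np.sum(xlogy(Y, Y) - xlogy(Y, mu) - (Y - mu))
    return float(max(dev, 0.0))


def pnmf_log_prior(
    F: FactorMatrix | np.ndarray, mu_l: np.ndarray, sigma2_l: np.ndarray
) -> float:
    """iid normal log-density of the non-spatial (mPNMF) factor prior.

    Each column ``F[:, l]`` is iid ``N(mu_l[l], sigma2_l[l])``; the parameters
    are factor-specific but shared across samples.
    """
    Fv = F.values if isinstance(F, FactorMatrix) else np.asarray(F, dtype=float)
    mu_l = np.atleast_1d(np.asarray(mu_l, dtype=float))
    sigma2_l = np.atleast_1d(np.asarray(sigma2_l, dtype=float))
    if np.any(sigma2_l <= 0):
        raise ValueError("sigma2 must be strictly positive")
    z2 = (Fv - mu_l[None, :]) ** 2 / sigma2_l[None, :]
    per_col = -0.5 * (np.log(2.0 * np.pi * sigma2_l)[None, :] + z2)
    return float(np.sum(per_col))
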