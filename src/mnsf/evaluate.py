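"""Evaluation metrics: Moran's I, factor matching, marker ranking, prediction.

These are the quantities used to judge a multi-sample factorization: spatial
autocorrelation of each recovered factor, optimal pairing of estimated against
true factors, factor-specific marker genes from the loading matrix, in-sample
multinomial prediction of annotated domains, cross-run factor stability, and
Poisson-deviance goodness of fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import NearestNeighbors

from .core_model import SampleData, linear_predictor, poisson_deviance

__all__ = [
    "SpatialWeights",
    "FactorMatching",
    "knn_weights",
    "morans_i",
    "match_factors",
    "pattern_markers",
    "layer_prediction_eval",
    "factor_stability",
    "goodness_of_fit",
]


@dataclass
class SpatialWeights:
    """Row-standardized k-nearest-neighbor weights (no self-neighbors)."""

    neighbors: np.ndarray  # (n, k) indices
    weights: np.ndarray  # (n, k) rows sum to 1


@dataclass
class FactorMatching:
    """Bijective pairing of estimated onto true factors with their correlations."""

    permutation: np.ndarray  # est index -> true index (or -1 if unassigned)
    correlations: np.ndarray  # matched |r| for each estimated factor
    corr_matrix: np.ndarray  # signed Pearson r, est x true


def knn_weights(coords: np.ndarray, k: int = 6) -> SpatialWeights:
    """k-NN spatial weights, row-standardized; k=6 mimics Visium's hex lattice."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if k < 1 or k >= n:
        raise ValueError("need 1 <= k < number of spots")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    neighbors = idx[:, 1:]  # drop self
    weights = np.full((n, k), 1.0 / k)
    return SpatialWeights(neighbors=neighbors, weights=weights)


def morans_i(values: np.ndarray, coords: np.ndarray, k: int = 6) -> float:
    """Moran's I with row-standardized k-NN weights.

    ``I = (n / sum(w)) * sum_ij w_ij z_i z_j / sum_i z_i^2`` with ``z``
    the centered values.  Near 0 for spatially random fields, positive for
    smooth structure, negative for alternation.
    """
    values = np.asarray(values, dtype=float).ravel()
    n = values.size
    if n < 3:
        raise ValueError("need at least 3 spots")
    z = values - values.mean()
    denom = float(np.sum(z**2))
    if denom == 0:
        raise ValueError("Moran's I is undefined for constant values")
    sw = knn_weights(coords, k=k)
    num = float(np.sum(sw.weights * z[sw.neighbors] * z[:, None]))
    w_total = float(np.sum(sw.weights))
    return (n / w_total) * num / denom


def _corr_matrix(F_est: np.ndarray, F_true: np.ndarray) -> np.ndarray:
    """Pearson correlations between columns; constant columns contribute 0."""
    A = F_est - F_est.mean(axis=0)
    B = F_true - F_true.mean(axis=0)
    sa = np.sqrt(np.sum(A**2, axis=0))
    sb = np.sqrt(np.sum(B**2, axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        C = (A.T @ B) / np.outer(sa, sb)
    return np.nan_to_num(C, nan=0.0)


def match_factors(
    F_est: np.ndarray | Sequence[np.ndarray],
    F_true: np.ndarray | Sequence[np.ndarray],
) -> FactorMatching:
    """Optimal pairing of estimated to true factors by total |Pearson r|.

    Accepts single matrices or per-sample lists (spots are concatenated across
    samples before correlating).  Solved with the Hungarian algorithm; with
    more estimated than true factors the surplus columns stay unassigned (-1).
    """
    if not isinstance(F_est, np.ndarray):
        F_est = np.vstack(list(F_est))
    if not isinstance(F_true, np.ndarray):
        F_true = np.vstack(list(F_true))
    if F_est.shape[0] != F_true.shape[0]:
        raise ValueError("estimated and true factors must cover the same spots")
    if F_est.shape[1] < F_true.shape[1]:
        raise ValueError("need at least as many estimated factors as true factors")
    C = _corr_matrix(F_est, F_true)
    rows, cols = linear_sum_assignment(-np.abs(C))
    permutation = np.full(F_est.shape[1], -1, dtype=int)
    permutation[rows] = cols
    correlations = np.zeros(F_est.shape[1])
    correlations[rows] = np.abs(C)[rows, cols]
    return FactorMatching(
        permutation=permutation, correlations=correlations, corr_matrix=C
    )


def pattern_markers(
    W: np.ndarray, gene_ids: np.ndarray | None = None
) -> List[List[Tuple[str, float]]]:
    """Factor-specific marker ranking from the loading matrix.

    Each gene's loading row is scaled to unit maximum and compared with every
    unit basis vector e_l; the gene is assigned to the factor minimizing the
    Euclidean distance (ties -> lower factor index) and genes within a factor
    are ranked by increasing distance, most specific first.  All-zero genes are
    excluded with a warning.
    """
    W = np.asarray(W, dtype=float)
    if np.any(W < 0):
        raise ValueError("W must be non-negative")
    G, L = W.shape
    if gene_ids is None:
        gene_ids = np.array([f"gene{g}" for g in range(G)])
    rowmax = W.max(axis=1)
    zero = rowmax == 0
    if np.any(zero):
        warnings.warn(
            f"excluding {int(zero.sum())} all-zero gene rows from marker ranking"
        )
    scaled = np.where(zero[:, None], 0.0, W / np.where(zero, 1.0, rowmax)[:, None])
    # distance of the scaled row to each unit basis vector
    dist = np.sqrt(
        ((scaled[:, None, :] - np.eye(L)[None, :, :]) ** 2).sum(axis=2)
    )  # (G, L)
    assign = np.argmin(dist, axis=1)  # argmin ties -> lowest index
    out: List[List[Tuple[str, float]]] = []
    for l in range(L):
        members = np.where((assign == l) & ~zero)[0]
        order = members[np.argsort(dist[members, l], kind="stable")]
        out.append([(str(gene_ids[g]), float(dist[g, l])) for g in order])
    return out


def layer_prediction_eval(
    F: np.ndarray | Sequence[np.ndarray],
    labels: np.ndarray | Sequence[np.ndarray],
) -> Tuple[float, float]:
    """In-sample multinomial regression of domain labels on factors.

    Returns (accuracy, deviance): accuracy is the fraction of spots whose
    arg-max predicted class equals the label; deviance is -2 x the fitted
    log-likelihood.  Spots with missing (None/NaN/'NA') labels are dropped.
    """
    if not isinstance(F, np.ndarray):
        F = np.vstack(list(F))
    if not isinstance(labels, np.ndarray):
        labels = np.concatenate([np.asarray(l) for l in labels])
    labels = np.asarray(labels)
    if labels.shape[0] != F.shape[0]:
        raise ValueError("labels and factors must cover the same spots")
    keep = np.array(
        [l is not None and str(l).lower() not in ("na", "nan", "none") for l in labels]
    )
    F, labels = F[keep], labels[keep].astype(str)
    classes, counts = np.unique(labels, return_counts=True)
    small = classes[counts < 2]
    if small.size:
        raise ValueError(f"classes with fewer than 2 spots: {small.tolist()}")
    model = LogisticRegression(max_iter=2000)
    model.fit(F, labels)
    pred = model.predict(F)
    accuracy = float(np.mean(pred == labels))
    prob = model.predict_proba(F)
    idx = np.searchsorted(model.classes_, labels)
    deviance = float(-2.0 * np.sum(np.log(np.maximum(prob[np.arange(len(labels)), idx], 1e-300))))
    return accuracy, deviance


def factor_stability(
    F_a: np.ndarray | Sequence[np.ndarray],
    F_b: np.ndarray | Sequence[np.ndarray],
) -> np.ndarray:
    """Pearson correlation matrix (L_a x L_b) between factors of two runs."""
    if not isinstance(F_a, np.ndarray):
        F_a = np.vstack(list(F_a))
    if not isinstance(F_b, np.ndarray):
        F_b = np.vstack(list(F_b))
    if F_a.shape[0] != F_b.shape[0]:
        raise ValueError("runs must cover the same spots")
    return _corr_matrix(F_a, F_b)


def goodness_of_fit(fit, dataset: Sequence[SampleData]) -> float:
    """Total Poisson deviance between observed counts and fitted NB means."""
    if len(fit.factors) != len(dataset):
        raise ValueError("fit and dataset have different numbers of samples")
    total = 0.0
    for fm, sample in zip(fit.factors, dataset):
        if fm.values.shape[0] != sample.n_spots:
            raise ValueError(f"{sample.sample_id}: fit/sample spot mismatch")
        mu = linear_predictor(fit.params.W, fm, sample.size_factors)
        total += poisson_deviance(sample.counts, np.maximum(mu, 1e-10))
    return total
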