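"""Size factors, deviance-based gene selection, and coordinate rescaling."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy.special import xlogy

from .core_model import SampleData, validate_dataset

__all__ = [
    "GeneSelection",
    "CoordinateTransform",
    "compute_size_factors",
    "gene_null_deviance",
    "select_top_genes",
    "rescale_coordinates",
]


@dataclass
class GeneSelection:
    """Result of deviance-based gene filtering.

    ``criterion`` is the per-gene maximum of the null Poisson deviance across
    samples; ``order`` gives the selected gene indices (into the original gene
    axis) sorted by decreasing criterion.
    """

    gene_ids: np.ndarray
    deviance_per_sample: np.ndarray  # (genes_selected, samples)
    criterion: np.ndarray  # (genes_selected,)
    order: np.ndarray  # (genes_selected,) indices into original axis


@dataclass
class CoordinateTransform:
    """Record of the per-sample centering/scaling, allowing exact inversion."""

    center: np.ndarray  # (2,)
    scale: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return (np.asarray(coords, dtype=float) - self.center) / self.scale

    def invert(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) * self.scale + self.center


def compute_size_factors(counts: np.ndarray, drop_zero: bool = False) -> np.ndarray:
    """Library-size factors ``s_i = libsize_i / mean(libsize)``; mean(s) == 1.

    Spots with zero total counts are an error by default; with
    ``drop_zero=True`` they receive NaN so the caller can drop them.
    """
    counts = np.asarray(counts)
    lib = counts.sum(axis=1).astype(float)
    zero = lib == 0
    if np.any(zero):
        if not drop_zero:
            raise ValueError(
                f"spots with zero total counts: {np.where(zero)[0].tolist()}"
            )
        lib[zero] = np.nan
    s = lib / np.nanmean(lib)
    return s


def gene_null_deviance(counts: np.ndarray, size_factors: np.ndarray) -> np.ndarray:
    """Per-gene Poisson deviance against a constant-rate null.

    The null predicts ``mu_ig = s_i * (sum_i y_ig / sum_i s_i)``: each gene has
    one rate, modulated only by the size factor.  Genes whose counts are exactly
    proportional to the size factors (including all-zero genes) get deviance 0.
    """
    Y = np.asarray(counts, dtype=float)
    s = np.asarray(size_factors, dtype=float)
    rate = Y.sum(axis=0) / s.sum()  # (genes,)
    mu = s[:, None] * rate[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        term = xlogy(Y, Y) - xlogy(Y, mu)
    term = np.where(mu > 0, term, 0.0)
    resid = np.where(mu > 0, Y - mu, 0.0)
    dev = 2.0 * np.sum(term - resid, axis=0)
    return np.maximum(dev, 0.0)


def select_top_genes(
    samples: Sequence[SampleData], n: int
) -> Tuple[List[SampleData], GeneSelection]:
    """Keep the top ``n`` genes by max-over-samples null Poisson deviance.

    Returns the subset samples (same order of selected genes in every sample)
    and the selection record.  Ties are broken by original gene order.
    """
    validate_dataset(samples)
    G = samples[0].n_genes
    if n > G:
        raise ValueError(f"requested {n} genes but only {G} available")
    dev = np.column_stack(
        [gene_null_deviance(s.counts, s.size_factors) for s in samples]
    )
    criterion = dev.max(axis=1)
    # stable sort on negated criterion -> decreasing, ties by gene order
    order = np.argsort(-criterion, kind="stable")[:n]
    gene_ids = (
        samples[0].gene_ids[order]
        if samples[0].gene_ids is not None
        else np.array([f"gene{i}" for i in order])
    )
    subset = [
        SampleData(
            counts=s.counts[:, order],
            coords=s.coords,
            size_factors=s.size_factors,
            sample_id=s.sample_id,
            labels=s.labels,
            spot_ids=s.spot_ids,
            gene_ids=s.gene_ids[order] if s.gene_ids is not None else gene_ids,
        )
        for s in samples
    ]
    return subset, GeneSelection(
        gene_ids=gene_ids,
        deviance_per_sample=dev[order],
        criterion=criterion[order],
        order=order,
    )


def rescale_coordinates(
    coords: np.ndarray,
) -> Tuple[np.ndarray, CoordinateTransform]:
    """Center to mean zero and scale both axes by the max absolute value.

    Aspect ratio is preserved (a single scale for both axes).  Makes kernel
    lengthscales comparable across samples of different physical extents.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an N x 2 matrix")
    center = coords.mean(axis=0)
    centered = coords - center
    scale = float(np.max(np.abs(centered)))
    if scale == 0:
        raise ValueError("all points are identical; cannot rescale")
    t = CoordinateTransform(center=center, scale=scale)
    return centered / scale, t
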