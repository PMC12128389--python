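"""Synthetic multi-sample spatial transcriptomics data.

The generator produces two or more samples on rectangular grids with a small
number of block-shaped latent spatial factors.  Across samples the factor
patterns can be rotated by quarter turns, nulled out (constant low value),
rescaled in physical size, smoothly distorted, or observed at different noise
levels — the regimes a multi-sample factorization must cope with when spatial
alignment is impossible.

Counts are drawn from the model's own observation layer: gene loadings ``W``
are non-negative with a factor-exclusive block of marker genes per factor,
log-factors are the log of the block pattern plus Gaussian noise, and counts
are negative-binomial with mean ``sz * sum_l W[g,l] * exp(F[i,l])``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core_model import SampleData

__all__ = [
    "SimDesign",
    "SimTruth",
    "make_block_patterns",
    "rotate_pattern",
    "simulate_dataset",
    "design_preset",
]

# exp-scale pattern levels: ~10:1 contrast between active and background spots
SIGNAL_HIGH = 1.0
SIGNAL_LOW = 0.1
# marker loadings: Gamma(2, 2.5) (mean 5) on the factor's own gene block,
# flat 0.05 background elsewhere
MARKER_SHAPE = 2.0
MARKER_SCALE = 2.5
BACKGROUND_LOADING = 0.05


@dataclass
class SimDesign:
    """Configuration of one simulated multi-sample dataset.

    Defaults reproduce the rotated-factor two-sample design: four quadrant
    factors on 36x36 grids, sample 2 rotated 90 degrees anticlockwise, 500
    genes, log-scale noise sd 0.3, NB dispersion 10.
    """

    grid_shape: Tuple[Tuple[int, int], ...] = ((36, 36), (36, 36))
    n_genes: int = 500
    n_factors: int = 4
    rotations: Tuple[int, ...] = (0, 1)
    null_factors: Tuple[frozenset, ...] = (frozenset(), frozenset())
    noise_sd: Tuple[float, ...] = (0.3, 0.3)
    distortion: Tuple[float, ...] = (0.0, 0.0)
    size_scale: Tuple[float, ...] = (1.0, 1.0)
    dispersion: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        M = len(self.grid_shape)
        for name in ("rotations", "null_factors", "noise_sd", "distortion", "size_scale"):
            if len(getattr(self, name)) != M:
                raise ValueError(f"{name} must have one entry per sample ({M})")
        self.null_factors = tuple(frozenset(s) for s in self.null_factors)
        for s in self.null_factors:
            if any(l < 0 or l >= self.n_factors for l in s):
                raise ValueError("null factor index out of range")
        if any(sd < 0 for sd in self.noise_sd):
            raise ValueError("noise_sd must be non-negative")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")

    @property
    def n_samples(self) -> int:
        return len(self.grid_shape)


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated counts.

    ``true_factors`` holds the noiseless exp-scale pattern per sample
    (spots x L); ``true_loadings`` the generative ``W`` (genes x L).
    """

    true_factors: List[np.ndarray]
    true_loadings: np.ndarray
    counts: List[np.ndarray]
    coords: List[np.ndarray]


def make_block_patterns(
    grid_shape: Tuple[int, int], n_factors: int, seed: int = 0
) -> np.ndarray:
    """Disjoint contiguous block patterns on a rectangular grid.

    Returns an array (L, rows, cols) of exp-scale fields taking the value
    ``SIGNAL_HIGH`` inside the factor's block and ``SIGNAL_LOW`` outside.  The
    grid is tiled into a near-square arrangement of L rectangles (quadrants for
    L=4, stripes for L=2), so patterns never overlap.
    """
    rows, cols = grid_shape
    if n_factors < 1:
        raise ValueError("need at least one factor")
    # choose a tiling br x bc with br*bc >= L, as square as possible
    br = int(np.floor(np.sqrt(n_factors)))
    while br >= 1 and n_factors % br:
        br -= 1
    br = max(br, 1)
    bc = int(np.ceil(n_factors / br))
    if rows < br or cols < bc:
        raise ValueError(
            f"grid {grid_shape} too small for {n_factors} disjoint blocks"
        )
    row_edges = np.linspace(0, rows, br + 1).astype(int)
    col_edges = np.linspace(0, cols, bc + 1).astype(int)
    fields = np.full((n_factors, rows, cols), SIGNAL_LOW)
    l = 0
    for i in range(br):
        for j in range(bc):
            if l >= n_factors:
                break
            fields[
                l, row_edges[i] : row_edges[i + 1], col_edges[j] : col_edges[j + 1]
            ] = SIGNAL_HIGH
            l += 1
    return fields


def rotate_pattern(field: np.ndarray, quarter_turns: int) -> np.ndarray:
    """Rotate a grid field anticlockwise by 90 degrees per quarter turn."""
    field = np.asarray(field)
    if field.ndim != 2:
        raise ValueError("pattern must be a 2-D grid field")
    return np.rot90(field, k=quarter_turns % 4)


def _grid_coords(grid_shape: Tuple[int, int], scale: float) -> np.ndarray:
    rows, cols = grid_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return scale * np.column_stack([cc.ravel(), rr.ravel()]).astype(float)


def _warp(coords: np.ndarray, amplitude: float, extent: Tuple[int, int]) -> np.ndarray:
    """Smooth sinusoidal coordinate distortion (identity at amplitude 0)."""
    if amplitude == 0:
        return coords
    rows, cols = extent
    out = coords.copy()
    out[:, 0] += amplitude * np.sin(2.0 * np.pi * coords[:, 1] / max(rows, 2))
    out[:, 1] += amplitude * np.sin(2.0 * np.pi * coords[:, 0] / max(cols, 2))
    return out


def simulate_dataset(design: SimDesign) -> Tuple[List[SampleData], SimTruth]:
    """Generate per-sample counts, coordinates and ground truth for a design."""
    rng = np.random.default_rng(design.seed)
    L, G = design.n_factors, design.n_genes

    # loadings: factor-exclusive marker blocks, flat background
    W = np.full((G, L), BACKGROUND_LOADING)
    group = np.array_split(np.arange(G), L)
    for l in range(L):
        W[group[l], l] = rng.gamma(MARKER_SHAPE, MARKER_SCALE, size=group[l].size)

    base = make_block_patterns(design.grid_shape[0], L, seed=design.seed)
    samples: List[SampleData] = []
    true_factors: List[np.ndarray] = []
    coords_list: List[np.ndarray] = []
    counts_list: List[np.ndarray] = []
    gene_ids = np.array([f"gene{g:04d}" for g in range(G)])

    for m in range(design.n_samples):
        shape = design.grid_shape[m]
        if shape == design.grid_shape[0]:
            fields = np.stack(
                [rotate_pattern(base[l], design.rotations[m]) for l in range(L)]
            )
        else:
            fields = make_block_patterns(shape, L, seed=design.seed)
            fields = np.stack(
                [rotate_pattern(fields[l], design.rotations[m]) for l in range(L)]
            )
        for l in design.null_factors[m]:
            fields[l] = SIGNAL_LOW

        pattern = fields.reshape(L, -1).T  # (N, L) exp scale, noiseless
        logF = np.log(pattern) + design.noise_sd[m] * rng.standard_normal(
            pattern.shape
        )
        coords = _grid_coords(fields.shape[1:], design.size_scale[m])
        coords = _warp(coords, design.distortion[m], fields.shape[1:])

        sz = np.ones(pattern.shape[0])
        mu = sz[:, None] * (np.exp(logF) @ W.T)
        phi = design.dispersion
        counts = rng.negative_binomial(n=phi, p=phi / (phi + mu))

        samples.append(
            SampleData(
                counts=counts,
                coords=coords,
                size_factors=sz,
                sample_id=f"sample{m + 1}",
                gene_ids=gene_ids,
            )
        )
        true_factors.append(pattern)
        coords_list.append(coords)
        counts_list.append(counts)

    truth = SimTruth(
        true_factors=true_factors,
        true_loadings=W,
        counts=counts_list,
        coords=coords_list,
    )
    return samples, truth


def design_preset(name: str, **overrides) -> SimDesign:
    """Named simulation designs.

    - ``fig1a``: two samples, four factors, sample 2 rotated 90 degrees.
    - ``fig1c``: as ``fig1a`` but factor 1 nulled (constant low) in sample 2.
    - ``figS1a``: sample 2 half the physical size of sample 1.
    - ``figS1b``: sample 2 smoothly distorted.
    - ``figS1c``: sample-specific noise levels.
    """
    presets = {
        "fig1a": {},
        "fig1c": {"null_factors": (frozenset(), frozenset({0}))},
        "figS1a": {"size_scale": (1.0, 0.5)},
        "figS1b": {"distortion": (0.0, 2.0)},
        "figS1c": {"noise_sd": (0.15, 0.6)},
    }
    if name not in presets:
        raise ValueError(f"unknown design preset {name!r}; options: {sorted(presets)}")
    kwargs = dict(presets[name])
    kwargs.update(overrides)
    return SimDesign(**kwargs)
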