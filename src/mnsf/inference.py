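"""Variational inference for multi-sample spatial factorization.

The model couples samples only through the shared non-negative loading matrix
``W``; every other parameter — GP kernel amplitude/lengthscale, affine mean
coefficients, variational state over the factor values at inducing points, NB
dispersion — is sample-specific.  The evidence lower bound therefore decomposes
into a sum of per-sample terms, and fitting proceeds by the per-sample update
scheme: in each outer iteration every sample (or data chunk) takes one Adam
step on its own negative ELBO, including a step on its private copy of ``W``;
the per-sample ``W`` updates are then averaged and negative entries set to
zero.

The expected NB log-likelihood under the variational posterior is estimated by
reparameterized Monte-Carlo draws of the factors (default, one draw per
iteration); a deterministic alternative using the lognormal identity
``E[exp F] = exp(mean + var/2)`` on the log-rate is available as
``objective="delta"``.  All gradients are analytic (NumPy), optimized with an
in-package Adam.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.spatial.distance import cdist
from scipy.special import digamma
from sklearn.decomposition import NMF

from .core_model import (
    FactorMatrix,
    ModelParams,
    SampleData,
    nb_log_likelihood,
    validate_dataset,
)
from .gp_prior import InducingSet
from .preprocess import CoordinateTransform, rescale_coordinates

__all__ = [
    "VariationalState",
    "FitConfig",
    "FitResult",
    "select_inducing_points",
    "chunk_partition",
    "chunk_data",
    "init_params",
    "elbo",
    "elbo_dataset",
    "fit",
    "fit_pnmf",
    "predict_factors",
]

_MU_FLOOR = 1e-10
_VAR_FLOOR = 1e-12


@dataclass
class VariationalState:
    """Free Gaussian q(U) per factor: mean and lower-triangular covariance factor."""

    q_mean: np.ndarray  # (L, n)
    q_cov_factor: np.ndarray  # (L, n, n), lower triangular, positive diagonal

    def __post_init__(self) -> None:
        self.q_mean = np.asarray(self.q_mean, dtype=float)
        self.q_cov_factor = np.asarray(self.q_cov_factor, dtype=float)
        L, n = self.q_mean.shape
        if self.q_cov_factor.shape != (L, n, n):
            raise ValueError("q_cov_factor must be (L, n, n)")
        for l in range(L):
            if np.any(np.diag(self.q_cov_factor[l]) <= 0):
                raise ValueError("q_cov_factor diagonal must be strictly positive")


@dataclass
class FitConfig:
    """Fitting configuration; defaults follow the method's standard settings
    (35% inducing points, single chunk, up to 1000 Adam iterations)."""

    L: int = 4
    inducing_fraction: float = 0.35
    n_chunks: int = 1
    learning_rate: float = 0.05
    max_iter: int = 1000
    mc_samples: int = 1
    convergence_tol: float = 1e-4
    seed: int = 0
    dispersion_init: float = 10.0
    optimize_dispersion: bool = False
    jitter: float = 1e-6
    nmf_iter: int = 200
    objective: str = "mc"  # "mc": reparameterized draws; "delta": lognormal mean

    def __post_init__(self) -> None:
        if not (0 < self.inducing_fraction <= 1):
            raise ValueError("inducing_fraction must be in (0, 1]")
        if self.n_chunks < 1:
            raise ValueError("n_chunks must be >= 1")
        if self.learning_rate <= 0 or self.dispersion_init <= 0:
            raise ValueError("learning_rate and dispersion_init must be > 0")
        if self.L < 1 or self.max_iter < 1 or self.mc_samples < 1:
            raise ValueError("L, max_iter and mc_samples must be >= 1")


@dataclass
class FitResult:
    """Fitted model: final parameters, per-sample posterior mean factors
    (log scale, at all observed spots), and the loss trajectory."""

    params: ModelParams
    factors: List[FactorMatrix]
    loss_trajectory: np.ndarray
    loss_per_unit: np.ndarray  # (iterations, units)
    w_min_trajectory: np.ndarray  # min entry of W after each iteration's update
    config: FitConfig
    converged: bool
    sample_ids: List[str]
    transforms: List[CoordinateTransform] = field(default_factory=list)
    _units: list = field(default_factory=list, repr=False)


# ---------------------------------------------------------------------------
# inducing points and chunking
# ---------------------------------------------------------------------------


def select_inducing_points(
    coords: np.ndarray, fraction: float, seed: int
) -> InducingSet:
    """Uniform random subset of ``ceil(fraction * N)`` spots, seeded.

    ``fraction=1`` returns all spots in their original order.
    """
    coords = np.asarray(coords, dtype=float)
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    N = coords.shape[0]
    if fraction == 1:
        idx = np.arange(N)
    else:
        n = int(np.ceil(fraction * N))
        idx = np.sort(np.random.default_rng(seed).choice(N, size=n, replace=False))
    return InducingSet(Z=coords[idx], indices=idx)


def chunk_partition(n_spots: int, n_chunks: int, seed: int) -> List[np.ndarray]:
    """Random disjoint, exhaustive partition of spot indices into near-equal chunks.

    Chunk sizes differ by at most one; ``n_chunks=1`` preserves spot order.
    """
    if not (1 <= n_chunks <= n_spots):
        raise ValueError(f"n_chunks must be in [1, {n_spots}]")
    if n_chunks == 1:
        return [np.arange(n_spots)]
    perm = np.random.default_rng(seed).permutation(n_spots)
    return [np.sort(part) for part in np.array_split(perm, n_chunks)]


def chunk_data(sample: SampleData, n_chunks: int, seed: int) -> List[SampleData]:
    """Split one sample's spots into random chunks (gene axis untouched)."""
    parts = chunk_partition(sample.n_spots, n_chunks, seed)
    if n_chunks == 1:
        return [sample]
    return [
        SampleData(
            counts=sample.counts[idx],
            coords=sample.coords[idx],
            size_factors=sample.size_factors[idx],
            sample_id=f"{sample.sample_id}_chunk{c}",
            labels=sample.labels[idx] if sample.labels is not None else None,
            spot_ids=sample.spot_ids[idx],
            gene_ids=sample.gene_ids,
        )
        for c, idx in enumerate(parts)
    ]


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def _nmf_init(
    dataset: Sequence[SampleData], L: int, seed: int, n_iter: int
) -> Tuple[np.ndarray, List[np.ndarray]]:
    """Multiplicative-update NMF (KL loss) on size-factor-normalized counts.

    Returns non-negative loadings ``W`` (G x L) and per-sample non-negative
    score matrices (N_m x L).  All-zero genes are dropped from the NMF and get
    zero loadings.
    """
    Ynorm = np.vstack(
        [s.counts / s.size_factors[:, None] for s in dataset]
    )
    nonzero = Ynorm.sum(axis=0) > 0
    if not np.all(nonzero):
        warnings.warn(
            f"dropping {int((~nonzero).sum())} all-zero genes from NMF initialization"
        )
    model = NMF(
        n_components=L,
        init="random",
        solver="mu",
        beta_loss="kullback-leibler",
        max_iter=n_iter,
        tol=1e-6,
        random_state=int(seed) % (2**31),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # NMF convergence chatter
        scores = model.fit_transform(Ynorm[:, nonzero])
    W = np.zeros((Ynorm.shape[1], L))
    W[nonzero] = model.components_.T
    # move scale into W so scores columns have unit mean (fixes the NMF
    # scale indeterminacy; the product scores @ W.T is unchanged)
    colmean = np.maximum(scores.mean(axis=0), 1e-12)
    scores = scores / colmean[None, :]
    W = W * colmean[None, :]
    splits = np.cumsum([s.n_spots for s in dataset])[:-1]
    return W, [np.ascontiguousarray(a) for a in np.split(scores, splits)]


@dataclass
class InitState:
    params: ModelParams
    vstates: List[VariationalState]
    inducing: List[InducingSet]
    scores: List[np.ndarray]  # non-negative NMF scores per sample


def init_params(
    dataset: Sequence[SampleData],
    L: int,
    seed: int,
    inducing_fraction: float = 0.35,
    dispersion_init: float = 10.0,
    nmf_iter: int = 200,
    coords_rescaled: bool = False,
) -> InitState:
    """Deterministic, seeded initialization from a plain NMF.

    ``W`` and per-sample factor scores come from multiplicative-update NMF on
    the column-concatenated, size-factor-normalized counts; ``q_mean`` is the
    log of the scores at the inducing spots; kernel amplitude starts at 1 and
    lengthscale at 0.1 x the coordinate range.
    """
    validate_dataset(dataset)
    ss = np.random.SeedSequence(seed)
    sub = ss.generate_state(1 + len(dataset)).astype(np.int64) % (2**31)
    W, scores = _nmf_init(dataset, L, int(sub[0]), nmf_iter)

    M = len(dataset)
    vstates, inducing = [], []
    amp = np.ones((M, L))
    ls = np.ones((M, L))
    b0 = np.zeros((M, L))
    b1 = np.zeros((M, L, 2))
    for m, s in enumerate(dataset):
        coords = s.coords if coords_rescaled else rescale_coordinates(s.coords)[0]
        ind = select_inducing_points(coords, inducing_fraction, int(sub[1 + m]))
        logF = np.log(np.maximum(scores[m], 1e-3))
        qm = logF[ind.indices].T.copy()  # (L, n)
        n = ind.n_points
        C = np.repeat(0.1 * np.eye(n)[None], L, axis=0)
        vstates.append(VariationalState(q_mean=qm, q_cov_factor=C))
        inducing.append(ind)
        rng_span = float(np.max(coords.max(axis=0) - coords.min(axis=0)))
        ls[m, :] = 0.1 * max(rng_span, 1e-6)
        b0[m, :] = logF.mean(axis=0)
    params = ModelParams(
        W=W,
        dispersion=np.full(M, dispersion_init),
        kernel_amplitude=amp,
        kernel_lengthscale=ls,
        mean_intercept=b0,
        mean_slope=b1,
    )
    return InitState(params=params, vstates=vstates, inducing=inducing, scores=scores)


# ---------------------------------------------------------------------------
# per-unit objective (negative ELBO) with analytic gradients
# ---------------------------------------------------------------------------


class _Unit:
    """One fitting unit: a sample or a chunk of a sample, with its own GP
    hyperparameters, variational state, inducing points and Adam state."""

    def __init__(
        self,
        sample_index: int,
        spot_idx: np.ndarray,
        Y: np.ndarray,
        X: np.ndarray,
        sz: np.ndarray,
        inducing: InducingSet,
        theta: Dict[str, np.ndarray],
        log_phi: float,
        jitter: float,
    ):
        self.sample_index = sample_index
        self.spot_idx = spot_idx
        self.Y = Y.astype(float)
        self.X = X
        self.sz = sz
        self.inducing = inducing
        self.theta = theta
        self.log_phi = log_phi
        self.jitter = jitter
        self.Dzz = cdist(inducing.Z, inducing.Z)
        self.Dxz = cdist(X, inducing.Z)

    @property
    def n_inducing(self) -> int:
        return self.inducing.n_points

    @property
    def n_spots(self) -> int:
        return self.X.shape[0]


def _chol_from_raw(Craw: np.ndarray) -> np.ndarray:
    """Lower-triangular factor with exp-parameterized (positive) diagonal."""
    C = np.tril(Craw, k=-1)
    C[np.diag_indices_from(C)] = np.exp(np.diag(Craw))
    return C


def _unit_value_grad(
    unit: _Unit,
    W: np.ndarray,
    want_grad: bool = True,
    optimize_phi: bool = False,
    mc_eps: Optional[np.ndarray] = None,
):
    """Negative ELBO of one unit and its gradients.

    Returns ``(value, grad_theta, grad_W, grad_log_phi, mean_F, var_F)``.
    The GP algebra follows the sparse conditional ``F | U``.  The expected NB
    log-likelihood is estimated by reparameterized Monte-Carlo draws when
    ``mc_eps`` (draws x spots x factors standard normals) is given, and by the
    deterministic lognormal-mean approximation ``E[exp F] = exp(mean + var/2)``
    otherwise.
    """
    th = unit.theta
    L = th["la"].shape[0]
    N, n = unit.n_spots, unit.n_inducing
    X, Z = unit.X, unit.inducing.Z
    Y, sz = unit.Y, unit.sz
    phi = float(np.exp(unit.log_phi))

    meanF = np.empty((N, L))
    varF = np.empty((N, L))
    kl_total = 0.0
    cache = []
    for l in range(L):
        alpha = float(np.exp(th["la"][l]))
        B = float(np.exp(th["lb"][l]))
        Mzz = np.exp(-unit.Dzz / B)
        Kuu = alpha * Mzz
        Kuu[np.diag_indices_from(Kuu)] += unit.jitter * alpha
        Kxu = alpha * np.exp(-unit.Dxz / B)
        cho = cho_factor(Kuu, lower=True)
        Luu = np.tril(cho[0])

        b0, b1 = th["b0"][l], th["b1"][l]
        mu_z = b0 + Z @ b1
        mu_x = b0 + X @ b1
        delta = th["qm"][l] - mu_z
        v = cho_solve(cho, delta)
        A = cho_solve(cho, Kxu.T).T  # (N, n)

        C = _chol_from_raw(th["Craw"][l])
        P = A @ C
        Q = np.sum(A * Kxu, axis=1)
        raw_var = alpha - Q + np.sum(P * P, axis=1)
        clip = raw_var > _VAR_FLOOR
        mF = mu_x + Kxu @ v
        vF = np.maximum(raw_var, _VAR_FLOOR)
        meanF[:, l] = mF
        varF[:, l] = vF

        Linv_C = solve_triangular(Luu, C, lower=True)
        kl = 0.5 * (
            np.sum(Linv_C**2)
            + float(delta @ v)
            - n
            + 2.0 * np.sum(np.log(np.diag(Luu)))
            - 2.0 * np.sum(np.diag(th["Craw"][l]))
        )
        kl_total += kl
        cache.append((alpha, B, Mzz, Kuu, Kxu, cho, A, v, delta, C, P, clip))

    # expected NB log-likelihood: MC draws (reparameterized) or delta form
    g_log_phi = 0.0
    if mc_eps is None:
        E = np.exp(meanF + 0.5 * varF)
        Lam = np.maximum(sz[:, None] * (E @ W.T), _MU_FLOOR)
        ll = nb_log_likelihood(Y, Lam, phi)
        value = -(ll - kl_total)
        if not want_grad:
            return value, None, None, 0.0, meanF, varF
        R = Y / Lam - (Y + phi) / (phi + Lam)
        gW = -(R.T @ (sz[:, None] * E))  # grad of objective wrt W
        H = (R @ W) * sz[:, None]  # dLL/dE
        gmean_all = H * E
        gvar_all = 0.5 * H * E
        if optimize_phi:
            g_log_phi = -_dll_dphi(Y, Lam, phi) * phi
    else:
        S = mc_eps.shape[0]
        sd = np.sqrt(varF)
        ll = 0.0
        gW = np.zeros_like(W)
        gmean_all = np.zeros((N, L))
        gvar_all = np.zeros((N, L))
        dphi = 0.0
        for s_ in range(S):
            EX = np.exp(meanF + sd * mc_eps[s_])
            Lam = np.maximum(sz[:, None] * (EX @ W.T), _MU_FLOOR)
            ll += nb_log_likelihood(Y, Lam, phi) / S
            if not want_grad:
                continue
            R = Y / Lam - (Y + phi) / (phi + Lam)
            gW -= (R.T @ (sz[:, None] * EX)) / S
            H = (R @ W) * sz[:, None]
            gmean_all += H * EX / S
            gvar_all += H * EX * mc_eps[s_] / (2.0 * sd) / S
            if optimize_phi:
                dphi += _dll_dphi(Y, Lam, phi) / S
        value = -(ll - kl_total)
        if not want_grad:
            return value, None, None, 0.0, meanF, varF
        if optimize_phi:
            g_log_phi = -dphi * phi

    grad = {k: np.zeros_like(v_) for k, v_ in th.items()}
    for l in range(L):
        alpha, B, Mzz, Kuu, Kxu, cho, A, v, delta, C, P, clip = cache[l]
        gmean = gmean_all[:, l]
        gvar = gvar_all[:, l] * clip

        t = A.T @ gmean
        G_A = np.outer(gmean, delta) - gvar[:, None] * Kxu + 2.0 * (
            gvar[:, None] * P
        ) @ C.T
        GK = cho_solve(cho, G_A.T).T  # G_A @ Kuu^{-1}
        G_Kxu = -gvar[:, None] * A + GK
        G_Kuu_ll = -A.T @ GK

        dKuu_lb = alpha * Mzz * unit.Dzz / B
        g_la_ll = (
            np.sum(G_Kuu_ll * Kuu) + np.sum(G_Kxu * Kxu) + alpha * np.sum(gvar)
        )
        g_lb_ll = np.sum(G_Kuu_ll * dKuu_lb) + np.sum(G_Kxu * Kxu * unit.Dxz / B)
        g_C_ll = 2.0 * np.tril((A * gvar[:, None]).T @ P)

        Kuu_inv = cho_solve(cho, np.eye(n))
        KiC = Kuu_inv @ C
        g_Kuu_kl = 0.5 * (Kuu_inv - KiC @ KiC.T - np.outer(v, v))
        g_la_kl = np.sum(g_Kuu_kl * Kuu)
        g_lb_kl = np.sum(g_Kuu_kl * dKuu_lb)

        # objective = -LL + KL
        grad["la"][l] = -g_la_ll + g_la_kl
        grad["lb"][l] = -g_lb_ll + g_lb_kl
        grad["qm"][l] = -t + v
        grad["b0"][l] = -(np.sum(gmean) - np.sum(t)) + (-np.sum(v))
        grad["b1"][l] = -(X.T @ gmean - Z.T @ t) + (-(Z.T @ v))
        G_C = -g_C_ll + np.tril(KiC)
        g_raw = np.tril(G_C, k=-1)
        g_raw[np.diag_indices_from(g_raw)] = np.diag(G_C) * np.diag(C) - 1.0
        grad["Craw"][l] = g_raw

    return value, grad, gW, g_log_phi, meanF, varF


def _dll_dphi(Y: np.ndarray, Lam: np.ndarray, phi: float) -> float:
    return float(
        np.sum(
            digamma(Y + phi) - digamma(phi) + np.log(phi / (phi + Lam)) + 1.0
            - (Y + phi) / (phi + Lam)
        )
    )


class _Adam:
    """Plain Adam over a dict of arrays (beta1=0.9, beta2=0.999)."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: Dict[str, np.ndarray] = {}
        self.v: Dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]):
        self.t += 1
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return params


# ---------------------------------------------------------------------------
# public ELBO (Monte-Carlo estimator)
# ---------------------------------------------------------------------------


def _marginal_q_f(
    sample_coords: np.ndarray,
    inducing: InducingSet,
    params: ModelParams,
    vstate: VariationalState,
    sample_index: int,
    jitter: float,
):
    """Per-factor marginal q(F): mean and per-spot variance, plus KL(q(U)||p(U))."""
    L = params.n_factors
    X, Z = sample_coords, inducing.Z
    N, n = X.shape[0], inducing.n_points
    meanF = np.empty((N, L))
    varF = np.empty((N, L))
    kl_total = 0.0
    for l in range(L):
        alpha = params.kernel_amplitude[sample_index, l]
        B = params.kernel_lengthscale[sample_index, l]
        Kuu = alpha * np.exp(-cdist(Z, Z) / B)
        Kuu[np.diag_indices_from(Kuu)] += jitter * alpha
        Kxu = alpha * np.exp(-cdist(X, Z) / B)
        cho = cho_factor(Kuu, lower=True)
        Luu = np.tril(cho[0])
        b0 = params.mean_intercept[sample_index, l]
        b1 = params.mean_slope[sample_index, l]
        delta = vstate.q_mean[l] - (b0 + Z @ b1)
        v = cho_solve(cho, delta)
        A = cho_solve(cho, Kxu.T).T
        C = vstate.q_cov_factor[l]
        P = A @ C
        meanF[:, l] = b0 + X @ b1 + Kxu @ v
        varF[:, l] = np.maximum(
            alpha - np.sum(A * Kxu, axis=1) + np.sum(P * P, axis=1), _VAR_FLOOR
        )
        Linv_C = solve_triangular(Luu, C, lower=True)
        kl_total += 0.5 * (
            np.sum(Linv_C**2)
            + float(delta @ v)
            - n
            + 2.0 * np.sum(np.log(np.diag(Luu)))
            - 2.0 * np.sum(np.log(np.diag(C)))
        )
    return meanF, varF, kl_total


def elbo(
    sample: SampleData,
    params: ModelParams,
    vstate: VariationalState,
    inducing: InducingSet,
    mc_samples: int = 100,
    seed: int = 0,
    sample_index: int = 0,
    jitter: float = 1e-6,
) -> float:
    """Monte-Carlo ELBO estimate for one sample.

    Factors are integrated through the sparse conditional: per-spot draws
    ``F ~ N(mean_F, var_F)`` from the marginal variational posterior enter the
    NB log-likelihood, and the exact Gaussian KL(q(U) || p(U)) is subtracted.
    The coordinates are used as given (rescale beforehand if desired).
    """
    if not np.any(np.max(params.W, axis=0) > 0):
        raise ValueError("W must have at least one strictly positive column")
    meanF, varF, kl_total = _marginal_q_f(
        sample.coords, inducing, params, vstate, sample_index, jitter
    )
    rng = np.random.default_rng(seed)
    phi = float(params.dispersion[sample_index])
    sd = np.sqrt(varF)
    ll = 0.0
    for _ in range(mc_samples):
        F = meanF + sd * rng.standard_normal(meanF.shape)
        mu = np.maximum(
            sample.size_factors[:, None] * (np.exp(F) @ params.W.T), _MU_FLOOR
        )
        ll += nb_log_likelihood(sample.counts, mu, phi)
    return ll / mc_samples - kl_total


def elbo_dataset(
    dataset: Sequence[SampleData],
    params: ModelParams,
    vstates: Sequence[VariationalState],
    inducing: Sequence[InducingSet],
    mc_samples: int = 100,
    seed: int = 0,
    jitter: float = 1e-6,
) -> float:
    """Multi-sample ELBO: the sum of per-sample ELBOs (independent samples)."""
    sub = np.random.SeedSequence(seed).generate_state(len(dataset)) % (2**31)
    return sum(
        elbo(
            s, params, vstates[m], inducing[m],
            mc_samples=mc_samples, seed=int(sub[m]), sample_index=m, jitter=jitter,
        )
        for m, s in enumerate(dataset)
    )


# ---------------------------------------------------------------------------
# the multi-sample training loop
# ---------------------------------------------------------------------------


def _build_units(
    dataset: Sequence[SampleData], config: FitConfig
) -> Tuple[List[_Unit], List[CoordinateTransform], List[SampleData]]:
    """Rescale coordinates per sample, chunk, initialize per-unit parameters."""
    transforms = []
    unit_samples: List[SampleData] = []
    unit_meta: List[Tuple[int, np.ndarray]] = []
    ss = np.random.SeedSequence(config.seed)
    sub = ss.generate_state(2 * len(dataset) + 1) % (2**31)
    for m, s in enumerate(dataset):
        coords, t = rescale_coordinates(s.coords)
        transforms.append(t)
        parts = chunk_partition(s.n_spots, config.n_chunks, int(sub[1 + m]))
        for idx in parts:
            unit_samples.append(
                SampleData(
                    counts=s.counts[idx],
                    coords=coords[idx],
                    size_factors=s.size_factors[idx],
                    sample_id=s.sample_id,
                    spot_ids=s.spot_ids[idx],
                    gene_ids=s.gene_ids,
                )
            )
            unit_meta.append((m, idx))

    init = init_params(
        unit_samples,
        config.L,
        seed=int(sub[0]),
        inducing_fraction=config.inducing_fraction,
        dispersion_init=config.dispersion_init,
        nmf_iter=config.nmf_iter,
        coords_rescaled=True,
    )
    units = []
    for u, us in enumerate(unit_samples):
        m, idx = unit_meta[u]
        n = init.inducing[u].n_points
        theta = {
            "la": np.zeros(config.L),
            "lb": np.log(init.params.kernel_lengthscale[u].copy()),
            "b0": init.params.mean_intercept[u].copy(),
            "b1": np.zeros((config.L, 2)),
            "qm": init.vstates[u].q_mean.copy(),
            "Craw": np.array(
                [
                    np.diag(np.log(np.diag(init.vstates[u].q_cov_factor[l])))
                    for l in range(config.L)
                ]
            ),
        }
        units.append(
            _Unit(
                sample_index=m,
                spot_idx=idx,
                Y=us.counts,
                X=us.coords,
                sz=us.size_factors,
                inducing=init.inducing[u],
                theta=theta,
                log_phi=float(np.log(config.dispersion_init)),
                jitter=config.jitter,
            )
        )
    return units, transforms, init.params.W


def fit(dataset: Sequence[SampleData], config: FitConfig) -> FitResult:
    """Fit the multi-sample model by the per-sample update scheme.

    Each outer iteration: (1) every unit (sample, or chunk of a sample) takes
    one Adam step on its own negative ELBO, updating its GP/variational
    parameters and a private copy of the shared ``W``; (2) the per-unit ``W``
    updates are averaged; (3) negative entries of the average are set to zero.
    Stops at ``max_iter`` or when the relative change of a 10-iteration moving
    average of the loss drops below ``convergence_tol``.
    """
    validate_dataset(dataset)
    if config.objective not in ("mc", "delta"):
        raise ValueError("objective must be 'mc' or 'delta'")
    units, transforms, W = _build_units(dataset, config)
    if not np.any(np.max(W, axis=0) > 0):
        raise ValueError("initial W must have at least one positive column")

    opt_theta = [_Adam(config.learning_rate) for _ in units]
    opt_W = [_Adam(config.learning_rate) for _ in units]
    opt_phi = [_Adam(config.learning_rate) for _ in units]
    mc_rngs = [
        np.random.default_rng(
            int(s) % (2**31)
        )
        for s in np.random.SeedSequence([config.seed, 7]).generate_state(len(units))
    ]

    losses: List[float] = []
    losses_per_unit: List[List[float]] = []
    w_mins: List[float] = []
    converged = False
    for it in range(config.max_iter):
        W_updates = []
        unit_losses = []
        for u, unit in enumerate(units):
            eps = (
                mc_rngs[u].standard_normal(
                    (config.mc_samples, unit.n_spots, config.L)
                )
                if config.objective == "mc"
                else None
            )
            value, grad, gW, g_lphi, _, _ = _unit_value_grad(
                unit, W, want_grad=True,
                optimize_phi=config.optimize_dispersion, mc_eps=eps,
            )
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"non-finite loss at iteration {it} "
                    f"(sample {unit.sample_index})"
                )
            unit_losses.append(value)
            unit.theta = opt_theta[u].step(unit.theta, grad)
            Wu = opt_W[u].step({"W": W.copy()}, {"W": gW})["W"]
            W_updates.append(Wu)
            if config.optimize_dispersion:
                unit.log_phi = float(
                    opt_phi[u].step(
                        {"p": np.array(unit.log_phi)}, {"p": np.array(g_lphi)}
                    )["p"]
                )
        W = np.mean(W_updates, axis=0)
        W[W < 0] = 0.0  # average first, then project
        w_mins.append(float(W.min()))
        losses.append(float(np.sum(unit_losses)))
        losses_per_unit.append([float(x) for x in unit_losses])

        if it >= 20:
            recent = np.mean(losses[-10:])
            prev = np.mean(losses[-20:-10])
            if abs(prev - recent) / (abs(prev) + 1e-12) < config.convergence_tol:
                converged = True
                break

    # posterior factor means at all observed spots, stitched over chunks
    M = len(dataset)
    L = config.L
    factors = [np.zeros((s.n_spots, L)) for s in dataset]
    for unit in units:
        _, _, _, _, meanF, _ = _unit_value_grad(unit, W, want_grad=False)
        factors[unit.sample_index][unit.spot_idx] = meanF

    # per-sample hyperparameters: mean across that sample's units
    amp = np.zeros((M, L))
    ls = np.zeros((M, L))
    b0 = np.zeros((M, L))
    b1 = np.zeros((M, L, 2))
    phi = np.zeros(M)
    counts = np.zeros(M)
    for unit in units:
        m = unit.sample_index
        amp[m] += np.exp(unit.theta["la"])
        ls[m] += np.exp(unit.theta["lb"])
        b0[m] += unit.theta["b0"]
        b1[m] += unit.theta["b1"]
        phi[m] += np.exp(unit.log_phi)
        counts[m] += 1
    for arr in (amp, ls, b0, phi):
        arr /= counts if arr.ndim == 1 else counts[:, None]
    b1 /= counts[:, None, None]

    params = ModelParams(
        W=W,
        dispersion=phi,
        kernel_amplitude=amp,
        kernel_lengthscale=ls,
        mean_intercept=b0,
        mean_slope=b1,
    )
    return FitResult(
        params=params,
        factors=[FactorMatrix(f) for f in factors],
        loss_trajectory=np.array(losses),
        loss_per_unit=np.array(losses_per_unit),
        w_min_trajectory=np.array(w_mins),
        config=config,
        converged=converged,
        sample_ids=[s.sample_id for s in dataset],
        transforms=transforms,
        _units=units,
    )


def predict_factors(
    fit_result: FitResult, sample_index: int, at: np.ndarray
) -> FactorMatrix:
    """Posterior mean of each factor at arbitrary locations (log scale).

    ``at`` is given in the sample's original coordinate units; predictions from
    a chunked fit average the per-chunk conditionals.
    """
    units = [u for u in fit_result._units if u.sample_index == sample_index]
    if not units:
        raise ValueError(f"unknown sample index {sample_index}")
    X = fit_result.transforms[sample_index].apply(np.asarray(at, dtype=float))
    L = fit_result.config.L
    out = np.zeros((X.shape[0], L))
    for unit in units:
        th = unit.theta
        for l in range(L):
            alpha = float(np.exp(th["la"][l]))
            B = float(np.exp(th["lb"][l]))
            Z = unit.inducing.Z
            Kuu = alpha * np.exp(-unit.Dzz / B)
            Kuu[np.diag_indices_from(Kuu)] += unit.jitter * alpha
            Kxu = alpha * np.exp(-cdist(X, Z) / B)
            cho = cho_factor(Kuu, lower=True)
            b0, b1 = th["b0"][l], th["b1"][l]
            delta = th["qm"][l] - (b0 + Z @ b1)
            out[:, l] += b0 + X @ b1 + Kxu @ cho_solve(cho, delta)
    return FactorMatrix(out / len(units))


# ---------------------------------------------------------------------------
# non-spatial variant (multi-sample probabilistic NMF)
# ---------------------------------------------------------------------------


def _pnmf_unit_value_grad(Y, sz, W, qm, qr, mu_l, lsig2, phi):
    """Negative ELBO and grads for the iid-normal-prior variant.

    q(F) is mean-field: F_il ~ N(qm_il, exp(2*qr_il)); prior F_.l ~
    N(mu_l, exp(lsig2_l)).  Returns value and grads wrt qm, qr, mu_l, lsig2, W.
    """
    s2 = np.exp(2.0 * qr)
    sig2 = np.exp(lsig2)[None, :]
    E = np.exp(qm + 0.5 * s2)
    Lam = np.maximum(sz[:, None] * (E @ W.T), _MU_FLOOR)
    ll = nb_log_likelihood(Y, Lam, phi)
    kl = 0.5 * np.sum(
        (s2 + (qm - mu_l[None, :]) ** 2) / sig2 - 1.0 + lsig2[None, :] - 2.0 * qr
    )
    value = -(ll - kl)

    R = Y / Lam - (Y + phi) / (phi + Lam)
    gW = -(R.T @ (sz[:, None] * E))
    H = (R @ W) * sz[:, None]
    gmean_ll = H * E
    gvar_ll = 0.5 * H * E
    g_qm = -gmean_ll + (qm - mu_l[None, :]) / sig2
    g_qr = -(gvar_ll * 2.0 * s2) + (s2 / sig2 - 1.0)
    g_mu = -np.sum((qm - mu_l[None, :]) / sig2, axis=0)
    g_lsig2 = 0.5 * np.sum(
        -(s2 + (qm - mu_l[None, :]) ** 2) / sig2 + 1.0, axis=0
    )
    return value, g_qm, g_qr, g_mu, g_lsig2, gW


def fit_pnmf(dataset: Sequence[SampleData], config: FitConfig) -> FitResult:
    """Fit the non-spatial variant: iid normal prior on log-factors.

    Shares the NB observation layer and the per-sample update scheme with the
    spatial model; the factor-level prior parameters (mu_l, sigma2_l) are
    shared across samples and combined by the same averaging step as ``W``.
    """
    validate_dataset(dataset)
    ss = np.random.SeedSequence(config.seed)
    W, scores = _nmf_init(dataset, config.L, int(ss.generate_state(1)[0] % 2**31),
                          config.nmf_iter)
    qm = [np.log(np.maximum(s_, 1e-3)) for s_ in scores]
    qr = [np.full_like(q, np.log(0.1)) for q in qm]
    mu_l = np.vstack(qm).mean(axis=0)
    lsig2 = np.log(np.maximum(np.vstack(qm).var(axis=0), 1e-2))
    phi = config.dispersion_init

    M = len(dataset)
    opts = [_Adam(config.learning_rate) for _ in range(M)]
    optW = [_Adam(config.learning_rate) for _ in range(M)]
    losses = []
    converged = False
    for it in range(config.max_iter):
        W_updates, prior_updates, unit_losses = [], [], []
        for m, s in enumerate(dataset):
            value, g_qm, g_qr, g_mu, g_ls, gW = _pnmf_unit_value_grad(
                s.counts.astype(float), s.size_factors, W, qm[m], qr[m],
                mu_l, lsig2, phi,
            )
            unit_losses.append(value)
            upd = opts[m].step(
                {"qm": qm[m], "qr": qr[m], "mu": mu_l.copy(), "ls": lsig2.copy()},
                {"qm": g_qm, "qr": g_qr, "mu": g_mu, "ls": g_ls},
            )
            qm[m], qr[m] = upd["qm"], upd["qr"]
            prior_updates.append((upd["mu"], upd["ls"]))
            W_updates.append(optW[m].step({"W": W.copy()}, {"W": gW})["W"])
        W = np.mean(W_updates, axis=0)
        W[W < 0] = 0.0
        mu_l = np.mean([p[0] for p in prior_updates], axis=0)
        lsig2 = np.mean([p[1] for p in prior_updates], axis=0)
        losses.append(float(np.sum(unit_losses)))
        if it >= 20:
            recent, prev = np.mean(losses[-10:]), np.mean(losses[-20:-10])
            if abs(prev - recent) / (abs(prev) + 1e-12) < config.convergence_tol:
                converged = True
                break

    params = ModelParams(
        W=W,
        dispersion=np.full(M, phi),
        kernel_amplitude=np.ones((M, config.L)),
        kernel_lengthscale=np.ones((M, config.L)),
        mean_intercept=np.tile(mu_l, (M, 1)),
        mean_slope=np.zeros((M, config.L, 2)),
    )
    return FitResult(
        params=params,
        factors=[FactorMatrix(q) for q in qm],
        loss_trajectory=np.array(losses),
        loss_per_unit=np.empty((0, 0)),
        w_min_trajectory=np.array([]),
        config=config,
        converged=converged,
        sample_ids=[s.sample_id for s in dataset],
    )
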