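"""Independent brute-force oracles shared across test modules."""

import numpy as np


def dense_conditional_oracle(U, Z, X, kp, beta0, beta1, jitter):
    """Schur-complement conditioning of the explicitly assembled joint Gaussian."""
    pts = np.vstack([Z, X])
    n = Z.shape[0]
    K = np.zeros((pts.shape[0], pts.shape[0]))
    for i in range(pts.shape[0]):
        for j in range(pts.shape[0]):
            d = np.sqrt(np.sum((pts[i] - pts[j]) ** 2))
            K[i, j] = kp.amplitude * np.exp(-d / kp.lengthscale)
    K[:n, :n] += jitter * kp.amplitude * np.eye(n)
    mu = beta0 + pts @ np.asarray(beta1)
    Kuu, Kux, Kxx = K[:n, :n], K[:n, n:], K[n:, n:]
    Kuu_inv = np.linalg.inv(Kuu)
    mean = mu[n:] + Kux.T @ Kuu_inv @ (U - mu[:n])
    cov = Kxx - Kux.T @ Kuu_inv @ Kux
    return mean, cov


def morans_i_dense_oracle(values, coords, k):
    """Double-loop Moran's I with explicit k-NN row-standardized weights."""
    n = len(values)
    z = values - values.mean()
    W = np.zeros((n, n))
    for i in range(n):
        d = np.sqrt(np.sum((coords - coords[i]) ** 2, axis=1))
        d[i] = np.inf
        nbrs = np.argsort(d, kind="stable")[:k]
        W[i, nbrs] = 1.0 / k
    num = sum(W[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return (n / W.sum()) * num / np.sum(z**2)
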