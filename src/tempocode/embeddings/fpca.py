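"""Functional PCA of densely sampled curves via quadrature eigendecomposition.

Curves are represented on their sampling grid; the covariance operator is
discretized with trapezoidal quadrature weights, so eigenfunctions are
orthonormal under the grid inner product <f, g> = sum_i w_i f_i g_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def quadrature_weights(times: np.ndarray) -> np.ndarray:
    """Trapezoid-rule weights for the (uniform or non-uniform) grid."""
    times = np.asarray(times, dtype=float)
    w = np.zeros_like(times)
    w[1:] += 0.5 * np.diff(times)
    w[:-1] += 0.5 * np.diff(times)
    return w


@dataclass
class FPCAModel:
    mean: np.ndarray                      # mu(t), length T
    eigenfunctions: np.ndarray            # R x T, orthonormal under quadrature
    scores: np.ndarray                    # M x R, per-curve weights
    explained_variance_ratio: np.ndarray  # length R, non-increasing
    times: np.ndarray
    weights: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project curves (rows) onto the fitted eigenfunctions."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        centered = X - self.mean[None, :]
        return centered @ (self.eigenfunctions * self.weights[None, :]).T

    def reconstruct(self, scores: np.ndarray | None = None) -> np.ndarray:
        s = self.scores if scores is None else np.atleast_2d(scores)
        return self.mean[None, :] + s @ self.eigenfunctions


def fpca_fit(X: np.ndarray, n_components: int, times: np.ndarray) -> FPCAModel:
    """Mean-centered functional PCA of the rows of ``X``.

    Eigenfunctions are oriented so each one's largest-magnitude value is
    positive; explained-variance fractions are relative to the total
    quadrature-weighted variance.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be a 2-D matrix with at least 2 rows")
    m, t = X.shape
    if not 1 <= n_components <= min(m, t):
        raise ValueError(
            f"n_components must be in [1, {min(m, t)}], got {n_components}"
        )
    times = np.asarray(times, dtype=float)
    if len(times) != t:
        raise ValueError("times length must match the number of columns")

    w = quadrature_weights(times)
    mean = X.mean(axis=0)
    centered = X - mean[None, :]
    cov = (centered.T @ centered) / (m - 1)

    sqrt_w = np.sqrt(w)
    sym = sqrt_w[:, None] * cov * sqrt_w[None, :]
    eigvals, eigvecs = np.linalg.eigh(sym)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]

    phi = (eigvecs[:, :n_components] / sqrt_w[:, None]).T  # R x T
    # sign convention: largest-|value| of each eigenfunction is positive
    for r in range(n_components):
        k = np.argmax(np.abs(phi[r]))
        if phi[r, k] < 0:
            phi[r] = -phi[r]

    scores = centered @ (phi * w[None, :]).T
    total = eigvals.sum()
    ratio = eigvals[:n_components] / total if total > 0 else np.zeros(n_components)
    return FPCAModel(
        mean=mean,
        eigenfunctions=phi,
        scores=scores,
        explained_variance_ratio=ratio,
        times=times,
        weights=w,
    )
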