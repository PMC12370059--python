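"""Non-negative canonical polyadic decomposition of trajectory tensors.

The five-way tensor has axes (ligand, ligand dose, drug, drug dose, time).
Fitting uses hierarchical alternating least squares (HALS) with random
non-negative initialization; the best of several restarts (by R2X) is kept.
R2X is reported as 1 - Var(reconstruction - A) / Var(A).

After fitting, temporal factors are conventionally rescaled to a fixed
trapezoidal area (default 20, time in hours); the inverse scale is folded
into per-component factors rho so the reconstruction is unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import reduce

import numpy as np

DEFAULT_MAX_ITER = 900
DEFAULT_RESTARTS = 5
DEFAULT_TARGET_AREA = 20.0
_CONVERGENCE_TOL = 1e-10


class NormalizationError(ValueError):
    pass


class RescaleError(ValueError):
    pass


def normalize_tensor_per_drug(tensor: np.ndarray, drug_axis: int = 2,
                              drug_labels=None) -> np.ndarray:
    """Divide each drug slab by its own global maximum (slab max becomes 1)."""
    tensor = np.asarray(tensor, dtype=float)
    out = np.empty_like(tensor)
    for k in range(tensor.shape[drug_axis]):
        slab = np.take(tensor, k, axis=drug_axis)
        m = slab.max()
        if m <= 0:
            name = drug_labels[k] if drug_labels is not None else f"index {k}"
            raise NormalizationError(
                f"drug slab {name} has no positive values; cannot normalize"
            )
        idx = [slice(None)] * tensor.ndim
        idx[drug_axis] = k
        out[tuple(idx)] = slab / m
    return out


def _unfold(tensor: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(tensor, mode, 0).reshape(tensor.shape[mode], -1)


def _khatri_rao(mats: list[np.ndarray]) -> np.ndarray:
    def kr(a, b):
        r = a.shape[1]
        return (a[:, None, :] * b[None, :, :]).reshape(-1, r)

    return reduce(kr, mats)


@dataclass
class CPDModel:
    rank: int
    factors: list[np.ndarray]          # axis order (I, J, K, L, T); time last
    lambdas: np.ndarray                # component scalars
    time_minutes: np.ndarray | None = None
    rho: np.ndarray | None = None      # area-rescale factors, set by rescale
    r2x: float = np.nan
    seed: int | None = None
    n_iter: int = 0
    converged: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rho is None:
            self.rho = np.ones(self.rank)

    @property
    def temporal_factors(self) -> np.ndarray:
        """Temporal patterns, one column per component (T x R)."""
        return self.factors[-1]

    def reconstruct(self) -> np.ndarray:
        kr = _khatri_rao(list(self.factors[1:]))
        first = self.factors[0] * (self.lambdas * self.rho)[None, :]
        shape = tuple(f.shape[0] for f in self.factors)
        return (first @ kr.T).reshape(shape)

    def weights(self, i: int, j: int, k: int, l: int) -> np.ndarray:
        """Per-component weights for trajectory (i, j, k, l):
        lambda_r * rho_r * a_i * a_j * a_k * a_l."""
        fI, fJ, fK, fL, _ = self.factors
        return self.lambdas * self.rho * fI[i] * fJ[j] * fK[k] * fL[l]


def cpd_weights(model: CPDModel, i: int, j: int, k: int, l: int) -> np.ndarray:
    return model.weights(i, j, k, l)


def r2x(tensor: np.ndarray, reconstruction: np.ndarray) -> float:
    return float(1.0 - np.var(reconstruction - tensor) / np.var(tensor))


def _hals_fit(tensor, rank, rng, max_iter, tol):
    shape = tensor.shape
    n_modes = tensor.ndim
    factors = [rng.uniform(0.1, 1.0, size=(s, rank)) for s in shape]
    unfoldings = [_unfold(tensor, n) for n in range(n_modes)]
    norm_sq = float(np.sum(tensor**2))
    prev_err = np.inf
    converged = False
    for it in range(max_iter):
        for n in range(n_modes):
            others = [factors[m] for m in range(n_modes) if m != n]
            grams = [f.T @ f for f in others]
            V = reduce(np.multiply, grams)
            W = unfoldings[n] @ _khatri_rao(others)
            F = factors[n]
            for r in range(rank):
                vrr = V[r, r]
                if vrr <= 0:
                    continue
                upd = F[:, r] + (W[:, r] - F @ V[:, r]) / vrr
                F[:, r] = np.maximum(upd, 0.0)
        # squared error via the Gram identity (no full reconstruction)
        cross = float(np.sum(W * factors[-1])) if n_modes else 0.0
        gram_all = reduce(
            np.multiply, [f.T @ f for f in factors]
        )
        err = norm_sq - 2.0 * cross + float(np.sum(gram_all))
        if prev_err - err < tol * max(norm_sq, 1.0):
            converged = True
            break
        prev_err = err
    return factors, it + 1, converged


def cpd_fit(
    tensor: np.ndarray,
    rank: int,
    seed: int = 0,
    max_iter: int = DEFAULT_MAX_ITER,
    restarts: int = DEFAULT_RESTARTS,
    time_minutes: np.ndarray | None = None,
) -> CPDModel:
    """Fit a non-negative CPD; best of ``restarts`` random inits by R2X."""
    tensor = np.asarray(tensor, dtype=float)
    if rank < 1:
        raise ValueError(f"rank must be >= 1, got {rank}")
    if np.any(tensor < 0):
        raise ValueError("tensor must be non-negative")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")

    best: CPDModel | None = None
    for restart in range(restarts):
        rng = np.random.default_rng(seed + restart)
        factors, n_iter, converged = _hals_fit(
            tensor, rank, rng, max_iter, _CONVERGENCE_TOL
        )
        norms = [np.linalg.norm(f, axis=0) for f in factors]
        lambdas = reduce(np.multiply, norms)
        unit = [
            np.where(nz > 0, f / np.where(nz > 0, nz, 1.0), f)
            for f, nz in zip(factors, norms)
        ]
        model = CPDModel(
            rank=rank,
            factors=unit,
            lambdas=lambdas,
            time_minutes=None if time_minutes is None else np.asarray(time_minutes),
            seed=seed + restart,
            n_iter=n_iter,
            converged=converged,
        )
        model.r2x = r2x(tensor, model.reconstruct())
        if best is None or model.r2x > best.r2x:
            best = model
    if not best.converged:
        warnings.warn(
            f"CPD did not converge within {max_iter} iterations "
            f"(best R2X {best.r2x:.4f}); returning partial fit",
            RuntimeWarning,
        )
        best.meta["non_converged"] = True
    return best


def rescale_temporal(
    model: CPDModel, target_area: float = DEFAULT_TARGET_AREA
) -> CPDModel:
    """Rescale every temporal pattern to a fixed trapezoidal area.

    Areas use time in hours. The per-component inverse scales are stored in
    ``rho`` and folded into the lambdas so the reconstruction is unchanged.
    """
    if model.time_minutes is None:
        raise RescaleError("model carries no time grid; cannot compute areas")
    t_hours = np.asarray(model.time_minutes, dtype=float) / 60.0
    temporal = model.temporal_factors
    areas = np.trapezoid(temporal, x=t_hours, axis=0)
    if np.any(areas <= 0):
        bad = np.nonzero(areas <= 0)[0].tolist()
        raise RescaleError(f"temporal component(s) {bad} have non-positive area")
    scale = target_area / areas          # multiply temporal factor by this
    rho = areas / target_area            # inverse scale enters the weights
    factors = [f.copy() for f in model.factors]
    factors[-1] = temporal * scale[None, :]
    return CPDModel(
        rank=model.rank,
        factors=factors,
        lambdas=model.lambdas.copy(),    # lambda * rho * a_T stays invariant
        time_minutes=model.time_minutes,
        rho=rho,
        r2x=model.r2x,
        seed=model.seed,
        n_iter=model.n_iter,
        converged=model.converged,
        meta=dict(model.meta),
    )
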