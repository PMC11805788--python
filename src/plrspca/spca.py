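"""Sparse PCA via variable projection with an elastic-net penalty.

Minimises, over a sparse loading matrix B (P x k) and an orthonormal matrix
H (P x k),

    1/2 ||X - X B H^T||_F^2 + alpha ||B||_1 + beta ||B||_F^2,

by alternating two exact/majorised steps:

* H-step (orthogonal Procrustes): H = U V^T from the thin SVD of X^T X B,
  the minimiser over the Stiefel manifold for fixed B.
* B-step (proximal gradient): one step on the smooth part with fixed step
  size 1/lambda_max(X^T X), followed by the elastic-net proximal operator
  b <- soft(b - step * grad, step * alpha) / (1 + 2 * step * beta).

Both steps are descent steps, so the objective trace is non-increasing.
Soft-thresholding produces exact zeros, which is what makes the row support
of B a selection of pairwise logratios.  Scores are Z = X B.

alpha controls sparsity (the l1 weight); beta is a small ridge weight kept at
1e-4 by default to stabilise collinear logratios without affecting selection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .coda import PlrMatrix, total_variance

__all__ = [
    "SpcaConfig",
    "SpcaFit",
    "spca_objective",
    "fit_spca",
    "adjusted_explained_variance",
    "selected_plrs",
    "fit_to_json",
]

# |b| below this is accumulated float noise, treated as an exact zero
_ZERO_GUARD = 1e-12


@dataclass(frozen=True)
class SpcaConfig:
    """Tuning parameters for one sparse-PCA fit."""

    alpha: float = 0.0
    beta: float = 1e-4
    k: int = 2
    max_iter: int = 1000
    tol: float = 1e-5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValueError("max_iter must be >= 1 and tol > 0")


@dataclass(frozen=True)
class SpcaFit:
    """Result of one sparse-PCA fit.

    B is the sparse loading matrix (exact zeros), H the orthonormal helper
    matrix, scores = X B.  ``objective_trace`` holds the objective after each
    accepted iteration and is non-increasing.
    """

    B: np.ndarray
    H: np.ndarray
    scores: np.ndarray
    objective_trace: np.ndarray
    config: SpcaConfig
    converged: bool
    pairs: tuple[tuple[str, str], ...] = ()

    @property
    def n_selected(self) -> int:
        return int(np.sum(np.any(self.B != 0.0, axis=1)))


def _check_centered(x: PlrMatrix) -> np.ndarray:
    if not x.centered:
        raise ValueError("sparse PCA expects a centred PlrMatrix")
    return x.values


def spca_objective(x: PlrMatrix, B: np.ndarray, H: np.ndarray, alpha: float, beta: float) -> float:
    """Evaluate 1/2 ||X - X B H^T||_F^2 + alpha ||B||_1 + beta ||B||_F^2."""
    X = _check_centered(x)
    if not np.allclose(H.T @ H, np.eye(H.shape[1]), atol=1e-6):
        raise ValueError("H must have orthonormal columns")
    resid = X - (X @ B) @ H.T
    return float(
        0.5 * np.sum(resid**2) + alpha * np.sum(np.abs(B)) + beta * np.sum(B**2)
    )


def _objective_from_gram(
    sq_norm: float, G: np.ndarray, B: np.ndarray, H: np.ndarray, alpha: float, beta: float
) -> float:
    # 1/2||X - XBH^T||^2 = 1/2||X||^2 - tr(B^T G H) + 1/2 tr(B^T G B), H^T H = I
    GB = G @ B
    return float(
        0.5 * sq_norm
        - np.sum(B * (G @ H))
        + 0.5 * np.sum(B * GB)
        + alpha * np.sum(np.abs(B))
        + beta * np.sum(B**2)
    )


def _orient_signs(B: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip component signs so each column's largest-|.| loading is positive.

    Flipping a column of B together with the same column of H leaves the
    objective unchanged; this fixes the sign indeterminacy for reproducible
    output.  Columns of all zeros are left alone.
    """
    B = B.copy()
    H = H.copy()
    for c in range(B.shape[1]):
        col = B[:, c] if np.any(B[:, c] != 0) else H[:, c]
        if np.any(col != 0) and col[np.argmax(np.abs(col))] < 0:
            B[:, c] *= -1.0
            H[:, c] *= -1.0
    return B, H


def fit_spca(
    x: PlrMatrix,
    config: SpcaConfig,
    *,
    init: "tuple[np.ndarray, np.ndarray] | None" = None,
) -> SpcaFit:
    """Fit sparse PCA on a centred PLR matrix.

    By default B and H are initialised from the k leading right singular
    vectors of X, which makes the alpha=0 fit coincide with classical PCA and
    the whole procedure deterministic.  ``init=(B0, H0)`` warm-starts the
    solver (used along a sparsity path).
    """
    X = _check_centered(x)
    n, P = X.shape
    k = config.k
    if k > min(n - 1, P):
        raise ValueError(f"k={k} exceeds min(n-1, P)={min(n - 1, P)}")

    G = X.T @ X
    sq_norm = float(np.sum(X**2))
    # step size 1/L with L = lambda_max(G); eigvalsh on the small Gram matrix
    L = float(np.linalg.eigvalsh(G)[-1])
    if L <= 0:
        raise ValueError("X has no variance; cannot fit sparse PCA")
    step = 1.0 / L
    shrink = 1.0 / (1.0 + 2.0 * step * config.beta)
    thresh = step * config.alpha

    if init is not None:
        B, H = (np.array(m, dtype=float, copy=True) for m in init)
        if np.all(B == 0.0):
            # degenerate warm start: fall back to spectral initialisation
            init = None
    if init is None:
        _, _, Vt = np.linalg.svd(X, full_matrices=False)
        B = Vt[:k].T.copy()
        H = Vt[:k].T.copy()

    trace = [_objective_from_gram(sq_norm, G, B, H, config.alpha, config.beta)]
    converged = False
    for _ in range(config.max_iter):
        # H-step: Procrustes polar factor of G B
        GB = G @ B
        if np.any(GB != 0.0):
            U, _, Vt = np.linalg.svd(GB, full_matrices=False)
            H = U @ Vt
        # B-step: proximal gradient on the smooth part
        grad = GB - G @ H
        Z = B - step * grad
        B = np.sign(Z) * np.maximum(np.abs(Z) - thresh, 0.0) * shrink
        B[np.abs(B) < _ZERO_GUARD] = 0.0
        obj = _objective_from_gram(sq_norm, G, B, H, config.alpha, config.beta)
        trace.append(obj)
        prev = trace[-2]
        if abs(prev - obj) <= config.tol * max(abs(prev), 1.0):
            converged = True
            break
    if not converged:
        warnings.warn(
            f"sparse PCA did not converge in {config.max_iter} iterations "
            f"(last relative change {abs(trace[-2] - trace[-1]):.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    B, H = _orient_signs(B, H)
    return SpcaFit(
        B=B,
        H=H,
        scores=X @ B,
        objective_trace=np.asarray(trace),
        config=config,
        converged=converged,
        pairs=x.pairs,
    )


def adjusted_explained_variance(x: PlrMatrix, fit: SpcaFit) -> float:
    """Percentage of total variability explained by the fitted components.

    Sparse components are correlated, so naive per-component variances
    double-count; the standard adjustment orthogonalises the score matrix
    Z = X B by a QR decomposition and sums the squared diagonal of R:

        100 * sum(diag(R)^2) / ((n - 1) * total_variance(X)).

    At alpha=0 this reduces to the classical cumulative eigenvalue ratio.
    """
    X = _check_centered(x)
    if np.all(fit.B == 0.0):
        return 0.0
    _, R = np.linalg.qr(X @ fit.B)
    tot = (x.n - 1) * total_variance(x)
    return float(100.0 * np.sum(np.diag(R) ** 2) / tot)


def selected_plrs(fit: SpcaFit) -> set[tuple[str, str]]:
    """Pairs whose loading row is nonzero in at least one component."""
    if not fit.pairs:
        raise ValueError("fit carries no pair labels")
    mask = np.any(fit.B != 0.0, axis=1)
    return {fit.pairs[p] for p in np.flatnonzero(mask)}


def fit_to_json(x: PlrMatrix, fit: SpcaFit) -> str:
    """Serialise a fit: config, per-component support, loadings, diagnostics."""
    labels = x.labels
    per_component = [
        [labels[p] for p in np.flatnonzero(fit.B[:, c] != 0.0)] for c in range(fit.B.shape[1])
    ]
    payload = {
        "config": {
            "alpha": fit.config.alpha,
            "beta": fit.config.beta,
            "k": fit.config.k,
            "max_iter": fit.config.max_iter,
            "tol": fit.config.tol,
        },
        "selected_per_component": per_component,
        "loadings": {labels[p]: fit.B[p].tolist() for p in range(fit.B.shape[0])},
        "explained_variance_pct": adjusted_explained_variance(x, fit),
        "n_selected": fit.n_selected,
        "converged": bool(fit.converged),
        "n_iterations": int(len(fit.objective_trace) - 1),
        "objective": float(fit.objective_trace[-1]),
    }
    return json.dumps(payload, indent=2, sort_keys=True)
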