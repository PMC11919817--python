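"""GP covariance functions built from dissimilarity matrices.

The core construction turns any dissimilarity d(x, x') into a squared-
exponential-style covariance

    k(x, x') = sigma^2 exp(-d(x, x')^2 / (2 l^2)),

with length scale ``l`` and output scale ``sigma`` as hyperparameters. A
multiple kernel sums several such components (one per dissimilarity index),
each with independent hyperparameters. Because beta-diversity dissimilarities
are not Euclidean-embeddable in general, the exponentiated matrices can be
indefinite; :func:`psd_repair` restores positive semidefiniteness by jitter
or eigenvalue clipping before any Cholesky factorization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

DEFAULT_JITTER_TOL = 1e-8


@dataclass
class KernelComponent:
    """One covariance component.

    ``kind`` is ``distance_rbf`` (dissimilarity-based, the main construction),
    ``euclidean_rbf`` (ordinary RBF on feature vectors) or ``linear``
    (``sigma^2 X X'^T``, no length scale).
    """

    kind: str
    source: str
    length_scale: float = 1.0
    output_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("distance_rbf", "euclidean_rbf", "linear"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        for name in ("length_scale", "output_scale"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive and finite, got {v}")


@dataclass
class KernelSpec:
    """Ordered list of components plus the PSD-repair policy."""

    components: list[KernelComponent]
    jitter: float = DEFAULT_JITTER_TOL
    psd_mode: str = "jitter"

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("kernel spec needs at least one component")
        sources = [c.source for c in self.components]
        if len(set(sources)) != len(sources):
            raise ValueError("component sources must be distinct within one spec")
        if self.psd_mode not in ("jitter", "clip"):
            raise ValueError(f"unknown psd_mode {self.psd_mode!r}")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")


def distance_kernel(D: np.ndarray, length_scale: float, output_scale: float) -> np.ndarray:
    """Entrywise sigma^2 exp(-d^2 / (2 l^2)) applied to a distance block."""
    if length_scale <= 0 or output_scale <= 0:
        raise ValueError("length_scale and output_scale must be strictly positive")
    D = np.asarray(D, dtype=float)
    if np.any(D < 0) or not np.all(np.isfinite(D)):
        raise ValueError("distances must be finite and non-negative")
    return output_scale**2 * np.exp(-(D**2) / (2.0 * length_scale**2))


def multiple_kernel(blocks: list[np.ndarray]) -> np.ndarray:
    """Elementwise sum of conformable covariance blocks (the additive kernel)."""
    if not blocks:
        raise ValueError("need at least one covariance block")
    shape = np.asarray(blocks[0]).shape
    total = np.zeros(shape)
    for b in blocks:
        b = np.asarray(b, dtype=float)
        if b.shape != shape:
            raise ValueError(f"covariance block shape {b.shape} != {shape}")
        total += b
    return total


def linear_kernel(X: np.ndarray, X2: np.ndarray | None = None, output_scale: float = 1.0) -> np.ndarray:
    """sigma^2 X X'^T on feature matrices (relative abundances)."""
    if output_scale <= 0:
        raise ValueError("output_scale must be strictly positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    X2 = X if X2 is None else np.atleast_2d(np.asarray(X2, dtype=float))
    return output_scale**2 * X @ X2.T


def euclidean_rbf_kernel(
    X: np.ndarray,
    X2: np.ndarray | None = None,
    length_scale: float = 1.0,
    output_scale: float = 1.0,
) -> np.ndarray:
    """Ordinary RBF kernel sigma^2 exp(-||x - x'||^2 / (2 l^2))."""
    from scipy.spatial.distance import cdist

    X = np.atleast_2d(np.asarray(X, dtype=float))
    X2 = X if X2 is None else np.atleast_2d(np.asarray(X2, dtype=float))
    return distance_kernel(cdist(X, X2), length_scale, output_scale)


def assemble_train_test(
    spec: KernelSpec,
    D_full: dict[str, np.ndarray],
    train_idx: np.ndarray,
    test_idx: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slice train/train, test/train and test-diagonal covariances.

    Kernels are evaluated on the full precomputed distance matrices and then
    sliced, so any split reproduces sub-blocks of the full-kernel matrix
    exactly. Returns ``(K_train, K_cross, k_diag_test)``.
    """
    train_idx = np.asarray(train_idx, dtype=int)
    test_idx = np.asarray(test_idx, dtype=int)
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test index sets overlap")

    n_train, n_test = len(train_idx), len(test_idx)
    K_train = np.zeros((n_train, n_train))
    K_cross = np.zeros((n_test, n_train))
    k_diag = np.zeros(n_test)
    for comp in spec.components:
        if comp.source not in D_full:
            raise ValueError(f"no distance matrix for component source {comp.source!r}")
        D = np.asarray(D_full[comp.source], dtype=float)
        if comp.kind == "linear":
            # here D_full carries the Gram matrix X X^T for the linear component
            K_full = comp.output_scale**2 * D
        else:
            K_full = distance_kernel(D, comp.length_scale, comp.output_scale)
        K_train += K_full[np.ix_(train_idx, train_idx)]
        K_cross += K_full[np.ix_(test_idx, train_idx)]
        k_diag += np.diag(K_full)[test_idx]
    return K_train, K_cross, k_diag


@dataclass
class PSDRepairResult:
    matrix: np.ndarray
    correction: float
    mode: str


def psd_repair(K: np.ndarray, mode: str = "jitter", tol: float = DEFAULT_JITTER_TOL) -> PSDRepairResult:
    """Make a symmetric matrix positive semidefinite.

    ``jitter`` adds lambda*I with lambda = max(0, tol - smallest eigenvalue),
    escalating tenfold until a Cholesky factorization succeeds. ``clip``
    eigendecomposes and floors eigenvalues at ``tol``. The applied correction
    magnitude is recorded; corrections above 1% of the mean diagonal trigger
    a loud warning.
    """
    K = np.asarray(K, dtype=float)
    if not np.all(np.isfinite(K)):
        raise ValueError("kernel matrix contains NaN/Inf")
    if np.max(np.abs(K - K.T), initial=0.0) > 1e-10:
        raise ValueError("kernel matrix is not symmetric within 1e-10")
    K = 0.5 * (K + K.T)
    if mode not in ("jitter", "clip"):
        raise ValueError(f"unknown psd mode {mode!r}")

    if mode == "clip":
        w, V = np.linalg.eigh(K)
        clipped = np.maximum(w, tol)
        correction = float(np.max(clipped - w))
        repaired = (V * clipped) @ V.T
        repaired = 0.5 * (repaired + repaired.T)
    else:
        lam_min = float(sla.eigh(K, eigvals_only=True, subset_by_index=[0, 0])[0])
        lam = max(0.0, tol - lam_min)
        n = K.shape[0]
        lam_floor = max(tol, 1e-12 * max(1.0, abs(float(np.mean(np.diag(K))))))
        repaired = K
        for _ in range(60):
            repaired = K + lam * np.eye(n)
            try:
                np.linalg.cholesky(repaired + 0.0)
                break
            except np.linalg.LinAlgError:
                lam = max(lam * 10.0, lam_floor)
        else:  # pragma: no cover - 60 escalations never exhausted in practice
            raise np.linalg.LinAlgError("jitter escalation failed to reach PSD")
        correction = lam

    mean_diag = float(np.mean(np.diag(K))) or 1.0
    if correction > 0.01 * abs(mean_diag):
        warnings.warn(
            f"PSD repair ({mode}) applied a large correction {correction:.3g} "
            f"(> 1% of mean diagonal {mean_diag:.3g}); the kernel is materially altered",
            UserWarning,
            stacklevel=2,
        )
    return PSDRepairResult(matrix=repaired, correction=correction, mode=mode)


def median_offdiag(D: np.ndarray) -> float:
    """Median off-diagonal distance; the default length-scale initializer."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 2:
        return 1.0
    iu = np.triu_indices(n, k=1)
    med = float(np.median(D[iu]))
    return med if med > 0 else 1.0
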