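"""Exact Gaussian-process regression with Gaussian noise.

Model: y = f(x) + eps, f ~ GP(0, k), eps ~ N(0, sigma_n^2). With training
kernel matrix K and K_y = K + sigma_n^2 I, the predictive distribution at a
test input is Gaussian with

    mu*      = k*^T K_y^-1 y
    sigma*^2 = k** + sigma_n^2 - k*^T K_y^-1 k*

and the log marginal likelihood is

    log p(y) = -1/2 y^T K_y^-1 y - 1/2 log|K_y| - n/2 log 2 pi.

Hyperparameters (per-component length scale l_c and output scale sigma_c,
plus the noise scale sigma_n) are optimized by Adam ascent on the log
marginal likelihood, with positivity enforced through a softplus
reparameterization. Gradients use the standard trace identity
d log p / d theta = 1/2 tr((alpha alpha^T - K_y^-1) dK/d theta) with
alpha = K_y^-1 y, evaluated via Cholesky solves (no explicit inverses of
K_y are formed for the solve path; the inverse needed by the trace term is
obtained by triangular back-substitution on the identity).

Targets are standardized to zero mean / unit variance for fitting, so the
zero-mean prior is well specified regardless of the target's units; all
predictions are returned on the original scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from microgp.kernels import (
    KernelSpec,
    assemble_train_test,
    distance_kernel,
    median_offdiag,
    psd_repair,
)

ADAM_BETA1 = 0.9
ADAM_BETA2 = 0.999
ADAM_EPS = 1e-8
_LOG2PI = float(np.log(2.0 * np.pi))


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _softplus_inv(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    # log(e^y - 1), stable for large y
    return y + np.log1p(-np.exp(-y))


@dataclass
class PredictiveDistribution:
    """Per-test-sample Gaussian predictive mean and variance, original scale."""

    mean: np.ndarray
    variance: np.ndarray
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        if self.mean.shape != self.variance.shape:
            raise ValueError("mean and variance shapes differ")
        if not (np.all(np.isfinite(self.mean)) and np.all(np.isfinite(self.variance))):
            raise ValueError("predictive distribution has non-finite entries")
        if np.any(self.variance <= 0):
            raise ValueError("predictive variances must be strictly positive")

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(self.variance)

    def __len__(self) -> int:
        return len(self.mean)


@dataclass
class GPModel:
    """Fitted (or initialized) GP: kernel spec, noise, data and cached factor."""

    spec: KernelSpec
    noise_variance: float
    D_full: dict[str, np.ndarray]
    train_idx: np.ndarray
    y_std: np.ndarray  # standardized training targets
    y_mean: float
    y_scale: float
    train_ids: list[str] | None = None
    history: dict = field(default_factory=dict)
    # caches, populated by _refresh
    _cho: tuple | None = None
    _alpha: np.ndarray | None = None
    _K_train: np.ndarray | None = None
    _diag_lift: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_variance <= 0:
            raise ValueError("noise variance must be strictly positive")
        if self.y_scale <= 0 or not np.isfinite(self.y_scale):
            raise ValueError("target scale must be positive and finite")
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        if self._cho is None:
            self._refresh()

    def _refresh(self) -> None:
        n_full = next(iter(self.D_full.values())).shape[0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            if self.spec.psd_mode == "jitter":
                # jitter repairs the kernel on the FULL sample set (train and
                # test jointly, no target information involved) and is then
                # sliced: off-diagonal blocks are untouched, every diagonal
                # gains the same lambda. This keeps the effective kernel PSD
                # everywhere, so predictive variances are non-negative by
                # construction rather than by flooring.
                K_all, _, _ = assemble_train_test(
                    self.spec, self.D_full, np.arange(n_full), np.empty(0, dtype=int)
                )
                rep = psd_repair(K_all, mode="jitter", tol=self.spec.jitter)
                K_train = rep.matrix[np.ix_(self.train_idx, self.train_idx)]
                self._diag_lift = rep.correction
            else:
                K_train_raw, _, _ = assemble_train_test(
                    self.spec, self.D_full, self.train_idx, np.empty(0, dtype=int)
                )
                rep = psd_repair(K_train_raw, mode="clip", tol=self.spec.jitter)
                K_train = rep.matrix
                self._diag_lift = 0.0
        self.history.setdefault("psd_correction", rep.correction)
        K_y = K_train + self.noise_variance * np.eye(len(self.train_idx))
        self._K_train = K_train
        self._cho = cho_factor(K_y, lower=True)
        self._alpha = cho_solve(self._cho, self.y_std)

    # ------------------------------------------------------------- science

    def log_marginal_likelihood(self) -> float:
        n = len(self.y_std)
        L = self._cho[0]
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        quad = float(self.y_std @ self._alpha)
        return -0.5 * quad - 0.5 * logdet - 0.5 * n * _LOG2PI

    def predict(self, K_cross: np.ndarray, k_diag_test: np.ndarray) -> PredictiveDistribution:
        """Posterior predictive from explicit cross-covariances (Eqs. above)."""
        K_cross = np.atleast_2d(np.asarray(K_cross, dtype=float))
        k_diag_test = np.asarray(k_diag_test, dtype=float)
        if K_cross.shape[1] != len(self.train_idx):
            raise ValueError(
                f"K_cross has {K_cross.shape[1]} columns; expected {len(self.train_idx)}"
            )
        if K_cross.shape[0] != len(k_diag_test):
            raise ValueError("K_cross rows and k_diag_test length differ")
        mu = K_cross @ self._alpha
        # v = L^-1 k*  =>  k*^T K_y^-1 k* = ||v||^2
        L, lower = self._cho
        v = solve_triangular(L, K_cross.T, lower=lower)
        var = k_diag_test + self._diag_lift + self.noise_variance - np.sum(v * v, axis=0)
        floor = self.noise_variance * 1e-6
        var = np.where(var <= 0, floor, var)
        return PredictiveDistribution(
            mean=mu * self.y_scale + self.y_mean,
            variance=var * self.y_scale**2,
        )

    def predict_indices(self, test_idx: np.ndarray) -> PredictiveDistribution:
        """Predict at rows of the full distance matrices given by index."""
        _, K_cross, k_diag = assemble_train_test(
            self.spec, self.D_full, self.train_idx, np.asarray(test_idx, dtype=int)
        )
        return self.predict(K_cross, k_diag)


def log_marginal_likelihood(model: GPModel) -> float:
    return model.log_marginal_likelihood()


def predict(model: GPModel, K_cross: np.ndarray, k_diag_test: np.ndarray) -> PredictiveDistribution:
    return model.predict(K_cross, k_diag_test)


# ----------------------------------------------------------------- fitting


def _pack_init(spec: KernelSpec, D_full: dict, train_idx: np.ndarray, n_comp: int) -> np.ndarray:
    """Initial hyperparameters on the standardized-target scale.

    l_c: median off-diagonal training distance; sigma_c^2 = var(y_std)/n_comp
    = 1/n_comp; sigma_n^2 = 0.1 * var(y_std) = 0.1.
    """
    theta = []
    for comp in spec.components:
        if comp.kind != "linear":
            D_tr = np.asarray(D_full[comp.source])[np.ix_(train_idx, train_idx)]
            theta.append(median_offdiag(D_tr))
        theta.append(1.0 / np.sqrt(n_comp))
    theta.append(np.sqrt(0.1))
    return np.array(theta, dtype=float)


def _unpack(spec: KernelSpec, theta: np.ndarray) -> tuple[list[tuple[float, float]], float]:
    """Split the flat hyperparameter vector into (l, sigma) per component + noise."""
    out = []
    k = 0
    for comp in spec.components:
        if comp.kind == "linear":
            out.append((None, theta[k]))
            k += 1
        else:
            out.append((theta[k], theta[k + 1]))
            k += 2
    return out, float(theta[k])


def _lml_and_grad(
    spec: KernelSpec,
    D_tr: dict[str, np.ndarray],
    y: np.ndarray,
    theta: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Log marginal likelihood and its gradient w.r.t. the raw hyperparameters."""
    n = len(y)
    per_comp, sigma_n = _unpack(spec, theta)
    blocks = []
    for comp, (l, s) in zip(spec.components, per_comp):
        D = D_tr[comp.source]
        if comp.kind == "linear":
            blocks.append(s**2 * D)
        else:
            blocks.append(distance_kernel(D, l, s))
    K = np.zeros((n, n))
    for b in blocks:
        K += b
    # repair warnings are summarized once per fit, not emitted per epoch
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        rep = psd_repair(K, mode=spec.psd_mode, tol=spec.jitter)
    K_y = rep.matrix + sigma_n**2 * np.eye(n)
    try:
        cho = cho_factor(K_y, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf, np.zeros_like(theta)
    alpha = cho_solve(cho, y)
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    lml = -0.5 * float(y @ alpha) - 0.5 * logdet - 0.5 * n * _LOG2PI

    K_inv = cho_solve(cho, np.eye(n))
    M = np.outer(alpha, alpha) - K_inv  # d lml/d theta = 1/2 tr(M dK/dtheta)

    grad = np.zeros_like(theta)
    k = 0
    for comp, (l, s), E in zip(spec.components, per_comp, blocks):
        D = D_tr[comp.source]
        if comp.kind == "linear":
            dK = (2.0 / s) * E  # E = s^2 G
            grad[k] = 0.5 * float(np.sum(M * dK))
            k += 1
        else:
            dK_dl = E * (D**2 / l**3)
            dK_ds = (2.0 / s) * E
            grad[k] = 0.5 * float(np.sum(M * dK_dl))
            grad[k + 1] = 0.5 * float(np.sum(M * dK_ds))
            k += 2
    grad[k] = 0.5 * float(np.sum(np.diag(M))) * 2.0 * sigma_n
    return lml, grad


def fit(
    spec: KernelSpec,
    D_full: dict[str, np.ndarray],
    y_train: np.ndarray,
    train_idx: np.ndarray,
    epochs: int = 200,
    learning_rate: float = 0.1,
    seed: int = 0,
    train_ids: list[str] | None = None,
) -> GPModel:
    """Maximize the log marginal likelihood with Adam for ``epochs`` steps.

    The best-likelihood iterate (not the last) is retained. Deterministic:
    the optimization itself is full-batch with a fixed initialization, so
    ``seed`` only tags the model for provenance.
    """
    train_idx = np.asarray(train_idx, dtype=int)
    y_train = np.asarray(y_train, dtype=float)
    if len(y_train) != len(train_idx):
        raise ValueError("y_train and train_idx lengths differ")
    if len(y_train) < 3:
        raise ValueError("need at least 3 training samples")

    mu_y = float(np.mean(y_train))
    s_y = float(np.std(y_train))
    if s_y <= 0:
        raise ValueError("training targets are constant; GP fit undefined")
    y = (y_train - mu_y) / s_y

    D_tr = {
        src: np.asarray(D)[np.ix_(train_idx, train_idx)] for src, D in D_full.items()
    }
    n_comp = len(spec.components)
    theta0 = _pack_init(spec, D_full, train_idx, n_comp)
    rho = _softplus_inv(theta0)

    m = np.zeros_like(rho)
    v = np.zeros_like(rho)
    best_lml = -np.inf
    best_theta = _softplus(rho)
    lml_trace: list[float] = []

    lr = learning_rate
    rho_prev = rho.copy()
    for t in range(1, epochs + 1):
        theta = _softplus(rho)
        lml, g_theta = _lml_and_grad(spec, D_tr, y, theta)
        if not np.isfinite(lml):
            # halve the step and retry the epoch once, then abort
            if lr == learning_rate:
                lr = learning_rate / 2.0
                rho = rho_prev
                continue
            raise RuntimeError(
                f"non-finite marginal likelihood at epoch {t}; trace: {lml_trace[-5:]}"
            )
        lml_trace.append(lml)
        if lml > best_lml:
            best_lml = lml
            best_theta = theta.copy()
        g = g_theta * _sigmoid(rho)  # chain rule through softplus
        m = ADAM_BETA1 * m + (1 - ADAM_BETA1) * g
        v = ADAM_BETA2 * v + (1 - ADAM_BETA2) * g**2
        m_hat = m / (1 - ADAM_BETA1**t)
        v_hat = v / (1 - ADAM_BETA2**t)
        rho_prev = rho
        rho = rho + lr * m_hat / (np.sqrt(v_hat) + ADAM_EPS)  # ascent

    if epochs == 0:
        best_theta = _softplus(rho)
    else:
        # evaluate the final iterate too
        theta = _softplus(rho)
        lml, _ = _lml_and_grad(spec, D_tr, y, theta)
        if np.isfinite(lml):
            lml_trace.append(lml)
            if lml > best_lml:
                best_lml = lml
                best_theta = theta.copy()

    per_comp, sigma_n = _unpack(spec, best_theta)
    fitted_components = []
    for comp, (l, s) in zip(spec.components, per_comp):
        fitted_components.append(
            type(comp)(
                kind=comp.kind,
                source=comp.source,
                length_scale=float(l) if l is not None else comp.length_scale,
                output_scale=float(s),
            )
        )
    fitted_spec = KernelSpec(
        components=fitted_components, jitter=spec.jitter, psd_mode=spec.psd_mode
    )
    return GPModel(
        spec=fitted_spec,
        noise_variance=float(sigma_n**2),
        D_full=D_full,
        train_idx=train_idx,
        y_std=y,
        y_mean=mu_y,
        y_scale=s_y,
        train_ids=train_ids,
        history={
            "epochs": epochs,
            "learning_rate": learning_rate,
            "seed": seed,
            "lml_trace": lml_trace,
            "best_lml": best_lml if np.isfinite(best_lml) else None,
        },
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out
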