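"""Scoring of predictive distributions and the repeated-split experiment.

Metrics
-------
* NLL: mean negative log predictive density of held-out targets (natural log).
* RMSE: root-mean-square error of the predictive means.
* Calibration: for confidence levels p_1 < ... < p_m, the empirical coverage
  p_hat_j of the central interval mu* +- z_{(1+p_j)/2} sigma*; ECE is the
  unweighted mean absolute gap |p_hat_j - p_j|. Default grid: 19 levels
  0.05, 0.10, ..., 0.95.
* Confidence/oracle curves: RMSE of the remaining test points as points are
  removed one at a time, by descending predictive variance (confidence) or
  descending absolute error (oracle), from 0 up to 90% removed. AUCO is the
  signed trapezoidal area between the two curves over the removal-fraction
  axis (the curves are retained so the sign is auditable).

The experiment harness repeats a 50/50 train/test split (10 times by
default), fits a GP per split and aggregates each metric as mean +- standard
error of the mean over splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from microgp import gp as gp_mod
from microgp.containers import DistanceMatrix, TargetVector
from microgp.gp import GPModel, PredictiveDistribution
from microgp.kernels import KernelComponent, KernelSpec

DEFAULT_LEVELS = np.round(np.arange(0.05, 0.951, 0.05), 10)


def _aligned(pred: PredictiveDistribution, y_test) -> np.ndarray:
    y = np.asarray(y_test, dtype=float)
    if y.shape != pred.mean.shape:
        raise ValueError(
            f"predictions ({pred.mean.shape}) and targets ({y.shape}) are misaligned"
        )
    return y


def nll(pred: PredictiveDistribution, y_test) -> float:
    """Mean negative Gaussian log predictive density."""
    y = _aligned(pred, y_test)
    logpdf = stats.norm.logpdf(y, loc=pred.mean, scale=pred.sd)
    return float(-np.mean(logpdf))


def rmse(means, y_test) -> float:
    means = np.asarray(means, dtype=float)
    y = np.asarray(y_test, dtype=float)
    if y.shape != means.shape:
        raise ValueError("predictions and targets are misaligned")
    if y.size == 0:
        raise ValueError("empty test set")
    return float(np.sqrt(np.mean((y - means) ** 2)))


@dataclass
class CalibrationCurve:
    levels: np.ndarray
    coverage: np.ndarray
    ece: float


def calibration(pred: PredictiveDistribution, y_test, levels=None) -> CalibrationCurve:
    """Empirical coverage of central predictive intervals at each level."""
    y = _aligned(pred, y_test)
    if y.size == 0:
        raise ValueError("empty test set")
    levels = DEFAULT_LEVELS if levels is None else np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise ValueError("empty confidence-level grid")
    if np.any(levels <= 0) or np.any(levels >= 1):
        raise ValueError("confidence levels must lie strictly in (0, 1)")
    if np.any(np.diff(levels) <= 0):
        raise ValueError("confidence levels must be strictly increasing")
    z = stats.norm.ppf((1.0 + levels) / 2.0)
    half = pred.sd[None, :] * z[:, None]  # m x N half-widths
    inside = np.abs(y[None, :] - pred.mean[None, :]) <= half
    coverage = inside.mean(axis=1)
    ece = float(np.mean(np.abs(coverage - levels)))
    return CalibrationCurve(levels=levels, coverage=coverage, ece=ece)


@dataclass
class ConfidenceCurves:
    fractions: np.ndarray
    confidence_rmse: np.ndarray
    oracle_rmse: np.ndarray
    auco: float


def confidence_oracle_curves(pred: PredictiveDistribution, y_test) -> ConfidenceCurves:
    """Error-vs-removal curves ranking by predictive variance and by true error."""
    y = _aligned(pred, y_test)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 test points for confidence/oracle curves")
    resid = np.abs(y - pred.mean)
    # stable sorts: descending key, ties broken by ascending sample index
    conf_order = np.argsort(-pred.variance, kind="stable")
    oracle_order = np.argsort(-resid, kind="stable")
    max_removed = int(np.floor(0.9 * n))

    def curve(order: np.ndarray) -> np.ndarray:
        sq = (y - pred.mean) ** 2
        total = float(sq.sum())
        out = np.empty(max_removed + 1)
        removed_sq = 0.0
        for k in range(max_removed + 1):
            out[k] = np.sqrt((total - removed_sq) / (n - k))
            if k < max_removed:
                removed_sq += sq[order[k]]
        return out

    fractions = np.arange(max_removed + 1) / n
    conf_curve = curve(conf_order)
    oracle_curve = curve(oracle_order)
    auco = float(np.trapezoid(conf_curve - oracle_curve, fractions))
    return ConfidenceCurves(
        fractions=fractions,
        confidence_rmse=conf_curve,
        oracle_rmse=oracle_curve,
        auco=auco,
    )


# --------------------------------------------------------------- harness


@dataclass
class SplitResult:
    split: int
    seed: int
    train_ids: list[str]
    test_ids: list[str]
    nll: float
    rmse: float
    ece: float
    auco: float
    calibration: CalibrationCurve
    curves: ConfidenceCurves
    model_history: dict


@dataclass
class EvaluationReport:
    splits: list[SplitResult]
    aggregate: dict[str, dict]
    manifest: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "manifest": self.manifest,
            "aggregate": self.aggregate,
            "splits": [
                {
                    "split": s.split,
                    "seed": s.seed,
                    "nll": s.nll,
                    "rmse": s.rmse,
                    "ece": s.ece,
                    "auco": s.auco,
                    "calibration": {
                        "levels": s.calibration.levels.tolist(),
                        "coverage": s.calibration.coverage.tolist(),
                    },
                    "curves": {
                        "fractions": s.curves.fractions.tolist(),
                        "confidence_rmse": s.curves.confidence_rmse.tolist(),
                        "oracle_rmse": s.curves.oracle_rmse.tolist(),
                    },
                    "train_ids": s.train_ids,
                    "test_ids": s.test_ids,
                }
                for s in self.splits
            ],
        }


def make_kernel_spec(
    metrics: list[str],
    psd_mode: str = "jitter",
    jitter: float = 1e-8,
) -> KernelSpec:
    """A kernel spec with one dissimilarity-RBF component per metric."""
    return KernelSpec(
        components=[
            KernelComponent(kind="distance_rbf", source=m) for m in metrics
        ],
        psd_mode=psd_mode,
        jitter=jitter,
    )


def split_indices(n: int, split: int, base_seed: int, train_fraction: float = 0.5):
    """Deterministic shuffled split; with odd n the extra sample goes to test."""
    rng = np.random.default_rng(base_seed + split)
    perm = rng.permutation(n)
    n_train = int(np.floor(n * train_fraction))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def repeated_split_experiment(
    distances: dict[str, DistanceMatrix],
    targets: TargetVector,
    spec: KernelSpec | None = None,
    n_splits: int = 10,
    train_fraction: float = 0.5,
    base_seed: int = 0,
    epochs: int = 200,
    learning_rate: float = 0.1,
) -> EvaluationReport:
    """Fit/predict/score over repeated deterministic 50/50 splits.

    ``distances`` maps metric names to full-sample distance matrices (computed
    once on train and test jointly — pairwise dissimilarities carry no target
    information). Sample ordering must agree with ``targets``.
    """
    names = list(distances)
    if not names:
        raise ValueError("need at least one distance matrix")
    ids = distances[names[0]].sample_ids
    for name in names[1:]:
        if distances[name].sample_ids != ids:
            raise ValueError(f"distance matrix {name!r} has mismatched sample IDs")
    if targets.sample_ids != ids:
        raise ValueError("targets and distance matrices have mismatched sample IDs")
    n = len(ids)
    if n < 20:
        raise ValueError("need at least 20 samples for the split experiment")
    if spec is None:
        spec = make_kernel_spec(names)
    D_full = {name: distances[name].values for name in names}

    splits: list[SplitResult] = []
    for s in range(n_splits):
        train_idx, test_idx = split_indices(n, s, base_seed, train_fraction)
        try:
            model = gp_mod.fit(
                spec,
                D_full,
                targets.y[train_idx],
                train_idx,
                epochs=epochs,
                learning_rate=learning_rate,
                seed=base_seed + s,
                train_ids=[ids[i] for i in train_idx],
            )
        except Exception as exc:
            raise RuntimeError(
                f"GP fit failed on split {s} (seed {base_seed + s}): {exc}"
            ) from exc
        pred = model.predict_indices(test_idx)
        y_test = targets.y[test_idx]
        cal = calibration(pred, y_test)
        curves = confidence_oracle_curves(pred, y_test)
        splits.append(
            SplitResult(
                split=s,
                seed=base_seed + s,
                train_ids=[ids[i] for i in train_idx],
                test_ids=[ids[i] for i in test_idx],
                nll=nll(pred, y_test),
                rmse=rmse(pred.mean, y_test),
                ece=cal.ece,
                auco=curves.auco,
                calibration=cal,
                curves=curves,
                model_history=model.history,
            )
        )

    aggregate = {}
    for key in ("nll", "rmse", "ece", "auco"):
        vals = np.array([getattr(s, key) for s in splits])
        agg = {"mean": float(vals.mean())}
        if len(vals) > 1:
            agg["sem"] = float(vals.std(ddof=1) / np.sqrt(len(vals)))
        else:
            agg["sem"] = None
        aggregate[key] = agg

    manifest = {
        "n_samples": n,
        "n_splits": n_splits,
        "train_fraction": train_fraction,
        "epochs": epochs,
        "learning_rate": learning_rate,
        "base_seed": base_seed,
        "metrics": names,
        "kernel_components": [
            {"kind": c.kind, "source": c.source} for c in spec.components
        ],
    }
    return EvaluationReport(splits=splits, aggregate=aggregate, manifest=manifest)
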