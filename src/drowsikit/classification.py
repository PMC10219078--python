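"""Balancing, splitting, training and evaluation of the window classifiers.

Three model families are supported, configured as in the original study:

* ``rf`` — random forest, entropy split criterion, 50 trees;
* ``svm`` — support-vector classifier, linear kernel, C = 1, probability
  estimates enabled;
* ``nn`` — a sequential feed-forward network with four hidden layers of five
  ReLU nodes and a single sigmoid output, trained with log-loss and the Adam
  optimiser (realised here with scikit-learn's multilayer perceptron).

Inputs are flattened 4x15 windows in row-major block order (EAR block, MAR
block, nose-X block, nose-Y block = 60 features). The nose-coordinate blocks
are standardised with a transform fitted on the training set and stored in
the model, since raw pixel coordinates are camera-dependent; EAR/MAR are
dimensionless already and stay raw.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .errors import BalancingError, ModelLayoutError, SplitError
from .window_labeling import Dataset, WindowSample

__all__ = [
    "BalanceConfig",
    "SplitConfig",
    "ModelSpec",
    "TrainedModel",
    "EvalReport",
    "balance",
    "split",
    "train",
    "grid_search",
    "evaluate",
]

DECISION_CUTOFF = 0.5


@dataclass(frozen=True)
class BalanceConfig:
    """How to equalise the two class counts before training.

    ``meet_at_mean`` (the default) oversamples the minority with replacement
    and undersamples the majority without, so that both classes end at
    ``round((n0 + n1) / 2)``.
    """

    strategy: str = "meet_at_mean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in (
            "meet_at_mean",
            "oversample_to_majority",
            "undersample_to_minority",
        ):
            raise ValueError(f"unknown balancing strategy {self.strategy!r}")


@dataclass(frozen=True)
class SplitConfig:
    """Train/test split: 70/30, stratified by label, seeded shuffle."""

    train_fraction: float = 0.7
    shuffle_seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly between 0 and 1")


@dataclass(frozen=True)
class ModelSpec:
    """Which classifier family to build and any hyperparameter overrides."""

    kind: str = "rf"
    hyperparameters: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("rf", "nn", "svm"):
            raise ValueError(f"unknown model kind {self.kind!r}")


def _make_estimator(spec: ModelSpec, seed: int):
    hp = dict(spec.hyperparameters)
    if spec.kind == "rf":
        params = {"criterion": "entropy", "n_estimators": 50, "random_state": seed}
        params.update(hp)
        return RandomForestClassifier(**params)
    if spec.kind == "svm":
        params = {"kernel": "linear", "C": 1.0, "probability": True, "random_state": seed}
        params.update(hp)
        return SVC(**params)
    # Sequential feed-forward network: 60 -> 5 -> 5 -> 5 -> 5 -> 1(sigmoid).
    params = {
        "hidden_layer_sizes": (5, 5, 5, 5),
        "activation": "relu",
        "solver": "adam",
        "batch_size": 32,
        "max_iter": 400,
        "random_state": seed,
    }
    params.update(hp)
    return MLPClassifier(**params)


@dataclass
class TrainedModel:
    """A fitted classifier plus the feature-layout contract it was fit under.

    ``nose_center``/``nose_scale`` standardise the trailing half of the
    feature vector (the nose blocks) at predict time exactly as at fit time.
    """

    kind: str
    estimator: Any
    n_features: int
    nose_center: np.ndarray
    nose_scale: np.ndarray

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise ModelLayoutError(
                f"model expects {self.n_features} features, got {X.shape[1]}"
            )
        X = X.copy()
        half = self.n_features // 2
        X[:, half:] = (X[:, half:] - self.nose_center) / self.nose_scale
        return X

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        """Probability of the drowsy class (label 1), in [0, 1]."""
        return self.estimator.predict_proba(self._prepare(X))[:, 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Hard labels at the fixed 0.5 cut-off."""
        return (self.predict_score(X) >= DECISION_CUTOFF).astype(int)


def _resample(
    samples: list[WindowSample], size: int, replace: bool, rng: np.random.Generator
) -> list[WindowSample]:
    idx = rng.choice(len(samples), size=size, replace=replace)
    return [samples[i] for i in idx]


def balance(dataset: Dataset, cfg: BalanceConfig = BalanceConfig()) -> Dataset:
    """Equalise the class counts by over-/under-sampling.

    The minority class grows by sampling with replacement; the majority
    shrinks by sampling without replacement. Deterministic under a fixed
    seed. A dataset that is already balanced passes through with its counts
    unchanged (samples may still be reordered under ``meet_at_mean``).
    """
    by_class = {0: [], 1: []}
    for s in dataset.samples:
        by_class[s.label].append(s)
    n0, n1 = len(by_class[0]), len(by_class[1])
    if n0 == 0 or n1 == 0:
        raise BalancingError(f"both classes must be non-empty, got counts ({n0}, {n1})")
    rng = np.random.default_rng(cfg.seed)
    if cfg.strategy == "meet_at_mean":
        target = round((n0 + n1) / 2)
    elif cfg.strategy == "oversample_to_majority":
        target = max(n0, n1)
    else:
        target = min(n0, n1)
    out: list[WindowSample] = []
    for label in (0, 1):
        cls = by_class[label]
        if len(cls) == target:
            out.extend(cls)
        elif len(cls) > target:
            out.extend(_resample(cls, target, replace=False, rng=rng))
        else:
            out.extend(_resample(cls, target, replace=True, rng=rng))
    return Dataset(out)


def split(dataset: Dataset, cfg: SplitConfig = SplitConfig()) -> tuple[Dataset, Dataset]:
    """Partition a dataset into train/test halves at ``train_fraction``.

    Stratified by label (requires both classes with >= 2 samples each);
    disjoint and exhaustive by construction.
    """
    y = [s.label for s in dataset.samples]
    if cfg.stratified and len(set(y)) < 2:
        raise SplitError("stratified split needs both classes present")
    idx = np.arange(len(dataset.samples))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=cfg.train_fraction,
        random_state=cfg.shuffle_seed,
        shuffle=True,
        stratify=y if cfg.stratified else None,
    )
    return (
        Dataset([dataset.samples[i] for i in train_idx]),
        Dataset([dataset.samples[i] for i in test_idx]),
    )


def _fit_nose_standardiser(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    half = X.shape[1] // 2
    center = X[:, half:].mean(axis=0)
    scale = X[:, half:].std(axis=0)
    scale[scale == 0.0] = 1.0
    return center, scale


def train(spec: ModelSpec, train_set: Dataset, seed: int = 0) -> TrainedModel:
    """Fit one classifier on a window dataset.

    Deterministic under a fixed seed for rf/svm; the network is additionally
    deterministic given single-threaded execution.
    """
    X, y = train_set.to_arrays()
    if X.size == 0:
        raise ModelLayoutError("training set is empty")
    center, scale = _fit_nose_standardiser(X)
    model = TrainedModel(
        kind=spec.kind,
        estimator=_make_estimator(spec, seed),
        n_features=X.shape[1],
        nose_center=center,
        nose_scale=scale,
    )
    model.estimator.fit(model._prepare(X), y)
    return model


def grid_search(
    spec: ModelSpec,
    train_set: Dataset,
    grid: Mapping[str, Sequence[Any]],
    folds: int = 5,
    seed: int = 0,
) -> tuple[dict[str, Any], pd.DataFrame]:
    """Exhaustive hyperparameter search by cross-validated accuracy.

    Ties break in favour of the first grid point in iteration order. Returns
    the winning configuration and the full score table (one row per point).
    """
    if folds < 2:
        raise ValueError(f"folds must be >= 2, got {folds}")
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    X, y = train_set.to_arrays()
    center, scale = _fit_nose_standardiser(X)
    half = X.shape[1] // 2
    Xs = X.copy()
    Xs[:, half:] = (Xs[:, half:] - center) / scale
    search = GridSearchCV(
        _make_estimator(spec, seed),
        param_grid=dict(grid),
        scoring="accuracy",
        cv=folds,
    )
    search.fit(Xs, y)
    table = pd.DataFrame(search.cv_results_)[
        ["params", "mean_test_score", "std_test_score", "rank_test_score"]
    ]
    return dict(search.best_params_), table


@dataclass
class EvalReport:
    """Point metrics, curves and the confusion matrix of one evaluation.

    Conventions: the drowsy class (1) is positive. ``sensitivity`` is
    TP/(TP+FN), ``specificity`` TN/(TN+FP); macro precision/F1 are unweighted
    means over the two classes. Curve AUCs use the trapezoidal rule. On a
    single-class test set the curves and AUCs are None but point metrics are
    still reported.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    macro_precision: float
    macro_f1: float
    confusion: dict[str, int]
    roc_points: list[tuple[float, float]] | None
    pr_points: list[tuple[float, float]] | None
    roc_auc: float | None
    pr_auc: float | None
    n_test: int = 0

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "macro_precision": self.macro_precision,
            "macro_f1": self.macro_f1,
            "confusion": self.confusion,
            "roc_auc": self.roc_auc,
            "pr_auc": self.pr_auc,
            "n_test": self.n_test,
        }

    def to_json(self, path: str | Path) -> None:
        with open(Path(path), "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def curves_to_csv(self, roc_path: str | Path, pr_path: str | Path) -> None:
        if self.roc_points is not None:
            pd.DataFrame(self.roc_points, columns=["fpr", "tpr"]).to_csv(
                roc_path, index=False
            )
        if self.pr_points is not None:
            pd.DataFrame(self.pr_points, columns=["recall", "precision"]).to_csv(
                pr_path, index=False
            )


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def metrics_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray | None = None
) -> EvalReport:
    """Compute the full metric suite from labels (and optional scores)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    n = len(y_true)
    sensitivity = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    prec_pos = _safe_div(tp, tp + fp)
    prec_neg = _safe_div(tn, tn + fn)
    f1_pos = _safe_div(2 * prec_pos * sensitivity, prec_pos + sensitivity)
    f1_neg = _safe_div(2 * prec_neg * specificity, prec_neg + specificity)

    roc_points = pr_points = None
    roc_auc = pr_auc = None
    if scores is not None and len(set(y_true.tolist())) == 2:
        from sklearn.metrics import precision_recall_curve, roc_curve

        fpr, tpr, _ = roc_curve(y_true, scores)
        roc_points = list(zip(fpr.tolist(), tpr.tolist()))
        roc_auc = float(np.trapezoid(tpr, fpr))
        precision, recall, _ = precision_recall_curve(y_true, scores)
        # precision_recall_curve returns recall in decreasing order
        pr_points = list(zip(recall.tolist(), precision.tolist()))
        pr_auc = float(-np.trapezoid(precision, recall))

    return EvalReport(
        accuracy=_safe_div(tp + tn, n),
        sensitivity=sensitivity,
        specificity=specificity,
        macro_precision=0.5 * (prec_pos + prec_neg),
        macro_f1=0.5 * (f1_pos + f1_neg),
        confusion={"tp": tp, "fn": fn, "tn": tn, "fp": fp},
        roc_points=roc_points,
        pr_points=pr_points,
        roc_auc=roc_auc,
        pr_auc=pr_auc,
        n_test=n,
    )


def evaluate(model: TrainedModel, test_set: Dataset) -> EvalReport:
    """Score a trained model on a held-out window dataset."""
    X, y = test_set.to_arrays()
    if X.size == 0:
        raise ModelLayoutError("test set is empty")
    scores = model.predict_score(X)
    y_pred = (scores >= DECISION_CUTOFF).astype(int)
    return metrics_from_predictions(y, y_pred, scores)


def save_model(model: TrainedModel, bundle_dir: str | Path) -> None:
    """Persist a model as a directory bundle: metadata JSON + weights blob."""
    import joblib

    bundle = Path(bundle_dir)
    bundle.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": 1,
        "kind": model.kind,
        "n_features": model.n_features,
        "nose_center": model.nose_center.tolist(),
        "nose_scale": model.nose_scale.tolist(),
    }
    with open(bundle / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    joblib.dump(model.estimator, bundle / "estimator.joblib")


def load_model(bundle_dir: str | Path) -> TrainedModel:
    """Load a model bundle written by :func:`save_model`."""
    import joblib

    bundle = Path(bundle_dir)
    with open(bundle / "meta.json") as fh:
        meta = json.load(fh)
    if meta.get("format_version") != 1:
        raise ModelLayoutError(f"unsupported bundle version {meta.get('format_version')}")
    return TrainedModel(
        kind=meta["kind"],
        estimator=joblib.load(bundle / "estimator.joblib"),
        n_features=int(meta["n_features"]),
        nose_center=np.asarray(meta["nose_center"]),
        nose_scale=np.asarray(meta["nose_scale"]),
    )
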