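"""SVM training, cross-validation, grid search and ratio-controlled splits.

The classifier contract is libsvm's C-SVC with a linear or Gaussian (RBF)
kernel, realized by :class:`sklearn.svm.SVC` behind the
:class:`CytokineSVC` estimator.  Evaluation follows the repeated k-fold
protocol: sequences are randomly partitioned into k near-equal groups,
each group serves once as the test set, and the reported aggregate is the
mean of the per-fold metrics.  Partitions are stratified by class by
default so that heavily imbalanced datasets (e.g. 1:9) keep both classes
in every fold; plain random partitioning is available via
``stratified=False``.

Hyperparameters are chosen by an exhaustive (C, gamma) grid search scored
by inner k-fold accuracy on a fold assignment shared across all cells;
ties are broken toward smaller C, then smaller gamma.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .errors import (
    CompositionError,
    SchemaError,
    TrainingError,
    ValidationError,
)
from .metrics import (
    METRIC_NAMES,
    EvaluationReport,
    confusion_from_labels,
    metrics,
)
from .types import FeatureMatrix

#: the default hyperparameter lattice: 2^-5 .. 2^5, step 2^1
DEFAULT_GRID = tuple(2.0**e for e in range(-5, 6))

KERNELS = ("linear", "gaussian")


def _as_sklearn_kernel(kernel: str) -> str:
    if kernel not in KERNELS:
        raise ValidationError(f"kernel must be one of {KERNELS}, got {kernel!r}")
    return "linear" if kernel == "linear" else "rbf"


class CytokineSVC(BaseEstimator, ClassifierMixin):
    """C-SVC with a linear or Gaussian kernel over +1/-1 labels.

    Parameters
    ----------
    kernel : ``"linear"`` or ``"gaussian"``.
    C : soft-margin penalty.
    gamma : RBF width; required iff ``kernel="gaussian"``.
    scale : if True, z-score features on the training set before fitting
        (off by default; most feature families already live in [0, 1]).
    """

    def __init__(
        self,
        kernel: str = "linear",
        C: float = 1.0,
        gamma: float | None = None,
        scale: bool = False,
    ):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.scale = scale

    def fit(self, X, y) -> "CytokineSVC":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        classes = set(np.unique(y))
        if not classes <= {-1, 1}:
            raise ValidationError(f"labels must be +1/-1, got {sorted(classes)}")
        if len(classes) < 2:
            raise TrainingError("training set contains a single class")
        sk_kernel = _as_sklearn_kernel(self.kernel)
        if sk_kernel == "rbf" and self.gamma is None:
            raise ValidationError("gamma is required for the gaussian kernel")
        if sk_kernel == "linear" and self.gamma is not None:
            raise ValidationError("gamma is meaningless for the linear kernel")
        self.scaler_ = None
        if self.scale:
            self.scaler_ = StandardScaler().fit(X)
            X = self.scaler_.transform(X)
        self.svc_ = SVC(
            kernel=sk_kernel,
            C=self.C,
            gamma=self.gamma if sk_kernel == "rbf" else "scale",
            random_state=0,
        )
        self.svc_.fit(X, y)
        self.classes_ = self.svc_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def _prepare(self, X) -> np.ndarray:
        check_is_fitted(self, "svc_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise SchemaError(
                f"model expects {self.n_features_in_} features, got {X.shape[1]}"
            )
        if self.scaler_ is not None:
            X = self.scaler_.transform(X)
        return X

    def predict(self, X) -> np.ndarray:
        return self.svc_.predict(self._prepare(X))

    def decision_function(self, X) -> np.ndarray:
        return self.svc_.decision_function(self._prepare(X))


# ---------------------------------------------------------------------------
# thin functional layer over the estimator
# ---------------------------------------------------------------------------

def _require_labels(features: FeatureMatrix) -> np.ndarray:
    if features.labels is None:
        raise ValidationError("feature matrix carries no labels")
    return features.labels


def train(
    features: FeatureMatrix,
    kernel: str = "linear",
    C: float = 1.0,
    gamma: float | None = None,
    scale: bool = False,
) -> CytokineSVC:
    """Fit a C-SVC on a labeled feature matrix."""
    y = _require_labels(features)
    return CytokineSVC(kernel=kernel, C=C, gamma=gamma, scale=scale).fit(
        features.values, y
    )


def predict(model: CytokineSVC, features: FeatureMatrix) -> np.ndarray:
    """Predict +1/-1 labels aligned with ``features.ids``."""
    return model.predict(features.values)


def evaluate_split(
    model: CytokineSVC, features: FeatureMatrix
) -> EvaluationReport:
    """Predict on a labeled matrix and derive the metric report."""
    y = _require_labels(features)
    return metrics(confusion_from_labels(y, model.predict(features.values)))


# ---------------------------------------------------------------------------
# fold assignment and cross-validation
# ---------------------------------------------------------------------------

def fold_assignment(
    labels: np.ndarray, k: int, seed: int, stratified: bool = True
) -> np.ndarray:
    """Seeded partition into k near-equal folds (sizes differ by <= 1).

    Stratified assignment shuffles within each class and deals items
    round-robin with a running fold counter, so per-class fold counts also
    differ by at most 1.
    """
    n = len(labels)
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValidationError(f"k={k} exceeds the {n} available items")
    rng = np.random.default_rng(seed)
    assign = np.empty(n, dtype=int)
    if stratified:
        order: list[int] = []
        for cls in (1, -1):
            idx = np.flatnonzero(labels == cls)
            rng.shuffle(idx)
            order.extend(idx.tolist())
    else:
        idx = np.arange(n)
        rng.shuffle(idx)
        order = idx.tolist()
    start = int(rng.integers(k))
    for pos, item in enumerate(order):
        assign[item] = (start + pos) % k
    return assign


@dataclass
class CVResult:
    """Per-fold reports plus mean and population SD of each metric."""

    fold_reports: list[EvaluationReport]
    seed: int
    mean: dict[str, float] = field(init=False)
    sd: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        values = {
            name: np.array([r.as_dict()[name] for r in self.fold_reports])
            for name in METRIC_NAMES
        }
        self.mean = {name: float(v.mean()) for name, v in values.items()}
        self.sd = {name: float(v.std()) for name, v in values.items()}


def kfold_cv(
    features: FeatureMatrix,
    k: int = 10,
    kernel: str = "linear",
    C: float = 1.0,
    gamma: float | None = None,
    seed: int = 0,
    stratified: bool = True,
    scale: bool = False,
) -> CVResult:
    """Seeded k-fold cross-validation; aggregate is the mean of fold metrics."""
    y = _require_labels(features)
    if stratified:
        for cls in (1, -1):
            count = int(np.sum(y == cls))
            if count < k:
                raise ValidationError(
                    f"class {cls:+d} has {count} members, fewer than k={k}"
                )
    assign = fold_assignment(y, k, seed, stratified)
    reports = []
    for fold in range(k):
        test_idx = np.flatnonzero(assign == fold)
        train_idx = np.flatnonzero(assign != fold)
        model = CytokineSVC(kernel=kernel, C=C, gamma=gamma, scale=scale).fit(
            features.values[train_idx], y[train_idx]
        )
        pred = model.predict(features.values[test_idx])
        reports.append(metrics(confusion_from_labels(y[test_idx], pred)))
    return CVResult(fold_reports=reports, seed=seed)


@dataclass
class RepeatedCVResult:
    """Repetition-level results mirroring a mean +/- SD summary table.

    ``rep_means[r][m]`` is metric ``m`` averaged over the folds of
    repetition ``r`` and ``rep_sds[r][m]`` the fold SD within that
    repetition; ``overall_mean``/``overall_sd`` aggregate the repetition
    means (both within- and across-repetition spreads are reported).
    """

    repetitions: list[CVResult]
    base_seed: int

    @property
    def rep_means(self) -> list[dict[str, float]]:
        return [rep.mean for rep in self.repetitions]

    @property
    def rep_sds(self) -> list[dict[str, float]]:
        return [rep.sd for rep in self.repetitions]

    @property
    def overall_mean(self) -> dict[str, float]:
        return {
            name: float(np.mean([rep.mean[name] for rep in self.repetitions]))
            for name in METRIC_NAMES
        }

    @property
    def overall_sd(self) -> dict[str, float]:
        return {
            name: float(np.std([rep.mean[name] for rep in self.repetitions]))
            for name in METRIC_NAMES
        }


def repeated_cv(
    features: FeatureMatrix,
    k: int = 10,
    reps: int = 10,
    kernel: str = "linear",
    C: float = 1.0,
    gamma: float | None = None,
    base_seed: int = 0,
    stratified: bool = True,
    scale: bool = False,
) -> RepeatedCVResult:
    """``reps`` independent k-fold runs with seeds base_seed, base_seed+1, ..."""
    runs = [
        kfold_cv(features, k, kernel, C, gamma, base_seed + r, stratified, scale)
        for r in range(reps)
    ]
    return RepeatedCVResult(repetitions=runs, base_seed=base_seed)


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

@dataclass
class GridSearchResult:
    """Accuracy surface over the (C, gamma) lattice and the best cell."""

    c_values: tuple[float, ...]
    gamma_values: tuple[float, ...]
    surface: np.ndarray  # shape (len(c_values), len(gamma_values))
    best_c: float
    best_gamma: float
    best_accuracy: float


def grid_search(
    features: FeatureMatrix,
    c_values: tuple[float, ...] = DEFAULT_GRID,
    gamma_values: tuple[float, ...] = DEFAULT_GRID,
    inner_k: int = 3,
    seed: int = 0,
    stratified: bool = True,
    scale: bool = False,
) -> GridSearchResult:
    """Exhaustive RBF (C, gamma) sweep scored by shared-fold CV accuracy.

    All cells reuse one inner fold assignment so surface differences come
    from the hyperparameters alone.  Ties break toward smaller C, then
    smaller gamma.
    """
    if not c_values or not gamma_values:
        raise ValidationError("both hyperparameter sets must be non-empty")
    if inner_k < 2:
        raise ValidationError(f"inner_k must be >= 2, got {inner_k}")
    y = _require_labels(features)
    assign = fold_assignment(y, inner_k, seed, stratified)
    c_values = tuple(sorted(c_values))
    gamma_values = tuple(sorted(gamma_values))
    surface = np.empty((len(c_values), len(gamma_values)))
    best: tuple[float, float, float] | None = None  # (acc, C, gamma)
    for ci, C in enumerate(c_values):
        for gi, gamma in enumerate(gamma_values):
            accs = []
            for fold in range(inner_k):
                test_idx = np.flatnonzero(assign == fold)
                train_idx = np.flatnonzero(assign != fold)
                model = CytokineSVC(
                    kernel="gaussian", C=C, gamma=gamma, scale=scale
                ).fit(features.values[train_idx], y[train_idx])
                pred = model.predict(features.values[test_idx])
                accs.append(float(np.mean(pred == y[test_idx])))
            acc = float(np.mean(accs))
            surface[ci, gi] = acc
            if best is None or acc > best[0]:
                best = (acc, C, gamma)
    assert best is not None
    return GridSearchResult(
        c_values=c_values,
        gamma_values=gamma_values,
        surface=surface,
        best_c=best[1],
        best_gamma=best[2],
        best_accuracy=best[0],
    )


# ---------------------------------------------------------------------------
# ratio-controlled split
# ---------------------------------------------------------------------------

def ratio_split(
    features: FeatureMatrix,
    positive_fraction: float,
    test_fraction: float,
    seed: int = 0,
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Stratified train/test split preserving a stated positive fraction.

    The dataset's own positive fraction must already equal
    ``positive_fraction`` within integer rounding; both resulting splits
    then inherit it, and the test split holds ``test_fraction`` of the
    items.
    """
    y = _require_labels(features)
    if not 0 < positive_fraction < 1:
        raise CompositionError("positive_fraction must lie strictly in (0, 1)")
    if not 0 < test_fraction < 1:
        raise CompositionError("test_fraction must lie strictly in (0, 1)")
    n = len(y)
    n_pos = int(np.sum(y == 1))
    n_neg = n - n_pos
    if abs(n_pos - positive_fraction * n) >= 1:
        raise CompositionError(
            f"dataset holds {n_pos} positives of {n} "
            f"({n_pos / n:.3f}); cannot realize positive fraction "
            f"{positive_fraction}"
        )
    n_test = round(test_fraction * n)
    n_test_pos = round(positive_fraction * n_test)
    n_test_neg = n_test - n_test_pos
    if not (0 < n_test_pos <= n_pos and 0 < n_test_neg <= n_neg):
        raise CompositionError(
            f"cannot draw a test set of {n_test_pos} positives and "
            f"{n_test_neg} negatives from {n_pos}/{n_neg}"
        )
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == -1)
    rng.shuffle(pos_idx)
    rng.shuffle(neg_idx)
    test_idx = np.sort(np.concatenate([pos_idx[:n_test_pos], neg_idx[:n_test_neg]]))
    train_idx = np.sort(np.concatenate([pos_idx[n_test_pos:], neg_idx[n_test_neg:]]))
    return features.subset(train_idx), features.subset(test_idx)


# ---------------------------------------------------------------------------
# libsvm-dialect model persistence
# ---------------------------------------------------------------------------

def save_model(model: CytokineSVC, path: str | Path) -> None:
    """Persist a fitted model in the plain-text libsvm model dialect."""
    check_is_fitted(model, "svc_")
    if model.scaler_ is not None:
        raise ValidationError(
            "libsvm-format export does not carry the feature scaler; "
            "retrain with scale=False to persist"
        )
    svc = model.svc_
    sk_kernel = _as_sklearn_kernel(model.kernel)
    # sklearn groups support vectors by class in classes_ order ([-1, +1]);
    # the libsvm header below declares labels in that same order.
    lines = [
        "svm_type c_svc",
        f"kernel_type {'linear' if sk_kernel == 'linear' else 'rbf'}",
    ]
    if sk_kernel == "rbf":
        lines.append(f"gamma {float(svc._gamma)!r}")
    lines += [
        "nr_class 2",
        f"total_sv {len(svc.support_vectors_)}",
        f"rho {float(-svc.intercept_[0])!r}",
        f"label {int(svc.classes_[0])} {int(svc.classes_[1])}",
        f"nr_sv {svc.n_support_[0]} {svc.n_support_[1]}",
        "SV",
    ]
    for coef, sv in zip(svc.dual_coef_[0], svc.support_vectors_):
        cells = " ".join(f"{j + 1}:{float(v)!r}" for j, v in enumerate(sv))
        lines.append(f"{float(coef)!r} {cells}")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class LibsvmModel:
    """A parsed libsvm text model able to reproduce decision values."""

    kernel: str
    gamma: float | None
    rho: float
    labels: tuple[int, int]
    dual_coef: np.ndarray
    support_vectors: np.ndarray

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.kernel == "linear":
            K = X @ self.support_vectors.T
        else:
            sq = (
                (X**2).sum(axis=1)[:, None]
                + (self.support_vectors**2).sum(axis=1)[None, :]
                - 2 * X @ self.support_vectors.T
            )
            K = np.exp(-self.gamma * sq)
        return K @ self.dual_coef - self.rho

    def predict(self, X) -> np.ndarray:
        dec = self.decision_function(X)
        # positive decision -> the second declared label (sklearn sign
        # convention preserved through rho = -intercept)
        return np.where(dec > 0, self.labels[1], self.labels[0])


def load_model(path: str | Path) -> LibsvmModel:
    """Parse a model written by :func:`save_model`."""
    lines = Path(path).read_text().splitlines()
    header: dict[str, str] = {}
    sv_start = None
    for i, line in enumerate(lines):
        if line.strip() == "SV":
            sv_start = i + 1
            break
        key, _, value = line.partition(" ")
        header[key] = value
    if sv_start is None:
        raise ValidationError(f"{path}: missing SV section")
    coefs: list[float] = []
    vecs: list[list[float]] = []
    for line in lines[sv_start:]:
        if not line.strip():
            continue
        toks = line.split()
        coefs.append(float(toks[0]))
        vecs.append([float(t.split(":", 1)[1]) for t in toks[1:]])
    labels = tuple(int(t) for t in header["label"].split())
    return LibsvmModel(
        kernel=header["kernel_type"],
        gamma=float(header["gamma"]) if "gamma" in header else None,
        rho=float(header["rho"]),
        labels=(labels[0], labels[1]),
        dual_coef=np.array(coefs),
        support_vectors=np.array(vecs),
    )
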