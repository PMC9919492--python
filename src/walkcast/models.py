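"""Uniform adapters over the six classifier families.

The families compared by the pipeline are logistic regression, RBF-kernel
support vector machine, gradient-boosted trees, multilayer perceptron,
decision tree and random forest.  None of them is implemented here — each
adapter wraps scikit-learn or XGBoost — but every family is exercised through
the identical ``fit(train, tune) / predict(X)`` contract so the evaluation
and search layers stay algorithm-agnostic.

Unstated hyperparameters default to the backing library's defaults; the
effective values are snapshotted into the fit report.  The MLP additionally
consumes the tune set for early stopping: it is trained epoch by epoch and
stops once the tune-set log-loss has failed to improve for ``patience``
consecutive epochs, restoring the best weights seen.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

__all__ = [
    "KINDS",
    "ArchitectureSpec",
    "ClassifierSpec",
    "FitReport",
    "Classifier",
    "build",
    "fit_with_tuning",
]

KINDS = (
    "logistic_regression",
    "rbf_svm",
    "gradient_boosted_trees",
    "mlp",
    "decision_tree",
    "random_forest",
)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Hidden-layer widths (input->output order) defining one MLP candidate."""

    hidden_layers: tuple[int, ...]
    activation: str = "relu"

    def __post_init__(self) -> None:
        object.__setattr__(self, "hidden_layers", tuple(int(w) for w in self.hidden_layers))
        if len(self.hidden_layers) < 1:
            raise ValueError("at least one hidden layer required")
        if any(w < 1 for w in self.hidden_layers):
            raise ValueError("layer widths must be positive")

    def as_dict(self) -> dict:
        return {"hidden_layers": list(self.hidden_layers), "activation": self.activation}


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier configuration: family, hyperparameters, seed."""

    kind: str
    hyperparams: dict = field(default_factory=dict)
    architecture: ArchitectureSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; one of {KINDS}")
        if (self.kind == "mlp") != (self.architecture is not None):
            raise ValueError("architecture must be given iff kind == 'mlp'")

    def as_dict(self) -> dict:
        return {
            "kind": self.kind,
            "hyperparams": dict(self.hyperparams),
            "architecture": self.architecture.as_dict() if self.architecture else None,
            "seed": self.seed,
        }


@dataclass
class FitReport:
    """What one fit call did: timing, iterations, tune-set usage, params."""

    wall_clock_s: float
    n_iterations: int | None
    tune_used: bool
    params_snapshot: dict
    notes: str = ""


class Classifier:
    """Common contract: ``fit(X, y, tune_X, tune_y)`` then ``predict(X)``.

    Labels are thresholded at 0.5 on the predicted positive-class probability
    for probability-producing families; the SVM thresholds its decision
    function at 0 (the margin equivalent).
    """

    kind: str

    def __init__(self, spec: ClassifierSpec):
        self.spec = spec
        self.kind = spec.kind
        self._fitted = False

    def fit(self, X, y, tune_X=None, tune_y=None) -> FitReport:
        if len(X) == 0:
            raise ValueError("empty training set")
        start = time.perf_counter()
        n_iter = self._fit_impl(
            np.asarray(X, dtype=np.float32),
            np.asarray(y),
            None if tune_X is None else np.asarray(tune_X, dtype=np.float32),
            None if tune_y is None else np.asarray(tune_y),
        )
        elapsed = time.perf_counter() - start
        self._fitted = True
        return FitReport(
            wall_clock_s=elapsed,
            n_iterations=n_iter,
            tune_used=self._uses_tune and tune_X is not None,
            params_snapshot=self._params_snapshot(),
            notes="" if self._uses_tune else "tune set recorded but unused",
        )

    def predict_score(self, X) -> np.ndarray:
        """Positive-class probability (or margin score for the SVM)."""
        raise NotImplementedError

    def predict(self, X) -> np.ndarray:
        raise NotImplementedError

    # subclass hooks -------------------------------------------------------
    _uses_tune = False

    def _fit_impl(self, X, y, tune_X, tune_y) -> int | None:
        raise NotImplementedError

    def _params_snapshot(self) -> dict:
        raise NotImplementedError


class _SklearnAdapter(Classifier):
    """Adapter over estimators exposing fit/predict_proba."""

    def __init__(self, spec: ClassifierSpec, estimator):
        super().__init__(spec)
        self.estimator = estimator

    def _fit_impl(self, X, y, tune_X, tune_y) -> int | None:
        self.estimator.fit(X, y)
        n_iter = getattr(self.estimator, "n_iter_", None)
        if isinstance(n_iter, np.ndarray):
            n_iter = int(n_iter.max())
        return n_iter

    def predict_score(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if hasattr(self.estimator, "predict_proba"):
            return self.estimator.predict_proba(X)[:, 1]
        return self.estimator.decision_function(X)

    def predict(self, X) -> np.ndarray:
        score = self.predict_score(X)
        threshold = 0.5 if hasattr(self.estimator, "predict_proba") else 0.0
        return (score >= threshold).astype(np.int8)

    def _params_snapshot(self) -> dict:
        return {
            k: v
            for k, v in self.estimator.get_params(deep=False).items()
            if isinstance(v, (int, float, str, bool, type(None), tuple))
        }


class _MLPAdapter(Classifier):
    """scikit-learn MLP driven epoch-by-epoch with explicit-tune-set early stop."""

    _uses_tune = True

    #: training-loop defaults; overridable through ClassifierSpec.hyperparams
    DEFAULTS = {"max_epochs": 100, "patience": 10, "learning_rate_init": 0.001, "batch_size": "auto"}

    def __init__(self, spec: ClassifierSpec):
        super().__init__(spec)
        hp = {**self.DEFAULTS, **spec.hyperparams}
        self.max_epochs = int(hp.pop("max_epochs"))
        self.patience = int(hp.pop("patience"))
        arch = spec.architecture
        self.estimator = MLPClassifier(
            hidden_layer_sizes=arch.hidden_layers,
            activation=arch.activation,
            solver="adam",
            random_state=spec.seed,
            max_iter=1,
            warm_start=False,
            **hp,
        )
        self.epochs_run_ = 0

    def _fit_impl(self, X, y, tune_X, tune_y) -> int:
        est = self.estimator
        classes = np.array([0, 1])
        best_loss = np.inf
        best_weights = None
        since_best = 0
        epochs = 0
        for epoch in range(self.max_epochs):
            est.partial_fit(X, y, classes=classes)
            epochs = epoch + 1
            if tune_X is None or len(tune_X) == 0:
                continue
            loss = log_loss(tune_y, est.predict_proba(tune_X), labels=classes)
            if loss < best_loss:
                best_loss = loss
                best_weights = (
                    [c.copy() for c in est.coefs_],
                    [b.copy() for b in est.intercepts_],
                )
                since_best = 0
            else:
                since_best += 1
                if since_best > self.patience:
                    break
        if best_weights is not None:
            est.coefs_, est.intercepts_ = best_weights
        self.epochs_run_ = epochs
        return epochs

    def predict_score(self, X) -> np.ndarray:
        return self.estimator.predict_proba(np.asarray(X, dtype=np.float32))[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.predict_score(X) >= 0.5).astype(np.int8)

    def _params_snapshot(self) -> dict:
        snap = {
            k: v
            for k, v in self.estimator.get_params(deep=False).items()
            if isinstance(v, (int, float, str, bool, type(None), tuple))
        }
        snap.update({"max_epochs": self.max_epochs, "patience": self.patience})
        return snap


def build(spec: ClassifierSpec) -> Classifier:
    """Construct the adapter named by ``spec.kind``; all randomness seeded."""
    hp = dict(spec.hyperparams)
    try:
        if spec.kind == "logistic_regression":
            return _SklearnAdapter(spec, LogisticRegression(random_state=spec.seed, **hp))
        if spec.kind == "rbf_svm":
            return _SklearnAdapter(spec, SVC(kernel="rbf", random_state=spec.seed, **hp))
        if spec.kind == "gradient_boosted_trees":
            return _SklearnAdapter(
                spec, XGBClassifier(random_state=spec.seed, eval_metric="logloss", **hp)
            )
        if spec.kind == "decision_tree":
            return _SklearnAdapter(spec, DecisionTreeClassifier(random_state=spec.seed, **hp))
        if spec.kind == "random_forest":
            return _SklearnAdapter(spec, RandomForestClassifier(random_state=spec.seed, **hp))
        if spec.kind == "mlp":
            return _MLPAdapter(spec)
    except TypeError as exc:
        raise ValueError(f"malformed hyperparameters for {spec.kind}: {exc}") from exc
    raise ValueError(f"unknown classifier kind {spec.kind!r}")  # pragma: no cover


def fit_with_tuning(
    classifier: Classifier,
    train: tuple[np.ndarray, np.ndarray],
    tune: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[Classifier, FitReport]:
    """Fit on the train split, passing the tune split to kinds that use it."""
    X, y = train
    if tune is None:
        report = classifier.fit(X, y)
    else:
        tX, ty = tune
        if len(tX) and len(X):
            # disjointness guard: identical rows in both splits defeat tuning
            if len(tX) == len(X) and np.array_equal(tX, X):
                raise ValueError("train and tune sets must be disjoint")
        report = classifier.fit(X, y, tX, ty)
    return classifier, report
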