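"""Shallow classifiers for the reduced feature spaces.

Two classifiers are provided, matching the common presets of CADx
pipelines:

* **Cubic SVM** — a support-vector machine with a degree-3 polynomial
  kernel, one-vs-one multiclass handling and standardized inputs.
* **ESD** (ensemble subspace discriminant) — a random-subspace ensemble of
  regularized linear discriminants: each of ``n_learners`` base models sees
  a random feature subset of size ``subspace_dim`` and the ensemble
  predicts the argmax of the mean class posteriors.  The pooled
  within-class covariance of each base model is shrunk toward its own
  diagonal, which keeps it invertible in the wide-matrix (d > n) regime
  deep features live in.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.svm import SVC

from .features import FeatureMatrix

__all__ = ["CubicSvmSpec", "EsdSpec", "TrainedModel", "train_cubic_svm",
           "train_esd", "predict", "save_model", "load_model"]


@dataclass
class CubicSvmSpec:
    """Degree-3 polynomial-kernel SVM preset (one-vs-one, standardized)."""

    kernel_degree: int = 3
    C: float = 1.0
    coef0: float = 1.0
    kernel_scale: str | float = "auto"  # auto = 1 / (d * Var[X])
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.kernel_degree != 3:
            raise ValueError("cubic SVM is fixed to kernel degree 3")
        if self.C <= 0:
            raise ValueError("box constraint C must be positive")


@dataclass
class EsdSpec:
    """Random-subspace ensemble of regularized linear discriminants."""

    n_learners: int = 30
    subspace_dim: int | None = None  # default ceil(d / 2)
    shrinkage: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_learners < 1:
            raise ValueError("n_learners must be >= 1")
        if not 0.0 <= self.shrinkage <= 1.0:
            raise ValueError("shrinkage must lie in [0, 1]")


@dataclass
class TrainedModel:
    """Fitted classifier with its preprocessing statistics."""

    kind: str                     # "cubic_svm" | "esd"
    spec: CubicSvmSpec | EsdSpec
    classes: np.ndarray           # training label set, ascending
    n_features: int
    mean: np.ndarray | None = None
    scale: np.ndarray | None = None
    svm: SVC | None = None
    learners: list = field(default_factory=list)  # (feature_idx, _RegLda)
    class_names: list[str] | None = None

    def _standardized(self, X: np.ndarray) -> np.ndarray:
        if self.mean is None:
            return X
        return (X - self.mean) / self.scale


class _RegLda:
    """Linear discriminant with pooled covariance shrunk toward its diagonal."""

    def __init__(self, shrinkage: float):
        self.shrinkage = shrinkage

    def fit(self, X: np.ndarray, y: np.ndarray, classes: np.ndarray) -> "_RegLda":
        n, d = X.shape
        G = classes.shape[0]
        self.means_ = np.vstack([X[y == c].mean(axis=0) for c in classes])
        self.priors_ = np.array([(y == c).mean() for c in classes])
        scatter = np.zeros((d, d))
        for c, mu in zip(classes, self.means_):
            R = X[y == c] - mu
            scatter += R.T @ R
        cov = scatter / max(n - G, 1)
        a = self.shrinkage
        cov = (1.0 - a) * cov + a * np.diag(np.diag(cov))
        # Jitter keeps the Cholesky factorization alive for constant features.
        eps = 1e-9 * max(np.trace(cov) / d, 1.0)
        cov[np.diag_indices_from(cov)] += eps
        chol = cho_factor(cov, lower=True)
        self.coef_ = cho_solve(chol, self.means_.T).T          # Sigma^-1 mu_k
        self.intercept_ = (-0.5 * np.einsum("kd,kd->k", self.means_, self.coef_)
                           + np.log(np.maximum(self.priors_, 1e-300)))
        return self

    def posteriors(self, X: np.ndarray) -> np.ndarray:
        scores = X @ self.coef_.T + self.intercept_
        scores -= scores.max(axis=1, keepdims=True)
        p = np.exp(scores)
        return p / p.sum(axis=1, keepdims=True)


def _check_trainable(F: FeatureMatrix) -> None:
    if np.unique(F.labels).shape[0] < 2:
        raise ValueError("training requires at least 2 classes")


def train_cubic_svm(F: FeatureMatrix, spec: CubicSvmSpec | None = None) -> TrainedModel:
    """Fit one-vs-one cubic-kernel SVMs on (optionally standardized) features."""
    spec = spec or CubicSvmSpec()
    _check_trainable(F)
    X = F.values
    mean = scale = None
    if spec.standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale == 0.0, 1.0, scale)
        X = (X - mean) / scale
    gamma = "scale" if spec.kernel_scale == "auto" else float(spec.kernel_scale)
    svm = SVC(kernel="poly", degree=spec.kernel_degree, C=spec.C,
              coef0=spec.coef0, gamma=gamma, decision_function_shape="ovr")
    svm.fit(X, F.labels)
    return TrainedModel(kind="cubic_svm", spec=spec, classes=svm.classes_.copy(),
                        n_features=F.n_features, mean=mean, scale=scale, svm=svm,
                        class_names=F.class_names)


def train_esd(F: FeatureMatrix, spec: EsdSpec | None = None) -> TrainedModel:
    """Fit the random-subspace discriminant ensemble.

    Each learner draws ``subspace_dim`` feature indices without replacement
    from a seeded generator, so the ensemble is reproducible.
    """
    spec = spec or EsdSpec()
    _check_trainable(F)
    d = F.n_features
    sub = spec.subspace_dim if spec.subspace_dim is not None else math.ceil(d / 2)
    if not 1 <= sub <= d:
        raise ValueError(f"subspace_dim={sub} out of range [1, {d}]")
    classes = np.unique(F.labels)
    rng = np.random.default_rng(spec.seed)
    learners = []
    for _ in range(spec.n_learners):
        idx = np.sort(rng.choice(d, size=sub, replace=False))
        lda = _RegLda(spec.shrinkage).fit(F.values[:, idx], F.labels, classes)
        learners.append((idx, lda))
    return TrainedModel(kind="esd", spec=spec, classes=classes, n_features=d,
                        learners=learners, class_names=F.class_names)


def predict(model: TrainedModel, F: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and per-class scores for every row of ``F``.

    ESD scores are mean posteriors (each row sums to 1); SVM scores are
    per-class decision values squashed through a logistic to [0, 1]
    (monotone in the decision value, suitable for one-vs-rest ROC).
    """
    if F.n_features != model.n_features:
        raise ValueError(
            f"model trained on {model.n_features} features, matrix has {F.n_features}"
        )
    if F.n_samples == 0:
        return (np.array([], dtype=int),
                np.zeros((0, model.classes.shape[0])))
    if model.kind == "cubic_svm":
        X = model._standardized(F.values)
        dec = model.svm.decision_function(X)
        if dec.ndim == 1:  # binary: one margin, symmetric per-class view
            dec = np.column_stack([-dec, dec])
        scores = 1.0 / (1.0 + np.exp(-dec))
        labels = model.svm.predict(X)
        return labels.astype(int), scores
    post = np.zeros((F.n_samples, model.classes.shape[0]))
    for idx, lda in model.learners:
        post += lda.posteriors(F.values[:, idx])
    post /= len(model.learners)
    labels = model.classes[np.argmax(post, axis=1)]
    return labels.astype(int), post


# --------------------------------------------------------------- persistence
def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize the fitted model plus a JSON manifest alongside it."""
    path = Path(path)
    joblib.dump(model, path)
    manifest = {
        "kind": model.kind,
        "spec": {k: v for k, v in vars(model.spec).items()},
        "classes": model.classes.tolist(),
        "class_names": model.class_names,
        "n_features": int(model.n_features),
        "file_sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
    }
    Path(str(path) + ".json").write_text(json.dumps(manifest, indent=2))


def load_model(path: str | Path) -> TrainedModel:
    model = joblib.load(path)
    if not isinstance(model, TrainedModel):
        raise TypeError(f"{path} does not hold a TrainedModel")
    return model
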