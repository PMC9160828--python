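"""SVM classifier (RBF or linear kernel) and the SWLDA linear baseline.

The SVM decision function is the kernel expansion over support vectors,

    f(x) = sum_{m=1..N} alpha_m y_m K(x, x_m) + b,

with the Gaussian kernel parameterized by its width sigma,
K(x, x') = exp(-||x - x'||^2 / (2 sigma^2)).  The quadratic program is solved
by libsvm (scikit-learn's SVC); the model object stores the support vectors,
signed dual coefficients and bias explicitly and evaluates the decision
function from them, so a serialized model reloads to bit-identical decisions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from .errors import ParameterError
from .featsel import SWLDASelector

__all__ = [
    "SVMParams",
    "SVMModel",
    "train_svm",
    "predict",
    "train_swlda_classifier",
    "accuracy",
    "resolve_sigma",
    "model_to_json",
    "model_from_json",
]


@dataclass(frozen=True)
class SVMParams:
    """Soft-margin SVM hyperparameters.

    ``sigma`` is the Gaussian kernel width (sigma, not gamma); ``sigma=None``
    resolves at fit time to the scale heuristic sigma = sqrt(d * Var[X] / 2),
    which makes the default kernel scale track the feature dimension.  C
    defaults to 1 and is searched, together with sigma, by the hyperparameter
    optimizer when enabled.
    """

    C: float = 1.0
    sigma: float | None = None
    kernel: str = "rbf"

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ParameterError("C must be positive")
        if self.sigma is not None and self.sigma <= 0:
            raise ParameterError("sigma must be positive")
        if self.kernel not in ("rbf", "linear"):
            raise ParameterError("kernel must be 'rbf' or 'linear'")


def resolve_sigma(params: SVMParams, X: np.ndarray) -> float | None:
    """Concrete kernel width for this training matrix (None for linear kernel)."""
    if params.kernel == "linear":
        return None
    if params.sigma is not None:
        return params.sigma
    X = np.asarray(X, dtype=float)
    var = float(X.var())
    if var <= 0:
        var = 1.0
    return float(np.sqrt(X.shape[1] * var / 2.0))


@dataclass
class SVMModel:
    """A fitted SVM: support vectors, dual coefficients, bias, kernel."""

    support_vectors: np.ndarray  # N x d
    dual_coef: np.ndarray  # alpha_m * y_m, signed, length N
    bias: float
    params: SVMParams
    sigma_: float | None  # resolved width (None for linear)
    classes_: np.ndarray  # sorted class labels; decision > 0 -> classes_[1]
    majority_label: object  # tie-break target for f(x) == 0
    n_features: int

    @property
    def n_support(self) -> int:
        return self.support_vectors.shape[0]

    @property
    def alphas(self) -> np.ndarray:
        """Dual multipliers alpha_m >= 0 (the magnitude of the signed coefficients)."""
        return np.abs(self.dual_coef)

    @property
    def support_labels(self) -> np.ndarray:
        """y_m in {-1, +1} per support vector."""
        return np.sign(self.dual_coef).astype(int)

    def kernel_matrix(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ParameterError(
                f"X has {X.shape[1]} features, model was trained with {self.n_features}"
            )
        if self.params.kernel == "linear":
            return X @ self.support_vectors.T
        sq = (
            (X**2).sum(axis=1)[:, None]
            - 2 * X @ self.support_vectors.T
            + (self.support_vectors**2).sum(axis=1)[None, :]
        )
        return np.exp(-np.maximum(sq, 0.0) / (2.0 * self.sigma_**2))

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.kernel_matrix(X) @ self.dual_coef + self.bias

    def primal_weights(self) -> np.ndarray:
        """w = sum_m alpha_m y_m x_m; defined only for the linear kernel."""
        if self.params.kernel != "linear":
            raise ParameterError("primal weights exist only for the linear kernel")
        return self.dual_coef @ self.support_vectors


def train_svm(X_train: np.ndarray, y_train: np.ndarray, params: SVMParams = SVMParams()) -> SVMModel:
    """Fit the soft-margin SVM; both classes must be present.

    The caller is responsible for standardizing features with *training*
    statistics (the validation engine does this per fold).
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train)
    classes = np.unique(y)
    if classes.size != 2:
        raise ParameterError(f"need exactly two classes in y_train, got {classes.size}")

    sigma = resolve_sigma(params, X)
    gamma = "scale" if sigma is None else 1.0 / (2.0 * sigma**2)
    clf = SVC(
        C=params.C,
        kernel=params.kernel,
        gamma=gamma if params.kernel == "rbf" else "scale",
        tol=1e-6,
        shrinking=True,
    )
    clf.fit(X, y)
    counts = [np.sum(y == c) for c in classes]
    majority = classes[int(np.argmax(counts))]
    return SVMModel(
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=clf.dual_coef_[0].copy(),
        bias=float(clf.intercept_[0]),
        params=params,
        sigma_=sigma,
        classes_=classes,
        majority_label=majority,
        n_features=X.shape[1],
    )


def predict(model: SVMModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels and decision values; f(x) = 0 resolves to the majority training class."""
    f = model.decision_function(X)
    labels = np.where(f > 0, model.classes_[1], model.classes_[0])
    labels = np.where(f == 0, model.majority_label, labels)
    return labels, f


def train_swlda_classifier(
    X: np.ndarray,
    y: np.ndarray,
    alpha_in: float = 0.10,
    alpha_out: float = 0.15,
    max_features: int | None = None,
) -> SWLDASelector:
    """SWLDA used directly as a linear classifier (selection + discriminant).

    Returns the fitted stepwise model; ``predict`` gives sign-of-score labels,
    falling back to the majority class (with ``empty_`` flagged) when the
    stepwise procedure selects nothing.
    """
    return SWLDASelector(alpha_in, alpha_out, max_features).fit(X, y)


def accuracy(y_true, y_pred) -> float:
    """Percentage of correctly classified samples."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size < 1:
        raise ParameterError("y_true and y_pred must have equal nonzero length")
    return 100.0 * float(np.mean(y_true == y_pred))


# ---------------------------------------------------------------------------
# Serialization: exact reload of the decision function.
# ---------------------------------------------------------------------------

def model_to_json(model: SVMModel, path: str | Path | None = None) -> str:
    payload = {
        "support_vectors": model.support_vectors.tolist(),
        "dual_coef": model.dual_coef.tolist(),
        "bias": model.bias,
        "params": {"C": model.params.C, "sigma": model.params.sigma,
                   "kernel": model.params.kernel},
        "sigma_": model.sigma_,
        "classes": model.classes_.tolist(),
        "majority_label": model.majority_label
        if not isinstance(model.majority_label, np.generic)
        else model.majority_label.item(),
        "n_features": model.n_features,
    }
    text = json.dumps(payload)
    if path is not None:
        Path(path).write_text(text)
    return text


def model_from_json(source: str | Path) -> SVMModel:
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = source
    d = json.loads(text)
    return SVMModel(
        support_vectors=np.asarray(d["support_vectors"], dtype=float),
        dual_coef=np.asarray(d["dual_coef"], dtype=float),
        bias=float(d["bias"]),
        params=SVMParams(**d["params"]),
        sigma_=d["sigma_"],
        classes_=np.asarray(d["classes"]),
        majority_label=d["majority_label"],
        n_features=int(d["n_features"]),
    )
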