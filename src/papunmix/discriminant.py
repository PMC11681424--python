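"""Fisher linear discriminants for EC vs. LEGH mucin, plus evaluation.

The two-class Fisher discriminant over per-patch mean dye amounts (or mean
sRGB values) is

    w ∝ S_W^{-1} (mu_LEGH - mu_EC),      D(x) = w . x + b,

with S_W the pooled within-class scatter and the bias placed at the
equal-prior class midpoint, b = -w . (mu_EC + mu_LEGH) / 2.  A patch is
assigned the model's positive class when D >= 0 (ties inclusive).

Bundled presets (:func:`preset_models`) carry fixed coefficients trained on
clinical mucin samples that are not distributed: a 2-D (EY, OG) model, a
3-D (EY, LG, OG) model, and an sRGB baseline.  Their printed orientation
puts the EY-rich / pink (EC) side at D >= 0, so the presets declare
``positive_label="EC"``; OG-rich mucin then lands on the negative, LEGH
side, consistent with the confusion matrices the coefficients were
validated against.  Freshly fitted models default to the LEGH-positive
convention.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_X_y

from .errors import DimensionError, ValidationError

__all__ = [
    "LinearDiscriminantModel",
    "FisherDiscriminant",
    "fit_fisher",
    "preset_models",
    "classify",
    "EvalReport",
    "evaluate",
    "evaluate_confusion",
    "cluster_legh_ratio",
]

CLASS_LABELS = ("EC", "LEGH")


@dataclass
class LinearDiscriminantModel:
    """Affine decision function D(x) = w . x + b over named features."""

    feature_names: tuple[str, ...]
    weights: np.ndarray
    bias: float
    positive_label: str = "LEGH"

    def __post_init__(self) -> None:
        self.feature_names = tuple(self.feature_names)
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        self.bias = float(self.bias)
        if self.weights.size != len(self.feature_names):
            raise DimensionError("weights and feature_names lengths differ")
        if self.positive_label not in CLASS_LABELS:
            raise ValidationError(
                f"positive_label must be one of {CLASS_LABELS}"
            )

    @property
    def negative_label(self) -> str:
        return "EC" if self.positive_label == "LEGH" else "LEGH"

    def decision(self, features) -> np.ndarray | float:
        """D(x) for a single feature vector or an (n, d) array."""
        x = np.asarray(features, dtype=float)
        if x.shape[-1] != self.weights.size:
            raise DimensionError(
                f"expected {self.weights.size} features "
                f"({list(self.feature_names)}), got {x.shape[-1]}"
            )
        d = x @ self.weights + self.bias
        return float(d) if d.ndim == 0 else d

    def classify(self, features):
        """Positive class iff D >= 0 (ties go to the positive class)."""
        d = self.decision(features)
        if np.ndim(d) == 0:
            return self.positive_label if d >= 0 else self.negative_label
        return np.where(d >= 0, self.positive_label, self.negative_label)

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "positive_label": self.positive_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearDiscriminantModel":
        return cls(
            feature_names=tuple(d["feature_names"]),
            weights=np.asarray(d["weights"], dtype=float),
            bias=float(d["bias"]),
            positive_label=d.get("positive_label", "LEGH"),
        )


def fit_fisher(
    samples_ec,
    samples_legh,
    feature_names=None,
    ridge: float = 0.0,
) -> LinearDiscriminantModel:
    """Fit a two-class Fisher discriminant (LEGH-positive convention).

    ``w = S_W^{-1}(mu_LEGH - mu_EC)`` with the pooled within-class scatter
    ``S_W``; this orientation automatically puts the LEGH mean on the
    D >= 0 side.  A singular scatter falls back to a ridge-regularized
    solve with a warning.
    """
    x0 = np.atleast_2d(np.asarray(samples_ec, dtype=float))
    x1 = np.atleast_2d(np.asarray(samples_legh, dtype=float))
    if x0.shape[0] < 2 or x1.shape[0] < 2:
        raise ValidationError("need at least 2 samples per class")
    if x0.shape[1] != x1.shape[1]:
        raise DimensionError("class samples have differing feature counts")
    d = x0.shape[1]
    if feature_names is None:
        feature_names = tuple(f"x{i}" for i in range(d))
    mu0, mu1 = x0.mean(axis=0), x1.mean(axis=0)
    sw = (x0 - mu0).T @ (x0 - mu0) + (x1 - mu1).T @ (x1 - mu1)
    if ridge > 0:
        sw = sw + ridge * np.eye(d)
    try:
        w = np.linalg.solve(sw, mu1 - mu0)
        if not np.all(np.isfinite(w)) or np.linalg.cond(sw) > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        lam = 1e-8 * max(np.trace(sw) / d, 1.0)
        warnings.warn(
            f"within-class scatter is singular; ridge-regularizing with {lam:.3g}",
            stacklevel=2,
        )
        w = np.linalg.solve(sw + lam * np.eye(d), mu1 - mu0)
    bias = -float(w @ (mu0 + mu1) / 2.0)
    return LinearDiscriminantModel(
        feature_names=tuple(feature_names),
        weights=w,
        bias=bias,
        positive_label="LEGH",
    )


class FisherDiscriminant(ClassifierMixin, BaseEstimator):
    """Two-class Fisher discriminant with the scikit-learn estimator API.

    Parameters
    ----------
    positive_label : str, default "LEGH"
        Class assigned when the decision function is >= 0.
    ridge : float, default 0.0
        Optional Tikhonov term added to the pooled within-class scatter.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
    weights_ : ndarray of shape (n_features,)
    bias_ : float
    model_ : LinearDiscriminantModel
    """

    def __init__(self, positive_label: str = "LEGH", ridge: float = 0.0):
        self.positive_label = positive_label
        self.ridge = ridge

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValidationError(f"expected exactly two classes, got {classes}")
        if self.positive_label not in classes:
            raise ValidationError(
                f"positive_label {self.positive_label!r} not among classes {classes}"
            )
        neg = classes[classes != self.positive_label][0]
        model = fit_fisher(X[y == neg], X[y == self.positive_label])
        self.model_ = LinearDiscriminantModel(
            feature_names=tuple(f"x{i}" for i in range(X.shape[1])),
            weights=model.weights,
            bias=model.bias,
            positive_label="LEGH",
        )
        self.classes_ = classes
        self.weights_ = model.weights
        self.bias_ = model.bias
        self._neg_label = neg
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted = hasattr(self, "weights_")
        if not check_is_fitted:
            raise ValidationError("FisherDiscriminant is not fitted")
        X = check_array(X, dtype=float)
        return X @ self.weights_ + self.bias_

    def predict(self, X):
        d = self.decision_function(X)
        out = np.empty(d.shape, dtype=object)
        out[d >= 0] = self.positive_label
        out[d < 0] = self._neg_label
        return out.astype(self.classes_.dtype)


def preset_models() -> dict[str, LinearDiscriminantModel]:
    """Bundled fixed discriminants: ``fisher_2d``, ``fisher_3d``, ``srgb``.

    Coefficients are shipped verbatim as published for the 14-band
    protocol; see the module docstring for the EC-positive orientation.
    sRGB features are gamma-encoded channel means in [0, 1].
    """
    text = resources.files("papunmix").joinpath("presets/discriminants.json").read_text()
    return {k: LinearDiscriminantModel.from_dict(v) for k, v in json.loads(text).items()}


def classify(model: LinearDiscriminantModel, features):
    """Label a feature vector with ``model`` (D >= 0 -> positive class)."""
    return model.classify(features)


@dataclass
class EvalReport:
    """Two-class confusion matrix and summary metrics.

    ``confusion`` rows are the true label in (EC, LEGH) order, columns the
    prediction.  Precision, recall and F are computed w.r.t. the stated
    ``positive_class``; a zero denominator yields 0 with the metric name
    recorded in ``undefined``.
    """

    confusion: np.ndarray
    accuracy: float
    precision: float
    recall: float
    f_value: float
    positive_class: str
    undefined: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "labels": list(CLASS_LABELS),
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f_value": self.f_value,
            "positive_class": self.positive_class,
            "undefined": list(self.undefined),
        }


def evaluate_confusion(confusion, positive_class: str) -> EvalReport:
    """Metrics from a 2x2 confusion matrix (rows true EC/LEGH, cols pred)."""
    cm = np.asarray(confusion, dtype=int)
    if cm.shape != (2, 2) or np.any(cm < 0):
        raise ValidationError("confusion must be a nonnegative 2x2 matrix")
    if positive_class not in CLASS_LABELS:
        raise ValidationError(f"positive_class must be one of {CLASS_LABELS}")
    p = CLASS_LABELS.index(positive_class)
    total = int(cm.sum())
    if total == 0:
        raise ValidationError("empty confusion matrix")
    tp = int(cm[p, p])
    fp = int(cm[1 - p, p])
    fn = int(cm[p, 1 - p])
    undefined = []

    def _ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    accuracy = np.trace(cm) / total
    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    f_value = _ratio(2 * precision * recall, precision + recall, "f_value")
    return EvalReport(
        confusion=cm,
        accuracy=float(accuracy),
        precision=float(precision),
        recall=float(recall),
        f_value=float(f_value),
        positive_class=positive_class,
        undefined=tuple(undefined),
    )


def evaluate(true_labels, predicted_labels, positive_class: str) -> EvalReport:
    """Confusion matrix and accuracy/precision/recall/F from label lists."""
    t = list(true_labels)
    pr = list(predicted_labels)
    if len(t) != len(pr):
        raise ValidationError("label lists must have equal length")
    bad = sorted({x for x in t + pr} - set(CLASS_LABELS))
    if bad:
        raise ValidationError(f"unknown label(s) {bad}; expected {CLASS_LABELS}")
    cm = np.zeros((2, 2), dtype=int)
    for ti, pi in zip(t, pr):
        cm[CLASS_LABELS.index(ti), CLASS_LABELS.index(pi)] += 1
    return evaluate_confusion(cm, positive_class)


def cluster_legh_ratio(patches) -> float | None:
    """Fraction of mucin patches classified LEGH, over mucin patches only.

    Nucleus and background patches are excluded from both numerator and
    denominator.  Returns ``None`` (undefined, not zero) when the cluster
    contains no classified mucin patch.
    """
    preds = [p.predicted for p in patches if p.label == "mucin" and p.predicted]
    if not preds:
        return None
    return sum(1 for q in preds if q == "LEGH") / len(preds)
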