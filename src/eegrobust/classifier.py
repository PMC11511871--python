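"""L2-regularized logistic regression with subject-level aggregation.

The classifier operates on log-transformed (optionally SIRT-preprocessed)
spectral features, one observation per sub-window.  Because a subject
contributes many windows, the subject-level prediction is the arithmetic mean
of the per-window probabilities, and all diagnostic metrics (AUROC, balanced
accuracy, sensitivity, specificity) are computed over subjects, not windows.

Regularization is expressed as the inverse strength ``C_reg`` (smaller values
mean stronger regularization), matching the scikit-learn convention; the
penalized-likelihood weight is lambda = 1 / C_reg.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

__all__ = [
    "LinearModel",
    "SubjectPrediction",
    "ClassifierMetrics",
    "fit_logreg",
    "predict_window_proba",
    "predict_subjects",
    "evaluate",
]


@dataclass
class LinearModel:
    """A fitted linear decision function p(y=1|x) = sigmoid(w.x + b)."""

    w: np.ndarray
    b: float
    inverse_reg_strength: float
    converged: bool
    n_iter: int = 0

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X) @ self.w + self.b

    def to_json(self, path, feature_fingerprint: str | None = None) -> None:
        payload = {
            "w": self.w.tolist(),
            "b": self.b,
            "inverse_reg_strength": self.inverse_reg_strength,
            "converged": self.converged,
            "feature_fingerprint": feature_fingerprint,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "LinearModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(w=np.asarray(d["w"]), b=d["b"],
                   inverse_reg_strength=d["inverse_reg_strength"],
                   converged=d["converged"])


@dataclass
class SubjectPrediction:
    subject_id: str
    probability: float
    logit: float
    label: int


@dataclass
class ClassifierMetrics:
    auroc: float
    balanced_accuracy: float
    sensitivity: float
    specificity: float


def fit_logreg(X: np.ndarray, y: np.ndarray, C_reg: float = 1.0,
               tol: float = 1e-3, max_iter: int = 100) -> LinearModel:
    """Fit L2-regularized logistic regression (lbfgs, deterministic).

    ``C_reg`` is the inverse regularization strength; the solved objective is
    0.5 ||w||^2 + C_reg * sum_i log(1 + exp(-y_i (w.x_i + b))).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit the classifier")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if C_reg <= 0:
        raise ValueError("C_reg must be positive")
    clf = LogisticRegression(C=C_reg, tol=tol, max_iter=max_iter,
                             solver="lbfgs")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    n_iter = int(np.max(clf.n_iter_))
    return LinearModel(w=clf.coef_.ravel().copy(), b=float(clf.intercept_[0]),
                       inverse_reg_strength=float(C_reg),
                       converged=n_iter < max_iter, n_iter=n_iter)


def predict_window_proba(model: LinearModel, X: np.ndarray) -> np.ndarray:
    """Per-window probability of the positive class."""
    return expit(model.decision(X))


def predict_subjects(window_probs: np.ndarray, subject_ids, labels) -> list:
    """Aggregate window probabilities to one prediction per subject.

    The subject probability is the arithmetic mean of the window
    probabilities; the subject logit is log(p / (1 - p)) of that mean.
    Subjects are returned in order of first appearance.
    """
    window_probs = np.asarray(window_probs, dtype=float)
    subject_ids = np.asarray(subject_ids)
    labels = np.asarray(labels)
    if not (len(window_probs) == len(subject_ids) == len(labels)):
        raise ValueError("window_probs, subject_ids and labels must align")
    if len(window_probs) == 0:
        raise ValueError("no windows to aggregate")
    preds = []
    seen = {}
    for sid in subject_ids:
        if sid not in seen:
            seen[sid] = True
    for sid in seen:
        sel = subject_ids == sid
        p = float(window_probs[sel].mean())
        lab = np.unique(labels[sel])
        if len(lab) != 1:
            raise ValueError(f"subject {sid} carries inconsistent labels")
        pc = min(max(p, 1e-12), 1 - 1e-12)
        preds.append(SubjectPrediction(subject_id=str(sid), probability=p,
                                       logit=float(np.log(pc / (1 - pc))),
                                       label=int(lab[0])))
    return preds


def evaluate(predictions, threshold: float = 0.5) -> ClassifierMetrics:
    """Subject-level AUROC and thresholded confusion metrics.

    AUROC uses the rank statistic with midranks for ties; balanced accuracy
    is the mean of sensitivity and specificity at ``threshold``.
    """
    y = np.array([p.label for p in predictions])
    prob = np.array([p.probability for p in predictions])
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to evaluate")
    auroc = float(roc_auc_score(y, prob))
    yhat = (prob >= threshold).astype(int)
    tp = int(np.sum((y == 1) & (yhat == 1)))
    fn = int(np.sum((y == 1) & (yhat == 0)))
    tn = int(np.sum((y == 0) & (yhat == 0)))
    fp = int(np.sum((y == 0) & (yhat == 1)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return ClassifierMetrics(auroc=auroc,
                             balanced_accuracy=(sens + spec) / 2.0,
                             sensitivity=sens, specificity=spec)
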