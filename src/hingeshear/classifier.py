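"""Logistic hinge/shear predictor over elemental contact-change counts.

The model is plain logistic regression on the 4-vector
N = (N_maint, N_exchpart, N_exchpair, N_new):

    logit(y) = w . N + b,        y = P(shear | N)

with label convention t = 0 for predominantly hinge and t = 1 for
predominantly shear. The published model (trained on 77 intuitively
labelled domain movements: 54 hinge, 23 shear) is shipped as the
constant :data:`PUBLISHED_MODEL`; in the published sign convention,

    y(N) = 1 / (1 + e^alpha),
    alpha = -0.2387 N_maint - 0.0356 N_exchpart
            + 0.4249 N_exchpair + 0.2122 N_new + 0.1467

so maintained and exchanged-partner contact changes push towards shear
and exchanged-pair and new contact changes push towards hinge.

Class assignment uses the boundaries 0.45 and 0.55: hinge for
0 <= y <= 0.45, shear for 0.55 <= y <= 1, mixed in between, and a
separate no-contact class when N = 0 (no interdomain contacts in either
conformation, so neither mechanism applies). Boundaries are applied to
the full-precision y, never to a rounded value.

The estimator :class:`HingeShearClassifier` follows the scikit-learn
API; the module-level functions are thin wrappers kept for pipeline use.
Fitting minimizes the cross-entropy E = -1/2 sum [t log y + (1-t) log(1-y)]
by Newton iterations (IRLS) from a zero start — the objective is convex,
so the fit is deterministic with no random seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.utils.validation import check_is_fitted

from .dcg import ElementalCounts

__all__ = [
    "LogisticModel",
    "PUBLISHED_MODEL",
    "TrainingSet",
    "ClassLabel",
    "SeparationWarning",
    "HingeShearClassifier",
    "predict",
    "classify",
    "fit",
    "cross_entropy",
    "roc_curve",
    "loocv",
    "precision_report",
    "read_training_set",
    "write_training_set",
    "read_model",
    "write_model",
]

FEATURE_NAMES = ("n_maint", "n_exchpart", "n_exchpair", "n_new")
DEFAULT_LOWER = 0.45
DEFAULT_UPPER = 0.55


class SeparationWarning(UserWarning):
    """Training data is completely separable; coefficients did not converge."""


@dataclass(frozen=True)
class LogisticModel:
    """Coefficients of the logistic predictor, logit(y) = w . N + b.

    ``w`` is ordered (maintained, exchanged-partner, exchanged-pair, new).
    """

    w: np.ndarray
    b: float

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.shape != (4,):
            raise ValueError("w must be a 4-vector")
        if not (np.all(np.isfinite(w)) and np.isfinite(self.b)):
            raise ValueError("model coefficients must be finite")
        object.__setattr__(self, "w", w)

    def alpha(self, counts: np.ndarray) -> np.ndarray:
        """The published-form exponent: y = 1 / (1 + e^alpha) = sigma(-alpha)."""
        x = np.atleast_2d(np.asarray(counts, dtype=float))
        return -(x @ self.w + self.b)

    def predict(self, counts: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(counts, dtype=float))
        return expit(x @ self.w + self.b)


# The published coefficients appear with y = 1/(1+e^alpha); internally we
# store logit(y) = w.N + b, i.e. w = -alpha coefficients, b = -alpha bias.
PUBLISHED_ALPHA_COEFFS = (-0.2387, -0.0356, 0.4249, 0.2122)
PUBLISHED_ALPHA_BIAS = 0.1467

PUBLISHED_MODEL = LogisticModel(
    w=-np.asarray(PUBLISHED_ALPHA_COEFFS), b=-PUBLISHED_ALPHA_BIAS
)

LABEL_NAMES = {0: "hinge", 1: "shear"}
LABEL_CODES = {"hinge": 0, "shear": 1}


@dataclass
class TrainingSet:
    """Labelled elemental-count vectors: t = 0 hinge, t = 1 shear."""

    counts: np.ndarray  # (n, 4) non-negative
    labels: np.ndarray  # (n,) in {0, 1}
    ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must have shape (n, 4)")
        n = self.counts.shape[0]
        if n == 0:
            raise ValueError("training set must be non-empty")
        if self.labels.shape != (n,) or len(self.ids) != n:
            raise ValueError("counts, labels and ids must have equal length")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 (hinge) or 1 (shear)")

    def __len__(self) -> int:
        return self.counts.shape[0]


class ClassLabel(NamedTuple):
    """Class assignment plus the prediction value (None for no-contact)."""

    value: str  # no_contact | hinge | mixed | shear
    y: float | None


def _counts_array(n: ElementalCounts | Sequence[float] | np.ndarray) -> np.ndarray:
    if isinstance(n, ElementalCounts):
        return np.asarray(n.as_tuple(), dtype=float)
    return np.asarray(n, dtype=float)


class HingeShearClassifier(BaseEstimator, ClassifierMixin):
    """Logistic hinge/shear classifier in the scikit-learn estimator API.

    Features are the four elemental contact-change counts in the order
    (maintained, exchanged-partner, exchanged-pair, new); the positive
    class (1) is shear. ``predict_proba[:, 1]`` is the prediction value
    y; :meth:`assign` applies the four-way hinge / mixed / shear /
    no-contact rule with the 0.45 / 0.55 boundaries.

    Parameters
    ----------
    lower, upper:
        Class boundaries on y (hinge <= lower < mixed < upper <= shear).
    max_iter, tol:
        Newton (IRLS) iteration cap and infinity-norm gradient tolerance.

    Attributes
    ----------
    coef_, intercept_:
        Fitted coefficients in logit(y) = coef_ . N + intercept_.
    model_:
        The same coefficients as a :class:`LogisticModel`.
    n_iter_:
        Newton iterations used.
    """

    def __init__(
        self,
        lower: float = DEFAULT_LOWER,
        upper: float = DEFAULT_UPPER,
        max_iter: int = 200,
        tol: float = 1e-8,
    ):
        self.lower = lower
        self.upper = upper
        self.max_iter = max_iter
        self.tol = tol

    @classmethod
    def from_published(
        cls, lower: float = DEFAULT_LOWER, upper: float = DEFAULT_UPPER
    ) -> "HingeShearClassifier":
        """A ready-to-use classifier carrying the published coefficients."""
        est = cls(lower=lower, upper=upper)
        est._set_model(PUBLISHED_MODEL)
        return est

    def _set_model(self, model: LogisticModel) -> None:
        self.model_ = model
        self.coef_ = model.w.reshape(1, 4)
        self.intercept_ = np.asarray([model.b])
        self.classes_ = np.asarray([0, 1])
        self.n_features_in_ = 4

    def _check_boundaries(self) -> None:
        if not (0.0 < self.lower <= self.upper < 1.0):
            raise ValueError(
                f"invalid class boundaries lower={self.lower}, upper={self.upper}"
            )

    def fit(self, X, y):
        """Fit by Newton/IRLS on the cross-entropy objective (zero start)."""
        self._check_boundaries()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] != 4:
            raise ValueError("X must have shape (n_samples, 4)")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        classes = np.unique(y)
        if not np.isin(classes, (0, 1)).all():
            raise ValueError("labels must be 0 (hinge) or 1 (shear)")
        if classes.size < 2:
            raise ValueError("both classes must be present to fit")
        t = y.astype(float)

        design = np.hstack([X, np.ones((X.shape[0], 1))])
        beta = np.zeros(design.shape[1])
        converged = False
        for it in range(1, self.max_iter + 1):
            p = expit(design @ beta)
            grad = design.T @ (t - p)
            if np.abs(grad).max() < self.tol:
                converged = True
                break
            wdiag = np.clip(p * (1.0 - p), 1e-12, None)
            hess = design.T @ (design * wdiag[:, None])
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(hess, grad, rcond=None)[0]
            beta = beta + step
        self.n_iter_ = it
        # every point strictly on its own side means the fitted hyperplane
        # separates the classes, so the MLE diverges (the likelihood keeps
        # improving as the coefficients scale up)
        margins = (design @ beta) * (2.0 * t - 1.0)
        self.separation_ = bool(np.all(margins > 0))
        if self.separation_:
            warnings.warn(
                "training data is completely separable; coefficients "
                "are capped by the iteration limit",
                SeparationWarning,
            )
        self._set_model(LogisticModel(w=beta[:4].copy(), b=float(beta[4])))
        return self

    def decision_function(self, X):
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        return np.atleast_2d(X) @ self.model_.w + self.model_.b

    def predict_proba(self, X):
        p1 = expit(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        """Binary 0/1 prediction at the natural 0.5 boundary."""
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)

    def assign(self, X) -> list[ClassLabel]:
        """Four-way assignment: no_contact / hinge / mixed / shear."""
        check_is_fitted(self, "model_")
        self._check_boundaries()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        ys = self.predict_proba(X)[:, 1]
        out: list[ClassLabel] = []
        for row, yv in zip(X, ys):
            if np.all(row == 0):
                out.append(ClassLabel("no_contact", None))
            elif yv <= self.lower:
                out.append(ClassLabel("hinge", float(yv)))
            elif yv >= self.upper:
                out.append(ClassLabel("shear", float(yv)))
            else:
                out.append(ClassLabel("mixed", float(yv)))
        return out


# ------------------------------------------------------------ functional API


def predict(
    n: ElementalCounts | Sequence[float] | np.ndarray,
    model: LogisticModel = PUBLISHED_MODEL,
) -> float:
    """Prediction value y in (0, 1); larger means more shear-like."""
    return float(model.predict(_counts_array(n))[0])


def classify(
    n: ElementalCounts | Sequence[float] | np.ndarray,
    model: LogisticModel = PUBLISHED_MODEL,
    lower: float = DEFAULT_LOWER,
    upper: float = DEFAULT_UPPER,
) -> ClassLabel:
    """Assign no_contact / hinge / mixed / shear with boundaries on y."""
    est = HingeShearClassifier(lower=lower, upper=upper)
    est._set_model(model)
    return est.assign(_counts_array(n).reshape(1, 4))[0]


def fit(
    data: TrainingSet, max_iter: int = 200, tol: float = 1e-8
) -> LogisticModel:
    """Fit a logistic model to a training set; see :class:`HingeShearClassifier`."""
    est = HingeShearClassifier(max_iter=max_iter, tol=tol)
    est.fit(data.counts, data.labels)
    return est.model_


def cross_entropy(model: LogisticModel, data: TrainingSet) -> float:
    """The training objective E = -1/2 sum [t log y + (1-t) log(1-y)]."""
    y = np.clip(model.predict(data.counts), 1e-300, 1 - 1e-16)
    t = data.labels.astype(float)
    return float(-0.5 * np.sum(t * np.log(y) + (1 - t) * np.log(1 - y)))


@dataclass
class RocResult:
    points: np.ndarray  # (k, 2) columns (false_positive_rate, true_positive_rate)
    auc: float
    hull_auc: float
    thresholds: np.ndarray


def _convex_hull_auc(points: np.ndarray) -> float:
    """Area under the upper convex hull of ROC points (incl. (0,0),(1,1))."""
    pts = np.vstack([points, [0.0, 0.0], [1.0, 1.0]])
    pts = pts[np.lexsort((-pts[:, 1], pts[:, 0]))]
    hull: list[np.ndarray] = []
    for p in pts:
        while len(hull) >= 2:
            o, a = hull[-2], hull[-1]
            cross = (a[0] - o[0]) * (p[1] - o[1]) - (a[1] - o[1]) * (p[0] - o[0])
            if cross >= 0:  # a is below or on chord o-p: drop it
                hull.pop()
            else:
                break
        hull.append(p)
    hp = np.asarray(hull)
    return float(np.trapezoid(hp[:, 1], hp[:, 0]))


def _roc_from_scores(labels: np.ndarray, scores: np.ndarray) -> RocResult:
    if np.unique(labels).size < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    points = np.column_stack([fpr, tpr])
    return RocResult(
        points=points,
        auc=float(_sk_auc(fpr, tpr)),
        hull_auc=_convex_hull_auc(points),
        thresholds=thr,
    )


def roc_curve(data: TrainingSet, model: LogisticModel = PUBLISHED_MODEL) -> RocResult:
    """ROC of the model on labelled data; shear (t=1) is the positive class.

    The curve sweeps the decision threshold over the distinct prediction
    values (plus endpoints); AUC is trapezoidal; the area under the
    upper convex hull is also reported.
    """
    return _roc_from_scores(data.labels, model.predict(data.counts))


@dataclass
class LoocvResult:
    y_heldout: np.ndarray  # NaN where the fold had to be skipped
    roc: RocResult


def loocv(data: TrainingSet, max_iter: int = 200, tol: float = 1e-8) -> LoocvResult:
    """Leave-one-out cross-validation: item i predicted by a model fit without it."""
    n = len(data)
    if n < 3:
        raise ValueError("LOOCV requires at least 3 items")
    if np.unique(data.labels).size < 2:
        raise ValueError("both classes must be present")
    y_out = np.full(n, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SeparationWarning)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            if np.unique(data.labels[mask]).size < 2:
                warnings.warn(f"fold {i} leaves a single class; skipped")
                continue
            est = HingeShearClassifier(max_iter=max_iter, tol=tol)
            est.fit(data.counts[mask], data.labels[mask])
            y_out[i] = est.predict_proba(data.counts[i : i + 1])[0, 1]
    ok = ~np.isnan(y_out)
    roc = _roc_from_scores(data.labels[ok], y_out[ok])
    return LoocvResult(y_heldout=y_out, roc=roc)


def precision_report(
    data: TrainingSet,
    model: LogisticModel = PUBLISHED_MODEL,
    lower: float = DEFAULT_LOWER,
    upper: float = DEFAULT_UPPER,
) -> pd.DataFrame:
    """Per-class precision of the hinge and shear predictions.

    Precision of a class = correctly predicted in that class / all
    predicted in that class. Mixed predictions count towards neither
    class; a class with no predictions gets precision NaN (undefined).
    """
    y = model.predict(data.counts)
    rows = []
    for cls, code in (("hinge", 0), ("shear", 1)):
        if cls == "hinge":
            pred_mask = y <= lower
        else:
            pred_mask = y >= upper
        predicted = int(pred_mask.sum())
        correct = int((data.labels[pred_mask] == code).sum())
        precision = correct / predicted if predicted else float("nan")
        rows.append(
            {
                "class": cls,
                "predicted": predicted,
                "correct": correct,
                "precision": precision,
                "precision_percent": 100.0 * precision if predicted else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("class")


# ------------------------------------------------------------------- file IO

_TRAINING_COLUMNS = ["id", "n_maint", "n_exchpart", "n_exchpair", "n_new", "label"]


def read_training_set(path: str | Path) -> TrainingSet:
    """Read a tab-separated training table (label column: hinge|shear)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_TRAINING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"training table missing columns: {sorted(missing)}")
    bad = ~df["label"].isin(LABEL_CODES)
    if bad.any():
        line = int(df.index[bad][0]) + 2  # +1 header, +1 one-based
        raise ValueError(
            f"unknown label {df['label'][bad].iloc[0]!r} on line {line}"
        )
    return TrainingSet(
        counts=df[list(FEATURE_NAMES)].to_numpy(dtype=float),
        labels=df["label"].map(LABEL_CODES).to_numpy(),
        ids=df["id"].astype(str).tolist(),
    )


def write_training_set(data: TrainingSet, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "id": data.ids,
            "n_maint": data.counts[:, 0].astype(int),
            "n_exchpart": data.counts[:, 1].astype(int),
            "n_exchpair": data.counts[:, 2].astype(int),
            "n_new": data.counts[:, 3].astype(int),
            "label": [LABEL_NAMES[t] for t in data.labels],
        }
    )
    df.to_csv(path, sep="\t", index=False)


MODEL_FORMAT_VERSION = 1


def write_model(model: LogisticModel, path: str | Path) -> None:
    """Key/value model file with a format-version line."""
    Path(path).write_text(
        f"format_version = {MODEL_FORMAT_VERSION}\n"
        f"w_maint = {float(model.w[0])!r}\n"
        f"w_exchpart = {float(model.w[1])!r}\n"
        f"w_exchpair = {float(model.w[2])!r}\n"
        f"w_new = {float(model.w[3])!r}\n"
        f"b = {float(model.b)!r}\n"
    )


def read_model(path: str | Path) -> LogisticModel:
    values: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        k, v = line.split("=", 1)
        values[k.strip()] = v.strip()
    try:
        w = np.asarray(
            [
                float(values["w_maint"]),
                float(values["w_exchpart"]),
                float(values["w_exchpair"]),
                float(values["w_new"]),
            ]
        )
        return LogisticModel(w=w, b=float(values["b"]))
    except KeyError as exc:
        raise ValueError(f"model file missing key {exc}") from exc
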