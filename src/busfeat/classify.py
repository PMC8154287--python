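"""Feature normalization, fusion and RBF-SVM classification.

Characteristic features (CF, the four handcrafted scores) and optional
externally computed deep-learning feature vectors (DLF) are fused serially
(CF first, then DLF), min-max normalized per feature, and classified with a
soft-margin SVM using the Gaussian kernel K(u, v) = exp(-g * ||u - v||^2).
The regularization constant c and kernel width g are chosen by 3-fold
stratified grid-search cross-validation; labels are 1 = malignant,
0 = benign.

Normalization is plain min-max fitted on the training set, with an explicit
per-feature direction: standard maps min -> 0, max -> 1; inverted maps
max -> 0, min -> 1 (used for the shape-complexity slope, where more
negative means more complex).  Test-time values outside the training range
extrapolate linearly rather than clip, keeping the map affine; such values
are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn import metrics as skmetrics
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationParams",
    "SVMConfig",
    "TrainedModel",
    "EvalMetrics",
    "DEFAULT_DIRECTIONS",
    "fit_normalizer",
    "apply_normalizer",
    "fuse",
    "cross_validate_grid",
    "train_svm",
    "confusion",
    "metrics",
    "roc_auc",
]

# SC slope is inverted (more negative slope = more complex = "larger" feature);
# everything else, including any DLF column, normalizes in the standard direction.
DEFAULT_DIRECTIONS = {"sc_score": "inverted"}

_POW2_GRID = tuple(2.0**k for k in range(-5, 6))


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature training min/max and mapping direction."""

    names: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray
    directions: tuple[str, ...]


@dataclass(frozen=True)
class SVMConfig:
    """Grid-search configuration (3-fold stratified CV by default)."""

    c_grid: tuple[float, ...] = _POW2_GRID
    g_grid: tuple[float, ...] = _POW2_GRID
    folds: int = 3
    seed: int = 0

    def validate(self) -> None:
        if not self.c_grid or not self.g_grid:
            raise ValueError("empty parameter grid")
        if min(self.c_grid) <= 0 or min(self.g_grid) <= 0:
            raise ValueError("c and g must be positive")


@dataclass
class TrainedModel:
    """Fitted SVM with its chosen (c, g) and the attached normalizer."""

    c: float
    g: float
    svc: SVC
    normalizer: NormalizationParams | None
    training_accuracy: float

    def decision_scores(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.normalizer is not None:
            x = apply_normalizer(self.normalizer, x)
        return self.svc.decision_function(x)

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.normalizer is not None:
            x = apply_normalizer(self.normalizer, x)
        return self.svc.predict(x).astype(int)


@dataclass(frozen=True)
class EvalMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float | None
    specificity: float | None
    accuracy: float
    precision: float | None
    f1: float | None
    auc: float | None = None

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy, "precision": self.precision,
            "f1": self.f1, "auc": self.auc,
        }


# ------------------------------------------------------------ normalization

def fit_normalizer(matrix: np.ndarray, names: tuple[str, ...] | list[str],
                   directions: dict[str, str] | None = None) -> NormalizationParams:
    """Per-feature min/max from the fitting set, with direction flags.

    ``directions`` maps feature name to "standard" or "inverted"; features
    not mentioned use the defaults (inverted for ``sc_score``, standard
    otherwise).  A constant feature cannot be normalized and is an error.
    """
    x = np.asarray(matrix, dtype=float)
    names = tuple(names)
    if x.ndim != 2 or x.shape[1] != len(names):
        raise ValueError("matrix columns must match feature names")
    dirs = dict(DEFAULT_DIRECTIONS)
    dirs.update(directions or {})
    mins = x.min(axis=0)
    maxs = x.max(axis=0)
    for i, name in enumerate(names):
        if maxs[i] <= mins[i]:
            raise ValueError(f"feature {name!r} is constant; min-max undefined")
    return NormalizationParams(
        names=names, mins=mins, maxs=maxs,
        directions=tuple(dirs.get(n, "standard") for n in names),
    )


def apply_normalizer(params: NormalizationParams, matrix: np.ndarray) -> np.ndarray:
    """Affine min-max map; out-of-range values extrapolate (and are logged)."""
    x = np.asarray(matrix, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != len(params.names):
        raise ValueError(
            f"matrix has {x.shape[1]} features, normalizer expects {len(params.names)}"
        )
    span = params.maxs - params.mins
    out = (x - params.mins) / span
    for i, d in enumerate(params.directions):
        if d == "inverted":
            out[:, i] = 1.0 - out[:, i]
        elif d != "standard":
            raise ValueError(f"unknown direction {d!r}")
    oob = (out < 0) | (out > 1)
    if oob.any():
        bad = [params.names[i] for i in np.unique(np.nonzero(oob)[1])]
        logger.warning(
            "%d normalized values outside [0, 1] (features %s); "
            "extrapolating linearly", int(oob.sum()), ", ".join(bad),
        )
    return out


# ------------------------------------------------------------------ fusion

def fuse(cf: np.ndarray, dlf: np.ndarray | None = None) -> np.ndarray:
    """Serial multi-feature vector: the 4 CF values followed by the DLF."""
    cf = np.asarray(cf, dtype=float).ravel()
    if cf.size != 4:
        raise ValueError("CF vector must have exactly 4 entries")
    if dlf is None:
        dlf = np.empty(0)
    dlf = np.asarray(dlf, dtype=float).ravel()
    out = np.concatenate([cf, dlf])
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite entries in the fused feature vector")
    return out


# --------------------------------------------------------------------- SVM

def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).astype(int)
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be 0 (benign) or 1 (malignant)")
    return y


def cross_validate_grid(x: np.ndarray, y: np.ndarray,
                        config: SVMConfig | None = None
                        ) -> tuple[float, float, np.ndarray]:
    """Stratified k-fold grid search; returns (best c, best g, accuracy surface).

    The surface has shape (len(c_grid), len(g_grid)) and holds mean
    validation accuracy over the folds.  Ties are broken toward the smallest
    c, then the smallest g (prefer the simpler model).
    """
    cfg = config or SVMConfig()
    cfg.validate()
    x = np.asarray(x, dtype=float)
    y = _check_labels(y)
    counts = np.bincount(y, minlength=2)
    if counts.min() < cfg.folds:
        raise ValueError(
            f"each class needs >= {cfg.folds} samples for {cfg.folds}-fold "
            "stratified CV; got " + str(dict(enumerate(counts)))
        )
    skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
    folds = list(skf.split(x, y))
    for _, val in folds:
        if len(np.unique(y[val])) < 2:
            raise ValueError("a validation fold is missing a class; "
                             "stratify or add data")
    surface = np.zeros((len(cfg.c_grid), len(cfg.g_grid)))
    for i, c in enumerate(cfg.c_grid):
        for j, g in enumerate(cfg.g_grid):
            accs = []
            for train, val in folds:
                svc = SVC(C=c, gamma=g, kernel="rbf")
                svc.fit(x[train], y[train])
                accs.append(float(np.mean(svc.predict(x[val]) == y[val])))
            surface[i, j] = float(np.mean(accs))
    best_i, best_j = np.unravel_index(int(np.argmax(surface)), surface.shape)
    # argmax returns the first maximum in row-major order, which with sorted
    # grids is already smallest-c-then-smallest-g — assert the grids are sorted
    return float(cfg.c_grid[best_i]), float(cfg.g_grid[best_j]), surface


def train_svm(x: np.ndarray, y: np.ndarray, c: float, g: float,
              normalizer: NormalizationParams | None = None) -> TrainedModel:
    """Fit the soft-margin RBF-SVM at fixed (c, g)."""
    x = np.asarray(x, dtype=float)
    y = _check_labels(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels are degenerate (single class)")
    xn = apply_normalizer(normalizer, x) if normalizer is not None else x
    svc = SVC(C=c, gamma=g, kernel="rbf")
    svc.fit(xn, y)
    train_acc = float(np.mean(svc.predict(xn) == y))
    return TrainedModel(c=float(c), g=float(g), svc=svc,
                        normalizer=normalizer, training_accuracy=train_acc)


# ----------------------------------------------------------------- metrics

def confusion(pred: np.ndarray, truth: np.ndarray) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) with malignant (1) as the positive class."""
    pred = _check_labels(np.asarray(pred))
    truth = _check_labels(np.asarray(truth))
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth lengths differ")
    tp = int(np.sum((pred == 1) & (truth == 1)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    tn = int(np.sum((pred == 0) & (truth == 0)))
    return tp, fp, fn, tn


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def metrics(tp: int, fp: int, fn: int, tn: int) -> EvalMetrics:
    """Sensitivity, specificity, accuracy, precision, F1 from the counts.

    Ratios with a zero denominator (for example precision with no positive
    predictions) are reported as missing (None), never coerced to 0.
    """
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("negative counts")
    n = tp + fp + fn + tn
    if n == 0:
        raise ValueError("empty confusion matrix")
    return EvalMetrics(
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        accuracy=(tp + tn) / n,
        precision=_ratio(tp, tp + fp),
        f1=_ratio(2 * tp, 2 * tp + fp + fn),
    )


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) over the full threshold sweep, and the AUC.

    The trapezoidal AUC equals the Mann-Whitney rank statistic with ties
    averaged.
    """
    scores = np.asarray(scores, dtype=float)
    truth = _check_labels(np.asarray(truth))
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite decision scores")
    if len(np.unique(truth)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = skmetrics.roc_curve(truth, scores)
    auc = float(skmetrics.auc(fpr, tpr))
    return np.column_stack([fpr, tpr]), auc
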