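"""Calibrated multi-classifier ensemble with cross-modality late fusion.

One ensemble is trained per feature set.  The pipeline for a train/test
split is:

1. z-score standardization fitted on the training rows (zero-variance
   features dropped);
2. SMOTE oversampling of the minority class (training folds only);
3. five fixed base classifiers — linear SVM, logistic regression, gradient
   boosting, AdaBoost, random forest — with standard hyperparameters and
   fixed seeds;
4. per classifier, an internal cross-validation on the training set yields
   out-of-fold probabilities whose minimum, maximum and geometric-mean-optimal
   threshold define a piecewise-linear calibration map sending
   ``[min, thr] -> [0, 0.5]`` and ``[thr, max] -> [0.5, 1]``;
5. the five calibrated test probabilities are averaged into the feature-set
   score; feature-set scores are averaged (late fusion) into the final
   prediction, positive iff the fused score >= 0.5.

The calibration step makes heterogeneous classifiers commensurable before
averaging: 0.5 always means "at this classifier's own operating point".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleConfig",
    "CalibrationParams",
    "zscore_fit_apply",
    "smote_oversample",
    "calibration_fit",
    "calibrate",
    "make_base_classifiers",
    "fit_predict_feature_set",
    "late_fuse",
    "fuse_multiclass",
]

DEFAULT_CLASSIFIERS = ("svm_linear", "logreg", "gboost", "adaboost", "rforest")


@dataclass(frozen=True)
class EnsembleConfig:
    """Knobs of the ensemble pipeline.

    ``calibration_cv`` is ``"loo"`` (internal leave-one-out, the default) or
    an integer k for a stratified k-fold fast mode on larger samples.
    """

    seed: int = 0
    calibration_cv: str | int = "loo"
    smote_k: int = 5
    classifiers: tuple[str, ...] = DEFAULT_CLASSIFIERS
    fusion: str = "average"  # "average" of calibrated scores, or "majority"


@dataclass(frozen=True)
class CalibrationParams:
    p_min: float
    p_thr: float
    p_max: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (self.p_min <= self.p_thr <= self.p_max):
            raise ValueError("require p_min <= p_thr <= p_max")


def zscore_fit_apply(
    train: pd.DataFrame, test: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize per feature with training statistics (population STD).

    Zero-variance training features are dropped from both tables; test
    features absent from the training table are an error (schema mismatch).
    """
    if len(train) < 2:
        raise ValueError("need at least 2 training rows")
    missing = set(test.columns) - set(train.columns)
    if missing:
        raise ValueError(f"test features absent from training table: {sorted(missing)[:5]}")
    test = test[train.columns]
    mean = train.mean(axis=0)
    std = train.std(axis=0, ddof=0)
    keep = std > 0
    cols = train.columns[keep]
    train_z = (train[cols] - mean[cols]) / std[cols]
    test_z = (test[cols] - mean[cols]) / std[cols]
    return train_z, test_z


def smote_oversample(
    X: np.ndarray, y: np.ndarray, k: int = 5, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Upsample the minority class to the majority count by interpolation.

    Each synthetic point is a convex combination of a minority sample and one
    of its k nearest minority neighbours.  ``k`` shrinks to ``minority - 1``
    when the minority class is small; a singleton minority class falls back
    to duplication with small jitter (logged).
    """
    rng = rng or np.random.default_rng(0)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("smote_oversample requires exactly 2 classes")
    if counts[0] == counts[1]:
        return X.copy(), y.copy()
    minority = classes[np.argmin(counts)]
    n_needed = int(abs(counts[0] - counts[1]))
    Xm = X[y == minority]
    if len(Xm) == 1:
        logger.warning("singleton minority class: duplicating with jitter")
        synth = np.repeat(Xm, n_needed, axis=0) + rng.normal(
            0.0, 1e-3, size=(n_needed, X.shape[1])
        )
    else:
        k_eff = min(k, len(Xm) - 1)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xm)
        _, idx = nn.kneighbors(Xm)  # first neighbour is the point itself
        base = rng.integers(0, len(Xm), size=n_needed)
        steps = rng.random(n_needed)
        neigh = idx[base, rng.integers(1, k_eff + 1, size=n_needed)]
        synth = Xm[base] + steps[:, None] * (Xm[neigh] - Xm[base])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    return X_out, y_out


def calibration_fit(oof_probs, labels) -> CalibrationParams:
    """Calibration parameters from out-of-fold training probabilities.

    Candidate thresholds are midpoints between consecutive distinct
    probabilities; the one maximizing the geometric mean of sensitivity and
    specificity wins, ties going to the smallest threshold.
    """
    p = np.asarray(oof_probs, dtype=float)
    y = np.asarray(labels).astype(int)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("probs and labels must be equal-length 1-D")
    if np.unique(y).size < 2:
        raise ValueError("both classes required to fit calibration")
    uniq = np.unique(p)
    if uniq.size == 1:
        warnings.warn("degenerate single-valued probabilities")
        v = float(uniq[0])
        return CalibrationParams(v, v, v, degenerate=True)
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos = int(np.sum(y == 1))
    n_neg = y.size - n_pos
    best_g, best_t = -1.0, None
    for t in candidates:  # ascending: first strict max = smallest threshold
        pred = p >= t
        sen = np.sum(pred & (y == 1)) / n_pos
        spe = np.sum(~pred & (y == 0)) / n_neg
        g = np.sqrt(sen * spe)
        if g > best_g + 1e-12:
            best_g, best_t = g, float(t)
    return CalibrationParams(float(uniq[0]), best_t, float(uniq[-1]))


def calibrate(p, params: CalibrationParams):
    """Map raw probabilities through the piecewise-linear calibration.

    ``[p_min, p_thr] -> [0, 0.5]`` and ``[p_thr, p_max] -> [0.5, 1]``;
    inputs outside the training range are clipped.  Degenerate parameters
    (all three anchors equal) map everything to 0.5.
    """
    p_arr = np.asarray(p, dtype=float)
    if params.p_min == params.p_max:
        out = np.full_like(p_arr, 0.5)
    else:
        xp, fp = [], []
        for x, f in ((params.p_min, 0.0), (params.p_thr, 0.5), (params.p_max, 1.0)):
            if not xp or x > xp[-1]:
                xp.append(x)
                fp.append(f)
            else:  # collapsed segment: the threshold anchor wins
                fp[-1] = max(fp[-1], 0.5) if f == 0.5 else fp[-1]
        if xp[0] == params.p_thr:
            fp[0] = 0.5
        out = np.interp(np.clip(p_arr, params.p_min, params.p_max), xp, fp)
    return float(out) if np.isscalar(p) else out


def make_base_classifiers(seed: int) -> dict[str, object]:
    """The five fixed base classifiers with standard hyperparameters."""
    return {
        "svm_linear": SVC(kernel="linear", C=1.0, random_state=seed),
        "logreg": LogisticRegression(C=1.0, max_iter=1000, random_state=seed),
        "gboost": GradientBoostingClassifier(
            n_estimators=100, max_depth=3, random_state=seed
        ),
        "adaboost": AdaBoostClassifier(n_estimators=50, random_state=seed),
        "rforest": RandomForestClassifier(n_estimators=100, random_state=seed),
    }


def _positive_prob(clf, X: np.ndarray) -> np.ndarray:
    """P(class 1); linear SVMs use a logistic link on decision values."""
    if hasattr(clf, "predict_proba"):
        col = int(np.flatnonzero(clf.classes_ == 1)[0])
        return clf.predict_proba(X)[:, col]
    d = clf.decision_function(X)
    if clf.classes_[1] != 1:
        d = -d
    return expit(d)


def _internal_splits(y: np.ndarray, config: EnsembleConfig):
    if config.calibration_cv == "loo":
        return list(LeaveOneOut().split(np.zeros_like(y), y))
    k = int(config.calibration_cv)
    k = min(k, int(np.min(np.bincount(y))))
    k = max(k, 2)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    return list(skf.split(np.zeros_like(y), y))


def fit_predict_feature_set(
    train: pd.DataFrame,
    y_train: np.ndarray,
    test: pd.DataFrame,
    config: EnsembleConfig | None = None,
) -> np.ndarray:
    """Calibrated ensemble score in [0, 1] for each test row of one feature set.

    Any base classifier that fails to fit is excluded from the average and
    logged; at least one must succeed.
    """
    config = config or EnsembleConfig()
    y_train = np.asarray(y_train).astype(int)
    if np.unique(y_train).size < 2:
        raise ValueError("training labels must contain both classes")
    train_z, test_z = zscore_fit_apply(train, test)
    Xtr = train_z.to_numpy(dtype=float)
    Xte = test_z.to_numpy(dtype=float)
    rng = np.random.default_rng(config.seed)
    splits = _internal_splits(y_train, config)

    calibrated = []
    for name, proto in make_base_classifiers(config.seed).items():
        if name not in config.classifiers:
            continue
        try:
            oof = np.empty(y_train.size)
            ok = np.zeros(y_train.size, dtype=bool)
            for tr_idx, te_idx in splits:
                y_in = y_train[tr_idx]
                if np.unique(y_in).size < 2:
                    continue
                X_in, y_b = smote_oversample(
                    Xtr[tr_idx], y_in, k=config.smote_k, rng=rng
                )
                clf = clone(proto).fit(X_in, y_b)
                oof[te_idx] = _positive_prob(clf, Xtr[te_idx])
                ok[te_idx] = True
            params = calibration_fit(oof[ok], y_train[ok])
            X_full, y_full = smote_oversample(Xtr, y_train, k=config.smote_k, rng=rng)
            final = clone(proto).fit(X_full, y_full)
            calibrated.append(calibrate(_positive_prob(final, Xte), params))
        except Exception:  # noqa: BLE001 - a failed member must not sink the ensemble
            logger.exception("base classifier %s failed; excluded from ensemble", name)
    if not calibrated:
        raise RuntimeError("all base classifiers failed")
    return np.mean(np.vstack(calibrated), axis=0)


def late_fuse(scores: dict[str, float], mode: str = "average") -> tuple[float, int]:
    """Fuse per-feature-set calibrated scores into a final score and class.

    ``average``: unweighted mean, positive iff >= 0.5.  ``majority``: strict
    vote of the per-set 0.5 decisions (score reported is the positive-vote
    fraction).  Sets with missing recordings simply do not contribute.
    """
    vals = [v for v in scores.values() if v is not None and not np.isnan(v)]
    if not vals:
        raise ValueError("no available feature-set scores for this subject")
    if mode == "majority":
        frac = float(np.mean([v >= 0.5 for v in vals]))
        return frac, int(frac >= 0.5)
    score = float(np.mean(vals))
    return score, int(score >= 0.5)


def fuse_multiclass(
    class_scores: dict[str, float], order: tuple[str, ...] = ("SCZ", "MDD", "HC")
) -> str:
    """Argmax over one-vs-rest fused scores; ties resolved by fixed order."""
    best, best_v = None, -np.inf
    for cls in order:
        v = class_scores.get(cls, -np.inf)
        if v > best_v + 1e-12:
            best, best_v = cls, v
    return best
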