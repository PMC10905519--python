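"""On-target activity models: information-gain ranking, forward feature
selection, SVM training with grid search, calibration, and persistence.

Two fully independent models are trained, one per editing mechanism
(CRISPRko / CRISPRi), because the guide preferences of the two mechanisms
differ (promoter-proximal placement and mid-spacer composition matter for
CRISPRi; terminal guanine and folding energy for CRISPRko). Features are
ranked by total split gain of a gradient-boosted tree ensemble, introduced
one by one in rank order, and the prefix maximizing mean cross-validated
F1 is kept. The SVM (RBF) hyperparameters come from a grid search under
10-fold cross-validation; class imbalance is repaired by SMOTE applied
inside each training fold only (``paper_mode=True`` instead oversamples
once globally before splitting, which mixes synthetic points into
validation folds but matches the common published ordering).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .dataset_builder import smote_oversample, stratified_kfold_split
from .guide_features import FEATURE_NAMES, N_FEATURES, FeatureVector, registry_hash

MODEL_FORMAT_VERSION = "lncguide-model-1"

DEFAULT_GRID = {"C": (0.1, 1.0, 10.0, 100.0), "gamma": (0.001, 0.01, 0.1, 1.0)}
BOOSTER_SETTINGS = dict(n_estimators=200, max_depth=4, learning_rate=0.1)


@dataclass(frozen=True)
class FeatureRanking:
    """Feature names ordered by descending information gain; ties broken by
    registry order (recorded in ``tie_rule``)."""

    order: tuple[str, ...]
    gains: tuple[float, ...]
    tie_rule: str = "registry_order"

    def __post_init__(self) -> None:
        if sorted(self.order) != sorted(FEATURE_NAMES):
            raise ValueError("ranking must be a permutation of the feature registry")
        if any(g < 0 or not np.isfinite(g) for g in self.gains):
            raise ValueError("gains must be finite and non-negative")


@dataclass
class TrainedModel:
    mechanism: str
    selected_features: tuple[str, ...]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    svm: SVC
    calibrator: LogisticRegression
    cv_record: list[dict]
    best_params: dict
    seed: int
    registry_hash: str = field(default_factory=registry_hash)

    def _columns(self) -> list[int]:
        return [FEATURE_NAMES.index(f) for f in self.selected_features]

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        Xs = (X[:, self._columns()] - self.scaler_mean) / self.scaler_scale
        return self.svm.decision_function(Xs)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        d = self.decision_values(X)
        return self.calibrator.predict_proba(d.reshape(-1, 1))[:, 1]


def rank_features_information_gain(
    X: np.ndarray, y: np.ndarray, seed: int = 0
) -> FeatureRanking:
    """Rank features by total split gain of a boosted tree ensemble
    (200 trees, depth 4, learning rate 0.1); constant or unused columns get
    gain 0 and fall back to registry order."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != N_FEATURES:
        raise ValueError(f"X must have {N_FEATURES} columns in registry order")
    clf = XGBClassifier(
        **BOOSTER_SETTINGS,
        random_state=seed,
        n_jobs=1,
        tree_method="exact",
        eval_metric="logloss",
    )
    clf.fit(X, np.asarray(y))
    raw = clf.get_booster().get_score(importance_type="total_gain")
    gains = np.zeros(N_FEATURES)
    for key, g in raw.items():
        gains[int(key[1:])] = g  # keys are "f0".."f26" in column order
    order = sorted(range(N_FEATURES), key=lambda i: (-gains[i], i))
    return FeatureRanking(
        tuple(FEATURE_NAMES[i] for i in order),
        tuple(float(gains[i]) for i in order),
    )


def _fold_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    return {
        "precision": float(precision_score(y_true, y_pred, zero_division=0)),
        "recall": float(recall_score(y_true, y_pred, zero_division=0)),
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "f1": float(f1_score(y_true, y_pred, zero_division=0)),
    }


def _cv_f1(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    gamma: float,
    k_folds: int,
    seed: int,
    smote_in_fold: bool,
) -> tuple[float, list[dict]]:
    """Mean CV F1 of an RBF SVM; standardization and (optionally) SMOTE are
    fit on each training fold only — the validation fold never leaks into
    either."""
    folds = stratified_kfold_split(y, k=k_folds, seed=seed)
    record = []
    for fold_no, (tr, te) in enumerate(folds):
        ytr = y[tr]
        if len(np.unique(ytr)) < 2 or len(np.unique(y[te])) < 2:
            raise ValueError(f"fold {fold_no}: degenerate single-class split")
        Xtr, ytr2 = X[tr], ytr
        if smote_in_fold and len(np.unique(ytr)) == 2:
            cnt = np.bincount(ytr)
            if cnt.min() != cnt.max() and cnt[cnt > 0].min() >= 2:
                Xtr, ytr2 = smote_oversample(Xtr, ytr, seed=seed + fold_no)
        scaler = StandardScaler().fit(Xtr)
        clf = SVC(C=C, gamma=gamma, kernel="rbf")
        clf.fit(scaler.transform(Xtr), ytr2)
        pred = clf.predict(scaler.transform(X[te]))
        record.append(_fold_metrics(y[te], pred))
    return float(np.mean([r["f1"] for r in record])), record


def forward_select_features(
    ranking: FeatureRanking,
    X: np.ndarray,
    y: np.ndarray,
    k_folds: int = 10,
    seed: int = 0,
    C: float = 1.0,
    gamma: str | float = "scale",
    smote_in_fold: bool = True,
) -> tuple[tuple[str, ...], list[float]]:
    """Introduce features in gain order, one at a time, scoring each prefix
    by mean CV F1; return the earliest prefix attaining the maximum and the
    full 27-point F1 curve.

    The selection loop uses a fixed mid-grid SVM (C=1, gamma='scale'); the
    final hyperparameters are chosen afterwards by ``grid_search_train`` on
    the selected prefix.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    cols = [FEATURE_NAMES.index(f) for f in ranking.order]
    curve: list[float] = []
    for m in range(1, N_FEATURES + 1):
        Xm = X[:, cols[:m]]
        g = gamma if isinstance(gamma, str) else float(gamma)
        try:
            f1, _ = _cv_f1(Xm, y, C, g, k_folds, seed, smote_in_fold)
        except ValueError as err:
            raise ValueError(f"forward selection failed at m={m}: {err}") from err
        curve.append(f1)
    best_m = int(np.argmax(curve)) + 1  # argmax returns the earliest maximum
    return tuple(ranking.order[:best_m]), curve


def grid_search_train(
    X: np.ndarray,
    y: np.ndarray,
    mechanism: str,
    selected_features: tuple[str, ...] | None = None,
    grid: dict | None = None,
    k_folds: int = 10,
    seed: int = 0,
    smote_in_fold: bool = True,
    paper_mode: bool = False,
) -> TrainedModel:
    """Grid-search an RBF SVM with k-fold CV, refit on all data, and fit a
    monotone sigmoid calibration from decision values to probabilities.

    ``paper_mode`` oversamples globally with SMOTE before splitting instead
    of inside each training fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if mechanism not in ("CRISPRko", "CRISPRi"):
        raise ValueError("mechanism must be CRISPRko or CRISPRi")
    feats = selected_features or FEATURE_NAMES
    cols = [FEATURE_NAMES.index(f) for f in feats]
    Xf = X[:, cols]
    if paper_mode:
        cnt = np.bincount(y)
        if cnt.min() != cnt.max():
            Xf, y = smote_oversample(Xf, y, seed=seed)
        smote_in_fold = False
    g = grid or DEFAULT_GRID
    best: tuple[float, float, float, list[dict]] | None = None
    for C in g["C"]:
        for gamma in g["gamma"]:
            f1, record = _cv_f1(Xf, y, C, gamma, k_folds, seed, smote_in_fold)
            if best is None or f1 > best[0]:
                best = (f1, C, gamma, record)
    assert best is not None
    _, C, gamma, record = best
    # final refit on all data (with SMOTE balance when used in folds)
    Xfit, yfit = Xf, y
    if smote_in_fold:
        cnt = np.bincount(y)
        if cnt.min() != cnt.max() and cnt[cnt > 0].min() >= 2:
            Xfit, yfit = smote_oversample(Xf, y, seed=seed)
    scaler = StandardScaler().fit(Xfit)
    svm = SVC(C=C, gamma=gamma, kernel="rbf")
    svm.fit(scaler.transform(Xfit), yfit)
    d = svm.decision_function(scaler.transform(Xf))
    calib = LogisticRegression()
    calib.fit(d.reshape(-1, 1), y)
    if calib.coef_[0, 0] < 0:  # enforce monotone increasing map
        raise RuntimeError("calibration map non-monotone in decision value")
    return TrainedModel(
        mechanism=mechanism,
        selected_features=tuple(feats),
        scaler_mean=scaler.mean_.copy(),
        scaler_scale=scaler.scale_.copy(),
        svm=svm,
        calibrator=calib,
        cv_record=record,
        best_params={"C": C, "gamma": gamma},
        seed=seed,
    )


def predict_ontarget(model: TrainedModel, fv: FeatureVector | np.ndarray) -> tuple[str, float]:
    """Calibrated activity probability and efficient/inefficient call
    (efficient iff p_on > 0.5)."""
    x = fv.as_array() if isinstance(fv, FeatureVector) else np.asarray(fv, dtype=float)
    p = float(model.predict_proba(x.reshape(1, -1))[0])
    return ("efficient" if p > 0.5 else "inefficient", p)


def minmax_normalize_scores(scores) -> tuple[np.ndarray, np.ndarray]:
    """Max-min normalization to [0,1] with the recommended mask at
    normalized score strictly greater than 0.5."""
    s = np.asarray(scores, dtype=float)
    if s.size < 2 or np.ptp(s) == 0:
        raise ValueError("normalization undefined: need >= 2 distinct scores")
    norm = (s - s.min()) / np.ptp(s)
    return norm, norm > 0.5


def save_model(model: TrainedModel, path: str | Path) -> None:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "registry_hash": model.registry_hash,
        "mechanism": model.mechanism,
        "selected_features": list(model.selected_features),
        "scaler_mean": model.scaler_mean,
        "scaler_scale": model.scaler_scale,
        "svm": model.svm,
        "calibrator": model.calibrator,
        "cv_record_json": json.dumps(model.cv_record),
        "best_params": model.best_params,
        "seed": model.seed,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: model format {payload.get('format_version')!r} != "
            f"{MODEL_FORMAT_VERSION!r}"
        )
    if payload["registry_hash"] != registry_hash():
        raise ValueError(f"{path}: feature registry hash mismatch")
    return TrainedModel(
        mechanism=payload["mechanism"],
        selected_features=tuple(payload["selected_features"]),
        scaler_mean=payload["scaler_mean"],
        scaler_scale=payload["scaler_scale"],
        svm=payload["svm"],
        calibrator=payload["calibrator"],
        cv_record=json.loads(payload["cv_record_json"]),
        best_params=payload["best_params"],
        seed=payload["seed"],
        registry_hash=payload["registry_hash"],
    )
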