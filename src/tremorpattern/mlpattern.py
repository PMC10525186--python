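"""Importance-ranked incremental feature selection and model evaluation.

The learning procedure:

1. stratified 50/50 split of the labeled feature table into a training
   and a testing half;
2. rank all 63 features by model-specific importance computed on the
   training half (Random Forest: mean impurity decrease; XGBoost: gain);
3. train models on growing prefixes of the ranking (k = 1 … 63), evaluate
   each on the testing half, and keep the prefix with the highest testing
   accuracy (smallest k on ties);
4. characterize the selected model with repeated stratified 5-fold
   cross-validation on the training half (5 repeats × 5 folds = 25
   evaluation rows) and a full metrics report on the testing half.

The positive class throughout is "A" (alternating pattern).
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split

from .segmentio import FEATURE_NAMES, ModelArtifact, SegmentRecord

POSITIVE_CLASS = "A"

RF_DEFAULTS = {"mtry": 1, "n_trees": 500}
XGB_DEFAULTS = {
    "nrounds": 300, "max_depth": 4, "eta": 0.05, "gamma": 0.0,
    "colsample_bytree": 0.4, "min_child_weight": 1, "subsample": 0.75,
}


@dataclass
class TrainConfig:
    algorithm: str = "RF"               # "RF" or "XGB"
    hyperparameters: dict = field(default_factory=dict)
    cv_folds: int = 5
    cv_repeats: int = 5
    split_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("RF", "XGB"):
            raise ValueError("algorithm must be 'RF' or 'XGB'")
        defaults = RF_DEFAULTS if self.algorithm == "RF" else XGB_DEFAULTS
        self.hyperparameters = {**defaults, **self.hyperparameters}

    def _derived_seed(self, stream: int) -> int:
        ss = np.random.SeedSequence(self.seed, spawn_key=(stream,))
        return int(ss.generate_state(1)[0] % (2 ** 31))

    @property
    def split_seed(self) -> int:
        return self._derived_seed(0)

    @property
    def model_seed(self) -> int:
        return self._derived_seed(1)

    @property
    def cv_seed(self) -> int:
        return self._derived_seed(2)


def make_estimator(cfg: TrainConfig):
    hp = cfg.hyperparameters
    if cfg.algorithm == "RF":
        return RandomForestClassifier(
            n_estimators=int(hp["n_trees"]),
            max_features=int(hp["mtry"]),
            random_state=cfg.model_seed,
            n_jobs=1,
        )
    from xgboost import XGBClassifier

    return XGBClassifier(
        n_estimators=int(hp["nrounds"]),
        max_depth=int(hp["max_depth"]),
        learning_rate=float(hp["eta"]),
        gamma=float(hp["gamma"]),
        colsample_bytree=float(hp["colsample_bytree"]),
        min_child_weight=float(hp["min_child_weight"]),
        subsample=float(hp["subsample"]),
        importance_type="gain",
        random_state=cfg.model_seed,
        n_jobs=1,
        eval_metric="logloss",
        verbosity=0,
    )


def _xy(ft: pd.DataFrame, subset: list[str] | None = None):
    cols = list(subset) if subset else list(FEATURE_NAMES)
    X = ft[cols].to_numpy(dtype=float)
    y = (ft["label"] == POSITIVE_CLASS).to_numpy(dtype=int)
    return X, y


# ---------------------------------------------------------------------------
# Splitting and ranking
# ---------------------------------------------------------------------------

def split_dataset(ft: pd.DataFrame, cfg: TrainConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified 50/50 split (per-class proportions preserved within ±1)."""
    counts = ft["label"].value_counts()
    if counts.min() < 2 or len(counts) < 2:
        raise ValueError("need both classes with >= 2 segments to split")
    train, test = train_test_split(
        ft,
        test_size=1.0 - cfg.split_fraction,
        stratify=ft["label"],
        random_state=cfg.split_seed,
    )
    return train.reset_index(drop=True), test.reset_index(drop=True)


def rank_features(train: pd.DataFrame, cfg: TrainConfig) -> list[str]:
    """All 63 feature names sorted by decreasing importance (ties: A→Z)."""
    if set(train["label"].unique()) - {"A", "S"}:
        raise ValueError("training table must be labeled A/S")
    X, y = _xy(train)
    est = make_estimator(cfg)
    est.fit(X, y)
    importances = np.asarray(est.feature_importances_, dtype=float)
    order = sorted(range(len(FEATURE_NAMES)),
                   key=lambda i: (-importances[i], FEATURE_NAMES[i]))
    return [FEATURE_NAMES[i] for i in order]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    n = tp + fn + fp + tn
    p_o = (tp + tn) / n
    p_e = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / n ** 2
    kappa = (p_o - p_e) / (1 - p_e) if p_e < 1 else 1.0
    div = lambda a, b: a / b if b else float("nan")
    return {
        "tp": tp, "fn": fn, "fp": fp, "tn": tn,
        "accuracy": p_o,
        "kappa": kappa,
        "sensitivity": div(tp, tp + fn),
        "specificity": div(tn, tn + fp),
        "ppv": div(tp, tp + fp),
        "npv": div(tn, tn + fn),
    }


def _clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def _roc_auc(y_true: np.ndarray, prob: np.ndarray):
    fpr, tpr, thr = roc_curve(y_true, prob)
    return fpr, tpr, thr, float(_auc(fpr, tpr))


def _calibration_bins(y_true: np.ndarray, prob: np.ndarray, n_bins: int = 10) -> list[dict]:
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bins = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (prob >= lo) & (prob < hi if hi < 1.0 else prob <= hi)
        if mask.sum() == 0:
            continue
        bins.append({
            "mean_predicted": float(np.mean(prob[mask])),
            "observed_rate": float(np.mean(y_true[mask])),
            "n": int(mask.sum()),
        })
    return bins


def evaluate(artifact: ModelArtifact, test: pd.DataFrame) -> dict:
    """Full metrics report of a trained model on a labeled feature table."""
    if len(test) == 0:
        raise ValueError("empty test set")
    X, y = _xy(test, artifact.feature_subset)
    prob = artifact.fitted_model.predict_proba(X)[:, 1]
    y_pred = (prob >= 0.5).astype(int)
    rep = _confusion_metrics(y, y_pred)
    k = rep["tp"] + rep["tn"]
    rep["accuracy_ci95"] = _clopper_pearson(k, len(y))
    fpr, tpr, thr, auc_val = _roc_auc(y, prob)
    rep["auc"] = auc_val
    rep["roc_points"] = [
        {"fpr": float(a), "tpr": float(b), "threshold": float(c)}
        for a, b, c in zip(fpr, tpr, thr)
    ]
    rep["calibration_bins"] = _calibration_bins(y, prob)
    rep["n"] = int(len(y))
    return rep


# ---------------------------------------------------------------------------
# Cross-validation and incremental training
# ---------------------------------------------------------------------------

def cross_validate(train: pd.DataFrame, subset: list[str], cfg: TrainConfig) -> dict:
    """Repeated stratified k-fold CV (5 × 5 → 25 fold rows by default).

    Each fold trains on 80% of the training half and validates on the held
    20%.  Returns per-fold accuracy/kappa/sensitivity/specificity, their
    mean and SD, and the mean per-fold validation AUC.
    """
    if not subset:
        raise ValueError("empty feature subset")
    X, y = _xy(train, subset)
    rskf = RepeatedStratifiedKFold(
        n_splits=cfg.cv_folds, n_repeats=cfg.cv_repeats, random_state=cfg.cv_seed
    )
    fold_rows, aucs = [], []
    for fold_idx, (tr, va) in enumerate(rskf.split(X, y), start=1):
        est = make_estimator(cfg)
        est.fit(X[tr], y[tr])
        prob = est.predict_proba(X[va])[:, 1]
        rep = _confusion_metrics(y[va], (prob >= 0.5).astype(int))
        rep["fold"] = fold_idx
        if len(np.unique(y[va])) == 2:
            aucs.append(_roc_auc(y[va], prob)[3])
        fold_rows.append(rep)
    folds = pd.DataFrame(fold_rows)
    metrics = ["accuracy", "kappa", "sensitivity", "specificity"]
    return {
        "folds": folds[["fold", *metrics, "ppv", "npv", "tp", "fn", "fp", "tn"]],
        "mean": folds[metrics].mean().to_dict(),
        "sd": folds[metrics].std(ddof=1).to_dict(),
        "mean_auc": float(np.mean(aucs)) if aucs else float("nan"),
    }


def incremental_train(
    train: pd.DataFrame,
    test: pd.DataFrame,
    ranking: list[str],
    cfg: TrainConfig,
    cv_final_only: bool = True,
) -> tuple[ModelArtifact, pd.DataFrame]:
    """Train on growing ranking prefixes; keep the best-testing-accuracy one.

    Returns the selected model artifact (with the 25-fold CV summary of its
    subset as training metrics) and the per-k testing accuracy curve.  With
    ``cv_final_only=False`` the repeated CV is additionally run for every
    prefix and its mean accuracy recorded in the curve.
    """
    if sorted(ranking) != sorted(FEATURE_NAMES):
        raise ValueError("ranking must cover all 63 features exactly once")
    curve = []
    fitted = {}
    for k in range(1, len(ranking) + 1):
        subset = ranking[:k]
        est = make_estimator(cfg)
        X, y = _xy(train, subset)
        est.fit(X, y)
        Xt, yt = _xy(test, subset)
        prob = est.predict_proba(Xt)[:, 1]
        acc = float(np.mean((prob >= 0.5).astype(int) == yt))
        row = {"k": k, "testing_accuracy": acc}
        if not cv_final_only:
            row["cv_mean_accuracy"] = cross_validate(train, subset, cfg)["mean"]["accuracy"]
        curve.append(row)
        fitted[k] = est
    curve_df = pd.DataFrame(curve)
    best_k = int(curve_df.loc[curve_df["testing_accuracy"].idxmax(), "k"])
    cv = cross_validate(train, ranking[:best_k], cfg)
    artifact = ModelArtifact(
        algorithm=cfg.algorithm,
        hyperparameters=dict(cfg.hyperparameters),
        ranking=list(ranking),
        feature_subset=list(ranking[:best_k]),
        fitted_model=fitted[best_k],
        training_metrics={
            "cv_mean": cv["mean"], "cv_sd": cv["sd"], "cv_mean_auc": cv["mean_auc"],
        },
        seed=cfg.seed,
        created=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    return artifact, curve_df


def classify_segment(seg: SegmentRecord, artifact: ModelArtifact) -> dict:
    """End-to-end single-segment classification: QC → features → model.

    Returns ``{"label": "A"|"S", "prob_A": p}`` or
    ``{"label": "fail", "reason": ...}`` when the periodicity check fails.
    """
    from .features import NotClassifiableError, extract_features

    try:
        feats = extract_features(seg)
    except NotClassifiableError as exc:
        return {"label": "fail", "reason": exc.qc.reason}
    x = np.array([[feats[name] for name in artifact.feature_subset]])
    prob_a = float(artifact.fitted_model.predict_proba(x)[:, 1][0])
    return {"label": "A" if prob_a >= 0.5 else "S", "prob_A": prob_a}
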