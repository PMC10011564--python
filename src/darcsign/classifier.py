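"""One-vs-rest boosted-tree models over the 224-feature somatic profiles.

Protocol: binarize a target phenotype label against all other samples,
split 40:60 (test:train) stratified on the label, grid-search the four
subsampling fractions with stratified K-fold cross-validation scored
lexicographically on (AUC desc, classification error asc, log loss asc),
refit the winner on the full training split with depth-3 trees and
learning rate 0.001, then derive the decision threshold as the minimum
point of a 0..1 step-0.001 grid achieving the maximum F1.

Feature attributions use the tree-path-dependent Shapley decomposition
built into XGBoost (``pred_contribs``); per-sample attributions plus the
bias term reproduce the model margin (local accuracy), which is enforced.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import log_loss, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .types import ValidationError

log = logging.getLogger(__name__)

CLASS_LABELS = ("BRCA2d", "CDK12d", "MMRd", "ATMd", "DDRwt")
DEFAULT_FOLDS = {"BRCA2d": 10, "CDK12d": 6, "MMRd": 6}
THRESHOLD_GRID = np.arange(1001) / 1000.0


@dataclass
class TrainConfig:
    """Hyperparameters and search settings for one binary model."""

    test_fraction: float = 0.40
    folds_by_label: dict = field(default_factory=lambda: dict(DEFAULT_FOLDS))
    default_folds: int = 6
    grid: tuple[float, ...] = (0.5, 0.75, 1.0)
    max_depth: int = 3
    learning_rate: float = 0.001
    max_rounds: int = 1_000_000
    patience: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0.5 <= g <= 1.0 for g in self.grid):
            raise ValidationError("grid fractions must lie within [0.5, 1.0]")
        if not 0 < self.test_fraction < 1:
            raise ValidationError("test_fraction must be in (0, 1)")

    def folds(self, label: str) -> int:
        return self.folds_by_label.get(label, self.default_folds)

    @classmethod
    def test_profile(cls, seed: int = 0) -> "TrainConfig":
        """Desk-scale profile: coarser grid, capped boosting rounds."""
        return cls(grid=(0.5, 1.0), max_rounds=300, patience=30, seed=seed)

    @classmethod
    def production_profile(cls, seed: int = 0) -> "TrainConfig":
        return cls(seed=seed)


@dataclass
class TrainedClassifier:
    """A fitted binary ensemble plus everything needed to reuse it safely."""

    label: str
    booster: xgb.Booster
    feature_names: list[str]
    params: dict
    n_rounds: int
    seed: int
    threshold: float | None = None
    cv_results: list[dict] = field(default_factory=list)


def binarize_labels(labels, target: str) -> np.ndarray:
    """Positive = the target phenotype; negative = everything else."""
    labels = np.asarray(labels)
    return (labels == target).astype(int)


def stratified_split(
    y, test_fraction: float = 0.40, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive, label-stratified train/test index sets."""
    y = np.asarray(y)
    idx = np.arange(len(y))
    train, test = train_test_split(
        idx, test_size=test_fraction, stratify=y, random_state=seed
    )
    return np.sort(train), np.sort(test)


def _as_matrix(X, feature_names: list[str] | None = None) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        if feature_names is not None and list(X.columns) != list(feature_names):
            raise ValidationError(
                "feature columns do not match the model's stored feature order"
            )
        return X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if feature_names is not None and X.shape[1] != len(feature_names):
        raise ValidationError(
            f"expected {len(feature_names)} features, got {X.shape[1]}"
        )
    return X


def _xgb_params(config: TrainConfig, candidate: dict) -> dict:
    return {
        "objective": "binary:logistic",
        "max_depth": config.max_depth,
        "eta": config.learning_rate,
        # early stopping monitors log loss: AUC plateaus on separable folds
        # long before the margins are fitted, firing patience degenerately
        "eval_metric": "logloss",
        "tree_method": "hist",
        "seed": config.seed,
        "nthread": 1,
        **candidate,
    }


def select_best(cv_results: list[dict]) -> int:
    """Index of the lexicographically best candidate.

    Ordered criteria: AUC (higher better), classification error at 0.5
    (lower better), log loss (lower better); remaining ties resolve to
    the earlier grid point, keeping selection deterministic.
    """
    if not cv_results:
        raise ValidationError("no grid candidates to select from")
    keys = [
        (-entry["auc"], entry["error"], entry["log_loss"], i)
        for i, entry in enumerate(cv_results)
    ]
    return min(keys)[3]


def _fold_scores(p: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    auc = roc_auc_score(y, p)
    error = float(np.mean((p >= 0.5).astype(int) != y))
    ll = log_loss(y, p, labels=[0, 1])
    return float(auc), error, float(ll)


def grid_search_train(
    X, y, label: str, config: TrainConfig | None = None
) -> TrainedClassifier:
    """Exhaustive subsampling-fraction grid search with stratified K-fold CV.

    Candidates are ranked lexicographically by (mean AUC desc, mean error
    asc, mean log loss asc); the winner is refit on the full training
    split for the mean early-stopped round count of its folds.
    """
    config = config or TrainConfig()
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"f{i}" for i in range(np.asarray(X).shape[1])
    ]
    Xm = _as_matrix(X)
    y = np.asarray(y, dtype=int)
    k = config.folds(label)
    n_pos = int(y.sum())
    if n_pos < k:
        raise ValidationError(
            f"{label}: {n_pos} positive samples < {k} folds; use a smaller k"
        )

    names = ("subsample", "colsample_bytree", "colsample_bylevel", "colsample_bynode")
    cv_results: list[dict] = []
    candidates: list[dict] = []
    for values in itertools.product(config.grid, repeat=len(names)):
        candidate = dict(zip(names, values))
        params = _xgb_params(config, candidate)
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
        aucs, errors, losses, rounds = [], [], [], []
        for tr, va in skf.split(Xm, y):
            dtr = xgb.DMatrix(Xm[tr], label=y[tr])
            dva = xgb.DMatrix(Xm[va], label=y[va])
            booster = xgb.train(
                params,
                dtr,
                num_boost_round=config.max_rounds,
                evals=[(dva, "val")],
                early_stopping_rounds=config.patience,
                verbose_eval=False,
            )
            best_it = booster.best_iteration
            p = booster.predict(dva, iteration_range=(0, best_it + 1))
            a, e, l = _fold_scores(p, y[va])
            aucs.append(a); errors.append(e); losses.append(l)
            rounds.append(best_it + 1)
        entry = {
            **candidate,
            "auc": float(np.mean(aucs)),
            "error": float(np.mean(errors)),
            "log_loss": float(np.mean(losses)),
            "rounds": float(np.mean(rounds)),
        }
        cv_results.append(entry)
        candidates.append(candidate)

    best_index = select_best(cv_results)
    winner, winner_entry = candidates[best_index], cv_results[best_index]
    n_rounds = max(1, int(round(winner_entry["rounds"])))
    booster = xgb.train(
        _xgb_params(config, winner), xgb.DMatrix(Xm, label=y), num_boost_round=n_rounds
    )
    log.info(
        "%s: grid winner %s (AUC %.3f, error %.3f), refit %d rounds",
        label, winner, winner_entry["auc"], winner_entry["error"], n_rounds,
    )
    return TrainedClassifier(
        label=label,
        booster=booster,
        feature_names=feature_names,
        params=_xgb_params(config, winner),
        n_rounds=n_rounds,
        seed=config.seed,
        cv_results=cv_results,
    )


def predict_proba(model: TrainedClassifier, X) -> np.ndarray:
    """Class-membership probabilities with feature-order enforcement."""
    Xm = _as_matrix(X, model.feature_names)
    return model.booster.predict(xgb.DMatrix(Xm))


def derive_threshold(y, probabilities) -> float:
    """Minimum grid threshold (step 0.001) achieving the maximum F1.

    A sample is predicted positive when its probability is >= the
    threshold, consistently here and in downstream classification.
    """
    y = np.asarray(y, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if y.sum() == 0:
        raise ValidationError("F1 is undefined without positive labels")
    preds = p[None, :] >= THRESHOLD_GRID[:, None]
    tp = (preds & (y == 1)).sum(axis=1)
    fp = (preds & (y == 0)).sum(axis=1)
    fn = ((~preds) & (y == 1)).sum(axis=1)
    denom = 2 * tp + fp + fn
    f1 = np.where(denom > 0, 2 * tp / np.maximum(denom, 1), 0.0)
    return float(THRESHOLD_GRID[int(np.argmax(f1))])


def evaluate(y, probabilities) -> dict:
    """ROC AUC, the F1-scan threshold, and precision/recall across the grid."""
    y = np.asarray(y, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    preds = p[None, :] >= THRESHOLD_GRID[:, None]
    tp = (preds & (y == 1)).sum(axis=1)
    fp = (preds & (y == 0)).sum(axis=1)
    fn = ((~preds) & (y == 1)).sum(axis=1)
    precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 1.0)
    recall = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
    threshold = derive_threshold(y, p)
    i = int(round(threshold * 1000))
    denom = 2 * tp[i] + fp[i] + fn[i]
    return {
        "auc": float(roc_auc_score(y, p)),
        "threshold": threshold,
        "f1": float(2 * tp[i] / denom) if denom else 0.0,
        "thresholds": THRESHOLD_GRID.copy(),
        "precision": precision,
        "recall": recall,
    }


def shapley_attributions(model: TrainedClassifier, X) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-sample tree-path-dependent Shapley attributions and base values.

    Local accuracy — attributions plus base value equal the model margin
    per sample — is checked to 1e-4 and violated only if the attribution
    and model disagree, which is an internal error.
    """
    Xm = _as_matrix(X, model.feature_names)
    dm = xgb.DMatrix(Xm)
    contribs = model.booster.predict(dm, pred_contribs=True)
    margins = model.booster.predict(dm, output_margin=True)
    recon = contribs.sum(axis=1)
    if not np.allclose(recon, margins, atol=1e-4):
        raise RuntimeError(
            "Shapley local accuracy violated: attributions do not reproduce "
            f"model margins (max deviation {np.abs(recon - margins).max():.2e})"
        )
    frame = pd.DataFrame(contribs[:, :-1], columns=model.feature_names)
    return frame, contribs[:, -1]


def feature_impact(model: TrainedClassifier, X) -> pd.Series:
    """Per-feature importance: sum over samples of |Shapley attribution|."""
    attributions, _ = shapley_attributions(model, X)
    return attributions.abs().sum(axis=0).sort_values(ascending=False)


# ---------------------------------------------------------------------------
# persistence: model artifact = directory {ensemble.json, metadata.json}


def save_model(model: TrainedClassifier, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    model.booster.save_model(str(path / "ensemble.json"))
    meta = {
        "label": model.label,
        "feature_names": model.feature_names,
        "threshold": model.threshold,
        "params": model.params,
        "n_rounds": model.n_rounds,
        "seed": model.seed,
        "cv_results": model.cv_results,
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> TrainedClassifier:
    path = Path(path)
    meta_path = path / "metadata.json"
    ensemble_path = path / "ensemble.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing model metadata: {meta_path}")
    if not ensemble_path.exists():
        raise FileNotFoundError(f"missing model ensemble: {ensemble_path}")
    meta = json.loads(meta_path.read_text())
    booster = xgb.Booster()
    booster.load_model(str(ensemble_path))
    return TrainedClassifier(
        label=meta["label"],
        booster=booster,
        feature_names=list(meta["feature_names"]),
        params=meta["params"],
        n_rounds=meta["n_rounds"],
        seed=meta["seed"],
        threshold=meta["threshold"],
        cv_results=meta.get("cv_results", []),
    )
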