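"""Electrophysiological fingerprinting of alpha vs beta cells.

A gradient-boosted decision-tree ensemble (XGBoost) is trained on the eight
whole-cell electrophysiology features to classify islet cells as alpha or
beta from their electrical behavior alone.  The model's predicted
probability is interpreted as an alpha score: 1.0 means a canonically
alpha-like electrophysiological profile, 0.0 beta-like.  Hyperparameter
search over a small grid stops at the first configuration whose validation
accuracy reaches the 0.75 gate, with early stopping (patience 100 boosting
rounds) on the area under the precision-recall curve.
"""

from __future__ import annotations

import itertools
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import xgboost as xgb
from sklearn.metrics import (
    average_precision_score,
    balanced_accuracy_score,
    confusion_matrix,
)
from sklearn.model_selection import train_test_split

from .datatypes import EPHYS_FEATURES

LABELS = ("beta", "alpha")  # encoded 0, 1: probability is P(alpha)

DEFAULT_GRID = {
    "max_depth": (2, 3, 4),
    "learning_rate": (0.05, 0.1),
    "subsample": (0.8, 1.0),
}


class FingerprintError(ValueError):
    pass


@dataclass
class TrainConfig:
    accuracy_gate: float = 0.75
    validation_fraction: float = 0.2
    early_stopping_rounds: int = 100
    max_boosting_rounds: int = 500
    grid: dict = field(default_factory=lambda: dict(DEFAULT_GRID))
    seed: int = 0


@dataclass
class FingerprintModel:
    """Fitted ensemble plus training metadata.

    Predictions go through the underlying booster, truncated at the
    early-stopping round, so in-memory and reloaded models score
    identically.
    """

    booster: xgb.Booster
    features: tuple[str, ...]
    metadata: dict

    def predict_alpha_score(self, X: pd.DataFrame) -> np.ndarray:
        # the full ensemble: early stopping bounds its size (best + patience),
        # and the rounds past the AUCPR plateau sharpen the probabilities
        return self.booster.inplace_predict(
            np.ascontiguousarray(X[list(self.features)].to_numpy(dtype=float))
        )

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.booster.save_model(os.fspath(path.with_suffix(".ubj")))
        meta = {"format_version": 1, "features": list(self.features),
                "metadata": self.metadata}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path) -> "FingerprintModel":
        path = Path(path)
        booster = xgb.Booster()
        booster.load_model(os.fspath(path.with_suffix(".ubj")))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(booster, tuple(meta["features"]), meta["metadata"])


def _encode_labels(y) -> np.ndarray:
    y = np.asarray(y, dtype=object)
    bad = set(np.unique(y)) - set(LABELS)
    if bad:
        raise FingerprintError(f"labels must be in {LABELS}, got {sorted(bad)}")
    return (y == "alpha").astype(int)


def _check_features(X: pd.DataFrame) -> pd.DataFrame:
    missing = [f for f in EPHYS_FEATURES if f not in X.columns]
    if missing:
        raise FingerprintError(f"missing feature columns: {missing}")
    return X[list(EPHYS_FEATURES)]


def train_classifier(
    X: pd.DataFrame, y, config: TrainConfig | None = None
) -> FingerprintModel:
    """Fit the alpha/beta classifier on labeled electrophysiology rows.

    An internal stratified validation split (``validation_fraction``)
    drives early stopping and the accuracy gate; grid configurations are
    tried in a fixed order and the first whose validation accuracy reaches
    the gate wins (ties in the full sweep break by fewer boosting rounds).
    """
    config = config or TrainConfig()
    X = _check_features(X)
    y01 = _encode_labels(y)
    if len(np.unique(y01)) < 2:
        raise FingerprintError("training data must contain both classes")
    if len(X) != len(y01):
        raise FingerprintError("X and y lengths differ")

    X_tr, X_val, y_tr, y_val = train_test_split(
        X.to_numpy(), y01, test_size=config.validation_fraction,
        stratify=y01, random_state=config.seed,
    )

    keys = sorted(config.grid)
    candidates = [dict(zip(keys, vals))
                  for vals in itertools.product(*(config.grid[k] for k in keys))]
    best = None  # (accuracy, -rounds, params, model)
    for params in candidates:
        model = xgb.XGBClassifier(
            n_estimators=config.max_boosting_rounds,
            objective="binary:logistic",
            eval_metric="aucpr",
            early_stopping_rounds=config.early_stopping_rounds,
            random_state=config.seed,
            n_jobs=1,
            tree_method="hist",
            **params,
        )
        model.fit(X_tr, y_tr, eval_set=[(X_val, y_val)], verbose=False)
        acc = float(np.mean(model.predict(X_val) == y_val))
        rounds = model.get_booster().num_boosted_rounds()
        key = (acc, -rounds)
        if best is None or key > best[0]:
            best = (key, params, model, acc, rounds)
        if acc >= config.accuracy_gate:
            best = (key, params, model, acc, rounds)
            break

    _, params, model, acc, rounds = best
    metadata = {
        "hyperparameters": params,
        "best_iteration": int(model.best_iteration),
        "n_rounds": rounds,
        "validation_accuracy": acc,
        "eval_metric": "aucpr",
        "early_stopping_rounds": config.early_stopping_rounds,
        "accuracy_gate": config.accuracy_gate,
        "seed": config.seed,
        "n_train": int(len(X_tr)),
        "n_validation": int(len(X_val)),
    }
    return FingerprintModel(model.get_booster(), tuple(EPHYS_FEATURES), metadata)


def score_cells(
    model: FingerprintModel, X: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Alpha probability per cell; rows with missing features are skipped.

    Returns the score table (``alpha_score``, ``predicted_label``) and the
    list of skipped cell ids.
    """
    missing_cols = [f for f in model.features if f not in X.columns]
    if missing_cols:
        raise FingerprintError(f"missing feature columns: {missing_cols}")
    X = X[list(model.features)]
    complete = X.dropna(axis=0, how="any")
    skipped = [c for c in X.index if c not in set(complete.index)]
    scores = model.predict_alpha_score(complete)
    table = pd.DataFrame(
        {
            "alpha_score": scores,
            "predicted_label": np.where(scores >= 0.5, "alpha", "beta"),
        },
        index=complete.index,
    )
    return table, skipped


@dataclass
class ClassifierAudit:
    confusion: pd.DataFrame
    accuracy: float
    balanced_accuracy: float
    aucpr: float
    importance_shares: pd.Series
    overreliant: bool

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.to_dict(),
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "aucpr": self.aucpr,
            "importance_shares": self.importance_shares.to_dict(),
            "overreliant": self.overreliant,
        }


def audit_classifier(
    model: FingerprintModel, X: pd.DataFrame, y,
    overreliance_threshold: float = 0.5,
) -> ClassifierAudit:
    """Held-out performance: confusion matrix, accuracy, balanced accuracy,
    AUCPR, and normalized feature-importance shares.  The overreliance flag
    is set when any single feature's share exceeds the threshold."""
    if len(X) == 0:
        raise FingerprintError("empty held-out set")
    X = _check_features(X)
    y01 = _encode_labels(y)
    prob = model.predict_alpha_score(X)
    pred = (prob >= 0.5).astype(int)
    conf = confusion_matrix(y01, pred, labels=[1, 0])
    confusion = pd.DataFrame(
        conf, index=["true_alpha", "true_beta"], columns=["pred_alpha", "pred_beta"]
    )
    if len(np.unique(y01)) == 2:
        aucpr = float(average_precision_score(y01, prob))
    else:
        aucpr = float("nan")
    gain = model.booster.get_score(importance_type="gain")
    # booster names features f0..f7 when trained on arrays
    raw = np.array([gain.get(f"f{i}", 0.0) for i in range(len(model.features))])
    if raw.sum() == 0:
        shares = np.full(len(raw), 1.0 / len(raw))
    else:
        shares = raw / raw.sum()
    importance = pd.Series(shares, index=list(model.features), name="share")
    return ClassifierAudit(
        confusion=confusion,
        accuracy=float(np.mean(pred == y01)),
        balanced_accuracy=float(balanced_accuracy_score(y01, pred)),
        aucpr=aucpr,
        importance_shares=importance,
        overreliant=bool(importance.max() > overreliance_threshold),
    )


def associate_scores(
    scores: pd.Series, covariates: pd.DataFrame
) -> pd.DataFrame:
    """OLS regression of alpha score on donor covariates.

    ``covariates`` may include ``age``, ``bmi``, ``cit`` (numeric), ``sex``
    (M/F, encoded as an indicator for M) and ``condition`` (ND/T1D,
    indicator for T1D).  Returns per-coefficient estimate, standard error,
    t and two-sided p, plus the model R^2 as table metadata (``.attrs``).
    """
    common = scores.index.intersection(covariates.index)
    y = scores.loc[common].astype(float)
    X = covariates.loc[common].copy()
    if "sex" in X.columns and X["sex"].dtype == object:
        X["sex"] = (X["sex"] == "M").astype(float)
    if "condition" in X.columns and X["condition"].dtype == object:
        X["condition"] = (X["condition"] == "T1D").astype(float)
    X = X.astype(float)
    if len(X) < X.shape[1] + 2:
        raise FingerprintError(
            f"need at least {X.shape[1] + 2} cells for {X.shape[1]} covariates"
        )
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # name the offending columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(design.to_numpy(), pivoting=True)
        bad = sorted(design.columns[i] for i in piv[rank:])
        raise FingerprintError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(y, design).fit()
    table = pd.DataFrame(
        {
            "coef": fit.params,
            "stderr": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    table.attrs["r_squared"] = float(fit.rsquared)
    table.attrs["n"] = int(fit.nobs)
    return table
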