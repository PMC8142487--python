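"""Coding-variant impact metapredictor.

Combines 12 individual impact-predictor scores (SIFT, PolyPhen-2, LRT,
MutationTaster, MutationAssessor, FATHMM, GERP++, PhyloP, CADD, VEST,
SiPhy, DANN) into a single damaging probability.  Six classifier
families are available behind one interface; the random-forest family is
the shipped default.  Model selection uses tenfold, 3-times-repeated
stratified cross-validation maximizing AUC over a small documented
hyperparameter grid, then refits on the full training set.

Scores enter the models raw (no rescaling); class imbalance is left
unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, RepeatedStratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .io_formats import PREDICTOR_NAMES, AnnotatedVariant, ContractError

__all__ = [
    "LABEL_NEUTRAL",
    "LABEL_NON_NEUTRAL",
    "LABEL_UNCERTAIN",
    "MODEL_FAMILIES",
    "DEFAULT_FAMILY",
    "ImpactTrainingSet",
    "CVConfig",
    "MetapredictorModel",
    "prepare_training_set",
    "stratified_split",
    "train_metapredictor",
    "predict_impact",
    "predict_impact_batch",
    "save_model",
    "load_model",
]

LABEL_NEUTRAL = "neutral"
LABEL_NON_NEUTRAL = "non_neutral"
LABEL_UNCERTAIN = "uncertain"
_VALID_LABELS = {LABEL_NEUTRAL, LABEL_NON_NEUTRAL, LABEL_UNCERTAIN}

DEFAULT_FAMILY = "random_forest"

_ARTIFACT_VERSION = 1


@dataclass
class ImpactTrainingSet:
    """Complete-score rows with binary labels for metapredictor training.

    ``X`` is n x 12 in :data:`PREDICTOR_NAMES` order; ``y`` holds 1 for
    ``non_neutral`` and 0 for ``neutral``.
    """

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[1] != len(PREDICTOR_NAMES):
            raise ContractError(
                f"X must be n x {len(PREDICTOR_NAMES)}, got {self.X.shape}"
            )
        if len(self.y) != len(self.X):
            raise ContractError("X and y lengths differ")
        if np.isnan(self.X).any():
            raise ContractError("training set must not contain missing scores")

    def __len__(self) -> int:
        return len(self.y)


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation scheme for model selection."""

    folds: int = 10
    repeats: int = 3
    metric: str = "roc_auc"


@dataclass
class MetapredictorModel:
    """A fitted impact metapredictor with its frozen feature order."""

    family: str
    estimator: object
    feature_order: tuple[str, ...] = PREDICTOR_NAMES
    cv_config: CVConfig = field(default_factory=CVConfig)
    best_params: dict = field(default_factory=dict)
    cv_auc: float = float("nan")


def _default_grids() -> dict[str, tuple[object, dict]]:
    """Estimator prototypes and small hyperparameter grids per family."""
    return {
        "logistic": (
            LogisticRegression(max_iter=5000),
            {"C": [0.01, 0.1, 1.0, 10.0]},
        ),
        "naive_bayes": (
            GaussianNB(),
            {"var_smoothing": [1e-9, 1e-7, 1e-5]},
        ),
        "svm_linear": (
            SVC(kernel="linear", probability=True),
            {"C": [0.1, 1.0, 10.0]},
        ),
        "svm_radial": (
            SVC(kernel="rbf", probability=True),
            {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.1]},
        ),
        "random_forest": (
            RandomForestClassifier(n_estimators=100),
            {"max_features": ["sqrt", None]},
        ),
        "gradient_boosting": (
            GradientBoostingClassifier(),
            {"n_estimators": [100, 300], "learning_rate": [0.05, 0.1]},
        ),
    }


MODEL_FAMILIES: tuple[str, ...] = tuple(_default_grids())


def prepare_training_set(
    labeled_variants: Sequence[tuple[Sequence[float | None], str]],
) -> ImpactTrainingSet:
    """Filter labeled score rows down to the usable training set.

    Rows with any missing predictor score are excluded, as are rows
    labeled ``uncertain``; surviving row order is preserved.
    """
    X_rows: list[list[float]] = []
    y_rows: list[int] = []
    for scores, label in labeled_variants:
        if label not in _VALID_LABELS:
            raise ContractError(f"unknown label '{label}'")
        if label == LABEL_UNCERTAIN:
            continue
        if len(scores) != len(PREDICTOR_NAMES):
            raise ContractError(
                f"expected {len(PREDICTOR_NAMES)} scores, got {len(scores)}"
            )
        if any(s is None or (isinstance(s, float) and np.isnan(s)) for s in scores):
            continue
        X_rows.append([float(s) for s in scores])
        y_rows.append(1 if label == LABEL_NON_NEUTRAL else 0)
    if not X_rows:
        raise ContractError("no usable rows remain after filtering")
    return ImpactTrainingSet(X=np.array(X_rows), y=np.array(y_rows))


def stratified_split(
    dataset: ImpactTrainingSet, train_fraction: float, seed: int
) -> tuple[ImpactTrainingSet, ImpactTrainingSet]:
    """Random per-class split into train and test partitions.

    Each class contributes ``round(train_fraction * class_size)`` rows to
    the training partition; the split is an exact partition and is
    reproducible for a fixed seed.
    """
    if not 0 < train_fraction < 1:
        raise ContractError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in (0, 1):
        members = np.flatnonzero(dataset.y == cls)
        if len(members) < 2:
            raise ContractError(f"class {cls} has fewer than 2 members")
        n_train = round(train_fraction * len(members))
        perm = rng.permutation(members)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    train_idx_arr = np.sort(np.array(train_idx, dtype=int))
    test_idx_arr = np.sort(np.array(test_idx, dtype=int))
    return (
        ImpactTrainingSet(X=dataset.X[train_idx_arr], y=dataset.y[train_idx_arr]),
        ImpactTrainingSet(X=dataset.X[test_idx_arr], y=dataset.y[test_idx_arr]),
    )


def train_metapredictor(
    train_set: ImpactTrainingSet,
    family: str = DEFAULT_FAMILY,
    cv_config: CVConfig | None = None,
    seed: int = 0,
) -> MetapredictorModel:
    """Select hyperparameters by repeated CV and refit on the full set.

    The grid search maximizes mean cross-validated AUC over the family's
    documented grid; the winning configuration is refit on all of
    ``train_set``.  Deterministic for a fixed seed.
    """
    cv_config = cv_config or CVConfig()
    grids = _default_grids()
    if family not in grids:
        raise ContractError(
            f"unknown family '{family}'; choose from {sorted(grids)}"
        )
    if len(np.unique(train_set.y)) < 2:
        raise ContractError("training set must contain both classes")
    prototype, grid = grids[family]
    prototype = _seeded(prototype, seed)
    cv = RepeatedStratifiedKFold(
        n_splits=cv_config.folds, n_repeats=cv_config.repeats, random_state=seed
    )
    search = GridSearchCV(prototype, grid, scoring=cv_config.metric, cv=cv, n_jobs=1)
    search.fit(train_set.X, train_set.y)
    return MetapredictorModel(
        family=family,
        estimator=search.best_estimator_,
        cv_config=cv_config,
        best_params=dict(search.best_params_),
        cv_auc=float(search.best_score_),
    )


def _seeded(estimator: object, seed: int) -> object:
    if "random_state" in estimator.get_params():
        estimator.set_params(random_state=seed)
    return estimator


def predict_impact(
    model: MetapredictorModel, variant: AnnotatedVariant | Sequence[float | None]
) -> float | None:
    """Damaging probability for one variant, or ``None`` if any score is missing.

    Missingness is a value, not an error: the caller (the feature
    builder) decides the fallback for unscorable variants.
    """
    if isinstance(variant, AnnotatedVariant):
        scores = variant.score_vector()
    else:
        scores = list(variant)
    if len(scores) != len(model.feature_order):
        raise ContractError(
            f"expected {len(model.feature_order)} scores, got {len(scores)}"
        )
    if any(s is None or (isinstance(s, float) and np.isnan(s)) for s in scores):
        return None
    X = np.asarray(scores, dtype=float).reshape(1, -1)
    proba = model.estimator.predict_proba(X)
    positive = list(model.estimator.classes_).index(1)
    return float(proba[0, positive])


def predict_impact_batch(
    model: MetapredictorModel, X: np.ndarray
) -> np.ndarray:
    """Vectorized damaging probabilities; rows with NaN give NaN."""
    X = np.asarray(X, dtype=float)
    out = np.full(len(X), np.nan)
    complete = ~np.isnan(X).any(axis=1)
    if complete.any():
        proba = model.estimator.predict_proba(X[complete])
        positive = list(model.estimator.classes_).index(1)
        out[complete] = proba[:, positive]
    return out


def save_model(model: MetapredictorModel, path: str | Path) -> None:
    """Serialize the model with its feature order and selection metadata."""
    joblib.dump(
        {
            "artifact_version": _ARTIFACT_VERSION,
            "family": model.family,
            "estimator": model.estimator,
            "feature_order": list(model.feature_order),
            "cv_config": model.cv_config,
            "best_params": model.best_params,
            "cv_auc": model.cv_auc,
        },
        path,
    )


def load_model(path: str | Path) -> MetapredictorModel:
    payload = joblib.load(path)
    if payload.get("artifact_version") != _ARTIFACT_VERSION:
        raise ContractError(
            f"unsupported model artifact version {payload.get('artifact_version')}"
        )
    return MetapredictorModel(
        family=payload["family"],
        estimator=payload["estimator"],
        feature_order=tuple(payload["feature_order"]),
        cv_config=payload["cv_config"],
        best_params=payload["best_params"],
        cv_auc=payload["cv_auc"],
    )
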