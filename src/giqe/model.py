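"""Feature-subset SVR ensemble ("semi-full combination subspace").

With five features and modest training sets, a single regressor on the full
feature vector risks overfitting.  The ensemble instead enumerates every
feature subset of size >= ``min_subset_size``, fits one epsilon-SVR (RBF
kernel) per subset on the masked, rescaled features, and averages the
component predictions.  Hyperparameters (cost H, tube width epsilon, kernel
width k) are selected once by cross-validated grid search on the training
set and shared by all components.

Fitting delegates to scikit-learn's libsvm-backed ``SVR``; fitted components
are stored as their explicit kernel expansion (support vectors, dual
coefficients, bias), so a trained model serializes to deterministic
structured text.
"""

from __future__ import annotations

import itertools
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.svm import SVR

from .features import FEATURE_NAMES, FeatureVector

__all__ = [
    "SubspaceMask",
    "TrainConfig",
    "GIQEModel",
    "QualityScore",
    "RbfSVRParams",
    "enumerate_subspaces",
    "split_by_source",
    "train_giqe",
    "predict_giqe",
    "predict_giqe_batch",
    "save_model",
    "load_model",
]

MOS_MIN, MOS_MAX = 1.0, 5.0


@dataclass(frozen=True)
class SubspaceMask:
    """An ordered subset of the five feature indices."""

    included: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.included:
            raise ValueError("subspace mask must be non-empty")
        if len(set(self.included)) != len(self.included):
            raise ValueError("duplicate feature indices in mask")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(FEATURE_NAMES[i] for i in self.included)


@dataclass(frozen=True)
class TrainConfig:
    """Training configuration: subset floor, hyperparameter grids, split."""

    min_subset_size: int = 2
    svr_cost_grid: tuple[float, ...] = (1.0, 10.0, 100.0, 1000.0)
    svr_epsilon_grid: tuple[float, ...] = (0.01, 0.1, 0.5)
    rbf_gamma_grid: tuple[float, ...] = tuple(2.0 ** e for e in range(-4, 3))
    cv_folds: int = 5
    split_fraction: float = 0.6
    split_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split_fraction must lie in (0, 1)")
        for g in (self.svr_cost_grid, self.svr_epsilon_grid, self.rbf_gamma_grid):
            if not len(g):
                raise ValueError("hyperparameter grids must be non-empty")


@dataclass
class RbfSVRParams:
    """Explicit RBF kernel expansion of a fitted epsilon-SVR component."""

    support_vectors: np.ndarray    # (n_sv, n_mask_features)
    dual_coef: np.ndarray          # (n_sv,)
    intercept: float
    gamma: float

    @classmethod
    def from_sklearn(cls, svr: SVR) -> "RbfSVRParams":
        return cls(
            support_vectors=np.asarray(svr.support_vectors_, float),
            dual_coef=np.asarray(svr.dual_coef_, float).ravel(),
            intercept=float(svr.intercept_[0]),
            gamma=float(svr._gamma),
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        d2 = (
            (X * X).sum(axis=1)[:, None]
            - 2.0 * X @ self.support_vectors.T
            + (self.support_vectors * self.support_vectors).sum(axis=1)[None, :]
        )
        return np.exp(-self.gamma * np.clip(d2, 0.0, None)) @ self.dual_coef + self.intercept


@dataclass
class GIQEModel:
    """Trained ensemble: per-subset SVR components plus the feature scaler."""

    masks: list[SubspaceMask]
    components: list[RbfSVRParams]
    scaler_min: np.ndarray
    scaler_scale: np.ndarray       # maps features to [0,1]: (x - min) * scale
    best_params: dict
    cv_scores: dict                # per-mask CV RMSE (diagnostic only)
    training_meta: dict

    def scale(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scaler_min) * self.scaler_scale


@dataclass(frozen=True)
class QualityScore:
    """Predicted quality on the 1..5 opinion scale."""

    value: float
    per_component: tuple[float, ...] | None = None


def enumerate_subspaces(n_features: int, min_size: int) -> list[SubspaceMask]:
    """All feature subsets of size >= min_size, in lexicographic order."""
    if not 1 <= min_size <= n_features:
        raise ValueError(f"min_size must be in 1..{n_features}, got {min_size}")
    masks = [
        SubspaceMask(included=combo)
        for size in range(min_size, n_features + 1)
        for combo in itertools.combinations(range(n_features), size)
    ]
    masks.sort(key=lambda m: m.included)
    return masks


def split_by_source(
    manifest: pd.DataFrame, cfg: TrainConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a manifest at source-image granularity (60/40 by default).

    All distorted versions of one reference land on the same side, so the
    test partition contains only unseen content.  Seeded and reproducible.
    """
    sources = sorted(manifest["reference"].unique())
    if len(sources) < 2:
        raise ValueError("need at least 2 distinct sources to split")
    rng = np.random.default_rng(cfg.split_seed)
    order = rng.permutation(len(sources))
    n_train = int(round(cfg.split_fraction * len(sources)))
    n_train = min(max(n_train, 1), len(sources) - 1)
    train_ids = {sources[i] for i in order[:n_train]}
    train = manifest[manifest["reference"].isin(train_ids)].reset_index(drop=True)
    test = manifest[~manifest["reference"].isin(train_ids)].reset_index(drop=True)
    return train, test


def _as_matrix(features) -> np.ndarray:
    rows = [
        f.to_array() if isinstance(f, FeatureVector) else np.asarray(f, float)
        for f in features
    ]
    X = np.vstack(rows)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    return X


def train_giqe(features, labels, cfg: TrainConfig | None = None) -> GIQEModel:
    """Fit the subset ensemble.

    The (H, epsilon, k) triple is chosen by ``cv_folds``-fold
    cross-validated grid search (RMSE criterion) on the full feature set,
    then every subset component is fitted with that triple.  Per-mask CV
    RMSEs are recorded for inspection.  Deterministic given
    (features, labels, cfg).
    """
    cfg = cfg or TrainConfig()
    X = _as_matrix(features)
    y = np.asarray(labels, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree in length")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 training samples")
    if np.ptp(y) == 0:
        raise ValueError("degenerate labels: zero variance")

    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    scale = np.where(span > 1e-12, 1.0 / np.where(span > 1e-12, span, 1.0), 1.0)
    Xs = (X - lo) * scale

    grid = {
        "C": list(cfg.svr_cost_grid),
        "epsilon": list(cfg.svr_epsilon_grid),
        "gamma": list(cfg.rbf_gamma_grid),
    }
    cv = KFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.split_seed)
    search = GridSearchCV(
        SVR(kernel="rbf"),
        grid,
        scoring="neg_root_mean_squared_error",
        cv=cv,
        n_jobs=1,
    )
    search.fit(Xs, y)
    best = {k: float(v) for k, v in search.best_params_.items()}

    masks = enumerate_subspaces(X.shape[1], cfg.min_subset_size)
    components, cv_scores = [], {}
    folds = list(cv.split(Xs))
    for mask in masks:
        cols = list(mask.included)
        svr = SVR(kernel="rbf", **best).fit(Xs[:, cols], y)
        components.append(RbfSVRParams.from_sklearn(svr))
        rmses = []
        for tr_idx, va_idx in folds:
            m = SVR(kernel="rbf", **best).fit(Xs[np.ix_(tr_idx, cols)], y[tr_idx])
            pred = m.predict(Xs[np.ix_(va_idx, cols)])
            rmses.append(float(np.sqrt(np.mean((pred - y[va_idx]) ** 2))))
        cv_scores[",".join(mask.names)] = float(np.mean(rmses))

    meta = {
        "n_samples": int(X.shape[0]),
        "min_subset_size": int(cfg.min_subset_size),
        "cv_folds": int(cfg.cv_folds),
        "split_seed": int(cfg.split_seed),
        "best_params": best,
        "data_fingerprint": float(np.sum(X) + np.sum(y)),
    }
    return GIQEModel(
        masks=masks,
        components=components,
        scaler_min=lo,
        scaler_scale=scale,
        best_params=best,
        cv_scores=cv_scores,
        training_meta=meta,
    )


def predict_giqe(model: GIQEModel, fv) -> QualityScore:
    """Ensemble prediction for one feature vector.

    Each component predicts on its masked features; the ensemble output is
    the unweighted mean, clipped to the 1..5 opinion scale.
    """
    x = fv.to_array() if isinstance(fv, FeatureVector) else np.asarray(fv, float)
    if x.ndim != 1 or not np.all(np.isfinite(x)):
        raise ValueError("feature vector must be a finite 1-D array")
    xs = model.scale(x[None, :])
    outs = tuple(
        float(comp.predict(xs[:, list(mask.included)])[0])
        for mask, comp in zip(model.masks, model.components)
    )
    value = float(np.clip(np.mean(outs), MOS_MIN, MOS_MAX))
    return QualityScore(value=value, per_component=outs)


def predict_giqe_batch(model: GIQEModel, features) -> np.ndarray:
    """Vectorized ensemble prediction for many feature vectors."""
    X = _as_matrix(features)
    Xs = model.scale(X)
    preds = np.column_stack(
        [
            comp.predict(Xs[:, list(mask.included)])
            for mask, comp in zip(model.masks, model.components)
        ]
    )
    return np.clip(preds.mean(axis=1), MOS_MIN, MOS_MAX)


def save_model(model: GIQEModel, path: str | os.PathLike) -> None:
    """Serialize a trained model as a single versioned JSON file."""
    doc = {
        "format": "giqe-model-v1",
        "scaler_min": model.scaler_min.tolist(),
        "scaler_scale": model.scaler_scale.tolist(),
        "best_params": model.best_params,
        "cv_scores": model.cv_scores,
        "training_meta": model.training_meta,
        "components": [
            {
                "mask": list(mask.included),
                "support_vectors": comp.support_vectors.tolist(),
                "dual_coef": comp.dual_coef.tolist(),
                "intercept": comp.intercept,
                "gamma": comp.gamma,
            }
            for mask, comp in zip(model.masks, model.components)
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True)


def load_model(path: str | os.PathLike) -> GIQEModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "giqe-model-v1":
        raise ValueError(f"unrecognized model file format in {path!r}")
    masks, comps = [], []
    for entry in doc["components"]:
        masks.append(SubspaceMask(included=tuple(entry["mask"])))
        comps.append(
            RbfSVRParams(
                support_vectors=np.array(entry["support_vectors"], float),
                dual_coef=np.array(entry["dual_coef"], float),
                intercept=float(entry["intercept"]),
                gamma=float(entry["gamma"]),
            )
        )
    return GIQEModel(
        masks=masks,
        components=comps,
        scaler_min=np.array(doc["scaler_min"], float),
        scaler_scale=np.array(doc["scaler_scale"], float),
        best_params=doc["best_params"],
        cv_scores=doc["cv_scores"],
        training_meta=doc["training_meta"],
    )
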