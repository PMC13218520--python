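"""High/low area classification and feature attribution.

Areas are labelled High when a proxy measure strictly exceeds the
unweighted national mean over included areas. Four model families
(logistic regression, random forest, support-vector machine, multilayer
perceptron) are tuned over small documented grids with stratified 10-fold
cross-validation; features are min-max scaled to [0, 1] with bounds
fitted on training folds only (held-out values are clipped). The best
family per target is interrogated with a sampling Shapley estimator to
rank feature influence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .shapley import shapley_table
from .synth import REGION_FEATURES

logger = logging.getLogger(__name__)

#: classification targets (binarised proxy measures)
TARGETS = ["p_m", "p_p", "p_p_given_m"]

#: minimum number of labelled areas accepted for training
MIN_REGIONS = 50


class DegenerateLabelsError(ValueError):
    """All areas fall in one class; training is refused."""


def default_features(region: pd.DataFrame) -> list[str]:
    """Feature columns present in the region table.

    If both a raw ONS income column and weekly household income are
    present, the former is dropped (the two are collinear).
    """
    feats = [c for c in REGION_FEATURES if c in region.columns]
    extra = [
        c
        for c in region.columns
        if c.startswith("imd_") and c != "imd_score" and c not in feats
    ]
    feats += extra
    if "ons_income" in region.columns and "household_income" in feats:
        logger.info("dropping collinear 'ons_income' (household_income present)")
    elif "ons_income" in region.columns:
        feats.append("ons_income")
    return feats


def binarize_targets(
    region: pd.DataFrame, targets: list[str] | None = None
) -> dict[str, pd.Series]:
    """High/low labels per target: True (High) iff value > unweighted mean.

    Areas with an undefined (NaN) target value are excluded per target.
    Labels for a target whose values are all equal are returned (all Low);
    training on them is refused downstream.
    """
    targets = targets or [t for t in TARGETS if t in region.columns]
    labels: dict[str, pd.Series] = {}
    for t in targets:
        vals = region[t].dropna()
        if len(vals) < 2:
            raise ValueError(f"need >=2 areas with defined {t}")
        labels[t] = (vals > vals.mean()).rename(f"high_{t}")
    return labels


def normalize_features(
    df: pd.DataFrame,
    feature_cols: list[str] | None = None,
    bounds: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Min-max scale features to [0, 1].

    When ``bounds`` (a frame with rows 'min' and 'max') is given, they are
    applied and out-of-range values are clipped — the leakage-free path
    for held-out data. Otherwise bounds are fitted on ``df``; zero-range
    features are dropped with a warning.

    Returns the scaled frame and the bounds used.
    """
    feature_cols = feature_cols or list(df.columns)
    if bounds is None:
        lo = df[feature_cols].min()
        hi = df[feature_cols].max()
        constant = [c for c in feature_cols if lo[c] == hi[c]]
        if constant:
            logger.warning("dropping zero-range feature(s): %s", constant)
            feature_cols = [c for c in feature_cols if c not in constant]
            lo, hi = lo[feature_cols], hi[feature_cols]
        bounds = pd.DataFrame({"min": lo, "max": hi}).T
    else:
        feature_cols = list(bounds.columns)
    lo = bounds.loc["min"]
    hi = bounds.loc["max"]
    scaled = (df[feature_cols] - lo) / (hi - lo)
    return scaled.clip(0.0, 1.0), bounds


def default_grids() -> dict[str, dict[str, list[Any]]]:
    """Small, documented hyperparameter grids per model family."""
    return {
        "logistic_regression": {"model__C": [0.01, 0.1, 1.0, 10.0]},
        "random_forest": {
            "model__n_estimators": [100, 300],
            "model__max_depth": [3, 6, None],
        },
        "support_vector": {
            "model__kernel": ["linear", "rbf"],
            "model__C": [0.1, 1.0, 10.0],
        },
        "neural_network": {
            "model__hidden_layer_sizes": [(8,), (16,), (32,), (8, 8), (16, 16), (32, 32)],
        },
    }


def _estimators(seed: int) -> dict[str, Pipeline]:
    return {
        "logistic_regression": Pipeline(
            [("scale", MinMaxScaler(clip=True)),
             ("model", LogisticRegression(max_iter=2000))]
        ),
        "random_forest": Pipeline(
            [("scale", MinMaxScaler(clip=True)),
             ("model", RandomForestClassifier(random_state=seed))]
        ),
        "support_vector": Pipeline(
            [("scale", MinMaxScaler(clip=True)),
             ("model", SVC(probability=True, random_state=seed))]
        ),
        # lbfgs without early stopping: at a few hundred areas a held-out
        # early-stopping split is too small to be meaningful
        "neural_network": Pipeline(
            [("scale", MinMaxScaler(clip=True)),
             ("model", MLPClassifier(
                 solver="lbfgs", max_iter=2000, alpha=1e-3,
                 random_state=seed))]
        ),
    }


@dataclass
class ModelReport:
    """Cross-validated result for one model family on one target."""

    family: str
    target: str
    accuracy_mean: float
    accuracy_sd: float
    best_params: dict
    estimator: Any = field(repr=False, default=None)


def train_and_select(
    region: pd.DataFrame,
    target: str,
    features: list[str] | None = None,
    seed: int = 0,
    n_folds: int = 10,
    grids: dict | None = None,
    min_regions: int = MIN_REGIONS,
) -> tuple[list[ModelReport], ModelReport]:
    """Tune all model families on one binarised target; pick the best.

    Each family is grid-searched with stratified ``n_folds``-fold CV on
    accuracy; the report carries the best combination's fold mean ± sd.
    The winning family's pipeline is refit on all data. Raises
    :class:`DegenerateLabelsError` when only one class is present, and
    ``ValueError`` when a class is too small to stratify across folds.
    """
    features = features or default_features(region)
    labels = binarize_targets(region, [target])[target]
    X = region.loc[labels.index, features]
    y = labels.to_numpy()
    if len(X) < min_regions:
        raise ValueError(f"need >= {min_regions} labelled areas, got {len(X)}")
    class_counts = np.bincount(y.astype(int), minlength=2)
    if class_counts.min() == 0:
        raise DegenerateLabelsError(
            f"target {target}: all areas on one side of the mean"
        )
    if class_counts.min() < n_folds:
        raise ValueError(
            f"minority class has {class_counts.min()} areas; cannot "
            f"stratify {n_folds} folds"
        )
    grids = grids or default_grids()
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    reports: list[ModelReport] = []
    for family, pipe in _estimators(seed).items():
        if family not in grids:
            continue
        search = GridSearchCV(
            pipe, grids[family], scoring="accuracy", cv=cv, refit=True, n_jobs=None
        )
        search.fit(X, y)
        i = search.best_index_
        reports.append(
            ModelReport(
                family=family,
                target=target,
                accuracy_mean=float(search.cv_results_["mean_test_score"][i]),
                accuracy_sd=float(search.cv_results_["std_test_score"][i]),
                best_params={
                    k.removeprefix("model__"): v for k, v in search.best_params_.items()
                },
                estimator=search.best_estimator_,
            )
        )
        logger.info(
            "%s on %s: accuracy %.3f ± %.3f",
            family, target, reports[-1].accuracy_mean, reports[-1].accuracy_sd,
        )
    best = max(reports, key=lambda r: r.accuracy_mean)
    return reports, best


def reports_frame(reports: list[ModelReport]) -> pd.DataFrame:
    """Tabulate model reports (one row per family × target)."""
    return pd.DataFrame(
        [
            {
                "target": r.target,
                "family": r.family,
                "accuracy_mean": r.accuracy_mean,
                "accuracy_sd": r.accuracy_sd,
                "best_params": str(r.best_params),
            }
            for r in reports
        ]
    )


def shap_rank(
    report: ModelReport,
    region: pd.DataFrame,
    features: list[str] | None = None,
    n_eval: int = 100,
    n_background: int = 100,
    n_samples: int = 64,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank features by mean |Shapley value| of the fitted best model.

    Attribution targets the model's P(High) output. Evaluation points and
    the background are subsampled from the labelled areas (at most
    ``n_eval`` / ``n_background`` rows). ``value_effect`` > 0 means high
    feature values push areas toward the High class.
    """
    if report.estimator is None:
        raise ValueError("model report carries no fitted estimator")
    features = features or default_features(region)
    labels = binarize_targets(region, [report.target])[report.target]
    X = region.loc[labels.index, features].reset_index(drop=True)
    rng = np.random.default_rng(seed)
    eval_idx = rng.choice(len(X), size=min(n_eval, len(X)), replace=False)
    bg_idx = rng.choice(len(X), size=min(n_background, len(X)), replace=False)
    est = report.estimator

    def predict(a: np.ndarray) -> np.ndarray:
        return est.predict_proba(pd.DataFrame(a, columns=features))[:, 1]

    return shapley_table(
        predict, X.iloc[eval_idx], X.iloc[bg_idx], n_samples=n_samples, rng=rng
    )
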