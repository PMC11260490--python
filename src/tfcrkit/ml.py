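"""Feature encoding, regressor registry, pooled training sets, evaluation
metrics and feature-attribution reports for score prediction.

The reference model is a gradient-boosted tree ensemble; the registry also
carries the other ten methods behind a common fit/predict surface.  Knobs
of the published boosted-tree configuration that the scikit-learn backend
does not support are logged and dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import pearsonr, spearmanr
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import (
    AdaBoostRegressor,
    GradientBoostingRegressor,
    HistGradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.linear_model import Ridge
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .treeshap import ensemble_shap

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

DEFAULT_L_PROMOTER = 4000
DEFAULT_L_TFCR = 11113

# published boosted-tree configuration; keys absent from the sklearn
# implementation are reported and dropped at construction time
REFERENCE_GB_PARAMS = {
    "loss_function": "RMSE",
    "iterations": 2000,
    "learning_rate": 0.1,
    "l2_leaf_reg": 5,
    "depth": 12,
    "border_count": 128,
    "bootstrap_type": "Bernoulli",
    "boosting_type": "Ordered",
}
_GB_PARAM_MAP = {
    "loss_function": ("loss", {"RMSE": "squared_error"}),
    "iterations": ("n_estimators", None),
    "learning_rate": ("learning_rate", None),
    "depth": ("max_depth", None),
}


# ---------------------------------------------------------------------------
# feature encoding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureVector:
    promoter_onehot: np.ndarray  # (4, L_p)
    tfcr_onehot: np.ndarray  # (4, L_t)
    distance: float

    def flatten(self) -> np.ndarray:
        """Position-major flat vector; distance is the final scalar."""
        return np.concatenate(
            [
                self.promoter_onehot.T.reshape(-1),
                self.tfcr_onehot.T.reshape(-1),
                [self.distance],
            ]
        )


def onehot_sequence(seq: str, length: int) -> np.ndarray:
    """4 x length one-hot matrix; N columns and right padding are all-zero."""
    if len(seq) > length:
        raise ValueError(f"sequence of length {len(seq)} exceeds window {length}")
    out = np.zeros((4, length))
    for i, base in enumerate(seq.upper()):
        idx = _BASE_INDEX.get(base)
        if idx is None and base != "N":
            raise ValueError(f"unexpected base {base!r}")
        if idx is not None:
            out[idx, i] = 1.0
    return out


def encode_features(
    promoter_seq: str,
    tfcr_seq: str,
    distance: float,
    l_promoter: int = DEFAULT_L_PROMOTER,
    l_tfcr: int = DEFAULT_L_TFCR,
) -> FeatureVector:
    return FeatureVector(
        promoter_onehot=onehot_sequence(promoter_seq, l_promoter),
        tfcr_onehot=onehot_sequence(tfcr_seq, l_tfcr),
        distance=float(distance),
    )


def feature_names(l_promoter: int, l_tfcr: int) -> list[str]:
    names = [
        f"prom_{pos}_{base}" for pos in range(l_promoter) for base in BASES
    ]
    names += [f"tfcr_{pos}_{base}" for pos in range(l_tfcr) for base in BASES]
    names.append("distance")
    return names


def encode_matrix(
    samples: Mapping[str, Sequence],
    l_promoter: int,
    l_tfcr: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode a make_regression_dataset-style dict into (X, y)."""
    rows = [
        encode_features(p, t, d, l_promoter, l_tfcr).flatten()
        for p, t, d in zip(
            samples["promoter_seq"], samples["tfcr_seq"], samples["distance"]
        )
    ]
    return np.asarray(rows), np.asarray(samples["score"], dtype=float)


# ---------------------------------------------------------------------------
# dataset handling
# ---------------------------------------------------------------------------


def split_dataset(records: Sequence, train_frac: float = 0.8, seed: int = 0):
    """Disjoint, exhaustive, seed-reproducible train/test split."""
    n = len(records)
    if n < 10:
        raise ValueError("need at least 10 records")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(train_frac * n))
    take = lambda idx: [records[i] for i in idx]
    return take(order[:n_train]), take(order[n_train:])


def build_pooled_training_set(
    per_species_stage_sets: Mapping[str, Sequence[Sequence]],
    per_species_total: int = 30_000,
    seed: int = 0,
) -> list:
    """Resample per-stage training sets into one pooled set.

    Every species contributes exactly ``per_species_total`` samples, drawn
    with replacement as floor(total / n_stages) per stage with the
    remainder assigned to the first stage.
    """
    rng = np.random.default_rng(seed)
    pooled: list = []
    for species in sorted(per_species_stage_sets):
        stages = per_species_stage_sets[species]
        if not stages:
            raise ValueError(f"species {species!r} has no stages")
        n_stages = len(stages)
        per_stage = per_species_total // n_stages
        remainder = per_species_total - per_stage * n_stages
        for s, stage_set in enumerate(stages):
            if not len(stage_set):
                raise ValueError(f"empty stage {s} for species {species!r}")
            count = per_stage + (remainder if s == 0 else 0)
            idx = rng.integers(0, len(stage_set), size=count)
            pooled.extend((species, s, stage_set[i]) for i in idx)
    return pooled


def enumerate_training_tasks(
    methods: Sequence[str], datasets: Sequence[str]
) -> list[tuple[str, str]]:
    """Cross-product of regression methods and stage-species datasets."""
    for m in methods:
        if m not in METHOD_REGISTRY:
            raise ValueError(f"unknown method {m!r}")
    return [(m, d) for m in methods for d in datasets]


# ---------------------------------------------------------------------------
# model registry
# ---------------------------------------------------------------------------


class ConvFeatureRegressor(BaseEstimator, RegressorMixin):
    """Lightweight convolutional stand-in: fixed random 1-D filters over the
    flattened one-hot input, max-pooled, followed by a ridge head.

    Deterministic under ``random_state``; not a trained deep network.
    """

    def __init__(self, n_filters: int = 32, kernel_size: int = 12,
                 alpha: float = 1.0, random_state: int = 0):
        self.n_filters = n_filters
        self.kernel_size = kernel_size
        self.alpha = alpha
        self.random_state = random_state

    def _featurize(self, X: np.ndarray) -> np.ndarray:
        n, d = X.shape
        k = min(self.kernel_size, d)
        windows = np.lib.stride_tricks.sliding_window_view(X, k, axis=1)
        conv = np.einsum("nwk,fk->nwf", windows, self._filters)
        return np.concatenate([conv.max(axis=1), conv.mean(axis=1), X[:, -1:]], axis=1)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        rng = np.random.default_rng(self.random_state)
        k = min(self.kernel_size, X.shape[1])
        self._filters = rng.standard_normal((self.n_filters, k))
        self._head = Ridge(alpha=self.alpha)
        self._head.fit(self._featurize(X), y)
        return self

    def predict(self, X):
        return self._head.predict(self._featurize(np.asarray(X, dtype=float)))


def _gb_trees_factory(params: dict, seed: int):
    mapped: dict = {"random_state": seed}
    merged = {**REFERENCE_GB_PARAMS, **params}
    for key, value in merged.items():
        if key in _GB_PARAM_MAP:
            target, translate = _GB_PARAM_MAP[key]
            mapped[target] = translate[value] if translate else value
        elif key in GradientBoostingRegressor().get_params():
            mapped[key] = value
        else:
            logger.info("gb_trees: dropping unsupported hyperparameter %s=%r", key, value)
    return GradientBoostingRegressor(**mapped)


METHOD_REGISTRY: dict[str, callable] = {
    "gb_trees": _gb_trees_factory,
    "svr": lambda p, s: SVR(**p),
    "mlp": lambda p, s: MLPRegressor(random_state=s, max_iter=500, **p),
    "knn": lambda p, s: KNeighborsRegressor(**p),
    "dtree": lambda p, s: DecisionTreeRegressor(random_state=s, **p),
    "rforest": lambda p, s: RandomForestRegressor(random_state=s, **p),
    "adaboost": lambda p, s: AdaBoostRegressor(random_state=s, **p),
    "gbdt": lambda p, s: GradientBoostingRegressor(random_state=s, **p),
    "xgb": lambda p, s: HistGradientBoostingRegressor(random_state=s, **p),
    "lgbm": lambda p, s: HistGradientBoostingRegressor(
        random_state=s, max_leaf_nodes=63, **p
    ),
    "cnn": lambda p, s: ConvFeatureRegressor(random_state=s, **p),
}


@dataclass
class ModelSpec:
    method: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHOD_REGISTRY:
            raise ValueError(
                f"unknown method {self.method!r}; choose from {sorted(METHOD_REGISTRY)}"
            )

    def build(self):
        return METHOD_REGISTRY[self.method](dict(self.hyperparams), self.seed)


def train_regressor(spec: ModelSpec, X: np.ndarray, y: np.ndarray):
    model = spec.build()
    model.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
    return model


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvalReport:
    pearson_r: float
    spearman_R: float
    r_squared: float
    mae: float
    rmse: float


def evaluate(model, X: np.ndarray, y: np.ndarray) -> EvalReport:
    """All five held-out metrics; constant predictions yield NaN
    correlations with a warning rather than an error."""
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("empty test set")
    pred = np.asarray(model.predict(np.asarray(X, dtype=float)), dtype=float)
    if np.ptp(pred) == 0 or np.ptp(y) == 0:
        warnings.warn("constant predictions or targets: correlations undefined")
        r = rho = float("nan")
    else:
        r = float(pearsonr(pred, y).statistic)
        rho = float(spearmanr(pred, y).statistic)
    return EvalReport(
        pearson_r=r,
        spearman_R=rho,
        r_squared=float(r2_score(y, pred)),
        mae=float(mean_absolute_error(y, pred)),
        rmse=float(np.sqrt(mean_squared_error(y, pred))),
    )


def cross_validate(
    spec: ModelSpec, X: np.ndarray, y: np.ndarray, k: int = 5
) -> list[EvalReport]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    folds = KFold(n_splits=k, shuffle=True, random_state=spec.seed)
    reports = []
    for train_idx, test_idx in folds.split(X):
        model = spec.build()
        model.fit(X[train_idx], y[train_idx])
        reports.append(evaluate(model, X[test_idx], y[test_idx]))
    return reports


# ---------------------------------------------------------------------------
# attribution
# ---------------------------------------------------------------------------


@dataclass
class AttributionReport:
    values: np.ndarray  # (n_samples, n_features)
    base_values: np.ndarray  # (n_samples,)
    feature_names: list[str]

    @property
    def mean_abs_importance(self) -> np.ndarray:
        return np.abs(self.values).mean(axis=0)

    def ranking(self) -> list[tuple[str, float]]:
        imp = self.mean_abs_importance
        order = np.argsort(-imp, kind="stable")
        return [(self.feature_names[i], float(imp[i])) for i in order]


def attribute(
    model, X: np.ndarray, feature_names_list: Sequence[str] | None = None
) -> AttributionReport:
    """Per-sample additive attributions for a tree model.

    base + sum(values) equals the model prediction for every sample.
    Non-tree models raise TypeError.
    """
    X = np.asarray(X, dtype=float)
    phi, base = ensemble_shap(model, X)
    names = (
        list(feature_names_list)
        if feature_names_list is not None
        else [f"f{i}" for i in range(X.shape[1])]
    )
    return AttributionReport(values=phi, base_values=base, feature_names=names)


def importance_by_permutation(
    model,
    X: np.ndarray,
    y: np.ndarray,
    metric: str = "rmse",
    n_repeats: int = 5,
    seed: int = 0,
    features: Sequence[int] | None = None,
) -> np.ndarray:
    """Mean loss increase when each feature column is permuted.

    Stand-in for implementation-specific loss-change diagnostics of boosted
    tree libraries; model-agnostic and seed-reproducible.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)

    def loss(pred: np.ndarray) -> float:
        if metric == "rmse":
            return float(np.sqrt(mean_squared_error(y, pred)))
        if metric == "mae":
            return float(mean_absolute_error(y, pred))
        raise ValueError(f"unknown metric {metric!r}")

    rng = np.random.default_rng(seed)
    baseline = loss(model.predict(X))
    cols = range(X.shape[1]) if features is None else features
    out = np.zeros(X.shape[1])
    for j in cols:
        deltas = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            deltas.append(loss(model.predict(Xp)) - baseline)
        out[j] = float(np.mean(deltas))
    return out
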