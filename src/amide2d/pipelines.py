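"""Scaler -> selector -> predictor pipelines and the chained SVR regressor.

Every model follows the same contract: features are standardised to zero
mean and unit variance, a feature-selection transformer reduces the 2975
spectral pixels to the informative subset, and a final predictor is tuned
by grid search inside a 5-fold group cross-validation (groups = proteins)
so that replicate spectra of one protein never straddle an inner split.

:class:`AnovaSVRChain` implements chained support-vector regression for a
pair of negatively correlated targets (sheet fraction first, then helix
fraction): the feature list is the deduplicated union of the top-k pixels
of two independent regression F-tests, the first stage predicts the first
target, and the second stage consumes the training features plus the first
stage's predictions as an extra standardised column.  The number of
features k is chosen outside the inner loop by minimising the training
RMSE, mirroring a manual tuning loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.decomposition import PCA
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.model_selection import GridSearchCV, GroupKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigurationError, DegenerateDesignError
from .selection import (
    FixedIndexSelector,
    TopKAnovaSelector,
    anova_f_regress,
    combine_chain_features,
    select_top_k,
)

__all__ = [
    "PipelineSpec",
    "build_pipeline",
    "inner_tune",
    "AnovaSVRChain",
    "fit_regression_chain",
    "predict_chain",
    "RegistryFit",
    "fit_sheet_registry_models",
    "fit_helix_length_classifier",
]

#: Default hyperparameter grids (standard desk-scale RBF/selection grids).
DEFAULT_K_GRID = (25, 50, 100)
DEFAULT_PCA_GRID = (5, 10, 20, 40)
DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID = ("scale", 1e-3, 1e-4)
DEFAULT_KNN_GRID = (3, 5, 11)
DEFAULT_DEPTH_GRID = (3, 5, None)
DEFAULT_STUMPS_GRID = (50, 100, 200)
RFOREST_TREES = 200

_CLASSIFIERS = {"svc_rbf", "knn", "dtree", "rforest", "adaboost"}
_REGRESSORS = {"svr_rbf"}


@dataclass
class PipelineSpec:
    """Configuration of one scaler/selector/predictor pipeline.

    ``selector`` is one of ``anova_f``, ``pca``, ``none`` or ``fixed``;
    ``predictor`` one of ``svc_rbf``, ``svr_rbf``, ``knn``, ``dtree``,
    ``rforest`` or ``adaboost``.  ``grid`` overrides the default
    hyperparameter search space (keys are pipeline parameter names such as
    ``select__k`` or ``predict__C``).
    """

    selector: str = "anova_f"
    predictor: str = "svc_rbf"
    grid: dict | None = None
    selector_params: dict = field(default_factory=dict)
    inner_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.selector not in ("anova_f", "pca", "none", "fixed"):
            raise ConfigurationError(f"unknown selector {self.selector!r}")
        if self.predictor not in _CLASSIFIERS | _REGRESSORS:
            raise ConfigurationError(f"unknown predictor {self.predictor!r}")
        if self.grid is not None and any(not v for v in self.grid.values()):
            raise ConfigurationError("hyperparameter grids must be non-empty")

    @property
    def is_classifier(self) -> bool:
        return self.predictor in _CLASSIFIERS


def build_pipeline(spec: PipelineSpec, *, epsilon: float | None = None) -> tuple[Pipeline, dict]:
    """Build the sklearn pipeline and its default search grid for a spec."""
    grid: dict = {}
    mode = "classif" if spec.is_classifier else "regress"

    if spec.selector == "anova_f":
        select = TopKAnovaSelector(mode=mode, **spec.selector_params)
        grid["select__k"] = list(DEFAULT_K_GRID)
    elif spec.selector == "pca":
        select = PCA(random_state=spec.seed, **spec.selector_params)
        grid["select__n_components"] = list(DEFAULT_PCA_GRID)
    elif spec.selector == "fixed":
        select = FixedIndexSelector(**spec.selector_params)
    else:
        select = "passthrough"

    if spec.predictor == "svc_rbf":
        predict = SVC(kernel="rbf")
        grid.update({"predict__C": list(DEFAULT_C_GRID), "predict__gamma": list(DEFAULT_GAMMA_GRID)})
    elif spec.predictor == "svr_rbf":
        predict = SVR(kernel="rbf", epsilon=0.1 if epsilon is None else epsilon)
        grid.update({"predict__C": list(DEFAULT_C_GRID), "predict__gamma": list(DEFAULT_GAMMA_GRID)})
    elif spec.predictor == "knn":
        predict = KNeighborsClassifier()
        grid["predict__n_neighbors"] = list(DEFAULT_KNN_GRID)
    elif spec.predictor == "dtree":
        predict = DecisionTreeClassifier(random_state=spec.seed)
        grid["predict__max_depth"] = list(DEFAULT_DEPTH_GRID)
    elif spec.predictor == "rforest":
        predict = RandomForestClassifier(n_estimators=RFOREST_TREES, random_state=spec.seed)
    else:  # adaboost over decision stumps
        predict = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1, random_state=spec.seed),
            random_state=spec.seed,
        )
        grid["predict__n_estimators"] = list(DEFAULT_STUMPS_GRID)

    if spec.grid is not None:
        grid = dict(spec.grid)
    pipeline = Pipeline([("scale", StandardScaler()), ("select", select), ("predict", predict)])
    return pipeline, grid


def inner_tune(
    X,
    y,
    groups,
    pipeline: Pipeline,
    grid: dict,
    *,
    inner_folds: int = 5,
    scoring: str = "accuracy",
) -> GridSearchCV:
    """Tune a pipeline by grid search in a group k-fold CV and refit it.

    All spectra of one protein stay on the same side of every inner split.
    Deterministic given the data: the first grid point encountered wins
    ties, and no stochastic component is left unseeded.
    """
    groups = np.asarray(groups)
    n_groups = np.unique(groups).size
    if n_groups < inner_folds:
        raise ConfigurationError(
            f"{n_groups} groups cannot support a {inner_folds}-fold group CV"
        )
    search = GridSearchCV(
        pipeline, grid, scoring=scoring, cv=GroupKFold(n_splits=inner_folds), refit=True
    )
    search.fit(X, y, groups=groups)
    return search


def _tuned_svr(X, y, groups, c_grid, gamma_grid, epsilon_rel, inner_folds) -> Pipeline:
    eps = max(epsilon_rel * float(np.std(y)), 1e-6)
    pipe = Pipeline([("scale", StandardScaler()), ("predict", SVR(kernel="rbf", epsilon=eps))])
    grid = {"predict__C": list(c_grid), "predict__gamma": list(gamma_grid)}
    search = inner_tune(
        X, y, groups, pipe, grid, inner_folds=inner_folds,
        scoring="neg_root_mean_squared_error",
    )
    return search.best_estimator_


class AnovaSVRChain(BaseEstimator, RegressorMixin):
    """Chained SVR over a dual-F-test feature union.

    ``fit`` expects ``Y`` with one column per chained target, in chain
    order (first column predicted first); predictions of earlier stages are
    appended to the feature block consumed by later stages.  Targets are
    conventionally percentages, predicted unclipped unless ``clip`` is set.

    Fitted attributes
    -----------------
    feature_indices_ : ndarray
        Union-selected feature columns (at most ``2 * k_``).
    k_ : int
        Per-test feature count chosen by the training-RMSE loop.
    stages_ : list of (target_name, fitted pipeline)
    training_rmse_ : ndarray
        Training RMSE per target at the selected k.
    """

    def __init__(
        self,
        k_grid: Sequence[int] = DEFAULT_K_GRID,
        c_grid: Sequence[float] = DEFAULT_C_GRID,
        gamma_grid: Sequence = DEFAULT_GAMMA_GRID,
        inner_folds: int = 5,
        epsilon_rel: float = 0.1,
        target_names: Sequence[str] = ("frac_beta_pct", "frac_alpha_pct"),
        clip: tuple[float, float] | None = None,
    ):
        self.k_grid = k_grid
        self.c_grid = c_grid
        self.gamma_grid = gamma_grid
        self.inner_folds = inner_folds
        self.epsilon_rel = epsilon_rel
        self.target_names = target_names
        self.clip = clip

    def _fit_stages(self, X, Y, idx, groups):
        Xs = X[:, idx]
        models, preds = [], []
        X_in = Xs
        for t in range(Y.shape[1]):
            model = _tuned_svr(
                X_in, Y[:, t], groups, self.c_grid, self.gamma_grid,
                self.epsilon_rel, self.inner_folds,
            )
            p = model.predict(X_in)
            models.append(model)
            preds.append(p)
            X_in = np.column_stack([Xs, *[q[:, None] for q in preds]])
        return models, np.column_stack(preds)

    def fit(self, X, Y, groups=None):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2 or Y.shape[1] != len(self.target_names):
            raise ValueError("Y must have one column per chained target")
        if groups is None:
            raise ConfigurationError("protein groups are required for inner tuning")
        n_features = X.shape[1]
        scores = [anova_f_regress(X, Y[:, t]) for t in range(Y.shape[1])]

        best = None
        for k in self.k_grid:
            if k > n_features:
                raise ValueError(f"k={k} exceeds the feature count {n_features}")
            idx = combine_chain_features(*[select_top_k(F, k) for F in scores])
            models, preds = self._fit_stages(X, Y, idx, groups)
            rmse = np.sqrt(np.mean((preds - Y) ** 2, axis=0))
            if best is None or float(rmse.mean()) < best[0]:
                best = (float(rmse.mean()), k, idx, models, rmse)

        _, self.k_, self.feature_indices_, models, self.training_rmse_ = best
        self.stages_ = list(zip(self.target_names, models))
        self.n_features_in_ = n_features
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from the fitted frame")
        Xs = X[:, self.feature_indices_]
        preds: list[np.ndarray] = []
        X_in = Xs
        for _, model in self.stages_:
            p = model.predict(X_in)
            preds.append(p)
            X_in = np.column_stack([Xs, *[q[:, None] for q in preds]])
        out = np.column_stack(preds)
        if self.clip is not None:
            out = np.clip(out, *self.clip)
        return out


def fit_regression_chain(
    frame,
    targets: Sequence[str] = ("frac_beta_pct", "frac_alpha_pct"),
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    **chain_params,
) -> AnovaSVRChain:
    """Fit an :class:`AnovaSVRChain` on a labelled feature frame."""
    missing = [t for t in targets if t not in frame.meta.columns]
    if missing:
        raise KeyError(f"frame lacks target columns {missing}")
    chain = AnovaSVRChain(k_grid=k_grid, target_names=tuple(targets), **chain_params)
    return chain.fit(frame.X, frame.meta[list(targets)].to_numpy(float), groups=frame.groups)


def predict_chain(chain: AnovaSVRChain, frame) -> np.ndarray:
    """Per-row predictions (columns in chain order, percent scale)."""
    return chain.predict(frame.X)


@dataclass
class RegistryFit:
    """One fitted sheet-registry regressor plus its feature list."""

    model: object
    feature_indices: np.ndarray

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if isinstance(self.model, DummyRegressor):
            return self.model.predict(X)
        return self.model.predict(X[:, self.feature_indices])


def fit_sheet_registry_models(
    X,
    y_parallel,
    y_antiparallel,
    groups,
    *,
    k: int = 40,
    parallel_override: Sequence[int] | None = None,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence = DEFAULT_GAMMA_GRID,
    epsilon_rel: float = 0.1,
    inner_folds: int = 5,
) -> dict[str, RegistryFit]:
    """Independent F-test + SVR fits for parallel / antiparallel sheet content.

    When ``parallel_override`` is given (typically the antiparallel model's
    selected features), the parallel model's feature list becomes the union
    of its own selection and the override — the domain-knowledge correction
    for the weak parallel-sheet signal.  A constant target yields a
    constant predictor with an empty own selection.
    """
    X = np.asarray(X, dtype=float)
    fits: dict[str, RegistryFit] = {}
    for name, y in (("antiparallel", y_antiparallel), ("parallel", y_parallel)):
        y = np.asarray(y, dtype=float)
        if float(np.std(y)) <= 1e-12:
            model = DummyRegressor(strategy="constant", constant=float(y[0])).fit(X[:, :1], y)
            idx = np.array([], dtype=int)
        else:
            idx = select_top_k(anova_f_regress(X, y), min(k, X.shape[1]))
            model = None
        if name == "parallel" and parallel_override is not None:
            idx = combine_chain_features(idx, parallel_override)
        if model is None:
            model = _tuned_svr(X[:, idx], y, groups, c_grid, gamma_grid, epsilon_rel, inner_folds)
        fits[name] = RegistryFit(model, idx)
    return fits


def fit_helix_length_classifier(
    X,
    y,
    groups,
    *,
    seed: int = 0,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    n_stumps_grid: Sequence[int] = DEFAULT_STUMPS_GRID,
    inner_folds: int = 5,
) -> GridSearchCV:
    """F-test selection + AdaBoost over decision stumps, inner-tuned.

    Boosting re-weights the training spectra at each iteration so that
    successive stumps focus on previously misclassified examples; the
    number of stumps and the feature count are tuned in the inner group CV.
    """
    if np.unique(np.asarray(y)).size < 2:
        raise DegenerateDesignError("helix-length training set contains a single class")
    spec = PipelineSpec(
        selector="anova_f",
        predictor="adaboost",
        grid={"select__k": list(k_grid), "predict__n_estimators": list(n_stumps_grid)},
        seed=seed,
    )
    pipeline, grid = build_pipeline(spec)
    return inner_tune(X, y, groups, pipeline, grid, inner_folds=inner_folds, scoring="accuracy")
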