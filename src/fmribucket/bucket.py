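"""The bucket-of-models build: split, covariate control, RFE, nine
classifiers, and iterative importance-based feature elimination.

The cohort is split 50:50 into training and testing halves (stratified by
group).  Age, sex and BMI are controlled by residualizing each feature on
the covariates with coefficients estimated on the training half only.
Recursive feature elimination proposes a candidate subset, then the loop
{fit all nine models -> drop zero-importance features and features whose
random-forest importance standard error exceeds the importance -> refit}
runs until every model clears the accuracy floor (69% by default), nothing
more is pruned, or the iteration cap is hit.

By default the floor is assessed by stratified cross-validation on the
training half.  Assessing it on the held-out test half — rebuilding until
the validation score clears the floor — leaks information from the test
set into feature selection; that mode remains available
(``floor_eval="test"``) for fidelity to the original procedure, but the
cross-validated mode is the scientifically safer default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureTable

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "CFS"

RF_NAME = "random_forest"
SVM_NAME = "linear_svm"
LOGISTIC_NAME = "logistic_regression"


def _scaled(estimator) -> Pipeline:
    return Pipeline([("scale", StandardScaler()), ("model", estimator)])


def default_models(seed: int = 0) -> list[tuple[str, object]]:
    """The nine classifiers of the bucket with pinned hyperparameters.

    Hyperparameters: 3 nearest neighbours; linear-kernel SVM at unit cost;
    unlimited-depth decision tree; 100-tree random forest; 50 rounds of
    boosting over depth-1 trees; Gaussian naive Bayes; default-regularized
    quadratic discriminant; L2 logistic regression; one hidden layer of
    100 units.  Scale-sensitive models are wrapped with a training-set
    standardizer.
    """
    return [
        ("k_nearest_neighbors", _scaled(KNeighborsClassifier(n_neighbors=3))),
        (SVM_NAME, _scaled(SVC(kernel="linear", C=1.0))),
        ("decision_tree", DecisionTreeClassifier(random_state=seed)),
        (RF_NAME, RandomForestClassifier(n_estimators=100, random_state=seed)),
        (
            "adaboost",
            AdaBoostClassifier(
                estimator=DecisionTreeClassifier(max_depth=1),
                n_estimators=50,
                random_state=seed,
            ),
        ),
        ("naive_bayes", GaussianNB()),
        # Ledoit-Wolf shrinkage keeps the class covariances invertible and
        # well-conditioned when features outnumber per-class samples, which
        # is the norm early in the build
        (
            "quadratic_discriminant",
            QuadraticDiscriminantAnalysis(solver="eigen", shrinkage="auto"),
        ),
        (LOGISTIC_NAME, _scaled(LogisticRegression(penalty="l2", max_iter=2000))),
        (
            "neural_net",
            _scaled(
                MLPClassifier(hidden_layer_sizes=(100,), max_iter=500, random_state=seed)
            ),
        ),
    ]


def fast_models(seed: int = 0) -> list[tuple[str, object]]:
    """A reduced three-model bucket for calibration studies at scale."""
    return [
        ("decision_tree", DecisionTreeClassifier(random_state=seed)),
        ("naive_bayes", GaussianNB()),
        (LOGISTIC_NAME, _scaled(LogisticRegression(penalty="l2", max_iter=2000))),
    ]


@dataclass
class BucketConfig:
    """Configuration of the model build.

    ``floor_eval``: "train_cv" checks the 69% floor by stratified 5-fold
    cross-validation on the training half (default, leakage-free);
    "test" checks it on held-out accuracy, reproducing the original
    rebuild-until-valid procedure.  ``covariate_mode``: "residualize"
    regresses age/sex/BMI out of every feature (train-estimated OLS),
    "append" adds them as extra features, "none" ignores them.
    """

    models: list[tuple[str, object]] | None = None
    accuracy_floor: float = 0.69
    split_ratio: float = 0.5
    max_iterations: int = 20
    floor_eval: str = "train_cv"
    covariate_mode: str = "residualize"
    use_rfe: bool = True
    stratify: bool = True
    positive_label: str = POSITIVE_LABEL
    covariates: tuple[str, ...] = ("age", "sex", "bmi")
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.accuracy_floor < 1:
            raise ValueError("accuracy_floor must lie in (0, 1)")
        if not 0 < self.split_ratio < 1:
            raise ValueError("split_ratio must lie in (0, 1)")
        if self.floor_eval not in ("train_cv", "test"):
            raise ValueError(f"unknown floor_eval {self.floor_eval!r}")
        if self.covariate_mode not in ("residualize", "append", "none"):
            raise ValueError(f"unknown covariate_mode {self.covariate_mode!r}")

    def build_models(self) -> list[tuple[str, object]]:
        specs = self.models if self.models is not None else default_models(self.seed)
        return [(name, clone(est)) for name, est in specs]


@dataclass
class BucketResult:
    """One build iteration: per-model predictions, accuracies, importances."""

    iteration: int
    features_used: list[str]
    predictions: pd.DataFrame  # models x test subjects, True = positive class
    accuracies: dict[str, float]
    rf_importances: pd.Series | None = None
    rf_importance_se: pd.Series | None = None
    svm_coef: pd.Series | None = None
    logistic_coef: pd.Series | None = None
    failed_models: list[str] = field(default_factory=list)

    @property
    def model_names(self) -> list[str]:
        return list(self.predictions.index)

    def min_accuracy(self) -> float:
        return min(self.accuracies.values())

    def mean_accuracy(self) -> float:
        return float(np.mean(list(self.accuracies.values())))


@dataclass
class BuildOutcome:
    """Final state of the iterative build plus the full iteration log."""

    final_features: list[str]
    final_result: BucketResult
    log: list[dict]
    converged: bool
    termination: str  # "floor" | "no_prune" | "max_iterations"
    train_index: pd.Index
    test_index: pd.Index
    rfe_features: list[str] | None = None


def split_cohort(
    table: FeatureTable, ratio: float = 0.5, seed: int = 0, stratify: bool = True
) -> tuple[pd.Index, pd.Index]:
    """Disjoint, exhaustive train/test subject-id sets (stratified by group)."""
    y = table.groups
    counts = y.value_counts()
    if len(counts) < 2:
        raise ValueError("both classes must be present to split")
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"class(es) {small} have fewer than 2 members")
    idx = table.counts.index
    train_idx, test_idx = train_test_split(
        idx,
        train_size=ratio,
        random_state=seed,
        stratify=y if stratify else None,
        shuffle=True,
    )
    return pd.Index(train_idx), pd.Index(test_idx)


def _encode_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    out = cov.copy()
    if "sex" in out.columns and out["sex"].dtype == object:
        out["sex"] = (out["sex"] == "M").astype(float)
    return out.astype(float)


def residualize_covariates(
    train_X: pd.DataFrame,
    test_X: pd.DataFrame,
    train_cov: pd.DataFrame,
    test_cov: pd.DataFrame,
    train_groups: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove covariate effects from each feature; return adjusted matrices.

    OLS with intercept, coefficients estimated on the training rows only
    and applied unchanged to the test rows.  Constant covariates are
    dropped; if none remain the inputs pass through unchanged.

    When ``train_groups`` is supplied the covariate slopes are estimated
    with the group label in the design (ANCOVA-style) and only the
    intercept-plus-covariate contribution is subtracted.  This matters
    when a covariate is imbalanced across groups (here sex: three quarters
    of one cohort is male versus one quarter of the other): a pooled
    regression would attribute genuine group differences to the covariate
    and strip them from every feature.
    """
    if train_cov.isna().any().any() or test_cov.isna().any().any():
        raise ValueError("covariates must be complete (no missing values)")
    train_cov = _encode_covariates(train_cov)
    test_cov = _encode_covariates(test_cov[train_cov.columns])
    keep = [c for c in train_cov.columns if train_cov[c].nunique() > 1]
    if not keep:
        return train_X.copy(), test_X.copy()
    C_tr = np.column_stack([np.ones(len(train_cov)), train_cov[keep].to_numpy()])
    C_te = np.column_stack([np.ones(len(test_cov)), test_cov[keep].to_numpy()])
    n_cov_cols = C_tr.shape[1]
    D_tr = C_tr
    if train_groups is not None:
        levels = pd.unique(np.asarray(train_groups))
        dummies = np.column_stack(
            [(np.asarray(train_groups) == lev).astype(float) for lev in levels[1:]]
        ) if len(levels) > 1 else np.empty((len(C_tr), 0))
        D_tr = np.column_stack([C_tr, dummies])
    if np.linalg.matrix_rank(D_tr) < D_tr.shape[1]:
        raise ValueError("covariate design is rank-deficient after dropping constants")
    beta, *_ = np.linalg.lstsq(D_tr, train_X.to_numpy(dtype=float), rcond=None)
    beta_cov = beta[:n_cov_cols]
    res_tr = train_X.to_numpy(dtype=float) - C_tr @ beta_cov
    res_te = test_X.to_numpy(dtype=float) - C_te @ beta_cov
    return (
        pd.DataFrame(res_tr, index=train_X.index, columns=train_X.columns),
        pd.DataFrame(res_te, index=test_X.index, columns=test_X.columns),
    )


def recursive_feature_elimination(
    train_X: pd.DataFrame,
    train_y: pd.Series,
    seed: int = 0,
    cv_folds: int = 5,
) -> list[str]:
    """Backward elimination ranked by logistic-regression coefficient size.

    One feature (the smallest |coefficient|) is removed per step; the
    returned subset is the one maximizing stratified k-fold cross-validated
    accuracy on the training data, with ties resolved toward the larger
    subset.  Feature order in the result follows the input column order.
    """
    if train_X.shape[1] < 2:
        raise ValueError("need at least 2 features for elimination")
    y = np.asarray(train_y)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    estimator = _scaled(LogisticRegression(penalty="l2", max_iter=2000))

    current = list(train_X.columns)
    trace: list[tuple[list[str], float]] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        while current:
            X = train_X[current].to_numpy(dtype=float)
            score = float(np.mean(cross_val_score(clone(estimator), X, y, cv=cv)))
            trace.append((list(current), score))
            if len(current) == 1:
                break
            model = clone(estimator).fit(X, y)
            coefs = np.abs(model.named_steps["model"].coef_[0])
            current.pop(int(np.argmin(coefs)))
    # first entry with the max score is the largest subset achieving it
    best_idx = int(np.argmax([s for _, s in trace]))
    best_score = trace[best_idx][1]
    for feats, score in trace:
        if score >= best_score:
            return feats
    return trace[best_idx][0]


def _positive_scores(model, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-sample score for the positive class and the decision cut.

    Probability 0.5 (or decision value 0) ties break toward the positive
    class: scores >= cut predict positive.
    """
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1], 0.5
    return model.decision_function(X), 0.0


def fit_bucket(
    train_X: pd.DataFrame,
    train_y: pd.Series,
    test_X: pd.DataFrame,
    test_y: pd.Series,
    config: BucketConfig,
    features: list[str] | None = None,
    iteration: int = 1,
) -> BucketResult:
    """Fit every model of the bucket on identical train rows and features.

    Records per-model test predictions and accuracy, the random-forest
    mean-decrease-in-impurity importances with their standard errors
    (per-tree standard deviation over sqrt(n_trees)), and the linear-SVM
    and logistic-regression coefficients.  A model that raises during fit
    or predict is logged, marked failed and excluded; the run continues.
    """
    if features is None:
        features = list(train_X.columns)
    if not features:
        raise ValueError("feature list is empty")
    Xtr = train_X[features].to_numpy(dtype=float)
    Xte = test_X[features].to_numpy(dtype=float)
    ytr = (np.asarray(train_y) == config.positive_label).astype(int)
    yte = (np.asarray(test_y) == config.positive_label).astype(int)

    predictions, accuracies, failed = {}, {}, []
    rf_imp = rf_se = svm_coef = logit_coef = None
    for name, model in config.build_models():
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(Xtr, ytr)
                scores, cut = _positive_scores(model, Xte)
        except Exception as err:  # noqa: BLE001 - any model failure is survivable
            logger.warning("model %s failed (%s); excluded from this iteration", name, err)
            failed.append(name)
            continue
        pred = scores >= cut
        predictions[name] = pred
        accuracies[name] = float(np.mean(pred == yte.astype(bool)))

        inner = model.named_steps["model"] if isinstance(model, Pipeline) else model
        if name == RF_NAME:
            per_tree = np.array([t.feature_importances_ for t in inner.estimators_])
            rf_imp = pd.Series(inner.feature_importances_, index=features)
            rf_se = pd.Series(per_tree.std(axis=0) / np.sqrt(len(per_tree)), index=features)
        elif name == SVM_NAME:
            svm_coef = pd.Series(inner.coef_[0], index=features)
        elif name == LOGISTIC_NAME:
            logit_coef = pd.Series(inner.coef_[0], index=features)

    if not predictions:
        raise RuntimeError("every model in the bucket failed to fit")
    pred_df = pd.DataFrame(predictions, index=test_X.index).T
    return BucketResult(
        iteration, list(features), pred_df, accuracies,
        rf_imp, rf_se, svm_coef, logit_coef, failed,
    )


def importance_prune(result: BucketResult) -> list[str]:
    """Drop zero-importance features, then those with SE above the importance.

    Order of survivors follows the input feature order.  If the rule would
    empty the list, the single top-importance feature is kept (warned).
    Without a random forest in the bucket there is nothing to prune on and
    the feature list passes through unchanged.
    """
    if result.rf_importances is None:
        return list(result.features_used)
    imp = result.rf_importances
    se = result.rf_importance_se
    survivors = [f for f in result.features_used if imp[f] > 0 and se[f] <= imp[f]]
    if not survivors:
        top = imp.idxmax()
        warnings.warn(
            "importance pruning would remove every feature; keeping top feature "
            f"{top!r}",
            stacklevel=2,
        )
        return [top]
    return survivors


def _floor_accuracies(
    train_X: pd.DataFrame,
    train_y: pd.Series,
    result: BucketResult,
    config: BucketConfig,
) -> dict[str, float]:
    """Per-model accuracies used for the floor check."""
    if config.floor_eval == "test":
        return dict(result.accuracies)
    ytr = (np.asarray(train_y) == config.positive_label).astype(int)
    X = train_X[result.features_used].to_numpy(dtype=float)
    n_splits = min(config.cv_folds, int(np.bincount(ytr).min()))
    if n_splits < 2:
        return dict(result.accuracies)
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=config.seed)
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, model in config.build_models():
            if name in result.failed_models:
                continue
            try:
                out[name] = float(np.mean(cross_val_score(model, X, ytr, cv=cv)))
            except Exception:  # noqa: BLE001
                continue
    return out


def iterate_build(
    table: FeatureTable,
    config: BucketConfig | None = None,
    seed: int | None = None,
    split: tuple[pd.Index, pd.Index] | None = None,
) -> BuildOutcome:
    """The full iterative build on a screened feature table.

    Splits the cohort (unless a split is supplied), applies covariate
    control, optionally narrows features by recursive elimination, then
    loops {fit bucket -> floor check -> importance prune -> refit} until
    every non-failed model clears the accuracy floor, no feature is pruned,
    or the iteration cap is reached (the last is flagged non-converged).
    Deterministic given the seed; feature sets never grow across
    iterations.
    """
    config = config or BucketConfig()
    if seed is None:
        seed = config.seed
    else:
        from dataclasses import replace

        config = replace(config, seed=seed)

    if split is None:
        train_idx, test_idx = split_cohort(
            table, config.split_ratio, seed=seed, stratify=config.stratify
        )
    else:
        train_idx, test_idx = split
    train_X = table.counts.loc[train_idx].astype(float)
    test_X = table.counts.loc[test_idx].astype(float)
    train_y = table.groups.loc[train_idx]
    test_y = table.groups.loc[test_idx]

    cov_cols = [c for c in config.covariates if c in table.metadata.columns]
    if config.covariate_mode == "residualize" and cov_cols:
        train_X, test_X = residualize_covariates(
            train_X, test_X,
            table.metadata.loc[train_idx, cov_cols],
            table.metadata.loc[test_idx, cov_cols],
            train_groups=train_y,
        )
    elif config.covariate_mode == "append" and cov_cols:
        train_X = train_X.join(_encode_covariates(table.metadata.loc[train_idx, cov_cols]))
        test_X = test_X.join(_encode_covariates(table.metadata.loc[test_idx, cov_cols]))

    rfe_features = None
    features = list(train_X.columns)
    if config.use_rfe and len(features) >= 2:
        rfe_features = recursive_feature_elimination(
            train_X, train_y, seed=seed, cv_folds=config.cv_folds
        )
        features = rfe_features

    log: list[dict] = []
    converged = False
    termination = "max_iterations"
    result = None
    for iteration in range(1, config.max_iterations + 1):
        result = fit_bucket(
            train_X, train_y, test_X, test_y, config, features, iteration
        )
        floor_acc = _floor_accuracies(train_X, train_y, result, config)
        floor_met = bool(floor_acc) and all(
            a >= config.accuracy_floor for a in floor_acc.values()
        )
        pruned = importance_prune(result)
        log.append(
            {
                "iteration": iteration,
                "n_features": len(features),
                "features": list(features),
                "test_accuracies": dict(result.accuracies),
                "floor_accuracies": floor_acc,
                "floor_met": floor_met,
                "failed_models": list(result.failed_models),
                "n_pruned": len(features) - len(pruned),
            }
        )
        if floor_met:
            converged, termination = True, "floor"
            break
        if len(pruned) == len(features):
            termination = "no_prune"
            break
        features = pruned
    if termination == "max_iterations":
        logger.warning("build hit max_iterations=%d without meeting the floor", config.max_iterations)

    return BuildOutcome(
        final_features=list(result.features_used),
        final_result=result,
        log=log,
        converged=converged,
        termination=termination,
        train_index=pd.Index(train_idx),
        test_index=pd.Index(test_idx),
        rfe_features=rfe_features,
    )
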