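"""Feature ranking, incremental subset selection, and KNN evaluation.

The selection procedure has two stages.  First a gradient-boosted tree
ensemble (XGBoost), tuned by Bayesian optimization with early stopping,
ranks the 20 per-sample statistics by split frequency ("F score").
Second, an incremental search evaluates the top-n subsets for
n = 1..20 with repeated stratified k-fold cross-validation and picks the
smallest subset statistically at the accuracy plateau.  The chosen
subset then feeds a k-nearest-neighbor classifier evaluated by
leave-one-out cross-validation and one-vs-rest ROC analysis.

Features are z-scored before KNN, with the scaler fit inside each
training fold to avoid leakage; ROC scores are the KNN neighbor-vote
fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc, confusion_matrix, roc_curve
from sklearn.model_selection import LeaveOneOut, StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .stats import FEATURE_COLUMNS, LABELS

__all__ = [
    "ModelConfig",
    "RankingResult",
    "SelectionCurve",
    "ClassifierReport",
    "rank_features",
    "incremental_selection",
    "knn_evaluate",
    "roc_one_vs_rest",
]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the selection/classification stage."""

    k_neighbors: int = 6
    cv_folds: int = 5
    cv_repeats: int = 5
    bayes_opt_budget: int = 12
    bayes_opt_init: int = 6
    early_stopping_rounds: int = 10
    n_estimators_max: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.bayes_opt_budget < self.bayes_opt_init:
            raise ValueError("budget must cover the initial random draws")


@dataclass
class RankingResult:
    """Features ordered by descending importance."""

    ranking: list[tuple[str, float]]
    hyperparameters: dict
    seed: int

    @property
    def ordered_features(self) -> list[str]:
        return [name for name, _ in self.ranking]

    def rank_of(self, feature: str) -> int:
        """1-based rank of a feature."""
        return self.ordered_features.index(feature) + 1


@dataclass
class SelectionCurve:
    """Accuracy (%) of the top-n feature subsets."""

    n_features: list[int]
    mean_accuracy: list[float]
    sd_accuracy: list[float]
    optimal_n: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_features": self.n_features,
                "mean_accuracy_pct": self.mean_accuracy,
                "sd_accuracy_pct": self.sd_accuracy,
            }
        )


@dataclass
class ClassifierReport:
    """KNN evaluation: OCA, LOO CVCA, per-class ROC, confusion matrix."""

    oca_pct: float
    cvca_pct: float
    auc_per_class: dict[str, float]
    roc_curves: dict[str, tuple[np.ndarray, np.ndarray]]
    confusion: pd.DataFrame
    k: int
    features: list[str]
    seed: int


_SEARCH_SPACE = {
    # (low, high, log-scale?)
    "learning_rate": (0.03, 0.4, True),
    "max_depth": (2, 6, False),
    "subsample": (0.6, 1.0, False),
    "min_child_weight": (1.0, 8.0, False),
}


def _decode_params(x: np.ndarray) -> dict:
    params = {}
    for xi, (name, (lo, hi, log)) in zip(x, _SEARCH_SPACE.items()):
        v = np.exp(np.log(lo) + xi * (np.log(hi) - np.log(lo))) if log else lo + xi * (hi - lo)
        if name == "max_depth":
            v = int(round(v))
        params[name] = v
    return params


def _table_xy(table: pd.DataFrame, features: list[str] | None = None):
    feats = list(features) if features is not None else list(FEATURE_COLUMNS)
    X = table[feats].to_numpy(dtype=float)
    labels = table["label"].to_numpy()
    classes = [c for c in LABELS if c in set(labels)]
    y = np.array([classes.index(l) for l in labels])
    return X, y, classes, feats


def _make_xgb(params: dict, config: ModelConfig, n_classes: int, seed: int) -> XGBClassifier:
    # column subsampling decorrelates importance among collinear features,
    # so near-duplicate informative columns both accumulate splits
    return XGBClassifier(
        n_estimators=config.n_estimators_max,
        objective="multi:softprob" if n_classes > 2 else "binary:logistic",
        tree_method="exact",
        colsample_bytree=0.7,
        n_jobs=1,
        random_state=seed,
        eval_metric="mlogloss" if n_classes > 2 else "logloss",
        early_stopping_rounds=None,
        verbosity=0,
        **params,
    )


def _cv_accuracy(
    X: np.ndarray, y: np.ndarray, params: dict, config: ModelConfig, seed: int
) -> float:
    """Stratified k-fold accuracy of an XGBoost fit with early stopping."""
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        model = _make_xgb(params, config, len(np.unique(y)), seed)
        model.set_params(early_stopping_rounds=config.early_stopping_rounds)
        model.fit(X[tr], y[tr], eval_set=[(X[te], y[te])], verbose=False)
        accs.append(float((model.predict(X[te]) == y[te]).mean()))
    return float(np.mean(accs))


def _bayes_optimize(
    X: np.ndarray, y: np.ndarray, config: ModelConfig, seed: int
) -> tuple[dict, list[tuple[dict, float]]]:
    """Gaussian-process Bayesian optimization over the XGBoost space.

    Random initial draws followed by expected-improvement proposals on a
    GP surrogate over the unit hypercube; the budget counts total
    objective evaluations.
    """
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern
    from scipy.stats import norm

    rng = np.random.default_rng(seed)
    dim = len(_SEARCH_SPACE)
    xs: list[np.ndarray] = []
    ys: list[float] = []
    history: list[tuple[dict, float]] = []

    def evaluate(x: np.ndarray) -> None:
        params = _decode_params(x)
        acc = _cv_accuracy(X, y, params, config, seed)
        xs.append(x)
        ys.append(acc)
        history.append((params, acc))

    for _ in range(config.bayes_opt_init):
        evaluate(rng.uniform(0, 1, dim))
    gp = GaussianProcessRegressor(
        kernel=Matern(length_scale=0.3, length_scale_bounds=(1e-2, 1e1), nu=2.5),
        normalize_y=True,
        random_state=seed,
        alpha=1e-4,
    )
    for _ in range(config.bayes_opt_budget - config.bayes_opt_init):
        gp.fit(np.array(xs), np.array(ys))
        cand = rng.uniform(0, 1, size=(256, dim))
        mu, sigma = gp.predict(cand, return_std=True)
        best = max(ys)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (mu - best) / np.maximum(sigma, 1e-12)
            ei = (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)
        evaluate(cand[int(np.argmax(ei))])
    best_params = history[int(np.argmax(ys))][0]
    return best_params, history


def rank_features(table: pd.DataFrame, config: ModelConfig = ModelConfig()) -> RankingResult:
    """Rank the 20 statistics by XGBoost split-frequency importance.

    Hyperparameters come from Bayesian optimization of cross-validated
    accuracy; the final model fits all samples with early stopping on a
    stratified holdout, and importance is the F score (number of splits
    using each feature, summed over all trees).  Features never used in
    a split score 0 and sort after all used features, ties broken by
    column order.
    """
    X, y, classes, feats = _table_xy(table)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes to rank features")
    counts = np.bincount(y)
    if counts.min() < config.cv_folds:
        raise ValueError("each class needs >= cv_folds samples")

    best_params, history = _bayes_optimize(X, y, config, config.seed)

    Xtr, Xval, ytr, yval = train_test_split(
        X, y, test_size=0.25, stratify=y, random_state=config.seed
    )
    model = _make_xgb(best_params, config, len(classes), config.seed)
    model.set_params(early_stopping_rounds=config.early_stopping_rounds)
    model.fit(Xtr, ytr, eval_set=[(Xval, yval)], verbose=False)

    fscores = model.get_booster().get_score(importance_type="weight")
    importance = {f: float(fscores.get(f"f{i}", 0.0)) for i, f in enumerate(feats)}
    order = sorted(
        feats, key=lambda f: (-importance[f], feats.index(f))
    )
    ranking = [(f, importance[f]) for f in order]
    return RankingResult(
        ranking=ranking,
        hyperparameters={**best_params, "n_evaluations": len(history)},
        seed=config.seed,
    )


def incremental_selection(
    table: pd.DataFrame,
    ranking: RankingResult,
    config: ModelConfig = ModelConfig(),
) -> SelectionCurve:
    """Accuracy of the top-n ranked subsets, n = 1..p.

    Each subset is evaluated with ``cv_repeats`` runs of stratified
    ``cv_folds``-fold cross-validation of an XGBoost classifier using
    the tuned hyperparameters.  The optimal n is the smallest subset
    whose mean accuracy comes within one pooled SD of the global
    maximum — a reproducible reading of "the plateau starts here".
    """
    params = {
        k: v for k, v in ranking.hyperparameters.items() if k in _SEARCH_SPACE
    }
    feats = ranking.ordered_features
    missing = set(feats) - set(table.columns)
    if missing:
        raise ValueError(f"ranking covers unknown columns: {sorted(missing)}")
    ns, means, sds = [], [], []
    for n in range(1, len(feats) + 1):
        X, y, _, _ = _table_xy(table, feats[:n])
        accs = []
        for rep in range(config.cv_repeats):
            skf = StratifiedKFold(
                n_splits=config.cv_folds, shuffle=True, random_state=config.seed + rep
            )
            for tr, te in skf.split(X, y):
                model = _make_xgb(params, config, len(np.unique(y)), config.seed + rep)
                model.set_params(n_estimators=60)
                model.fit(X[tr], y[tr], verbose=False)
                accs.append(float((model.predict(X[te]) == y[te]).mean()))
        ns.append(n)
        means.append(100.0 * float(np.mean(accs)))
        sds.append(100.0 * float(np.std(accs, ddof=1)))
    means_arr, sds_arr = np.array(means), np.array(sds)
    best = int(np.argmax(means_arr))
    pooled_sd = float(np.sqrt(np.mean(sds_arr**2)))
    at_plateau = means_arr >= means_arr[best] - pooled_sd
    optimal_n = int(np.argmax(at_plateau)) + 1
    return SelectionCurve(ns, list(means_arr), list(sds_arr), optimal_n)


def knn_evaluate(
    table: pd.DataFrame,
    feature_subset: list[str],
    config: ModelConfig = ModelConfig(),
) -> ClassifierReport:
    """KNN classification of the table on a feature subset.

    Features are z-scored (scaler fit on each training fold).  OCA fits
    and scores on all samples; CVCA uses leave-one-out.  ROC curves are
    one-vs-rest on the LOO neighbor-vote fractions.
    """
    if not feature_subset:
        raise ValueError("feature subset is empty")
    X, y, classes, _ = _table_xy(table, list(feature_subset))
    n = len(y)
    if config.k_neighbors >= n:
        raise ValueError(f"k={config.k_neighbors} must be < n_samples={n}")
    if np.bincount(y).min() < 1:
        raise ValueError("every class needs at least one sample")

    def fit_knn(Xtr, ytr):
        scaler = StandardScaler().fit(Xtr)
        knn = KNeighborsClassifier(n_neighbors=config.k_neighbors)
        knn.fit(scaler.transform(Xtr), ytr)
        return scaler, knn

    scaler, knn = fit_knn(X, y)
    oca = 100.0 * float((knn.predict(scaler.transform(X)) == y).mean())

    loo_pred = np.empty(n, dtype=int)
    loo_proba = np.zeros((n, len(classes)))
    for tr, te in LeaveOneOut().split(X):
        s, m = fit_knn(X[tr], y[tr])
        Xte = s.transform(X[te])
        loo_pred[te] = m.predict(Xte)
        proba = m.predict_proba(Xte)
        for j, cls_idx in enumerate(m.classes_):
            loo_proba[te, cls_idx] = proba[:, j]
    cvca = 100.0 * float((loo_pred == y).mean())

    aucs, curves = roc_one_vs_rest(loo_proba, y, class_names=classes)
    conf = confusion_matrix(y, loo_pred, labels=range(len(classes)))
    conf_df = pd.DataFrame(conf, index=classes, columns=classes)
    return ClassifierReport(
        oca_pct=oca,
        cvca_pct=cvca,
        auc_per_class=aucs,
        roc_curves=curves,
        confusion=conf_df,
        k=config.k_neighbors,
        features=list(feature_subset),
        seed=config.seed,
    )


def roc_one_vs_rest(
    scores: np.ndarray,
    y: np.ndarray,
    class_names: list[str] | None = None,
) -> tuple[dict[str, float], dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Per-class one-vs-rest ROC curves and trapezoidal AUCs.

    ``scores`` is (n_samples, n_classes) with each column the score for
    that class being positive (e.g. KNN vote fractions); every class
    must have at least one positive and one negative sample.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    n_classes = scores.shape[1]
    if class_names is None:
        class_names = [str(i) for i in range(n_classes)]
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs >= 2 classes present")
    aucs, curves = {}, {}
    for idx, name in enumerate(class_names):
        pos = (y == idx).astype(int)
        if pos.sum() == 0 or pos.sum() == len(pos):
            raise ValueError(f"class {name!r} lacks positives or negatives")
        fpr, tpr, _ = roc_curve(pos, scores[:, idx])
        aucs[name] = float(auc(fpr, tpr))
        curves[name] = (fpr, tpr)
    return aucs, curves
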