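"""Binary LLPS-behavior classifier and its cross-validation protocol.

The model takes the 131-feature vector (29 protein + 97 RNA + 5
condition features) and predicts whether the protein–RNA pair forms
liquid-like condensates under the given conditions.  Evaluation follows
repeated stratified group 10-fold cross-validation (SG10CV): records
sharing a protein sequence form a group and never straddle a
train/test split; each 9:1 fold tunes hyperparameters by inner
stratified 5-fold CV on ROC-AUC; the whole 10-fold loop is repeated
(default 10 times) and per-repeat mean ROC-AUCs are averaged.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.base import clone
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import GroupKFold, StratifiedGroupKFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .preprocess import (
    CONDITION_FEATURE_NAMES,
    condition_vector,
    encode_label,
    filter_for_behavior_model,
)
from .protein_features import PROTEIN_FEATURE_NAMES, protein_descriptors
from .rna_features import RNA_FEATURE_NAMES, rna_descriptors

log = logging.getLogger(__name__)

N_FEATURES = 131
FPR_GRID = np.linspace(0.0, 1.0, 101)


def feature_names() -> list[str]:
    """The 131 feature names in vector order (protein ⊕ RNA ⊕ condition)."""
    return PROTEIN_FEATURE_NAMES + RNA_FEATURE_NAMES + CONDITION_FEATURE_NAMES


def sequence_feature_names() -> list[str]:
    """The 126 sequence-derived feature names (protein ⊕ RNA)."""
    return PROTEIN_FEATURE_NAMES + RNA_FEATURE_NAMES


def assemble_features(protein_seq: str, rna_seq: str, conditions) -> np.ndarray:
    """Build one 131-feature vector from sequences and a ConditionVector."""
    cond = conditions.as_array() if hasattr(conditions, "as_array") else np.asarray(
        conditions, dtype=float
    )
    if cond.shape != (5,):
        raise ValueError(f"expected 5 condition features, got shape {cond.shape}")
    return np.concatenate(
        [protein_descriptors(protein_seq), rna_descriptors(rna_seq), cond]
    )


class _DescriptorCache:
    """Per-unique-sequence descriptor cache (datasets repeat sequences)."""

    def __init__(self):
        self.protein: dict[str, np.ndarray] = {}
        self.rna: dict[str, np.ndarray] = {}

    def protein_vec(self, seq: str) -> np.ndarray:
        if seq not in self.protein:
            self.protein[seq] = protein_descriptors(seq)
        return self.protein[seq]

    def rna_vec(self, seq: str) -> np.ndarray:
        if seq not in self.rna:
            self.rna[seq] = rna_descriptors(seq)
        return self.rna[seq]


def featurize_records(records, config: dict | None = None):
    """Filter records and build the design matrix for the behavior model.

    Returns ``(X, y, groups, kept, excluded)`` where X is (n, 131),
    y the binary labels, and groups the exact protein sequences used as
    cross-validation group keys.
    """
    kept, excluded = filter_for_behavior_model(records, config)
    cache = _DescriptorCache()
    rows, labels, groups = [], [], []
    for record in kept:
        cond = condition_vector(record, config)
        rows.append(
            np.concatenate(
                [
                    cache.protein_vec(record.protein_sequence),
                    cache.rna_vec(record.rna_sequence),
                    cond.as_array(),
                ]
            )
        )
        labels.append(encode_label(record.morphology))
        groups.append(record.protein_sequence)
    X = np.array(rows, dtype=float) if rows else np.empty((0, N_FEATURES))
    return X, np.array(labels, dtype=int), np.array(groups, dtype=object), kept, excluded


# ---------------------------------------------------------------------------
# Cross-validation plans
# ---------------------------------------------------------------------------

@dataclass
class CVPlan:
    """Group-intact fold assignment for one k-fold pass."""

    k: int
    seed: int
    folds: list[tuple[np.ndarray, np.ndarray]]
    repeat: int = 0

    def test_groups(self, groups) -> list[set]:
        groups = np.asarray(groups, dtype=object)
        return [set(groups[test]) for _, test in self.folds]


def make_sg10cv_plan(labels, groups, k: int = 10, seed: int = 0, repeat: int = 0) -> CVPlan:
    """Stratified group k-fold plan: label-balanced, group-intact folds.

    Groups are assigned whole to folds so no protein sequence appears in
    both train and test of any fold; fold label distributions track the
    overall distribution.  Deterministic given the seed.
    """
    labels = np.asarray(labels)
    groups = np.asarray(groups, dtype=object)
    n_groups = len(set(groups))
    if n_groups < k:
        raise ValueError(f"{n_groups} groups < {k} folds")
    splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [
        (train.copy(), test.copy())
        for train, test in splitter.split(np.zeros(len(labels)), labels, groups)
    ]
    return CVPlan(k=k, seed=seed, folds=folds, repeat=repeat)


def make_g10cv_plan(groups, k: int = 10) -> CVPlan:
    """Unstratified group k-fold plan (size-balanced, deterministic)."""
    groups = np.asarray(groups, dtype=object)
    n_groups = len(set(groups))
    if n_groups < k:
        raise ValueError(f"{n_groups} groups < {k} folds")
    splitter = GroupKFold(n_splits=k)
    folds = [
        (train.copy(), test.copy())
        for train, test in splitter.split(np.zeros(len(groups)), groups=groups)
    ]
    return CVPlan(k=k, seed=0, folds=folds)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def standardize(train_matrix):
    """Fit a zero-mean / unit-variance transform on the training rows only.

    Zero-variance columns pass through unscaled (logged).  Returns the
    fitted transform and the transformed training matrix.
    """
    train_matrix = np.asarray(train_matrix, dtype=float)
    if train_matrix.size == 0:
        raise ValueError("empty training matrix")
    scaler = StandardScaler()
    transformed = scaler.fit_transform(train_matrix)
    constant = np.where(np.isclose(scaler.var_, 0.0))[0]
    if constant.size:
        log.warning("%d zero-variance column(s) pass through unscaled", constant.size)
    return scaler, transformed


# ---------------------------------------------------------------------------
# Algorithms
# ---------------------------------------------------------------------------

@dataclass
class AlgorithmSpec:
    name: str
    factory: callable          # (params, seed) -> unfitted estimator
    default_grid: dict         # param name -> list of values
    needs_scaling: bool
    has_importances: bool


def _make_lightgbm(params, seed):
    from lightgbm import LGBMClassifier

    return LGBMClassifier(
        random_state=seed, n_jobs=1, verbose=-1, deterministic=True,
        force_row_wise=True, **params,
    )


ALGORITHMS: dict[str, AlgorithmSpec] = {
    "lr": AlgorithmSpec(
        "lr",
        lambda p, s: LogisticRegression(max_iter=2000, random_state=s, **p),
        {"C": [0.01, 0.1, 1.0, 10.0, 100.0]},
        needs_scaling=True,
        has_importances=False,
    ),
    "knn": AlgorithmSpec(
        "knn",
        lambda p, s: KNeighborsClassifier(**p),
        {"n_neighbors": [3, 5, 11]},
        needs_scaling=True,
        has_importances=False,
    ),
    "svm": AlgorithmSpec(
        "svm",
        lambda p, s: SVC(probability=True, random_state=s, **p),
        {"C": [0.1, 1.0, 10.0]},
        needs_scaling=True,
        has_importances=False,
    ),
    "gaussiannb": AlgorithmSpec(
        "gaussiannb",
        lambda p, s: GaussianNB(**p),
        {},
        needs_scaling=True,
        has_importances=False,
    ),
    "rf": AlgorithmSpec(
        "rf",
        lambda p, s: RandomForestClassifier(random_state=s, n_jobs=1, **p),
        {"n_estimators": [100, 300], "max_depth": [3, None]},
        needs_scaling=False,
        has_importances=True,
    ),
    "lightgbm": AlgorithmSpec(
        "lightgbm",
        _make_lightgbm,
        {"n_estimators": [100, 300]},
        needs_scaling=False,
        has_importances=True,
    ),
    "adaboost": AlgorithmSpec(
        "adaboost",
        lambda p, s: AdaBoostClassifier(random_state=s, **p),
        {"n_estimators": [50, 100], "learning_rate": [0.5, 1.0]},
        needs_scaling=False,
        has_importances=True,
    ),
}


def get_algorithm(name: str) -> AlgorithmSpec:
    try:
        return ALGORITHMS[name]
    except KeyError:
        raise ValueError(
            f"unknown algorithm {name!r}; choose from {sorted(ALGORITHMS)}"
        ) from None


def _expand_grid(grid: dict) -> list[dict]:
    if not grid:
        return [{}]
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*grid.values())]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> float:
    """ROC-AUC = P(score+ > score-) + 0.5 P(tie) over class pairs."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC-AUC undefined: only one class present")
    return float(roc_auc_score(labels, scores))


def _interp_tpr(scores, labels) -> np.ndarray:
    fpr, tpr, _ = roc_curve(labels, scores)
    grid_tpr = np.interp(FPR_GRID, fpr, tpr)
    grid_tpr[0] = 0.0
    grid_tpr[-1] = 1.0
    return grid_tpr


# ---------------------------------------------------------------------------
# Hyperparameter tuning
# ---------------------------------------------------------------------------

def tune_hyperparameters(
    X, y, algorithm: str, grid: dict | None = None, seed: int = 0, inner_k: int = 5
) -> dict:
    """Exhaustive grid search by inner stratified k-fold ROC-AUC.

    The inner loop is stratified but not grouped; ties break by grid
    order.  Inner folds whose validation split holds a single class are
    skipped with a warning; if all folds degenerate the search errors.
    """
    spec = get_algorithm(algorithm)
    settings = _expand_grid(grid if grid is not None else spec.default_grid)
    if not settings:
        raise ValueError("empty hyperparameter grid")
    if len(settings) == 1:
        return settings[0]
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    inner = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
    best_params, best_score = None, -np.inf
    for params in settings:
        fold_scores = []
        for train_idx, val_idx in inner.split(X, y):
            y_train, y_val = y[train_idx], y[val_idx]
            if len(np.unique(y_val)) < 2 or len(np.unique(y_train)) < 2:
                log.warning("skipping degenerate inner fold for %s", algorithm)
                continue
            model, scaler = _fit_one(spec, params, seed, X[train_idx], y_train)
            scores = _predict_proba(model, scaler, X[val_idx])
            fold_scores.append(roc_auc(scores, y_val))
        if not fold_scores:
            raise ValueError("all inner folds degenerate; cannot tune")
        mean_score = float(np.mean(fold_scores))
        if mean_score > best_score:
            best_score, best_params = mean_score, params
    return best_params


def _fit_one(spec: AlgorithmSpec, params: dict, seed: int, X, y):
    scaler = None
    if spec.needs_scaling:
        scaler, X = standardize(X)
    model = spec.factory(params, seed)
    model.fit(X, y)
    return model, scaler


def _predict_proba(model, scaler, X) -> np.ndarray:
    if scaler is not None:
        X = scaler.transform(X)
    return model.predict_proba(X)[:, 1]


# ---------------------------------------------------------------------------
# Fitted model bundle
# ---------------------------------------------------------------------------

@dataclass
class ModelBundle:
    """A fitted classifier plus everything needed to apply it safely."""

    algorithm: str
    params: dict
    model: object
    scaler: object | None
    feature_names: list[str]
    train_groups: frozenset = frozenset()

    def predict_proba(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        return _predict_proba(self.model, self.scaler, X)

    @property
    def importances(self) -> np.ndarray | None:
        return getattr(self.model, "feature_importances_", None)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ModelBundle":
        return joblib.load(path)


def fit_behavior_model(
    X, y, algorithm: str = "adaboost", params: dict | None = None,
    seed: int = 0, groups=None, names: list[str] | None = None,
) -> ModelBundle:
    """Fit one classifier on the full provided training data."""
    spec = get_algorithm(algorithm)
    model, scaler = _fit_one(spec, params or {}, seed, np.asarray(X, float), y)
    return ModelBundle(
        algorithm=algorithm,
        params=params or {},
        model=model,
        scaler=scaler,
        feature_names=names or feature_names(),
        train_groups=frozenset(groups) if groups is not None else frozenset(),
    )


def predict_behavior(bundle: ModelBundle, X):
    """LLPS probability and hard label (threshold 0.5) for vector(s)."""
    proba = bundle.predict_proba(X)
    return proba, (proba >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# Repeated SG10CV
# ---------------------------------------------------------------------------

@dataclass
class RocSummary:
    """ROC curves and AUCs aggregated over folds and repeats."""

    fpr_grid: np.ndarray
    repeat_mean_tpr: list[np.ndarray]
    fold_aucs: list[list[float]]
    repeat_mean_aucs: list[float]
    overall_mean_auc: float

    @property
    def overall_mean_tpr(self) -> np.ndarray:
        return np.mean(self.repeat_mean_tpr, axis=0)


@dataclass
class ImportanceReport:
    """Feature importances averaged within repeats, then across them."""

    feature_names: list[str]
    repeat_means: list[np.ndarray]
    repeat_stds: list[np.ndarray]
    grand_mean: np.ndarray

    def top(self, n: int = 10) -> list[tuple[str, float]]:
        order = np.argsort(self.grand_mean)[::-1][:n]
        return [(self.feature_names[i], float(self.grand_mean[i])) for i in order]


@dataclass
class RepeatResult:
    repeat: int
    plan: CVPlan
    fold_bundles: list[ModelBundle]
    fold_test_groups: list[set]
    fold_aucs: list[float]

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))


@dataclass
class SGCVResult:
    roc: RocSummary
    importances: ImportanceReport | None
    repeats: list[RepeatResult] = field(default_factory=list)


def run_repeated_sg10cv(
    X, y, groups, algorithm: str = "adaboost",
    repeats: int = 10, k: int = 10, seed: int = 0,
    grid: dict | None = None, tune: bool = True,
    names: list[str] | None = None,
) -> SGCVResult:
    """Run the full repeated SG10CV evaluation protocol.

    For each repeat a fresh stratified-group fold plan is drawn (seed
    ``seed + repeat``); within each fold, hyperparameters are tuned on
    the training split by inner stratified 5-fold CV, the best setting
    is refitted on the whole training split, and the held-out split is
    scored.  ROC curves are vertically averaged on a common FPR grid per
    repeat and then across repeats; impurity importances (tree models)
    are averaged the same way.
    """
    spec = get_algorithm(algorithm)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    groups = np.asarray(groups, dtype=object)
    names = names or feature_names()

    repeat_results: list[RepeatResult] = []
    repeat_mean_tpr, fold_aucs_all, repeat_mean_aucs = [], [], []
    importance_means, importance_stds = [], []

    for r in range(repeats):
        plan = make_sg10cv_plan(y, groups, k=k, seed=seed + r, repeat=r)
        bundles, aucs, tprs, fold_importances = [], [], [], []
        for train_idx, test_idx in plan.folds:
            X_train, y_train = X[train_idx], y[train_idx]
            if tune:
                params = tune_hyperparameters(
                    X_train, y_train, algorithm, grid=grid, seed=seed + r
                )
            else:
                params = _expand_grid(grid)[0] if grid else {}
            model, scaler = _fit_one(spec, params, seed + r, X_train, y_train)
            bundle = ModelBundle(
                algorithm=algorithm, params=params, model=model, scaler=scaler,
                feature_names=names, train_groups=frozenset(groups[train_idx]),
            )
            scores = bundle.predict_proba(X[test_idx])
            aucs.append(roc_auc(scores, y[test_idx]))
            tprs.append(_interp_tpr(scores, y[test_idx]))
            if spec.has_importances:
                fold_importances.append(bundle.importances)
            bundles.append(bundle)
        repeat_results.append(
            RepeatResult(
                repeat=r, plan=plan, fold_bundles=bundles,
                fold_test_groups=plan.test_groups(groups), fold_aucs=aucs,
            )
        )
        fold_aucs_all.append(aucs)
        repeat_mean_aucs.append(float(np.mean(aucs)))
        repeat_mean_tpr.append(np.mean(tprs, axis=0))
        if spec.has_importances:
            stack = np.vstack(fold_importances)
            importance_means.append(stack.mean(axis=0))
            importance_stds.append(stack.std(axis=0))

    roc = RocSummary(
        fpr_grid=FPR_GRID.copy(),
        repeat_mean_tpr=repeat_mean_tpr,
        fold_aucs=fold_aucs_all,
        repeat_mean_aucs=repeat_mean_aucs,
        overall_mean_auc=float(np.mean(repeat_mean_aucs)),
    )
    importances = None
    if spec.has_importances:
        importances = ImportanceReport(
            feature_names=names,
            repeat_means=importance_means,
            repeat_stds=importance_stds,
            grand_mean=np.mean(importance_means, axis=0),
        )
    return SGCVResult(roc=roc, importances=importances, repeats=repeat_results)
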