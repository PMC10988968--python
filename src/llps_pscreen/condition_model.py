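"""Classifier-chains model for the conditions under which LLPS occurs.

Given only the 126 sequence-derived features (29 protein + 97 RNA), a
chain of five classifiers predicts the class of each experimental
condition in the fixed order pH -> temperature -> protein concentration
-> RNA concentration -> ionic strength (3, 3, 5, 5, 5 classes).  Each
link consumes the base features plus the classes of all upstream links:
true classes at training time (teacher forcing), predicted classes at
prediction time.  Evaluation pools out-of-fold predictions from group
10-fold CV (groups = protein sequence) into per-condition macro-averaged
one-vs-rest ROC-AUCs and confusion matrices.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import AdaBoostClassifier
from sklearn.metrics import confusion_matrix

from .behavior_model import make_g10cv_plan, roc_auc, sequence_feature_names
from .preprocess import BinningScheme, bin_condition, table1_schemes

log = logging.getLogger(__name__)

#: chain order and the scheme each condition is binned with
CHAIN_ORDER: list[tuple[str, str]] = [
    ("pH", "pH"),
    ("temperature", "temperature"),
    ("protein_conc", "protein_conc"),
    ("rna_conc", "rna_conc"),
    ("ionic_strength", "ionic_strength"),
]
CONDITION_NAMES = [name for name, _ in CHAIN_ORDER]
N_CLASSES = (3, 3, 5, 5, 5)

#: default base-learner setting (ensemble of 50 depth-1 weak learners)
DEFAULT_BASE_PARAMS = {"n_estimators": 50}


def build_condition_targets(
    condition_vectors, schemes: dict[str, BinningScheme] | None = None
) -> np.ndarray:
    """Bin condition vectors into the (n, 5) class-index target matrix.

    Column order follows the chain: pH, temperature, protein conc, RNA
    conc, ionic strength.  Classes are 1-based.
    """
    schemes = schemes or table1_schemes()
    rows = []
    for cv in condition_vectors:
        values = {
            "pH": cv.ph,
            "temperature": cv.temperature,
            "protein_conc": cv.log_protein_conc,
            "rna_conc": cv.log_rna_conc,
            "ionic_strength": cv.ionic_strength,
        }
        rows.append(
            [bin_condition(values[name], schemes[key]) for name, key in CHAIN_ORDER]
        )
    return np.array(rows, dtype=int)


@dataclass
class ChainModel:
    """Five fitted classifiers connected in the fixed chain order."""

    classifiers: list
    condition_names: list[str]
    classes_per_target: list[np.ndarray]
    feature_names: list[str]
    pass_probabilities: bool = False

    def predict(self, X) -> tuple[np.ndarray, list[np.ndarray]]:
        """Sequential chained prediction (upstream predictions feed
        downstream inputs).  Returns (class indices (n,5), per-condition
        probability arrays)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        n = X.shape[0]
        augmented = X
        classes = np.zeros((n, len(self.classifiers)), dtype=int)
        probabilities: list[np.ndarray] = []
        for i, clf in enumerate(self.classifiers):
            proba = clf.predict_proba(augmented)
            predicted = self.classes_per_target[i][np.argmax(proba, axis=1)]
            classes[:, i] = predicted
            probabilities.append(proba)
            link_out = proba if self.pass_probabilities else predicted.reshape(-1, 1)
            augmented = np.hstack([augmented, link_out.astype(float)])
        return classes, probabilities


def train_chain(
    X, targets, seed: int = 0, base_params: dict | None = None,
    pass_probabilities: bool = False, names: list[str] | None = None,
) -> ChainModel:
    """Train the classifier chain with teacher forcing.

    Link i is fitted on the base features plus the *true* classes of
    links 1..i-1.  Every target must have >= 2 classes in the training
    data; a single-class target raises an error naming the condition.
    """
    X = np.asarray(X, dtype=float)
    targets = np.asarray(targets, dtype=int)
    if targets.ndim != 2 or targets.shape[1] != len(CONDITION_NAMES):
        raise ValueError(f"targets must be (n, {len(CONDITION_NAMES)})")
    params = dict(DEFAULT_BASE_PARAMS)
    if base_params:
        params.update(base_params)

    classifiers, classes_per_target = [], []
    augmented = X
    for i, name in enumerate(CONDITION_NAMES):
        y = targets[:, i]
        observed = np.unique(y)
        if len(observed) < 2:
            raise ValueError(
                f"condition {name!r} has a single class in training data"
            )
        clf = AdaBoostClassifier(random_state=seed, **params)
        clf.fit(augmented, y)
        classifiers.append(clf)
        classes_per_target.append(clf.classes_)
        if pass_probabilities:
            link_out = clf.predict_proba(augmented)
        else:
            link_out = y.reshape(-1, 1)  # teacher forcing: true upstream class
        augmented = np.hstack([augmented, link_out.astype(float)])
    return ChainModel(
        classifiers=classifiers,
        condition_names=list(CONDITION_NAMES),
        classes_per_target=classes_per_target,
        feature_names=names or sequence_feature_names(),
        pass_probabilities=pass_probabilities,
    )


def predict_chain(chain: ChainModel, X) -> tuple[np.ndarray, list[np.ndarray]]:
    """Chained prediction for feature vector(s); see ChainModel.predict."""
    return chain.predict(X)


def macro_roc_auc(y_true, proba, classes) -> float:
    """Macro average of one-vs-rest per-class ROC-AUCs.

    Classes absent from *y_true* are skipped with a warning (the pooled
    truth may not cover every class).
    """
    y_true = np.asarray(y_true)
    aucs = []
    for j, cls in enumerate(classes):
        indicator = (y_true == cls).astype(int)
        if len(np.unique(indicator)) < 2:
            log.warning("class %s absent (or universal) in pooled truth; skipped", cls)
            continue
        aucs.append(roc_auc(proba[:, j], indicator))
    if not aucs:
        raise ValueError("no class with both positives and negatives")
    return float(np.mean(aucs))


@dataclass
class ConditionEvaluation:
    """Pooled out-of-fold evaluation of the chain under group 10-fold CV."""

    condition_names: list[str]
    macro_aucs: dict[str, float]
    confusion_matrices: dict[str, np.ndarray]
    pooled_true: np.ndarray
    pooled_pred: np.ndarray
    pooled_proba: dict[str, np.ndarray]


def macro_roc_from_g10cv(
    X, targets, groups, k: int = 10, seed: int = 0,
    base_params: dict | None = None, pass_probabilities: bool = False,
) -> ConditionEvaluation:
    """Evaluate the chain by pooling out-of-fold predictions over G10CV.

    Every record is predicted exactly once out-of-fold; per condition,
    the pooled probabilities give a macro-averaged one-vs-rest ROC-AUC
    and the pooled hard predictions a confusion matrix.
    """
    X = np.asarray(X, dtype=float)
    targets = np.asarray(targets, dtype=int)
    plan = make_g10cv_plan(groups, k=k)

    n = len(X)
    pooled_pred = np.zeros((n, len(CONDITION_NAMES)), dtype=int)
    pooled_proba = {name: [None] * n for name in CONDITION_NAMES}
    pooled_classes = {name: set() for name in CONDITION_NAMES}

    for train_idx, test_idx in plan.folds:
        chain = train_chain(
            X[train_idx], targets[train_idx], seed=seed,
            base_params=base_params, pass_probabilities=pass_probabilities,
        )
        classes, probabilities = chain.predict(X[test_idx])
        pooled_pred[test_idx] = classes
        for i, name in enumerate(CONDITION_NAMES):
            pooled_classes[name].update(chain.classes_per_target[i])
            for row, idx in enumerate(test_idx):
                pooled_proba[name][idx] = dict(
                    zip(chain.classes_per_target[i], probabilities[i][row])
                )

    macro_aucs, confusions, proba_arrays = {}, {}, {}
    for i, name in enumerate(CONDITION_NAMES):
        class_list = sorted(pooled_classes[name])
        proba = np.array(
            [
                [entry.get(cls, 0.0) for cls in class_list]
                for entry in pooled_proba[name]
            ]
        )
        macro_aucs[name] = macro_roc_auc(targets[:, i], proba, class_list)
        all_labels = sorted(set(class_list) | set(np.unique(targets[:, i])))
        confusions[name] = confusion_matrix(
            targets[:, i], pooled_pred[:, i], labels=all_labels
        )
        proba_arrays[name] = proba
    return ConditionEvaluation(
        condition_names=list(CONDITION_NAMES),
        macro_aucs=macro_aucs,
        confusion_matrices=confusions,
        pooled_true=targets.copy(),
        pooled_pred=pooled_pred,
        pooled_proba=proba_arrays,
    )
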