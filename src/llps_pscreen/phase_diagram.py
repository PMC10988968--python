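"""Concentration–concentration phase diagrams from behavior predictions.

For one protein–RNA pair, the protein and RNA log10 concentrations are
swept over 20-point axes spanning [min - 1.0, max + 1.0] of the pair's
observed values (400 grid points total) while the other condition
features are held constant; the fitted behavior model labels every grid
point.  The pair's experimental records are overlaid and scored with a
simple accuracy.  The model used must not have seen the pair's protein
group during training.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior_model import ModelBundle, SGCVResult, predict_behavior
from .preprocess import ConditionVector, condition_vector, encode_label
from .protein_features import protein_descriptors
from .rna_features import rna_descriptors

N_AXIS_POINTS = 20


class LeakageError(ValueError):
    """The pair's protein group was in the model's training data."""


@dataclass
class PhaseDiagram:
    protein_axis: np.ndarray          # 20 log10-µM values
    rna_axis: np.ndarray              # 20 log10-µM values
    probabilities: np.ndarray         # (20, 20), rows = protein axis
    labels: np.ndarray                # (20, 20) hard labels at 0.5
    overlay: pd.DataFrame             # experimental points with true labels
    fixed_conditions: dict
    protein_sequence: str
    rna_sequence: str
    pair_accuracy: float

    def to_frame(self) -> pd.DataFrame:
        """Long-format TSV-ready table of the 400 grid predictions."""
        rows = []
        for i, p in enumerate(self.protein_axis):
            for j, r in enumerate(self.rna_axis):
                rows.append(
                    {
                        "log_protein_conc": p,
                        "log_rna_conc": r,
                        "probability": self.probabilities[i, j],
                        "label": int(self.labels[i, j]),
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def plot(self, ax=None):
        """Cosmetic raster plot; the TSV export is the tested artifact."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.pcolormesh(
            self.protein_axis, self.rna_axis, self.labels.T,
            cmap="coolwarm", shading="nearest", alpha=0.6,
        )
        for _, row in self.overlay.iterrows():
            marker = "D"
            color = "blue" if row["label"] == 1 else "red"
            ax.scatter(
                row["log_protein_conc"], row["log_rna_conc"],
                marker=marker, c=color, edgecolors="black",
            )
        ax.set_xlabel("Protein conc. (log10 µM)")
        ax.set_ylabel("RNA conc. (log10 µM)")
        return ax


def grid_axes(
    log_protein_concs, log_rna_concs, n_points: int = N_AXIS_POINTS
) -> tuple[np.ndarray, np.ndarray]:
    """20 equally spaced axis values from min - 1.0 to max + 1.0."""
    log_protein_concs = np.asarray(log_protein_concs, dtype=float)
    log_rna_concs = np.asarray(log_rna_concs, dtype=float)
    if log_protein_concs.size == 0 or log_rna_concs.size == 0:
        raise ValueError("at least one record is required to place the axes")
    protein_axis = np.linspace(
        log_protein_concs.min() - 1.0, log_protein_concs.max() + 1.0, n_points
    )
    rna_axis = np.linspace(
        log_rna_concs.min() - 1.0, log_rna_concs.max() + 1.0, n_points
    )
    return protein_axis, rna_axis


def _pair_conditions(records) -> list[ConditionVector]:
    return [condition_vector(r) for r in records]


def _features_for(bundle, protein_vec, rna_vec, cond_array) -> np.ndarray:
    return np.concatenate([protein_vec, rna_vec, cond_array])


def pair_accuracy(bundle: ModelBundle, pair_features, pair_labels) -> float:
    """Fraction of the pair's records whose prediction matches the label."""
    _, predicted = predict_behavior(bundle, pair_features)
    pair_labels = np.asarray(pair_labels, dtype=int)
    return float(np.mean(predicted == pair_labels))


def build_phase_diagram(
    bundle: ModelBundle,
    protein_sequence: str,
    rna_sequence: str,
    pair_records,
    fixed_conditions: dict | None = None,
) -> PhaseDiagram:
    """Build the 20x20 diagram for one protein–RNA pair.

    ``fixed_conditions`` (ionic_strength, pH, temperature) defaults to
    the component-wise median of the pair's own records.  Raises
    :class:`LeakageError` if the protein group was in the bundle's
    training manifest.
    """
    if bundle.train_groups and protein_sequence in bundle.train_groups:
        raise LeakageError(
            "pair's protein group was in the model's training data; "
            "use a fold model that held this group out"
        )
    conditions = _pair_conditions(pair_records)
    if not conditions:
        raise ValueError("no records for the pair")
    log_p = [c.log_protein_conc for c in conditions]
    log_r = [c.log_rna_conc for c in conditions]
    if fixed_conditions is None:
        fixed_conditions = {
            "ionic_strength": float(np.median([c.ionic_strength for c in conditions])),
            "pH": float(np.median([c.ph for c in conditions])),
            "temperature": float(np.median([c.temperature for c in conditions])),
        }
    protein_axis, rna_axis = grid_axes(log_p, log_r)

    protein_vec = protein_descriptors(protein_sequence)
    rna_vec = rna_descriptors(rna_sequence)
    grid_features = np.array(
        [
            _features_for(
                bundle, protein_vec, rna_vec,
                np.array(
                    [
                        p, r,
                        fixed_conditions["ionic_strength"],
                        fixed_conditions["pH"],
                        fixed_conditions["temperature"],
                    ]
                ),
            )
            for p in protein_axis
            for r in rna_axis
        ]
    )
    proba, labels = predict_behavior(bundle, grid_features)
    n = len(protein_axis)
    proba = proba.reshape(n, n)
    labels = labels.reshape(n, n)

    pair_features = np.array(
        [
            _features_for(bundle, protein_vec, rna_vec, c.as_array())
            for c in conditions
        ]
    )
    true_labels = [encode_label(r.morphology) for r in pair_records]
    overlay = pd.DataFrame(
        {
            "record_id": [r.record_id for r in pair_records],
            "log_protein_conc": log_p,
            "log_rna_conc": log_r,
            "label": true_labels,
        }
    )
    return PhaseDiagram(
        protein_axis=protein_axis,
        rna_axis=rna_axis,
        probabilities=proba,
        labels=labels,
        overlay=overlay,
        fixed_conditions=fixed_conditions,
        protein_sequence=protein_sequence,
        rna_sequence=rna_sequence,
        pair_accuracy=pair_accuracy(bundle, pair_features, true_labels),
    )


def select_diagram_model(result: SGCVResult, protein_sequence: str) -> ModelBundle:
    """Pick the fold model for a diagram from a repeated-CV run.

    Among the repeats (ties broken toward the earliest), the one with
    the highest mean ROC-AUC supplies the fold whose test split held the
    pair's protein group out of training.
    """
    candidates = []
    for rep in result.repeats:
        for fold_i, test_groups in enumerate(rep.fold_test_groups):
            if protein_sequence in test_groups:
                candidates.append((rep.mean_auc, rep.repeat, fold_i, rep))
    if not candidates:
        raise ValueError(
            "no fold held the pair's protein group out; "
            "retrain with the pair held out"
        )
    # max mean AUC; earliest repeat wins ties (sort is stable, use -auc, repeat)
    candidates.sort(key=lambda t: (-t[0], t[1]))
    _, _, fold_i, rep = candidates[0]
    return rep.fold_bundles[fold_i]
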