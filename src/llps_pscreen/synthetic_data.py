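"""Synthetic LLPS experiment datasets with controlled, known structure.

Every pipeline stage is testable without the curated dataset: the
generator emits schema-compliant experiment records whose condition
values span the published class ranges and whose labels follow a
planted logistic rule in ionic strength, the two log concentrations,
and the protein's arginine/lysine fraction.  Ground truth (coefficients
and clean labels) is emitted alongside so tests never re-derive it.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dataset_io import ExperimentRecord
from .preprocess import table1_schemes

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: default planted-rule coefficients on standardized covariates
DEFAULT_COEFFICIENTS = {
    "intercept": 0.0,
    "log_protein_conc": 2.0,
    "log_rna_conc": 1.5,
    "ionic_strength": -2.0,
    "frac_RK": 1.5,
}

#: condition sampling spans (matching the published class ranges)
SPANS = {
    "log_protein_conc": (-1.64, 2.7),
    "log_rna_conc": (-4.7, 2.3),
    "ionic_strength": (0.0, 0.4),
    "temperature": (0.0, 40.0),
}


def _uniform_moments(lo: float, hi: float) -> tuple[float, float]:
    return (lo + hi) / 2.0, (hi - lo) / math.sqrt(12.0)


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic dataset draw."""

    n: int = 500
    n_proteins: int = 40
    n_rnas: int = 60
    protein_length: tuple[int, int] = (10, 500)
    rna_length: tuple[int, int] = (10, 200)
    coefficients: dict = field(default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    noise_temperature: float = 0.4    # 0 -> deterministic threshold labels
    label_flip_rate: float = 0.0
    include_violations: bool = False  # inject filter-violating records
    condition_signal: bool = True     # condition dataset: plant the chain signal
    copy_noise_rate: float = 0.0      # condition dataset: ionic!=pH class rate
    seed: int = 0

    def __post_init__(self):
        if self.n_proteins < 1 or self.n_rnas < 1:
            raise ValueError("need at least one protein and one RNA")
        if self.n < 1:
            raise ValueError("need at least one record")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _random_protein(rng: np.random.Generator, length: int, frac_rk: float,
                    frac_aromatic: float | None = None) -> str:
    letters = []
    others = [a for a in AA20 if a not in "RK"]
    for _ in range(length):
        if rng.random() < frac_rk:
            letters.append("R" if rng.random() < 0.5 else "K")
        elif frac_aromatic is not None and rng.random() < frac_aromatic:
            letters.append(rng.choice(list("FWY")))
        else:
            letters.append(rng.choice(others))
    return "".join(letters)


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


def _sequence_pools(spec: SyntheticSpec, rng: np.random.Generator,
                    aromatic_bias: bool = False):
    proteins = []
    for _ in range(spec.n_proteins):
        length = int(rng.integers(spec.protein_length[0], spec.protein_length[1] + 1))
        frac_rk = float(rng.uniform(0.02, 0.35))
        frac_ar = float(rng.uniform(0.05, 0.35)) if aromatic_bias else None
        proteins.append(_random_protein(rng, length, frac_rk, frac_ar))
    rnas = [
        _random_rna(rng, int(rng.integers(spec.rna_length[0], spec.rna_length[1] + 1)))
        for _ in range(spec.n_rnas)
    ]
    # uneven usage weights give realistic repeated-sequence group structure
    protein_weights = rng.dirichlet(np.full(spec.n_proteins, 0.6))
    rna_weights = rng.dirichlet(np.full(spec.n_rnas, 0.6))
    return proteins, rnas, protein_weights, rna_weights


def _conc_record(rng: np.random.Generator, log_um: float) -> tuple[float, str]:
    """Express a log10-µM concentration in a randomly chosen unit."""
    c_um = 10.0**log_um
    unit = rng.choice(["uM", "mM", "nM"], p=[0.7, 0.15, 0.15])
    factor = {"uM": 1.0, "mM": 1e-3, "nM": 1e3}[unit]
    return c_um * factor, unit


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[list[ExperimentRecord], dict]:
    """Generate behavior-model records with a planted logistic label rule.

    The latent score is linear in the standardized planted covariates
    (ionic strength, both log concentrations, the protein's R/K
    fraction); labels are Bernoulli(sigmoid(score / noise_temperature)),
    or a hard threshold when the noise temperature is 0, then flipped at
    ``label_flip_rate``.  Returns (records, ground truth).
    """
    rng = np.random.default_rng(spec.seed)
    proteins, rnas, p_weights, r_weights = _sequence_pools(spec, rng)
    frac_rk = np.array([(p.count("R") + p.count("K")) / len(p) for p in proteins])

    moments = {name: _uniform_moments(*span) for name, span in SPANS.items()}
    moments["frac_RK"] = _uniform_moments(0.02, 0.35)
    coef = spec.coefficients

    records, z_scores, clean_labels, probabilities = [], [], [], []
    for i in range(spec.n):
        p_idx = int(rng.choice(spec.n_proteins, p=p_weights))
        r_idx = int(rng.choice(spec.n_rnas, p=r_weights))
        log_p = float(rng.uniform(*SPANS["log_protein_conc"]))
        log_r = float(rng.uniform(*SPANS["log_rna_conc"]))
        ionic = float(rng.uniform(*SPANS["ionic_strength"]))
        ph = float(np.clip(rng.normal(7.0, 1.0), 0.0, 14.0))
        if rng.random() < 0.6:
            temperature: float | str = "room temperature"
        else:
            temperature = round(float(rng.uniform(*SPANS["temperature"])), 1)

        covariates = {
            "log_protein_conc": log_p,
            "log_rna_conc": log_r,
            "ionic_strength": ionic,
            "frac_RK": frac_rk[p_idx],
        }
        z = coef["intercept"] + sum(
            coef[name] * (value - moments[name][0]) / moments[name][1]
            for name, value in covariates.items()
        )
        if spec.noise_temperature == 0:
            p_llps = 1.0 if z > 0 else 0.0
        else:
            p_llps = float(_sigmoid(np.array(z / spec.noise_temperature)))
        label = int(rng.random() < p_llps) if 0 < p_llps < 1 else int(p_llps)
        clean = label
        if spec.label_flip_rate > 0 and rng.random() < spec.label_flip_rate:
            label = 1 - label

        p_value, p_unit = _conc_record(rng, log_p)
        r_value, r_unit = _conc_record(rng, log_r)
        records.append(
            ExperimentRecord(
                record_id=f"syn{i:05d}",
                protein_sequence=proteins[p_idx],
                rna_sequence=rnas[r_idx],
                morphology="liquid" if label == 1 else "solute",
                protein_conc_value=p_value,
                protein_conc_unit=p_unit,
                rna_conc_value=r_value,
                rna_conc_unit=r_unit,
                salts=[("NaCl", ionic, "M")],  # I(NaCl) = c, so I == ionic
                ph=ph,
                temperature_raw=temperature,
                source="synthetic",
            )
        )
        z_scores.append(z)
        clean_labels.append(clean)
        probabilities.append(p_llps)

    if spec.include_violations:
        records.extend(_violation_records(rng, proteins[0], rnas[0]))

    truth = {
        "coefficients": dict(coef),
        "noise_temperature": spec.noise_temperature,
        "planted_features": ["ionic_strength", "log_protein_conc", "log_rna_conc"],
        "planted_protein_features": ["frac_R", "frac_K"],
        "z": np.array(z_scores),
        "probability": np.array(probabilities),
        "clean_label": np.array(clean_labels, dtype=int),
        "proteins": proteins,
        "rnas": rnas,
    }
    return records, truth


def _violation_records(rng, protein: str, rna: str) -> list[ExperimentRecord]:
    """A handful of records that must be excluded by the filters."""
    base = dict(
        protein_conc_value=10.0, protein_conc_unit="uM",
        rna_conc_value=1.0, rna_conc_unit="uM",
        salts=[("NaCl", 0.15, "M")], ph=7.0, temperature_raw=25.0,
    )
    return [
        ExperimentRecord("viol-short-protein", "MKVQR", rna, "liquid", **base),
        ExperimentRecord("viol-short-rna", protein, "ACGUA", "liquid", **base),
        ExperimentRecord(
            "viol-salt", protein, rna, "liquid",
            **{**base, "salts": [("LiBr", 0.1, "M")]},
        ),
        ExperimentRecord("viol-gel", protein, rna, "gel", **base),
        ExperimentRecord("viol-solid", protein, rna, "solid", **base),
        ExperimentRecord(
            "viol-crowder", protein, rna, "liquid",
            has_crowder_or_small_molecule=True, **base,
        ),
    ]


def generate_condition_dataset(
    spec: SyntheticSpec,
) -> tuple[list[ExperimentRecord], dict]:
    """Generate liquid-only records with a chain-learnable dependency.

    The pH class is a deterministic function of the protein's
    aromaticity tercile; the ionic-strength class copies the pH class
    (flipped to a random class at ``copy_noise_rate``); temperature and
    the two concentrations are independent.  With
    ``condition_signal=False`` every condition is independent of the
    sequences (a null dataset).
    """
    rng = np.random.default_rng(spec.seed)
    proteins, rnas, p_weights, r_weights = _sequence_pools(
        spec, rng, aromatic_bias=True
    )
    aromaticity = np.array(
        [sum(p.count(a) for a in "FWY") / len(p) for p in proteins]
    )
    terciles = np.quantile(aromaticity, [1 / 3, 2 / 3])
    protein_ph_class = 1 + np.searchsorted(terciles, aromaticity, side="right")

    schemes = table1_schemes()
    ionic_edges = schemes["ionic_strength"].edges
    # interior sampling windows for each pH class (within the published bins)
    ph_windows = {1: (4.5, 6.9), 2: (7.05, 7.95), 3: (8.05, 9.5)}

    records = []
    ph_classes, ionic_classes = [], []
    for i in range(spec.n):
        p_idx = int(rng.choice(spec.n_proteins, p=p_weights))
        r_idx = int(rng.choice(spec.n_rnas, p=r_weights))
        if spec.condition_signal:
            ph_class = int(protein_ph_class[p_idx])
        else:
            ph_class = int(rng.integers(1, 4))
        ph = float(rng.uniform(*ph_windows[ph_class]))

        ionic_class = ph_class
        if spec.condition_signal:
            if spec.copy_noise_rate > 0 and rng.random() < spec.copy_noise_rate:
                ionic_class = int(rng.integers(1, 6))
        else:
            ionic_class = int(rng.integers(1, 6))
        lo, hi = ionic_edges[ionic_class - 1], ionic_edges[ionic_class]
        margin = 0.05 * (hi - lo)
        ionic = float(rng.uniform(lo + margin, hi - margin))

        log_p = float(rng.uniform(*SPANS["log_protein_conc"]))
        log_r = float(rng.uniform(*SPANS["log_rna_conc"]))
        temperature = round(float(rng.uniform(*SPANS["temperature"])), 1)

        p_value, p_unit = _conc_record(rng, log_p)
        r_value, r_unit = _conc_record(rng, log_r)
        records.append(
            ExperimentRecord(
                record_id=f"cond{i:05d}",
                protein_sequence=proteins[p_idx],
                rna_sequence=rnas[r_idx],
                morphology="liquid",
                protein_conc_value=p_value,
                protein_conc_unit=p_unit,
                rna_conc_value=r_value,
                rna_conc_unit=r_unit,
                salts=[("NaCl", ionic, "M")],
                ph=ph,
                temperature_raw=temperature,
                source="synthetic",
            )
        )
        ph_classes.append(ph_class)
        ionic_classes.append(ionic_class)

    truth = {
        "aromaticity": aromaticity,
        "terciles": terciles,
        "protein_ph_class": protein_ph_class,
        "ph_class": np.array(ph_classes, dtype=int),
        "ionic_class": np.array(ionic_classes, dtype=int),
        "proteins": proteins,
        "rnas": rnas,
    }
    return records, truth
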