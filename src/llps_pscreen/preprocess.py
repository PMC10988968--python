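"""Turn raw experiment records into model-ready condition features.

The five experimental-condition features are: log10 protein
concentration (µM), log10 RNA concentration (µM), ionic strength
(mol/L), pH, and temperature (°C).  This module performs the unit
unification, the salt -> ionic-strength conversion, the behavior-model
filtering rules, binary label encoding (solute=0, liquid=1), and the
binning of condition values into the published class schemes.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from Bio.SeqUtils import molecular_weight as _bio_mw

from .config import load_default_config
from .dataset_io import AMINO_ACIDS, RNA_BASES, ExperimentRecord

log = logging.getLogger(__name__)

ROOM_TEMPERATURE_C = 25.0

_UNIT_TO_UM = {"M": 1e6, "mM": 1e3, "uM": 1.0, "nM": 1e-3}

#: fixed order of the five condition features in the 131-feature vector
CONDITION_FEATURE_NAMES = [
    "log_protein_conc",
    "log_rna_conc",
    "ionic_strength",
    "pH",
    "temperature",
]


class UnsupportedSaltError(ValueError):
    """Salt species not covered by the dissociation table."""


@dataclass
class ConditionVector:
    """The five preprocessed condition features for one experiment."""

    log_protein_conc: float  # log10 µM
    log_rna_conc: float      # log10 µM
    ionic_strength: float    # mol/L
    ph: float
    temperature: float       # °C

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.log_protein_conc,
                self.log_rna_conc,
                self.ionic_strength,
                self.ph,
                self.temperature,
            ],
            dtype=float,
        )


def to_micromolar(
    value: float, unit: str, molecular_weight: float | None = None
) -> float:
    """Convert a concentration to µM.

    ``mg/mL`` needs the molar mass (g/mol): c[µM] = value * 1e6 / MW.
    """
    if value < 0:
        raise ValueError(f"negative concentration {value}")
    if unit in _UNIT_TO_UM:
        return value * _UNIT_TO_UM[unit]
    if unit == "mg/mL":
        if molecular_weight is None or molecular_weight <= 0:
            raise ValueError("mg/mL conversion requires a molecular weight")
        return value * 1e6 / molecular_weight
    raise ValueError(f"unknown concentration unit {unit!r}")


def log_concentration(c_um: float) -> float:
    """Common (base-10) logarithm of a µM concentration; c must be > 0."""
    if c_um <= 0:
        raise ValueError(f"cannot log-transform non-positive concentration {c_um}")
    return math.log10(c_um)


def ionic_strength(
    salts: list[tuple[str, float]], config: dict | None = None
) -> float:
    """Ionic strength I = 1/2 Σ c_i z_i² (mol/L) over fully dissociated ions.

    *salts* is a list of (species, molarity) pairs; the species table in
    the configuration supplies stoichiometry and charges.  Additive over
    salts; unsupported species raise :class:`UnsupportedSaltError`.
    """
    config = config or load_default_config()
    table = config["salts"]
    aliases = config.get("salt_aliases", {})
    total = 0.0
    for species, molarity in salts:
        species = aliases.get(species, species)
        if species not in table:
            raise UnsupportedSaltError(f"unsupported salt species {species!r}")
        if molarity < 0:
            raise ValueError(f"negative molarity for {species}")
        for stoich, charge in table[species]:
            total += molarity * stoich * charge**2
    return 0.5 * total


def normalize_temperature(raw: float | str, unit: str | None = None) -> float:
    """Normalize a temperature record to °C.

    Accepts a Celsius number, a Kelvin number (``unit="K"`` or a
    ``"310.15 K"`` string), or the token ``"room temperature"`` which is
    defined as 25 °C.
    """
    if isinstance(raw, str):
        token = raw.strip()
        low = token.lower()
        if low in ("room temperature", "rt", "room temp"):
            return ROOM_TEMPERATURE_C
        if low.endswith("k"):
            return float(low[:-1].strip()) - 273.15
        for suffix in ("°c", "c"):
            if low.endswith(suffix):
                low = low[: -len(suffix)].strip()
                break
        try:
            return float(low)
        except ValueError:
            raise ValueError(f"unrecognized temperature {raw!r}") from None
    value = float(raw)
    if unit is not None and unit.upper() == "K":
        return value - 273.15
    return value


def sequence_molecular_weight(sequence: str, kind: str) -> float:
    """Average molar mass (g/mol) of a protein or RNA sequence."""
    if kind == "protein":
        return _bio_mw(sequence, seq_type="protein")
    if kind == "rna":
        return _bio_mw(sequence, seq_type="RNA")
    raise ValueError(f"unknown sequence kind {kind!r}")


def condition_vector(
    record: ExperimentRecord, config: dict | None = None
) -> ConditionVector:
    """Compute the five condition features for one record.

    Raises ``ValueError`` (with a reason) when a condition is missing or
    not convertible; callers performing dataset filtering catch this and
    record the reason.
    """
    config = config or load_default_config()

    def conc_um(value, unit, sequence, kind) -> float:
        if value is None or unit is None:
            raise ValueError(f"missing {kind} concentration")
        mw = None
        if unit == "mg/mL":
            mw = sequence_molecular_weight(sequence, kind)
        return to_micromolar(value, unit, molecular_weight=mw)

    p_um = conc_um(
        record.protein_conc_value,
        record.protein_conc_unit,
        record.protein_sequence,
        "protein",
    )
    r_um = conc_um(
        record.rna_conc_value, record.rna_conc_unit, record.rna_sequence, "rna"
    )
    if record.ph is None:
        raise ValueError("missing pH")
    if record.temperature_raw is None:
        raise ValueError("missing temperature")
    ionic = ionic_strength(
        [
            (species, to_micromolar(value, unit) * 1e-6)
            for species, value, unit in record.salts
        ],
        config,
    )
    return ConditionVector(
        log_protein_conc=log_concentration(p_um),
        log_rna_conc=log_concentration(r_um),
        ionic_strength=ionic,
        ph=float(record.ph),
        temperature=normalize_temperature(record.temperature_raw),
    )


def encode_label(morphology: str) -> int:
    """Binary LLPS label: solute -> 0 (negative), liquid -> 1 (positive)."""
    if morphology == "solute":
        return 0
    if morphology == "liquid":
        return 1
    raise ValueError(
        f"morphology {morphology!r} has no binary label; filter gel/solid first"
    )


def filter_for_behavior_model(
    records: list[ExperimentRecord], config: dict | None = None
) -> tuple[list[ExperimentRecord], list[tuple[ExperimentRecord, str]]]:
    """Apply the behavior-model dataset filters.

    Kept records are solute/liquid, free of crowding agents or small
    molecules, have protein and RNA sequences of length >= 10 over the
    standard alphabets, and have all five conditions present and
    convertible (supported salts, positive concentrations).  Exclusion
    is an outcome, not an error: excluded records come back with a
    reason.  The filter is idempotent.
    """
    config = config or load_default_config()
    kept: list[ExperimentRecord] = []
    excluded: list[tuple[ExperimentRecord, str]] = []
    for record in records:
        if record.morphology not in ("solute", "liquid"):
            excluded.append((record, "morphology"))
            continue
        if record.has_crowder_or_small_molecule:
            excluded.append((record, "crowding agent or small molecule"))
            continue
        if set(record.protein_sequence) - AMINO_ACIDS:
            excluded.append((record, "non-standard protein alphabet"))
            continue
        if set(record.rna_sequence) - RNA_BASES:
            excluded.append((record, "non-ACGU RNA alphabet"))
            continue
        if len(record.protein_sequence) < 10 or len(record.rna_sequence) < 10:
            excluded.append((record, "sequence length < 10"))
            continue
        try:
            condition_vector(record, config)
        except (ValueError, UnsupportedSaltError) as exc:
            excluded.append((record, str(exc)))
            continue
        kept.append(record)
    return kept, excluded


@dataclass
class BinningScheme:
    """Ordered class boundaries for one experimental condition.

    ``edges`` has n+1 entries for n classes.  The first interval is
    closed on both ends; later intervals are left-open, right-closed,
    so a value exactly on a shared boundary belongs to the lower class.
    """

    name: str
    edges: np.ndarray

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        if self.edges.ndim != 1 or len(self.edges) < 2:
            raise ValueError("edges must be a 1-D array of >= 2 boundaries")
        if not np.all(np.diff(self.edges) > 0):
            raise ValueError(f"edges must be strictly increasing: {self.edges}")

    @property
    def n_classes(self) -> int:
        return len(self.edges) - 1


def bin_condition(value: float, scheme: BinningScheme) -> int:
    """Class index (1..n) of *value* under *scheme*.

    Values outside the overall range clamp to the terminal classes with
    a logged warning; NaN is an error.
    """
    if math.isnan(value):
        raise ValueError(f"NaN value for condition {scheme.name}")
    edges = scheme.edges
    if value < edges[0] or value > edges[-1]:
        log.warning(
            "%s=%g outside [%g, %g]; clamping", scheme.name, value, edges[0], edges[-1]
        )
        return 1 if value < edges[0] else scheme.n_classes
    # right-closed intervals: a value on a shared boundary -> lower class
    idx = int(np.searchsorted(edges[1:], value, side="left")) + 1
    return min(idx, scheme.n_classes)


def fit_quantile_bins(values, n: int, name: str = "condition") -> BinningScheme:
    """Fit class boundaries at equal quantiles of the observed values.

    For n=5 the boundaries sit at the 20/40/60/80/100th percentiles; for
    n=3 at 1/3 and 2/3.  Requires at least *n* distinct values.
    """
    values = np.asarray(values, dtype=float)
    if len(np.unique(values)) < n:
        raise ValueError(f"need >= {n} distinct values to fit {n} quantile bins")
    qs = np.linspace(0, 100, n + 1)
    # order-statistic percentiles: boundaries are observed values
    edges = np.percentile(values, qs, method="lower")
    if not np.all(np.diff(edges) > 0):
        raise ValueError("quantile boundaries are not strictly increasing")
    return BinningScheme(name=name, edges=edges)


def table1_schemes(config: dict | None = None) -> dict[str, BinningScheme]:
    """The published fixed class boundaries for the five conditions."""
    config = config or load_default_config()
    return {
        name: BinningScheme(name=name, edges=np.asarray(edges, dtype=float))
        for name, edges in config["condition_bins"].items()
    }
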