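"""Read and write LLPS experiment tables and FASTA sequence files.

One table row is one wet-lab experiment: a protein sequence, an RNA
sequence, the concentrations of both (value and unit in separate
columns), the salts in the buffer, pH, temperature, and the observed
condensate morphology (solute / liquid / gel / solid).  Rows that fail
validation are returned as explicit rejects with reasons — never
silently dropped.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .config import load_default_config

log = logging.getLogger(__name__)

MORPHOLOGIES = ("solute", "liquid", "gel", "solid")
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
RNA_BASES = frozenset("ACGU")

#: logical field -> default column name in the table
DEFAULT_COLUMN_MAP = {
    "record_id": "record_id",
    "protein_sequence": "protein_sequence",
    "rna_sequence": "rna_sequence",
    "protein_conc_value": "protein_conc",
    "protein_conc_unit": "protein_conc_unit",
    "rna_conc_value": "rna_conc",
    "rna_conc_unit": "rna_conc_unit",
    "salts": "salts",
    "ph": "pH",
    "temperature": "temperature",
    "morphology": "morphology",
    "has_crowder_or_small_molecule": "has_crowder_or_small_molecule",
    "source": "pmidlink",
}

MANDATORY_FIELDS = ("protein_sequence", "rna_sequence", "morphology")


class SchemaError(ValueError):
    """A mandatory column is missing from the input table."""


class DuplicateIdentifierError(ValueError):
    """A FASTA file contains the same identifier more than once."""


@dataclass
class ExperimentRecord:
    """A single curated LLPS experiment."""

    record_id: str
    protein_sequence: str
    rna_sequence: str
    morphology: str
    protein_conc_value: float | None = None
    protein_conc_unit: str | None = None
    rna_conc_value: float | None = None
    rna_conc_unit: str | None = None
    salts: list[tuple[str, float, str]] = field(default_factory=list)
    ph: float | None = None
    temperature_raw: float | str | None = None
    has_crowder_or_small_molecule: bool = False
    source: str = ""

    def validate(self) -> list[str]:
        """Return a list of contract violations (empty if well-formed)."""
        problems = []
        if self.morphology not in MORPHOLOGIES:
            problems.append(f"unknown morphology {self.morphology!r}")
        bad = sorted(set(self.protein_sequence) - AMINO_ACIDS)
        if bad:
            problems.append(f"non-standard amino acid(s) {''.join(bad)}")
        bad = sorted(set(self.rna_sequence) - RNA_BASES)
        if bad:
            problems.append(f"non-ACGU base(s) {''.join(bad)}")
        for value, unit, what in (
            (self.protein_conc_value, self.protein_conc_unit, "protein"),
            (self.rna_conc_value, self.rna_conc_unit, "RNA"),
        ):
            if value is not None and value < 0:
                problems.append(f"negative {what} concentration")
        if self.ph is not None and not (0.0 <= self.ph <= 14.0):
            problems.append(f"pH {self.ph} outside [0, 14]")
        return problems


@dataclass
class RejectedRecord:
    row: int
    record_id: str
    reason: str


def normalize_unit(token: str, config: dict | None = None) -> str:
    """Map a concentration unit spelling onto its canonical token."""
    config = config or load_default_config()
    aliases = config["unit_aliases"]
    token = token.strip()
    if token in aliases:
        return aliases[token]
    raise ValueError(f"unknown concentration unit {token!r}")


def normalize_rna_sequence(seq: str) -> str:
    """Uppercase and map DNA-style T to U (logged, not silent)."""
    seq = seq.strip().upper()
    if "T" in seq:
        log.warning("RNA sequence contains T; mapping T->U")
        seq = seq.replace("T", "U")
    return seq


def _parse_salts(text: str, config: dict) -> list[tuple[str, float, str]]:
    """Parse ``"NaCl:0.15:M; MgCl2:10:mM"`` into (species, value, unit)."""
    if text is None or (isinstance(text, float) and math.isnan(text)):
        return []
    text = str(text).strip()
    if not text:
        return []
    aliases = config["salt_aliases"]
    out = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(":")
        if len(parts) != 3:
            raise ValueError(f"malformed salt entry {chunk!r}")
        species, value, unit = (p.strip() for p in parts)
        species = aliases.get(species, species)
        out.append((species, float(value), unit))
    return out


def _cell(row: pd.Series, colmap: dict, key: str):
    col = colmap.get(key)
    if col is None or col not in row.index:
        return None
    value = row[col]
    if isinstance(value, float) and math.isnan(value):
        return None
    return value


def read_records(
    path: str | Path,
    dialect: str | None = None,
    column_map: dict | None = None,
    config: dict | None = None,
) -> tuple[list[ExperimentRecord], list[RejectedRecord]]:
    """Read an experiment table; return (records, rejects).

    The dialect (``"csv"`` or ``"tsv"``) is auto-detected from the file
    extension unless given.  ``column_map`` overrides the default
    logical-field -> column-name mapping.  Row conservation holds:
    every data row becomes exactly one record or one reject.
    """
    path = Path(path)
    config = config or load_default_config()
    colmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        colmap.update(column_map)
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    sep = "\t" if dialect == "tsv" else ","
    frame = pd.read_csv(path, sep=sep, dtype={colmap["record_id"]: str})

    for key in MANDATORY_FIELDS:
        if colmap[key] not in frame.columns:
            raise SchemaError(f"missing mandatory column {colmap[key]!r}")

    records: list[ExperimentRecord] = []
    rejects: list[RejectedRecord] = []
    for i, (_, row) in enumerate(frame.iterrows()):
        rid = _cell(row, colmap, "record_id") or f"row{i}"
        try:
            record = _row_to_record(row, rid, colmap, config)
        except (ValueError, TypeError) as exc:
            rejects.append(RejectedRecord(i, str(rid), str(exc)))
            continue
        problems = record.validate()
        if problems:
            rejects.append(RejectedRecord(i, record.record_id, "; ".join(problems)))
        else:
            records.append(record)
    return records, rejects


def _row_to_record(
    row: pd.Series, rid: str, colmap: dict, config: dict
) -> ExperimentRecord:
    morphology = _cell(row, colmap, "morphology")
    if morphology is None:
        raise ValueError("missing morphology")
    morphology = str(morphology).strip().lower()
    if morphology not in MORPHOLOGIES:
        raise ValueError(f"unknown morphology {morphology!r}")

    def conc(which: str) -> tuple[float | None, str | None]:
        value = _cell(row, colmap, f"{which}_conc_value")
        unit = _cell(row, colmap, f"{which}_conc_unit")
        if value is None:
            return None, None
        value = float(value)
        unit = normalize_unit(str(unit), config) if unit is not None else None
        return value, unit

    pv, pu = conc("protein")
    rv, ru = conc("rna")
    ph = _cell(row, colmap, "ph")
    temperature = _cell(row, colmap, "temperature")
    crowder = _cell(row, colmap, "has_crowder_or_small_molecule")
    if isinstance(crowder, str):
        crowder = crowder.strip().lower() in ("true", "1", "yes")
    return ExperimentRecord(
        record_id=str(rid),
        protein_sequence=str(_cell(row, colmap, "protein_sequence")).strip().upper(),
        rna_sequence=normalize_rna_sequence(str(_cell(row, colmap, "rna_sequence"))),
        morphology=morphology,
        protein_conc_value=pv,
        protein_conc_unit=pu,
        rna_conc_value=rv,
        rna_conc_unit=ru,
        salts=_parse_salts(_cell(row, colmap, "salts"), config),
        ph=float(ph) if ph is not None else None,
        temperature_raw=temperature,
        has_crowder_or_small_molecule=bool(crowder),
        source=str(_cell(row, colmap, "source") or ""),
    )


def write_records(records: list[ExperimentRecord], path: str | Path) -> None:
    """Write records back to a CSV/TSV table (inverse of read_records)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    rows = []
    for r in records:
        rows.append(
            {
                "record_id": r.record_id,
                "protein_sequence": r.protein_sequence,
                "rna_sequence": r.rna_sequence,
                "protein_conc": r.protein_conc_value,
                "protein_conc_unit": r.protein_conc_unit,
                "rna_conc": r.rna_conc_value,
                "rna_conc_unit": r.rna_conc_unit,
                "salts": ";".join(f"{s}:{v!r}:{u}" for s, v, u in r.salts),
                "pH": r.ph,
                "temperature": r.temperature_raw,
                "morphology": r.morphology,
                "has_crowder_or_small_molecule": r.has_crowder_or_small_molecule,
                "pmidlink": r.source,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an identifier -> sequence catalog.

    Description lines are stripped to the identifier; sequences are
    uppercased and multi-line entries joined.  Duplicate identifiers
    raise :class:`DuplicateIdentifierError`.
    """
    catalog: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in catalog:
            raise DuplicateIdentifierError(f"duplicate identifier {rec.id!r}")
        catalog[rec.id] = str(rec.seq).upper()
    return catalog


def write_feature_table(
    records: list[ExperimentRecord],
    vectors,
    path: str | Path,
    feature_names: list[str] | None = None,
) -> None:
    """Write aligned (record, feature-vector) pairs to a TSV.

    Columns: record id, the 131 named features in fixed order, and the
    binary label (empty for gel/solid records).  Reading the file back
    reproduces the numeric payload bitwise (pandas round-trips Python
    float repr).
    """
    import numpy as np

    from .behavior_model import feature_names as default_names

    vectors = np.asarray(vectors, dtype=float)
    if len(records) != len(vectors):
        raise ValueError(
            f"{len(records)} records but {len(vectors)} feature vectors"
        )
    names = feature_names or default_names()
    label = {
        "solute": 0,
        "liquid": 1,
    }
    frame = pd.DataFrame(
        vectors.reshape(len(records), -1) if len(records) else [], columns=names
    )
    frame.insert(0, "record_id", [r.record_id for r in records])
    frame["label"] = [label.get(r.morphology) for r in records]
    frame.to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
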