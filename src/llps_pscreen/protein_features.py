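"""The 29 protein-sequence descriptors.

Composition and physicochemical descriptors computed with Biopython's
ProteinAnalysis: the 20 amino-acid fractions, sequence length, average
molecular weight, aromaticity (fraction of F/W/Y), the Guruprasad
dipeptide-weight instability index, the isoelectric point (bisection on
the net-charge curve), GRAVY (mean Kyte–Doolittle hydropathy), and the
three secondary-structure fractions (helix: V,I,Y,F,W,L; turn: N,P,G,S;
sheet: E,M,A,L).
"""
from __future__ import annotations

import numpy as np
from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint
from Bio.SeqUtils.ProtParam import ProteinAnalysis

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
MIN_LENGTH = 10

PROTEIN_FEATURE_NAMES: list[str] = [f"frac_{aa}" for aa in AA_ORDER] + [
    "sequence_length",
    "molecular_weight",
    "aromaticity",
    "instability_index",
    "isoelectric_point",
    "gravy",
    "helix_fraction",
    "turn_fraction",
    "sheet_fraction",
]


def validate_protein_sequence(seq: str, min_length: int = MIN_LENGTH) -> str:
    """Uppercase and check alphabet/length; errors name the position."""
    seq = seq.strip().upper()
    if len(seq) < min_length:
        raise ValueError(f"protein sequence length {len(seq)} < {min_length}")
    for i, aa in enumerate(seq):
        if aa not in AA_ORDER:
            raise ValueError(f"non-standard amino acid {aa!r} at position {i}")
    return seq


def protein_descriptors(seq: str) -> np.ndarray:
    """Compute the fixed-order 29-vector of protein descriptors."""
    seq = validate_protein_sequence(seq)
    analysis = ProteinAnalysis(seq)
    percents = analysis.amino_acids_percent  # given in percent, 0..100
    helix, turn, sheet = analysis.secondary_structure_fraction()
    values = [percents[aa] / 100.0 for aa in AA_ORDER] + [
        float(len(seq)),
        analysis.molecular_weight(),
        analysis.aromaticity(),
        analysis.instability_index(),
        analysis.isoelectric_point(),
        analysis.gravy(),
        helix,
        turn,
        sheet,
    ]
    return np.array(values, dtype=float)


def isoelectric_point(seq: str) -> float:
    """pH at which the sequence's net charge crosses zero (bisection)."""
    seq = validate_protein_sequence(seq, min_length=1)
    return IsoelectricPoint(seq).pi()


def charge_at_pH(seq: str, ph: float) -> float:
    """Net charge of the sequence at a given pH (for pI verification)."""
    seq = validate_protein_sequence(seq, min_length=1)
    return IsoelectricPoint(seq).charge_at_pH(ph)
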