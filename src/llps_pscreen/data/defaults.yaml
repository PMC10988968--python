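# Default configuration: unit aliases, supported salts, condition class
# boundaries, and physical constants used by the preprocessing layer.

room_temperature_c: 25.0

# Concentration unit aliases -> canonical token.
unit_aliases:
  "M": "M"
  "mol/L": "M"
  "mM": "mM"
  "uM": "uM"
  "µM": "uM"      # micro sign
  "μM": "uM"      # greek mu
  "um": "uM"
  "nM": "nM"
  "mg/mL": "mg/mL"
  "mg/ml": "mg/mL"

# Supported salt species: fully dissociated ion inventory as
# (stoichiometry, charge) pairs per formula unit.  Ionic strength is
# I = 1/2 * sum_i c * nu_i * z_i^2 over these ions.
salts:
  NaCl:       [[1, 1], [1, -1]]
  KCl:        [[1, 1], [1, -1]]
  LiCl:       [[1, 1], [1, -1]]
  MgCl2:      [[1, 2], [2, -1]]
  CaCl2:      [[1, 2], [2, -1]]
  ZnCl2:      [[1, 2], [2, -1]]
  Na2SO4:     [[2, 1], [1, -2]]
  NaH2PO4:    [[1, 1], [1, -1]]
  Na2HPO4:    [[2, 1], [1, -2]]
  KH2PO4:     [[1, 1], [1, -1]]
  K2HPO4:     [[2, 1], [1, -2]]
  # Tris buffer titrated with HCl, treated as a 1:1 monovalent electrolyte.
  Tris-HCl:   [[1, 1], [1, -1]]

salt_aliases:
  "NaCl": "NaCl"
  "KCl": "KCl"
  "LiCl": "LiCl"
  "MgCl2": "MgCl2"
  "MgCl₂": "MgCl2"
  "CaCl2": "CaCl2"
  "CaCl₂": "CaCl2"
  "ZnCl2": "ZnCl2"
  "ZnCl₂": "ZnCl2"
  "Na2SO4": "Na2SO4"
  "NaH2PO4": "NaH2PO4"
  "Na2HPO4": "Na2HPO4"
  "KH2PO4": "KH2PO4"
  "K2HPO4": "K2HPO4"
  "Tris-HCl": "Tris-HCl"
  "TrisHCl": "Tris-HCl"
  "Tris·HCl": "Tris-HCl"

# Published class boundaries for the condition-prediction targets.
# Edges are interval boundaries (n classes -> n+1 edges).  Convention:
# the first interval is closed on both ends; subsequent intervals are
# left-open, right-closed.
condition_bins:
  pH:             [0.0, 7.0, 8.0, 14.0]
  temperature:    [0.0, 25.0, 30.0, 40.0]
  ionic_strength: [0.0, 0.032, 0.066, 0.14, 0.17, 0.40]
  protein_conc:   [-1.64, -0.49, -0.29, 0.84, 1.5, 2.7]
  rna_conc:       [-4.7, -3.7, -2.4, -1.0, -0.12, 2.3]
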