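{
  "comment": "Van der Waals radii in Angstrom (Bondi-style values, common extensions for metals). Used by the voxel occupancy function; elements not listed fall back to 'default'.",
  "default": 1.7,
  "radii": {
    "H": 1.2,
    "B": 1.92,
    "C": 1.7,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "NA": 2.27,
    "MG": 1.73,
    "P": 1.8,
    "S": 1.8,
    "CL": 1.75,
    "K": 2.75,
    "CA": 2.31,
    "MN": 2.05,
    "FE": 2.0,
    "CO": 2.0,
    "NI": 1.63,
    "CU": 1.4,
    "ZN": 1.39,
    "SE": 1.9,
    "BR": 1.85,
    "CD": 1.58,
    "I": 1.98,
    "HG": 1.55
  }
}
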