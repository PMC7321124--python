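{
  "comment": "Pharmacophore channel assignment rules for protein heavy atoms, keyed by residue name and PDB atom name. AutoDock-flavoured typing: aromatic ring carbons are both hydrophobic and aromatic, carboxylates are acceptor + negative-ionizable, guanidinium/ammonium nitrogens are donor + positive-ionizable. The excluded_volume channel is set for every heavy atom regardless of these rules.",
  "channels": [
    "hydrophobic",
    "aromatic",
    "acceptor",
    "donor",
    "positive_ionizable",
    "negative_ionizable",
    "metal",
    "excluded_volume"
  ],
  "metals": ["ZN", "MG", "CA", "MN", "FE", "CO", "NI", "CU", "NA", "K", "CD", "HG"],
  "backbone": {
    "N": ["donor"],
    "O": ["acceptor"],
    "OXT": ["acceptor", "negative_ionizable"]
  },
  "residues": {
    "ALA": {"CB": ["hydrophobic"]},
    "VAL": {"CB": ["hydrophobic"], "CG1": ["hydrophobic"], "CG2": ["hydrophobic"]},
    "LEU": {"CB": ["hydrophobic"], "CG": ["hydrophobic"], "CD1": ["hydrophobic"], "CD2": ["hydrophobic"]},
    "ILE": {"CB": ["hydrophobic"], "CG1": ["hydrophobic"], "CG2": ["hydrophobic"], "CD1": ["hydrophobic"]},
    "PRO": {"CB": ["hydrophobic"], "CG": ["hydrophobic"], "CD": ["hydrophobic"]},
    "MET": {"CB": ["hydrophobic"], "CG": ["hydrophobic"], "SD": ["hydrophobic"], "CE": ["hydrophobic"]},
    "CYS": {"CB": ["hydrophobic"], "SG": ["donor"]},
    "SER": {"OG": ["acceptor", "donor"]},
    "THR": {"OG1": ["acceptor", "donor"], "CG2": ["hydrophobic"]},
    "ASN": {"CB": ["hydrophobic"], "OD1": ["acceptor"], "ND2": ["donor"]},
    "GLN": {"CB": ["hydrophobic"], "CG": ["hydrophobic"], "OE1": ["acceptor"], "NE2": ["donor"]},
    "ASP": {"CB": ["hydrophobic"], "CG": ["negative_ionizable"], "OD1": ["acceptor", "negative_ionizable"], "OD2": ["acceptor", "negative_ionizable"]},
    "GLU": {"CB": ["hydrophobic"], "CG": ["hydrophobic"], "CD": ["negative_ionizable"], "OE1": ["acceptor", "negative_ionizable"], "OE2": ["acceptor", "negative_ionizable"]},
    "LYS": {"CB": ["hydrophobic"], "CG": ["hydrophobic"], "CD": ["hydrophobic"], "CE": ["hydrophobic"], "NZ": ["donor", "positive_ionizable"]},
    "ARG": {"CB": ["hydrophobic"], "CG": ["hydrophobic"], "CD": ["hydrophobic"], "NE": ["donor", "positive_ionizable"], "CZ": ["positive_ionizable"], "NH1": ["donor", "positive_ionizable"], "NH2": ["donor", "positive_ionizable"]},
    "HIS": {"CB": ["hydrophobic"], "CG": ["aromatic"], "ND1": ["aromatic", "acceptor", "donor", "positive_ionizable"], "CD2": ["aromatic"], "CE1": ["aromatic"], "NE2": ["aromatic", "acceptor", "donor", "positive_ionizable"]},
    "PHE": {"CB": ["hydrophobic"], "CG": ["hydrophobic", "aromatic"], "CD1": ["hydrophobic", "aromatic"], "CD2": ["hydrophobic", "aromatic"], "CE1": ["hydrophobic", "aromatic"], "CE2": ["hydrophobic", "aromatic"], "CZ": ["hydrophobic", "aromatic"]},
    "TYR": {"CB": ["hydrophobic"], "CG": ["hydrophobic", "aromatic"], "CD1": ["hydrophobic", "aromatic"], "CD2": ["hydrophobic", "aromatic"], "CE1": ["hydrophobic", "aromatic"], "CE2": ["hydrophobic", "aromatic"], "CZ": ["aromatic"], "OH": ["acceptor", "donor"]},
    "TRP": {"CB": ["hydrophobic"], "CG": ["hydrophobic", "aromatic"], "CD1": ["aromatic"], "CD2": ["hydrophobic", "aromatic"], "NE1": ["aromatic", "donor"], "CE2": ["hydrophobic", "aromatic"], "CE3": ["hydrophobic", "aromatic"], "CZ2": ["hydrophobic", "aromatic"], "CZ3": ["hydrophobic", "aromatic"], "CH2": ["hydrophobic", "aromatic"]},
    "GLY": {}
  }
}
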