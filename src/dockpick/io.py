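"""Structure and label I/O.

Reads protein/ligand structure files, extracts the binding pocket as the
sphere of protein heavy atoms around the ligand's center of mass, computes
the three per-protocol pose-quality statistics (RMSDmin, RMSDave, nRMSD)
from lists of pose RMSDs, and loads/saves tidy long-format label tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ComplexRecord",
    "PocketStructure",
    "LabelTriple",
    "LabelMatrix",
    "TARGETS",
    "default_protocols",
    "vdw_radius",
    "load_complex",
    "extract_pocket",
    "compute_label_triple",
    "load_label_table",
    "save_label_table",
]

#: Target order used everywhere a (…, 3) label axis appears.
TARGETS = ("rmsd_min", "rmsd_ave", "n_rmsd")


class FormatError(ValueError):
    """A structure or table file could not be parsed."""


def _load_data(name: str) -> dict:
    with resources.files("dockpick.data").joinpath(name).open() as fh:
        return json.load(fh)


_VDW = _load_data("vdw_radii.json")


def default_protocols() -> list[str]:
    """The bundled 14-entry docking-protocol registry, in canonical order."""
    return list(_load_data("protocols.json")["protocols"])


def vdw_radius(element: str) -> float:
    """Van der Waals radius (Å) for an element symbol; table fallback for
    unknown elements is the carbon-like default."""
    return float(_VDW["radii"].get(element.upper(), _VDW["default"]))


@dataclass
class ComplexRecord:
    """A protein–ligand complex: protein atoms, ligand heavy-atom info and
    the crystal resolution that thresholds the nRMSD count."""

    id: str
    protein_coords: np.ndarray  # (n_atoms, 3) Å
    protein_elements: list[str]
    protein_residues: list[str]
    protein_atom_names: list[str]
    ligand_coords: np.ndarray  # heavy atoms only, (n, 3) Å
    ligand_masses: np.ndarray
    resolution: float
    ligand_mol: object | None = None  # rdkit Mol when loaded from SDF/SMILES

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")
        if len(self.ligand_coords) < 1:
            raise ValueError("ligand must have at least one heavy atom")

    @property
    def ligand_center(self) -> np.ndarray:
        """Mass-weighted center of the ligand heavy atoms (Å)."""
        w = self.ligand_masses / self.ligand_masses.sum()
        return w @ self.ligand_coords


@dataclass
class PocketStructure:
    """Binding-site point cloud: coordinates, vdW radii and the 8 boolean
    pharmacophore channel flags per heavy atom."""

    coords: np.ndarray  # (n, 3) Å
    vdw_radii: np.ndarray  # (n,) Å
    channel_flags: np.ndarray  # (n, 8) bool
    center: np.ndarray  # (3,) Å
    elements: list[str] | None = None
    residues: list[str] | None = None
    atom_names: list[str] | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.vdw_radii = np.asarray(self.vdw_radii, dtype=float).reshape(-1)
        self.channel_flags = np.asarray(self.channel_flags, dtype=bool).reshape(-1, 8)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        n = len(self.coords)
        if len(self.vdw_radii) != n or len(self.channel_flags) != n:
            raise ValueError("coords, vdw_radii and channel_flags disagree in length")
        if n and (self.vdw_radii <= 0).any():
            raise ValueError("vdW radii must be positive")

    def __len__(self) -> int:
        return len(self.coords)


@dataclass(frozen=True)
class LabelTriple:
    """(RMSDmin, RMSDave, nRMSD) for one complex under one protocol."""

    rmsd_min: float
    rmsd_ave: float
    n_rmsd: int

    def __post_init__(self):
        if self.rmsd_min < 0 or self.rmsd_ave < 0:
            raise ValueError("RMSD statistics must be non-negative")
        if self.rmsd_min > self.rmsd_ave + 1e-12:
            raise ValueError("rmsd_min cannot exceed rmsd_ave")
        if self.n_rmsd < 0:
            raise ValueError("n_rmsd must be a non-negative count")


def _heavy(elements) -> np.ndarray:
    return np.array([e.upper() not in ("H", "D") for e in elements], dtype=bool)


def load_complex(protein_path, ligand_path, resolution: float, complex_id: str | None = None) -> ComplexRecord:
    """Load a PDB protein and an SDF ligand (first molecule) into a record.

    The ligand center is computed from heavy atoms only, mass-weighted, so
    structures with or without explicit hydrogens give the same center.
    """
    from rdkit import Chem

    protein_path, ligand_path = Path(protein_path), Path(ligand_path)
    for p in (protein_path, ligand_path):
        if not p.exists():
            raise FormatError(f"file not found: {p}")
    try:
        st = gemmi.read_structure(str(protein_path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse PDB file {protein_path}: {exc}") from exc
    coords, elements, residues, names = [], [], [], []
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    elements.append(atom.element.name.upper())
                    residues.append(res.name)
                    names.append(atom.name)
        break  # first model only
    if not coords:
        raise FormatError(f"no atoms found in {protein_path}")

    supplier = Chem.SDMolSupplier(str(ligand_path), removeHs=False, sanitize=True)
    mol = next((m for m in supplier if m is not None), None)
    if mol is None:
        raise FormatError(f"cannot parse SDF file {ligand_path}")
    conf = mol.GetConformer()
    lig_coords, lig_masses = [], []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() > 1:
            p = conf.GetAtomPosition(atom.GetIdx())
            lig_coords.append([p.x, p.y, p.z])
            lig_masses.append(atom.GetMass())
    if not lig_coords:
        raise ValueError(f"ligand in {ligand_path} has no heavy atoms")

    return ComplexRecord(
        id=complex_id or protein_path.stem,
        protein_coords=np.asarray(coords, dtype=float),
        protein_elements=elements,
        protein_residues=residues,
        protein_atom_names=names,
        ligand_coords=np.asarray(lig_coords, dtype=float),
        ligand_masses=np.asarray(lig_masses, dtype=float),
        resolution=float(resolution),
        ligand_mol=mol,
    )


def extract_pocket(record: ComplexRecord | PocketStructure, radius: float = 15.0) -> PocketStructure:
    """Protein heavy atoms within ``radius`` Å of the ligand center of mass.

    Accepts either a complex record or an existing pocket (re-extraction
    with the same radius is a no-op). Channel flags are initialized to
    excluded-volume only; see :func:`dockpick.featurize.assign_channels`.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if isinstance(record, PocketStructure):
        keep = np.linalg.norm(record.coords - record.center, axis=1) <= radius
        return PocketStructure(
            coords=record.coords[keep],
            vdw_radii=record.vdw_radii[keep],
            channel_flags=record.channel_flags[keep],
            center=record.center,
            elements=[e for e, k in zip(record.elements, keep) if k] if record.elements else None,
            residues=[r for r, k in zip(record.residues, keep) if k] if record.residues else None,
            atom_names=[a for a, k in zip(record.atom_names, keep) if k] if record.atom_names else None,
        )

    center = record.ligand_center
    heavy = _heavy(record.protein_elements)
    dist = np.linalg.norm(record.protein_coords - center, axis=1)
    keep = heavy & (dist <= radius)
    idx = np.flatnonzero(keep)
    elements = [record.protein_elements[i] for i in idx]
    flags = np.zeros((len(idx), 8), dtype=bool)
    flags[:, 7] = True  # excluded volume: every heavy atom
    return PocketStructure(
        coords=record.protein_coords[idx],
        vdw_radii=np.array([vdw_radius(e) for e in elements]),
        channel_flags=flags,
        center=center,
        elements=elements,
        residues=[record.protein_residues[i] for i in idx],
        atom_names=[record.protein_atom_names[i] for i in idx],
    )


def compute_label_triple(pose_rmsds, resolution: float) -> LabelTriple:
    """Summarize a self-docking run: minimum and mean pose RMSD plus the
    count of poses with RMSD strictly below the crystal resolution."""
    rmsds = np.asarray(pose_rmsds, dtype=float)
    if rmsds.size == 0:
        raise ValueError("pose_rmsds must be non-empty")
    if (rmsds < 0).any():
        raise ValueError("pose RMSDs must be non-negative")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    return LabelTriple(
        rmsd_min=float(rmsds.min()),
        rmsd_ave=float(rmsds.mean()),
        n_rmsd=int((rmsds < resolution).sum()),
    )


class LabelMatrix:
    """Per-complex ``P × 3`` table of (RMSDmin, RMSDave, nRMSD) labels.

    Values are stored as an (n_complexes, P, 3) float array in registry
    order; missing (complex, protocol) entries are NaN and exposed through
    :attr:`mask` rather than silently zero.
    """

    def __init__(self, complex_ids, values, protocols=None):
        self.protocols = list(protocols) if protocols is not None else default_protocols()
        self.complex_ids = list(complex_ids)
        self.values = np.asarray(values, dtype=float)
        if self.values.shape != (len(self.complex_ids), len(self.protocols), 3):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.complex_ids)}, {len(self.protocols)}, 3)"
            )

    def __len__(self) -> int:
        return len(self.complex_ids)

    @property
    def mask(self) -> np.ndarray:
        """(n, P) boolean array: True where the label triple is present."""
        return np.isfinite(self.values).all(axis=2)

    def index_of(self, protocol: str) -> int:
        return self.protocols.index(protocol)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view: one row per present (complex, protocol)."""
        rows = []
        for i, cid in enumerate(self.complex_ids):
            for j, prot in enumerate(self.protocols):
                if np.isfinite(self.values[i, j]).all():
                    rows.append((cid, prot, *self.values[i, j]))
        df = pd.DataFrame(rows, columns=["complex_id", "protocol", *TARGETS])
        df["n_rmsd"] = df["n_rmsd"].astype(int)
        return df


def load_label_table(path, protocols=None) -> LabelMatrix:
    """Read a tidy delimited label table (complex_id, protocol, rmsd_min,
    rmsd_ave, n_rmsd) into a :class:`LabelMatrix`.

    Protocol names outside the registry and duplicate (complex, protocol)
    rows are rejected.
    """
    protocols = list(protocols) if protocols is not None else default_protocols()
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    required = {"complex_id", "protocol", *TARGETS}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"label table {path} lacks columns: {sorted(missing)}")
    unknown = sorted(set(df["protocol"]) - set(protocols))
    if unknown:
        raise ValueError(f"unknown protocol name(s) in label table: {unknown}")
    dup = df.duplicated(subset=["complex_id", "protocol"])
    if dup.any():
        offender = df.loc[dup.idxmax(), ["complex_id", "protocol"]].tolist()
        raise ValueError(f"duplicate (complex, protocol) row: {offender}")

    ids = list(dict.fromkeys(df["complex_id"]))  # keep first-appearance order
    pidx = {p: j for j, p in enumerate(protocols)}
    values = np.full((len(ids), len(protocols), 3), np.nan)
    cidx = {c: i for i, c in enumerate(ids)}
    for row in df.itertuples(index=False):
        values[cidx[row.complex_id], pidx[row.protocol]] = (
            row.rmsd_min, row.rmsd_ave, row.n_rmsd,
        )
    return LabelMatrix(ids, values, protocols)


def save_label_table(matrix: LabelMatrix, path) -> None:
    """Write a label matrix as tidy CSV with round-trip float precision."""
    df = matrix.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")
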