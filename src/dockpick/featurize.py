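"""Featurization: pocket voxelization and ligand fingerprints/descriptors.

The protein leg sees an 8-channel occupancy grid. Each atom contributes to
a voxel through the pair-correlation occupancy

    n(r) = 1 - exp(-(r_vdw / r)^12),

where ``r`` is the euclidean distance from the voxel center to the atom
and ``r_vdw`` its van der Waals radius; per voxel and channel, occupancies
of the atoms carrying that channel flag are combined with a maximum, which
keeps every value in [0, 1]. The ligand leg sees a 1024-bit circular
fingerprint of bond radius 2 concatenated with 183 physico-chemical
descriptors (standardized with training-fold statistics).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from sklearn.preprocessing import StandardScaler

from .io import PocketStructure

logger = logging.getLogger(__name__)

__all__ = [
    "CHANNELS",
    "VoxelGrid",
    "voxel_contribution",
    "assign_channels",
    "load_channel_rules",
    "voxelize",
    "random_rotation_matrix",
    "random_rotation",
    "ligand_fingerprint",
    "ligand_descriptors",
    "default_descriptor_names",
    "DescriptorStandardizer",
    "FeatureSet",
]

#: Fixed channel order of the voxel grid.
CHANNELS = (
    "hydrophobic",
    "aromatic",
    "acceptor",
    "donor",
    "positive_ionizable",
    "negative_ionizable",
    "metal",
    "excluded_volume",
)

FINGERPRINT_BITS = 1024
N_DESCRIPTORS = 183


# ---------------------------------------------------------------------------
# voxel grid


@dataclass
class VoxelGrid:
    """8 × E × E × E occupancy tensor with its placement metadata."""

    values: np.ndarray
    origin: np.ndarray  # Å corner of the grid
    resolution: float  # Å per voxel
    channels: tuple = CHANNELS

    def save(self, path) -> None:
        """Write the tensor (.npy) with a JSON sidecar describing it."""
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.values)
        sidecar = {
            "channels": list(self.channels),
            "origin": [float(v) for v in self.origin],
            "resolution": float(self.resolution),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path) -> "VoxelGrid":
        path = Path(path)
        values = np.load(path.with_suffix(".npy"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            values=values,
            origin=np.asarray(meta["origin"], dtype=float),
            resolution=float(meta["resolution"]),
            channels=tuple(meta["channels"]),
        )


def voxel_contribution(r, rvdw):
    """Occupancy 1 - exp(-(rvdw/r)^12) of an atom at distance ``r``.

    Monotonically decreasing in ``r``; tends to 1 as ``r`` → 0 (the value
    at ``r`` = 0 is defined as this limit) and to 0 as ``r`` → ∞.
    """
    r = np.asarray(r, dtype=float)
    rvdw = np.asarray(rvdw, dtype=float)
    if (rvdw <= 0).any():
        raise ValueError("rvdw must be positive")
    if (r < 0).any():
        raise ValueError("r must be non-negative")
    with np.errstate(divide="ignore", over="ignore"):
        x12 = (rvdw / r) ** 12  # inf at r=0 -> occupancy 1, the limit value
        out = 1.0 - np.exp(-x12)
    return out if out.ndim else float(out)


def voxelize(
    pocket: PocketStructure,
    center=None,
    edge: float = 24.0,
    resolution: float = 1.0,
    dtype=np.float64,
    _atom_chunk: int = 128,
) -> VoxelGrid:
    """Convert a pocket into an 8-channel occupancy grid.

    The cubic grid of side ``edge`` Å is centered on ``center`` (default:
    the pocket center, i.e. the ligand center of mass) with ``resolution``
    Å voxels; voxel (i, j, k) is evaluated at its geometric center. All
    pocket atoms contribute, including those outside the grid box.
    ``dtype=np.float32`` trades the last digits for ~7× speed (used by
    rotation augmentation, where grids feed a float32 network anyway).
    """
    n_f = edge / resolution
    n = int(round(n_f))
    if abs(n_f - n) > 1e-9 or n <= 0:
        raise ValueError(f"edge/resolution must be a positive integer, got {n_f}")
    center = np.asarray(center if center is not None else pocket.center, dtype=float)
    origin = center - edge / 2.0
    values = np.zeros((len(CHANNELS), n, n, n), dtype=dtype)
    if len(pocket) == 0:
        return VoxelGrid(values=values, origin=origin, resolution=resolution)

    ax = (origin[:, None] + (np.arange(n) + 0.5) * resolution).astype(dtype)
    flags = pocket.channel_flags
    for lo in range(0, len(pocket), _atom_chunk):
        sl = slice(lo, lo + _atom_chunk)
        coords = pocket.coords[sl].astype(dtype)
        radii = pocket.vdw_radii[sl].astype(dtype)
        d2 = (
            (coords[:, 0, None, None, None] - ax[0][None, :, None, None]) ** 2
            + (coords[:, 1, None, None, None] - ax[1][None, None, :, None]) ** 2
            + (coords[:, 2, None, None, None] - ax[2][None, None, None, :]) ** 2
        )
        with np.errstate(divide="ignore", over="ignore"):
            x2 = radii[:, None, None, None] ** 2 / d2
            x6 = x2 * x2 * x2
            contrib = -np.expm1(-(x6 * x6))
        for c in range(len(CHANNELS)):
            m = flags[sl, c]
            if m.any():
                np.maximum(values[c], contrib[m].max(axis=0), out=values[c])
    return VoxelGrid(values=values, origin=origin, resolution=resolution)


# ---------------------------------------------------------------------------
# channel assignment


def load_channel_rules(path=None) -> dict:
    """Load the channel rule table (bundled default, or a user JSON)."""
    if path is None:
        with resources.files("dockpick.data").joinpath("channel_rules.json").open() as fh:
            return json.load(fh)
    return json.loads(Path(path).read_text())


def assign_channels(pocket: PocketStructure, rules: dict | None = None) -> PocketStructure:
    """Set the 8 pharmacophore flags of each pocket atom from the rule table.

    Requires element/residue/atom-name context on the pocket. Atoms not
    covered by any rule keep only the excluded-volume flag (logged once per
    distinct residue/atom-name pair).
    """
    if pocket.elements is None or pocket.residues is None or pocket.atom_names is None:
        raise ValueError("pocket lacks element/residue/atom-name context")
    rules = rules or load_channel_rules()
    cidx = {name: i for i, name in enumerate(CHANNELS)}
    metals = {m.upper() for m in rules["metals"]}
    backbone = rules["backbone"]
    residues = rules["residues"]

    flags = np.zeros((len(pocket), 8), dtype=bool)
    flags[:, cidx["excluded_volume"]] = True
    unknown_logged: set[tuple[str, str]] = set()
    for i, (elem, res, name) in enumerate(
        zip(pocket.elements, pocket.residues, pocket.atom_names)
    ):
        elem = elem.upper()
        if elem in metals:
            flags[i, cidx["metal"]] = True
            continue
        res_table = residues.get(res.upper())
        if res_table is not None and name in res_table:
            for ch in res_table[name]:
                flags[i, cidx[ch]] = True
        elif res_table is not None and name in backbone:
            for ch in backbone[name]:
                flags[i, cidx[ch]] = True
        elif res_table is not None and name in ("CA", "C", "CB"):
            pass  # plain backbone carbons: excluded volume only
        else:
            key = (res, name)
            if key not in unknown_logged:
                logger.info("no channel rule for residue %s atom %s; excluded volume only", res, name)
                unknown_logged.add(key)
    return PocketStructure(
        coords=pocket.coords.copy(),
        vdw_radii=pocket.vdw_radii.copy(),
        channel_flags=flags,
        center=pocket.center.copy(),
        elements=list(pocket.elements),
        residues=list(pocket.residues),
        atom_names=list(pocket.atom_names),
    )


# ---------------------------------------------------------------------------
# rotation augmentation


def random_rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Uniformly random proper rotation, sampled via a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def random_rotation(coords, pivot, rng: np.random.Generator, matrix=None) -> np.ndarray:
    """Rotate ``coords`` about ``pivot`` by a uniformly random rotation.

    A fixed ``matrix`` may be supplied (e.g. identity in tests) instead of
    sampling from ``rng``.
    """
    R = random_rotation_matrix(rng) if matrix is None else np.asarray(matrix)
    coords = np.asarray(coords, dtype=float)
    pivot = np.asarray(pivot, dtype=float)
    return (coords - pivot) @ R.T + pivot


# ---------------------------------------------------------------------------
# ligand features


def _as_mol(molecule):
    from rdkit import Chem

    if isinstance(molecule, str):
        mol = Chem.MolFromSmiles(molecule)
        if mol is None:
            raise ValueError(f"cannot parse SMILES: {molecule!r}")
        return mol
    return molecule


def ligand_fingerprint(molecule, n_bits: int = FINGERPRINT_BITS, radius: int = 2) -> np.ndarray:
    """Hashed circular fingerprint (bond radius 2, folded to 1024 bits)."""
    from rdkit.Chem import rdFingerprintGenerator

    mol = _as_mol(molecule)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def default_descriptor_names() -> list[str]:
    """The fixed default descriptor list: 183 2D physico-chemical
    descriptors, chosen deterministically (sorted names, numerically
    fragile entries excluded)."""
    from rdkit.Chem import Descriptors

    exclude = {"Ipc"}  # can overflow on large molecules
    names = sorted(name for name, _ in Descriptors.descList if name not in exclude)
    return names[:N_DESCRIPTORS]


def ligand_descriptors(molecule, names: list[str] | None = None) -> np.ndarray:
    """Real descriptor vector (default length 183); deterministic, with
    non-finite or failing descriptors replaced by 0 (warned once)."""
    from rdkit.Chem import Descriptors

    mol = _as_mol(molecule)
    names = names if names is not None else default_descriptor_names()
    fn = dict(Descriptors.descList)
    out = np.zeros(len(names))
    bad = []
    for i, name in enumerate(names):
        try:
            v = float(fn[name](mol))
        except Exception:  # descriptor failure on exotic molecules
            v = np.nan
        if np.isfinite(v):
            out[i] = v
        else:
            bad.append(name)
    if bad:
        warnings.warn(f"non-finite descriptor value(s) replaced by 0: {bad[:5]}...")
    return out


class DescriptorStandardizer:
    """Per-feature z-scoring with statistics from the training fold only.

    Constant features get scale 1 (so they map to zero, not NaN).
    """

    def fit(self, train_matrix) -> "DescriptorStandardizer":
        train_matrix = np.asarray(train_matrix, dtype=float)
        if train_matrix.ndim != 2 or train_matrix.shape[0] < 2:
            raise ValueError("need a 2D matrix with at least 2 training rows")
        self._scaler = StandardScaler().fit(train_matrix)
        self.mean_ = self._scaler.mean_
        self.scale_ = self._scaler.scale_
        return self

    def transform(self, matrix) -> np.ndarray:
        return self._scaler.transform(np.asarray(matrix, dtype=float))

    def fit_transform(self, matrix) -> np.ndarray:
        return self.fit(matrix).transform(matrix)


# ---------------------------------------------------------------------------
# assembled model inputs


@dataclass
class FeatureSet:
    """Model-ready features for a set of complexes.

    ``ligand`` is always present; the protein leg is served either from
    precomputed ``grids`` or from ``pockets`` (which enables per-epoch
    rotation augmentation).
    """

    ligand: np.ndarray  # (n, D_total)
    grids: np.ndarray | None = None  # (n, 8, E, E, E)
    pockets: list[PocketStructure] | None = None
    grid_edge: float = 24.0
    grid_resolution: float = 1.0

    def __post_init__(self):
        self.ligand = np.asarray(self.ligand, dtype=np.float32)
        if self.grids is None and self.pockets is None:
            raise ValueError("FeatureSet needs grids or pockets")
        n = len(self.ligand)
        if self.grids is not None and len(self.grids) != n:
            raise ValueError("grids/ligand length mismatch")
        if self.pockets is not None and len(self.pockets) != n:
            raise ValueError("pockets/ligand length mismatch")

    def __len__(self) -> int:
        return len(self.ligand)

    def ensure_grids(self) -> np.ndarray:
        """Voxelize pockets (unrotated) if grids are not yet present."""
        if self.grids is None:
            self.grids = np.stack(
                [
                    voxelize(p, edge=self.grid_edge, resolution=self.grid_resolution).values
                    for p in self.pockets
                ]
            ).astype(np.float32)
        return self.grids

    def subset(self, indices) -> "FeatureSet":
        indices = np.asarray(indices)
        return FeatureSet(
            ligand=self.ligand[indices],
            grids=self.grids[indices] if self.grids is not None else None,
            pockets=[self.pockets[i] for i in indices] if self.pockets is not None else None,
            grid_edge=self.grid_edge,
            grid_resolution=self.grid_resolution,
        )
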