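"""Synthetic benchmark generator.

Emulates the statistical shape of a self-docking benchmark without any
external data: pockets are pharmacophore-typed point clouds inside a 15 Å
sphere, ligands are sparse binary fingerprints plus correlated real
descriptors, and the per-protocol label triples are a planted noisy
function of low-dimensional projections of those features:

- ``rmsd_ave = softplus(w_pᵀ z + b_p + u_family) + noise``, clipped
  positive — protocol weights ``w_p`` share a common prior with a
  protocol-specific perturbation, so some protocols are "easier" than
  others;
- ``rmsd_min = c · rmsd_ave`` with ``c ~ U(0.3, 1)`` drawn per complex;
- ``n_rmsd ~ Binomial(n_poses, σ(−a · (rmsd_ave − resolution)))``, so
  accurate protocols produce more sub-resolution poses.

The planted parameters are kept on the benchmark object so that
parameter-recovery and learnability tests can check them.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .io import LabelMatrix, PocketStructure, default_protocols, vdw_radius
from .featurize import CHANNELS

__all__ = [
    "SyntheticConfig",
    "SyntheticBenchmark",
    "generate_pocket",
    "generate_ligand_features",
    "generate_labels",
    "make_benchmark",
    "save_benchmark",
    "load_benchmark",
]

# element -> (draw probability, pharmacophore-flag distribution)
_ELEMENTS = ("C", "N", "O", "S", "ZN")
_ELEMENT_P = np.array([0.60, 0.15, 0.15, 0.05, 0.05])
_FLAG_DIST = {
    "C": {"hydrophobic": 0.7, "aromatic": 0.3},
    "N": {"donor": 0.5, "acceptor": 0.2, "positive_ionizable": 0.3},
    "O": {"acceptor": 0.7, "negative_ionizable": 0.3},
    "S": {"hydrophobic": 1.0},
    "ZN": {"metal": 1.0},
}


def _channel_probs() -> np.ndarray:
    """Marginal probability of each non-excluded channel per atom."""
    probs = np.zeros(7)
    for elem, pe in zip(_ELEMENTS, _ELEMENT_P):
        for ch, pc in _FLAG_DIST[elem].items():
            probs[CHANNELS.index(ch)] += pe * pc
    return probs


@dataclass
class SyntheticConfig:
    """Generator settings; defaults define the desk-scale study conditions."""

    n_complexes: int = 200
    n_families: int = 25
    family_zipf: float = 1.0  # family sizes ∝ 1/rank^zipf
    pocket_atoms: int = 60
    pocket_radius: float = 15.0
    n_protocols: int = 14
    n_poses: int = 20
    noise_sd: float = 0.3  # Å, additive noise on rmsd_ave
    fingerprint_bits: int = 1024
    fingerprint_density: float = 0.05
    n_descriptors: int = 183
    n_fp_factors: int = 8  # latent dims read from the fingerprint
    fp_bits_per_factor: int = 32  # sparse support of each fingerprint factor
    n_desc_factors: int = 4  # latent dims read from the descriptors
    pocket_signal_scale: float = 1.0  # weight of pocket composition in the labels
    base_weight_scale: float = 0.8
    protocol_weight_scale: float = 0.3
    protocol_bias_mean: float = 1.2
    protocol_bias_sd: float = 0.5
    family_effect_sd: float = 0.3
    count_slope: float = 1.5
    resolution_range: tuple = (1.5, 2.5)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_complexes, self.n_families, self.pocket_atoms,
               self.n_protocols, self.n_poses) <= 0:
            raise ValueError("all counts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @classmethod
    def signal_dominant(cls, n_complexes: int = 500, seed: int = 0) -> "SyntheticConfig":
        """Learnability-benchmark conditions: low label noise, strong
        planted weights and clear protocol heterogeneity."""
        return cls(
            n_complexes=n_complexes,
            noise_sd=0.15,
            base_weight_scale=1.0,
            protocol_bias_sd=0.8,
            n_desc_factors=8,
            fp_bits_per_factor=16,
            pocket_signal_scale=0.6,
            seed=seed,
        )


@dataclass
class SyntheticBenchmark:
    """A fully assembled in-memory benchmark plus its planted parameters."""

    config: SyntheticConfig
    ids: list
    pockets: list
    fingerprints: np.ndarray  # (n, bits) uint8
    descriptors: np.ndarray  # (n, D)
    labels: LabelMatrix
    families: dict  # id -> family name
    resolutions: np.ndarray
    features_z: np.ndarray  # (n, d) planted low-dimensional features
    planted: dict  # weights, biases, projections

    @property
    def family_list(self) -> list:
        return [self.families[i] for i in self.ids]


def generate_pocket(rng: np.random.Generator, n_atoms: int = 60,
                    radius: float = 15.0) -> PocketStructure:
    """Atoms uniform in the sphere; elements and one pharmacophore flag per
    atom from the fixed categorical distributions; vdW radii from the
    bundled element table. The excluded-volume flag is always set."""
    if n_atoms < 0:
        raise ValueError("n_atoms must be >= 0")
    center = np.zeros(3)
    if n_atoms == 0:
        return PocketStructure(
            coords=np.empty((0, 3)), vdw_radii=np.empty(0),
            channel_flags=np.empty((0, 8), dtype=bool), center=center, elements=[],
        )
    direction = rng.normal(size=(n_atoms, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    r = radius * rng.uniform(size=n_atoms) ** (1.0 / 3.0)
    coords = direction * r[:, None]

    elem_idx = rng.choice(len(_ELEMENTS), size=n_atoms, p=_ELEMENT_P)
    elements = [_ELEMENTS[i] for i in elem_idx]
    flags = np.zeros((n_atoms, 8), dtype=bool)
    flags[:, CHANNELS.index("excluded_volume")] = True
    for i, elem in enumerate(elements):
        dist = _FLAG_DIST[elem]
        names = list(dist)
        ch = names[rng.choice(len(names), p=np.array([dist[c] for c in names]))]
        flags[i, CHANNELS.index(ch)] = True
    return PocketStructure(
        coords=coords,
        vdw_radii=np.array([vdw_radius(e) for e in elements]),
        channel_flags=flags,
        center=center,
        elements=elements,
    )


def generate_ligand_features(rng: np.random.Generator, bits: int = 1024,
                             density: float = 0.05, n_descriptors: int = 183,
                             desc_scales: np.ndarray | None = None):
    """One ligand: Bernoulli fingerprint bits plus a normal descriptor
    vector with per-dimension scales (exercising downstream
    standardization)."""
    fp = (rng.uniform(size=bits) < density).astype(np.uint8)
    if desc_scales is None:
        desc_scales = np.ones(n_descriptors)
    desc = rng.normal(size=n_descriptors) * desc_scales
    return fp, desc


def _softplus(x):
    return np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_labels(features_z: np.ndarray, weights: np.ndarray, biases: np.ndarray,
                    noise_sd: float, n_poses: int, resolutions: np.ndarray,
                    rng: np.random.Generator, count_slope: float = 1.5,
                    family_effects: np.ndarray | None = None,
                    ids=None, protocols=None) -> LabelMatrix:
    """Planted label triples from low-dimensional features.

    ``weights`` is (P, d), ``biases`` (P,); ``family_effects`` an optional
    per-complex additive offset. With ``noise_sd = 0`` the RMSD labels are
    a deterministic function of the features.
    """
    n, _ = features_z.shape
    p = len(weights)
    mean = features_z @ weights.T + biases  # (n, P)
    if family_effects is not None:
        mean = mean + family_effects[:, None]
    ave = _softplus(mean)
    if noise_sd > 0:
        ave = ave + rng.normal(scale=noise_sd, size=ave.shape)
    ave = np.maximum(ave, 0.05)
    c = rng.uniform(0.3, 1.0, size=n)  # per-complex min/ave ratio
    amin = c[:, None] * ave
    p_hit = _sigmoid(-count_slope * (ave - resolutions[:, None]))
    counts = rng.binomial(n_poses, p_hit)
    values = np.stack([amin, ave, counts.astype(float)], axis=2)
    ids = ids if ids is not None else [f"cplx-{i:04d}" for i in range(n)]
    protocols = protocols if protocols is not None else default_protocols()[:p]
    return LabelMatrix(ids, values, protocols)


def make_benchmark(config: SyntheticConfig | None = None) -> SyntheticBenchmark:
    """Assemble a complete benchmark usable by every downstream module."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_complexes
    ids = [f"cplx-{i:04d}" for i in range(n)]

    # family sizes from a Zipf profile over n_families
    w = 1.0 / np.arange(1, cfg.n_families + 1) ** cfg.family_zipf
    sizes = rng.multinomial(n, w / w.sum())
    fam_names = [f"PF{i:05d}" for i in range(cfg.n_families)]
    fam_of = np.repeat(np.arange(cfg.n_families), sizes)
    rng.shuffle(fam_of)
    families = {cid: fam_names[f] for cid, f in zip(ids, fam_of)}

    pockets = [generate_pocket(rng, cfg.pocket_atoms, cfg.pocket_radius) for _ in range(n)]
    desc_scales = np.exp(rng.normal(scale=1.0, size=cfg.n_descriptors))
    fps = np.empty((n, cfg.fingerprint_bits), dtype=np.uint8)
    descs = np.empty((n, cfg.n_descriptors))
    for i in range(n):
        fps[i], descs[i] = generate_ligand_features(
            rng, cfg.fingerprint_bits, cfg.fingerprint_density,
            cfg.n_descriptors, desc_scales,
        )
    resolutions = rng.uniform(*cfg.resolution_range, size=n)

    # planted projections: pocket channel fractions + fp/descriptor factors
    probs = _channel_probs()
    frac = np.stack([p.channel_flags[:, :7].mean(axis=0) for p in pockets])
    z_pocket = (frac - probs) / np.sqrt(probs * (1 - probs) / cfg.pocket_atoms)
    z_pocket = cfg.pocket_signal_scale * z_pocket
    # sparse fingerprint factors: each reads a small random support of bits,
    # mimicking substructure keys rather than a dense hash-wide projection
    proj_fp = np.zeros((cfg.fingerprint_bits, cfg.n_fp_factors))
    bpf = min(cfg.fp_bits_per_factor, cfg.fingerprint_bits)
    for f in range(cfg.n_fp_factors):
        sel = rng.choice(cfg.fingerprint_bits, size=bpf, replace=False)
        proj_fp[sel, f] = rng.choice([-1.0, 1.0], size=bpf) / np.sqrt(
            bpf * cfg.fingerprint_density
        )
    proj_desc = rng.normal(size=(cfg.n_descriptors, cfg.n_desc_factors)) / np.sqrt(cfg.n_descriptors)
    z = np.concatenate([z_pocket, fps @ proj_fp, (descs / desc_scales) @ proj_desc], axis=1)

    d = z.shape[1]
    w0 = rng.normal(scale=cfg.base_weight_scale / np.sqrt(d), size=d)
    weights = w0 + rng.normal(scale=cfg.protocol_weight_scale / np.sqrt(d),
                              size=(cfg.n_protocols, d))
    biases = rng.normal(cfg.protocol_bias_mean, cfg.protocol_bias_sd, size=cfg.n_protocols)
    fam_effect_values = rng.normal(scale=cfg.family_effect_sd, size=cfg.n_families)
    fam_effects = fam_effect_values[fam_of]

    labels = generate_labels(
        z, weights, biases, cfg.noise_sd, cfg.n_poses, resolutions, rng,
        count_slope=cfg.count_slope, family_effects=fam_effects, ids=ids,
        protocols=default_protocols()[: cfg.n_protocols],
    )
    return SyntheticBenchmark(
        config=cfg, ids=ids, pockets=pockets, fingerprints=fps, descriptors=descs,
        labels=labels, families=families, resolutions=resolutions, features_z=z,
        planted={
            "w0": w0, "weights": weights, "biases": biases,
            "family_effects": fam_effect_values, "proj_fp": proj_fp,
            "proj_desc": proj_desc, "desc_scales": desc_scales,
        },
    )


# ---------------------------------------------------------------------------
# fixture serialization


def _pocket_to_pdb(pocket: PocketStructure) -> str:
    lines = []
    for i in range(len(pocket)):
        x, y, z = pocket.coords[i]
        elem = (pocket.elements[i] if pocket.elements else "C").upper()
        name = f"{elem}{i % 1000}"[:4]  # unique within the residue
        lines.append(
            f"HETATM{i + 1:5d} {name:<4s}UNK A   1    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {elem:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def save_benchmark(bench: SyntheticBenchmark, outdir) -> None:
    """Serialize the benchmark: pockets as minimal PDB files with a JSON
    sidecar (exact flags/radii/center), labels as tidy CSV, families and
    config as JSON, ligand features as .npy arrays."""
    from .io import save_label_table

    outdir = Path(outdir)
    (outdir / "pockets").mkdir(parents=True, exist_ok=True)
    for cid, pocket in zip(bench.ids, bench.pockets):
        (outdir / "pockets" / f"{cid}.pdb").write_text(_pocket_to_pdb(pocket))
        sidecar = {
            "center": pocket.center.tolist(),
            "vdw_radii": pocket.vdw_radii.tolist(),
            "channel_flags": pocket.channel_flags.astype(int).tolist(),
            "elements": pocket.elements,
        }
        (outdir / "pockets" / f"{cid}.json").write_text(json.dumps(sidecar))
    save_label_table(bench.labels, outdir / "labels.csv")
    (outdir / "families.json").write_text(json.dumps(bench.families, indent=1))
    (outdir / "resolutions.json").write_text(
        json.dumps(dict(zip(bench.ids, bench.resolutions.tolist())))
    )
    cfg = asdict(bench.config)
    cfg["resolution_range"] = list(cfg["resolution_range"])
    (outdir / "config.json").write_text(json.dumps(cfg, indent=1))
    np.save(outdir / "fingerprints.npy", bench.fingerprints)
    np.save(outdir / "descriptors.npy", bench.descriptors)
    np.save(outdir / "features_z.npy", bench.features_z)
    np.savez(outdir / "planted.npz", **bench.planted)


def load_benchmark(outdir) -> SyntheticBenchmark:
    """Re-read a serialized benchmark (coordinates at PDB precision)."""
    import gemmi

    from .io import load_label_table

    outdir = Path(outdir)
    cfg_raw = json.loads((outdir / "config.json").read_text())
    cfg_raw["resolution_range"] = tuple(cfg_raw["resolution_range"])
    cfg = SyntheticConfig(**cfg_raw)
    labels = load_label_table(outdir / "labels.csv",
                              protocols=default_protocols()[: cfg.n_protocols])
    families = json.loads((outdir / "families.json").read_text())
    res_map = json.loads((outdir / "resolutions.json").read_text())
    ids = labels.complex_ids
    pockets = []
    for cid in ids:
        st = gemmi.read_structure(str(outdir / "pockets" / f"{cid}.pdb"))
        atoms = [
            (a.serial, [a.pos.x, a.pos.y, a.pos.z])
            for model in st for chain in model for res in chain for a in res
        ]
        coords = [xyz for _, xyz in sorted(atoms)]  # file order, not gemmi grouping
        side = json.loads((outdir / "pockets" / f"{cid}.json").read_text())
        pockets.append(PocketStructure(
            coords=np.asarray(coords).reshape(-1, 3),
            vdw_radii=np.asarray(side["vdw_radii"]),
            channel_flags=np.asarray(side["channel_flags"], dtype=bool),
            center=np.asarray(side["center"]),
            elements=side["elements"],
        ))
    planted = dict(np.load(outdir / "planted.npz"))
    return SyntheticBenchmark(
        config=cfg, ids=ids, pockets=pockets,
        fingerprints=np.load(outdir / "fingerprints.npy"),
        descriptors=np.load(outdir / "descriptors.npy"),
        labels=labels, families=families,
        resolutions=np.array([res_map[c] for c in ids]),
        features_z=np.load(outdir / "features_z.npy"),
        planted=planted,
    )
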