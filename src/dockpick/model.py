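"""The two-legged multi-task docking-quality network and its losses.

Protein voxel grids pass through five 3D-convolutional layers with ReLU
activations, are flattened and projected to a protein latent vector; the
ligand fingerprint + descriptor vector passes through three linear layers
with ReLU. Both latents are concatenated (default size 1024), batch
normalized, and read out by three per-protocol linear heads with ReLU —
one head each for RMSDmin, RMSDave (mean-squared-error loss) and nRMSD
(Poisson negative log-likelihood, the natural loss for a pose count).
The training objective is the unweighted sum of the three.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from . import _nn
from .io import TARGETS

__all__ = [
    "ModelConfig",
    "Prediction",
    "DockingQualityNet",
    "build_model",
    "poisson_nll",
    "mse_loss",
    "combined_loss",
    "combined_loss_and_grad",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    The convolutional channel widths/strides are deliberately small CPU
    defaults; the printed-configuration constants (8 input channels, 24³
    grid, 1207-long ligand vector, 1024 concatenated latent, 14 protocols,
    3 heads) are the contract.
    """

    n_protocols: int = 14
    grid_channels: int = 8
    grid_edge_voxels: int = 24
    conv_channels: tuple = (8, 16, 24, 32, 48)
    conv_kernel: int = 3
    conv_strides: tuple = (2, 2, 1, 2, 1)
    conv_padding: int = 1
    protein_latent: int = 512
    ligand_dim: int = 1207
    ligand_widths: tuple = (768, 640, 512)

    def __post_init__(self):
        if self.n_protocols < 1:
            raise ValueError("n_protocols must be >= 1")
        if len(self.conv_channels) != len(self.conv_strides):
            raise ValueError("conv_channels and conv_strides must have equal length")
        if len(self.ligand_widths) != 3:
            raise ValueError("the ligand leg has three linear layers")

    @property
    def ligand_latent(self) -> int:
        return self.ligand_widths[-1]

    @property
    def latent_dim(self) -> int:
        return self.protein_latent + self.ligand_latent

    def conv_output_voxels(self) -> int:
        """Spatial edge length after the convolutional stack."""
        e = self.grid_edge_voxels
        for s in self.conv_strides:
            e = (e + 2 * self.conv_padding - self.conv_kernel) // s + 1
            if e <= 0:
                raise ValueError("convolutional stack reduces the grid to nothing")
        return e


@dataclass
class Prediction:
    """Per-protocol predictions; all entries are non-negative (ReLU heads)."""

    rmsd_min: np.ndarray  # (batch, P) Å
    rmsd_ave: np.ndarray  # (batch, P) Å
    n_rmsd: np.ndarray  # (batch, P) Poisson rates

    def stack(self) -> np.ndarray:
        """(batch, 3, P) array in canonical target order."""
        return np.stack([self.rmsd_min, self.rmsd_ave, self.n_rmsd], axis=1)

    @classmethod
    def from_stack(cls, arr: np.ndarray) -> "Prediction":
        return cls(rmsd_min=arr[:, 0], rmsd_ave=arr[:, 1], n_rmsd=arr[:, 2])


class DockingQualityNet:
    """The assembled two-leg network with explicit forward/backward."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.config = config
        c = config

        conv_layers: list[_nn.Layer] = []
        c_in = c.grid_channels
        for li, (c_out, stride) in enumerate(zip(c.conv_channels, c.conv_strides)):
            conv_layers.append(
                _nn.Conv3d(c_in, c_out, kernel=c.conv_kernel, stride=stride,
                           padding=c.conv_padding, rng=rng,
                           needs_input_grad=li > 0)
            )
            conv_layers.append(_nn.ReLU())
            c_in = c_out
        flat = c.conv_channels[-1] * c.conv_output_voxels() ** 3
        conv_layers += [
            _nn.Flatten(),
            _nn.Linear(flat, c.protein_latent, rng),
            _nn.ReLU(),
        ]
        self.protein_leg = _nn.Sequential(*conv_layers)

        lig_layers: list[_nn.Layer] = []
        d_in = c.ligand_dim
        for width in c.ligand_widths:
            lig_layers += [_nn.Linear(d_in, width, rng), _nn.ReLU()]
            d_in = width
        self.ligand_leg = _nn.Sequential(*lig_layers)

        self.batchnorm = _nn.BatchNorm1d(c.latent_dim)
        self.heads = {}
        for t in TARGETS:
            head = _nn.Linear(c.latent_dim, c.n_protocols, rng)
            # positive bias start: targets are positive quantities, and a
            # zero-rate start would make the Poisson NLL gradient ~ -y/eps
            head.b.value[:] = 1.0
            self.heads[t] = _nn.Sequential(head, _nn.ReLU())

    def params(self) -> list[_nn.Param]:
        out = self.protein_leg.params() + self.ligand_leg.params() + self.batchnorm.params()
        for t in TARGETS:
            out += self.heads[t].params()
        return out

    def forward(self, grids: np.ndarray, ligand: np.ndarray, train: bool = False) -> np.ndarray:
        """Forward pass; returns a (batch, 3, P) non-negative array."""
        grids = np.asarray(grids, dtype=np.float32)
        ligand = np.asarray(ligand, dtype=np.float32)
        zp = self.protein_leg.forward(grids, train=train)
        zl = self.ligand_leg.forward(ligand, train=train)
        self._latent = np.concatenate([zp, zl], axis=1)
        h = self.batchnorm.forward(self._latent, train=train)
        outs = [self.heads[t].forward(h, train=train) for t in TARGETS]
        return np.stack(outs, axis=1)

    def backward(self, grad: np.ndarray) -> None:
        """Accumulate parameter gradients from a (batch, 3, P) output grad."""
        gh = np.zeros_like(self._latent)
        for i, t in enumerate(TARGETS):
            gh += self.heads[t].backward(np.ascontiguousarray(grad[:, i]))
        gz = self.batchnorm.backward(gh)
        np_lat = self.config.protein_latent
        self.protein_leg.backward(np.ascontiguousarray(gz[:, :np_lat]))
        self.ligand_leg.backward(np.ascontiguousarray(gz[:, np_lat:]))

    @property
    def latent_dim(self) -> int:
        return self.config.latent_dim


def build_model(config: ModelConfig | None = None, rng: np.random.Generator | None = None) -> DockingQualityNet:
    """Build the network, validating the configuration at build time."""
    return DockingQualityNet(config or ModelConfig(), rng=rng)


# ---------------------------------------------------------------------------
# losses


def poisson_nll(y, y_hat, eps: float = 1e-8):
    """Poisson negative log-likelihood  ŷ − y·log(ŷ) + log(y!).

    The rate inside the logarithm is floored at ``eps`` so a ReLU head
    emitting an exact zero stays finite; log(y!) is evaluated through the
    log-gamma function.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if (y < 0).any():
        raise ValueError("counts must be non-negative")
    if (y_hat < 0).any():
        raise ValueError("predicted rates must be non-negative")
    out = y_hat - y * np.log(np.maximum(y_hat, eps)) + gammaln(y + 1.0)
    return out if out.ndim else float(out)


def mse_loss(y, y_hat):
    """Mean squared error."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {y_hat.shape}")
    return float(np.mean((y - y_hat) ** 2))


def combined_loss(labels, prediction, mask=None, eps: float = 1e-8) -> float:
    """Unweighted sum of the three objectives over non-masked entries.

    ``labels`` is (batch, P, 3) in canonical target order (NaN = missing);
    ``prediction`` is a (batch, 3, P) array or :class:`Prediction`.
    MSE terms for RMSDmin/RMSDave and the mean Poisson NLL for nRMSD are
    each averaged over the valid (complex, protocol) entries.
    """
    loss, _ = combined_loss_and_grad(labels, prediction, mask=mask, eps=eps)
    return loss


def combined_loss_and_grad(labels, prediction, mask=None, eps: float = 1e-8):
    """Combined loss plus its gradient w.r.t. the (batch, 3, P) prediction."""
    if isinstance(prediction, Prediction):
        prediction = prediction.stack()
    pred = np.asarray(prediction, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if labels.shape != (pred.shape[0], pred.shape[2], 3):
        raise ValueError(f"labels shape {labels.shape} does not match prediction {pred.shape}")
    y = labels.transpose(0, 2, 1)  # (batch, 3, P)
    valid = np.isfinite(y)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)[:, None, :]
    if not valid.any():
        raise ValueError("all label entries are masked")

    grad = np.zeros_like(pred)
    total = 0.0
    for i, kind in enumerate(("mse", "mse", "poisson")):
        v = valid[:, i]
        n = v.sum()
        if n == 0:
            continue
        yi = np.where(v, y[:, i], 0.0)
        pi = pred[:, i]
        if kind == "mse":
            diff = np.where(v, pi - yi, 0.0)
            total += float((diff**2).sum() / n)
            grad[:, i] = 2.0 * diff / n
        else:
            pfloor = np.maximum(pi, eps)
            nll = np.where(v, pi - yi * np.log(pfloor) + gammaln(yi + 1.0), 0.0)
            total += float(nll.sum() / n)
            grad[:, i] = np.where(v, 1.0 - yi / pfloor, 0.0) / n
    return total, grad
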