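"""Scikit-learn-style estimator wrapping the multi-task docking-quality net.

:class:`ProtocolQualityRegressor` follows the sklearn estimator contract
(constructor stores hyperparameters untouched, ``fit``/``predict``,
``get_params``/``set_params``, fitted attributes with a trailing
underscore), so it composes with sklearn model selection. ``X`` is a
:class:`~dockpick.featurize.FeatureSet` (voxel grids or pockets plus
ligand vectors); ``y`` is the (n, P, 3) label array with NaN marking
missing (complex, protocol) entries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .featurize import FeatureSet, voxelize, random_rotation_matrix
from .io import PocketStructure
from .model import ModelConfig, DockingQualityNet, Prediction, combined_loss_and_grad
from ._nn import Adam

__all__ = ["ProtocolQualityRegressor"]


class ProtocolQualityRegressor(BaseEstimator, RegressorMixin):
    """Multi-task regressor of per-protocol (RMSDmin, RMSDave, nRMSD).

    Training minimizes MSE(RMSDmin) + MSE(RMSDave) + PoissonNLL(nRMSD)
    with Adam (β1 = 0.99 as the reference configuration prints, β2 =
    0.999), a starting learning rate of 1e-3 decayed exponentially by
    γ = 0.95 per epoch, and batches of 32. With ``augment=True`` and a
    FeatureSet carrying pockets, every training pocket is re-voxelized
    after a fresh uniform rotation about the ligand center each epoch;
    validation/prediction always uses unrotated grids.

    Parameters mirror :class:`~dockpick.model.ModelConfig` plus the
    training schedule; ``random_state`` fans out to independent streams
    for initialization, shuffling and rotations.
    """

    def __init__(
        self,
        n_protocols: int = 14,
        conv_channels: tuple = (8, 16, 24, 32, 48),
        conv_strides: tuple = (2, 2, 1, 2, 1),
        conv_kernel: int = 3,
        conv_padding: int = 1,
        protein_latent: int = 512,
        ligand_widths: tuple = (768, 640, 512),
        epochs: int = 200,
        batch_size: int = 32,
        lr: float = 1e-3,
        lr_decay: float = 0.95,
        beta1: float = 0.99,
        beta2: float = 0.999,
        augment: bool = True,
        nll_eps: float = 1e-8,
        random_state: int | None = None,
        verbose: int = 0,
    ):
        self.n_protocols = n_protocols
        self.conv_channels = conv_channels
        self.conv_strides = conv_strides
        self.conv_kernel = conv_kernel
        self.conv_padding = conv_padding
        self.protein_latent = protein_latent
        self.ligand_widths = ligand_widths
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.lr_decay = lr_decay
        self.beta1 = beta1
        self.beta2 = beta2
        self.augment = augment
        self.nll_eps = nll_eps
        self.random_state = random_state
        self.verbose = verbose

    # -- helpers ----------------------------------------------------------

    def learning_rate(self, epoch: int) -> float:
        """lr at epoch e = lr0 · γ^e."""
        return self.lr * self.lr_decay**epoch

    @staticmethod
    def _as_feature_set(X) -> FeatureSet:
        if isinstance(X, FeatureSet):
            return X
        if isinstance(X, tuple) and len(X) == 2:
            grids, ligand = X
            return FeatureSet(ligand=ligand, grids=np.asarray(grids, dtype=np.float32))
        raise TypeError("X must be a FeatureSet or a (grids, ligand) tuple")

    def _augmented_grids(self, pockets: list[PocketStructure], edge, res, rng) -> np.ndarray:
        out = np.empty((len(pockets), 8, int(round(edge / res))) + (int(round(edge / res)),) * 2,
                       dtype=np.float32)
        for i, pocket in enumerate(pockets):
            R = random_rotation_matrix(rng)
            rotated = PocketStructure(
                coords=(pocket.coords - pocket.center) @ R.T + pocket.center,
                vdw_radii=pocket.vdw_radii,
                channel_flags=pocket.channel_flags,
                center=pocket.center,
            )
            out[i] = voxelize(rotated, edge=edge, resolution=res, dtype=np.float32).values
        return out

    # -- sklearn API ------------------------------------------------------

    def fit(self, X, y, validation=None):
        """Train on (X, y); optionally record validation loss per epoch.

        ``validation`` is an (X_val, y_val) pair evaluated (unrotated,
        batch-norm in inference mode) after every epoch.
        """
        X = self._as_feature_set(X)
        y = np.asarray(y, dtype=float)
        n = len(X)
        if n == 0:
            raise ValueError("empty training set")
        if y.shape[0] != n or y.ndim != 3 or y.shape[2] != 3:
            raise ValueError(f"y must be (n, P, 3); got {y.shape}")
        if y.shape[1] != self.n_protocols:
            raise ValueError(f"y has {y.shape[1]} protocols, expected {self.n_protocols}")

        init_ss, shuffle_ss, rot_ss = np.random.SeedSequence(self.random_state).spawn(3)
        rng_init = np.random.default_rng(init_ss)
        rng_shuffle = np.random.default_rng(shuffle_ss)
        rng_rot = np.random.default_rng(rot_ss)

        base_grids = X.ensure_grids()
        edge_voxels = base_grids.shape[-1]
        self.config_ = ModelConfig(
            n_protocols=self.n_protocols,
            grid_channels=base_grids.shape[1],
            grid_edge_voxels=edge_voxels,
            conv_channels=tuple(self.conv_channels),
            conv_kernel=self.conv_kernel,
            conv_strides=tuple(self.conv_strides),
            conv_padding=self.conv_padding,
            protein_latent=self.protein_latent,
            ligand_dim=X.ligand.shape[1],
            ligand_widths=tuple(self.ligand_widths),
        )
        self.net_ = DockingQualityNet(self.config_, rng=rng_init)
        opt = Adam(self.net_.params(), lr=self.lr, beta1=self.beta1, beta2=self.beta2)

        augmenting = self.augment and X.pockets is not None
        history = []
        for epoch in range(self.epochs):
            opt.lr = self.learning_rate(epoch)
            grids = (
                self._augmented_grids(X.pockets, X.grid_edge, X.grid_resolution, rng_rot)
                if augmenting
                else base_grids
            )
            order = rng_shuffle.permutation(n)
            losses, weights = [], []
            for lo in range(0, n, self.batch_size):
                idx = order[lo : lo + self.batch_size]
                pred = self.net_.forward(grids[idx], X.ligand[idx], train=True)
                loss, grad = combined_loss_and_grad(y[idx], pred, eps=self.nll_eps)
                opt.zero_grad()
                self.net_.backward(grad.astype(np.float32))
                opt.step()
                losses.append(loss)
                weights.append(len(idx))
            row = {
                "epoch": epoch,
                "lr": opt.lr,
                "train_loss": float(np.average(losses, weights=weights)),
            }
            if validation is not None:
                X_val, y_val = validation
                pred = self.predict(X_val)
                from .model import combined_loss

                row["val_loss"] = combined_loss(np.asarray(y_val, dtype=float), pred,
                                                eps=self.nll_eps)
            history.append(row)
            if self.verbose:
                print(f"epoch {epoch:4d}  " + "  ".join(
                    f"{k}={v:.5g}" for k, v in row.items() if k != "epoch"))
        self.history_ = pd.DataFrame(history)
        self.n_features_in_ = X.ligand.shape[1]
        return self

    def predict(self, X, batch_size: int = 64) -> np.ndarray:
        """Predict (n, 3, P) target values; deterministic (batch norm uses
        running statistics, no stochastic layers at inference)."""
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted")
        X = self._as_feature_set(X)
        grids = X.ensure_grids()
        out = [
            self.net_.forward(grids[lo : lo + batch_size], X.ligand[lo : lo + batch_size],
                              train=False)
            for lo in range(0, len(X), batch_size)
        ]
        return np.concatenate(out, axis=0)

    def predict_triples(self, X) -> Prediction:
        return Prediction.from_stack(self.predict(X))

    def score(self, X, y) -> float:
        """Pooled Pearson R on RMSDave over present labels (the headline
        ligand-centric metric), not the sklearn default R²."""
        from .evaluation import pearson_r

        pred = self.predict(X)
        y = np.asarray(y, dtype=float)
        yt, ph = y[:, :, 1], pred[:, 1, :]
        ok = np.isfinite(yt)
        return pearson_r(yt[ok], ph[ok])
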