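"""Two-stage dimensionality reduction of call spectrograms.

Stage one trains an auto-encoder with a 32-unit bottleneck on the
prepared spectrogram matrices and keeps the encoder half as the 32-D
call representation.  Stage two projects the 32-D embeddings to 2-D with
UMAP, where distances between points track similarity of the calls'
spectro-temporal patterns and density clustering becomes meaningful.

The auto-encoder here is a fully connected network (flattened input ->
256 -> 32 -> 256 -> output, ReLU hidden activations) built on
scikit-learn's multilayer perceptron and trained with Adam on the
mean-squared reconstruction error.  The bottleneck width of 32 is the
method's fixed design point; the surrounding architecture and training
schedule are configuration, exposed in :class:`AutoencoderConfig` and
recorded in run logs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neural_network import MLPRegressor

BOTTLENECK_DIM = 32


@dataclass
class AutoencoderConfig:
    epochs: int = 50
    lr: float = 1e-3
    batch: int = 32
    seed: int = 0
    hidden: int = 256


class Autoencoder:
    """Dense auto-encoder with a fixed 32-D bottleneck.

    ``fit`` trains on an ``(n_samples, n_bins, n_frames)`` or already
    flattened ``(n_samples, n_features)`` array; ``encode`` returns the
    32-D bottleneck activations.  Training is deterministic for a fixed
    config and single-threaded BLAS.
    """

    def __init__(self, config: AutoencoderConfig | None = None):
        self.config = config or AutoencoderConfig()
        self._mlp = None
        self._n_features = None
        self.loss_history: list = []

    @staticmethod
    def _flatten(inputs) -> np.ndarray:
        X = np.asarray(inputs, dtype=float)
        if X.ndim == 3:
            X = X.reshape(X.shape[0], -1)
        if X.ndim != 2:
            raise ValueError("inputs must be (n, bins, frames) or (n, features)")
        return X

    def fit(self, inputs) -> "Autoencoder":
        X = self._flatten(inputs)
        if X.shape[0] < 8:
            raise ValueError(f"need at least 8 training inputs, got {X.shape[0]}")
        cfg = self.config
        self._mlp = MLPRegressor(
            hidden_layer_sizes=(cfg.hidden, BOTTLENECK_DIM, cfg.hidden),
            activation="relu", solver="adam", learning_rate_init=cfg.lr, alpha=0.0,
            batch_size=min(cfg.batch, X.shape[0]), max_iter=cfg.epochs,
            shuffle=True, random_state=cfg.seed, tol=0.0,
            n_iter_no_change=cfg.epochs + 1, verbose=False,
        )
        import warnings as _w
        with _w.catch_warnings():
            _w.filterwarnings("ignore", message=".*Maximum iterations.*")
            self._mlp.fit(X, X)
        self._n_features = X.shape[1]
        self.loss_history = [float(v) for v in self._mlp.loss_curve_]
        if not np.isfinite(self.loss_history[-1]):
            raise RuntimeError(
                f"non-finite reconstruction loss (lr={cfg.lr}, epoch={len(self.loss_history)})")
        return self

    def encode(self, inputs) -> np.ndarray:
        """Project inputs to the 32-D bottleneck (always exactly 32-D)."""
        if self._mlp is None:
            raise RuntimeError("autoencoder is not trained")
        X = self._flatten(inputs)
        if X.shape[1] != self._n_features:
            raise ValueError(f"expected {self._n_features} features, got {X.shape[1]}")
        h = X
        for layer in range(2):  # input->hidden, hidden->bottleneck
            h = np.maximum(h @ self._mlp.coefs_[layer] + self._mlp.intercepts_[layer], 0.0)
        if not np.all(np.isfinite(h)):
            raise RuntimeError("non-finite embedding")
        return h

    def reconstruct(self, inputs) -> np.ndarray:
        if self._mlp is None:
            raise RuntimeError("autoencoder is not trained")
        return self._mlp.predict(self._flatten(inputs))

    def save(self, path) -> None:
        np.savez(path, n_features=self._n_features,
                 loss_history=np.asarray(self.loss_history),
                 **{f"W{i}": w for i, w in enumerate(self._mlp.coefs_)},
                 **{f"b{i}": b for i, b in enumerate(self._mlp.intercepts_)})


def train_autoencoder(inputs, config: AutoencoderConfig | None = None) -> Autoencoder:
    """Train an auto-encoder on prepared spectrogram inputs.

    The recorded ``loss_history`` allows checking that the final
    reconstruction loss undercuts the initial one.
    """
    return Autoencoder(config).fit(inputs)


def encode(inputs, model: Autoencoder) -> np.ndarray:
    """One 32-D embedding per call, in input order."""
    return model.encode(inputs)


@dataclass
class ProjectionConfig:
    n_neighbors: int = 15
    min_dist: float = 0.1
    seed: int = 0


def project_2d(embeddings, config: ProjectionConfig | None = None) -> np.ndarray:
    """UMAP projection of the 32-D embeddings to 2-D.

    Deterministic given ``config.seed`` (UMAP runs single-threaded when a
    random state is fixed).  Requires at least ``n_neighbors + 1`` points.
    """
    cfg = config or ProjectionConfig()
    X = np.asarray(embeddings, dtype=float)
    if X.ndim != 2:
        raise ValueError("embeddings must be a 2-D array")
    if X.shape[0] < cfg.n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors + 1 = {cfg.n_neighbors + 1} points, got {X.shape[0]}")
    import warnings as _w
    with _w.catch_warnings():
        _w.filterwarnings("ignore")  # umap warns about forced single-threading with a seed
        from umap import UMAP
        proj = UMAP(n_components=2, n_neighbors=cfg.n_neighbors, min_dist=cfg.min_dist,
                    random_state=cfg.seed).fit_transform(X)
    return np.asarray(proj, dtype=float)
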