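"""Self-supervised posture autoencoder.

A short posture window ``X_t`` (L time samples x S spine points x 2
coordinates) is compressed by a small dense encoder to a latent code ``Z`` of
dimension ``D``; a mirrored decoder reconstructs an *extended* sequence that
also contains past and future window-lengths of postures. Predicting the
flanks forces ``Z`` to summarize the local dynamics, not just the current
shape, which is what makes the frozen latents useful to a downstream action
classifier.

Pre-training minimizes mean squared reconstruction error of the extended
sequence (centre and flanks equally weighted) with Adam, early-stopping on a
held-out split. Training is bit-reproducible given a seed. Weights use Xavier
(Glorot) initialization, which also serves as the no-pre-training baseline in
transfer experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._nn import Adam, Dense, Sequential, Tanh
from .preprocess import PostureWindow, WindowingConfig, extract_windows_indexed
from .trackdata_io import Track

__all__ = [
    "LatentCode",
    "TrainConfig",
    "EncoderModel",
    "new_encoder",
    "encode",
    "encode_batch",
    "decode",
    "pretrain",
    "export_latents",
    "import_latents",
    "constant_baseline_mse",
]


@dataclass(frozen=True)
class LatentCode:
    """Low-dimensional latent representation Z of one posture window."""

    z: np.ndarray

    def __post_init__(self):
        if not np.all(np.isfinite(self.z)):
            raise ValueError("latent code has non-finite entries")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings shared by pre-training and fine-tuning.

    ``encoder_lr_fraction`` and ``min_steps`` only affect classifier
    fine-tuning: the encoder is updated at a fraction of the head's learning
    rate (discriminative fine-tuning, which protects pre-trained features
    from the initially-random head's gradients), and small labelled sets are
    still granted at least ``min_steps`` optimizer steps so the training
    budget does not collapse with the dataset size.
    """

    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    encoder_lr_fraction: float = 0.15
    min_steps: int = 1500
    val_fraction: float = 0.1
    seed: int = 0


@dataclass
class EncoderModel:
    """Encoder/decoder pair plus the architecture manifest.

    ``config`` keys: L, S, D, context_windows, hidden. The first encoder layer
    takes L*S*2 inputs; the decoder emits (1 + 2*context_windows)*L*S*2.
    """

    config: dict
    encoder: Sequential
    decoder: Sequential
    pretrained: bool = False
    fine_tuned: bool = False
    seed: int = 0
    history: list[dict] = field(default_factory=list)

    @property
    def input_dim(self) -> int:
        c = self.config
        return c["L"] * c["S"] * 2

    @property
    def output_dim(self) -> int:
        c = self.config
        return (1 + 2 * c["context_windows"]) * c["L"] * c["S"] * 2

    @property
    def latent_dim(self) -> int:
        return self.config["D"]

    def copy(self) -> "EncoderModel":
        clone = new_encoder(
            window_cfg=WindowingConfig(
                samples_per_window=self.config["L"],
                spine_points=self.config["S"],
                context_windows=self.config["context_windows"],
            ),
            latent_dim=self.config["D"],
            hidden=self.config["hidden"],
            seed=self.seed,
        )
        clone.encoder.set_weights(self.encoder.get_weights())
        clone.decoder.set_weights(self.decoder.get_weights())
        clone.pretrained = self.pretrained
        clone.fine_tuned = self.fine_tuned
        clone.history = list(self.history)
        return clone

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "config": self.config,
            "pretrained": self.pretrained,
            "fine_tuned": self.fine_tuned,
            "seed": self.seed,
        }
        (directory / "model.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
        arrays = {}
        for tag, net in (("enc", self.encoder), ("dec", self.decoder)):
            for i, p in enumerate(net.params):
                arrays[f"{tag}_{i}"] = p
        np.savez(directory / "weights.npz", **arrays)
        if self.history:
            pd.DataFrame(self.history).to_csv(directory / "training_log.csv", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "EncoderModel":
        directory = Path(directory)
        manifest = json.loads((directory / "model.json").read_text())
        cfg = manifest["config"]
        model = new_encoder(
            window_cfg=WindowingConfig(
                samples_per_window=cfg["L"], spine_points=cfg["S"],
                context_windows=cfg["context_windows"],
            ),
            latent_dim=cfg["D"], hidden=cfg["hidden"], seed=manifest["seed"],
        )
        with np.load(directory / "weights.npz") as blob:
            for tag, net in (("enc", model.encoder), ("dec", model.decoder)):
                net.set_weights([blob[f"{tag}_{i}"] for i in range(len(net.params))])
        model.pretrained = manifest["pretrained"]
        model.fine_tuned = manifest["fine_tuned"]
        log = directory / "training_log.csv"
        if log.exists():
            model.history = pd.read_csv(log).to_dict("records")
        return model


def new_encoder(
    window_cfg: WindowingConfig | None = None,
    latent_dim: int = 10,
    hidden: int = 64,
    seed: int = 0,
) -> EncoderModel:
    """Build a Xavier-initialised encoder/decoder pair (not pre-trained)."""
    if window_cfg is None:
        window_cfg = WindowingConfig()
    L, S, C = window_cfg.samples_per_window, window_cfg.spine_points, window_cfg.context_windows
    in_dim = L * S * 2
    out_dim = (1 + 2 * C) * L * S * 2
    rng = np.random.default_rng(seed)
    encoder = Sequential([Dense(in_dim, hidden, rng), Tanh(), Dense(hidden, latent_dim, rng)])
    decoder = Sequential([Dense(latent_dim, hidden, rng), Tanh(), Dense(hidden, out_dim, rng)])
    return EncoderModel(
        config={"L": L, "S": S, "D": latent_dim, "context_windows": C, "hidden": hidden},
        encoder=encoder, decoder=decoder, seed=seed,
    )


def _flatten_windows(windows: list[PostureWindow], model: EncoderModel,
                     with_targets: bool) -> tuple[np.ndarray, np.ndarray | None]:
    X = np.stack([w.x.reshape(-1) for w in windows])
    if X.shape[1] != model.input_dim:
        raise ValueError(f"window shape mismatch: expected {model.input_dim} "
                         f"features, got {X.shape[1]}")
    Y = None
    if with_targets:
        if any(w.context is None for w in windows):
            raise ValueError("windows lack past/future context targets")
        Y = np.stack([w.context.reshape(-1) for w in windows])
        if Y.shape[1] != model.output_dim:
            raise ValueError(f"context shape mismatch: expected {model.output_dim} "
                             f"features, got {Y.shape[1]}")
    return X, Y


def encode(model: EncoderModel, window: PostureWindow) -> LatentCode:
    """Compress one posture window into its latent code (deterministic)."""
    X, _ = _flatten_windows([window], model, with_targets=False)
    return LatentCode(z=model.encoder.forward(X)[0].copy())


def encode_batch(model: EncoderModel, windows: list[PostureWindow]) -> np.ndarray:
    X, _ = _flatten_windows(windows, model, with_targets=False)
    return model.encoder.forward(X)


def decode(model: EncoderModel, code: LatentCode) -> np.ndarray:
    """Reconstruct the extended posture sequence from a latent code.

    Returns an ((1 + 2*context_windows) * L, S, 2) array whose centre L
    samples reconstruct X_t and whose flanks predict past/future postures.
    """
    z = np.asarray(code.z, dtype=float).reshape(1, -1)
    if z.shape[1] != model.latent_dim:
        raise ValueError(f"latent dimension mismatch: expected {model.latent_dim}, "
                         f"got {z.shape[1]}")
    out = model.decoder.forward(z)[0]
    c = model.config
    return out.reshape((1 + 2 * c["context_windows"]) * c["L"], c["S"], 2)


def pretrain(
    windows: list[PostureWindow],
    cfg: TrainConfig = TrainConfig(),
    model: EncoderModel | None = None,
    latent_dim: int = 10,
    hidden: int = 64,
) -> EncoderModel:
    """Self-supervised pre-training: reconstruct the extended sequence.

    Minimizes MSE over centre + flanks with Adam; a ``val_fraction`` held-out
    split is monitored and the best-validation weights are restored at the
    end. Raises on an empty window list or a non-finite loss.
    """
    if not windows:
        raise ValueError("pretrain requires at least one window")
    if model is None:
        w0 = windows[0]
        L, S, _ = w0.x.shape
        C = (w0.context.shape[0] // L - 1) // 2 if w0.context is not None else 0
        model = new_encoder(
            WindowingConfig(samples_per_window=L, spine_points=S, context_windows=C),
            latent_dim=latent_dim, hidden=hidden, seed=cfg.seed,
        )
    X, Y = _flatten_windows(windows, model, with_targets=True)

    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(X))
    n_val = int(round(cfg.val_fraction * len(X)))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        train_idx, val_idx = order, order[:0]
    Xtr, Ytr = X[train_idx], Y[train_idx]
    Xva, Yva = X[val_idx], Y[val_idx]

    params = model.encoder.params + model.decoder.params
    opt = Adam(params, lr=cfg.learning_rate)
    best_val = np.inf
    best = None
    model.history = []
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(Xtr))
        losses = []
        for start in range(0, len(Xtr), cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            xb, yb = Xtr[idx], Ytr[idx]
            pred = model.decoder.forward(model.encoder.forward(xb))
            err = pred - yb
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            losses.append(loss * len(idx))
            grad = 2.0 * err / err.size
            model.encoder.backward(model.decoder.backward(grad))
            opt.step(model.encoder.grads + model.decoder.grads)
        train_loss = sum(losses) / len(Xtr)
        if len(Xva):
            pred = model.decoder.forward(model.encoder.forward(Xva))
            val_loss = float(np.mean((pred - Yva) ** 2))
        else:
            val_loss = train_loss
        model.history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < best_val:
            best_val = val_loss
            best = (model.encoder.get_weights(), model.decoder.get_weights())
    if best is not None:
        model.encoder.set_weights(best[0])
        model.decoder.set_weights(best[1])
    model.pretrained = True
    return model


def constant_baseline_mse(train_targets: np.ndarray, test_targets: np.ndarray) -> float:
    """MSE of always predicting the training-set mean extended sequence."""
    mean = train_targets.mean(axis=0, keepdims=True)
    return float(np.mean((test_targets - mean) ** 2))


def export_latents(
    model: EncoderModel,
    tracks: list[Track],
    cfg: WindowingConfig,
    out: str | Path,
) -> pd.DataFrame:
    """Encode every valid window of ``tracks`` and write a tidy CSV with
    columns ``larva_id, t_center, z_1..z_D``."""
    rows = []
    for track in tracks:
        windows = extract_windows_indexed(track, cfg)
        if windows:
            Z = encode_batch(model, windows)
            for w, z in zip(windows, Z):
                rows.append({"larva_id": w.larva_id, "t_center": w.t_center,
                             **{f"z_{i + 1}": z[i] for i in range(model.latent_dim)}})
    columns = ["larva_id", "t_center"] + [f"z_{i + 1}" for i in range(model.latent_dim)]
    table = pd.DataFrame(rows, columns=columns)
    table.to_csv(out, index=False, float_format="%.9g")
    return table


def import_latents(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
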