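"""Action classification over the posture-autoencoder latent space.

A tagger is a linear softmax head on top of the encoder's latent code. The
head is trained with class-weighted cross-entropy (inverse-frequency weights
to counter class imbalance); unless the encoder is frozen, its weights are
fine-tuned jointly with the head. Predictions are made per window and mapped
to the window's centre timestep, with no temporal smoothing of the argmax
sequence — disagreements between taggers tend to trace back to such
window-local decisions, and no principled smoothing rule is available, so a
smoothing hook exists but defaults to off. Ties in the probability vector
resolve to the first class in dictionary order.

``small_action`` is a class like any other: no priority rules.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._nn import Adam, Dense, Sequential, softmax
from .autoencoder import EncoderModel, TrainConfig, new_encoder
from .preprocess import PostureWindow, WindowingConfig, extract_windows_indexed
from .simulate import DEFAULT_DICTIONARY
from .trackdata_io import LabelSet, LabelSpec, Track

logger = logging.getLogger(__name__)

__all__ = [
    "ActionDictionary",
    "TaggerModel",
    "Prediction",
    "UNTAGGED",
    "train_tagger",
    "predict",
    "predictions_to_labelset",
    "transfer_experiment",
]

#: Marker used in ``Prediction.labels`` for timesteps without a valid window.
UNTAGGED = -1


@dataclass(frozen=True)
class ActionDictionary:
    """Ordered set of action class names."""

    names: tuple[str, ...] = tuple(spec.name for spec in DEFAULT_DICTIONARY)

    def __post_init__(self):
        if not self.names or len(set(self.names)) != len(self.names):
            raise ValueError("action dictionary must be non-empty with unique names")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class TaggerModel:
    """Encoder + softmax classification head + action dictionary."""

    encoder: EncoderModel
    head: Sequential
    dictionary: ActionDictionary
    freeze_encoder: bool = False
    seed: int = 0
    history: list[dict] = field(default_factory=list)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        self.encoder.save(directory / "encoder")
        manifest = {"dictionary": list(self.dictionary.names),
                    "freeze_encoder": self.freeze_encoder, "seed": self.seed}
        (directory / "tagger.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
        np.savez(directory / "head.npz",
                 **{f"p_{i}": p for i, p in enumerate(self.head.params)})
        if self.history:
            pd.DataFrame(self.history).to_csv(directory / "training_log.csv", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "TaggerModel":
        directory = Path(directory)
        encoder = EncoderModel.load(directory / "encoder")
        manifest = json.loads((directory / "tagger.json").read_text())
        dictionary = ActionDictionary(tuple(manifest["dictionary"]))
        head = _new_head(encoder.latent_dim, len(dictionary), manifest["seed"])
        with np.load(directory / "head.npz") as blob:
            head.set_weights([blob[f"p_{i}"] for i in range(len(head.params))])
        return cls(encoder=encoder, head=head, dictionary=dictionary,
                   freeze_encoder=manifest["freeze_encoder"], seed=manifest["seed"])


@dataclass
class Prediction:
    """Per-timestep class probabilities and argmax labels for one track.

    ``labels[k]`` is an index into the dictionary, or ``UNTAGGED`` (-1) when
    preprocessing invalidated the window at timestep k; the matching
    probability row is NaN. Valid probability rows sum to 1.
    """

    larva_id: int
    t: np.ndarray
    probabilities: np.ndarray
    labels: np.ndarray
    dictionary: ActionDictionary


def _new_head(latent_dim: int, n_classes: int, seed: int) -> Sequential:
    rng = np.random.default_rng(seed + 104729)
    return Sequential([Dense(latent_dim, n_classes, rng)])


def train_tagger(
    encoder: EncoderModel,
    labelled: list[tuple[PostureWindow, str]],
    cfg: TrainConfig = TrainConfig(),
    dictionary: ActionDictionary | None = None,
    freeze_encoder: bool = False,
) -> TaggerModel:
    """Fine-tune a classification head (and, unless frozen, the encoder).

    ``labelled`` pairs each posture window with a class name from the
    dictionary. Classes with no examples are kept in the dictionary (with a
    warning) so the output layout is stable. The caller's encoder is never
    mutated; training operates on a copy.

    The optimization budget is ``max(cfg.epochs * batches_per_epoch,
    cfg.min_steps)`` Adam steps, so tiny labelled sets still receive a full
    training run. The encoder (when not frozen) is updated at
    ``cfg.encoder_lr_fraction`` of the head's learning rate.
    """
    if not labelled:
        raise ValueError("train_tagger requires a non-empty labelled set")
    if dictionary is None:
        dictionary = ActionDictionary()
    unknown = {name for _, name in labelled if name not in dictionary.names}
    if unknown:
        raise ValueError(f"labels outside the dictionary: {sorted(unknown)}")
    missing = set(dictionary.names) - {name for _, name in labelled}
    if missing:
        logger.warning("no examples for classes %s; proceeding with present classes",
                       sorted(missing))

    model = encoder.copy()
    head = _new_head(model.latent_dim, len(dictionary), cfg.seed)
    windows = [w for w, _ in labelled]
    X = np.stack([w.x.reshape(-1) for w in windows])
    if X.shape[1] != model.input_dim:
        raise ValueError(f"window shape mismatch: expected {model.input_dim} "
                         f"features, got {X.shape[1]}")
    y = np.array([dictionary.index(name) for _, name in labelled])

    counts = np.bincount(y, minlength=len(dictionary)).astype(float)
    weights = np.where(counts > 0, 1.0 / np.maximum(counts, 1.0), 0.0)
    if np.any(weights > 0):
        weights = weights / weights[weights > 0].mean()
    sample_w = weights[y]

    rng = np.random.default_rng(cfg.seed)
    opt_head = Adam(head.params, lr=cfg.learning_rate)
    opt_enc = None
    if not freeze_encoder:
        opt_enc = Adam(model.encoder.params,
                       lr=cfg.learning_rate * cfg.encoder_lr_fraction)
    n_batches = max(1, -(-len(X) // cfg.batch_size))
    budget = max(cfg.epochs * n_batches, cfg.min_steps)
    history = []
    onehot = np.eye(len(dictionary))[y]
    steps = 0
    while steps < budget:
        perm = rng.permutation(len(X))
        total_loss, total_correct, seen = 0.0, 0, 0
        for start in range(0, len(X), cfg.batch_size):
            if steps >= budget:
                break
            idx = perm[start:start + cfg.batch_size]
            xb, yb, wb = X[idx], onehot[idx], sample_w[idx]
            z = model.encoder.forward(xb)
            probs = softmax(head.forward(z))
            wsum = wb.sum()
            loss = float(-(wb * np.log(np.maximum(probs[np.arange(len(idx)), y[idx]],
                                                  1e-12))).sum() / wsum)
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite classification loss")
            grad = wb[:, None] * (probs - yb) / wsum
            gz = head.backward(grad)
            opt_head.step(head.grads)
            if opt_enc is not None:
                model.encoder.backward(gz)
                opt_enc.step(model.encoder.grads)
            total_loss += loss * len(idx)
            total_correct += int((probs.argmax(axis=1) == y[idx]).sum())
            seen += len(idx)
            steps += 1
        history.append({"epoch": len(history), "train_loss": total_loss / seen,
                        "train_accuracy": total_correct / seen})
    model.fine_tuned = not freeze_encoder
    return TaggerModel(encoder=model, head=head, dictionary=dictionary,
                       freeze_encoder=freeze_encoder, seed=cfg.seed, history=history)


def predict_windows(model: TaggerModel, windows: list[PostureWindow]) -> np.ndarray:
    """Class-probability matrix (n_windows x n_classes) for a window batch."""
    X = np.stack([w.x.reshape(-1) for w in windows])
    if X.shape[1] != model.encoder.input_dim:
        raise ValueError(f"window shape mismatch: expected {model.encoder.input_dim} "
                         f"features, got {X.shape[1]}")
    return softmax(model.head.forward(model.encoder.encoder.forward(X)))




def predict(
    model: TaggerModel,
    track: Track,
    cfg: WindowingConfig,
    smooth: "callable | None" = None,
) -> Prediction:
    """Tag every timestep of ``track``; invalidated windows stay untagged.

    ``smooth`` is an optional hook mapping the (T, n_classes) probability
    array to a same-shaped array; the default applies no smoothing.
    """
    T = track.n_frames
    n = len(model.dictionary)
    probs = np.full((T, n), np.nan)
    labels = np.full(T, UNTAGGED, dtype=int)
    windows = extract_windows_indexed(track, cfg)
    if windows:
        P = predict_windows(model, windows)
        for w, row in zip(windows, P):
            probs[w.frame_index] = row
    if smooth is not None:
        probs = smooth(probs)
    tagged = ~np.isnan(probs[:, 0])
    # argmax with ties resolved to the first class in dictionary order
    labels[tagged] = probs[tagged].argmax(axis=1)
    return Prediction(larva_id=track.larva_id, t=track.t.copy(),
                      probabilities=probs, labels=labels, dictionary=model.dictionary)


def predictions_to_labelset(
    predictions: list[Prediction],
    dictionary: ActionDictionary | None = None,
) -> LabelSet:
    """Convert per-track predictions into a writable LabelSet
    (provenance ``predicted``; untagged timesteps become empty lists)."""
    if dictionary is None:
        if not predictions:
            dictionary = ActionDictionary()
        else:
            dictionary = predictions[0].dictionary
    colors = {spec.name: spec.color for spec in DEFAULT_DICTIONARY}
    labelset = LabelSet(
        dictionary=[LabelSpec(name, colors.get(name, "#808080")) for name in dictionary.names]
    )
    for pred in predictions:
        labelset.assignments[pred.larva_id] = [
            [] if lab == UNTAGGED else [int(lab)] for lab in pred.labels
        ]
        labelset.provenance[pred.larva_id] = "predicted"
        labelset.times[pred.larva_id] = pred.t
    labelset.validate()
    return labelset


def _stratified_subsample(labelled, per_class: int, rng: np.random.Generator):
    by_class: dict[str, list[int]] = {}
    for i, (_, name) in enumerate(labelled):
        by_class.setdefault(name, []).append(i)
    picked = []
    for name in sorted(by_class):
        idx = by_class[name]
        take = min(per_class, len(idx))
        picked.extend(rng.choice(idx, size=take, replace=False))
    return [labelled[i] for i in sorted(picked)]


def transfer_experiment(
    pretrained: EncoderModel,
    train_sizes: list[int],
    n_seeds: int,
    labelled: list[tuple[PostureWindow, str]],
    test_set: list[tuple[PostureWindow, str]],
    cfg: TrainConfig = TrainConfig(epochs=150),
    dictionary: ActionDictionary | None = None,
) -> pd.DataFrame:
    """Pre-trained versus Xavier-initialised encoders at several training sizes.

    For each (size, arm, seed) a tagger is trained on a stratified subsample
    of ``labelled`` (``size`` windows per class) with an identical training
    budget in both arms, then scored as macro-f1 on the fixed ``test_set``.
    The "False" arm draws a fresh Xavier-initialised encoder per seed.
    Returns a tidy table (size, pretrained, seed, macro_f1).
    """
    from .evaluate import macro_f1

    if dictionary is None:
        dictionary = ActionDictionary()
    n_classes_avail = len({name for _, name in labelled})
    rows = []
    for size in train_sizes:
        if size * n_classes_avail > len(labelled):
            logger.warning("train size %d/class exceeds available data; skipped", size)
            continue
        for seed in range(n_seeds):
            rng = np.random.default_rng(cfg.seed + 7919 * seed + size)
            subsample = _stratified_subsample(labelled, size, rng)
            run_cfg = dataclasses.replace(cfg, seed=cfg.seed + seed)
            for arm_pretrained in (True, False):
                if arm_pretrained:
                    enc = pretrained
                else:
                    enc = new_encoder(
                        WindowingConfig(
                            samples_per_window=pretrained.config["L"],
                            spine_points=pretrained.config["S"],
                            context_windows=pretrained.config["context_windows"],
                        ),
                        latent_dim=pretrained.latent_dim,
                        hidden=pretrained.config["hidden"],
                        seed=run_cfg.seed + 15485863,
                    )
                tag = train_tagger(enc, subsample, run_cfg, dictionary=dictionary)
                P = predict_windows(tag, [w for w, _ in test_set])
                pred_names = [dictionary.names[i] for i in P.argmax(axis=1)]
                true_names = [name for _, name in test_set]
                score = macro_f1(true_names, pred_names, dictionary)
                rows.append({"size": size, "pretrained": arm_pretrained,
                             "seed": seed, "macro_f1": score})
    return pd.DataFrame(rows, columns=["size", "pretrained", "seed", "macro_f1"])
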