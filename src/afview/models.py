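"""Binary AF classifiers and the two-phase transfer-learning protocol.

A classifier is a convolutional backbone with its original classification
layers replaced by global average pooling and a single dense unit with a
sigmoid, emitting ``pAF`` in [0, 1].  Adaptation happens in two phases:

* retrain — only the new head is trained (the base stays frozen), Adam,
  binary cross-entropy, default learning rate 1e-3, batch 64; the returned
  model is the epoch checkpoint maximizing validation accuracy;
* fine-tune — all base parameters train at a very low rate (default 1e-5,
  batch 32) except batch-normalization layers, which stay frozen so their
  running statistics survive the small target-domain dataset.

The fully instantiable backbone is ``tinycnn`` (three conv blocks, one BN
layer, 64 features), sized for CPU-scale experiments; the named ImageNet
architectures are registered shape-only for parameter accounting and
input-size contracts (their pretrained weights are not bundled).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .architectures import LAYER_TABLES, layer_table
from .registry import get_backbone_info

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "TrainedClassifier",
    "build_classifier",
    "count_trainable_params",
    "retrain",
    "fine_tune",
    "predict",
]


@dataclass(frozen=True)
class ModelSpec:
    backbone_id: str = "tinycnn"
    input_size: int | None = None  # None: the backbone's published D
    pretrained: bool = False
    seed: int = 0

    @property
    def D(self) -> int:
        info = get_backbone_info(self.backbone_id)
        if self.input_size is not None and self.backbone_id != "tinycnn":
            if self.input_size != info.input_size:
                raise ValueError(
                    f"{self.backbone_id} expects D={info.input_size}, got {self.input_size}"
                )
        return self.input_size or info.input_size


@dataclass
class TrainConfig:
    """Hyperparameters of one adaptation phase.

    Defaults follow the study protocol: retrain lr 1e-3 / batch 64,
    fine-tune lr 1e-5 / batch 32, binary cross-entropy, Adam, up to 450
    epochs with early stopping (patience on validation loss), model
    selection by maximum validation accuracy, BN frozen while fine-tuning.
    """

    phase: str = "retrain"  # "retrain" | "fine_tune"
    learning_rate: float | None = None
    batch_size: int | None = None
    max_epochs: int = 450
    patience: int = 20
    freeze_bn_in_finetune: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.phase not in ("retrain", "fine_tune"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.learning_rate is None:
            self.learning_rate = 1e-3 if self.phase == "retrain" else 1e-5
        if self.batch_size is None:
            self.batch_size = 64 if self.phase == "retrain" else 32
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("learning_rate and batch_size must be positive")


@dataclass
class TrainedClassifier:
    """Backbone + binary head with phase state."""

    spec: ModelSpec
    network: nn.Network
    phase: str = "untrained"  # untrained | retrained | fine_tuned
    history: list[dict] = field(default_factory=list)

    @property
    def feature_dim(self) -> int:
        return self.network.head.params["W"].shape[0]

    def predict(self, images: np.ndarray) -> np.ndarray:
        return predict(self, images)


def _build_tinycnn(seed: int) -> nn.Network:
    rng = np.random.default_rng(seed)
    return nn.Network(
        [
            nn.Conv2D(3, 8, k=3, name="conv1", rng=rng),
            nn.ReLU("relu1"),
            nn.MaxPool2D(2, "pool1"),
            nn.Conv2D(8, 16, k=3, name="conv2", rng=rng),
            nn.BatchNorm(16, "bn1", frozen=True),
            nn.ReLU("relu2"),
            nn.MaxPool2D(2, "pool2"),
            nn.Conv2D(16, 64, k=3, name="conv3", rng=rng),
            nn.ReLU("relu3"),
            nn.MaxPool2D(2, "pool3"),
            nn.GlobalAvgPool("gap"),
            nn.Dense(64, 1, name="head", rng=rng),
        ]
    )


def build_classifier(spec: ModelSpec) -> TrainedClassifier:
    """Instantiate an untrained classifier for a registered backbone.

    Only ``tinycnn`` is weight-instantiable in this package; the ImageNet
    entries are registered shape-only (see :mod:`afview.architectures`) and
    raise here with a pointer to the registry.
    """
    info = get_backbone_info(spec.backbone_id)  # raises for unknown ids
    _ = spec.D  # validates the input-size contract
    if spec.backbone_id != "tinycnn":
        raise NotImplementedError(
            f"{spec.backbone_id} is registered shape-only (feature_dim={info.feature_dim}, "
            f"D={info.input_size}); weight instantiation is available for 'tinycnn'"
        )
    return TrainedClassifier(spec=spec, network=_build_tinycnn(spec.seed))


def count_trainable_params(model, phase: str) -> int:
    """Exact number of parameters receiving gradient updates in a phase.

    Accepts a :class:`TrainedClassifier` (counted from its actual arrays)
    or a backbone id / :class:`ModelSpec` (counted from the shape-level
    layer table).
    """
    if phase not in ("retrain", "fine_tune"):
        raise ValueError(f"unknown phase {phase!r}")
    if isinstance(model, TrainedClassifier):
        refs = model.network.trainable_refs(phase)
        return sum(int(layer.params[key].size) for layer, key in refs)
    backbone_id = model.backbone_id if isinstance(model, ModelSpec) else str(model)
    info = get_backbone_info(backbone_id)
    if info.layer_table is not None:
        table = layer_table(info.layer_table)
        return table.retrain_trainable() if phase == "retrain" else table.finetune_trainable()
    if phase == "retrain":
        return info.feature_dim + 1
    raise NotImplementedError(
        f"fine-tune parameter count needs a shape-level layer table; "
        f"{backbone_id} has none (available: {sorted(LAYER_TABLES)})"
    )


def _epoch_eval(logits: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    loss, _ = nn.bce_loss_and_grad(logits, y)
    acc = float(np.mean((nn.sigmoid(logits.ravel()) >= 0.5) == (y.ravel() == 1)))
    return float(loss), acc


def _train_loop(model, train, val, config, forward_backward, evaluate):
    """Shared epoch loop: shuffle, update, early-stop, best-val-acc checkpoint."""
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.network.trainable_refs(config.phase), lr=config.learning_rate)
    Xtr, ytr = train
    best = {"val_acc": -1.0, "state": model.network.get_state(), "epoch": -1}
    bad_epochs, best_val_loss = 0, np.inf
    history = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(ytr)) if len(ytr) else np.array([], int)
        losses = []
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo : lo + config.batch_size]
            losses.append(forward_backward(Xtr[idx], ytr[idx], opt))
        tr_loss, tr_acc = evaluate(*train)
        val_loss, val_acc = evaluate(*val)
        history.append(
            dict(epoch=epoch, train_loss=tr_loss, train_acc=tr_acc,
                 val_loss=val_loss, val_acc=val_acc)
        )
        if val_acc > best["val_acc"]:
            best = {"val_acc": val_acc, "state": model.network.get_state(), "epoch": epoch}
        if val_loss < best_val_loss - 1e-12:
            best_val_loss, bad_epochs = val_loss, 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break
    model.network.set_state(best["state"])
    model.history.extend(history)
    return history


def retrain(
    model: TrainedClassifier,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    config: TrainConfig | None = None,
) -> tuple[TrainedClassifier, list[dict]]:
    """Train only the head on frozen base features.

    Base features are computed once and cached, which is mathematically
    identical to full forward passes with a frozen base.  Returns the
    checkpoint with maximum validation accuracy.
    """
    config = config or TrainConfig(phase="retrain")
    if config.phase != "retrain":
        raise ValueError("config.phase must be 'retrain'")
    (Xtr, ytr), (Xval, yval) = train_data, val_data
    if len(ytr) == 0 or len(yval) == 0:
        raise ValueError("empty training or validation data")
    net = model.network
    Ftr = net.features(Xtr)
    Fval = net.features(Xval)

    def forward_backward(fb, yb, opt):
        logits = net.head.forward(fb)
        loss, dz = nn.bce_loss_and_grad(logits, yb)
        net.head.backward(dz)
        opt.step()
        return loss

    def evaluate(F, y):
        return _epoch_eval(net.head.forward(F), y)

    history = _train_loop(model, (Ftr, ytr), (Fval, yval), config, forward_backward, evaluate)
    model.phase = "retrained"
    return model, history


def fine_tune(
    model: TrainedClassifier,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    config: TrainConfig | None = None,
) -> tuple[TrainedClassifier, list[dict]]:
    """Slowly adapt all non-BN parameters of a retrained model."""
    config = config or TrainConfig(phase="fine_tune")
    if config.phase != "fine_tune":
        raise ValueError("config.phase must be 'fine_tune'")
    if model.phase != "retrained":
        warnings.warn("fine-tuning a model that was not retrained first", stacklevel=2)
    (Xtr, ytr), (Xval, yval) = train_data, val_data
    if len(ytr) == 0 or len(yval) == 0:
        raise ValueError("empty training or validation data")
    net = model.network
    if config.freeze_bn_in_finetune:
        for layer in net.layers:
            if isinstance(layer, nn.BatchNorm):
                layer.frozen = True

    def forward_backward(xb, yb, opt):
        logits = net.forward(xb, training=True)
        loss, dz = nn.bce_loss_and_grad(logits, yb)
        net.backward(dz)
        opt.step()
        return loss

    def evaluate(X, y):
        logits = np.concatenate(
            [net.forward(X[lo : lo + 64]) for lo in range(0, len(y), 64)]
        )
        return _epoch_eval(logits, y)

    history = _train_loop(model, (Xtr, ytr), (Xval, yval), config, forward_backward, evaluate)
    model.phase = "fine_tuned"
    return model, history


def save_classifier(model: TrainedClassifier, path) -> None:
    """Serialize weights (npz) with a JSON sidecar (spec, phase, history)."""
    import json
    from pathlib import Path

    path = Path(path)
    np.savez(path, **model.network.get_state())
    sidecar = {
        "backbone_id": model.spec.backbone_id,
        "input_size": model.spec.D,
        "seed": model.spec.seed,
        "phase": model.phase,
        "history": model.history,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar))


def load_classifier(path) -> TrainedClassifier:
    import json
    from pathlib import Path

    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    spec = ModelSpec(
        backbone_id=sidecar["backbone_id"],
        input_size=sidecar["input_size"],
        seed=sidecar["seed"],
    )
    model = build_classifier(spec)
    with np.load(path) as data:
        model.network.set_state({k: data[k] for k in data.files})
    model.phase = sidecar["phase"]
    model.history = sidecar["history"]
    return model


def predict(model: TrainedClassifier, images: np.ndarray) -> np.ndarray:
    """pAF probabilities for a batch of preprocessed D x D x 3 images."""
    images = np.asarray(images)
    if images.ndim == 3:
        images = images[None]
    D = model.spec.D
    if images.shape[1:] != (D, D, 3):
        raise ValueError(f"expected (n, {D}, {D}, 3) input, got {images.shape}")
    return np.concatenate(
        [model.network.predict_proba(images[lo : lo + 64]) for lo in range(0, len(images), 64)]
    )
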