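"""Tumor-patch classification: keep tumor patches, reject the rest.

A slide's tissue patches are filtered before multiple-instance learning
so the MIL model never sees stroma, glass edges or pure immune
infiltrate — regions that would otherwise add label noise to the bags.
The desk-scale backbone is a compact CNN trained from scratch on
downsampled 256x256 patches; the ImageNet-pretrained MobileNet-V2
fine-tuning mode (last layers unfrozen, flatten + dense head) is kept as
a configuration value for real-slide use but requires a deep-learning
framework with pretrained weights and is not trainable here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .nn import Adam, SmallCNN, downsample, softmax, softmax_cross_entropy
from .tiling import Patch

CHECKPOINT_VERSION = 1


@dataclass
class ClassifierConfig:
    backbone: str = "small_cnn"  # or "mobilenet_v2_finetune"
    n_unfrozen_layers: int = 7   # only meaningful in finetune mode
    input_size: int = 32         # patch is block-mean pooled to this extent
    channels: tuple = (8, 16)
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 20
    seed: int = 0

    def validate(self):
        if self.backbone not in ("small_cnn", "mobilenet_v2_finetune"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.backbone == "mobilenet_v2_finetune" and self.n_unfrozen_layers < 1:
            raise ValueError("n_unfrozen_layers must be >= 1 in finetune mode")


@dataclass
class ClassifierMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion_counts: dict  # keys tp, fp, fn, tn (tumor = positive class)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


class PatchClassifier:
    """Maps a 256x256 RGB patch to a tumor probability."""

    def __init__(self, config: ClassifierConfig):
        config.validate()
        if config.backbone == "mobilenet_v2_finetune":
            raise NotImplementedError(
                "mobilenet_v2_finetune requires a deep-learning framework with "
                "ImageNet weights; use backbone='small_cnn'"
            )
        self.config = config
        self.net = SmallCNN(
            in_size=config.input_size,
            channels=config.channels,
            out_dim=2,
            seed=config.seed,
            prefix="clf",
        )
        self.trained = False
        self.history: list[float] = []  # per-epoch mean training loss

    def _prep(self, pixels: np.ndarray) -> np.ndarray:
        return downsample(pixels, self.config.input_size)

    def predict_proba(self, pixels: np.ndarray) -> np.ndarray:
        """Tumor probability for a stack of (N, 256, 256, 3) patches."""
        x = self._prep(np.asarray(pixels))
        logits, _ = self.net.forward(x)
        return softmax(logits, axis=1)[:, 1]

    def save(self, path) -> None:
        np.savez(
            path,
            __version__=CHECKPOINT_VERSION,
            __config__=json.dumps(asdict(self.config)),
            __trained__=self.trained,
            **self.net.params,
        )

    @classmethod
    def load(cls, path) -> "PatchClassifier":
        data = np.load(path, allow_pickle=False)
        cfg = json.loads(str(data["__config__"]))
        cfg["channels"] = tuple(cfg["channels"])
        model = cls(ClassifierConfig(**cfg))
        for k in model.net.params:
            model.net.params[k] = data[k]
        model.trained = bool(data["__trained__"])
        return model


def train_classifier(
    patches: list[Patch], labels, config: ClassifierConfig | None = None
) -> PatchClassifier:
    """Train the patch classifier on labelled patches.

    ``labels`` are truthy for tumor.  The loss is cross-entropy with
    inverse-frequency class weights (synthetic cohorts can be skewed).
    ``epochs=0`` returns the untrained network with a warning —
    predictions are still valid probabilities.
    """
    config = config or ClassifierConfig()
    labels = np.asarray(labels).astype(int)
    if len(patches) != labels.size:
        raise ValueError("patches and labels must have equal length")
    classes = np.unique(labels)
    if config.epochs > 0 and classes.size < 2:
        raise ValueError(
            f"training set contains a single class {classes.tolist()}; need both"
        )
    model = PatchClassifier(config)
    if config.epochs == 0:
        warnings.warn("epochs=0: returning untrained classifier")
        return model

    x = model._prep(np.stack([p.pixels for p in patches]))
    n = x.shape[0]
    freq = np.bincount(labels, minlength=2) / n
    class_weights = np.where(freq > 0, 1.0 / np.maximum(freq, 1e-12), 0.0)
    class_weights /= class_weights.sum()

    rng = np.random.default_rng(config.seed)
    opt = Adam(lr=config.learning_rate)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits, cache = model.net.forward(x[idx])
            loss, dlogits = softmax_cross_entropy(logits, labels[idx], class_weights)
            grads = model.net.backward(dlogits, cache)
            opt.step(model.net.params, grads)
            losses.append(loss)
        model.history.append(float(np.mean(losses)))
    model.trained = True
    return model


def classify_patches(
    model: PatchClassifier, patches: list[Patch], threshold: float = 0.5
) -> tuple[list[Patch], list[Patch]]:
    """Partition patches into (tumor, rejected) at ``threshold``.

    Fills ``tumor_prob`` on every patch; tumor iff prob >= threshold.
    The partition is exhaustive and disjoint by construction.
    """
    if not model.trained:
        warnings.warn("classifying with an untrained model")
    if not patches:
        return [], []
    probs = model.predict_proba(np.stack([p.pixels for p in patches]))
    tumor, rejected = [], []
    for p, prob in zip(patches, probs):
        p.tumor_prob = float(prob)
        (tumor if prob >= threshold else rejected).append(p)
    return tumor, rejected


def evaluate_classifier(predictions, truth) -> ClassifierMetrics:
    """Accuracy/precision/recall/F1 and the 2x2 confusion table.

    ``predictions`` and ``truth`` are equal-length binary vectors with
    tumor as the positive class.
    """
    pred = np.asarray(predictions).astype(bool)
    true = np.asarray(truth).astype(bool)
    if pred.size == 0:
        raise ValueError("empty input")
    if pred.shape != true.shape:
        raise ValueError("length mismatch")
    tp = int((pred & true).sum())
    fp = int((pred & ~true).sum())
    fn = int((~pred & true).sum())
    tn = int((~pred & ~true).sum())
    total = pred.size
    precision = tp / (tp + fp) if tp + fp > 0 else float("nan")
    recall = tp / (tp + fn) if tp + fn > 0 else float("nan")
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return ClassifierMetrics(
        accuracy=(tp + tn) / total,
        precision=precision,
        recall=recall,
        f1=f1,
        confusion_counts={"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    )
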