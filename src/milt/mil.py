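"""Multiple-instance learning core for slide-level TPS prediction.

A slide is a bag of tumor patches carrying one weak label: the
pathologist's TPS, quantized to 12 discrete values spanning 0–0.9.  Per
patch, a compact CNN produces a ``num_features``-dimensional feature
vector squashed into [0,1]; a gated-attention network assigns each patch
a normalized weight; the distribution-pooling filter summarizes the bag
as the attention-weighted marginal distribution of each feature over
``n_bins`` bins of the unit interval (a smoothed histogram, Gaussian
kernel of width ``sigma``); and a small fully connected head maps that
``num_features x n_bins`` representation to a distribution over the 12
labels.  The bag prediction is the expected TPS under that distribution,
and a slide's TPS-AI is the mean over its inference bags.

Distribution pooling rather than mean/max pooling is the load-bearing
choice: the TPS is a *proportion*, so the shape of the per-patch feature
distribution across the bag — not any single extreme patch — carries the
label information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    Adam,
    GatedAttention,
    MLP,
    SmallCNN,
    accumulate,
    downsample,
    sigmoid,
    softmax,
    softmax_cross_entropy,
)
DEFAULT_LABEL_SET = (0.0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass
class Bag:
    bag_id: int
    patch_refs: np.ndarray  # indices into the slide's tumor-patch list
    prediction: float | None = None  # TPS fraction once inferred


@dataclass
class MILConfig:
    num_features: int = 32
    n_bags_train: int = 100
    bag_size_infer: int = 200
    n_bags_infer: int = 100
    n_bins: int = 21
    sigma: float = 0.05
    label_set: tuple = DEFAULT_LABEL_SET
    backbone: str = "small_cnn"      # or "resnet18" (needs a DL framework)
    input_size: int = 32             # crop is block-mean pooled to this extent
    channels: tuple = (8, 16)
    attention_dim: int = 16
    head_hidden: int = 64
    crop_size: int = 224
    augment: bool = True
    n_aug_variants: int = 8          # precomputed RandomCrop/flip variants per patch
    loss: str = "cross_entropy"      # or "mse_on_expected_value"
    learning_rate: float = 3e-3
    epochs: int = 300
    pretrain_epochs: int = 0         # optional mean-pooling warm start of the extractor
    accum_bags: int = 0              # bags per optimizer step; 0 = all bags in an epoch
    patience: int = 50               # early-stop window on validation loss
    seed: int = 0

    def validate(self):
        ls = np.asarray(self.label_set, dtype=float)
        if ls.size != 12 or not np.all(np.diff(ls) > 0):
            raise ValueError("label_set must hold 12 strictly increasing values")
        if ls[0] != 0.0 or ls[-1] != 0.9:
            raise ValueError("label_set must range from 0 to 0.9")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.loss not in ("cross_entropy", "mse_on_expected_value"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.crop_size % self.input_size != 0:
            raise ValueError("crop_size must be a multiple of input_size")


def quantize_label(tps_fraction: float, label_set=DEFAULT_LABEL_SET) -> float:
    """Snap a TPS fraction in [0,1] to the nearest discrete label (idempotent)."""
    ls = np.asarray(label_set, dtype=float)
    return float(ls[np.argmin(np.abs(ls - tps_fraction))])


# ---------------------------------------------------------------------------
# bagging
# ---------------------------------------------------------------------------

def build_bags_train(tumor_patches, n_bags: int = 100, seed: int = 0) -> list[Bag]:
    """Random permutation + round-robin partition into ``n_bags`` bags.

    Bags are disjoint, their union is the input, and sizes differ by at
    most one.
    """
    n = len(tumor_patches)
    if n < n_bags:
        raise ValueError(
            f"cannot split {n} patches into {n_bags} non-empty bags"
        )
    perm = np.random.default_rng(seed).permutation(n)
    return [Bag(bag_id=i, patch_refs=perm[i::n_bags]) for i in range(n_bags)]


def build_bags_infer(
    tumor_patches, n_bags: int = 100, bag_size: int = 200, seed: int = 0
) -> tuple[list[Bag], np.ndarray]:
    """Sampling-with-replacement bags with a full-cover guarantee.

    Every patch appears in at least one bag; the remaining
    ``n_bags*bag_size - n`` slots are filled uniformly at random.
    Returns the bags plus per-patch recalculation counts (summing to
    ``n_bags * bag_size``).
    """
    n = len(tumor_patches)
    if n < 1:
        raise ValueError("need at least one tumor patch")
    total = n_bags * bag_size
    if n > total:
        raise ValueError(
            f"{n} patches cannot all be covered by {n_bags} bags of {bag_size}"
        )
    rng = np.random.default_rng(seed)
    slots = np.concatenate([np.arange(n), rng.integers(0, n, size=total - n)])
    rng.shuffle(slots)
    bags = [
        Bag(bag_id=i, patch_refs=slots[i * bag_size:(i + 1) * bag_size])
        for i in range(n_bags)
    ]
    counts = np.bincount(slots, minlength=n)
    return bags, counts


# ---------------------------------------------------------------------------
# distribution pooling
# ---------------------------------------------------------------------------

def _pool_forward(features, weights, n_bins, sigma):
    centers = np.linspace(0.0, 1.0, n_bins)
    diff = centers[None, None, :] - features[:, :, None]      # (n, d, b)
    u = np.exp(-0.5 * (diff / sigma) ** 2)
    raw = np.einsum("i,ijb->jb", weights, u)                  # (d, b)
    z = raw.sum(axis=1, keepdims=True)
    h = raw / z
    return h, (u, diff, z, h, weights, features)


def _pool_backward(dh, cache, sigma):
    u, diff, z, h, weights, features = cache
    draw = (dh - (dh * h).sum(axis=1, keepdims=True)) / z      # (d, b)
    dw = np.einsum("ijb,jb->i", u, draw)
    dker = u * (diff / sigma**2)                               # d u / d f_ij
    dfeat = weights[:, None] * np.einsum("ijb,jb->ij", dker, draw)
    return dfeat, dw


def distribution_pooling(
    features: np.ndarray, weights: np.ndarray, n_bins: int = 21, sigma: float = 0.05
) -> np.ndarray:
    """Attention-weighted marginal feature distribution of a bag.

    For feature dimension j and bin center c_b (``n_bins`` equally
    spaced over [0,1])::

        h[j, b] ∝ sum_i  w_i · exp(-(c_b - f_ij)^2 / (2 sigma^2))

    with each row renormalized to sum to one.  Invariant to instance
    permutation and to splitting an instance's weight mass across
    duplicates.
    """
    features = np.asarray(features, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if features.ndim != 2:
        raise ValueError("features must be (n_instances, num_features)")
    if features.min() < 0.0 or features.max() > 1.0:
        raise ValueError(
            "features outside [0,1]: the extractor must squash its output"
        )
    if weights.shape != (features.shape[0],) or (weights < 0).any():
        raise ValueError("weights must be one non-negative value per instance")
    if not np.isclose(weights.sum(), 1.0, atol=1e-6):
        raise ValueError("weights must sum to 1")
    h, _ = _pool_forward(features, weights, n_bins, sigma)
    return h


# ---------------------------------------------------------------------------
# the MIL model
# ---------------------------------------------------------------------------

@dataclass
class SlideData:
    """One slide's tumor patches plus its weak label, ready for MIL."""

    slide_id: str
    pixels: np.ndarray = field(repr=False)   # (n_patches, 256, 256, 3) uint8
    label_fraction: float = 0.0
    split: str = "train"


@dataclass
class SlidePrediction:
    slide_id: str
    tps_ai_percent: float | None
    n_tumor_patches: int
    n_bags: int
    no_tumor: bool = False


def center_crop(pixels: np.ndarray, size: int) -> np.ndarray:
    """Center-crop (N, H, W, C) to (N, size, size, C)."""
    h, w = pixels.shape[1:3]
    y0, x0 = (h - size) // 2, (w - size) // 2
    return pixels[:, y0:y0 + size, x0:x0 + size, :]


def augment_crop(pixels: np.ndarray, size: int, rng) -> np.ndarray:
    """RandomCrop + RandomHorizontalFlip + RandomVerticalFlip per patch."""
    n, h, w, _ = pixels.shape
    out = np.empty((n, size, size, pixels.shape[3]), dtype=pixels.dtype)
    for i in range(n):
        y0 = rng.integers(0, h - size + 1)
        x0 = rng.integers(0, w - size + 1)
        crop = pixels[i, y0:y0 + size, x0:x0 + size, :]
        if rng.random() < 0.5:
            crop = crop[:, ::-1]
        if rng.random() < 0.5:
            crop = crop[::-1, :]
        out[i] = crop
    return out


class MILModel:
    """Feature extractor + gated attention + distribution pooling + head."""

    def __init__(self, config: MILConfig):
        config.validate()
        if config.backbone == "resnet18":
            raise NotImplementedError(
                "resnet18 feature extraction requires a deep-learning framework "
                "with pretrained weights; use backbone='small_cnn'"
            )
        if config.backbone != "small_cnn":
            raise ValueError(f"unknown backbone {config.backbone!r}")
        self.config = config
        self.labels = np.asarray(config.label_set, dtype=float)
        self.extractor = SmallCNN(
            in_size=config.input_size,
            channels=config.channels,
            out_dim=config.num_features,
            seed=config.seed,
            prefix="feat",
        )
        self.attention = GatedAttention(
            config.num_features, config.attention_dim, seed=config.seed + 1,
            prefix="att",
        )
        self.head = MLP(
            [config.num_features * config.n_bins, config.head_hidden, 12],
            seed=config.seed + 2,
            prefix="head",
            final_zero=True,
        )
        self.params = {}
        for mod in (self.extractor, self.attention, self.head):
            self.params.update(mod.params)
            mod.params = self.params  # share one flat dict
        self.trained = False
        self.history: dict[str, list] = {"train_loss": [], "val_loss": []}

    # -- per-stage ops ---------------------------------------------------

    def extract_features(self, pixels: np.ndarray) -> np.ndarray:
        """Per-patch feature vectors in [0,1]^num_features.

        ``pixels`` must already be crop_size x crop_size (augmented or
        center-cropped upstream).
        """
        pixels = np.asarray(pixels)
        cs = self.config.crop_size
        if pixels.shape[1:3] != (cs, cs):
            raise ValueError(
                f"expected {cs}x{cs} crops, got {pixels.shape[1:3]}"
            )
        x = downsample(pixels, self.config.input_size)
        out, _ = self.extractor.forward(x)
        return sigmoid(out)

    def attention_weights(self, features: np.ndarray) -> np.ndarray:
        """Normalized gated-attention weights, one per instance."""
        features = np.atleast_2d(np.asarray(features, dtype=float))
        if features.shape[0] < 1:
            raise ValueError("need at least one instance")
        w, _ = self.attention.forward(features)
        return w

    def bag_transform(self, rep: np.ndarray) -> np.ndarray:
        """Label probabilities (softmax over the 12 TPS labels).

        The representation rows are probabilities over ``n_bins`` bins;
        the head sees them scaled by ``n_bins`` (i.e. as bin densities)
        purely for conditioning — entries of order one train faster than
        entries of order 1/n_bins.
        """
        logits, _ = self.head.forward(rep.reshape(1, -1) * self.config.n_bins)
        return softmax(logits, axis=1)[0]

    def predict_bag_from_features(self, features: np.ndarray) -> float:
        """Bag-level TPS fraction: expected value of the label distribution."""
        w = self.attention_weights(features)
        rep = distribution_pooling(features, w, self.config.n_bins, self.config.sigma)
        p = self.bag_transform(rep)
        return float(p @ self.labels)

    # -- training --------------------------------------------------------

    def _bag_forward(self, x):
        """x: downsampled (n, s, s, 3) crops. Returns (pred, probs, caches)."""
        cfg = self.config
        out, c_cnn = self.extractor.forward(x)
        feats = sigmoid(out)
        w, c_att = self.attention.forward(feats)
        rep, c_pool = _pool_forward(feats, w, cfg.n_bins, cfg.sigma)
        logits, c_head = self.head.forward(rep.reshape(1, -1) * cfg.n_bins)
        probs = softmax(logits, axis=1)[0]
        pred = float(probs @ self.labels)
        return pred, probs, logits, (c_cnn, feats, c_att, c_pool, c_head, rep.shape)

    def _bag_loss_grads(self, x, label_fraction: float):
        """Loss and full parameter gradients for one bag (no augmentation here)."""
        cfg = self.config
        pred, probs, logits, caches = self._bag_forward(x)
        c_cnn, feats, c_att, c_pool, c_head, rep_shape = caches
        target_idx = int(np.argmin(np.abs(self.labels - label_fraction)))
        if cfg.loss == "cross_entropy":
            loss, dlogits = softmax_cross_entropy(logits, np.array([target_idx]))
        else:  # mse on the expected-value readout
            y = quantize_label(label_fraction, cfg.label_set)
            loss = (pred - y) ** 2
            # d pred / d logits_k = p_k (l_k - pred)
            dlogits = (2.0 * (pred - y) * probs * (self.labels - pred))[None, :]
        grads = {}
        g_head, dflat = self.head.backward(dlogits, c_head)
        accumulate(grads, g_head)
        drep = dflat.reshape(rep_shape) * cfg.n_bins
        dfeat_pool, dw = _pool_backward(drep, c_pool, cfg.sigma)
        g_att, dfeat_att = self.attention.backward(dw, c_att)
        accumulate(grads, g_att)
        dfeat = dfeat_pool + dfeat_att
        dout = dfeat * feats * (1.0 - feats)  # sigmoid squash
        accumulate(grads, self.extractor.backward(dout, c_cnn))
        return loss, grads, pred


def _pretrain_extractor(model, variants, labels, config, rng):
    """Mean-pooling MIL regression warm start of the feature extractor.

    A slide's TPS is by definition the mean over tumor patches of the
    local positive-cell fraction, so the mean-pooling bag model —
    slide prediction = mean_i sigmoid(a·z_i + b) over raw per-patch
    extractor outputs z_i — is the natural first-order reading of the
    weak labels and has no cold-start saddle: every patch of a slide
    receives the same residual gradient.  The scalar readout is
    discarded afterwards; only the shaped extractor weights remain.
    """
    from .nn import Dense

    ro = Dense(config.num_features, 1, np.random.default_rng(config.seed + 3), "ro")
    ro_params = dict(ro.params)
    # start at the mean label so the sigmoid readout cannot die at 0 or 1
    ybar = float(np.clip(np.mean(labels), 1e-3, 1 - 1e-3))
    ro_params["ro/b"][:] = np.log(ybar / (1.0 - ybar))
    opt = Adam(lr=config.learning_rate, clip_norm=5.0)
    n_var = variants[0].shape[0]
    for _ in range(config.pretrain_epochs):
        total, losses = {}, []
        for si, y in enumerate(labels):
            kk = rng.integers(0, n_var, size=variants[si].shape[1])
            x = variants[si][kk, np.arange(variants[si].shape[1])]
            out, c_cnn = model.extractor.forward(x)
            sraw, c_ro = ro.forward(out, ro_params)
            s = sigmoid(sraw[:, 0])
            pred = s.mean()
            losses.append((pred - y) ** 2)
            ds = np.full_like(s, 2.0 * (pred - y) / s.size) * s * (1.0 - s)
            grads = {}
            dout = ro.backward(ds[:, None], c_ro, ro_params, grads)
            accumulate(grads, model.extractor.backward(dout, c_cnn))
            accumulate(total, grads)
        opt.step({**model.params, **ro_params}, total)
        model.history["pretrain_loss"].append(float(np.mean(losses)))


def train_mil(slide_data: list[SlideData], config: MILConfig | None = None) -> MILModel:
    """Train the MIL model on slides with slide-level TPS labels.

    Slides must carry split tags assigned at the slide level (3/1/1
    train/val/test); only ``train`` slides contribute gradients and only
    ``val`` slides drive early stopping.  Training runs in two phases:
    a mean-pooling regression warm start that shapes the feature
    extractor from the weak labels alone, then the full
    attention/distribution-pooling/head objective.  Each epoch every
    training slide's patches are re-partitioned into ``n_bags_train``
    fresh random bags, each inheriting the slide's quantized label;
    RandomCrop and flips are applied per patch per epoch when
    ``augment`` is on.  Gradients are accumulated over ``accum_bags``
    bags per optimizer step (default: all bags of an epoch) — bags carry
    a single label each, so stepping per bag makes the optimizer chase
    one label at a time and saturate the squashed features.  Training
    stops at ``epochs`` or once the validation loss has not improved for
    ``patience`` epochs.
    """
    config = config or MILConfig()
    model = MILModel(config)
    model.history["pretrain_loss"] = []
    train_slides = [s for s in slide_data if s.split == "train"]
    val_slides = [s for s in slide_data if s.split == "val"]
    if not train_slides:
        raise ValueError("no slides with split == 'train'")
    for s in slide_data:
        if len(s.pixels) == 0:
            raise ValueError(f"slide {s.slide_id} has zero tumor patches")

    rng = np.random.default_rng(config.seed)
    opt = Adam(lr=config.learning_rate, clip_norm=5.0)
    best_val, best_params, since_best = np.inf, None, 0

    # Augmented crops are precomputed once per slide (a small pool of
    # RandomCrop/flip variants per patch, sampled per epoch): the network
    # pass, not the augmentation, should dominate each step.
    n_var = config.n_aug_variants if config.augment else 1
    variants = []
    for s in train_slides:
        vs = []
        for _ in range(n_var):
            crops = (
                augment_crop(s.pixels, config.crop_size, rng)
                if config.augment
                else center_crop(s.pixels, config.crop_size)
            )
            vs.append(downsample(crops, config.input_size).astype(np.float32))
        variants.append(np.stack(vs))  # (n_var, n_patches, s, s, 3)
    val_x = [
        downsample(center_crop(s.pixels, config.crop_size), config.input_size)
        for s in val_slides
    ]

    if config.pretrain_epochs > 0:
        _pretrain_extractor(
            model, variants, [s.label_fraction for s in train_slides], config, rng
        )

    for epoch in range(config.epochs):
        # fresh random bags every epoch
        tasks = []
        for si, s in enumerate(train_slides):
            # small slides cannot fill n_bags_train non-empty bags; clamp
            n_bags = min(config.n_bags_train, len(s.pixels))
            bags = build_bags_train(
                range(len(s.pixels)), n_bags, seed=int(rng.integers(2**31))
            )
            tasks.extend((si, bag) for bag in bags)
        order = rng.permutation(len(tasks))
        accum = config.accum_bags if config.accum_bags > 0 else len(tasks)
        losses, total, in_batch = [], {}, 0
        for ti in order:
            si, bag = tasks[ti]
            s = train_slides[si]
            kk = rng.integers(0, n_var, size=bag.patch_refs.size)
            x = variants[si][kk, bag.patch_refs]
            loss, grads, _ = model._bag_loss_grads(x, s.label_fraction)
            accumulate(total, grads)
            in_batch += 1
            if in_batch >= accum:
                opt.step(model.params, total)
                total, in_batch = {}, 0
            losses.append(loss)
        if in_batch:
            opt.step(model.params, total)
        model.history["train_loss"].append(float(np.mean(losses)))

        if val_slides:
            vloss = float(
                np.mean(
                    [
                        model._bag_loss_grads(x, s.label_fraction)[0]
                        for x, s in zip(val_x, val_slides)
                    ]
                )
            )
            model.history["val_loss"].append(vloss)
            if vloss < best_val - 1e-6:
                best_val, since_best = vloss, 0
                best_params = {k: v.copy() for k, v in model.params.items()}
            else:
                since_best += 1
                if since_best >= config.patience:
                    break

    if best_params is not None:
        for k in model.params:
            model.params[k][...] = best_params[k]
    model.trained = True
    return model


def predict_bags(
    model: MILModel, features: np.ndarray, bags: list[Bag]
) -> np.ndarray:
    """Predict each bag's TPS fraction from precomputed patch features."""
    preds = np.empty(len(bags))
    for i, bag in enumerate(bags):
        preds[i] = model.predict_bag_from_features(features[bag.patch_refs])
        bag.prediction = float(preds[i])
    return preds


def predict_slide(
    model: MILModel,
    tumor_pixels: np.ndarray,
    config: MILConfig | None = None,
    slide_id: str = "slide",
    seed: int = 0,
) -> SlidePrediction:
    """Slide-level TPS-AI percent: mean of inference-bag predictions x 100.

    ``tumor_pixels`` is the (n, 256, 256, 3) stack of the slide's tumor
    patches.  With zero tumor patches an explicit no-tumor result is
    returned rather than a number.
    """
    config = config or model.config
    n = len(tumor_pixels)
    if n == 0:
        return SlidePrediction(
            slide_id=slide_id, tps_ai_percent=None, n_tumor_patches=0,
            n_bags=0, no_tumor=True,
        )
    feats = model.extract_features(center_crop(np.asarray(tumor_pixels), config.crop_size))
    bags, _ = build_bags_infer(
        range(n), n_bags=config.n_bags_infer, bag_size=config.bag_size_infer,
        seed=seed,
    )
    preds = predict_bags(model, feats, bags)
    return SlidePrediction(
        slide_id=slide_id,
        tps_ai_percent=float(preds.mean() * 100.0),
        n_tumor_patches=n,
        n_bags=len(bags),
    )


def save_mil(model: MILModel, path) -> None:
    import json
    from dataclasses import asdict

    cfg = asdict(model.config)
    cfg["label_set"] = list(cfg["label_set"])
    cfg["channels"] = list(cfg["channels"])
    np.savez(path, __config__=json.dumps(cfg), __trained__=model.trained,
             **model.params)


def load_mil(path) -> MILModel:
    import json

    data = np.load(path, allow_pickle=False)
    cfg = json.loads(str(data["__config__"]))
    cfg["label_set"] = tuple(cfg["label_set"])
    cfg["channels"] = tuple(cfg["channels"])
    model = MILModel(MILConfig(**cfg))
    for k in model.params:
        model.params[k][...] = data[k]
    model.trained = bool(data["__trained__"])
    return model
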