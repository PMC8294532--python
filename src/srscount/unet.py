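"""Reduced U-Net for SRS cell segmentation.

A symmetric encoder/decoder with half the kernel budget of the original
U-Net design: by default five levels with 16/32/64/128/256 kernels, two
same-padding 3x3 conv + ReLU layers per block, 2x2 max pooling between
encoder blocks, 2x2 transposed convolutions with skip concatenation in
the decoder, and a single-kernel 1x1 sigmoid head that emits a per-pixel
cell probability.  Same-padding convolutions keep the output the same
size as the input, which is what makes lossless patch-wise inference
(split -> predict -> combine) possible.

Training minimises mean pixel-wise binary cross-entropy with Adam
(alpha=0.001, beta1=0.9, beta2=0.999, eps=1e-8, batch 16) and early
stopping: a random 20% of the patches form a validation split, and
training stops once the validation loss has not improved for
``patience`` epochs; the weights of the best epoch are restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import tiling
from .imaging import CalibratedImage
from .nn import Adam, Conv2D, MaxPool2, ReLU, UpConv2, bce_with_logits, sigmoid


@dataclass
class SegModelConfig:
    """Architecture hyper-parameters of the reduced U-Net."""

    in_channels: int = 2
    kernels_per_level: tuple[int, ...] = (16, 32, 64, 128, 256)
    conv_size: int = 3
    pool_size: int = 2

    def __post_init__(self) -> None:
        self.kernels_per_level = tuple(self.kernels_per_level)
        if len(self.kernels_per_level) < 1:
            raise ValueError("need at least one level")
        if any(k < 1 for k in self.kernels_per_level):
            raise ValueError("kernel counts must be positive")
        if self.in_channels < 1:
            raise ValueError("in_channels must be positive")

    @property
    def levels(self) -> int:
        return len(self.kernels_per_level)

    @property
    def size_multiple(self) -> int:
        """Spatial sizes must be divisible by this (pooling depth)."""
        return self.pool_size ** (self.levels - 1)


@dataclass
class TrainConfig:
    """Optimiser and early-stopping settings."""

    batch_size: int = 16
    lr_alpha: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    val_fraction: float = 0.2
    patience_epochs: int = 25
    max_epochs: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.patience_epochs > self.max_epochs:
            raise ValueError("patience_epochs must not exceed max_epochs")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be positive")


@dataclass
class TrainHistory:
    """Per-epoch losses plus the early-stopping outcome (epochs are 1-based)."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = 0
    epochs_run: int = 0


class EarlyStopping:
    """Stop after ``patience`` epochs without a strict validation improvement."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        """Record epoch's validation loss; return True when training should stop."""
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = epoch
        return epoch - self.best_epoch >= self.patience


class UNet:
    """The network itself: stateless configuration + mutable weights."""

    def __init__(self, config: SegModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        ks = config.kernels_per_level
        L = config.levels
        k = config.conv_size

        def block(c_in, c_out):
            return [Conv2D(c_in, c_out, k, rng), ReLU(),
                    Conv2D(c_out, c_out, k, rng), ReLU()]

        self.enc = [block(config.in_channels if i == 0 else ks[i - 1], ks[i])
                    for i in range(L)]
        self.pools = [MaxPool2() for _ in range(L - 1)]
        self.ups = [(UpConv2(ks[i + 1], ks[i], rng), ReLU()) for i in range(L - 1)]
        self.dec = [block(2 * ks[i], ks[i]) for i in range(L - 1)]
        self.head = Conv2D(ks[0], 1, 1, rng)

    # -- plumbing ---------------------------------------------------------
    def _layers(self):
        for blk in self.enc:
            yield from blk
        yield from self.pools
        for up, relu in self.ups:
            yield up
            yield relu
        for blk in self.dec:
            yield from blk
        yield self.head

    def parameters(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params())
        return out

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.parameters())

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (p, _), w in zip(self.parameters(), weights):
            p[...] = w

    # -- forward/backward -------------------------------------------------
    def _check_size(self, h: int, w: int) -> None:
        m = self.config.size_multiple
        if h % m or w % m:
            raise ValueError(
                f"input spatial size {h}x{w} must be a multiple of {m} "
                f"(pool_size^(levels-1) = {self.config.pool_size}^"
                f"{self.config.levels - 1})"
            )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Logits of shape (N, H, W, 1) for input (N, H, W, C)."""
        if x.ndim != 4 or x.shape[3] != self.config.in_channels:
            raise ValueError(
                f"expected (N, H, W, {self.config.in_channels}) input, got {x.shape}")
        self._check_size(x.shape[1], x.shape[2])
        x = np.ascontiguousarray(x, dtype=np.float32)
        L = self.config.levels
        skips = []
        h = x
        for i in range(L):
            if i > 0:
                h = self.pools[i - 1].forward(h, train)
            for layer in self.enc[i]:
                h = layer.forward(h, train)
            if i < L - 1:
                skips.append(h)
        for i in reversed(range(L - 1)):
            up, relu = self.ups[i]
            h = relu.forward(up.forward(h, train), train)
            h = np.concatenate([skips[i], h], axis=-1)
            for layer in self.dec[i]:
                h = layer.forward(h, train)
        return self.head.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        L = self.config.levels
        ks = self.config.kernels_per_level
        g = self.head.backward(dlogits)
        dskips = [None] * (L - 1)
        for i in range(L - 1):
            for layer in reversed(self.dec[i]):
                g = layer.backward(g)
            dskips[i] = g[..., : ks[i]]
            up, relu = self.ups[i]
            g = up.backward(relu.backward(g[..., ks[i]:]))
        for i in reversed(range(L)):
            if i < L - 1:
                g = g + dskips[i]
            for layer in reversed(self.enc[i]):
                g = layer.backward(g)
            if i > 0:
                g = self.pools[i - 1].backward(g)

    def predict_proba_patches(self, x: np.ndarray, batch: int = 8) -> np.ndarray:
        """Per-pixel cell probabilities, shape (N, H, W)."""
        out = []
        for i in range(0, len(x), batch):
            logits = self.forward(x[i:i + batch], train=False)
            out.append(sigmoid(logits)[..., 0])
        return np.concatenate(out, axis=0)

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            in_channels=self.config.in_channels,
            kernels_per_level=np.asarray(self.config.kernels_per_level),
            **{f"p{i}": p for i, (p, _) in enumerate(self.parameters())},
        )

    @classmethod
    def load(cls, path) -> "UNet":
        data = np.load(path)
        cfg = SegModelConfig(
            in_channels=int(data["in_channels"]),
            kernels_per_level=tuple(int(v) for v in data["kernels_per_level"]),
        )
        model = cls(cfg)
        model.set_weights([data[f"p{i}"] for i in range(len(model.parameters()))])
        return model


def build_model(config: SegModelConfig | None = None, seed: int = 0) -> UNet:
    """Construct a freshly initialised reduced U-Net."""
    return UNet(config or SegModelConfig(), seed=seed)


def expected_parameter_count(config: SegModelConfig) -> int:
    """Closed-form layer-by-layer parameter sum for a given architecture.

    Each conv layer contributes ``k_h * k_w * C_in * C_out + C_out``; the
    2x2 transposed convs contribute ``4 * C_in * C_out + C_out``.
    """
    ks = config.kernels_per_level
    L = config.levels
    k2 = config.conv_size ** 2
    total = 0
    c_prev = config.in_channels
    for i in range(L):
        total += k2 * c_prev * ks[i] + ks[i]
        total += k2 * ks[i] * ks[i] + ks[i]
        c_prev = ks[i]
    for i in range(L - 1):
        total += config.pool_size ** 2 * ks[i + 1] * ks[i] + ks[i]   # up-conv
        total += k2 * (2 * ks[i]) * ks[i] + ks[i]
        total += k2 * ks[i] * ks[i] + ks[i]
    total += 1 * ks[0] * 1 + 1                                        # 1x1 head
    return total


def train(model: UNet, patches: np.ndarray, masks: np.ndarray,
          train_config: TrainConfig | None = None) -> tuple[UNet, TrainHistory]:
    """Fit ``model`` in place; returns it with best-epoch weights restored.

    ``patches`` is (N, H, W, C) in [0, 1]; ``masks`` is (N, H, W) with
    values in {0, 1}.  Deterministic given ``train_config.seed``.
    """
    cfg = train_config or TrainConfig()
    patches = np.asarray(patches, dtype=np.float32)
    masks = np.asarray(masks, dtype=np.float32)
    if patches.ndim != 4 or masks.ndim != 3 or patches.shape[:3] != masks.shape:
        raise ValueError("patches (N,H,W,C) and masks (N,H,W) must be aligned")
    if patches.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if not np.all(np.isin(np.unique(masks), (0.0, 1.0))):
        raise ValueError("masks must contain only values in {0, 1}")

    n = patches.shape[0]
    n_val = max(1, int(round(cfg.val_fraction * n)))
    if n - n_val < 1:
        raise ValueError("too few samples for a non-empty train/validation split")
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    y = masks[..., None]

    opt = Adam(model.parameters(), lr=cfg.lr_alpha, beta1=cfg.beta1,
               beta2=cfg.beta2, eps=cfg.epsilon)
    stopper = EarlyStopping(cfg.patience_epochs)
    history = TrainHistory()
    best_weights = model.get_weights()

    def eval_loss(idx) -> float:
        tot = 0.0
        for i in range(0, len(idx), cfg.batch_size):
            b = idx[i:i + cfg.batch_size]
            logits = model.forward(patches[b], train=False)
            loss, _ = bce_with_logits(logits, y[b])
            tot += loss * len(b)
        return tot / len(idx)

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(tr_idx)
        running = 0.0
        for i in range(0, len(order), cfg.batch_size):
            b = order[i:i + cfg.batch_size]
            logits = model.forward(patches[b], train=True)
            loss, dlogits = bce_with_logits(logits, y[b])
            model.backward(dlogits)
            opt.step()
            running += loss * len(b)
        history.train_loss.append(running / len(order))
        val_loss = eval_loss(val_idx)
        history.val_loss.append(val_loss)
        improved = val_loss < stopper.best
        stop = stopper.update(epoch, val_loss)
        if improved:
            best_weights = model.get_weights()
        if stop:
            break
    history.best_epoch = stopper.best_epoch
    history.epochs_run = len(history.val_loss)
    model.set_weights(best_weights)
    return model, history


class UNetSegmenter(BaseEstimator):
    """Scikit-learn-style wrapper around the reduced U-Net.

    ``fit(X, y)`` trains on aligned patch stacks (``X``: (N, H, W, 2) in
    [0, 1], ``y``: (N, H, W) in {0, 1}); ``predict_proba`` / ``predict``
    run whole images of arbitrary size through the split-and-combine
    tiling and return a probability map / binary mask of the input
    shape.  A pixel is a cell pixel iff its probability is strictly
    greater than ``prob_threshold``.
    """

    def __init__(self, in_channels=2, kernels_per_level=(16, 32, 64, 128, 256),
                 batch_size=16, learning_rate=0.001, beta1=0.9, beta2=0.999,
                 epsilon=1e-8, val_fraction=0.2, patience=25, max_epochs=300,
                 prob_threshold=0.5, patch_px=256, random_state=0):
        self.in_channels = in_channels
        self.kernels_per_level = kernels_per_level
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.epsilon = epsilon
        self.val_fraction = val_fraction
        self.patience = patience
        self.max_epochs = max_epochs
        self.prob_threshold = prob_threshold
        self.patch_px = patch_px
        self.random_state = random_state

    def _model_config(self) -> SegModelConfig:
        return SegModelConfig(in_channels=self.in_channels,
                              kernels_per_level=tuple(self.kernels_per_level))

    def fit(self, X, y):
        cfg = self._model_config()
        if self.patch_px % cfg.size_multiple:
            raise ValueError(
                f"patch_px={self.patch_px} must be a multiple of {cfg.size_multiple}")
        self.model_ = UNet(cfg, seed=self.random_state)
        tcfg = TrainConfig(batch_size=self.batch_size, lr_alpha=self.learning_rate,
                           beta1=self.beta1, beta2=self.beta2, epsilon=self.epsilon,
                           val_fraction=self.val_fraction,
                           patience_epochs=self.patience, max_epochs=self.max_epochs,
                           seed=self.random_state + 1)
        self.model_, self.history_ = train(self.model_, X, y, tcfg)
        return self

    def _as_array(self, image) -> np.ndarray:
        if isinstance(image, CalibratedImage):
            image = image.pixels
        image = np.asarray(image, dtype=np.float32)
        if image.ndim != 3 or image.shape[2] != self.in_channels:
            raise ValueError(
                f"expected HxWx{self.in_channels} image, got shape {image.shape}")
        return image

    def predict_proba(self, image) -> np.ndarray:
        """Probability map of the input's spatial shape, values in (0, 1)."""
        if not hasattr(self, "model_"):
            raise RuntimeError("segmenter is not fitted")
        arr = self._as_array(image)
        grid = tiling.split(arr, self.patch_px)
        batch = np.stack([tile for _, _, tile in grid.patches])
        probs = self.model_.predict_proba_patches(batch)
        return tiling.combine(grid, list(probs.astype(np.float32)))

    def predict(self, image) -> np.ndarray:
        """Binary mask: probability strictly greater than ``prob_threshold``."""
        return (self.predict_proba(image) > self.prob_threshold).astype(np.uint8)


def predict(model: UNet, image, run_config=None, patch_px: int | None = None,
            prob_threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Functional inference: (probability map, binary mask) for one image."""
    if run_config is not None:
        patch_px = run_config.patch_size_px
        prob_threshold = run_config.prob_threshold
    patch_px = patch_px or 256
    seg = UNetSegmenter(in_channels=model.config.in_channels,
                        kernels_per_level=model.config.kernels_per_level,
                        prob_threshold=prob_threshold, patch_px=patch_px)
    seg.model_ = model
    prob = seg.predict_proba(image)
    return prob, (prob > prob_threshold).astype(np.uint8)
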