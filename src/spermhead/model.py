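"""The sperm-head CNN: a multi-branch, densely-composed architecture.

The network is built from two composite units.  A *dense multi-branch
block* (Block D) applies a pre-activated 1x1 bottleneck convolution
(128 filters), feeds the result through parallel pre-activated 5x5 and
3x3 convolutions (32 filters each), adds the two branches element-wise,
and concatenates the 32-channel sum onto the block input — so every
block grows the channel count by the branch width, DenseNet-style.  A
*transition block* (Block E) halves the channel count with a
pre-activated 1x1 convolution and downsamples 2x2.  Four components
repeat Block D 3, 4, 6 and 3 times, each followed by one transition;
with the stem convolution this yields 1 + 3*(3+4+6+3) + 4 = 53
convolutional layers.  Every convolution is preceded by batch
normalization and LeakyReLU; classification is by global average
pooling into an L2-regularized dense softmax layer.

Training uses Adam with inverse-time learning-rate decay and
categorical cross-entropy, and the returned weights are those of the
epoch with the lowest development-set loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .nn import (Adam, AvgPool2x2, BatchNorm, Conv2d, Dense, GlobalAvgPool,
                 Layer, LeakyReLU, softmax, softmax_cross_entropy)

__all__ = [
    "ArchitectureConfig", "TrainingConfig", "TrainedModel", "SpermHeadNet",
    "SpermHeadCNNClassifier", "build_model", "count_conv_layers", "train",
    "predict_proba", "DivergenceError", "SMALL_ARCHITECTURE",
]


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class ArchitectureConfig:
    """Structural hyperparameters of the network."""

    num_classes: int = 5
    stem_filters: int = 64
    bottleneck_filters: int = 128
    branch_filters: int = 32
    repetitions: tuple[int, ...] = (3, 4, 6, 3)
    transition_ratio: float = 0.5
    leaky_slope: float = 0.3
    l2_lambda: float = 0.005

    def __post_init__(self) -> None:
        if min(self.num_classes, self.stem_filters, self.bottleneck_filters,
               self.branch_filters) < 1:
            raise ValueError("all filter/class counts must be >= 1")
        if not (0 < self.transition_ratio <= 1):
            raise ValueError("transition_ratio must be in (0, 1]")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be >= 0")
        if not self.repetitions or min(self.repetitions) < 1:
            raise ValueError("repetitions must be a non-empty tuple of positives")

    @property
    def conv_layer_count(self) -> int:
        """Stem + three convolutions per dense block + one per transition."""
        return 1 + 3 * sum(self.repetitions) + len(self.repetitions)


#: Scaled-down preset used for CPU-sized experiments and tests.
SMALL_ARCHITECTURE = dict(stem_filters=16, bottleneck_filters=32,
                          branch_filters=8, repetitions=(1, 1, 2, 1))


@dataclass
class TrainingConfig:
    """Optimizer and loop settings (defaults: the 35-px greyscale preset)."""

    learning_rate: float = 5e-4
    decay: float = 0.0055
    beta_1: float = 0.9
    beta_2: float = 0.999
    batch_size: int = 1024
    epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if not (0 < self.beta_1 < 1 and 0 < self.beta_2 < 1):
            raise ValueError("beta_1 and beta_2 must lie in (0, 1)")


class _BlockD:
    """Pre-activated bottleneck -> parallel 5x5/3x3 branches -> add -> concat."""

    def __init__(self, in_channels: int, cfg: ArchitectureConfig,
                 rng: np.random.Generator) -> None:
        self.in_channels = in_channels
        self.bn1 = BatchNorm(in_channels)
        self.act1 = LeakyReLU(cfg.leaky_slope)
        self.conv1 = Conv2d(in_channels, cfg.bottleneck_filters, 1, rng)
        self.bn2 = BatchNorm(cfg.bottleneck_filters)
        self.act2 = LeakyReLU(cfg.leaky_slope)
        self.conv5 = Conv2d(cfg.bottleneck_filters, cfg.branch_filters, 5, rng)
        self.conv3 = Conv2d(cfg.bottleneck_filters, cfg.branch_filters, 3, rng)
        self.out_channels = in_channels + cfg.branch_filters

    def layers(self) -> list[Layer]:
        return [self.bn1, self.act1, self.conv1, self.bn2, self.act2,
                self.conv5, self.conv3]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        t = self.act1.forward(self.bn1.forward(x, training), training)
        a = self.conv1.forward(t, training)
        u = self.act2.forward(self.bn2.forward(a, training), training)
        branch = self.conv5.forward(u, training) + self.conv3.forward(u, training)
        return np.concatenate([x, branch], axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx_skip = dy[..., :self.in_channels]
        dbranch = np.ascontiguousarray(dy[..., self.in_channels:])
        du = self.conv5.backward(dbranch) + self.conv3.backward(dbranch)
        da = self.bn2.backward(self.act2.backward(du))
        dt = self.conv1.backward(da)
        return dx_skip + self.bn1.backward(self.act1.backward(dt))


class _BlockE:
    """Pre-activated 1x1 channel-halving convolution + 2x2 average pool."""

    def __init__(self, in_channels: int, cfg: ArchitectureConfig,
                 rng: np.random.Generator) -> None:
        self.bn = BatchNorm(in_channels)
        self.act = LeakyReLU(cfg.leaky_slope)
        self.out_channels = max(1, int(in_channels * cfg.transition_ratio))
        self.conv = Conv2d(in_channels, self.out_channels, 1, rng)
        self.pool = AvgPool2x2()

    def layers(self) -> list[Layer]:
        return [self.bn, self.act, self.conv, self.pool]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        t = self.act.forward(self.bn.forward(x, training), training)
        return self.pool.forward(self.conv.forward(t, training), training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dt = self.conv.backward(self.pool.backward(dy))
        return self.bn.backward(self.act.backward(dt))


class SpermHeadNet:
    """The assembled network graph with explicit forward/backward."""

    def __init__(self, config: ArchitectureConfig, input_shape: tuple[int, int, int],
                 seed: int = 0) -> None:
        h, w, c = input_shape
        if h < 16 or w < 16:
            raise ValueError("input spatial dims must be >= 16")
        if h // 2 ** len(config.repetitions) < 1 or w // 2 ** len(config.repetitions) < 1:
            raise ValueError("input too small for the downsampling schedule")
        self.config = config
        self.input_shape = input_shape
        rng = np.random.default_rng(seed)
        # the stem is pre-activated like every other convolution
        self.stem_bn = BatchNorm(c)
        self.stem_act = LeakyReLU(config.leaky_slope)
        self.stem = Conv2d(c, config.stem_filters, 3, rng)
        self.components: list[list[_BlockD]] = []
        self.transitions: list[_BlockE] = []
        channels = config.stem_filters
        self.channel_trace: list[int] = [channels]
        for reps in config.repetitions:
            blocks = []
            for _ in range(reps):
                blk = _BlockD(channels, config, rng)
                channels = blk.out_channels
                blocks.append(blk)
            self.components.append(blocks)
            self.channel_trace.append(channels)
            tr = _BlockE(channels, config, rng)
            channels = tr.out_channels
            self.transitions.append(tr)
            self.channel_trace.append(channels)
        self.head_bn = BatchNorm(channels)
        self.head_act = LeakyReLU(config.leaky_slope)
        self.gap = GlobalAvgPool()
        self.dense = Dense(channels, config.num_classes, rng, l2=config.l2_lambda)

    # -- structure ---------------------------------------------------------
    def layers(self) -> list[Layer]:
        out: list[Layer] = [self.stem_bn, self.stem_act, self.stem]
        for blocks, tr in zip(self.components, self.transitions):
            for blk in blocks:
                out.extend(blk.layers())
            out.extend(tr.layers())
        out.extend([self.head_bn, self.head_act, self.gap, self.dense])
        return out

    def conv_layers_per_component(self) -> list[int]:
        """Convolution count of each component's dense blocks (three per
        block; the transition convolutions are tallied separately)."""
        return [sum(sum(isinstance(ly, Conv2d) for ly in blk.layers())
                    for blk in blocks)
                for blocks in self.components]

    # -- compute -----------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=nn.DTYPE)
        z = self.stem_act.forward(self.stem_bn.forward(x, training), training)
        z = self.stem.forward(z, training)
        for blocks, tr in zip(self.components, self.transitions):
            for blk in blocks:
                z = blk.forward(z, training)
            z = tr.forward(z, training)
        z = self.head_act.forward(self.head_bn.forward(z, training), training)
        return self.dense.forward(self.gap.forward(z, training), training)

    def backward(self, dlogits: np.ndarray) -> None:
        dz = self.gap.backward(self.dense.backward(dlogits))
        dz = self.head_bn.backward(self.head_act.backward(dz))
        for blocks, tr in zip(reversed(self.components), reversed(self.transitions)):
            dz = tr.backward(dz)
            for blk in reversed(blocks):
                dz = blk.backward(dz)
        self.stem_bn.backward(self.stem_act.backward(self.stem.backward(dz)))

    # -- weights -----------------------------------------------------------
    def get_state(self) -> list:
        state = []
        for ly in self.layers():
            entry = {k: v.copy() for k, v in ly.params.items()}
            if isinstance(ly, BatchNorm):
                entry["running_mean"] = ly.running_mean.copy()
                entry["running_var"] = ly.running_var.copy()
            state.append(entry)
        return state

    def set_state(self, state: list) -> None:
        for ly, entry in zip(self.layers(), state):
            for k in ly.params:
                ly.params[k][...] = entry[k]
            if isinstance(ly, BatchNorm):
                ly.running_mean[...] = entry["running_mean"]
                ly.running_var[...] = entry["running_var"]


def build_model(config: ArchitectureConfig, input_shape: tuple[int, int, int],
                seed: int = 0) -> SpermHeadNet:
    """Construct the network with LeCun-uniform weights at ``seed``."""
    return SpermHeadNet(config, input_shape, seed=seed)


def count_conv_layers(model: SpermHeadNet) -> int:
    """Number of convolution operations, by structural traversal."""
    return sum(isinstance(ly, Conv2d) for ly in model.layers())


@dataclass
class TrainedModel:
    architecture: ArchitectureConfig
    net: SpermHeadNet
    history: list[dict] = field(default_factory=list)
    best_epoch: int = 0  # 1-based


def _forward_batched(net: SpermHeadNet, x: np.ndarray, batch: int = 32) -> np.ndarray:
    outs = [net.forward(x[i:i + batch], training=False) for i in range(0, len(x), batch)]
    return np.concatenate(outs, axis=0)


def _eval_loss_acc(net: SpermHeadNet, x: np.ndarray, onehot: np.ndarray) -> tuple[float, float]:
    logits = _forward_batched(net, x)
    loss, _ = softmax_cross_entropy(logits, onehot)
    loss += net.dense.l2_penalty()
    acc = float((logits.argmax(axis=1) == onehot.argmax(axis=1)).mean())
    return loss, acc


def train(net: SpermHeadNet, train_data: tuple[np.ndarray, np.ndarray],
          dev_data: tuple[np.ndarray, np.ndarray] | None,
          config: TrainingConfig) -> TrainedModel:
    """Run the training loop; keep the weights of the lowest-dev-loss epoch.

    ``train_data``/``dev_data`` are ``(images, onehot_labels)`` pairs with
    images shaped (n, H, W, C).  Without a dev set, selection falls back to
    the lowest training loss.
    """
    x, y = train_data
    if len(x) == 0:
        raise ValueError("empty training set")
    if y.shape[1] != net.config.num_classes:
        raise ValueError("label width does not match num_classes")
    opt = Adam([ly for ly in net.layers()], lr=config.learning_rate,
               decay=config.decay, beta_1=config.beta_1, beta_2=config.beta_2)
    rng = np.random.default_rng(config.seed)
    history: list[dict] = []
    best = (np.inf, None, 0)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(x))
        ep_loss, ep_correct = 0.0, 0
        for start in range(0, len(x), config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x[idx], y[idx]
            logits = net.forward(xb, training=True)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            loss += net.dense.l2_penalty()
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            net.backward(dlogits)
            opt.step()
            ep_loss += loss * len(idx)
            ep_correct += int((logits.argmax(axis=1) == yb.argmax(axis=1)).sum())
        entry = {"epoch": epoch, "train_loss": ep_loss / len(x),
                 "train_acc": ep_correct / len(x), "lr": opt.current_lr}
        if dev_data is not None and len(dev_data[0]):
            dl, da = _eval_loss_acc(net, dev_data[0], dev_data[1])
            entry["dev_loss"], entry["dev_acc"] = dl, da
            select_on = dl
        else:
            entry["dev_loss"] = entry["dev_acc"] = float("nan")
            select_on = entry["train_loss"]
        history.append(entry)
        if select_on < best[0]:
            best = (select_on, net.get_state(), epoch)
    if best[1] is not None:
        net.set_state(best[1])
    return TrainedModel(architecture=net.config, net=net, history=history,
                        best_epoch=best[2])


def predict_proba(model: TrainedModel | SpermHeadNet, images: np.ndarray,
                  batch: int = 32) -> np.ndarray:
    """Class-probability matrix (rows sum to 1); labels are row argmax."""
    net = model.net if isinstance(model, TrainedModel) else model
    images = np.asarray(images, dtype=nn.DTYPE)
    if images.ndim == 3:
        images = images[None]
    if images.shape[1:] != net.input_shape:
        raise ValueError(f"expected images of shape {net.input_shape}, "
                         f"got {images.shape[1:]}")
    return softmax(_forward_batched(net, images, batch=batch).astype(np.float64))


class SpermHeadCNNClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn estimator wrapping the multi-branch sperm-head CNN.

    Parameters mirror :class:`ArchitectureConfig` and
    :class:`TrainingConfig`; fitted state lives in trailing-underscore
    attributes.  ``X`` is an array of images shaped ``(n, H, W)`` or
    ``(n, H, W, 3)`` with values in [0, 1]; greyscale input is replicated
    to three channels.
    """

    def __init__(self, stem_filters: int = 64, bottleneck_filters: int = 128,
                 branch_filters: int = 32, repetitions: tuple[int, ...] = (3, 4, 6, 3),
                 transition_ratio: float = 0.5, leaky_slope: float = 0.3,
                 l2_lambda: float = 0.005, learning_rate: float = 5e-4,
                 decay: float = 0.0055, beta_1: float = 0.9, beta_2: float = 0.999,
                 batch_size: int = 1024, epochs: int = 50, random_state: int = 0):
        self.stem_filters = stem_filters
        self.bottleneck_filters = bottleneck_filters
        self.branch_filters = branch_filters
        self.repetitions = repetitions
        self.transition_ratio = transition_ratio
        self.leaky_slope = leaky_slope
        self.l2_lambda = l2_lambda
        self.learning_rate = learning_rate
        self.decay = decay
        self.beta_1 = beta_1
        self.beta_2 = beta_2
        self.batch_size = batch_size
        self.epochs = epochs
        self.random_state = random_state

    @staticmethod
    def _as_images(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=nn.DTYPE)
        if X.ndim == 3:
            X = np.repeat(X[..., None], 3, axis=-1)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError("X must be (n, H, W) or (n, H, W, 3)")
        return X

    def _encode(self, y: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.classes_, y)
        if not np.array_equal(self.classes_[idx], np.asarray(y)):
            raise ValueError("y contains labels unseen in classes_")
        onehot = np.zeros((len(y), len(self.classes_)), dtype=nn.DTYPE)
        onehot[np.arange(len(y)), idx] = 1.0
        return onehot

    def fit(self, X, y, dev=None):
        """Fit on images X / labels y; ``dev=(X_dev, y_dev)`` enables
        lowest-dev-loss checkpoint selection."""
        X = self._as_images(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        arch = ArchitectureConfig(
            num_classes=len(self.classes_), stem_filters=self.stem_filters,
            bottleneck_filters=self.bottleneck_filters,
            branch_filters=self.branch_filters, repetitions=tuple(self.repetitions),
            transition_ratio=self.transition_ratio, leaky_slope=self.leaky_slope,
            l2_lambda=self.l2_lambda)
        tcfg = TrainingConfig(
            learning_rate=self.learning_rate, decay=self.decay, beta_1=self.beta_1,
            beta_2=self.beta_2, batch_size=self.batch_size, epochs=self.epochs,
            seed=self.random_state)
        net = build_model(arch, X.shape[1:], seed=self.random_state)
        dev_arrays = None
        if dev is not None:
            dev_arrays = (self._as_images(dev[0]), self._encode(np.asarray(dev[1])))
        trained = train(net, (X, self._encode(y)), dev_arrays, tcfg)
        self.net_ = trained.net
        self.history_ = trained.history
        self.best_epoch_ = trained.best_epoch
        self.architecture_ = arch
        self.n_conv_layers_ = count_conv_layers(trained.net)
        return self

    def predict_proba(self, X) -> np.ndarray:
        return predict_proba(self.net_, self._as_images(X))

    def predict(self, X) -> np.ndarray:
        # lowest-index tie-break is argmax's native behaviour
        return self.classes_[self.predict_proba(X).argmax(axis=1)]
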