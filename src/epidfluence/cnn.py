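"""Four-branch convolutional classifier for comparison-map stacks.

The DD, luminance, contrast and structure maps of a baseline/error pair
feed four independent feature-extractor branches.  Each branch is a
VGG-style stack — 13 convolutional layers in blocks of {2,2,3,3,3}, four
2x2 max-pooling layers that halve the spatial size and double the
channel count, and one global average-pooling layer that reduces each
channel to its mean.  The four branch vectors are concatenated and
passed through two fully connected layers emitting ``n`` class scores;
the predicted class is the arg-max of the softmax probabilities.

A reduced variant (128x128 inputs, blocks {2,2,3}, two max pools) keeps
the same construction at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .comparison import ComparisonMaps
from . import nn

#: canonical branch order
BRANCH_MAPS = ("dd", "luminance", "contrast", "structure")


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description for the four-branch network.

    ``conv_blocks`` gives the number of convolutions per block; a max
    pool follows every block except the last, and the last block ends in
    the global average pool.  Channel width doubles block to block
    starting from ``base_width``.
    """

    n_classes: int
    input_size: int = 512
    conv_blocks: tuple[int, ...] = (2, 2, 3, 3, 3)
    base_width: int = 8
    fc_hidden: int = 64

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        stride = 2 ** self.n_max_pools
        if self.input_size % stride:
            raise ValueError(
                f"input size {self.input_size} not divisible by {stride}"
            )

    @property
    def n_conv(self) -> int:
        return sum(self.conv_blocks)

    @property
    def n_max_pools(self) -> int:
        return len(self.conv_blocks) - 1

    @property
    def block_widths(self) -> tuple[int, ...]:
        return tuple(self.base_width * 2**i for i in range(len(self.conv_blocks)))

    @classmethod
    def default(cls, n_classes: int) -> "NetworkSpec":
        """The full-scale architecture: 13 conv / 4 max-pool / 1 avg-pool."""
        return cls(n_classes=n_classes)

    @classmethod
    def reduced(
        cls, n_classes: int, input_size: int = 128, base_width: int = 4
    ) -> "NetworkSpec":
        """Desk-scale variant with proportionally fewer pooling stages."""
        return cls(
            n_classes=n_classes,
            input_size=input_size,
            conv_blocks=(2, 2, 3),
            base_width=base_width,
            fc_hidden=32,
        )


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings (rectifier activations, Adam, cross-entropy)."""

    epochs: int = 50
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0
    #: stop as soon as full-training-set accuracy reaches this level
    early_stop_train_acc: float | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch size must be >= 1")


class FourBranchCNN:
    """The assembled network: four extractor branches plus the head."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        self.spec = spec
        self.branches = [self._build_branch(rng) for _ in range(4)]
        feat = 4 * spec.block_widths[-1]
        self.head = nn.Sequential(
            [
                nn.Dense(feat, spec.fc_hidden, rng),
                nn.ReLU(),
                nn.Dense(spec.fc_hidden, spec.n_classes, rng),
            ]
        )

    def _build_branch(self, rng: np.random.Generator) -> nn.Sequential:
        spec = self.spec
        layers: list[nn.Layer] = []
        c_in = 1
        for b, n_conv in enumerate(spec.conv_blocks):
            width = spec.block_widths[b]
            for _ in range(n_conv):
                layers.append(nn.Conv3x3(c_in, width, rng))
                layers.append(nn.ReLU())
                c_in = width
            if b < spec.n_max_pools:
                layers.append(nn.MaxPool2())
        layers.append(nn.GlobalAvgPool())
        return nn.Sequential(layers)

    # -- introspection ----------------------------------------------------
    def layer_census(self) -> dict[str, int]:
        """Per-branch layer counts plus the head's dense-layer count."""
        b = self.branches[0].layers
        return {
            "branches": len(self.branches),
            "conv_per_branch": sum(isinstance(l, nn.Conv3x3) for l in b),
            "max_pool_per_branch": sum(isinstance(l, nn.MaxPool2) for l in b),
            "avg_pool_per_branch": sum(isinstance(l, nn.GlobalAvgPool) for l in b),
            "fully_connected": sum(
                isinstance(l, nn.Dense) for l in self.head.layers
            ),
        }

    # -- forward / backward ----------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        s = self.spec.input_size
        if x.ndim != 4 or x.shape[1] != 4 or x.shape[2:] != (s, s):
            raise ValueError(
                f"expected input of shape (N, 4, {s}, {s}), got {x.shape}"
            )

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._check_input(x)
        feats = [
            br.forward(x[:, k, :, :, None].astype(np.float32))
            for k, br in enumerate(self.branches)
        ]
        self._feat_width = feats[0].shape[1]
        return self.head.forward(np.concatenate(feats, axis=1))

    def backward(self, grad_logits: np.ndarray) -> None:
        g = self.head.backward(grad_logits)
        w = self._feat_width
        for k, br in enumerate(self.branches):
            br.backward(g[:, k * w : (k + 1) * w])

    @property
    def params(self) -> list[np.ndarray]:
        out = [p for br in self.branches for p in br.params]
        return out + self.head.params

    @property
    def grads(self) -> list[np.ndarray]:
        out = [g for br in self.branches for g in br.grads]
        return out + self.head.grads


@dataclass
class CnnModel:
    """A trained network plus its label coding and training trace."""

    network: FourBranchCNN
    classes: np.ndarray
    spec: NetworkSpec
    config: TrainConfig
    loss_trace: list[float] = field(default_factory=list)


def build_network(n_classes: int, spec: NetworkSpec | None = None,
                  seed: int = 0) -> FourBranchCNN:
    spec = replace(spec, n_classes=n_classes) if spec else NetworkSpec(n_classes)
    return FourBranchCNN(spec, np.random.default_rng(seed))


def normalize_stack(maps: ComparisonMaps, size: int | None = None) -> np.ndarray:
    """Build the (4, H, W) network input from one comparison-map set.

    Each branch map is standardized per sample — zero mean, unit variance
    over its own pixels, clipped to +-8 sigma.  The SSIM component maps
    concentrate within a sliver of their nominal [-1, 1] range (a small
    shift leaves most windows nearly identical), so a fixed range scaling
    would hand the network near-constant inputs; per-sample
    standardization gives every branch O(1) contrast at any noise level
    and needs no labels, so it applies identically at train and test
    time.  ``size`` optionally block-averages the maps down (the crop
    side must be an integer multiple of it).
    """
    stack = np.stack(
        [np.asarray(maps.as_dict()[name], dtype=np.float64) for name in BRANCH_MAPS]
    )
    if size is not None and size != stack.shape[-1]:
        h = stack.shape[1]
        if h % size:
            raise ValueError(f"cannot reduce {h} to {size} by block averaging")
        f = h // size
        stack = stack.reshape(4, size, f, size, f).mean(axis=(2, 4))
    mu = stack.mean(axis=(1, 2), keepdims=True)
    sd = stack.std(axis=(1, 2), keepdims=True)
    stack = np.clip((stack - mu) / (sd + 1e-8), -8.0, 8.0)
    return stack.astype(np.float32)


def train_cnn(
    stacks: np.ndarray,
    labels: np.ndarray,
    spec: NetworkSpec,
    cfg: TrainConfig | None = None,
) -> CnnModel:
    """Minimise softmax cross-entropy over the training stacks with Adam.

    ``stacks``: (N, 4, H, W) normalized inputs; ``labels``: class labels
    (any integer coding).  Deterministic for a fixed ``cfg.seed``.
    Raises on divergence (non-finite loss).
    """
    cfg = cfg or TrainConfig()
    y = np.asarray(labels)
    classes = np.unique(y)
    y_idx = np.searchsorted(classes, y)
    spec = replace(spec, n_classes=max(spec.n_classes, len(classes)))

    rng = np.random.default_rng(cfg.seed)
    net = FourBranchCNN(spec, rng)
    opt = nn.Adam(net.params, net.grads, lr=cfg.learning_rate)
    n = len(y_idx)
    trace: list[float] = []
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = net.forward(stacks[idx])
            loss, grad = nn.cross_entropy_grad(logits, y_idx[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {_epoch}: loss={loss}"
                )
            net.backward(grad)
            opt.step()
            epoch_loss += loss * len(idx)
        trace.append(epoch_loss / n)
        if cfg.early_stop_train_acc is not None:
            model = CnnModel(net, classes, spec, cfg, trace)
            pred, _ = predict_classes(model, stacks)
            if float(np.mean(pred == y)) >= cfg.early_stop_train_acc:
                break
    return CnnModel(net, classes, spec, cfg, trace)


def predict_classes(
    model: CnnModel, stacks: np.ndarray, batch_size: int = 32
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted class labels and softmax score vectors (rows sum to 1)."""
    scores = []
    for start in range(0, len(stacks), batch_size):
        logits = model.network.forward(stacks[start : start + batch_size])
        scores.append(nn.softmax(logits.astype(np.float64)))
    sc = np.concatenate(scores, axis=0)
    return model.classes[np.argmax(sc, axis=1)], sc


def predict_cnn(model: CnnModel, maps: ComparisonMaps) -> tuple[int, np.ndarray]:
    """Classify a single comparison-map set; returns (class, score vector)."""
    stack = normalize_stack(maps, size=model.spec.input_size)
    cls, sc = predict_classes(model, stack[None])
    return int(cls[0]), sc[0]
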