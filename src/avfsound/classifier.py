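"""The concatenated stenosis classifier: ResNet50 + ANN.

Two branches are fused: a bottleneck residual network (ResNet50 by
default) consuming the STFT spectrogram image of a cardiac cycle, and a
small fully connected ANN consuming its band-limited sample-entropy
vector. Their output feature vectors are concatenated and passed
through a dense head ending in a single sigmoid unit — stenosis (S)
versus normal (N).

The tunable structure maps onto five two-level screening factors:
A = ANN hidden layers (2 or 3), B = ANN nodes (4 or 10), C = filtering
method (traditional band-pass vs EMD), D = head layers (2 or 4),
E = head nodes (4 or 10).

The standard ResNet50 layer accounting used throughout counts the stem
convolution, the max-pool stage, and 3 convolutions per bottleneck
block: 50 = 1 + 1 + [3+3x2] + [3+3x3] + [3+3x5] + [3+3x2] for stage
depths (3, 4, 6, 3).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn
from ._nn import Adam, BatchNorm2D, Bottleneck, Conv2D, Dense, GlobalAvgPool, MaxPool2D, ReLU, Sequential


@dataclass(frozen=True)
class ResNetSpec:
    """Architecture schedule of the residual image branch.

    ``stage_blocks`` are the bottleneck-block counts of the four stages
    (ResNet50: 3, 4, 6, 3); ``base_width`` is the stem channel count
    (64 for the full network), each stage doubling it; every bottleneck
    expands channels 4x, so the output feature width is 32*base_width.
    """

    stage_blocks: tuple[int, int, int, int] = (3, 4, 6, 3)
    base_width: int = 64

    @property
    def feature_dim(self) -> int:
        return 32 * self.base_width


#: Desk-scale variant: one block per stage at a quarter width (512-d features).
REDUCED_SPEC = ResNetSpec(stage_blocks=(1, 1, 1, 1), base_width=16)
FULL50_SPEC = ResNetSpec()


def stage_conv_counts(spec: ResNetSpec) -> list[int]:
    """Per-stage convolutional-layer counts, 3 + 3*(blocks-1) each."""
    return [3 + 3 * (b - 1) for b in spec.stage_blocks]


def count_conv_layers(spec: ResNetSpec) -> int:
    """Total layer count: stem (1) + max-pool stage (1) + stage terms."""
    return 1 + 1 + sum(stage_conv_counts(spec))


@dataclass
class ModelConfig:
    """Everything needed to build and train one concatenated model."""

    ann_layers: int = 2          # factor A: 2 or 3
    ann_nodes: int = 4           # factor B: 4 or 10
    filtering: str = "EMD"       # factor C: "TF" or "EMD"
    head_layers: int = 2         # factor D: 2 or 4
    head_nodes: int = 4          # factor E: 4 or 10
    image_size_px: int = 224
    resnet_variant: str = "full50"   # "full50" or "reduced"
    seed: int = 0
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-4
    class_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.ann_layers < 1 or self.head_layers < 1:
            raise ValueError("layer counts must be >= 1")
        if self.ann_nodes < 1 or self.head_nodes < 1:
            raise ValueError("node counts must be >= 1")
        if self.filtering not in ("TF", "EMD"):
            raise ValueError("filtering must be 'TF' or 'EMD'")
        if self.resnet_variant not in ("full50", "reduced"):
            raise ValueError("resnet_variant must be 'full50' or 'reduced'")

    @property
    def resnet_spec(self) -> ResNetSpec:
        return FULL50_SPEC if self.resnet_variant == "full50" else REDUCED_SPEC


class ResNetBackbone:
    """Bottleneck residual network producing a global feature vector.

    Stem 7x7/2 convolution -> 3x3/2 max-pool -> four bottleneck stages
    (strides 1, 2, 2, 2) -> global average pool. No classification
    layer: the concatenation head classifies.
    """

    MIN_IMAGE = 8

    def __init__(self, spec: ResNetSpec, image_size_px: int, rng: np.random.Generator):
        if image_size_px < self.MIN_IMAGE:
            raise ValueError(
                f"image size {image_size_px} too small for the stride schedule "
                f"(minimum {self.MIN_IMAGE})"
            )
        self.spec = spec
        w = spec.base_width
        layers: list[_nn.Layer] = [
            Conv2D(3, w, 7, stride=2, pad=3, rng=rng),
            BatchNorm2D(w),
            ReLU(),
            MaxPool2D(3, 2, 1),
        ]
        cin = w
        for stage, blocks in enumerate(spec.stage_blocks):
            cmid = w * (2**stage)
            for b in range(blocks):
                stride = 2 if (stage > 0 and b == 0) else 1
                layers.append(Bottleneck(cin, cmid, stride, rng))
                cin = 4 * cmid
        layers.append(GlobalAvgPool())
        self.net = Sequential(layers)
        self.out_dim = cin

    def params(self):
        return self.net.params()

    def forward(self, images: np.ndarray, train: bool) -> np.ndarray:
        return self.net.forward(images, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.net.backward(dy)


class ANNBranch:
    """Fully connected branch on the entropy features: ``n_layers``
    hidden layers of ``n_nodes`` ReLU units; outputs the last hidden
    activation (width ``n_nodes``)."""

    def __init__(self, n_layers: int, n_nodes: int, input_dim: int, rng: np.random.Generator):
        layers: list[_nn.Layer] = []
        din = input_dim
        for _ in range(n_layers):
            layers += [Dense(din, n_nodes, rng), ReLU()]
            din = n_nodes
        self.net = Sequential(layers)
        self.out_dim = n_nodes
        self.input_dim = input_dim

    def params(self):
        return self.net.params()

    def forward(self, feats: np.ndarray, train: bool) -> np.ndarray:
        return self.net.forward(feats, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.net.backward(dy)


class ConcatenatedModel:
    """Both branches fused by feature concatenation + dense head.

    The head has ``head_layers`` ReLU layers of ``head_nodes`` units and
    a single output unit; :meth:`forward` returns logits, with the
    sigmoid applied at prediction time.
    """

    def __init__(self, resnet: ResNetBackbone, ann: ANNBranch,
                 head_layers: int, head_nodes: int, rng: np.random.Generator):
        self.resnet = resnet
        self.ann = ann
        self.concat_dim = resnet.out_dim + ann.out_dim
        layers: list[_nn.Layer] = []
        din = self.concat_dim
        for _ in range(head_layers):
            layers += [Dense(din, head_nodes, rng), ReLU()]
            din = head_nodes
        layers.append(Dense(din, 1, rng))
        self.head = Sequential(layers)

    def params(self):
        return self.resnet.params() + self.ann.params() + self.head.params()

    def forward(self, images: np.ndarray, feats: np.ndarray, train: bool) -> np.ndarray:
        a = self.resnet.forward(images, train)
        b = self.ann.forward(feats, train)
        z = self.head.forward(np.concatenate([a, b], axis=1), train)
        return z[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits[:, None])
        self.resnet.backward(d[:, : self.resnet.out_dim])
        self.ann.backward(d[:, self.resnet.out_dim :])

    def predict_proba(self, images: np.ndarray, feats: np.ndarray) -> np.ndarray:
        return _nn.sigmoid(self.forward(images, feats, train=False))


def build_resnet(spec: ResNetSpec, image_size_px: int,
                 rng: np.random.Generator | None = None) -> ResNetBackbone:
    return ResNetBackbone(spec, image_size_px, rng or np.random.default_rng(0))


def build_ann(n_layers: int, n_nodes: int, input_dim: int,
              rng: np.random.Generator | None = None) -> ANNBranch:
    if n_layers < 1 or n_nodes < 1 or input_dim < 1:
        raise ValueError("layers, nodes and input_dim must all be >= 1")
    return ANNBranch(n_layers, n_nodes, input_dim, rng or np.random.default_rng(0))


def build_concatenated(resnet: ResNetBackbone, ann: ANNBranch,
                       head_layers: int, head_nodes: int,
                       rng: np.random.Generator | None = None) -> ConcatenatedModel:
    return ConcatenatedModel(resnet, ann, head_layers, head_nodes,
                             rng or np.random.default_rng(0))


@dataclass
class TrainedModel:
    config: ModelConfig
    model: ConcatenatedModel
    training_history: list[dict]
    feat_mean: np.ndarray
    feat_std: np.ndarray
    class_threshold: float = 0.5


def _as_nchw(images: np.ndarray) -> np.ndarray:
    images = np.asarray(images, dtype=np.float64)
    if images.ndim != 4:
        raise ValueError(f"expected 4-D image array, got shape {images.shape}")
    if images.shape[-1] in (1, 3) and images.shape[1] not in (1, 3):
        images = images.transpose(0, 3, 1, 2)
    return images


def train(images: np.ndarray, features: np.ndarray, labels: np.ndarray,
          cfg: ModelConfig) -> TrainedModel:
    """Fit the concatenated model by minibatch Adam on binary
    cross-entropy. Fully deterministic under ``cfg.seed``.

    ``images``: (n, H, W, 3) or (n, 3, H, W) in [0, 1];
    ``features``: (n, d) entropy vectors (z-scored internally using
    training statistics); ``labels``: (n,) in {0, 1}, 1 = stenosis.
    """
    images = _as_nchw(images)
    feats = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if len(images) == 0:
        raise ValueError("empty training set")
    if not (len(images) == len(feats) == len(y)):
        raise ValueError("images, features and labels must align one-to-one")
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")

    feat_mean = feats.mean(axis=0)
    feat_std = feats.std(axis=0)
    feat_std[feat_std == 0] = 1.0
    feats = (feats - feat_mean) / feat_std

    rng = np.random.default_rng(cfg.seed)
    resnet = build_resnet(cfg.resnet_spec, cfg.image_size_px, rng)
    ann = build_ann(cfg.ann_layers, cfg.ann_nodes, feats.shape[1], rng)
    model = build_concatenated(resnet, ann, cfg.head_layers, cfg.head_nodes, rng)
    opt = Adam(model.params(), lr=cfg.learning_rate)

    n = len(y)
    history: list[dict] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = model.forward(images[idx], feats[idx], train=True)
            loss, dlogits = _nn.bce_with_logits(logits, y[idx])
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
            correct += int(np.sum((logits >= 0) == (y[idx] >= 0.5)))
        history.append({"epoch": epoch, "loss": epoch_loss / n, "accuracy": correct / n})
    return TrainedModel(config=cfg, model=model, training_history=history,
                        feat_mean=feat_mean, feat_std=feat_std,
                        class_threshold=cfg.class_threshold)


def predict(tm: TrainedModel, images: np.ndarray, features: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle probabilities and labels (1 = stenosis).

    A cycle is labeled stenotic when its probability is >= the class
    threshold — ties go to the positive class.
    """
    images = _as_nchw(images)
    feats = np.asarray(features, dtype=np.float64)
    if len(images) != len(feats):
        raise ValueError("images and features must align one-to-one")
    if feats.ndim != 2 or feats.shape[1] != tm.feat_mean.shape[0]:
        raise ValueError(
            f"feature width {feats.shape} does not match training width "
            f"{tm.feat_mean.shape[0]}"
        )
    feats = (feats - tm.feat_mean) / tm.feat_std
    probs = tm.model.predict_proba(images, feats)
    return (probs >= tm.class_threshold).astype(int), probs
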