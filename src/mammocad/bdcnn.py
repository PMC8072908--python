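"""Mass/background patch classifier (BD-CNN).

A small CNN that maps a 200x200 grayscale patch to P(background), P(mass).
Three convolutional blocks (conv -> batch-norm -> ReLU -> 2x2 max-pool) with
128 kernels each of size 5x5, 3x3, 3x3, a flattening layer, a 1024-node
fully connected layer, and a 2-way softmax.  Training is plain SGD on
cross-entropy at learning rate 1e-4 and stops after 200 epochs or as soon as
the training accuracy reaches 100%.  The same network doubles as the fitness
function for PSO bounding-box refinement: fitness = P(mass).

Patch intensities are assumed on an 8-bit scale and are divided by 255
before entering the network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from . import nn

__all__ = [
    "BDCNNConfig",
    "PatchDataset",
    "Model",
    "TrainingHistory",
    "build_model",
    "train",
    "predict_proba",
    "predict_mass_probability",
    "save_checkpoint",
    "load_checkpoint",
]

BACKGROUND, MASS = 0, 1
INTENSITY_SCALE = 255.0


@dataclass(frozen=True)
class BDCNNConfig:
    """Architecture and training hyperparameters.

    Defaults follow the published recipe: 200x200 input, three blocks of 128
    kernels (5x5, 3x3, 3x3), FC-1024, softmax-2, SGD at lr 1e-4, stop at 200
    epochs or 100% training accuracy.  Batch size is unspecified in the
    recipe; 32 is used.
    """

    input_size: tuple[int, int] = (200, 200)
    block_kernels: tuple[int, ...] = (128, 128, 128)
    block_kernel_sizes: tuple[int, ...] = (5, 3, 3)
    fc_nodes: int = 1024
    n_classes: int = 2
    learning_rate: float = 1e-4
    max_epochs: int = 200
    stop_train_accuracy: float = 1.0
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if len(self.block_kernels) != len(self.block_kernel_sizes):
            raise ValueError("block_kernels and block_kernel_sizes must have equal length")
        h, w = self.input_size
        if h < 2 ** len(self.block_kernels) or w < 2 ** len(self.block_kernels):
            raise ValueError("input too small for the number of pooling stages")


@dataclass
class PatchDataset:
    """Labeled patches: (N, H, W) float32 on the 0..255 intensity scale;
    labels 0 = background, 1 = mass; provenance records (image id, box)."""

    patches: np.ndarray
    labels: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.patches = np.asarray(self.patches, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.patches.ndim != 3 or len(self.patches) != len(self.labels):
            raise ValueError("patches must be (N, H, W) with one label per patch")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class Model:
    net: nn.Sequential
    config: BDCNNConfig
    trained: bool = False
    _inference_net: nn.Sequential | None = None

    def n_parameters(self) -> int:
        return self.net.n_parameters()

    def inference_net(self) -> nn.Sequential:
        """Inference view of the network with batch norm folded into the
        preceding convolution's weights (exact under running statistics)."""
        if self._inference_net is None:
            self._inference_net = _fold_batchnorm(self.net)
        return self._inference_net


def _fold_batchnorm(net: nn.Sequential) -> nn.Sequential:
    layers: list[nn.Layer] = []
    src = net.layers
    i = 0
    while i < len(src):
        layer = src[i]
        nxt = src[i + 1] if i + 1 < len(src) else None
        if isinstance(layer, nn.Conv2d) and isinstance(nxt, nn.BatchNorm2d):
            scale = (nxt.gamma / np.sqrt(nxt.running_var + nxt.eps)).astype(np.float32)
            shift = (nxt.beta - nxt.running_mean * scale).astype(np.float32)
            folded = nn.Conv2d(layer.in_channels, layer.out_channels, layer.k,
                               np.random.default_rng(0), compute_dx=False)
            folded.weight = layer.weight * scale
            folded.bias = layer.bias * scale + shift
            layers.append(folded)
            i += 2
        elif isinstance(layer, (nn.ReLU, nn.MaxPool2d)):
            layers.append(type(layer)())
            i += 1
        else:
            layers.append(layer)  # Flatten/Dense: stateless in eval or shared params
            i += 1
    return nn.Sequential(layers)


@dataclass
class TrainingHistory:
    loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)

    @property
    def epochs(self) -> int:
        return len(self.loss)

    def to_csv(self, path: str | Path) -> None:
        lines = ["epoch,loss,train_accuracy"]
        for i, (l, a) in enumerate(zip(self.loss, self.train_accuracy), start=1):
            lines.append(f"{i},{l},{a}")
        Path(path).write_text("\n".join(lines) + "\n")


def build_model(config: BDCNNConfig = BDCNNConfig()) -> Model:
    """Assemble the network; weights are drawn from config.seed."""
    rng = np.random.default_rng(config.seed)
    layers: list[nn.Layer] = []
    in_ch = 1
    h, w = config.input_size
    for i, (kernels, ksize) in enumerate(zip(config.block_kernels, config.block_kernel_sizes)):
        layers.append(nn.Conv2d(in_ch, kernels, ksize, rng, compute_dx=(i > 0)))
        layers.append(nn.BatchNorm2d(kernels))
        layers.append(nn.ReLU())
        layers.append(nn.MaxPool2d())
        in_ch = kernels
        h, w = h // 2, w // 2
    layers.append(nn.Flatten())
    layers.append(nn.Dense(in_ch * h * w, config.fc_nodes, rng))
    layers.append(nn.ReLU())
    layers.append(nn.Dense(config.fc_nodes, config.n_classes, rng))
    return Model(net=nn.Sequential(layers), config=config)


def _prepare_batch(patches: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """(N, H, W) intensities -> (N, h, w, 1) float32 scaled to [0, 1] (NHWC)."""
    x = np.asarray(patches, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    if x.shape[1:] != tuple(size):
        x = np.stack(
            [_sk_resize(p, size, order=1, preserve_range=True, anti_aliasing=False) for p in x]
        ).astype(np.float32)
    return (x / INTENSITY_SCALE)[..., None]


def predict_proba(model: Model, patches: np.ndarray, batch_size: int = 8) -> np.ndarray:
    """(N, H, W) patches -> (N, 2) class probabilities [background, mass]."""
    x = _prepare_batch(patches, model.config.input_size)
    net = model.inference_net()
    # run the conv stack in small cache-friendly chunks, but the dense head
    # (which re-reads its whole weight matrix per call) once per batch
    split = next(i for i, l in enumerate(net.layers) if isinstance(l, nn.Flatten))
    conv_part, head = net.layers[:split + 1], net.layers[split + 1:]
    feats = []
    for i in range(0, len(x), batch_size):
        h = x[i:i + batch_size]
        for layer in conv_part:
            h = layer.forward(h, train=False)
        feats.append(h.copy())
    z = np.concatenate(feats, axis=0)
    for layer in head:
        z = layer.forward(z, train=False)
    return nn.softmax(z)


def predict_mass_probability(model: Model, patch: np.ndarray) -> float:
    """Softmax probability that a single patch is a mass, in [0, 1]."""
    if model.net is None:
        raise RuntimeError("model is uninitialized")
    return float(predict_proba(model, patch[None] if patch.ndim == 2 else patch)[0, MASS])


def _accuracy(net: nn.Sequential, x_all: np.ndarray, labels: np.ndarray, batch_size: int) -> float:
    correct = 0
    for i in range(0, len(x_all), batch_size):
        logits = net.forward(x_all[i:i + batch_size], train=False)
        correct += int((logits.argmax(axis=1) == labels[i:i + batch_size]).sum())
    return correct / len(labels)


def train(model: Model, data: PatchDataset, config: BDCNNConfig | None = None):
    """SGD on cross-entropy until max_epochs or 100% training accuracy.

    The training accuracy is recomputed on the full training set after each
    epoch (inference mode) and the stop rule fires exactly when it reaches
    config.stop_train_accuracy.  Returns (model, TrainingHistory); the run
    is reproducible from config.seed.
    """
    cfg = config or model.config
    labels = data.labels
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("training data must contain both classes")
    x_all = _prepare_batch(data.patches, cfg.input_size)
    rng = np.random.default_rng(cfg.seed + 1)  # decoupled from weight init
    history = TrainingHistory()
    n = len(labels)
    for _epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            logits = model.net.forward(x_all[idx], train=True)
            loss, grad = nn.softmax_cross_entropy(logits, labels[idx])
            model.net.backward(grad)
            model.net.sgd_step(cfg.learning_rate)
            losses.append(loss)
        model._inference_net = None  # weights changed
        acc = _accuracy(model.inference_net(), x_all, labels, cfg.batch_size)
        history.loss.append(float(np.mean(losses)))
        history.train_accuracy.append(acc)
        if acc >= cfg.stop_train_accuracy:
            break
    model.trained = True
    model._inference_net = None
    model.net.release_buffers()  # free training activations (~2.5 GB)
    return model, history


# ---------------------------------------------------------------------------
# checkpointing

def save_checkpoint(model: Model, path: str | Path) -> None:
    """Save weights (npz) with the config and seed embedded."""
    path = Path(path)
    arrays = {}
    for li, layer in enumerate(model.net.layers):
        for name in getattr(layer, "trainable", ()):
            arrays[f"{li}.{name}"] = getattr(layer, name)
        if isinstance(layer, nn.BatchNorm2d):
            arrays[f"{li}.running_mean"] = layer.running_mean
            arrays[f"{li}.running_var"] = layer.running_var
    cfg = asdict(model.config)
    np.savez_compressed(path, __config__=json.dumps({"config": cfg, "trained": model.trained}),
                        **arrays)


def load_checkpoint(path: str | Path) -> Model:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["__config__"]))
        cfg_dict = meta["config"]
        for key in ("input_size", "block_kernels", "block_kernel_sizes"):
            cfg_dict[key] = tuple(cfg_dict[key])
        config = BDCNNConfig(**cfg_dict)
        model = build_model(config)
        for li, layer in enumerate(model.net.layers):
            for name in getattr(layer, "trainable", ()):
                getattr(layer, name)[...] = data[f"{li}.{name}"]
            if isinstance(layer, nn.BatchNorm2d):
                layer.running_mean[...] = data[f"{li}.running_mean"]
                layer.running_var[...] = data[f"{li}.running_var"]
        model.trained = bool(meta["trained"])
    return model
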