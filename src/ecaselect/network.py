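"""ECA-DeepNet: a deep CNN for cropped motor-imagery decoding with channel
attention.

The architecture splits the first convolution into a temporal convolution
(shared across electrodes) and a spatial convolution (across electrodes),
followed by four convolution - batchnorm - ELU - maxpool blocks with filter
counts (32, 64, 128, 256), an inter-layer ECA attention module after every
pool, and a convolutional classifier with a log-softmax head.  An input-facing
CA layer (a full-linear-map attention over the EEG electrodes) precedes the
stack; its learned weights drive channel selection.

Two representations exist side by side: :class:`NetworkSpec` is the
declarative layer table (names, kernels, symbolically traced output shapes,
closed-form parameter counts) and :class:`EcaDeepNet` is the runtime model
whose trainable arrays are counted directly — the two counts must always
agree.
"""

from __future__ import annotations

import io
import json
import math
import zipfile
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _nn
from .attention import adaptive_kernel_size
from .preprocess import SampleSet

__all__ = [
    "ConfigurationError",
    "TrainingDivergedError",
    "LayerSpec",
    "NetworkSpec",
    "Hyperparameters",
    "TrainedModel",
    "elu",
    "build_eca_deepnet",
    "count_parameters",
    "train_model",
]

DEFAULT_SEED = 20200220


class ConfigurationError(ValueError):
    """The requested architecture cannot be realized (e.g. input too short)."""


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"training diverged (non-finite loss) at epoch {epoch}")
        self.epoch = epoch


def elu(x: float) -> float:
    """Exponential linear unit: ``x`` if positive, else ``exp(x) - 1``."""
    x = float(x)
    return x if x > 0 else math.expm1(x)


@dataclass
class LayerSpec:
    name: str
    kind: str
    filters: int | None
    kernel: tuple[int, int] | None
    output_shape: tuple[int, ...]
    activation: str | None
    parameters: int


@dataclass
class NetworkSpec:
    """Declarative ECA-DeepNet layer stack for a given input geometry.

    Output shapes follow the ``maps x time x space`` convention: e.g. the
    temporal convolution of a 22 x 1,000 input yields ``(32, 991, 22)``.
    """

    channels: int
    time_samples: int
    classes: int
    filters: tuple[int, int, int, int] = (32, 64, 128, 256)
    temporal_kernel: int = 10
    pool_size: int = 3
    include_ca_layer: bool = True
    layers: list[LayerSpec] = field(default_factory=list)

    def layer(self, name: str) -> LayerSpec:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(f"no layer named {name!r} in this network spec")

    @property
    def total_parameters(self) -> int:
        return sum(l.parameters for l in self.layers)

    @property
    def classifier_kernel(self) -> int:
        return self.layer("Conv-Classifier").kernel[0]

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "NetworkSpec":
        d = json.loads(s)
        d["filters"] = tuple(d["filters"])
        d["layers"] = [
            LayerSpec(
                name=l["name"],
                kind=l["kind"],
                filters=l["filters"],
                kernel=tuple(l["kernel"]) if l["kernel"] else None,
                output_shape=tuple(l["output_shape"]),
                activation=l["activation"],
                parameters=l["parameters"],
            )
            for l in d["layers"]
        ]
        return cls(**d)


def build_eca_deepnet(
    channels: int,
    time_samples: int,
    classes: int,
    hp: "Hyperparameters | None" = None,
    filters: tuple[int, int, int, int] = (32, 64, 128, 256),
    temporal_kernel: int = 10,
    pool_size: int = 3,
    include_ca_layer: bool = True,
) -> NetworkSpec:
    """Symbolically trace the ECA-DeepNet stack and return its layer table.

    For the canonical 22-channel, 1,000-sample, 4-class input the traced
    output shapes are (32,991,22) -> (32,991,1) -> (32,330,1) -> (64,321,1)
    -> (64,107,1) -> (128,98,1) -> (128,32,1) -> (256,23,1) -> (256,7,1) -> 4,
    and the classifier kernel spans the full remaining temporal extent (7).
    Raises :class:`ConfigurationError` naming the first layer whose input is
    too short.
    """
    if channels < 2:
        raise ConfigurationError("at least 2 EEG channels are required")
    if time_samples < 100:
        raise ConfigurationError("at least 100 time samples are required")
    del hp  # structural layout does not depend on training hyperparameters

    layers: list[LayerSpec] = []
    if include_ca_layer:
        layers.append(
            LayerSpec(
                "CA-Layer", "ca_attention", None, None,
                (channels, time_samples, 1), None, channels**2 + channels,
            )
        )

    tk, p = temporal_kernel, pool_size
    length = time_samples

    def conv_out(l: int, k: int, name: str) -> int:
        if l < k:
            raise ConfigurationError(
                f"{name}: input length {l} is shorter than its kernel {k}"
            )
        return l - k + 1

    def pool_out(l: int, name: str) -> int:
        o = l // p
        if o < 1:
            raise ConfigurationError(f"{name}: pooling a length-{l} input gives nothing")
        return o

    length = conv_out(length, tk, "Conv-Time")
    layers.append(
        LayerSpec("Conv-Time", "temporal_conv", filters[0], (tk, 1),
                  (filters[0], length, channels), "Linear", filters[0] * tk)
    )
    layers.append(
        LayerSpec("Conv-Spat", "spatial_conv", filters[0], (1, channels),
                  (filters[0], length, 1), "Linear", filters[0] * filters[0] * channels)
    )
    prev = filters[0]
    for i, f in enumerate(filters, start=1):
        if i > 1:
            length = conv_out(length, tk, f"Conv-{i}")
            layers.append(
                LayerSpec(f"Conv-{i}", "map_conv", f, (tk, 1),
                          (f, length, 1), "Linear", f * prev * tk)
            )
        layers.append(
            LayerSpec(f"BatchNorm-{i}", "batchnorm", None, None, (f, length, 1), None, 2 * f)
        )
        layers.append(
            LayerSpec(f"Activation-{i}", "elu", None, None, (f, length, 1), "ELU", 0)
        )
        length = pool_out(length, f"Pool-{i}")
        layers.append(
            LayerSpec(f"Pool-{i}", "maxpool", None, (p, 1), (f, length, 1), None, 0)
        )
        k = adaptive_kernel_size(f)
        layers.append(
            LayerSpec(f"ECA-{i}", "eca", None, (k,), (f, length, 1), None, k + 1)
        )
        if i < len(filters):
            layers.append(
                LayerSpec(f"dropout-{i}", "dropout", None, None, (f, length, 1), None, 0)
            )
        prev = f

    # The classifier convolution spans the full remaining temporal extent
    # (7 for the canonical input), collapsing it to a class vector.
    layers.append(
        LayerSpec("Conv-Classifier", "map_conv", classes, (length, 1),
                  (classes, 1, 1), "Linear", classes * prev * length + classes)
    )
    layers.append(
        LayerSpec("LogSoftmax", "log_softmax", None, None, (classes,), "Logsoftmax", 0)
    )
    return NetworkSpec(
        channels=channels,
        time_samples=time_samples,
        classes=classes,
        filters=tuple(filters),
        temporal_kernel=tk,
        pool_size=p,
        include_ca_layer=include_ca_layer,
        layers=layers,
    )


def count_parameters(spec: NetworkSpec, layer_name: str = "total") -> int:
    """Trainable scalars in one named layer, or in the whole network."""
    if layer_name == "total":
        return spec.total_parameters
    return spec.layer(layer_name).parameters


@dataclass
class Hyperparameters:
    """Training hyperparameters with the search-space ranges enforced.

    Defaults are the modal values of the per-subject tuning results; the
    seed fixes every source of randomness (initialization, shuffling,
    dropout).
    """

    dropout_rate: float = 0.5
    optimizer: str = "AdamW"
    learning_rate: float = 1e-3
    batch_size: int = 16
    weight_decay: float = 1e-4
    epochs: int = 200
    patience: int = 30
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_rate <= 0.9):
            raise ValueError("dropout_rate must lie in [0, 0.9]")
        if self.optimizer.lower() not in ("adamw", "adadelta", "adagrad"):
            raise ValueError("optimizer must be one of AdamW, Adadelta, Adagrad")
        if not (1e-5 <= self.learning_rate <= 1e-1):
            raise ValueError("learning_rate must lie in [1e-5, 1e-1]")
        if self.batch_size not in (4, 8, 16, 32, 64):
            raise ValueError("batch_size must be one of 4, 8, 16, 32, 64")
        if self.weight_decay not in (1e-5, 1e-4, 1e-3, 1e-2):
            raise ValueError("weight_decay must be one of 1e-5, 1e-4, 1e-3, 1e-2")
        if self.epochs < 1:
            raise ValueError("epochs must be positive")


class _Runtime:
    """The live layer stack built from a NetworkSpec."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator, dropout_rate: float):
        self.spec = spec
        self.layers: list[_nn.Layer] = []
        self.ca_layer: _nn.CALayer | None = None
        c = spec.channels
        prev = spec.filters[0]
        for ls in spec.layers:
            if ls.kind == "ca_attention":
                self.ca_layer = _nn.CALayer(c, rng, name=ls.name)
                self.layers.append(self.ca_layer)
            elif ls.kind == "temporal_conv":
                self.layers.append(_nn.TemporalConv(ls.filters, ls.kernel[0], rng, name=ls.name))
            elif ls.kind == "spatial_conv":
                self.layers.append(_nn.SpatialConv(ls.filters, ls.filters, c, rng, name=ls.name))
                prev = ls.filters
            elif ls.kind == "map_conv":
                bias = ls.name == "Conv-Classifier"
                self.layers.append(
                    _nn.MapConv(ls.filters, prev, ls.kernel[0], rng, bias=bias, name=ls.name)
                )
                prev = ls.filters
            elif ls.kind == "batchnorm":
                self.layers.append(_nn.BatchNorm(ls.output_shape[0], name=ls.name))
            elif ls.kind == "elu":
                self.layers.append(_nn.Elu(name=ls.name))
            elif ls.kind == "maxpool":
                self.layers.append(_nn.MaxPool(ls.kernel[0], name=ls.name))
            elif ls.kind == "eca":
                self.layers.append(_nn.EcaModule(ls.output_shape[0], rng, name=ls.name))
            elif ls.kind == "dropout":
                self.layers.append(_nn.Dropout(dropout_rate, rng, name=ls.name))
            elif ls.kind == "log_softmax":
                pass  # fused into the loss / predict path
            else:  # pragma: no cover
                raise ValueError(f"unknown layer kind {ls.kind!r}")

    def params(self) -> list[_nn.Param]:
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x[:, :, 0]  # (N, classes, 1) -> logits (N, classes)

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits[:, :, None]
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def state(self) -> dict[str, np.ndarray]:
        d = {p.name: p.value.copy() for p in self.params()}
        for layer in self.layers:
            if isinstance(layer, _nn.BatchNorm):
                d[f"{layer.name}.running_mean"] = layer.running_mean.copy()
                d[f"{layer.name}.running_var"] = layer.running_var.copy()
        return d

    def load_state(self, d: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value[...] = d[p.name]
        for layer in self.layers:
            if isinstance(layer, _nn.BatchNorm):
                layer.running_mean[...] = d[f"{layer.name}.running_mean"]
                layer.running_var[...] = d[f"{layer.name}.running_var"]


@dataclass
class TrainedModel:
    """A fitted ECA-DeepNet plus its training history and provenance."""

    spec: NetworkSpec
    runtime: _Runtime
    history: list[dict]
    hyperparameters: Hyperparameters
    seed: int
    class_values: np.ndarray  # original label values, index = network output

    @property
    def channel_count(self) -> int:
        return self.spec.channels

    def predict_logits(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        outs = [
            self.runtime.forward(x[i : i + batch_size], training=False)
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(outs, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        idx = self.predict_logits(x, batch_size).argmax(axis=1)
        return self.class_values[idx]

    def attention_vectors(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Per-sample CA-layer attention, shape (N, C)."""
        if self.runtime.ca_layer is None:
            raise ValueError("this network was built without a CA layer")
        x = np.asarray(x, dtype=float)
        outs = []
        for i in range(0, x.shape[0], batch_size):
            self.runtime.forward(x[i : i + batch_size], training=False)
            outs.append(self.runtime.ca_layer.last_attention.copy())
        return np.concatenate(outs, axis=0)

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(self.history)

    def save(self, path: str) -> None:
        """Single-file checkpoint: parameter state + spec + hyperparameters."""
        state = self.runtime.state()
        buf = io.BytesIO()
        np.savez(buf, **state)
        meta = {
            "spec": json.loads(self.spec.to_json()),
            "hyperparameters": asdict(self.hyperparameters),
            "seed": self.seed,
            "class_values": self.class_values.tolist(),
            "history": self.history,
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("state.npz", buf.getvalue())
            zf.writestr("meta.json", json.dumps(meta))

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            with np.load(io.BytesIO(zf.read("state.npz"))) as f:
                state = {k: f[k] for k in f.files}
        spec = NetworkSpec.from_json(json.dumps(meta["spec"]))
        hp = Hyperparameters(**meta["hyperparameters"])
        rt = _Runtime(spec, np.random.default_rng(meta["seed"]), hp.dropout_rate)
        rt.load_state(state)
        return cls(spec, rt, meta["history"], hp, meta["seed"], np.array(meta["class_values"]))

    def save_history_csv(self, path: str) -> None:
        self.history_frame().to_csv(path, index=False)


def train_model(
    samples: SampleSet,
    hp: Hyperparameters | None = None,
    spec: NetworkSpec | None = None,
    val_samples: SampleSet | None = None,
) -> TrainedModel:
    """Train an ECA-DeepNet on cropped samples; deterministic given the seed.

    The loss is the negative log-likelihood of the log-softmax head.  When
    validation samples are given, training stops early after ``hp.patience``
    epochs without validation-loss improvement and the best state is
    restored.  A non-finite loss raises :class:`TrainingDivergedError` naming
    the epoch.
    """
    hp = hp or Hyperparameters()
    class_values = np.unique(samples.labels)
    if class_values.size < 2:
        raise ValueError("training requires at least two classes")
    label_index = {v: i for i, v in enumerate(class_values)}
    y = np.array([label_index[v] for v in samples.labels])
    x = samples.samples

    if spec is None:
        spec = build_eca_deepnet(samples.n_channels, samples.n_times, class_values.size)
    if spec.channels != samples.n_channels or spec.time_samples != samples.n_times:
        raise ValueError(
            f"network spec input {spec.channels}x{spec.time_samples} does not match "
            f"samples {samples.n_channels}x{samples.n_times}"
        )

    rng = np.random.default_rng(hp.seed)
    rt = _Runtime(spec, rng, hp.dropout_rate)
    opt = _nn.make_optimizer(hp.optimizer, rt.params(), hp.learning_rate, hp.weight_decay)

    if val_samples is not None:
        yv = np.array([label_index[v] for v in val_samples.labels])
        xv = val_samples.samples

    best_val = np.inf
    best_state = None
    stall = 0
    history: list[dict] = []
    n = x.shape[0]
    for epoch in range(hp.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for i in range(0, n, hp.batch_size):
            idx = order[i : i + hp.batch_size]
            logits = rt.forward(x[idx], training=True)
            loss, dlogits = _nn.nll_loss_and_grad(logits, y[idx])
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            opt.zero_grad()
            rt.backward(dlogits)
            opt.step()
            losses.append(loss * idx.size)
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
        row = {
            "epoch": epoch,
            "train_loss": float(np.sum(losses) / n),
            "train_acc": correct / n,
        }
        if val_samples is not None:
            vlogits = np.concatenate(
                [rt.forward(xv[i : i + 64], training=False) for i in range(0, xv.shape[0], 64)]
            )
            vloss, _ = _nn.nll_loss_and_grad(vlogits, yv)
            row["val_loss"] = vloss
            row["val_acc"] = float((vlogits.argmax(axis=1) == yv).mean())
            history.append(row)
            if vloss < best_val - 1e-12:
                best_val, best_state, stall = vloss, rt.state(), 0
            else:
                stall += 1
                if stall >= hp.patience:
                    break
        else:
            history.append(row)
    if best_state is not None:
        rt.load_state(best_state)
    return TrainedModel(spec, rt, history, hp, hp.seed, class_values)
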