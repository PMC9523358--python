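"""EEG decoders: a shallow and a deep convolutional network over raw segments.

The shallow decoder factorises its first stage into a *temporal*
convolution (40 filters, kernel 3 x 1 along time, applied to every
channel) followed by a *spatial* convolution (40 filters, kernel 1 x C
across the full channel axis), then batch norm, a squaring nonlinearity,
average pooling (30 x 1, stride 4 x 1), a log activation, dropout 0.5, and
a dense softmax head.  Square -> average-pool -> log computes a smoothed
log band-power, so the network learns frequency-and-space filters whose
power discriminates the classes -- no handcrafted features are extracted
beforehand; the input is the raw (band-filtered) segment tensor.

The deep decoder stacks four convolution--max-pool blocks (25/50/100/200
filters, temporal kernel 10 x 1, pooling 3 x 1 stride 3 x 1, ELU
activations, batch norm, dropout) with the same split first block.

Training follows a fixed recipe: Adam, learning rate 6.25e-4, batch size
8, negative-log-likelihood loss, a fixed number of epochs (150 for valence
runs, 50 for arousal), no early stopping or schedules.  All stochastic
elements -- weight init, batch shuffling, dropout -- derive from the run
seed, so identical seeds give identical training histories.

Because the temporal convolution slides over every channel, the cost of
the convolution stage is proportional to the channel count; reducing 246
channels to a selected 68 cuts those FLOPs to 68/246.  See
:func:`conv_stage_flops`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from . import nn
from .errors import ValidationError
from .io import SegmentSet

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "TrainedModel",
    "build_model",
    "build_deep_model",
    "train",
    "predict",
    "conv_stage_flops",
    "channel_reduction_ratio",
    "save_model",
    "load_model",
    "DEFAULT_EPOCHS",
]

#: Fixed epoch budget per classification scale.
DEFAULT_EPOCHS = {"valence": 150, "arousal": 50}

_DEEP_FILTERS = (25, 50, 100, 200)
_DEEP_KERNEL = 10
_DEEP_POOL = 3


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters.

    ``n_channels`` is C (all channels) or K (after selection);
    ``n_timepoints`` is P, the samples per segment.
    """

    n_channels: int
    n_timepoints: int
    architecture: str = "shallow"
    n_classes: int = 2
    n_temporal_filters: int = 40
    temporal_kernel: int = 3
    pool_length: int = 30
    pool_stride: int = 4
    dropout: float = 0.5

    def __post_init__(self):
        if self.architecture not in ("shallow", "deep"):
            raise ValidationError(f"architecture must be shallow/deep, got {self.architecture!r}")
        if self.n_channels < 1 or self.n_classes < 2:
            raise ValidationError("need >= 1 channel and >= 2 classes")
        if self.architecture == "shallow":
            min_p = self.temporal_kernel + self.pool_length - 1
            if self.n_timepoints < min_p:
                raise ValidationError(
                    f"P={self.n_timepoints} too short for kernel {self.temporal_kernel} "
                    f"+ pool {self.pool_length}; minimal admissible P is {min_p}"
                )
        else:
            t = self.n_timepoints
            for _ in _DEEP_FILTERS:
                t = (t - _DEEP_KERNEL + 1 - _DEEP_POOL) // _DEEP_POOL + 1
                if t < 1:
                    min_p = _minimal_deep_p()
                    raise ValidationError(
                        f"P={self.n_timepoints} too short for the deep architecture; "
                        f"minimal admissible P is {min_p}"
                    )

    @property
    def pooled_length(self) -> int:
        """Time steps after the shallow conv + pool stage."""
        t_conv = self.n_timepoints - self.temporal_kernel + 1
        return (t_conv - self.pool_length) // self.pool_stride + 1


def _minimal_deep_p() -> int:
    t = 1
    for _ in _DEEP_FILTERS:
        t = (t - 1) * _DEEP_POOL + _DEEP_POOL + _DEEP_KERNEL - 1
    return t


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters (defaults are the study recipe)."""

    optimizer: str = "adam"
    learning_rate: float = 0.000625
    batch_size: int = 8
    epochs: int = 150
    seed: int = 0

    def __post_init__(self):
        if self.optimizer != "adam":
            raise ValidationError(f"only adam is supported, got {self.optimizer!r}")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValidationError("learning_rate > 0, batch_size >= 1, epochs >= 1 required")


@dataclass
class TrainedModel:
    """A (possibly untrained) network plus its spec and provenance."""

    spec: ModelSpec
    network: nn.Network
    seed: int = 0
    history: list[dict] = field(default_factory=list)

    @property
    def is_trained(self) -> bool:
        return bool(self.history)


def _build_network(spec: ModelSpec, rng: np.random.Generator) -> nn.Network:
    F = spec.n_temporal_filters
    if spec.architecture == "shallow":
        layers = [
            nn.TemporalConv(1, F, spec.temporal_kernel, rng),
            nn.SpatialConv(F, F, spec.n_channels, rng),
            nn.BatchNorm(F),
            nn.Square(),
            nn.AvgPoolTime(spec.pool_length, spec.pool_stride),
            nn.LogActivation(),
            nn.Dropout(spec.dropout),
            nn.Flatten(),
            nn.Dense(F * spec.pooled_length, spec.n_classes, rng),
        ]
        return nn.Network(layers)
    layers = [
        nn.TemporalConv(1, _DEEP_FILTERS[0], _DEEP_KERNEL, rng),
        nn.SpatialConv(_DEEP_FILTERS[0], _DEEP_FILTERS[0], spec.n_channels, rng),
        nn.BatchNorm(_DEEP_FILTERS[0]),
        nn.Elu(),
        nn.MaxPoolTime(_DEEP_POOL, _DEEP_POOL),
    ]
    t = (spec.n_timepoints - _DEEP_KERNEL + 1 - _DEEP_POOL) // _DEEP_POOL + 1
    f_prev = _DEEP_FILTERS[0]
    for f in _DEEP_FILTERS[1:]:
        layers += [
            nn.Dropout(spec.dropout),
            nn.TemporalConv(f_prev, f, _DEEP_KERNEL, rng),
            nn.BatchNorm(f),
            nn.Elu(),
            nn.MaxPoolTime(_DEEP_POOL, _DEEP_POOL),
        ]
        t = (t - _DEEP_KERNEL + 1 - _DEEP_POOL) // _DEEP_POOL + 1
        f_prev = f
    layers += [
        nn.Dropout(spec.dropout),
        nn.Flatten(),
        nn.Dense(f_prev * t, spec.n_classes, rng),
    ]
    return nn.Network(layers)


def build_model(spec: ModelSpec, seed: int = 0) -> TrainedModel:
    """Instantiate an untrained shallow decoder.

    The weights here use ``seed``; :func:`train` re-initialises from its
    own config seed so that a training run is a pure function of
    (spec, data, config).
    """
    if spec.architecture != "shallow":
        raise ValidationError("build_model builds the shallow architecture; see build_deep_model")
    return TrainedModel(spec=spec, network=_build_network(spec, np.random.default_rng(seed)), seed=seed)


def build_deep_model(spec: ModelSpec, seed: int = 0) -> TrainedModel:
    """Instantiate the untrained deep (four-block) decoder."""
    if spec.architecture != "deep":
        spec = replace(spec, architecture="deep")
    return TrainedModel(spec=spec, network=_build_network(spec, np.random.default_rng(seed)), seed=seed)


def _check_segments(spec: ModelSpec, segments: SegmentSet) -> None:
    if segments.n_timepoints != spec.n_timepoints or segments.n_channels != spec.n_channels:
        raise ValidationError(
            f"segments are (P={segments.n_timepoints}, C={segments.n_channels}); "
            f"model expects (P={spec.n_timepoints}, C={spec.n_channels})"
        )


def train(model: TrainedModel, train_segments: SegmentSet, config: TrainConfig) -> TrainedModel:
    """Train for exactly ``config.epochs`` epochs; returns a new TrainedModel.

    Weight initialisation, per-epoch batch shuffling, and dropout masks all
    derive from ``config.seed``, so a rerun with the same data and config
    reproduces the history bit for bit.  The final partial batch of each
    epoch is kept.  The recorded history has one entry per epoch with the
    mean batch loss and training accuracy.
    """
    _check_segments(model.spec, train_segments)
    y = train_segments.labels
    n = len(y)
    if n == 0:
        raise ValidationError("cannot train on an empty segment set")
    if len(np.unique(y)) < 2:
        raise ValidationError("training set contains a single class")
    rng = np.random.default_rng(config.seed)
    network = _build_network(model.spec, rng)
    optimizer = nn.Adam(network, lr=config.learning_rate)
    x = train_segments.tensor[:, None, :, :]  # (N, 1, P, C)
    history: list[dict] = []
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            scores = network.forward(x[idx], training=True, rng=rng)
            loss, grad = nn.nll_loss_and_grad(scores, y[idx])
            network.backward(grad)
            optimizer.step()
            losses.append(loss)
            correct += int((scores.argmax(axis=1) == y[idx]).sum())
        history.append(
            {"epoch": epoch, "loss": float(np.mean(losses)), "train_acc": correct / n}
        )
    return TrainedModel(spec=model.spec, network=network, seed=config.seed, history=history)


def predict(model: TrainedModel, segments: SegmentSet, batch_size: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities (N x n_classes) and hard labels.

    Inference is deterministic: dropout off, batch norm uses running
    statistics.  Ties go to the lower class index.
    """
    _check_segments(model.spec, segments)
    n = segments.n_segments
    if n == 0:
        return np.empty((0, model.spec.n_classes)), np.empty(0, dtype=np.int64)
    rng = np.random.default_rng(0)  # unused at inference; forward API symmetry
    x = segments.tensor[:, None, :, :]
    probs = np.empty((n, model.spec.n_classes))
    for start in range(0, n, batch_size):
        scores = model.network.forward(x[start : start + batch_size], training=False, rng=rng)
        probs[start : start + batch_size] = np.exp(nn.log_softmax(scores))
    return probs, probs.argmax(axis=1).astype(np.int64)


def conv_stage_flops(spec: ModelSpec) -> int:
    """Analytic multiply-add count of the temporal+spatial convolution stage.

    Temporal: ``2 * kernel * F * T_conv`` per channel, over ``C`` channels.
    Spatial: ``2 * F_in * C * F_out`` per output time step.  Both terms are
    linear in C, which is the mechanism by which top-K channel selection
    reduces compute by exactly K/C.
    """
    F = spec.n_temporal_filters if spec.architecture == "shallow" else _DEEP_FILTERS[0]
    kt = spec.temporal_kernel if spec.architecture == "shallow" else _DEEP_KERNEL
    t_conv = spec.n_timepoints - kt + 1
    temporal = 2 * kt * F * t_conv * spec.n_channels
    spatial = 2 * F * F * spec.n_channels * t_conv
    return temporal + spatial


def channel_reduction_ratio(spec: ModelSpec, k: int) -> float:
    """FLOP ratio of the conv stage after reducing ``spec.n_channels`` -> k."""
    if not 1 <= k <= spec.n_channels:
        raise ValidationError(f"k must be in [1, {spec.n_channels}], got {k}")
    reduced = replace(spec, n_channels=k)
    return conv_stage_flops(reduced) / conv_stage_flops(spec)


_SPEC_FIELDS = (
    "n_channels", "n_timepoints", "architecture", "n_classes",
    "n_temporal_filters", "temporal_kernel", "pool_length", "pool_stride", "dropout",
)


def save_model(model: TrainedModel, path) -> None:
    """Checkpoint: spec + seed as attrs, weight arrays as datasets."""
    with h5py.File(path, "w") as f:
        for name in _SPEC_FIELDS:
            f.attrs[name] = getattr(model.spec, name)
        f.attrs["seed"] = model.seed
        for i, arr in enumerate(model.network.state()):
            f.create_dataset(f"state_{i}", data=arr)
        if model.history:
            f.create_dataset("history_loss", data=[h["loss"] for h in model.history])
            f.create_dataset("history_acc", data=[h["train_acc"] for h in model.history])


def load_model(path) -> TrainedModel:
    with h5py.File(path, "r") as f:
        kwargs = {name: f.attrs[name] for name in _SPEC_FIELDS}
        kwargs["architecture"] = str(kwargs["architecture"])
        for key in ("n_channels", "n_timepoints", "n_classes", "n_temporal_filters",
                    "temporal_kernel", "pool_length", "pool_stride"):
            kwargs[key] = int(kwargs[key])
        kwargs["dropout"] = float(kwargs["dropout"])
        spec = ModelSpec(**kwargs)
        seed = int(f.attrs["seed"])
        network = _build_network(spec, np.random.default_rng(seed))
        i, arrays = 0, []
        while f"state_{i}" in f:
            arrays.append(f[f"state_{i}"][()])
            i += 1
        network.load_state(arrays)
        history = []
        if "history_loss" in f:
            for e, (lo, ac) in enumerate(zip(f["history_loss"][()], f["history_acc"][()])):
                history.append({"epoch": e, "loss": float(lo), "train_acc": float(ac)})
    return TrainedModel(spec=spec, network=network, seed=seed, history=history)
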