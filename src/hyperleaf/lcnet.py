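"""The five CNN architectures and the training protocol.

The centerpiece is the hybrid 3D-2D network ("hybrid_lcnet"): two 3x3x3
3D convolutional stems (stride 2 everywhere, BN + ReLU) reduce a
112 x 112 x N reflectance cube to a (32, depth, 28, 28) volume (spectral
depth 8 for N = 30, 4 for N = 15), an adaptive average pool collapses the
spectral axis to 2, the volume is reshaped to 64 channels at 28 x 28, and
four ShuffleNetV2 units (downsample to 128@14x14, basic, downsample to
256@7x7, basic) plus a 1x1 conv to 512, global average pooling, dropout and
a linear classifier finish the job.

Companions: "lcnet3d" (same stem and unit widths, genuinely 3D units —
3x3x3 depthwise, 1x1x1 pointwise, strides (1,2,2) — so it differs from the
hybrid only by the depthwise-kernel inflation), "lcnet2d" (bands-as-channels
2D counterpart), and 2D/3D ShuffleNetV2 at width multiplier 0.25 (stages
32/64/128, repeats 4/8/4, head conv to 1024).

Training follows the pinned protocol: Adam (defaults), cross-entropy,
initial learning rate 1e-3 halved every 20 epochs, batch 64, 200 epochs —
all configurable, fully seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._nn import (
    Adam, AdaptiveAvgPoolDepth, BatchNorm, Conv, Dropout, FoldDepth,
    GlobalAvgPool, Linear, MaxPool, Sequential, ShuffleBasicUnit,
    ShuffleDownUnit, conv_out_len, shuffle_permutation, softmax_cross_entropy,
)

__all__ = [
    "ArchitectureConfig",
    "TrainConfig",
    "EfficiencyReport",
    "ARCH_IDS",
    "conv_out_len",
    "channel_shuffle",
    "build_model",
    "Model",
    "count_parameters",
    "analytic_parameter_count",
    "count_flops",
    "learning_rate",
    "train_cnn",
    "predict",
    "repeat_experiment",
    "to_model_input",
]

ARCH_IDS = ("hybrid_lcnet", "lcnet3d", "lcnet2d", "shufflenetv2_2d", "shufflenetv2_3d")
_3D_STEM_ARCHS = ("hybrid_lcnet", "lcnet3d", "shufflenetv2_3d")


@dataclass(frozen=True)
class ArchitectureConfig:
    arch_id: str
    n_bands: int
    n_classes: int = 6
    width_mult: float = 0.25
    dropout: float = 0.2
    spatial: int = 112

    def __post_init__(self):
        if self.arch_id not in ARCH_IDS:
            raise ValueError(f"unknown arch_id {self.arch_id!r}")
        if self.arch_id in _3D_STEM_ARCHS and self.n_bands < 8:
            raise ValueError(
                f"{self.arch_id} needs >= 8 spectral bands, got {self.n_bands}"
            )
        if self.n_bands < 1:
            raise ValueError("n_bands must be >= 1")


@dataclass
class TrainConfig:
    lr0: float = 1e-3
    lr_decay: float = 0.5
    lr_step_epochs: int = 20
    epochs: int = 200
    batch_size: int = 64
    seed: int = 0
    n_repeats: int = 5

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.lr0 <= 0:
            raise ValueError("training hyperparameters must be positive")


@dataclass(frozen=True)
class EfficiencyReport:
    """Parameter and FLOP accounting for one architecture and input size.

    ``flops`` counts 2 x multiply-accumulates of convolution and linear
    layers only (BN and activations excluded); the convention is recorded.
    """

    params: int
    flops: int
    input_shape: tuple
    convention: str = "2*MAC, conv+linear only"

    @property
    def params_m(self) -> float:
        return round(self.params / 1e6, 2)

    @property
    def flops_g(self) -> float:
        return round(self.flops / 1e9, 2)


def channel_shuffle(feature_map: np.ndarray, groups: int = 2,
                    channel_axis: int = 0) -> np.ndarray:
    """Channel shuffle: reshape channels to (groups, C/groups), transpose,
    flatten — a fixed permutation; all other axes untouched."""
    C = feature_map.shape[channel_axis]
    perm = shuffle_permutation(C, groups)
    return np.take(feature_map, perm, axis=channel_axis)


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

class Model:
    """Ordered named-layer container with an auditable layer list."""

    def __init__(self, named_layers, config: ArchitectureConfig):
        self.named_layers = list(named_layers)
        self.config = config
        self._seq = Sequential([l for _, l in self.named_layers])

    @property
    def input_layout(self) -> str:
        """"volume" = (1, N, H, W) single-channel cube; "planes" = (N, H, W)."""
        return "volume" if self.config.arch_id in _3D_STEM_ARCHS else "planes"

    def input_shape(self) -> tuple:
        c = self.config
        if self.input_layout == "volume":
            return (1, c.n_bands, c.spatial, c.spatial)
        return (c.n_bands, c.spatial, c.spatial)

    def parameters(self):
        return self._seq.params()

    def atomic_layers(self):
        return self._seq.atomic()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self._seq.forward(np.asarray(x, dtype=np.float32), training)

    def backward(self, dlogits: np.ndarray):
        return self._seq.backward(dlogits)

    def trace(self, x: np.ndarray) -> list[tuple[str, tuple]]:
        """Forward a probe batch, recording the output shape of every named
        top-level layer (the symbolic shape-walk audit)."""
        shapes = []
        h = np.asarray(x, dtype=np.float32)
        for name, layer in self.named_layers:
            h = layer.forward(h, training=False)
            shapes.append((name, tuple(h.shape[1:])))
        return shapes

    def set_dropout_rng(self, rng: np.random.Generator):
        for l in self.atomic_layers():
            if isinstance(l, Dropout):
                l.rng = rng

    def get_state(self):
        return (
            [p.value.copy() for p in self.parameters()],
            [b.copy() for b in self._seq.buffers()],
        )

    def set_state(self, state):
        values, buffers = state
        for p, v in zip(self.parameters(), values):
            p.value[...] = v
        for b, v in zip(self._seq.buffers(), buffers):
            b[...] = v


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _hybrid_stem(rng):
    return [
        ("stem.conv1", Sequential([
            Conv(1, 16, (3, 3, 3), (2, 2, 2), (1, 1, 1), rng=rng,
                 needs_input_grad=False),
            BatchNorm(16, relu=True)])),
        ("stem.conv2", Sequential([
            Conv(16, 32, (3, 3, 3), (2, 2, 2), (1, 1, 1), rng=rng),
            BatchNorm(32, relu=True)])),
        ("stem.pool_spectral", AdaptiveAvgPoolDepth(2)),
    ]


def _lcnet_head(in_ch, n_classes, dropout, rng, d=2):
    one = (1,) * d
    return [
        ("head.conv", Sequential([
            Conv(in_ch, 512, one, one, (0,) * d, rng=rng),
            BatchNorm(512, relu=True)])),
        ("head.gap", GlobalAvgPool()),
        ("head.dropout", Dropout(dropout)),
        ("head.fc", Linear(512, n_classes, rng=rng)),
    ]


def _lcnet_units(d, stride_down, rng):
    return [
        ("stage.down1", ShuffleDownUnit(64, 128, d=d, stride=stride_down, rng=rng)),
        ("stage.basic1", ShuffleBasicUnit(128, d=d, rng=rng)),
        ("stage.down2", ShuffleDownUnit(128, 256, d=d, stride=stride_down, rng=rng)),
        ("stage.basic2", ShuffleBasicUnit(256, d=d, rng=rng)),
    ]


def build_model(config: ArchitectureConfig, seed: int = 0) -> Model:
    """Construct the pinned architecture with seeded Kaiming initialization."""
    rng = np.random.default_rng(seed)
    c = config
    if c.arch_id == "hybrid_lcnet":
        layers = _hybrid_stem(rng)
        layers.append(("bridge.reshape", FoldDepth()))          # (32,2,H,W)->(64,H,W)
        layers += _lcnet_units(2, (2, 2), rng)
        layers += _lcnet_head(256, c.n_classes, c.dropout, rng, d=2)
    elif c.arch_id == "lcnet3d":
        layers = _hybrid_stem(rng)
        layers.append(("bridge.fold", FoldDepth(keep_3d=True)))  # ->(64,1,H,W)
        layers += _lcnet_units(3, (1, 2, 2), rng)
        layers += _lcnet_head(256, c.n_classes, c.dropout, rng, d=3)
    elif c.arch_id == "lcnet2d":
        layers = [
            ("stem.conv1", Sequential([
                Conv(c.n_bands, 16, (3, 3), (2, 2), (1, 1), rng=rng,
                     needs_input_grad=False),
                BatchNorm(16, relu=True)])),
            ("stem.conv2", Sequential([
                Conv(16, 64, (3, 3), (2, 2), (1, 1), rng=rng),
                BatchNorm(64, relu=True)])),
        ]
        layers += _lcnet_units(2, (2, 2), rng)
        layers += _lcnet_head(256, c.n_classes, c.dropout, rng, d=2)
    elif c.arch_id in ("shufflenetv2_2d", "shufflenetv2_3d"):
        d = 2 if c.arch_id == "shufflenetv2_2d" else 3
        in_ch = c.n_bands if d == 2 else 1
        st2 = (2,) * d
        st_stage = (2, 2) if d == 2 else (1, 2, 2)
        stages = [(32, 4), (64, 8), (128, 4)]  # width_mult 0.25
        layers = [
            ("stem.conv", Sequential([
                Conv(in_ch, 24, (3,) * d, st2, (1,) * d, rng=rng,
                     needs_input_grad=False),
                BatchNorm(24, relu=True)])),
            ("stem.pool", MaxPool((3,) * d, st2, (1,) * d)),
        ]
        prev = 24
        for si, (ch, reps) in enumerate(stages, start=2):
            layers.append((f"stage{si}.down",
                           ShuffleDownUnit(prev, ch, d=d, stride=st_stage, rng=rng)))
            for r in range(reps - 1):
                layers.append((f"stage{si}.basic{r + 1}",
                               ShuffleBasicUnit(ch, d=d, rng=rng)))
            prev = ch
        layers += [
            ("head.conv", Sequential([
                Conv(prev, 1024, (1,) * d, (1,) * d, (0,) * d, rng=rng),
                BatchNorm(1024, relu=True)])),
            ("head.gap", GlobalAvgPool()),
            ("head.dropout", Dropout(c.dropout)),
            ("head.fc", Linear(1024, c.n_classes, rng=rng)),
        ]
    else:  # pragma: no cover - guarded by config validation
        raise ValueError(c.arch_id)
    return Model(layers, c)


# ---------------------------------------------------------------------------
# accounting
# ---------------------------------------------------------------------------

def count_parameters(model: Model) -> int:
    """Total trainable scalars, summed from the actual parameter arrays."""
    return int(sum(p.value.size for p in model.parameters()))


def analytic_parameter_count(model: Model) -> int:
    """Independent closed-form layer sum: convs k-volume x C_in x C_out
    (/C for depthwise), BN 2C, linear C_in x C_out + C_out."""
    total = 0
    for layer in model.atomic_layers():
        if hasattr(layer, "param_count_formula"):
            total += layer.param_count_formula()
    return total


def count_flops(model: Model, input_shape: tuple | None = None) -> EfficiencyReport:
    """2 x MAC for conv/linear layers on one input, via a probe forward pass."""
    input_shape = tuple(input_shape) if input_shape else model.input_shape()
    probe = np.zeros((1,) + input_shape, dtype=np.float32)
    model.forward(probe, training=False)
    macs = 0
    for layer in model.atomic_layers():
        if isinstance(layer, Conv):
            macs += layer.macs(layer.last_out_spatial)
        elif isinstance(layer, Linear):
            macs += layer.macs()
    return EfficiencyReport(
        params=count_parameters(model), flops=2 * macs, input_shape=input_shape
    )


def audit_table(model: Model) -> list[dict]:
    """Per-named-layer audit: output shape and parameter count."""
    probe = np.zeros((1,) + model.input_shape(), dtype=np.float32)
    shapes = model.trace(probe)
    rows = []
    for (name, layer), (_, shape) in zip(model.named_layers, shapes):
        rows.append({
            "layer": name,
            "out_shape": shape,
            "params": int(sum(p.value.size for p in layer.params())),
        })
    return rows


# ---------------------------------------------------------------------------
# training protocol
# ---------------------------------------------------------------------------

def learning_rate(config: TrainConfig, epoch: int) -> float:
    """Step-decay schedule; ``epoch`` is 1-based.  With the defaults the rate
    is 1e-3 for epochs 1-20, 5e-4 for 21-40, 2.5e-4 for 41-60, ..."""
    if epoch < 1:
        raise ValueError("epoch is 1-based")
    return config.lr0 * config.lr_decay ** ((epoch - 1) // config.lr_step_epochs)


def to_model_input(images: np.ndarray, arch_id: str,
                   out: np.ndarray | None = None) -> np.ndarray:
    """Re-layout (n, H, W, B) cubes for an architecture: single-channel
    volumes (n, 1, B, H, W) for 3D stems, band-planes (n, B, H, W) for 2D.
    Reflectance is clipped to [0, 2].  ``out`` may supply a preallocated
    destination of the target shape."""
    x = np.transpose(np.asarray(images, dtype=np.float32), (0, 3, 1, 2))
    if arch_id in _3D_STEM_ARCHS:
        x = x[:, None]
    if out is None:
        out = np.empty(x.shape, dtype=np.float32)
    np.clip(x, 0.0, 2.0, out=out)
    return out


def _eval(model: Model, X, y0, batch_size):
    losses, correct = 0.0, 0
    n = X.shape[0]
    for i in range(0, n, batch_size):
        xb, yb = X[i:i + batch_size], y0[i:i + batch_size]
        logits = model.forward(xb, training=False)
        loss, _ = softmax_cross_entropy(logits, yb)
        losses += loss * xb.shape[0]
        correct += int((logits.argmax(axis=1) == yb).sum())
    return losses / n, correct / n


@dataclass
class TrainResult:
    history: list
    best_state: tuple
    best_epoch: int
    best_val_accuracy: float


def train_cnn(model: Model, train_set, val_set, config: TrainConfig) -> TrainResult:
    """Train with Adam + step-decayed learning rate; track per-epoch train and
    validation loss/accuracy; return the best-validation-accuracy checkpoint.
    Fully seeded (shuffling, dropout)."""
    X_tr, y_tr = train_set
    X_va, y_va = val_set
    if X_tr.shape[0] == 0:
        raise ValueError("empty training set")
    y0_tr = np.asarray(y_tr, dtype=int) - 1
    y0_va = np.asarray(y_va, dtype=int) - 1
    rng = np.random.default_rng(config.seed)
    model.set_dropout_rng(np.random.default_rng(rng.integers(2**31)))
    opt = Adam(model.parameters(), lr=config.lr0)
    history = []
    best = (-1.0, None, -1)
    n = X_tr.shape[0]
    for epoch in range(1, config.epochs + 1):
        opt.lr = learning_rate(config, epoch)
        order = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            xb, yb = X_tr[idx], y0_tr[idx]
            logits = model.forward(xb, training=True)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            ep_loss += loss * xb.shape[0]
            ep_correct += int((logits.argmax(axis=1) == yb).sum())
        val_loss, val_acc = _eval(model, X_va, y0_va, config.batch_size)
        history.append({
            "epoch": epoch,
            "lr": opt.lr,
            "train_loss": ep_loss / n,
            "train_accuracy": ep_correct / n,
            "val_loss": val_loss,
            "val_accuracy": val_acc,
        })
        if val_acc > best[0]:
            best = (val_acc, model.get_state(), epoch)
    model.set_state(best[1])
    return TrainResult(history=history, best_state=best[1], best_epoch=best[2],
                       best_val_accuracy=best[0])


def predict(model: Model, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Predicted labels 1..K in eval mode."""
    preds = []
    for i in range(0, X.shape[0], batch_size):
        logits = model.forward(X[i:i + batch_size], training=False)
        preds.append(logits.argmax(axis=1) + 1)
    return np.concatenate(preds)


# ---------------------------------------------------------------------------
# repeated-split experiment
# ---------------------------------------------------------------------------

def _default_runner(arch_id, train, val, test, seed, train_config, n_bands, n_classes):
    cfg = ArchitectureConfig(arch_id=arch_id, n_bands=n_bands, n_classes=n_classes)
    model = build_model(cfg, seed=seed)
    tc = replace(train_config, seed=seed)
    X_tr = to_model_input(train[0], arch_id)
    X_va = to_model_input(val[0], arch_id)
    X_te = to_model_input(test[0], arch_id)
    train_cnn(model, (X_tr, train[1]), (X_va, val[1]), tc)
    return predict(model, X_te)


def repeat_experiment(
    arch_ids,
    pool,            # (images (n,H,W,B), labels, leaf_ids) — the 80% train+val pool
    test,            # (images, labels) — fixed held-out 20%
    n_repeats: int = 5,
    seed: int = 0,
    train_config: TrainConfig | None = None,
    runner=None,
):
    """Repeated random 60/20 re-splitting of the train+validation pool with a
    frozen test fold; reports mean +/- sd accuracy per architecture and the
    pairwise Dunn-Bonferroni comparison across architectures.

    The re-split is stratified by class at the leaf level, so sub-blocks and
    augmented copies of one leaf never straddle the train/val boundary.
    """
    from .evaluation import classification_metrics, confusion, dunn_bonferroni

    train_config = train_config or TrainConfig()
    images, labels, leaf_ids = pool
    labels = np.asarray(labels)
    leaf_ids = np.asarray(leaf_ids)
    test_images, test_labels = test
    n_classes = int(max(labels.max(), np.max(test_labels)))
    runner = runner or (
        lambda a, tr, va, te, s: _default_runner(
            a, tr, va, te, s, train_config, images.shape[-1], n_classes)
    )
    ss = np.random.SeedSequence(seed)
    accs = {a: [] for a in arch_ids}
    reports = {a: [] for a in arch_ids}
    for rep_ss in ss.spawn(n_repeats):
        rep_seed = int(rep_ss.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(rep_seed)
        # leaf-level stratified 75/25 split of the pool (= 60/20 of the total)
        leaf_label = {}
        for lid, lab in zip(leaf_ids, labels):
            leaf_label[lid] = lab
        tr_leaves, va_leaves = set(), set()
        for lab in np.unique(list(leaf_label.values())):
            lids = sorted(l for l, la in leaf_label.items() if la == lab)
            lids = [lids[i] for i in rng.permutation(len(lids))]
            cut = int(round(len(lids) * 0.75))
            tr_leaves.update(lids[:cut])
            va_leaves.update(lids[cut:])
        tr_idx = np.array([i for i, l in enumerate(leaf_ids) if l in tr_leaves])
        va_idx = np.array([i for i, l in enumerate(leaf_ids) if l in va_leaves])
        for arch in arch_ids:
            y_pred = runner(
                arch,
                (images[tr_idx], labels[tr_idx]),
                (images[va_idx], labels[va_idx]),
                (test_images, test_labels),
                rep_seed,
            )
            cm = confusion(test_labels, y_pred, n_classes)
            rep = classification_metrics(cm)
            accs[arch].append(rep.accuracy)
            reports[arch].append(rep)
    stats_table = {}
    for arch in arch_ids:
        v = np.asarray(accs[arch])
        stats_table[arch] = {
            "accuracy_mean": float(v.mean()),
            "accuracy_sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            "cell": f"{100 * v.mean():.2f} ± {100 * (v.std(ddof=1) if v.size > 1 else 0.0):.2f}",
            "values": v,
            "reports": reports[arch],
        }
    dunn = dunn_bonferroni({a: accs[a] for a in arch_ids}) if (
        len(arch_ids) >= 2 and n_repeats >= 3
    ) else None
    return {"per_arch": stats_table, "dunn": dunn}
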