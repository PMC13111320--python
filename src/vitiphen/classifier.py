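"""Depthwise-separable CNN stage classifier.

The trunk is a MobileNetV2-style stack adapted to 26x3x1 pseudo-images: a 3x3
stem (stride 1, 'same' padding), 16 inverted-residual bottleneck blocks whose
stride-2 steps act only along the 26-row time axis (the 3-wide feature axis is
never collapsed), a 1x1 projection to a 32- or 64-wide feature map, global
average pooling, one hidden dense layer and a 4-way softmax head. Widths scale
with a width multiplier so the same architecture runs from desk-scale to the
full-width configuration.

Losses: plain categorical cross-entropy, class-weighted cross-entropy (static
or with per-epoch adaptive weights driven by per-class validation error
rates), and focal loss. Class weights are renormalized to sum to 1 after every
update.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from vitiphen import nn
from vitiphen.preprocessing import NormalizationParams, build_pseudo_image
from vitiphen.stages import N_INTERVALS, STAGE_INDEX, STAGE_ORDER, STAGES, interval_midpoint_day
from vitiphen.synthetic_data import SiteSeries

__all__ = [
    "ConvCostSpec",
    "save_model",
    "load_model",
    "conv_cost",
    "NetworkSpec",
    "PhenologyNet",
    "build_network",
    "LossConfig",
    "WEIGHT_MAPPINGS",
    "ClassWeightState",
    "update_class_weights",
    "compute_loss",
    "make_samples",
    "train_model",
    "predict_stages",
    "transitions_from_stages",
]


# --------------------------------------------------------------------------
# separable-convolution cost accounting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvCostSpec:
    """Multiply-add cost model of one convolutional layer.

    ``d_k``: square kernel size, ``m``: input channels, ``n``: output
    channels, ``d_f``: square output spatial size.
    """

    d_k: int
    m: int
    n: int
    d_f: int

    def __post_init__(self) -> None:
        if min(self.d_k, self.m, self.n, self.d_f) < 1:
            raise ValueError("all cost-spec fields must be positive integers")


def conv_cost(spec: ConvCostSpec) -> tuple[int, int, float]:
    """Multiply-add counts for standard vs depthwise-separable convolution.

    Returns ``(z_standard, z_separable, ratio)`` where the ratio equals
    ``1/n + 1/d_k**2`` exactly.
    """
    z_n = spec.d_k**2 * spec.m * spec.n * spec.d_f**2
    z_s = spec.d_k**2 * spec.m * spec.d_f**2 + spec.m * spec.n * spec.d_f**2
    return z_n, z_s, z_s / z_n


# --------------------------------------------------------------------------
# network
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkSpec:
    """Architecture constants of the adapted trunk."""

    input_rows: int = N_INTERVALS
    input_cols: int = 3
    stem_filters: int = 32
    n_blocks: int = 16
    width_multiplier: float = 1.0
    expansion: int = 4
    final_feature_width: int = 64
    n_classes: int = 4

    def __post_init__(self) -> None:
        if self.final_feature_width not in (32, 64):
            raise ValueError("final_feature_width must be 32 or 64")


# Base output widths of the 16 bottleneck blocks (before the width
# multiplier); stride-2 rows mark the blocks that halve the time axis.
_BLOCK_PLAN = [
    (16, 1), (16, 1),
    (24, 2), (24, 1),
    (32, 2), (32, 1), (32, 1),
    (48, 2), (48, 1), (48, 1),
    (64, 2), (64, 1), (64, 1),
    (64, 1), (64, 1), (64, 1),
]


def _width(base: int, multiplier: float) -> int:
    return max(4, int(round(base * multiplier)))


class PhenologyNet:
    """The assembled classifier: trunk + pooled head emitting 4 logits."""

    def __init__(self, spec: NetworkSpec, dropout: float, kernel_size: int, seed: int = 0):
        if kernel_size not in (3, 5):
            raise ValueError("kernel_size must be 3 or 5")
        if spec.input_cols < 3 and kernel_size > 3:  # pragma: no cover - guard
            raise ValueError("kernel too wide for input")
        rng = np.random.default_rng(seed)
        self.spec = spec
        layers: list[nn.Layer] = [
            nn.Conv2d(1, _width(spec.stem_filters, spec.width_multiplier), kernel_size, rng=rng),
            nn.BatchNorm2d(_width(spec.stem_filters, spec.width_multiplier)),
            nn.ReLU6(),
        ]
        in_ch = _width(spec.stem_filters, spec.width_multiplier)
        plan = _BLOCK_PLAN[: spec.n_blocks]
        for base_out, stride_rows in plan:
            out_ch = _width(base_out, spec.width_multiplier)
            layers.append(
                nn.InvertedResidual(
                    in_ch, out_ch, 3, stride=(stride_rows, 1), expansion=spec.expansion, rng=rng
                )
            )
            in_ch = out_ch
        layers += [
            nn.Conv2d(in_ch, spec.final_feature_width, 1, rng=rng),
            nn.BatchNorm2d(spec.final_feature_width),
            nn.ReLU6(),
            nn.GlobalAvgPool(),
            nn.Dense(spec.final_feature_width, spec.final_feature_width, rng=rng),
        ]
        self.trunk = nn.Sequential(*layers)
        self.head_act = nn.ReLU6()
        self.head_drop = nn.Dropout(dropout, rng=np.random.default_rng(seed + 1))
        self.head = nn.Dense(spec.final_feature_width, spec.n_classes, rng=rng)

    # -- plumbing ----------------------------------------------------------

    def params(self):
        return self.trunk.params() + self.head.params()

    @property
    def param_count(self) -> int:
        return sum(p.size for p, _ in self.params())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1:] != (1, self.spec.input_rows, self.spec.input_cols):
            raise ValueError(
                f"expected input (batch, 1, {self.spec.input_rows}, {self.spec.input_cols}),"
                f" got {x.shape}"
            )
        h = self.trunk.forward(np.ascontiguousarray(x, dtype=np.float32), train)
        h = self.head_act.forward(h, train)
        h = self.head_drop.forward(h, train)
        return self.head.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.head.backward(dlogits)
        g = self.head_drop.backward(g)
        g = self.head_act.backward(g)
        self.trunk.backward(g)

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch_size):
            logits = self.forward(x[i : i + batch_size], train=False)
            out.append(_softmax(logits))
        return np.concatenate(out, axis=0)


def build_network(
    spec: NetworkSpec | None = None,
    dropout: float = 0.45,
    kernel_size: int = 3,
    seed: int = 0,
) -> PhenologyNet:
    return PhenologyNet(spec or NetworkSpec(), dropout, kernel_size, seed)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# --------------------------------------------------------------------------
# losses and adaptive class weights
# --------------------------------------------------------------------------

WEIGHT_MAPPINGS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "identity": lambda y: y,
    "cube": lambda y: y**3,
    "exp": lambda y: np.exp(y),
    "exp100": lambda y: np.exp(100.0 * y),
    "ten_y": lambda y: 10.0**y,
}


@dataclass
class LossConfig:
    mode: str = "weighted_ce"  # plain_ce | weighted_ce | focal
    weight_mapping: str = "exp"
    focal_exponent: float = 2.0
    weights: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    adaptive: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("plain_ce", "weighted_ce", "focal"):
            raise ValueError(f"unknown loss mode {self.mode!r}")
        if self.weight_mapping not in WEIGHT_MAPPINGS:
            raise ValueError(f"unknown weight mapping {self.weight_mapping!r}")
        if self.focal_exponent < 0:
            raise ValueError("focal_exponent must be >= 0")
        self.weights = np.asarray(self.weights, dtype=float)


@dataclass
class ClassWeightState:
    """Per-class validation recall, error rate and normalized weights."""

    recall: np.ndarray  # TS_j: true-positive fraction per class
    error_rate: np.ndarray  # Mr_j = 1 - TS_j
    weights: np.ndarray  # normalized to sum 1
    epoch: int = 0


def update_class_weights(
    confusion: np.ndarray,
    mapping: str | Callable[[np.ndarray], np.ndarray] = "exp",
    prev: ClassWeightState | None = None,
) -> ClassWeightState:
    """Recompute adaptive class weights from a confusion-count matrix.

    ``confusion[i, j]`` counts true class ``i`` predicted ``j``. The
    true-positive fraction is per-class recall; a class with no samples this
    epoch carries its previous recall forward (1.0 if there is no history).
    Weights are ``alpha(Mr_j)`` renormalized to a probability vector.
    """
    conf = np.asarray(confusion, dtype=float)
    if conf.shape[0] != conf.shape[1]:
        raise ValueError("confusion matrix must be square")
    alpha = WEIGHT_MAPPINGS[mapping] if isinstance(mapping, str) else mapping
    support = conf.sum(axis=1)
    recall = np.ones(conf.shape[0]) if prev is None else prev.recall.copy()
    seen = support > 0
    recall[seen] = np.diag(conf)[seen] / support[seen]
    mr = 1.0 - recall
    raw = np.asarray(alpha(mr), dtype=float)
    total = raw.sum()
    # mappings with alpha(0) = 0 (identity, cube, ...) degenerate when every
    # class is perfectly recalled; fall back to uniform weights
    weights = raw / total if total > 0 else np.full(mr.size, 1.0 / mr.size)
    return ClassWeightState(
        recall=recall, error_rate=mr, weights=weights, epoch=(prev.epoch + 1 if prev else 1)
    )


_EPS = 1e-12


def compute_loss(probs: np.ndarray, onehot: np.ndarray, cfg: LossConfig) -> float:
    """Mean loss of a batch of probability vectors against one-hot labels."""
    p = np.clip(np.asarray(probs, dtype=float), _EPS, 1.0)
    z = np.asarray(onehot, dtype=float)
    logp = np.log(p)
    if cfg.mode == "plain_ce":
        per = -(z * logp).sum(axis=1)
    elif cfg.mode == "weighted_ce":
        per = -(z * (cfg.weights[None, :] * logp)).sum(axis=1)
    else:  # focal
        per = -(z * (1.0 - p) ** cfg.focal_exponent * logp).sum(axis=1)
    return float(per.mean())


def _loss_grad_logits(
    logits: np.ndarray, onehot: np.ndarray, cfg: LossConfig
) -> tuple[float, np.ndarray]:
    """Loss value and gradient w.r.t. logits (softmax folded in)."""
    s = _softmax(logits)
    z = np.asarray(onehot, dtype=float)
    b = logits.shape[0]
    loss = compute_loss(s, z, cfg)
    if cfg.mode == "plain_ce":
        grad = (s - z) / b
    elif cfg.mode == "weighted_ce":
        wy = (z * cfg.weights[None, :]).sum(axis=1, keepdims=True)
        grad = wy * (s - z) / b
    else:  # focal
        a = cfg.focal_exponent
        p = np.clip((s * z).sum(axis=1), _EPS, 1.0)  # prob of the true class
        dl_dp = a * (1.0 - p) ** (a - 1.0) * np.log(p) - (1.0 - p) ** a / p
        # chain rule with dp/dlogit_k = p * (z_k - s_k)
        grad = dl_dp[:, None] * p[:, None] * (z - s) / b
    return loss, grad


# --------------------------------------------------------------------------
# training data assembly
# --------------------------------------------------------------------------

def make_samples(
    collection: Sequence[SiteSeries],
    params: NormalizationParams | None = None,
    causal: bool = True,
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int]]]:
    """Per-interval training samples from preprocessed site-seasons.

    Each non-pre-season interval ``t`` yields one sample: the causal
    pseudo-image up to ``t`` (full image when ``causal=False``) labeled with
    the stage at ``t``. Returns ``(X (n,1,26,3), y (n,) class index, meta)``
    with meta entries ``(site_id, interval)``.
    """
    xs, ys, meta = [], [], []
    for s in collection:
        for t in range(1, N_INTERVALS + 1):
            stage = s.timeline.stage_per_interval[t - 1]
            if stage == "pre_season":
                continue
            img = build_pseudo_image(s, t if causal else N_INTERVALS, params)
            xs.append(img.tensor)
            ys.append(STAGES.index(stage))
            meta.append((s.site_id, t))
    return np.stack(xs), np.array(ys, dtype=int), meta


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, k: int = 4) -> np.ndarray:
    conf = np.zeros((k, k), dtype=int)
    np.add.at(conf, (y_true, y_pred), 1)
    return conf


def train_model(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    theta: Mapping[str, float | int],
    loss_cfg: LossConfig | None = None,
    seed: int = 42,
    spec: NetworkSpec | None = None,
) -> tuple[PhenologyNet, list[dict]]:
    """Train a classifier under hyperparameters ``theta``.

    ``theta`` carries learning_rate, batch_size, dropout, kernel_size and
    epochs. With an adaptive loss configuration the class weights are
    recomputed after every epoch from the validation confusion matrix.
    Deterministic under ``seed``. Raises if a stage class is absent from the
    training labels.
    """
    loss_cfg = loss_cfg or LossConfig()
    n_classes = (spec or NetworkSpec()).n_classes
    present = np.bincount(y_train, minlength=n_classes)
    for ci, cnt in enumerate(present):
        if cnt == 0:
            raise ValueError(f"class {STAGES[ci]!r} absent from the training set")

    model = build_network(
        spec, dropout=float(theta["dropout"]), kernel_size=int(theta["kernel_size"]), seed=seed
    )
    opt = nn.Adam(model.params(), lr=float(theta["learning_rate"]))
    rng = np.random.default_rng(seed + 1)
    batch = int(theta["batch_size"])
    epochs = int(theta["epochs"])

    weight_state: ClassWeightState | None = None
    history: list[dict] = []
    n = x_train.shape[0]
    for epoch in range(1, epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, batch):
            idx = order[i : i + batch]
            xb, yb = x_train[idx], y_train[idx]
            onehot = np.eye(n_classes)[yb]
            logits = model.forward(xb, train=True)
            loss, grad = _loss_grad_logits(logits, onehot, loss_cfg)
            model.backward(grad)
            opt.step()
            epoch_loss += loss * len(idx)
        epoch_loss /= n

        val_probs = model.predict_proba(x_val)
        val_pred = val_probs.argmax(axis=1)
        conf = _confusion(y_val, val_pred, n_classes)
        val_loss = compute_loss(val_probs, np.eye(n_classes)[y_val], loss_cfg)
        if loss_cfg.mode == "weighted_ce" and loss_cfg.adaptive:
            weight_state = update_class_weights(conf, loss_cfg.weight_mapping, weight_state)
            loss_cfg.weights = weight_state.weights
        recall = np.where(conf.sum(axis=1) > 0, np.diag(conf) / np.maximum(conf.sum(axis=1), 1), np.nan)
        history.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss,
                "val_loss": val_loss,
                "val_accuracy": float((val_pred == y_val).mean()),
                "per_class_recall": recall.tolist(),
                "class_weights": loss_cfg.weights.tolist(),
            }
        )
    return model, history


# --------------------------------------------------------------------------
# inference
# --------------------------------------------------------------------------

def predict_stages(
    model: PhenologyNet, series: SiteSeries, params: NormalizationParams | None = None
) -> tuple[list[str], np.ndarray]:
    """Classify every interval of a site-season from its causal pseudo-image.

    Returns the 26 predicted stage names and the (26, 4) probability matrix.
    """
    imgs = np.stack(
        [build_pseudo_image(series, t, params).tensor for t in range(1, N_INTERVALS + 1)]
    )
    probs = model.predict_proba(imgs)
    stages = [STAGES[i] for i in probs.argmax(axis=1)]
    return stages, probs


def transitions_from_stages(
    stage_per_interval: Sequence[str], season_start_day: int = 1
) -> dict[str, int]:
    """Stage-onset days from a per-interval stage sequence.

    The sequence is first monotonized by a running maximum over the stage
    order (phenology cannot regress); the onset of a stage is the midpoint day
    of the first interval carrying it. Stages never predicted have no onset.
    """
    idx = [STAGE_INDEX[s] for s in stage_per_interval]
    mono = np.maximum.accumulate(idx)
    onsets: dict[str, int] = {}
    for i, si in enumerate(mono):
        name = STAGE_ORDER[si]
        if name != "pre_season" and name not in onsets:
            onsets[name] = interval_midpoint_day(i + 1, season_start_day)
    return onsets


# --------------------------------------------------------------------------
# checkpointing
# --------------------------------------------------------------------------

def save_model(model: PhenologyNet, path_prefix: str, extra: dict | None = None) -> None:
    """Write weights (``<prefix>.npz``) and a JSON sidecar (``<prefix>.json``)
    holding the architecture spec, dropout/kernel settings and any extra
    metadata (normalization params, seed, theta)."""
    import json
    from dataclasses import asdict

    arrays = {f"p{i}": p for i, (p, _) in enumerate(model.params())}
    bn_state = {}
    idx = 0
    for layer in _iter_bn(model):
        bn_state[f"bn{idx}_mean"] = layer.running_mean
        bn_state[f"bn{idx}_var"] = layer.running_var
        idx += 1
    np.savez(path_prefix + ".npz", **arrays, **bn_state)
    meta = {
        "spec": asdict(model.spec),
        "dropout": model.head_drop.rate,
        "kernel_size": model.trunk.layers[0].k,
        "extra": extra or {},
    }
    with open(path_prefix + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_model(path_prefix: str) -> tuple[PhenologyNet, dict]:
    import json

    with open(path_prefix + ".json") as fh:
        meta = json.load(fh)
    spec = NetworkSpec(**meta["spec"])
    model = PhenologyNet(spec, meta["dropout"], meta["kernel_size"], seed=0)
    data = np.load(path_prefix + ".npz")
    for i, (p, _) in enumerate(model.params()):
        p[...] = data[f"p{i}"]
    for idx, layer in enumerate(_iter_bn(model)):
        layer.running_mean = data[f"bn{idx}_mean"]
        layer.running_var = data[f"bn{idx}_var"]
    return model, meta["extra"]


def _iter_bn(model: PhenologyNet):
    stack = list(model.trunk.layers)
    while stack:
        layer = stack.pop(0)
        if isinstance(layer, nn.BatchNorm2d):
            yield layer
        elif isinstance(layer, nn.InvertedResidual):
            stack = list(layer.body.layers) + stack
        elif isinstance(layer, nn.Sequential):
            stack = list(layer.layers) + stack
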