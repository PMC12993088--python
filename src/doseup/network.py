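"""Dense convolutional super-resolution network for array measurements.

Architecture
------------
A DenseNet-style fully convolutional model mapping a 1-channel H x W masked
array measurement to a 1-channel 3H x 3W dose map:

* stem: 3x3 convolution, 1 -> ``stem_channels`` (16) feature maps;
* dense block 1 (16 layers): each layer is ReLU -> 3x3 convolution producing
  ``growth_rate`` (8) new channels, concatenated onto everything before it in
  the block (16 -> 24 -> 32 -> ... -> 144 channels);
* a transposed convolution with 3x3 kernel and stride 3 (channel-preserving)
  that triples the spatial resolution;
* dense block 2 (4 layers) at the high resolution;
* head: 1x1 convolution to a single channel.

Training minimizes MSE plus an equivariance penalty: for a square symmetry g,
the features of the transformed input must match the transformed features of
the original input, evaluated at every dense-layer output and at the network
output.  Optimization uses AdamW under a cosine-annealing learning-rate
schedule with warm restarts (cycle lengths 16, 32, 64 epochs).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from ._autodiff import Var
from .detector import ArrayMeasurement
from .grids import DoseGrid
from .symmetry import D4, d4_apply

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "TrainingHistory",
    "DenseUpsampler",
    "build_network",
    "equivariance_loss",
    "lr_at",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class NetworkSpec:
    """Architecture hyperparameters.

    The defaults are the full-scale model; :meth:`scaled` returns the reduced
    profile (4 + 2 dense layers) used for CPU-scale experiments.
    """

    stem_channels: int = 16
    block1_layers: int = 16
    block2_layers: int = 4
    growth_rate: int = 8
    upsample_kernel: int = 3
    upsample_stride: int = 3
    layer_kernel: int = 3
    activation: str = "relu"
    normalization: str = "none"

    def __post_init__(self) -> None:
        if self.upsample_kernel != self.upsample_stride:
            raise ValueError("transposed convolution requires kernel == stride")
        if self.layer_kernel != 3 or self.activation != "relu":
            raise ValueError("only 3x3 ReLU dense layers are supported")

    @classmethod
    def scaled(cls) -> "NetworkSpec":
        return cls(block1_layers=4, block2_layers=2)

    def channel_widths(self) -> dict:
        """Concatenated channel counts after the stem and after each layer."""
        b1 = [self.stem_channels + k * self.growth_rate
              for k in range(self.block1_layers + 1)]
        b2 = [b1[-1] + k * self.growth_rate for k in range(self.block2_layers + 1)]
        return {"block1": b1, "block2": b2}


class DenseUpsampler:
    """The dense super-resolution model; weights live in ``params``."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        self.params: dict[str, Var] = {}
        rng = np.random.default_rng(seed)

        def p(name, shape, std):
            self.params[name] = Var(
                rng.normal(0.0, std, size=shape), requires_grad=True, name=name
            )

        def zeros(name, shape):
            self.params[name] = Var(
                np.zeros(shape, dtype=np.float32), requires_grad=True, name=name
            )

        g = spec.growth_rate
        p("stem.w", (3, 3, 1, spec.stem_channels), math.sqrt(2.0 / 9.0))
        zeros("stem.b", (spec.stem_channels,))
        c = spec.stem_channels
        for k in range(spec.block1_layers):
            p(f"b1.{k}.w", (3, 3, c, g), math.sqrt(2.0 / (9 * c)))
            zeros(f"b1.{k}.b", (g,))
            c += g
        p("up.w", (3, 3, c, c), math.sqrt(2.0 / c))
        zeros("up.b", (c,))
        for k in range(spec.block2_layers):
            p(f"b2.{k}.w", (3, 3, c, g), math.sqrt(2.0 / (9 * c)))
            zeros(f"b2.{k}.b", (g,))
            c += g
        p("head.w", (c, 1), math.sqrt(2.0 / c))
        zeros("head.b", (1,))

    def parameters(self) -> list[Var]:
        return list(self.params.values())

    def zero_grad(self) -> None:
        for v in self.params.values():
            v.zero_grad()

    def forward(self, x, collect_taps: bool = False) -> tuple[Var, list[Var]]:
        """Run the network on a (N, H, W, 1) batch.

        Returns the (N, 3H, 3W, 1) output and, if requested, the list of
        dense-layer feature maps (the taps of the equivariance loss).
        """
        if not isinstance(x, Var):
            x = Var(x)
        if x.data.ndim != 4 or x.data.shape[-1] != 1:
            raise ValueError("input must have shape (N, H, W, 1)")
        P = self.params
        taps: list[Var] = []
        h = ad.conv3x3(x, P["stem.w"], P["stem.b"])
        for k in range(self.spec.block1_layers):
            f = ad.conv3x3(ad.relu(h), P[f"b1.{k}.w"], P[f"b1.{k}.b"])
            if collect_taps:
                taps.append(f)
            h = ad.concat(h, f)
        h = ad.conv_transpose3(h, P["up.w"], P["up.b"])
        for k in range(self.spec.block2_layers):
            f = ad.conv3x3(ad.relu(h), P[f"b2.{k}.w"], P[f"b2.{k}.b"])
            if collect_taps:
                taps.append(f)
            h = ad.concat(h, f)
        out = ad.conv1x1(ad.relu(h), P["head.w"], P["head.b"])
        return out, taps


def build_network(spec: NetworkSpec | None = None, seed: int = 0) -> DenseUpsampler:
    """Construct the model from an architecture spec."""
    return DenseUpsampler(spec or NetworkSpec(), seed=seed)


# --------------------------------------------------------------------------
# losses
# --------------------------------------------------------------------------


def _equivariance_terms(
    model: DenseUpsampler,
    x: np.ndarray,
    g_idx: int,
    out: Var,
    taps: list[Var],
    tap_mode: str,
) -> Var:
    """Mean equivariance error for one transform, reusing the plain forward."""
    xt = np.ascontiguousarray(d4_apply(x, g_idx, axes=(1, 2)))
    out_t, taps_t = model.forward(xt, collect_taps=(tap_mode == "all"))
    feats = (taps + [out]) if tap_mode == "all" else [out]
    feats_t = (taps_t + [out_t]) if tap_mode == "all" else [out_t]
    total: Var | None = None
    for f, ft in zip(feats, feats_t):
        term = ad.mse(ft, ad.d4t(f, g_idx))
        total = term if total is None else ad.add(total, term)
    return ad.scale(total, 1.0 / len(feats))


def equivariance_loss(
    model: DenseUpsampler,
    batch: np.ndarray,
    transforms=(1,),
    tap_mode: str = "all",
) -> float:
    """Mean equivariance error of the model over a batch and transforms.

    For each square symmetry ``g`` the error compares the features (all dense
    layers plus the output when ``tap_mode="all"``; output only when
    ``tap_mode="output"``) of the transformed input against the transformed
    features of the original input, with MSE averaged over taps and
    transforms.  Zero exactly when every compared pair of maps is identical.
    """
    transforms = tuple(transforms)
    if not transforms:
        raise ValueError("transforms must be non-empty")
    for g in transforms:
        if g not in D4:
            raise ValueError(f"not a square symmetry index: {g}")
    if tap_mode not in ("all", "output"):
        raise ValueError("tap_mode must be 'all' or 'output'")
    x = np.asarray(batch, dtype=np.float32)
    out, taps = model.forward(x, collect_taps=(tap_mode == "all"))
    total = 0.0
    for g in transforms:
        total += float(_equivariance_terms(model, x, g, out, taps, tap_mode).data)
    return total / len(transforms)


# --------------------------------------------------------------------------
# learning-rate schedule and optimizer
# --------------------------------------------------------------------------


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    The default epoch count 112 decomposes into cosine-annealing cycles of
    16 + 32 + 64 epochs (warm restarts at epochs 16 and 48).
    """

    epochs: int = 112
    batch_size: int = 32
    lr0: float = 1e-3
    lr_min: float = 1e-6
    first_cycle: int = 16
    cycle_mult: int = 2
    weight_decay: float = 1e-2
    betas: tuple[float, float] = (0.9, 0.999)
    eps: float = 1e-8
    w_eq: float = 1.0
    eq_transforms: tuple[int, ...] = tuple(range(1, 8))
    tap_mode: str = "all"
    resample_noise: float | None = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class TrainingHistory:
    """Per-epoch traces recorded by :func:`train`."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)


def lr_at(epoch: int, cfg: TrainConfig) -> float:
    """Closed-form cosine-annealing-with-warm-restarts learning rate.

    Cycle lengths are ``first_cycle * cycle_mult**k`` (16, 32, 64, ...); the
    rate equals ``lr0`` at every cycle start (epochs 0, 16, 48 by default) and
    decays to ``lr_min`` along a half cosine within each cycle.
    """
    if not 0 <= epoch < cfg.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs})")
    start, length = 0, cfg.first_cycle
    while epoch >= start + length:
        start += length
        length *= cfg.cycle_mult
    t = (epoch - start) / length
    return cfg.lr_min + (cfg.lr0 - cfg.lr_min) * (1.0 + math.cos(math.pi * t)) / 2.0


class AdamW:
    """AdamW with decoupled weight decay."""

    def __init__(self, params: list[Var], cfg: TrainConfig):
        self.params = params
        self.cfg = cfg
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        b1, b2 = self.cfg.betas
        self.t += 1
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mh = self.m[i] / bc1
            vh = self.v[i] / bc2
            p.data -= np.float32(lr) * (
                mh / (np.sqrt(vh) + self.cfg.eps)
            ) + np.float32(lr * self.cfg.weight_decay) * p.data


# --------------------------------------------------------------------------
# training and inference
# --------------------------------------------------------------------------


def _pair_arrays(pairs) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack pairs into arrays: stored inputs, targets, pooled targets, mask."""
    x = np.stack([p.input.grid.values for p in pairs]).astype(np.float32)[..., None]
    y = np.stack([p.target.values for p in pairs]).astype(np.float32)[..., None]
    k = pairs[0].input.layout.grid_pitch_mm / pairs[0].target.spacing_mm
    k = int(round(k))
    n, hh, ww, _ = y.shape
    pooled = y.reshape(n, hh // k, k, ww // k, k, 1).mean(axis=(2, 4))
    mask = pairs[0].input.layout.chamber_mask.astype(np.float32)[None, :, :, None]
    return x, y, pooled, mask


def train(
    model: DenseUpsampler,
    train_pairs,
    val_pairs,
    cfg: TrainConfig | None = None,
) -> tuple[DenseUpsampler, TrainingHistory]:
    """Train the model with the compound MSE + equivariance loss.

    One square symmetry is drawn per batch for the equivariance term.  When
    ``resample_noise`` is set, the measurement noise of each input is redrawn
    every epoch from the noiseless pooled target (noise as augmentation);
    otherwise the stored noisy inputs are used as-is.  Validation loss is the
    plain MSE on the held-out pairs.  Deterministic for a fixed seed up to the
    numeric backend's reduction order.
    """
    cfg = cfg or TrainConfig()
    if not train_pairs or not val_pairs:
        raise ValueError("train and validation sets must be non-empty")
    train_sims = {p.sim_id for p in train_pairs}
    if train_sims & {p.sim_id for p in val_pairs}:
        raise ValueError("train and validation sets share sim_ids")
    rng = np.random.default_rng(cfg.seed)
    x_tr, y_tr, pooled_tr, mask = _pair_arrays(train_pairs)
    x_va, y_va, _, _ = _pair_arrays(val_pairs)
    opt = AdamW(model.parameters(), cfg)
    hist = TrainingHistory()
    n = len(train_pairs)
    use_eq = cfg.w_eq > 0 and len(cfg.eq_transforms) > 0

    for epoch in range(cfg.epochs):
        lr = lr_at(epoch, cfg)
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            yb = y_tr[idx]
            if cfg.resample_noise is not None:
                sigma = cfg.resample_noise * yb.reshape(len(idx), -1).max(axis=1)
                noise = rng.standard_normal(pooled_tr[idx].shape).astype(np.float32)
                xb = np.clip(pooled_tr[idx] + sigma[:, None, None, None] * noise, 0, None)
                xb = np.ascontiguousarray(xb * mask)
            else:
                xb = x_tr[idx]
            model.zero_grad()
            out, taps = model.forward(xb, collect_taps=use_eq and cfg.tap_mode == "all")
            loss = ad.mse(out, Var(yb))
            if use_eq:
                g_idx = int(rng.choice(cfg.eq_transforms))
                eq = _equivariance_terms(model, xb, g_idx, out, taps, cfg.tap_mode)
                loss = ad.add(loss, ad.scale(eq, cfg.w_eq))
            ad.backward(loss)
            opt.step(lr)
            losses.append(float(loss.data))
        # validation: plain MSE, no gradient bookkeeping needed
        val_losses = []
        for s in range(0, len(val_pairs), cfg.batch_size):
            out, _ = model.forward(x_va[s : s + cfg.batch_size])
            d = out.data.astype(np.float64) - y_va[s : s + cfg.batch_size]
            val_losses.append(float((d * d).mean()) * len(d))
        hist.train_loss.append(float(np.mean(losses)))
        hist.val_loss.append(float(np.sum(val_losses) / len(val_pairs)))
        hist.lr.append(lr)
    return model, hist


def predict(model: DenseUpsampler, m: ArrayMeasurement) -> DoseGrid:
    """Upsample one masked array measurement to the high-resolution grid.

    The output triples the resolution (53x53 at 5 mm -> 159x159 at 1.67 mm),
    shares the physical center of the measurement, and is clamped at zero.
    """
    x = m.grid.values.astype(np.float32)[None, :, :, None]
    out, _ = model.forward(x)
    values = np.clip(out.data[0, :, :, 0].astype(float), 0.0, None)
    f = 3
    spacing = m.grid.spacing_mm / f
    shift = (f - 1) * m.grid.spacing_mm / (2.0 * f)
    origin = (m.grid.origin_mm[0] - shift, m.grid.origin_mm[1] - shift)
    return DoseGrid(values, spacing, origin)


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------


def save_checkpoint(path, model: DenseUpsampler, train_seed: int | None = None) -> None:
    """Persist architecture spec + weights (+ training seed) as an .npz file."""
    meta = {"spec": model.spec.__dict__, "train_seed": train_seed}
    arrays = {k.replace(".", "__"): v.data for k, v in model.params.items()}
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_checkpoint(path) -> DenseUpsampler:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        spec = NetworkSpec(**meta["spec"])
        model = DenseUpsampler(spec)
        for k, v in model.params.items():
            v.data = z[k.replace(".", "__")].astype(np.float32)
    return model
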