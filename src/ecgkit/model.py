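"""The 1D convolutional classifier.

Architecture: a Conv1D stem expands the single input channel, an evolving
normalization-activation (EvoNorm) layer follows, then four residual blocks,
then flatten and a dense head. Each residual block has two pathways whose
outputs are multiplied elementwise:

* path A: MaxPool1D -> Conv1D (kernel 1, channel projection)
* path B: EvoNorm -> Dropout -> strided Conv1D -> squeeze-and-excitation gate

EvoNorm comes in two series: S0 normalizes by per-sample group variance and
gates with x*sigmoid(v*x); B0 divides by the larger of the batch standard
deviation and v*x plus the instance standard deviation, with running batch
statistics used at inference. The SE gate pools each channel over time,
passes the pooled vector through a two-layer bottleneck, and rescales the
channels by the resulting sigmoid weights.

The EvoNorm layer, the SE gate, and gradient clipping are independent
ablation switches (``use_evo``, ``use_se`` here; ``use_gc`` on the training
side), so the model can be run with any subset of the three components.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Parameter, Tensor

__all__ = [
    "ModelConfig",
    "EvoNorm1d",
    "SEBlock1d",
    "ResidualBlock1d",
    "EcgNet",
    "evo_norm",
    "se_block",
    "build_model",
]

_EPS = 1e-5


@dataclass
class ModelConfig:
    """Every architectural free parameter of the network.

    ``input_len``/``in_channels`` are 187/1 for beat tasks and 3000/4 for the
    rhythm (atrial-fibrillation) task. ``n_classes`` is 5, 2, or 1 (a single
    sigmoid unit for binary tasks). ``se_ratio`` defaults to 0.25. The
    ablation switches ``use_se``/``use_evo`` disable the squeeze-and-
    excitation gates and the EvoNorm layers respectively.
    """

    input_len: int = 187
    in_channels: int = 1
    n_classes: int = 5
    stem_filters: int = 32
    stem_kernel: int = 5
    block_filters: tuple = (64, 128, 192, 256)
    block_kernel: int = 5
    pool_size: int = 2
    dropout: float = 0.1
    se_ratio: float = 0.25
    evo_variant: str = "S0"  # S0 | B0 | none
    evo_groups: int = 8
    use_se: bool = True
    use_evo: bool = True
    head_hidden: int = 64

    def __post_init__(self):
        if not 0.0 < self.se_ratio <= 1.0:
            raise ValueError(f"se_ratio must be in (0, 1], got {self.se_ratio}")
        if len(self.block_filters) != 4:
            raise ValueError("block_filters must list exactly 4 widths")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.evo_variant not in ("S0", "B0", "none"):
            raise ValueError(f"unknown EvoNorm variant {self.evo_variant!r}")
        if self.use_evo and self.evo_variant == "S0":
            for c in (self.stem_filters, *self.block_filters):
                if c % self.evo_groups:
                    raise ValueError(
                        f"evo_groups={self.evo_groups} must divide channel width {c}"
                    )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "ModelConfig":
        d = json.loads(Path(path).read_text())
        d["block_filters"] = tuple(d["block_filters"])
        return cls(**d)


# ---------------------------------------------------------------------------
# functional forms (ndarray in, ndarray out) used by tests and docs
# ---------------------------------------------------------------------------

def evo_norm(x, variant: str, groups: int, gamma, beta, v,
             eps: float = _EPS, training: bool = True,
             running_var=None) -> np.ndarray:
    """Evolving normalization-activation on a (batch, time, channels) array.

    S0: ``y = x*sigmoid(v*x) / sqrt(GroupVar(x)+eps) * gamma + beta`` with the
    group variance taken over time and the channels of each group, per sample.
    B0 (training): ``y = x / max(sqrt(BatchVar+eps), v*x + sqrt(InstVar+eps))
    * gamma + beta``; at inference ``running_var`` replaces the batch variance.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError("expected (batch, time, channels)")
    B, T, C = x.shape
    gamma = np.broadcast_to(np.asarray(gamma, dtype=np.float64), (C,))
    beta = np.broadcast_to(np.asarray(beta, dtype=np.float64), (C,))
    v = np.broadcast_to(np.asarray(v, dtype=np.float64), (C,))
    if variant == "S0":
        if C % groups:
            raise ValueError(f"channels {C} not divisible by groups {groups}")
        xg = x.reshape(B, T, groups, C // groups)
        var = xg.var(axis=(1, 3), keepdims=True)  # (B,1,G,1)
        den = np.sqrt(var + eps)
        num = x * _sigmoid_np(v * x)
        y = (num.reshape(B, T, groups, C // groups) / den).reshape(B, T, C)
        return y * gamma + beta
    if variant == "B0":
        inst_sd = np.sqrt(x.var(axis=1, keepdims=True) + eps)  # (B,1,C)
        if training or running_var is None:
            batch_sd = np.sqrt(x.var(axis=(0, 1)) + eps)  # (C,)
        else:
            batch_sd = np.sqrt(np.asarray(running_var) + eps)
        den = np.maximum(batch_sd, v * x + inst_sd)
        return x / den * gamma + beta
    raise ValueError(f"unknown EvoNorm variant {variant!r}")


def _sigmoid_np(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def se_reduced_width(channels: int, ratio: float) -> int:
    return max(1, int(round(ratio * channels)))


def se_block(x, w1, b1, w2, b2) -> np.ndarray:
    """Squeeze-and-excitation on a (batch, time, channels) array.

    Squeeze: mean over time per channel. Excitation: dense(C->r) -> ReLU ->
    dense(r->C) -> sigmoid. The input is rescaled per channel by the
    excitation weights, which lie in (0, 1).
    """
    x = np.asarray(x, dtype=np.float64)
    s = x.mean(axis=1)  # (B, C)
    h = np.maximum(s @ w1 + b1, 0.0)
    w = _sigmoid_np(h @ w2 + b2)
    return x * w[:, None, :]


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def _uniform_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = float(np.sqrt(1.0 / fan_in))
    return rng.uniform(-bound, bound, size=shape)


class Conv1d:
    def __init__(self, rng, in_ch, out_ch, kernel, stride=1, pad=0):
        fan_in = kernel * in_ch
        self.w = Parameter(_uniform_init(rng, (kernel, in_ch, out_ch), fan_in))
        self.b = Parameter(np.zeros(out_ch))
        self.stride, self.pad = stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv1d(self.w, self.b, stride=self.stride, pad=self.pad)

    def parameters(self):
        return [self.w, self.b]


class Dense:
    def __init__(self, rng, n_in, n_out):
        self.w = Parameter(_uniform_init(rng, (n_in, n_out), n_in))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    def parameters(self):
        return [self.w, self.b]


class EvoNorm1d:
    """EvoNorm layer (S0 or B0) with per-channel gamma, beta, v parameters."""

    def __init__(self, channels: int, variant: str = "S0", groups: int = 8,
                 eps: float = _EPS, momentum: float = 0.9):
        if variant == "S0" and channels % groups:
            raise ValueError(f"channels {channels} not divisible by groups {groups}")
        self.variant, self.groups, self.eps = variant, groups, eps
        self.gamma = Parameter(np.ones((1, 1, channels)))
        self.beta = Parameter(np.zeros((1, 1, channels)))
        self.v = Parameter(np.ones((1, 1, channels)))
        self.running_var = np.ones(channels)
        self.momentum = momentum

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        B, T, C = x.shape
        if self.variant == "S0":
            g = self.groups
            xg = x.reshape(B, T, g, C // g)
            var = (xg * xg).mean(axis=(1, 3), keepdims=True) - \
                xg.mean(axis=(1, 3), keepdims=True) ** 2
            den = (var + self.eps).sqrt()
            num = x * (self.v * x).sigmoid()
            y = (num.reshape(B, T, g, C // g) / den).reshape(B, T, C)
            return y * self.gamma + self.beta
        # B0
        inst_var = (x * x).mean(axis=1, keepdims=True) - x.mean(axis=1, keepdims=True) ** 2
        inst_sd = (inst_var + self.eps).sqrt()
        if training:
            bvar = (x * x).mean(axis=(0, 1)) - x.mean(axis=(0, 1)) ** 2
            self.running_var = (
                self.momentum * self.running_var
                + (1 - self.momentum) * bvar.data.reshape(-1)
            )
            batch_sd = (bvar + self.eps).sqrt().reshape(1, 1, C)
        else:
            batch_sd = Tensor(np.sqrt(self.running_var + self.eps).reshape(1, 1, C))
        den = batch_sd.maximum(self.v * x + inst_sd)
        return x / den * self.gamma + self.beta

    def parameters(self):
        return [self.gamma, self.beta, self.v]


class _NormBypass:
    """Parameter-free stand-in when EvoNorm is ablated: per-sample
    standardization by the global activation variance, then ReLU."""

    eps = _EPS

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        var = (x * x).mean(axis=(1, 2), keepdims=True) - \
            x.mean(axis=(1, 2), keepdims=True) ** 2
        return (x / (var + self.eps).sqrt()).relu()

    def parameters(self):
        return []


class SEBlock1d:
    """Channel-attention gate: temporal mean -> bottleneck -> sigmoid scale."""

    def __init__(self, rng, channels: int, ratio: float = 0.25):
        r = se_reduced_width(channels, ratio)
        self.fc1 = Dense(rng, channels, r)
        self.fc2 = Dense(rng, r, channels)
        self.reduced_width = r

    def __call__(self, x: Tensor) -> Tensor:
        B, T, C = x.shape
        s = x.mean(axis=1)  # squeeze: (B, C)
        w = self.fc2(self.fc1(s).relu()).sigmoid()
        return x * w.reshape(B, 1, C)

    def parameters(self):
        return self.fc1.parameters() + self.fc2.parameters()


def _stride_pad(t_in: int, kernel: int, stride: int) -> int:
    """Padding making a strided conv emit exactly t_in // stride steps."""
    target = t_in // stride
    lo = stride * (target - 1) - (t_in - kernel)
    hi = stride * target - 1 - (t_in - kernel)
    for two_p in range(max(lo, 0), hi + 1):
        if two_p % 2 == 0:
            return two_p // 2
    raise ValueError(
        f"no symmetric padding matches length {t_in}, kernel {kernel}, stride {stride}"
    )


class ResidualBlock1d:
    """Two-path multiplicative block.

    Path A: MaxPool1D(pool) -> Conv1D(kernel 1). Path B: EvoNorm -> Dropout ->
    Conv1D(kernel, stride=pool) -> SE. Output is the elementwise product;
    both paths emit (time // pool) x filters.
    """

    def __init__(self, rng, cfg: ModelConfig, t_in: int, in_ch: int, out_ch: int):
        self.pool = cfg.pool_size
        self.t_out = t_in // self.pool
        if self.t_out < 1:
            raise ValueError(f"time length {t_in} cannot survive pooling by {self.pool}")
        self.conv_a = Conv1d(rng, in_ch, out_ch, kernel=1)
        pad = _stride_pad(t_in, cfg.block_kernel, self.pool)
        self.conv_b = Conv1d(rng, in_ch, out_ch, cfg.block_kernel,
                             stride=self.pool, pad=pad)
        if cfg.use_evo and cfg.evo_variant != "none":
            self.norm = EvoNorm1d(in_ch, cfg.evo_variant, cfg.evo_groups)
        else:
            self.norm = _NormBypass()
        self.se = SEBlock1d(rng, out_ch, cfg.se_ratio) if cfg.use_se else None
        self.p_drop = cfg.dropout

    def __call__(self, x: Tensor, training: bool = False, rng=None) -> Tensor:
        a = self.conv_a(x.maxpool1d(self.pool))
        b = self.norm(x, training=training)
        if training and self.p_drop > 0 and rng is not None:
            keep = 1.0 - self.p_drop
            mask = (rng.random(b.shape) < keep) / keep
            b = b * Tensor(mask)
        b = self.conv_b(b)
        if self.se is not None:
            b = self.se(b)
        if a.shape != b.shape:  # build-time arithmetic should prevent this
            raise RuntimeError(f"path shape mismatch: {a.shape} vs {b.shape}")
        return a * b

    def parameters(self):
        ps = self.conv_a.parameters() + self.conv_b.parameters() + self.norm.parameters()
        if self.se is not None:
            ps += self.se.parameters()
        return ps


class EcgNet:
    """Stem conv -> EvoNorm -> 4 residual blocks -> flatten -> dense head.

    The head ends in ``n_classes`` logits; ``predict_proba`` applies softmax
    (or a single sigmoid when ``n_classes == 1``).
    """

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        t = cfg.input_len
        k = cfg.stem_kernel
        if k % 2 == 0:
            raise ValueError("stem_kernel must be odd for same-length output")
        self.stem = Conv1d(rng, cfg.in_channels, cfg.stem_filters, k, pad=(k - 1) // 2)
        if cfg.use_evo and cfg.evo_variant != "none":
            self.stem_norm = EvoNorm1d(cfg.stem_filters, cfg.evo_variant, cfg.evo_groups)
        else:
            self.stem_norm = _NormBypass()
        self.blocks = []
        ch = cfg.stem_filters
        for out_ch in cfg.block_filters:
            if t // cfg.pool_size < 1:
                raise ValueError(
                    f"input_len {cfg.input_len} too short to survive 4 poolings"
                )
            self.blocks.append(ResidualBlock1d(rng, cfg, t, ch, out_ch))
            t //= cfg.pool_size
            ch = out_ch
        self.flat_dim = t * ch
        self.fc1 = Dense(rng, self.flat_dim, cfg.head_hidden)
        self.fc2 = Dense(rng, cfg.head_hidden, cfg.n_classes)

    # -- forward -------------------------------------------------------------
    def forward(self, x, training: bool = False, rng=None) -> Tensor:
        """Logits for a (batch, time) or (batch, time, channels) array."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[:, :, None]
        if x.shape[1] != self.cfg.input_len or x.shape[2] != self.cfg.in_channels:
            raise ValueError(
                f"expected input ({self.cfg.input_len}, {self.cfg.in_channels}), "
                f"got {x.shape[1:]}"
            )
        h = Tensor(x)
        h = self.stem(h)
        h = self.stem_norm(h, training=training)
        for blk in self.blocks:
            h = blk(h, training=training, rng=rng)
        h = h.reshape(h.shape[0], self.flat_dim)
        h = self.fc1(h).relu()
        return self.fc2(h)

    def predict_proba(self, x, batch_size: int = 256) -> np.ndarray:
        """Class probabilities: softmax rows, or sigmoid for a single unit."""
        x = np.asarray(x, dtype=np.float64)
        outs = []
        for i in range(0, len(x), batch_size):
            z = self.forward(x[i : i + batch_size]).data
            if self.cfg.n_classes == 1:
                outs.append(_sigmoid_np(z))
            else:
                z = z - z.max(axis=1, keepdims=True)
                e = np.exp(z)
                outs.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(outs, axis=0)

    def predict(self, x) -> np.ndarray:
        p = self.predict_proba(x)
        if self.cfg.n_classes == 1:
            return (p[:, 0] >= 0.5).astype(int)
        return p.argmax(axis=1)

    # -- parameters ----------------------------------------------------------
    def parameters(self):
        ps = self.stem.parameters() + self.stem_norm.parameters()
        for blk in self.blocks:
            ps += blk.parameters()
        return ps + self.fc1.parameters() + self.fc2.parameters()

    def num_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def param_report(self) -> dict:
        rep = {
            "stem": sum(p.data.size for p in self.stem.parameters()
                        + self.stem_norm.parameters()),
            "head": sum(p.data.size for p in self.fc1.parameters()
                        + self.fc2.parameters()),
        }
        for i, blk in enumerate(self.blocks):
            rep[f"block{i}"] = sum(p.data.size for p in blk.parameters())
        rep["total"] = self.num_params()
        return rep

    # -- checkpointing -------------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight list length mismatch")
        for p, w in zip(params, weights):
            if p.data.shape != w.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {w.shape}")
            p.data = np.asarray(w, dtype=np.float64).copy()

    def save(self, path) -> None:
        path = Path(path)
        np.savez(path, *[p.data for p in self.parameters()])
        self.cfg.to_json(path.with_suffix(".json"))

    @classmethod
    def load(cls, path, seed: int = 0) -> "EcgNet":
        path = Path(path)
        cfg = ModelConfig.from_json(path.with_suffix(".json"))
        net = cls(cfg, seed=seed)
        with np.load(path if path.suffix else path.with_suffix(".npz")) as z:
            net.set_weights([z[k] for k in z.files])
        return net


def build_model(cfg: ModelConfig, seed: int = 0) -> EcgNet:
    """Construct the network; raises if ``input_len`` cannot survive pooling."""
    return EcgNet(cfg, seed=seed)
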