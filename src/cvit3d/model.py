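"""The 3D C-Vit network.

A hybrid CNN/Transformer classifier for grading pediatric brain tumors
(low vs high grade) from five co-registered MRI sequences (CE-T1WI, T1WI,
T2WI, FLAIR, ADC) stacked as input channels. The pipeline:

1. **CAEFF** (channel-attention-enhanced feature fusion): each sequence is
   processed by its own convolutional path. The T1WI path (channel index 1)
   gets squeeze-and-excitation channel attention; every other sequence is
   softly routed between a standard convolution and a depthwise separable
   group convolution (DSGC) by a learned gate in (0,1) — a convex blend
   ``g_c * std + (1 - g_c) * dsgc`` whose endpoints recover hard routing.
2. **MSFE** (multi-scale feature extraction): a gating network recalibrates
   channels by their pooled global context, then DSGC downsamples.
3. Spatial positions are linearly projected to tokens, a CLS token is
   prepended, and a stack of pre-norm transformer encoder blocks (multi-head
   self-attention + GELU MLP, residual connections) mixes them.
4. A two-stage scaling head (linear -> layer norm -> linear -> linear) maps
   the CLS token to a single logit; sigmoid(logit) is P(high grade).

DSGC = per-channel (depthwise) KxKxK convolution followed by a 1x1x1
pointwise convolution grouped by gcd(C_in, C_out).
"""

from __future__ import annotations

import json
import math
import pickle
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from . import _nn as nn
from ._nn import Tensor

SEQUENCE_ORDER = ("CE-T1WI", "T1WI", "T2WI", "FLAIR", "ADC")
SE_CHANNEL_INDEX = 1  # T1WI


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Architectural hyperparameters of the 3D C-Vit network.

    ``stem_channels`` is the per-sequence path width in CAEFF;
    ``msfe_channels`` gives the output width of each successive MSFE stage.
    All convolution stages use 3x3x3 kernels, padding 1 and the stride
    recorded per stage, so spatial extents follow the standard
    ``(in + 2P - K) // S + 1`` rule on every axis.
    """

    in_sequences: tuple[str, ...] = SEQUENCE_ORDER
    input_shape: tuple[int, int, int] = (16, 64, 64)  # (D, H, W)
    stem_channels: int = 8
    stem_stride: int = 2
    msfe_channels: tuple[int, ...] = (24, 32)
    msfe_strides: tuple[int, ...] = (2, 2)
    embed_dim: int = 96
    depth: int = 2
    num_heads: int = 4
    mlp_ratio: float = 2.0
    se_reduction: int = 4
    gate_threshold: float = 0.5
    dropout: float = 0.0
    num_outputs: int = 1

    def __post_init__(self):
        if len(self.in_sequences) != 5:
            raise ValueError("exactly 5 input sequences are required")
        if self.embed_dim % self.num_heads:
            raise ValueError(
                f"embed_dim {self.embed_dim} not divisible by num_heads {self.num_heads}")
        if self.stem_channels % self.se_reduction:
            raise ValueError(
                f"stem_channels {self.stem_channels} not divisible by "
                f"se_reduction {self.se_reduction}")
        if len(self.msfe_channels) != len(self.msfe_strides):
            raise ValueError("msfe_channels and msfe_strides lengths differ")
        if not 0.0 <= self.gate_threshold <= 1.0:
            raise ValueError("gate_threshold must lie in [0, 1]")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.num_outputs != 1:
            raise ValueError("binary grading uses a single logit")

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.num_heads

    def stage_grids(self) -> list[tuple[int, int, int]]:
        """Spatial grid after the stem and after each MSFE stage."""
        def shrink(g, s):
            return tuple((e + 2 * 1 - 3) // s + 1 for e in g)
        grids = [shrink(self.input_shape, self.stem_stride)]
        for s in self.msfe_strides:
            grids.append(shrink(grids[-1], s))
        return grids

    @property
    def token_grid(self) -> tuple[int, int, int]:
        return self.stage_grids()[-1]

    @property
    def num_tokens(self) -> int:
        d, h, w = self.token_grid
        return d * h * w + 1  # + CLS

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        for k in ("in_sequences", "input_shape", "msfe_channels", "msfe_strides"):
            d[k] = tuple(d[k])
        return cls(**d)


#: "paper": the dims printed for the original model (embed 768, 12 heads,
#: 8 layers).  NOTE these dims are internally inconsistent with the
#: originally reported 1.82 M parameter total (8 encoder layers at width 768
#: alone exceed it); the preset is kept verbatim and documented, not "fixed".
#: "desk": a small CPU-friendly preset used throughout the test suite.
PRESETS: dict[str, ModelConfig] = {
    "desk": ModelConfig(),
    "paper": ModelConfig(
        stem_channels=16,
        msfe_channels=(64, 128),
        msfe_strides=(2, 2),
        embed_dim=768,
        depth=8,
        num_heads=12,
        mlp_ratio=4.0,
        se_reduction=16,
        dropout=0.1,
    ),
}


def preset(name: str, **overrides) -> ModelConfig:
    cfg = PRESETS[name]
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class VolumeBatch:
    """A batch of 5-sequence volumes: data [B, 5, D, H, W], optional mask
    [B, 1, D, H, W] in {0,1} and binary labels (1 = high grade)."""

    data: np.ndarray
    mask: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(f"expected [B, 5, D, H, W], got shape {self.data.shape}")
        if self.data.shape[1] != 5:
            raise ValueError(f"channel axis must have length 5, got {self.data.shape[1]}")
        if not np.isfinite(self.data).all():
            raise ValueError("volume batch contains NaN/Inf")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if not np.isin(self.mask, (0, 1)).all():
                raise ValueError("mask values must be in {0, 1}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if not np.isin(self.labels, (0, 1)).all():
                raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return self.data.shape[0]


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _global_avg_pool(x: Tensor) -> Tensor:
    """[B, C, D, H, W] -> [B, C] channel descriptors."""
    return x.mean(axis=(2, 3, 4))


class SEBlock(nn.Module):
    """Squeeze-and-excitation: global average pool -> bottleneck MLP
    (width C/reduction, ReLU) -> sigmoid weights in (0,1) -> channel rescale."""

    def __init__(self, channels: int, reduction: int, rng, dtype=np.float32):
        if channels % reduction:
            raise ValueError(
                f"channels {channels} not divisible by SE reduction {reduction}")
        hidden = channels // reduction
        self.fc1 = nn.Linear(channels, hidden, rng, dtype=dtype)
        self.fc2 = nn.Linear(hidden, channels, rng, dtype=dtype)

    def __call__(self, x: Tensor) -> tuple[Tensor, np.ndarray]:
        s = _global_avg_pool(x)                        # F_sq
        w = nn.sigmoid(self.fc2(nn.relu(self.fc1(s))))  # F_ex
        b, c = w.shape
        out = x * w.reshape(b, c, 1, 1, 1)             # F_scale
        return out, w.data.copy()


class GateNetwork(nn.Module):
    """Per-channel gates: pooled channel means -> affine map -> sigmoid."""

    def __init__(self, channels: int, rng, dtype=np.float32):
        self.fc = nn.Linear(channels, channels, rng, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        pooled = _global_avg_pool(x)
        if np.isnan(pooled.data).any():
            raise FloatingPointError("NaN in gate network input")
        return nn.sigmoid(self.fc(pooled))  # [B, C] in (0,1)


class DSGC(nn.Module):
    """Depthwise separable group convolution.

    Stage A (DC): depthwise KxKxK convolution (one filter per channel).
    Stage B (PGC): pointwise 1x1x1 convolution grouped by gcd(C_in, C_out);
    with gcd 1 this degenerates to an ordinary pointwise convolution.
    """

    def __init__(self, c_in: int, c_out: int, rng, kernel=3, stride=1,
                 padding=1, dtype=np.float32):
        self.depthwise = nn.Conv3d(c_in, c_in, kernel, stride, padding,
                                   groups=c_in, rng=rng, dtype=dtype)
        self.pointwise = nn.Conv3d(c_in, c_out, 1, 1, 0,
                                   groups=math.gcd(c_in, c_out), rng=rng,
                                   dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return self.pointwise(self.depthwise(x))


class CAEFF(nn.Module):
    """Multi-sequence fusion stem.

    Each of the five input sequences runs its own path to ``stem_channels``
    features.  The T1WI path (index 1) is standard convolution + SE; every
    other path is the gated convex blend of a standard convolution and a
    DSGC.  Path outputs are concatenated along channels.
    """

    def __init__(self, cfg: ModelConfig, rng, dtype=np.float32):
        c = cfg.stem_channels
        s = cfg.stem_stride
        self.std_convs = [nn.Conv3d(1, c, 3, s, 1, rng=rng, dtype=dtype)
                          for _ in range(5)]
        self.se = SEBlock(c, cfg.se_reduction, rng, dtype=dtype)
        self.dsgc = {i: DSGC(1, c, rng, stride=s, dtype=dtype)
                     for i in range(5) if i != SE_CHANNEL_INDEX}
        self.dsgc_paths = list(self.dsgc.values())  # for parameter collection
        self.gate = GateNetwork(4, rng, dtype=dtype)
        self.gate_threshold = cfg.gate_threshold

    def __call__(self, x: Tensor, gate_override: float | None = None,
                 hard: bool = False) -> tuple[Tensor, dict]:
        if x.shape[1] != 5:
            raise ValueError(f"CAEFF requires 5 input channels, got {x.shape[1]}")
        gated_idx = [i for i in range(5) if i != SE_CHANNEL_INDEX]
        gates = self.gate(nn.concat([x[:, i:i + 1] for i in gated_idx], axis=1))
        if gate_override is not None:
            gates = Tensor(np.full_like(gates.data, gate_override))
        elif hard:
            gates = Tensor((gates.data >= self.gate_threshold)
                           .astype(gates.data.dtype))
        record = {"gates": gates.data.copy(), "gated_channels": gated_idx}
        outs = []
        for i in range(5):
            xi = x[:, i:i + 1]
            std = self.std_convs[i](xi)
            if i == SE_CHANNEL_INDEX:
                out, se_w = self.se(std)
                record["se_weights"] = se_w
            else:
                j = gated_idx.index(i)
                g = gates[:, j:j + 1].reshape(x.shape[0], 1, 1, 1, 1)
                out = g * std + (1.0 - g) * self.dsgc[i](xi)
            outs.append(out)
        return nn.concat(outs, axis=1), record


class MSFE(nn.Module):
    """Gating network recalibration followed by DSGC downsampling."""

    def __init__(self, c_in: int, c_out: int, stride: int, rng, dtype=np.float32):
        self.gn = GateNetwork(c_in, rng, dtype=dtype)
        self.dsgc = DSGC(c_in, c_out, rng, stride=stride, dtype=dtype)

    def __call__(self, x: Tensor, gn_override: float | None = None
                 ) -> tuple[Tensor, np.ndarray]:
        w = self.gn(x)
        if gn_override is not None:
            w = Tensor(np.full_like(w.data, gn_override))
        b, c = w.shape
        out = self.dsgc(x * w.reshape(b, c, 1, 1, 1))
        return out, w.data.copy()


class Tokenizer(nn.Module):
    """Flatten the spatial grid to tokens, prepend CLS, add positions.

    Token ``t`` (1-based after CLS) corresponds to flat spatial index
    ``t - 1`` in C-order over (D', H', W'); ``token_index``/``grid_index``
    expose the bijection.
    """

    def __init__(self, c_in: int, grid: tuple[int, int, int], embed_dim: int,
                 rng, dtype=np.float32):
        self.grid = grid
        self.embed_dim = embed_dim
        self.proj = nn.Linear(c_in, embed_dim, rng, dtype=dtype)
        self.cls = nn.Parameter(nn._trunc_normal(rng, (1, 1, embed_dim), 0.02)
                                .astype(dtype))
        n = int(np.prod(grid)) + 1
        self.pos = nn.Parameter(nn._trunc_normal(rng, (1, n, embed_dim), 0.02)
                                .astype(dtype))

    def token_index(self, d: int, h: int, w: int) -> int:
        return 1 + int(np.ravel_multi_index((d, h, w), self.grid))

    def grid_index(self, token: int) -> tuple[int, int, int]:
        return tuple(int(v) for v in np.unravel_index(token - 1, self.grid))

    def __call__(self, x: Tensor) -> Tensor:
        b, c = x.shape[0], x.shape[1]
        if tuple(x.shape[2:]) != tuple(self.grid):
            raise ValueError(f"tokenizer grid {self.grid} vs feature {x.shape[2:]}")
        v = int(np.prod(self.grid))
        tok = self.proj(x.reshape(b, c, v).transpose(0, 2, 1))  # [B, V, E]
        cls = self.cls + Tensor(np.zeros((b, 1, self.embed_dim),
                                         dtype=self.cls.data.dtype))
        toks = nn.concat([cls, tok], axis=1)
        return toks + self.pos


class MHSA(nn.Module):
    """Multi-head scaled dot-product self-attention with output projection."""

    def __init__(self, embed_dim: int, num_heads: int, rng, dtype=np.float32):
        if embed_dim % num_heads:
            raise ValueError("embed_dim not divisible by num_heads")
        self.h = num_heads
        self.dh = embed_dim // num_heads
        self.qkv = nn.Linear(embed_dim, 3 * embed_dim, rng, dtype=dtype)
        self.proj = nn.Linear(embed_dim, embed_dim, rng, dtype=dtype)

    def __call__(self, x: Tensor) -> tuple[Tensor, np.ndarray]:
        b, t, e = x.shape
        qkv = self.qkv(x).reshape(b, t, 3, self.h, self.dh)
        qkv = qkv.transpose(2, 0, 3, 1, 4)  # [3, B, h, T, dh]
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.dh))
        attn = nn.softmax(scores, axis=-1)            # [B, h, T, T]
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, t, e)
        return self.proj(out), attn.data.copy()


class EncoderBlock(nn.Module):
    """Pre-norm transformer block: LN -> MHSA -> +res, LN -> MLP(GELU) -> +res."""

    def __init__(self, embed_dim: int, num_heads: int, mlp_ratio: float, rng,
                 dtype=np.float32):
        hidden = int(round(mlp_ratio * embed_dim))
        self.ln1 = nn.LayerNorm(embed_dim, dtype=dtype)
        self.attn = MHSA(embed_dim, num_heads, rng, dtype=dtype)
        self.ln2 = nn.LayerNorm(embed_dim, dtype=dtype)
        self.fc1 = nn.Linear(embed_dim, hidden, rng, dtype=dtype)
        self.fc2 = nn.Linear(hidden, embed_dim, rng, dtype=dtype)

    def __call__(self, x: Tensor, p_drop: float = 0.0, rng=None,
                 training: bool = False) -> tuple[Tensor, np.ndarray]:
        a, maps = self.attn(self.ln1(x))
        x = x + nn.dropout(a, p_drop, rng, training)
        m = self.fc2(nn.gelu(self.fc1(self.ln2(x))))
        x = x + nn.dropout(m, p_drop, rng, training)
        return x, maps


class Head(nn.Module):
    """Two-stage scaling head on the CLS token:
    linear(E->E) -> LayerNorm -> linear(E->E/2) -> linear(->1)."""

    def __init__(self, embed_dim: int, rng, dtype=np.float32):
        half = embed_dim // 2
        self.scale1 = nn.Linear(embed_dim, embed_dim, rng, dtype=dtype)
        self.ln = nn.LayerNorm(embed_dim, dtype=dtype)
        self.scale2 = nn.Linear(embed_dim, half, rng, dtype=dtype)
        self.classifier = nn.Linear(half, 1, rng, dtype=dtype)

    def __call__(self, cls: Tensor) -> Tensor:
        return self.classifier(self.scale2(self.ln(self.scale1(cls))))


# ---------------------------------------------------------------------------
# the full network
# ---------------------------------------------------------------------------

class CVit3D(nn.Module):
    """CAEFF -> MSFE stages -> tokenize -> encoder stack -> head."""

    def __init__(self, config: ModelConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.caeff = CAEFF(config, rng, dtype=dtype)
        widths = [5 * config.stem_channels, *config.msfe_channels]
        self.msfe = [MSFE(widths[i], widths[i + 1], config.msfe_strides[i],
                          rng, dtype=dtype)
                     for i in range(len(config.msfe_channels))]
        self.tokenizer = Tokenizer(widths[-1], config.token_grid,
                                   config.embed_dim, rng, dtype=dtype)
        self.blocks = [EncoderBlock(config.embed_dim, config.num_heads,
                                    config.mlp_ratio, rng, dtype=dtype)
                       for _ in range(config.depth)]
        self.head = Head(config.embed_dim, rng, dtype=dtype)

    # -- forward -------------------------------------------------------------
    def forward(self, batch: VolumeBatch | np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None,
                hard_gates: bool = False) -> tuple[Tensor, dict]:
        """Returns (logits [B, 1], interpretability bundle).

        The bundle carries the CAEFF gate record, SE weights, per-stage GN
        weights, per-layer attention maps and the CLS feature vector.
        """
        data = batch.data if isinstance(batch, VolumeBatch) else np.asarray(batch)
        if tuple(data.shape[2:]) != tuple(self.config.input_shape):
            raise ValueError(
                f"[input] volume shape {data.shape[2:]} does not match "
                f"configured input_shape {self.config.input_shape}")
        x = Tensor(data.astype(self.dtype, copy=False))
        x, record = self.caeff(x, hard=hard_gates)
        gn_weights = []
        for i, stage in enumerate(self.msfe):
            try:
                x, w = stage(x)
            except ValueError as e:  # pragma: no cover - defensive
                raise ValueError(f"[msfe stage {i}] {e}") from e
            gn_weights.append(w)
        toks = self.tokenizer(x)
        if rng is None:
            rng = np.random.default_rng(0)
        attention = []
        for blk in self.blocks:
            toks, maps = blk(toks, self.config.dropout, rng, training)
            attention.append(maps)
        cls = toks[:, 0]
        logits = self.head(cls)
        bundle = {
            "gates": record["gates"],
            "gated_channels": record["gated_channels"],
            "se_weights": record["se_weights"],
            "gn_weights": gn_weights,
            "attention": attention,          # list of [B, h, T, T]
            "cls_features": cls.data.copy(),
        }
        return logits, bundle

    __call__ = forward

    def predict_proba(self, data: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Sigmoid probabilities of high grade, [n]."""
        out = []
        for i in range(0, len(data), batch_size):
            logits, _ = self.forward(VolumeBatch(data[i:i + batch_size]))
            out.append(1.0 / (1.0 + np.exp(-logits.data[:, 0])))
        return np.concatenate(out) if out else np.empty(0)

    # -- persistence ----------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Checkpoint (pickled arrays) + JSON config sidecar."""
        path = Path(path)
        with open(path, "wb") as f:
            pickle.dump(self.state_dict(), f)
        path.with_suffix(path.suffix + ".json").write_text(self.config.to_json())

    @classmethod
    def load(cls, path: str | Path, dtype=np.float32) -> "CVit3D":
        path = Path(path)
        config = ModelConfig.from_json(
            path.with_suffix(path.suffix + ".json").read_text())
        model = cls(config, dtype=dtype)
        with open(path, "rb") as f:
            model.load_state_dict(pickle.load(f))
        return model


# ---------------------------------------------------------------------------
# analytic parameter counting
# ---------------------------------------------------------------------------

def count_params(config: ModelConfig) -> tuple[int, list[dict]]:
    """Per-layer analytic parameter table; the total equals the instantiated
    network's trainable parameter count exactly."""
    k3 = 27
    rows: list[dict] = []

    def add(layer: str, n: int):
        rows.append({"layer": layer, "params": int(n)})

    c = config.stem_channels
    for i, seq in enumerate(config.in_sequences):
        add(f"caeff.std_conv[{seq}]", k3 * 1 * c + c)
    hidden = c // config.se_reduction
    add("caeff.se", (c * hidden + hidden) + (hidden * c + c))
    for i, seq in enumerate(config.in_sequences):
        if i == SE_CHANNEL_INDEX:
            continue
        add(f"caeff.dsgc[{seq}]", (1 * 1 * k3 + 1) + (c * 1 + c))
    add("caeff.gate", 4 * 4 + 4)

    widths = [5 * c, *config.msfe_channels]
    for i in range(len(config.msfe_channels)):
        ci, co = widths[i], widths[i + 1]
        g = math.gcd(ci, co)
        add(f"msfe[{i}].gn", ci * ci + ci)
        add(f"msfe[{i}].dsgc", (ci * k3 + ci) + (co * (ci // g) + co))

    e = config.embed_dim
    v = int(np.prod(config.token_grid))
    add("tokenizer.proj", widths[-1] * e + e)
    add("tokenizer.cls", e)
    add("tokenizer.pos", (v + 1) * e)

    hid = int(round(config.mlp_ratio * e))
    for i in range(config.depth):
        add(f"block[{i}].ln1", 2 * e)
        add(f"block[{i}].attn.qkv", e * 3 * e + 3 * e)
        add(f"block[{i}].attn.proj", e * e + e)
        add(f"block[{i}].ln2", 2 * e)
        add(f"block[{i}].mlp", (e * hid + hid) + (hid * e + e))

    half = e // 2
    add("head.scale1", e * e + e)
    add("head.ln", 2 * e)
    add("head.scale2", e * half + half)
    add("head.classifier", half + 1)

    return sum(r["params"] for r in rows), rows
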