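"""Analytic shape and FLOPs accounting for 3D convolutions and the network.

Conventions
-----------
* A "FLOP" here is one multiply; additions, biases and softmax are not
  counted.  ``multiply_add=True`` doubles every count for comparison with
  the MAC*2 convention used by some profilers.
* All arithmetic is exact integer arithmetic.
* For a standard convolution producing V = H_out*W_out*D_out voxels:
  ``FLOPs_trad = K1*K2*K3*C_in*C_out*V``.  For the depthwise separable
  group convolution (DSGC): a depthwise term ``K1*K2*K3*C_in*V`` plus a
  pointwise term ``V*C_out*C_in/gcd(C_in, C_out)`` (1x1x1 convolution
  grouped by the gcd).
* Attention FLOPs: QKV projections + two attention matmuls + output
  projection, biases and softmax ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .model import ModelConfig, SE_CHANNEL_INDEX


@dataclass(frozen=True)
class ConvSpec:
    """Kernel extents K1..K3, symmetric padding P, stride S, channels."""

    K1: int
    K2: int
    K3: int
    P: int
    S: int
    C_in: int
    C_out: int

    def __post_init__(self):
        for name in ("K1", "K2", "K3", "S", "C_in", "C_out"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.P < 0:
            raise ValueError("P must be nonnegative")

    @property
    def kernel_volume(self) -> int:
        return self.K1 * self.K2 * self.K3


@dataclass(frozen=True)
class TensorShape:
    """Spatial extents of a feature map (voxels)."""

    H: int
    W: int
    D: int

    def __post_init__(self):
        if min(self.H, self.W, self.D) < 1:
            raise ValueError("all extents must be positive")

    @property
    def voxels(self) -> int:
        return self.H * self.W * self.D


def conv_output_shape(shape: TensorShape, spec: ConvSpec) -> TensorShape:
    """Output extents: floor((in + 2P - K)/S) + 1 per axis."""
    out = {}
    for axis, ext, k in (("H", shape.H, spec.K1), ("W", shape.W, spec.K2),
                         ("D", shape.D, spec.K3)):
        o = (ext + 2 * spec.P - k) // spec.S + 1
        if o < 1:
            raise ValueError(
                f"non-positive output extent on axis {axis}: "
                f"(in={ext}, K={k}, P={spec.P}, S={spec.S}) -> {o}")
        out[axis] = o
    return TensorShape(**out)


def flops_standard(spec: ConvSpec, out: TensorShape,
                   multiply_add: bool = False) -> int:
    """Multiply count of a dense convolution."""
    n = spec.kernel_volume * spec.C_in * spec.C_out * out.voxels
    return 2 * n if multiply_add else n


def flops_dsgc(spec: ConvSpec, out: TensorShape,
               multiply_add: bool = False) -> int:
    """Multiply count of depthwise + gcd-grouped pointwise convolution."""
    g = math.gcd(spec.C_in, spec.C_out)
    depthwise = spec.kernel_volume * spec.C_in * out.voxels
    pointwise = out.voxels * spec.C_out * (spec.C_in // g)
    n = depthwise + pointwise
    return 2 * n if multiply_add else n


def reduction_ratio(spec: ConvSpec) -> float:
    """FLOPs_DSGC / FLOPs_trad = 1/C_out + 1/(gcd * K^3), independent of the
    output grid.  Equals 1 + 1/K^3 (no saving) when C_out = 1."""
    g = math.gcd(spec.C_in, spec.C_out)
    closed = Fraction(1, spec.C_out) + Fraction(1, g * spec.kernel_volume)
    return float(closed)


# ---------------------------------------------------------------------------
# whole-model report
# ---------------------------------------------------------------------------

@dataclass
class ComplexityReport:
    rows: list[dict]

    @property
    def total_flops(self) -> int:
        return sum(r["flops"] for r in self.rows)

    @property
    def total_params(self) -> int:
        return sum(r["params"] for r in self.rows)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.rows)


def _linear_flops(d_in: int, d_out: int, tokens: int) -> int:
    return d_in * d_out * tokens


def model_complexity_report(config: ModelConfig, batch: int = 1,
                            multiply_add: bool = False) -> ComplexityReport:
    """Per-layer multiply counts and parameters for one input volume.

    Convolution rows delegate to :func:`flops_standard` / :func:`flops_dsgc`;
    SE / gate MLPs are counted as linear maps on pooled descriptors;
    attention rows count the QKV/output projections and the two attention
    matmuls.
    """
    from .model import count_params

    d, h, w = config.input_shape
    rows: list[dict] = []
    params = {r["layer"]: r["params"] for r in count_params(config)[1]}

    def add(layer: str, flops: int, pcount: int | None = None, **extra):
        rows.append({"layer": layer,
                     "flops": (2 * flops if multiply_add else flops) * batch,
                     "params": params.get(layer, 0) if pcount is None else pcount,
                     **extra})

    c = config.stem_channels
    stem_spec = ConvSpec(3, 3, 3, 1, config.stem_stride, 1, c)
    shape0 = TensorShape(H=h, W=w, D=d)
    shape1 = conv_output_shape(shape0, stem_spec)
    for i, seq in enumerate(config.in_sequences):
        add(f"caeff.std_conv[{seq}]", flops_standard(stem_spec, shape1))
        if i != SE_CHANNEL_INDEX:
            add(f"caeff.dsgc[{seq}]", flops_dsgc(stem_spec, shape1),
                flops_trad=flops_standard(stem_spec, shape1),
                reduction_ratio=reduction_ratio(stem_spec))
    hidden = c // config.se_reduction
    add("caeff.se", c * hidden + hidden * c + c * shape1.voxels)
    add("caeff.gate", 4 * 4)

    widths = [5 * c, *config.msfe_channels]
    shape = shape1
    for i in range(len(config.msfe_channels)):
        spec = ConvSpec(3, 3, 3, 1, config.msfe_strides[i],
                        widths[i], widths[i + 1])
        out = conv_output_shape(shape, spec)
        add(f"msfe[{i}].gn", widths[i] * widths[i] + widths[i] * shape.voxels)
        add(f"msfe[{i}].dsgc", flops_dsgc(spec, out),
            flops_trad=flops_standard(spec, out),
            reduction_ratio=reduction_ratio(spec))
        shape = out

    e = config.embed_dim
    v = shape.voxels
    t = v + 1
    add("tokenizer.proj", _linear_flops(widths[-1], e, v))
    add("tokenizer.cls", 0)
    add("tokenizer.pos", 0)

    hid = int(round(config.mlp_ratio * e))
    for i in range(config.depth):
        add(f"block[{i}].ln1", 0)
        add(f"block[{i}].attn.qkv", _linear_flops(e, 3 * e, t))
        attn_mm = t * t * config.head_dim * config.num_heads  # q@k^T
        attn_av = t * t * config.head_dim * config.num_heads  # attn@v
        add(f"block[{i}].attn.matmuls", attn_mm + attn_av, 0)
        add(f"block[{i}].attn.proj", _linear_flops(e, e, t))
        add(f"block[{i}].ln2", 0)
        add(f"block[{i}].mlp", _linear_flops(e, hid, t) + _linear_flops(hid, e, t))

    half = e // 2
    add("head.scale1", _linear_flops(e, e, 1))
    add("head.ln", 0)
    add("head.scale2", _linear_flops(e, half, 1))
    add("head.classifier", _linear_flops(half, 1, 1))
    return ComplexityReport(rows)
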