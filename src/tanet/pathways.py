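"""The three segmentation pathways and their fusion.

* Spatial pathway (SP): three 3x3 stride-2 conv + BN + ReLU blocks with
  channels 64/64/128 — rich low-level detail at 1/8 resolution.
* Handcrafted pathway (HP): three local-binary-convolution (LBC) blocks.
  Each block applies ``m`` *fixed* sparse anchor filters (entries in
  {-1, +1}), a ReLU, and a learnable 1x1 recombination — the LBP texture
  operator recast as a trainable layer.  Anchors never update; gradients
  flow through them to earlier layers.
* Context pathway (CP): a lightweight depthwise-separable stack that
  downsamples fast to 1/32, multiplies in a global-average-pooled context
  descriptor, and returns to 1/8.  Two intermediate taps (1/16 and 1/32)
  provide class logits for auxiliary supervision.

All three pathways emit maps at 1/8 of the crop resolution; the fusion block
concatenates them, batch-normalizes, and applies channel attention
``v_out = v . w + v`` with ``w`` from a sigmoid squeeze bottleneck.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "LBCBlockSpec", "make_anchors", "make_lbc_spec", "LBCBlock",
    "lbc_block_forward",
    "SpatialPath", "HandcraftedPath", "ContextPath",
    "FusionModule", "reweight", "SegmentationHead", "count_learnable_params",
]


# ---------------------------------------------------------------------------
# LBC blocks

@dataclass
class LBCBlockSpec:
    """Specification of one LBC block: fixed anchors + learnable 1x1 weights.

    ``anchors``: (m, C_in, k, k) immutable filters whose nonzero entries are
    drawn from {-1, +1}; each filter has ceil(sparsity * k^2 * C_in) nonzero
    entries.  ``recombination``: (C_out, m) weights of the 1x1 layer.
    """

    m: int
    kernel_size: int
    sparsity: float
    anchors: np.ndarray
    recombination: np.ndarray

    def __post_init__(self):
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel size must be odd")
        if self.anchors.shape[:1] != (self.m,):
            raise ValueError("anchor count must equal m")
        nz = self.anchors[self.anchors != 0]
        if nz.size and not np.all(np.isin(nz, (-1.0, 1.0))):
            raise ValueError("anchor nonzeros must be +/-1")
        self.anchors.setflags(write=False)


def make_anchors(m: int, c_in: int, k: int, sparsity: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Draw ``m`` sparse +/-1 anchor filters of shape (c_in, k, k)."""
    n_entries = k * k * c_in
    n_nonzero = max(1, math.ceil(sparsity * n_entries))
    anchors = np.zeros((m, n_entries), dtype=np.float32)
    for i in range(m):
        idx = rng.choice(n_entries, size=n_nonzero, replace=False)
        anchors[i, idx] = rng.choice([-1.0, 1.0], size=n_nonzero)
    return anchors.reshape(m, c_in, k, k)


def make_lbc_spec(c_in: int, c_out: int, *, k: int = 3, sparsity: float = 0.5,
                  m: int | None = None,
                  rng: np.random.Generator | None = None) -> LBCBlockSpec:
    rng = rng or np.random.default_rng(0)
    if m is None:
        m = max(2 * c_in, 16)
    anchors = make_anchors(m, c_in, k, sparsity, rng)
    recomb = (rng.standard_normal((c_out, m)) * np.sqrt(2.0 / m)).astype(np.float32)
    return LBCBlockSpec(m=m, kernel_size=k, sparsity=sparsity,
                        anchors=anchors, recombination=recomb)


def lbc_block_forward(x, spec: LBCBlockSpec, stride: int = 1):
    """y = conv1x1(ReLU(conv_fixed(x))) — the LBC feature map.

    Gradients reach ``x`` and the recombination weights; the anchors are
    constants.  Accepts a numpy array or a Tensor.
    """
    xt = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))
    if xt.shape[1] != spec.anchors.shape[1]:
        raise ValueError(
            f"input has {xt.shape[1]} channels, anchors expect {spec.anchors.shape[1]}")
    k = spec.kernel_size
    diff = nn.conv2d(xt, Tensor(spec.anchors), stride=stride, padding=k // 2)
    bitmaps = nn.relu(diff)
    w = spec.recombination if isinstance(spec.recombination, Tensor) \
        else Tensor(spec.recombination)
    recomb = nn.reshape(w, (w.shape[0], w.shape[1], 1, 1))
    out = nn.conv2d(bitmaps, recomb)
    return out if isinstance(x, Tensor) else out.data


class LBCBlock(nn.Module):
    """An LBC block wired for the handcrafted pathway: fixed anchors
    (stride-2 spatial reduction), ReLU, learnable 1x1, then BN + ReLU."""

    def __init__(self, c_in: int, c_out: int, *, k: int = 3, stride: int = 2,
                 sparsity: float = 0.5, m: int | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if m is None:
            m = max(2 * c_in, 16)
        self.stride = stride
        self.k = k
        self.anchors = Tensor(make_anchors(m, c_in, k, sparsity, rng))
        self._buffer_names.add("anchors")
        self.recomb = nn.Conv2d(m, c_out, 1, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(c_out)

    @property
    def m(self) -> int:
        return self.anchors.shape[0]

    def forward(self, x):
        diff = nn.conv2d(x, self.anchors, stride=self.stride, padding=self.k // 2)
        y = self.recomb(nn.relu(diff))
        return nn.relu(self.bn(y))


def count_learnable_params(kind: str, k: int, c_in: int, c_out: int,
                           m: int | None = None) -> int:
    """Learnable parameter count of one layer, biases excluded.

    ``standard``: a k x k convolution = k^2 * c_in * c_out.
    ``lbc``: only the 1x1 recombination = m * c_out (the m anchor filters
    are fixed and contribute nothing learnable).  With m = c_in the
    standard/LBC ratio is exactly k^2.
    """
    if k < 1 or k % 2 == 0:
        raise ValueError("kernel size must be odd and >= 1")
    if c_in < 1 or c_out < 1:
        raise ValueError("channel counts must be >= 1")
    if kind == "standard":
        return k * k * c_in * c_out
    if kind == "lbc":
        m = c_in if m is None else m
        if m < 1:
            raise ValueError("m must be >= 1")
        return m * c_out
    raise ValueError(f"unknown layer kind {kind!r}")


# ---------------------------------------------------------------------------
# Pathways

class SpatialPath(nn.Module):
    """Three stride-2 conv blocks (channels 64/64/128) -> 1/8 resolution."""

    CHANNELS = (64, 64, 128)

    def __init__(self, in_channels: int = 1, channels=CHANNELS,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        blocks = []
        c_in = in_channels
        for c_out in channels:
            blocks.append(nn.Conv2d(c_in, c_out, 3, stride=2, bias=False, rng=rng))
            blocks.append(nn.BatchNorm2d(c_out))
            c_in = c_out
        self.blocks = nn.ModuleList(blocks)
        self.out_channels = c_in

    def forward(self, x):
        if x.shape[2] % 8 or x.shape[3] % 8:
            raise ValueError("spatial path input dims must be divisible by 8")
        h = x
        for i in range(0, len(self.blocks), 2):
            h = nn.relu(self.blocks[i + 1](self.blocks[i](h)))
        return h


class HandcraftedPath(nn.Module):
    """Three stride-2 LBC blocks mirroring the spatial path's resolution plan."""

    CHANNELS = (64, 64, 128)

    def __init__(self, in_channels: int = 1, channels=CHANNELS,
                 sparsity: float = 0.5, anchor_seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(anchor_seed)
        blocks = []
        c_in = in_channels
        for c_out in channels:
            blocks.append(LBCBlock(c_in, c_out, stride=2, sparsity=sparsity, rng=rng))
            c_in = c_out
        self.blocks = nn.ModuleList(blocks)
        self.out_channels = c_in

    def forward(self, x):
        if x.shape[2] % 8 or x.shape[3] % 8:
            raise ValueError("handcrafted path input dims must be divisible by 8")
        h = x
        for b in self.blocks:
            h = b(h)
        return h


class _SeparableBlock(nn.Module):
    def __init__(self, c_in, c_out, stride=2, rng=None):
        super().__init__()
        self.dw = nn.DepthwiseConv2d(c_in, 3, stride=stride, rng=rng)
        self.pw = nn.Conv2d(c_in, c_out, 1, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(c_out)

    def forward(self, x):
        return nn.relu(self.bn(self.pw(self.dw(x))))


class ContextPath(nn.Module):
    """Fast-downsampling separable stack with a global context tail.

    Five stride-2 separable blocks reach 1/32; the tail global-average pool
    yields a 1x1 descriptor that is broadcast-multiplied onto the 1/32 map,
    which is then upsampled to 1/8 for fusion.  The 1/16 and 1/32 stage
    outputs are projected to class logits for auxiliary supervision.
    """

    CHANNELS = (16, 32, 64, 96, 96)

    def __init__(self, n_classes: int, in_channels: int = 1, channels=CHANNELS,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        blocks = []
        c_in = in_channels
        for c_out in channels:
            blocks.append(_SeparableBlock(c_in, c_out, stride=2, rng=rng))
            c_in = c_out
        self.blocks = nn.ModuleList(blocks)
        self.aux1_head = nn.Conv2d(channels[3], n_classes, 1, rng=rng)  # 1/16 tap
        self.aux2_head = nn.Conv2d(channels[4], n_classes, 1, rng=rng)  # 1/32 tap
        self.out_channels = channels[4]

    def forward(self, x):
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError("context path input dims must be divisible by 32")
        h = x
        taps = []
        for i, b in enumerate(self.blocks):
            h = b(h)
            if i >= 3:
                taps.append(h)
        f16, f32 = taps
        g = nn.global_avg_pool(f32)
        ctx = nn.mul(f32, g)
        ctx = nn.upsample_bilinear(ctx, x.shape[2] // 8, x.shape[3] // 8)
        return ctx, self.aux1_head(f16), self.aux2_head(f32)


# ---------------------------------------------------------------------------
# Fusion and head

def reweight(v_concat: Tensor, w_concat) -> Tensor:
    """Channel attention: v_out = v . w + v (w broadcast per channel)."""
    return nn.add(nn.mul(v_concat, w_concat), v_concat)


class FusionModule(nn.Module):
    """Concatenate pathway outputs, batch-normalize, re-weight channels."""

    def __init__(self, channels: tuple[int, int, int], bottleneck_ratio: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        c_f = sum(channels)
        hidden = max(c_f // bottleneck_ratio, 4)
        self.bn = nn.BatchNorm2d(c_f)
        self.fc1 = nn.Conv2d(c_f, hidden, 1, rng=rng)
        self.fc2 = nn.Conv2d(hidden, c_f, 1, rng=rng)
        self.out_channels = c_f

    def attention(self, v_concat: Tensor) -> Tensor:
        g = nn.global_avg_pool(v_concat)
        return nn.sigmoid(self.fc2(nn.relu(self.fc1(g))))

    def forward(self, sp_map: Tensor, hp_map: Tensor, cp_map: Tensor):
        if not (sp_map.shape[2:] == hp_map.shape[2:] == cp_map.shape[2:]):
            raise ValueError(
                f"pathway outputs must share spatial dims, got "
                f"{sp_map.shape[2:]}, {hp_map.shape[2:]}, {cp_map.shape[2:]}")
        v_concat = self.bn(nn.concat([sp_map, hp_map, cp_map], axis=1))
        w_concat = self.attention(v_concat)
        return reweight(v_concat, w_concat), w_concat


class SegmentationHead(nn.Module):
    """1x1 projection to class logits plus bilinear upsample to full crop."""

    def __init__(self, c_in: int, n_classes: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        self.proj = nn.Conv2d(c_in, n_classes, 1, rng=rng or np.random.default_rng(0))
        self.n_classes = n_classes

    def forward(self, v_output: Tensor, out_size: int) -> Tensor:
        return nn.upsample_bilinear(self.proj(v_output), out_size, out_size)
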