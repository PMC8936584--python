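"""Coarse segmentation: the FCN-8-style net producing the rough mask ``z``.

The coarse mask only has to be rough — it exists to drive the localization
network — so the encoder is a compact VGG-style stack of stride-2 stages with
FCN-8 skip fusion: class scores from the 1/8, 1/16 and 1/32 stages are
upsampled and summed, then bilinearly upsampled back to the input resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from . import nn
from .nn import Tensor

__all__ = ["EchoImage", "preprocess", "CoarseFCN"]

TOTAL_STRIDE = 32


@dataclass
class EchoImage:
    """A preprocessed frame: (C, H, W) float values in [0, 1], square."""

    values: np.ndarray
    spacing: float | None = None  # optional mm per pixel

    def __post_init__(self):
        if self.values.ndim != 3 or self.values.shape[0] not in (1, 3):
            raise ValueError(f"expected (C in {{1,3}}, H, W), got {self.values.shape}")
        if self.values.shape[1] != self.values.shape[2]:
            raise ValueError("working frames must be square")


def preprocess(raw_image: np.ndarray, target_size: int) -> EchoImage:
    """Bicubic-resize a raw frame to the square working resolution, [0, 1].

    Accepts (H, W), (H, W, C) or (C, H, W) input in uint8/uint16/float.
    """
    raw = np.asarray(raw_image)
    if raw.size == 0:
        raise ValueError("empty image")
    if raw.ndim == 2:
        raw = raw[None]
    elif raw.ndim == 3 and raw.shape[-1] in (1, 3) and raw.shape[0] not in (1, 3):
        raw = np.moveaxis(raw, -1, 0)
    if raw.ndim != 3:
        raise ValueError(f"cannot interpret image of shape {np.shape(raw_image)}")
    if raw.shape[1] < 8 or raw.shape[2] < 8:
        raise ValueError("image smaller than 8x8")
    if raw.dtype == np.uint8:
        img = raw.astype(np.float64) / 255.0
    elif raw.dtype == np.uint16:
        img = raw.astype(np.float64) / 65535.0
    else:
        img = raw.astype(np.float64)
        hi = img.max()
        if hi > 1.0:
            img = img / hi
    if img.shape[1:] != (target_size, target_size):
        img = resize(img, (img.shape[0], target_size, target_size),
                     order=3, mode="edge", anti_aliasing=True, preserve_range=True)
    return EchoImage(values=np.clip(img, 0.0, 1.0).astype(np.float32))


class _ConvBNReLU(nn.Module):
    def __init__(self, c_in, c_out, stride=1, rng=None):
        super().__init__()
        self.conv = nn.Conv2d(c_in, c_out, 3, stride=stride, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(c_out)

    def forward(self, x):
        return nn.relu(self.bn(self.conv(x)))


class CoarseFCN(nn.Module):
    """Compact fully convolutional net with FCN-8 skip fusion.

    Five stride-2 stages reach 1/32 resolution; 1x1 score layers at 1/8,
    1/16 and 1/32 are fused coarse-to-fine and the result is upsampled to
    the input resolution, so the output mask always matches the input grid.
    """

    CHANNELS = (16, 32, 64, 96, 128)

    def __init__(self, n_classes: int, in_channels: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.n_classes = n_classes
        c = self.CHANNELS
        self.stage1 = _ConvBNReLU(in_channels, c[0], stride=2, rng=rng)   # 1/2
        self.stage2 = nn.Sequential(_ConvBNReLU(c[0], c[1], stride=2, rng=rng),
                                    _ConvBNReLU(c[1], c[1], rng=rng))      # 1/4
        self.stage3 = nn.Sequential(_ConvBNReLU(c[1], c[2], stride=2, rng=rng),
                                    _ConvBNReLU(c[2], c[2], rng=rng))      # 1/8
        self.stage4 = _ConvBNReLU(c[2], c[3], stride=2, rng=rng)           # 1/16
        self.stage5 = _ConvBNReLU(c[3], c[4], stride=2, rng=rng)           # 1/32
        self.score8 = nn.Conv2d(c[2], n_classes, 1, rng=rng)
        self.score16 = nn.Conv2d(c[3], n_classes, 1, rng=rng)
        self.score32 = nn.Conv2d(c[4], n_classes, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        """x: (B, C, H, W) -> per-pixel class logits (B, K, H, W)."""
        H, W = x.shape[2], x.shape[3]
        if H % TOTAL_STRIDE or W % TOTAL_STRIDE:
            raise ValueError(
                f"input resolution {H}x{W} not divisible by the net's "
                f"total stride {TOTAL_STRIDE}")
        f8 = self.stage3(self.stage2(self.stage1(x)))
        f16 = self.stage4(f8)
        f32 = self.stage5(f16)
        s = self.score32(f32)
        s = nn.upsample_bilinear(s, f16.shape[2], f16.shape[3]) + self.score16(f16)
        s = nn.upsample_bilinear(s, f8.shape[2], f8.shape[3]) + self.score8(f8)
        return nn.upsample_bilinear(s, H, W)

    def segment(self, image: np.ndarray) -> np.ndarray:
        """Argmax coarse mask for one (C, H, W) image or a (B, C, H, W) batch."""
        arr = np.asarray(image, dtype=np.float32)
        squeeze = arr.ndim == 3
        if squeeze:
            arr = arr[None]
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                logits = self.forward(Tensor(arr))
        finally:
            self.train(was_training)
        labels = logits.data.argmax(axis=1)
        return labels[0] if squeeze else labels
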