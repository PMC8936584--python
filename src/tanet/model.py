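"""The assembled trilateral attention network.

One forward pass: the frozen coarse FCN proposes a rough mask ``z``; the
localization network regresses one affine transform per region from ``z``;
each region is cropped out of the frame by the differentiable bilinear
sampler; the three pathways segment every crop (pathway weights shared
across regions); fused features go through a shared (N+1)-class head.  At
inference the per-crop label maps are pasted back to frame coordinates with
the inverse transforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .coarse import CoarseFCN
from .pathways import (ContextPath, FusionModule, HandcraftedPath,
                       SegmentationHead, SpatialPath)
from .stn import (LocalizationNet, ThetaSet, coarse_to_input, inverse_remap)
from .nn import Tensor

__all__ = ["TaNetConfig", "TaNet"]


@dataclass
class TaNetConfig:
    """Architecture hyperparameters.

    ``resolution`` is the square working resolution of frames; ``crop_size``
    the resolution of per-region crops (must be divisible by 32 for the
    context pathway).  The full-scale configuration uses 512/512; the
    desk-scale configuration 128/64.
    """

    n_regions: int
    resolution: int = 512
    crop_size: int = 512
    in_channels: int = 1
    sp_channels: tuple = (64, 64, 128)
    hp_channels: tuple = (64, 64, 128)
    hp_sparsity: float = 0.5
    cp_channels: tuple = (16, 32, 64, 96, 96)
    fusion_bottleneck_ratio: int = 4
    scale_clip: tuple = (0.05, 1.5)
    theta_margin: float = 0.1
    anchor_seed: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.crop_size % 32:
            raise ValueError("crop_size must be divisible by 32")
        if self.resolution % 32:
            raise ValueError("resolution must be divisible by 32")

    @property
    def n_classes(self) -> int:
        return self.n_regions + 1

    @classmethod
    def tiny(cls, n_regions: int, **kw) -> "TaNetConfig":
        """Desk-scale configuration used throughout the test suite."""
        kw.setdefault("resolution", 128)
        kw.setdefault("crop_size", 64)
        return cls(n_regions=n_regions, **kw)

    def to_dict(self) -> dict:
        from dataclasses import asdict
        d = asdict(self)
        for k in ("sp_channels", "hp_channels", "cp_channels", "scale_clip"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TaNetConfig":
        d = dict(d)
        for k in ("sp_channels", "hp_channels", "cp_channels", "scale_clip"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


class TaNet(nn.Module):
    """Localization + trilateral segmentation, end-to-end differentiable."""

    def __init__(self, config: TaNetConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        k = config.n_classes
        self.coarse = CoarseFCN(k, in_channels=config.in_channels, rng=rng)
        self.loc = LocalizationNet(config.n_regions, scale_clip=config.scale_clip,
                                   rng=rng)
        self.sp = SpatialPath(config.in_channels, config.sp_channels, rng=rng)
        self.hp = HandcraftedPath(config.in_channels, config.hp_channels,
                                  sparsity=config.hp_sparsity,
                                  anchor_seed=config.anchor_seed)
        self.cp = ContextPath(k, config.in_channels, config.cp_channels, rng=rng)
        self.fusion = FusionModule(
            (self.sp.out_channels, self.hp.out_channels, self.cp.out_channels),
            bottleneck_ratio=config.fusion_bottleneck_ratio, rng=rng)
        self.head = SegmentationHead(self.fusion.out_channels, k, rng=rng)

    # -- building blocks -----------------------------------------------------

    def coarse_labels(self, images: np.ndarray) -> np.ndarray:
        """Frozen coarse pass: (B, C, H, W) -> integer labels (B, H, W)."""
        return self.coarse.segment(images)

    def predict_thetas(self, coarse_labels: np.ndarray) -> Tensor:
        """(B, H, W) coarse labels -> (B, N, 4) transform parameters."""
        z = coarse_to_input(coarse_labels, self.config.n_regions)
        return self.loc(Tensor(z.astype(np.float32)))

    def segment_crop(self, crop: Tensor):
        """Run the three pathways + fusion + head on one batch of crops."""
        sp_map = self.sp(crop)
        hp_map = self.hp(crop)
        cp_map, aux1, aux2 = self.cp(crop)
        fused, _ = self.fusion(sp_map, hp_map, cp_map)
        logits = self.head(fused, crop.shape[2])
        return logits, aux1, aux2

    def forward_rois(self, images: Tensor, thetas: Tensor):
        """Crop every region with its transform and segment the crops.

        ``images``: (B, C, H, W); ``thetas``: (B, N, 4).  All N x B crops run
        through the shared pathways as one batch (so batch norm sees every
        region at once); the result is split back into a list of N tuples
        (logits, aux1, aux2), each over the image batch.
        """
        cs = self.config.crop_size
        B = images.shape[0]
        N = self.config.n_regions
        crops = []
        for i in range(N):
            theta_i = nn.reshape(nn.narrow(thetas, 1, i, 1), (B, 4))
            grid = nn.affine_grid(theta_i, cs, cs)
            crops.append(nn.grid_sample(images, grid))
        logits, aux1, aux2 = self.segment_crop(nn.concat(crops, axis=0))
        return [(nn.narrow(logits, 0, i * B, B),
                 nn.narrow(aux1, 0, i * B, B),
                 nn.narrow(aux2, 0, i * B, B)) for i in range(N)]

    # -- inference -----------------------------------------------------------

    def segment_frame(self, image: np.ndarray) -> dict:
        """Full-frame inference for one (C, H, W) image in [0, 1].

        Returns the remapped frame mask, the per-region transforms and the
        per-crop label maps.
        """
        image = np.asarray(image, dtype=np.float32)
        if image.ndim != 3:
            raise ValueError("expected a (C, H, W) image")
        H, W = image.shape[1:]
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                z = self.coarse_labels(image[None])
                thetas_t = self.predict_thetas(z)
                roi_out = self.forward_rois(Tensor(image[None]), thetas_t)
        finally:
            self.train(was_training)
        thetas = ThetaSet.from_stack(np.stack(
            [np.array([[p[0], 0.0, p[2]], [0.0, p[1], p[3]]])
             for p in thetas_t.data[0]]))
        crop_labels = [out[0].data[0].argmax(axis=0) for out in roi_out]
        mask = inverse_remap(crop_labels, thetas, H, W)
        return {"mask": mask, "thetas": thetas, "crop_labels": crop_labels,
                "coarse": z[0]}
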