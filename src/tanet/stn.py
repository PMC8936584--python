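"""Spatial-transformer localization: affine ROI attention for echo frames.

The spatial transformer consists of three pieces:

* a **localization network** ``L`` that regresses, from a coarse multi-label
  segmentation mask, one shear-free affine transform per cardiac region
  (scales ``s_x, s_y`` and translations ``t_x, t_y``; the off-diagonal shear
  entries are structurally zero),
* a **grid generator** mapping the canonical target grid through each affine
  matrix to source coordinates, and
* a differentiable **bilinear sampler** that resamples the frame (or feature
  map) at those coordinates, with zero padding outside the image.

All coordinates use the align-corners convention: (-1, -1) is the centre of
the top-left pixel and (+1, +1) the centre of the bottom-right pixel, so the
identity transform is an exact identity resampling.

Ground-truth transforms are derived from label masks as margin-expanded tight
bounding boxes, and segmented crops are pasted back to frame coordinates with
the inverse transform (``inverse_remap``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "AffineTheta", "ThetaSet", "SamplingGrid", "ROICrop",
    "make_sampling_grid", "bilinear_sample", "theta_gt_from_mask",
    "sample_labels_nearest", "inverse_remap", "LocalizationNet",
    "coarse_to_input",
]


@dataclass(frozen=True)
class AffineTheta:
    """One region's shear-free affine transform in normalized coordinates."""

    s_x: float
    s_y: float
    t_x: float
    t_y: float

    def __post_init__(self):
        vals = (self.s_x, self.s_y, self.t_x, self.t_y)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"non-finite affine parameters: {vals}")

    def matrix(self) -> np.ndarray:
        """The 2x3 matrix [[s_x, 0, t_x], [0, s_y, t_y]]."""
        return np.array([[self.s_x, 0.0, self.t_x],
                         [0.0, self.s_y, self.t_y]], dtype=np.float64)

    @classmethod
    def from_matrix(cls, m) -> "AffineTheta":
        m = np.asarray(m, dtype=np.float64)
        if m.shape != (2, 3):
            raise ValueError(f"expected a 2x3 matrix, got {m.shape}")
        return cls(s_x=float(m[0, 0]), s_y=float(m[1, 1]),
                   t_x=float(m[0, 2]), t_y=float(m[1, 2]))

    def inverse(self) -> "AffineTheta":
        if self.s_x == 0.0 or self.s_y == 0.0:
            raise ValueError("singular transform: zero scale cannot be inverted")
        return AffineTheta(s_x=1.0 / self.s_x, s_y=1.0 / self.s_y,
                           t_x=-self.t_x / self.s_x, t_y=-self.t_y / self.s_y)

    def as_vector(self) -> np.ndarray:
        return np.array([self.s_x, self.s_y, self.t_x, self.t_y], dtype=np.float64)


@dataclass
class ThetaSet:
    """Ordered per-region transforms; ``region_ids`` are the mask labels."""

    thetas: list[AffineTheta]
    region_ids: list[int]

    def __post_init__(self):
        if len(self.thetas) != len(self.region_ids):
            raise ValueError("thetas and region_ids must have equal length")
        if any(r <= 0 for r in self.region_ids):
            raise ValueError("region ids must be positive integers")
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("region ids must be unique")
        if sorted(self.region_ids) != list(self.region_ids):
            raise ValueError("region ids must be sorted ascending")

    def __len__(self):
        return len(self.thetas)

    def stack(self) -> np.ndarray:
        """(N, 2, 3) array, row-major, suitable for JSON serialization."""
        return np.stack([t.matrix() for t in self.thetas])

    @classmethod
    def from_stack(cls, arr, region_ids=None) -> "ThetaSet":
        arr = np.asarray(arr)
        n = arr.shape[0]
        ids = list(region_ids) if region_ids is not None else list(range(1, n + 1))
        return cls([AffineTheta.from_matrix(m) for m in arr], ids)


@dataclass
class SamplingGrid:
    """Source coordinates (x_s, y_s) for every target pixel of an H'xW' crop."""

    source_coords: np.ndarray  # (H', W', 2)
    height: int
    width: int


@dataclass
class ROICrop:
    """A resampled per-region patch plus the transform that produced it."""

    values: np.ndarray  # (C, H', W')
    region_id: int
    theta: AffineTheta = field(default_factory=lambda: AffineTheta(1.0, 1.0, 0.0, 0.0))


def _target_grid(h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    xt = np.linspace(-1.0, 1.0, w) if w > 1 else np.zeros(1)
    yt = np.linspace(-1.0, 1.0, h) if h > 1 else np.zeros(1)
    return np.meshgrid(xt, yt)


def make_sampling_grid(theta: AffineTheta, out_h: int, out_w: int) -> SamplingGrid:
    """Map the canonical target grid through ``theta`` (pointwise affine)."""
    if out_h < 1 or out_w < 1:
        raise ValueError("grid dimensions must be >= 1")
    XT, YT = _target_grid(out_h, out_w)
    m = theta.matrix()
    homog = np.stack([XT, YT, np.ones_like(XT)], axis=-1)  # (H', W', 3)
    coords = homog @ m.T                                   # (H', W', 2)
    return SamplingGrid(source_coords=coords, height=out_h, width=out_w)


def bilinear_sample(image: np.ndarray, grid: SamplingGrid,
                    region_id: int = 0,
                    theta: AffineTheta | None = None) -> ROICrop:
    """Resample ``image`` (C, H, W) at the grid's source coordinates.

    Each output pixel is the truncated-kernel weighted sum over input pixels
    (zero outside the image).  For differentiable use inside the network the
    underlying :func:`tanet.nn.grid_sample` op is called on Tensors directly;
    this wrapper serves the numpy-level API.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3:
        raise ValueError(f"expected (C, H, W) image, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    if not np.all(np.isfinite(grid.source_coords)):
        raise ValueError("grid contains non-finite coordinates")
    g = grid.source_coords[None].astype(np.float64)
    with nn.no_grad():
        out = nn.grid_sample(Tensor(image[None]), Tensor(g))
    return ROICrop(values=out.data[0], region_id=region_id,
                   theta=theta or AffineTheta(1.0, 1.0, 0.0, 0.0))


def theta_gt_from_mask(mask: np.ndarray, region_id: int,
                       margin: float = 0.1) -> AffineTheta:
    """Ground-truth transform: margin-expanded tight bounding box of a region.

    The box is the axis-aligned hull of the region's pixels, expanded by
    ``margin`` times the box extent on each side and clipped to the frame.
    Scales are box half-extents in normalized coordinates; translations are
    the normalized box centre.  A region covering the whole frame with zero
    margin yields the identity transform.
    """
    mask = np.asarray(mask)
    H, W = mask.shape
    rows, cols = np.nonzero(mask == region_id)
    if rows.size == 0:
        raise MissingRegionError(f"region {region_id} absent from mask")
    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    dr = (r1 - r0) * margin
    dc = (c1 - c0) * margin
    r0 = max(r0 - dr, 0.0)
    r1 = min(r1 + dr, H - 1.0)
    c0 = max(c0 - dc, 0.0)
    c1 = min(c1 + dc, W - 1.0)

    def norm(v, n):
        return 2.0 * v / (n - 1) - 1.0 if n > 1 else 0.0

    x0, x1 = norm(c0, W), norm(c1, W)
    y0, y1 = norm(r0, H), norm(r1, H)
    return AffineTheta(s_x=max((x1 - x0) / 2.0, 1.0 / max(W - 1, 1)),
                       s_y=max((y1 - y0) / 2.0, 1.0 / max(H - 1, 1)),
                       t_x=(x1 + x0) / 2.0, t_y=(y1 + y0) / 2.0)


class MissingRegionError(ValueError):
    """Raised when a requested region has no pixels in the mask."""


def sample_labels_nearest(labels: np.ndarray, theta: AffineTheta,
                          out_h: int, out_w: int) -> np.ndarray:
    """Crop an integer label map through ``theta`` with nearest-neighbour
    sampling (labels are categorical; bilinear averaging would invent
    classes).  Out-of-frame pixels become background 0."""
    labels = np.asarray(labels)
    H, W = labels.shape
    grid = make_sampling_grid(theta, out_h, out_w).source_coords
    px = np.rint((grid[..., 0] + 1.0) * 0.5 * (W - 1)).astype(np.int64)
    py = np.rint((grid[..., 1] + 1.0) * 0.5 * (H - 1)).astype(np.int64)
    valid = (px >= 0) & (px < W) & (py >= 0) & (py < H)
    out = np.zeros((out_h, out_w), dtype=labels.dtype)
    out[valid] = labels[py[valid], px[valid]]
    return out


def inverse_remap(roi_labels: list[np.ndarray], thetas: ThetaSet,
                  H: int, W: int, labels: str = "all") -> np.ndarray:
    """Paste per-region crop label maps back to frame coordinates.

    Each crop is mapped through the inverse of its transform.  With
    ``labels="all"`` (default) every nonbackground label a crop predicts is
    pasted — a region's crop covers its margin-expanded bounding box, so
    e.g. the ventricle crop legitimately segments the thin walls it
    contains; with ``labels="own"`` region ``i``'s crop contributes only
    pixels labelled ``i``.  A frame pixel claimed through several crops goes
    to the crop whose sampling point is nearest its crop centre; exact ties
    go to the lower region id.  Unclaimed pixels stay background (0).
    """
    if labels not in ("all", "own"):
        raise ValueError("labels must be 'all' or 'own'")
    if len(roi_labels) != len(thetas):
        raise ValueError("one label map per transform required")
    out = np.zeros((H, W), dtype=np.int64)
    best = np.full((H, W), np.inf)
    XF, YF = _target_grid(H, W)  # frame pixels in normalized coords
    for crop, theta, rid in zip(roi_labels, thetas.thetas, thetas.region_ids):
        if theta.s_x == 0.0 or theta.s_y == 0.0:
            raise ValueError(f"singular theta for region {rid}")
        ch, cw = crop.shape
        # crop-space (target) coordinates of every frame pixel
        xt = (XF - theta.t_x) / theta.s_x
        yt = (YF - theta.t_y) / theta.s_y
        px = np.rint((xt + 1.0) * 0.5 * (cw - 1)).astype(np.int64)
        py = np.rint((yt + 1.0) * 0.5 * (ch - 1)).astype(np.int64)
        inside = (px >= 0) & (px < cw) & (py >= 0) & (py < ch)
        lab = np.zeros((H, W), dtype=np.int64)
        lab[inside] = crop[py[inside], px[inside]]
        dist = xt * xt + yt * yt
        wanted = (lab == rid) if labels == "own" else (lab > 0)
        claim = inside & wanted & (dist < best)
        out[claim] = lab[claim]
        best[claim] = dist[claim]
    return out


def coarse_to_input(labels: np.ndarray, n_regions: int,
                    with_coords: bool = True) -> np.ndarray:
    """Encode a coarse label map (or batch) for the localization network.

    One-hot over the N+1 classes (label-permutation stable in magnitude),
    optionally concatenated with two fixed coordinate channels in [-1, 1]
    that make box moments linearly readable after pooling.
    """
    labels = np.asarray(labels)
    squeeze = labels.ndim == 2
    if squeeze:
        labels = labels[None]
    B, H, W = labels.shape
    K = n_regions + 1
    if labels.min() < 0 or labels.max() > n_regions:
        raise ValueError(f"coarse labels must lie in [0, {n_regions}]")
    onehot = np.zeros((B, K, H, W), dtype=np.float32)
    for k in range(K):
        onehot[:, k] = labels == k
    if with_coords:
        XT, YT = _target_grid(H, W)
        coords = np.broadcast_to(
            np.stack([XT, YT]).astype(np.float32)[None], (B, 2, H, W))
        onehot = np.concatenate([onehot, coords], axis=1)
    return onehot[0] if squeeze else onehot


class LocalizationNet(nn.Module):
    """The regression network ``L``: coarse mask -> per-region transforms.

    Eight 3x3 convolution blocks (batch norm + ReLU, stride 2 on every other
    block), global average pooling, and a linear head emitting four values
    per region mapped into the N x 2 x 3 layout with zero shear.  The head
    has near-zero weights and an identity bias (s=1, t=0) so an untrained network
    predicts identity transforms and early training cannot collapse crops.
    predicts near-identity transforms and early training cannot collapse
    crops.  Scales are clamped to ``scale_clip`` in the forward pass to keep
    the inverse transform well defined.
    """

    CHANNELS = (16, 16, 32, 32, 64, 64, 128, 128)

    def __init__(self, n_regions: int, with_coords: bool = True,
                 scale_clip: tuple[float, float] = (0.05, 1.5),
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.n_regions = n_regions
        self.with_coords = with_coords
        self.scale_clip = scale_clip
        c_in = n_regions + 1 + (2 if with_coords else 0)
        blocks = []
        for i, c_out in enumerate(self.CHANNELS):
            stride = 2 if i % 2 == 0 else 1
            blocks += [nn.Conv2d(c_in, c_out, 3, stride=stride, bias=False, rng=rng),
                       nn.BatchNorm2d(c_out)]
            c_in = c_out
        self.blocks = nn.ModuleList(blocks)
        self.head = nn.Linear(self.CHANNELS[-1], n_regions * 4, rng=rng)
        # near-zero head + identity bias: an untrained net predicts ~identity
        # transforms, yet gradients still reach the body on the first step
        self.head.weight.data[:] = (rng.standard_normal(self.head.weight.shape)
                                    * 1e-3).astype(np.float32)
        bias = np.tile(np.array([1.0, 1.0, 0.0, 0.0], dtype=np.float32), n_regions)
        self.head.bias.data[:] = bias

    def forward(self, z: Tensor) -> Tensor:
        """z: (B, C_in, H, W) encoded coarse mask -> (B, N, 4) parameters."""
        expected = self.n_regions + 1 + (2 if self.with_coords else 0)
        if z.shape[1] != expected:
            raise ValueError(
                f"localization head configured for {self.n_regions} regions "
                f"(expects {expected} input channels), got {z.shape[1]}")
        h = z
        for i in range(0, len(self.blocks), 2):
            h = nn.relu(self.blocks[i + 1](self.blocks[i](h)))
        h = nn.global_avg_pool(h)
        h = nn.reshape(h, (h.shape[0], h.shape[1]))
        theta = nn.reshape(self.head(h), (h.shape[0], self.n_regions, 4))
        scales = nn.clip(nn.narrow(theta, 2, 0, 2), *self.scale_clip)
        trans = nn.narrow(theta, 2, 2, 2)
        return nn.concat([scales, trans], axis=2)

    def predict_theta(self, coarse_labels: np.ndarray) -> ThetaSet:
        """Numpy-level inference on one coarse mask -> :class:`ThetaSet`."""
        z = coarse_to_input(coarse_labels, self.n_regions, self.with_coords)
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                theta = self.forward(Tensor(z[None].astype(np.float32)))
        finally:
            self.train(was_training)
        params = theta.data[0]  # (N, 4)
        thetas = [AffineTheta(float(p[0]), float(p[1]), float(p[2]), float(p[3]))
                  for p in params]
        return ThetaSet(thetas, list(range(1, self.n_regions + 1)))
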