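"""Losses and overlap metrics.

The network loss is the mean over regions of a per-ROI segmentation loss;
each per-ROI loss is a principal per-pixel softmax cross-entropy plus two
auxiliary cross-entropies on the context-pathway taps, weighted by alpha_1
and alpha_2 (both default 1).  Localization pre-training uses the smooth-L1
loss on the free affine parameters.  Evaluation reports per-region IoU and
Dice (= F1 on masks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["LossConfig", "RegionMetrics", "seg_loss", "total_loss",
           "smooth_l1", "iou_dice", "aggregate_metrics"]


@dataclass
class LossConfig:
    alpha1: float = 1.0
    alpha2: float = 1.0

    def __post_init__(self):
        if not (np.isfinite(self.alpha1) and np.isfinite(self.alpha2)):
            raise ValueError("loss weights must be finite")


def seg_loss(main_logits: Tensor, aux1: Tensor | None, aux2: Tensor | None,
             gt_labels: np.ndarray, cfg: LossConfig | None = None) -> Tensor:
    """L_p + alpha1 * L_aux1 + alpha2 * L_aux2, all mean per-pixel CE.

    Auxiliary logit maps are bilinearly upsampled to the ground-truth
    resolution before the loss (preserves thin-wall labels, which
    downsampling the ground truth would destroy).
    """
    cfg = cfg or LossConfig()
    gt_labels = np.asarray(gt_labels)
    H, W = gt_labels.shape[-2:]
    loss = nn.softmax_cross_entropy(main_logits, gt_labels)
    if cfg.alpha1 != 0.0 and aux1 is not None:
        up1 = nn.upsample_bilinear(aux1, H, W)
        loss = loss + cfg.alpha1 * nn.softmax_cross_entropy(up1, gt_labels)
    if cfg.alpha2 != 0.0 and aux2 is not None:
        up2 = nn.upsample_bilinear(aux2, H, W)
        loss = loss + cfg.alpha2 * nn.softmax_cross_entropy(up2, gt_labels)
    return loss


def total_loss(per_roi_losses: list) -> Tensor:
    """Arithmetic mean of the per-ROI segmentation losses."""
    if len(per_roi_losses) == 0:
        raise ValueError("need at least one per-ROI loss")
    out = per_roi_losses[0]
    for l in per_roi_losses[1:]:
        out = out + l
    return out * (1.0 / len(per_roi_losses))


def smooth_l1(theta_pred, theta_gt) -> Tensor:
    """Elementwise smooth-L1 between predicted and ground-truth transforms,
    averaged over all free entries and regions.

    Accepts Tensors/arrays of matching shape or a pair of
    :class:`~tanet.stn.ThetaSet`.
    """
    from .stn import ThetaSet  # local import to avoid a cycle

    if isinstance(theta_pred, ThetaSet):
        theta_pred = np.stack([t.as_vector() for t in theta_pred.thetas])
    if isinstance(theta_gt, ThetaSet):
        theta_gt = np.stack([t.as_vector() for t in theta_gt.thetas])
    pred = theta_pred if isinstance(theta_pred, Tensor) else Tensor(np.asarray(theta_pred))
    gt = np.asarray(theta_gt.data if isinstance(theta_gt, Tensor) else theta_gt)
    if tuple(pred.shape) != gt.shape:
        raise ValueError(f"shape mismatch: {tuple(pred.shape)} vs {gt.shape}")
    return nn.smooth_l1_loss(pred, gt)


@dataclass
class RegionMetrics:
    """Per-region IoU/Dice for one frame plus their arithmetic means.

    Background is never a region; means run over the named cardiac regions
    present in the ground truth.
    """

    per_region: dict[int, tuple[float, float]] = field(default_factory=dict)

    @property
    def mean_iou(self) -> float:
        if not self.per_region:
            return float("nan")
        return float(np.mean([v[0] for v in self.per_region.values()]))

    @property
    def mean_dice(self) -> float:
        if not self.per_region:
            return float("nan")
        return float(np.mean([v[1] for v in self.per_region.values()]))


def iou_dice(pred_mask: np.ndarray, gt_mask: np.ndarray,
             region_ids) -> RegionMetrics:
    """Per-region IoU = |P&G|/|P|G| and Dice = 2|P&G|/(|P|+|G|).

    Regions absent from the ground truth are skipped (whether or not they
    are predicted); regions present in the ground truth but never predicted
    score 0.
    """
    pred_mask = np.asarray(pred_mask)
    gt_mask = np.asarray(gt_mask)
    if pred_mask.shape != gt_mask.shape:
        raise ValueError("masks must share shape")
    out = RegionMetrics()
    for rid in region_ids:
        p = pred_mask == rid
        g = gt_mask == rid
        ng = int(g.sum())
        if ng == 0:
            continue
        inter = int((p & g).sum())
        union = int(p.sum()) + ng - inter
        iou = inter / union if union else 0.0
        dice = 2.0 * inter / (p.sum() + ng)
        out.per_region[int(rid)] = (float(iou), float(dice))
    return out


def aggregate_metrics(per_frame: list[RegionMetrics]) -> dict:
    """Average per-frame metrics over frames, then over regions.

    Returns ``{"per_region": {rid: {"iou", "dice", "n_frames"}},
    "mean_iou", "mean_dice"}``; background excluded throughout.
    """
    acc: dict[int, list[tuple[float, float]]] = {}
    for fm in per_frame:
        for rid, (iou, dice) in fm.per_region.items():
            acc.setdefault(rid, []).append((iou, dice))
    per_region = {
        rid: {"iou": float(np.mean([v[0] for v in vals])),
              "dice": float(np.mean([v[1] for v in vals])),
              "n_frames": len(vals)}
        for rid, vals in sorted(acc.items())
    }
    mean_iou = float(np.mean([d["iou"] for d in per_region.values()])) if per_region else float("nan")
    mean_dice = float(np.mean([d["dice"] for d in per_region.values()])) if per_region else float("nan")
    return {"per_region": per_region, "mean_iou": mean_iou, "mean_dice": mean_dice,
            "background_included": False}
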