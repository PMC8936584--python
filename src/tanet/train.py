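"""Two-stage training protocol and evaluation.

Stage 1 pre-trains (a) the coarse FCN with per-pixel cross-entropy and (b)
the localization network against ground-truth transforms with smooth-L1,
with the coarse net frozen.  Stage 2 fine-tunes everything except the coarse
net and the fixed LBC anchors end-to-end against the mean per-ROI
segmentation loss.  Optimization is Adam at lr 1e-3 with plateau reduction
(factor 0.5, patience 5) throughout; defaults follow the full-scale protocol
(batch 16, 100 fine-tune epochs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import nn
from .coarse import CoarseFCN
from .losses import LossConfig, aggregate_metrics, iou_dice, seg_loss, smooth_l1, total_loss
from .model import TaNet
from .nn import Tensor
from .phantom import PhantomSample
from .stn import MissingRegionError, coarse_to_input, sample_labels_nearest, theta_gt_from_mask

__all__ = [
    "AugmentationSpec", "TrainConfig", "sample_transform", "augment",
    "split_dataset", "pretrain_coarse", "pretrain_localizer",
    "finetune_end_to_end", "evaluate_segmentation", "theta_error",
    "coarse_pixel_accuracy", "gradient_flow_report",
]


# ---------------------------------------------------------------------------
# Configuration

@dataclass
class AugmentationSpec:
    rotation_deg: float = 15.0
    shift_frac: float = 0.25
    scale_choices: tuple = (0.75, 1.0, 1.25)
    hflip: bool = True
    vflip: bool = True

    @classmethod
    def disabled(cls) -> "AugmentationSpec":
        return cls(rotation_deg=0.0, shift_frac=0.0, scale_choices=(1.0,),
                   hflip=False, vflip=False)


@dataclass
class TrainConfig:
    batch_size: int = 16
    lr: float = 1e-3
    coarse_epochs: int = 60
    coarse_max_steps: int | None = None
    loc_epochs: int = 80
    finetune_epochs: int = 100
    optimizer: str = "adam"
    plateau_factor: float = 0.5
    plateau_patience: int = 5
    finetune_batch_size: int | None = None  # None: use batch_size
    loc_lr_scale: float = 0.02  # localizer lr multiplier during fine-tuning
    seed: int = 0
    augment: bool = False
    aug: AugmentationSpec = field(default_factory=AugmentationSpec)
    splits: tuple = (0.2, 0.6, 0.2)
    loss: LossConfig = field(default_factory=LossConfig)

    @classmethod
    def tiny(cls, seed: int = 0, **kw) -> "TrainConfig":
        """Desk-scale protocol used by the test suite and examples."""
        kw.setdefault("batch_size", 8)
        kw.setdefault("finetune_batch_size", 2)
        kw.setdefault("coarse_max_steps", 200)
        kw.setdefault("coarse_epochs", 200)
        kw.setdefault("loc_epochs", 80)
        kw.setdefault("finetune_epochs", 30)
        kw.setdefault("augment", False)
        return cls(seed=seed, **kw)

    def to_dict(self) -> dict:
        from dataclasses import asdict
        d = asdict(self)
        d["splits"] = list(d["splits"])
        d["aug"]["scale_choices"] = list(d["aug"]["scale_choices"])
        return d


# ---------------------------------------------------------------------------
# Augmentation

def sample_transform(spec: AugmentationSpec, rng: np.random.Generator) -> dict:
    """One random draw of the augmentation parameters."""
    return {
        "angle": float(rng.uniform(-spec.rotation_deg, spec.rotation_deg)),
        "shift_y": float(rng.uniform(-spec.shift_frac, spec.shift_frac)),
        "shift_x": float(rng.uniform(-spec.shift_frac, spec.shift_frac)),
        "scale": float(rng.choice(np.asarray(spec.scale_choices, dtype=float))),
        "hflip": bool(spec.hflip and rng.random() < 0.5),
        "vflip": bool(spec.vflip and rng.random() < 0.5),
    }


def _apply_transform(arr: np.ndarray, params: dict, order: int) -> np.ndarray:
    """Apply one geometric transform about the frame centre.

    ``order`` 1 = bilinear (images), 0 = nearest (label masks).
    """
    H, W = arr.shape[-2:]
    c = np.array([(H - 1) / 2.0, (W - 1) / 2.0])
    t = np.array([params["shift_y"] * H, params["shift_x"] * W])
    a = np.deg2rad(params["angle"])
    R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    S = np.diag([params["scale"] * (-1.0 if params["vflip"] else 1.0),
                 params["scale"] * (-1.0 if params["hflip"] else 1.0)])
    A = np.linalg.inv(R @ S)
    offset = c - A @ (c + t)
    if (params["angle"] == 0.0 and params["scale"] == 1.0
            and not params["hflip"] and not params["vflip"]
            and params["shift_y"] == 0.0 and params["shift_x"] == 0.0):
        return arr.copy()
    cval = 0
    if arr.ndim == 3:
        return np.stack([ndimage.affine_transform(ch, A, offset=offset, order=order,
                                                  mode="constant", cval=cval)
                         for ch in arr])
    return ndimage.affine_transform(arr, A, offset=offset, order=order,
                                    mode="constant", cval=cval)


def augment(image: np.ndarray, mask: np.ndarray, spec: AugmentationSpec,
            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Identical geometric transform on an image (bilinear) and its mask
    (nearest); deterministic given the generator state."""
    params = sample_transform(spec, rng)
    return (_apply_transform(image, params, order=1),
            _apply_transform(mask, params, order=0))


# ---------------------------------------------------------------------------
# Splits and batching

def split_dataset(samples: list[PhantomSample], fractions=(0.2, 0.6, 0.2),
                  seed: int = 0):
    """Subject-wise disjoint (coarse_train, fine_train, test) splits."""
    if len(fractions) != 3 or not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must be three values summing to 1")
    subjects = sorted({s.subject_id for s in samples})
    if len(subjects) < 3:
        raise ValueError("need at least one subject per split")
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    n = len(order)
    n_coarse = max(1, round(fractions[0] * n))
    n_test = max(1, round(fractions[2] * n))
    n_fine = n - n_coarse - n_test
    if n_fine < 1:
        raise ValueError("fewer subjects than splits")
    groups = (set(order[:n_coarse]),
              set(order[n_coarse:n_coarse + n_fine]),
              set(order[n_coarse + n_fine:]))
    return tuple([s for s in samples if s.subject_id in g] for g in groups)


def _iter_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def _stack_images(samples) -> np.ndarray:
    return np.stack([s.image.values for s in samples]).astype(np.float32)


def _stack_masks(samples) -> np.ndarray:
    return np.stack([s.mask for s in samples])


def _check_finite(loss_value: float, stage: str):
    if not np.isfinite(loss_value):
        raise RuntimeError(
            f"{stage} training diverged (loss = {loss_value}); "
            "reduce the learning rate or inspect the inputs")


# ---------------------------------------------------------------------------
# Stage 1a: coarse segmentation

def pretrain_coarse(train: list[PhantomSample], val: list[PhantomSample],
                    coarse: CoarseFCN, cfg: TrainConfig) -> dict:
    """Cross-entropy training of the coarse FCN; restores the best-validation
    weights before returning the loss history."""
    if not train:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(coarse.parameters(), lr=cfg.lr)
    sched = nn.ReduceLROnPlateau(opt, cfg.plateau_factor, cfg.plateau_patience)
    images, masks = _stack_images(train), _stack_masks(train)
    history = {"train_loss": [], "val_loss": []}
    best, best_state = np.inf, None
    steps = 0
    for _epoch in range(cfg.coarse_epochs):
        coarse.train()
        ep_losses = []
        for idx in _iter_batches(len(train), cfg.batch_size, rng):
            bi, bm = images[idx], masks[idx]
            if cfg.augment:
                pairs = [augment(i, m, cfg.aug, rng) for i, m in zip(bi, bm)]
                bi = np.stack([p[0] for p in pairs]).astype(np.float32)
                bm = np.stack([p[1] for p in pairs])
            loss = nn.softmax_cross_entropy(coarse(Tensor(bi)), bm)
            _check_finite(loss.item(), "coarse")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_losses.append(loss.item())
            steps += 1
            if cfg.coarse_max_steps and steps >= cfg.coarse_max_steps:
                break
        history["train_loss"].append(float(np.mean(ep_losses)))
        vl = _coarse_val_loss(coarse, val if val else train)
        history["val_loss"].append(vl)
        sched.step(vl)
        if vl < best:
            best, best_state = vl, coarse.state_dict()
        if cfg.coarse_max_steps and steps >= cfg.coarse_max_steps:
            break
    if best_state is not None:
        coarse.load_state_dict(best_state)
    return history


def _coarse_val_loss(coarse: CoarseFCN, samples) -> float:
    coarse.eval()
    with nn.no_grad():
        loss = nn.softmax_cross_entropy(
            coarse(Tensor(_stack_images(samples))), _stack_masks(samples))
    return loss.item()


def coarse_pixel_accuracy(coarse: CoarseFCN, samples) -> float:
    pred = coarse.segment(_stack_images(samples))
    return float((pred == _stack_masks(samples)).mean())


# ---------------------------------------------------------------------------
# Stage 1b: localization

def _theta_targets(samples, n_regions: int, margin: float) -> tuple[list, np.ndarray]:
    """(kept samples, (B, N, 4) targets); samples missing a region are
    skipped with a warning."""
    kept, targets = [], []
    for s in samples:
        try:
            vecs = [theta_gt_from_mask(s.mask, rid, margin=margin).as_vector()
                    for rid in range(1, n_regions + 1)]
        except MissingRegionError as e:
            warnings.warn(f"skipping sample {s.sample_id}: {e}")
            continue
        kept.append(s)
        targets.append(np.stack(vecs))
    if not kept:
        raise ValueError("no sample has all regions present")
    return kept, np.stack(targets).astype(np.float32)


def pretrain_localizer(train: list[PhantomSample], val: list[PhantomSample],
                       model: TaNet, cfg: TrainConfig) -> dict:
    """Smooth-L1 training of the localization net on frozen-coarse masks."""
    n = model.config.n_regions
    margin = model.config.theta_margin
    train, t_train = _theta_targets(train, n, margin)
    val, t_val = _theta_targets(val, n, margin) if val else (train, t_train)
    # the coarse net is frozen in this stage: precompute its masks once
    z_train = model.coarse_labels(_stack_images(train))
    z_val = model.coarse_labels(_stack_images(val))
    enc_train = coarse_to_input(z_train, n).astype(np.float32)
    enc_val = coarse_to_input(z_val, n).astype(np.float32)
    rng = np.random.default_rng(cfg.seed + 1)
    opt = nn.Adam(model.loc.parameters(), lr=cfg.lr)
    sched = nn.ReduceLROnPlateau(opt, cfg.plateau_factor, cfg.plateau_patience)
    history = {"train_loss": [], "val_loss": []}
    best, best_state = np.inf, None
    for _epoch in range(cfg.loc_epochs):
        model.loc.train()
        ep = []
        for idx in _iter_batches(len(train), cfg.batch_size, rng):
            theta = model.loc(Tensor(enc_train[idx]))
            loss = smooth_l1(theta, t_train[idx])
            _check_finite(loss.item(), "localizer")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep.append(loss.item())
        history["train_loss"].append(float(np.mean(ep)))
        model.loc.eval()
        with nn.no_grad():
            vl = smooth_l1(model.loc(Tensor(enc_val)), t_val).item()
        history["val_loss"].append(vl)
        sched.step(vl)
        if vl < best:
            best, best_state = vl, model.loc.state_dict()
    if best_state is not None:
        model.loc.load_state_dict(best_state)
    return history


def theta_error(model: TaNet, samples: list[PhantomSample]) -> float:
    """Held-out mean entry-wise |theta - theta_gt| over the free parameters."""
    n = model.config.n_regions
    samples, targets = _theta_targets(samples, n, model.config.theta_margin)
    z = model.coarse_labels(_stack_images(samples))
    enc = coarse_to_input(z, n).astype(np.float32)
    model.loc.eval()
    with nn.no_grad():
        pred = model.loc(Tensor(enc)).data
    return float(np.abs(pred - targets).mean())


# ---------------------------------------------------------------------------
# Stage 2: end-to-end fine-tuning

def _finetune_parameters(model: TaNet):
    """Everything except the frozen coarse net (anchors are buffers and never
    appear among parameters)."""
    names, params = [], []
    for name, p in model.named_parameters():
        if name.startswith("coarse."):
            continue
        names.append(name)
        params.append(p)
    return names, params


def _roi_targets(masks: np.ndarray, thetas: np.ndarray, region_index: int,
                 crop_size: int) -> np.ndarray:
    """Per-ROI targets: the ground-truth mask cropped through each sample's
    *current* transform for this region (nearest-neighbour; labels stay
    categorical).  Prediction and target always see the same window, so the
    segmentation loss is well posed whatever the localizer currently does."""
    from .stn import AffineTheta

    out = np.zeros((len(masks), crop_size, crop_size), dtype=np.int64)
    for b in range(len(masks)):
        theta = AffineTheta(*thetas[b, region_index])
        out[b] = sample_labels_nearest(masks[b], theta, crop_size, crop_size)
    return out


def _finetune_batch_loss(model: TaNet, images: np.ndarray, enc_z: np.ndarray,
                         masks: np.ndarray, loss_cfg: LossConfig) -> Tensor:
    cs = model.config.crop_size
    thetas = model.loc(Tensor(enc_z))
    roi_out = model.forward_rois(Tensor(images), thetas)
    per_roi = [seg_loss(logits, aux1, aux2,
                        _roi_targets(masks, thetas.data, i, cs), loss_cfg)
               for i, (logits, aux1, aux2) in enumerate(roi_out)]
    return total_loss(per_roi)


def finetune_end_to_end(train: list[PhantomSample], val: list[PhantomSample],
                        model: TaNet, cfg: TrainConfig) -> dict:
    """Joint training of localization + pathways + fusion + head.

    The coarse net stays frozen (it only supplies the rough mask to the
    localizer) and the LBC anchors are immutable by construction.  The
    pretrained localizer trains at ``cfg.loc_lr_scale`` times the base
    learning rate: it starts close to its optimum while the segmentation
    trunk starts from scratch, and a full-rate localizer drifts on the noisy
    transform gradients before the trunk can supply a clean signal.
    """
    n = model.config.n_regions
    images = _stack_images(train)
    masks = _stack_masks(train)
    enc = coarse_to_input(model.coarse_labels(images), n).astype(np.float32)
    if val:
        v_images = _stack_images(val)
        v_masks = _stack_masks(val)
        v_enc = coarse_to_input(model.coarse_labels(v_images), n).astype(np.float32)
    rng = np.random.default_rng(cfg.seed + 2)
    names, params = _finetune_parameters(model)
    loc_params = [p for nm, p in zip(names, params) if nm.startswith("loc.")]
    trunk_params = [p for nm, p in zip(names, params) if not nm.startswith("loc.")]
    opt = nn.Adam(trunk_params, lr=cfg.lr)
    opt_loc = nn.Adam(loc_params, lr=cfg.lr * cfg.loc_lr_scale)
    sched = nn.ReduceLROnPlateau(opt, cfg.plateau_factor, cfg.plateau_patience)
    batch = cfg.finetune_batch_size or cfg.batch_size
    history = {"train_loss": [], "val_loss": []}
    best, best_state = np.inf, None
    for _epoch in range(cfg.finetune_epochs):
        model.train()
        model.coarse.eval()
        ep = []
        for idx in _iter_batches(len(train), batch, rng):
            loss = _finetune_batch_loss(model, images[idx], enc[idx],
                                        masks[idx], cfg.loss)
            _check_finite(loss.item(), "fine-tuning")
            opt.zero_grad()
            opt_loc.zero_grad()
            loss.backward()
            opt.step()
            opt_loc.step()
            ep.append(loss.item())
        history["train_loss"].append(float(np.mean(ep)))
        if val:
            model.eval()
            with nn.no_grad():
                vl = _finetune_batch_loss(model, v_images, v_enc, v_masks,
                                          cfg.loss).item()
        else:
            vl = history["train_loss"][-1]
        history["val_loss"].append(vl)
        sched.step(vl)
        if vl < best:
            best, best_state = vl, model.state_dict()
    if best_state is not None:
        model.load_state_dict(best_state)
    return history


# ---------------------------------------------------------------------------
# Evaluation and audits

def evaluate_segmentation(model: TaNet, samples: list[PhantomSample]):
    """Full inference on every sample; per-frame and aggregated IoU/Dice."""
    region_ids = list(range(1, model.config.n_regions + 1))
    per_frame, rows = [], []
    for s in samples:
        result = model.segment_frame(s.image.values)
        m = iou_dice(result["mask"], s.mask, region_ids)
        per_frame.append(m)
        for rid, (iou, dice) in sorted(m.per_region.items()):
            rows.append({"sample_id": s.sample_id, "region": rid,
                         "iou": iou, "dice": dice})
    return per_frame, aggregate_metrics(per_frame), rows


def gradient_flow_report(model: TaNet, samples: list[PhantomSample],
                         loss_cfg: LossConfig | None = None) -> dict[str, bool]:
    """Backprop one batch through the fine-tuning loss and report which
    trainable tensors received a nonzero gradient (frozen coarse excluded)."""
    n = model.config.n_regions
    images = _stack_images(samples)
    masks = _stack_masks(samples)
    enc = coarse_to_input(model.coarse_labels(images), n).astype(np.float32)
    model.train()
    model.coarse.eval()
    model.zero_grad()
    loss = _finetune_batch_loss(model, images, enc, masks, loss_cfg or LossConfig())
    loss.backward()
    names, params = _finetune_parameters(model)
    return {name: bool(p.grad is not None and np.any(p.grad != 0))
            for name, p in zip(names, params)}
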