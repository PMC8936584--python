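"""Synthetic echo phantoms: cone-sector images with known region masks.

The generator emulates the geometry of B-mode echocardiograms well enough to
exercise every network component without clinical data: a dark cone-shaped
imaging sector on a black background, multiplicative unit-mean gamma speckle,
and bright-walled regions with known label masks.

Two modes mirror the two study configurations:

* ``plax`` — five regions: three anechoic (dark-interior, bright-rimmed)
  elliptical chambers (LV, RV, LA) and two thin bright curved ribbons (SW,
  PW) hugging the upper and lower LV border.  The walls are deliberately
  thin (<= 8% of the frame height) and adjacent to the LV, preserving the
  thin-wall separation difficulty of real parasternal long-axis views.
* ``ivc`` — one elongated tubular vessel.

Frames within one synthetic subject share region geometry up to a small
frame-to-frame jitter, mimicking video frames from one patient, so datasets
can be split subject-wise.  Ground-truth affine transforms are derived from
the masks via :func:`tanet.stn.theta_gt_from_mask`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .coarse import EchoImage
from .stn import ThetaSet, theta_gt_from_mask

__all__ = ["PhantomSample", "generate_phantom", "generate_dataset",
           "REGION_NAMES", "n_regions_for_mode"]

REGION_NAMES = {
    "plax": {1: "LV", 2: "RV", 3: "LA", 4: "SW", 5: "PW"},
    "ivc": {1: "IVC"},
}

SPECKLE_SHAPE = 4.0          # gamma shape; scale = 1/shape gives unit mean
BLUR_SIGMA = 0.7             # px, mild post-speckle smoothing
THETA_MARGIN = 0.1           # bounding-box expansion per side for theta_gt


def n_regions_for_mode(mode: str) -> int:
    if mode not in REGION_NAMES:
        raise ValueError(f"unknown mode {mode!r}; choose 'ivc' or 'plax'")
    return len(REGION_NAMES[mode])


@dataclass
class PhantomSample:
    image: EchoImage
    mask: np.ndarray
    thetas_gt: ThetaSet
    subject_id: int
    mode: str
    sample_id: str = ""


def _grids(size: int):
    c = (np.arange(size) + 0.5) / size
    xx, yy = np.meshgrid(c, c)
    return yy, xx  # row (y), col (x) in (0, 1)


def _sector_mask(size: int) -> np.ndarray:
    yy, xx = _grids(size)
    ay, ax = 0.04, 0.5
    dy, dx = yy - ay, xx - ax
    r = np.hypot(dy, dx)
    ang = np.abs(np.arctan2(dx, dy))        # 0 = straight down from the apex
    return (r <= 0.92) & (ang <= np.deg2rad(38.0)) & (dy >= 0)


def _ellipse_r2(size: int, cy, cx, ay, ax, angle):
    yy, xx = _grids(size)
    th = np.deg2rad(angle)
    dy, dx = yy - cy, xx - cx
    u = np.cos(th) * dx + np.sin(th) * dy
    v = -np.sin(th) * dx + np.cos(th) * dy
    return (u / ax) ** 2 + (v / ay) ** 2, u, v


def _jitter(rng, base: dict, pos: float, scale: float, ang: float) -> dict:
    out = dict(base)
    out["cy"] = base["cy"] + rng.uniform(-pos, pos)
    out["cx"] = base["cx"] + rng.uniform(-pos, pos)
    f = np.exp(rng.uniform(-scale, scale))
    out["ay"] = base["ay"] * f
    out["ax"] = base["ax"] * np.exp(rng.uniform(-scale, scale))
    out["angle"] = base["angle"] + rng.uniform(-ang, ang)
    return out


_PLAX_BASE = {
    "LV": {"cy": 0.52, "cx": 0.42, "ay": 0.15, "ax": 0.20, "angle": -15.0},
    "RV": {"cy": 0.24, "cx": 0.38, "ay": 0.075, "ax": 0.14, "angle": -12.0},
    "LA": {"cy": 0.60, "cx": 0.70, "ay": 0.095, "ax": 0.105, "angle": 10.0},
}
_IVC_BASE = {"IVC": {"cy": 0.50, "cx": 0.50, "ay": 0.045, "ax": 0.27, "angle": -35.0}}
_RING_IN, _RING_OUT = 1.03, 1.31   # SW/PW band in LV-normalized radius


def _subject_geometry(mode: str, rng: np.random.Generator) -> dict:
    base = _PLAX_BASE if mode == "plax" else _IVC_BASE
    return {name: _jitter(rng, p, pos=0.02, scale=0.08, ang=4.0)
            for name, p in base.items()}


def _frame_geometry(geom: dict, rng: np.random.Generator) -> dict:
    return {name: _jitter(rng, p, pos=0.006, scale=0.025, ang=1.5)
            for name, p in geom.items()}


def _render(mode: str, size: int, geom: dict,
            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    sector = _sector_mask(size)
    img = np.where(sector, 0.28, 0.02)
    mask = np.zeros((size, size), dtype=np.int64)

    def claim(label, region):
        region = region & sector & (mask == 0)
        mask[region] = label
        return region

    if mode == "plax":
        lv = geom["LV"]
        r2, u, v = _ellipse_r2(size, **lv)
        r = np.sqrt(r2)
        band = (r > _RING_IN) & (r <= _RING_OUT) & (np.abs(u) < 0.92 * lv["ax"])
        sw = claim(4, band & (v < 0))
        pw = claim(5, band & (v >= 0))
        lv_in = claim(1, r <= 1.0)
        r2_rv, _, _ = _ellipse_r2(size, **geom["RV"])
        rv = claim(2, r2_rv <= 1.0)
        r2_la, _, _ = _ellipse_r2(size, **geom["LA"])
        la = claim(3, r2_la <= 1.0)
        # appearance: bright chamber rims, brighter ribbons, dark interiors
        for r2c in (r2_rv, r2_la):
            rc = np.sqrt(r2c)
            img[sector & (rc > 1.0) & (rc <= 1.25)] = 0.70
        img[sector & (r > 1.0) & (r <= _RING_IN)] = 0.55
        img[sw | pw] = 0.88
        for interior in (lv_in, rv, la):
            img[interior] = 0.08
    else:
        tube = geom["IVC"]
        r2, _, _ = _ellipse_r2(size, **tube)
        r = np.sqrt(r2)
        interior = claim(1, r <= 1.0)
        img[sector & (r > 1.0) & (r <= 1.6)] = 0.85
        img[interior] = 0.08

    speckle = rng.gamma(shape=SPECKLE_SHAPE, scale=1.0 / SPECKLE_SHAPE,
                        size=img.shape)
    img = ndimage.gaussian_filter(img * speckle, sigma=BLUR_SIGMA)
    return np.clip(img, 0.0, 1.0), mask


def _build_sample(mode: str, size: int, geom: dict, rng: np.random.Generator,
                  subject_id: int, sample_id: str) -> PhantomSample:
    n = n_regions_for_mode(mode)
    img, mask = _render(mode, size, geom, rng)
    present = set(np.unique(mask)) - {0}
    if present != set(range(1, n + 1)):
        missing = sorted(set(range(1, n + 1)) - present)
        raise ValueError(
            f"frame of size {size} too small/jittered to place regions {missing}")
    thetas = ThetaSet(
        [theta_gt_from_mask(mask, rid, margin=THETA_MARGIN)
         for rid in range(1, n + 1)],
        list(range(1, n + 1)))
    image = EchoImage(values=img[None].astype(np.float32))
    return PhantomSample(image=image, mask=mask, thetas_gt=thetas,
                         subject_id=subject_id, mode=mode, sample_id=sample_id)


def generate_phantom(mode: str, size: int, seed: int) -> PhantomSample:
    """One phantom frame; deterministic in ``seed``."""
    if size < 64:
        raise ValueError("size must be >= 64 to place all regions")
    n_regions_for_mode(mode)
    rng = np.random.default_rng(seed)
    geom = _subject_geometry(mode, rng)
    return _build_sample(mode, size, geom, rng, subject_id=seed,
                         sample_id=f"{mode}_{seed:06d}")


def generate_dataset(mode: str, n_subjects: int, frames_per_subject: int,
                     seed: int, size: int = 128) -> list[PhantomSample]:
    """Phantom frames grouped into synthetic subjects.

    Frames of one subject share region geometry with small frame-to-frame
    jitter; subject ids enable subject-wise splitting.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    if size < 64:
        raise ValueError("size must be >= 64 to place all regions")
    rng = np.random.default_rng(seed)
    samples = []
    for s in range(n_subjects):
        geom = _subject_geometry(mode, rng)
        for f in range(frames_per_subject):
            fg = _frame_geometry(geom, rng)
            samples.append(_build_sample(
                mode, size, fg, rng, subject_id=s,
                sample_id=f"{mode}_s{s:03d}_f{f:03d}"))
    return samples
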