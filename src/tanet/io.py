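"""Readers and writers: PNG images/masks, theta JSON, metrics, checkpoints."""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .nn import Module
from .stn import ThetaSet

__all__ = [
    "save_image", "load_image", "save_mask", "load_mask",
    "save_thetas", "load_thetas", "write_metrics_csv", "write_json",
    "save_checkpoint", "load_checkpoint", "load_config", "write_run_manifest",
]

# distinct colours for up to 8 labels; label 0 (background) is black
_PALETTE = [
    (0, 0, 0), (31, 119, 180), (44, 160, 44), (214, 39, 40),
    (255, 201, 14), (148, 103, 189), (140, 86, 75), (227, 119, 194),
]


def save_image(path, image: np.ndarray):
    """Write a (H, W) or (C, H, W) float image in [0, 1] as 8-bit PNG."""
    arr = np.asarray(image)
    if arr.ndim == 3:
        arr = arr[0] if arr.shape[0] == 1 else np.moveaxis(arr, 0, -1)
    Image.fromarray(np.clip(arr * 255.0, 0, 255).astype(np.uint8)).save(path)


def load_image(path) -> np.ndarray:
    """Read a PNG/TIFF frame as grayscale float (H, W) in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=np.float64)
    return arr / 255.0


def save_mask(path, mask: np.ndarray, region_names: dict | None = None):
    """Write an integer label mask as single-channel indexed PNG.

    A sidecar ``<path>.labels.json`` records the label -> region-name map
    when one is given.
    """
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() > 255:
        raise ValueError("labels must fit 8-bit indexed PNG")
    im = Image.fromarray(mask.astype(np.uint8), mode="P")
    pal = []
    for i in range(256):
        pal.extend(_PALETTE[i % len(_PALETTE)] if i < len(_PALETTE) else (i, i, i))
    im.putpalette(pal)
    im.save(path)
    if region_names is not None:
        sidecar = Path(str(path) + ".labels.json")
        sidecar.write_text(json.dumps(
            {str(k): v for k, v in region_names.items()}, indent=1))


def load_mask(path) -> np.ndarray:
    with Image.open(path) as im:
        if im.mode not in ("P", "L"):
            raise ValueError(f"mask {path} is not an indexed/grayscale PNG")
        return np.asarray(im, dtype=np.int64)


def save_thetas(path, thetas: ThetaSet):
    """Serialize transforms as a plain-text JSON [N][2][3] array."""
    payload = {"region_ids": thetas.region_ids,
               "theta": thetas.stack().tolist()}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_thetas(path) -> ThetaSet:
    payload = json.loads(Path(path).read_text())
    return ThetaSet.from_stack(np.asarray(payload["theta"]),
                               payload.get("region_ids"))


def write_metrics_csv(path, rows: list[dict]):
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["sample_id", "region", "iou", "dice"])
        writer.writeheader()
        for row in rows:
            writer.writerow(row)


def write_json(path, payload: dict):
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def save_checkpoint(path, module: Module, meta: dict | None = None):
    state = {f"param/{k}": v for k, v in module.state_dict().items()}
    if meta:
        state["meta"] = np.frombuffer(
            json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path, module: Module) -> dict:
    with np.load(path) as data:
        state = {k[len("param/"):]: data[k] for k in data.files
                 if k.startswith("param/")}
        meta = json.loads(data["meta"].tobytes().decode()) if "meta" in data.files else {}
    module.load_state_dict(state)
    return meta


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def write_run_manifest(path, config: dict, seed: int):
    """Record what a run was: config, its hash, the seed, versions."""
    blob = json.dumps(config, sort_keys=True)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "versions": {"numpy": np.__version__},
    }
    write_json(path, manifest)
    return manifest
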