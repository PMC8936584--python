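# tanet — trilateral attention network for echocardiogram segmentation

`tanet` implements an end-to-end network for localizing and segmenting
cardiac regions in 2-D echocardiograms, for researchers who need per-region
masks (left ventricle, septal and posterior walls, right ventricle, left
atrium in parasternal long-axis views; the vessel in inferior-vena-cava
views) from which quantitative cardiac indices are derived.

The pipeline couples a spatial-transformer attention module to a
three-pathway segmentation trunk:

1. a compact FCN-8-style net produces a rough mask `z = FCN(I)`;
2. a localization net regresses one shear-free affine transform per region,
   `theta = L(z)` with `theta_r = [[s_x, 0, t_x], [0, s_y, t_y]]`;
3. a differentiable bilinear sampler crops each region,
   `V_i^c = sum_{n,m} ROI_{nm}^c max(0, 1-|x_s-m|) max(0, 1-|y_s-n|)`;
4. each crop runs through three concurrent pathways — spatial (SP: three
   stride-2 conv blocks, 64/64/128 channels), handcrafted (HP: three
   local-binary-convolution blocks, i.e. fixed sparse ±1 anchor filters +
   ReLU + learnable 1×1 recombination), and context (CP: fast-downsampling
   separable stack with a global-average-pooled descriptor) — fused by
   channel attention `v_out = v_concat · w_concat + v_concat`;
5. per-crop label maps are pasted back to frame coordinates through the
   inverse transforms.

Training follows a two-stage protocol: pre-train the coarse net
(cross-entropy) and the localizer (smooth-L1 against transforms derived
from mask bounding boxes), then fine-tune end-to-end against the mean
per-region segmentation loss `L = (1/N) sum_i L_seg(ROI_i, ROI_i^gt)`, where
`L_seg = L_p + a1 L_aux1 + a2 L_aux2` adds auxiliary supervision on the
context pathway (a1 = a2 = 1).

An LBC block with `m` anchors has `m · c_out` learnable parameters against
`k² · c_in · c_out` for a standard convolution — a `k²`-fold reduction when
`m = c_in` (9× to 169× for k = 3…13).

Because no public dataset with these annotations exists, the package ships a
synthetic echo-phantom generator (`tanet.phantom`): cone-sector images with
unit-mean gamma speckle, bright-walled chambers and thin wall ribbons, known
label masks, ground-truth transforms, and subject structure for subject-wise
splits. Everything — including the reverse-mode autodiff engine in
`tanet.nn` that the networks run on — is pure numpy/scipy.

## Worked example

```python
import numpy as np
from tanet import (TaNet, TaNetConfig, TrainConfig, generate_dataset,
                   split_dataset, pretrain_coarse, pretrain_localizer,
                   finetune_end_to_end, evaluate_segmentation, theta_error)

samples = generate_dataset("plax", n_subjects=10, frames_per_subject=3,
                           seed=321, size=128)
coarse_train, fine_train, test = split_dataset(samples, (0.2, 0.6, 0.2), seed=0)

model = TaNet(TaNetConfig.tiny(n_regions=5, seed=0))
cfg = TrainConfig.tiny(seed=0)
pretrain_coarse(coarse_train, fine_train, model.coarse, cfg)
pretrain_localizer(fine_train, coarse_train, model, cfg)
print(f"held-out transform error: {theta_error(model, test):.3f}")
finetune_end_to_end(fine_train, coarse_train, model, cfg)
_, agg, _ = evaluate_segmentation(model, test)
print(f"mean IoU {agg['mean_iou']:.3f}, mean Dice {agg['mean_dice']:.3f}")
```

prints (exactly, under the fixed seeds):

```
held-out transform error: 0.017
mean IoU 0.860, mean Dice 0.922
```

The transform error is the mean entry-wise |theta − theta_gt| over the four
free affine parameters of all five regions on held-out subjects (0.017 in
normalized coordinates ≈ 1 pixel at 128 px); IoU/Dice are averaged per
region over held-out frames, background excluded.

The same pipeline is available from the shell:

```
tanet generate --mode plax --subjects 10 --frames 3 --size 128 --seed 321 --out data/
tanet train --config examples/tiny.yaml --stage all --out run/
tanet segment --checkpoint run/tanet.npz --images data/ --gt data/ --out seg/
tanet evaluate --pred seg/ --gt data/ --regions 5 --out eval/
```

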