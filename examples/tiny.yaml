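# Desk-scale training configuration for the phantom pipeline.
# Generate the dataset first:
#   tanet generate --mode plax --subjects 10 --frames 3 --size 128 --seed 321 --out data/
data:
  dir: data/
model:
  resolution: 128
  crop_size: 64
  seed: 0
train:
  batch_size: 8
  finetune_batch_size: 2
  lr: 1.0e-3
  coarse_epochs: 200
  coarse_max_steps: 200
  loc_epochs: 80
  finetune_epochs: 30
  seed: 0
  augment: false
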