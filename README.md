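# sauseg

A 3D split-attention nested-U-Net toolkit for multi-label volumetric
segmentation, built to run entirely on CPU with NumPy. It covers the full
pipeline: NIfTI I/O and label schemas, synthetic T1-like phantom generation,
landmark-based intensity standardization, training-time augmentation, a
split-attention encoder/decoder network with dense skip pathways, two-step
(pre-train on auxiliary labels, fine-tune on manual labels) patch training,
patch-fusion whole-volume inference, and accuracy/reliability metrics
(Dice, ASSD, structure volumes, intra-session and total coefficients of
variation).

The network is implemented on a small reverse-mode autodiff engine over
NumPy arrays (`sauseg.network.autograd`) — no deep-learning framework is
required. Convolutions are evaluated as batched GEMMs over im2col blocks;
gradients are verified against finite differences in the test suite.

## Layout

- `sauseg.io_schema` — `Volume3D`, `LabelVolume`, `LabelSchema`, NIfTI read/write,
  the default 34-class whole-brain schema, run configuration.
- `sauseg.phantom` — deterministic nested-ellipsoid phantoms, corrupted
  "auxiliary" label maps, test–retest pairs, multi-center scan sets.
- `sauseg.preprocess` — pluggable rigid-registration contract (identity /
  known-transform / custom backends), zero padding, Nyul-style histogram
  landmark standardization.
- `sauseg.augment` — Gaussian noise, polynomial bias field, scale+rotation
  affine, elastic deformation (7³ control grid); one displacement field is
  shared between image and labels.
- `sauseg.network` — EvoNorm-S0 conv units, split-attention (cardinality K=2,
  radix R=2, G=K·R=4 feature groups) residual blocks, nested skip pathways,
  softmax classifier head.
- `sauseg.training` — uniform/balanced patch sampling, cross-entropy,
  AdamW+AMSGrad, two-step pre-train/fine-tune (learning rates 1e-3 / 1e-4,
  batch size 4; reference patch size 96³).
- `sauseg.inference` — covering patch plans (grid or random-with-repair,
  default 128 patches, 12³ overlap), OR logical label fusion, back-registration
  to native space.
- `sauseg.metrics` — Dice, 6-connected boundary ASSD (mm), volumes in cc,
  CVs_avg / CVt reliability statistics, per-structure report tables.

## CLI

```bash
sauseg phantom --out work/phantom --shape 64 --seed 1
sauseg preprocess --in t1.nii.gz --out t1_std.nii.gz --pad 24
sauseg train --stage pretrain --config train.yaml --out work/run1
sauseg train --stage finetune --config train.yaml --init work/run1/ckpt_final.npz --out work/run2
sauseg segment --ckpt work/run2/ckpt_final.npz --in t1.nii.gz --out seg.nii.gz \
    --schema schema.tsv --patch 96 --overlap 12 --pad 24
sauseg evaluate --pred seg.nii.gz --truth gt.nii.gz --out report.csv
```

The train config is YAML with `data` (image/labels path pairs), optional
`network`, `augment` and optimizer settings; see `sauseg.cli` for keys.

## Reference vs desk configuration

The reference configuration (4 pyramid levels, 32 base channels, 96³ patches,
300k iterations) matches the published training setup but is far beyond CPU
budgets; `NetworkConfig.desk()` / `TrainConfig.desk()` provide a scaled-down
preset (3 levels, 8 base channels, ≤2000 iterations) that trains on synthetic
phantoms in minutes and is used throughout the tests.
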