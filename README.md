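# perfmap

CT-perfusion (CTP) analysis toolkit for acute-stroke imaging research:

- **phantom** — a digital perfusion phantom that renders 4-D CTP stacks
  (Hounsfield units over time) from known per-voxel perfusion parameters:
  brain, artery, ischemic core and penumbra regions, a gamma-variate bolus,
  optional noise, anatomical texture, skull, rigid inter-frame motion and
  smooth bolus-arrival delay fields. Every downstream stage is testable
  against its known ground truth, with no data downloads.
- **preprocess** — rigid motion correction of all frames to the first frame
  (coarse-to-fine stochastic-gradient SSD; 8x down-sampling then full
  resolution, 2,000/8,000 samples, 300 iterations per level) and a 3-D
  bilateral filter guided by the temporal-mean volume (spatial sd 3 mm,
  range sd 20 HU).
- **nlr** — the ground-truth engine: voxel-wise non-linear regression with a
  box-shaped impulse response (height CBF, width MTT, position = delay/TTP),
  minimized by a downhill simplex (300 iterations, init CBF 60 mL/100 g/min,
  MTT 5 s, delay 3.5 s), plus automatic AIF/VOF selection from a 100-voxel
  sample. CBV follows from the central volume principle. A numba-compiled
  kernel fits whole volumes in seconds; scipy's Nelder-Mead is kept as the
  scalar reference path.
- **unet** — a U-Net-style regressor that predicts one normalized perfusion
  map (CBV, CBF or TTP) directly from the registered, filtered stack, with
  no AIF input. Modifications mirror the perfusion-regression variant: 2x2
  convolutions, average pooling, 2x2 up-convolutions, 1x1 head; time frames
  enter as input channels. Training is two-stage (sub-sampled pre-training,
  full-resolution fine-tuning) with Adam (lr 1e-5, batch 8) under MSE loss,
  and threefold subject-wise cross-validation. Implemented in pure numpy
  with manual backprop — no GPU or DL framework needed at desk scale.
- **evaluation** — normalized-map MSE/PSNR, deterministic threshold-surrogate
  segmentation of ischemic core (CBV) and total hypoperfused territory
  (CBF/TTP, penumbra = mismatch), Dice coefficients, lesion volumes,
  Pearson correlation, Bland-Altman limits, coefficient of repeatability
  (1.96 x sd of paired differences), ICC(1,k) and the Friedman test.
- **pipeline / cli** — a fully seeded end-to-end driver producing
  cross-validation MSE tables, DSC/volume agreement tables and Bland-Altman
  plots from a single config + seed.

## Tests

```bash
python -m pytest tests/
```

The suite includes brute-force oracles (exhaustive bilateral filter,
trapezoid-rule convolution, grid-search deconvolution, finite-difference
gradients, hand-computed agreement statistics) and a `tests/test_acceptance.py`
that re-runs the scaled-down replication end to end; the full suite takes
roughly 20 minutes on one CPU, of which the acceptance replication is the
bulk.

## CLI

```bash
perfmap phantom --spec spec.yaml --out data/ --seed 0   # synthetic dataset
perfmap preprocess data/stack.nii.gz --out filtered.nii.gz
perfmap nlr filtered.nii.gz --out maps/                 # CBV/CBF/MTT/TTP
perfmap cv --out run/ --seed 0                          # threefold CV tables
perfmap train --maps cbv --out run/                     # single map model
perfmap predict filtered.nii.gz --model m.npz --out map.nii.gz
perfmap eval --pred maps_a/ --gt maps_b/ --out report/
perfmap run --out run/ --seed 0                         # full replication
```

All commands accept YAML configs; every run writes a frozen copy of its
resolved configuration, and reruns with the same seed are bit-identical.

## Real data

The public UniToBrain dataset (Zenodo doi: 10.5281/zenodo.481760) can be
loaded with `perfmap.pipeline.load_unitobrain(path)` after a manual
download; it is optional and never required by the tests — the synthetic
phantom module covers the whole pipeline.
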