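# hippovaso

Hippocampus-tailored laminar VASO fMRI analysis, driven by a synthetic
hippocampal phantom so that every stage is verifiable by parameter recovery
without any data download.

The package implements:

- **phantom** — a folded C-shaped ribbon with subfield bands
  (Sub/CA1/CA2/CA3/DG-CA4), an SRLM lamina beyond the inner surface, WM/CSF
  compartments and bright-vessel voxels; a randomized block task design
  (18 s trials, 12 s inter-trial intervals, 15 trials per condition); and a
  forward simulator producing interleaved blood-nulled / not-nulled volumes
  every 3000 ms (308 time points per run by default) with laminar CBV
  responses, surface-weighted BOLD responses, inversion-power-dependent
  inflow, slow drift and Gaussian noise. Includes `inversion_efficiency`
  and the steady-state blood `nulling_time` solver.
- **preprocess** — demultiplexing by contrast tag, steady-state/noise-volume
  trimming, edge-slice cropping, and BOLD-contamination correction by
  pairwise dynamic division (`vaso[k] = nulled[k] / notnulled[k]`).
- **qc** — tSNR maps (mean / SD after optional linear detrend) and
  inflow-vs-RF-power diagnostic curves.
- **nuisance** — Gaussian mask erosion (σ = 0.8 mm, threshold 0.9) and
  aCompCor: 5 principal components each from WM and CSF, 16 nuisance
  columns together with 6 motion regressors.
- **glm** — canonical double-gamma HRF, design matrices with a DCT
  high-pass basis (128 s cutoff), voxel-wise OLS, memory−math contrast
  (sign-flipped for VASO), 18-connectivity cluster-extent thresholding
  (k = 20), subfield cluster means, and a Friedman rank test.
- **laminar** — 20 equidistant depth bins spanning corresponding
  inner/outer surface vertices plus 10 SRLM-extension bins (Sub/CA1/CA2
  only; DG/CA4 excluded), mid-thickness anchor validation, trilinear
  sampling, math-baseline z-transform, and depth-wise GLM contrasts.
- **pipeline / cli** — a YAML-configurable end-to-end runner with a JSON
  manifest; deterministic given the seed.

## CLI

```sh
hippovaso simulate  --out-dir sim --grid 48 --seed 0
hippovaso preprocess --in sim/interleaved.nii --tags sim/interleaved.json \
    --head 2 --tail 2 --out-dir pre
hippovaso qc tsnr   --in pre/vaso.nii --meta pre/vaso.json \
    --mask sim/labels.nii --out tsnr.nii
hippovaso qc inflow --out inflow.tsv
hippovaso run       --out-dir out --seed 0         # full pipeline
```

`hippovaso run` writes NIfTI volumes, GIFTI surfaces, BIDS-style TSVs and a
`manifest.json` capturing every decision value (trim counts, erosion σ,
component counts, cutoff, cluster extent, bin convention).

## Conventions

- Volumes are NIfTI-1; world coordinates come from the affine; surfaces are
  GIFTI meshes in world mm with index-wise vertex correspondence.
- Depth-bin indices are 1-based: bin 1 = deepest SRLM-extension point,
  bin 11 = inner surface, bin 30 = outer surface; spacing = thickness / 19.
- VASO activation is reported with the sign flipped (a CBV increase lowers
  the blood-nulled signal); the flip is recorded in provenance.
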