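# dimani

Direct anatomical contrast of thalamic subnuclei from diffusion MRI.

Conventional T1/T2 images are nearly flat inside the thalamus, which makes
direct targeting of individual subnuclei (Vim for essential-tremor DBS, the
anterior nucleus for epilepsy, CM for Tourette's, ...) difficult: surgical
teams fall back on atlases that ignore inter-individual anatomy. A
surprisingly simple diffusion-MRI contrast fixes much of this: **average
the diffusion-weighted volumes voxelwise**, keeping only volumes with
b > 100 s/mm². In the resulting trace-like image

S̄(x) = (1/N) Σᵢ S(x, bᵢ, gᵢ),  S(x, b, g) = S₀(x) · exp(−b gᵀ D(x) g),

voxels where water diffuses freely and isotropically (CSF, large isotropic
nuclei) are dark, and voxels with restricted or anisotropic diffusion
(myelinated laminae, white-matter tracts) are bright — by Jensen's
inequality the spherical mean of exp(−b gᵀDg) strictly increases with
anisotropy at fixed mean diffusivity. Averaging over a q-space-uniform
direction set makes the contrast insensitive to the particular gradient
table, and averaging N volumes suppresses noise as 1/√N, so the same
anatomy appears across scanners, field strengths and direction counts.

This package provides:

- **`dimani.contrast`** — the averaged-DWI contrast with five aggregation
  variants (mean, median, centromean = trimmed mean of the middle 50%,
  sum, l2norm), b-value/shell selection, per-region statistics, and a 3D
  contrast-limited adaptive histogram equalization (CLAHE) with foreground
  masking for display.
- **`dimani.phantom`** — labeled diffusion-tensor phantoms with Rician
  noise, electrostatically optimized uniform gradient schemes, and greedy
  direction subsampling; includes a schematic thalamus preset with an
  alternating-anisotropy "zebra" laminar stack.
- **`dimani.repro`** — per-nucleus Dice coefficients across sessions and
  raters (all-pairs reports), plus a seeded boundary perturber for
  synthetic rater variability.
- **`dimani.dwi_io`** — NIfTI-1 + FSL `bvals`/`bvecs` I/O with gradient
  validation, and multilabel segmentation I/O.
- **`dimani` CLI** — `compute`, `b0mean`, `phantom`, `dice`, `subsample`
  subcommands with YAML configs and JSON provenance sidecars.

## Worked example

Build the schematic thalamus phantom noise-free, compute the mean
diffusion-weighted contrast, and summarize it per region:

```python
from dimani import preset_thalamus, build_phantom, compute_contrast, region_stats

spec = preset_thalamus(seed=7, noise_sigma=0.0)
ds, lm = build_phantom(spec)                      # 48 dirs, b=1500, 4 b0s
img = compute_contrast(ds, method="mean", b_threshold=100)
print(region_stats(img, lm).to_string(index=False))
```

```
 label name      mean           sd     n
     1  CSF  1.110900 2.220446e-16 94389
     2  VLa 40.337130 7.105427e-15  4480
     3 VLPv 35.203156 0.000000e+00  4480
     4   MD 34.993775 7.105427e-15  1039
     5   CM 35.876838 0.000000e+00   123
     6   Hb 34.993775 0.000000e+00    33
     7   IC 40.328427 0.000000e+00  6048
```

With S₀ = 100, the CSF-like surround (MD 3.0·10⁻³ mm²/s) collapses to
100·e^(−1500·0.003) ≈ 1.11 — dark. The isotropic gray-like MD nucleus
(MD 0.7·10⁻³) sits at 100·e^(−1.05) ≈ 35.0, and the high-anisotropy
laminae (VLa, FA 0.8) and internal-capsule-like region rise to ≈ 40.3 at
the *same* mean diffusivity — the Jensen gap that makes the laminar
"zebra" banding (VLa vs VLPv: 40.3 vs 35.2) visible. At the default 2%
Rician noise the adjacent-lamina contrast is ≈ 18× the within-lamina SD.

The same pipeline from the shell:

```sh
dimani phantom --preset thalamus --seed 7 --out ph/
dimani compute --dwi ph/dwi.nii.gz --bval ph/bvals --bvec ph/bvecs \
       --method mean --equalize --out dimani.nii.gz
dimani dice --labels ph/labels.nii.gz --labels ph/labels.nii.gz \
       --names ph/names.json --out report.csv
```

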