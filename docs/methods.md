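# Methods

## The contrast

The core operation averages, voxelwise, the diffusion-weighted volumes of
a 4D dMRI acquisition. "Weighted" means strictly b > b_threshold with
b_threshold = 100 s/mm² by default, so nominal b0 volumes (including
slightly non-zero nominal values) are excluded; the b0 volumes get their
own companion average (`b0_mean`). On multi-shell data all weighted
volumes are pooled by default; an optional `shell` selector (|b − shell| ≤
tolerance, default 50 s/mm²) restricts to one shell, which is how
multi-shell archives are typically displayed.

Five aggregators are provided. For the per-voxel weighted series
s₁…s_n (sorted internally so results are bit-identical under any
permutation of the input volumes):

| method     | definition                                        |
|------------|---------------------------------------------------|
| mean       | Σ sᵢ / n                                          |
| median     | middle value; average of the two central for even n |
| centromean | mean after discarding the lowest and highest ⌊n/4⌋ values |
| sum        | Σ sᵢ                                              |
| l2norm     | √(Σ sᵢ²)                                          |

The centromean rule is a symmetric trimmed mean: "middle 50%" is
interpreted as dropping ⌊n/4⌋ from each end, which reproduces the exact
middle half when 4 | n and degrades gracefully otherwise.

Why the contrast works: under the single-tensor model
S = S₀ exp(−b gᵀDg), the average over a q-space-uniform direction set
approximates the spherical mean of the exponential. At fixed mean
diffusivity (trace/3) and S₀, that mean is minimized by the isotropic
tensor and strictly increases with anisotropy (Jensen's inequality applied
to the convex exponential). High-MD isotropic compartments (CSF) are
darkest; anisotropic, low-MD tissue is brightest. For purely isotropic
tissue the signal is identical for every direction, so the mean contrast
is exactly independent of the direction scheme — the mechanism behind
cross-protocol stability, which the test suite verifies to 1e-10 on the
phantom. More directions do not change the contrast, only the noise: the
SD of the mean across realizations scales as 1/√N (verified over
N ∈ {6, 12, 24, 48}).

## Adaptive equalization

For display, a 3D CLAHE: the volume is divided into tiles (default tile
size shape//8 per axis, minimum 4 voxels), a histogram of `n_bins` = 256
bins is clipped at `clip_limit` (default 0.01) × the tile's voxel count
with the excess redistributed uniformly, each tile gets the CDF of its
clipped histogram as its intensity mapping, and voxel outputs blend the 8
surrounding tile mappings trilinearly (clamped at the volume boundary).
Output is in [0, 1]. With one tile and clip_limit = 1 this reduces
exactly to global histogram equalization, which is the oracle used in the
tests; an independent CLAHE implementation (scikit-image's) serves as a
cross-check at rank-correlation level.

The implementation is in-package rather than delegated because
equalization here supports a foreground mask: only masked voxels enter the
histograms and the background stays exactly 0. Without masking, the large
dark background would dominate every tile histogram and compress the
tissue range. Masked-first equalization is the default order when a mask
is supplied. A constant-valued input has no rank information to spread;
it returns an all-zero image with a warning rather than an error.

## The phantom

The synthetic generator emulates a 7T-like single-shell acquisition: 48
unit directions at b = 1500 s/mm², 4 b0 volumes, 1.25 mm isotropic voxels
on a 48³ grid, S₀ = 100. Regions are geometric primitives (boxes,
ellipsoids, interleaved slab stacks) each carrying one symmetric
positive-definite tensor in mm²/s; overlaps resolve by list order (later
wins, recorded in provenance). The forward model is deliberately the
simplest that exercises every claim: monoexponential single-tensor, no
exchange, no kurtosis, no multi-compartment terms. Noise is Rician —
magnitude MRI: √((S+n₁)² + n₂²) with n₁, n₂ ~ N(0, σ²) — with σ
defaulting to 2% of S₀; at S = 0 this gives the Rayleigh floor with mean
σ√(π/2), which the tests check in closed form.

Tissue parameters are literature-typical placeholders, not fitted values:
CSF MD 3.0·10⁻³ mm²/s (FA 0), tissue MD 0.7·10⁻³ with FA 0 (MD-like
nucleus, Hb), 0.2/0.8 alternating (the zebra laminae, equal MD), 0.4
(CM-like), 0.8 (capsule-like). Prolate tensors with target (MD, FA) are
built by solving FA(r) = (1−r)/√(1+2r²) for the eigenvalue ratio r by
bracketed root-finding. All randomness flows through two named seeds
(direction_seed, noise_seed); builds are bit-deterministic.

### Gradient schemes

Directions minimize the antipodally symmetrized electrostatic energy
E = Σ_{i<j} (1/|vᵢ−vⱼ| + 1/|vᵢ+vⱼ|) by projected repulsion descent with
an adaptive step, from a seeded random start, until the relative energy
decrease of an accepted step falls below 1e-8 (or 10,000 iterations). For
n = 3 the optimum is an orthogonal triad, recovered to |dot| ≤ 1e-3; for
n = 50 the minimum folded pairwise angle (~19.4°) is an order of
magnitude above the median of random schemes (~1.9°).

Subsampling to m directions (the direction-count experiment) is greedy
construction on the same energy followed by two deterministic exchange
(local-search) refinements: first best-improvement swaps on the subset
energy, then swaps that strictly increase the subset's minimum folded
angle. Plain greedy insertion alone stops far from a local optimum for
small m; the exchange passes close that gap while keeping the procedure
deterministic (ties break on index). b0 volumes are never subsampled —
the CLI's `subsample` always carries them through and emits the matching
volume-index list so the 4D file can be sliced consistently.

## Dice reproducibility

Dice(A,B) = 2|A∩B|/(|A|+|B|) per label, over the union of labels present
in either map. Both-empty pairs count as 1.0 (agreement on absence),
one-empty as 0.0; the convention is recorded in report metadata. The
all-pairs report over k maps yields C(k,2) comparisons per label when
every map contains every label (28 for a k=8 test-retest design, 3 for a
three-rater design); pairs where neither map contains the label are
skipped rather than reported as trivial 1.0s. No registration or
resampling happens inside the module — inputs must already share a voxel
grid, and a mismatched affine raises rather than silently resampling,
because nearest-neighbour resampling would corrupt the overlap counts.

The synthetic rater perturber flips each 6-connected foreground boundary
voxel with a given probability to a uniformly chosen differing neighbor
label, decided simultaneously against the original map. Expected Dice
decreases monotonically with the flip rate, and structures with higher
surface-to-volume ratio (small nuclei) lose more Dice at equal rate —
the qualitative behavior seen when tiny structures are the least
reproducible to segment.

## Numerical and design choices

- Aggregation sorts the per-voxel series first, making every method
  bit-identical under volume permutation (at the cost of one sort).
- Images are written as 32-bit float NIfTI-1; label maps as int16/int32.
  Affines round-trip exactly.
- bvecs are accepted in FSL 3×N layout; an N×3 file is auto-detected by
  shape and accepted with a warning. Directions are used as given (no
  world-coordinate rotation): the contrast aggregates over directions and
  is insensitive to a global rotation of the scheme.
- Non-unit weighted bvecs are an error by default with an explicit
  renormalization flag; non-finite voxels likewise (zero-fill flag).
- Problem sizes in the test suite and acceptance script (48³ phantom, 200
  noise realizations, 100 random schemes, 1000 random subsets × 20
  parents) were chosen to give stable statistics while keeping a full run
  in the tens of seconds.

## What the phantom does and does not show

The phantom demonstrates mechanism, not anatomy: regions are
piecewise-constant, boundaries are hard (no partial volume), there is no
EPI distortion, motion, eddy-current artifact or bias field, and the
tensors are placeholders. Two consequences matter when reading test
results:

- Passing the region-ordering and zebra tests shows the physics of the
  contrast (Jensen ordering, noise averaging), not that any particular
  human nucleus will be visible at a given field strength.
- Within a piecewise-constant region, voxel ranks are set entirely by
  noise, so rank agreement between the mean and order-statistic
  aggregators (median, trimmed mean) is capped near the mean-vs-median
  correlation of i.i.d. samples (≈ 0.80–0.87 image-wide) at any noise
  level. On real anatomy, with continuous spatial variation everywhere,
  cross-method rank agreement is far higher. The measured Spearman values
  are reported as-is by the acceptance script (sum ≡ 1.0, l2norm ≈ 0.97,
  centromean ≈ 0.94, median ≈ 0.87 on the default phantom); treat the
  last two as a property of the phantom's flatness, not of the methods.
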