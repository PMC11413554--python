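# Methods

## Forward model and the RL update

The package models image formation as `MI = OI ∗ PSF + N`: the object
`OI` blurred by the instrument PSF, plus shot noise `N` whose counts are
Poisson-distributed with variance equal to the mean. Restoration uses the
Richardson-Lucy iteration

    EIₙ₊₁ = EIₙ × [ FSP ∗ ( MI / (PSF ∗ EIₙ) ) ]

where `FSP` is the PSF reversed along every axis. The initial estimate is
the measured image itself — the conventional RL choice, which also makes
`iterations = 0` an exact identity. There is no automatic stopping rule;
the iteration count is a user decision (typically 5–20 for fluorescence
stacks), trading restoration sharpness against noise-artifact build-up.

## Convolution engine

All convolutions are circular (periodic boundary), the natural boundary of
FFT convolution: the volume wraps onto itself rather than being padded
with arbitrary values, which avoids injecting unrepresentative edge
content. Kernels are centered at `floor(size/2)` per axis for odd *and*
even sizes, and the flip is a full index reversal; FFT path, direct
summation oracle and PSF flip all share this single convention, so a
centered delta kernel is exactly the identity element.

Arithmetic is 32-bit floating point with 64-bit accumulation for global
sums, matching the precision class of GPU deconvolution pipelines while
keeping conservation checks tight. The direct-summation oracle
(`direct_circular_convolve`) accumulates in float64 and exists only as an
independent cross-check of the FFT path at small sizes.

`inverse_filter` implements the one-shot Fourier division as a baseline.
Spectral magnitudes below `1e-6 × max|FFT(PSF)|` are raised to that floor
with phase preserved — enough to prevent division overflow, deliberately
not enough to suppress the noise amplification the baseline is meant to
exhibit.

## Numerical choices in the RL core

- **Division guard.** The re-blur denominator is floored at
  `epsilon = 1e-12 × max(MI)`. At float32 precision this never binds on
  voxels carrying signal, so flux conservation is unaffected at the 1e-4
  level asserted in the tests.
- **Negativity clamp.** Round-off can leave tiny negative values after the
  multiplicative update; they are clamped to zero at the end of each
  iteration.
- **PSF spectrum caching.** The PSF and flipped-PSF spectra are computed
  once per run (`FFTConvolver`), halving the FFT count of each iteration.
- **Flux conservation and PSF parity.** The identity
  `sum(EIₙ₊₁) = sum(MI)` holds exactly when the flipped-PSF convolution is
  the adjoint of the PSF convolution. With center `floor(size/2)` and full
  reversal this is the case for odd-sized PSFs; an even-sized PSF incurs a
  one-voxel offset between the pair, and conservation then holds only
  approximately. Realistic PSF models are odd-sized; the test suite uses
  odd sizes for conservation checks and documents this as a known
  limitation for even sizes.
- **Backends.** The `backend` selector accepts `auto | cpu`. `auto` is a
  fallback chain that resolves to the reference CPU path in this build; an
  accelerated FFT backend can be registered behind the same contract
  (bit-level agreement is not required of such a backend, but 1e-4
  relative agreement on volumes up to 64³ is).

## Valid-region calculus

A length-`w` convolution output voxel is "valid" when it depends only on
real data. Each convolution with a `w_PSF`-wide kernel removes
`w_PSF − 1` samples from each end's validity; an RL iteration performs two
convolutions, so the valid width obeys

    valid(w_data, w_PSF, n) = w_data − n · (2·w_PSF − 2)

A negative result means no voxel of the output is formally free of
boundary influence — e.g. `valid(512, 32, 10) = −108`. The rule is
verified against a brute-force oracle that embeds the data in a sea of
NaNs and counts the survivors of `2n` convolutions. In practice results
well beyond this limit are accepted because PSFs decay to near zero at
their borders, so the dependence on edge data fades with distance; the
calculus quantifies the formal price of chunking and of iteration count.

## Gaussian propagation closed form

For a point-like object, `MI = PSF`. If PSF and measured image are
centered Gaussians of variance `r²` and the estimate is a Gaussian of
variance `b²`, the RL ratio image is Gaussian with variance
`t = r²(r² + b²)/b²`, and one full update yields a Gaussian with

    variance  v = b²(r² + t) / (b² + r² + t)

whose amplitude is independent of the estimate's amplitude (it cancels
between the numerator estimate and the ratio's denominator). At
`b² = r² = 1` this gives `v = 3/4` exactly: the first iteration contracts
the relative variance to 75%. Iterating the recursion gives a strictly
decreasing positive sequence (75%, 61.2%, 52.4%, ...). The closed form is
derived in the continuous, infinite-domain limit; the discrete fine-grid
simulation (`simulate_gaussian_rl_1d`, step 0.01 on ±10) reproduces it to
well under 1% and is the authoritative cross-check in the tests.

## Block engine

The block path bounds peak memory by deconvolving padded sub-volumes
independently:

- **Pad rule.** Pad width per axis = `round(padding_fract × PSF_size)`
  (round-half-up), default `padding_fract = 1.2`. Padding is clipped at
  volume faces — face blocks are not extended beyond the data, so volume
  edges behave exactly as in the un-split computation.
- **Count selection.** Starting from one block, the axis with the largest
  padded extent is split further (ties broken in z, y, x order) until the
  largest padded block fits `max_block_voxels`. The rule is deterministic,
  and shrinking the budget never decreases the block count. If even
  single-voxel cores cannot fit, or a padded block cannot contain the PSF,
  the layout is rejected with an explanatory error.
- **Partition.** Cores tile the volume exactly; when an axis does not
  divide evenly the earliest blocks take the extra voxel (core widths
  differ by at most one). Split and merge order is z-major for
  reproducible float summation.
- **Merge.** A hard crop to cores — no feathering or weighted blending.
  Each output voxel is written exactly once. A single-block layout is
  bit-identical to the non-block path. Within each padded block the same
  circular boundary applies as in the non-block path, so block results
  differ from the un-split result only near core seams (within 2% away
  from seams in the 64³ acceptance check).

## Synthetic data

The generators emulate the inputs the method is designed for, seeded and
bit-reproducible:

- **Bead phantoms** (fluorescent beads on a grid): non-overlapping spheres
  at uniform-random integer centers; a voxel belongs to a bead iff its
  center lies within the radius, so total intensity is exactly
  `count × voxels_per_sphere × intensity`. Default test scene: 48³ volume,
  8 beads of radius 3, intensity 100.
- **Filament phantoms** (microtubule-like): seeded random-walk polylines
  of unit width and constant intensity.
- **PSFs**: sampled anisotropic Gaussians (default σ = (2, 1.5, 1.5)
  voxels on 9³–21³ grids — wider axially than laterally, as in real
  optics), and an astigmatic "hourglass" PSF whose lateral width grows
  linearly away from the waist with the elongation axis rotating 90°
  across focus. Slices of the hourglass carry equal energy, approximating
  defocus that spreads but does not absorb light.
- **Noise**: Poisson counting at `photon_scale` expected counts per
  intensity unit, then rescaled back, so `photon_scale` dials SNR without
  changing units. Restoration tests use `photon_scale = 1` with bead
  intensity 100 (peak SNR ≈ 10 after blurring).

What the phantoms do *not* emulate: real optical aberrations beyond
astigmatism, depth-dependent PSF variation, background autofluorescence,
detector read noise and sample motion. Passing tests therefore demonstrate
the correctness of the algorithmic machinery under the stated model, not
restoration quality on any particular instrument's data.

## Interfaces

Volumes are multi-page TIFF z-stacks, axis order (z, y, x), pages = z;
8/16-bit unsigned and 32-bit float input, 32-bit float output. MRC is not
supported in this build. The sklearn-style estimators
(`RichardsonLucyDeconvolver`, `InverseFilterDeconvolver`) are the primary
API and compose with sklearn pipelines; the module-level functions
(`rl_deconvolve`, `block_rl_deconvolve`, `inverse_filter`) expose the same
code paths. The CLI (`rldeconv deconv|phantom|validwidth`) is a thin layer
over the library: `deconv` output is bit-identical to the corresponding
library call. Progress reporting uses a `(completed_units, total_units)`
callback — per iteration in the non-block path, per block in the block
path — mirrored by INFO-level log lines.

## Problem sizes

Test and acceptance computations run at desk scale by design: convolution
oracles up to 16³ ⊛ 5³, conservation checks at 32³, block-versus-full
comparisons on a 64³ phantom at 10 iterations, and the Gaussian
simulation on a 2001-point 1-D grid. These sizes exercise every code path
(multi-block layouts, seam masking, noise) while completing in seconds.

## Known limitations

- Circular boundaries wrap content from opposite faces; objects touching
  a volume face acquire wrap-around ghosts, in both block and non-block
  paths.
- Even-sized PSFs break exact flux conservation (see above).
- No regularized RL variants (total-variation, damped) and no iteration
  auto-stopping.
- The Gaussian closed form assumes `MI = PSF` (point-like object) and
  shared centering; it is an oracle for quality control, not a general
  two-parameter propagation law.
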