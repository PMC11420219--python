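# Methods

## Forward model and geometry

Volumes are real 3D grids indexed `(z, y, x)` with the optical (beam) axis
along `z` and the tilt axis along `y`; projections are `(y, x)` images.
The simulator's projector computes, for each tilt angle α, the line
integral of the volume along rays rotated by α in the `(z, x)` plane
(trilinear interpolation, zero outside the grid). This is the CTF-free,
parallel-beam real-space equivalent of the Fourier-slice acquisition model;
the contrast transfer function is treated as identity and assumed to be
handled by external preprocessing. The discrete model is only approximate,
so slice-theorem consistency is tested with tolerances (relative L2 < 5% at
low frequencies) rather than exactly.

Noise is pixel-wise i.i.d. zero-mean Gaussian. Because no standard
definition exists for tilt-series SNR, the package fixes one and records it
in configs: `SNR = Var(clean projection stack, pooled) / Var(noise)`. This
pooled-variance convention makes, e.g., SNR 1/4 mean noise with four times
the pooled signal variance. Frame simulation emits `F` frames per tilt
with `F` times the per-tilt noise variance, so the frame average reproduces
the single-exposure SNR.

## FBP

Single-axis geometry factorizes over y, so reconstruction is stacked 2D
FBP: a 1D frequency filter along x of every projection row (ramp `|f|`, or
the Hamming-windowed ramp `|f|·(0.54 + 0.46 cos(πf/f_Nyq))`), zero-padded
2× against wrap-around, then linear-interpolation back-projection with
uniform angular weights. The output is scaled by the mean angular spacing
in radians; on a dense full-range scheme this restores the phantom's
intensity scale to within a few percent (verified by test), which keeps the
two half-reconstructions and any full-series FBP on one scale. The
classical π/(2K) constant sometimes quoted for ramp-filtered FBP
corresponds to a different filter normalization and halves the scale under
this one.

## Wedge masks

With the tilt axis along y, a tilt range `|α| ≤ α_max` measures the Fourier
point `k` iff `|k_z| ≤ tan(α_max)·|k_x|` (independent of `k_y`); the
complement is the missing wedge. Masks are binary, fftshift-centered, and
point-symmetric, so masked real volumes stay real. Boundary points
(equality) count as measured. Two consequences of the inequality are worth
noting: on the full cubic grid the 60° wedge occupies `1/(2·tan 60°) ≈
0.289` of the voxels, while the familiar angular fraction 1/3 holds inside
the Nyquist ball (every in-plane disc contains a 120°/360° wedge) — tests
measure there; and the beam-axis plane `k_x = 0` is unmeasured for every
`α_max < 90°`, so the α → 90° limit leaves that single plane masked rather
than none.

Rotated masks are evaluated analytically at `R_φ⁻¹k` instead of resampling
a binary grid, avoiding interpolation of a discontinuous field. Rotations
are intrinsic z–y–z Euler angles (radians internally, degrees at user
interfaces); Haar-uniform sampling delegates to
`scipy.spatial.transform.Rotation.random`.

## Sub-tomograms and normalization

The sliding-window planner clamps the last window of each axis to the
boundary, guaranteeing full coverage; reassembly averages overlapping
windows uniformly, making extract → reassemble exactly the identity (a
tested invariant). Content masking (Gaussian-smoothed deviation from the
median, percentile threshold) with a minimum-fill fraction can restrict
fitting to windows containing sample.

Model inputs are standardized per cube to zero mean and unit variance using
the `v0` cube's statistics, with the inverse applied to model outputs
before reassembly. This stand-in normalization is a package design choice:
it keeps the two half-reconstructions scale-consistent through refinement
and makes the `mean` rotation fill equal ≈ 0 in model space.

## Fitting loop

Defaults follow the reference regime: Adam with a constant learning rate
4·10⁻⁴, no dropout (a 0.3 option exists for the heavier regularization
regime of related tools), one full pass over the pairs per epoch,
mini-batch 8 (desk preset 4), fresh Haar rotations every epoch, and a
wedge update of the `v0` cubes after each optimizer pass (measured Fourier
content preserved exactly; only the wedge complement is replaced by the
model prediction). The loss uses a unitary FFT so Parseval holds; the
weight-2 factor sits inside the squared norm, i.e. the inpainting term
carries 4× weight. Epochs are fixed by config (no automatic stopping); an
optional held-out fraction of pairs records a validation loss per epoch.
One seed fans out (via independent child generators) to initialization,
rotation sampling, and batch shuffling, making runs bit-reproducible.

Refinement always uses the original, never wedge-updated cubes: `fit`
operates on internal standardized copies and leaves the caller's pairs
untouched (tested by snapshot comparison).

## Network

The U-Net is built from a small NumPy layer library written for this
package: volumetric convolutions as shift-and-GEMM (one BLAS matmul per
kernel offset in a channels-last layout, ~25–30 GFLOP/s on one CPU core),
kernel-2 stride-2 transposed convolutions, 2³ max pooling, leaky ReLU
(slope 0.1), dropout, and Adam; backward passes are hand-written and
verified against central finite differences in float64 (relative error
< 1e-5).

The frozen full-size layout — three 3×3×3 convolutions per encoder/decoder
stage, channels 64/128/256 with a two-convolution 512-channel bottleneck,
transposed-conv upsampling with skip concatenation, a two-convolution
64-channel refinement head and a 1×1×1 output projection, biases, no
normalization layers — totals 27,260,865 trainable parameters (27.3 M).
Normalization-free blocks keep the layout simple and were sufficient for
stable fitting at desk scale. The desk preset (16 channels, two levels,
two convolutions per stage, no head; ~0.34 M parameters) is the package's
problem-size choice for tests and CPU runs.

## Desk-scale study and what it shows

The pinned end-to-end study uses a 64×96×96 phantom of random spheres, rods
and shells, ±60° tilts at 2°, SNR 1/4, even/odd split, ramp FBP, 32-voxel
cubes (3×3×2 grid, no overlap), the desk network, 30 epochs. Under these
conditions the refined tomogram correlates with ground truth at CC ≈ 0.69
versus ≈ 0.21 for FBP of the full noisy series, and wedge-restricted CC
rises from ≈ 0 (FBP) to ≈ 0.6 — the method denoises and fills the wedge.

The training loss, however, is bounded below by the noise energy of its
targets (the Noise2Noise floor). At SNR 1/4 the floor sits at roughly 60%
of the epoch-1 loss, so the loss can fall by at most ≈ 40% regardless of
model quality; the suite asserts the fitted model lands within 25% of the
oracle floor computed from the known clean phantom (in practice it lands
within a few percent). A
larger relative loss drop is only observable at higher SNR or from a
colder start — the loss curve is a convergence diagnostic here, not a
quality metric.

What passing these tests does **not** show about real data: the simulator
has no CTF, no per-tilt dose variation, no alignment errors, and
Gaussian rather than shot-dominated noise; phantoms are piecewise-smooth
geometric bodies, far simpler than cellular material. Real-data use relies
on upstream alignment and CTF correction, and wedge-filled content is
model prior, not measurement — compare against a data-consistent FBP
before interpreting fine structure.

## Numerical choices

- Wedge-boundary points measured; mask comparisons carry a 1e-9 slack for
  float-exact symmetry.
- Rotation fill during fitting: cube mean (≈ 0 after standardization);
  corner artefacts from rotation are accepted since the loss masks
  down-weight the affected regions.
- FSC: shell width one frequency voxel, shells indexed by rounded radius,
  corner voxels beyond Nyquist discarded; first-crossing rule for the
  0.143 resolution, Nyquist (2·voxel) when never crossing. Shells whose
  denominator energy is below 1e-12 of the volume's total spectrum energy
  are reported as undefined (NaN) — this flags zeroed wedges without
  breaking scale invariance.
- Degenerate inputs: constant volumes are an error for CC (undefined) and
  an empty-mask warning for content masking; per-cube std of 0 falls back
  to 1 in standardization.
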