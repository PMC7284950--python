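# Methods

This note documents the models and algorithms implemented in `ctrecon`, the
parameters that matter, the numerical choices made where the design was
open, and what the synthetic phantoms do and do not establish about real CT
data.

## Motion-blur degradation model

Uniform linear patient motion during a CT exposure degrades the image as

    I_b = P * I_c + N

where `P` is a line-shaped point spread function (PSF), `*` is 2D
convolution and `N` an optional noise term.  The PSF is parameterized by

* **angle** (degrees counter-clockwise from horizontal; the kernel depends
  on it only modulo 180°), and
* **amplitude** (blur length in pixels; amplitude 1 is the identity).

The kernel is rasterized by symmetric sub-pixel coverage weighting: a pixel
whose center lies within half a pixel (perpendicular distance) of the
motion segment receives weight proportional to the chord length the segment
covers, clipped to the segment's half-length `amplitude/2`; the kernel is
then normalized to unit mass.  Axis-aligned angles produce exactly uniform
`1xL` kernels; oblique angles are an approximation to anti-aliased line
rendering and are documented as such.  Convolution uses border-replicate
padding by default (preserves constant images, no dark frame on CT);
zero padding is available for strict linear-convolution semantics.  Noise
defaults to none — the additive-Gaussian option exists for experimentation
and carries no fidelity claim.  Values are clipped to the representable
range after noise.

The standard evaluation grids sweep angles 0°/30°/60°/90° at amplitude 15
and amplitudes 5/15/20/25 at angle 45°.

## Restoration metrics

* **Shannon entropy** over `N` equal-width histogram bins spanning
  `[0, 2^n - 1]` (default `N = 256`, exposed because CT exports may be 8- or
  12/16-bit): `E = -sum p_i log2 p_i`, `p_i = Num_i / (W*H)`, zero-count
  bins contribute nothing.
* **Entropy ratio** `E_r = E(test) / E(clear)`.  For CT-like piecewise-
  constant images, blurring creates new intermediate gray values and raises
  the entropy, so `E_r > 1` for degraded images and approaches 1 from above
  as restoration improves.  This direction holds for *structured* images;
  for dense random textures blurring can lower entropy (averaging narrows
  the histogram), which is why the test fixtures are piecewise-constant
  phantoms.  The angle trend (ratio growing as the blur rotates from 0° to
  90°) additionally requires an anisotropic object; the trend fixture is an
  x-elongated ellipsoid, where blur across the short axis creates the most
  new partial-intensity area.
* **MSE / PSNR**: `PSNR = 10 log10((2^n - 1)^2 / MSE)` in dB; identical
  images report an infinite-PSNR sentinel rather than raising.
* **Reconstruction accuracy** of a binary mask against a reference:
  primary value `|recon ∩ ref| / |ref|` (the fraction of the reference
  recovered), with the Jaccard index `|∩| / |∪|` reported alongside since
  the primary metric alone does not penalize over-segmentation.

## Pre-segmentation

Two deterministic stages precede reconstruction:

1. **Seeded region growing**: FIFO flood fill from user seeds accepting a
   voxel when `|value - running region mean| <= tolerance` under 6- (default)
   or 26-connectivity.  The adaptive running mean is stabler on CT than a
   fixed seed value; this is a package choice, not a requirement of the
   method.  Defaults: tolerance in intensity units chosen per volume (the
   CLI default 20 HU-like units suits soft-tissue contrast).
2. **Histogram refinement**: the organ's gray range is estimated as the
   [1st, 99th] percentiles of intensities inside the rough mask; voxels
   outside the range are dropped and the largest 6-connected component is
   kept.  The output is always a subset of the rough mask.

Full-3D growing is the default (the reconstruction consumes a volume);
per-slice seeding is expressed through the same seed list.

## Golden-section Marching Cubes

Classic Marching Cubes classifies each cube cell of the voxel lattice by an
8-bit corner code (a corner is *inside* when its value `>=` the isovalue —
ties are inside, fixed and documented) and reads the triangulation from the
standard 256-entry table.  The table transcription is validated at import:
every referenced edge must be an active edge of its configuration and every
active edge must be used, which catches transcription errors.

Instead of interpolating the crossing along each active edge from the two
corner scalars, the equivalent point is placed at the fixed parametric
fraction g = (sqrt(5) - 1)/2 ≈ 0.6180339887 from the edge's lower-indexed
endpoint (index coordinates scaled by voxel spacing).  Its normal is the
golden-fraction blend of the per-grid-point normal field at the two
endpoints, renormalized to unit length.  The per-grid-point field is the
central-difference gradient (one-sided at boundaries, divided by spacing),
sign-flipped so normals point from high values to low — outward for bright
objects.  The blend is written without renormalization in its original
formulation; renormalizing is required for the unit-length invariant of the
per-triangle normals and is flagged as a choice.  A blend that cancels to
zero falls back to the owning triangle's face normal (counted in stats).

**Per-edge caching.**  Every lattice edge has a canonical key (lower
endpoint + axis).  An interior edge is shared by four cubes; the cache
guarantees its point and normal are computed exactly once, and
instrumentation counters (`per_edge_computation_max`, which must be 1, and
`per_edge_request_max`, typically > 1) prove the four-to-one reduction at
run time.  Cell traversal is exhaustive: `(nx-1)(ny-1)(nz-1)` cells — for a
512x512 stack of 135 slices, 511·511·134 = 34,990,214 cells.

Degenerate triangles (repeated cached vertex or world-space area below
1e-12) are dropped and counted.  No ambiguous-case resolution is applied;
saddle configurations may open holes, which `mesh_topology` detects
(boundary-edge count, Euler characteristic) and reports rather than fixes.

**Consequences of fixed-fraction placement** (measured, documented):

* Vertex positions ignore the scalar values, so inverting the volume's
  contrast leaves every vertex in place and only flips the winding; the
  mesh is *not* equivariant under spatial mirroring, because mirroring
  relabels which endpoint of each edge is lower-indexed.
* The extracted surface is displaced sub-voxel from the true isosurface
  and jittered at a fixed fraction of the edge length independent of
  resolution.  On sphere phantoms the mesh area exceeds the analytic
  `4*pi*r^2` by a roughly resolution-independent ~+10% (measured +9.7%,
  +10.5%, +9.9% at 32³/64³/128³); the convergence test therefore uses a
  documented 15% tolerance and the acceptance script reports the bias
  itself.  Topology is unaffected: sphere meshes are closed with Euler
  characteristic 2.

**Isosurface direction smoothing.**  Each triangle's unit normal is
replaced by the renormalized mean of its own and its neighbors' *original*
normals — a single simultaneous (Jacobi) pass over the whole mesh, which is
order-independent and deterministic.  The neighborhood is vertex-sharing by
default ("edge" available via config): vertex-sharing maximizes the
smoothing support.  Pass count defaults to 1; more passes smooth more at
the cost of rounding genuine creases.  A zero mean (exactly opposing
neighborhood) keeps the original normal and is counted.  Vertex positions
are never moved — this is normal-field smoothing, not Laplacian vertex
smoothing.  On phantoms it reduces the mean adjacent-normal angular
deviation (the "squamous" scale artifact) and brings the normals closer to
the analytic radial field of a sphere, both asserted in tests and reported
by the acceptance script.

## GAN deblurring network

The restoration model is an image-to-image translation GAN supervised by
clear/blurred pairs:

* **Generator**: U-net with encoder C64-C128-C256-C512-C512-C512 and
  decoder DC512-DC512-DC512-DC256-DC128-DC64 plus a final stride-1 C3, all
  kernels 5x5, leaky-rectifier activations (slope 0.2) after every
  convolution/deconvolution and tanh on the output.  Skip connections
  concatenate encoder level ℓ with decoder level 6-ℓ.
* **Discriminator**: four stride-2 convolutions (64-128-256-512) and two
  fully-connected stages (512, 1) with a sigmoid probability output.
* **Objective**: `L = L_rec + λ L_adv` with λ = 0.01.  `L_rec` is the
  pixel-wise squared L2 distance, averaged per element so the magnitude is
  resolution-independent (a documented variant of the raw squared norm).
  The discriminator minimizes `-E[log D(f)] - E[log(1 - D(f_hat))]`
  (probabilities clamped to [1e-7, 1-1e-7]); the generator minimizes the
  non-saturating form `-E[log D(f_hat)]` for its adversarial term.

Unspecified details decided here: stride-2 down/upsampling, no
normalization layers, Adam (lr 2e-4, β1 0.5), inputs normalized to [-1, 1]
to match tanh, grayscale replicated to 3 channels to honor the 3-channel
output map and collapsed by the channel mean on output.  The discriminator
scores the clear image and the generator output independently
(unconditional on each input).

The layers are implemented directly on numpy — im2col convolutions backed
by BLAS matrix products, hand-derived reverse-mode gradients (verified
against finite differences), float32 throughout, fully deterministic given
a seed.  Training is smoke-scale by design: overfitting four 64x64 phantom
pairs for 200 single-pair iterations validates the architecture, gradient
flow and loss wiring (~6 CPU-minutes); it demonstrably raises restored
PSNR above blurred PSNR on the training pairs but says nothing about
generalization to unseen anatomy, which would require full-scale training
on real CT.

## Phantoms

Synthetic volumes with analytic ground truth stand in for CT data: spheres
and ellipsoids (closed-form area and outward normals), a two-blob fixture
(levels 100/200 on zero background) for segmentation, a "liver-like"
union of three overlapping ellipsoids with Gaussian-smoothed junctions as a
stress shape (no anatomical claim), linear ramps and constants for gradient
and degenerate-input checks.  Occupancy is anti-aliased by 3x3x3
supersampling, so boundary voxels carry partial-volume values and
mid-level isosurfacing recovers the analytic surface with sub-voxel error;
the occupancy integral matches the analytic object volume within 0.5%.
Phantom objects must sit at least one voxel inside the grid (watertightness
tests require interior surfaces).  Default study conditions: 64³ grids,
object/background levels 200/20, blur grids as above, 512x512 slice renders
available for full-CT-size checks.

What phantoms do not model: CT noise texture, beam hardening, anatomy's
intensity overlap between organs.  Passing tests establish algorithmic
correctness (placement, caching, topology, metric formulas, gradient flow),
not clinical segmentation or restoration quality.

## Problem sizes and tolerances

Tests run on 32³-64³ volumes (extraction ≈ 1 s at 64³), 50-triangle random
meshes for smoothing oracles (agreement to 1e-12), 64x64 images for the
GAN smoke run, and counting-only checks at the full 512x512x135 clinical
size.  Golden-section placement is asserted to 1e-12; kernel mass to
1e-12; unit normals to 1e-9; the sphere-area check uses the documented 15%
band around the analytic value discussed above.
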