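# Methods

`craniowrap` reconstructs a watertight, genus-0 craniofacial surface
from a motion-corrected isotropic T2w fetal-head MRI volume in three
stages — volumetric segmentation, distance-field shrink-wrapping, and
intensity-driven deformable refinement — followed by quantitative
evaluation and print-ready export. Because no clinical cohort ships
with the package, a parametric phantom generator provides the training
and evaluation domain; this note records the model, the parameters that
matter, and the design choices made where the published description
leaves the details open.

## The phantom generator

The generator emulates the features of a T2w single-shot TSE fetal
acquisition after slice-to-volume reconstruction (SVR), at 0.8 mm
isotropic resolution in a 120 mm field of view:

* **Geometry.** An ellipsoidal cranium (default semi-axes 35 x 30 x 42
  mm, a late second / third trimester head) with protruding implicit
  ellipsoid features: nose, lips, chin and two thin ear flaps (about
  2.4 mm thick, protruding 3–8 mm laterally). All features overlap the
  cranium, so the union is genus 0 in the continuum; the voxelization
  is verified (and, at coarse grids, repaired by a one-voxel closing)
  to have Euler number 1 as a solid — one component, no tunnels, no
  cavities — which the shrink-wrap stage requires.
* **Contrast.** Amniotic fluid brighter than soft tissue (fluid 1.0,
  tissue 0.45 in arbitrary units), the T2w polarity; configurable
  inversion. An optional maternal-tissue cap touching the scalp
  reproduces the main clinical failure mode: a tissue/tissue interface
  with no fluid gap.
* **Corruption.** A smooth multiplicative bias field (default +/-15 %,
  a low-frequency Gaussian random field) and additive Gaussian noise
  (sigma = 0.03). Gaussian rather than Rician: at the SNR of interest
  the difference is immaterial for the segmentation and refinement
  behaviour being tested.
* **Population.** The seed drives noise, bias *and* a mild (+/-8 %)
  anatomical size jitter, so consecutive seeds emulate a biometric
  range rather than one fixed head.

What the phantom does **not** emulate: SVR motion artefacts, gestational
age–specific biometry, cortical/skull substructure, or realistic ear
morphology. Consequently the segmentation task is easier than the
clinical one; passing the phantom metrics demonstrates that the
pipeline machinery is correct, not that clinical performance would
match.

The two region-restricted evaluation ingredients the tests use — the
degraded segmentation (`degrade_mask`: Gaussian blur + threshold, which
erases the thin ear flaps exactly as a low-resolution network does) and
the per-feature bounding boxes — come from the same generator.

## Segmentation network

A 3D attention U-Net with five encoder and four decoder resolution
levels, 3^3 convolutions, ReLU activations, dropout 0.5 inside each
double-conv block, instance normalisation, average-pool downsampling,
nearest-neighbour upsampling followed by a 3^3 convolution, additive
attention gates on the skip connections, and a 1^3 head mapping to two
channels (head, background). Input is a 128-voxel isotropic grid;
preprocessing is reorientation to the radiological (LPS) frame,
background cropping (threshold 0.1 x the 99.5th-percentile intensity,
4-voxel margin), quantile-based histogram matching (256 quantiles) to a
fixed synthetic reference volume, aspect-preserving resampling with
symmetric padding to 128^3, and rescaling to [0, 1]. Matching runs
*before* interpolation: for continuous clinical intensities the order
is immaterial, but for near-binary contrast the partial-volume boundary
voxels must be formed by mixing standardised intensities -- matching a
resampled two-level image collapses the whole mixture band onto a
single reference rank and erases sub-voxel boundary information. The
resample transform is recorded and inverted exactly; predictions are
mapped back to native space as probabilities (trilinear) before
thresholding, which keeps sub-voxel boundary information.

**The matching reference.** Quantile matching maps each image's
tissue/fluid class boundary onto the reference intensity at the same
rank, and the tissue fraction varies with head size. Against a
hard-gap bimodal reference, a smaller-than-reference head sends its
darkest fluid across the gap onto tissue intensities -- a spatially
coherent artefact (in the darkest bias-field region) that defeats any
learned intensity boundary and produced exactly such hallucinated
blobs in early experiments. The shipped reference is therefore a
small-head phantom wrapped in a dense mid-intensity partial-volume
shell: every plausible boundary rank falls inside the shell's flat
stretch of the quantile function, pinning the mapped class boundary to
the same intensity (measured drift < 0.01 over the +/- 8 % biometric
range). Training labels are soft (trilinear partial-volume) values in
network space, which removes nearest-neighbour label aliasing at the
boundary; predictions remain binary.

The implementation is pure numpy. Convolutions run as per-tap
contiguous matmuls over a zero-padded, flattened volume, blocked in
z-slabs sized to keep the accumulator cache-resident; gradients are
exact (verified against finite differences) and training is
deterministic for a fixed seed.

**Clinical-scale vs desk-scale.** The reference configuration is
channels (32, 64, 128, 256, 512), AdamW (default betas, weight decay
1e-5) with a linearly decaying learning rate initialised at 1e-3, and
100,000 batch-1 epochs over three semi-supervised stages. Those values
are retained as defaults of `NetworkConfig` / `TrainPlan`. The desk
configuration used for the phantom experiments divides the channel
widths by 16 — (2, 4, 8, 16, 32) — and runs 150 batch-1 epochs with the
same linear-decay schedule initialised at 2e-2: a decay spanning a few
hundred iterations needs a larger initial rate than one spanning 10^5,
and 2e-2 saturates the phantom task (held-out Dice plateaus) within the
budget. Dropout stays at the published 0.5.

Post-processing keeps the largest 6-connected component and fills
internal cavities. This step is pipeline glue: it guarantees the
genus-0 precondition of the surface stage regardless of stray
false-positive blobs.

The staged semi-supervised loop replaces the human "manual refinement"
of pseudo-labels with a pluggable refiner callable; the default is
morphological cleanup (closing + largest component + fill), and tests
use an oracle refiner to verify the bookkeeping (training set sizes
never decrease; held-out accuracy does not degrade).

## Surface extraction (shrink-wrap)

The signed Euclidean distance transform (SEDT) of the mask is defined
as *(distance to nearest foreground voxel centre) − (distance to
nearest background voxel centre)*: negative inside, positive outside,
zero level set on the boundary. Note this two-sided convention has
gradient magnitude approaching 2 at the boundary (both terms vary, in
opposite senses), so the deformation step moves each vertex along its
normal by `clip(d/2, ±step)` — the Newton step for this field; a
full-`d` step oscillates across the level set and never converges.

The initial surface is an icosphere centred on the mask centroid with
radius 1.1x the largest centroid-to-foreground distance. Each
iteration: normal-driven motion, light Taubin smoothing (lambda = 0.1,
mu = -0.105) to suppress voxelisation, and incremental remeshing.
Defaults at 0.8 mm voxels: step 0.4 mm, edge-length bounds
(0.8, 2.0) mm, convergence when the maximum distance-driven
displacement falls below 0.05 mm, at most 400 iterations (with a
warning and best-so-far result on non-convergence).

The remesher is the classical local loop: bisect edges above the upper
bound (longest first), collapse edges below the lower bound to their
midpoint under a link-condition guard (the one-ring intersection of the
endpoints must be exactly the two opposite vertices) plus normal-flip
and max-length guards, then tangential-only relaxation toward the
one-ring centroid. Both operations preserve the Euler characteristic,
so a genus-0 input stays genus 0 by construction; watertightness under
repeated remeshing is property-tested.

Marching cubes over the same mask serves as an independent oracle in
the tests (mean symmetric surface distance below one voxel); it is
deliberately not the implementation path, because the deformable
construction is what guarantees spherical topology and provides the
vertex dynamics the refinement stage continues.

## Surface refinement (four forces)

The update is `v += step * (w_dist F_dist + w_balloon F_balloon +
w_edge F_edge + w_smooth F_smooth)` with per-vertex displacement capped
at half the smallest incident edge length (fold-over guard), remeshing
every 10 iterations, and rollback-plus-step-halving if a remesh ever
breaks topology (three strikes aborts; never observed on phantoms).

* **Distance force** — unit vector along the normal toward the SEDT
  zero level set of the *baseline* segmentation, with magnitude ramping
  linearly from 0 at |d| <= leash/2 to 1 at |d| >= leash
  (leash 3 mm). Inside the leash the surface is free; beyond it the
  original segmentation wins.
* **Balloon force** — outward unit normal wherever the mean intensity
  sampled 0.5–1.5 voxels outward is closer to the tissue level than the
  fluid level; the two levels come from a k-means (k = 2) split of the
  image. This is the inflation that grows the surface into
  under-segmented ears, and the intensity gate is its stopping rule.
* **Edge force** — vector along the normal to the strongest intensity
  gradient with tissue-to-fluid polarity within +/-3 mm (15 samples),
  gradient floor 0.05; exact ties resolve to the nearest edge. The
  polarity requirement means a maternal-wall interface (tissue-tissue,
  wrong sign) does not qualify, which is the guard against the
  documented failure mode of snapping to adjacent maternal tissue.
* **Smoothing force** — the uniform umbrella operator (vector to the
  one-ring centroid). On a closed surface this has a small inward
  component proportional to curvature; with the default weight the
  resulting drift is below the convergence tolerance on
  well-conditioned meshes, and the distance/edge forces pin the surface
  elsewhere.

Weights `w_dist = 1.0, w_balloon = 0.3, w_edge = 1.0, w_smooth = 0.4`,
step 0.2 mm, at most 200 iterations. The published description names
the four roles but no formulas or weights; these defaults were chosen
so the stated qualitative properties hold on phantoms (ears recovered,
global volume change under 10 %, reduction to a distance-constrained
smoother when edge and balloon weights are zero) and live in one
auditable `RefineConfig`.

## Evaluation

Voxel overlap (Dice, recall, precision) is computed on masks voxelized
at the template grid by z-ray crossing parity with jittered ray
origins; the icosphere volume check ties the rasteriser to the analytic
ball volume within 2 %. Surface distances are symmetric, from
area-uniform samples to the exact nearest triangle (KD-tree candidate
pruning, Ericson point-triangle classification). Topology reports give
exact V/E/F, Euler characteristic, boundary-edge counts and
self-intersection counts from pruned Möller triangle-triangle tests.
The qualitative-scoring structures (overall quality 1–4, 23 superficial
landmarks, 11 deep structures) are data containers with JSON
round-tripping and per-landmark visibility aggregation; scoring itself
is observer work by design. The 23 default landmark names are the
standard facial anthropometric set (9 midline + 7 bilateral pairs);
the figure naming them in the source publication is an image, so any
23-name list may be substituted.

## Print export

`resample_mesh` refines toward a target resolution (0.1 mm for
printing) by uniform 4:1 subdivision — exact planar refinement, volume
preserved to machine precision — followed by the incremental remesher
to tidy outlier edges. The display stand (2 cm cylindrical stand on a
2 cm thick, 6 cm diameter base, 0.3 cm x 1 cm rectangular cut-out at
0.1 cm offset) is built as stacked constant-cross-section prisms from
2D polygon differences with ear-clipping triangulation (including a
bridged hole for the base-top annulus), which gives the published
dimensions exactly and watertightness by construction; no mesh-boolean
backend is involved. The cut-out's placement is not fully specified in
the source: here it is a radial slot, 3 mm wide, starting 1 mm from the
stand axis and cutting through the wall over the full stand height.

## Desk-scale experiment sizes

The segmentation acceptance experiment trains on 20 phantoms and
evaluates on 5 held-out phantoms (anatomy seeds 1–25) at 128^3 with the
(2, 4, 8, 16, 32) network and 150 epochs — the package's chosen desk
problem size. Geometry acceptance runs use a 1.6 mm / 75^3 phantom for
the ear-recovery and shape-preservation checks and 1 mm digital balls
for the distance-field oracles.

## Known limitations

* The numpy network trains batch-1 on CPU; it is a faithful desk-scale
  implementation of the architecture, not a performance-parity
  replacement for a GPU training stack.
* Self-intersection counting is exact but quadratic after pruning;
  it is intended for test-scale meshes (10^3–10^4 faces).
* The refinement assumes the fluid/tissue polarity is globally
  consistent; strong bias fields that invert local contrast would
  defeat the balloon gate.
* Oblique NIfTI geometries are rejected rather than resampled; SVR
  outputs are axis-aligned by construction.
* `surface_distance` uses KD-tree candidate triangles (k = 12 plus
  incident-triangle fallback); distances are exact for the candidate
  set, approximate only in adversarial meshes with highly non-uniform
  triangle sizes.
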