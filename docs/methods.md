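# Methods

This note documents the models, parameters and design choices behind
`srsplan`, and what the synthetic phantoms do and do not establish about
behaviour on real patients.

## Scope and overall model

The package implements a closed planning loop for linac-based SRS of a
solitary brain metastasis with coplanar fixed-field IMRT: predict a 3D dose
from anatomy, convert it into a deliverable plan by voxel-wise dose
mimicking, and verify the delivery dosimetrically.  All clinical-style
conventions follow routine SRS practice: a 30 Gy / 5-fraction prescription,
coverage defined as D95%(PGTV) at or above the prescription, high-dose
spillage (> 105% of the prescription) confined to the target or below 15%
of the target volume, and fall-off tracked by R50% and D2cm.

## Synthetic phantoms

Each case is a head-sized ellipsoid (default semi-axes 80 × 95 × 150 mm,
5 mm skull shell) sampled on a 96 × 96 × 32 grid at 2.5 mm (a full-scale
224 × 224 × 32 preset exists; the desk grid keeps every pipeline stage
tractable on one CPU core).  Tissue classes carry fixed HU (air −1000,
skull 700, brain 40, tumor 55) plus additive Gaussian noise (SD 20 HU),
which exercises the clipping/normalization path.  The nine OARs are
geometric primitives (spheres, capsules, a z-cylinder) at anatomically
plausible offsets; the PGTV is a sphere whose centre is rejection-sampled in
the posterior brain so that it never touches an OAR — deliberately mirroring
the single-lesion setting in which OARs are well separated from the target.
Masks are rasterized by the voxel-centre rule.

Small-group cases draw radii from 8–16 mm (≤ 20 cc), large-group from
18–24 mm (> 20 cc).  Every random draw flows from one integer seed, so a
spec reproduces its case bit-identically.

**Reference dose.**  The phantom's "clinical" dose is produced by the
package's own planning machinery: nine auto-configured beams, a fluence
optimization against an idealized objective — 110% of the prescription
inside the PGTV, exponential fall-off with an 8 mm length constant outside
(emulating the steep gradients clinical SRS plans exhibit; this choice puts
R50% of generated plans in the 3–5 range and D2cm near 10–19 Gy, the
magnitudes seen in clinical SRS cohorts) — followed by plan renormalization
so that D95%(PGTV) equals 1.02 × prescription.  The 2% margin is the usual
normalization headroom and absorbs the small coverage perturbation that MLC
sequencing introduces downstream.  Because the reference dose is made by
the same engine that later mimics it, the loop is self-consistent: tests can
demand exact clinical criteria without modelling engine mismatch.

**What this does not show.**  The phantoms have homogeneous
water-equivalent tissue, a single convex target, well-separated OARs and an
idealized dose objective.  Passing tests therefore demonstrate the internal
consistency and correctness of the pipeline's algorithms, not predictive
performance on heterogeneous clinical anatomy, multi-lesion cases, or
targets abutting OARs.

## Preprocessing

CT is clipped to [−200, 300] HU and mapped affinely to [−1, 1]
(x → (x − 50)/250).  Dose maps affinely from [0, 42] Gy to [−1, 1]; the
42 Gy ceiling is 1.4 × the prescription, chosen to cover observed hot spots
(D2% rarely exceeds ~37 Gy clinically; phantom references peak near 42 Gy —
doses above the ceiling are clipped with a logged warning).  Structures are
encoded into one integer-label channel with a fixed priority order (PGTV
highest, so it survives any overlap); a one-hot mode is available when
channel count is not a constraint.  The crop window is centred on the PGTV
centroid and padded with air HU / zero dose at volume borders; the stored
metadata (offset, geometries, normalization constants) makes the mapping
invertible, and `restore_dose` clamps the rare negative voxels of the affine
inverse to 0 Gy.

Grouping is by rasterized PGTV volume with an inclusive 20 cc threshold
(exactly 20.0 cc is "small").

## Dose engine

The engine is a deliberately simple, fully self-consistent analytic model —
not a transport calculation.  Each beamlet deposits

    d(v) = exp(−μ_eff · depth_v) · exp(−lat² / 2σ²) · (SAD / (SAD + depth_v))²

with μ_eff = 0.004 mm⁻¹ (effective attenuation of a 6 MV beam in water),
σ = 3 mm lateral penumbra, SAD = 1000 mm.  Depth is geometric depth below
the head surface along the beam axis (homogeneous water-equivalent medium;
HU heterogeneity is ignored by design).  Beamlet rays are parallel within a
field — at SAD = 1000 mm and SRS field sizes below ~60 mm the fan angle is
under 2°, and a parallel model keeps the deposition matrix exactly
reproducible by a brute-force loop.  Dose is deposited only inside the
external contour; matrix entries below 10⁻⁴ of their column maximum are
dropped (sparsity floor).

Beam auto-configuration: the primary direction joins the head-mask centroid
to the PGTV centroid, projected into the axial plane (the head centroid
stands in for a brain contour, which phantoms do not carry separately);
four more fields clockwise and four counter-clockwise at 20° give nine
uniformly spaced coplanar beams, isocentre at the PGTV centroid.  Gantry
angles follow IEC 61217 (0° from the anterior, clockwise seen from the
couch end) — a convention choice, stated because printed angles depend on
it.  The degenerate case (PGTV centroid = head centroid) falls back to
gantry 0 with a log message.  The beamlet lattice (5 mm beamlets) covers the
target projection with a 12 mm margin so the penumbra and near-target
gradients are controllable.

## Fluence optimization

Mimicking minimizes Σ_v w_v (D f − t)_v² over f ≥ 0 with importance weights
10 inside the PGTV, 3 in the 20 mm shell, 1 elsewhere — a generic
target-first weighting; the shell term is what shapes fall-off (R50, D2cm).
The solver is projected gradient with a Barzilai–Borwein step and monotone
backtracking (30 halvings max), stopping at a 10⁻⁶ relative objective
decrease or 500 iterations; the recorded objective history is
non-increasing by construction.  An optional smoothness penalty
λ‖∇f‖² (first differences on each beamlet lattice, λ scaled by the data
term's mean column curvature, default relative weight 0.1 in the pipeline,
0 for the bare operation) discourages jagged beamlet patterns.  This mirrors
the smoothing every clinical optimizer applies: without it the inverse
problem's null space produces fluence that no finite segment set can
deliver, and delivered-vs-planned agreement degrades.

## MLC sequencing

The deliverable model is a dual-layer orthogonal MLC idealized as binary
transmission (no leakage or tongue-and-groove): a segment's opening is the
intersection of one contiguous interval per leaf-pair row (layer 1) and one
per column (layer 2).  Sequencing quantizes each beam's fluence into 10
equal levels of its own maximum and threshold-decomposes the level sets.
Two deliverable shapings are generated per level — the row/column interval
closure (an outer approximation) and the largest cross-convex subset found
by iterated longest-run reduction (an inner approximation that never opens
extra beamlets) — and a non-negative least-squares refit of the continuous
segment weights against the unquantized fluence keeps whichever combination
reconstructs best (segment-weight optimization, the standard last step of
clinical sequencers; aperture shapes stay quantized, weights are
continuous).  A greedy repair loop then adds cross-convex apertures over the
largest under-dosed residual region until the reconstruction error is
within half a quantization step; this is what handles ring- and horn-shaped
level sets that no single dual-layer segment can form.  Typical plans use
10–25 segments per beam.  Where level sets are row- and column-convex the
reconstruction equals the quantized map exactly, so the half-step error
bound holds there by construction.

## Verification

3D verification is a gamma analysis between the optimized (planned) and the
sequenced-and-recomputed (delivered) dose on the patient grid.  2D
verification emulates a detector-array measurement: every field is
recomputed at gantry 0 onto a coronal plane at 50 mm water-equivalent depth
with 2.5 mm detector pitch, the per-field maps are composited, and the
planned and delivered composites are compared.  Gamma uses 3%/3 mm with
global normalization to the reference maximum, a 10% lower-dose threshold
(points below it are excluded from the denominator), a search radius of
3 × DTA, and trilinear up-sampling of the evaluated distribution for
sub-voxel distance-to-agreement (odd factors keep voxel centres on the fine
lattice; the plane uses factor 3, the volume factor 1).  These conventions
are stated because pass rates depend on them; all are configurable.

## Networks and training

Both predictors are resolution-preserving encoder–decoders with dual
3 × 3 × 3 convolutions + feature normalization + ReLU per level, 2 × 2 × 2
max-pooling, and filter counts doubling from `base_filters` to
`base_filters · 2^depth` at the bottleneck (full-scale preset: depth 4,
base 32 → 512).  The attention variant runs separate structure and CT
encoders; at the bottleneck every spatial position is a token and
multi-head attention (scores softmax(QKᵀ/√d), queries from the structure
stream, keys/values from CT, full-scale 8 heads × 64 dims) fuses the two,
after which a single decoder with skip connections from the structure
encoder predicts dose.  Design points that were genuinely open and are
therefore explicit knobs: the √d score scaling (on by default, for
numerical stability; a flag disables it), fusion placed at the bottleneck
only (token count is tractable there), skip connections taken from the
structure encoder, and the plain U-Net wired structures-only by default
(a flag adds the CT channel).

The layer stack, backpropagation and Adam are implemented in numpy as a
compact in-repo NN core — convolutions by im2col with the input gradient
expressed as a convolution with the channel-transposed flipped kernel;
gradients are verified against finite differences in the test suite.
Feature normalization computes per-channel statistics over the current
sample's spatial extent (mini-batches are processed sample-wise and their
gradients accumulated), with running estimates for inference.

Training: Kaiming initialization, MSE between predicted and reference dose,
Adam (lr 10⁻⁴, batch 2), up to 1000 epochs, lr ÷ 10 when the validation
loss plateaus (50-epoch patience), early stop after 100 epochs without
improvement, fixed 80/20 validation split drawn from the training seed.
Everything is seed-deterministic.  The convergence smoke tests use the
small preset (depth 2, base 8) on 32 × 32 × 16 crops with lr 10⁻³ — the
memorization regime that demonstrates the gradients and optimizer work;
generalization is out of scope at desk scale.

## Numerical conventions and degenerate inputs

* Dq% interpolates linearly between order statistics of the sorted voxel
  doses (equivalent to the linear-interpolation quantile at 1 − q/100);
  q = 100 is the structure minimum.
* CI is 0 when the prescription isodose volume is empty (logged); it lies
  in [0, 1] by Cauchy–Schwarz.
* D2cm defaults to the maximum dose on the 20 mm distance shell
  (width = one voxel pitch) outside the PGTV, by exact Euclidean distance
  transform with physical spacing; a `mode="beyond"` flag takes the maximum
  over the whole ≥ 20 mm exterior.  The shell raises a padding error when
  it falls outside the grid.
* Isodose Dice with both volumes empty is defined as 1 (logged convention).
* Gamma with an identically zero reference is an error, as is an empty
  above-threshold set.
* Empty masks raise; negative fluence or dose raise.

## Known limitations

Homogeneous analytic dose physics (no Monte Carlo, scatter, heterogeneity
or leakage modelling); coplanar beams only; single convex target per case;
a single prescription level; phantoms with schematic anatomy; desk-scale
network presets are far smaller than the full-scale configuration and are
validated for optimization sanity, not dosimetric prediction accuracy.
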