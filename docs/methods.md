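# Methods

This note documents the models implemented in `vasculomorph`, the defaults
and why they were chosen, the numerical conventions that matter for
reproducibility, and what the synthetic phantoms do and do not establish
about real data.

## Image geometry

All volumes are `Volume3D` objects: a 3D array plus voxel spacing and
origin in µm. Indexing is 0-based and voxel (i,j,k) is *centred* at
`origin + index·spacing`. Anisotropic spacing is carried through every
stage — distance maps, branch lengths, structuring elements and streamline
geometry all work in physical units — and nothing resamples implicitly.
NIfTI orientation is taken as stored-array order without reorientation to
canonical axes: all maps in a run live on one grid, so reorientation would
only add risk. TIFF stacks carry no spacing metadata and require an
explicit spacing at read time.

## Relaxometry

Per voxel the multi-echo magnitude signal is modelled as
`S(TE) = S0·exp(−R2*·TE)` with TE in ms and R2* in ms⁻¹. The fit is a
bounded nonlinear least squares: a closed-form log-linear estimate
(weighted to the voxel's positive echoes, since the log of a non-positive
sample is undefined) initializes a vectorized projected Gauss–Newton
refinement over all voxels simultaneously, with step halving on residual
increase and projection onto the box `0 < S0 < 2¹⁶`, `0 < R2* < 1 ms⁻¹`
(i.e. T2* > 1 ms for 16-bit data). Parameters finishing at a bound are
flagged in an `at_bound` map; voxels whose series is identically zero are
set to the upper R2* bound and flagged. Outside the fit mask R2* is exactly
zero — the background-masking convention the ΔR2* maps inherit.

The Gauss–Newton refinement is written in-house rather than looping a
generic optimizer per voxel because the two-parameter normal equations have
a closed-form solve, which makes the whole-volume fit vectorizable and
deterministic; on noiseless data the log-linear initializer is already the
exact solution, which the tests exploit as an oracle.

ΔR2* is the voxel-wise difference `R2*(post) − R2*(pre)` on the
intersection of the two fit masks. Negative values are retained: clipping
would bias ROI summaries. The same fitter serves R2 mapping of spin-echo
echo trains — the decay model is sequence-agnostic.

Background masking thresholds the first echo (highest SNR) with the
intermeans algorithm and keeps the largest 26-connected component. A
uniform nonzero volume is defined as all-foreground; an all-zero volume is
an error.

## Vessel segmentation

The tubeness response at scale σ (in voxel units of the finest axis) is
computed by Gaussian smoothing with σ²-normalized second derivatives, per
voxel eigendecomposition of the 3×3 Hessian, ordering by magnitude
|λ₁| ≤ |λ₂| ≤ |λ₃|, and the classical line measure √(λ₂λ₃) gated on
λ₂, λ₃ < 0, with dark vessels handled by negating the input first. Scale
normalization by σ² is required for the multi-scale maximum to be unbiased
across scales. Two numerical details:

* the input is centred (mean-subtracted) before filtering because truncated
  derivative kernels do not sum exactly to zero, so a constant offset would
  otherwise leak a spurious response — this also makes the response exactly
  invariant to intensity offsets;
* on anisotropic grids the per-axis Gaussian width is scaled so the
  *physical* smoothing scale is isotropic.

The response is homogeneous of degree 1 in the input, and the intermeans
threshold is equivariant under positive affine intensity maps, so the final
mask is invariant to affine rescaling of the input — a property test.

The intermeans (Ridler–Calvard) threshold iterates
`T ← (mean(x<T) + mean(x≥T))/2` from the global mean until the change is
below 1e-6 of the intensity range; `response ≥ T` is vessel. The 3D size
filter removes 26-connected foreground components and fills 6-connected
background holes strictly smaller than the minimum size (a 3-voxel
component survives a 3-voxel filter). Presets: σ = {0.8, 1.0, 1.2} with
minimum size 3 for µMRI-resolution data; σ = 1.5ⁿ, n = 0…5 with minimum
size 27 for µCT-resolution data.

The exact eigenvalue weighting of published vesselness variants differs
between implementations; the plain geometric mean √(λ₂λ₃) is used here as
the simplest member of that family, chosen deliberately and stated openly.

## Morphometry

Skeletonization uses topology-preserving parallel 3D thinning (Lee-style,
via scikit-image), which is deterministic. Branch decomposition classifies
skeleton voxels by 26-neighbour degree (1 = endpoint, ≥3 = junction),
merges adjacent junction voxels into one junction node (digital thinning
leaves small clusters of high-degree voxels at furcations), and walks the
degree-2 chains between nodes in fixed raster order. Spur branches of at
most 2 voxels beyond a junction are pruned by default (flag to disable):
they are thinning artifacts that would otherwise dominate branch-length
statistics. The paper-level choice of a spur threshold is not prescribed
anywhere; 2 voxels is the smallest value that removes single-voxel
artifacts without touching real branches.

Branch length is the polyline length of consecutive voxel centres in µm
(no spline smoothing — reproducible and matches the voxel-graph
definition). Radius is the exact Euclidean distance transform (anisotropic
sampling, distance from a foreground voxel centre to the nearest background
voxel centre) sampled along the skeleton; per branch the mean and maximum
are reported. An exact EDT is used rather than a chamfer approximation: it
is strictly more accurate and testable against closed forms. On digital
cylinders of radius 2–6 voxels the recovered mean radius is within
0.5 voxel of truth; the residual bias is the digitization/partial-volume
effect and is documented, not corrected.

Fractional vascular volume is the voxel-count ratio `|vessel ∧ roi|/|roi|`.
The coarse-grid variant divides the volume into integer blocks (the last
block absorbs the remainder) and reports per-cell occupancy; occupancies
recompose exactly to the global vessel voxel count, an integer identity
asserted in the tests.

## Zonal analysis

The spherical structuring element contains every voxel offset whose centre
lies within diameter/2 in *physical* µm (anisotropy-aware; 100 µm diameter
at 30 µm isotropic voxels gives the 19-voxel ball). Zones from a tumor ROI:
tumor = eroded ROI, transition = dilated − eroded, normal = brain outside
the dilation; all clipped to the brain mask and pairwise disjoint by
construction. Note that a ~100 µm element produces a ~100 µm-thick shell on
smooth ROIs; the element diameter is a free parameter for studies that
define a wider interface zone.

Each branch takes the zone of the majority of its skeleton voxels, ties
broken toward the more tumor-proximal zone (tumor > transition > normal),
which is conservative for tumor statistics. Zone pairs are compared with
two-sided Mann–Whitney rank-sum tests on branch lengths and radii — chosen
because branch-length distributions are right-skewed, making a rank test
safer than a t-test; no multiplicity correction is applied by default
(three pairwise tests; Holm step-down available behind a flag). Simulations
in the test suite confirm type-I error within [0.02, 0.08] at α = 0.05 on
null data and >95% power at p < 0.001 for a 2× length contrast with 100
branches per zone.

## DTI

With unit gradient directions gᵢ and b-value b, the log-linear system
`ln(Sᵢ/S0) = −b·gᵢᵀDgᵢ` is solved per voxel by least squares — an exact
6×6 solve for the six-direction scheme (b = 1700 s/mm², orientations
[1,1,0], [1,0,1], [0,1,1], [−1,1,0], [1,0,−1], [0,−1,1]). Signals are
floored at 1e-12 before the log. No weighted or iterative refinement: with
six directions the system is determined, and the unweighted solve composes
exactly with the simulator (round-trip identity to machine precision, the
test oracle). ADC is the eigenvalue mean and FA the standard normalized
eigenvalue deviation, defined as 0 for the zero tensor and clipped to
[0, 1]. Noise can make fitted tensors indefinite; negative eigenvalues are
clamped to zero for the scalar maps with a per-voxel flag rather than
propagated as NaNs.

FACT tracking is boundary-to-boundary: from a seed voxel centre the track
advances along the voxel's principal eigenvector to the exit face of the
current voxel (ties at corners resolved by fixed axis priority x > y > z),
bidirectionally, with the eigenvector sign flipped to keep a non-negative
dot product with the incoming direction. Termination: FA below threshold
(default 0.2), turning angle above threshold (default 40°), or the volume
edge. Tracking operates in physical µm, so anisotropic DTI grids are
handled as acquired without resampling.

## Registration and validation

The landmark warp is a 3D thin-plate spline with the biharmonic kernel
U(r) = ‖r‖ — the correct 3D kernel, not the 2D r²·log r form — plus an
affine tail, implemented on scipy's degree-1 polyharmonic RBF
interpolator. Zero regularization interpolates landmarks exactly and
affine-consistent landmarks reproduce the affine everywhere (zero bending
energy). At least 4 non-coplanar, non-duplicate landmark pairs are
required. Volume warping is backward mapping: the transform must map
target-grid coordinates to source coordinates; binary volumes use
nearest-neighbour interpolation only; out-of-field voxels are zero.
Coordinates that round-off epsilon outside the grid are snapped to the
boundary before interpolation.

Resampling supports integer block factors: mean-bin downsampling (on binary
input this yields partial-volume fractions and conserves total mass) and
repetition upsampling, making upsample-then-downsample an identity on
integer data.

The FV correlation reports Pearson r, the OLS line of one grid on the
other, and the 95% *mean-response* confidence band of that fit. Cells where
both FVs are zero are included by default (a flag excludes them — whether
empty cells belong in such correlations is a study-level choice, so both
behaviors are exposed). The ΔR2*-vs-FV comparison reports per-ROI medians,
1D histograms on shared edges and a joint 2D histogram; bin ranges default
to the robust 1st–99th percentiles (32 bins) and values are clipped into
that range so the 2D marginals recompose the 1D histograms exactly.

## Synthetic phantoms

The generator grows a vascular tree by random-walk branching: walkers step
with log-normal segment lengths, Gaussian-perturbed directions and
truncated-normal radii, all drawn from per-zone parameters, and branch
stochastically (more often in tortuous tissue). The domain contains a tumor
sphere with a transition shell symmetric about its surface; a segment's
zone is the zone of its midpoint. Growth continues until each zone reaches
its target fractional volume; each accepted segment credits its
Monte-Carlo-estimated *newly added* union volume to the zones its capsule
occupies (so overlaps, domain clipping and boundary straddling do not
starve or overfill a zone), and generation fails loudly if targets remain
unreachable after a bounded number of attempts. Realized per-zone FVs land
within 20% relative of target, verified by an independent Monte-Carlo
oracle.

Defaults emulate the qualitative tumor-versus-normal contrast reported for
rodent gliomas — tumor vessels shorter (mean 150 µm vs 300 µm), slightly
thinner, denser (target FV 0.08 vs 0.03) and more tortuous than normal
brain, with the transition shell intermediate, at imaging-realistic voxel
sizes (~30–60 µm) and SNR 20 Rician noise. No quantitative tumor vessel
statistics are prescribed by any source; these are free parameters of the
phantom, chosen once to produce clearly separated zonal distributions at
realistic densities, and documented as such.

Rasterization is a voxel-centre in/out test against the union of capsules
(cylinder plus hemispherical caps), without anti-aliasing — binary ground
truth semantics for Dice. The multi-echo simulator renders tissue decay
with a spatially varying R2*, an elevated-R2* rim within a configurable
number of voxels of a vessel (the susceptibility boundary effect), vessel
lumina at a constant near-zero signal (no mobile protons), optional support
mask, and Gaussian or Rician noise (magnitude of a complex Gaussian) with
σ = S0/SNR. The DWI simulator renders `S0·exp(−b·gᵀDg)` from a tensor
field and rejects indefinite tensors.

What the phantoms do *not* emulate: real susceptibility field physics
(dipole convolution), partial-volume mixing at vessel boundaries
(rasterization is binary), hemodynamics, anatomy, coil inhomogeneity, or
motion. Passing tests therefore establish the correctness and calibration
of the *computational chain* — recovery of known parameters, preservation
of topology, statistical calibration, the direction of the partial-volume
bias — not the biological accuracy of any particular acquisition.

## Problem sizes and seeds

The test suite and the acceptance script run phantom segmentation at 128³
voxels (31 µm), the pipeline demo at 40–48³, relaxometry recovery at 500
voxels, and the statistical calibrations at 200 null and 100 alternative
replicates — sizes at which every quantity is stable to well within its
tolerance while the whole suite runs in about a minute. A single global
seed fans out to per-stage seeds via the fixed scheme
`stage_seed = (seed·1009 + stage_index) mod 2³¹`, so stages rerun in
isolation reproduce their in-pipeline outputs, and identical
configuration + seed reruns are byte-identical on all tabular outputs.

## Known limitations

* Branch decomposition treats junction clusters heuristically; highly
  pathological skeletons (dense loops at junctions) may split or merge
  branches differently from other tools.
* Radius estimates inherit the ±0.5 voxel digitization bias of the EDM;
  sub-voxel vessels are systematically inflated (the partial-volume effect
  the validation quantifies, not a bug to correct silently).
* Resampling supports integer block factors only; arbitrary-grid
  resampling must go through the TPS warp with an affine landmark set.
* The tensor fit is unweighted log-linear; at very low SNR a weighted or
  positive-definite-constrained estimator would be less biased.
* `compare_zones` treats branches as independent observations; spatial
  correlation along the tree is ignored, as in the workflow it mirrors.
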