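# Methods

This note documents the models, numerical choices and known limitations
behind `tagflow3d`. It is written for users who need to judge what the
package's validation results do and do not demonstrate.

## The synthetic tagged phantom

The phantom stands in for a tagged 3D cine acquisition of a left
ventricle with *exactly known* motion. It is deliberately simple: an
annular wall, parametric systolic motion, multiplicative tags.

**Anatomy.** The myocardium is an annulus (default endocardial radius
8 mm, epicardial 14 mm, 30 mm long-axis extent) on a 64×64×24 grid at
0.70×0.70×1.5 mm — matrix and resolution representative of a small-animal
short-axis stack. The wall carries a smooth random texture
(Gaussian-filtered white noise, correlation σ = 1.5 voxels, ±15 %
modulation, reproducible from a seed); the cavity and background are
dark. The assembled volume is blurred with a σ = 0.6 voxel Gaussian
representing the acquisition point-spread function: a real scan is
band-limited and never contains the aliased hard edges of the raw
geometric model.

**Tags.** A tag family is a set of parallel saturation planes defined in
*physical* (mm) space — a tagging pulse saturates planes of tissue
regardless of how the voxel grid samples them. Spacing and width are
quoted in in-plane pixel units (defaults 6 and 2 px = 4.2 and 1.4 mm at
0.7 mm pixels). Because the slice spacing (1.5 mm) is about twice the
pixel size, the physical definition matters: a slice-parallel family
(β = 90°) has its 4.2 mm period sampled by only ~2.8 slices, close to
the Nyquist limit — exactly the resolution penalty that makes the
oblique-angle choice interesting. The three default families have
normals along x, y, and the oblique direction
(cos β cos 45°, cos β sin 45°, sin β); β defaults to 30°. Stripe edges
are softened by a σ = 0.5 voxel Gaussian by default (an imaged tag is
never a perfect step); `tag_field` itself defaults to hard edges so the
saturation values are exact.

**Fading.** Saturated magnetization recovers as
`f(t) = 1 − e^(−t/T1)` with T1 = 900 ms; each phase multiplies the base
anatomy by the product of its families' tag fields at that phase's time.
Phases default to 50–350 ms after tagging (systole at roughly 100 bpm).

**Motion.** The ground-truth displacement is an analytic field with
three components: torsion (rotation angle linear in z, −6°/+6° at
apex/base by default — the systolic "wringing"), radial contraction
(linear inward scaling, 12 % peak), and longitudinal shortening (linear
in z, apex fixed, 3 mm = 2 slices at the base). The field scales exactly
linearly with the phase fraction, so the peak field defines the whole
trajectory. Defaults give ~3 px peak in-plane and 2 slices through-plane
excursion — a realistic systolic range at this resolution. Phases are
rendered by warping the (faded, tagged) reference image with the
*inverse* of the ground-truth field, obtained by fixed-point iteration,
so the exported truth is exact at material grid points rather than
approximate.

**Noise.** Optional zero-mean Gaussian noise with σ given as a
percentage of the global maximum intensity of the noiseless data.

What the phantom does *not* model: k-space acquisition, slice-profile
effects, blood flow, respiratory or cardiac gating artifacts, papillary
muscles, or physiologic inhomogeneity of contraction. Passing the
validation battery therefore demonstrates correct mechanics of the
tracker and strain chain under realistic geometry, tag physics, fading
and noise — not robustness to every confound of in-vivo data.

## The tracker

Both stages minimize a sum of squared differences (SSD) between a
filtered volume pair by safeguarded Gauss-Newton iteration; all motion
is estimated in voxel units per axis.

**Pre-filtering.** Both stages first remove the local intensity offset
with a difference-of-Gaussians band-pass (`G_σ − G_2σ`, σ = 1 voxel).
This is essential for tagged data: T1 relaxation brightens the stripes
between phases, and matching raw intensities rewards transforms that
merely blur the brighter image. A pure high-pass (image minus its
smoothed copy) is offered as an option but keeps all voxel noise; the
band-pass measurably improves both clean and noisy tracking.

**Global stage.** A 6-parameter transform (translation + small-angle
rotation about the volume centre) is fit coarse-to-fine over a Gaussian
pyramid (3 levels × 8 iterations by default). Safeguards, each there for
a measured failure mode: border voxels are excluded from the cost so it
stays continuous as samples cross the grid edge; symmetric gradients
(template gradient at the warped position averaged with the target
gradient) cancel first-order interpolation bias at sub-voxel offsets;
per-iteration steps are clamped (2 voxels / 0.1 rad) and must *strictly*
decrease the SSD, since near-flat directions (rotating an almost
rotationally symmetric ring) otherwise let the estimate wander; a
translation-only fallback step is tried when the joint step fails (weak
rotation columns can misdirect the weakest translation component); and
each finer level keeps the inherited estimate only if it beats the
identity on that level's data, because coarse levels of band-passed
tagged data can carry almost no energy.

**Local stage.** Initialized from the global motion, each voxel's flow
vector is refined by Gauss-Newton on the band-passed pair, with the
normal equations accumulated over a local inspection window (uniform
weights). The window defaults to 7×7×3 voxels — about 4.9×4.9×4.5 mm,
i.e. physically isotropic at the default anisotropic voxel size — chosen
by phantom optimization: a 3-voxel window holds too few independent
samples to constrain three motion components, while a z-extent much
larger than the slice spacing blurs through-plane landmarks across tag
periods. Per voxel, the solve is performed in the eigenbasis of the
windowed structure matrix and update components along eigenvalues below
25 % of the largest are suppressed: the aperture problem makes those
motion directions unobservable in the window, so the voxel keeps its
(global) initialization along them rather than fitting noise. Steps are
clamped to 1 voxel per iteration and halved (up to four times) if the
windowed SSD increases, so the accepted SSD sequence is non-increasing.
Voxels whose strongest structure eigenvalue is below 1 % of the
volume-wide maximum (empty background; 2D slices whose material left the
plane) are left at their initialization and flagged invalid — without
this floor the slice-wise 2D tracker drifts without bound on basal
slices that the wall vacates during systole. Out-of-view samples compare
against the empty background (zero on band-passed data) instead of being
dropped, so "move everything out of view" is never a descent direction.

**Integration.** Adjacent phases are compared pair-wise; the resulting
Eulerian flow increments are integrated along each material trajectory,
`U_{p+1}(X) = U_p(X) + flow(X + U_p(X))`, with trilinear sampling of the
increment at the tracked sub-voxel position. The Lagrangian reading of
"vector integration" is required for material-point strain to be
meaningful. Pair-wise estimation plus band-pass filtering makes the
chain insensitive to tag fading, at the cost of random-walk error
accumulation over phases (visible in the per-phase RMS).

**2D mode.** The identical algorithm runs independently per slice with
2-vector flow, 2D pyramids and the leading 2D window extents; its output
is the in-plane projection a conventional 2D tagged analysis would
measure. On motion with a through-plane component the 2D tracker watches
material move through its plane and mis-attributes the pattern change to
in-plane motion, which is the basis of the 2D-vs-3D comparison.

## Strain

Displacement is converted to mm, differentiated on the reference grid
(central differences in the mask interior, one-sided at mask boundaries,
flagged where no valid neighbour exists), and assembled into
`F = I + ∂u/∂X` and `E = ½(FᵀF − I)`. E vanishes identically for rigid
motion, making it appropriate for the large rotations of systole.
Principal strains are the eigenvalues of E sorted descending; ε1 is
radial wall thickening when positive, ε3 the combined
circumferential-longitudinal shortening. The ε1 eigenvector sign is
fixed outward-radial (positive-x on ties); the α angle — between the
greatest-stretch direction and the in-plane radial line from the
endocardial centre — is folded into [0°, 90°] and is sign-invariant.
ε2 is computed and stored although regional reports quote ε1 and ε3.
Optional Gaussian pre-smoothing of the displacement before
differentiation (off by default) is available for noisy fields.

## Regional analysis

Contours drawn on a subset of slices at one phase are resampled to a
fixed vertex count by arc length, linearly interpolated between drawn
slices, and propagated to other phases by warping the vertices with the
measured displacement. Masks rasterize "inside epicardium, outside
endocardium" at voxel centres. Sectorization follows the standard
convention: sector 1 starts at the ray from each slice's wall centroid
through the anterior RV insertion point, proceeding counterclockwise
viewed from the apex (configurable); sectors map pairwise onto the six
anatomical regions AS, PS, PST, PL, AL, ANT; slices between the extreme
masked slices split into three equal longitudinal groups. A voxel
exactly on a boundary takes the lower sector index. Regional tables
report mean ± SD per (region, level) — over voxels for a single subject,
over per-subject cell means across subjects. Bull's-eye maps use 22
equal longitudinal rings (apex innermost) × 12 sectors; empty cells are
NaN, never zero. A `--drop-apical N` option excludes the most apical
masked slices, which are often hard to segment.

## Validation experiments and problem sizes

The experiment drivers regenerate everything from a config and seeds, so
every number is reproducible. The reference experiment uses the default
64×64×24 phantom with 8 phases; tracking it takes ~15 s on one CPU core.

* **Accuracy**: per-axis end-systolic RMS over myocardial voxels,
  reported in voxels and mm. Typical reference values are ~0.22 px
  in-plane and ~0.42 px through-plane.
* **β sweep**: β ∈ {0,…,90°} in 15° steps, tags regenerated per angle.
  Each angle's RMS is averaged over three phantom texture realizations,
  because the single-realization angle effect on the z error
  (≈ +0.02 voxels between 30° and 90°) is comparable to realization
  scatter; averaging separates the systematic effect from noise. The
  slice-parallel extreme (90°) degrades through-plane accuracy relative
  to the oblique optimum (30°) while in-plane errors barely move.
* **Noise sweep**: 5–20 % noise, three realizations per level; errors
  reported against ground truth and against the noise-free baseline
  estimate (the conventional way to isolate the effect of noise from
  the tracker's intrinsic error). Through-plane error dominates at every
  level, and the worst in-plane deviation from baseline stays below
  0.3 mm at 20 % noise.
* **2D vs 3D**: identical settings for both trackers; in-plane errors
  pooled over x and y at end-systole. With 2 slices of through-plane
  motion the slice-wise tracker's in-plane RMS is several-fold larger
  than the 3D tracker's (dominated by basal slices whose material leaves
  the plane).

## Design choices that were genuinely open

* The "matrix multiplication" combining anatomy and tags is element-wise
  multiplication by a [0, 1] tag factor — the only reading that makes
  tags dark and fading multiplicative.
* The oblique family's azimuth is +45° from the x-tag normal
  (configurable); only the 45° angle to the in-plane tags is physically
  constrained.
* Cavity intensity is a free parameter (default 5 % of M0): blood is
  dark in the tagged images but its exact level is not constrained.
* Noise percentage refers to the *global* maximum of the noiseless
  data, not per-slice maxima.
* The deformation model uses a linear longitudinal profile; real
  shortening is spatially heterogeneous. This limits the realism of the
  through-plane error estimates but keeps the ground truth exact and
  smooth.
* Strain defaults to the reference-to-end-systole pair; any phase pair
  can be selected.
* The local window is uniform-weighted. Gaussian weighting was tried and
  improves single-pair in-plane error but systematically corrupts the
  through-plane component on later, faded phases; uniform weights are
  kept.

## Known limitations

* Errors accumulate over phases as a partial random walk; sequences much
  longer than the ~8-phase systolic window would benefit from reference
  re-anchoring, which is not implemented.
* The tracker has no explicit smoothness or incompressibility prior —
  regularization beyond the windowed least squares is deliberately out
  of scope — so per-voxel errors are uncorrelated at the window scale.
* Voxels without local structure inherit the global-stage motion; in
  pathological cases with large non-rigid motion and no texture this is
  a biased fallback (it is flagged in the validity mask).
* The 2D mode's error depends strongly on how much material leaves each
  slice; its absolute value is phantom-specific even though its ordering
  relative to 3D is robust.
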