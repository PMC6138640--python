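# Methods

This note documents the models, algorithms and numerical choices behind
nbaxis, and what its validation does and does not establish.

## The measurement problem

A larval brain neuroblast (NB) divides asymmetrically every few hours,
budding a small ganglion mother cell (GMC) from its basal pole.  The
quantities of interest are directional: the 3D division axis of each
mitosis, the deviation angle α between successive axes of one cell, the
angle β between an axis and the direction toward the last-born daughter,
the fraction of the NB surface ensheathed by cortex glia, and an
EdU-incorporation volume as a proliferation readout.  Conditions
(daughter ablation, centriole loss, RNAi) are compared by two-tailed
Mann–Whitney U tests on these per-cell quantities.

Confocal time-lapse stacks are strongly anisotropic (z-step 0.8 µm
against ~0.26 µm xy pixels — the xy size is a configurable default, not
a measured value), so every geometric operation converts voxel indices
to physical micrometres first; angles computed on indices would be
biased toward the fine-sampled plane.

## Inter-axis angle

`axis_angle` implements α = arccos(v₁·v₂ / |v₁||v₂|) with the standard
componentwise dot product, v = basal − apical.  The cosine is clamped to
[−1, 1] so floating-point round-off can never produce NaN; results live
on [0°, 180°] with no folding at 90°, because oriented apical→basal axes
are compared and mean deviations above 45° are meaningful (e.g. after
daughter ablation).  Agreement with an extended-precision (long-double)
oracle is better than 10⁻⁹ degrees.

## Shape-based axis extraction

When only a membrane marker is available the axis is recovered from the
telophase dumbbell in three steps: (1) the in-plane long axis of the
cell on the xy maximum projection — 2D PCA by default, or a
user-supplied landmark line replacing the interactive equivalent;
(2) the stack is resampled on the plane spanned by that line and z
(bilinear interpolation at quarter-z-step resolution) and the two pole
extremities located along the in-slice principal axis, giving sub-voxel
pole z coordinates; (3) pole (y, x) positions recovered on the
corresponding z slices.

Extremity picking on a coarse-z grid is biased when the axis points near
z (the projection PCA direction is then arbitrary and the slice plane
can miss the basal lobe), so the direction is refined by iterating the
axis through the two lobe centroids: for a two-lobed body of revolution
the lobe centroids lie exactly on the symmetry axis, making the fixed
point of the iteration the true axis.  Final poles are centroids of the
extremal slab (one max-spacing thick) pushed out to the extreme
projection, which stays on-axis by symmetry.  On noiseless anisotropic
renders the recovered axis is within ~2° of truth; with default noise
the median error over 100 scenes is ~1°.

Lobes are split at the neck — the minimal cross-section of the
voxel-count profile along the axis (40 bins, interior 15–85%), accepted
only if below 0.9 × both flanking maxima; profiles without such a
minimum (spheres, interphase blobs) raise "not telophase".  The apical
pole is assigned to the larger lobe, the stem-cell side of an asymmetric
division; lobe volumes within 10% of each other raise a
`lobe-ambiguity` QC flag instead of silently guessing.  Both the neck
ratio and the ambiguity tolerance are configurable, as the original
manual procedure documents no equivalent rule.

## Centrosome axis, rounding, daughter axis

With a centrosome marker the axis is simply apical→basal spot.
`detect_centrosomes` does greedy peak picking with a physical exclusion
radius, background-subtracted centroid refinement, and a log-parabola
sub-voxel fit in z (the coarse z-step dominates the localization error
otherwise; residual spot error ~0.1 µm, axis error ~2°).  Apical/basal
assignment is left to the caller, since it requires polarity context the
image alone does not carry.

Mitotic rounding onset is the first frame whose mask sphericity
π^⅓(6V)^⅔/A reaches a threshold (default 0.92) after having been below
it; a series that never rounds returns its last frame with a QC flag.
The daughter (β) axis runs from the cell centroid through the centroid
of the contact patch — cell voxels within 1.2 × the maximal voxel
spacing of the daughter mask, a physical criterion because an
anisotropic voxel dilation would skew the patch along z — with a
daughter-centroid fallback (flagged) when no patch exists.  Both the
interface and centroid conventions are exposed, as the original choice
is not documented.

## Segmentation

`segment_cell` thresholds the blurred membrane channel (Otsu by
default), closes the shell morphologically, and takes the enclosed
interior containing the seed.  Membrane voxels are then assigned to the
cell up to their midline (equidistant between the cell interior and
everything else, by anisotropy-aware distance transforms), so the mask
boundary follows the membrane centre and touching neighbours keep their
half of a shared membrane.  Segmented sphere volumes are accurate to a
few percent; a neighbour's interior leaks in at below 5%.

The prescribed preprocessing is a 0.8 × 0.8 × 0.8 *voxel* Gaussian blur
(sigma in voxels, not µm, reflective boundaries).  A 0.75 gamma
adjustment exists for display only: its output carries a
`display_only` flag and measurement entry points refuse it.

## Surface morphometry

Areas come from marching cubes at level 0.5 on the spacing-aware mask,
summing raw triangle areas (no mesh smoothing).  Binary masks are
volume-smoothed (Gaussian, 0.5 voxel SD) before extraction: the level
set then interpolates the boundary at sub-voxel resolution, removing
the staircase overestimate (~9% for a sphere at 0.26 µm sampling) at
the cost of slight edge rounding on polyhedra (−4% on a cube) — both
within the 5% accuracy this package claims for surface areas.
Sphericity uses a stronger 1-voxel smoothing: as a dimensionless ratio
it benefits from fully suppressed staircase area, and its edge-rounding
bias largely cancels.  Contact fraction counts triangle area whose
centroid lies within 0.5 µm (configurable; ≈2 xy pixels) of the glial
mask by anisotropic distance transform.  Against the spherical-cap
closed form 1 − (1 − cos θ)/2 the measured fractions agree within ~2
percentage points; the residual is a rim band of triangles within
lateral reach of the cap edge, of angular width ≈ contact distance /
radius.

The voxel classifier (`classify_voxels`) is a Gaussian naive-Bayes model
on intensity, 3³ local mean and 3³ local variance.  It is a deliberately
simple, deterministic replacement for an interactive pixel-classification
workflow, present so the EdU pipeline runs end-to-end; any externally
produced probability map in [0, 1] is equally accepted.

## Synthetic scenes

The generator defines the study conditions.  Axis directions follow a
Markov process on the sphere: the first axis uniform, each next axis
rotated from its predecessor by a deviation θ ~ Normal(µ, σ) truncated
to [0°, 180°] about a uniform azimuth.  (µ, σ) come from the
per-condition presets — control 24 ± 15°, daughter ablation 36 ± 20°,
control ablation 23 ± 16°, β reference 14 ± 7°, and the other published
summaries carried in `CONDITION_PRESETS`.  A truncated normal on the
angle, not a von Mises–Fisher density, is used deliberately: the
published per-condition numbers are plain mean ± SD of angles, so this
parametrization reproduces them directly.  Truncation at 0° shifts the
distribution mean upward by ~1.8° for the control preset; recovery tests
therefore compare against the preset parameters with tolerances (±3°
mean, ±4° SD) that absorb both this shift and measurement error.  For
β-type scenarios the next axis can instead be centred on the current
daughter direction (`centre_on="gmc"`), optionally with random
tangential daughter displacement between divisions, producing the
β < α ordering characteristic of daughter-guided orientation.

Each cycle renders three frames: an elongated interphase blob (capsule
of two offset spheres, elongation 2.8, volume-preserving — elongated
enough that its sphericity ~0.85 sits clearly below the rounding
threshold), a rounded metaphase sphere with two centrosome spots at
±0.6 r on the axis, and a telophase dumbbell of two overlapping spheres
(default NB radius 5 µm, consistent with ~10 µm cell diameters; NB:GMC
volume ratio 4:1; centre separation 0.8 × the radius sum, leaving an
open ~2.4 µm cytoplasmic neck).  Membranes are Gaussian shells
(σ 0.3 µm) on each cell's outer surface — a union surface within one
cell, separate shells for distinct cells, so touching neighbours remain
separable.  After its division the daughter persists as its own tangent
cell until the next telophase, where it is omitted so the nascent lobe
is unobstructed.  Glia is a shell at NB radius + 0.4 µm covering a
spherical-cap complement of the requested fraction.  Rendering applies
an anisotropic Gaussian PSF stand-in (0.6, 0.2, 0.2) µm — shape, not
optics, is what downstream measurements consume — then Poisson photon
noise (scale 200, peak SNR ≈ 13) and Gaussian read noise, at default
spacing (0.8, 0.26, 0.26) µm.  All randomness flows from the scene seed
and the frame index, making every stack bit-reproducible.

What the generator does *not* emulate: neighbouring lineages and tissue
context, cell tracking ambiguity, photobleaching and depth-dependent
attenuation, membrane texture, and ablation physics (an ablation
condition is purely a different deviation preset).  Passing recovery
tests therefore demonstrates correctness of the geometry and
measurement code under realistic sampling and noise — not robustness to
every artefact of real brain movies.

## Statistics

U is computed from midrank rank sums.  For tie-free pooled samples with
n₁ + n₂ ≤ 20 the two-tailed p is exact: the complete null distribution
of U from the shift-algorithm recursion (cached per (n₁, n₂)), p =
min(1, 2·P(U ≤ min(U₁, U₂))).  Otherwise the normal approximation with
midrank tie correction and 0.5 continuity correction is used.  The
switchover and tie policy are declared in every output, since the
original analysis does not state its choices.  Raw pairwise p values are
reported without multiple-testing correction, matching the original
presentation; a Holm adjustment is available behind a flag (off by
default).  Summaries use sample SD (n − 1), type-7 linear-interpolation
quartiles, whiskers clipped to the most extreme points within 1.5 × IQR.
A single-value sample reports SD 0 with an explicit flag.

## Problem sizes and tolerances

Validation sizes are chosen so the whole suite runs in minutes on one
CPU: 100 noisy scenes for recovery medians, 200 rendered divisions per
preset for parameter recovery, 100 seeded replicates for the power
check (n = 35 per arm, the study's scale), 10⁴ permutations for the
type-I error of the exact test.  The power contrast (24 ± 15 vs
36 ± 20, n = 35) has true Mann–Whitney power close to the 80% decision
line, so the significant fraction typically lands at 81–86%.  The
Monte-Carlo power and near-null checks draw angle samples from the
generator and route them through the measurement bookkeeping and test
machinery without rasterizing each division; rendering fidelity is
validated separately, and the ~1° median extraction error is negligible
against the 15–20° condition SDs, so rasterizing would not change the
power estimate.

## Known limitations

- The pole finder assumes a two-lobed telophase; heavily deformed or
  multi-lobed cells are rejected rather than guessed at.
- Apical/basal disambiguation relies on volume asymmetry; near-symmetric
  divisions are flagged, not resolved.
- No drift or rotation registration between frames: axes are compared in
  the microscope frame, as in the original measurements.
- The classifier is intentionally minimal; it is not a substitute for a
  trained pixel classifier on heterogeneous real signal.
- Exact U p values require tie-free data; heavily tied samples always
  take the approximation path regardless of size.
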