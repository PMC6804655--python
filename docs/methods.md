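# Methods

## Study design

The package reproduces, on synthetic phantoms, a comparison of vascular
model fidelity for stereotactic electrode planning.  One ground-truth
vascular tree per phantom is rendered as three modality volumes that
differ only in the smallest vessel diameter they reveal — the gold
standard shows everything, the intermediate modality vessels ≥ 2 mm, the
worst ≥ 4 mm.  Implantations are planned against each modality's vessel
model; the frozen trajectories are then re-scored against the gold model
("true" risk) and against the gold model pruned at 1–4 mm diameters, and
paired statistics ask at which pruning diameter a degraded modality
becomes indistinguishable from the pruned gold standard.

## Head phantom

A spherical intracranial space (radius 40 mm) on a 96³ grid at 1 mm
isotropic voxels, inside a 3 mm skull shell.  Gray matter is a 3 mm
cortical ribbon plus six planar sulcal infoldings reaching 15 mm deep, so
sulcal-model extraction (erode the intracranial mask, intersect with GM)
has real work to do.  Eight spherical target regions (radius 5 mm) sit on
a 24 mm shell; their centres are re-jittered until they are ≥ 6 mm from
the vascular tree and ≥ 18 mm from each other — targets a surgeon could
actually reach, and far enough apart that the ≥ 10 mm inter-electrode
constraint is satisfiable.

The vascular tree grows by recursive bifurcation from two roots near the
inner surface: segment lengths 6–12 mm, bifurcation probability 0.65,
branching angles 20–40°, direction jitter ≤ 12°.  Radii start at 4 mm and
each child multiplies its parent's radius by 0.75 ± 0.08 (uniform); the
jitter makes the caliber distribution continuous, as in real vasculature —
with a fixed decay the tree would carry discrete caliber "generations",
and a whole generation sitting just below a visibility threshold would
make threshold comparisons pathologically one-sided.  Growth stops below
0.35 mm radius, so calibers span ~0.8–8 mm in diameter and every pruning
threshold in {1, 2, 3, 4} mm is informative.  The growth domain is
discretised on a fixed canonical lattice, so the truth tree is identical
whatever rendering grid is configured.

Rendering paints each visible segment (true diameter ≥ the modality's
floor) at unit contrast, applies a Gaussian blur of 0.5 voxel as a
partial-volume proxy, and adds Gaussian noise (σ = 0.02).  All three
modalities share blur, contrast and noise level — relative detectability
is the only degradation under study; only the noise realisation differs.
An optional known affine misalignment (resampling the clean tube image
before blur) emulates acquisition in a different frame for registration
experiments.

What the phantom does **not** emulate: anatomically realistic vascular
territories, flow or contrast dynamics, soft (contrast-dependent)
visibility cutoffs, non-Gaussian imaging noise, and tissue other than the
binary masks.  Passing tests show the analysis chain is correct under
these idealisations, not that any particular clinical modality behaves
like the phantom's.

## Model generation

Vessels are enhanced with a multiscale Hessian line filter (scales
{0.5, 1, 2, 3} mm, σ²-normalised, asymmetry weight α = 0.25, both ratio
exponents 1.0; response zero wherever the two cross-sectional eigenvalues
are not both negative).  After intracranial masking, an isosurface is
extracted at a user threshold (default: Otsu over the strictly positive
responses — the unattended stand-in for interactive thresholding), and
connected components under 30 vertices are dropped as noise.

Centreline and radii: the mesh interior is voxelised (surface marked by
triangle subdivision, exterior flood-filled), and the centreline taken as
the ridge of the interior Euclidean distance transform — voxels within a
quarter voxel of their 3×3×3 depth maximum, computed on a 2× refined
lattice so vessels only one or two voxels across keep a distinct axis.
Each surface vertex is then matched to its medial ball — the ridge point p
minimising the power distance |v − p| − depth(p) — and the vertex radius
is the distance to that point.  (A plain nearest-ridge-point readout is
corrupted by shallow spurious ridge voxels; the power-distance matching is
the standard medial-ball correspondence.)  On analytic cylinders of radius
1–4 mm at 1 mm voxels the median radius error is ≤ 0.35 mm; on full
phantoms the median bias against the true segment radii is ≤ 0.1 mm.  A
3-D thinning routine was rejected for this step: the installed library
erases objects with even-width (e.g. 2×2 voxel) cross sections entirely.

Pruning removes vertices whose local diameter is strictly below the
threshold, with incident faces; the strictly-below convention means a
vessel of exactly the threshold diameter survives, which keeps the
visibility floor (diameter ≥ δ renders) and pruning at δ consistent.

## Registration

Nine-parameter affine (rotation, translation, independent scales about the
volume centre) maximising Studholme NMI, (H(A)+H(B))/H(A,B).  Numerical
choices that matter:

- the metric is evaluated on volumes smoothed by 1 voxel **and** sampled
  on a probe lattice offset 0.37 voxel from the native grid.  Both fight
  the interpolation artifact: with sharp images sampled on-lattice, NMI
  rewards candidates whose sampling aligns with the moving grid (a unit
  scale factor, an integer shift) over true alignment;
- 128-bin joint histograms: at 64 bins the smoothed metric's optimum for
  an axis-aligned pure-scale misalignment sits ~1% off the true scale;
- schedule: Nelder–Mead on a downsampled pair for the bulk misalignment,
  two full-mobility rounds on a half-density probe (a fresh simplex
  recovers from premature collapse), then a small-simplex polish on the
  full-density probe.  Deterministic given the seed; restarts only fire
  if no start improves on the initial transform, in which case the
  initial transform is returned with a warning.

Recovered parameters for misalignments within ±5 voxels / ±5° / scale
0.95–1.05 on noiseless renders are within 0.5 voxel, 0.5° and 1%.  The
exception is *axis-aligned pure scale with no rotation or translation*:
there the NMI landscape is flat to < 5×10⁻⁴ across ~±1.5% of one scale
axis for desk-scale content, so no NMI maximiser can pin that axis to 1%;
the package documents 2% for that degenerate configuration.

Mesh vertices transform through the recovered matrix; per-vertex radii
scale by the mean of the three scale factors (the convention for
anisotropic scale, where a single radius has no exact image).

## Planner

Target candidates are ROI voxel centres at ≥ margin + electrode radius
(3 + 0.65 mm by default) from every critical surface.  Entry candidates
are area-uniform skull-surface samples at 5 mm spacing with outward
normals.  Hard constraints: intracerebral length ≤ 90 mm, drilling angle
≤ 30° from the inward skull normal, optional entry-ROI traversal, and no
collision with any critical mesh, the electrode modelled as a cylinder of
its diameter (clearance checked at all 128 nodes).  The raw entry × target
product runs past 10⁵ pairs per electrode; after the cheap geometric
filters a seeded subsample of at most 30 pairs per electrode receives the
expensive collision-and-metric evaluation, escalating by 4× whenever a
sample yields no feasible candidate.  These caps are the package's
desk-scale working point and are configurable.

Candidate cost is w_rs·RS − w_gm·gm_ratio + w_len·(length/max_length) with
weights (1, 0.3, 0.1); gm_ratio is the fraction of electrode contact
centres (placed from the target backwards at the spec's spacing) inside
gray matter.  Plan assembly picks one candidate per electrode subject to
≥ 10 mm pairwise segment-to-segment spacing: instances up to 4096
combinations are solved exactly by enumeration over precomputed
compatibility matrices; larger ones use greedy depth-first search with
forward checking (most-constrained electrode first, candidates in
ascending cost, a step budget against pathological backtracking).
Risk-regime rule: one sub-margin node puts the whole trajectory in the
risky branch of the RS equation; distances above 10 mm are clamped so
safe-branch contributions stay non-negative.  Electrode default: 1.3 mm
diameter, 10 contacts, 2.4 mm contact length, 5 mm spacing — a generic
stand-in, configurable.

## Statistics

Shapiro–Wilk at α = 0.05 gates each paired comparison into a paired t test
(normal differences) or a Wilcoxon signed-rank test (otherwise; zero
differences dropped, an all-zero vector short-circuits to p = 1 with a
warning).  Bonferroni over n = 3 comparisons gives the per-comparison
threshold 0.05/3 = 0.01666…, conventionally quoted truncated as 0.016;
the package reports full precision and compares against the exact value.
Equivalence is inferred from non-significance, as in the study design this
mirrors; that is weaker than a formal equivalence test (TOST) and is
documented as such.

## Known limitations

- **Equivalence by non-significance is fragile under phantom precision.**
  In the noiseless arm the δ-visibility model and the gold model pruned at
  δ are geometrically identical and paired differences vanish exactly.  In
  the imaging arm the two models are segmented independently; the default
  cohort reproduces the expected pattern — each degraded modality is
  non-significant against the pruned gold model only at its own
  visibility diameter — but the p-values at the matching diameter sit
  within a factor of a few of the 0.016 threshold (one of the four,
  the 4 mm model's minimum distance, falls marginally below it), because
  a signed-rank test at n ≈ 80 flags any sign-asymmetric sub-voxel
  surface difference however small in magnitude (medians here are
  ~1e-3 RS and ~0.2 mm MD); exactly-zero pairs are dropped, sharpening
  the test further.  Clinical data escape this because within-pair
  variability is orders of magnitude larger.  Readers should weigh the
  paired-difference magnitudes, not only the p-values.
- Radius estimates carry ~half-voxel noise, so pruning at a threshold δ
  keeps or drops vessels within ~±0.5 mm of δ stochastically.
- The planner's candidate subsampling trades optimality for speed; the
  exact-enumeration path exists only for small instances.
- Hemorrhage risk as a function of vessel size or type is not modelled;
  the risk score is a geometric surrogate.
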