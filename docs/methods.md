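# Methods

## Scope and model

`cordpolar` quantifies the spatial organisation of immunolabelled neuron
populations in spinal-cord cross-sections.  The unit of observation is one
section imaged as a four-channel confocal z-stack (ChAT, GAD-67,
Parvalbumin, Calbindin) with two hand-drawn regions: the gray-matter
outline and the central canal.  The study design it targets is four
genotype groups × three animals × eight sections (two per lumbar level
L3–L6).  Three layers of inference are kept strictly separate:

- **counts** — per-animal sums over sections, compared across genotypes by
  one-way ANOVA (animals are the replicates, n = 3 per genotype);
- **radial position** — per-cell normalised distances, compared by a
  nested one-way ANOVA with animals nested in genotype, so cells within an
  animal never masquerade as independent replicates;
- **angular position** — per-cell mirrored angles, pooled across animals
  within genotype, compared by circular nonparametrics.

The pooling of cells across animals for the circular layer reproduces the
workflow this package re-implements; an independent per-animal summary can
be built from the per-cell table, but the pooled mode is the default.

## Image processing

Per channel: maximum-intensity projection; masking to the gray-matter ROI;
background subtraction; maximum-entropy thresholding; despeckle and
closing.  Order matters and is fixed: the threshold sees
background-subtracted, in-mask pixels only.

*Background subtraction* estimates the background as a grayscale opening
with a disk structuring element (radius 20 px by default) — the flat-disk
reading of the classical rolling ball.  The disk footprint is applied
through skimage's sequence decomposition, which is two orders of magnitude
faster than the literal footprint at a worst-case amplitude deviation
below 0.3% on noise; the estimate is clamped at the image so the
subtraction is non-negative by construction.

*Maximum-entropy threshold* (Kapur–Sahoo–Wong): a 256-bin histogram over
the observed in-mask min–max (so 16-bit input reproduces the 8-bit
histogram dialect of the common macro implementation), objective
H_bg + H_fg with empty candidate sides excluded, ties resolved toward the
lower threshold, and the returned value placed at the upper edge of the
selected background bin.  Masked-out pixels are excluded from the
histogram; including them would flood the zero bin and corrupt the
optimum.  A manual override parameter exists because operators sometimes
adjust automatic thresholds.

*Cleanup*: one 3×3 median pass (despeckle) followed by one 3×3 closing —
the defaults of the macro environment the chain mirrors.  On cleaned
disk-like masks a second pass is a no-op; on raw salt noise it is not,
which is why the idempotence check runs on segmented sections.

## Detection and colocalisation

Particles are 8-connected components, area = pixel count × (µm/px)²,
filtered by inclusive marker-specific windows derived from somal diameters
(A = π(d/2)²): ChAT 78.5–1256.6 µm², Parvalbumin 78.5–314 µm², GAD-67
50–314 µm², Calbindin 78.5–490.9 µm².  ChAT⁺ cells split at 491 µm² (25 µm
diameter): below → interneuron, at or above → motor neuron; the shared
printed bound is assigned to the motor class so the rule is deterministic.
Touching cells are not split (no watershed) — a known undercount mode
under crowding — and no circularity or edge filters are applied.

Colocalisation is anchored: a cell of marker A is double positive for B
when ≥ 20% of A's pixels (inclusive at exactly 0.20) lie on B's
thresholded mask.  A-in-B and B-in-A generally differ; the pipeline always
anchors on the first-listed marker (ChAT–GAD-67, PV–GAD-67, PV–Calbindin).

## Canal-referenced geometry

Angles use the mathematical convention (0° right, 90° dorsal); with image
rows increasing downward and a dorsal-up mount, the vertical offset sign
is flipped; a per-section `dorsal_up` flag handles inverted mounts.
Left-side angles — strictly between 90° and 270° — are mirrored with
θ′ = 180° − θ (mod 360); 90° and 270° themselves are left unchanged.  The
mirror preserves sin θ (the dorsoventral coordinate) and is idempotent.

Radial normalisation has three selectable variants because the verbal
definition of "normalised to the gray matter" is genuinely ambiguous:

- `radial_fraction` (default): distance to the canal over the
  canal-to-boundary distance along the same ray — bounded in [0, 1], 0 at
  the canal, 1 at the edge, monotone along every ray.  This matches the
  semantics "0 closest to the canal, 1 farthest".
- `edge_map`: depth in the Euclidean distance transform of the gray mask
  over the maximum depth — the literal "distance map from the tissue
  edge" reading (note it is 0 at the edge and 1 at the deepest point, so
  it *decreases* outward).
- `canal_over_depthmax`: canal distance over maximum depth — a hybrid that
  is 0 at the canal but not bounded by 1.

The boundary radius along a ray is read from a cached lookup (3600 rays,
0.25 px marching, farthest in-mask sample per ray, robust to small
non-convexities); depth maps are sampled bilinearly at sub-pixel
centroids.

## Circular statistics

Degrees at every interface, radians internally.  Mean and variance come
from the mean resultant vector (variance = 1 − R̄, unitless in [0, 1]).
The circular median minimises mean arc distance; the minimiser of this
piecewise-linear objective is searched over data points and adjacent-gap
midpoints, ties broken toward the circular mean, and antipodally symmetric
data (zero resultant) raise rather than return an arbitrary direction.

The multi-sample test is Fisher's nonparametric common-median test: pool,
find the pooled circular median, count per group the angles on the
clockwise half-circle (signed deviation < 0), and refer
P = N²/(M(N−M)) Σ mᵢ²/nᵢ − NM/(N−M) to χ²(k−1).  It is the circular
analogue of Kruskal–Wallis and matches the multi-sample median test of the
standard circular toolbox.

Post hoc pairs use the two-sample Kuiper statistic
V = max(F_a − F_b) + max(F_b − F_a) over circular ECDFs (rotation
invariant; simultaneous jumps at cross-sample ties).  P-values default to
seeded label permutation — exact up to Monte-Carlo error, with the
add-one estimator (1 + #{V* ≥ V})/(n_perm + 1) — vectorised across
permutations; Stephens' asymptotic approximation is available.  The
pairwise family for FDR adjustment is the six genotype pairs within one
cell class; each class is its own family.  Benjamini–Hochberg is the
standard step-up (delegated to statsmodels, verified against a plain-loop
oracle).  Post hoc tests run only after a significant omnibus.

Mean-direction confidence intervals use the standard dispersion-based
large-sample interval (the circular-toolbox formula, with the r ≥ 0.9
variant), raising when the resultant is too small for the interval to
exist.

## Linear statistics

One-way ANOVA is the classical between/within F.  The nested ANOVA uses
sequential (genotype-first) sums of squares for unbalanced data:
SS_genotype = Σ Nᵢ(ȳᵢ − ȳ)², SS_animal = Σ nᵢⱼ(ȳᵢⱼ − ȳᵢ)²,
F = MS_genotype/MS_animal with (k−1, Σ(aᵢ−1)) df.  With one value per
animal this reduces exactly to a one-way ANOVA on animal means (verified
numerically); when all animal means coincide, F = 0 by convention.
Shapiro–Wilk screening is exposed as a thin wrapper over the standard
routine and is not part of this package's contribution.

## Synthetic sections

The generator emulates the pipeline's inputs, not confocal physics.  The
gray matter is a union of a central band and two mirrored ellipse pairs
(dorsal and ventral horn lobes), evaluated so the mask is bit-exactly
symmetric about the vertical midline; the canal is a midline disk.
Default scale: 640×640 px at 1.0 µm/px — a deliberately reduced field
(a real lumbar cord is ~3× wider) that keeps a 96-section study tractable
while preserving all geometric relationships; the pixel size is
configurable for realistic calibrations.

Cells are uniform-intensity disks (not Gaussian blobs) so the thresholded
area has a closed-form expectation; each flagged channel receives the
disk with its amplitude split across three z-planes (weights 0.25, 0.5,
0.25, so the max projection recovers half the nominal amplitude).
Background is constant (2000) plus an optional smooth linear gradient;
Gaussian noise is per-voxel; everything is clipped to uint16.  With
amplitude 20000, noise sd 2000 gives a projected SNR of 5 — the
moderate-noise verification regime.

Six default populations (~200 cells/section, drawn per section from a
Poisson clipped to ±20% of the mean) mimic the marker biology: large
ventral-horn ChAT⁺ motor neurons (26–38 µm), peri-canal ChAT⁺
interneurons, a ChAT⁺/GAD-67⁺ lamina-X-like population, broadly
distributed GAD-67⁺ cells, and dorsally weighted Parvalbumin⁺ and
Calbindin⁺ cells with configured co-expression fractions (PV∩GAD 30%,
PV∩CB 20%) assigned to exactly round(fraction × n) cells.  Angular laws
are bilateral von Mises mixture pairs (µ and 180° − µ), so raw sections
are statistically symmetric and the laterality mirror folds each pair
onto its right-side mode.  Note that folding changes the mean: the
mirrored distribution of a bilateral pair is the fold of the right
component about the vertical axis, whose mean is pulled toward the
horizontal axis at moderate κ.  Recovery checks therefore compare
detected angle statistics with the realised ground-truth angles rather
than with the nominal component µ.

Placement is rejection sampling in polar coordinates (angle from the
mixture, depth from a uniform or beta law on the canal-to-boundary
fraction), with a 100-attempt budget per cell.  A candidate must fit
entirely inside the gray matter (edge-depth margin of the cell radius
plus 2 px) and clear the canal.  Overlapping placements are allowed by
default; with `enforce_separation` (used by all recovery studies), cells
sharing a channel keep a 4 µm edge-to-edge gap — rasterised disk edges
extend up to half a pixel beyond the nominal radius and the 3×3 closing
bridges binary gaps of up to 2 px, so 4 µm is the smallest gap that
guarantees components never merge while cells of disjoint channels merely
must not overlap — enough to keep spurious cross-channel colocalisation
identically zero without exceeding packing capacity.  Diameter ranges sit
strictly inside their marker windows because a disk rendered exactly at a
window bound can rasterise or despeckle to just below it.

What the generator does **not** emulate: point-spread functions, tile
mosaic artefacts, intensity heterogeneity within somata, touching-cell
clumps beyond what the separation flag allows, anatomically exact laminae.
Passing recovery tests therefore demonstrates correctness of the
measurement chain, not robustness to every property of real tissue —
segmentation quality on real images still depends on staining and imaging
quality.

## Verification experiments and problem sizes

The `verify` module and `scripts/acceptance.py` run, from scratch:
noise-free and SNR ≈ 5 full studies (4 × 3 × 8 = 96 sections, ~205
cells/section) checking exact count/colocalisation recovery, sub-pixel
centroid error, and pooled mirrored-mean agreement with ground truth
within 3°; type-I calibration of the common-median and permutation-Kuiper
tests (1000 uniform-null replicates, n = 50/group, nominal α = 0.05);
a brute-force Benjamini–Hochberg comparison over all 2⁸ sign patterns of
an 8-p-value fixture; and the sensitivity run — a 7.5° shift of one
genotype's population at pooled n = 2000/group and κ = 2.4 (the
concentration implied by the observed circular variances ≈ 0.25),
detected when the omnibus test and all three shifted-genotype Kuiper
pairs reach q < 0.05, over 20 seeded replicates, alongside matched null
count and distance layers.  Study-level permutation counts default to
n_perm = 2000 (p-resolution 5 × 10⁻⁴, ample for q < 0.05 decisions over
six pairs); the API default for a single Kuiper call is 10⁴.

## Numerical conventions and degenerate inputs

- Histogram thresholding requires ≥ 2 distinct in-mask values; constant
  channels raise a degenerate-histogram error.
- Empty particle lists are valid (a marker may be absent); empty masks,
  empty angle samples and coincident cell/canal centroids raise.
- The circular mean requires R̄ > 10⁻⁹; the CI additionally requires the
  dispersion condition 2R² > n·χ²₁(level).
- Determinism: every random draw descends from a single seed via
  `numpy` SeedSequence spawning; re-running a study with the same config
  reproduces byte-identical CSV tables (hashed in the run log).

## Known limitations

- No watershed: touching same-channel cells merge and are then usually
  rejected by the size window — an undercount mode under crowding.
- The nested-ANOVA weighting for unequal cells per animal follows the
  sequential decomposition above; other weightings exist and give
  slightly different F values in unbalanced designs.
- The common-median test's χ² reference is asymptotic; at n ≈ 10 per
  group its p-values are approximate (the permutation cross-check in the
  tests bounds the discrepancy).
- The three distance-normalisation variants genuinely differ; analyses
  should state which was used.  `radial_fraction` is the default because
  it alone matches the "0 at canal, 1 at edge" semantics.
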