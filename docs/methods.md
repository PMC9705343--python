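# Methods

This note documents the models, conventions and numerical choices behind
`cardioscar`, and what the synthetic-data generators do and do not emulate.

## Scar mapping from LGE-CMR

**Model.** Scar is defined on the z scale of a remote healthy-myocardium
reference ROI: `z = (I − μ_remote)/σ_remote` per wall voxel (sample mean and
SD of the supplied ROI, ddof = 1).  Labels are healthy myocardium (HM,
z < 2), heterogeneous tissue (HT, 2 ≤ z < 3) and dense scar (DS, z ≥ 3);
boundaries are inclusive on the scar side.  The remote ROI is an explicit
input — automatic remote detection is out of scope, and the generators emit
a suitable ROI.  Normalization requires ≥ 30 ROI voxels and a non-degenerate
SD, and is invariant to any affine intensity rescaling `I → aI + b, a > 0`.

**Wall halves.** The wall is the set of voxel centers inside the epicardial
and outside the endocardial contour polygon of their slice.  Each wall voxel
joins the half whose bounding contour is nearer (in-plane polygon
distance); exact ties go to the endocardial half.  The partition is exact:
`endo_half ∪ epi_half = wall`, intersection empty.

**Surface projection.** Each contour stack becomes a triangulated surface:
rings of `n_theta` nodes resampled by polar angle around the slice centroid
(valid for star-shaped contours), stitched between slices, with duplicate
boundary rings closing the half-slice gaps at the stack ends so the surface
spans the full covered wall height.  Node area is barycentric (one third of
incident triangle areas).  Every half-wall voxel is assigned to the node of
its own slice's ring at the nearest polar angle — the discrete transmural
ray through the node — and a node's signal intensity is the mean z of its
voxels; its label follows the 2/3-SD rule.  Nodes with no voxels are
flagged unmapped and excluded from areas; stack-end cap rings inherit their
neighbor ring's values.  `n_theta` should roughly match the contour
circumference divided by the in-plane voxel size (default 64 for the
bundled phantoms); much finer sampling starves nodes of voxels.  On
noiseless phantoms compartment areas agree with analytic sector areas to
within ~5 % (one node/voxel of boundary discretization).

**Quantification.** Compartment areas are label-wise node-area sums (cm²).
Scar mass is volumetric, not surface-based: TSM = (volume of wall voxels
with z ≥ 2) × 1.05 g/ml, TMM the whole wall at the same density (standard
CMR convention).  Ventricular volumes use Simpson slice-area summation of
endocardial contours at the two cine phases; LVEF = 100·(EDV−ESV)/EDV.
Compartment areas are reported as surface areas of labeled regions (not
en-face projections) — an interpretation choice, stated here because either
reading is defensible.  Longitudinal change is
`100·(follow-up − baseline)/baseline` on scalar summaries; no image
registration between timepoints is attempted.

## Optical mapping

**Preprocessing.** Voltage dyes report depolarization as a *negative*
fluorescence deflection; polarity is detected globally (median-to-extremum
asymmetry) and corrected.  The last k beats of the drive train (default 3)
are averaged on the stimulus grid, optionally smoothed (spatial Gaussian
σ = 1 px, temporal moving average of 3 frames by default), and each pixel
is min/max normalized to [0, 1]; pixels with amplitude below 5 % of the
median amplitude are invalidated.

**Activation** is the time of maximal positive dF/dt, refined by a
quadratic fit through the three derivative samples around the discrete
maximum (ties take the earlier frame; a maximum at the window edge
invalidates the pixel).  Note that for an exactly linear upstroke the
derivative is flat and the earliest-sample rule places activation at the
ramp start; for any smooth (curved) upstroke the interpolated maximum falls
at the steepest point, e.g. the midpoint of a sinusoidal rise.

**APD80** is the first post-peak crossing of 20 % normalized amplitude,
linearly interpolated between frames, minus the activation time.  The
reference point is the dF/dt_max instant (not upstroke onset), consistent
with the activation convention.  Pixels that never recross 20 % within the
beat window are invalidated.

**Conduction velocity.** A plane `T(x, y) = a·x + b·y + c` is least-squares
fit to the activation map over a 5×5 pixel window (≥ 6 valid neighbors
required).  The gradient `g = (a, b)` (ms/mm) is the local isochrone
normal; speed is `1/|g|` (reported in cm/s, capped at 200 cm/s — faster
estimates are treated as artifacts) and direction is `g/|g|`.  Windows that
are fully valid use an equivalent separable normal-equation solution for
speed.  For noiseless planar waves the estimator is exact away from
boundaries; regional summaries use medians (means available), chosen for
robustness since the summary statistic is otherwise a free choice.
Isochrone level sets are provided for visualization and QC only.

**ROIs.** HM and HT masks are inputs (disjoint, ≥ 10 valid pixels each);
the synthetic generator provides boundary-eroded ground-truth ROIs so
regional medians are not diluted by plane-fit windows straddling the patch
rim.  Automatic HT detection from the images is out of scope.

## Voltage maps

Node amplitude is the inverse-distance-weighted (power 2) mean of all
points within the 5 mm filling-density radius; a coincident point wins
outright; nodes farther than the radius from every point stay unmapped and
never enter areas.  Classes: DS ≤ 0.5 mV, HT (0.5, 1.5], healthy > 1.5
(the upper boundary inclusive, matching the ≤ 1.5 mV total-scar rule).
Triangles are assigned whole to a class when at least two (mapped) vertices
agree, otherwise split equally; triangles with unmapped vertices contribute
only their mapped fraction.  DS + HT + healthy = mapped area by
construction.  Interior unmapped holes are excluded from areas, a stated
interpretation of how a clinical area tool may differ.

## Histology

Five-level ordinal scores map linearly to 20/40/60/80/100 %.  Per-animal
values are section-extent-weighted means per compartment and variable; the
result is invariant to a common rescaling of the extents, so extents may be
given in mm² or in counting-grid squares (the 20 mm × 40 mm / 1250-square
grid makes one square 0.64 mm²).  Vascularization uses the same five-level
scale as the other four variables.

## Exact rank tests

U (Mann-Whitney) and W+ (Wilcoxon) are computed from mid-ranks.  The null
distribution is the exact conditional permutation distribution given the
observed pooled multiset (group assignments) or the observed |differences|
(sign vectors); ties therefore need no correction.  Problems with up to
20,000 assignments are enumerated directly; larger ones use a shift
(convolution) count over doubled mid-ranks, which is exact in integer
arithmetic (int64 up to ~C(62,31), arbitrary precision beyond).  Two-sided
p is twice the smaller tail, capped at 1; zero paired differences are
dropped with a warning (the test conditions on nonzero differences).
Quantiles use linear interpolation of order statistics (R type 7).
Because the rejection region {p < 0.05} has conditional mass strictly
below 0.05, the test is conservative at any sample size; the acceptance
suite verifies ≤ 5 % empirical type-I error over 10,000 null simulations.

## Synthetic data generators

All randomness derives from one explicit seed per spec
(`numpy.random.default_rng`); identical spec + seed gives bit-identical
output, and noise is a fixed unit-variance field scaled by `noise_sd`, so
raising the noise level on the same seed degrades recovery monotonically.

**CMR phantom.** An annular wall (circle-in-circle per slice, the simplest
geometry that exercises the endo/epi-half semantics) on a configurable
grid (default 48×48×6 voxels of 1.5×1.5×5 mm).  Remote-wall texture is
Gaussian and the designated remote ROI is standardized so its sample mean
and SD are *exactly* the configured values — a noiseless scar region at
offset k SD then scores exactly z = k, making threshold tests sharp.  Scar
regions are angular sectors over a slice range confined to a transmural
compartment.  The generator derives its wall masks from its own contours
with the same rule as the analysis, so construction and recovery agree up
to discretization.  No MRI physics, partial-volume or motion effects are
modeled.

**Optical movies.** Travel times are slowness-weighted shortest paths
(fast-marching style, 8-connected geometric metric), so a slow HT patch
bends isochrones; within the patch |∇T| equals the local slowness, which is
what the CV estimator measures.  The action-potential template has a linear
upstroke centered on the activation instant and a half-cosine
repolarization scaled so the 20 %-crossing falls exactly APD80 after
activation — activation, APD80 and speed ground truth are closed-form.
Polarity is inverted by default to force the preprocessing to handle dye
sign.  The default pixel size is 0.5 mm: a mapped-tissue scale consistent
with macroscopic wavefront imaging (the physical camera pixel pitch is a
sensor property, not the tissue sampling).  The grid metric overestimates
off-axis path lengths by up to ~8 %, so specs aimed at quantitative CV
recovery should use edge-origin (near-planar) propagation, as the bundled
studies do.  No ionic or bidomain dynamics, motion, or photon statistics.

**Voltage maps.** An LV-like ellipsoid (icosphere scaled to 25×25×35 mm)
with mapping points at every mesh vertex, guaranteeing the 5 mm fill rule.
Patch cores draw amplitudes from their class range; each rim follows a
deterministic profile — a steep ramp through the class threshold flanked by
plateaus value-symmetric about it out to the fill radius — which pins the
interpolated threshold crossing to the patch radius, so measured areas are
stable (< 2 %) under mesh refinement.  A consequence is a thin
border-zone ring around dense-scar patches, which is also physiologic.
Ground-truth classes are defined by the amplitudes themselves and
ground-truth areas by the same triangle rule, so the quantity under test is
the interpolation + thresholding, not the area bookkeeping.

**Histology tables.** Categorical draws per section/variable/compartment
from configurable five-level distributions with uniform section extents;
ground-truth per-animal means apply the weighting formula directly.

What passing on these generators does *not* show: robustness to real-world
segmentation error, partial volume, motion or fluorescence heterogeneity,
non-annular anatomies, or catheter sampling bias — the generators emulate
the measurement geometry and noise, not the acquisition physics.

## The two-arm study

Per animal: baseline and follow-up CMR phantoms implementing the arm's
remodeling rule (control: a fraction — default 0.8 — of the epicardial HT
sector converts to DS while HT keeps its width; treated: the HT sector
widens — default +50 % — with stable DS; endocardial sectors grow ~45 % in
both arms), one optical movie with arm-specific HT electrophysiology
(treated CV ratio 0.80 / APD ratio 1.12; control 0.517 / 1.40, chosen so
the arm medians of (HT−HM)/HM fall near −20 %/+12 % vs −48 %/+40 %), and a
histology table with arm-specific epicardial score distributions.
Per-animal multiplicative jitter (~6 %) on geometry, fractions and ratios
provides biological variability.  All seeds fan out deterministically from
one top-level seed via `SeedSequence.spawn`.

Analysis stages receive only data (volumes, contours, ROI masks, movies,
tables) — never the arm label, which is attached at the statistics stage
(the blinding analog).  Endpoints: ΔEnHT, ΔEnDS, ΔEpHT, ΔEpDS, ΔCV, ΔAPD
and five histology variables × two compartments, each compared with the
exact Mann-Whitney test and summarized as median (IQR).

**Problem sizes.** The default study uses 40×40×6 CMR grids and 32×32
optical movies at 2 ms framing (a full 19-animal study in a few seconds);
the null-calibration replicates use 28×28×4 grids and 24×24 movies at 3 ms.
These are deliberate desk-scale settings: endpoint contrasts live in
relative changes and regional medians, which these grids resolve, and the
chosen sizes keep 200-replicate calibrations practical.  The sector-width
quantization of coarse grids produces tied Δ values across animals, which
the exact tests are specifically built to handle.

## Known limitations

* Surface-area semantics for CMR compartments (vs en-face projection) and
  voxel-level TSM thresholding (vs post-projection) are documented
  interpretation choices.
* The angular node binning assumes star-shaped contours; strongly
  non-convex walls would need a true ray casting.
* CV estimation near patch rims mixes speeds within the fit window; ROI
  erosion by the window radius is required for unbiased regional medians.
* The EAM area rule quantizes at triangle scale; meaningful comparisons
  need patches an order of magnitude larger than a triangle.
* Exact tests are conservative under heavy ties (attainable levels well
  below 0.05), which is the safe direction for small-n inference.
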