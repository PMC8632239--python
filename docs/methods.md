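# Methods

## Phantom geometry

Each phantom is defined analytically in a right-handed RAS millimeter
frame (x right, y anterior, z superior; voxel indices 0-based with the
center of voxel (0,0,0) at the grid origin; NIfTI affines encode this
exactly).

The tumor is a union of ellipsoids: a maxillary body (semi-axes
16 × 15 × 14 mm centered at (10, 6, 0)) plus one posterior lobe whose
center moves posteriorly and whose size grows from S1 to S4, emulating
increasing posterior extension. The internal carotid artery (ICA) is a
2.5-mm-radius tube swept along a natural cubic spline through four
control points running superiorly with a slight posterior bow at both
ends, so its closest approach to the tumor happens mid-height, away
from the tube end caps. A bone surrogate (ellipsoid shell, outer
semi-axes 58 × 68 × 60 mm, 4 mm thick) carries six fiducial divots.

**Clearance calibration.** The tube is the radius-offset of its
centerline, so the tumor-to-carotid surface clearance equals
(minimum distance from the centerline to the tumor surface) − radius.
Point-to-ellipsoid distances are computed exactly from the Lagrange
formulation of the nearest-point problem (vectorized bisection on the
multiplier; ~1e-14 relative precision), and the centerline is
translated posteriorly by a scalar found with Brent's method until the
clearance matches the preset value to 1e-6 mm. The independent check —
closest-point distance between the triangulated surfaces — agrees to
within ~0.007 mm (facet chord error), comfortably inside the 0.1-mm
acceptance band.

## Volume synthesis

Voxel occupancy is the exact analytic inside test at voxel centers.
Material intensities (arbitrary units): background 0, bone 400,
fiducial 500, tumor 800, ICA 1000 — tumor and vessel deliberately
exceed bone, as the physical materials did on CBCT. Overlap priority
ICA > tumor > fiducial > bone guarantees the vessel is never erased.
Optional additive Gaussian noise emulates acquisition noise; the
generator makes no attempt at CBCT physics (no projections, beam
hardening, or scatter), so segmentation results on these volumes bound
only the pipeline's algorithmic behavior, not clinical contouring
difficulty.

## Imaging chain

- *Segmentation*: global threshold (default: midpoint of the bone and
  tumor intensities) followed by morphological closing then opening
  with a Euclidean ball — the deterministic surrogate for the manual
  smoothing a human operator would do; the radius is exposed
  (default 1.6 mm) and small components can be dropped.
- *Morphology*: all ball-shaped structuring elements are realized by
  thresholding the Euclidean distance transform, so mm radii are
  isotropic rather than tied to an iterated 3×3×3 neighborhood.
- *Surfaces*: marching cubes at the 0.5 occupancy level on the
  zero-padded mask (always watertight); vertices in world mm.
- *Signed distance*: EDT(outside) − EDT(inside) at voxel centers,
  negative strictly inside; values at arbitrary points by trilinear
  interpolation, with out-of-bounds samples raising rather than
  truncating. The zero level sits at the voxel-center sign change; the
  ≤ half-voxel bias this implies is absorbed by the stated tolerances.
- *Alert cloud*: the proximity shell is the Euclidean-ball dilation of
  the vessel mask minus the vessel. Because the voxel EDT measures
  center-to-center distance — which exceeds distance to the vessel
  *surface* by about half a voxel — the dilation radius is
  margin + spacing/2, so the realized shell sits at the nominal margin
  from the surface (measured 1.81 mm on the 2.5-mm cylinder benchmark
  and 1.92 mm around the S2 carotid, for a 2-mm margin at 0.8-mm
  voxels, both within the half-voxel tolerance).

## Registration

Paired-point rigid registration is the closed-form SVD (Kabsch)
solution with the standard reflection guard; FRE is the RMS residual
(the usual fiducial-registration-error convention; the alternative mean
residual is strictly smaller, so RMS is the conservative gate). Six
divots by default (configurable); the acceptance gate is 1 mm. With
0.25-mm isotropic localization noise the expected FRE is
σ·sqrt(1 − 2/N) ≈ 0.20 mm, and the maximum over 100 runs stays well
under the gate.

## Cutting-plane analysis

The plane contains the pointer tip and shaft axis; roll fixes the
lateral axis and hence the normal. The isolated area is a
floor(30/0.5)+1 × (2·floor(5.5/0.5)+1) = 61 × 23 lattice (0.5-mm step;
the sampling density is a package choice, exposed in
`PlaneSamplingSpec`, since only the 30 × 11 mm extent is prescribed by
the protocol being modeled).

**Boundary conventions.** The protocol's verbal rules leave d = 2, 5
and 10 mm ambiguous ("<2", ">2", "5–10", ">10"). One convention is
applied everywhere and recorded in run metadata: an adequate carotid
distance is strictly > 2 mm (so d_ICA = 2 is orange), and the 5–10 mm
tumor band is closed (d_tumor = 5 and 10 are both G). The nine zone
codes then partition the (d_ICA, d_tumor) plane exactly; this totality
and exclusivity is property-tested on 10^6 pairs including boundary
values.

Plane-level flags derive from the raw distances, not the codes:
intratumoral ⇔ min d_tumor ≤ 0; exactly one of damaged
(min d_ICA ≤ 0), danger (min d_ICA ≤ 2, none ≤ 0), adequate holds.
The tip-level alert (breach / proximity / clear) mirrors the sonic
alarms and is consistent with the zone code at the tip (breach ⇔ R).
The whole-plane breach flag, not the tip alert, drives the
carotid-guided resampling, since a plane can cross the vessel far from
the tip.

## Behavior model

Human placement is emulated, not reproduced. The *ideal* plane for a
margin portion is the mid-gap plane of the local tumor–carotid
corridor: within the portion's z-band (an 18-mm band above or below
z = 0, standing in for the split at the nasopharyngeal vault, which has
no synthetic counterpart), the carotid centerline point with the
smallest tumor clearance defines the common normal; the plane sits
halfway across the gap with its normal along it, shaft in-plane toward
the portion. On every preset this plane clears both structures by half
the local clearance — the zero-noise invariant the tests check.

Noise: rotations ~ N(0, rot_sd²) about the two in-plane axes and a
translation ~ N(0, trans_sd²) along the normal. Default calibration:
unguided 8° / 3 mm, guided 4° / 1.5 mm — guidance halves the placement
error; carotid-guided adds resampling of breaching poses (up to 5
redraws, modeling the breach alarm; an exhausted budget returns the
last pose flagged). Per-surgeon heterogeneity is a multiplicative
LogNormal(0, 0.25²) factor on both SDs. These numbers are stated
defaults chosen to give plausible error magnitudes at the phantom
scale; **no numeric claim about human performance rests on them** —
every assertion about simulated behavior is ordinal (guided better
than unguided), and the absolute zone percentages of the simulation
(e.g. its large blue fraction, from the 30-mm strip extending beyond
the corridor) are not comparable to human data.

The study runner is a full factorial (surgeon × preset × setting ×
portion × replicate) with one named seed substream per cell, so runs
are bit-reproducible and changing the surgeon count does not perturb
other cells. Plane distances come either from the analytic geometry
(default; exact) or from voxel distance fields (the imaging-pipeline
route); the two agree on plane-level flags except for rare borderline
planes within voxelization error.

## Statistics

Zone comparisons operate on plane-level percentages (one value per
delineation), matching a report structure of per-category means with
one p-value per row; comparing pooled raw point distances instead is
possible but not what the row-wise tests describe. Kruskal–Wallis uses
the tie-corrected H; the p-value reference is chi-square (k−1 df) by
default, with a seeded permutation option that is preferable for small
groups, where the chi-square approximation deviates by more than
Monte-Carlo error. The all-pairs post-hoc follows Steel–Dwass:
pairwise tie-corrected standardized rank sums referred to the
studentized range with k groups; an exact variant enumerates the
permutation distribution of the maximum pairwise statistic (the
single-step max-T adjustment the asymptotic reference approximates)
and is used for small samples. Flag counts use the Freeman–Halton
exact test (full enumeration of tables with the observed margins).
Significance is reported at α = 0.05 with no multiplicity correction
beyond the Steel–Dwass procedure itself. The gain pools the two guided
settings and is the per-surgeon difference in the rate of clear-margin
(and carotid-spared) planes versus unguided.

## Problem sizes and numerical choices

Default acquisition grid 256 × 256 × 192 at 0.8 mm; tests and the
bundled analyses use a compact 160 × 184 × 160 field of view that still
contains the whole phantom, and the bundled study runs 8 surgeons × 4
phantoms × 3 settings × 2 portions × 10 replicates (1920
delineations). Distance-field interpolation is trilinear; mesh
clearance measurements shortlist candidate vertices with a KD-tree and
resolve them with exact point-triangle distances; all random number
use flows from explicit seeds through named substreams.

## Known limitations

- No skull anatomy, nasal corridor, endoscope optics, or CBCT physics;
  phantom realism is limited to controlled clearances and contrasts.
- The behavior model is a two-parameter Gaussian perturbation; it has
  no learning, no approach choice, and no exposure failures.
- Interior signed distances of the tumor *union* report distance to the
  nearest component surface, which understates depth inside overlap
  regions (the zone logic only uses the sign there).
- The exact Steel–Dwass variant is limited to small samples by
  enumeration cost.
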