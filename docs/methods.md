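# Methods

## Eye model and projection

The eye is treated as a perfect sphere whose diameter equals the measured
axial length (AL), so `R = AL / 2` mm.  This is the model's central
assumption and its central correction: conventional 2D analyzers fix AL at
24 mm, which misstates every physical distance in proportion to the true
AL.  Eyes outside 20–27 mm are rejected by default (`check_range=False`
overrides) because very long eyes are frequently staphylomatous and violate
the spherical assumption; the package makes no attempt to model aspheric or
staphylomatous globes.

Image-to-sphere mapping is an inverse stereographic projection: center of
projection at the anterior pole, image plane tangent at the posterior pole,
`rho = 2 R tan(theta / 2)`.  The true raster-scan optics of UWF devices are
proprietary and unpublished, so the frame is calibrated by field of view
instead: the image circle of radius `min(width, height) / 2` px is assumed
to span the device FOV (default 200°, configurable), giving
`scale = radius_px / (2 R tan(FOV / 4))` px/mm.  Stereographic projection
was chosen because it is the standard conformal choice for fundus work and
is self-consistent under the package's own forward/inverse pair; all
downstream guarantees (exact AL scaling of distances, AL-invariance of
angles, round-trip identity at machine precision) hold for any radial
calibration of this family.

Whether published distance values of this kind are chords or geodesics is
rarely stated; spherical triangulation implies arcs, so geodesics are
implemented: `d = R · atan2(|p×q|, p·q)`, numerically stable at both ends of
the range.  Vertex angles are angles between great-circle tangents; polygon
areas use the Van Oosterom–Strackee signed solid angle over a fan
triangulation.  Unit vectors within 1e-6 of unit norm are renormalized,
anything farther is rejected.

Coordinate frame: +z anterior, −z posterior pole, +y superior (image-up),
+x temporal-in-image for right eyes.  Left eyes can be mirrored
horizontally with `FundusFrame(mirror_os=True)`; sector assignment itself
depends only on the fovea–disc axis and is laterality-neutral.

## Montage

A gaze change rotates the globe, so registration is solved as a rotation on
the sphere rather than a 2D warp: landmarks are reverse-projected and the
Wahba problem is solved by SVD (Kabsch, determinant forced to +1).  Each
off-axis view is paired with the on-axis view through the optic disc plus
five vascular bifurcations, one per 40° region between auxiliary directions
−10°…190° (regions are half-open, lower edge closed; ties at wedge
boundaries are snapped to the lower-closed edge within 1e-9 degrees).  A 2D
affine least-squares fit on the raw pixels is retained as a comparison path
for workflows that align in the image domain.  Nominal gaze rotation
defaults to 35° up/down and is used only for initialization/validation —
the working estimate always comes from the landmarks.

Composites are stored equirectangularly (colatitude × longitude, default
0.1°/bin).  Overlaps are resolved by nearest-own-view-center priority with
no feathering, so measurements never read interpolated seams.

## Enhancement (stand-in)

The choroidal-vessel enhancement used on real montages in the source
workflow is unpublished; the module ships a deterministic stand-in with the
same role: long-wavelength channel selection → wide median-filter
background removal (kernel ≈ 1/8 image width) → CLAHE → [0, 1]
normalization, with every step and parameter recorded in a provenance list
so the original can be slotted in.  The pipeline is invariant to input gain
and offset up to normalization.  Binarization is Otsu by default (vessels
dark); note Otsu assumes reasonably balanced classes and will overestimate
sparse vessel area on noisy rasters — use a fixed threshold there.

## Localization and measurement

The ampulla center is the point minimizing the summed squared perpendicular
distances to the annotated inflowing-vessel lines (closed-form normal
equations; exact intersection for two lines; all-parallel within 0.5° is an
error).  Lines are intersected in the 2D image domain of the view where the
ampulla is most central and the result reverse-projected — matching how
graders draw on images — with the on-sphere transfer handled by the
estimated view rotation.

Sectors come from the signed angle at the disc between the disc→fovea
direction and the disc→ampulla direction, positive toward superior:
[0°, 90°) → UL, (−90°, 0°) → LL, [90°, 180°] → UN, (−180°, −90°] → LN.
Boundaries are half-open for determinism.  Two vertex conventions exist for
the fovea/disc/ampulla angle; the disc vertex is the default (it is the
angle sectorization is built on) and the ampulla vertex is a named variant.
Empty sectors contribute no rows to distance means (NaN, never zero).

## Statistics

Friedman (k = 4 matched sectors), Wilcoxon signed-rank (zeros dropped, ties
mid-ranked), and Mann–Whitney U are all two-sided at α = 0.05 with Holm
correction within each family of pairwise contrasts.  Exact p-values: full
`(k!)^n` enumeration for Friedman (guarded, practical to n ≈ 6–8 at k = 3–4),
sign-assignment convolution for Wilcoxon (n ≤ 25, valid under ties), and
arrangement enumeration for Mann–Whitney (min(n) ≤ 10); larger samples use
tie-corrected normal/χ² approximations.  ICC defaults to ICC(2,1) — two-way
random effects, absolute agreement, single measurement — computed from
ANOVA mean squares, with ICC(1) and ICC(3) and average-measure forms
selectable; repeatability across occasions/raters is the intended use.
Stepwise regression is bidirectional by AIC starting from the full model
(AIC knowingly admits a spurious term with probability ≈ P(χ²₁ > 2) ≈ 0.16
per noise variable); a p-value-threshold variant (enter 0.05 / remove 0.10,
starting empty) is provided for stricter selection.

## Phantom generator

The generator encodes the normative study conditions as defaults:

| parameter | default | note |
|---|---|---|
| n eyes | 74 (37 M / 37 F) | balanced split |
| axial length | N(24.92, 1.11²) mm, truncated [22.47, 26.97] | |
| quadrant counts (UL, LL, UN, LN) | men: 2.00/2.19/2.30/1.95; women: 1.68/2.05/2.08/1.95 | rounded truncated normal, min 0; sex means average to 1.84/2.12/2.19/1.95, total 8.10/eye |
| quadrant distances | 14.04/15.55/13.29/13.66 mm, SD 1.12/1.31/1.03/1.20 | clipped to (5 mm, πR) |
| distance–AL slope | 0.37 mm per mm AL | residual SDs shrunk so marginal SDs stay nominal |
| disc position | 15° nasal of the posterior pole | fovea at the pole; both configurable |
| gaze rotation | 35° up/down | |
| on-axis gradeable field | 140° full angle | calibrated so the on-axis yield fraction matches the normative on-axis/montage count ratio |

Counts use rounded truncated normals rather than Poisson because the
reported per-quadrant SDs (~0.6 at means ~2) are far sub-Poissonian.
Azimuths are uniform within each quadrant's angular range — the true
within-quadrant angular distribution is unknown, and this is the flagged
assumption most likely to differ from real eyes.  Ampullae are placed so
the *true geodesic* disc distance follows the quadrant distribution, which
makes the full chain exactly identifiable: generate → annotate → register →
localize → measure reproduces every distance to < 1e-12 mm without noise,
and `degrade()` adds Gaussian pixel jitter and binomial ampulla dropout for
noise studies (median distance error < 0.3 mm at 0.5 px jitter).

What the phantom does **not** emulate: real vessel appearance and contrast,
media opacities and eyelash artifacts, grader bias in line placement
(jitter is isotropic and unbiased), eccentricity-dependent annotation
error, non-spherical globes, and any correlation structure between counts
and distances.  Passing phantom tests therefore demonstrates correctness of
the geometry/measurement chain under the stated conditions, not clinical
performance on real images.

## Problem sizes and numerics

The validation suite uses 10,000-eye cohorts for parameter recovery (3-SE
bounds on the recovered means), 200 replicate 74-eye cohorts for the
Friedman power check, 100 Monte-Carlo seeds for rotation recovery under
0.5 px jitter, and 10⁴ pixels for the projection round trip — sizes chosen
so every Monte-Carlo bound is comfortably inside its sampling error.  Exact
enumeration oracles are limited to the sample sizes where full enumeration
is feasible (2⁶–2⁸ sign assignments, (3!)⁴ orderings, C(10,5)
arrangements).  Known degenerate inputs — anterior-pole projection,
coincident axis points, all-parallel vessel lines, all-zero paired
differences, constant images, zero between-subject variance — raise typed
errors or warnings rather than returning silent garbage.
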