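# Methods

## Geometry

**Cornea.** The anterior corneal surface is a conicoid,
`z(r) = r² / (R + √(R² − (1+Q) r²))` (sag in mm, posterior positive, apex at
the origin), with apical radius `R` and asphericity `Q`. Group defaults:
regular/myopic `R = 7.8 mm, Q = −0.25`; keratoconic `R = 6.6 mm, Q = −0.50`
plus a Gaussian cone bump (default 40 µm amplitude, σ = 1.5 mm, centred
1 mm inferior — the typical inferior-paracentral cone location);
post-keratoplasty `R = 7.6 mm, Q = −0.20` plus band-limited random
irregularity (sum of low-order `(r/6)^n cos(mθ+φ)` modes, n ≤ 4, m ≤ 3,
normalized to a 25 µm RMS over the 12-mm disc, drawn from a seed).
Perturbations protrude anteriorly and therefore *reduce* the local fluid
gap. They are deliberately not re-anchored at the apex: the lens is
referenced to the unperturbed conicoid (see below), so a central cone
reduces the central clearance by its full amplitude, which is the
physically meaningful behaviour.

**Lens.** The back surface is a spherical optic zone (BOZR, default
7.60 mm within the 6.90–8.45 mm range; optic-zone semi-diameter 4 mm)
continued by a slope-matched quadratic periphery scaled so the sag at the
lens semi-diameter equals the sagittal height (default 4000 µm; group
defaults 3800/4000/4200 µm for regular/keratoconic/post-graft cohorts,
within the 3800–4800 µm fitting range; diameter 15.6 mm, centre thickness
300 µm). Only the back surface matters for the reservoir, so a two-zone
analytic surface stands in for the four-zone commercial design. Vertical
asymmetry is produced by the default inferior decentration of 0.3 mm plus
0.5° of tilt about the horizontal meridian; both are configurable.

**Gap.** The lens rests on its scleral landing zone, so its axial position
is fixed relative to the *conicoid*: the clearance over the conicoid apex
equals `apex_clearance_um` (default 300 µm, the middle of the 200–400 µm
fitting target). The geometric reservoir is
`gap(x,y) = z_cornea − z_lens ≥ 0`; negative clearance anywhere inside the
12-mm disc raises a lens-touch error.

## Ground-truth fields and cohort calibration

A cohort's true thickness field is the geometric gap multiplied by a smooth
polar control field (3 annulus rows × 8 sector columns; periodic linear
interpolation in angle, quadratic interpolation across control radii
1.0/3.5/5.5 mm, angular variation tapered to its mean inside 1 mm so the
field is continuous at the apex). The control values are calibrated by
iterative proportional fitting until the field's 17 region means equal the
programmed targets on the same quadrature the measurement pipeline uses
(convergence < 10⁻³ µm, typically ~30 iterations).

Two shaping choices temper the raw geometry:

- **Shape tempering** (default 0.5): deviations of the geometric gap about
  its disc mean are halved before calibration. The raw conicoid-vs-lens gap
  under the default decentration/tilt reaches near-touch extremes at the
  superior periphery that a clinically fitted lens would not show; the
  tempered field keeps the smooth, decentration-driven shape while bounding
  the pointwise spread.
- **Free-region targets**: where a cohort's trajectory is anchored at named
  regions (e.g. superior mid-periphery and inferior periphery), the
  remaining baselines follow the tempered geometric shape through an
  affine-plus-curvature map, and free regions share one fractional
  reduction, with both solved so the 17-region mean reduction and mean
  percent reduction equal the programmed cohort means exactly.

**Settling.** Region trajectories follow
`T_r(t) = C_r + (T0_r − C_r) e^(−t/τ)` with τ = 120.7 min (which puts
~73 % of the 4-h change inside the first 2 h — the closed form is
`1/(1+e^(−120/τ))` and is independent of the plateau) and per-region
plateaus implied by the programmed 0- and 240-min targets. The field at
each time point is re-calibrated to those targets, so region means stay
exactly on-curve.

**Between-eye variability.** Each eye scales the group field by
`f_e(t) = 1 + a_e + (b_e − a_e)·s(t)`, where `s(t)` is the settling
progress and `a_e, b_e ~ N(0, 0.04)` are baseline/endpoint deviations — a
4 % scale SD reproduces a ±3-percentage-point spread in per-eye percent
reductions at a 47 % mean. By default the drawn deviations are re-centred
so their cohort mean is exactly zero: cohort means then equal the
programmed trajectory by construction and recovery experiments measure the
*pipeline's* error rather than Monte-Carlo sampling noise; set
`center_cohort=False` for fully independent draws. Eyes also vary in
apical radius (SD 0.1 mm) and, for post-graft eyes, in their irregularity
seed; these affect the rendered images but not the programmed gap truth,
which is stored per eye per region. Laterality alternates OD/OS so the
nasal/temporal mirroring is exercised routinely.

## Rendering

Frames are 512 × 512, 16 mm wide (31.25 µm lateral pitch) with a default
axial pitch of 15 µm of optical path per pixel — the axial pitch is an
instrument property that the pipeline reads from metadata, so it is
configurable rather than hard-coded. Row positions encode optical path
(`row = margin + z · n_fluid · 1000 / axial_pitch`), so the ridge
separation in pixels is `gap · n_fluid / axial_pitch` exactly. The two
boundaries render as Gaussian ridges (σ = 1.3 px) with distinct contrast —
epithelium 0.9, lens back surface 0.65 over a 0.08 background — mirroring
the brighter specular return of the epithelial surface; distinct contrast
also makes the two-ridge correspondence well-posed for any segmenter.
Boundaries are rendered for |s| ≤ 6.3 mm (beyond the limbus there is no
reservoir); speckle is multiplicative gamma noise with shape `1/cv²`
(default cv = 0.3), and `noise_level = 0` is exactly noise-free.
Boundaries leaving the image raise a field-of-view error.

## Segmentation

Deterministic and classical: Gaussian smoothing (σ = 1.2 px), intensity
normalization against the median background, restriction to the contiguous
column span with ridge evidence, then a minimum-cost path per boundary
(cost = −normalized intensity + 0.02·Δrow² smoothness penalty, |Δrow| ≤ 8
per column, ties resolved to the smaller row). The second path is searched
strictly above and strictly below the first (6-px exclusion), keeping the
side with stronger ridge evidence — a hard one-sided constraint prevents
the second path from riding the first ridge's shoulder. Sub-pixel
refinement is a 3-point parabolic fit; columns whose ridge strength falls
below 0.25 are invalid; interior invalid runs up to 10 % of the width are
linearly interpolated; frames with under 30 % valid columns, or with no
detectable ridge pair (flat contrast), are rejected with a labelled error.
Non-square frames are resized to 512 × 512 for detection and coordinates
mapped back exactly (pixel-centre-aligned linear transform).

## Reconstruction and regionization

Thickness is measured along the A-scan direction (standard OCT practice)
as `Δrow · axial_pitch / n_fluid` with n_fluid = 1.336 (saline); ray
bending at the lens surfaces is not modelled (thin lens, near-normal
incidence over the central 12 mm). The polar map has 120 radial cells over
0–6 mm and 64 angular cells whose centres coincide with the 64
half-meridian rays, so ray-to-cell assignment is exact (nearest-ray in
angle for other layouts); within a ray, samples are linearly interpolated
in radius, and interior sampling gaps wider than ~3 native spacings stay
missing. For OS eyes angles are mirrored about the vertical meridian so
0° is nasal for both eyes. Region summaries integrate on angular
*half*-cells so the sector boundaries (odd multiples of 22.5°) fall on
sub-cell edges: region quadrature then nests exactly (partition
conservation to 10⁻⁹) while the map itself stays ray-aligned. Means are
area-weighted (`r·dr·dθ`); regions under 50 % coverage are reported
missing, never imputed. Sector labels are meridian-centred (the scheme
figure labels sectors by compass meridian); boundary angles belong to the
counter-clockwise sector.

## Statistics

Observed metrics per eye/region need only the 0/120/240-min samples:
4-h reduction, percent reduction (per eye first, then averaged — matching
the convention in which a cohort percent carries a between-eye SD), and
2-h fraction. The exponential fit is 3-parameter bounded least squares
(T0, C, τ; τ-grid initialization with linear solves for T0 and C), with a
labelled fallback to observed metrics when it fails; a two-phase decay is
deliberately not the default because five time points cannot constrain
five parameters. Meridional asymmetry is inferior-minus-superior and
nasal-minus-temporal per annulus (positive vertical = inferior thicker).

The repeated-measures ANOVA is a split-plot decomposition computed from
orthonormal contrast scores: up to two within factors (time, region) and
one between factor (group), each within effect tested against its own
subject-by-effect stratum, Greenhouse–Geisser ε = tr(M)²/(q·tr(M²)) with
M = C S Cᵀ from the pooled within-group covariance (ε = 1 exactly for
2-level factors), Bonferroni-adjusted pairwise post hocs. Sums of squares
use cell-size-weighted grand means, which coincides with Type III for the
balanced cohorts the generator produces; unbalanced between-group designs
are supported but reported as weighted-means analyses. Incomplete subjects
are dropped (complete-case) with a logged count.

## Problem sizes and determinism

Recovery experiments run the full pipeline on study-sized cohorts (30
regular eyes for the zonal trajectory; 29/35/11 eyes for the three group
trajectories) and render only the time points each quantity needs (0/240
min for reductions, plus 120 min for kinetics, 0 min alone for the
baseline extreme) — about 8 000 frames in a few minutes on one CPU. Every
random draw derives from a single master seed through `SeedSequence`
spawning; regenerated datasets and tables are byte-identical under the
same seed, and segmentation itself is seed-free.

## What the synthetic data do and do not show

The generator reproduces the measurement chain's failure modes that matter
for metrology — speckle, anisotropic pixels, boundary curvature, thin-gap
ridge merging, laterality, decentred asymmetric reservoirs, missing
columns — so passing recovery tests demonstrates the *pipeline* is
unbiased at the micrometre level under these conditions. It does not
emulate eyelid occlusion, motion artefacts, refraction through the lens,
conjunctival compression mechanics, or real instrument PSFs; accuracy
claims therefore transfer to clinical scans only insofar as those effects
are secondary. Settling is programmed as a single-exponential law, so the
kinetics experiments validate recovery of that law's parameters, not the
biological truth of single-phase settling.
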