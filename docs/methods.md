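# Methods

`hipshape` implements a 2-D landmark pipeline for the left proximal femur:
statistical shape modelling, automated geometric morphometrics,
radiographic hip-OA (rHOA) grading, per-mode association models, and
composite "OA risk shape" reconstruction. Because cohorts of this kind are
access-controlled, the pipeline ships with a synthetic cohort generator
that reproduces the statistical structure the analysis relies on; this
note records the model, the defaults, and the design decisions, in that
order.

## Landmark schema and conventions

An outline is 85 ordered 2-D points in mm: medial shaft (1–6), lesser
trochanter (7–10), inferior neck (11–14), femoral head circle (15–28),
superior head–neck junction (29–34), superior neck (35–42), greater
trochanter (43–58), lateral shaft (59–70), distal shaft (71–77), and the
superior acetabulum (78–85) with the lateral acetabular edge at point 78.
Indices are 1-based in the public API. Coordinates are x medial-positive,
y superior-positive (left hip, AP view); image-native y-down files are
flipped at read time. The head-circle set (15–28), superior-head set
(22–31), acetabular set (78–84) and edge point (78) are the anatomically
fixed sets; the neck, shaft and trochanter sets are configuration defaults
matching the synthetic template and can be overridden in a YAML schema for
other annotation conventions.

## Statistical shape model

Configurations are aligned by generalized Procrustes analysis: centring,
scale removal (centroid size 1; classical point-distribution-model
practice — absolute mm measures are always taken from the original
coordinates, never from the aligned frame), and iterative optimal
rotation to the evolving mean, to convergence (RMS mean change < 1e-10,
max 100 iterations). The converged mean is put in a canonical orientation
(principal axis vertical, farthest point inferior), which makes the
fitted model invariant to rigid motion of the whole input set rather than
invariant only up to rotation.

PCA is an SVD of the centred aligned coordinates; modes ("hip shape
modes", HSMs) are ordered by variance with a pinned sign convention (the
element of largest magnitude is positive). Numerically null directions
(singular value below 1e-9 of the largest) are dropped. Raw per-mode
score SDs and variance fractions are stored; scores are standardized to
mean 0 / SD 1 over the training cohort, and ten modes are carried into
the association stage by default. Full-rank reconstruction is lossless;
truncated reconstruction error decreases monotonically in the number of
modes.

## Geometric morphometrics

All measures operate on one configuration in original mm coordinates;
geometrically undefined cases return NaN sentinels with a diagnostic
rather than raising, so cohort runs degrade gracefully.

* **Head circle** — geometric least-squares circle through points 15–28:
  algebraic (Kasa) fit refined by Levenberg–Marquardt on the radial
  residuals; the RMS residual is reported and feeds the alpha-angle
  tolerance.
* **Narrowest neck width (NNW)** — minimum vertex-to-segment distance
  between the superior and inferior neck border polylines (polyline, not
  point-set, distances throughout: landmarks sample a continuous
  contour). Crossing borders are an error.
* **Neck axis** — the line from the head-circle centre through the
  midpoint of the narrowest-neck span; "centre of the neck" is otherwise
  undefined, and the NNW midpoint is the operational choice.
* **Alpha angle (AA)** — walk the superior outline from the head apex
  (the walk point most nearly opposite the neck axis, a frame-independent
  notion) toward the neck; the junction is the first point whose distance
  from the circle centre exceeds `r * (1 + delta)`; AA is the angle at
  the centre between the neck axis and the centre-to-junction ray.
  Default `delta = max(0.02, 3 * rms / r)`: the tolerance is tied to the
  circle-fit quality so landmark noise alone rarely triggers a spurious
  junction. Three residual SDs rather than two because the walk crosses
  several on-circle head points; at two SDs roughly one noisy subject in
  ten would "depart" on the head itself and read a pathological angle.
  The walk granularity is the landmark spacing, so AA moves in steps of a
  few degrees between neighbouring junction candidates.
* **Lateral centre-edge angle (LCEA)** — signed angle between the
  vertical through the head centre and the ray to point 78,
  lateral-positive; negative values (dysplasia) are reported, not
  clipped. By definition the measure is relative to the image vertical,
  so it is translation- but not rotation-invariant.
* **Neck-shaft angle (NSA)** — obtuse angle between the neck axis and
  the shaft axis (principal direction of midpoints of medial/lateral
  shaft points paired by nearest y).
* **Minimum joint-space width (mJSW)** — minimum vertex-to-segment
  distance between the superior-head polyline (22–31) and the acetabular
  polyline (78–84); intersecting contours give 0 with a warning.

## rHOA grading

Osteophyte areas (mm², three sites) are graded 0–3 as the number of area
cut-points strictly exceeded; mJSW is height-adjusted (least-squares
residual of mJSW on height, shifted back to the cohort mean, so the
adjusted value is uncorrelated with height but stays in mm) and graded
0–3 against descending cut-points; the total score (0–12) maps onto four
overall grades; moderate rHOA is overall grade 2 only and severe is
grade ≥ 3. Everywhere a value equal to a cut-point takes the lower grade.
The published source for the cut-points and the sum-to-grade map is
outside this package, so they are explicit configuration with defaults
chosen to separate the generator's severity classes: areas (2.5, 8, 20)
mm² per site, JSN cut-points (2.6, 2.0, 1.4) mm, and totals 0 → 0,
1 → 1, 2–3 → 2, ≥ 4 → 3.

## Association models

One model per mode and outcome, with the standardized mode score as the
single exposure (no joint all-modes model): logistic regression for the
binary outcomes and Cox proportional hazards (Efron ties) for time to
THR, under four adjustment sets — unadjusted; "model 2" (age, sex,
height, weight, white/other ethnicity); model 2 + AA; model 2 + LCEA.
Effects are OR/HR per 1 SD with Wald 95% CIs and two-sided Wald p-values.
Significance uses a strict Bonferroni threshold `p < 0.05/K` (0.005 for
ten modes). Outcomes with fewer than two events, separation, or diverged
fits yield flagged non-estimable rows, not exceptions.

Attenuation between a base and an angle-adjusted model is reported on the
excess-odds scale, `100 * (OR_base - OR_adj) / (OR_base - 1)`. The
excess-odds rather than log-odds scale is deliberate: for the canonical
pair of ORs (1.49 base, 1.19 AA-adjusted) the excess-odds scale gives
61.2% — consistent with the published "more than 60%" reading — whereas
the log scale gives 56% and fails it. The same formula covers protective
ORs through the shared excess term; a base OR of exactly 1 is undefined
(NaN).

## Composite shapes

For one outcome, every mode significant at the Bonferroni threshold
contributes `beta * raw_sd * factor * mode` to a single offset vector:
beta is the log-odds (log-hazard) coefficient per SD — coefficients, not
ORs — raw_sd the mode's non-standardized score SD (so each mode
contributes in proportion to its share of shape variance), and the
visual factor (default 5) exaggerates the offset for display only. The
factor is stored in the output metadata so rendered exaggeration is
never mistaken for physical mm. No significant modes means the composite
is the mean shape with an empty inclusion list — a finding, not an
error. Sex-stratified composites (sex-specific betas over the shared
shape model) are supported as an extension.

## Synthetic cohort generator

The generator defines the study conditions; everything downstream is
tested against it.

**Template.** A parametric left-hip outline built from geometric
primitives: head circle (r = 25 mm), neck band (half-width 15.8 mm,
NNW 31.6 mm), neck-shaft angle 135°, vertical shaft (half-width 15 mm),
hand-designed trochanter lobes, and a concentric acetabular arc 4 mm
above the head (template LCEA 36°). The superior head–neck junction has
a waist profile dipping inside the head circle and exiting it on the
neck side at 45° from the neck axis, so the template's baseline alpha
angle is 45° and a growing cam bump moves the departure point apex-ward
in steps (~45° → 55° → 67° → 81° → 97°).

**Deformation modes.** Four hand-designed unit-norm fields —
*cam_bump* (radial Gaussian bump centred on the junction),
*acetabular_coverage* (tangential rotation of the acetabular arc about
the head centre, largest at the lateral edge), *neck_width* (superior
neck border along its outward normal) and *troch_size* (trochanter lobes
inflated radially). The fields are first projected off the similarity
group (translations, rotation, scaling) so they live in the shape
tangent space — Procrustes alignment then leaves them intact to first
order and PCA can recover them cleanly — and then Gram–Schmidt
orthonormalized in order, so the cam field stays pure. Scores are
Gaussian with SDs (3.0, 2.5, 2.0, 1.5) mm (free parameters: real
per-mode score spreads are not published) and are independent by
default; an optional correlation matrix is supported.

**Landmark variation.** Isotropic Gaussian perturbation of every point
(default SD 0.35 mm — the published 1.94 mm figure is the mean
correction distance for the ~10% of images that needed correction, so
typical per-point placement error is well below it), plus extra
variability (SD 0.9 mm) of the lateral acetabular edge point alone: the
edge is the least reproducible landmark (sourcil definition, os
acetabuli), and without this term the coverage mode and the measured
LCEA are collinear at r ≈ 0.95, which makes LCEA-adjustment analyses
numerically unstable.

**Outcomes.** The subject's outline — modes plus local landmark
variation — *is* the anatomy. Its alpha angle and LCEA are computed with
a vectorized replica of the measurement stage (batched Kasa circle fit,
batched narrowest-neck midpoint, batched departure walk) and drive the
severe-type outcomes: per-SD log-odds on the standardized anatomy angles
(severe rHOA: AA log 1.6, LCEA −log 1.3; hospital HOA: log 1.7, −log 1.5;
THR log-hazards 0.35 / −0.25). Routing these effects through the realized
angles rather than the latent scores is essential: a fitted PCA mode is a
near-perfect linear readout of its latent score (r ≈ 0.98), so if
outcomes depended on the latent score directly, adjusting for the
(coarser) measured angle could not attenuate anything — the attenuation
phenomenon the adjustment analyses exist to detect would be absent by
construction. The moderate outcome keeps direct per-SD mode effects
(neck_width log 1.25, troch_size log 1.15) plus a positive LCEA effect
(log 1.2; greater coverage), and small age/sex/weight effects round out
all four models. Latent severity is sampled severe-first, then moderate
among the remainder.

Intercepts (and the THR baseline hazard, with administrative censoring
at 6 years) are calibrated by Monte-Carlo bisection on a fixed internal
sample of 200,000 subjects to marginal prevalences of 5.7% moderate,
1.7% severe, 1.3% hospital HOA and 0.6% THR; the angle reference
mean/SD used for per-SD effects are frozen during calibration so sampled
subjects stay mutually independent. Covariates follow documented margins
(age N(63.7, 7.6²) years, 47.8% male, sex-specific height/weight
normals, 96.8% white ethnicity) — defaults, not fitting targets.

**Radiographic phenotype.** Osteophyte areas are gamma-distributed
conditional on the latent class (control (0.5, 1.0); moderate
(1.5, 2.0); severe (6, 4), shape/scale in mm²), and the acetabular arc
is pulled radially inward by 0.8 mm (moderate) or 1.8 mm (severe), so
the grading stage re-derives rHOA from the generated landmarks and
areas with realistic misclassification.

**What the generator does not emulate.** Real DXA image texture and
point-placement failure modes; right hips; correlated (non-isotropic)
landmark noise along the contour; osteophytes as outline deformations
(areas are attached as numbers, not drawn into the outline); secular and
age trends in shape; and the true population's mode structure — four
named modes stand in for a continuum. Passing tests therefore show the
pipeline's statistical machinery is correct under these conditions, not
that any particular anatomical claim transfers to real cohorts.
A known, realistic artefact: the joint-space narrowing applied to cases
enters the landmark data and therefore the shape model itself, so one
fitted mode partly encodes disease — associations between that mode and
radiographically derived outcomes are partly definitional, as they can
be in real radiographic shape–OA analyses.

## Problem sizes and numerical tolerances

Test and acceptance runs use cohorts of 150–20,000 subjects (shape-model
recovery at n = 10,000 noise-free; association parameter recovery at
n = 20,000 with 200 replicates; type-I error at n = 5,000 with 1,000
replicates; adjustment-direction checks at n = 10,000), sizes at which
every check has comfortable statistical power while a full run stays in
the minutes range on one core. Geometric agreement against brute-force
oracles (dense sampling, refined grid search, scalar walks) is required
to 0.05°/0.05 mm on random cohorts and to 1e-6 on analytic cases.
Orthonormality and standardization are enforced at 1e-8; GPA converges
at 1e-10.

## Known limitations

AP-view 2-D geometry only (no 3-D alpha angle, no Dunn view); the
point-based departure rule makes AA a step function of the underlying
bump with a few-degree granularity; the exact departure tolerance and
neck-centre convention of other implementations may differ — ours are
declared, not claimed identical; grading cut-points are package defaults
pending an authoritative source; and the synthetic generator's caveats
above.
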