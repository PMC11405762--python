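# Methods

This package re-creates, at desk scale, a voxel-wise ("Imiomics"-style)
analysis of whole-body composition against cardiopulmonary exercise
test (CPET) indices. Because the underlying human data cannot be
redistributed, the package generates its own synthetic cohort — phantom
water/fat image volumes plus breath-by-breath ramp-test traces — and
runs the full analysis chain on it: CPET index computation and
inclusion filtering, deformable registration of every subject to a
common reference geometry, per-subject tissue-volume (Jacobian) and
fat-fraction maps, and mass-univariate Pearson correlation maps with
significance and cluster filtering, stratified by sex.

## Synthetic cohort

**Joint distribution.** Each subject is drawn from a Gaussian copula: a
multivariate standard normal over seven latent morphology factors
(skeletal muscle, trunk/gluteal subcutaneous fat, visceral fat, liver,
lung, heart), four tissue fat fractions, and the per-sex Gaussian
marginals of the anthropometrics and CPET endpoints (height, weight,
waist, V̇O2peak, V̇E/V̇CO2-slope, ΔV̇O2/ΔWR, RERpeak, peak-HR fraction,
lean-mass fraction). Pairwise correlations — the "planted effects" —
are configured directly on this latent scale; the matrix is validated
to be symmetric positive semi-definite before sampling. Defaults follow
the published characteristics of the 50-year-old study cohort (per-sex
means and SDs); weight–V̇O2peak correlation defaults to +0.5.

**Derived quantities.** V̇O2kg is never drawn: it is V̇O2peak/weight, so
the marginals cannot become mutually inconsistent. A correlation
requested against `vo2kg` is resolved into an equivalent V̇O2peak
correlation by first-order linearization of the ratio (exact for the
linearized ratio; realized sample correlations deviate by ~0.01–0.02 at
the cohort's coefficients of variation). Similarly, peak workload is
derived as (V̇O2peak − V̇O2 intercept)/ΔV̇O2/ΔWR with a 300 mL/min
intercept, which reproduces the published peak-workload means from the
published V̇O2peak and slope distributions. Lean mass is a per-sex
fraction of weight (defaults 0.704/0.589, reproducing the published
V̇O2lean means) plus noise; BMI is always weight/height².
Peak heart rate is a fraction (mean 0.97, SD 0.05) of the predicted
220 − age; the source cohort reports no peak-HR or lean-mass
distributions, so these are stated assumptions. Smoking prevalence
defaults to 10% purely to exercise the exclusion filter.

**Phantoms.** Bodies are nested analytic shapes painted onto a
configurable grid (default 64×48×128 voxels at 4×4×8 mm — the same
anisotropic foot–head aspect as thick-slice whole-body water–fat MRI,
at desk scale): elliptic-cylinder trunk with a subcutaneous shell and a
muscular body wall, cylinder thighs and arms with subcutaneous sheaths,
paired posterior gluteal ellipsoids, and interior ellipsoids for the
visceral depot, liver, lungs, heart, plus bone rods (femora, humeri,
spine) and a head. Liver and heart are lateralized as in real anatomy,
so the label map is mirror-symmetric only up to those organs; the body
outline is bilaterally symmetric. There is no dedicated leg-fat label:
all non-gluteal subcutaneous fat shares the `subq_trunk` class.
Compartment volume scales linearly with its latent factor at 12% per
SD (ellipsoid axes by the cube root, cylinder radii by the square
root, shell thicknesses linearly), making volume strictly monotone in
the factor. Every labelled voxel emits water and fat channels equal to
a per-tissue total signal split by the subject's tissue fat fraction
(lungs emit low signal; bone is marrow-like at FF 0.4). Shapes that no
longer fit the grid raise an error naming the compartment.

**Breath traces.** The ramp protocol is 10 W/min from 50 W (males) or
30 W (females), sampled every 2 s as a breath-by-breath surrogate, with
60 s of rest before exercise and a final plateau at peak workload
lasting one peak-averaging window (30 s). Channels are constructed so
the noise-free trace inverts exactly through the index pipeline: V̇O2
is linear in workload with slope equal to the subject's true
ΔV̇O2/ΔWR (plateau samples remain on the regression line); RER rises
linearly from 0.8 to the true RERpeak at the plateau; V̇CO2 = RER·V̇O2;
V̇E is piecewise linear in V̇CO2 with the true V̇E/V̇CO2-slope below the
respiratory compensation point (placed at 85% of peak V̇CO2) and a
1.4× steeper slope beyond it; HR ramps linearly to the true peak.
Additive Gaussian noise (defaults: 20 mL/min on both gas channels,
0.5 L/min on V̇E, 2 bpm on HR — about 1% of peak signal) models
breath-to-breath variability. No recovery phase is synthesized; no
index uses one.

## CPET indices

V̇O2peak is the maximum of the trailing rolling-mean V̇O2 (window
default 30 s, a common clinical averaging choice) over the exercise
phase; RERpeak is the maximum of the ratio of rolling means. The
V̇E/V̇CO2-slope is the OLS slope (with intercept; V̇CO2 in L/min) from
exercise onset to the respiratory compensation point, detected by an
exhaustive two-segment piecewise-linear fit in the V̇E–V̇CO2 plane
(breakpoint at minimum total RSS, accepted when the second slope
exceeds the first by a configurable factor, default 1.15); without an
accepted breakpoint the fit covers the whole exercise phase.
ΔV̇O2/ΔWR is the OLS slope of V̇O2 on workload over samples strictly
above the starting load. V̇O2kg, V̇O2lean and V̇O2HR divide V̇O2peak by
weight, lean mass and peak HR; a missing lean mass yields a missing
V̇O2lean only. Inclusion requires peak HR ≥ 85% of (220 − age),
RERpeak ≥ 1.0 (the boundary is included, reading "less than 1
excluded" strictly) and no active smoking; every exclusion carries
machine-readable reason codes.

## Registration and volume maps

Subjects are registered to a common reference phantom — the
all-zero-latent geometry with mean fat fractions. Phantom geometry
depends only on the latent factors, so the per-sex templates coincide;
sex-stratified analyses nevertheless keep separate template bookkeeping
for provenance, and pooled analyses use the shared template.

The registration is a multi-resolution symmetric-forces demons
optimisation written for this package: similarity is
sum-of-squared-differences over two equally weighted channels (the
fat-fraction image and the binary body mask), the update field is
smoothed per iteration (fluid-like) and the accumulated field smoothed
again (diffusion-like), updates are magnitude-capped, and the best
field by similarity is kept per pyramid level, guaranteeing the final
cost never exceeds the initial cost. There is no randomness; results
are bit-reproducible. Defaults: 3 levels (shrink 4/2/1), 60/30/10
iterations, field smoothing 12 mm, update smoothing 6 mm, step cap
2 mm per level-voxel-scale, and a 0.75-voxel Gaussian pre-smoothing of
the finest-level channels (coarser levels are smoothed by the pyramid
itself), which reduces voxelization noise in the force field. These were chosen on registration quality
metrics measured on phantom pairs: mean endpoint error against known
synthetic warps, volume conservation (the integral of the Jacobian
over the body mask matches the true body-volume ratio within 5%),
fold-freeness, and per-voxel correlation between the Jacobian and the
generating latent factor across factorial cohorts.

Local tissue volume is the Jacobian determinant of x ↦ x + u(x),
computed with spacing-aware central differences (one-sided at the grid
edge); it is reported in reference space for the reference→subject
mapping, so J > 1 means the subject is locally larger than the
reference. The raw Jacobian (not log J) is the default volume
correlate, mirroring the "local volume change" reading; log J is a
config toggle. Fat content is the fat fraction fat/(water+fat),
undefined where total signal is zero; subject fat maps are resampled
to reference space with trilinear interpolation (labels would use
nearest-neighbour), and any voxel undefined in any subject is removed
from the analysis mask.

**Known fidelity limit.** Interfaces between compartments with equal
fat fraction (gluteal vs other subcutaneous fat, muscle vs muscle) are
invisible to the similarity channels, so the attribution of local
volume change near such interfaces is smeared by the field
regularization. On factorial phantom cohorts the per-voxel correlation
between the Jacobian and the generating factor plateaus around
0.7–0.8 inside subcutaneous and visceral labels (lower for small deep
organs). Voxel-wise correlations with planted effects are attenuated
by roughly this factor; the original whole-body pipeline used a
purpose-built registration with stronger anatomical constraints, which
this documented substitute does not attempt to reverse-engineer.

## Statistics

At every analysis-mask voxel, Pearson's r between the per-subject map
value and the CPET index, with two-sided p from
t = r·√(n−2)/√(1−r²) on n−2 degrees of freedom. Voxels whose map
values have zero variance are undefined and excluded from both
significance masks and summary denominators. Thresholding uses raw
p < 0.05 with no multiple-testing correction, reproducing the
mass-univariate procedure; Benjamini–Hochberg FDR is available behind
a flag and never silently on. The "many adjacent voxels in one
anatomical structure" reporting rule is quantified as connected
components (26-connectivity) of at least 27 voxels, computed within
each anatomical label so a cluster never spans structures; both
numbers are configurable and logged. Males and females are analysed
separately; pooled maps are optional. Region summaries report per-label
mean r, significant-voxel share and largest intra-label cluster,
replacing visual map reading with numbers. No smoothing is applied to
the maps by default (a toggle exists), and no covariate adjustment is
performed.

Renders show significant voxels on a diverging blue–red scale
symmetric about zero in [−1, 1] (red positive, blue negative) over the
greyscale reference anatomy, with a colourbar.

## Problem sizes and numerical choices

Default problem sizes: desk grid 64×48×128 at 4×4×8 mm; cohorts of
tens of subjects for end-to-end runs; 10,000 draws per sex for
calibration checks; 1,000 subjects for index-recovery checks; planted
effect recovery uses 100 included females plus 50 included males at
the desk grid. Calibration checks use 3–4 standard errors; exact
recoveries are asserted to ~1e-8; oracle equivalences to 1e-10.
Registration raises rather than returning a folding (non-positive
Jacobian) field; the PSD check on the planted correlation matrix
tolerates eigenvalues above −1e-8; degenerate inputs (zero-variance
covariates, empty masks, empty exercise phases) raise explicit errors.

## What the synthetic data does and does not show

The generator reproduces the published marginal distributions, the
ramp protocol, and configurable cross-correlations, and its phantoms
make compartment volume exactly monotone in the latent factors, so
pipeline properties (calibration, exact closure, planted-effect
recovery, type-I control) are meaningful end-to-end checks. It does
not attempt anatomically realistic bodies, acquisition physics,
multi-echo reconstruction, registration-quality heterogeneity, or
population structure beyond Gaussian correlations — so passing tests
validate the analysis machinery, not claims about real cohorts.
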