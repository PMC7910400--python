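# Methods

## Scope and conventions

petquant analyzes (and simulates) two kinds of data: static
contrast-phantom images for image-quality metrics, and dynamic regional
time-activity curves (TACs) for reference-tissue binding
quantification. All geometry is in world millimetres with a
voxel-center convention, 0-based indices, and the axial axis along z;
concentrations are kBq/ml and assumed decay-corrected to a common time
origin (the package performs no decay correction). Frame times are
seconds; kinetic rate constants are 1/min.

## Phantom model and rasterization

The synthetic phantom is a warm cylinder (default radius 108 mm, height
186 mm, background 4.3 kBq/ml — approximately 29 MBq over the cylinder
volume) containing six spheres with inner diameters 9.9, 12.4, 15.4,
19.8, 24.8 and 31.3 mm on a 45 mm-radius circle in the central plane.
The four smallest are hot at a 3.88:1 ratio to background; the two
largest are water-filled (cold). Rasterization assigns each voxel the
volume-fraction-weighted mixture of sphere/background/outside
concentrations; fractions at surfaces are resolved by `subsample`^3
sub-voxel center counting (default 4), with voxels classified as
surely-inside/outside using a half-diagonal margin so only a thin
boundary shell is subsampled. Convergence is quadratic in practice:
ROI-level means change by < 0.2 % between subsample 8 and 16.

The scanner point-spread function is an isotropic Gaussian applied
separably in world units with zero (air) boundary conditions and a
6-sigma kernel cutoff, which conserves total activity to 1e-6 relative
as long as the phantom sits several sigma inside the grid. Realistic
widths are 2-7 mm FWHM, bracketing the resolution of a dedicated
high-resolution brain tomograph and a whole-body TOF PET/MR.

Noise is zero-mean Gaussian with voxel SD
`scale * sqrt(max(v,0) / prompts)`: variance proportional to the local
mean and inversely proportional to the acquired prompt count. The
calibration `scale = 1250` puts the 4.3 kBq/ml background at ~5 %
voxel noise for a high-count (1.35e8 prompt) frame and ~17 % for a
low-count (1.2e7) frame, spanning the range encountered in practice.
Values are deliberately not clipped at zero — non-negativity is a
property of iterative reconstruction, which is out of scope — and all
metrics tolerate small negative excursions. This model reproduces the
two empirical behaviours the metrics probe (noise level vs counts and
vs smoothing) without simulating sinograms; it does not reproduce the
spatial correlation structure or bias of iterative reconstruction, so
simulated recovery-vs-noise trajectories are illustrative rather than
scanner-predictive.

### Closed-form oracles

Two closed forms provide an independent check of the rasterize+blur
pipeline. A uniform sphere of radius R convolved with an isotropic
Gaussian has the radial profile

    f(r) = 1/2 [erf((R+r)/(sigma sqrt2)) + erf((R-r)/(sigma sqrt2))]
           - sigma/(r sqrt(2 pi)) [exp(-(R-r)^2/(2 sigma^2))
                                   - exp(-(R+r)^2/(2 sigma^2))]

with the r->0 limit `erf(R/(sigma sqrt2)) - sqrt(2/pi)(R/sigma)
exp(-R^2/(2 sigma^2))`. A uniform cylinder factorizes exactly into a
blurred disc times a blurred slab; the blurred disc at in-plane
distance d equals a noncentral-chi-square CDF,
`ncx2.cdf((R/sigma)^2, df=2, nc=(d/sigma)^2)`, and the slab is an erf
pair. Both forms are verified against direct numerical 3-D convolution
in the test suite, and the full blurred-phantom value (background
cylinder plus all sphere contrasts) can be evaluated at arbitrary
points — including every voxel center of an ROI — giving an analytic
prediction of the recovery coefficients that the voxelized pipeline
must match (it agrees within ~0.6 percentage points at subsample 4).

## ROI scheme

Following the standard sphere-phantom protocol, each sphere gets (a) a
single-slice circular ROI of its physical inner diameter placed on the
transaxial slice where it is most visible — operationalized as the
slice extremizing the in-ROI mean within one radius of the geometric
center, ties resolving to the slice nearest the center then the lower
index — and (b) a spherical VOI of the same diameter. The background
grid places 12 ROI centers per sphere size uniformly on a 90 mm-radius
circle, rotated 15 degrees so centers interleave with the spheres, on
the central plane and at +/-1 cm and +/-2 cm axial offsets
(nearest-slice rounding, recorded in metadata) — 60 background ROIs per
sphere size. Centers are concentric across sphere sizes. The layout is
validated exactly: every ROI must keep a configurable margin (default
15 mm) from every sphere surface and lie inside the cylinder;
infeasible layouts raise an error listing the violating ROIs. With the
default geometry the largest background ROIs pass within ~2 mm of the
cylinder wall; the analytic oracle includes the wall's blur deficit, so
this is accounted for rather than assumed away.

Voxel membership is binary center-inclusion (no fractional weights),
matching common ROI tools and keeping the metric inputs unambiguous.
On coarse grids this produces a few percent of lattice jitter in
single-slice means of the smallest spheres; ordering properties
(VOI <= single-slice recovery, recovery monotone in diameter) are
therefore guaranteed only on adequately sampled grids (~1.2 mm voxels
for a 9.9 mm sphere).

## Image-quality metrics

Hot/cold recovery, %BG variability (sample SD over mean of the 60
background-ROI means, K-1 denominator) and voxel noise (CoV of pooled
background voxels per sphere size) are implemented exactly as defined
above. Two reporting decisions: recovery values are not clamped to
[0, 100] (resolution-modelling reconstructions legitimately overshoot
via Gibbs ringing); and for replicated noisy acquisitions, voxel noise
is computed per replicate and then averaged (mean +/- SD), never by
pooling voxels across realizations. The denominator of voxel noise is
the pooled-voxel mean over the same ROIs as its SD. Line profiles are
single-voxel-width nearest-voxel samples at the minimum in-plane pitch
along an arbitrary segment, divided by injected activity (MBq).
`sensitivity_percent` converts a cps/kBq sensitivity to percent
(1 kBq = 1000 decays/s) with an optional line-source length
re-normalization.

## Kinetic models

The reference-region curve is a gamma-variate
`C_R(t) = A t^alpha exp(-t/beta)` (t in minutes), sampled as exact
frame averages on a 1 s grid (frame-average error < 0.5 % for 60 s
frames). Defaults A = 9 kBq/ml/min^2, alpha = 2, beta = 2 min give a
bolus-like curve peaking at ~19 kBq/ml at 4 min that has essentially
cleared by 20 min. That clearance speed is a deliberate modelling
choice: reference-input Logan analysis is asymptotically unbiased only
once the reference contribution to the target has settled, and with
these defaults the plot is linear beyond t* = 20 min for every
parameter combination exercised (worst noiseless bias 2.7 % across
BP_ND in {0.5, 2, 4}, R1 in {0.8, 1.2}, k2 in {0.05, 0.15}/min).
Slower-clearing references — common for real tracers — reintroduce a
transient negative bias at slow efflux (small k2a = k2/(1+BP_ND)); the
package exposes this honestly (see Limitations) rather than correcting
it.

Target TACs follow the SRTM operational equation
`C_T = R1 C_R + (k2 - R1 k2a) [C_R (x) exp(-k2a t)]` with the
convolution evaluated on the fine grid by an exact-exponential
trapezoidal recursion, then frame-averaged. SRTM is the simulator only;
it is never fit as an estimator.

The Logan implementation uses frame-duration-weighted
piecewise-constant integration (exact at frame boundaries for
frame-average data; evaluated at frame mid-times for the plot),
ordinary least squares over frames with mid-time >= t* (default
20 min, configurable), and reports n, R^2 and the maximum relative
residual as a linearity diagnostic. The optional reference-efflux term
`C_R/(k2' C_T)` on the abscissa is omitted by default — with a late t*
and a cleared reference its influence is small — and is recorded in the
fit result when supplied. No errors-in-variables correction is applied:
with noisy TACs the estimator carries the well-known negative bias
(shared noisy denominators against a negative intercept -1/k2a), which
grows with BP_ND and 1/k2a. Late-window ratios select frames whose
mid-time falls in the final window (default 30 min; exactly the six
final 300 s frames of the 17-frame schedule) and divide
duration-weighted means.

Supported schedules are the 16-frame (4x60, 3x120, 8x300, 1x600 s) and
17-frame (4x60, 3x120, 10x300 s) 60-min protocols; arbitrary
contiguous schedules are accepted.

## Cross-scanner comparison and pipeline

A comparison report is the per-region ratio of scanner A to scanner B
with deviation `|ratio - 1| x 100 %`; across subjects the arithmetic
mean of per-subject ratios is reported per tracer and region (mean of
ratios, not ratio of means). `run_pipeline` executes phantom
simulation, ROI placement, metrics, TAC simulation, Logan/ratio
fitting and the comparison from one validated configuration; the seed
is mandatory (never defaulted), every stochastic stage draws a child
seed from it, and fixed-seed runs produce byte-identical CSV outputs
plus a JSON provenance sidecar recording all parameters. The demo
configuration uses a 96 x 96 x 89 grid, one high-count noise replicate
pair, and two striatal-like regions (BP_ND 2.5 and 3.0) with 5 %
proportional frame noise; these sizes keep a full run in the
tens-of-seconds range while exercising every stage.

## Numerical choices

- Rasterization boundary shell: half-voxel-diagonal margin; subsample 4
  default (0.5 % total-activity accuracy; 0.6 pp recovery accuracy).
- PSF kernel truncation at 6 sigma (activity conservation to 1e-6).
- Fine kinetic grid 1 s; exponential convolution via a linear filter
  with exact pole `exp(-k2a dt)`.
- Slice/plane selection by nearest-slice rounding; ties toward the
  geometric center, then the lower index.
- Sample standard deviations (denominator n-1) throughout.
- Degenerate inputs raise typed errors (`InvalidSpecError`,
  `GeometryError`, `UndefinedContrastError`, `ConfigError` with dotted
  field paths) rather than returning sentinel values.

## What the simulations do and do not show

The generators reproduce the features the metrics measure: known true
concentrations and contrast, resolution loss with object size and PSF
width, count-dependent noise, known BP_ND with realistic frame
schedules. They do not emulate iterative-reconstruction bias,
correlated noise textures, attenuation/scatter residuals, TOF effects,
motion, or template-based region definition (region masks are user
inputs). Passing tests therefore validate the analysis implementations
and their stated invariants, not any specific scanner's absolute
numbers.

## Known limitations

- With 5 % flat proportional frame noise, Logan BP_ND at the slowest
  equilibration corner (BP_ND = 4, k2 = 0.05/min, i.e. k2a = 0.01/min)
  shows a median underestimation of ~11-12 % at t* = 20 min — the
  uncorrected OLS noise bias; the package reports it rather than
  correcting it. Multilinear or likelihood-based estimators would
  reduce it and are out of scope.
- Voxel membership is binary; fractional-weight ROIs are a possible
  extension and would mainly affect the smallest sphere on coarse
  grids.
- The noise model is Gaussian and spatially white; real reconstructed
  noise is neither, so absolute %BG/noise values are calibrated only in
  order of magnitude.
- Background ROI placement is a declarative ring layout; published
  protocols leave the centers to the operator, so numeric %BG values
  are comparable across petquant runs but not guaranteed to match any
  specific manual placement.
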