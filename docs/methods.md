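# Methods

## The model

`dbatlas` works on pixel-level maps of areal bone mineral density (aBMD,
g/cm²) of the proximal femur, sampled on a 0.5 × 0.5 mm grid, each scan
segmented by 65 ordered landmarks around the bone contour. The pipeline
has five stages.

**Registration.** A common template is built by averaging landmark sets
after translation to a common centroid (anchored to the first subject's
frame, so the template lives in an absolute coordinate system); the
template mask is the fill of the mean contour, with femoral-neck (FN),
trochanteric (TR) and total (TOT) ROI masks. Each scan is brought into
template space with a thin-plate spline (TPS) fitted from the template's
mean landmarks to the subject's landmarks (backward mapping), kernel
U(r) = r² log r², exact interpolation by default (λ = 0 — landmark noise
is small at ~0.5 mm). Intensities are sampled bilinearly; in-mask values
are first extended two pixels beyond the subject mask by nearest-neighbour
fill so the bilinear kernel does not erode a NaN ring at the boundary.
BMD values are warped unchanged: no Jacobian/mass-preservation correction
is applied to areal density under the warp. The deformations here are
small (similarity + jitter), so the area change is ≲2%; a correction flag
was considered and left out of scope.

**Atlas.** The age-conditional distribution of BMD at each template pixel
is estimated by Gaussian-kernel local weighting: at each age-grid point a
(default 20–97 y, step 0.25 y) subjects get weights
exp(−((ageᵢ − a)/h)²/2) with bandwidth h = 5 y, and weighted empirical
quantiles are read off at 99 equispaced levels (0.01…0.99), followed by a
monotone rearrangement across levels (a no-op in practice, kept as a hard
guarantee). This is a deliberately simple substitute for a vector-GAM
quantile smoother: the same object (smooth conditional quantile surfaces)
with one tunable (h) and no knot placement. The u = 0.5 slice is the
median aging trajectory M(a); intermediate ages are linear interpolations
between grid slices. Inverting the per-pixel quantile function gives the
conditional CDF, clamped to [0.005, 0.995] because nothing outside the
1%–99% levels is estimated.

Age-grid points with effective sample size Σwᵢ < 10 are flagged
unreliable. Two boundary phenomena of this estimator matter downstream
and are *not* corrected: (i) within ~one bandwidth of the age-grid ends
the kernel is one-sided and the median surface flattens, which biases
bone-age readout toward the interior (measured at up to +3…5 y within
5 y of the 97-y end on synthetic data); (ii) the smoothing bias from
curvature of the trajectory is ≲1 y elsewhere.

**Densitometric bone age (DBA).** For a template-space map, RMSE(a) is
the root-mean-square difference to M(a) over pixels valid in both maps,
evaluated by exhaustive grid scan (default 0.1 y); DBA is the grid argmin.
Ties break to the youngest age (the least-aged bone consistent with the
data); an argmin at a grid endpoint is flagged `boundary_hit` but not
censored. Chronological age is not an input. Maps with < 95% valid
template pixels are refused rather than scored, since RMSE over a partial
femur is biased. The RMSE curve is returned with the estimate so flat
minima can be inspected. Short-term precision from duplicate scans uses
the RMS-CV convention: per-pair SD = |d|/√2, CV% = 100·RMS(SD)/grand
mean, plus Bland–Altman bias and 1.96·SD limits.

DBA is only identifiable where M(a) actually changes with age: on the
young plateau (below ~45 y in the synthetic population) the RMSE curve is
nearly flat and the argmin is effectively arbitrary within the plateau.
This is a property of the definition, not of the implementation; analyses
that need a well-defined bone age should restrict to subjects whose bone
age plausibly lies in the declining range.

**Scanner harmonisation.** Cross-scanner calibration is per-pixel
quantile-matching regression: OLS of group A's empirical quantiles on
group B's over levels 0.05–0.95, giving per-pixel slope/intercept fields
(identity fallback with a flag at zero-variance pixels). The groups must
be matched for age and BMI so quantile differences are attributable to
the scanners.

**Fracture evaluation and patterns.** Scores are compared as binary
classifiers of incident fracture with ROC (trapezoidal AUC, equal to the
tie-corrected Mann–Whitney U/(n₁n₀)) and precision–recall curves
(step-wise/achievable interpolation; the random baseline equals
prevalence). Bootstrap CIs (default 1000 reps) resample cases and
controls separately — at ~2% prevalence unstratified resamples often
lose every case — and paired AUC differences reuse identical resamples.
BMD-like scores are negated so every classifier is oriented
higher = riskier. The DBA/T-score agreement matrix inverts the cohort's
fitted linear DBA~T relation at T = −2.5 and −1 to obtain DBA category
cuts. For pattern mapping, each map is converted to a quantile map — the
atlas conditional CDF evaluated at the subject's DBA, i.e. the
probability of a lower BMD among the population with similar bone age —
which cancels the aging component of the texture. Group differences are
tested per pixel with a two-sided Mann–Whitney U (normal approximation
with tie and continuity corrections; exact enumeration is available for
small groups) and reported as Benjamini–Hochberg q-values over in-mask
pixels, significant at q < 0.05. No spatial-dependence correction is
applied on top of the pixel-wise FDR.

## The synthetic cohort generator

No public pixel-BMD dataset exists, so the generator provides cohorts
with the statistical structure the method assumes, plus ground truth:

- **Geometry** — a stylised femur silhouette (head circle, neck capsule,
  greater-trochanter bump, shaft) with ~15,000 in-mask pixels at the
  default 220 × 160 grid; 65 contour landmarks resampled uniformly by
  arclength from a fixed anchor. Only the topology matters: the method is
  geometry-agnostic once in template space.
- **Median surface** — analytic: base(p) − (rate/10)·softplus(age − 45)·d(p),
  with base ≈ 0.8–1.2 g/cm², decline rate 0.05 g/cm² per decade scaled by
  a spatial field d(p) strongest near the trochanter, and a softplus knee
  (width 4 y) at 45 y giving a young plateau and a strictly decreasing
  trajectory thereafter. Closed-form components are exposed for oracle
  tests.
- **Subjects** — "same path, different speed": a Gaussian bone-age offset
  (SD 7 y) shifts the subject along the trajectory; a Gaussian quantile
  offset (SD 1, × population SD 0.06 g/cm²) shifts the level, spanning
  T-scores of roughly −4 to +2; iid pixel noise (SD 0.02 g/cm²); a small
  random similarity transform plus 0.5 mm landmark jitter model
  repositioning and morphology; per-scanner linear calibration
  (slope, intercept) is applied last. Repeat scans share the subject's
  surface and redraw noise, jitter and repositioning.
- **Fractures** — risk is logistic in the bone-age offset (slope 0.18/y
  on top of a 2% baseline prevalence), so fracture cases are on average
  ~9 y "older-boned" than their chronological age; conditional on
  fracture the type is FN (70%) or TR (30%). FN cases get a focal
  Gaussian band deficit (SD 2.5 mm) across the mid neck, amplitude
  0.03 g/cm²; TR cases a diffuse deficit shaped by the blurred TR-ROI
  indicator, amplitude 0.02 g/cm². The amplitudes place the generator in
  a regime where global accelerated aging dominates the risk signal and
  the site deficit is a modest overlay — the regime in which a whole-bone
  age estimate is competitive with region scores while each region score
  is still most sensitive to its own pattern.
- **Determinism** — one seed sequence spawns a child per subject, so a
  cohort is bit-reproducible and extending it never reshuffles earlier
  subjects.

What the generator does *not* emulate: real trabecular texture and its
spatial correlation (pixel noise is iid), projection/rotation effects of
repositioning beyond a similarity transform, BMI-related soft-tissue
artifacts, secular or device drift, male or non-European reference
populations, and anatomically faithful femur shape. Passing tests
therefore demonstrate the estimators' statistical correctness and the
pipeline's internal consistency — not clinical performance on real DXA.

## Problem sizes and numerical choices

Tests and the reference experiments run on a reduced 96 × 72 grid
(~3,000 in-mask pixels) with a 1,600-subject reference population and a
0.5-y atlas age grid; the bone-age search grid is always 0.1 y. These
sizes keep atlas sampling noise (the dominant error; subject-level
offsets do not average out across pixels) near 1 y of bone-age
equivalent. The parameter-recovery experiment uses a 500-subject cohort
aged 70–80 with offsets N(0, 7 y) and low noise (quantile-offset SD
0.05, pixel noise 0.02), so effective bone ages stay on the declining,
identifiable part of the trajectory and clear of the 97-y edge. The
region-specificity experiment uses 6,000 subjects aged 45–80 at 3%
prevalence, leaving atlas headroom so high-risk subjects' bone age does
not saturate at the search ceiling.

Degenerate inputs are handled explicitly: collinear or duplicated
landmarks raise a registration error; zero-variance pixels fall back to
identity calibration with a flag; all-tie pixels get p = 1; empty ROIs
and partial-coverage maps are errors, not silent NaNs.

## Known limitations

- Kernel edge bias near the age-grid boundaries (above); a local-linear
  quantile smoother would reduce it and is the main candidate improvement.
- The quantile atlas assumes independence across pixels only in its
  estimation; quantile maps are marginally calibrated per pixel but make
  no claim about joint spatial distributions.
- Pixel-wise FDR treats pixels as separate tests; spatially correlated
  signals make q-values conservative in extent, not in location.
- The "population with a similar DBA" used for quantile maps is the
  atlas conditional at age = DBA; an empirical ±2.5-y DBA-binned variant
  would be a useful sensitivity check and is not implemented.
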