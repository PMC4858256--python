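# Methods

## Flow model

At each of the `ny` slow-axis locations the scanner records `R = 4`
consecutive B-scans of the same cross-section before moving on.  With 245
A-scans per B-scan at a 68 kHz line rate, consecutive repeats are ~3.6 ms
apart.  Backscatter from static tissue is stable over that interval while
backscatter from moving red blood cells decorrelates, so the flow signal
at A-scan `x` and depth `z` is the average magnitude of the consecutive
complex differences:

    I_flow(x, z) = 1/(R-1) * sum_{i=0}^{R-2} |C_{i+1}(x, z) - C_i(x, z)|

`compute_flow` evaluates this exactly (no registration between locations;
the scanner's active motion tracking is assumed to have done its job).
Two useful exact properties follow: the result is invariant under a global
phase rotation of all repeats, and homogeneous of degree one in the signal
amplitude.

The raw `|dC|` values are mapped affinely onto the display range [0, 255]
before any metric is computed, because the metrics divide by 255.  The
default mapping clips at the volume's 99.5th percentile and scales that to
255 — robust to isolated outliers.  A `max` mode and a `fixed` mode (an
explicit factor) exist; the fixed mode is what cross-condition experiments
should use, since comparing flux between volumes is only meaningful when
they share one raw-to-display mapping, as the values from a single
instrument do.  Whether the device subtracts a noise floor before display
is not publicly specified; no subtraction is applied here, and the scaling
mode is the only display-calibration knob.

## Layer segmentation and the disc margin

The pre-laminar slab is bounded by the inner limiting membrane (ILM) above
and one continuous surface below — the RPE/Bruch's-membrane complex
outside the disc, the anterior lamina cribrosa within it.  Per A-scan, the
intensity profile is Gaussian-smoothed along depth (sigma = 2 samples) and
differentiated by central differences.  The ILM is the first sample whose
gradient exceeds an adaptive threshold (that A-scan's gradient mean + 2 SD),
refined to the local gradient peak; ties across the peak are broken toward
the deeper sample, so an ideal step edge lands on the first sample at or
below the edge (this fixes the half-sample ambiguity testably).  The lower
surface is the strongest absolute gradient at least 4 samples below the
ILM.  Both surfaces are median-filtered (3x3) en face and the ordering
invariant is enforced.  If more than 5% of A-scans have no gradient above
threshold, segmentation fails with a per-A-scan diagnostic mask rather
than returning a bad surface.

The disc margin is the termination of Bruch's membrane.  The bright band
is sought in a symmetric window around the lower surface (the surface
estimate may sit at either flank of the band), the band-peak map is
median-smoothed to suppress residual speckle fades, and presence is
declared above 0.75x the band brightness at the scan edges.  Tracing each
B-scan inward from both edges gives two termination points per row; a
terminus requires a sustained (>= 3 px) absence so isolated dropouts are
ignored.  An ellipse is fit to all termini by RANSAC (seeded; residual
threshold 2 px) because a handful of outlier termini otherwise skew a
direct conic fit by tens of percent in area; fewer than 6 termini is an
error (no disc in the scene).  The ellipse interior is the disc mask;
`Area_ONH` is its pixel count (the mm^2 conversion is metadata — all three
perfusion metrics are ratios, so units cancel).

Manual overrides ("semi-automatic" operation) always win, bit-exactly: a
full surface is returned verbatim, a control-point CSV is interpolated by
thin-plate splines, and a manual disc polygon is rasterized in place of
the automatic fit.  Coordinates are 0-based, depth increases with z, and
depth intervals are half-open `[z_ilm, z_alc)`.

## En-face projection and vessel detection

The pre-laminar mask selects voxels inside the disc with
`z_ilm <= z < z_alc`; maximum intensity projection through that slab gives
the en-face angiogram `F(x, y)`; empty-slab pixels are zeroed and flagged.

Vessels are detected with a multiscale Hessian ridge filter of the Frangi
family.  Per scale sigma in {1, 2, 3, 4} px, the Gaussian-derivative
Hessian is computed with sigma^2-normalised derivatives; with eigenvalues
sorted as |l1| <= |l2|, the bright-ridge response is zero where l2 > 0 and
otherwise `exp(-Rb^2/2 beta^2) * (1 - exp(-S^2/2 c^2))`, with
Rb = |l1|/|l2|, S = sqrt(l1^2+l2^2), beta = 0.5 and c equal to half the
maximum Hessian norm over the image, recomputed at every scale.  V is the
maximum response over scales.  The scale grid matches vessel calibres of
roughly 20-80 um at the ~10 um/px sampling of a 2.4 mm / 245-location
scan.  (scikit-image's `frangi` is deliberately not used as the
implementation: it omits the sigma^2 normalisation and freezes the
adaptive cutoff at the first scale; it serves instead as an independent
single-scale cross-check in the test suite, where the normalisation
cancels and the two implementations must agree.)

Binarization defaults to a fixed threshold V > 0.15.  On en-face
angiograms the response across a perfused tube stays above ~0.3 while
background and inter-vessel pixels stay below ~0.1, so any cut in that gap
recovers the vessel area; 0.15 is its midpoint, and measured densities are
insensitive to the exact value across 0.10-0.20.  This permissive reading
("a pixel is vessel once it shows appreciable vesselness") is consistent
with healthy discs being ~3/4 vessel by area.  Disc-restricted Otsu and
two-level hysteresis variants are available; Otsu recovers centerlines
rather than areas (it halves the apparent width) and is therefore not the
default.

## Perfusion metrics and QC

Within the disc mask, on the 2-D en-face MIP (the summation index of the
flux definition is the en-face pixel):

* flux = mean of F/255 over disc pixels;
* vessel area density = |vessel AND disc| / |disc|;
* normalized flux = mean of F/255 over vessel pixels only — flux "in the
  vessels", insensitive to how much viable tissue remains.

These satisfy exactly `flux = d*nf + (1-d)*b`, with `b` the mean
normalized flow over non-vessel disc pixels; the identity is asserted to
1e-12 in the tests as a conservation check.  A disc with no detected
vessel pixels has *undefined* normalized flux (NaN, flagged), never 0 —
zero would fake perfect ischemia and corrupt group means.

Scan-level QC excludes an eye when its device signal strength (0-10)
falls below 6 or when noticeable eye movement was flagged; strength 6 is
included, 5 excluded.  Missing strength is treated as excluded, with a
warning.

## Synthetic scenes

`make_scene`/`generate_volume` produce ground-truthed repeated-B-scan
volumes.  Geometry: a tilted ILM plane, an anterior-LC/RPE surface one
slab below (slab thickness 0.35 nz) with a shallow cup inside the disc,
a circular disc of default radius 0.75 mm where the bright RPE band is
absent, and a bundle of non-overlapping wavy vessels running roughly
vertically (the superior-inferior course of the central vessel branches).
Tube radii are drawn from 3-4 px (60-80 um diameter) and the lateral gap
between tubes is computed from the requested en-face vessel fraction, so
the fill inside the disc lands near the target while the vasculature stays
tubular at every fill — crowded capillary plexuses that merge into sheets
are *not* emulated.

Signal model: the reflectivity map (vitreous ~0, tissue 0.5, vessels 0.6,
RPE band 1.0, sub-RPE 0.55, lamina shadow 0.15) is blurred laterally with
a Gaussian beam-waist PSF (sigma 0.7 px ~ 15 um) and a static uniform
random phase is attached per voxel.  This is an incoherent PSF model:
static voxels are bit-identical across repeats for any PSF, and
decorrelation is confined exactly to vessel voxels.  Rigorous coherent
speckle formation (amplitude fading, speckle grain) is intentionally out
of scope, so tests passing here say nothing about segmentation robustness
to real speckle texture.  A vessel voxel with decorrelation magnitude
delta in [0, 1] is re-drawn per repeat as `A_k * exp(i*phi_k)` with phi_k
uniform on [0, 2*pi*delta] and amplitude jitter `A_k = A(1 + 0.2 delta
eta_k)`.  The expected pair-difference magnitude is `4(theta - sin
theta)/theta^2` with `theta = pi*delta` (monotone in delta), which is what
makes mean vessel flow — and, under a shared intensity mapping,
normalized flux — increase with delta.  Complex Gaussian noise (SD 0.02
per voxel, ~4% of the tissue amplitude) is added per repeat; the noise
floor of the flow signal in avascular tissue is not characterised
publicly, so this default is a free parameter chosen to keep the
background MIP an order of magnitude below vessel signal.

Desk-scale defaults are 128x128 en face (the full 245-location geometry is
available by config) because the test suite and the acceptance script
re-run the whole pipeline dozens of times; all pixel-unit parameters are
expressed per-pixel so the scenes scale.

## Cohort simulation

`generate_cohort` draws per-eye records from group-specific multivariate
Gaussians (normal / POAG / NTG).  Default means and SDs follow the
published group summaries for this study design (e.g. normal flux
0.33 ± 0.04, POAG 0.24 ± 0.07, NTG 0.25 ± 0.06).  Metric-covariate
correlations are the square roots of the published univariate R^2 values,
signed by the clinically reported directions (perfusion higher with better
VF mean deviation, thicker RNFL, larger rim area; lower with higher PSD,
larger cup/disc ratio, higher IOP); metric-metric and covariate-covariate
correlations are plausible fixed values (e.g. flux-normalized-flux 0.85,
MD-PSD -0.75).  The assembled pairwise matrix is projected to the nearest
valid correlation matrix by eigenvalue clipping at construction;
user-supplied matrices must already be positive semidefinite or they are
rejected.  MOPP is computed from the simulated pressures via
`2/3(MAP - IOP)`, `MAP = DBP + (SBP-DBP)/3`, rather than drawn
independently — the published MOPP summary came from a blood-pressure
subgroup and is not internally consistent with the full-group BP/IOP
means, and internal consistency with the formula was judged more valuable.
Normal eyes carry no visual-field columns (the study design does not
perimeter normals).  Perfusion metrics are clipped to [0, 1] and SBP is
floored at DBP + 5 mmHg.

## Statistics

* MOPP as above; rejects SBP < DBP.
* Sample size: the default method is the normal-approximation formula
  `n = 2((z_{1-a/2} + z_power) sd / delta)^2` rounded up, which gives 28
  per group for a 15% difference on 0.300 ± 0.06 at 80% power — the
  convention of common power software for this design.  An exact
  noncentral-t method (smallest integer n reaching the requested power,
  typically one eye more) is available, and the exact power function
  backs the Monte-Carlo cross-check: true power at n=28 is ~0.787, inside
  the 0.80 ± 0.03 simulation band.
* One-way fixed-effects ANOVA across the three groups; two-group input
  satisfies F = t^2 exactly.  Degenerate inputs are defined: zero
  between-group variance gives F=0, p=1.
* Two-tailed independent t-tests for POAG vs NTG, pooled variance by
  default (Welch by flag; identical for balanced equal-variance input).
* Univariate least-squares regressions; R^2 equals the squared Pearson
  correlation by construction and is cross-checked on every run.
* 95% CIs are t-based on per-group SD/sqrt(n), matching the
  mean ± SD (CI) presentation of the summary tables.
* No multiple-testing correction anywhere, deliberately: the analysis
  plan this package reproduces uses nominal p < 0.05 throughout.

`build_tables` emits the four table shapes: group summaries with ANOVA p
(demographics, then perfusion metrics), the POAG-vs-NTG t-test table, and
the per-group regression grid (R^2, p) of each metric on each covariate.

## Numerical and design choices

* Step-edge boundaries land on the deeper sample; depth intervals are
  half-open, so `preLC voxel count = sum over disc pixels of
  (z_alc - z_ilm)` holds exactly.
* The 8-bit look of the flow display is never quantised inside the metric
  path; only exported images are cast.
* RANSAC (disc fit) is seeded, and every stochastic stage takes an
  explicit seed, so pipeline reruns are byte-identical.
* Pipeline runs are fail-fast; partial outputs are quarantined, never
  overwritten; a manifest records version, seeds, parameters and stage
  timings.

## Known limitations

* The scene generator's vasculature is a parallel tube bundle; branching,
  crossing and capillary-sheet topologies are not represented, and the
  vessel detector's area accuracy is only demonstrated for tubular
  geometry up to ~0.75 en-face fill.
* The incoherent speckle model means segmentation robustness to coherent
  speckle, shadowing and motion artifacts is untested.
* Flow is a decorrelation magnitude, not a velocity; no claim links delta
  to physical flow speed beyond monotonicity.
* Lamina cribrosa and deeper tissue are outside the analysed slab by
  design (limited light penetration at 840 nm motivates the pre-laminar
  restriction).
* Sectoral (quadrant / clock-hour) sub-disc metrics are not implemented.
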