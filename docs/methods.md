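# Methods

This note records the models, calibrations and numerical choices behind
`hemoflow`, and what the synthetic-data tests do and do not demonstrate
about real assay data.

## Channel hemodynamics

Flow in the native lumen is modeled as steady, laminar, incompressible
pressure-driven flow of a Newtonian fluid (whole blood approximated at
3.5 cP) in a straight rectangular duct with no-slip walls. The axial
velocity is the classical single Fourier series in the short dimension;
flow rate and wall shear follow by termwise integration/differentiation.
Two numerical points matter:

* the shear series is summed as π²/8 minus a sech-correction series, which
  converges exponentially in the aspect ratio, and sech is evaluated as
  2e⁻ˣ/(1+e⁻²ˣ) to avoid cosh overflow at high aspect ratio;
* 400 odd terms bound the relative truncation residual far below the 10⁻⁸
  requirement for any aspect ratio ≥ 1 (the residual is reported in every
  `FlowSolution`).

The shear-to-flow ratio is geometric, so viscosity never enters the
conversion; the solver is therefore used only for the inlet condition
(flow rate for a 150 or 3500 s⁻¹ initial wall shear). The full 3-D flow
through the injury junction is intentionally out of scope: the straight-duct
inlet condition is the only quantity consumed downstream. Wall shear is
evaluated at the midpoint of the long wall, the conventional reporting
point for rectangular microchannels. For width < height the solver
transposes the cross-section, so the reported point is always on the longer
wall.

Recalcification co-flow: perfect-mixing steady-state mass balance gives a
final concentration of stock·r/(1+r). Note that a 100 mM CaCl₂ co-flow at
r = 0.1 mixes to 100/11 ≈ 9.09 mM, just below the commonly quoted
10–15 mM target band; the function computes the exact balance and emits a
warning when the result leaves the configured band rather than silently
adjusting anything.

## Synthetic assay traces

Each assay trace is piecewise linear in clot area: zero during the lag
phase, linear growth at a constant slope, then a plateau (for occluders,
deposition stops at the occlusion time). The normalized outlet flow is 1
before occlusion and 0 after; non-occluders keep flow high until the
1200 s assay end. The platelet fluorescence channel scales with area such
that its peak fold change over the first-frame baseline equals the
configured amplitude. Optional Gaussian noise is added to all three series
(area noise as configured; fluorescence at 1% of baseline; flow at SD 0.01,
small enough that the 0.05 occlusion threshold is effectively never crossed
spuriously).

Event times (lag, occlusion) are snapped to the 5 s sampling grid so that
grid-quantized occlusion detection is unbiased; without snapping, detected
bleeding times would carry a systematic +Δt/2 offset.

## Cohort calibration

The defaults encode the study conditions:

| arm | closure probability | group mean BT (s, censored incl.) |
| --- | --- | --- |
| trauma, venous | 0.65 | 776 |
| trauma, arterial | 0.43 | 890 |
| control, venous | 1.00 | 317 |
| control, arterial | 1.00 | 327 |

Because non-occluding assays enter the group mean at the 1200 s censor
value, the occluder bleeding-time distribution cannot simply be centred on
the printed mean. The occluder mean is solved as
(group_mean − (1−p)·1200)/p, and the occluder distribution is a truncated
normal on [200 s, 1020 s] whose *location* is solved numerically so its
truncated mean equals that value exactly (the upper bound, censor time
minus the 3 min hold, guarantees a detected occlusion is never re-censored).
The printed ± dispersions are not usable as SDs of a censored mixture and
are treated as free parameters (default occluder SD 150 s trauma, 60 s
control). The same exact-mean truncated-normal construction is used for
covariates whose published mean sits near a physiologic bound (trauma WBC
10.02·10³/µL with SD 5.12 would otherwise be biased ≈ +0.3 by truncation
at zero).

Growth slopes are log-normal, truncated to [2, 25] µm²/s. The lower bound
keeps every depositing assay unambiguously above the 1.5 µm²/s
classification threshold; the upper bound keeps clots within the physical
scale of the injury site (unbounded draws produced areas larger than the
device and, statistically, high-leverage outliers that corrupted the
covariate couplings). A configurable fraction of non-occluding trauma
assays (default 15%) deposits essentially nothing, mirroring the
little-to-no-deposition phenotype reported in a subset of trauma samples;
other non-occluders grow until the assay end without sealing. Platelet
amplitudes are group-separated (control ≈ 12–15× fold change, trauma
≈ 2.5–3×), encoding the attenuated platelet contribution that motivates
the assay.

## Covariate coupling

Coupled covariates are built as mean + SD·(sign·√R²·z + √(1−R²)·ε), where
z is the standardized *measured* assay output and ε is iid standard
normal, so the population R² equals the target. Outputs are measured, not
latent: growth rates are extracted by the kinetics stage from the generated
traces at generation time (bleeding times come from ground truth, which the
detector reproduces exactly on the snapped grid). This matches how a
correlation analysis sees real data — through the measurement chain — and
avoids a ~2% attenuation that coupling to latent parameters would leave.
Two small corrections keep the delivered covariate on target:

* integer covariates (GCS) are rounded, which adds ≈ 1/12 variance; the
  continuous coupling is strengthened by (SD² + 1/12)/SD² to compensate;
* clamping to physiologic bounds is applied only outside those bounds, and
  marginals are placed so clamping is rare (< 1%) at the default effect
  sizes, leaving the calibration intact.

Default couplings follow the reported significant correlations: VWF
(R² = 0.35), D-Dimer (0.33) and MPV (0.25) negative against venous BT;
SaO₂ (0.45) positive against arterial BT; GCS (0.56), RBC (0.38, negative)
and MCV (0.25) against arterial growth rate. The sign of the GCS coupling
is not published; positive was chosen (better neurological status with
better-preserved clot growth) and is configurable. Uncoupled covariates are
drawn from plausible clinical marginals (documented in
`synth.default_covariates`); they are statistical stand-ins, not
mechanistic models of plasma biochemistry.

## Image synthesis and quantification

Synthetic stacks render each trace as a brightfield + fluorescence pair:
the clot mask grows outward from the ROI centre in a fixed
distance-ordered fill with pixel count round(area/µm-per-px²), so mask
area matches the trace within one pixel-quantization unit; total
fluorescence over the ROI equals the trace's platelet signal (baseline
spread uniformly, excess on clot pixels). Quantification reverses this:
MFI is the plain sum of the image matrix over the ROI (no background
subtraction by default, configurable), and area segmentation is a global
Otsu threshold on the median-subtracted frame with a polarity flag,
removal of connected components under 5 px, and a detection guard — the
Otsu class separation must exceed 4 robust (MAD-based) background-noise
SDs, estimated from the sub-threshold population only, since otherwise
thresholding a clot-free frame would always mask about half of it.
Automated thresholding stands in for the manual outlining used on real
images; with synthetic ground truth available, segmentation accuracy is
asserted directly (disk at 10× noise recovered within 2% by area;
noiseless round trips exact to pixel quantization).

## Kinetic feature extraction

Bleeding time: the earliest sample at which the normalized outlet flow
falls below 0.05 and stays below it for at least 180 s (a run reaching the
end of the record counts its duration to the last sample); censored at
1200 s otherwise. Traces that end before the censor time without occluding
are rejected as incomplete unless explicitly flagged as early-stopped.

Lag/growth segmentation operates on the window from perfusion start to the
bleeding time (so the post-occlusion plateau cannot dilute the growth
rate):

1. **LOESS smoothing** — tricube nearest-neighbour weights, local
   quadratic, span 0.3 (span and degree configurable; no value is
   published, and the span is deliberately exposed). Without robustness
   iterations LOESS is a linear smoother, so the n×n smoothing operator is
   built once per time grid (vectorized normal equations on a normalized
   local basis, for conditioning) and cached — this is what makes
   10,000-assay cohort runs cheap.
2. **Inflection points** — the second divided difference of the smoothed
   series is classified convex/concave/flat against 0.2× its peak
   magnitude (the 0.2 default sits above the ≈16% side-lobes a tricube
   local-quadratic fit rings around a slope discontinuity); only runs
   persisting ≥3 samples count. Adjacent opposite-sign runs mark a true
   inflection and contribute the zero crossing between them (a logistic
   yields its midpoint); an isolated run flanked by flat curvature marks a
   slope change and contributes its curvature peak (smearing is symmetric,
   so the peak sits at the bend).
3. **Boundary refinement** — smoothing spreads a bend over roughly a
   window width, so the provisional lag→growth boundary is re-fit on the
   *raw* series with a continuous two-piece (hinge) linear least-squares
   model over a window around it; the knot at the SSE minimum becomes the
   boundary. Exact for noiseless piecewise-linear bends; under noise at 5%
   of the plateau it roughly halves the growth-rate error.
4. **Slopes and labels** — per-point slopes on the raw series by central
   differences with a 3-point running average; a segment's slope is the
   mean over its interior points (boundary samples straddle two regimes
   and are excluded). Segments with |slope| ≤ 1.5 µm²/s are lag, above it
   growth, ties to lag. The published sentence assigns "lag" to slopes
   *above* the threshold, which contradicts the meaning of a lag phase;
   the default implements the physically consistent orientation and
   `lag_rule="above_threshold"` gives the literal reading. Lag time is the
   start of the first growth segment; growth rate is the duration-weighted
   mean slope of the first contiguous growth run; both definitions are
   configurable since the source text does not define them.

Recovery behaviour, asserted in the test suite: on noiseless traces lag
and BT are recovered within one 5 s sampling interval and growth within
2%; with noise at 5% of the plateau the median growth-rate error over 200
seeded replicates stays under 10%.

## Statistics

Group comparisons use the Welch (unequal-variance) t-test by default — the
safer reading of "unpaired t-tests" for 34-vs-10 group sizes — with a
Student flag available. Correlations are pairwise-complete Pearson with
t-based two-sided p (n−2 df), no multiplicity adjustment by default
(matching the exploratory framing; Benjamini–Hochberg is available behind
a flag). Censored bleeding times enter comparisons and correlations at
their 1200 s face value, as plotted cohort data do; censoring-aware
survival modeling is explicitly out of scope. ISS subgrouping assigns the
cutoff value (default 16) to the polytrauma side.

## Determinism and problem sizes

All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical (seed, config) reproduces every
trace, covariate table and pipeline artifact byte for byte. Calibration
checks run at 10,000 assays per arm, where Monte-Carlo error on group mean
bleeding times is ≈ 3–4 s and on closure frequencies ≈ 0.5 percentage
points; the default pipeline run mirrors the study size (34 + 10 patients).

## Limitations

The generator reproduces the *statistical* structure of the assay, not its
biophysics: traces are piecewise linear (no embolization, retraction or
multi-phase growth), flow is a clean step (no gradual occlusion), covariates
are linearly coupled Gaussians (no mechanistic VWF/ADAMTS13 or oxygenation
models), and image stacks have idealized uniform illumination with a single
connected clot. Passing tests therefore demonstrate that the analysis
pipeline is correct and well-calibrated on data with known ground truth —
not that the assay's biology is modeled. Parameters the source material
does not pin down (LOESS span, dispersions, lag/growth-rate definitions,
amplitude scales) are explicit configuration with documented defaults.
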