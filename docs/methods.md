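# Methods

This note documents the models, algorithms, numerical choices, and known
limitations of `octlayers`, in the order data flows through the toolkit.

## Device profiles and quality gating

A `DeviceProfile` carries grid geometry (A-scans × B-scans × depth
pixels), lateral field of view, axial sampling (µm/px), and the quality
gate. The built-in `cirrus-like` profile (512×128×1024 over 6×6 mm,
≈1.95 µm/px from a 2 mm scan depth, signal strength ≥ 7) and
`spectralis-like` profile (512×49×496, 3.87 µm/px, SNR ≥ 20 dB with a
required frame-averaging count of 16) describe typical macular-cube
exports; they are configuration defaults, not measurements, and every
field is overridable. The Spectralis-style fast-macular B-scan count is
not standardized across studies; 49 is an assumption exposed in config.

Quality gating is a pure threshold function — pass iff quality ≥
threshold and (where required) ART equals the required count; a missing
quality value raises rather than passing silently, and the gate is
monotone in the quality value (property-tested).

## File formats

- **Raw `.img`**: headerless uint8 cube. The export does not self-describe
  its byte order; the default (depth fastest, then lateral, then B-scan)
  matches the common 512×128 macular cube layout and is configurable via
  `axis_order`. File size must equal the profile's voxel count exactly;
  any mismatch is a geometry error naming both byte counts.
- **`.vol` (HSF layout)**: 2048-byte header (magic `HSF-OCT-`), an SLO
  image block (skipped), then per-B-scan headers + float32 reflectivity.
  Raw reflectivity is mapped to display intensity by the conventional
  fourth-root transform, clipped to [0,1]; sentinel values (>1e6) become
  0. The package's own `.vol` writer inverts the transform (stores d⁴),
  so round-trips agree to ~1e-8; it exists for fixtures and interchange
  tests, not for producing files other vendors' software would ingest.
- **Internal format**: float32 cube + JSON sidecar (profile, metadata).
  Sidecar/cube inconsistencies are corrupt-file errors; writing a volume
  with non-finite values is refused.

## Phantom generative model

The phantom stands in for a scanned retina wherever ground truth is
needed. Bruch's membrane is placed so the retina is vertically centred,
plus a smooth random relief (white noise blurred with a wide Gaussian,
scaled to `undulation_um`, default 10 µm SD) shared by all surfaces.
Eight layers stack above BM with base thicknesses (µm) RNFL 32, GCIP 66,
INL 35, OPL 25, ONL 63, IS 22, OS 23, RPE 33 — chosen so the composite
means land near typical adult macular values (mRNFL ≈ 32, GCIP ≈ 66,
INL+OPL ≈ 60, ONL+PR ≈ 108, RPE ≈ 33, total ≈ 299). A Gaussian foveal pit
(default depth 120 µm, radius 0.75 mm) thins the inner layers — weights
RNFL 1.0, GCIP 1.0, INL 0.8, OPL 0.5, shares proportional to
weight × thickness — which makes total thickness minimal at the pit, the
property the fovea finder exploits. Specs that would drive any layer
below ~0.5 µm (surfaces crossing) are rejected.

Rendering paints each voxel with its enclosing layer's mean reflectivity
(alternating bright/dark bands as in real B-scans: bright RNFL and
RPE/photoreceptor complex, dark nuclear layers), applies an axial
Gaussian blur (default FWHM 8 µm) as a point-spread surrogate, then
multiplicative gamma speckle (shape k = 4, mean 1, variance 1/k — the
standard first-order OCT speckle model) and clips to [0,1].

*What the phantom does not model*: vascular shadowing, motion/registration
artifacts, axial curvature, pathology-driven layer irregularity, or
device-specific noise spectra. Segmentation accuracy measured on phantoms
is therefore an algorithmic bound under clean(ish) conditions, not a
clinical error estimate.

Cohort simulators are direct generative versions of the statistical
models: paired eyes draw device-A thickness from N(µ_layer, σ_layer²) and
device-B = A + bias + N(0, σ_d²), truncated at 1 µm (a warning fires when
>1% of the mass would be non-positive); longitudinal cohorts use a
subject-level random intercept shared by both eyes (default SD = the
per-layer population SD), annual slope, age and sex fixed effects
(−0.05 µm per year of age, +1 µm for males — small, plausible magnitudes;
they exist so the adjustment machinery has something to adjust for), an
MS-group deficit, and i.i.d. visit residuals (default SD 1.5 µm, chosen so
per-eye change SDs over ~1.4 years land near 2 µm). An optional eye-level
intercept (`eye_sd_um`, default 0) can break the match between generator
and analysis model for robustness experiments.

## Preprocessing

Normalization maps each B-scan's 1st percentile to 0 and 99th to 1,
clipped (constant images map to zeros). Percentile rescaling was chosen
over histogram matching for robustness and parameter-lightness; it is
idempotent up to the percentile discretization.

The coarse ILM is the first depth where the axially smoothed (σ = 3 px)
A-scan exceeds `vitreous + 0.3·(max − vitreous)`; the coarse BM is the
steepest intensity fall-off within ~30 µm below the deepest strong
reflector (deepest sample ≥ 0.7 × column max — "deepest", not
"brightest", so a bright RNFL cannot capture the search). Both maps are
median-filtered over a 3 (B-scans) × 7 (A-scans) window, which removes
isolated speckle-induced outliers. If more than 10% of A-scans carry no
supra-threshold signal the volume is rejected as low-signal. On default
phantoms the coarse estimates carry ≈1–1.6 px of systematic bias
(threshold/gradient offsets); their noise-induced deviation shrinks as
speckle weakens (tested).

Flattening shifts each A-scan by an integer so BM aligns to the median BM
row. Integer circular shifts were chosen over interpolation so the
operation is exactly invertible (`unflatten` restores the input
bit-for-bit) and preserves each column's intensity multiset. The ROI band
is [min ILM − 15 px, target BM + 10 px], both margins configurable.

## Boundary classification

Features (recipe `v1`, 12 per pixel, fixed order): raw intensity; axially
smoothed intensity at σ = 1, 2, 4 px; first and second axial derivatives
at σ = 1, 2 px; signed distances to the coarse ILM and to the flattened BM
row; normalized lateral eccentricity; depth below the ROI top. The recipe
identifier travels with every trained model and predictions refuse
mismatched recipes. Classification happens in flattened space, where the
geometric context features are most informative.

Training labels: pixels within τ = 1 px of surface k get class k (nearest
surface wins in overlaps), all other ROI pixels are background; classes
are balanced by per-class subsampling (cap 20 000). The forest is
scikit-learn's `RandomForestClassifier` (50 trees, depth ≤ 12, single
thread, seeded); a boundary class with zero labelled pixels aborts
training with the class named. Training on phantom ground truth replaces
the manual-segmentation training a clinical deployment would use; the
model manifest records the provenance.

## Surface extraction

The coupled-surface problem — maximize Σₖ Σ_column log(pₖ + ε) with
ε = 1e-9, subject to ordering, per-pair separation bounds, and hard
smoothness bounds Δₖ — is solved exactly as a maximum-closure /
minimum-s-t-cut problem: one node per (surface, column, depth) within the
feasibility band implied by the minimum separations; intra-column arcs
make membership monotone in depth; smoothness arcs link adjacent columns
at depth offset Δₖ; separation arcs link adjacent surfaces at the min/max
offsets; bottom-of-band nodes are forced into the closure by a capacity
exceeding the total negative weight. Capacities are integers (the flow
backend requires 32-bit): weights are scaled by min(1e8, 2×10⁹ / Σ|w₋|),
so quantization is ~1e-8 log-units on small instances and ~1e-5 on
realistic B-scans — far below the cost differences between distinct
surface families. The surfaces are read off the *minimal* source-side cut
(residual-graph reachability), which among equally optimal families
returns the shallowest — the tie-break toward smallest total depth,
implemented structurally rather than via an infinitesimal depth penalty
(not representable after integer scaling).

Default constraints (configuration, generous physiological bounds):
minimum separation 1 px everywhere; maximum separations from upper-bound
layer thicknesses divided by the axial sampling; smoothness 2 px per
lateral step, 4 px for the ILM (which dives steeply at the pit). The
solver validates every constraint on its own output before returning.
Smoothness is a hard Δ-bound rather than a soft penalty — an
interpretation choice that keeps the problem exactly solvable and
testable against enumeration. By default each B-scan is solved as an
independent 2-D problem; `coupling="full3d"` adds inter-B-scan smoothness
arcs at higher cost.

`solve_reference` is an independent exhaustive dynamic program over joint
per-column depth tuples (exponential in the surface count; tiny instances
only). The acceptance battery checks the min-cut solution equals it in
objective and surfaces on 25 seeded random instances.

Manual correction accepts point edits `(surface, y, x, new_depth)`; the
edited surface is re-interpolated along its B-scan with a monotone cubic
(PCHIP) through the edits, decaying to zero 10 A-scans away, so the
change is local. Ordering is re-validated afterwards; violations are
rejected with the offending surface pairs listed, never silently fixed.

## Thickness and the fovea

Layer thickness = surface separation × axial sampling, using the solver's
(continuous-capable) depths. The fovea is the argmin of total thickness
within the central 2×2 mm, ties broken toward the scan centre then
lexicographically. Per-layer means are unweighted over A-scans whose
centres fall in the closed 5×5 mm square centred on the fovea; a fovea
beyond ±1 mm (window would leave a 6×6 mm scan) raises an error — the
scan is flagged, not clamped. A-scan centres are taken on a grid spanning
[−fov/2, +fov/2] inclusive.

The composite "ONL+PR" is interpreted as ONL + photoreceptor inner +
outer segments — inferred from the 8-layer/9-boundary accounting, since
clinical tables print composites without enumerating the base layers.
`INL+OPL = INL + OPL` and `total = Σ base layers` hold exactly by
construction and are asserted as invariants.

## Agreement statistics

Differences are *device b minus device a* ("spectralis minus cirrus" in
the default naming); swapping roles negates the mean difference and
mirrors the LOA (tested).

- **Bland–Altman** (n ≥ 3 pairs): d̄, s (ddof 1), CI(d̄) = d̄ ±
  t₀.₉₇₅,ₙ₋₁·s/√n, LOA = d̄ ± 1.96·s, CI(LOA) = LOA ± t₀.₉₇₅,ₙ₋₁·s·√(3/n).
  The √(3/n) LOA-variance approximation with t quantiles is the standard
  textbook choice; the multiplier 1.96 is kept literal so the LOA
  symmetry identity `upper − d̄ = d̄ − lower` holds to 1e-9 (asserted on
  every result). Zero-variance input collapses the LOA with a warning and
  degenerate CIs.
- **Agreement index**: `1 − |X_a − X_b|/((X_a+X_b)/2)`. The absolute
  value is applied deliberately: without it the index could exceed 1,
  contradicting its use as a ≤1 similarity score. It is ≤ 1 always, = 1
  iff the readings are equal, swap- and scale-invariant, and can go
  negative for grossly discordant pairs. Aggregation is the unweighted
  per-eye mean ± SD per layer.
- **Repeated-measures Bland–Altman** on per-eye changes: the difference
  SD is rebuilt as √(σ²_between + σ²_within) from one-way ANOVA
  estimators over subject clusters (unbalanced-design n₀; negative
  between-components floored at 0; one-eye-per-subject degenerates to the
  plain sample SD). CIs use the number of subjects as the effective n — a
  conservative choice among the several published repeated-measures
  variants; the variant used is stated here precisely because the
  literature admits alternatives.
- **Mixed models** (statsmodels `MixedLM`, REML, fitted with
  L-BFGS/Powell): rate of change = `thickness ~ years + age + sex` with a
  per-subject random intercept shared by both eyes (intereye correlation
  enters through the shared intercept; no separate eye-level intercept by
  default); group comparison = `thickness ~ group + age + sex`, same
  random structure. Inference is Wald (normal quantiles) on the REML fit.
  Under the matched generator the slope test's type-I error is ≈5%
  (4.2% over the suite's 500 seeded null replicates) and 95% CI coverage
  ≈95%. No multiple-testing correction is applied (α = 0.05 per test, as
  is conventional for this analysis battery).

## Problem sizes used in tests and the acceptance script

Phantom segmentation runs on a compact profile — 96 A-scans × 12 B-scans
× 192 depth px over the same 6×6 mm field at 3.87 µm/px — the package's
default test geometry: it preserves the full 9-surface structure, the
foveal pit, and the noise model while keeping a train-on-3 / test-on-2
experiment in tens of seconds. Statistical recoveries use n = 10⁴ paired
eyes, 100 replicate cohorts of 200 subjects for slope recovery/coverage,
500 null replicates of 40 subjects for the type-I error, and 50 replicate
cohorts of 150 subjects for the group deficit; recovery values are
Monte-Carlo means of the estimator over replicates, so their standard
errors are an order of magnitude below the quantities themselves.

## Known limitations

- The classifier is trained on phantoms; applying it to clinical scans
  would require retraining on manual segmentations of real volumes.
- Per-B-scan solving ignores inter-B-scan smoothness by default (the 3-D
  coupling flag exists but costs more); sub-pixel surface refinement is
  not performed, so solver output is integer-valued in practice.
- The coarse ILM/BM estimator carries a ~1–1.6 px systematic bias on
  phantoms; downstream stages absorb it (it only positions the ROI and
  geometric features), but it is not a boundary-accuracy oracle.
- `.vol` parsing targets the common HSF layout; encrypted or DICOM
  exports are out of scope, as are SLO/fundus images.
- Eyes of one subject share only an intercept in the mixed models;
  eye-specific slopes or nested eye intercepts are not modelled.
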