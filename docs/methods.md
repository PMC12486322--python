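# Methods

## Scope and data model

The pipeline analyses tracer-labelled terminal fields in cleared spinal
cord and extracellular recordings from cutaneous afferents. All imaging
arrays use axis order (z, y, x) = (dorsoventral, rostrocaudal,
mediolateral) with per-axis voxel sizes in µm; the default voxel is
2 × 1 × 1 µm (z step × pixel), matching the two-photon configuration the
method targets. Micrometre coordinates are `index × voxel size`; indices
are 0-based; interval membership is half-open `[start, end)` throughout
(epochs, windows), so boundary events are counted exactly once.

## Stack processing

1. *Background subtraction*: tracer − autofluorescence, clamped at zero.
   Clamping (rather than keeping negative residuals) reflects that
   intensities are photon counts; it is also what makes the subsequent
   whole-stack statistics meaningful.
2. *Binarization*: a voxel is terminal-positive when its intensity
   strictly exceeds the whole-stack mean + `k_bin`·SD (default 3,
   population SD, computed over **all** voxels of the subtracted stack —
   the dominant zero background is what turns mean + 3 SD into a
   high-percentile cut). Statistics are computed after subtraction; the
   strict inequality makes the constant-stack case well defined (empty
   mask). Both choices are configurable.
3. *Denoising*: positive voxels with zero positive neighbours are
   removed. "Single pixels" are interpreted in 3D with 26-connectivity
   (configurable: 6/18/26): the objects are 3D voxel clouds, and per-slice
   2D removal would delete genuine single-slice intersections of thin
   fibres. Isolated voxels are exactly the size-1 connected components,
   which makes the operation idempotent.

## Morphometry

* **Centre of mass** — the unweighted centroid of the binary mask (the
  stacks are binarized before measurement, so intensity weighting would
  be meaningless). For alignment the centre is rounded to the nearest
  voxel with ties toward negative infinity (deterministic).
* **Summed projections** — per-pixel counts of collapsed voxels; the
  pixels of every projection sum to the mask's voxel count (a conservation
  law the tests enforce).
* **Spans** — each projection is thresholded at its mean + `k_span`·SD
  (default 1, strict >); the span is the axis-aligned bounding-rectangle
  extent of surviving pixels, converted with `(max − min + 1) ×` pixel
  size. ML and RC spans come from the dorsoventral projection, the DV span
  from the rostrocaudal projection.
* **Areal density** — total positive voxels ÷ (number of projection
  pixels > 0 × pixel area, µm²). The mean + 1 SD threshold applies only to
  span measurement, not to the density denominator; whether the original
  procedure thresholded the density denominator is ambiguous, so a
  configuration flag (`density_on_thresholded`) supports both readings.
* **Focus offsets** — |COM_ML − medial border| and |COM_DV − dorsal
  border|, with the grey–white borders supplied as annotations (automatic
  grey–white segmentation is out of scope).
* **Derived metrics** — percent change `100(x − x_ref)/x_ref` and planar
  focus shift `√(ΔML² + ΔDV²)`.

## Synthetic data

The generators define the study conditions for every test; their defaults
were fixed once, at design time, and are not tuned per run.

**Single-stack phantom** (`StackPhantomParams`): anisotropic Gaussian
blobs (default one blob, σ = 5 × 10 × 10 µm, peak 60) over an
autofluorescent background (mean 20, SD 2) shared by both channels, plus
sparse hot pixels (rate 5·10⁻⁵, intensity 300) in the tracer channel
only — they are what the isolated-voxel removal exists for. Ground truth
(count, centroid, extents, projected areas) is computed from the
noise-free support at half maximum. The default grid (25 × 49 × 49
voxels) is a tight crop in which the blob occupies a few percent of the
stack; in that regime the blob's own contribution to the stack SD places
the mean + 3 SD threshold at the blob's half-maximum, so the binarized
count tracks the half-maximum truth (the tests check within 10%). With a
small blob in a large stack the same rule cuts far down the Gaussian
shoulders instead — a genuine property of stack-histogram thresholding,
not an artefact of the phantom.

**Cohort phantom** (`FieldPhantomParams`): a terminal field is modelled
as a curved sheet — an elliptical territory in the RC × ML plane
(default semi-axes 60 × 24 µm in a 48 × 384 × 160 voxel grid) carrying a
plateau-like thickness profile T(y, x) = T_max·(1 − ρ¹⁶)^½ around a
midline surface that waves along RC with saturated (flat-topped) crests.
This construction decouples the three effects the analysis must recover:

* span multipliers scale the territory semi-axes (ML, RC) or the solved
  DV extent;
* the density multiplier scales the sheet thickness — the dorsoventral
  areal density *is* the mean thickness in voxels per µm²;
* the focus displacement translates the territory centre.

The wave amplitude is solved per specimen as (DV extent − thickness)/2 so
the configured DV span holds regardless of thickness (valid while
extent ≥ thickness). Sheet intensity is peak·(0.7 + 0.3·dome), far above
the noise, so the processing chain recovers the support essentially
exactly (measured/true count ≈ 1.000 in the tests); a Gaussian-blob
construction was deliberately not used here because a lattice of blobs
quantizes a 14% span effect to whole lattice cells and couples density to
span through projection overlap. Within-group biological variability is
modelled as 3% multiplicative jitter on sizes and thickness plus a small
centre jitter. Default group effects mirror the measured genotype
contrast: ML × 1.14, RC × 1.30, DV × 1.00, density × 0.78, focus shifted
(18.75, 1.42) µm. Per-specimen seeds depend only on the cohort seed and
specimen index — not the group — so identity effects produce seed-matched
identical pairs, a property the tests rely on.

What the cohort phantom does **not** emulate: optical physics (PSF,
depth-dependent attenuation, clearing shrinkage), tile-stitching
artefacts, fibre-level texture inside the field, or asymmetric/lobed
field shapes. Passing the recovery tests therefore shows the measurement
chain is correct and unbiased for smooth sheet-like fields under the
stated noise, not that it is robust to every real-world confound.

**Fibre responses** (`FiberModel`): spike trains are inhomogeneous
Poisson, piecewise-constant within epochs, thinned by an absolute
refractory period (default 1 ms), fully seeded. Rate rules per class:
ramps drive all mechanosensitive classes at dynamic gain × ramp velocity
(Hz per mm/s) when the epoch force exceeds the fibre's threshold; holds
drive SAMs at static gain × suprathreshold force (Hz/mN) and nobody else;
during a vibration ramp the fibre fires at a fixed rate (100 Hz) from the
moment the linearly growing envelope crosses its threshold — which is
what makes the measured "force at first spike" a consistent estimator of
the model threshold (bias ≈ envelope slope / rate ≈ +0.1 mN); manual taps
are modelled as a dedicated epoch kind whose implied probe velocity
exceeds the 1.5 mm/s ceiling of the mechanical stimulator, since the real
manoeuvre is literally manual and unquantified. Tap-units emit exactly
one deterministic spike to a tap and nothing else; mechano-insensitive
fibres are silent to all mechanical epochs. Default class parameters
(CV ranges, thresholds, gains) are centred on the measured class
summaries (e.g., SAM threshold 7.5 mN, Aβ CV ≈ 14–15 m/s).

## Afferent classification

CV = distance/latency (mm/ms ≡ m/s). Aβ is strictly > 10 m/s; the Aδ band
[1.5, 10] is inclusive, so the boundary value 10 m/s is Aδ. The class
decision runs in order: (1) silent to every stimulus →
mechano-insensitive; (2) at most one spike, only to the manual tap →
tap-unit; (3) Aβ with ≥ 1 spike during the 2 s holds → SAM, else RAM;
(4) Aδ with mechanical threshold ≤ 1 mN and a response at the slowest
ramp → D-hair, else AM. The SAM hold criterion (≥ 1 spike) and the D-hair
cutoffs are configuration defaults, not claims — the source procedure
states only "spike pattern and sensitivity". A fibre firing more than one
spike to the tap but nothing to controlled stimuli falls through to the
CV branch. The toy threshold-crossing spike detector (mean + 5 SD,
1 ms refractory) exists for synthetic traces only; real spike sorting is
out of scope.

## Statistics

Summary-statistics paths are first-class: t and F are computed from
(mean, SEM, n) triples with SD = SEM·√n, since published tables are the
only available inputs. Raw-sample paths delegate to scipy.stats and agree
with the summary paths to machine precision when summaries are computed
from the samples. The default t test is pooled (df = n₁ + n₂ − 2 —
matching the printed degrees of freedom throughout); Welch with
Satterthwaite df is available explicitly or via an "auto" trigger (F-ratio
variance test at α = 0.05), a made-explicit reading of "with Welch's
correction for datasets with unequal variances". The two-sided Fisher test
uses the point-probability method (sum of hypergeometric probabilities ≤
the observed one, margins fixed) with a 10⁻⁷ relative slack absorbing pmf
rounding — documented because software differs on the two-sided
definition; p is snapped to 1 when the full support is included. Tukey
uses the studentized range on the pooled within-group mean square
(Tukey–Kramer for unequal n); Bonferroni multiplies pairwise pooled-t p
by the number of comparisons, capped at 1. Two-way repeated-measures
ANOVA is intentionally not implemented: it would require raw per-fibre
repeated measures that are not available, and it is an off-the-shelf
procedure.

Reproduction of printed t/F values from printed (1–4 significant figure)
summaries carries a ±3% tolerance; recomputation gives e.g. t(4) = 0.5058
vs 0.5061, F(2, 68) = 20.62 vs 20.66, F(2, 26) = 2.583 vs 2.543. The
published percentage labels for mechano-insensitive proportions (26% vs
18%) are transposed relative to their own counts (4/22 = 18.2%,
10/38 = 26.3%); this package reports proportions computed from counts.

## Problem sizes and reproducibility

The synthetic studies use cohorts of 20 specimens per group on
48 × 384 × 160 voxel grids, 200 fibres per class, and 10,000 null
simulations for the type-I check — sizes chosen so the whole acceptance
run completes in well under a minute while keeping sampling error far
inside the tolerances. Every random quantity is driven by explicit seeds
(numpy `SeedSequence`); identical seeds reproduce stacks, spike trains
and result files byte for byte.

## Known limitations

* The phantom geometry is smooth and convex-ish; real terminal fields are
  lobed and textured. Absolute spans/densities are therefore scaled-down
  model quantities; the pipeline's claims concern ratios and recovery.
* The spike generator produces times, not waveforms; multi-unit
  separation and receptive-field mapping are out of scope.
* The mean + 3 SD rule is sensitive to the labelled fraction of the
  stack; users applying it to stacks where the structure occupies ≫ a few
  percent (or ≪ 0.1%) of voxels should inspect the recorded threshold in
  the mask provenance.
* Vibration-frequency tuning (25 vs 50 Hz) is not analysed.
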