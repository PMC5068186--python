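# Methods

## Scope and model

`valvepet` quantifies focal 18F-fluoride uptake in the aortic valve from
gated PET volumes in SUV units. The analysis chain is: cardiac-gate
selection → valve-plane fit from the three leaflet-base landmarks →
en-face reslicing → per-slice ROI statistics → whole-valve and
most-diseased-segment (MDS) summaries → blood-pool correction (ratio or
subtraction). Agreement statistics and a sample-size framework sit on
top of the per-scan metrics. A digital phantom supplies gated volumes
with known ground truth so every stage is testable without patient data.

## Valve geometry

The en-face frame is fitted to the right-coronary, noncoronary and
left-coronary cusp-base landmarks: origin at their centroid, z-axis the
unit plane normal oriented cranially, x-axis toward the right-coronary
landmark. The x-axis convention is ours — on a workstation the in-plane
rotation is arbitrary, but deterministic sector ROIs need a fixed frame.
All three landmarks lie at z = 0 by construction; the fit is invariant
under cyclic relabelling up to that in-plane convention.

Reslicing produces contiguous slices of configurable thickness (default
3 mm) centered on the landmark centroid. Each slab is averaged through
its thickness from 3 symmetric trilinear sub-samples (exact for fields
varying linearly along the normal). A slab no thicker than a native
voxel is sampled once at its center: sub-voxel "averaging" would only
interpolate between adjacent voxels, so native-thickness reslicing along
a grid axis is an exact no-op, and noise-free phantoms are recovered
exactly. Samples outside the volume contribute zero and set a per-slice
flag rather than aborting (a valve near the volume edge should degrade,
not fail). Rigid shifts for coregistration use cubic-spline resampling,
which keeps integer-voxel shifts exact and shift/unshift round-trip
error below 10⁻³ of the image maximum for PSF-smooth images; plain
trilinear resampling does not reach that.

## Uptake metrics

Per-slice statistics use pixel-center containment (simple, deterministic
and convergent under grid refinement). Whole-valve SUVmean/SUVmax are
unweighted across-slice averages over every slice with a non-empty valve
ROI. MDS selects, independently for the mean and the max statistic, the
contiguous slice pair maximizing the summed value (ties to the more
caudal pair); both pairs are reported so either convention can be
audited, since "the two hottest contiguous slices" does not by itself
say which statistic drives the choice. TBR divides by, and corrected SUV
subtracts, the blood pool; negative corrected values are allowed and
flagged. Per-cusp flags compare each 120° sector's SUVmax against
`threshold × blood pool` with threshold 1.25 by default — a configurable
stand-in for a visual windowing call anchored at right-atrium blood
activity, not a claim of equivalence to a human read.

Blood pool comes from either (a) circular ROIs on 5 contiguous axial
slices of the brachiocephalic vein, most caudal at the innominate
junction, or (b) a 2-cm² ROI in the right-atrium center at the
right-coronary-ostium level plus the same pixels one slice superior.
The 2-cm² ROI is realised as the `round(area / pixel area)` pixels
closest to the atrium center, so its pixel count is exact at any
spacing.

## Phantom

The phantom paints, in world mm on an isotropic grid (default 2 mm,
72×72×96): blood pool in a chamber blob, atrium sphere, aortic-root
column and a brachiocephalic vein; lesions as flat-core blobs with
Gaussian shoulders (core = nominal radius, σ = radius/2), max-combined
with blood; faint lung background; zero myocardium. The flat core is
what lets a noise-free pipeline recover the configured peak exactly — a
pure Gaussian peak lives in one voxel and cannot survive two-slice MDS
averaging unchanged.

Per scan, the blood SUV is drawn from a zero-truncated normal
(defaults 1.10 ± 0.35, the configured between-scan spread). Lesion and
lung activity scale with `(blood / mean)^coupling` (default coupling 1):
tissue uptake tracks circulating tracer availability, so a scan is a
global rescaling of a reference pattern and the true lesion-to-blood
ratio is stable across scans. This is the mechanism that makes ratio
correction (TBR) reproducible while uncorrected SUV and subtraction
correction inherit the full blood-level swing; with coupling 0 the
lesion activity is fixed and TBR itself becomes physiologically
variable.

Gating: event phases are uniform on [0,1), binned into 4 equal gates;
gate 2 covers the 50–75 % RR diastolic window. The valve substructure
(lesions) is rigidly displaced along the valve normal per gate with
weights (1, 0.5, 0, 0.5) × amplitude (default 3 mm) — the smallest
motion model that makes gating matter, with diastole at rest. Each gate
is blurred with a Gaussian PSF (default 4 mm FWHM, chosen for
qualitative realism; no scanner is being modelled) and receives
signal-dependent Gaussian noise with σ ∝ √(activity / gate events), a
desk-scale surrogate for list-mode reconstruction noise. All randomness
derives from `(seed, scan_index)`, so outputs are bit-identical on
re-run and scan 2 of a pair redraws blood and noise on the same anatomy.

The vein tapers from 5 mm radius at the junction to 2 mm over 10 mm of
ascent through low-uptake lung, so after PSF blur its measured SUVmean
declines monotonically on the 5 ROI slices (the nonphysiological
cranial gradient), while the large atrium is flat to < 1 % across
adjacent slices. An analysis-stage craniocaudal ROI-placement jitter
(normal, SD 1.5 mm per scan, `RunConfig.roi_level_jitter_mm`) emulates
manual slice selection; on the vein's gradient it perturbs the blood
estimate by several percent per scan, on the atrium it does nothing —
which is precisely why the atrium-referenced TBR is the more
reproducible metric in simulated scan-rescan studies.

What the phantom does not emulate: attenuation, scatter, randoms,
reconstruction correlations, observer ROI variability on real anatomy,
respiratory motion, and myocardial spillover. Passing tests therefore
demonstrate the correctness and internal consistency of the analysis
chain and the direction of protocol effects, not clinical effect sizes.

## Agreement statistics

Bland–Altman uses d = m₁ − m₂, sample SD (n−1), limits bias ± 1.96 SD;
"width within ±0.2" is read as half-width ≤ 0.2 (full width also
derivable from the report). Percentage error is 100 · 2 SD(d) / mean of
all 2n measurements (pooling both lists; averaging pairwise means gives
the same number). Cohen's κ uses the asymptotic SE for its 95 % CI
(via statsmodels); the interpretation bands are implemented as
half-open intervals (−∞, .20] poor, (.20, .40] fair, (.40, .60]
moderate, (.60, .80] good, (.80, 1] very good, closing the gaps in the
conventional scale consistently with labelling κ = 0.81 "very good".
ICC is the two-way absolute-agreement single-measure form ICC(A,1),
computed from the mean-squares decomposition (pingouin's equivalent
serves as a test oracle).

Sample size per group for a two-sided two-sample t-test is the smallest
integer n whose noncentral-t power meets the target, iterating upward
from n = 2 (hence exact ceil rounding); the default grid spans 10–30 %
detectable differences at 80/90/95 % power with common SD 18.75 %.

## Problem sizes and defaults

Simulated reproducibility studies use 15 scan pairs on the default
72×72×96 grid with 2·10⁵ events per scan — a study-scale dataset that a
single scan-pair analysis completes in seconds. Monte-Carlo checks use
1000 blood-pool draws, 10⁴ Bland–Altman differences, and 5 × 500
subjects for ICC bias. Defaults throughout (2 mm voxels, 3 mm slices,
4 mm FWHM, 4 gates, 1.25 cusp threshold) are single choices made for
realism and determinism, not fitted quantities.
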