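# Methods

## Problem and model

Wearable fall-detection research validates classifiers against public
repositories of triaxial accelerometer traces recorded while volunteers
perform scripted ADLs and mimicked falls. Because traces vary enormously in
length and content, the pipeline reduces each trace to a single observation
window before computing statistics: a sliding window of duration t_W holds
N_W = round(t_W · f_s) samples (ties round up; fewer than 2 samples is an
error), and for every admissible start m the combined per-axis max–min
variation A_wdiff[m] = √(Σ_axis (max − min)²) is evaluated. The window with
the largest A_wdiff[m] is the analysis interval; the rest of the trace is
ignored. A fall shows up there as a free-fall valley of the acceleration
module followed by a sharp impact peak, so this interval is where falls and
energetic ADLs are most distinguishable.

Indexing is 0-based half-open internally. Ties in the arg-max are broken by
the earliest start index so runs are reproducible. The profile is computed
with O(N) running max/min (monotonic deques); tests pin it element-wise to
the direct O(N·N_W) evaluation.

## The twelve statistics

With SMV[i] = √(A_X² + A_Y² + A_Z²) over the window (all accelerations in g):

| statistic | definition | unit |
| --- | --- | --- |
| μ_SMV | mean SMV | g |
| σ_SMV | population SD of SMV (1/N_W normalizer) | g |
| μ_SMVdiff | (1/N_W) Σ \|SMV[i+1] − SMV[i]\| | g |
| μ_θ | (1/N_W) Σ arccos(⟨a_i, a_{i+1}⟩ / (SMV_i·SMV_{i+1})) | rad |
| μ_Ap | mean √(A_H1² + A_H2²) over the horizontal pair | g |
| A_wdiff(max) | the window's variation score | g |
| SMV_max, SMV_min | impact peak / free-fall valley | g |
| γ_SMV | population skewness of SMV | — |
| SMA | (1/N_W) Σ (\|A_X\| + \|A_Y\| + \|A_Z\|) | g |
| E | Σ_axis (1/N_W) Σ_i \|DFT(axis)[i]\|² | g² |
| μ_R | (1/N_W) Σ_m R[m], R[m] the biased normalized autocorrelation of SMV | — |

Numerical choices:

* The consecutive-sample statistics (μ_SMVdiff, μ_θ) use the N_W − 1 pairs
  fully inside the window while keeping the 1/N_W prefactor; no sample
  outside the window is ever read.
* The arccos argument is clamped to [−1, 1]; zero-magnitude vectors
  contribute angle 0.
* The DFT is plain and unnormalized, with no taper and no padding; by
  Parseval's identity E equals the sum of squared window samples, which the
  tests use as an independent oracle at 1e-9 relative tolerance.
* The autocorrelation normalizer is biased, 1/(σ²·N_W), with lags
  0…N_W − 1, so R[0] = 1 whenever σ > 0.
* For a constant window (σ_SMV = 0), γ_SMV and μ_R are undefined and
  reported as NaN rather than a numeric sentinel, which would bias group
  means. Downstream statistics drop NaNs listwise per feature and log the
  counts.

The horizontal pair (A_H1, A_H2) for μ_Ap consists of the two components
other than the gravity-dominant axis, inferred as the axis with the largest
absolute mean over the *full* trace (pre-event orientation defines the
standing reference); a metadata override wins, and ties fall back to x, y, z
order with a warning. μ_SMV, σ_SMV, μ_SMVdiff, μ_θ, SMV_max, SMV_min,
γ_SMV, μ_R and E are invariant under fixed 3-D rotations of the data; SMA,
μ_Ap and A_wdiff(max) are axis-dependent and are documented as such.
Traces are canonically stored in g; γ_SMV, μ_θ and μ_R are unit-invariant
while the amplitude-like statistics scale linearly (E quadratically), so the
unit convention is fixed once and applied everywhere (m/s² inputs are
divided by 9.80665 on read).

## Catalogue and selection

The bundled catalogue transcribes the published metadata of 25 repositories
into one flat CSV (trivially diffable). Selection criteria are a required
body position, a minimum total sample count, a minimum accelerometer range,
and name-based exclusions for purpose-based discards that no numeric rule
expresses (one repository targets fall-risk scoring and holds only 5
falls). Two records that were published as a single joint release share a
`release_group` and pool their sample counts against the minimum-samples
floor. Both bundled presets require a range of at least ±4.5 g: a sensor
whose range cannot represent the 4–5 g impact peaks typical of falls
under-records precisely the phenomenon being studied (a ±2 g device is the
canonical failure case, and ±4 g still clips the band). With these rules the
waist preset selects 7 datasets and the wrist preset 6. "Hip" is kept as a
position label distinct from "waist"; the one hip-mounted repository is not
comparable to the waist-mounted group.

The activity taxonomy maps raw labels to five classes — basic, standard,
sporting, near-fall, fall — via a bundled YAML map with normalized lookup;
any label starting with "fall" resolves to the fall class (subtype names are
open-ended), and unmapped labels raise instead of being dropped. Bare
"stumble"/"trip"/"misstep" are near-falls: they involve a loss of balance
that does not end on the ground.

## Comparison stage

Per slice × feature, each dataset's values are summarized by quartiles
(linear interpolation of order statistics — a fixed, documented convention),
whiskers attached to the most extreme points within 1.5·IQR of the box, and
outliers beyond. Mean differences are tested with a classical one-way
fixed-effects ANOVA (F and p via scipy); a table where every value is
identical is flagged degenerate rather than raised. No variance-homogeneity
pre-test or Welch correction is applied — the comparison deliberately
mirrors the standard textbook procedure.

The post-hoc display uses Tukey–Kramer comparison intervals: with q_crit the
studentized-range quantile at level α for k groups and within-group degrees
of freedom ν, group i gets the half-width (q_crit/2)·s_pooled/√n_i. For
equal group sizes the sum of two half-widths equals the Tukey–Kramer
critical difference (q_crit/√2)·s_pooled·√(1/n_i + 1/n_j), so
interval-disjointness decisions coincide exactly with the pairwise test
(verified in tests against an independent Tukey HSD implementation); for
unequal sizes it is the standard graphical approximation. Significance is
*defined* as disjointness, and the resulting matrix is symmetric with a
false diagonal. Groups left with fewer than two defined values, and slices
with fewer than two datasets, are dropped with logged reasons.

## Synthetic data generator

The generator emulates what a body-worn accelerometer records for each
movement class, building the SMV envelope first and distributing it to
components through a time-varying gravity direction (falls are characterized
by module valleys and peaks, not per-axis templates):

* **basic** — unit gravity plus Gaussian sensor noise (default SD 0.03 g),
  optional slow reorientation;
* **standard** — adds a gait sinusoid (1.8 Hz, 0.25 g) plus a smaller
  second-harmonic lateral sway, noise SD 0.05 g;
* **sporting** — faster and larger gait (2.8 Hz, 0.6 g), noise SD 0.08 g;
* **fall** — pre-fall gait to 40% of the trace, linear free-fall decay of
  the envelope to 0.3 g over 0.3 s, a 0.1 s half-sine impact whose mid
  sample is pinned to exactly `impact_peak_g`, a damped oscillation around
  1 g, then rest with gravity rotated by π/2 (lying down);
* **near fall** — dip and recovery with a mild overshoot (≤ 1.4 g), no
  rotation, no impact ≥ 2 g.

Components are clipped to the simulated sensor range, so a narrow-range
device caps the observable peak at range·√3 — the same mechanism that makes
small-range sensors unsuitable for fall data. A single trace is fully
deterministic given (params, f_s, seed). Scenario builders derive one child
seed per (dataset, class, trace) slot with a counter-based scheme and inject
the per-trace variability of real corpora: fall impact peaks drawn uniformly
from 3–8 g (falls typically exceed 4–5 g), ±15% gait-amplitude and ±10%
gait-frequency jitter. Two bundled scenarios exist: `null` (five datasets
with identical parameters and different seeds — between-dataset differences
are pure sampling noise, so downstream rejections estimate the type-I
error) and `heterogeneous` (five datasets differing in sampling rate
(25–100 Hz), noise level, and one dataset with all amplitudes doubled —
detectable heterogeneity of the kind attributed to sensor, testbed and
subject differences).

What the generator does **not** model: biomechanical realism beyond the
phase structure (no subject-specific gait spectra, no secondary impact
bounces with realistic timing), demographic effects, sensor bias/drift or
quantization, and non-scripted daily-life segmentation. Passing tests
therefore demonstrate that the pipeline's statistics and inference behave
correctly on signals with the right phase structure and known ground truth —
not that any particular real repository pair is or is not homogeneous.

## Problem sizes and defaults

Default window duration 0.5 s, with 1 s and 2 s presets (`short`/`medium`/
`long`), since published analyses repeat the procedure at several window
durations. Default α = 0.05. Scenario defaults are 5 datasets with
10/10/6/6/20 traces of basic/standard/sporting/near-fall/fall per dataset,
8 s traces at 25–100 Hz — a deliberately desk-sized corpus (260 traces)
that keeps a full simulate→extract→compare run in seconds while leaving
the heterogeneous effect (doubled amplitudes ≈ 3.5 pooled SDs on SMV_max)
detectable with power ≈ 1. The type-I calibration in the acceptance script
uses 2000 Monte-Carlo replicates of 4 normal groups of 10, and the null
scenario check pools 4 replicates of a 5 × 40-fall corpus (48 feature-level
tests). The 12 feature statistics on the null scenario are correlated and
non-normal (uniform impact-peak draws), so its empirical rejection rate is
only approximately α; the strict binomial-CI check applies to the normal
Monte-Carlo, while the scenario-level rate is reported and required to be
consistent with α in a wide band.

## Known limitations

* The catalogue stores one nominal sampling rate and accelerometer range per
  repository; multi-position devices with different per-position specs keep
  the primary sensing point's values, with the variants in `notes`.
* Quartile and rounding conventions (linear interpolation; half-up N_W
  rounding) are fixed choices where published practice is silent; changing
  them shifts boxplot fences and window lengths slightly.
* The post-hoc interval display is exact only for equal group sizes;
  unequal-n decisions are the usual graphical approximation of the
  Tukey–Kramer test.
* No resampling, filtering or gap-filling is applied to input traces;
  irregular timestamps are accepted and the metadata rate is authoritative.
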