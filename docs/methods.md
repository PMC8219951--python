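# Methods

`headkin` implements the complete trace-to-result computation for a swine
rotational-acceleration model of traumatic brain injury in which head
kinematics are measured directly with a skull-mounted triaxial angular-rate
sensor and compared against the impulsive load recorded at the pneumatic
actuator (machine) side-arm. Because no animal recordings are distributed,
a first-class synthetic-data layer emulates the study conditions; every
downstream stage is exercised and tested against that layer's known ground
truth.

## Signal conditioning

**Channel-class filter.** Both sensor streams are low-pass filtered with the
automotive-safety channel frequency class (CFC) filter, class 1000. The
realization is the canonical one: a two-pole Butterworth designed from the
published SAE J211 difference-equation coefficients with the analog corner
prewarped to 2.0775 × CFC, applied forward and then backward. The cascade
is therefore four-pole and phaseless, with unit DC gain and its composite
−3 dB point at 1.65 × CFC (1.65 kHz for CFC 1000); the single-pass corner
factor is chosen by the standard precisely so the *two-pass* response
crosses −3 dB there. Tests measure the attenuation of a 1.65 kHz tone and
compare it against the analytic frequency response of the same coefficients
(two-pass amplitude ≈ 0.715), rather than against a nominal corridor
figure. Edge handling: the trace is reflect-padded by 10 ms (well beyond
the filter settle time) before filtering and trimmed after; traces begin
near rest, so reflection introduces negligible bias. The filter refuses
sampling rates at or below 2 × 1.65 × CFC and names the minimum rate.

**Resultant.** The triaxial resultant is the sample-wise Euclidean
magnitude √(ω_c² + ω_s² + ω_a²), computed *after* per-axis filtering. It
dominates the absolute value of every individual channel and is invariant
under axis permutation and sign flips.

**Windowing and excursion.** Report windows start a configurable 4 ms
before the rise time (the last crossing of 5% of peak before the peak),
clipping at the trace start with a logged warning. Angular excursion is the
cumulative trapezoidal integral of ω(t).

## Metric extraction

**Spike screening.** Candidate peaks are the local maxima of the filtered
trace. A candidate is rejected when any of three rules fires: its value is
below 100 rad/s; its width at half *prominence* is under 0.4 ms; or it
jumps by more than 0.3 rad/s from an immediately adjacent sample. Width is
measured at half prominence (not half of the global maximum) because a
0.4 ms criterion only discriminates artifacts when measured locally. The
neighbour-jump rule is applied, by default, after subtracting the median
absolute sample-to-sample change in a 1 ms neighbourhood of the candidate —
a raw 0.3 rad/s jump criterion would mis-fire on the genuine pulse slope at
moderate sampling rates — and the raw rule remains available as a strict
mode. The highest surviving candidate is the peak angular velocity; ties
break toward the earlier peak, and every candidate's fate (accepted /
below_min / too_narrow / neighbor_jump) is logged for audit. Screening is
applied to the skull streams only; the machine stream takes its global
maximum (configurable).

**Durations.** FWHM is the interval between the last up-crossing of half
the peak value before the peak and the first down-crossing after it, with
linear interpolation between bracketing samples. Time-to-peak runs from the
last crossing of 5% of the peak value to the peak. Both are reported in
milliseconds. Because FWHM takes the *first* down-crossing, a delayed
off-axis shoulder in the resultant does not extend the measured width
unless it overlaps the crossing itself.

**Per-animal summary.** Each animal yields three rows — machine, skull
resultant, skull coronal — each carrying peak angular velocity (rad/s),
FWHM (ms), and time-to-peak (ms), extracted on that same stream.

## Statistics

- **COV** = 100 × SD/mean (SD with n−1 denominator), undefined for
  non-positive means. Reported values round half-up to one decimal; full
  precision is retained in machine-readable output.
- **Grades**: good < 5%, acceptable [5, 10], marginal (10, 20]. The
  published scale stops at 20%, so larger values get an explicit
  out-of-band "poor" label rather than a forced "marginal".
- **Percent transfer / change**: 100·a/b and 100·(a−b)/b, full precision,
  rounded half-up only for headline parity.
- **Paired t**: standard t on per-animal differences, df = n−1, two-sided.
  Effect sizes: d_z = mean_diff/SD_diff always, plus the independent-groups
  conversion d_z·√(2(1−r)) with the measured cross-condition correlation,
  each labelled with its formula. Published repeated-measures d values are
  not used as oracles: several plausible variants reconstruct materially
  different numbers from summary statistics alone.
- **One-vs-many (single-case) t**: t = (x* − mean)/(SD·√(1 + 1/n)),
  df = n−1, two-sided and deliberately uncorrected (a liberal criterion for
  declaring single-subject replication of non-significance). Type-I error
  at α = 0.05 calibrates to [0.03, 0.07] over 10,000 simulations.
- **Correlation and regression**: product-moment r with the t-based p;
  histology outcomes regress on peak + FWHM through ordinary least squares
  (statsmodels), omnibus F on (2, n−3) df, with a rank-deficiency warning
  and pseudo-inverse fit for collinear predictors.

## Immunohistochemistry quantification

Pixel intensity maps to optical density via OD = −log10((I+1)/255)
(I₀ = 255, ε = 1 guards log 0), and the image unmixes through the inverse
of a stain matrix whose rows are unit OD vectors. The default rows are the
published Ruifrok–Johnston hematoxylin and DAB vectors with an orthogonal
unit residual; the matrix condition number is logged and singular matrices
are rejected. Negative unmixed concentrations are clipped to zero with the
clipped fraction logged. The float mix/unmix transforms are exact inverses,
so the round trip is checked to 1e-6 OD; 8-bit renderings quantize on top
of that.

Bulb counting binarizes the inverted 8-bit DAB channel
(255·(1 − 10^−OD)) at a threshold defined as the intensity of the lightest
rater-accepted positive bulb (an exact minimum, not a percentile — the
margin to the background distribution is logged as a fragility diagnostic).
Components use 8-connectivity and are kept when their equivalent diameter
falls in 2–50 μm; this size filter stands in for the rater's morphology
cross-referencing, which is out of scope. Border objects are counted once
(included) since the per-field count-per-area protocol states no exclusion
rule; the choice is configurable. IgG extravasation is the percent of
pixels above a consistent pre-determined background threshold, averaged
over the six-image protocol (other counts accepted with a warning). The
IgG background threshold is a required configuration parameter: the
protocol never states its value.

## Synthetic data: what it emulates, what it does not

**Pulses** are parameterized by (peak, FWHM, time-to-peak). FWHM fixes the
base duration by closed form — half-sine T = 1.5 × FWHM, sine-squared
T = 2 × FWHM — and a requested time-to-peak splits the pulse into unequal
rise/fall quarter-waves whose 5%-rise time-to-peak matches exactly while
the FWHM closed form is preserved. The default machine impulse is
250.68 rad/s peak, 5.82 ms FWHM, 6.45 ms time-to-peak at 25 kHz with a
≥ 10 ms quiet lead-in.

**Skull response** is phenomenological (no neck/restraint mass-spring
model): the coronal channel scales the machine pulse by the transfer ratio
(default 0.51) and broadens its FWHM (default 1.91×) while keeping the
machine's rise duration — the skull tracks the drive on the way up and the
decay is what broadens. Sagittal and axial components are half-sine bursts
(defaults 55 and 62 rad/s, 4 ms FWHM) anchored *after the coronal half-max
down-crossing* (default 4 ms after it, axial a further 3 ms), because the
multiplanar motion follows the coronal deceleration; anchoring at the
crossing rather than the peak keeps the off-axis support clear of the
half-max crossing for every broadening draw, so the resultant FWHM tracks
the broadened coronal FWHM. Skull sampling is 50 kHz. Sensor noise is
white Gaussian (no noise spectrum is published for either sensor; the SD
is configurable, default 1 rad/s skull, 0.5 rad/s machine). Optional spike
artifacts are additive one-to-few-sample rectangles, matching the form the
rejection rules target; none are injected by default because the protocol
filters before screening and a raw one-sample spike does not survive the
CFC filter.

**Cohorts** draw mean-preserving log-normal per-animal factors — 8.9% CV
on transfer ratio and broadening (the observed skull-peak dispersion),
1.1% CV on the achieved machine peak — with all per-animal seeds spawned
deterministically from the cohort seed and every draw recorded in a JSON
manifest. Log-normal keeps parameters positive and the CV interpretable.

**IHC fields** are 877 × 660 μm at a default 2 μm/pixel: disjoint DAB
disks (5–15 μm diameter, rejection-sampled with a 2 px clearance so
rasterized disks stay 8-disconnected, capped retries) and an irregular
IgG region covering a specified pixel fraction, composed over a uniform
hematoxylin background through Beer–Lambert OD synthesis, with Gaussian
noise added in 8-bit intensity space.

Known gaps between the synthetic and real regimes — hence what passing
tests do and do not show: the generator's coronal channel *is* the
broadened pulse, so synthetic coronal and resultant metrics coincide,
whereas the animal data show the resultant substantially broader than the
coronal (off-axis energy inside the main pulse); machine FWHM carries no
between-animal variation (observed COV 2.5%); skull time-to-peak comes out
near the machine's (~6.4 ms) rather than the observed 5.7 ± 1.2 ms; and
real micrographs have texture, uneven illumination and rater-dependent
morphology that the flat-background fields do not reproduce. Passing tests
demonstrate the *computations* (filtering, screening, geometry, statistics,
deconvolution, counting) on calibrated inputs, not biological fidelity.

## Numerical choices and scales

Internal units are seconds and rad/s; reports use ms and rad/s. Half-max
and rise crossings interpolate linearly. Uniform sampling is enforced to
1e-9 s. Monte-Carlo problem sizes were chosen to keep the default suite
fast while leaving clear statistical margin: 100 replicate cohorts of nine
animals for the reproducibility bands, 1,000 random 200-sample traces for
the screening-oracle sweep, 10,000 simulations for single-case calibration,
and 100 noisy fields (0–40 bulbs, 8-bit noise SD 4) for count recovery. A
replicate cohort that fails extraction outright (a low transfer draw puts
an animal's skull peak under the literal 100 rad/s screening floor) counts
against the reproducibility band rather than being resampled.
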