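# Methods

`preful` implements phase-resolved functional lung MRI analysis: it turns a
free-breathing 2D+t proton-MRI series of a single coronal slice into
quantitative maps of regional ventilation, normalized perfusion and
flow-volume-loop (FVL) correlation, classifies voxels into defect
categories, and summarizes cohorts of such measurements. Because clinical
series of this kind are rarely shareable, a seeded dynamic phantom with
analytic ground truth is a first-class part of the package; every stage of
the pipeline is validated against it.

## Signal model and phantom

The free-breathing signal in a lung voxel is modeled as a superposition of
two periodic components: proton-density dilution over the respiratory
cycle (inspiration expands the parenchyma, so end-expiration is the signal
*maximum*), and blood-inflow enhancement over the cardiac cycle. The
phantom realizes this directly:

    lung:   S(x,t) = S0(x) · (1 − a(x)·r(t)) + A_q(x)·c(t)
    vessel: S(x,t) = S0(x) + A_q(x)·c(t)
    other:  S(x,t) = S0(x)

with `r(t), c(t) ∈ [0,1]` periodic waveforms (`r = 0` at end-expiration),
`a(x)` the local compression amplitude, and `A_q(x)` the cardiac pulsation
amplitude in signal units. The regional ventilation this model implies is
available in closed form,

    RV(x) = 100 · (1 − a(x)/2) · a(x) / (1 − a(x))  [%],

which is the ventilation formula below evaluated on the noiseless model
(`S_exp = S0`, `S_insp = S0(1−a)`, `S_mid = S0(1−a/2)`); for the default
`a = 0.10` it equals 10.556 %.

Default phantom parameters emulate a low-field free-breathing acquisition:
128×128 matrix at 1.7×1.7 mm, 250 frames at 300 ms (74.7 s first-to-last),
breathing at 0.25 Hz, cardiac pulsation at 1.2 Hz (safely below the
1.667 Hz Nyquist limit of the 3.33 Hz frame rate; specs at or above
Nyquist are rejected). The anatomy is deliberately minimal: two lung
ellipses inside a body ellipse with a small bright vessel disc between
them (the full-blood reference target). Baselines are background 10, body
120, lung 55, vessel 200 signal units; lung `A_q = 4` and vessel
`A_q = 40`, so true normalized lung perfusion is 10 %, matching the scale
reported for healthy parenchyma. Defects are ellipses with an amplitude
multiplier (default 0.1, i.e. a 90 % reduction); `defect_covering_fraction`
sizes one to cover a requested fraction of total lung area. Diaphragm
motion is a vertical displacement of the caudal lung proportional to
`r(t)`, ramped from the lung apex; the exact per-frame displacement field
is part of the ground truth. Noise is additive Gaussian (Rician optional);
the default is noiseless because the phantom's primary role is analytic
verification, and noisy conditions are exercised explicitly in tests.

What the phantom does **not** emulate: bSSFP banding and off-resonance,
k-space/parallel-imaging artifacts, breathing-rate variability, cardiac
arrhythmia, through-plane motion, and realistic anatomy. Passing tests
demonstrate the correctness of the algorithms under the stated model, not
clinical performance on patient data.

## Respiratory signal, mid-expiration, registration

The respiratory surrogate is the mean signal over a coarse body mask
(lower multi-Otsu threshold on the temporal mean, minus the brightest
decile, which removes the pulsating mediastinal core), low-passed at
0.5 Hz with a zero-lag (forward-backward Butterworth) filter so peak
timings are unshifted. End-expiration peaks and end-inspiration troughs
are detected with a minimum separation of half the dominant respiratory
period; respiratory phase is assigned by linear time interpolation between
consecutive end-expiration peaks (phase 0 at each peak); frames before the
first or after the last peak carry no phase and are excluded from cycle
reconstruction. Fewer than two detected breaths is an error.

The registration reference is the frame whose smoothed surrogate is
closest to the midpoint between the median peak and median trough levels,
searched on the limbs descending from each peak (ties go to the earliest
frame). For the symmetric waveforms used here the mid-position signal
state is identical on either limb, so the choice of limb is a fixed
convention rather than a physiological claim.

Registration is 2D symmetric-forces demons with Gaussian field smoothing
(σ = 2 px, 40 iterations). Two choices matter and were driven by the
contract that motionless input must produce essentially zero estimated
displacement while 3 px of diaphragm motion must be recovered to ≤ 1 px
mean residual in the lung:

* the fields are *estimated* on a temporally low-passed copy of the series
  (the registration guidance) and then applied to the raw frames — cardiac
  inflow intensity change is signal, not motion, and must not be warped
  away;
* demons forces are suppressed where the frame-to-reference intensity
  difference is below 5 % of the reference's robust intensity range —
  ventilation-induced intensity changes (a few percent of tissue signal)
  otherwise masquerade as motion along intensity edges, contaminating
  sharp defect borders.

On the default phantoms this yields < 0.001 px spurious displacement on
motionless input and ≈ 0.4 px mean residual under 3 px diaphragm motion.

## Segmentation and the full-blood reference

The lung mask is a classical baseline: body outline from the lower
threshold of a 3-class multi-Otsu on the temporal-mean image (air / lung /
soft tissue), hole-filled, largest component; lung candidates are
body voxels below an ISODATA (intermeans) threshold computed within the
body — ISODATA rather than Otsu because Otsu's histogram-bin threshold can
cut inside a narrow lung intensity mode when the lung/tissue gap is wide.
Candidates are opened and closed (4-connected structuring element), specks
below 0.5 % of the image area dropped, and the two largest components kept.
A user-supplied mask bypasses the baseline entirely and is only validated.

The full-blood reference — the region defining 100 % normalized
perfusion — is searched in the inter-lung corridor: the bounding rows of
the lungs crossed with the columns between the two lung components,
excluding lung voxels. Candidate voxels must exceed an adaptive amplitude
floor (the 75th percentile of corridor cardiac-band amplitudes or half the
corridor maximum, whichever is higher; the percentile alone degenerates
when most of the corridor is static). Among the candidates' 4-connected
components the highest mean amplitude wins; ties break to larger area,
then to smaller centroid column.

## Phase-resolved cycles and the three maps

Frames are sorted into `n_bins = 15` phase bins (`floor(phase · n_bins)`)
and averaged per voxel; 15 bins balance per-bin occupancy (≈ 17 frames of
250) against phase resolution. Empty bins are filled by circular linear
interpolation and flagged; more than 30 % empty bins aborts with an
insufficient-coverage error. The implementation is accumulation-ordered so
that it reproduces a per-voxel brute-force loop bit-for-bit.

**Ventilation.** `RV = 100·(S_mid/S_insp − S_mid/S_exp)` per voxel, with
`S_insp`/`S_exp` the minimum/maximum of the reconstructed respiratory
cycle and `S_mid` the value at the mid-expiration bin (the bin on the
expiratory return of the lung-mean cycle closest to the midpoint of its
extremes). The measure is dimensionless, invariant under global intensity
scaling, zero without modulation, and positive when `S_exp > S_insp`.
Voxels with non-positive `S_insp` are marked no-data.

**Perfusion.** Cardiac phase comes from the analytic-signal angle of the
band-passed (0.6–2.0 Hz) blood-seed mean signal, with phase 0 at peak
inflow; the detected frequency is the spectral peak in the band, and a
series whose cardiac band carries under 5 % of the seed's AC power is
rejected as having no cardiac signal. The cardiac cycle is reconstructed
from the band-passed voxel time courses (sorting the raw signal leaves
respiratory leakage in the per-bin means, biasing amplitudes up by several
percent of the reference). Per-voxel amplitude is the cycle's
peak-to-trough; `Q = 100 · amplitude / (mean amplitude over the full-blood
region)`, so the reference region averages exactly 100 % by construction.

**FVL correlation.** The volume proxy is the reconstructed respiratory
cycle; flow is its circular central difference across bins. The healthy
reference region is the largest 4-connected component of voxels between
the 80th and 90th ventilation percentiles (linear-interpolation
percentiles). The map value is the Pearson correlation between a voxel's
flow curve and the reference region's mean flow curve — bounded in
[−1, 1], invariant under per-voxel affine rescaling of the cycle, no-data
for zero-variance flow.

## Defect classification and metrics

Thresholds (defaults as calibrated at 1.5 T in the PREFUL literature, kept
configurable and recorded in every report together with a field-strength
caveat): perfusion defect `Q < 2 %`; ventilation defect `RV < 0.40 · P90`
of the in-lung ventilation distribution (or FVL correlation `< 0.9` in FVL
mode — the printed "0.9 %" can only sensibly be a correlation threshold).
Comparisons are strict: a value exactly at a threshold is non-defect. The
four categories — exclusive ventilation defect, exclusive perfusion
defect, combined V/Q defect, V/Q match — partition the valid lung area
exactly; voxels lacking data in any required map are excluded from all
denominators. `VDP = exclusive-V + combined`, `QDP = exclusive-Q +
combined`. Both the regional-ventilation and the FVL-based classification
are computed on every run; the regional-ventilation one is the headline.

Severity strata from vital capacity (% predicted) close the printed
integer bins continuously: mild `VC ≥ 88`, moderate `58 ≤ VC < 88`,
severe `VC < 58`; values above 100 are mild.

## Cohort statistics

Two-group comparisons are gated on Shapiro-Wilk at α = 0.05 (the
conventional default; recorded in each result): both samples normal →
unpaired t test (pooled variance by default, matching era-typical
software; Welch by flag), otherwise two-sided Mann-Whitney U, exact when
both groups have ≤ 8 tieless observations. Zero-variance samples bypass
the gate to the nonparametric branch with a warning. Note that gating
slightly inflates the procedure's type-I error (measured ≈ 0.052 at
nominal 0.05, n = 50 per group, 20 000 null simulations) — an inherent
property of conditional test selection, documented rather than corrected.
More than two groups use one-way ANOVA. Correlation matrices are Spearman
with average ranks and pairwise-complete observations (≥ 3 pairs per
cell; constant columns are no-data). Summaries are mean ± SEM
(SD/√n). No multiplicity adjustment is applied silently; Holm and
Benjamini-Hochberg adjusted columns are available and labeled as such.

## Numerical conventions

* 0-based row-major indexing; masks align voxel-for-voxel with the series.
* Percentiles use linear interpolation between closest ranks everywhere.
* All connected-component operations are 4-connected with deterministic
  labeling order; component ties break by area, then labeling order.
* Bin-edge phases (`phase·n_bins` integral) go to that bin (floor rule);
  phase 1.0 wraps to bin 0.
* All randomness flows through a single integer seed per phantom spec;
  identical spec + seed is bit-identical output, and the full pipeline is
  deterministic given its input.

## Known limitations

* The lung segmentation baseline assumes the three-class intensity
  structure of a coronal proton-MRI slice; it replaces the trained
  segmentation models used clinically and will not match their robustness
  on pathological anatomy. User-supplied masks are first-class for this
  reason.
* Defect thresholds are 1.5 T calibrations applied unchanged; at other
  field strengths the ventilation-related metrics shift and the report
  carries a caveat rather than a recalibration.
* Phase assignment is by time interpolation within each breath, not
  amplitude binning; under strong amplitude drift the two differ.
* The FVL correlation is computed between flow curves at matched phase
  bins, not between 2D loop point sets.
* Single-slice 2D analysis only; no through-plane motion handling.
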