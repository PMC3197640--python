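# Methods

`ehtlab` quantifies the contractile function of engineered heart tissue
(EHT) from post-deflection recordings and provides a synthetic-data
generator with ground truth so every stage of the pipeline can be
validated without laboratory data. This note documents the models, the
numerical choices, and what the synthetic validation does and does not
establish about real recordings.

## Post mechanics

An EHT is suspended between two elastic silicone posts; contraction bends
the posts toward each other. Treating a post as a cylindrical
Euler–Bernoulli cantilever of modulus *E*, radius *R* and length *L*, a
tip deflection δ corresponds to the force

F = 3πER⁴δ / (4L³)

All computation is in SI units; `PostGeometry.from_mm` accepts the
mm-scale numbers protocols quote. Post geometry is lab-specific and is
therefore mandatory configuration; `DEFAULT_GEOMETRY`
(E = 1.0 MPa, R = 0.5 mm, L = 10 mm) is illustrative only. The sign
convention is positive δ = posts bent toward each other, so force traces
are non-negative at rest. `cross_sectional_stress` divides force by the
cross-section of the tissue idealized as a circular cylinder
(default diameter 0.72 mm); note that 0.061 mN over that section is
0.150 mN/mm² by this formula.

Small-deflection beam theory only: no large-deflection or finite-element
corrections are attempted.

## Synthetic twitch model

The twitch template is a two-phase raised cosine: a half-cosine rise over
`time_to_peak` and a half-cosine fall over `relaxation_time`. It is
single-peaked, starts and ends exactly at the diastolic offset, and has a
continuous first derivative, so maximal contraction/relaxation slopes are
well defined in closed form (πA/2·t_rise and πA/2·t_fall for amplitude
A). The shape of real hEHT twitches is not constrained beyond these
properties; any smooth single-peaked template with controllable rise and
fall times would serve.

Default preset (one spontaneously beating hEHT well):

| parameter | default | unit | meaning |
|---|---|---|---|
| peak_force | 61 | µN | twitch amplitude above diastole |
| time_to_peak | 0.25 | s | baseline → peak |
| relaxation_time | 0.35 | s | peak → baseline |
| diastolic_force | 5 | µN | resting post pre-load |
| base_frequency | 0.5 | Hz | mean spontaneous rate |
| interval_cv | 0.05 | – | beat-interval coefficient of variation |
| noise_sd | 1.0 | µN | additive Gaussian sensor noise |
| dt | 0.01 | s | sampling grid (100 Hz) |

Beat intervals are lognormal with mean 1/f and the given cv (strictly
positive by construction; degenerate at cv = 0). "Irregular beating" is
modeled phenomenologically as cv inflation plus randomly skipped beats
(an interval doubling with probability `skip_prob`), not as an
electrophysiological mechanism. Only twitches that fit entirely inside
the recording are rendered and annotated; overlapping twitches are summed
and flagged. All randomness flows from one integer seed through numpy's
`SeedSequence`, so identical seed + parameters give bit-identical traces.

## Effect models

**Calcium.** Twitch amplitude follows a Hill occupancy
f(c) = c² / (c² + EC50²). EC50 is solved in closed form from the
requirement that 0.2 mM yields 10 % of the 1.8 mM baseline force
(EC50 = 0.641 mM with Hill slope 2), and the resulting curve is verified
to plateau: f(2.2)/f(3.0) = 0.964 ≥ 0.95. The generator applies
f(c)/f(1.8) so the preset amplitude holds at baseline calcium.

**Proarrhythmic compounds.** Relaxation velocity and force each follow a
descending Hill curve bounded below by 1 − max_reduction (default 0.4,
matching maximal observed effects of 30–50 %). The relaxation Hill acts
at a lower concentration than the force Hill for hERG-blocker-like
presets. Internally the generator stretches `relaxation_time` by
force_scale/relaxation_scale so that the *measured* maximal relaxation
slope (∝ amplitude/relaxation_time) scales exactly by the relaxation
factor. Above `scatter_onset` the interval cv inflates and beats are
skipped with increasing probability. Concentration–effect maps are
phenomenological; no ionic currents are modeled.

**Chronotropy.** Isoprenaline multiplies the beat frequency by a gain
(> 1, default 1.3); carbachol on top of isoprenaline restores the
baseline schedule.

## Twitch detection and measurement

The original recognition software is unpublished; the reconstruction is
deliberately minimal:

1. moving-average smoothing (default 50 ms) with reflect padding;
2. local maxima via prominence-based peak picking, requiring prominence
   above 20 % of the smoothed trace's dynamic range **and** above 6× the
   post-smoothing noise level, with a 250 ms refractory separation. The
   noise level is estimated robustly as the MAD of the raw first
   differences scaled to an SD and divided by √window; without this floor,
   sensor noise passes the fractional-prominence criterion on
   low-amplitude recordings (e.g. at strongly reduced calcium) and
   fabricates twitches;
3. per-twitch diastolic baseline = 10th percentile of the smoothed signal
   over the windows to the adjacent peaks. The decile rather than the
   strict minimum makes the baseline stable under noise (the minimum of a
   few hundred noisy samples is biased low by about two noise SDs, which
   would inflate every amplitude); on noiseless traces the two coincide;
4. amplitude = smoothed peak − baseline; maximal slopes from the smoothed
   first differences over the rising (foot → peak) and falling
   (peak → foot) limbs; contraction/relaxation times between the
   10 %-of-amplitude crossings and the peak. The 10 % foot fraction is a
   package convention (no standard fractional threshold exists) chosen
   for stability under noise;
5. twitches whose limbs are truncated by the recording boundary never
   reach the 10 % crossing and are dropped — only "measurable" twitches
   enter the averages.

Smoothing attenuates the peak and the extremal slopes by O((w/t_rise)²);
at the defaults this is < 1 % on amplitude and < 2 % on slopes. The
oracle-equivalence tests therefore use a finer window on noiseless
single-twitch inputs. Frequency is reported as n_intervals / Σ intervals
(Hz and bpm) and is flagged undefined below two twitches rather than
fabricated.

## Rhythm statistics

Beat intervals of a single recording are not normally distributed, so
scatter is summarized as the interdecile range (IDR = P90 − P10) and
group comparisons use the Mann-Whitney U test. Percentiles use linear
interpolation on (k−1)/(n−1) plotting positions everywhere in the
package (numpy's default); the convention is frozen by tests because any
percentile convention must be pinned for reproducibility.

The exact Mann-Whitney mode computes the permutation null of the midrank
U statistic: with ties, by explicit enumeration of all C(n_a+n_b, n_a)
group assignments (guarded to ≤ 2×10⁶ splits); without ties, by the
closed-form exact null, which is identical to enumeration and scales to
larger groups. Exactness matters because the experiments use n = 4
biological replicates per group, where the normal approximation is
unreliable. Two-sided p = 2·min(lower tail, upper tail), capped at 1.

## Dose–response thresholds

Cumulative dosing re-measures the same wells at baseline and at each
concentration, so the t-test is paired (two-tailed, n−1 df). Percent-of-
baseline normalization divides each well/parameter by that well's
baseline (baseline rows are exactly 100; zero baselines are flagged, not
divided).

The threshold concentration is read under a monotone-read rule: the
lowest ladder concentration at which the effect is significant (p < α
*and* in the pharmacologically expected direction — decrease for force
and velocities, increase for IDR) and stays significant at every higher
concentration. Rationale: cumulative dosing of a monotone
concentration–effect relationship cannot produce an isolated mid-ladder
significance, so such one-offs are treated as the expected false
positives of an uncorrected five-test ladder rather than as thresholds.
No multiple-testing correction is applied across the ladder (matching
practice for these screens); the report carries this caveat explicitly.

## Alignment score

Sarcomere orientations are axial (defined modulo 180°). Because the raw
interquartile range is meaningless across the 0°/180° wrap, each sample
is first canonicalized: rotated so its circular axial mean (via angle
doubling) sits at 90°, then folded into [0°, 180°). This makes the
dispersion invariant under global image rotation and reduces to the plain
IQR for concentrated samples. Relative dispersion is expressed against
90° (90° ≙ 100 % ≙ 1) and the alignment score is its inverse
(score = 90/dispersion): 9° dispersion ⇒ score 10. Zero dispersion is
reported as an infinite-score flag, not a number. Scores are computed per
(image, rater), averaged across raters within an image, then summarized
per group; groups are compared with a two-sample two-tailed t-test.
Automatic extraction of orientations from images is out of scope; the
generator samples axial angles from a von Mises distribution on the
doubled angle for validation.

## Synthetic video tracking

The renderer draws two dark marker squares whose separation shrinks by
δ(t) (each post moves δ/2), with exact area-coverage anti-aliasing so the
darkness-weighted centroid of a marker equals its true sub-pixel center.
The tracker applies an Otsu threshold, keeps the two largest dark
components (grown by one pixel to recover anti-aliased edges), and takes
darkness-weighted centroids. Resting separation is estimated as the 90th
percentile of per-frame separations — diastole dominates a recording at
0.5 Hz with ~0.6 s twitches — and δ(t) = (rest − separation)/scale.
Inter-marker distance rather than absolute marker position is used, so
plate drift cancels. Lost frames (≤ 5 %) are linearly interpolated and
flagged; more is an error. The camera model has no vignetting, focus
drift or motion blur.

## Problem sizes and tolerances

Validation uses 60-s recordings at 100 Hz (the standard recording window)
for statistics-level checks, and 8–30 s for the video path, whose
rendering cost per frame dominates. The negative-control property uses
100 simulated four-well, five-step ladders; drug-recovery and
IDR-monotonicity properties use 10–20 seeds per condition. Numerical
tolerances in tests reflect the known smoothing attenuation (1–5 %),
sampling noise at the stated seed counts, and machine precision (1e−12
relative) for the algebraic beam inverse.

## What passing tests do and do not show

The generator reproduces the statistical structure the analysis assumes:
regular lognormal beating, single-peaked smooth twitches, additive
Gaussian noise, Hill-type concentration effects. Real recordings add
baseline drift, correlated pixel noise, partial twitch fusion at high
rates, focus loss and biological amplitude run-down — none of which are
emulated. Passing the suite therefore establishes the correctness of the
arithmetic and the internal consistency of the pipeline, not the
robustness of peak detection on arbitrary laboratory video. Thresholds
measured on synthetic compounds validate the threshold *logic*; they say
nothing about any real compound's potency, which depends on living
tissue pharmacology.

## Known limitations

- The twitch template is stylized; kinetic parameters measured on real
  data should be compared within, not across, waveform conventions.
- The irregularity model (cv inflation + skipped beats) reproduces the
  scatter phenotype, not arrhythmia mechanisms; no EAD/DAD morphology is
  generated or classified.
- The exact Mann-Whitney tie mode is combinatorial; it refuses beyond
  ~2×10⁶ splits (use the no-tie exact or normal mode there).
- `alignment_score` diverges as dispersion → 0; perfectly aligned
  synthetic samples must be handled through the infinite-score flag.
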