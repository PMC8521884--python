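# Methods

This note documents the models, constants and design choices behind
`phenomarks`, in the spirit of a statistical-software methods appendix. It
describes what the code computes and why; every empirical number cited here
is one the test suite or `scripts/acceptance.py` computes at run time.

## Study structure being modeled

The pipeline targets a remote-assessment design: participants with major
depressive disorder complete weekly smartphone assessments (study days 0, 7,
14, 21, 28) while clinicians administer the MADRS at baseline, ~week 2 and
week 4 (days 0, 14, 28). During each assessment the participant views 13
affective images and speaks about each for at least 10 s; front-camera video
is processed by a face tracker into per-frame AU presence/intensity and head
pose, and the microphone records audio. The analysis sample consists of
treatment responders (≥30 % MADRS reduction over 4 weeks; eligibility
required baseline MADRS ≥ 20).

## Stimulus protocol

Image valence norms are z-scored over the pool (population SD; at pool sizes
of several hundred the population/sample distinction is immaterial).
Classes: neutral |z| ≤ 0.5, positive z ≥ 1.5, negative z ≤ −1.5, with the
in-between "buffer" images excluded to separate the classes. The negative
rule is stated in the source protocol without a sign; it is read here as
z ≤ −1.5 by symmetry with the positive rule, and the threshold is an
overridable configuration constant rather than a hidden assumption. Boundary
inclusion (closed neutral band, inclusive outer thresholds) is likewise a
documented convention; the classes partition the real line.

Each sequence follows the fixed pattern N P N X N P N X N P N X N
(7 neutral, 3 positive, 3 negative; neutral first and last; positive never
adjacent to negative). Images are drawn uniformly at random within class,
excluding everything the subject has already seen (study-wide no-repeat);
drawing from a depleted class raises an error naming it.

## Facial markers

The tracker's AU stream is gated first: frames with `success != 1` or
`confidence < 0.70` are dropped, and if nothing survives the markers are
*missing*, never zero. The AU→emotion map is not part of the source
protocol; the package defaults to the EMFACS/Ekman basic-emotion prototypes
(happiness {6,12}; sadness {1,4,15}; surprise {1,2,5,26}; fear
{1,2,4,5,7,20,26}; anger {4,5,7,23}; disgust {9,15}) because they are
conventional, auditable and swappable via configuration.

Per frame, each emotion's *match* is the fraction of its constituent AUs
present and its *intensity* the mean of their 0–5 intensities. "Most
probable emotion" is operationalized as argmax by match with a 0.5 floor,
ties broken by intensity then by a fixed emotion order; a frame below the
floor is unlabeled. One label per frame makes the six counts plus the
unlabeled fraction an exact partition (Σ = 1), which the tests assert to
1e-12. Per-frame emotion intensity uses the mean (not max or sum) of
constituent AUs so every intensity marker stays on the native 0–5 AU scale.
Overall expressivity sums the six per-frame emotion intensities and averages
over frames; an alternative composite that averages raw AU intensities
directly is provided (`overall_expressivity_au`) but is not the default.
Counts are computed within each stimulus response and aggregated later, so
per-condition analyses remain well defined.

## Voice marker

Speech/non-speech segmentation uses a windowed log-energy detector with
Praat-convention constants: 10 ms windows, sounding iff within 25 dB of the
loudest window, silent gaps < 0.3 s bridged, sounding runs < 0.1 s dropped.
All constants are configuration. The threshold is *relative*, so rescaling
the recording by any positive constant leaves the segmentation unchanged; the
corollary is that a recording containing no speech at all (only uniform
noise) is outside the detector's operating assumptions — digital silence
yields zero segments, but a noise-only recording will be segmented as
sounding. Voice percentage is speech time over total recording time, bounded
in [0,1]; reading "ratio of speech to white space" as speech/silence odds
would be unbounded and is deliberately not the default.

## Movement markers

Framewise displacement is the Euclidean norm of the translation difference
between consecutive frames, in raw tracker units per frame (all study video
is 30 fps; a per-second normalization flag exists for mixed-rate data).
Angular change is the norm of the componentwise Euler-angle difference —
adequate in the small-angle regime of a seated, front-facing subject;
quaternion geodesics would be the alternative for large rotations. Quality-
gated frames break the chain: no displacement is computed across a gap
(consecutive `frame` indices only). Head movement mean/SD are the mean and
sample SD (n−1) of the displacement series.

## Longitudinal analysis

Visit bins: days 0–6 → baseline, 7–21 → week 2, 22–35 → week 4, later days
excluded. Within subject × bin, assessments are averaged; subjects with an
empty bin are dropped (complete case), and analyses refuse to run with fewer
than two complete subjects. Min–max normalization to [0,1] exists for
plotting only and is never applied before testing.

The omnibus test is the one-way within-subject ANOVA,
F = MS_time/MS_error with df (k−1, (n−1)(k−1)). Sphericity is screened with
Mauchly's W computed in an orthonormal contrast basis, with the Box series
chi-square approximation (first and second order terms, df k(k−1)/2 − 1,
α = 0.05); at k = 2 sphericity holds trivially. Following the source
procedure *literally*, when sphericity is violated the reported row statistic
is Mauchly's W and its p-value. Because using a sphericity test as the
effect test is unconventional, the Greenhouse–Geisser-corrected F and its
p-value are always computed and stored alongside (`gg_eps`, `gg_p`) as a
robustness field; the paper-literal statistic populates the table columns.

BH-FDR is applied across the omnibus p-values of the 17 markers within one
stimulus condition (a whole-table family option exists; the choice of family
is configuration because the source layout is per-condition). Direction is
the sign of (week-4 mean − baseline mean) when the FDR-adjusted p < 0.05,
else "n/a". Pairwise visit contrasts use Tukey's HSD,
q = |Δmean|/√(MS_error/n) against the studentized-range distribution with
(k, df_error); Tukey already controls the familywise error over the three
contrasts, so no additional BH is layered on top. Degenerate inputs are
handled explicitly: zero error variance with a real time effect reports
F = ∞, p = 0 with a warning; identical columns give F = 0 and null Tukey
contrasts (q = 0, p = 1); a degenerate error term with nonzero differences
flags contrasts as NaN rather than inventing values.

Clinical rules: eligibility MADRS ≥ 20; responder (baseline − week4)/baseline
≥ 0.30; severity bands > 34 severe, 20–34 moderate, 7–19 mild, < 7
asymptomatic.

## Synthetic cohort generator

The generator is first-class code, not a fixture. A per-subject latent
severity on the MADRS scale starts at a truncated-normal baseline (mean 34.1,
SD 4.9, bounds [25, 45]) and declines linearly to baseline × (1 −
`response_fraction`) at day 28. `response_fraction` defaults to 0.45: the
responder criterion (≥ 30 %) is an inclusion lower bound, while the emulated
cohort's mean trajectory moves from the moderate/severe range into the
non-clinical range, which a 30 % mean drop would not achieve. Day-to-day
severity wobble is Gaussian (SD 1.5 points). The day-0 MADRS observation is
the latent baseline itself (the baseline rating anchors the trajectory);
later visits add Gaussian rater noise (SD 2 points), rounded to integers and
clipped to [0, 60]. In the `madrs_noise_sd = 0` deterministic limit, exact
unrounded values are returned so analytic identities (e.g. week-4/baseline =
1 − response_fraction) hold to machine precision; rounding is considered part
of the observation-noise model.

Severity drives four latent channels through linear links anchored at
severity 34 and clipped to valid ranges — expressivity level (slope 1/15
AU-intensity units per MADRS point, anchor 1.0), voice fraction (0.010,
anchor 0.55), head-movement rate (0.020 units/frame, anchor 0.50) and
head-pose rate (0.0005 rad/frame, anchor 0.012). Linear links were chosen
for transparent parameter recovery; the slopes are the generator's "default
treatment effect" and imply a large standardized change on overall
expressivity (Cohen's d well above 1.2 at the default noise levels, verified
by simulation in the test suite). Emotion *counts* are generated as null
markers (episode share + noise, independent of severity), mirroring the
mostly-flat count findings the design anticipates. Inter-assessment marker
variability is not described by any source; the per-assessment noise SDs
(intensity 0.05, count 0.03, voice 0.04, movement 0.06, pose 0.002) are free
parameters chosen once as plausible measurement noise and documented here.

Missingness is assessment-level, missing-completely-at-random (default rate
0.15, giving roughly two-thirds to three-quarters complete cases at n = 18 —
the same order as a realistic remote study); downstream complete-case
exclusion is triggered by empty visit bins.

Two paths share this latent model. The *fast path*
(`simulate_marker_table`) emits the tidy 17-marker table directly, with
overall expressivity defined as the sum of the six generated intensities —
the same identity the extraction stage satisfies. The *rendered path*
(`simulate_cohort` → `iter_records`) emits OpenFace-dialect frame tables and
audio: emotion episodes (≈1 s, covering ≈60 % of frames, mixed toward
happiness under positive stimuli and toward negative emotions under negative
stimuli) co-activate the emotion's AU set at the latent expressivity level;
presence flags are intensity > 1.0 (documented constant); pose follows an
isotropic random walk whose expected step length equals the movement rate;
audio alternates speech bursts (white noise, amplitude 0.3) and near-silence
(0.003) at the latent duty cycle. Records are rendered lazily from
per-record seed streams, so output is bit-identical for a given seed
regardless of iteration order and cohorts of any size stream to disk.

What the generator does *not* emulate: real AU estimation noise and
correlated tracker failures, facial-appearance confounds, acoustic phonetics
(pitch, jitter), informative missingness, non-responders, and item-level
MADRS behavior. Passing tests therefore demonstrate that the pipeline's
logic and statistics are correct under the assumed generative structure, not
that the markers are valid on real clinical video.

## Calibration and problem sizes

The test suite and acceptance script verify, at fixed seeds: type-I error of
the omnibus test under a spherical null (n = 18, k = 3, 1000 reps; rejection
rate expected in [0.03, 0.07]); ≥ 90 % recovery of the "+" direction for
overall expressivity, voice percentage and head movement mean over 200
simulated cohorts at generator defaults; and oracle equivalence of the ANOVA,
Mauchly, Tukey and BH routines against independent brute-force
implementations on 100+ random instances (|Δ| < 1e-8; 1e-6 for distribution
tail probabilities). Rendered-path checks use small cohorts (2–4 subjects,
1–1.5 s responses) — the rendering is linear in subjects × responses ×
duration, so these exercise identical code paths at convenient sizes.

## Known limitations

* The paper-literal "report W when sphericity fails" rule makes the row
  statistic insensitive to the actual time effect for those rows; consult
  `gg_p` for inference in that case.
* The VAD assumes some speech is present; it has no absolute silence floor.
* Euler-angle differences are not rotation-invariant for large head turns.
* BH family choice (per condition vs whole table) materially affects
  borderline rows; both are available, per-condition is the default.
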