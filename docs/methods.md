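# Methods

`swrlab` re-implements, as a tested library, the quantitative analysis
stack of a mouse social-memory electrophysiology study: vCA1 LFP spectral
measures, sharp-wave-ripple (SWR) detection, social-discrimination
behavioral scoring, confocal histology quantification, and the group
statistics that tie them together. Every stage is driven by a synthetic
data generator with known ground truth, so the whole pipeline is
verifiable without raw recordings. This note documents the models, the
defaults and why they were chosen, the numerical decisions, and what the
synthetic validation does and does not establish about real data.

## Spectral pipeline

The LFP is conditioned with a zero-phase 60 Hz IIR notch (quality factor
30, i.e. 2 Hz of −3 dB bandwidth) followed by a zero-phase 4th-order
Butterworth low-pass at 100 Hz. A "0–100 Hz band-pass" is implemented as
a low-pass with explicit mean removal, since a true 0 Hz lower edge is a
no-op beyond DC. All filters are applied forward–backward
(`sosfiltfilt`), preserving timing for the envelope analyses downstream.

Power spectra use Welch averaging with 2 s Hann segments and 50 %
overlap. Two seconds resolves the 4 Hz theta edge while averaging ~300
segments over a 5-min trial; the segment length is configurable. The
spectrum is restricted to the estimator bins in [0, 100] Hz and
normalized to unit sum, making band powers dimensionless fractions of
total low-frequency power and scale-invariant: multiplying the trace by
any positive constant leaves the normalized spectrum unchanged.
Normalization is applied once per session (not per time window); the
whole-session convention is the simpler reading of "summed power across
time for the entire session" and is flagged here as the place to start a
sensitivity analysis if per-window normalization ever matters.

Band powers sum bins over half-open intervals `[lo, hi)`, so disjoint
bands tiling [0, 100) partition unity exactly. Theta is 4–12 Hz, low
gamma 30–55 Hz. Session band powers can be divided by the baseline
trial's band power to give the baseline ratio used throughout the study
design.

## Sharp-wave-ripple detection

The detector is the classical Hilbert-envelope construction: notch,
band-pass 150–250 Hz, analytic-signal magnitude, z-scored against the
whole recording's envelope mean and SD. Events are excursions of the
smoothed envelope above 3 SD lasting at least 15 ms. Unstated details
are surfaced as configuration with these defaults:

- **Smoothing** (`smooth_ms = 8`): a short moving average of the
  z-scored envelope before thresholding, our reading of a
  "rolling-average amplitude threshold" applied to a z-scored signal. A
  strictly local baseline (rolling mean/SD over a window of seconds) is
  available via `ripple_envelope(..., rolling_baseline_s=...)` for
  recordings with a drifting noise floor; the global z-score is the
  default because the z-score-first construction implies a
  whole-recording reference.
- **Boundaries** (`boundary_sd = 0.5`): after the 3 SD / 15 ms core
  test, event edges are extended outward to the nearest 0.5 SD crossing.
  Peak-only intervals systematically underestimate ripple duration.
- **Merging** (`merge_gap_ms = 15`): events whose extended boundaries
  sit closer than 15 ms are merged — envelope ringing should not split
  one ripple into two.
- **Immobility**: detection runs on the whole trace; events whose
  envelope peak falls in a mobile epoch are flagged and excluded from
  summaries by default (`immobile_only=True`), because SWRs are a
  quiet-wakefulness phenomenon and the study normalizes event counts to
  immobility time.

Summaries report count, mean peak z, mean duration, mean onset-to-onset
interval (undefined below two events; onset-to-onset chosen over
offset-to-onset as the more common convention), events per
immobility-second, the same measures per 60 s bin, and each measure's
ratio to a baseline-trial summary. The first-minute window of the
familiar trial is extracted with a half-open `[0, 60)` s slice.

### Temporal resolution limit of the duration gate

A 150–250 Hz band-pass has ~10 ms of impulse-response width, so any
burst — however brief — appears at least that wide in the envelope. At
moderate amplitudes (≲15× the envelope noise SD) a 10 ms burst stays
above 3 SD for well under 15 ms and is correctly rejected, while 25 ms
and longer ripples pass. At extreme amplitudes (≳20× the envelope noise
SD) the stretched skirts of even a 10 ms burst can exceed 3 SD for more
than 15 ms; no fixed-level duration rule can reject those while keeping
weak long ripples. The validation suite therefore demonstrates the
duration gate at 10× the envelope noise SD, squarely inside the regime
where the rule is physically meaningful.

## Synthetic LFP generator

Traces are a sum of: an 8 Hz theta and a 40 Hz low-gamma carrier, each
amplitude-modulated at 30 % depth by a slow (0.05–0.2 Hz) sinusoid so
their spectral mass stays inside the band; 1/f ("pink") noise generated
by spectral shaping with exponent 1.0 (configurable) and scaled to a
target SD; a 60 Hz line-noise sinusoid; and Hann-windowed ripple bursts
with frequencies in 150–250 Hz. The mobility track alternates immobile
and mobile bouts with exponential lengths (mean immobile bout 10 s); the
mobile-bout mean is set so the long-run immobile fraction matches the
configured target. Ripple count is Poisson with mean rate × immobile
seconds; each burst is placed uniformly over immobile samples and
redrawn (up to 100 attempts) if it would cross a mobility boundary or
overlap a previous burst, so the ground truth satisfies the invariants
the detector is scored against.

Defaults emulate the study's recording conditions: 1 kHz sampling (the
recording rate is metadata, not a contract), 3-min baseline and 5-min
social trials, theta 40 µV > gamma 10 µV > line 5 µV over 15 µV pink
noise, ripples of 25–80 ms at 25–50 µV (≥ 12× the ~2 µV ripple-band
envelope noise SD, comfortably above the 5× floor the detector
validation assumes), rate 0.2 events per immobility-second, immobility
fraction 0.5.

What the generator does *not* emulate: sharp-wave deflections coupled to
the ripple, spindle or movement artifacts, electrode drift,
non-stationary line noise, or state-dependent theta/gamma modulation.
Passing the detector oracle therefore shows the implementation is
correct under clean, stationary conditions with known morphology — not
that the default thresholds are optimal for any particular real
recording.

## Behavioral measures

The three-trial direct social interaction test yields per-mouse
difference scores: novelty score N1 − F and discrimination score F − N2
(signed; the absolute value is exposed separately since figures often
report magnitudes). Missing trials produce NaN markers rather than
dropped mice, so missingness propagates visibly. The object-location
discrimination ratio is (moved − familiar)/(moved + familiar), bounded
in [−1, 1], antisymmetric, undefined at zero total exploration.
Familiarization time-to-criterion is the first time cumulative
exploration reaches 30 s, censored at 600 s (reaching exactly 600 s
counts as reached). Elevated-plus-maze summaries count zone dwell times
and entries over a 300 s session from a transition log; the initial
center placement is not an entry — an entry requires a transition. That
convention (and the upstream four-paw scoring question) is a documented
choice, not something the measures themselves can decide.

The behavior generator draws one row per mouse × drug × trial around a
(genotype × virus × drug × trial) cell-mean profile, with a Gaussian
per-mouse random intercept. `within_mouse_corr` (default 0.5) is the
intraclass correlation: the total noise SD (default 15 s) is split
between intercept and residual. The default profile encodes the study's
qualitative result structure — wild types prefer novelty in every cell
(60 vs 30 s), knockouts are flat (~34 s), and DREADD-carrying knockouts
recover preference under CNO (55 vs 30 s) — with magnitudes in the range
typical for 5-min social trials.

## Group statistics

`t_from_summaries` computes the unpaired two-tailed t directly from
published-style summaries (mean, SEM, n), recovering SDs as SEM·√n. The
pooled (classical Student) variant is the default — it reproduces the
study's printed df — and Welch is a flag. On summaries derived from raw
samples it matches the raw-sample t to machine precision.

`fit_factorial` owns design construction and term bookkeeping and
delegates the numerics: pure between-subject designs to OLS with a
type-II ANOVA table; one-between × one-within designs to the classical
mixed-design ANOVA (exact F tests); and general designs with a random
intercept per mouse — e.g. electrode-level band powers, three electrodes
nested per mouse — to a linear mixed model with per-term Wald F tests.
For the Wald tests the denominator df is approximated as
(number of subjects − number of fixed-effect parameters), floored at 1;
digit-level parity with any particular mixed-model implementation is not
a contract. Bonferroni adjustment is min(1, p·m); Tukey pairwise
comparisons use standard studentized-range machinery; a two-tailed
Pearson correlation covers the theta-power–vs–investigation analysis.

Calibration is verified by simulation: under a null mixed design
(n = 10/group, 1000 replicates) every term's type-I rate must fall in
0.05 ± 0.02, and a 40 s genotype × trial interaction at noise SD 20 s
and n = 13/group must be detected in ≥ 80 % of replicates.

## Histology quantification

Each z-slice receives a rolling-ball background subtraction (radius 50
px), implemented with the grayscale-morphology ball construction. The
background is estimated on a Gaussian-presmoothed copy (sigma 2 px) and
subtracted from the original slice, mirroring the presmoothing of
desktop background-subtraction tools: without it the ball rides the
noise minima and biases the background low by roughly the noise
amplitude. A constant image subtracts to exactly zero, and the output is
never negative. Two residual biases are worth knowing about: the ball
cap penetrates a bright plateau of width w by up to w²/8r intensity
units (negligible when labeled structures are much narrower than the
ball), and any leftover noise-floor bias is additive, so it partially
cancels in the target/reference ratio.

Region intensity is the maximum over slices of the per-slice ROI mean
("max mean gray value"); the CA2 value is divided by the corpus-callosum
value of the same section, and a brain's normalized intensity is the
mean over (typically three) sections. ROIs are polygons rasterized with
a center-in rule. Cell density divides a manual count by ROI area × 40
µm section thickness, converted to cells/mm³; co-label fractions turn
(A+, B+, A+B+) counts into the two conditional percentages.

The stack generator places non-overlapping rectangular ROIs (default 12
px wide, interior) over a flat background with per-slice signal levels
and Gaussian pixel noise, recording the true normalized ratio. The
validation regime — signal 4× a background of 10, SNR 10 — recovers a
true ratio of 2.0 within 5 % on every one of 20 seeds (bias < 2 %).
Real tissue adds structured background, depth-dependent attenuation and
anisotropic PSF blur that this generator does not model.

## Pipeline and determinism

`pipeline.run` drives simulate → detect/measure → summarize → statistics
from one `RunConfig` whose defaults are the study constants (60 Hz
notch; 0–100, 4–12, 30–55, 150–250 Hz; 3 SD; 15 ms; radius 50; 40 µm;
3-min baseline; 5-min trial; 60 s familiar window). The global seed fans
out to per-stage child seeds via `SeedSequence.spawn`, so stages can be
re-run in isolation from the logged effective config. Outputs are CSV
tables plus a JSON summary, an effective-config JSON that replays to
identical outputs, and a run log that records every parameter used and
deliberately no timestamps — two runs with one seed are byte-identical.

## Validation problem sizes

The studies in `swrlab.validation` (run by the test suite and
`scripts/acceptance.py`) use: 100 fuzzed traces for unit-sum
normalization; 20 simulated 5-min trials (~600 true ripples) for
detector precision/recall; 200 replicates at n = 14/group for
behavioral sign recovery; 1000 null and 200 effect replicates for
factorial calibration and power; 20 stacks for histology recovery; and
two full pipeline runs for determinism. Together they complete in about
a minute on one core.

## Known limitations

- The duration gate's amplitude regime (above) is a physical limit of
  envelope-based detection, not an implementation artifact.
- Mixed-model Wald F tests use an approximate denominator df; for
  publication-grade electrode-level inference, confirm against a
  dedicated mixed-model package.
- The generators are oracles for correctness, not realism: thresholds
  tuned here should be re-examined on real recordings with their own
  noise floors.
- Vendor acquisition formats are out of scope; traces enter as float32
  binary + JSON sidecar or are simulated.
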