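# Methods

## Scope and design

`stethosim` models a paired-device auscultation study as four coupled
stages: (1) simulation of a study-shaped cohort of lung-sound recordings
with ground-truth adventitious events, (2) normalization and Butterworth
band-limiting, (3) rule-based detection of crackles and wheezes with
per-recording continuous scores, and (4) agreement evaluation (PPA/NPA, ROC
cutoff-interval optimization, Cohen's kappa, cohort summary) stratified by
device.  Every stage is deterministic given a configuration and a seed.

## Acoustic models and their assumptions

**Crackle.**  A half-sine unidirectional deflection of width
`initial_deflection_fraction × 2CD` followed by an exponentially damped
sinusoid at the oscillation frequency, with the decay constant
`λ = ln(10)/(T_total − T_defl)` so the envelope reaches exactly 10 % of the
peak at the total duration.  This makes "total duration width" an
operationally measurable quantity shared by the generator and the detector.
Two-cycle duration is fixed by the oscillation frequency (2CD = 2/f).
Assumptions: additivity over background noise, no reverberation or chest
transfer function, stationary morphology within an event.

**Wheeze/rhonchus.**  A Tukey-windowed (α = 0.1) sinusoid plus optional
harmonics at relative amplitude 0.3^h.  The light taper keeps the RMS of a
pure wheeze within ~3 % of A/√2 while avoiding spectral splatter at the
edges.  Wheezes and rhonchi are pooled as one category.

**Vesicular background.**  Gaussian noise band-passed to 100–1000 Hz
(4th-order Butterworth, zero-phase) and amplitude-modulated by
`0.25 + 0.75 sin²(πt/T)` with breath-cycle period T = 3 s (a typical
pediatric respiratory rate of ~20/min).  Overall RMS 0.02 leaves headroom so
event mixing rarely clips.

**Event loudness.**  Events are mixed at a fixed event-to-noise power ratio
measured over the event's own support; the default 25 dB represents clearly
audible adventitious sounds.  Detector validation additionally uses a
harder 20 dB batch.

**Devices.**  One master render at 44100 Hz ("one ground truth, two
observations"); each device profile is an anti-aliased polyphase resampling
to the device rate followed by bit-depth quantization — 44100 Hz/32-bit
float for the high-fidelity profile, 4000 Hz/16-bit PCM for the
low-fidelity one.  16-bit quantization uses the PCM int16 convention so the
WAV round trip is exact.

## Cohort generator

Defaults mirror the emulated study design: four groups (9 normal, 5
wheeze-only, 5 crackles ± wheeze, 6 CF clear-chest), four posterior-thorax
quadrants per participant, two devices, 20-second recordings, and four
aberrant recordings excluded per device (near-silent "poor chest contact"
or clipped/dropout "cable failure" signals).  Event densities per
20-second recording are Poisson with mean 6 crackles and 2 wheeze
segments; crackle oscillation frequencies are drawn uniformly in
[150, 800] Hz (2CD 2.5–13.3 ms), total durations at 1.4–1.8 × 2CD (max
~24 ms), wheeze dominant frequencies in [150, 900] Hz and durations in
[80, 2000] ms — all comfortably inside the waveform criteria and the
analysis band.  These densities and loudness values are stated assumptions,
not measurements.  Demographics are covariates only: the female count is
fixed at `round(0.28 × n)`, ages are log-normal with median ≈ 6.7 years,
and weight follows a linear pediatric weight-for-age rule.

Per-site audio is rendered lazily from seeds spawned with NumPy's
`SeedSequence`, so any single recording can be reproduced bit-identically
without materializing the cohort (≈ 700 MB of master audio) in memory.

What the generator does **not** emulate: heart sounds, transmitted voice,
ambient clinic noise, sensor coupling variation, respiratory-phase
dependence of events, or fine vs coarse crackle subtypes.  Consequently,
passing tests demonstrate the correctness of the measurement and evaluation
machinery under the stated acoustic model — not clinical performance on real
recordings.

## Preprocessing

Peak normalization to 0.9 (per recording), then a 6th-order Butterworth
high-pass at 100 Hz and a 4th-order low-pass at 1000 Hz, both zero-phase
(`sosfiltfilt`, second-order sections for numerical robustness).
Zero-phase filtering was chosen because the analysis is offline and the
crackle criteria measure timing and duration, which forward-only filtering
would bias; the squared magnitude response (−6 dB at the cutoffs) is the
documented consequence.  At sample rates at or below twice the low-pass
cutoff the low-pass stage is unrealizable and skipped with a warning; the
4000 Hz device (Nyquist 2000 Hz) still receives both stages.

## Detection

**Crackles.**  Candidates are proposed where a 5 ms mean-rectified envelope
exceeds 4 × a rolling-median baseline (1 s window, computed on a ~200 Hz
decimated envelope).  The envelope window is deliberately comparable to the
shortest in-criterion crackle (~5 ms total duration): a longer window
dilutes short transients below any usable threshold at realistic
event-to-noise ratios.  Each candidate window (10 ms before to 40 ms after
the peak) is then measured: deflection onset is the last point before the
peak where the Hilbert envelope is below 10 % of peak; 2CD is the time from
onset to the fifth baseline crossing (the deflection's return to baseline
plus two full oscillation cycles); total duration is the time from onset
until the envelope stays below 10 % of peak for ≥ 3 ms.  Acceptance
requires 2CD < 20 ms and total < 25 ms.  The Hilbert envelope is used
because a moving-maximum envelope widens transients by its window length
and systematically inflates measured durations.  The 10 %-of-peak floor
also provides natural noise immunity: background excursions never decay
below 10 % of their own peak, so they fail the total-duration criterion.

**Wheezes.**  A Hann spectrogram (50 ms frames, 12.5 ms hop; ≤ 25 Hz
resolution at 4000 Hz) is scanned for tonal frames: spectral peak magnitude
> 6 × the frame's median magnitude, with both statistics restricted to the
100–1000 Hz analysis band — outside it the band-pass has already emptied
the spectrum, which would deflate the median and mark every frame tonal.
Consecutive tonal frames with < 20 % relative peak-frequency jump are
merged, and the merged region's support is refined in the time domain: the
region is narrow-band filtered (± 25 % around the dominant frequency) and
the support is the contiguous run above half the envelope maximum
containing the peak (a first-to-last crossing span would bridge unrelated
noise excursions).  Segments must exceed 25 ms and 100 Hz.

**Scores.**  The per-recording continuous scores play the role of an opaque
classifier's probability outputs: `crackle_score = 1 − exp(−n/4)` (four
accepted crackles ≈ 0.632) and `wheeze_score` = detected tonal time divided
by recording duration, capped at 1.  Both are monotone in event load.
Presence calls are strict (`score > cutoff`), so a score of exactly 0 is
never called present.  No attempt is made to match any particular
classifier's score distribution.

## Evaluation

PPA = tp/(tp+fn) and NPA = tn/(tn+fp) against the ground-truth tags;
"TPR" is reported as PPA by default, with the precision-style tp/(tp+fp)
reading available via configuration, since both readings circulate and they
differ whenever false positives and false negatives are imbalanced.  The
ROC enumerates one operating point per distinct score value plus a sentinel
below the minimum (the only way to call everything positive under strict
`>`); the optimal cutoff is the point maximizing PPA + NPA, ties broken
toward higher NPA then lower cutoff, and is reported as the maximal
half-open interval `[lo, hi)` of cutoffs producing the identical confusion
table.  The sentinel cutoff may be slightly negative; it is a label for
"below every score", not a probability.  Cohen's kappa is computed per
sound type via scikit-learn, with the degenerate both-raters-constant case
defined as 1.0; the pipeline's inter-rater figure re-runs the deterministic
labelling operator on the recordings of 20 % of participants and reports
the per-sound kappas and their minimum.  Excluded recordings never enter
evaluation.  Cohort summaries use standard medians, linearly interpolated
IQRs, and integer percentages.

## Numerical choices and degenerate inputs

All filters are designed as second-order sections; zero-length or all-zero
signals raise explicit degenerate-input errors rather than returning NaN;
undefined agreement metrics (zero denominators) are reported as `None`,
never 0; quantization error is bounded by 2⁻¹⁵ by construction; the whole
rendered mix is rescaled if its peak exceeds 1 (power ratios unaffected).

## Problem sizes

The default cohort (200 × 20 s recordings, master rate 44.1 kHz) evaluates
end to end in under a minute on one core thanks to lazy rendering; detector
validation uses an 8-recording 20 dB batch; ROC equivalence checks use
≤ 100-recording score sets against a brute-force dense-cutoff oracle.

## Known limitations

The detector's duration measurements operate on band-limited audio, so
low-frequency crackles whose true total duration is near the 25 ms limit
can be broadened past it by the 100 Hz high-pass ringing and rejected
(~3–4 % of generated crackles); this is a property of measuring the
criterion after the study's own preprocessing, not a bug.  Overlapping
crackles closer than the candidate window may be merged and counted once.
The low- vs high-fidelity device comparison reflects resampling and
quantization only; real device differences (microphone response, onboard
processing) are out of scope.
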