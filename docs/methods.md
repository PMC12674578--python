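# Methods

This note documents the models and procedures implemented in `dolphinpam`,
the choices made where the method definitions were open, and what the
synthetic-data tests do and do not demonstrate about real recordings.

## Signal model and SNR

Audio is held as float64 in the symmetric range [−1, 1] (16-bit PCM
divided by 32768). Min-max normalization to [0, 1] — the convention of
released whistle-clip datasets — exists only as an export option, because
it introduces a DC offset and rescales variance, both of which would
corrupt the variance-ratio SNR. Analysis always runs on the symmetric
representation.

The windowed SNR is a broadband variance ratio: for each contiguous,
non-overlapping 2-ms window (starting at sample 0, trailing remainder
dropped), `snr_db = 10·log10(var(window)/var(noise))`. The noise reference
is the sample variance (ddof = 1) of a vocalization-free segment, chosen
by the analyst or auto-selected as the minimum-variance 1-s stretch on a
half-length-hop grid — the stretch least likely to contain transients. An
alternative reading of "mean SNR per window" would average a per-sample
SNR inside each window; the defining formula is written in variances, so
the variance ratio is implemented. A window of exactly zero variance maps
to a −120 dB floor rather than −∞ so downstream arithmetic stays total.

Consequences that the property tests pin down: adding a DC offset to the
raw input leaves the SNR series unchanged after filtering; scaling signal
and noise together changes nothing; doubling the noise variance lowers
every window by exactly 10·log10(2) dB.

## High-pass filter

Butterworth high-pass, order 5, cut-off 3 kHz (both configurable),
designed in second-order sections. It is applied forward-backward
(zero-phase): detected peak times feed inter-click-interval measurement,
and a causal application would delay transients by a frequency-dependent
group delay and bias ICIs. The cost is doubled attenuation in dB; the
−3 dB-at-cutoff property is therefore stated — and measured in the tests —
on the single-pass prototype, whose magnitude response is exposed
separately (`highpass_magnitude_db`).

## Peak detection and ICI classification

A 2-ms window is a peak iff its SNR ≥ *Th* and both neighbors are < *Th*.
This two-sided rule is implemented literally, including its consequence
that two adjacent supra-threshold windows yield no peak: a click whose
energy straddles a window boundary (clicks arriving at exactly the window
phase of the 2-ms grid) can be missed. An optional `local_max` mode
(strict local maximum above *Th*, left-strict tie break) is available for
dense buzzes, default off. Synthetic test scenes place click centers
mid-window — the "isolated click" regime the rule is designed for.

When no threshold is supplied it is chosen from the sensitivity curve of
peak count versus threshold. The count of windows passing the one-sided
criterion is non-increasing in *Th* (the two-sided count need not be); the
suggested threshold is the plateau onset of that curve, located as the
largest positive second difference of log10(count+1) over thresholds whose
count is still positive, then advanced while the count still drops by more
than 20% per grid step. The log scale makes the exponential noise decay
near-linear so the bend into the signal plateau dominates; the advance
step handles noise decays so steep they span only a couple of grid points.
On pure-noise scenes this lands above the noise tail and yields zero
sequences.

Peaks group into sequences wherever the gap to the previous peak is
≤ 2.0 s; sequences with fewer than 3 peaks are discarded, so every
reported mean ICI averages at least two intervals. Both values are
configurable; 2.0 s comfortably exceeds the slowest (ECT) ICI regime.
Sequence duration is last-minus-first peak time, and the sequence SNR is
the mean over its peak windows.

Mean ICI maps to a category by a total, exclusive partition: FB at or
below 0.017 s, BPS above 0.017 s up to and including 0.22 s, ECT above.
The 0.22 s point belongs to BPS because the ECT definition requires an
interval strictly longer than 0.22 s.

## Whistle duration classes

Class 1: d ≤ 0.2 s; class 2: 0.2 < d < 0.4 s; class 3: 0.4 ≤ d < 0.8 s;
class 4: d ≥ 0.8 s. The published class definitions leave d = 0.4 s
unassigned (class 2 open above, class 3 open below); it is assigned to
class 3 so that every boundary except the two stated closures (0.2 to
class 1, 0.8 to class 4) follows one convention (lower-closed,
upper-open). Label files round-trip at 6-decimal (µs) precision.
Spectrogram exports use a Hann window of 1024 points; the overlap is not
part of the interchange convention and is fixed at 50%. The colormap is
viridis (any perceptually uniform map serves). The OFFSET in exported clip
names is the floor of the whistle start second.

## Activity blocks

The built-in schedule reproduces the study day: five ORD training
sessions, one PLAY and one FFR session across 2021-11-20/21, NIGHT from
19:00 to 07:00, and FREE_ACT filling every daytime gap. The block grid
runs 10:21 (day 1) through 10:11 (day 2) — 287 five-minute blocks aligned
with the block-file names. Three conventions the source material leaves
open: an event belongs to the half-open block [start, start+300 s)
containing its *start* time; a block's activity is that of the window
containing its *midpoint*; and a block is excluded when its span
*intersects* an exclusion window (default 05:00–07:00, a period of
external disturbance). FREE_ACT rows are kept in the table but flagged out
of statistics, since unstructured behavior provides no reliable context.

## Statistics

All tests are rank-based; count data are discrete and heavily tied.

- **Mann-Whitney U**: exact by full enumeration of all C(n+m, n)
  labelings (midranks for ties, two-sided deviation of U from nm/2) when
  both groups have ≤ 8 observations; otherwise the tie-corrected normal
  approximation with continuity correction. The switch point keeps the
  largest enumeration at C(16,8) = 12 870 labelings.
- **Kruskal-Wallis**: tie-corrected H with a χ²(k−1) p-value; all-equal
  input returns H = 0, p = 1 by convention.
- **Dunn post hoc** (3+ groups): pooled-midrank z with tie correction
  T = Σ(t³−t)/(12(N−1)), Bonferroni multiplier = number of pairs. Written
  in-package from the standard formula and cross-checked in the tests
  against an independently coded rank oracle.
- **KDE**: Gaussian kernel, bandwidth 0.4 *in count units* by default —
  the literal reading of the stated bandwidth. Because 0.4 counts is
  narrow relative to per-block count spreads, a `factor` mode
  (bandwidth × sample SD, the convention of KDE softwares that take a
  scale factor) is available via configuration. The default grid extends
  5 bandwidths past the data range at a step ≤ h/10, which makes the
  trapezoid integral 1 to within 10⁻³.

Two-sided alternatives are used throughout.

## Synthetic data

The generator emulates the recording conditions: 192 kHz mono audio,
i.i.d. Gaussian background noise of controlled variance, clicks as
Gaussian-windowed tone bursts (default 60 kHz center, 100 µs duration —
inside the 40–80 kHz dominant band of bottlenose clicks), and whistles as
Hann-windowed linear chirps within 1–25 kHz. Event amplitude is calibrated
so the 2-ms window containing the event reaches the requested SNR over the
noise variance: the burst energy E satisfies E/N_win = σ²(10^(SNR/10) − 1).
Measured window SNRs land within ±1 dB of the request after filtering.

Simulated days draw per-block counts from Poisson rates — defaults of 12
whistles and 50 pulsed vocalizations per block during activity versus 2
and 5 overnight, matching the observed per-block density peaks of the two
conditions — with event times uniform within the block. Whistle durations
are lognormal with mean 0.63 s and SD 0.45 s (the dataset-level duration
statistics), so all four duration classes are populated; pulsed categories
are multinomial in the proportions 517:489:271 (ECT:BPS:FB). All
randomness flows from one explicit seed; identical specs and seeds produce
bit-identical audio.

What the generator does *not* model: pool reverberation and multipath,
overlapping vocalizations from multiple animals at matched amplitudes,
non-stationary noise (pumps cycling, visitor noise), frequency-modulated
click spectra, and whistle contour structure. Passing tests therefore
demonstrate the pipeline's correctness on its stated contract — isolated
transients over stationary noise — not field-grade detection performance.

## Problem sizes in the test suite

Detector-recovery scenes are a few seconds of 192 kHz audio per ICI regime
(0.01, 0.1, 0.4 s), clicks at 15 dB window SNR against a 10 dB operating
threshold. The behavioral-contrast property runs 100 independently seeded
simulated days (287 blocks each) and requires activity-vs-night
Mann-Whitney p < 0.001 for both whistle and pulsed counts in at least 95
of them; at the default rate contrast the observed rate is 100/100. These
sizes were chosen as the smallest that exercise each property with
negligible flakiness.

## Known limitations

- The two-sided peak criterion misses clicks whose energy splits across a
  window boundary; `local_max` mode is the escape hatch.
- The sensitivity-knee threshold is a heuristic; on recordings whose noise
  is strongly non-stationary the analyst should supply *Th* explicitly.
- Whistle *detection* is out of scope by design: whistles are annotated
  manually, and this package manages those annotations.
- Per-vocalization SNR is reported as the mean over peak windows; other
  definitions (e.g. over the whole event span) would give different values
  for long, sparse sequences.
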