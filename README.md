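# dolphinpam

Passive-acoustic-monitoring (PAM) analysis of bottlenose dolphin
(*Tursiops truncatus*) vocalizations in managed-care settings: detection
and classification of pulsed vocalizations, management of manually
annotated whistles, per-block vocalization counting against a daily
activity schedule, and nonparametric comparison of vocal rates across
behavioral contexts. A synthetic-scene generator provides ground-truthed
hydrophone audio so the entire pipeline is testable without field
recordings.

## Who it is for

Bioacousticians working with continuous hydrophone recordings stored as
timestamped 5-minute WAV blocks (`YYYYMMDD_hhmmss_192.wav`), who need to
(a) find echolocation click trains, burst-pulse sounds and feeding buzzes
automatically, (b) organize analyst-made whistle annotations, and (c) ask
whether vocal output differs between behavioral contexts such as training
sessions, play, feeding and overnight rest.

## The method

**Pulsed vocalizations.** The signal is high-pass filtered (Butterworth,
5th order, 3 kHz cut-off, applied zero-phase) and split into contiguous
2-ms windows. Each window's SNR is the variance ratio against a
vocalization-free noise segment:

    SNR = 10 · log10( σ²_window / σ²_noise )   [dB]

A window is a *peak* when its SNR reaches the detection threshold *Th*
while both neighbors stay below *Th* (an isolated transient, not a
plateau). *Th* is either supplied or chosen from a sensitivity analysis of
peak count versus threshold (the knee where the noise-driven decay gives
way to the signal plateau). Peaks separated by less than 2 s group into
sequences; each sequence is classified by its mean inter-click interval
(ICI):

| category | mean ICI |
|---|---|
| feeding buzz (FB) | ≤ 0.017 s |
| burst-pulse sound (BPS) | 0.017 – 0.22 s |
| echolocation click train (ECT) | > 0.22 s |

**Whistles.** Analyst annotations travel as Audacity-importable
tab-separated label files (start s, end s, tag) and are binned into four
duration classes (class 1: d ≤ 0.2 s; class 2: 0.2 < d < 0.4 s; class 3:
0.4 ≤ d < 0.8 s; class 4: d ≥ 0.8 s). Each annotation can be exported as a
[0, 1]-normalized WAV clip plus a 0–25 kHz linear-scale spectrogram PNG
(`<block>-colspectro-W-<OFFSET>.{wav,png}`).

**Behavioral statistics.** Events are tallied into 5-minute blocks labeled
by the activity containing the block midpoint (ORD training, PLAY, FFR
feeding, NIGHT, FREE_ACT); disturbance windows and unstructured FREE_ACT
blocks are flagged out of statistics. Per-block counts are compared with a
Mann-Whitney U test (pooled activity vs night; exact enumeration for small
groups, tie-corrected normal approximation otherwise), Kruskal-Wallis
across contexts, Dunn's post hoc z tests with Bonferroni correction, and
Gaussian KDE curves (bandwidth 0.4 counts) per condition.

## Worked example

Render a 12-second synthetic scene containing one train in each ICI
regime over Gaussian background noise, then detect and classify:

```python
from dolphinpam.synthetic_data import SceneSpec, ClickTrainSpec, render_scene
from dolphinpam.pulse_detection import detect_and_classify

spec = SceneSpec(
    duration_s=12.0, seed=42, noise_variance=1e-4,
    events=(
        ClickTrainSpec(onset_s=0.501, n_clicks=30, ici_s=0.008, per_click_snr_db=20.0),
        ClickTrainSpec(onset_s=3.501, n_clicks=12, ici_s=0.1,   per_click_snr_db=18.0),
        ClickTrainSpec(onset_s=7.501, n_clicks=6,  ici_s=0.4,   per_click_snr_db=16.0),
    ),
)
rec, truth = render_scene(spec)
for seq in detect_and_classify(rec, th_db=10.0):
    print(f"{seq.category}: {seq.n_peaks} peaks, mean ICI {seq.mean_ici_s*1000:.1f} ms, "
          f"span {seq.start_s:.3f}-{seq.end_s:.3f} s, mean SNR {seq.mean_snr_db:.1f} dB")
```

prints

```
FB: 30 peaks, mean ICI 8.0 ms, span 0.501-0.733 s, mean SNR 20.2 dB
BPS: 12 peaks, mean ICI 100.0 ms, span 3.501-4.601 s, mean SNR 18.2 dB
ECT: 6 peaks, mean ICI 400.0 ms, span 7.501-9.501 s, mean SNR 16.2 dB
```

Every injected click is recovered (30/12/6 peaks), the mean ICI of each
sequence reproduces the generator's setting, the measured per-peak SNR
matches the requested calibration to within a fraction of a dB, and the
three ICI regimes land in their three categories.

The same workflow is available from the shell:

```
dolphinpam simulate --mode scene --seed 42 --out scene/
dolphinpam detect scene/scene.wav --th-db 10 --out out/
dolphinpam blocks out/*.labels.txt --out blocks.csv
dolphinpam stats blocks.csv --out stats/
```

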