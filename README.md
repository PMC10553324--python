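# wristpd

Continuous, objective assessment of Parkinson's disease (PD) motor
signs from a wrist-worn tri-axial accelerometer sampled at 50 Hz.

Clinical rating scales and patient motor diaries capture PD motor
fluctuations only intermittently and subjectively.  `wristpd`
implements a spectral-pattern approach for 24-h wrist recordings: it
detects tremor, dyskinesia and bradykinesia from band-limited power
spectral densities, classifies every 30-minute interval into one of
eight motor states (OFF, ON, ON with non-troublesome / troublesome
dyskinesia, daytime / nighttime motor inactivity, not worn, not
detectable), and computes the agreement statistics used to validate
such a device against the standard four-state patient motor diary.
A seeded synthetic-signal generator makes the whole pipeline testable
without clinical data.

It is intended for researchers in digital health and movement
disorders who need a transparent, fully scripted reference pipeline
for wrist-accelerometry motor-state analysis.

## Method

Recordings are split into 5-s epochs; each epoch gets a Welch PSD
(Hann window, 2.5-s segments, 50 % overlap) per axis and for the
gravity-removed vector magnitude ("combined" channel), after a
zero-phase 0.25 Hz high-pass.  Detection operates on band integrals
of the combined channel:

* **Tremor** (per epoch): the spectral peak over 0.5–12 Hz must fall in
  the rest-tremor band 3–7 Hz, the transverse axes (y, z) must jointly
  carry the tremor-band power with matching per-axis peak frequencies
  (the supination–pronation gate), and ∫PSD(3–7 Hz) must reach a floor.
* **Dyskinesia** (per 30-min window): an epoch is dyskinetic when both
  ∫PSD(1–3 Hz) and ∫PSD(3–8 Hz) exceed thresholds and the spectrum is
  broadband (not concentrated around a single peak); the window is
  dyskinetic when such epochs form a majority.
* **Bradykinesia** (per epoch): requires upright, non-sedentary posture
  (gravity orientation + activity floor) and ∫PSD(0.5–3 Hz) between a
  motionless floor and a brisk-movement ceiling.
* **Intensity** scores on the 0–4 clinical scale are piecewise-linear
  in log10 band power between two calibrated anchors (reversed for
  bradykinesia: less residual movement means more severe slowness).

Diary comparison uses pooled two-dichotomy counting (OFF-vs-rest and
ON-vs-rest, sleep as negative in both; intervals reported NOT WORN or
NOT DETECTABLE are excluded), and per 24-h acquisition:

```
sensitivity = TP/(TP+FN)       specificity = TN/(TN+FP)
accuracy    = (TP+TN)/(TP+TN+FP+FN)
kappa       = 2(TP·TN − FN·FP) / ((TP+FP)(FP+TN) + (TP+FN)(FN+TN))
```

See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

Simulate a fluctuating day (night sleep, a morning wearing-off OFF
block, mild afternoon dyskinesia), analyse it, and compare the result
with the generated diary:

```bash
wristpd simulate fluctuating_day --seed 5 --out-dir day/
wristpd analyze day/fluctuating_day_recording.csv --out-dir day/report/
wristpd compare --timeline day/report/timeline.csv \
                --diary day/fluctuating_day_diary.csv --out day/table.csv
```

The state summary (`day/report/state_durations.csv`) for this seed:

```
state                    hours  percent
OFF                        3.0     12.5
ON                         8.0     33.3
ON_NON_TROUBLESOME_DYSK    2.0      8.3
DAYTIME_INACTIVITY         3.0     12.5
NIGHTTIME_INACTIVITY       8.0     33.3
```

3 h OFF is the scripted wearing-off periods (tremor + bradykinesia),
2 h non-troublesome dyskinesia is the scripted mild-dyskinesia block,
and the inactivity states cover scripted sleep and rest, split at the
06:00/22:00 local-clock day boundary.  `summary.json` additionally
reports 1.98 h of impactful dyskinesia (intensity > 0.5), i.e. 12.4 %
of a 16-h waking day, binned by score (score 2: 1.96 h).  The
comparison table shows perfect agreement with the error-free diary:

```
acquisition  tn  tp  fn  fp  sensitivity  specificity  accuracy  kappa
1            70  26   0   0         1.0          1.0       1.0    1.0
```

(26 diary-covered OFF half-hours → TP, 70 negatives pooled over the
two dichotomies; 96 counts = 2 × 48 intervals.)

`analyze` also renders a state pie chart, per-day stacked histograms
and a four-row temporal panel (states, dyskinesia intensity,
tremor/bradykinesia intensity, spectrogram).

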