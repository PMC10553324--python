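# Methods

## Signal model and pre-processing

Input is tri-axial wrist acceleration in g at 50 Hz (x = forearm
longitudinal axis, y/z transverse), optionally with a near-body
temperature channel (°C, ~1 Hz) and an illuminance channel.  The
recording clock is the local calendar clock of `start_time`; no
timezone arithmetic is applied, so the day/night boundary is wherever
the wearer's clock says it is.

The recording is divided into equal, contiguous epochs; the trailing
partial epoch is discarded.  The epoch length defaults to **5 s**: at
50 Hz this holds ≥ 15 cycles of the slowest tremor (3 Hz) and yields a
0.4 Hz Welch grid with 2.5-s Hann segments at 50 % overlap — enough
resolution to separate the 3 Hz and 7 Hz band edges while keeping at
least two averaged segments per epoch.  Gravity is removed by a
4th-order zero-phase Butterworth high-pass at **0.25 Hz**, half the
lower edge of the bradykinesia band (0.5 Hz) so that band is preserved.

The "combined" channel is, by default, the PSD of the high-passed
Euclidean magnitude of the three axes.  The magnitude projects
movement onto the gravity direction, so purely gravity-orthogonal
oscillation is attenuated; the alternative reading — summing the three
per-axis PSDs — is available via `SpectralConfig.combined_mode =
"spectra_sum"`.  The magnitude default was kept because it is
insensitive to device orientation for the axial component that most
daily movement carries.

Band powers are trapezoidal integrals with the PSD linearly
interpolated at the band edges, which makes adjacent bands exactly
additive (∫1–3 + ∫3–8 = ∫1–8).  Peak frequencies consider grid nodes
only, ties resolved toward the lower frequency.

**Parseval caveat.**  With three 2.5-s segments per 5-s epoch the PSD
integral of a stochastic epoch is a high-variance estimate: the
single-epoch integral scatters ±15 % around the epoch's sample
variance even for ideal white noise, and per-epoch high-pass filtering
adds edge transients (the filter's time constant, ~4 s, is comparable
to the epoch).  The Parseval property therefore holds, and is tested,
for the ensemble mean over epochs, not realisation-by-realisation.

## Detectors

All thresholds below are configuration values; none is a clinical
constant.  They were calibrated **once** against the synthetic
generator by measuring each condition's median combined-channel band
power (`wristpd calibrate`) and placing thresholds geometrically
between adjacent tiers.  Powers are in g².

* **Tremor** (per epoch).  Detected when (a) the combined-channel peak
  over 0.5–12 Hz lies in 3–7 Hz, (b) the supination–pronation gate
  passes: the transverse axes jointly carry ≥ ρ_axis = 0.6 of the
  summed per-axis 3–7 Hz power, and every transverse axis holding
  ≥ 25 % of that power peaks within Δf = 0.5 Hz of the combined peak,
  and (c) ∫PSD(3–7) ≥ θ_t0 = 5·10⁻⁴.  The gate is a concrete
  formalisation of "inter-axis comparison of frequency content"; it is
  deliberately pluggable because no published criterion exists.
  Intensity: increasing log-power map anchored at (5·10⁻⁴ → 0.5,
  5·10⁻² → 4.0).
* **Dyskinesia** (per 30-min window of 360 epochs).  Epoch flag:
  ∫PSD(1–3) > θ₁₃ = 1.5·10⁻⁴ AND ∫PSD(3–8) > θ₃₈ = 2.5·10⁻⁴ AND the
  spectrum is broadband — at most 50 % of the 1–8 Hz power within
  ±0.6 Hz of the in-band peak.  The broadband condition separates
  sustained low-frequency tremor (≈3.5 Hz, which leaks into 1–3 Hz
  through window smearing) from choreiform movement; rhythmic
  oscillation concentrates ~95 % of its in-band power at the peak,
  band-limited choreic noise ~30 %.  Window detected when flagged
  epochs exceed the majority fraction q = 0.5; the decision depends
  only on the flagged fraction, hence is order-invariant, and isolated
  tremor epochs inside a dyskinetic window cannot veto it.  Intensity
  per epoch from ∫PSD(1–8) with anchors (2.3·10⁻⁴, 6·10⁻²); epochs not
  flagged carry intensity 0 so that sporadic movement bursts do not
  masquerade as dyskinesia in the traces and histograms.
* **Posture** (per epoch).  "Upright/non-sedentary" is approximated
  from a wrist device as: epoch-mean gravity vector within
  α_max = 35° of the configured upright reference (+x, forearm
  hanging) and epoch magnitude SD above the rest floor 0.01 g.  A
  wrist sensor cannot observe trunk posture; this proxy is the main
  known approximation of the pipeline.
* **Bradykinesia** (per epoch).  Upright-active posture and
  θ_low = 2·10⁻⁵ < ∫PSD(0.5–3) < θ_high = 3·10⁻³.  The floor excludes
  motionless sitting/resting; the ceiling excludes gait and other
  brisk movement.  Intensity: decreasing log-power map over
  (θ_low, θ_high) — slower residual movement scores higher.
* **Wear** (per epoch).  Worn iff mean near-body temperature
  ≥ 30 °C or magnitude SD ≥ 0.01 g; without a temperature channel the
  movement rule alone applies (motionless wear, e.g. sleep, is then
  indistinguishable from non-wear — a documented limitation).

## State classification (30-min intervals)

Exactly one of eight states per interval, by fixed precedence:
NOT_WORN (worn fraction < 0.5) → ON_TROUBLESOME_DYSK (dyskinesia
fraction ≥ 0.75 and max intensity > 2.5) → ON_NON_TROUBLESOME_DYSK
(detected dyskinesia, max intensity in (0.5, 2.5]) → daytime/nighttime
inactivity (active fraction < 0.2, split at the [06:00, 22:00)
local-clock day window) → OFF (tremor + bradykinesia fraction among
active epochs > 0.5 and above the dyskinesia fraction) → ON (activity
present, parkinsonian fraction ≤ 0.25, no impactful dyskinesia) →
NOT_DETECTABLE.  The boundary intensity 2.5 itself is non-troublesome;
0.5 itself is not impactful.  Windows with parkinsonian fractions
between 0.25 and 0.5 are deliberately NOT_DETECTABLE rather than
forced into ON or OFF.  Tremor/bradykinesia fractions are computed
among *active* epochs so that predominance is judged over periods with
actual movement.  The qualitative words behind these cutoffs
("predominant", "majority", "overwhelming majority", "reduced
activity", "relevant") have no published numeric values; 0.5 / 0.5 /
0.75 / 0.2 / 0.25 are this package's fixed, configurable choices.

The interval grid anchors at the recording's first sample by default;
`StatesConfig.snap_to_half_hour` aligns it to wall-clock :00/:30 for
diary comparison.  Dyskinesia duration histograms bin intensity into
scores 1–4 with edges 0.5/1.5/2.5/3.5 (≤ 0.5 excluded as not
impactful), and the waking-day percentage uses a 16-h denominator.

## Diary comparison and statistics

Device states are projected onto the diary's four classes (both
inactivity states → Asleep-equivalent).  Intervals with a missing
diary entry or with device NOT_WORN / NOT_DETECTABLE are excluded.
Counting pools two dichotomies — OFF-vs-rest and ON-vs-rest, sleep
negative in both — so each compared interval contributes exactly two
counts; this pooled scheme is inferred from the structure of the
published validation table, where every row total equals twice the
diary-covered half-hours, and a configuration switch reports the
dichotomies separately.  Rates and the two-class kappa are evaluated
exactly (rational arithmetic); display rounding is half-up at two
decimals computed on the exact ratio (39/40 prints 0.98).  Study means
are unweighted across acquisitions; the kappa SD uses the sample
(n−1) convention — on the shipped validation table both the n−1 and n
conventions round to the same 0.10.

The shipped validation table contains one internal inconsistency: one
acquisition's printed sensitivity/accuracy do not follow from its own
counts (they duplicate the neighbouring row).  The package always
recomputes rates from counts; consequently its mean sensitivity from
the counts is 0.86 where the published summary (averaging the printed
column) shows 0.85.

## Synthetic generator

Each scripted segment synthesises one condition (amplitudes in
`wristpd.synthetic.AMPLITUDES`, orientations as unit gravity vectors):
tremor is a frequency-wandering (±0.15 Hz) sinusoid with ~0.07/0.05 g
transverse rotational components and a 0.05 g axial component;
dyskinesia is 1–8 Hz band-limited noise with axial SD 0.0345 g (mild)
or 0.134 g (severe), tiers chosen so their expected intensities
(~1.8 / ~3.5) straddle the troublesome cutoff 2.5; bradykinesia is
0.5–3 Hz noise (axial SD 0.025 g) in upright orientation; normal
activity is a ~2 Hz gait sinusoid (0.12 g axial) with a weak second
harmonic; sleep/rest are sub-floor noise with occasional 5-s posture
turns; not-worn is a 0.0015 g sensor-noise floor with the temperature
relaxing exponentially (τ = 2 min) between 33 °C (worn) and 24 °C
(ambient).  Ground-truth states are the majority segment kind per
30-min interval; the diary maps the truth onto the four diary classes
(not-worn → missing) with an optional per-interval error rate.  Each
segment draws from a counter-derived substream of the script seed, so
simulations are reproducible and locally editable.

What the generator does **not** emulate: real actigraphy
non-stationarity, mixed simultaneous symptoms (tremor during
dyskinesia), gradual ON/OFF transitions inside an interval, gait
pathologies, and diary timing noise.  Passing the end-to-end checks
therefore demonstrates internal consistency of detectors, classifier
and statistics under the stated spectral models — not clinical
performance, which can only come from patient data.

## Problem sizes and numerical choices

End-to-end checks use ten 24-h synthetic days (480 intervals,
~173 000 epochs) with error-free diaries; detector checks use 100
epochs per tremor frequency at 3.5–6.5 Hz and 100 epochs per
non-tremor condition; Parseval uses 30-epoch ensembles.  Dyskinesia
decisions use strict inequalities at the thresholds; zero-power epochs
score intensity 0 (increasing maps) by clipping; undefined rates
(zero denominators) raise and are excluded from study means with a
warning rather than silently propagating NaN.

## Known limitations

Wrist-only posture sensing; unpublished device thresholds replaced by
synthetic calibration; magnitude-channel attenuation of
gravity-orthogonal movement; 30-min interval granularity hides
sub-interval fluctuations; single-accelerometer bradykinesia detection
is intrinsically ambiguous against voluntary slowness — mitigated, not
solved, by the posture gate.
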