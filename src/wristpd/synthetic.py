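"""Seeded generator of labelled synthetic wrist recordings.

Each scripted segment emulates one movement condition through its
spectral signature on a wrist-worn tri-axial accelerometer (units of g,
gravity included):

* ``tremor`` — a 3–7 Hz supination–pronation oscillation: the forearm
  rotation tilts the device in the gravity field, so the oscillation is
  carried mainly by the transverse (y, z) axes, with a smaller axial
  (along-gravity) component that keeps it visible in the vector
  magnitude; the instantaneous frequency wanders by ±0.15 Hz.
* ``dyskinesia_mild`` / ``dyskinesia_severe`` — sustained band-limited
  (1–8 Hz) choreiform noise on all axes at two amplitude tiers placed
  on either side of the troublesome-intensity cutoff.
* ``bradykinesia`` — upright orientation with low-amplitude 0.5–3 Hz
  movement, between the motionless floor and brisk movement.
* ``normal_activity`` — a gait oscillation near 2 Hz with a weak
  second harmonic and a small broadband remainder.
* ``sleep`` / ``rest`` — near-floor noise with occasional posture
  turns (sleep) in lying/sitting orientations.
* ``not_worn`` — sensor noise on a table; the simulated near-body
  temperature decays toward ambient with a 2-minute time constant.

The generator is deterministic given the script seed; each segment
draws from its own counter-derived substream, so editing one segment
leaves the others untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
from scipy import signal as sp_signal

from .diary_compare import DiaryState, DiaryTimeline, write_diary_csv
from .recording_io import (
    AccelRecording,
    AuxChannel,
    ValidationError,
    write_recording_csv,
)
from .states import MotorState, StatesConfig, StateTimeline

__all__ = [
    "Segment",
    "SimulationScript",
    "SEGMENT_KINDS",
    "simulate_recording",
    "make_fixture_day",
    "random_day_script",
    "preset_script",
    "PRESETS",
]

SEGMENT_KINDS = (
    "sleep",
    "rest",
    "normal_activity",
    "tremor",
    "bradykinesia",
    "dyskinesia_mild",
    "dyskinesia_severe",
    "not_worn",
)

#: device orientation (unit gravity vector in device axes) per condition
ORIENTATIONS = {
    "lying": (0.05, 0.15, 0.99),
    "lying_side": (0.05, 0.95, 0.30),
    "sitting": (0.20, 0.68, 0.70),
    "upright": (0.97, 0.17, 0.17),
    "table": (0.0, 0.0, 1.0),
}

_KIND_ORIENTATION = {
    "sleep": "lying",
    "rest": "sitting",
    "normal_activity": "upright",
    "tremor": "sitting",
    "bradykinesia": "upright",
    "dyskinesia_mild": "sitting",
    "dyskinesia_severe": "sitting",
    "not_worn": "table",
}

#: signal amplitudes (g) defining the study conditions; the detector
#: thresholds in the default configuration were calibrated once against
#: these values (see ``wristpd calibrate``)
AMPLITUDES = {
    "sensor_noise_g": 0.002,
    "sleep_noise_g": 0.003,
    "rest_noise_g": 0.004,
    "gait_axial_g": 0.12,
    "gait_harmonic_g": 0.012,
    "gait_swing_g": 0.05,
    "activity_noise_g": 0.004,
    "tremor_rot_y_g": 0.07,
    "tremor_rot_z_g": 0.05,
    "tremor_axial_g": 0.05,
    "tremor_background_g": 0.008,
    "brady_axial_std_g": 0.025,
    "brady_transverse_std_g": 0.010,
    "dysk_mild_axial_std_g": 0.0345,
    "dysk_severe_axial_std_g": 0.134,
    "dysk_transverse_std_ratio": 0.9,
    "notworn_noise_g": 0.0015,
}

TEMP_WORN_C = 33.0
TEMP_AMBIENT_C = 24.0
TEMP_TAU_S = 120.0
TEMP_FS = 1.0

_KIND_TO_STATE = {
    "normal_activity": MotorState.ON,
    "tremor": MotorState.OFF,
    "bradykinesia": MotorState.OFF,
    "dyskinesia_mild": MotorState.ON_NON_TROUBLESOME_DYSK,
    "dyskinesia_severe": MotorState.ON_TROUBLESOME_DYSK,
    "not_worn": MotorState.NOT_WORN,
    # sleep/rest resolve to day/night inactivity via the local clock
}

_STATE_TO_DIARY = {
    MotorState.OFF: DiaryState.OFF,
    MotorState.ON: DiaryState.ON_OR_ON_NTD,
    MotorState.ON_NON_TROUBLESOME_DYSK: DiaryState.ON_OR_ON_NTD,
    MotorState.ON_TROUBLESOME_DYSK: DiaryState.ON_TD,
    MotorState.DAYTIME_INACTIVITY: DiaryState.ASLEEP,
    MotorState.NIGHTTIME_INACTIVITY: DiaryState.ASLEEP,
    MotorState.NOT_WORN: DiaryState.MISSING,
    MotorState.NOT_DETECTABLE: DiaryState.MISSING,
}


@dataclass
class Segment:
    kind: str
    duration_s: float
    tremor_hz: float = 5.0
    amplitude_scale: float = 1.0


@dataclass
class SimulationScript:
    segments: list[Segment]
    start_time: datetime = field(
        default_factory=lambda: datetime(2023, 5, 1, 0, 0, 0)
    )
    seed: int = 0
    fs: float = 50.0
    subject_id: str = "sim"

    def validate(self) -> None:
        if not self.segments:
            raise ValidationError("script must contain at least one segment")
        total = 0.0
        for seg in self.segments:
            if seg.kind not in SEGMENT_KINDS:
                raise ValidationError(f"unknown segment kind {seg.kind!r}")
            if seg.duration_s <= 0:
                raise ValidationError("segment durations must be positive")
            if seg.kind == "tremor" and not 3.0 <= seg.tremor_hz <= 7.0:
                raise ValidationError("tremor_hz must lie in [3, 7] Hz")
            total += seg.duration_s
        if total > 15 * 86400:  # device memory limit: 15 consecutive days
            raise ValidationError("total scripted duration exceeds 15 days")

    @property
    def duration_s(self) -> float:
        return sum(s.duration_s for s in self.segments)


# ---------------------------------------------------------------------------
# signal building blocks


def _bandlimited_noise(
    rng: np.random.Generator, n: int, fs: float, lo: float, hi: float, std: float
) -> np.ndarray:
    sos = sp_signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = sp_signal.sosfilt(sos, rng.standard_normal(n))
    s = y.std()
    return y * (std / s) if s > 0 else y


def _lowpass_noise(
    rng: np.random.Generator, n: int, fs: float, cutoff: float, std: float
) -> np.ndarray:
    sos = sp_signal.butter(2, cutoff, btype="lowpass", fs=fs, output="sos")
    y = sp_signal.sosfilt(sos, rng.standard_normal(n))
    s = y.std()
    return y * (std / s) if s > 0 else y


def _orientation_track(
    kind: str, n: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """(n, 3) unit gravity vector; sleep includes occasional turns."""
    base = np.asarray(ORIENTATIONS[_KIND_ORIENTATION[kind]], dtype=float)
    base = base / np.linalg.norm(base)
    track = np.tile(base, (n, 1))
    if kind != "sleep":
        return track
    alt = np.asarray(ORIENTATIONS["lying_side"], dtype=float)
    alt = alt / np.linalg.norm(alt)
    poses = [base, alt]
    t = 0.0
    pose_idx = 0
    ramp_n = int(5 * fs)  # 5 s turn
    while True:
        t += rng.uniform(20 * 60, 45 * 60)  # turn every 20–45 min
        i0 = int(t * fs)
        if i0 + ramp_n >= n:
            break
        frm, to = poses[pose_idx % 2], poses[(pose_idx + 1) % 2]
        w = 0.5 * (1 - np.cos(np.linspace(0, np.pi, ramp_n)))
        seg = (1 - w)[:, None] * frm + w[:, None] * to
        seg /= np.linalg.norm(seg, axis=1, keepdims=True)
        track[i0 : i0 + ramp_n] = seg
        track[i0 + ramp_n :] = to
        pose_idx += 1
    return track


def _tremor_phase(
    rng: np.random.Generator, n: int, fs: float, hz: float, jitter_hz: float = 0.15
) -> np.ndarray:
    wander = _lowpass_noise(rng, n, fs, 0.2, 0.5)
    f_inst = hz + jitter_hz * np.clip(wander, -1.0, 1.0)
    return 2 * np.pi * np.cumsum(f_inst) / fs


def _segment_signal(
    seg: Segment, fs: float, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Acceleration (n, 3) in g, gravity included, and the worn flag."""
    A = AMPLITUDES
    n = int(round(seg.duration_s * fs))
    g = _orientation_track(seg.kind, n, fs, rng)
    acc = g.copy()
    acc += A["sensor_noise_g"] * rng.standard_normal((n, 3))
    scale = seg.amplitude_scale
    worn = seg.kind != "not_worn"

    if seg.kind == "sleep":
        acc += A["sleep_noise_g"] * scale * rng.standard_normal((n, 3))
    elif seg.kind == "rest":
        acc += A["rest_noise_g"] * scale * rng.standard_normal((n, 3))
    elif seg.kind == "not_worn":
        acc += A["notworn_noise_g"] * rng.standard_normal((n, 3))
    elif seg.kind == "normal_activity":
        f_gait = rng.uniform(1.7, 2.1)
        t = np.arange(n) / fs
        ph = rng.uniform(0, 2 * np.pi)
        axial = A["gait_axial_g"] * scale * np.sin(2 * np.pi * f_gait * t + ph)
        axial += A["gait_harmonic_g"] * scale * np.sin(
            2 * np.pi * 2 * f_gait * t + 2 * ph + 0.7
        )
        acc += axial[:, None] * g
        acc[:, 0] += A["gait_swing_g"] * scale * np.sin(
            2 * np.pi * f_gait * t + ph + 1.2
        )
        acc += A["activity_noise_g"] * scale * rng.standard_normal((n, 3))
    elif seg.kind == "tremor":
        phase = _tremor_phase(rng, n, fs, seg.tremor_hz)
        acc[:, 1] += A["tremor_rot_y_g"] * scale * np.sin(phase)
        acc[:, 2] += A["tremor_rot_z_g"] * scale * np.sin(phase + 0.5)
        acc += (A["tremor_axial_g"] * scale * np.sin(phase + 1.0))[:, None] * g
        acc += A["tremor_background_g"] * rng.standard_normal((n, 3))
    elif seg.kind == "bradykinesia":
        slow = _bandlimited_noise(
            rng, n, fs, 0.5, 3.0, A["brady_axial_std_g"] * scale
        )
        acc += slow[:, None] * g
        for k in (1, 2):
            acc[:, k] += _bandlimited_noise(
                rng, n, fs, 0.5, 3.0, A["brady_transverse_std_g"] * scale
            )
    elif seg.kind in ("dyskinesia_mild", "dyskinesia_severe"):
        tier = "mild" if seg.kind == "dyskinesia_mild" else "severe"
        axial_std = A[f"dysk_{tier}_axial_std_g"] * scale
        chorea = _bandlimited_noise(rng, n, fs, 1.0, 8.0, axial_std)
        acc += chorea[:, None] * g
        tr_std = axial_std * A["dysk_transverse_std_ratio"]
        for k in range(3):
            acc[:, k] += _bandlimited_noise(rng, n, fs, 1.0, 8.0, tr_std)
    return acc, worn


# ---------------------------------------------------------------------------
# top-level simulation


def _truth_states(
    script: SimulationScript, states_cfg: StatesConfig
) -> list[MotorState]:
    """Majority segment kind per 30-min interval, mapped to a state."""
    interval_s = states_cfg.interval_s
    n_windows = int(script.duration_s // interval_s)
    bounds = np.cumsum([0.0] + [s.duration_s for s in script.segments])
    states = []
    for w in range(n_windows):
        w0, w1 = w * interval_s, (w + 1) * interval_s
        cover: dict[str, float] = {}
        for seg, s0, s1 in zip(script.segments, bounds[:-1], bounds[1:]):
            overlap = min(w1, s1) - max(w0, s0)
            if overlap > 0:
                cover[seg.kind] = cover.get(seg.kind, 0.0) + overlap
        kind = max(cover, key=lambda k: cover[k])
        if kind in _KIND_TO_STATE:
            states.append(_KIND_TO_STATE[kind])
        else:  # sleep/rest → inactivity, split on the local clock
            midpoint = script.start_time + timedelta(seconds=(w0 + w1) / 2)
            h = midpoint.hour + midpoint.minute / 60
            day = states_cfg.day_start_h <= h < states_cfg.day_end_h
            states.append(
                MotorState.DAYTIME_INACTIVITY
                if day
                else MotorState.NIGHTTIME_INACTIVITY
            )
    return states


def simulate_recording(
    script: SimulationScript,
    diary_error_rate: float = 0.0,
    with_temperature: bool = True,
    states_cfg: StatesConfig | None = None,
) -> tuple[AccelRecording, StateTimeline, DiaryTimeline]:
    """Generate a recording plus its ground-truth timeline and diary.

    Deterministic given ``script.seed``; the diary equals the
    class-mapped truth timeline, with each entry independently replaced
    by a random different state with probability ``diary_error_rate``.
    """
    script.validate()
    states_cfg = states_cfg or StatesConfig()
    fs = script.fs
    parts, worn_flags = [], []
    for idx, seg in enumerate(script.segments):
        rng = np.random.default_rng([script.seed, idx])
        acc, worn = _segment_signal(seg, fs, rng)
        parts.append(acc)
        worn_flags.append((acc.shape[0], worn))
    acc = np.concatenate(parts, axis=0)

    temperature = None
    if with_temperature:
        n_temp = int(acc.shape[0] / fs * TEMP_FS)
        target = np.empty(n_temp)
        pos = 0
        for n_seg, worn in worn_flags:
            n_t = int(round(n_seg / fs * TEMP_FS))
            target[pos : pos + n_t] = TEMP_WORN_C if worn else TEMP_AMBIENT_C
            pos += n_t
        target[pos:] = target[pos - 1] if pos else TEMP_AMBIENT_C
        alpha = float(np.exp(-1.0 / (TEMP_TAU_S * TEMP_FS)))
        temp = np.empty(n_temp)
        prev = target[0]
        for i in range(n_temp):
            prev = target[i] + (prev - target[i]) * alpha
            temp[i] = prev
        temperature = AuxChannel(temp, fs=TEMP_FS)

    rec = AccelRecording(
        start_time=script.start_time,
        fs=fs,
        ax=acc[:, 0],
        ay=acc[:, 1],
        az=acc[:, 2],
        temperature=temperature,
        subject_id=script.subject_id,
    )
    truth = StateTimeline(
        interval_s=states_cfg.interval_s,
        start_time=script.start_time,
        states=_truth_states(script, states_cfg),
    )

    entries = [_STATE_TO_DIARY[s] for s in truth.states]
    if diary_error_rate > 0:
        rng = np.random.default_rng([script.seed, 10_000])
        choices = [
            DiaryState.ASLEEP,
            DiaryState.OFF,
            DiaryState.ON_OR_ON_NTD,
            DiaryState.ON_TD,
        ]
        for i, e in enumerate(entries):
            if e is DiaryState.MISSING:
                continue
            if rng.random() < diary_error_rate:
                entries[i] = rng.choice([c for c in choices if c is not e])
    diary = DiaryTimeline(start_time=script.start_time, entries=entries)
    return rec, truth, diary


# ---------------------------------------------------------------------------
# day presets


def _day(segments: list[tuple[float, float, str]], seed: int, **kw) -> SimulationScript:
    """Build a script from (start_h, end_h, kind) triples."""
    segs = [
        Segment(kind=k, duration_s=(h1 - h0) * 3600.0, **_seg_kw(k, kw))
        for h0, h1, k in segments
    ]
    return SimulationScript(segments=segs, seed=seed)


def _seg_kw(kind: str, kw: dict) -> dict:
    return {"tremor_hz": kw.get("tremor_hz", 5.0)} if kind == "tremor" else {}


PRESETS = {
    # wearing-off: ON → 1.5 h OFF block → ON, plus an afternoon repeat
    "fluctuating_day": [
        (0, 7, "sleep"),
        (7, 10, "normal_activity"),
        (10, 11, "tremor"),
        (11, 11.5, "bradykinesia"),
        (11.5, 14, "normal_activity"),
        (14, 16, "dyskinesia_mild"),
        (16, 17.5, "tremor"),
        (17.5, 20, "normal_activity"),
        (20, 22, "rest"),
        (22, 24, "sleep"),
    ],
    # OFF confined to the early morning
    "early_morning_off": [
        (0, 6, "sleep"),
        (6, 7.5, "tremor"),
        (7.5, 8.5, "bradykinesia"),
        (8.5, 12, "normal_activity"),
        (12, 14, "dyskinesia_mild"),
        (14, 18, "normal_activity"),
        (18, 22, "rest"),
        (22, 24, "sleep"),
    ],
    # tremor/bradykinesia but no dyskinesia (no motor fluctuation profile)
    "nonfluctuating_day": [
        (0, 7, "sleep"),
        (7, 11, "normal_activity"),
        (11, 12, "tremor"),
        (12, 13, "bradykinesia"),
        (13, 18, "normal_activity"),
        (18, 22, "rest"),
        (22, 24, "sleep"),
    ],
    # good medication response: mild dyskinesia from noon to evening
    "full_adherence": [
        (0, 7, "sleep"),
        (7, 12, "normal_activity"),
        (12, 18, "dyskinesia_mild"),
        (18, 21, "normal_activity"),
        (21, 22, "rest"),
        (22, 24, "sleep"),
    ],
    # missed oral dose: OFF dominates the afternoon, movement collapses
    "missed_dose": [
        (0, 7, "sleep"),
        (7, 9, "normal_activity"),
        (9, 11, "tremor"),
        (11, 13, "bradykinesia"),
        (13, 15, "tremor"),
        (15, 17, "bradykinesia"),
        (17, 22, "rest"),
        (22, 24, "sleep"),
    ],
}


def preset_script(profile: str, seed: int, tremor_hz: float = 5.0) -> SimulationScript:
    if profile not in PRESETS:
        raise KeyError(
            f"unknown preset {profile!r}; available: {', '.join(sorted(PRESETS))}"
        )
    return _day(PRESETS[profile], seed, tremor_hz=tremor_hz)


def random_day_script(seed: int) -> SimulationScript:
    """A random but realistic fluctuating day on a half-hour grid.

    Night sleep flanks a waking day filled with blocks of activity,
    OFF periods (tremor and/or bradykinesia), dyskinesia of both tiers,
    daytime rest and an occasional not-worn gap.
    """
    rng = np.random.default_rng([seed, 424242])
    day: list[tuple[float, float, str]] = [(0, 7, "sleep")]
    kinds = (
        "normal_activity",
        "tremor",
        "bradykinesia",
        "dyskinesia_mild",
        "dyskinesia_severe",
        "rest",
        "not_worn",
    )
    weights = np.array([0.30, 0.15, 0.13, 0.14, 0.08, 0.13, 0.07])
    t = 7.0
    while t < 21.5:
        kind = rng.choice(kinds, p=weights / weights.sum())
        dur = rng.choice([0.5, 1.0, 1.5, 2.0])
        dur = min(dur, 21.5 - t)
        day.append((t, t + dur, kind))
        t += dur
    day.append((21.5, 22.0, "rest"))
    day.append((22.0, 24.0, "sleep"))
    script = _day(day, seed, tremor_hz=float(rng.uniform(3.5, 6.5)))
    return script


def make_fixture_day(
    profile: str, seed: int, out_dir: str | Path, diary_error_rate: float = 0.0
) -> dict[str, Path]:
    """Write a preset day to disk: recording CSV (+ aux sidecar),
    ground-truth timeline CSV and diary CSV.  Returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    script = preset_script(profile, seed)
    rec, truth, diary = simulate_recording(script, diary_error_rate=diary_error_rate)
    paths = {
        "recording": out_dir / f"{profile}_recording.csv",
        "truth": out_dir / f"{profile}_truth.csv",
        "diary": out_dir / f"{profile}_diary.csv",
    }
    write_recording_csv(rec, paths["recording"])
    truth.to_frame().to_csv(paths["truth"], index=False)
    write_diary_csv(diary, paths["diary"])
    return paths
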