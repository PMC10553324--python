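"""Patient motor-diary handling and device-vs-diary confusion counts.

The diary is a 30-minute grid with four states — Asleep, OFF, ON (with
or without non-troublesome dyskinesia), and ON with troublesome
dyskinesia — the standard patient motor-symptom diary format.  Device
timelines are mapped onto the same four classes (both inactivity states
count as Asleep-equivalent) and compared interval by interval.

Counting follows the pooled OFF+ON scheme: each compared interval is
scored once in the OFF-vs-rest dichotomy and once in the ON-vs-rest
dichotomy, so the four confusion counts always total twice the number
of compared intervals.  Intervals where the device reports NOT_WORN or
NOT_DETECTABLE, or where the diary entry is missing, are excluded.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path

import pandas as pd

from .recording_io import FormatError, ValidationError
from .states import MotorState, StateTimeline

__all__ = [
    "DiaryState",
    "DiaryTimeline",
    "ConfusionCounts",
    "read_diary_csv",
    "write_diary_csv",
    "align_timelines",
    "confusion_counts",
]


class DiaryState(enum.Enum):
    ASLEEP = "ASLEEP"
    OFF = "OFF"
    ON_OR_ON_NTD = "ON_OR_ON_NTD"
    ON_TD = "ON_TD"
    MISSING = "MISSING"


_TOKEN_MAP = {
    "asleep": DiaryState.ASLEEP,
    "sleep": DiaryState.ASLEEP,
    "sleeping": DiaryState.ASLEEP,
    "off": DiaryState.OFF,
    "on": DiaryState.ON_OR_ON_NTD,
    "on_ntd": DiaryState.ON_OR_ON_NTD,
    "on_or_on_ntd": DiaryState.ON_OR_ON_NTD,
    "on with non-troublesome dyskinesia": DiaryState.ON_OR_ON_NTD,
    "on/on with non-troublesome dyskinesia": DiaryState.ON_OR_ON_NTD,
    "on_td": DiaryState.ON_TD,
    "on with troublesome dyskinesia": DiaryState.ON_TD,
    "missing": DiaryState.MISSING,
    "": DiaryState.MISSING,
}

#: device states projected onto the diary's four classes
DEVICE_TO_DIARY = {
    MotorState.OFF: DiaryState.OFF,
    MotorState.ON: DiaryState.ON_OR_ON_NTD,
    MotorState.ON_NON_TROUBLESOME_DYSK: DiaryState.ON_OR_ON_NTD,
    MotorState.ON_TROUBLESOME_DYSK: DiaryState.ON_TD,
    MotorState.DAYTIME_INACTIVITY: DiaryState.ASLEEP,
    MotorState.NIGHTTIME_INACTIVITY: DiaryState.ASLEEP,
}

#: device states excluded from the comparison altogether
EXCLUDED_DEVICE_STATES = frozenset(
    {MotorState.NOT_WORN, MotorState.NOT_DETECTABLE}
)


@dataclass
class DiaryTimeline:
    """One diary entry per 30-minute interval; gaps are MISSING."""

    start_time: datetime
    entries: list[DiaryState]
    interval_s: float = 1800.0

    @property
    def n_intervals(self) -> int:
        return len(self.entries)

    def interval_start(self, k: int) -> datetime:
        return self.start_time + timedelta(seconds=k * self.interval_s)


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            tn=self.tn + other.tn,
            fn=self.fn + other.fn,
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def parse_diary_token(token: str) -> DiaryState:
    key = str(token).strip().lower().replace("-", "-")
    if key in _TOKEN_MAP:
        return _TOKEN_MAP[key]
    key_compact = key.replace(" ", "_").replace("/", "_")
    if key_compact in _TOKEN_MAP:
        return _TOKEN_MAP[key_compact]
    raise FormatError(f"unknown diary state token {token!r}")


def read_diary_csv(path: str | Path) -> DiaryTimeline:
    """Read a diary CSV with columns ``interval_start`` (ISO-8601) and
    ``state``; intervals absent from the file become MISSING."""
    table = pd.read_csv(path, comment="#")
    for col in ("interval_start", "state"):
        if col not in table.columns:
            raise FormatError(f"missing mandatory column '{col}' in {path}")
    stamps = [datetime.fromisoformat(str(s)) for s in table["interval_start"]]
    states = [
        parse_diary_token("" if pd.isna(s) else s) for s in table["state"]
    ]
    if len(stamps) == 0:
        raise FormatError(f"empty diary in {path}")
    if len(set(stamps)) != len(stamps):
        raise FormatError(f"duplicate interval_start entries in {path}")
    t0 = min(stamps)
    span = (max(stamps) - t0).total_seconds()
    if any(abs((s - t0).total_seconds()) % 1800 > 1e-6 for s in stamps):
        raise FormatError("diary interval_start values are not on a 30-min grid")
    n = int(span // 1800) + 1
    entries = [DiaryState.MISSING] * n
    for stamp, state in zip(stamps, states):
        entries[int((stamp - t0).total_seconds() // 1800)] = state
    return DiaryTimeline(start_time=t0, entries=entries)


def write_diary_csv(diary: DiaryTimeline, path: str | Path) -> None:
    rows = [
        {"interval_start": diary.interval_start(k).isoformat(), "state": e.value}
        for k, e in enumerate(diary.entries)
        if e is not DiaryState.MISSING
    ]
    pd.DataFrame(rows, columns=["interval_start", "state"]).to_csv(path, index=False)


def align_timelines(
    diary: DiaryTimeline, device: StateTimeline
) -> list[tuple[DiaryState, DiaryState]]:
    """Pair diary and device entries on the shared 30-minute grid.

    Returns ``(diary_state, device_state_as_diary_class)`` pairs over
    the overlapping span, dropping intervals where the diary is MISSING
    or the device reported NOT_WORN / NOT_DETECTABLE.
    """
    if abs(diary.interval_s - device.interval_s) > 1e-9:
        raise ValidationError("diary and device interval lengths differ")
    shift = (device.start_time - diary.start_time).total_seconds()
    if abs(shift % diary.interval_s) > 1e-6 and abs(
        shift % diary.interval_s - diary.interval_s
    ) > 1e-6:
        raise ValidationError(
            "diary and device grids are offset by a non-integer number of intervals"
        )
    k_shift = int(round(shift / diary.interval_s))
    pairs = []
    for j, dev_state in enumerate(device.states):
        i = j + k_shift  # diary index covering the same interval
        if not 0 <= i < diary.n_intervals:
            continue
        d = diary.entries[i]
        if d is DiaryState.MISSING or dev_state in EXCLUDED_DEVICE_STATES:
            continue
        pairs.append((d, DEVICE_TO_DIARY[dev_state]))
    return pairs


def _dichotomy(
    pairs: list[tuple[DiaryState, DiaryState]], positives: frozenset[DiaryState]
) -> ConfusionCounts:
    tp = fp = tn = fn = 0
    for ref, dev in pairs:
        ref_pos, dev_pos = ref in positives, dev in positives
        if dev_pos and ref_pos:
            tp += 1
        elif dev_pos and not ref_pos:
            fp += 1
        elif not dev_pos and not ref_pos:
            tn += 1
        else:
            fn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


_OFF_POSITIVE = frozenset({DiaryState.OFF})
_ON_POSITIVE = frozenset({DiaryState.ON_OR_ON_NTD, DiaryState.ON_TD})


def confusion_counts(
    pairs: list[tuple[DiaryState, DiaryState]], mode: str = "pooled"
) -> ConfusionCounts:
    """Confusion counts over aligned pairs.

    ``off_dichotomy``: positive = OFF on each side; ``on_dichotomy``:
    positive = any ON class; ``pooled``: element-wise sum of the two,
    so every pair contributes exactly two counts.  Asleep-equivalent
    intervals are negatives in both dichotomies.
    """
    if not pairs:
        raise ValidationError("cannot compute confusion counts over zero pairs")
    if mode == "off_dichotomy":
        return _dichotomy(pairs, _OFF_POSITIVE)
    if mode == "on_dichotomy":
        return _dichotomy(pairs, _ON_POSITIVE)
    if mode == "pooled":
        return _dichotomy(pairs, _OFF_POSITIVE) + _dichotomy(pairs, _ON_POSITIVE)
    raise ValueError(f"unknown mode {mode!r}")
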