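"""State-classification rules, summaries and the end-to-end pipeline."""

from datetime import datetime, timedelta

import numpy as np
import pytest

from wristpd.detectors import DyskinesiaWindowResult
from wristpd.recording_io import ValidationError
from wristpd.states import (
    MotorState,
    StatesConfig,
    StateTimeline,
    WindowFeatures,
    classify_recording,
    classify_window,
    dyskinesia_score_histogram,
    read_timeline_csv,
    summarize_durations,
    waking_day_percent,
)

NOON = datetime(2023, 5, 1, 12, 15, 0)


def _dysk(detected: bool, fraction: float, max_intensity: float) -> DyskinesiaWindowResult:
    n = 10
    series = np.full(n, max_intensity if detected else 0.0)
    return DyskinesiaWindowResult(
        detected=detected,
        epoch_flags=np.full(n, detected),
        fraction=fraction,
        intensity_series=series,
        max_intensity=max_intensity,
    )


def _features(
    dysk=None,
    tremor=0.0,
    brady=0.0,
    active=0.8,
    worn=1.0,
    midpoint=NOON,
) -> WindowFeatures:
    dysk = dysk if dysk is not None else _dysk(False, 0.0, 0.0)
    return WindowFeatures(
        dysk=dysk,
        tremor_fraction=tremor,
        brady_fraction=brady,
        active_fraction=active,
        worn_fraction=worn,
        max_dysk_intensity=dysk.max_intensity,
        clock_midpoint=midpoint,
    )


@pytest.mark.parametrize(
    "features,expected",
    [
        # troublesome dyskinesia: overwhelming majority, intensity > 2.5
        (_features(dysk=_dysk(True, 0.8, 3.0)), MotorState.ON_TROUBLESOME_DYSK),
        # non-troublesome: majority with intensity in (0.5, 2.5]
        (_features(dysk=_dysk(True, 0.6, 1.5)), MotorState.ON_NON_TROUBLESOME_DYSK),
        # 2.5 itself is still non-troublesome
        (_features(dysk=_dysk(True, 0.9, 2.5)), MotorState.ON_NON_TROUBLESOME_DYSK),
        # detected dyskinesia that never reaches 0.5 does not block ON
        (_features(dysk=_dysk(True, 0.6, 0.4)), MotorState.ON),
        # nighttime inactivity
        (
            _features(active=0.05, midpoint=datetime(2023, 5, 1, 23, 15)),
            MotorState.NIGHTTIME_INACTIVITY,
        ),
        # daytime inactivity
        (
            _features(active=0.05, midpoint=datetime(2023, 5, 1, 10, 15)),
            MotorState.DAYTIME_INACTIVITY,
        ),
        # OFF: predominant bradykinesia + tremor among active epochs
        (_features(tremor=0.3, brady=0.4), MotorState.OFF),
        # plain ON
        (_features(), MotorState.ON),
        # not worn wins over everything
        (_features(dysk=_dysk(True, 0.9, 3.5), worn=0.3), MotorState.NOT_WORN),
        # ambiguous: some parkinsonian signs but no predominance
        (_features(tremor=0.2, brady=0.2), MotorState.NOT_DETECTABLE),
    ],
)
def test_classification_precedence(features, expected):
    assert classify_window(features) == expected


def test_troublesome_boundary_is_monotone_in_intensity():
    """Raising the max intensity through 2.5 can only move a detected
    dyskinesia window from non-troublesome to troublesome, never back."""
    seen = []
    for m in np.linspace(0.6, 4.0, 35):
        state = classify_window(_features(dysk=_dysk(True, 0.9, float(m))))
        seen.append(state)
    switch = [s == MotorState.ON_TROUBLESOME_DYSK for s in seen]
    assert switch == sorted(switch)  # once troublesome, stays troublesome
    assert MotorState.ON_NON_TROUBLESOME_DYSK in seen
    assert MotorState.ON_TROUBLESOME_DYSK in seen


@pytest.mark.parametrize(
    "hhmm,expected",
    [
        ((5, 45), MotorState.NIGHTTIME_INACTIVITY),
        ((6, 15), MotorState.DAYTIME_INACTIVITY),
        ((21, 45), MotorState.DAYTIME_INACTIVITY),
        ((22, 15), MotorState.NIGHTTIME_INACTIVITY),
    ],
)
def test_day_night_split_at_clock_boundaries(hhmm, expected):
    midpoint = datetime(2023, 5, 1, *hhmm)
    assert classify_window(_features(active=0.0, midpoint=midpoint)) == expected


def test_overwhelming_majority_required_for_troublesome():
    state = classify_window(_features(dysk=_dysk(True, 0.6, 3.0)))
    assert state not in (
        MotorState.ON_TROUBLESOME_DYSK,
        MotorState.ON_NON_TROUBLESOME_DYSK,
        MotorState.ON,
    )


# ---------------------------------------------------------------------------
# summaries


def _timeline(states: list[MotorState]) -> StateTimeline:
    return StateTimeline(
        interval_s=1800.0, start_time=datetime(2023, 5, 1), states=states
    )


def test_duration_summary_counts_half_hours():
    states = [MotorState.OFF] * 8 + [MotorState.ON] * 30 + [
        MotorState.NIGHTTIME_INACTIVITY
    ] * 10
    out = summarize_durations(_timeline(states))
    by_state = dict(zip(out["state"], out["hours"]))
    assert by_state["OFF"] == 4.0
    assert by_state["ON"] == 15.0
    assert out["percent"].sum() == pytest.approx(100.0)
    assert out.attrs["worn_percent"] == pytest.approx(100.0)


def test_uniform_day_is_all_one_state():
    out = summarize_durations(_timeline([MotorState.ON] * 48))
    by_state = dict(zip(out["state"], out["percent"]))
    assert by_state["ON"] == pytest.approx(100.0)


def test_dyskinesia_histogram_bins():
    hours = 3600.0
    trace = np.concatenate(
        [np.full(int(2 * hours / 5), 1.0), np.full(int(hours / 5), 3.0)]
    )
    hist = dyskinesia_score_histogram(trace, 5.0)
    assert hist == {1: pytest.approx(2.0), 2: 0.0, 3: pytest.approx(1.0), 4: 0.0}


def test_low_intensity_dyskinesia_not_impactful():
    hist = dyskinesia_score_histogram(np.full(720, 0.3), 5.0)
    assert all(v == 0.0 for v in hist.values())


def test_histogram_edge_membership():
    # 1.5 belongs to score 1, 1.6 to score 2
    hist = dyskinesia_score_histogram(np.array([1.5, 1.6]), 1800.0)
    assert hist[1] == pytest.approx(0.5) and hist[2] == pytest.approx(0.5)


def test_histogram_rejects_out_of_range():
    with pytest.raises(ValidationError):
        dyskinesia_score_histogram(np.array([4.5]), 5.0)


@pytest.mark.parametrize("hours,expected", [(4.0, 25.0), (0.0, 0.0), (16.0, 100.0), (20.0, 100.0)])
def test_waking_day_percent(hours, expected):
    assert waking_day_percent(hours) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# pipeline


def test_pipeline_recovers_scripted_states():
    from wristpd.synthetic import Segment, SimulationScript, simulate_recording

    script = SimulationScript(
        segments=[
            Segment("sleep", 3600.0),
            Segment("normal_activity", 3600.0),
            Segment("tremor", 1800.0),
            Segment("dyskinesia_severe", 1800.0),
        ],
        start_time=datetime(2023, 5, 1, 2, 0, 0),
        seed=17,
    )
    rec, truth, _ = simulate_recording(script)
    tl = classify_recording(rec)
    assert tl.n_intervals == 6  # floor(3 h / 30 min)
    assert tl.states == truth.states
    assert tl.states[0] == MotorState.NIGHTTIME_INACTIVITY
    assert tl.states[4] == MotorState.OFF
    assert tl.states[5] == MotorState.ON_TROUBLESOME_DYSK


def test_all_not_worn_day():
    from wristpd.synthetic import Segment, SimulationScript, simulate_recording

    script = SimulationScript(segments=[Segment("not_worn", 3 * 3600.0)], seed=5)
    rec, _, _ = simulate_recording(script)
    tl = classify_recording(rec)
    assert all(s == MotorState.NOT_WORN for s in tl.states)


def test_timeline_csv_roundtrip(tmp_path):
    states = [MotorState.ON, MotorState.OFF, MotorState.NOT_WORN]
    tl = StateTimeline(
        interval_s=1800.0,
        start_time=datetime(2023, 5, 1, 8, 0),
        states=states,
        worn_fraction=np.array([1.0, 1.0, 0.1]),
    )
    path = tmp_path / "tl.csv"
    tl.to_frame().to_csv(path, index=False)
    back = read_timeline_csv(path)
    assert back.states == states
    assert back.start_time == tl.start_time
    assert back.interval_s == tl.interval_s
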