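"""Thirty-minute motor-state classification and timeline summaries.

Every 30-minute interval of a recording is assigned exactly one of
eight states: OFF, ON, ON with non-troublesome dyskinesia, ON with
troublesome dyskinesia, daytime motor inactivity, nighttime motor
inactivity, not worn, or not detectable.  The decision is a fixed
precedence cascade over window-level features aggregated from the
epoch detectors:

1. NOT_WORN when the device was off the body for most of the window;
2. ON_TROUBLESOME_DYSK when dyskinesia covers an overwhelming majority
   of the window with maximum intensity above 2.5;
3. ON_NON_TROUBLESOME_DYSK when dyskinesia covers a majority with
   maximum intensity in (0.5, 2.5];
4. daytime/nighttime inactivity when little motor activity is present,
   split at the local-clock day window (06:00–22:00 by default);
5. OFF when bradykinesia and/or tremor predominate among the active
   epochs and outweigh any dyskinesia;
6. ON when activity is present without relevant bradykinesia/tremor
   and without impactful dyskinesia (max intensity ≤ 0.5);
7. NOT_DETECTABLE otherwise.

The boundary value 2.5 itself is non-troublesome ("troublesome"
requires strictly greater than 2.5), and 0.5 itself is not impactful.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .recording_io import AccelRecording, ValidationError
from .detectors import (
    BradyConfig,
    DyskinesiaConfig,
    DyskinesiaWindowResult,
    PostureConfig,
    TremorConfig,
    WearConfig,
    _dyskinesia_from_powers,
    narrowband_fraction,
)
from .spectral import SpectralConfig, band_weights, batch_spectra

__all__ = [
    "MotorState",
    "StatesConfig",
    "WindowFeatures",
    "StateTimeline",
    "classify_window",
    "classify_recording",
    "summarize_durations",
    "dyskinesia_score_histogram",
    "waking_day_percent",
]


class MotorState(enum.Enum):
    OFF = "OFF"
    ON = "ON"
    ON_NON_TROUBLESOME_DYSK = "ON_NON_TROUBLESOME_DYSK"
    ON_TROUBLESOME_DYSK = "ON_TROUBLESOME_DYSK"
    DAYTIME_INACTIVITY = "DAYTIME_INACTIVITY"
    NIGHTTIME_INACTIVITY = "NIGHTTIME_INACTIVITY"
    NOT_WORN = "NOT_WORN"
    NOT_DETECTABLE = "NOT_DETECTABLE"


@dataclass
class StatesConfig:
    interval_s: float = 1800.0
    worn_min: float = 0.5        # min worn fraction to consider the window
    q_over: float = 0.75         # "overwhelming majority" dyskinesia fraction
    a_min: float = 0.2           # active fraction below which inactivity
    p_off: float = 0.5           # brady+tremor predominance for OFF
    relevant_frac: float = 0.25  # brady+tremor fraction that blocks plain ON
    impactful_intensity: float = 0.5
    troublesome_intensity: float = 2.5
    day_start_h: float = 6.0     # local-clock day window [start, end)
    day_end_h: float = 22.0
    snap_to_half_hour: bool = False  # align the interval grid to :00/:30

    def validate(self) -> None:
        for name in ("worn_min", "q_over", "a_min", "p_off", "relevant_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.day_start_h < self.day_end_h <= 24:
            raise ValidationError("day window must satisfy 0 <= start < end <= 24")


@dataclass
class WindowFeatures:
    """Detector outputs aggregated over one 30-minute window.

    ``tremor_fraction`` and ``brady_fraction`` are shares of the
    *active* epochs in the window (0 when no epoch is active), so that
    predominance is judged among periods with actual movement.
    """

    dysk: DyskinesiaWindowResult
    tremor_fraction: float
    brady_fraction: float
    active_fraction: float
    worn_fraction: float
    max_dysk_intensity: float
    clock_midpoint: datetime


@dataclass
class StateTimeline:
    interval_s: float
    start_time: datetime
    states: list[MotorState]
    dysk_intensity: np.ndarray = field(default_factory=lambda: np.array([]))
    tremor_intensity: np.ndarray = field(default_factory=lambda: np.array([]))
    brady_intensity: np.ndarray = field(default_factory=lambda: np.array([]))
    worn_fraction: np.ndarray = field(default_factory=lambda: np.array([]))
    epoch_s: float = 5.0

    @property
    def n_intervals(self) -> int:
        return len(self.states)

    def interval_start(self, k: int) -> datetime:
        return self.start_time + timedelta(seconds=k * self.interval_s)

    def to_frame(self) -> pd.DataFrame:
        epw = max(int(round(self.interval_s / self.epoch_s)), 1)
        rows = []
        for k, state in enumerate(self.states):
            sl = slice(k * epw, (k + 1) * epw)
            rows.append(
                {
                    "interval_start": self.interval_start(k).isoformat(),
                    "state": state.value,
                    "max_dysk_intensity": _safe_max(self.dysk_intensity[sl]),
                    "mean_tremor_intensity": _safe_mean(self.tremor_intensity[sl]),
                    "mean_brady_intensity": _safe_mean(self.brady_intensity[sl]),
                    "worn_fraction": (
                        float(self.worn_fraction[k])
                        if self.worn_fraction.size
                        else float("nan")
                    ),
                }
            )
        return pd.DataFrame(rows)


def read_timeline_csv(path) -> StateTimeline:
    """Read a timeline CSV written via :meth:`StateTimeline.to_frame`.

    Only the state sequence and worn fraction are recovered; the
    epoch-level intensity traces are not part of the interval table.
    """
    table = pd.read_csv(path, comment="#")
    for col in ("interval_start", "state"):
        if col not in table.columns:
            raise ValidationError(f"missing column '{col}' in timeline CSV {path}")
    stamps = [datetime.fromisoformat(str(s)) for s in table["interval_start"]]
    if len(stamps) < 1:
        raise ValidationError(f"empty timeline CSV {path}")
    interval_s = (
        (stamps[1] - stamps[0]).total_seconds() if len(stamps) > 1 else 1800.0
    )
    states = [MotorState(s) for s in table["state"]]
    worn = (
        table["worn_fraction"].to_numpy(dtype=float)
        if "worn_fraction" in table.columns
        else np.array([])
    )
    return StateTimeline(
        interval_s=interval_s,
        start_time=stamps[0],
        states=states,
        worn_fraction=worn,
    )


def _safe_max(x: np.ndarray) -> float:
    return float(np.max(x)) if x.size else 0.0


def _safe_mean(x: np.ndarray) -> float:
    return float(np.mean(x)) if x.size else 0.0


def _in_day_window(when: datetime, cfg: StatesConfig) -> bool:
    h = when.hour + when.minute / 60 + when.second / 3600
    return cfg.day_start_h <= h < cfg.day_end_h


def classify_window(f: WindowFeatures, cfg: StatesConfig | None = None) -> MotorState:
    """Assign one motor state to a window (deterministic precedence)."""
    cfg = cfg or StatesConfig()
    if f.worn_fraction < cfg.worn_min:
        return MotorState.NOT_WORN
    dysk_impactful = f.dysk.detected and f.max_dysk_intensity > cfg.impactful_intensity
    if (
        f.dysk.detected
        and f.dysk.fraction >= cfg.q_over
        and f.max_dysk_intensity > cfg.troublesome_intensity
    ):
        return MotorState.ON_TROUBLESOME_DYSK
    if (
        f.dysk.detected
        and cfg.impactful_intensity
        < f.max_dysk_intensity
        <= cfg.troublesome_intensity
    ):
        return MotorState.ON_NON_TROUBLESOME_DYSK
    if f.active_fraction < cfg.a_min:
        return (
            MotorState.DAYTIME_INACTIVITY
            if _in_day_window(f.clock_midpoint, cfg)
            else MotorState.NIGHTTIME_INACTIVITY
        )
    parkinsonian = f.tremor_fraction + f.brady_fraction
    if parkinsonian > cfg.p_off and parkinsonian > f.dysk.fraction:
        return MotorState.OFF
    if parkinsonian <= cfg.relevant_frac and not dysk_impactful:
        return MotorState.ON
    return MotorState.NOT_DETECTABLE


# ---------------------------------------------------------------------------
# Full-recording pipeline


def classify_recording(rec: AccelRecording, cfg=None) -> StateTimeline:
    """Segment → spectra → detectors → window features → state per window.

    The pipeline is a vectorised equivalent of the per-epoch detector
    functions (tests assert the equivalence): band powers are quadrature
    dot products over the batch PSD array, posture/wear use per-epoch
    means and standard deviations of the raw signal.
    """
    from .config import PipelineConfig

    cfg = cfg or PipelineConfig()
    cfg.validate()
    sp: SpectralConfig = cfg.spectral
    st: StatesConfig = cfg.states
    epoch_s = cfg.epoch_s

    start_time = rec.start_time
    offset_epochs = 0
    if st.snap_to_half_hour:
        sec_into_half_hour = (
            start_time.minute * 60 + start_time.second
        ) % 1800 + start_time.microsecond / 1e6
        if sec_into_half_hour > 0:
            skip_s = 1800 - sec_into_half_hour
            offset_epochs = int(np.ceil(skip_s / epoch_s))
            start_time = start_time + timedelta(seconds=offset_epochs * epoch_s)

    freqs, psd = batch_spectra(rec, epoch_s=epoch_s, cfg=sp)
    psd = psd[offset_epochs:]
    n_epochs = psd.shape[0]
    epw = int(round(st.interval_s / epoch_s))  # epochs per window
    n_windows = n_epochs // epw
    if n_windows == 0:
        raise ValidationError("recording shorter than one 30-minute interval")

    psd_c = psd[:, 3, :]
    w37 = band_weights(freqs, *cfg.tremor.band)
    p37_c = psd_c @ w37
    p37_axes = psd[:, :3, :] @ w37            # (n_epochs, 3)
    p_brady = psd_c @ band_weights(freqs, *cfg.brady.band)
    p13 = psd_c @ band_weights(freqs, *cfg.dyskinesia.band_low)
    p38 = psd_c @ band_weights(freqs, *cfg.dyskinesia.band_high)
    p18 = psd_c @ band_weights(freqs, *cfg.dyskinesia.intensity_band)
    nb = narrowband_fraction(freqs, psd_c, p18, cfg.dyskinesia)

    # --- tremor gates, vectorised -----------------------------------------
    search = (freqs >= cfg.tremor.search_band[0] - 1e-12) & (
        freqs <= cfg.tremor.search_band[1] + 1e-12
    )
    band = (freqs >= cfg.tremor.band[0] - 1e-12) & (
        freqs <= cfg.tremor.band[1] + 1e-12
    )
    f_search, f_band = freqs[search], freqs[band]
    peak_c = f_search[np.argmax(psd_c[:, search], axis=1)]
    in_band = (peak_c >= cfg.tremor.band[0] - 1e-9) & (
        peak_c <= cfg.tremor.band[1] + 1e-9
    )
    total_axes = p37_axes.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        transverse_share = np.where(
            total_axes > 0, (p37_axes[:, 1] + p37_axes[:, 2]) / total_axes, 0.0
        )
        share_y = np.where(total_axes > 0, p37_axes[:, 1] / total_axes, 0.0)
        share_z = np.where(total_axes > 0, p37_axes[:, 2] / total_axes, 0.0)
    peak_y = f_band[np.argmax(psd[:, 1, :][:, band], axis=1)]
    peak_z = f_band[np.argmax(psd[:, 2, :][:, band], axis=1)]
    agree_y = (share_y < cfg.tremor.min_axis_share) | (
        np.abs(peak_y - peak_c) <= cfg.tremor.delta_f + 1e-9
    )
    agree_z = (share_z < cfg.tremor.min_axis_share) | (
        np.abs(peak_z - peak_c) <= cfg.tremor.delta_f + 1e-9
    )
    tremor = (
        in_band
        & (p37_c >= cfg.tremor.theta_power)
        & (transverse_share >= cfg.tremor.rho_axis)
        & agree_y
        & agree_z
        & (total_axes > 0)
    )
    tremor_intensity = np.where(tremor, cfg.tremor.intensity.score(p37_c), 0.0)

    # --- posture / activity / wear, from the raw signal -------------------
    n_per = int(round(epoch_s * rec.fs))
    cut0, cut1 = offset_epochs * n_per, (offset_epochs + n_epochs) * n_per
    ax = rec.ax[cut0:cut1].reshape(n_epochs, n_per)
    ay = rec.ay[cut0:cut1].reshape(n_epochs, n_per)
    az = rec.az[cut0:cut1].reshape(n_epochs, n_per)
    mag = np.sqrt(ax**2 + ay**2 + az**2)
    mag_std = mag.std(axis=1)
    gvec = np.stack([ax.mean(axis=1), ay.mean(axis=1), az.mean(axis=1)], axis=1)
    gnorm = np.linalg.norm(gvec, axis=1)
    ref = np.asarray(cfg.posture.upright_ref, dtype=float)
    ref = ref / np.linalg.norm(ref)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(gnorm > 0, gvec @ ref / np.where(gnorm > 0, gnorm, 1.0), -1.0)
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    active = mag_std >= cfg.posture.movement_floor_g
    upright_active = (angle < cfg.posture.alpha_max_deg) & active

    brady = (
        upright_active
        & (p_brady > cfg.brady.theta_low)
        & (p_brady < cfg.brady.theta_high)
    )
    brady_intensity = np.where(brady, cfg.brady.intensity.score(p_brady), 0.0)

    if rec.temperature is not None:
        t_mid = (np.arange(offset_epochs, offset_epochs + n_epochs) + 0.5) * epoch_s
        t_axis = np.arange(rec.temperature.values.size) / rec.temperature.fs
        temp = np.interp(t_mid, t_axis, rec.temperature.values)
        worn = (temp >= cfg.wear.t_wear_c) | (mag_std >= cfg.wear.movement_floor_g)
    else:
        worn = mag_std >= cfg.wear.movement_floor_g

    # --- window aggregation and classification ----------------------------
    def per_window(x: np.ndarray) -> np.ndarray:
        return x[: n_windows * epw].reshape(n_windows, epw)

    states: list[MotorState] = []
    worn_fraction = per_window(worn.astype(float)).mean(axis=1)
    for k in range(n_windows):
        sl = slice(k * epw, (k + 1) * epw)
        dysk = _dyskinesia_from_powers(
            p13[sl], p38[sl], p18[sl], cfg.dyskinesia, nb[sl]
        )
        n_active = int(active[sl].sum())
        if n_active:
            tremor_frac = float((tremor[sl] & active[sl]).sum() / n_active)
            brady_frac = float((brady[sl] & active[sl]).sum() / n_active)
        else:
            tremor_frac = brady_frac = 0.0
        feats = WindowFeatures(
            dysk=dysk,
            tremor_fraction=tremor_frac,
            brady_fraction=brady_frac,
            active_fraction=float(active[sl].mean()),
            worn_fraction=float(worn_fraction[k]),
            max_dysk_intensity=dysk.max_intensity,
            clock_midpoint=start_time
            + timedelta(seconds=(k + 0.5) * st.interval_s),
        )
        states.append(classify_window(feats, st))

    # expose the dyskinesia intensity trace for the whole recording
    dysk_all = _dyskinesia_from_powers(p13, p38, p18, cfg.dyskinesia, nb)
    return StateTimeline(
        interval_s=st.interval_s,
        start_time=start_time,
        states=states,
        dysk_intensity=dysk_all.intensity_series,
        tremor_intensity=tremor_intensity,
        brady_intensity=brady_intensity,
        worn_fraction=worn_fraction,
        epoch_s=epoch_s,
    )


# ---------------------------------------------------------------------------
# Summaries


def summarize_durations(tl: StateTimeline) -> pd.DataFrame:
    """Hours and percentage per state, plus the worn share of the day.

    One row per state (half-hour quanta); the ``worn_percent`` attribute
    of the frame holds the share of intervals not classified NOT_WORN.
    """
    hours_per_interval = tl.interval_s / 3600.0
    counts = {state: 0 for state in MotorState}
    for s in tl.states:
        counts[s] += 1
    n = tl.n_intervals
    rows = [
        {
            "state": state.value,
            "hours": counts[state] * hours_per_interval,
            "percent": 100.0 * counts[state] / n if n else 0.0,
        }
        for state in MotorState
    ]
    out = pd.DataFrame(rows)
    out.attrs["worn_percent"] = (
        100.0 * (n - counts[MotorState.NOT_WORN]) / n if n else 0.0
    )
    return out


#: score-bin edges for the dyskinesia duration histogram; intensities at
#: or below the first edge are "not impactful" and excluded
DYSK_SCORE_EDGES = (0.5, 1.5, 2.5, 3.5, 4.0)


def dyskinesia_score_histogram(
    intensity: np.ndarray, sample_s: float
) -> dict[int, float]:
    """Hours spent at each dyskinesia score {1, 2, 3, 4}.

    Score 1 covers intensities in (0.5, 1.5], score 2 (1.5, 2.5],
    score 3 (2.5, 3.5], score 4 (3.5, 4].  Intensities ≤ 0.5 are not
    impactful and contribute to no bin.
    """
    intensity = np.asarray(intensity, dtype=float)
    if intensity.size and (intensity.min() < 0 or intensity.max() > 4):
        raise ValidationError("dyskinesia intensities must lie in [0, 4]")
    hours = sample_s / 3600.0
    out = {}
    e = DYSK_SCORE_EDGES
    for score, (lo, hi) in enumerate(zip(e[:-1], e[1:]), start=1):
        out[score] = float(((intensity > lo) & (intensity <= hi)).sum()) * hours
    return out


def waking_day_percent(impactful_hours: float, waking_day_h: float = 16.0) -> float:
    """Impactful-dyskinesia duration as a percentage of a 16-h waking day."""
    if not 0 <= impactful_hours <= 24:
        raise ValidationError("impactful_hours must be within [0, 24]")
    return min(100.0 * impactful_hours / waking_day_h, 100.0)
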