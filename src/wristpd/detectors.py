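"""Epoch- and window-level motor-sign detectors.

Tremor, bradykinesia and device wear are decided per epoch; dyskinesia
is decided over a wider window (30 min by default) because dyskinetic
movement is sustained, which also lets it take precedence over isolated
tremor-like epochs downstream.

Detection bands follow the clinical phenomenology: parkinsonian rest
tremor is a 3–7 Hz supination–pronation oscillation, dyskinesia is
irregular broadband movement assessed through the 1–3 Hz and 3–8 Hz
band powers, and bradykinetic movement while upright lives in
0.5–3 Hz between a motionless floor and a brisk-movement ceiling.
Intensities are mapped to a 0–4 scale (the range used by clinical
rating scales) through a piecewise-linear function of log10 band power
anchored at two calibrated powers.

All numeric thresholds are configuration values calibrated once against
the synthetic generator (``wristpd calibrate``); they are not clinical
constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording_io import Epoch, ValidationError
from .spectral import EpochSpectrum, band_power, peak_frequency

__all__ = [
    "IntensityMap",
    "TremorConfig",
    "PostureConfig",
    "BradyConfig",
    "DyskinesiaConfig",
    "WearConfig",
    "TremorEpochResult",
    "BradyEpochResult",
    "DyskinesiaWindowResult",
    "detect_tremor_epoch",
    "detect_posture_epoch",
    "detect_bradykinesia_epoch",
    "detect_dyskinesia_window",
    "detect_wear_epoch",
    "intensity_from_power",
]


# ---------------------------------------------------------------------------
# Intensity mapping


@dataclass
class IntensityMap:
    """Monotone map from band power (g²) to a 0–4 intensity score.

    The score is piecewise linear in log10(power): for an increasing
    map, ``anchor_power_low`` maps to 0.5 and ``anchor_power_high`` to
    4.0; a decreasing map (used for bradykinesia, where *less* residual
    movement power means *more* severe slowness) reverses the scores at
    the same anchors.  Outside the anchors the line is extrapolated and
    clipped to [0, 4].
    """

    anchor_power_low: float
    anchor_power_high: float
    direction: str = "increasing"

    def __post_init__(self) -> None:
        if not 0 < self.anchor_power_low < self.anchor_power_high:
            raise ValidationError(
                "intensity anchors must satisfy 0 < low < high, got "
                f"({self.anchor_power_low}, {self.anchor_power_high})"
            )
        if self.direction not in ("increasing", "decreasing"):
            raise ValidationError(f"unknown direction {self.direction!r}")

    def score(self, p):
        p = np.asarray(p, dtype=float)
        if not np.all(np.isfinite(p)) or np.any(p < 0):
            raise ValidationError("band power must be finite and non-negative")
        lo, hi = np.log10(self.anchor_power_low), np.log10(self.anchor_power_high)
        with np.errstate(divide="ignore"):
            t = (np.log10(p) - lo) / (hi - lo)
        s = 0.5 + 3.5 * t if self.direction == "increasing" else 4.0 - 3.5 * t
        out = np.clip(s, 0.0, 4.0)
        return float(out) if out.ndim == 0 else out


def intensity_from_power(p: float, imap: IntensityMap) -> float:
    """0–4 intensity score for one band-power value."""
    return float(imap.score(p))


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class TremorConfig:
    band: tuple[float, float] = (3.0, 7.0)          # tremor band, Hz
    search_band: tuple[float, float] = (0.5, 12.0)  # where the peak must win
    theta_power: float = 5e-4                       # detection floor, g²
    rho_axis: float = 0.6        # min transverse share of 3–7 Hz power
    delta_f: float = 0.5         # per-axis peak agreement tolerance, Hz
    min_axis_share: float = 0.25 # axis share below which its peak is not gated
    intensity: IntensityMap = field(
        default_factory=lambda: IntensityMap(5e-4, 5e-2, "increasing")
    )


@dataclass
class PostureConfig:
    upright_ref: tuple[float, float, float] = (1.0, 0.0, 0.0)
    alpha_max_deg: float = 35.0     # max gravity angle from upright reference
    movement_floor_g: float = 0.01  # epoch magnitude std separating rest


@dataclass
class BradyConfig:
    band: tuple[float, float] = (0.5, 3.0)
    theta_low: float = 2e-5    # motionless floor, g²
    theta_high: float = 3e-3   # brisk-movement ceiling, g²
    intensity: IntensityMap | None = None  # default: decreasing over thresholds

    def __post_init__(self) -> None:
        if self.theta_low >= self.theta_high:
            raise ValidationError(
                f"theta_low ({self.theta_low}) must be < theta_high ({self.theta_high})"
            )
        if self.intensity is None:
            self.intensity = IntensityMap(self.theta_low, self.theta_high, "decreasing")


@dataclass
class DyskinesiaConfig:
    band_low: tuple[float, float] = (1.0, 3.0)
    band_high: tuple[float, float] = (3.0, 8.0)
    theta_13: float = 1.5e-4   # threshold on the 1–3 Hz integral, g²
    theta_38: float = 2.5e-4   # threshold on the 3–8 Hz integral, g²
    majority_q: float = 0.5    # fraction of flagged epochs for detection
    intensity_band: tuple[float, float] = (1.0, 8.0)
    # dyskinetic movement is broadband: an epoch whose 1–8 Hz power is
    # concentrated within ±peak_halfwidth_hz of the spectral peak is a
    # narrowband (tremor-like) oscillation and is never flagged
    narrowband_veto: float = 0.5
    peak_halfwidth_hz: float = 0.6
    intensity: IntensityMap = field(
        default_factory=lambda: IntensityMap(2.3e-4, 6e-2, "increasing")
    )


@dataclass
class WearConfig:
    t_wear_c: float = 30.0        # near-body temperature above which worn
    movement_floor_g: float = 0.01


# ---------------------------------------------------------------------------
# Results


@dataclass
class TremorEpochResult:
    detected: bool
    peak_hz: float | None
    raw_power: float   # ∫PSD over 3–7 Hz, combined channel, g²
    intensity: float   # 0–4


@dataclass
class BradyEpochResult:
    detected: bool
    raw_power: float   # ∫PSD over 0.5–3 Hz, combined channel, g²
    intensity: float   # 0–4
    posture: str       # "upright_active" or "other"


@dataclass
class DyskinesiaWindowResult:
    detected: bool
    epoch_flags: np.ndarray       # per-epoch booleans
    fraction: float               # share of flagged epochs
    intensity_series: np.ndarray  # per-epoch 0–4 scores (0 where unflagged)
    max_intensity: float


# ---------------------------------------------------------------------------
# Detectors


def detect_tremor_epoch(
    spec: EpochSpectrum, cfg: TremorConfig | None = None
) -> TremorEpochResult:
    """Tremor decision for one epoch.

    Three gates must pass: (a) the combined-channel spectral peak over
    the search band lies inside the tremor band; (b) the
    supination–pronation gate — the transverse axes (y, z) jointly carry
    at least ``rho_axis`` of the summed per-axis tremor-band power, and
    each transverse axis that carries a non-negligible share peaks at
    the same frequency as the combined channel (± ``delta_f``); (c) the
    combined tremor-band power reaches the detection floor.
    """
    cfg = cfg or TremorConfig()
    lo, hi = cfg.band
    raw = band_power(spec, "combined", lo, hi)
    peak_c = peak_frequency(spec, "combined", *cfg.search_band)

    in_band = lo - 1e-9 <= peak_c <= hi + 1e-9
    detected = in_band and raw >= cfg.theta_power
    if detected:
        bp_axes = {ch: band_power(spec, ch, lo, hi) for ch in ("x", "y", "z")}
        total = sum(bp_axes.values())
        if total <= 0:
            detected = False
        else:
            transverse = bp_axes["y"] + bp_axes["z"]
            if transverse / total < cfg.rho_axis:
                detected = False
            else:
                for ch in ("y", "z"):
                    if bp_axes[ch] / total < cfg.min_axis_share:
                        continue
                    pk = peak_frequency(spec, ch, lo, hi)
                    if abs(pk - peak_c) > cfg.delta_f + 1e-9:
                        detected = False
                        break
    intensity = float(cfg.intensity.score(raw)) if detected else 0.0
    return TremorEpochResult(
        detected=detected,
        peak_hz=peak_c if detected else None,
        raw_power=raw,
        intensity=intensity,
    )


def gravity_vector(epoch: Epoch) -> np.ndarray:
    """Low-passed gravity estimate: the epoch-mean acceleration vector."""
    return np.array([epoch.ax.mean(), epoch.ay.mean(), epoch.az.mean()])


def detect_posture_epoch(epoch: Epoch, cfg: PostureConfig | None = None) -> str:
    """``"upright_active"`` when the gravity vector is near the upright
    reference and the epoch shows more movement than the rest floor;
    ``"other"`` otherwise.

    A wrist device cannot observe trunk posture directly: this is an
    orientation-plus-activity proxy for "standing / non-sedentary".
    """
    cfg = cfg or PostureConfig()
    g = gravity_vector(epoch)
    norm = np.linalg.norm(g)
    if norm == 0:
        return "other"
    ref = np.asarray(cfg.upright_ref, dtype=float)
    ref = ref / np.linalg.norm(ref)
    angle = np.degrees(np.arccos(np.clip(g @ ref / norm, -1.0, 1.0)))
    moving = float(np.std(epoch.magnitude())) >= cfg.movement_floor_g
    return "upright_active" if (angle < cfg.alpha_max_deg and moving) else "other"


def detect_bradykinesia_epoch(
    spec: EpochSpectrum, posture: str, cfg: BradyConfig | None = None
) -> BradyEpochResult:
    """Bradykinesia decision for one epoch.

    Requires upright, non-sedentary posture and a 0.5–3 Hz combined
    band power strictly between the motionless floor and the
    brisk-movement ceiling.  Intensity decreases with residual power:
    the slower the movement, the higher the score.
    """
    cfg = cfg or BradyConfig()
    raw = band_power(spec, "combined", *cfg.band)
    detected = posture == "upright_active" and cfg.theta_low < raw < cfg.theta_high
    intensity = float(cfg.intensity.score(raw)) if detected else 0.0
    return BradyEpochResult(
        detected=detected, raw_power=raw, intensity=intensity, posture=posture
    )


def detect_dyskinesia_window(
    specs: list[EpochSpectrum], cfg: DyskinesiaConfig | None = None
) -> DyskinesiaWindowResult:
    """Dyskinesia decision over a window of epochs.

    An epoch is flagged when both the 1–3 Hz and the 3–8 Hz integrals
    exceed their thresholds; the window is dyskinetic when flagged
    epochs form a majority (> ``majority_q``).  The decision depends
    only on the flagged fraction, so it is invariant to epoch order.
    """
    cfg = cfg or DyskinesiaConfig()
    if len(specs) == 0:
        raise ValidationError("dyskinesia window must contain at least one epoch")
    p13 = np.array([band_power(s, "combined", *cfg.band_low) for s in specs])
    p38 = np.array([band_power(s, "combined", *cfg.band_high) for s in specs])
    p18 = np.array([band_power(s, "combined", *cfg.intensity_band) for s in specs])
    psd_c = np.stack([s.psd_c for s in specs])
    nb = narrowband_fraction(specs[0].freqs, psd_c, p18, cfg)
    return _dyskinesia_from_powers(p13, p38, p18, cfg, nb)


def narrowband_fraction(
    freqs: np.ndarray,
    psd_c: np.ndarray,
    p18: np.ndarray,
    cfg: DyskinesiaConfig,
) -> np.ndarray:
    """Share of the 1–8 Hz power lying within ±peak_halfwidth_hz of the
    in-band spectral peak, per epoch (rows of ``psd_c``)."""
    lo, hi = cfg.intensity_band
    mask = (freqs >= lo - 1e-12) & (freqs <= hi + 1e-12)
    f_in = freqs[mask]
    sub = np.atleast_2d(psd_c)[:, mask]
    df = float(freqs[1] - freqs[0])
    half_bins = max(int(round(cfg.peak_halfwidth_hz / df)), 1)
    peak_idx = np.argmax(sub, axis=1)
    local = np.empty(sub.shape[0])
    for i, k in enumerate(peak_idx):  # narrow windows; cheap even batched
        local[i] = sub[i, max(k - half_bins, 0) : k + half_bins + 1].sum() * df
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(p18 > 0, np.minimum(local / np.maximum(p18, 1e-300), 1.0), 1.0)


def _dyskinesia_from_powers(
    p13: np.ndarray,
    p38: np.ndarray,
    p18: np.ndarray,
    cfg: DyskinesiaConfig,
    narrowband: np.ndarray | None = None,
) -> DyskinesiaWindowResult:
    flags = (p13 > cfg.theta_13) & (p38 > cfg.theta_38)
    if narrowband is not None:
        flags = flags & (narrowband < cfg.narrowband_veto)
    fraction = float(flags.mean())
    detected = fraction > cfg.majority_q
    series = np.where(flags, cfg.intensity.score(p18), 0.0)
    return DyskinesiaWindowResult(
        detected=detected,
        epoch_flags=flags,
        fraction=fraction,
        intensity_series=series,
        max_intensity=float(series.max(initial=0.0)),
    )


def detect_wear_epoch(
    epoch: Epoch,
    temperature_slice: np.ndarray | None = None,
    cfg: WearConfig | None = None,
) -> bool:
    """Worn iff near-body temperature reaches the wear threshold (when a
    temperature channel exists) or the epoch shows real movement."""
    cfg = cfg or WearConfig()
    warm = (
        temperature_slice is not None
        and len(temperature_slice) > 0
        and float(np.mean(temperature_slice)) >= cfg.t_wear_c
    )
    moving = float(np.std(epoch.magnitude())) >= cfg.movement_floor_g
    return bool(warm or moving)
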