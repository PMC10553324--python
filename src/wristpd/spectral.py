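"""Per-epoch power spectral density estimation and band integrals.

Each epoch is analysed with a Welch-averaged periodogram (Hann window,
2.5 s segments, 50 % overlap by default, i.e. a 0.4 Hz grid at 50 Hz)
after gravity removal with a zero-phase 4th-order high-pass at 0.25 Hz.
Four channels are produced: one PSD per axis and a "combined" channel.
The combined channel is, by default, the PSD of the high-passed vector
magnitude ``sqrt(ax² + ay² + az²)``; a configuration switch selects the
alternative reading in which the per-axis PSDs are summed instead.

All PSDs use one-sided density normalisation, so the integral over
(0, Nyquist] approximates the variance of the gravity-removed signal
(Parseval).  Band powers are trapezoidal integrals with linear
interpolation at the band edges, which makes adjacent bands exactly
additive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .recording_io import AccelRecording, Epoch, ValidationError, segment_epochs

__all__ = [
    "SpectralConfig",
    "EpochSpectrum",
    "compute_epoch_spectrum",
    "band_power",
    "peak_frequency",
    "spectrogram_matrix",
    "batch_spectra",
]

CHANNELS = ("x", "y", "z", "combined")


@dataclass
class SpectralConfig:
    """Welch estimator and detrending parameters."""

    segment_s: float = 2.5       # Welch segment length
    overlap: float = 0.5         # fractional overlap between segments
    highpass_hz: float = 0.25    # gravity-removal cutoff
    highpass_order: int = 4
    window: str = "hann"
    combined_mode: str = "magnitude"  # or "spectra_sum"

    def validate(self) -> None:
        if not 0 < self.overlap < 1:
            raise ValidationError("overlap must be in (0, 1)")
        if self.segment_s <= 0 or self.highpass_hz <= 0:
            raise ValidationError("segment_s and highpass_hz must be positive")
        if self.combined_mode not in ("magnitude", "spectra_sum"):
            raise ValidationError(f"unknown combined_mode {self.combined_mode!r}")


@dataclass
class EpochSpectrum:
    """PSD of one epoch on a shared frequency grid (g²/Hz)."""

    freqs: np.ndarray
    psd_x: np.ndarray
    psd_y: np.ndarray
    psd_z: np.ndarray
    psd_c: np.ndarray
    epoch_index: int = 0

    def psd(self, channel: str) -> np.ndarray:
        try:
            return {
                "x": self.psd_x,
                "y": self.psd_y,
                "z": self.psd_z,
                "combined": self.psd_c,
            }[channel]
        except KeyError:
            raise ValueError(f"unknown channel {channel!r}; use one of {CHANNELS}")


def _highpass_sos(fs: float, cfg: SpectralConfig) -> np.ndarray:
    return signal.butter(
        cfg.highpass_order, cfg.highpass_hz, btype="highpass", fs=fs, output="sos"
    )


def _welch_params(fs: float, cfg: SpectralConfig) -> tuple[int, int]:
    nperseg = int(round(cfg.segment_s * fs))
    noverlap = int(nperseg * cfg.overlap)
    return nperseg, noverlap


def _psd_rows(x: np.ndarray, fs: float, cfg: SpectralConfig) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD along the last axis of ``x`` (any leading shape)."""
    nperseg, noverlap = _welch_params(fs, cfg)
    if x.shape[-1] < nperseg:
        raise ValidationError(
            f"epoch of {x.shape[-1]} samples shorter than one Welch segment "
            f"({nperseg} samples)"
        )
    freqs, psd = signal.welch(
        x, fs=fs, window=cfg.window, nperseg=nperseg, noverlap=noverlap, axis=-1
    )
    return freqs, psd


def _detrended_channels(
    stack: np.ndarray, fs: float, cfg: SpectralConfig
) -> np.ndarray:
    """High-pass the (..., 4, n) channel stack [x, y, z, magnitude]."""
    sos = _highpass_sos(fs, cfg)
    return signal.sosfiltfilt(sos, stack, axis=-1)


def _epoch_channel_stack(ax, ay, az) -> np.ndarray:
    mag = np.sqrt(ax**2 + ay**2 + az**2)
    return np.stack([ax, ay, az, mag], axis=-2)


def compute_epoch_spectrum(
    epoch: Epoch, fs: float, cfg: SpectralConfig | None = None
) -> EpochSpectrum:
    """PSD of one epoch for each axis and the combined channel."""
    cfg = cfg or SpectralConfig()
    cfg.validate()
    stack = _epoch_channel_stack(epoch.ax, epoch.ay, epoch.az)
    hp = _detrended_channels(stack, fs, cfg)
    freqs, psd = _psd_rows(hp, fs, cfg)
    psd_x, psd_y, psd_z, psd_m = psd
    psd_c = psd_x + psd_y + psd_z if cfg.combined_mode == "spectra_sum" else psd_m
    return EpochSpectrum(
        freqs=freqs,
        psd_x=psd_x,
        psd_y=psd_y,
        psd_z=psd_z,
        psd_c=psd_c,
        epoch_index=epoch.index,
    )


def batch_spectra(
    rec: AccelRecording, epoch_s: float = 5.0, cfg: SpectralConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """All epoch spectra of a recording at once.

    Returns ``(freqs, psd)`` where ``psd`` has shape
    ``(n_epochs, 4, n_freqs)`` with channel order x, y, z, combined.
    Each row is numerically identical to :func:`compute_epoch_spectrum`
    on the corresponding epoch (epochs are filtered independently).
    """
    cfg = cfg or SpectralConfig()
    cfg.validate()
    n_per = int(round(epoch_s * rec.fs))
    n_epochs = rec.n_samples // n_per
    if n_epochs == 0:
        nperseg, _ = _welch_params(rec.fs, cfg)
        freqs = np.fft.rfftfreq(nperseg, d=1.0 / rec.fs)
        return freqs, np.zeros((0, 4, freqs.size))
    cut = n_epochs * n_per
    axes = [a[:cut].reshape(n_epochs, n_per) for a in (rec.ax, rec.ay, rec.az)]
    stack = _epoch_channel_stack(*axes)  # (n_epochs, 4, n_per)
    hp = _detrended_channels(stack, rec.fs, cfg)
    freqs, psd = _psd_rows(hp, rec.fs, cfg)
    if cfg.combined_mode == "spectra_sum":
        psd = psd.copy()
        psd[:, 3, :] = psd[:, 0, :] + psd[:, 1, :] + psd[:, 2, :]
    return freqs, psd


# ---------------------------------------------------------------------------
# Band integrals and peaks


def band_weights(freqs: np.ndarray, f_lo: float, f_hi: float) -> np.ndarray:
    """Quadrature weights w such that ``psd @ w`` is the trapezoidal
    integral of the PSD over [f_lo, f_hi] with linearly interpolated
    band edges.  Exactly additive over adjacent bands."""
    if not (0 <= f_lo < f_hi):
        raise ValueError(f"band must satisfy 0 <= f_lo < f_hi, got [{f_lo}, {f_hi}]")
    if f_hi > freqs[-1] + 1e-9:
        raise ValueError(
            f"band [{f_lo}, {f_hi}] extends beyond the grid (Nyquist {freqs[-1]} Hz)"
        )
    inner = np.flatnonzero((freqs > f_lo) & (freqs < f_hi))
    nodes = np.concatenate(([f_lo], freqs[inner], [f_hi]))
    # trapezoid coefficient of each node
    d = np.diff(nodes)
    coef = np.zeros(nodes.size)
    coef[:-1] += d / 2
    coef[1:] += d / 2
    w = np.zeros(freqs.size)
    if inner.size:
        w[inner] += coef[1:-1]
    # distribute the interpolated edge nodes onto their bracketing bins
    for node_f, c in ((f_lo, coef[0]), (f_hi, coef[-1])):
        k = np.searchsorted(freqs, node_f)
        if k < freqs.size and abs(freqs[k] - node_f) < 1e-12:
            w[k] += c
        else:
            lo_bin, hi_bin = k - 1, k
            t = (node_f - freqs[lo_bin]) / (freqs[hi_bin] - freqs[lo_bin])
            w[lo_bin] += c * (1 - t)
            w[hi_bin] += c * t
    return w


def band_power(
    spec: EpochSpectrum, channel: str, f_lo: float, f_hi: float
) -> float:
    """Integral of the PSD over [f_lo, f_hi] in g²."""
    w = band_weights(spec.freqs, f_lo, f_hi)
    return float(spec.psd(channel) @ w)


def peak_frequency(
    spec: EpochSpectrum, channel: str, f_lo: float, f_hi: float
) -> float:
    """Frequency of the maximum PSD value inside [f_lo, f_hi].

    Only grid nodes are considered; ties break toward the lower
    frequency.
    """
    freqs = spec.freqs
    mask = (freqs >= f_lo - 1e-12) & (freqs <= f_hi + 1e-12)
    if not mask.any():
        raise ValueError(f"band [{f_lo}, {f_hi}] contains no grid node")
    sub = spec.psd(channel)[mask]
    return float(freqs[mask][np.argmax(sub)])


def spectrogram_matrix(
    rec: AccelRecording, cfg: SpectralConfig | None = None, epoch_s: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Combined-channel PSD of every epoch as a (freq × time) matrix.

    Column ``k`` equals ``compute_epoch_spectrum(epoch_k).psd_c``.
    """
    freqs, psd = batch_spectra(rec, epoch_s=epoch_s, cfg=cfg)
    return freqs, psd[:, 3, :].T
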