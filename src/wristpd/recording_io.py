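"""Data model and CSV I/O for wrist-worn accelerometer recordings.

A recording is a tri-axial acceleration signal sampled at a fixed rate
(50 Hz by default) in units of g, optionally accompanied by a near-body
temperature channel (°C) and an illuminance channel (lux) sampled at
their own, typically much lower, rates.  The on-disk format is a plain
CSV with ``#``-prefixed header lines carrying the sampling rate, the
recording start timestamp (ISO-8601, local clock) and the subject label;
auxiliary channels live in a ``<stem>.aux.csv`` sidecar so the main file
stays a strict one-row-per-sample table.

Analysis operates on fixed-length epochs ("time sequences"): the
recording is divided into equal, contiguous, non-overlapping blocks and
any trailing partial block is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AuxChannel",
    "AccelRecording",
    "Epoch",
    "FormatError",
    "ValidationError",
    "read_recording_csv",
    "write_recording_csv",
    "segment_epochs",
]

#: conversion constant; acceleration is stored in g throughout
G_TO_MS2 = 9.80665


class FormatError(ValueError):
    """Raised when a file does not conform to the recording/diary dialect."""


class ValidationError(ValueError):
    """Raised when data violate a container invariant."""


@dataclass
class AuxChannel:
    """A low-rate auxiliary series (temperature or lux)."""

    values: np.ndarray
    fs: float  # Hz

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ValidationError("auxiliary channel rate must be positive")
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValidationError("auxiliary channel must be a non-empty 1-D series")

    @property
    def duration_s(self) -> float:
        return self.values.size / self.fs

    def slice_seconds(self, t0: float, t1: float) -> np.ndarray:
        """Values covering the time interval [t0, t1)."""
        i0 = max(int(np.floor(t0 * self.fs)), 0)
        i1 = min(int(np.ceil(t1 * self.fs)), self.values.size)
        return self.values[i0:i1]


@dataclass
class AccelRecording:
    """Time-anchored tri-axial wrist acceleration with optional aux channels.

    Parameters
    ----------
    start_time
        Local calendar timestamp of the first sample.  Day/night
        boundaries downstream are interpreted on this local clock; no
        timezone arithmetic is performed.
    fs
        Sampling rate in Hz (the same for all three axes).
    ax, ay, az
        Acceleration in g.  ``ax`` is the forearm-longitudinal axis,
        ``ay``/``az`` the transverse axes (see ``axis_convention``).
    """

    start_time: datetime
    fs: float
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    temperature: AuxChannel | None = None
    lux: AuxChannel | None = None
    subject_id: str = ""
    axis_convention: str = "x-longitudinal"

    def __post_init__(self) -> None:
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        n = self.ax.size
        if n < 1:
            raise ValidationError("recording must contain at least one sample")
        if not (self.ay.size == n and self.az.size == n):
            raise ValidationError(
                "axis length mismatch: "
                f"ax={self.ax.size}, ay={self.ay.size}, az={self.az.size}"
            )
        for name in ("ax", "ay", "az"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValidationError(f"non-finite samples in {name}")
        for aux_name in ("temperature", "lux"):
            aux = getattr(self, aux_name)
            if aux is None:
                continue
            # aux channel must cover the same span within one of its samples
            if abs(aux.duration_s - self.duration_s) > 1.0 / aux.fs + 1e-9:
                raise ValidationError(
                    f"{aux_name} span {aux.duration_s:.2f}s does not match "
                    f"recording span {self.duration_s:.2f}s"
                )

    @property
    def n_samples(self) -> int:
        return self.ax.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def magnitude(self) -> np.ndarray:
        """Euclidean norm of the three axes, in g (gravity included)."""
        return np.sqrt(self.ax**2 + self.ay**2 + self.az**2)

    def allclose(self, other: "AccelRecording", rtol: float = 1e-6) -> bool:
        """Field-by-field equality to the declared CSV precision."""
        if (
            self.start_time != other.start_time
            or abs(self.fs - other.fs) > 1e-9
            or self.subject_id != other.subject_id
            or self.axis_convention != other.axis_convention
            or self.n_samples != other.n_samples
        ):
            return False
        for name in ("ax", "ay", "az"):
            if not np.allclose(
                getattr(self, name), getattr(other, name), rtol=rtol, atol=1e-8
            ):
                return False
        for name in ("temperature", "lux"):
            a, b = getattr(self, name), getattr(other, name)
            if (a is None) != (b is None):
                return False
            if a is not None and not (
                abs(a.fs - b.fs) < 1e-9
                and a.values.size == b.values.size
                and np.allclose(a.values, b.values, rtol=rtol, atol=1e-8)
            ):
                return False
        return True


@dataclass
class Epoch:
    """One fixed-length analysis block of a recording (a "time sequence")."""

    index: int
    t0: float  # offset from recording start, s
    duration_s: float
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.ax.size

    def magnitude(self) -> np.ndarray:
        return np.sqrt(self.ax**2 + self.ay**2 + self.az**2)


# ---------------------------------------------------------------------------
# CSV dialect


def _parse_header(path: Path) -> tuple[dict[str, str], int]:
    meta: dict[str, str] = {}
    n = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta, n


def _interpolate_gaps(x: np.ndarray, max_gap: int, name: str) -> np.ndarray:
    """Linearly fill non-finite runs of at most ``max_gap`` samples."""
    bad = ~np.isfinite(x)
    if not bad.any():
        return x
    idx = np.arange(x.size)
    # locate runs of consecutive bad samples
    edges = np.flatnonzero(np.diff(np.concatenate(([0], bad.view(np.int8), [0]))))
    starts, ends = edges[::2], edges[1::2]
    if np.max(ends - starts) > max_gap or starts[0] == 0 or ends[-1] == x.size:
        raise ValidationError(
            f"non-finite gap in {name} too long to interpolate "
            f"(limit {max_gap} samples) or at the series boundary"
        )
    out = x.copy()
    out[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return out


def read_recording_csv(
    path: str | Path,
    on_nonfinite: str = "reject",
    max_gap_s: float = 0.2,
) -> AccelRecording:
    """Read a recording written by :func:`write_recording_csv`.

    Parameters
    ----------
    on_nonfinite
        ``"reject"`` raises on any NaN/inf sample; ``"interpolate"``
        linearly fills gaps no longer than ``max_gap_s`` seconds.
    """
    path = Path(path)
    meta, n_header = _parse_header(path)
    for key in ("fs", "start_time"):
        if key not in meta:
            raise FormatError(f"missing required header field '{key}' in {path}")
    fs = float(meta["fs"])
    if fs <= 0:
        raise ValidationError(f"declared fs must be positive, got {fs}")
    table = pd.read_csv(path, skiprows=n_header)
    for col in ("ax_g", "ay_g", "az_g"):
        if col not in table.columns:
            raise FormatError(f"missing mandatory column '{col}' in {path}")
    axes = {}
    for col in ("ax_g", "ay_g", "az_g"):
        x = table[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            if on_nonfinite == "reject":
                raise ValidationError(f"non-finite samples in column {col}")
            elif on_nonfinite == "interpolate":
                x = _interpolate_gaps(x, max(int(round(max_gap_s * fs)), 1), col)
            else:
                raise ValueError(f"unknown on_nonfinite policy {on_nonfinite!r}")
        axes[col] = x

    temperature = lux = None
    aux_path = path.with_suffix(".aux.csv") if path.suffix == ".csv" else None
    if aux_path is not None and aux_path.exists():
        aux_meta, aux_header = _parse_header(aux_path)
        aux = pd.read_csv(aux_path, skiprows=aux_header)
        if "temperature_c" in aux.columns:
            temperature = AuxChannel(
                aux["temperature_c"].to_numpy(dtype=float),
                fs=float(aux_meta.get("fs_aux", 1.0)),
            )
        if "lux" in aux.columns:
            lux = AuxChannel(
                aux["lux"].to_numpy(dtype=float), fs=float(aux_meta.get("fs_aux", 1.0))
            )

    return AccelRecording(
        start_time=datetime.fromisoformat(meta["start_time"]),
        fs=fs,
        ax=axes["ax_g"],
        ay=axes["ay_g"],
        az=axes["az_g"],
        temperature=temperature,
        lux=lux,
        subject_id=meta.get("subject_id", ""),
        axis_convention=meta.get("axis_convention", "x-longitudinal"),
    )


def write_recording_csv(rec: AccelRecording, path: str | Path) -> None:
    """Write a recording (and aux sidecar, if present) as plain CSV.

    Acceleration is stored with 8 significant digits, which preserves
    the declared ≥ 6-significant-digit roundtrip contract.
    """
    path = Path(path)
    t = np.arange(rec.n_samples) / rec.fs
    with open(path, "w") as fh:
        fh.write("# wristpd-recording v1\n")
        fh.write(f"# fs = {rec.fs:g}\n")
        fh.write(f"# start_time = {rec.start_time.isoformat()}\n")
        if rec.subject_id:
            fh.write(f"# subject_id = {rec.subject_id}\n")
        fh.write(f"# axis_convention = {rec.axis_convention}\n")
        pd.DataFrame(
            {"time_s": t, "ax_g": rec.ax, "ay_g": rec.ay, "az_g": rec.az}
        ).to_csv(fh, index=False, float_format="%.8g")
    if rec.temperature is not None or rec.lux is not None:
        aux_path = path.with_suffix(".aux.csv")
        cols: dict[str, np.ndarray] = {}
        rates = []
        if rec.temperature is not None:
            cols["temperature_c"] = rec.temperature.values
            rates.append(rec.temperature.fs)
        if rec.lux is not None:
            cols["lux"] = rec.lux.values
            rates.append(rec.lux.fs)
        if len(set(rates)) > 1:
            raise ValidationError("temperature and lux must share a rate to be co-tabulated")
        fs_aux = rates[0]
        n_aux = max(v.size for v in cols.values())
        with open(aux_path, "w") as fh:
            fh.write("# wristpd-aux v1\n")
            fh.write(f"# fs_aux = {fs_aux:g}\n")
            pd.DataFrame(
                {"time_s": np.arange(n_aux) / fs_aux, **cols}
            ).to_csv(fh, index=False, float_format="%.8g")


# ---------------------------------------------------------------------------
# Epoch segmentation


def segment_epochs(rec: AccelRecording, epoch_s: float = 5.0) -> list[Epoch]:
    """Divide the recording into equal contiguous epochs.

    The trailing partial epoch, if any, is discarded.  A recording
    shorter than one epoch yields an empty list.
    """
    n_per = int(round(epoch_s * rec.fs))
    if n_per < 8:
        raise ValidationError(
            f"epoch of {epoch_s}s at {rec.fs}Hz holds {n_per} < 8 samples"
        )
    n_epochs = rec.n_samples // n_per
    out = []
    for k in range(n_epochs):
        sl = slice(k * n_per, (k + 1) * n_per)
        out.append(
            Epoch(
                index=k,
                t0=k * epoch_s,
                duration_s=epoch_s,
                ax=rec.ax[sl],
                ay=rec.ay[sl],
                az=rec.az[sl],
            )
        )
    return out
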