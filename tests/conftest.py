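"""Shared fixtures: all test data are generated programmatically."""

from __future__ import annotations

from datetime import datetime

import numpy as np
import pytest

from wristpd.recording_io import AccelRecording, AuxChannel, Epoch
from wristpd.spectral import SpectralConfig, batch_spectra, compute_epoch_spectrum
from wristpd.synthetic import Segment, SimulationScript, simulate_recording

FS = 50.0
T0 = datetime(2023, 5, 1, 0, 0, 0)


def make_epoch(ax, ay, az, fs: float = FS, index: int = 0) -> Epoch:
    ax, ay, az = (np.asarray(v, dtype=float) for v in (ax, ay, az))
    return Epoch(index=index, t0=0.0, duration_s=ax.size / fs, ax=ax, ay=ay, az=az)


def tone_epoch(
    freq_hz: float,
    amp: float = 0.1,
    axis: str = "x",
    seconds: float = 5.0,
    gravity=(0.0, 0.0, 1.0),
    fs: float = FS,
) -> Epoch:
    """Gravity plus a pure tone on one axis."""
    n = int(seconds * fs)
    t = np.arange(n) / fs
    sig = {k: np.zeros(n) for k in "xyz"}
    sig[axis] = amp * np.sin(2 * np.pi * freq_hz * t)
    g = np.asarray(gravity, dtype=float)
    return make_epoch(sig["x"] + g[0], sig["y"] + g[1], sig["z"] + g[2], fs=fs)


def segment_spectra(kind: str, seconds: float, seed: int, **seg_kw):
    """Epoch spectra of one simulated segment (batch path)."""
    script = SimulationScript(
        segments=[Segment(kind, seconds, **seg_kw)], seed=seed
    )
    rec, _, _ = simulate_recording(script, with_temperature=False)
    return batch_spectra(rec)


def segment_recording(kind: str, seconds: float, seed: int, **seg_kw):
    script = SimulationScript(segments=[Segment(kind, seconds, **seg_kw)], seed=seed)
    return simulate_recording(script, with_temperature=False)[0]


@pytest.fixture(scope="session")
def spectral_cfg() -> SpectralConfig:
    return SpectralConfig()


@pytest.fixture(scope="session")
def fixture_day(tmp_path_factory):
    """One 24-h preset day on disk, shared by file-level tests."""
    from wristpd.synthetic import make_fixture_day

    out = tmp_path_factory.mktemp("fixture_day")
    return make_fixture_day("fluctuating_day", seed=5, out_dir=out)


@pytest.fixture
def small_recording() -> AccelRecording:
    rng = np.random.default_rng(7)
    n = int(60 * FS)
    return AccelRecording(
        start_time=T0,
        fs=FS,
        ax=0.02 * rng.standard_normal(n),
        ay=0.7 + 0.02 * rng.standard_normal(n),
        az=0.7 + 0.02 * rng.standard_normal(n),
        temperature=AuxChannel(np.full(60, 32.5), fs=1.0),
        subject_id="unit",
    )
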