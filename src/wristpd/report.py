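"""Figure rendering for analysis reports.

Figures are side outputs of the CLI; every quantitative result is also
written as CSV/JSON so downstream checks never depend on rendering.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .recording_io import AccelRecording
from .spectral import SpectralConfig, spectrogram_matrix
from .states import MotorState, StateTimeline, summarize_durations

STATE_COLORS = {
    MotorState.OFF: "#d62728",
    MotorState.ON: "#2ca02c",
    MotorState.ON_NON_TROUBLESOME_DYSK: "#98df8a",
    MotorState.ON_TROUBLESOME_DYSK: "#ff7f0e",
    MotorState.DAYTIME_INACTIVITY: "#c7c7c7",
    MotorState.NIGHTTIME_INACTIVITY: "#7f7f7f",
    MotorState.NOT_WORN: "#17becf",
    MotorState.NOT_DETECTABLE: "#e377c2",
}


def save_pie_chart(tl: StateTimeline, path: Path) -> None:
    """Percentage duration of the recorded motor states."""
    summary = summarize_durations(tl)
    nz = summary[summary["hours"] > 0]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.pie(
        nz["percent"],
        labels=nz["state"],
        autopct="%1.0f%%",
        colors=[STATE_COLORS[MotorState(s)] for s in nz["state"]],
    )
    ax.set_title("Motor-state share of recording")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def save_daily_histograms(tl: StateTimeline, path: Path) -> None:
    """Stacked per-day hours in each motor state."""
    per_day = int(round(86400 / tl.interval_s))
    n_days = max(int(np.ceil(tl.n_intervals / per_day)), 1)
    counts = np.zeros((n_days, len(MotorState)))
    order = list(MotorState)
    for k, s in enumerate(tl.states):
        counts[k // per_day, order.index(s)] += tl.interval_s / 3600.0
    fig, ax = plt.subplots(figsize=(1.8 * n_days + 3, 4))
    bottom = np.zeros(n_days)
    x = np.arange(n_days)
    for j, state in enumerate(order):
        ax.bar(
            x,
            counts[:, j],
            bottom=bottom,
            color=STATE_COLORS[state],
            label=state.value,
        )
        bottom += counts[:, j]
    ax.set_xticks(x, [f"day {d + 1}" for d in x])
    ax.set_ylabel("hours")
    ax.legend(fontsize=7, ncol=2)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def save_temporal_panel(
    rec: AccelRecording,
    tl: StateTimeline,
    path: Path,
    spectral_cfg: SpectralConfig | None = None,
) -> None:
    """Four-row panel: states, dyskinesia intensity, tremor/bradykinesia
    intensity, and the recording spectrogram."""
    fig, axes = plt.subplots(4, 1, figsize=(12, 9), sharex=True)
    hours_interval = np.arange(tl.n_intervals) * tl.interval_s / 3600.0
    for k, s in enumerate(tl.states):
        axes[0].barh(
            0,
            tl.interval_s / 3600.0,
            left=hours_interval[k],
            color=STATE_COLORS[s],
            height=1,
        )
    axes[0].set_yticks([])
    axes[0].set_title("motor states")

    t_epoch = np.arange(tl.dysk_intensity.size) * tl.epoch_s / 3600.0
    axes[1].plot(t_epoch, tl.dysk_intensity, lw=0.5, color="#ff7f0e")
    axes[1].axhspan(0, 0.5, color="0.9")  # not-impactful range
    axes[1].set_ylim(0, 4)
    axes[1].set_ylabel("dyskinesia 0–4")

    axes[2].plot(t_epoch, tl.tremor_intensity, lw=0.5, color="#d62728", label="tremor")
    axes[2].plot(t_epoch, tl.brady_intensity, lw=0.5, color="#1f77b4", label="bradykinesia")
    axes[2].set_ylim(0, 4)
    axes[2].set_ylabel("intensity 0–4")
    axes[2].legend(fontsize=7)

    freqs, mat = spectrogram_matrix(rec, cfg=spectral_cfg, epoch_s=tl.epoch_s)
    t_cols = np.arange(mat.shape[1]) * tl.epoch_s / 3600.0
    with np.errstate(divide="ignore"):
        db = 10 * np.log10(np.maximum(mat, 1e-12))
    axes[3].pcolormesh(t_cols, freqs, db, shading="auto", cmap="magma")
    axes[3].set_ylim(0, 12)
    axes[3].set_ylabel("Hz")
    axes[3].set_xlabel("hours since recording start")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
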