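"""Quick-look plots: dF/F0 time courses and frequency-trace stages."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers can switch backends first

import matplotlib.pyplot as plt
import numpy as np

from .imaging import DffTraces
from .ssr import FrequencyTrace

__all__ = ["plot_dff_timecourse", "plot_trace_stages"]


def plot_dff_timecourse(dff: DffTraces, ax=None, show_mean: bool = True):
    """All per-ROI dF/F0 traces with the baseline window shaded gray and
    stimulus onsets marked; optionally the across-ROI mean superimposed."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for j in range(dff.n_cells):
        ax.plot(dff.times, dff.dff[:, j], color="0.7", lw=0.7)
    if show_mean and dff.n_cells > 1:
        ax.plot(dff.times, dff.dff.mean(axis=1), color="C0", lw=1.8, label="mean")
        ax.legend(frameon=False)
    a, b = dff.f0_window
    ax.axvspan(dff.times[a], dff.times[b - 1], color="0.85", zorder=0)
    for ev in dff.events:
        if ev.modality != "none":
            ax.axvline(ev.onset_time, color="C3", lw=0.8, ls="--")
            ax.annotate(ev.label, (ev.onset_time, ax.get_ylim()[1]), fontsize=8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel(r"$\Delta F/F_0$ (%)")
    return ax


def plot_trace_stages(stages: dict[str, FrequencyTrace], ax=None):
    """Overlay raw / gust-corrected / smoothed frequency traces."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for name, tr in stages.items():
        ax.plot(tr.times, tr.rate, lw=1.0, label=name)
    ax.axvline(0.0, color="k", lw=0.8, ls=":")
    ax.set_xlabel("time from stimulus onset (s)")
    ax.set_ylabel("firing rate (spikes/s)")
    ax.legend(frameon=False)
    return ax
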