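"""Three-step air-gust correction and peak/AUC mining of frequency traces.

Step 1 bins raw traces; step 2 subtracts the per-sensillum mean blank
air-gust trace (dissociating the mechanosensitive component); step 3 smooths
the corrected traces with a 400 ms centered rolling average. Each stage's
traces are mined for peak rate and trapezoidal area-under-curve within a
stage-specific response window: [0, 1] s for raw and gust-corrected traces,
[-0.5, 1] s for smoothed traces (the rolling mean shifts response mass
earlier). Negative corrected rates are retained so areas cancel correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import AlignmentError, AnalysisConfig, SpikeTrain, ValidationError
from .ssr import FrequencyTrace, frequency_trace, mean_trace

__all__ = [
    "ResponseMetrics",
    "GroupError",
    "mean_gust_trace",
    "gust_correct",
    "smooth",
    "extract_metrics",
    "run_three_step",
    "run_three_step_traces",
    "delta_summary",
    "GUST_TREATMENT",
]

GUST_TREATMENT = "air gust"
STAGES = ("raw", "gust_corrected", "smoothed")


class GroupError(ValidationError):
    """A required trace group (e.g. air-gust traces for a sensillum) is missing."""


@dataclass
class ResponseMetrics:
    """Peak rate (spikes/s) and trapezoidal AUC (spikes) within a window."""

    peak_rate: float
    auc: float
    window: tuple[float, float]
    stage: str


def mean_gust_trace(traces: Sequence[FrequencyTrace]) -> FrequencyTrace:
    """Per-bin mean of the raw air-gust traces of one sensillum."""
    if not traces:
        raise GroupError("no air-gust traces supplied")
    sensilla = {tr.sensillum for tr in traces}
    if len(sensilla) > 1:
        raise ValidationError(f"gust traces mix sensilla: {sorted(sensilla)}")
    for tr in traces:
        if tr.stage != "raw":
            raise ValidationError("gust mean is computed from raw traces")
    return mean_trace(list(traces))


def gust_correct(trace: FrequencyTrace, gust_mean: FrequencyTrace) -> FrequencyTrace:
    """Subtract the mean gust trace bin-for-bin; stage becomes gust_corrected.

    Values may go negative; they are deliberately not clipped.
    """
    if trace.stage != "raw":
        raise ValidationError("gust correction applies to raw traces")
    if not trace.same_grid(gust_mean):
        raise AlignmentError("trace and gust mean are on different bin grids")
    return replace(
        trace,
        rate=trace.rate - gust_mean.rate,
        stage="gust_corrected",
        sem=None,
    )


def smooth(trace: FrequencyTrace, window: float = 0.400) -> FrequencyTrace:
    """Centered rolling mean over ``window / bin_width`` consecutive bins.

    Output is defined only where the full window fits, so the trace shortens
    by k - 1 bins; output times are the means of the contributing bin times.
    """
    ratio = window / trace.bin_width
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ValidationError("smoothing window must be an integer number of bins")
    if k > trace.rate.size:
        raise ValidationError(
            f"smoothing window of {k} bins exceeds trace length {trace.rate.size}"
        )
    kernel = np.full(k, 1.0 / k)
    rate = np.convolve(trace.rate, kernel, mode="valid")
    times = np.convolve(trace.times, kernel, mode="valid")
    return replace(trace, times=times, rate=rate, stage="smoothed", sem=None)


def _window_for_stage(stage: str, config: AnalysisConfig) -> tuple[float, float]:
    if stage in ("raw", "gust_corrected"):
        return config.response_window_raw
    if stage == "smoothed":
        return config.response_window_smoothed
    raise ValidationError(f"unknown processing stage {stage!r}")


def extract_metrics(
    trace: FrequencyTrace, config: AnalysisConfig | None = None
) -> ResponseMetrics:
    """Peak and trapezoidal AUC over the stage's response window.

    Window endpoints are closed on both sides (the trapezoid needs both
    endpoints); samples are the bin nodes falling inside the window.
    """
    config = config or AnalysisConfig()
    w0, w1 = _window_for_stage(trace.stage, config)
    mask = (trace.times >= w0 - 1e-9) & (trace.times <= w1 + 1e-9)
    if not mask.any():
        raise ValidationError(
            f"no samples inside the [{w0}, {w1}] s response window"
        )
    t = trace.times[mask]
    r = trace.rate[mask]
    auc = float(np.trapezoid(r, t)) if t.size > 1 else 0.0
    return ResponseMetrics(
        peak_rate=float(r.max()), auc=auc, window=(w0, w1), stage=trace.stage
    )


def _group_key(tr: FrequencyTrace, within_cohort: bool):
    return (tr.cohort, tr.sensillum) if within_cohort else tr.sensillum


def run_three_step_traces(
    traces: Sequence[FrequencyTrace],
    config: AnalysisConfig | None = None,
    gust_treatment: str = GUST_TREATMENT,
    within_cohort: bool = True,
    per_fly_gust: bool = False,
) -> pd.DataFrame:
    """Three-step pipeline on pre-binned raw traces.

    Returns one row per (fly, sensillum, neuron, treatment, cohort, stage)
    with peak and AUC. The gust mean is computed per sensillum, pooling
    flies within each cohort by default (``within_cohort=False`` pools
    cohorts; ``per_fly_gust=True`` uses each fly's own gust trace).
    """
    config = config or AnalysisConfig()
    gust_groups: dict = {}
    for tr in traces:
        if tr.treatment == gust_treatment:
            gust_groups.setdefault(_group_key(tr, within_cohort), []).append(tr)

    def gust_mean_for(tr: FrequencyTrace) -> FrequencyTrace:
        group = gust_groups.get(_group_key(tr, within_cohort))
        if not group:
            raise GroupError(
                f"no {gust_treatment!r} traces for sensillum {tr.sensillum!r} "
                f"(cohort {tr.cohort!r})"
            )
        if per_fly_gust:
            own = [g for g in group if g.fly == tr.fly]
            if not own:
                raise GroupError(
                    f"no {gust_treatment!r} trace for fly {tr.fly!r}, "
                    f"sensillum {tr.sensillum!r}"
                )
            group = own
        return mean_gust_trace(group)

    rows = []
    for tr in traces:
        corrected = gust_correct(tr, gust_mean_for(tr))
        smoothed = smooth(corrected, config.smooth_window)
        for staged in (tr, corrected, smoothed):
            m = extract_metrics(staged, config)
            rows.append(
                {
                    "fly": tr.fly,
                    "sensillum": tr.sensillum,
                    "neuron": tr.neuron,
                    "treatment": tr.treatment,
                    "cohort": tr.cohort,
                    "stage": m.stage,
                    "peak_rate": m.peak_rate,
                    "auc": m.auc,
                    "window_start": m.window[0],
                    "window_end": m.window[1],
                }
            )
    return pd.DataFrame(rows)


def run_three_step(
    trains: Iterable[SpikeTrain],
    config: AnalysisConfig | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Bin spike trains at the configured bin width, then run the pipeline."""
    config = config or AnalysisConfig()
    traces = [frequency_trace(tr, config.bin_width) for tr in trains]
    if not traces:
        raise ValidationError("no spike trains supplied")
    return run_three_step_traces(traces, config, **kwargs)


def delta_summary(
    metrics: pd.DataFrame,
    stage: str = "gust_corrected",
    cohorts: tuple[str, str] = ("heatshock", "control"),
) -> pd.DataFrame:
    """Heatshock-minus-control mean peak and AUC per (sensillum, treatment).

    A grid cell with a missing cohort is reported with NaN deltas and a zero
    n for the absent cohort — absent, not zero.
    """
    hs, ctrl = cohorts
    sub = metrics[metrics["stage"] == stage]
    if sub.empty:
        raise ValidationError(f"no metrics at stage {stage!r}")
    rows = []
    for (sensillum, treatment), cell in sub.groupby(["sensillum", "treatment"]):
        g_hs = cell[cell["cohort"] == hs]
        g_ct = cell[cell["cohort"] == ctrl]
        present = bool(len(g_hs)) and bool(len(g_ct))
        rows.append(
            {
                "sensillum": sensillum,
                "treatment": treatment,
                "delta_peak": g_hs["peak_rate"].mean() - g_ct["peak_rate"].mean()
                if present
                else float("nan"),
                "delta_auc": g_hs["auc"].mean() - g_ct["auc"].mean()
                if present
                else float("nan"),
                "n_heatshock": int(len(g_hs)),
                "n_control": int(len(g_ct)),
                "stage": stage,
            }
        )
    return pd.DataFrame(rows)
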