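"""dF/F0 time-course processing for ROI-averaged cation imaging.

The processing chain mirrors standard ex vivo antennal imaging practice:
per-frame background subtraction, percent change relative to a pre-stimulus
baseline window (dF/F0), responder classification against baseline noise,
replicate/cell aggregation with SEM, global-extremum timepoint selection and
dose-response extraction at that frame. No interpolation is performed
anywhere: readout times must be acquired frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import (
    AlignmentError,
    AnalysisConfig,
    ImagingRecording,
    StimulusEvent,
    ValidationError,
    default_f0_window,
)

__all__ = [
    "DffTraces",
    "RoiClassification",
    "AggregateTrace",
    "DoseResponseCurve",
    "DegenerateBaselineError",
    "compute_dff",
    "classify_responders",
    "aggregate",
    "find_extremum_time",
    "dose_response",
]


class DegenerateBaselineError(ValidationError):
    """Background-corrected baseline fluorescence is not positive for an ROI."""


@dataclass
class DffTraces:
    """Per-ROI percent change from baseline (frames x cell ROIs).

    ``f0_values`` are the background-corrected baseline fluorescences (a.u.);
    the mean of ``dff`` over ``f0_window`` is 0 for every ROI by construction.
    """

    dff: np.ndarray
    times: np.ndarray
    f0_window: tuple[int, int]
    f0_values: np.ndarray
    roi_names: list[str]
    events: list[StimulusEvent]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[0]

    @property
    def n_cells(self) -> int:
        return self.dff.shape[1]

    def first_stimulus_onset(self) -> float | None:
        onsets = [ev.onset_time for ev in self.events if ev.modality != "none"]
        return min(onsets) if onsets else None


@dataclass
class RoiClassification:
    """Responder/non-responder labels with the score behind each label.

    score = peak |dF/F0| in the response window / baseline SD; an ROI is a
    responder iff score >= threshold. A zero baseline SD with nonzero window
    signal yields an infinite score (flagged responder); zero SD with a flat
    window yields score 0 (non-responder).
    """

    labels: np.ndarray  # str array: "responder" | "non_responder"
    scores: np.ndarray
    threshold: float
    roi_names: list[str]

    @property
    def is_responder(self) -> np.ndarray:
        return self.labels == "responder"

    @property
    def responder_fraction(self) -> float:
        return float(np.mean(self.is_responder))


@dataclass
class AggregateTrace:
    """Per-frame mean and SEM across units (replicates or cells).

    With a single unit the SEM is undefined (NaN), not zero: the sample SD
    of one observation does not exist.
    """

    mean: np.ndarray
    sem: np.ndarray
    n: int
    unit_mode: str
    times: np.ndarray | None = None


@dataclass
class DoseResponseCurve:
    """Mean dF/F0 (+/- SEM) at one fixed post-stimulus frame per concentration."""

    points: pd.DataFrame  # columns: concentration_mm, mean, sem, n
    eval_time: float


def compute_dff(
    rec: ImagingRecording,
    f0_window: tuple[int, int] | None = None,
    config: AnalysisConfig | None = None,
    background: str = "per_frame",
) -> DffTraces:
    """Background-subtract and normalize to percent change from baseline.

    F(r,t) = raw(r,t) - raw(bg,t); F0(r) = mean of F(r,.) over the baseline
    window; dff = 100 * (F - F0) / F0. ``background`` may be ``"per_frame"``
    (default) or ``"mean"`` (temporal mean of the background trace).
    """
    config = config or AnalysisConfig()
    if f0_window is None:
        f0_window = config.f0_window or default_f0_window(rec, config.f0_n_frames)
    a, b = int(f0_window[0]), int(f0_window[1])
    if not 0 <= a < b <= rec.n_frames:
        raise ValidationError(f"f0_window {f0_window} outside the recording's frames")
    onset = rec.first_stimulus_onset()
    if onset is not None and (b - 1) * rec.frame_interval >= onset:
        raise ValidationError(
            "f0_window overlaps a stimulus: it must lie wholly before the "
            f"first stimulus at {onset} s"
        )
    if background not in ("per_frame", "mean"):
        raise ValidationError("background must be 'per_frame' or 'mean'")

    bg = rec.trace_matrix[:, rec.background_roi]
    if background == "mean":
        bg = np.full_like(bg, bg.mean())
    cells = rec.trace_matrix[:, rec.cell_indices]
    corrected = cells - bg[:, None]
    f0 = corrected[a:b].mean(axis=0)
    bad = np.flatnonzero(f0 <= 0)
    if bad.size:
        names = [rec.cell_names[i] for i in bad]
        raise DegenerateBaselineError(
            f"baseline fluorescence <= 0 for ROI(s) {names}; "
            "check background region or baseline window"
        )
    dff = 100.0 * (corrected - f0) / f0
    return DffTraces(
        dff=dff,
        times=rec.frame_times,
        f0_window=(a, b),
        f0_values=f0,
        roi_names=rec.cell_names,
        events=list(rec.events),
    )


def classify_responders(
    dff: DffTraces,
    window: tuple[float, float] | None = None,
    k: float | None = None,
    config: AnalysisConfig | None = None,
    direction: int = 0,
) -> RoiClassification:
    """Label each ROI responder/non-responder by peak signal over baseline SD.

    ``window`` is in seconds from recording start and must begin at or after
    the first stimulus onset; default is onset to onset + 50 s (ten frames at
    the 5 s interval). ``direction`` +1/-1 restricts the peak to
    increases/decreases (signed variant); 0 uses |dF/F0|.
    """
    config = config or AnalysisConfig()
    if k is None:
        k = config.responder_k
    onset = dff.first_stimulus_onset()
    if window is None:
        if onset is None:
            raise ValidationError("no stimulus events; pass a response window explicitly")
        window = (onset, onset + 50.0)
    if onset is not None and window[0] < onset:
        raise ValidationError("response window must start at or after stimulus onset")

    a, b = dff.f0_window
    baseline = dff.dff[a:b]
    if baseline.shape[0] < 2:
        raise ValidationError("baseline window must span at least 2 frames")
    sd = baseline.std(axis=0, ddof=1)

    mask = (dff.times >= window[0] - 1e-9) & (dff.times <= window[1] + 1e-9)
    if not mask.any():
        raise ValidationError("response window contains no sampled frames")
    seg = dff.dff[mask]
    if direction == 0:
        peak = np.abs(seg).max(axis=0)
    elif direction in (+1, -1):
        peak = np.maximum((direction * seg).max(axis=0), 0.0)
    else:
        raise ValidationError("direction must be -1, 0 or +1")

    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(sd > 0, peak / np.where(sd > 0, sd, 1.0), np.where(peak > 0, np.inf, 0.0))
    labels = np.where(scores >= k, "responder", "non_responder")
    return RoiClassification(
        labels=labels, scores=scores, threshold=float(k), roi_names=list(dff.roi_names)
    )


def _as_matrix(traces: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    if isinstance(traces, np.ndarray) and traces.ndim == 2:
        return np.asarray(traces, dtype=float)
    arrs = [np.asarray(t, dtype=float).ravel() for t in traces]
    if not arrs:
        raise ValidationError("aggregate needs at least one unit")
    lengths = {a.size for a in arrs}
    if len(lengths) != 1:
        raise AlignmentError(f"unit series lengths differ: {sorted(lengths)}")
    return np.vstack(arrs)


def aggregate(
    traces: Sequence[np.ndarray] | np.ndarray,
    unit_mode: str = "per_cell",
    times: np.ndarray | None = None,
) -> AggregateTrace:
    """Per-frame mean and SEM (= sample SD / sqrt(n)) across units."""
    if unit_mode not in ("per_replicate", "per_cell"):
        raise ValidationError("unit_mode must be 'per_replicate' or 'per_cell'")
    mat = _as_matrix(traces)  # units x frames
    n = mat.shape[0]
    mean = mat.mean(axis=0)
    if n == 1:
        sem = np.full(mat.shape[1], np.nan)
    else:
        sem = mat.std(axis=0, ddof=1) / np.sqrt(n)
    return AggregateTrace(mean=mean, sem=sem, n=n, unit_mode=unit_mode, times=times)


def find_extremum_time(
    agg_by_condition: Mapping[str, AggregateTrace],
    search_window: tuple[float, float],
) -> float:
    """Frame time maximizing max over conditions of |mean dF/F0|.

    All conditions must share frame times; ties break to the earliest frame.
    """
    if not agg_by_condition:
        raise ValidationError("no conditions supplied")
    aggs = list(agg_by_condition.values())
    times = aggs[0].times
    if times is None:
        raise ValidationError("AggregateTrace.times required for extremum search")
    for a in aggs[1:]:
        if a.times is None or len(a.times) != len(times) or not np.allclose(a.times, times):
            raise AlignmentError("conditions do not share frame times")
    mask = (times >= search_window[0] - 1e-9) & (times <= search_window[1] + 1e-9)
    if not mask.any():
        raise ValidationError("search window contains no sampled frames")
    envelope = np.max(np.vstack([np.abs(a.mean) for a in aggs]), axis=0)
    idx = int(np.argmax(envelope[mask]))  # argmax returns the first (earliest) max
    return float(times[mask][idx])


def dose_response(
    recordings: Mapping[float, Sequence[DffTraces]],
    eval_time: float,
) -> DoseResponseCurve:
    """Mean and SEM of dF/F0 at one acquired frame time per concentration.

    ``eval_time`` must be a sampled frame time in every recording;
    interpolation is refused. Units are individual cell ROIs pooled across
    the recordings of each concentration.
    """
    rows = []
    for conc in sorted(recordings):
        values: list[np.ndarray] = []
        for dff in recordings[conc]:
            hits = np.flatnonzero(np.isclose(dff.times, eval_time, atol=1e-9))
            if hits.size == 0:
                raise ValidationError(
                    f"eval_time {eval_time} s is not a sampled frame at {conc} mM; "
                    "interpolation is not performed"
                )
            values.append(dff.dff[hits[0]])
        v = np.concatenate(values)
        sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")
        rows.append(
            {"concentration_mm": float(conc), "mean": float(v.mean()), "sem": sem, "n": int(v.size)}
        )
    points = pd.DataFrame(rows)
    if points["concentration_mm"].duplicated().any():
        raise ValidationError("concentrations must be unique")
    return DoseResponseCurve(points=points, eval_time=float(eval_time))
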