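"""Shared domain types and on-disk formats.

All times are seconds from recording start; stimulus-relative times are
computed where needed, never stored. Spike-count windows and rate bins are
half-open ``[a, b)`` throughout the package so that adjacent windows never
double-count a spike.

On-disk formats are deliberately plain text:

* ``recording.csv`` — one ``frame`` index column plus one column per ROI;
  the background region's column is named ``bg``.
* ``events.json`` — stimulus events, frame interval and free-form metadata.
* ``spikes.csv`` — one ``time_s`` column; recording metadata is carried in a
  single JSON comment line (``# {...}``) so that empty trains round-trip.
* ``config.yaml`` — the analysis constants (:class:`AnalysisConfig`).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MODALITIES",
    "StimulusEvent",
    "ImagingRecording",
    "SpikeTrain",
    "AnalysisConfig",
    "ValidationError",
    "SchemaError",
    "ParseError",
    "AlignmentError",
    "DesignError",
    "read_imaging_recording",
    "write_imaging_recording",
    "read_spike_train",
    "write_spike_train",
    "read_spike_trains",
    "default_f0_window",
]

MODALITIES = ("odor", "solvent", "mechanical", "none")


class ValidationError(ValueError):
    """A domain invariant was violated."""


class SchemaError(ValidationError):
    """A file lacks a required column or field."""


class ParseError(ValidationError):
    """A file cell could not be parsed; message names row and column."""


class AlignmentError(ValidationError):
    """Series that must share a time grid do not."""


class DesignError(ValidationError):
    """An experimental-design table is malformed or incomplete."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusEvent:
    """A stimulus application: label, onset (s from recording start), duration.

    ``modality`` distinguishes odorants from solvent controls, mechanical
    (blank air gust) stimuli and the no-stimulus placeholder.
    """

    label: str
    onset_time: float
    duration: float = 0.5
    modality: str = "odor"

    def __post_init__(self) -> None:
        if self.onset_time < 0:
            raise ValidationError(f"event {self.label!r}: onset_time must be >= 0")
        if self.duration < 0:
            raise ValidationError(f"event {self.label!r}: duration must be >= 0")
        if self.modality not in MODALITIES:
            raise ValidationError(
                f"event {self.label!r}: modality {self.modality!r} not in {MODALITIES}"
            )

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "onset_time": self.onset_time,
            "duration": self.duration,
            "modality": self.modality,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusEvent":
        return cls(
            label=d["label"],
            onset_time=float(d["onset_time"]),
            duration=float(d.get("duration", 0.5)),
            modality=d.get("modality", "odor"),
        )


@dataclass
class ImagingRecording:
    """ROI-averaged fluorescence matrix with a stimulus-event schedule.

    ``trace_matrix`` is frames x ROIs in arbitrary fluorescence units.
    Exactly one ROI (``background_roi``, a column index) is the background
    region used for noise subtraction downstream.
    """

    trace_matrix: np.ndarray
    roi_names: list[str]
    background_roi: int
    frame_interval: float = 5.0
    events: list[StimulusEvent] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.trace_matrix = np.asarray(self.trace_matrix, dtype=float)
        if self.trace_matrix.ndim != 2:
            raise ValidationError("trace_matrix must be 2-D (frames x ROIs)")
        if not np.all(np.isfinite(self.trace_matrix)):
            raise ValidationError("trace_matrix contains non-finite values")
        if len(self.roi_names) != self.n_rois:
            raise ValidationError("roi_names length must match trace_matrix columns")
        if len(set(self.roi_names)) != len(self.roi_names):
            raise ValidationError("roi_names must be unique")
        if not 0 <= self.background_roi < self.n_rois:
            raise SchemaError(f"background_roi index {self.background_roi} out of range")
        if self.frame_interval <= 0:
            raise ValidationError("frame_interval must be > 0")
        span = self.span
        for ev in self.events:
            if ev.onset_time > span:
                raise ValidationError(
                    f"event {ev.label!r} at {ev.onset_time} s lies beyond the "
                    f"{span} s recording span"
                )

    @property
    def n_frames(self) -> int:
        return self.trace_matrix.shape[0]

    @property
    def n_rois(self) -> int:
        return self.trace_matrix.shape[1]

    @property
    def span(self) -> float:
        return self.n_frames * self.frame_interval

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def cell_indices(self) -> np.ndarray:
        return np.array([i for i in range(self.n_rois) if i != self.background_roi])

    @property
    def cell_names(self) -> list[str]:
        return [self.roi_names[i] for i in self.cell_indices]

    def first_stimulus_onset(self) -> float | None:
        onsets = [ev.onset_time for ev in self.events if ev.modality != "none"]
        return min(onsets) if onsets else None


@dataclass
class SpikeTrain:
    """Sorted spike times on one SSR recording plus its metadata labels.

    Default span is 13 s (3 s pre- and 10 s post-stimulus) with stimulus
    onset at 3 s and 0.5 s stimulus duration.
    """

    spike_times: np.ndarray
    span: float = 13.0
    stimulus_onset: float = 3.0
    stimulus_duration: float = 0.5
    treatment: str = ""
    sensillum: str = ""
    neuron: str = ""
    cohort: str = "control"
    genotype: str = ""
    fly: str = ""
    allow_duplicates: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times, dtype=float).ravel()
        if t.size and t.min() < 0:
            raise ValidationError("spike times must be >= 0")
        if t.size and t.max() > self.span:
            raise ValidationError("spike times must lie within [0, span]")
        if t.size and np.any(np.diff(t) < 0):
            warnings.warn("spike times were unsorted; sorting", stacklevel=2)
            t = np.sort(t)
        if t.size and np.any(np.diff(t) == 0) and not self.allow_duplicates:
            raise ValidationError(
                "duplicate spike times (acquisition artifact); "
                "pass allow_duplicates=True to keep them"
            )
        if not 0 <= self.stimulus_onset <= self.span:
            raise ValidationError("stimulus_onset must lie within [0, span]")
        if self.stimulus_onset + self.stimulus_duration > self.span:
            raise ValidationError("stimulus extends beyond recording span")
        self.spike_times = t

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def _meta_dict(self) -> dict:
        return {
            "span": self.span,
            "stimulus_onset": self.stimulus_onset,
            "stimulus_duration": self.stimulus_duration,
            "treatment": self.treatment,
            "sensillum": self.sensillum,
            "neuron": self.neuron,
            "cohort": self.cohort,
            "genotype": self.genotype,
            "fly": self.fly,
        }


@dataclass
class AnalysisConfig:
    """Every fixed constant the pipeline uses, in one place.

    * ``f0_window`` — half-open frame-index window for the baseline; ``None``
      means the default rule (``f0_n_frames`` frames ending immediately
      before the first stimulus frame).
    * ``response_window_raw`` / ``response_window_smoothed`` — seconds
      relative to stimulus onset for metric extraction at the raw /
      gust-corrected stages and the smoothed stage respectively.
    * ``bin_width`` (25 ms) and ``smooth_window`` (400 ms, i.e. 16 bins).
    * ``responder_k`` — responder threshold in baseline-SD multiples.
    * ``consistency_multiplier`` — resting-activity consistency tolerance in
      pooled Poisson SEs.
    """

    f0_window: tuple[int, int] | None = None
    f0_n_frames: int = 10
    response_window_raw: tuple[float, float] = (0.0, 1.0)
    response_window_smoothed: tuple[float, float] = (-0.5, 1.0)
    bin_width: float = 0.025
    smooth_window: float = 0.400
    responder_k: float = 5.0
    consistency_multiplier: float = 2.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.f0_window is not None:
            a, b = self.f0_window
            if not (0 <= a < b):
                raise ValidationError("f0_window must satisfy 0 <= start < stop")
            self.f0_window = (int(a), int(b))
        if self.f0_n_frames <= 0:
            raise ValidationError("f0_n_frames must be positive")
        for name in ("response_window_raw", "response_window_smoothed"):
            a, b = getattr(self, name)
            if not a < b:
                raise ValidationError(f"{name} must be well-ordered")
            setattr(self, name, (float(a), float(b)))
        if self.bin_width <= 0:
            raise ValidationError("bin_width must be > 0")
        ratio = self.smooth_window / self.bin_width
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValidationError(
                "smooth_window must be a positive integer multiple of bin_width"
            )
        if self.responder_k <= 0:
            raise ValidationError("responder_k must be > 0")

    @property
    def smooth_bins(self) -> int:
        return int(round(self.smooth_window / self.bin_width))

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["f0_window"] is not None:
            d["f0_window"] = list(d["f0_window"])
        d["response_window_raw"] = list(d["response_window_raw"])
        d["response_window_smoothed"] = list(d["response_window_smoothed"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if d.get("f0_window") is not None:
            d["f0_window"] = tuple(d["f0_window"])
        for name in ("response_window_raw", "response_window_smoothed"):
            if name in d:
                d[name] = tuple(d[name])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def replace(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)


def default_f0_window(rec: ImagingRecording, n_frames: int = 10) -> tuple[int, int]:
    """Baseline window: ``n_frames`` frames ending immediately before the
    first stimulus frame (half-open frame-index window)."""
    onset = rec.first_stimulus_onset()
    if onset is None:
        stop = min(n_frames, rec.n_frames)
        return (0, stop)
    onset_frame = int(math.floor(onset / rec.frame_interval + 1e-9))
    stop = onset_frame
    start = stop - n_frames
    if start < 0:
        raise ValidationError(
            f"not enough pre-stimulus frames for a {n_frames}-frame baseline window"
        )
    return (start, stop)


# ---------------------------------------------------------------------------
# imaging recording I/O
# ---------------------------------------------------------------------------

_BG_NAME = "bg"


def write_imaging_recording(
    rec: ImagingRecording, csv_path: str | Path, events_path: str | Path | None = None
) -> None:
    """Write ``recording.csv`` plus an ``events.json`` sidecar.

    The background ROI's column is written under the reserved name ``bg``.
    """
    csv_path = Path(csv_path)
    if events_path is None:
        events_path = csv_path.with_suffix(".events.json")
    names = list(rec.roi_names)
    names[rec.background_roi] = _BG_NAME
    df = pd.DataFrame(rec.trace_matrix, columns=names)
    df.insert(0, "frame", np.arange(rec.n_frames))
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(csv_path, index=False, float_format="%.17g")
    payload = {
        "frame_interval": rec.frame_interval,
        "events": [ev.to_dict() for ev in rec.events],
        "meta": rec.meta,
    }
    Path(events_path).write_text(json.dumps(payload, indent=2))


def read_imaging_recording(
    csv_path: str | Path, events_path: str | Path | None = None
) -> ImagingRecording:
    """Read a recording CSV (+ events JSON sidecar) into an ImagingRecording."""
    csv_path = Path(csv_path)
    if events_path is None:
        events_path = csv_path.with_suffix(".events.json")
    df = pd.read_csv(csv_path, float_precision="round_trip")
    if "frame" in df.columns:
        df = df.drop(columns=["frame"])
    if _BG_NAME not in df.columns:
        raise SchemaError(f"{csv_path}: no background ROI column named {_BG_NAME!r}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(f"{csv_path}: non-numeric cell at row {row}, column {col!r}")
        if df[col].isna().any():
            row = int(np.flatnonzero(df[col].isna().to_numpy())[0])
            raise ParseError(f"{csv_path}: missing value at row {row}, column {col!r}")
    frame_interval, events, meta = 5.0, [], {}
    events_path = Path(events_path)
    if events_path.exists():
        payload = json.loads(events_path.read_text())
        frame_interval = float(payload.get("frame_interval", 5.0))
        events = [StimulusEvent.from_dict(d) for d in payload.get("events", [])]
        meta = payload.get("meta", {})
    return ImagingRecording(
        trace_matrix=df.to_numpy(dtype=float),
        roi_names=list(df.columns),
        background_roi=list(df.columns).index(_BG_NAME),
        frame_interval=frame_interval,
        events=events,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# spike train I/O
# ---------------------------------------------------------------------------


def write_spike_train(train: SpikeTrain, path: str | Path) -> None:
    """Write ``spikes.csv``: JSON metadata comment line, then one time per row."""
    lines = ["# " + json.dumps(train._meta_dict()), "time_s"]
    lines += [f"{t:.9f}" for t in train.spike_times]
    Path(path).write_text("\n".join(lines) + "\n")


def read_spike_train(path: str | Path) -> SpikeTrain:
    """Read a spike-train CSV written by :func:`write_spike_train`.

    Unsorted times are sorted with a warning; negative times are rejected.
    """
    path = Path(path)
    text = path.read_text().splitlines()
    meta: dict = {}
    rows: list[float] = []
    for i, line in enumerate(text):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            meta.update(json.loads(line.lstrip("# ")))
            continue
        if line == "time_s":
            continue
        try:
            rows.append(float(line.split(",")[0]))
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric time at line {i + 1}") from exc
    return SpikeTrain(spike_times=np.array(rows, dtype=float), **meta)


def read_spike_trains(directory: str | Path, pattern: str = "*.csv") -> list[SpikeTrain]:
    """Read every spike-train CSV in a directory (sorted by filename)."""
    return [read_spike_train(p) for p in sorted(Path(directory).glob(pattern))]
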