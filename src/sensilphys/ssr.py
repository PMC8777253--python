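"""Spike-train response magnitudes, resting activity and frequency traces.

Window conventions: every count window and rate bin is half-open ``[a, b)``.
Frequency traces use 25 ms bins anchored at stimulus onset so traces from
different flies align bin-for-bin by construction; a final partial bin is
dropped rather than padded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_core import (
    AlignmentError,
    DesignError,
    SpikeTrain,
    ValidationError,
)

__all__ = [
    "RestingActivity",
    "ConsistencyReport",
    "FrequencyTrace",
    "UsageError",
    "count_spikes",
    "response_magnitude",
    "response_profile",
    "resting_activity_no_treatment",
    "resting_activity_prestim",
    "resting_consistency",
    "frequency_trace",
    "mean_trace",
]

NO_TREATMENT_SPAN = 13.0  # s; fixed divisor of the no-treatment estimator
PRESTIM_N_TREATMENTS = 16  # fixed divisor of the pre-stimulus estimator


class UsageError(ValidationError):
    """An operation was applied to data it is not defined for."""


def count_spikes(train: SpikeTrain, window: tuple[float, float]) -> int:
    """Number of spikes with ``window[0] <= t < window[1]``."""
    a, b = window
    if a >= b:
        raise ValidationError(f"window [{a}, {b}) is empty or reversed")
    if a < 0 or b > train.span + 1e-9:
        raise ValidationError(f"window [{a}, {b}) exceeds the recording span")
    t = train.spike_times
    return int(np.searchsorted(t, b, side="left") - np.searchsorted(t, a, side="left"))


def response_magnitude(train: SpikeTrain) -> int:
    """Spikes in [onset, onset+1) minus spikes in [onset-1, onset)."""
    onset = train.stimulus_onset
    if onset - 1.0 < 0 or onset + 1.0 > train.span + 1e-9:
        raise ValidationError("1 s pre/post windows exceed the recording span")
    post = count_spikes(train, (onset, onset + 1.0))
    pre = count_spikes(train, (onset - 1.0, onset))
    return post - pre


def response_profile(trains: Iterable[SpikeTrain]) -> pd.DataFrame:
    """Tidy response-profile table keyed by (sensillum, neuron, treatment, cohort).

    ``delta_spikes`` is the mean over flies of the per-train (post - pre)
    count; ``sem`` its standard error; ``n_flies`` the number of trains.
    """
    rows = [
        {
            "sensillum": tr.sensillum,
            "neuron": tr.neuron,
            "treatment": tr.treatment,
            "cohort": tr.cohort,
            "fly": tr.fly,
            "delta_spikes": response_magnitude(tr),
        }
        for tr in trains
    ]
    if not rows:
        raise ValidationError("no spike trains supplied")
    per_train = pd.DataFrame(rows)
    grouped = (
        per_train.groupby(["sensillum", "neuron", "treatment", "cohort"])["delta_spikes"]
        .agg(delta_spikes="mean", sem="sem", n_flies="size")
        .reset_index()
    )
    return grouped


@dataclass
class RestingActivity:
    """Spontaneous firing-rate estimate; ``method`` fixes the divisor."""

    method: str  # "no_treatment_13s" | "prestim_16x1s"
    rate: float
    components: dict = field(default_factory=dict)


def resting_activity_no_treatment(train: SpikeTrain) -> RestingActivity:
    """Total count over the 13 s no-treatment recording divided by 13."""
    if train.treatment != "no treatment":
        raise UsageError(
            f"no-treatment estimator applied to treatment {train.treatment!r}"
        )
    if abs(train.span - NO_TREATMENT_SPAN) > 1e-9:
        raise ValidationError("no-treatment estimator requires a 13 s recording")
    count = train.n_spikes
    return RestingActivity(
        method="no_treatment_13s",
        rate=count / NO_TREATMENT_SPAN,
        components={"count": count, "divisor": NO_TREATMENT_SPAN},
    )


def resting_activity_prestim(trains: Sequence[SpikeTrain]) -> RestingActivity:
    """Pooled 1 s pre-stimulus counts across the 16 treatments, divided by 16."""
    if not trains:
        raise DesignError("prestim estimator needs one train per treatment")
    ident = {(tr.fly, tr.sensillum, tr.neuron) for tr in trains}
    if len(ident) > 1:
        raise UsageError(f"trains mix identities: {sorted(ident)}")
    labels = [tr.treatment for tr in trains]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise DesignError(f"duplicate treatment(s): {dupes}")
    if len(labels) != PRESTIM_N_TREATMENTS:
        raise DesignError(
            f"expected {PRESTIM_N_TREATMENTS} treatments, got {len(labels)}"
        )
    counts = [
        count_spikes(tr, (tr.stimulus_onset - 1.0, tr.stimulus_onset)) for tr in trains
    ]
    total = int(sum(counts))
    return RestingActivity(
        method="prestim_16x1s",
        rate=total / PRESTIM_N_TREATMENTS,
        components={"count": total, "divisor": PRESTIM_N_TREATMENTS, "per_treatment": counts},
    )


@dataclass
class ConsistencyReport:
    """Agreement check between the two resting-activity estimators.

    The tolerance is ``multiplier`` pooled Poisson standard errors, with the
    pooled rate taken as the mean of the two estimates: SE^2 = lam/13 + lam/16.
    """

    rate_a: float
    rate_b: float
    abs_diff: float
    rel_diff: float
    tolerance: float
    passed: bool
    method_a: str
    method_b: str


def resting_consistency(
    a: RestingActivity, b: RestingActivity, multiplier: float = 2.5
) -> ConsistencyReport:
    lam = 0.5 * (a.rate + b.rate)
    tol = multiplier * math.sqrt(lam / NO_TREATMENT_SPAN + lam / PRESTIM_N_TREATMENTS)
    diff = abs(a.rate - b.rate)
    rel = diff / lam if lam > 0 else (0.0 if diff == 0 else float("inf"))
    return ConsistencyReport(
        rate_a=a.rate,
        rate_b=b.rate,
        abs_diff=diff,
        rel_diff=rel,
        tolerance=tol,
        passed=diff <= tol,
        method_a=a.method,
        method_b=b.method,
    )


@dataclass
class FrequencyTrace:
    """Stimulus-aligned binned firing rate.

    ``times`` are bin centers in seconds relative to stimulus onset;
    ``stage`` tags the processing step (raw | gust_corrected | smoothed).
    ``sem`` and ``n`` are populated by :func:`mean_trace`.
    """

    times: np.ndarray
    rate: np.ndarray
    bin_width: float
    stage: str = "raw"
    sensillum: str = ""
    neuron: str = ""
    treatment: str = ""
    cohort: str = ""
    fly: str = ""
    n: int = 1
    sem: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.times.shape != self.rate.shape:
            raise ValidationError("times and rate must have equal length")
        if self.bin_width <= 0:
            raise ValidationError("bin_width must be > 0")
        if self.stage == "raw" and self.rate.size and self.rate.min() < 0:
            raise ValidationError("raw rates cannot be negative")

    def same_grid(self, other: "FrequencyTrace") -> bool:
        return (
            self.times.size == other.times.size
            and abs(self.bin_width - other.bin_width) < 1e-12
            and bool(np.allclose(self.times, other.times, atol=1e-9))
        )


def frequency_trace(train: SpikeTrain, bin_width: float = 0.025) -> FrequencyTrace:
    """Bin spikes into ``[onset + k*w, onset + (k+1)*w)`` bins tiling the span.

    Anchoring the grid at stimulus onset makes traces from different
    recordings align exactly; a trailing partial bin is dropped.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0")
    w = bin_width
    onset = train.stimulus_onset
    n_pre = int(math.floor(onset / w + 1e-9))
    n_post = int(math.floor((train.span - onset) / w + 1e-9))
    ks = np.arange(-n_pre, n_post)
    edges = onset + np.arange(-n_pre, n_post + 1) * w
    idx = np.searchsorted(train.spike_times, edges, side="left")
    counts = np.diff(idx)
    return FrequencyTrace(
        times=(ks + 0.5) * w,
        rate=counts / w,
        bin_width=w,
        stage="raw",
        sensillum=train.sensillum,
        neuron=train.neuron,
        treatment=train.treatment,
        cohort=train.cohort,
        fly=train.fly,
    )


def _shared(values: Iterable[str]) -> str:
    vals = set(values)
    return vals.pop() if len(vals) == 1 else ""


def mean_trace(traces: Sequence[FrequencyTrace]) -> FrequencyTrace:
    """Per-bin mean across traces on an identical grid and stage (+ SEM)."""
    if not traces:
        raise ValidationError("mean_trace needs at least one trace")
    first = traces[0]
    for tr in traces[1:]:
        if not first.same_grid(tr):
            raise AlignmentError("traces do not share a bin grid")
        if tr.stage != first.stage:
            raise ValidationError("traces mix processing stages")
    mat = np.vstack([tr.rate for tr in traces])
    n = mat.shape[0]
    sem = mat.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.full(mat.shape[1], np.nan)
    return FrequencyTrace(
        times=first.times.copy(),
        rate=mat.mean(axis=0),
        bin_width=first.bin_width,
        stage=first.stage,
        sensillum=_shared(tr.sensillum for tr in traces),
        neuron=_shared(tr.neuron for tr in traces),
        treatment=_shared(tr.treatment for tr in traces),
        cohort=_shared(tr.cohort for tr in traces),
        fly=_shared(tr.fly for tr in traces),
        n=n,
        sem=sem,
    )
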