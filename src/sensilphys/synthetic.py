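"""Synthetic fluorescence recordings and spike trains with known ground truth.

The generators emulate the statistical structure the analysis assumes:

* imaging — stimulus-locked indicator transients (difference-of-exponentials
  kernel) on a baseline with mild exponential photobleaching, i.i.d. Gaussian
  frame noise, a responder/non-responder mixture, and a background region
  that carries offset plus noise only;
* SSR — inhomogeneous Poisson spike trains with a constant resting rate plus
  alpha-function odor and mechanical (air-gust) response kernels starting at
  stimulus onset. The mechanical gain differs between the ``control`` and
  ``heatshock`` cohorts, encoding the gained-mechanosensitivity phenotype of
  support-cell-ablated flies.

Cell-type presets fix the flux direction of the transient per indicator:
OSNs show a Ca2+ increase and a K+ decrease; tormogen cells show a Ca2+
increase in a 58% responder subpopulation and no K+ change; thecogen cells
show no Ca2+ change and a small K+ increase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import (
    DesignError,
    ImagingRecording,
    SpikeTrain,
    StimulusEvent,
    ValidationError,
)

__all__ = [
    "IMAGING_PRESETS",
    "ODORANTS",
    "TREATMENT_PANEL",
    "NEURON_BY_SENSILLUM",
    "ImagingSimParams",
    "SpikeSimParams",
    "simulate_imaging_recording",
    "simulate_spike_train",
    "simulate_cohort",
    "default_design",
    "default_params_map",
    "alpha_kernel",
    "alpha_integral",
    "rate_function",
    "dose_amplitude",
]

# ---------------------------------------------------------------------------
# imaging
# ---------------------------------------------------------------------------

#: preset -> (default transient amplitude in % of baseline, responder fraction,
#: required sign of the amplitude: +1 influx, -1 efflux, 0 no change)
IMAGING_PRESETS: dict[str, tuple[float, float, int]] = {
    "osn_ca": (30.0, 1.0, +1),
    "osn_k": (-10.0, 1.0, -1),
    "tormogen_ca": (30.0, 0.58, +1),
    "tormogen_k": (0.0, 1.0, 0),
    "thecogen_ca": (0.0, 1.0, 0),
    "thecogen_k": (5.0, 1.0, +1),
}


def _default_imaging_events() -> list[StimulusEvent]:
    # bath application of the Orco agonist at 300 s; it is not washed out,
    # so duration is nominal
    return [StimulusEvent(label="VUAA1", onset_time=300.0, duration=0.0, modality="odor")]


@dataclass
class ImagingSimParams:
    """Parameters of the imaging simulator.

    ``transient_amplitude`` is signed percent of baseline (+ influx,
    - efflux). ``rise_tau``/``decay_tau`` parameterize the
    difference-of-exponentials transient, which is normalized to peak 1 on
    the sampled frame grid so a noise-free responder's peak dF/F0 equals the
    amplitude exactly. ``bleach_rate`` is the fractional fluorescence decay
    per frame (single multiplicative exponential on the baseline).
    """

    n_cells: int = 30
    responder_fraction: float = 0.58
    transient_amplitude: float = 30.0
    rise_tau: float = 15.0
    decay_tau: float = 120.0
    baseline_level: float = 100.0
    bleach_rate: float = 1e-4
    noise_sd: float = 2.0
    background_noise_sd: float | None = None  # None -> same as noise_sd
    background_level: float = 20.0
    frame_interval: float = 5.0
    n_frames: int = 180
    events: list[StimulusEvent] = field(default_factory=_default_imaging_events)
    preset: str | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValidationError("responder_fraction must lie in [0, 1]")
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise ValidationError("taus must be > 0")
        if self.rise_tau >= self.decay_tau:
            raise ValidationError("rise_tau must be < decay_tau")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.background_noise_sd is not None and self.background_noise_sd < 0:
            raise ValidationError("background_noise_sd must be >= 0")
        if self.baseline_level <= 0:
            raise ValidationError("baseline_level must be > 0")
        if self.bleach_rate < 0:
            raise ValidationError("bleach_rate must be >= 0")
        if self.preset is not None:
            if self.preset not in IMAGING_PRESETS:
                raise ValidationError(f"unknown preset {self.preset!r}")
            _, _, sign = IMAGING_PRESETS[self.preset]
            if sign == 0 and self.transient_amplitude != 0.0:
                raise ValidationError(
                    f"preset {self.preset!r} is a no-change cell type; "
                    "transient_amplitude must be 0"
                )
            if sign != 0 and math.copysign(1, self.transient_amplitude) != sign:
                raise ValidationError(
                    f"preset {self.preset!r} requires amplitude sign {sign:+d}"
                )

    @classmethod
    def from_preset(cls, preset: str, **overrides) -> "ImagingSimParams":
        amp, frac, _ = IMAGING_PRESETS[preset]
        kw = dict(transient_amplitude=amp, responder_fraction=frac, preset=preset)
        kw.update(overrides)
        return cls(**kw)


def dose_amplitude(preset: str, concentration_mm: float, k_half: float = 20.0) -> float:
    """Transient amplitude (%) at an extracellular KCl concentration.

    Both OSN and thecogen K+ responses shrink in magnitude as ambient [K+]
    rises (the electrochemical driving force collapses); a simple saturating
    ``A / (1 + c/k_half)`` decline reproduces the mirrored dose-response
    structure with the preset's sign.
    """
    amp, _, sign = IMAGING_PRESETS[preset]
    if sign == 0:
        return 0.0
    scale_max = 20.0  # % at the low-concentration limit, signed by preset
    return math.copysign(scale_max, amp) / (1.0 + concentration_mm / k_half)


def _transient_kernel(
    frame_times: np.ndarray, onset: float, rise_tau: float, decay_tau: float
) -> np.ndarray:
    """Difference-of-exponentials transient, peak-normalized on the sampled grid."""
    dt = frame_times - onset
    k = np.where(dt >= 0, np.exp(-np.maximum(dt, 0) / decay_tau) - np.exp(-np.maximum(dt, 0) / rise_tau), 0.0)
    peak = k.max()
    return k / peak if peak > 0 else k


def simulate_imaging_recording(
    params: ImagingSimParams, seed: int | np.random.SeedSequence
) -> tuple[ImagingRecording, dict]:
    """Simulate one recording; returns the recording and a truth dict.

    Truth holds per-cell ``responder`` flags and signed ``amplitude`` values
    (% of baseline). Identical (params, seed) pairs give bit-identical output.
    """
    rng = np.random.default_rng(seed)
    n, m = params.n_frames, params.n_cells
    t = np.arange(n) * params.frame_interval

    responders = rng.random(m) < params.responder_fraction
    amplitudes = np.where(responders, params.transient_amplitude, 0.0)

    signal = np.zeros(n)
    for ev in params.events:
        if ev.modality == "odor":
            signal += _transient_kernel(t, ev.onset_time, params.rise_tau, params.decay_tau)
    bleach = np.exp(-params.bleach_rate * np.arange(n))

    cells = (
        params.baseline_level * bleach[:, None]
        + (amplitudes[None, :] / 100.0) * params.baseline_level * signal[:, None]
    )
    bg = np.full(n, params.background_level)
    bg_sd = params.noise_sd if params.background_noise_sd is None else params.background_noise_sd
    if params.noise_sd > 0:
        cells = cells + rng.normal(0.0, params.noise_sd, size=(n, m))
    if bg_sd > 0:
        bg = bg + rng.normal(0.0, bg_sd, size=n)

    matrix = np.column_stack([bg, cells])
    roi_names = ["bg"] + [f"cell_{i + 1:03d}" for i in range(m)]
    rec = ImagingRecording(
        trace_matrix=matrix,
        roi_names=roi_names,
        background_roi=0,
        frame_interval=params.frame_interval,
        events=list(params.events),
        meta={"preset": params.preset or "", "simulated": True},
    )
    truth = {"responder": responders, "amplitude": amplitudes}
    return rec, truth


# ---------------------------------------------------------------------------
# SSR spike trains
# ---------------------------------------------------------------------------


@dataclass
class SpikeSimParams:
    """Inhomogeneous-Poisson spike-train parameters.

    The rate is ``baseline_rate + odor_gain * A(t - onset) + g_mech *
    M(t - onset)`` with peak-normalized alpha kernels ``A`` (tau
    ``odor_tau`` = 0.1 s, ~0.4 s response duration) and ``M`` (tau
    ``mech_tau`` = 0.05 s, a briefer gust transient). ``g_mech`` is
    ``mech_gain`` for the control cohort and ``mech_gain_heatshock`` for the
    support-cell-ablated cohort.
    """

    baseline_rate: float = 8.0
    odor_gain: float = 150.0
    odor_tau: float = 0.1
    mech_gain: float = 5.0
    mech_gain_heatshock: float = 40.0
    mech_tau: float = 0.05
    span: float = 13.0
    stimulus_onset: float = 3.0
    stimulus_duration: float = 0.5
    n_trials: int = 1

    def __post_init__(self) -> None:
        for name in ("baseline_rate", "odor_gain", "mech_gain", "mech_gain_heatshock"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.odor_tau <= 0 or self.mech_tau <= 0:
            raise ValidationError("kernel taus must be > 0")
        if not 0 <= self.stimulus_onset <= self.span:
            raise ValidationError("stimulus_onset must lie within [0, span]")

    def mech_gain_for(self, cohort: str) -> float:
        return self.mech_gain_heatshock if cohort == "heatshock" else self.mech_gain


def alpha_kernel(t: np.ndarray | float, tau: float) -> np.ndarray:
    """Peak-normalized alpha function ``(t/tau) * exp(1 - t/tau)``, zero for t <= 0."""
    t = np.asarray(t, dtype=float)
    out = np.where(t > 0, (t / tau) * np.exp(1.0 - t / tau), 0.0)
    return out


def alpha_integral(tau: float, upper: float) -> float:
    """Closed-form integral of the peak-normalized alpha kernel over [0, upper]."""
    if upper <= 0:
        return 0.0
    x = upper / tau
    return math.e * tau * (1.0 - math.exp(-x) * (1.0 + x))


def rate_function(params: SpikeSimParams, cohort: str = "control"):
    """Return (lambda(t) callable in spikes/s, its supremum over the span)."""
    g = params.mech_gain_for(cohort)
    onset = params.stimulus_onset

    def lam(t):
        dt = np.asarray(t, dtype=float) - onset
        return (
            params.baseline_rate
            + params.odor_gain * alpha_kernel(dt, params.odor_tau)
            + g * alpha_kernel(dt, params.mech_tau)
        )

    lam_max = params.baseline_rate + params.odor_gain + g
    return lam, lam_max


def simulate_spike_train(
    params: SpikeSimParams,
    seed: int | np.random.SeedSequence,
    cohort: str = "control",
    **labels,
) -> SpikeTrain:
    """Sample one train by thinning a homogeneous Poisson process at the rate
    supremum; extra keyword labels populate the SpikeTrain metadata."""
    rng = np.random.default_rng(seed)
    lam, lam_max = rate_function(params, cohort)
    if lam_max <= 0:
        times = np.empty(0)
    else:
        n = rng.poisson(lam_max * params.span)
        cand = np.sort(rng.uniform(0.0, params.span, size=n))
        keep = rng.uniform(0.0, lam_max, size=n) < lam(cand)
        times = cand[keep]
    return SpikeTrain(
        spike_times=times,
        span=params.span,
        stimulus_onset=params.stimulus_onset,
        stimulus_duration=params.stimulus_duration,
        cohort=cohort,
        **labels,
    )


# ---------------------------------------------------------------------------
# cohort designs
# ---------------------------------------------------------------------------

#: the 14 "odorant" treatments (the solvent hexane rides on a gust like any
#: odorant presentation), plus "no treatment" and the blank "air gust"
ODORANTS = [
    "hexane",
    "ethyl acetate",
    "ethyl lactate",
    "CO2",
    "methyl acetate",
    "ethyl hexanoate",
    "2,3-butanedione",
    "1-hexanol",
    "benzaldehyde",
    "1-octen-3-ol",
    "pentyl acetate",
    "2-heptanone",
    "geosmin",
    "isoamyl acetate",
]
TREATMENT_PANEL = ["no treatment", "air gust"] + ODORANTS

NEURON_BY_SENSILLUM = {"ab1": "ab1ABC", "ab2": "ab2A", "ab3": "ab3A"}

#: treatments that carry no odor ligand (gust only, or nothing at all)
_NO_ODOR = {"air gust", "hexane"}


def default_params_map(base: SpikeSimParams | None = None) -> dict[str, SpikeSimParams]:
    """Per-treatment simulator parameters derived from a base setting.

    "no treatment" carries neither odor nor mechanical drive; the blank air
    gust and the solvent hexane carry the mechanical component only; every
    odorant carries both.
    """
    base = base or SpikeSimParams()
    out: dict[str, SpikeSimParams] = {}
    for label in TREATMENT_PANEL:
        if label == "no treatment":
            out[label] = replace(base, odor_gain=0.0, mech_gain=0.0, mech_gain_heatshock=0.0)
        elif label in _NO_ODOR:
            out[label] = replace(base, odor_gain=0.0)
        else:
            out[label] = base
    return out


def default_design(
    n_flies: int = 9,
    sensilla: Sequence[str] = ("ab1", "ab2", "ab3"),
    cohorts: Sequence[str] = ("control", "heatshock"),
    treatments: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Full-factorial design table: sensillum x treatment x cohort rows."""
    treatments = list(treatments) if treatments is not None else TREATMENT_PANEL
    rows = [
        {"sensillum": s, "treatment": t, "cohort": c, "n_flies": n_flies}
        for c in cohorts
        for s in sensilla
        for t in treatments
    ]
    return pd.DataFrame(rows)


def simulate_cohort(
    design: pd.DataFrame,
    params_map: Mapping[str, SpikeSimParams],
    seed: int,
) -> list[SpikeTrain]:
    """One train per fly x design row, with per-row deterministic sub-seeds.

    Seeds derive from ``SeedSequence(seed, spawn_key=(row, fly))`` so any
    subset of the design reproduces identically.
    """
    required = {"sensillum", "treatment", "cohort", "n_flies"}
    missing = required - set(design.columns)
    if missing:
        raise DesignError(f"design table lacks columns: {sorted(missing)}")
    trains: list[SpikeTrain] = []
    for row_idx, row in enumerate(design.itertuples(index=False)):
        if row.treatment not in params_map:
            raise DesignError(f"unknown treatment label {row.treatment!r}")
        params = params_map[row.treatment]
        neuron = NEURON_BY_SENSILLUM.get(row.sensillum, row.sensillum)
        for fly_idx in range(int(row.n_flies)):
            ss = np.random.SeedSequence(seed, spawn_key=(row_idx, fly_idx))
            trains.append(
                simulate_spike_train(
                    params,
                    ss,
                    cohort=row.cohort,
                    treatment=row.treatment,
                    sensillum=row.sensillum,
                    neuron=neuron,
                    fly=f"fly{fly_idx + 1:02d}",
                    genotype=getattr(row, "genotype", ""),
                )
            )
    return trains
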