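# sensilphys

Analysis pipelines for *Drosophila* antennal sensillum physiology: live
cation-imaging time courses of olfactory sensory neurons (OSNs) and their
support cells, and single-sensillum-recording (SSR) spike trains, including
the air-gust (mechanoresponse) correction needed to dissociate olfactory
from mechanosensory response components in support-cell-ablated flies.

It is aimed at insect sensory neurophysiologists who export ROI-averaged
fluorescence matrices from imaging software and spike-time lists from SSR
acquisition, and want a reproducible, scriptable path from those exports to
responder classifications, dose-response curves, resting-activity
estimates and corrected response metrics. A synthetic-data module generates
recordings and spike trains with known ground truth, so every stage of the
pipeline can be validated end to end without any raw recordings.

## What it computes

**Imaging.** For a frames × ROIs fluorescence matrix with one background
region, per-frame background subtraction and baseline normalization give
percent change from baseline:

    F(r,t) = raw(r,t) − raw(bg,t)
    F₀(r)  = mean of F(r,·) over a pre-stimulus window (10 cycles / 50 s)
    ΔF/F₀(r,t) = 100 · (F(r,t) − F₀(r)) / F₀(r)

Each ROI is classified responder/non-responder by the score
`max |ΔF/F₀| in the response window / SD of baseline ΔF/F₀` against a
threshold (default 5). Replicates or cells are aggregated as per-frame mean
± SEM; dose-response curves are read out at the frame where
`max over conditions |mean ΔF/F₀|` peaks — never interpolated.

**SSR.** Spike trains are 13 s recordings (3 s pre-, 10 s post-stimulus,
0.5 s stimuli). Response magnitude is `spikes in [onset, onset+1 s) −
spikes in [onset−1 s, onset)`. Resting activity has two estimators — total
no-treatment count / 13, and pooled 1 s pre-stimulus counts across the 16
treatments / 16 — with a Poisson-calibrated consistency check. Frequency
traces use 25 ms bins anchored at stimulus onset.

**Air-gust correction.** A three-step pipeline: (1) raw binned traces;
(2) subtraction of the per-sensillum mean blank air-gust trace;
(3) a 400 ms centered rolling average. Each stage is mined for peak rate
and trapezoidal AUC within its response window ([0, 1] s raw/corrected,
[−0.5, 1] s smoothed), and heatshock-minus-control deltas summarize the
gained-mechanosensitivity phenotype of thecogen-cell-ablated cohorts.

**Synthetic data.** Imaging: baseline × exponential bleaching +
difference-of-exponentials transients (signed per cell-type preset:
OSN Ca²⁺ ↑ / K⁺ ↓, tormogen Ca²⁺ ↑ in a 58 % responder subpopulation / K⁺
flat, thecogen Ca²⁺ flat / K⁺ ↑) + Gaussian noise. SSR: inhomogeneous
Poisson trains, `λ(t) = baseline + odor_gain·A(t) + mech_gain·M(t)` with
alpha-function kernels, sampled by thinning; the mechanical gain is larger
in the heatshock cohort.

## Worked example

```python
import numpy as np
from sensilphys import *
from sensilphys.synthetic import default_design, default_params_map

# --- imaging: tormogen-cell Ca2+ preset, 40 cells ---
params = ImagingSimParams.from_preset("tormogen_ca", n_cells=40)
rec, truth = simulate_imaging_recording(params, seed=42)
dff = compute_dff(rec)
cls = classify_responders(dff)
agg = aggregate(dff.dff.T, unit_mode="per_cell", times=dff.times)
t_peak = find_extremum_time({"VUAA1": agg}, (300.0, 895.0))
i = np.argmin(np.abs(dff.times - t_peak))
print(f"responders: {cls.is_responder.sum()}/{params.n_cells} "
      f"(truth: {truth['responder'].sum()}), fraction {cls.responder_fraction:.3f}")
print(f"extremum at {t_peak:.0f} s ({t_peak-300:.0f} s post-stimulus); "
      f"mean dF/F0 {agg.mean[i]:.1f} +/- {agg.sem[i]:.1f} % (n={agg.n} cells)")

# --- SSR: ab3 sensillum, 16 treatments, 2 cohorts, 6 flies ---
design = default_design(n_flies=6, sensilla=("ab3",))
trains = simulate_cohort(design, default_params_map(), seed=42)
metrics = run_three_step(trains)
deltas = delta_summary(metrics, stage="raw")
row = deltas[deltas.treatment == "air gust"].iloc[0]
print(f"air gust delta (heatshock - control): peak {row.delta_peak:+.1f} spikes/s, "
      f"AUC {row.delta_auc:+.2f} spikes")
```

This prints (seed 42):

```
responders: 21/40 (truth: 21), fraction 0.525
extremum at 335 s (35 s post-stimulus); mean dF/F0 24.4 +/- 3.1 % (n=40 cells)
air gust delta (heatshock - control): peak +26.7 spikes/s, AUC +6.67 spikes
```

The classifier recovers the simulated responder mixture cell-for-cell at
this signal-to-noise ratio (30 % transients over ~3.5 % baseline noise);
the responder fraction is the binomial draw around the 0.58 preset. The
positive air-gust deltas reflect the elevated mechanical gain built into
the heatshock cohort.

A command-line layer mirrors the library:

```
sensilphys simulate imaging --out sim/ --seed 1 --preset tormogen_ca
sensilphys dff --recording sim/recording.csv --events sim/events.json --out dff.csv
sensilphys simulate ssr --out ssr/ --seed 1 --n-flies 4
sensilphys correct --spikes ssr/ --out corrected/
```

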