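# Methods

## Scope and data model

The package operates on two kinds of recordings:

* **Imaging recordings** — ROI-averaged fluorescence matrices (frames ×
  ROIs, arbitrary units) sampled every 5 s over 180 cycles (15 min), with
  exactly one background ROI and a stimulus-event schedule. ROI averaging
  and segmentation are upstream of this package.
* **Spike trains** — sorted spike times on a 13 s window (3 s pre-,
  10 s post-stimulus; 0.5 s stimuli), labeled by sensillum (ab1/ab2/ab3),
  neuron, treatment, cohort (control/heatshock) and fly. Spike sorting is
  upstream.

All times are seconds from recording start. Count windows and rate bins
are half-open `[a, b)`: a spike on a shared boundary belongs to the later
window, and no spike is ever counted twice. Duplicate spike times are
rejected by default (an acquisition artifact) behind an override flag.

## ΔF/F₀ normalization

`F(r,t) = raw(r,t) − raw(bg,t)`, `F₀(r)` is the mean of `F` over a
baseline window, and `ΔF/F₀ = 100·(F − F₀)/F₀`. The baseline window
defaults to 10 frames (50 s) ending immediately before the first stimulus
frame. Consequences that the tests rely on:

* the baseline-window mean of ΔF/F₀ is exactly 0 for every ROI;
* ΔF/F₀ is invariant to adding a shared constant to all ROIs (it cancels
  in `F`) and to rescaling all ROIs by any c > 0 (it cancels in the ratio);
* a non-positive `F₀` is a hard error naming the ROI — it indicates a
  mis-drawn background region, not recoverable data.

Background subtraction is per-frame by default. A temporal-mean background
mode exists and is the right choice for **single-frame readouts** (the
dose-response curves): with per-frame subtraction, the background ROI's
noise at the one evaluation frame enters every cell identically and can
never be averaged away across cells, which would dominate the SEM of a
pooled-cell curve point. No detrending for photobleaching is applied by
default; the synthetic generator's mild bleaching therefore shows up as a
small shared negative drift, as it does in real recordings.

## Responder classification

The original visual responder/non-responder judgement is formalized as

    score(r) = max over response window of |ΔF/F₀(r,t)| / SD_baseline(r)

with `responder ⇔ score ≥ k`, default `k = 5`. `SD_baseline` is the sample
SD (ddof 1) of ΔF/F₀ over the baseline window. Degenerate cases: zero SD
with signal in the window gives score +∞ (responder); zero SD with a flat
window gives score 0 (non-responder). A signed variant (`direction=±1`)
restricts the peak to the preset's flux direction.

Because the score is a studentized maximum, its null tails are governed by
the baseline window's degrees of freedom: with only 10 baseline frames
(t with 9 df), the per-cell false-positive rate at k = 5 is of order
10⁻² across a 10-frame response window — a few expected false calls per
1000 non-responders. Validation runs that require cell-for-cell agreement
with ground truth therefore use a 60-frame baseline window (59 df, expected
false calls ≈ 0.005 per 1000 cells). With 30 % transients over 2 % baseline
noise the responder scores sit near 15, far from the threshold, so
sensitivity is not at issue at any window length.

## Aggregation, extremum timepoint, dose-response

Aggregate traces are per-frame mean and SEM (`sample SD/√n`) across units,
where a unit is either a replicate (antenna) or a single cell — the caller
chooses explicitly. At n = 1 the SEM is reported as NaN, not 0: the sample
SD of one observation does not exist, and plots must show the gap.

The dose-response readout frame is chosen by `find_extremum_time`: the
frame maximizing `max over conditions |mean ΔF/F₀|` within a post-stimulus
search window, ties broken to the earliest frame (deterministic). Curve
points are mean ± SEM of ΔF/F₀ at that exact frame across pooled cells;
interpolation is refused so the readout is always an acquired sample.

## SSR analysis

* **Response magnitude**: `count[onset, onset+1 s) − count[onset−1 s, onset)`,
  an integer per train; profiles are per-(sensillum, neuron, treatment,
  cohort) means with SEM.
* **Resting activity**: (a) total no-treatment count / 13; (b) pooled 1 s
  pre-stimulus counts across the 16 treatments / 16. Both are unbiased for
  a homogeneous Poisson train. Their consistency check passes when
  `|rate_a − rate_b| ≤ m·sqrt(λ̂/13 + λ̂/16)` with `λ̂` the mean of the two
  estimates. The multiplier defaults to `m = 2.5`: the two estimators use
  disjoint data, so the pooled-SE difference is approximately normal and
  m = 2 would give only ~95.4 % nominal coverage — no margin over the 95 %
  internal-consistency expectation for a finite sample of flies. m = 2.5
  gives ~98.8 % nominal coverage while still failing grossly discrepant
  pairs (e.g. 1 vs 9 spikes/s).
* **Frequency traces**: 25 ms bins `[onset + k·w, onset + (k+1)·w)`
  anchored at stimulus onset, so traces from different flies align
  bin-for-bin by construction instead of by post hoc timestamp matching.
  A trailing partial bin is dropped rather than padded (padding would
  deflate its rate). Rate = count/width; summing rate·width over bins
  returns the spike count exactly.

## Three-step air-gust correction

1. **Raw**: binned traces as above.
2. **Gust-corrected**: subtract the mean blank-air-gust trace, computed per
   sensillum pooling flies within each cohort (per-fly and cross-cohort
   variants are flags). Negative rates are retained — clipping would bias
   the AUC and break the cancellation the correction exists to provide.
3. **Smoothed**: 400 ms centered rolling mean (16 bins at 25 ms). Output is
   defined only where the full window fits, so the trace shortens by 15
   bins and output times are the means of contributing bin times. The
   smoothed response window is widened to [−0.5, 1] s precisely because
   the centered mean spreads response mass earlier.

Metrics per stage: peak = max rate among in-window samples; AUC =
trapezoidal integral over in-window samples (exact for piecewise-linear
rate profiles sampled at the bin nodes). Window endpoints are closed on
both sides, since the trapezoid needs both endpoints. Delta summaries are
heatshock-minus-control means per (sensillum, treatment) for peak and AUC
separately; a grid cell missing a cohort is reported as absent (NaN), not
zero.

### Statistical behaviour of the corrected traces

Two properties matter when validating the correction against ground truth:

* **Residual nullness.** A max-based peak of a corrected pure-gust trace is
  positive almost surely (it is the maximum of zero-mean noise), so "the
  residual is zero" is tested on a signed statistic: the corrected trace's
  value at the time where the cohort's smoothed mean gust response peaks.
  Across flies these values sum to zero by construction and are
  exchangeable, so a sign test is the appropriate null check.
* **Peak recovery.** At 25 ms resolution a raw or corrected single-bin rate
  has shot-noise SD `sqrt(λ/w/n)` — ≈ 27 spikes/s for λ ≈ 160 spikes/s and
  n = 9 flies — and a max-over-bins estimator is positively biased by about
  one SD. Odor-component recovery is therefore assessed on the smoothed
  stage against *stage-matched truth*: the known odor kernel pushed through
  identical binning and smoothing. This is the same reasoning that
  motivates smoothing in the experimental workflow; it compares like with
  like and leaves the smoothing attenuation out of the error.

## Synthetic-data generators

**Imaging.** Cell trace = `baseline·exp(−b·frame) +
(amplitude/100)·baseline·K(t − onset) + ε`, background ROI = offset + ε,
ε i.i.d. Gaussian per frame. `K` is a difference of exponentials
(rise τ 15 s, decay τ 120 s — a support-cell-scale transient peaking tens
of seconds after a bath-applied agonist) normalized to peak 1 **on the
sampled frame grid**, so a noise-free responder's ΔF/F₀ peak equals the
configured amplitude exactly — the property the recovery tests assert.
Defaults: baseline 100 a.u., background 20 a.u., noise SD 2 a.u.
(≈ 2.5–3.5 % in ΔF/F₀ units), bleaching 10⁻⁴/frame (≈ 1.8 % over 15 min),
responder fraction 0.58 for the tormogen Ca²⁺ preset (the observed 42 %
non-responding subpopulation), 30 % transients for the Ca²⁺ presets, −10 %
for OSN K⁺, +5 % for the small thecogen K⁺ influx. Dose-response
amplitudes decline as `A/(1 + [KCl]/20 mM)` — a simple driving-force
collapse giving strictly monotone, sign-mirrored curves between thecogen
cells and OSNs.

**SSR.** Inhomogeneous Poisson,
`λ(t) = baseline + odor_gain·A(t−onset) + g_mech·M(t−onset)`, with
peak-normalized alpha kernels: odor τ = 0.1 s (≈ 0.4 s response duration,
matching typical odor-evoked bursts) and mechanical τ = 0.05 s (a briefer
gust transient, deliberately shorter than the odor kernel so the
correction's component separation is identifiable). Defaults: baseline
8 spikes/s (typical A-neuron resting rates), odor gain 150 spikes/s
(strong diagnostic-odor burst), mechanical gain 5 spikes/s for intact
flies vs 40 spikes/s for the heatshock (support-cell-ablated) cohort —
the gained-mechanosensitivity phenotype. Sampling is by thinning against
the rate supremum (exact for bounded rates); an independent time-rescaling
simulator serves as the distributional oracle in the tests, never as the
generator. Cohort simulation derives one seed per (design row, fly) from a
seed-sequence spawn key, so any subset of a design reproduces identically.

The default treatment panel has 16 entries: "no treatment" (no drive at
all), a blank "air gust" (mechanical only), the solvent hexane (mechanical
only — the solvent rides on a gust), and 13 odorants (odor + mechanical).
Odor gain is per-treatment, not per-(sensillum, treatment): every odorant
drives every simulated neuron equally, which is simpler than real tuning
curves but sufficient for validating the correction pipeline.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: temporally correlated imaging noise and motion
artifacts; indicator binding kinetics, saturation and buffering; spike
waveform overlap and sorting errors; neuron-specific odor tuning;
ephaptic interactions between neighboring neurons; trial-to-trial
adaptation; stimulus-timing jitter between flies (the real motivation for
the 400 ms smoothing window, which here only has to remove residual
subtraction noise).

## Numerical conventions and degenerate inputs

* Windows in seconds are compared with a 10⁻⁹ tolerance; frame/bin
  membership is never decided by floating-point equality alone.
* CSV round trips are exact: matrices are written with `%.17g` and parsed
  with the round-trip float parser; spike times are written at nanosecond
  precision.
* Empty spike trains are valid everywhere (zero counts, zero rates);
  empty windows, reversed windows, mismatched grids, mixed processing
  stages, missing background ROIs and missing gust groups are hard errors.
* The extremum tie-break (earliest frame) and the first-index `argmax` make
  every pipeline output deterministic for a fixed seed and config; the
  test suite asserts bit-reproducibility.

## Problem sizes used in validation

Validation runs are desk-scale by design: 1000-cell mixtures for the
classifier; 250 cells per concentration for dose-response curves; 300
simulated flies per rate for resting-activity calibration; 500 trials per
setting for response-magnitude bias; and a full 16-treatment × 3-sensilla
× 2-cohort design at n = 9 flies per cell (the upper end of realistic
per-treatment sample sizes) for the end-to-end correction. The acceptance
script completes in a few seconds.

## Known limitations

* The responder threshold k = 5 is a formalization of a visual judgement;
  its operating characteristics are calibrated only on the synthetic noise
  model.
* The gust correction assumes the mechanical component is identical in
  distribution across treatments within a (cohort, sensillum) group;
  per-fly correction is available but noisier.
* Peak metrics on unsmoothed 25 ms bins are max-statistics of small Poisson
  counts (40 spikes/s granularity) and are weakly identified at single-fly
  resolution; AUC is the better-behaved statistic at that stage.
* No inferential statistics are provided (t-tests/ANOVA are deliberately
  out of scope); outputs are descriptive means with SEM, exportable to any
  statistics environment.
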