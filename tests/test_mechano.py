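"""Air-gust correction, rolling-average smoothing, peak/AUC mining and
cohort delta summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from sensilphys.io_core import AlignmentError, AnalysisConfig, ValidationError
from sensilphys.mechano import (
    GroupError,
    delta_summary,
    extract_metrics,
    gust_correct,
    mean_gust_trace,
    run_three_step,
    run_three_step_traces,
    smooth,
)
from sensilphys.ssr import FrequencyTrace
from sensilphys.synthetic import (
    SpikeSimParams,
    alpha_kernel,
    default_design,
    default_params_map,
    simulate_cohort,
)

from conftest import SEED

W = 0.025


def make_trace(rate, t0=-3.0, stage="raw", **labels):
    rate = np.asarray(rate, dtype=float)
    times = t0 + (np.arange(rate.size) + 0.5) * W
    return FrequencyTrace(times=times, rate=rate, bin_width=W, stage=stage, **labels)


def kernel_trace(gain, tau, n=520, t0=-3.0, baseline=0.0, **labels):
    times = t0 + (np.arange(n) + 0.5) * W
    return make_trace(baseline + gain * alpha_kernel(times, tau), t0=t0, **labels)


class TestGustCorrect:
    def test_self_subtraction_is_zero(self):
        g = kernel_trace(40.0, 0.05, treatment="air gust", sensillum="ab1")
        out = gust_correct(g, mean_gust_trace([g]))
        assert np.allclose(out.rate, 0.0)
        assert out.stage == "gust_corrected"

    def test_zero_gust_mean_is_identity(self):
        tr = kernel_trace(150.0, 0.1)
        zero = make_trace(np.zeros(520))
        assert np.allclose(gust_correct(tr, zero).rate, tr.rate)

    def test_recovers_odor_component_bin_exactly(self):
        odor = kernel_trace(150.0, 0.1)
        mech = kernel_trace(40.0, 0.05)
        both = make_trace(odor.rate + mech.rate)
        residual = gust_correct(both, mech)
        assert np.allclose(residual.rate, odor.rate, atol=1e-12)

    def test_grid_mismatch_rejected(self):
        a = kernel_trace(10.0, 0.1)
        b = make_trace(np.zeros(519))
        with pytest.raises(AlignmentError):
            gust_correct(a, b)

    def test_negative_values_not_clipped(self):
        tr = make_trace(np.zeros(520))
        g = make_trace(np.full(520, 5.0))
        assert np.allclose(gust_correct(tr, g).rate, -5.0)

    def test_mean_gust_mixed_sensilla_rejected(self):
        a = kernel_trace(1.0, 0.05, sensillum="ab1")
        b = kernel_trace(1.0, 0.05, sensillum="ab2")
        with pytest.raises(ValidationError, match="sensilla"):
            mean_gust_trace([a, b])

    def test_empty_gust_group_rejected(self):
        with pytest.raises(GroupError):
            mean_gust_trace([])


class TestSmooth:
    def test_constant_trace_preserved_and_shortened(self):
        tr = make_trace(np.full(100, 7.0))
        out = smooth(tr, 0.4)  # k = 16
        assert out.rate.size == 100 - 15
        assert np.allclose(out.rate, 7.0)
        assert out.stage == "smoothed"

    def test_single_bin_window_is_identity(self):
        tr = make_trace(np.arange(20.0))
        out = smooth(tr, W)
        assert np.allclose(out.rate, tr.rate)
        assert np.allclose(out.times, tr.times)

    def test_window_larger_than_trace_rejected(self):
        with pytest.raises(ValidationError):
            smooth(make_trace(np.ones(10)), 0.4)

    def test_non_integer_window_rejected(self):
        with pytest.raises(ValidationError):
            smooth(make_trace(np.ones(100)), 0.41)

    @given(st.integers(0, 1000))
    def test_equals_sliding_window_oracle(self, case):
        rng = np.random.default_rng(case)
        n = rng.integers(20, 80)
        tr = make_trace(rng.uniform(0, 100, n))
        k = int(rng.choice([2, 4, 8, 16]))
        out = smooth(tr, k * W)
        oracle = np.array([tr.rate[i : i + k].mean() for i in range(n - k + 1)])
        t_oracle = np.array([tr.times[i : i + k].mean() for i in range(n - k + 1)])
        assert np.allclose(out.rate, oracle, atol=1e-9)
        assert np.allclose(out.times, t_oracle, atol=1e-9)

    def test_never_exceeds_input_max(self, rng):
        tr = make_trace(rng.uniform(0, 200, 200))
        assert smooth(tr, 0.4).rate.max() <= tr.rate.max() + 1e-12


class TestExtractMetrics:
    def test_all_zero_trace(self):
        m = extract_metrics(make_trace(np.zeros(520)))
        assert m.peak_rate == 0.0 and m.auc == 0.0
        assert m.window == (0.0, 1.0)

    def test_triangle_closed_form(self):
        # height 40 spikes/s, base 0.5 s -> area = 0.5 * 0.5 * 40 = 10 spikes;
        # trapezoid is exact on a piecewise-linear pulse sampled at its nodes
        times = np.arange(-0.5, 1.5 + W / 2, W)
        apex, half = 0.5, 0.25
        rate = np.maximum(0.0, 40.0 * (1 - np.abs(times - apex) / half))
        tr = FrequencyTrace(times=times, rate=rate, bin_width=W, stage="raw")
        m = extract_metrics(tr)
        assert m.peak_rate == pytest.approx(40.0)
        assert m.auc == pytest.approx(10.0, abs=1e-12)

    def test_refinement_oracle(self, rng):
        times = np.arange(0.0, 1.0 + W / 2, W)
        rate = rng.uniform(0, 80, times.size)
        tr = FrequencyTrace(times=times, rate=rate, bin_width=W, stage="raw")
        m = extract_metrics(tr)
        fine = np.linspace(times[0], times[-1], (times.size - 1) * 100 + 1)
        oracle = np.trapezoid(np.interp(fine, times, rate), fine)
        assert m.auc == pytest.approx(oracle, rel=1e-9)

    def test_smoothed_stage_uses_widened_window(self):
        tr = make_trace(np.ones(520), stage="smoothed")
        m = extract_metrics(tr)
        assert m.window == (-0.5, 1.0)

    def test_window_from_config_override(self):
        tr = make_trace(np.linspace(0, 519, 520))
        cfg = AnalysisConfig(response_window_raw=(0.0, 2.0))
        assert extract_metrics(tr, cfg).window == (0.0, 2.0)

    def test_no_samples_in_window_rejected(self):
        tr = make_trace(np.ones(10), t0=5.0)
        with pytest.raises(ValidationError):
            extract_metrics(tr)


class TestRunThreeStep:
    def test_noise_free_pure_mech_cancels(self):
        # every treatment is the same mechanical kernel -> corrected ~ 0
        traces = []
        for i in range(3):
            for treatment in ("air gust", "hexane"):
                traces.append(
                    kernel_trace(40.0, 0.05, baseline=8.0, treatment=treatment,
                                 sensillum="ab2", fly=f"fly{i:02d}", cohort="control")
                )
        table = run_three_step_traces(traces)
        corrected = table[table["stage"] != "raw"]
        assert np.allclose(corrected["peak_rate"], 0.0, atol=1e-9)
        assert np.allclose(corrected["auc"], 0.0, atol=1e-9)

    def test_noise_free_odor_recovered_after_correction(self):
        traces = []
        for i in range(2):
            fly = f"fly{i:02d}"
            gust = kernel_trace(40.0, 0.05, baseline=8.0, treatment="air gust",
                                sensillum="ab1", fly=fly, cohort="control")
            odor_plus = make_trace(
                8.0 + 150.0 * alpha_kernel(gust.times, 0.1)
                + 40.0 * alpha_kernel(gust.times, 0.05),
                treatment="ethyl acetate", sensillum="ab1", fly=fly, cohort="control",
            )
            traces += [gust, odor_plus]
        table = run_three_step_traces(traces)
        stage2 = table[(table["stage"] == "gust_corrected")
                       & (table["treatment"] == "ethyl acetate")]
        true_peak = 150.0 * alpha_kernel(traces[0].times, 0.1).max()
        assert np.allclose(stage2["peak_rate"], true_peak, atol=1e-9)

    def test_missing_gust_group_rejected(self):
        tr = kernel_trace(10.0, 0.1, treatment="CO2", sensillum="ab3", fly="f")
        with pytest.raises(GroupError, match="ab3"):
            run_three_step_traces([tr])

    def test_config_bin_width_propagates(self):
        design = default_design(n_flies=1, sensilla=("ab1",),
                                cohorts=("control",),
                                treatments=["air gust", "CO2"])
        trains = simulate_cohort(design, default_params_map(), SEED)
        cfg = AnalysisConfig(bin_width=0.05, smooth_window=0.4)
        table = run_three_step(trains, cfg)
        assert set(table["stage"]) == {"raw", "gust_corrected", "smoothed"}
        assert len(table) == 2 * 3

    def test_no_treatment_unbiased_in_zero_mech_design(self):
        # with no mechanical drive anywhere, correcting "no treatment" trains
        # by the gust mean leaves zero-mean fluctuations only
        base = SpikeSimParams(odor_gain=0.0, mech_gain=0.0, mech_gain_heatshock=0.0)
        design = default_design(n_flies=40, sensilla=("ab1",), cohorts=("control",),
                                treatments=["air gust", "no treatment"])
        trains = simulate_cohort(design, default_params_map(base), SEED)
        table = run_three_step(trains)
        aucs = table[(table["stage"] == "gust_corrected")
                     & (table["treatment"] == "no treatment")]["auc"]
        se = aucs.std(ddof=1) / np.sqrt(len(aucs))
        assert abs(aucs.mean()) < 3 * se + 1e-12


class TestDeltaSummary:
    @staticmethod
    def _metrics(peaks_by_cohort):
        rows = []
        for cohort, peaks in peaks_by_cohort.items():
            for i, p in enumerate(peaks):
                rows.append(
                    {"fly": f"fly{i}", "sensillum": "ab1", "neuron": "ab1ABC",
                     "treatment": "air gust", "cohort": cohort, "stage": "raw",
                     "peak_rate": p, "auc": p / 2}
                )
        return pd.DataFrame(rows)

    def test_identical_cohorts_give_zero(self):
        d = delta_summary(self._metrics({"control": [10, 12], "heatshock": [10, 12]}),
                          stage="raw")
        assert d["delta_peak"].iloc[0] == 0.0
        assert d["delta_auc"].iloc[0] == 0.0

    def test_heatshock_excess_positive(self):
        d = delta_summary(self._metrics({"control": [10.0], "heatshock": [30.0]}),
                          stage="raw")
        assert d["delta_peak"].iloc[0] == 20.0

    def test_missing_cohort_marked_absent(self):
        d = delta_summary(self._metrics({"heatshock": [30.0]}), stage="raw")
        assert np.isnan(d["delta_peak"].iloc[0])
        assert d["n_control"].iloc[0] == 0
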