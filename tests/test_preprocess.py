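import numpy as np
import pytest
from scipy.optimize import brentq

from oepsc.errors import ParameterError, UndefinedLatencyError
from oepsc.preprocess import (
    AveragedTrace,
    average_condition,
    lowpass_gaussian,
    onset_latency,
    peak_amplitude,
    pct_reduction,
)
from oepsc.sweeps import SweepSet
from oepsc.synth import epsc_kernel, kernel_peak_time

from conftest import DT_MS, FS, STIM, kernel_sweepset


def trace_from(samples, stim=STIM, condition="baseline"):
    return AveragedTrace(np.asarray(samples, float), FS, stim, 1, 0, condition)


class TestLowpass:
    def test_dc_gain_unity(self):
        ss = SweepSet("c", "baseline", FS, 0.01, np.full((2, 2000), -42.0))
        out = lowpass_gaussian(ss, 1000.0)
        assert np.allclose(out.sweeps, -42.0, atol=1e-6 * 42)

    def test_half_power_at_cutoff(self):
        # a pure sinusoid at the cutoff frequency comes out at 1/sqrt(2) amplitude
        t = np.arange(40000) / FS
        ss = SweepSet("c", "baseline", FS, 0.01, np.sin(2 * np.pi * 1000.0 * t)[None, :])
        out = lowpass_gaussian(ss, 1000.0)
        mid = slice(5000, 35000)  # away from edges
        gain = out.sweeps[0, mid].std() / ss.sweeps[0, mid].std()
        assert gain == pytest.approx(2 ** -0.5, rel=0.02)

    def test_smoothing_reduces_noise_variance(self):
        rng = np.random.default_rng(0)
        ss = SweepSet("c", "baseline", FS, 0.01, rng.normal(0, 5, (1, 4000)))
        out = lowpass_gaussian(ss)
        assert out.sweeps.var() < ss.sweeps.var()

    def test_cutoff_above_nyquist_rejected(self):
        ss = SweepSet("c", "baseline", FS, 0.01, np.zeros((1, 1000)))
        with pytest.raises(ParameterError):
            lowpass_gaussian(ss, FS)


class TestAverage:
    def test_identical_sweeps_average_to_themselves(self):
        row = np.linspace(-1, 1, 500)
        ss = SweepSet("c", "agonist", FS, 0.01, np.tile(row, (6, 1)), drug="U69")
        trace = average_condition(ss)  # default omits 4 for agonist
        assert trace.omitted_leading_sweeps == 4 and trace.n_sweeps_averaged == 2
        assert np.allclose(trace.samples, row)

    def test_antisymmetric_pair_averages_to_zero(self):
        s = np.sin(np.linspace(0, 5, 400))
        ss = SweepSet("c", "baseline", FS, 0.01, np.vstack([s, -s]))
        assert np.allclose(average_condition(ss, omit_leading=0).samples, 0.0)

    def test_omission_arithmetic_exact(self):
        rng = np.random.default_rng(1)
        data = rng.normal(0, 1, (10, 300))
        ss = SweepSet("c", "baseline", FS, 0.005, data)
        trace = average_condition(ss, omit_leading=4)
        assert np.allclose(trace.samples, data[4:].mean(axis=0))

    def test_omitting_all_sweeps_rejected(self):
        ss = SweepSet("c", "baseline", FS, 0.001, np.zeros((3, 100)))
        with pytest.raises(ParameterError):
            average_condition(ss, omit_leading=3)

    def test_average_commutes_with_filter(self):
        ss = kernel_sweepset([[(2.5, 150.0)], [(3.0, 90.0)], [(6.0, 120.0)]], noise_sd=4.0)
        a = average_condition(lowpass_gaussian(ss), omit_leading=0).samples
        b = lowpass_gaussian(
            SweepSet("c", "baseline", FS, STIM, ss.sweeps.mean(axis=0)[None, :])
        ).sweeps[0]
        assert np.allclose(a, b, atol=1e-9)


class TestPeakAndOnset:
    def test_triangular_pulse_peak(self):
        n = int(0.12 * FS)
        samples = np.zeros(n)
        i0 = int(STIM * FS) + 40
        samples[i0 : i0 + 21] = -500.0 * (1 - np.abs(np.arange(21) - 10) / 10)
        peak, t_peak = peak_amplitude(trace_from(samples))
        assert peak == pytest.approx(500.0)
        assert t_peak == pytest.approx((i0 + 10) / FS)

    def test_flat_trace_zero_peak(self):
        peak, _ = peak_amplitude(trace_from(np.zeros(int(0.12 * FS))))
        assert peak == 0.0

    def test_kernel_peak_matches_closed_form(self, single_kernel_set):
        trace = average_condition(single_kernel_set, omit_leading=0)
        peak, t_peak = peak_amplitude(trace)
        assert peak == pytest.approx(200.0, rel=0.005)
        expected_t = STIM + (2.5 + kernel_peak_time(0.5, 5.0)) / 1000.0
        assert t_peak == pytest.approx(expected_t, abs=2 / FS)

    def test_step_onset_latency(self):
        n = int(0.12 * FS)
        samples = np.zeros(n)
        samples[int((STIM + 0.002) * FS) :] = -100.0
        assert onset_latency(trace_from(samples)) == pytest.approx(2.0, abs=1000 / FS)

    def test_flat_trace_has_undefined_latency(self):
        with pytest.raises(UndefinedLatencyError):
            onset_latency(trace_from(np.zeros(int(0.12 * FS))))

    def test_kernel_onset_latency_matches_root_of_closed_form(self):
        # noiseless kernel starting 3 ms after the flash: latency = 3 ms + t10,
        # where t10 solves k(t) = 0.1 * k(peak) for the dual-exponential kernel
        ss = kernel_sweepset([[(3.0, 200.0)]], snap=True)
        trace = average_condition(ss, omit_leading=0)
        k = lambda t: epsc_kernel(np.array([t]), 0.5, 5.0, 200.0)[0]
        t10 = brentq(lambda t: k(t) - 0.1 * (-200.0), 1e-6, kernel_peak_time(0.5, 5.0))
        assert onset_latency(trace) == pytest.approx(3.0 + t10, abs=1.5 * DT_MS)

    def test_onset_latency_amplitude_invariant(self, single_kernel_set):
        trace = average_condition(single_kernel_set, omit_leading=0)
        scaled = trace_from(trace.samples * 7.3)
        assert onset_latency(scaled) == pytest.approx(onset_latency(trace), abs=1e-9)


class TestPctReduction:
    def test_identical_traces_zero(self, single_kernel_set):
        t = average_condition(single_kernel_set, omit_leading=0)
        assert pct_reduction(t, t) == pytest.approx(0.0)

    def test_abolished_response_full_reduction(self, single_kernel_set):
        t = average_condition(single_kernel_set, omit_leading=0)
        flat = trace_from(np.zeros_like(t.samples))
        assert pct_reduction(t, flat) == pytest.approx(100.0)

    def test_arithmetic(self, single_kernel_set):
        t = average_condition(single_kernel_set, omit_leading=0)
        quarter = trace_from(t.samples * 0.25)
        assert pct_reduction(t, quarter) == pytest.approx(75.0)

    def test_invariant_to_common_scaling(self, single_kernel_set):
        t = average_condition(single_kernel_set, omit_leading=0)
        drug = trace_from(t.samples * 0.4)
        r1 = pct_reduction(t, drug)
        r2 = pct_reduction(trace_from(t.samples * 3), trace_from(drug.samples * 3))
        assert r1 == pytest.approx(r2)
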