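import numpy as np
import pytest

from oepsc.detect import (
    DetectionSettings,
    detect_events,
    differentiate,
    events_per_episode,
)
from oepsc.errors import ParameterError
from oepsc.sweeps import SweepSet
from oepsc.synth import SimConfig, MonoConfig, NoiseConfig, PolyConfig, kernel_derivative, simulate

from conftest import DT_MS, FS, STIM, grid_snap, kernel_sweepset


class TestDifferentiate:
    def test_constant_trace_zero_derivative(self):
        ss = SweepSet("c", "baseline", FS, 0.01, np.full((2, 500), -30.0))
        assert np.allclose(differentiate(ss).sweeps, 0.0)

    def test_linear_ramp_slope(self):
        # -1 pA per sample at 20 kHz is -20 pA/ms
        ss = SweepSet("c", "baseline", FS, 0.01, -np.arange(500, dtype=float)[None, :])
        assert np.allclose(differentiate(ss).sweeps, -20.0)

    def test_kernel_derivative_matches_closed_form(self):
        ss = kernel_sweepset([[(2.5, 200.0)]])
        deriv = differentiate(ss).sweeps[0]
        t_ms = (np.arange(ss.n_samples) / FS - STIM) * 1000.0
        analytic = kernel_derivative(t_ms - grid_snap(2.5), 0.5, 5.0, 200.0)
        # away from the onset kink and the trace endpoints
        mask = (t_ms > grid_snap(2.5) + 3 * DT_MS) & (t_ms < 40.0)
        err = np.abs(deriv[mask] - analytic[mask]) / np.abs(analytic[mask]).max()
        assert err.max() < 0.01


class TestDetect:
    def test_settings_invariants(self):
        with pytest.raises(ParameterError):
            DetectionSettings(threshold=50.0)
        with pytest.raises(ParameterError):
            DetectionSettings(capture_length=0.0)
        with pytest.raises(ParameterError):
            DetectionSettings(detection_window=(10.0, 50.0))

    def test_single_kernel_single_event(self):
        ss = kernel_sweepset([[(2.5, 200.0)]])
        events = detect_events(differentiate(ss))
        assert len(events) == 1
        ev = events[0]
        # the steepest-slope point sits one sample after the (grid-aligned) onset
        assert ev.latency == pytest.approx(grid_snap(2.5), abs=1.5 * DT_MS)
        expected = abs(kernel_derivative(np.array([DT_MS]), 0.5, 5.0, 200.0)[0])
        assert ev.max_slope == pytest.approx(expected, rel=0.01)
        assert ev.max_slope >= 50.0

    def test_two_separated_kernels_two_events(self):
        ss = kernel_sweepset([[(2.5, 200.0), (6.5, 200.0)]])
        events = detect_events(differentiate(ss))
        assert len(events) == 2
        lats = sorted(ev.latency for ev in events)
        assert lats[0] == pytest.approx(2.5, abs=2 * DT_MS)
        assert lats[1] == pytest.approx(6.5, abs=2 * DT_MS)

    def test_all_slopes_exceed_threshold(self):
        cfg = SimConfig(seed=5, n_sweeps=20)
        ss, _ = simulate(cfg)
        events = detect_events(differentiate(ss))
        assert all(ev.max_slope >= 50.0 for ev in events)

    def test_noise_rarely_crosses_ten_sigma(self):
        # white slope noise at SD = |threshold|/10: zero events expected
        n = int(0.12 * FS)
        zero_sweeps = 0
        n_sweeps = 200
        for i in range(n_sweeps):
            d = np.random.default_rng(7000 + i).normal(0.0, 5.0, n)
            dss = SweepSet("c", "baseline", FS, STIM, d[None, :])
            if not detect_events(dss, keep_capture=False):
                zero_sweeps += 1
        assert zero_sweeps / n_sweeps >= 0.99

    def test_translation_equivariance(self):
        events = [[(2.5, 150.0), (7.0, 90.0)]]
        a = kernel_sweepset(events)
        b_sweeps = np.roll(a.sweeps, 200, axis=1)  # shift stimulus and data together
        b = SweepSet("cellX", "baseline", FS, STIM + 200 / FS, b_sweeps)
        lat_a = sorted(ev.latency for ev in detect_events(differentiate(a)))
        lat_b = sorted(ev.latency for ev in detect_events(differentiate(b)))
        assert np.allclose(lat_a, lat_b, atol=1e-9)

    def test_amplitude_scaling_never_loses_events(self):
        ss = kernel_sweepset([[(2.5, 60.0), (8.0, 40.0)]])
        n_small = len(detect_events(differentiate(ss)))
        big = ss.replace(sweeps=ss.sweeps * 3.0)
        assert len(detect_events(differentiate(big))) >= n_small

    def test_min_separation_merges_close_runs(self):
        ss = kernel_sweepset([[(2.5, 200.0), (4.0, 200.0)]])
        derivs = differentiate(ss)
        loose = detect_events(derivs, DetectionSettings(min_event_separation=0.0))
        merged = detect_events(derivs, DetectionSettings(min_event_separation=5.0))
        assert len(loose) == 2 and len(merged) == 1

    def test_recall_precision_on_ground_truth(self):
        # strong, separated events in modest noise: recall and precision >= 0.95
        cfg = SimConfig(
            seed=11,
            n_sweeps=100,
            mono=MonoConfig(prob=1.0, amp_mean=200.0, amp_sd=20.0),
            poly=PolyConfig(rate=1.0, amp_mean=150.0, amp_sd=20.0, latency_mean=9.0, latency_sd=1.0),
            noise=NoiseConfig(sd=4.0),
        )
        ss, truth = simulate(cfg)
        from oepsc.preprocess import lowpass_gaussian

        # the guarantee applies to events separated by >= 2 ms; keep only
        # sweeps whose injected events all satisfy the separation
        def well_separated(evs):
            onsets = sorted(ev.onset for ev in evs)
            return all(b - a >= 2.0 for a, b in zip(onsets, onsets[1:]))

        keep = {si for si, evs in enumerate(truth.per_sweep) if well_separated(evs)}
        events = [
            ev
            for ev in detect_events(differentiate(lowpass_gaussian(ss)), keep_capture=False)
            if ev.sweep_index in keep
        ]
        tp = 0
        n_true = sum(len(truth.per_sweep[si]) for si in keep)
        matched = set()
        by_sweep = {}
        for ev in events:
            by_sweep.setdefault(ev.sweep_index, []).append(ev)
        for si, true_events in enumerate(truth.per_sweep):
            if si not in keep:
                continue
            for te in true_events:
                cands = [
                    (abs(ev.latency - te.onset), k)
                    for k, ev in enumerate(by_sweep.get(si, []))
                    if abs(ev.latency - te.onset) < 1.5 and (si, k) not in matched
                ]
                if cands:
                    matched.add((si, min(cands)[1]))
                    tp += 1
        recall = tp / n_true
        precision = tp / max(len(events), 1)
        assert recall >= 0.95 and precision >= 0.95


class TestEventsPerEpisode:
    def test_zero_events(self):
        ss = kernel_sweepset([[]] * 10)
        assert events_per_episode([], ss) == 0.0

    def test_simple_rate(self):
        ss = kernel_sweepset([[(2.5, 200.0), (6.5, 200.0), (12.0, 200.0)]] * 10)
        events = detect_events(differentiate(ss))
        assert events_per_episode(events, ss) == pytest.approx(3.0)

    def test_generative_rate_recovered(self):
        cfg = SimConfig(seed=21, n_sweeps=200, noise=NoiseConfig(sd=2.0))
        ss, truth = simulate(cfg)
        # ground-truth rate approximates prob + poly rate = 0.9 + 1.9
        assert truth.events_per_episode() == pytest.approx(2.8, rel=0.10)
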