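"""Derivative-threshold deconvolution of compound EPSCs into discrete events.

Each sweep is differentiated (pA/ms; numerically identical to nA·s⁻¹) and
scanned for excursions below a negative slope threshold (default −50 pA/ms)
inside a detection window around the light flash (default −50 to +50 ms).  An
event opens when the derivative crosses below threshold and closes when it
returns above it; the event's latency is the time of its most-negative
derivative sample (the maximum-slope point, which is what the latency
histograms bin), and its reported slope is that value's magnitude.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Tuple

import numpy as np

from .errors import ParameterError
from .sweeps import SweepSet


@dataclasses.dataclass
class DetectionSettings:
    """Event-detection parameters.

    ``threshold`` is the derivative threshold in pA/ms (negative).
    ``time_to_peak`` and ``peak_measurement_interval`` are template metadata
    kept for provenance/logging parity with acquisition-software settings;
    they do not alter threshold-crossing results.  Only ``threshold``,
    ``min_event_separation``, the capture window, and ``detection_window``
    affect output.
    """

    threshold: float = -50.0
    min_event_separation: float = 0.0  # ms
    capture_baseline: float = 1.0  # ms before the opening crossing
    capture_length: float = 5.0  # ms after the opening crossing
    time_to_peak: float = 0.8  # ms; provenance only
    peak_measurement_interval: float = 0.0  # ms; provenance only
    detection_window: Tuple[float, float] = (-50.0, 50.0)  # ms re flash

    def __post_init__(self):
        if not self.threshold < 0:
            raise ParameterError("threshold must be negative (inward slope)")
        if self.capture_length <= 0 or self.capture_baseline < 0:
            raise ParameterError("capture_length must be > 0 and capture_baseline >= 0")
        if self.min_event_separation < 0:
            raise ParameterError("min_event_separation must be >= 0")
        lo, hi = self.detection_window
        if not (lo < 0 <= hi) and not (lo <= 0 < hi):
            raise ParameterError("detection_window must contain 0 (the flash)")


@dataclasses.dataclass
class EventRecord:
    """One deconvolved synaptic event."""

    cell_id: str
    condition: str
    drug: Optional[str]
    sweep_index: int
    latency: float  # ms re flash, at the most-negative derivative sample
    max_slope: float  # pA/ms, magnitude
    capture: Optional[np.ndarray] = None
    label: str = "unassigned"


def differentiate(sweeps: SweepSet) -> SweepSet:
    """First temporal derivative of each sweep, in pA/ms.

    Central differences in the interior, one-sided at the endpoints; length
    preserved.  1 pA/ms ≡ 1 nA·s⁻¹, so printed slope thresholds carry over
    unchanged.
    """
    if sweeps.n_samples < 3:
        raise ParameterError("differentiation requires at least 3 samples per sweep")
    dt_ms = 1000.0 / sweeps.sample_rate
    deriv = np.gradient(sweeps.sweeps, dt_ms, axis=1)
    return sweeps.replace(sweeps=deriv)


def _runs_below(x: np.ndarray, threshold: float) -> List[Tuple[int, int]]:
    """Half-open index runs where x < threshold."""
    below = x < threshold
    if not below.any():
        return []
    d = np.diff(below.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if below[0]:
        starts.insert(0, 0)
    if below[-1]:
        ends.append(x.size)
    return list(zip(starts, ends))


def detect_events(
    derivs: SweepSet,
    settings: Optional[DetectionSettings] = None,
    keep_capture: bool = True,
) -> List[EventRecord]:
    """Threshold-crossing event detection on derivative sweeps.

    ``derivs`` must be the output of :func:`differentiate` (typically applied
    to low-pass-filtered sweeps).  Events whose most-negative point falls
    outside the detection window are discarded.  With
    ``min_event_separation`` = 0 every re-crossing opens a new event;
    otherwise runs closer than the separation (opening-to-opening, ms) are
    merged into one event.
    """
    if settings is None:
        settings = DetectionSettings()
    fs = derivs.sample_rate
    dt_ms = 1000.0 / fs
    t_ms = (np.arange(derivs.n_samples) / fs - derivs.stim_time) * 1000.0
    lo, hi = settings.detection_window
    n_cap_pre = int(round(settings.capture_baseline / dt_ms))
    n_cap_post = int(round(settings.capture_length / dt_ms))

    events: List[EventRecord] = []
    for si in range(derivs.n_sweeps):
        d = derivs.sweeps[si]
        runs = _runs_below(d, settings.threshold)
        if settings.min_event_separation > 0 and len(runs) > 1:
            merged = [runs[0]]
            for s, e in runs[1:]:
                if (s - merged[-1][0]) * dt_ms < settings.min_event_separation:
                    merged[-1] = (merged[-1][0], e)
                else:
                    merged.append((s, e))
            runs = merged
        for s, e in runs:
            k = s + int(np.argmin(d[s:e]))
            lat = t_ms[k]
            if not (lo <= lat <= hi):
                continue
            capture = None
            if keep_capture:
                c0 = max(0, s - n_cap_pre)
                c1 = min(d.size, s + n_cap_post + 1)
                capture = d[c0:c1].copy()
            events.append(
                EventRecord(
                    cell_id=derivs.cell_id,
                    condition=derivs.condition,
                    drug=derivs.drug,
                    sweep_index=si,
                    latency=float(lat),
                    max_slope=float(-d[k]),
                    capture=capture,
                )
            )
    return events


def events_per_episode(
    events: List[EventRecord],
    sweeps: SweepSet,
    window: Optional[Tuple[float, float]] = None,
) -> float:
    """Mean number of detected events per stimulation sweep (episode).

    ``window`` restricts counting to a latency interval in ms re flash; all
    sweeps that contributed to detection count as episodes.
    """
    n_episodes = sweeps.n_sweeps
    if n_episodes == 0:
        raise ParameterError("no episodes")
    if window is None:
        count = len(events)
    else:
        lo, hi = window
        count = sum(1 for ev in events if lo <= ev.latency <= hi)
    return count / n_episodes


def events_to_frame(events: List[EventRecord]):
    """Tidy table of events (capture windows omitted)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "cell_id": ev.cell_id,
                "condition": ev.condition,
                "drug": ev.drug,
                "sweep_index": ev.sweep_index,
                "latency_ms": ev.latency,
                "max_slope_pa_per_ms": ev.max_slope,
                "label": ev.label,
            }
            for ev in events
        ],
        columns=[
            "cell_id",
            "condition",
            "drug",
            "sweep_index",
            "latency_ms",
            "max_slope_pa_per_ms",
            "label",
        ],
    )
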