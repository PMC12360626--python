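"""Filtering, condition averaging, and averaged-trace metrics.

The analysis chain mirrors standard compound-EPSC practice: baseline-subtracted
sweeps are smoothed with a 1 kHz low-pass Gaussian filter, averaged within each
pharmacological condition (omitting the first four sweeps of drug conditions to
let the wash equilibrate), and the averaged trace yields the peak amplitude
(inward peak magnitude) and the onset latency (flash to 10% rise).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import DataError, ParameterError, UndefinedLatencyError
from .sweeps import SweepSet

#: −3 dB Gaussian cutoff relation: sigma_t = sqrt(ln 2) / (2 pi f_c).
#: With this sigma the transfer function exp(-2 pi^2 sigma^2 f^2) equals
#: 2^{-1/2} (half power) exactly at f = f_c, the usual instrumentation meaning
#: of a named low-pass cutoff.
_SIGMA_FACTOR = math.sqrt(math.log(2.0)) / (2.0 * math.pi)


@dataclasses.dataclass
class AveragedTrace:
    """Mean trace of a condition's retained sweeps, with provenance."""

    samples: np.ndarray
    sample_rate: float
    stim_time: float
    n_sweeps_averaged: int
    omitted_leading_sweeps: int
    condition: str
    drug: Optional[str] = None
    cell_id: str = ""

    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate


def gaussian_sigma_samples(cutoff_hz: float, sample_rate: float) -> float:
    """Gaussian kernel width (in samples) for a given −3 dB cutoff."""
    return _SIGMA_FACTOR / cutoff_hz * sample_rate


def lowpass_gaussian(sweeps: SweepSet, cutoff: float = 1000.0) -> SweepSet:
    """Low-pass each sweep with a Gaussian kernel of −3 dB cutoff ``cutoff`` Hz.

    Edge handling is by reflection; output length is unchanged and DC gain is 1.
    """
    if not 0 < cutoff < sweeps.sample_rate / 2:
        raise ParameterError(
            f"cutoff {cutoff} Hz must lie in (0, Nyquist={sweeps.sample_rate / 2:g}) Hz"
        )
    sigma = gaussian_sigma_samples(cutoff, sweeps.sample_rate)
    filtered = gaussian_filter1d(sweeps.sweeps, sigma=sigma, axis=1, mode="reflect")
    return sweeps.replace(sweeps=filtered)


def baseline_subtract_then_filter(
    sweeps: SweepSet, cutoff: float = 1000.0, baseline_window=None
) -> SweepSet:
    """Standard preprocessing order: baseline-subtract each sweep, then low-pass."""
    from .sweeps import baseline_subtract

    return lowpass_gaussian(baseline_subtract(sweeps, baseline_window), cutoff)


def default_omit_leading(condition: str) -> int:
    """First-sweep omission rule: 4 for drug washes, 0 otherwise."""
    return 4 if condition in ("agonist", "antagonist") else 0


def average_condition(sweeps: SweepSet, omit_leading: Optional[int] = None) -> AveragedTrace:
    """Pointwise mean of the retained sweeps.

    ``omit_leading`` defaults to 4 for agonist/antagonist conditions (drug
    equilibration) and 0 otherwise.
    """
    if omit_leading is None:
        omit_leading = default_omit_leading(sweeps.condition)
    if omit_leading < 0:
        raise ParameterError("omit_leading must be non-negative")
    if omit_leading >= sweeps.n_sweeps:
        raise ParameterError(
            f"omitting {omit_leading} sweeps leaves none of {sweeps.n_sweeps} to average"
        )
    retained = sweeps.sweeps[omit_leading:]
    return AveragedTrace(
        samples=retained.mean(axis=0),
        sample_rate=sweeps.sample_rate,
        stim_time=sweeps.stim_time,
        n_sweeps_averaged=retained.shape[0],
        omitted_leading_sweeps=omit_leading,
        condition=sweeps.condition,
        drug=sweeps.drug,
        cell_id=sweeps.cell_id,
    )


def _window_slice(trace: AveragedTrace, window: Optional[Tuple[float, float]]):
    if window is None:
        window = (trace.stim_time, trace.stim_time + 0.050)
    start, stop = float(window[0]), float(window[1])
    if stop <= start:
        raise ParameterError(f"empty search window {window}")
    if start < trace.stim_time - 1e-12:
        raise ParameterError("search window must start at or after the stimulus")
    i0 = int(np.floor(start * trace.sample_rate))
    i1 = min(int(np.ceil(stop * trace.sample_rate)) + 1, trace.samples.size)
    if i1 - i0 < 1 or i0 >= trace.samples.size:
        raise ParameterError("search window lies outside the trace")
    return i0, i1


def peak_amplitude(
    trace: AveragedTrace, search_window: Optional[Tuple[float, float]] = None
) -> Tuple[float, float]:
    """Inward peak magnitude (pA, positive) and its time (s) on the averaged trace.

    The peak is the minimum of the signed trace within ``search_window``
    (default: stimulus to stimulus + 50 ms).
    """
    i0, i1 = _window_slice(trace, search_window)
    seg = trace.samples[i0:i1]
    k = int(np.argmin(seg))
    return float(abs(min(seg[k], 0.0))), (i0 + k) / trace.sample_rate


def onset_latency(
    trace: AveragedTrace,
    rise_fraction: float = 0.10,
    search_window: Optional[Tuple[float, float]] = None,
) -> float:
    """Latency (ms) from the flash to the trace first reaching ``rise_fraction``
    of its inward peak, linearly interpolated between samples.

    The threshold is a fraction of the peak, so the latency is invariant to
    amplitude scaling.  Raises :class:`UndefinedLatencyError` when the trace
    has no inward peak.
    """
    if not 0 < rise_fraction < 1:
        raise ParameterError("rise_fraction must be in (0, 1)")
    i0, i1 = _window_slice(trace, search_window)
    seg = trace.samples[i0:i1]
    peak = seg.min()
    if peak >= 0:
        raise UndefinedLatencyError("trace has no inward (negative) peak in the window")
    thresh = rise_fraction * peak  # negative
    below = np.nonzero(seg <= thresh)[0]
    j = int(below[0])
    if j == 0:
        t_cross = i0 / trace.sample_rate
    else:
        y0, y1 = seg[j - 1], seg[j]
        frac = (thresh - y0) / (y1 - y0)
        t_cross = (i0 + j - 1 + frac) / trace.sample_rate
    return (t_cross - trace.stim_time) * 1000.0


def pct_reduction(
    baseline: AveragedTrace,
    drug: AveragedTrace,
    search_window: Optional[Tuple[float, float]] = None,
) -> float:
    """Percent reduction of the inward peak: 100 × (1 − peak_drug / peak_baseline).

    Negative values indicate facilitation.  Both traces must share the
    stimulus time and sampling rate (same cell, same protocol).
    """
    if not math.isclose(baseline.stim_time, drug.stim_time) or not math.isclose(
        baseline.sample_rate, drug.sample_rate
    ):
        raise ParameterError("baseline and drug traces must share stim_time and sample_rate")
    pb, _ = peak_amplitude(baseline, search_window)
    pd, _ = peak_amplitude(drug, search_window)
    if pb == 0:
        raise DataError("baseline peak amplitude is zero; % reduction undefined")
    return 100.0 * (1.0 - pd / pb)
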