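"""Double-Gaussian latency modelling: histogram, mixture fit, trough, early/late split.

Compound oEPSC latencies are bimodal: a short-latency, low-jitter monosynaptic
population and a longer-latency, higher-jitter polysynaptic (recurrent)
population.  A two-component Gaussian curve is least-squares fitted to the
binned latency counts; the trough of the fitted curve between the two
component means is the early/late classification boundary.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar
from scipy.signal import find_peaks

from .errors import FitError, NoBimodalityError, NoTroughError, ParameterError

log = logging.getLogger(__name__)


@dataclasses.dataclass
class LatencyHistogram:
    bin_edges: np.ndarray  # ms, uniform
    counts: np.ndarray
    bin_width: float  # ms
    range: Tuple[float, float]
    n_dropped: int = 0

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclasses.dataclass
class LatencySplitModel:
    """Fitted double-Gaussian f(t) = a1·G(t; mu1, s1) + a2·G(t; mu2, s2) and its trough."""

    a1: float
    mu1: float
    sigma1: float
    a2: float
    mu2: float
    sigma2: float
    trough: Optional[float]
    sse: float
    converged: bool
    n_events: int
    bin_width: float = float("nan")

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return double_gaussian(t, self.a1, self.mu1, self.sigma1, self.a2, self.mu2, self.sigma2)

    def to_text(self) -> str:
        lines = [
            f"a1 = {self.a1:.6g}",
            f"mu1_ms = {self.mu1:.6g}",
            f"sigma1_ms = {self.sigma1:.6g}",
            f"a2 = {self.a2:.6g}",
            f"mu2_ms = {self.mu2:.6g}",
            f"sigma2_ms = {self.sigma2:.6g}",
            f"trough_ms = {self.trough if self.trough is not None else 'nan'}",
            f"sse = {self.sse:.6g}",
            f"converged = {self.converged}",
            f"n_events = {self.n_events}",
            f"bin_width_ms = {self.bin_width:.6g}",
        ]
        return "\n".join(lines) + "\n"


def double_gaussian(t, a1, mu1, s1, a2, mu2, s2):
    return a1 * np.exp(-((t - mu1) ** 2) / (2 * s1**2)) + a2 * np.exp(
        -((t - mu2) ** 2) / (2 * s2**2)
    )


def build_histogram(
    latencies: Sequence[float],
    bin_width: float = 0.5,
    range: Tuple[float, float] = (0.0, 10.0),
) -> LatencyHistogram:
    """Bin latencies (ms) on a uniform grid; out-of-range values are dropped
    (and logged), matching a histogram restricted to the plotted window."""
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive")
    lo, hi = float(range[0]), float(range[1])
    if hi <= lo:
        raise ParameterError("empty histogram range")
    lat = np.asarray(latencies, dtype=float)
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(lat, bins=edges)
    n_dropped = lat.size - int(counts.sum())
    if n_dropped:
        log.info("build_histogram: dropped %d latencies outside [%g, %g] ms", n_dropped, lo, hi)
    return LatencyHistogram(edges, counts, bin_width, (lo, hi), n_dropped)


def _smoothed_peaks(counts: np.ndarray) -> np.ndarray:
    """Indices of local maxima of a 3-bin moving average of counts."""
    kernel = np.ones(3) / 3.0
    sm = np.convolve(counts.astype(float), kernel, mode="same")
    # pad so maxima at the histogram edges are found too
    padded = np.concatenate([[-1.0], sm, [-1.0]])
    peaks, _ = find_peaks(padded)
    return peaks - 1, sm


def fit_double_gaussian(
    hist: LatencyHistogram,
    min_count: int = 30,
    n_restarts: int = 10,
    restart_seed: int = 0,
) -> LatencySplitModel:
    """Least-squares double-Gaussian fit to bin-center/count pairs.

    Initialisation: the two highest local maxima of a 3-bin moving average of
    the counts seed the component means and amplitudes; sigmas start at the
    bin width.  The fit is repeated from ``n_restarts`` jittered starts (fixed
    ``restart_seed``) and the best SSE wins.  Raises
    :class:`NoBimodalityError` when the smoothed counts have fewer than two
    local maxima, and :class:`FitError` when no start converges.
    """
    counts = np.asarray(hist.counts, dtype=float)
    total = int(counts.sum())
    if total < min_count:
        raise FitError(f"only {total} events in range; need >= {min_count} to fit")
    peaks, smoothed = _smoothed_peaks(counts)
    if peaks.size < 2:
        raise NoBimodalityError(
            "latency histogram has fewer than two local maxima; no evidence of two populations"
        )
    order = np.argsort(smoothed[peaks])[::-1]
    p1, p2 = sorted(peaks[order[:2]])
    centers = hist.centers
    lo, hi = hist.range
    span = hi - lo
    init = np.array(
        [
            max(counts[p1], 1.0),
            centers[p1],
            hist.bin_width,
            max(counts[p2], 1.0),
            centers[p2],
            hist.bin_width,
        ]
    )
    lower = [1e-9, lo, hist.bin_width / 10.0, 1e-9, lo, hist.bin_width / 10.0]
    upper = [np.inf, hi, span, np.inf, hi, span]

    rng = np.random.default_rng(restart_seed)
    best = None
    best_sse = np.inf
    for k in range(n_restarts):
        p0 = init.copy()
        if k > 0:
            p0 = p0 * rng.uniform(0.7, 1.3, size=6)
            p0[[1, 4]] = np.clip(init[[1, 4]] + rng.normal(0, hist.bin_width, 2), lo, hi)
        p0 = np.clip(p0, lower, upper)
        try:
            popt, _ = curve_fit(
                double_gaussian, centers, counts, p0=p0, bounds=(lower, upper), maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((double_gaussian(centers, *popt) - counts) ** 2))
        if sse < best_sse:
            best_sse = sse
            best = popt
    if best is None:
        raise FitError("double-Gaussian fit failed to converge from every start")
    a1, mu1, s1, a2, mu2, s2 = best
    if mu1 > mu2:  # keep component 1 the early one
        a1, mu1, s1, a2, mu2, s2 = a2, mu2, s2, a1, mu1, s1
    model = LatencySplitModel(
        a1=float(a1),
        mu1=float(mu1),
        sigma1=float(s1),
        a2=float(a2),
        mu2=float(mu2),
        sigma2=float(s2),
        trough=None,
        sse=best_sse,
        converged=True,
        n_events=total,
        bin_width=hist.bin_width,
    )
    model.trough = find_trough(model)
    return model


def find_trough(model: LatencySplitModel) -> float:
    """Location (ms) of the minimum of the fitted curve on [mu1, mu2].

    Found on a dense 1 µs grid then refined with a bounded scalar minimiser.
    Raises :class:`NoTroughError` when the curve has no interior minimum
    (components too overlapped to separate).
    """
    if not model.converged:
        raise FitError("model did not converge; no trough")
    mu1, mu2 = model.mu1, model.mu2
    if not mu2 > mu1:
        raise NoTroughError("component means coincide")
    grid = np.arange(mu1, mu2, 1e-3)  # 1 µs steps (ms units)
    if grid.size < 3:
        raise NoTroughError("component means are closer than the search resolution")
    vals = model.predict(grid)
    k = int(np.argmin(vals))
    if k == 0 or k == grid.size - 1:
        raise NoTroughError(
            "fitted curve is monotone between the component means (components too overlapped)"
        )
    res = minimize_scalar(
        lambda t: float(model.predict(t)),
        bounds=(grid[k - 1], grid[k + 1]),
        method="bounded",
        options={"xatol": 1e-7},
    )
    return float(res.x)


def classify(latencies: Sequence[float], trough: float) -> np.ndarray:
    """Label each latency ``early`` (< trough) or ``late`` (>= trough).

    A latency exactly at the trough is labelled late (documented tie-break);
    early + late counts always sum to the input count.
    """
    lat = np.asarray(latencies, dtype=float)
    return np.where(lat < trough, "early", "late")


def label_events(events, trough: float) -> None:
    """Assign early/late labels to :class:`~oepsc.detect.EventRecord` objects in place."""
    for ev in events:
        ev.label = "early" if ev.latency < trough else "late"


def trough_sensitivity(
    latencies: Sequence[float],
    bin_widths: Sequence[float] = (0.25, 0.5, 1.0),
    range: Tuple[float, float] = (0.0, 10.0),
) -> dict:
    """Trough location as a function of bin width (robustness check for the split)."""
    out = {}
    for bw in bin_widths:
        try:
            model = fit_double_gaussian(build_histogram(latencies, bw, range))
            out[bw] = model.trough
        except (FitError, NoTroughError):
            out[bw] = None
    return out
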