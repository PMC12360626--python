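"""Per-cell, per-condition drug-effect quantification.

Summaries combine the averaged-trace metrics (peak amplitude, onset latency)
with early/late event statistics from the derivative deconvolution.  Percent
reduction is always computed within a cell and then aggregated across cells;
early/late slope means pool events within a cell by default.  A hand-rolled
Kruskal–Wallis / Dunn rank comparison is provided for group screening; richer
mixed-model statistics are deliberately left to external tools, fed by the
tidy tables this module exports.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .detect import DetectionSettings, EventRecord, detect_events, differentiate
from .errors import DataError, ParameterError
from .latency import classify
from .preprocess import (
    average_condition,
    baseline_subtract_then_filter,
    onset_latency,
    peak_amplitude,
)
from .sweeps import SweepSet


@dataclasses.dataclass
class ConditionSummary:
    """Per-cell, per-condition metrics."""

    cell_id: str
    condition: str
    drug: Optional[str]
    peak_amplitude: float  # pA, magnitude
    onset_latency: float  # ms; nan when undefined
    events_per_episode_early: float
    events_per_episode_late: float
    mean_slope_early: float  # pA/ms; nan when no early events
    mean_slope_late: float
    n_events_early: int
    n_events_late: int
    n_episodes: int


@dataclasses.dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


@dataclasses.dataclass
class RankCompareResult:
    h: float
    p_value: float
    pairwise: pd.DataFrame  # columns: group_i, group_j, z, p_raw, p_adjusted


def summarize_condition(
    sweeps: SweepSet,
    events: Sequence[EventRecord],
    trough: float,
    classification_window: Tuple[float, float] = (0.0, 20.0),
    omit_leading: Optional[int] = None,
    cutoff: float = 1000.0,
) -> ConditionSummary:
    """Fill a :class:`ConditionSummary` from a sweep set and its detected events.

    Events are split at ``trough`` within ``classification_window`` (ms re
    flash).  The averaged trace follows the preprocessing defaults (baseline
    subtraction, 1 kHz Gaussian filter, first-four-sweep omission for drug
    washes); all sweeps count as episodes for the event rates.
    """
    if sweeps.n_sweeps == 0:
        raise ParameterError("no episodes")
    filtered = baseline_subtract_then_filter(sweeps, cutoff=cutoff)
    trace = average_condition(filtered, omit_leading=omit_leading)
    peak, _ = peak_amplitude(trace)
    try:
        onset = onset_latency(trace)
    except Exception:
        onset = float("nan")
    lo, hi = classification_window
    in_win = [ev for ev in events if lo <= ev.latency <= hi]
    labels = classify([ev.latency for ev in in_win], trough)
    early = [ev for ev, lab in zip(in_win, labels) if lab == "early"]
    late = [ev for ev, lab in zip(in_win, labels) if lab == "late"]
    n_ep = sweeps.n_sweeps
    return ConditionSummary(
        cell_id=sweeps.cell_id,
        condition=sweeps.condition,
        drug=sweeps.drug,
        peak_amplitude=peak,
        onset_latency=onset,
        events_per_episode_early=len(early) / n_ep,
        events_per_episode_late=len(late) / n_ep,
        mean_slope_early=float(np.mean([e.max_slope for e in early])) if early else float("nan"),
        mean_slope_late=float(np.mean([e.max_slope for e in late])) if late else float("nan"),
        n_events_early=len(early),
        n_events_late=len(late),
        n_episodes=n_ep,
    )


def analyze_condition(
    sweeps: SweepSet,
    trough: float,
    settings: Optional[DetectionSettings] = None,
    **kwargs,
) -> Tuple[ConditionSummary, List[EventRecord]]:
    """Convenience wrapper: filter, differentiate, detect, then summarise."""
    filtered = baseline_subtract_then_filter(sweeps, cutoff=kwargs.get("cutoff", 1000.0))
    events = detect_events(differentiate(filtered), settings, keep_capture=False)
    return summarize_condition(sweeps, events, trough, **kwargs), events


def summaries_to_frame(summaries: Sequence[ConditionSummary]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(s) for s in summaries])


def effect_table(summaries: Sequence[ConditionSummary]) -> pd.DataFrame:
    """One row per cell × non-baseline condition with % reduction and paired deltas.

    Every cell must contribute a baseline summary; missing antagonist rows are
    simply absent (cells lost during a wash are a normal occurrence).
    """
    by_cell: Dict[str, Dict[str, ConditionSummary]] = {}
    for s in summaries:
        by_cell.setdefault(s.cell_id, {})[s.condition] = s
    rows = []
    for cell_id, conds in by_cell.items():
        if "baseline" not in conds:
            raise DataError(f"cell {cell_id!r} has no baseline condition")
        base = conds["baseline"]
        for cond, s in conds.items():
            if cond == "baseline":
                continue
            if base.peak_amplitude == 0:
                raise DataError(f"cell {cell_id!r}: baseline peak is zero")
            rows.append(
                {
                    "cell_id": cell_id,
                    "condition": cond,
                    "drug": s.drug,
                    "pct_reduction": 100.0 * (1.0 - s.peak_amplitude / base.peak_amplitude),
                    "onset_latency_baseline_ms": base.onset_latency,
                    "delta_events_per_episode_early": s.events_per_episode_early
                    - base.events_per_episode_early,
                    "delta_events_per_episode_late": s.events_per_episode_late
                    - base.events_per_episode_late,
                    "peak_baseline_pa": base.peak_amplitude,
                    "peak_condition_pa": s.peak_amplitude,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "condition",
            "drug",
            "pct_reduction",
            "onset_latency_baseline_ms",
            "delta_events_per_episode_early",
            "delta_events_per_episode_late",
            "peak_baseline_pa",
            "peak_condition_pa",
        ],
    )


def ecdf_events(latencies_by_condition: Dict[str, Sequence[float]]) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Right-continuous empirical CDF of event latency per condition.

    Returns, per condition, the sorted unique latencies and the cumulative
    fraction at each (terminal value 1).
    """
    out = {}
    for cond, lats in latencies_by_condition.items():
        lat = np.sort(np.asarray(lats, dtype=float))
        if lat.size == 0:
            raise DataError(f"condition {cond!r} has no events")
        x, counts = np.unique(lat, return_counts=True)
        y = np.cumsum(counts) / lat.size
        out[cond] = (x, y)
    return out


def cumulative_event_curve(
    events: Sequence[EventRecord],
    n_episodes: int,
    window: Tuple[float, float] = (0.0, 20.0),
    dt: float = 0.1,
) -> Tuple[np.ndarray, np.ndarray]:
    """Cumulative events per episode as a function of latency (condition comparison curve)."""
    if n_episodes < 1:
        raise ParameterError("need at least one episode")
    grid = np.arange(window[0], window[1] + dt / 2, dt)
    lats = np.sort([ev.latency for ev in events])
    counts = np.searchsorted(lats, grid, side="right")
    return grid, counts / n_episodes


def latency_effect_regression(
    onset_latencies_ms: Sequence[float], pct_reductions: Sequence[float]
) -> RegressionResult:
    """Simple linear regression of per-cell % peak reduction on onset latency.

    A positive, significant slope indicates latency-dependent (recurrent-
    pathway) inhibition; a flat fit indicates pathway-independent suppression.
    """
    x = np.asarray(onset_latencies_ms, dtype=float)
    y = np.asarray(pct_reductions, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ParameterError("regression needs at least 3 cells")
    if np.ptp(x) == 0:
        raise DataError("zero variance in onset latency")
    if np.ptp(y) == 0:
        # perfectly constant response: flat fit, no explained variance
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, int(x.size))
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


# ---------------------------------------------------------------------------
# Rank statistics (implemented from the rank formulas)
# ---------------------------------------------------------------------------

def _ranks_with_ties(values: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Mid-ranks and the tie-group sizes."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(values.size, dtype=float)
    sorted_vals = values[order]
    i = 0
    tie_sizes = []
    while i < values.size:
        j = i
        while j + 1 < values.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        tie_sizes.append(j - i + 1)
        i = j + 1
    return ranks, np.asarray(tie_sizes)


def rank_compare(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> RankCompareResult:
    """Kruskal–Wallis omnibus with tie correction plus Dunn pairwise z tests.

    H = 12/(N(N+1)) · Σ nᵢ·r̄ᵢ² − 3(N+1), divided by 1 − Σ(t³−t)/(N³−N);
    Dunn z uses the tie-corrected rank variance with Bonferroni adjustment of
    the two-sided p-values.  The chi-square/normal tail probabilities come
    from scipy's distribution functions.
    """
    if len(groups) < 2:
        raise ParameterError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ParameterError("each group needs at least 2 values")
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    if np.ptp(pooled) == 0:
        raise DataError("all values identical; rank statistic degenerate")
    ranks, tie_sizes = _ranks_with_ties(pooled)
    sizes = [a.size for a in arrays]
    idx = np.cumsum([0] + sizes)
    mean_ranks = [ranks[idx[i] : idx[i + 1]].mean() for i in range(len(arrays))]

    h = 12.0 / (n_total * (n_total + 1)) * sum(
        n_i * rbar**2 for n_i, rbar in zip(sizes, mean_ranks)
    ) - 3.0 * (n_total + 1)
    tie_term = float(np.sum(tie_sizes**3 - tie_sizes))
    correction = 1.0 - tie_term / (n_total**3 - n_total)
    if correction <= 0:
        raise DataError("tie correction degenerate")
    h /= correction
    df = len(arrays) - 1
    p = float(stats.chi2.sf(h, df))

    # Dunn pairwise comparisons
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    rows = []
    m = len(arrays) * (len(arrays) - 1) // 2
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p_raw = 2.0 * float(stats.norm.sf(abs(z)))
            rows.append(
                {
                    "group_i": i,
                    "group_j": j,
                    "z": z,
                    "p_raw": p_raw,
                    "p_adjusted": min(1.0, p_raw * m),
                }
            )
    return RankCompareResult(h=float(h), p_value=p, pairwise=pd.DataFrame(rows))
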