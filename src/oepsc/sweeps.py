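"""Voltage-clamp sweep sets: data model, HDF5/CSV I/O, and recording-quality filtering.

A :class:`SweepSet` holds one cell's sweeps for a single pharmacological
condition, together with the light-stimulus time, sampling rate, and optional
per-sweep series-resistance readings.  Currents are stored in pA with the
physiological sign convention for a voltage-clamped cell at −65 mV: inward
(excitatory) currents are negative.  Summary quantities elsewhere in the
package (amplitudes, slopes) are reported as positive magnitudes while raw
traces keep their sign.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np

from .errors import DataError, FormatError, ParameterError

CONDITIONS = ("baseline", "agonist", "antagonist", "ttx", "ttx_4ap", "custom")
DRUGS = ("U69", "DAMGO", "DPDPE", "nor-BNI", "CTAP", "TIPPpsi", "none")


@dataclasses.dataclass
class SweepSet:
    """Ordered voltage-clamp sweeps for one cell and condition.

    Parameters
    ----------
    cell_id : str
        Opaque cell identifier.
    condition : str
        One of ``baseline, agonist, antagonist, ttx, ttx_4ap, custom``.
    sample_rate : float
        Samples per second (Hz).
    stim_time : float
        Light-flash time in seconds from sweep start; must lie inside the sweep.
    sweeps : ndarray, shape (n_sweeps, n_samples)
        Current in pA, inward negative.  Sweep order is acquisition order,
        which the first-four-sweep omission rule and the series-resistance
        increase rule both rely on.
    drug : str, optional
        Agonist/antagonist label.
    series_resistance : ndarray, optional
        Per-sweep series resistance in MΩ.
    inter_sweep_interval : float
        Seconds between consecutive stimulations (metadata; nominally 30 s).
    holding_potential : float
        Holding potential in mV (metadata; nominally −65 mV).
    """

    cell_id: str
    condition: str
    sample_rate: float
    stim_time: float
    sweeps: np.ndarray
    drug: Optional[str] = None
    series_resistance: Optional[np.ndarray] = None
    inter_sweep_interval: float = 30.0
    holding_potential: float = -65.0

    def __post_init__(self):
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))
        if self.sweeps.ndim != 2:
            raise DataError("sweeps must be a 2-D array (n_sweeps, n_samples)")
        if self.sweeps.shape[0] == 0 or self.sweeps.shape[1] < 2:
            raise DataError("sweep set must contain at least one sweep of >=2 samples")
        if self.condition not in CONDITIONS:
            raise DataError(f"unknown condition {self.condition!r}; expected one of {CONDITIONS}")
        if self.drug is not None and self.drug not in DRUGS:
            raise DataError(f"unknown drug {self.drug!r}; expected one of {DRUGS}")
        if not self.sample_rate > 0:
            raise DataError("sample_rate must be positive")
        if not (0.0 <= self.stim_time < self.duration):
            raise DataError(
                f"stim_time {self.stim_time} s must lie within the sweep "
                f"(duration {self.duration:.4f} s)"
            )
        if self.series_resistance is not None:
            self.series_resistance = np.asarray(self.series_resistance, dtype=float)
            if self.series_resistance.shape != (self.n_sweeps,):
                raise DataError("series_resistance must have one value per sweep")

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    @property
    def n_samples(self) -> int:
        return self.sweeps.shape[1]

    @property
    def duration(self) -> float:
        """Sweep duration in seconds."""
        return self.n_samples / self.sample_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds from sweep start."""
        return np.arange(self.n_samples) / self.sample_rate

    def replace(self, **kwargs) -> "SweepSet":
        return dataclasses.replace(self, **kwargs)

    def allclose(self, other: "SweepSet", atol: float = 1e-9) -> bool:
        """True if the two sets agree in metadata and traces within ``atol`` pA."""
        if (
            self.cell_id != other.cell_id
            or self.condition != other.condition
            or self.drug != other.drug
            or self.sweeps.shape != other.sweeps.shape
        ):
            return False
        if not np.isclose(self.sample_rate, other.sample_rate):
            return False
        if not np.isclose(self.stim_time, other.stim_time):
            return False
        if (self.series_resistance is None) != (other.series_resistance is None):
            return False
        if self.series_resistance is not None and not np.allclose(
            self.series_resistance, other.series_resistance, atol=atol
        ):
            return False
        return np.allclose(self.sweeps, other.sweeps, atol=atol)


@dataclasses.dataclass
class QCReport:
    """Series-resistance quality-control outcome for one sweep set.

    ``passed`` is True only when every sweep's Rs stays below ``rs_max`` and
    the relative increase over the reference sweep stays within
    ``increase_max``.  When no Rs data exist the report is not assessable and
    ``passed`` is None — QC never passes by omission.
    """

    sweep_pass: Optional[np.ndarray]
    max_rs: Optional[float]
    relative_increase: Optional[float]
    passed: Optional[bool]
    assessable: bool
    rs_max: float
    increase_max: float

    def __str__(self):
        if not self.assessable:
            return "QC: not assessable (no series-resistance data)"
        lines = [
            f"QC: {'PASS' if self.passed else 'FAIL'}",
            f"  max Rs            : {self.max_rs:.2f} MOhm (limit {self.rs_max:g})",
            f"  relative increase : {100 * self.relative_increase:.1f}% "
            f"(limit {100 * self.increase_max:g}%)",
            f"  sweeps passing    : {int(self.sweep_pass.sum())}/{self.sweep_pass.size}",
        ]
        return "\n".join(lines)


def qc_series_resistance(
    sweeps: SweepSet,
    rs_max: float = 10.0,
    increase_max: float = 0.20,
    reference_rs: Optional[float] = None,
) -> QCReport:
    """Apply the whole-cell recording inclusion rule: Rs < ``rs_max`` MΩ throughout
    and no relative increase beyond ``increase_max``.

    The relative increase is (max Rs − reference Rs) / reference Rs.  The
    reference defaults to the first sweep of this set; pass ``reference_rs``
    (e.g. the first passing baseline sweep) to anchor the rule across
    conditions of one cell.
    """
    rs = sweeps.series_resistance
    if rs is None:
        return QCReport(None, None, None, None, False, rs_max, increase_max)
    if np.any(rs <= 0):
        raise DataError("series resistance values must be positive")
    ref = float(rs[0]) if reference_rs is None else float(reference_rs)
    if ref <= 0:
        raise DataError("reference series resistance must be positive")
    sweep_pass = rs < rs_max
    max_rs = float(rs.max())
    rel_inc = (max_rs - ref) / ref
    passed = bool(sweep_pass.all() and rel_inc <= increase_max)
    return QCReport(sweep_pass, max_rs, rel_inc, passed, True, rs_max, increase_max)


def baseline_subtract(sweeps: SweepSet, window: Optional[tuple] = None) -> SweepSet:
    """Subtract each sweep's mean over a pre-stimulus window.

    ``window`` is a (start, stop) interval in seconds from sweep start and must
    lie entirely before ``stim_time``.  The default is the 50 ms ending 1 ms
    before the flash (clipped to the sweep start for short pre-stimulus
    segments).  After subtraction the window mean of every sweep is zero, so
    the operation is idempotent.
    """
    if window is None:
        stop = sweeps.stim_time - 0.001
        start = max(0.0, stop - 0.050)
        window = (start, stop)
    start, stop = float(window[0]), float(window[1])
    if not (0.0 <= start < stop):
        raise ParameterError(f"invalid baseline window {window}")
    if stop > sweeps.stim_time:
        raise ParameterError("baseline window must end at or before the stimulus")
    i0 = int(round(start * sweeps.sample_rate))
    i1 = int(round(stop * sweeps.sample_rate))
    if i1 > sweeps.n_samples or i1 - i0 < 1:
        raise ParameterError("baseline window lies outside the sweep")
    means = sweeps.sweeps[:, i0:i1].mean(axis=1, keepdims=True)
    return sweeps.replace(sweeps=sweeps.sweeps - means)


# ---------------------------------------------------------------------------
# I/O.  Two native layouts:
#   hdf5 — dataset "sweeps" (n_sweeps x n_samples float pA) with attributes
#          sample_rate_hz, stim_time_s, condition, drug, cell_id, plus optional
#          dataset "series_resistance_mohm";
#   csv  — one row per sweep, with a JSON sidecar <path>.meta.json carrying the
#          same attributes.
# NWB requires the optional pynwb dependency.
# ---------------------------------------------------------------------------

_FORMATS = ("hdf5", "csv", "nwb")


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def save_sweeps(sweeps: SweepSet, path, format: str = "hdf5") -> None:
    """Write a :class:`SweepSet` to ``path`` in the given layout."""
    if format not in _FORMATS:
        raise ParameterError(f"unknown format {format!r}; expected one of {_FORMATS}")
    path = Path(path)
    if format == "nwb":
        raise FormatError(
            "NWB output requires the optional pynwb dependency "
            "(pip install 'oepsc[nwb]'); use the hdf5 or csv layout instead"
        )
    if format == "hdf5":
        with h5py.File(path, "w") as f:
            d = f.create_dataset("sweeps", data=sweeps.sweeps)
            d.attrs["units"] = "pA"
            f.attrs["sample_rate_hz"] = sweeps.sample_rate
            f.attrs["stim_time_s"] = sweeps.stim_time
            f.attrs["condition"] = sweeps.condition
            f.attrs["drug"] = sweeps.drug if sweeps.drug is not None else ""
            f.attrs["cell_id"] = sweeps.cell_id
            f.attrs["inter_sweep_interval_s"] = sweeps.inter_sweep_interval
            f.attrs["holding_potential_mv"] = sweeps.holding_potential
            if sweeps.series_resistance is not None:
                f.create_dataset("series_resistance_mohm", data=sweeps.series_resistance)
        return
    # csv
    np.savetxt(path, sweeps.sweeps, delimiter=",", fmt="%.9g")
    meta = {
        "sample_rate_hz": sweeps.sample_rate,
        "stim_time_s": sweeps.stim_time,
        "condition": sweeps.condition,
        "drug": sweeps.drug,
        "cell_id": sweeps.cell_id,
        "inter_sweep_interval_s": sweeps.inter_sweep_interval,
        "holding_potential_mv": sweeps.holding_potential,
    }
    if sweeps.series_resistance is not None:
        meta["series_resistance_mohm"] = [float(v) for v in sweeps.series_resistance]
    _meta_path(path).write_text(json.dumps(meta, indent=1))


def load_sweeps(path, format: Optional[str] = None) -> SweepSet:
    """Read a :class:`SweepSet` written by :func:`save_sweeps`.

    ``format`` is inferred from the file suffix when omitted (.h5/.hdf5 → hdf5,
    .csv → csv).  Raises :class:`FormatError` naming the missing field when the
    file does not conform to the layout.
    """
    path = Path(path)
    if format is None:
        format = {".h5": "hdf5", ".hdf5": "hdf5", ".csv": "csv", ".nwb": "nwb"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise ParameterError(f"cannot infer format from suffix of {path.name!r}")
    if format not in _FORMATS:
        raise ParameterError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "nwb":
        raise FormatError(
            "NWB input requires the optional pynwb dependency (pip install 'oepsc[nwb]')"
        )
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            if "sweeps" not in f:
                raise FormatError(f"{path.name}: missing dataset 'sweeps'")
            for attr in ("sample_rate_hz", "stim_time_s"):
                if attr not in f.attrs:
                    raise FormatError(f"{path.name}: missing attribute {attr!r}")
            drug = str(f.attrs.get("drug", "")) or None
            rs = f["series_resistance_mohm"][:] if "series_resistance_mohm" in f else None
            return SweepSet(
                cell_id=str(f.attrs.get("cell_id", path.stem)),
                condition=str(f.attrs.get("condition", "custom")),
                sample_rate=float(f.attrs["sample_rate_hz"]),
                stim_time=float(f.attrs["stim_time_s"]),
                sweeps=f["sweeps"][:],
                drug=drug,
                series_resistance=rs,
                inter_sweep_interval=float(f.attrs.get("inter_sweep_interval_s", 30.0)),
                holding_potential=float(f.attrs.get("holding_potential_mv", -65.0)),
            )
    # csv
    meta_file = _meta_path(path)
    if not meta_file.exists():
        raise FormatError(f"{path.name}: missing sidecar header {meta_file.name}")
    meta = json.loads(meta_file.read_text())
    for key in ("sample_rate_hz", "stim_time_s"):
        if key not in meta:
            raise FormatError(f"{meta_file.name}: missing field {key!r}")
    try:
        data = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError as exc:  # ragged rows
        raise FormatError(f"{path.name}: malformed sweep matrix ({exc})") from exc
    rs = meta.get("series_resistance_mohm")
    return SweepSet(
        cell_id=str(meta.get("cell_id", path.stem)),
        condition=str(meta.get("condition", "custom")),
        sample_rate=float(meta["sample_rate_hz"]),
        stim_time=float(meta["stim_time_s"]),
        sweeps=data,
        drug=meta.get("drug"),
        series_resistance=None if rs is None else np.asarray(rs, dtype=float),
        inter_sweep_interval=float(meta.get("inter_sweep_interval_s", 30.0)),
        holding_potential=float(meta.get("holding_potential_mv", -65.0)),
    )


def _as_sweepset(
    sweeps: Sequence[Sequence[float]],
    sample_rate: float,
    stim_time: float,
    **kwargs,
) -> SweepSet:
    """Convenience constructor used by tests and the simulator."""
    kwargs.setdefault("cell_id", "cell0")
    kwargs.setdefault("condition", "baseline")
    return SweepSet(sample_rate=sample_rate, stim_time=stim_time, sweeps=np.asarray(sweeps), **kwargs)
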