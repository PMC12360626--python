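"""End-to-end orchestration: simulate/load → preprocess → detect → split → drug effects.

A :class:`PipelineConfig` is a flat, typed key-value document (YAML on disk).
Unknown keys are errors — detection thresholds like −50 vs −5.0 must never be
silently mistyped.  Every run writes its intermediates plus a manifest with
content hashes, the full parameter set, and the package version, so a rerun
with the same config and inputs reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from . import __version__
from .detect import DetectionSettings, detect_events, differentiate, events_to_frame
from .drugfx import effect_table, latency_effect_regression, summaries_to_frame, summarize_condition
from .errors import ParameterError, PipelineStageError
from .latency import build_histogram, fit_double_gaussian, label_events
from .preprocess import baseline_subtract_then_filter
from .sweeps import SweepSet, load_sweeps
from .synth import preset_cohort


@dataclasses.dataclass
class SimulateSection:
    receptor: str = "KOR"
    n_cells: int = 4
    n_sweeps: int = 20
    noise_sd: float = 8.0


@dataclasses.dataclass
class PreprocessSection:
    cutoff: float = 1000.0  # Hz
    omit_leading: Optional[int] = None  # None -> condition default (4 for drug washes)


@dataclasses.dataclass
class SplitSection:
    bin_width: float = 0.5  # ms
    range: Tuple[float, float] = (0.0, 10.0)
    min_count: int = 30


@dataclasses.dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "oepsc_run"
    inputs: Optional[List[str]] = None  # sweep-set files; alternative to simulate
    simulate: Optional[SimulateSection] = None
    detection: DetectionSettings = dataclasses.field(default_factory=DetectionSettings)
    preprocess: PreprocessSection = dataclasses.field(default_factory=PreprocessSection)
    split: SplitSection = dataclasses.field(default_factory=SplitSection)


_SECTION_TYPES = {
    "simulate": SimulateSection,
    "detection": DetectionSettings,
    "preprocess": PreprocessSection,
    "split": SplitSection,
}


def _build_section(cls, data: dict, name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ParameterError(f"unknown keys in section {name!r}: {sorted(unknown)}")
    if name == "split" and "range" in data:
        data = {**data, "range": tuple(data["range"])}
    if name == "detection" and "detection_window" in data:
        data = {**data, "detection_window": tuple(data["detection_window"])}
    return cls(**data)


def load_config(path) -> PipelineConfig:
    """Read a YAML pipeline config, rejecting unknown keys at every level."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    allowed = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise ParameterError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in raw.items():
        if key in _SECTION_TYPES:
            if value is None:
                value = {}
            kwargs[key] = _build_section(_SECTION_TYPES[key], dict(value), key)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and return the run manifest.

    Stages: acquire sweep sets (simulate a cohort or load files), preprocess,
    deconvolve, fit the latency split on pooled baseline events, classify,
    summarise per cell × condition, tabulate drug effects, and regress %
    reduction on onset latency when at least three cells carry a drug wash.
    Any stage failure aborts with the stage name.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- acquire -----------------------------------------------------------
    sweep_sets: List[SweepSet] = []
    try:
        if config.simulate is not None:
            sim = config.simulate
            cohort = preset_cohort(
                sim.n_cells,
                sim.receptor,
                seed=config.seed,
                n_sweeps=sim.n_sweeps,
                noise_sd=sim.noise_sd,
            )
            for cell in cohort:
                sweep_sets.extend([cell.baseline, cell.drug])
        elif config.inputs:
            for p in config.inputs:
                sweep_sets.append(load_sweeps(p))
        else:
            raise ParameterError("config must provide either 'simulate' or 'inputs'")
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("acquire", str(exc)) from exc

    # --- preprocess + detect ----------------------------------------------
    events_by_set = []
    try:
        for ss in sweep_sets:
            filtered = baseline_subtract_then_filter(ss, cutoff=config.preprocess.cutoff)
            events = detect_events(differentiate(filtered), config.detection, keep_capture=False)
            events_by_set.append(events)
    except Exception as exc:
        raise PipelineStageError("detect", str(exc)) from exc

    # --- latency split on pooled baseline events ---------------------------
    try:
        baseline_lat = [
            ev.latency
            for ss, evs in zip(sweep_sets, events_by_set)
            if ss.condition == "baseline"
            for ev in evs
        ]
        hist = build_histogram(baseline_lat, config.split.bin_width, config.split.range)
        model = fit_double_gaussian(hist, min_count=config.split.min_count)
        trough = model.trough
    except Exception as exc:
        raise PipelineStageError("split", str(exc)) from exc

    # --- classify + summarise ----------------------------------------------
    try:
        summaries = []
        all_events = []
        for ss, evs in zip(sweep_sets, events_by_set):
            label_events(evs, trough)
            all_events.extend(evs)
            summaries.append(
                summarize_condition(
                    ss, evs, trough,
                    omit_leading=config.preprocess.omit_leading,
                    cutoff=config.preprocess.cutoff,
                )
            )
        effects = effect_table(summaries)
    except Exception as exc:
        raise PipelineStageError("drugfx", str(exc)) from exc

    regression_text = "n < 3 cells with drug washes; regression not computed\n"
    if len(effects) >= 3:
        try:
            reg = latency_effect_regression(
                effects["onset_latency_baseline_ms"], effects["pct_reduction"]
            )
            regression_text = (
                f"slope_pct_per_ms = {reg.slope:.4f}\n"
                f"intercept_pct = {reg.intercept:.4f}\n"
                f"r_squared = {reg.r_squared:.4f}\n"
                f"p_value = {reg.p_value:.4g}\n"
                f"n = {reg.n}\n"
            )
        except Exception:
            pass  # degenerate cohorts (e.g. zero latency variance) simply skip the fit

    # --- write outputs ------------------------------------------------------
    outputs = {
        "events.csv": lambda p: events_to_frame(all_events).to_csv(p, index=False),
        "split_model.txt": lambda p: p.write_text(model.to_text()),
        "summaries.csv": lambda p: summaries_to_frame(summaries).to_csv(p, index=False),
        "effects.csv": lambda p: effects.to_csv(p, index=False),
        "regression.txt": lambda p: p.write_text(regression_text),
    }
    manifest: Dict[str, object] = {
        "version": __version__,
        "seed": config.seed,
        "trough_ms": trough,
        "n_sweep_sets": len(sweep_sets),
        "n_events": len(all_events),
        "detection_settings": dataclasses.asdict(config.detection),
        "files": {},
    }
    for name, writer in outputs.items():
        path = out_dir / name
        writer(path)
        manifest["files"][name] = _sha256(path)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
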