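"""End-to-end experiment orchestration.

Runs the in-silico analogue of the phantom study: for every requested scan
mode x breathing pattern x replicate, generate a surrogate trace, plan and
reconstruct the 4DCT, and evaluate image quality (CNR and the relative dose
proxy), dimensional accuracy and positional accuracy. Results land in a
deterministic, JSON-serialisable :class:`ComparisonReport` together with the
cross-mode ordering summaries. A separate pathway evaluates externally
supplied phase series (real scanner exports) with the same metric suite.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .acquisition import (
    AcquisitionConfig,
    ScanMode,
    check_data_sufficiency,
    dose_proxy,
    plan_scan,
    reconstruct_4dct,
)
from .errors import FourDCTError, InvalidParameterError
from .io import read_phase4dct, read_trace_csv, write_phase4dct, write_trace_csv
from .phantom import (
    AXIS_INDEX,
    MotionModel,
    PhantomSpec,
    analytic_target_volume,
    ground_truth_displacement,
)
from .qametrics import (
    CNRResult,
    ROISpec,
    SegmentationConfig,
    cnr,
    dimensional_report,
    dose_normalized_cnr,
    measure_structure,
    positional_report,
    roi_statistics,
    segment_target,
)
from .respsignal import (
    GatingConfig,
    detect_cycles,
    generate_irregular,
    generate_sinusoid,
    summarize_trace,
)

logger = logging.getLogger("fourdct")

__all__ = [
    "SignalParams",
    "ExperimentConfig",
    "ComparisonReport",
    "cell_seed",
    "run_phantom_experiment",
    "evaluate_external",
    "make_fixtures",
]

#: Study breathing patterns: normal (1 cm, 4 s), rapid (2 cm, 4 s) and
#: irregular (1 cm, 4 s, 15% cycle-to-cycle variability).
DEFAULT_PATTERNS = {
    "normal": dict(kind="sinusoid", amplitude_mm=10.0, period_s=4.0, irregularity_pct=0.0),
    "rapid": dict(kind="sinusoid", amplitude_mm=20.0, period_s=4.0, irregularity_pct=0.0),
    "irregular": dict(kind="irregular", amplitude_mm=10.0, period_s=4.0, irregularity_pct=15.0),
}


@dataclass(frozen=True)
class SignalParams:
    kind: str = "sinusoid"  # sinusoid | irregular
    amplitude_mm: float = 10.0
    period_s: float = 4.0
    irregularity_pct: float = 0.0
    duration_s: float = 30.0
    sample_rate_hz: float = 25.0


@dataclass
class ExperimentConfig:
    """Full experiment grid: sub-configs, patterns, modes, replicates, seeds."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    gating: GatingConfig = field(default_factory=GatingConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    modes: tuple[str, ...] = ("volume", "helical")
    patterns: tuple[str, ...] = ("normal", "rapid", "irregular")
    replicates: int = 1
    base_seed: int = 0
    duration_s: float = 30.0
    sample_rate_hz: float = 25.0
    motion_scale: float = 1.0
    acquisition_overrides: dict = field(default_factory=dict)
    roi_diameter_px: float = 20.0
    roi_offset_px: int = 30

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise InvalidParameterError("replicates must be >= 1")
        unknown = set(self.patterns) - set(DEFAULT_PATTERNS)
        if unknown:
            raise InvalidParameterError(f"unknown patterns: {sorted(unknown)}")

    def signal_params(self, pattern: str) -> SignalParams:
        base = DEFAULT_PATTERNS[pattern]
        return SignalParams(
            kind=base["kind"],
            amplitude_mm=base["amplitude_mm"],
            period_s=base["period_s"],
            irregularity_pct=base["irregularity_pct"],
            duration_s=self.duration_s,
            sample_rate_hz=self.sample_rate_hz,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        kwargs: dict = {}
        if "phantom" in d:
            kwargs["phantom"] = PhantomSpec(
                **{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in d["phantom"].items()
                }
            )
        if "gating" in d:
            kwargs["gating"] = GatingConfig(**d["gating"])
        if "segmentation" in d:
            kwargs["segmentation"] = SegmentationConfig(**d["segmentation"])
        if "acquisition" in d:
            kwargs["acquisition_overrides"] = dict(d["acquisition"])
        if "metrics" in d:
            for key in ("roi_diameter_px", "roi_offset_px"):
                if key in d["metrics"]:
                    kwargs[key] = d["metrics"][key]
        sig = d.get("signal", {})
        for src, dst in (("duration_s", "duration_s"), ("sample_rate_hz", "sample_rate_hz")):
            if src in sig:
                kwargs[dst] = sig[src]
        exp = d.get("experiment", {})
        for key in ("modes", "patterns"):
            if key in exp:
                kwargs[key] = tuple(exp[key])
        for key in ("replicates", "base_seed"):
            if key in exp:
                kwargs[key] = exp[key]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass(frozen=True)
class ComparisonReport:
    """Grid of per-cell metric blocks plus cross-mode summaries."""

    cells: dict
    summaries: dict
    config_echo: dict

    def to_dict(self) -> dict:
        return {
            "cells": self.cells,
            "summaries": self.summaries,
            "config": self.config_echo,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(_jsonable(self.to_dict()), indent=indent, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (ScanMode,)):
        return obj.value
    return obj


def cell_seed(base_seed: int, mode: str, pattern: str, replicate: int) -> int:
    """Stable per-cell seed: base + CRC32 of the cell key, kept below 2^31."""
    h = zlib.crc32(f"{mode}|{pattern}|{replicate}".encode())
    return int((base_seed + h) % (2**31))


def _generate_trace(params: SignalParams, seed: int):
    if params.kind == "irregular" or params.irregularity_pct > 0:
        return generate_irregular(
            params.amplitude_mm,
            params.period_s,
            params.irregularity_pct,
            params.duration_s,
            params.sample_rate_hz,
            seed=seed,
        )
    return generate_sinusoid(
        params.amplitude_mm, params.period_s, params.duration_s, params.sample_rate_hz
    )


def _voxel_index(spec: PhantomSpec, position_mm: np.ndarray) -> tuple[int, int, int]:
    return tuple(
        int(round((position_mm[a] - spec.origin_mm[a]) / spec.spacing_mm[a]))
        for a in range(3)
    )


def _phase_cnr(config: ExperimentConfig, phases, motion: MotionModel, dose_value: float):
    """CNR per phase with the target ROI tracking the known target position
    and the background ROI offset along +x, averaged into CNR_avg."""
    spec = config.phantom
    axis = AXIS_INDEX[spec.motion_axis]
    values = []
    for vol, label in zip(phases.phases, phases.phase_labels_pct):
        center = np.array(spec.target_center_mm, dtype=float)
        center[axis] += float(ground_truth_displacement(motion, label))
        cv = _voxel_index(spec, center)
        target = ROISpec(cv, diameter_px=config.roi_diameter_px)
        background = ROISpec(
            (cv[0] + config.roi_offset_px, cv[1], cv[2]),
            diameter_px=config.roi_diameter_px,
        )
        values.append(cnr(roi_statistics(vol, target, background)))
    values = np.asarray(values)
    avg = float(values.mean())
    return CNRResult(
        cnr_per_phase=values,
        cnr_avg=avg,
        dose_normalized_cnr=dose_normalized_cnr(avg, dose_value),
        dose_units="mAs_per_mm",
    )


def _run_cell(config: ExperimentConfig, mode: str, pattern: str, replicate: int) -> dict:
    seed = cell_seed(config.base_seed, mode, pattern, replicate)
    params = config.signal_params(pattern)
    trace = _generate_trace(params, seed)
    acq = AcquisitionConfig(
        mode=ScanMode(mode), seed=seed, **config.acquisition_overrides
    )
    spec = config.phantom
    motion = MotionModel(trace, scale=config.motion_scale, axis=spec.motion_axis)

    try:
        summary = summarize_trace(detect_cycles(trace))
        suff = check_data_sufficiency(acq, summary)
        summary_d = dataclasses.asdict(summary)
        suff_d = {
            "sufficient": suff.sufficient,
            "coverage_s": suff.coverage_s,
            "required_s": suff.required_s,
            "margin_s": suff.margin_s,
        }
    except FourDCTError:
        summary_d, suff_d = None, None

    plan = plan_scan(acq, spec, trace, config.gating)
    phases = reconstruct_4dct(plan, spec, motion, acq)
    dose = dose_proxy(plan, acq)
    dim = dimensional_report(phases, analytic_target_volume(spec), config.segmentation)
    pos = positional_report(phases, motion, trace, config.segmentation)
    cnr_res = _phase_cnr(config, phases, motion, dose.dose_proxy_mas_per_mm)

    return {
        "mode": mode,
        "pattern": pattern,
        "replicate": replicate,
        "seed": seed,
        "trace_summary": summary_d,
        "sufficiency": suff_d,
        "cnr": {
            "per_phase": cnr_res.cnr_per_phase,
            "avg": cnr_res.cnr_avg,
            "dose_normalized": cnr_res.dose_normalized_cnr,
            "dose_units": cnr_res.dose_units,
        },
        "dimensional": {
            "phase_labels_pct": dim.phase_labels_pct,
            "per_phase_volume_cm3": dim.per_phase_volume_cm3,
            "reference_volume_cm3": dim.reference_volume_cm3,
            "mean_abs_volume_diff_cm3": dim.mean_abs_volume_diff_cm3,
            "cov_volume": dim.cov_volume,
            "cov_integrated_hu": dim.cov_integrated_hu,
        },
        "positional": {
            "phase_labels_pct": pos.phase_labels_pct,
            "per_phase_centroid_mm": pos.per_phase_centroid_mm,
            "per_phase_truth_mm": pos.per_phase_truth_mm,
            "per_phase_abs_error_mm": pos.per_phase_abs_error_mm,
            "mean_abs_error_mm": pos.mean_abs_error_mm,
            "surrogate_correlation": pos.surrogate_correlation,
        },
        "dose": {
            "proxy_mas_per_mm": dose.dose_proxy_mas_per_mm,
            "scan_time_s": dose.scan_time_s,
        },
    }


def _summaries(config: ExperimentConfig, cells: dict) -> dict:
    def cell_values(mode, pattern, path):
        vals = []
        for rep in range(config.replicates):
            cell = cells.get(f"{mode}:{pattern}:{rep}")
            if cell is None:
                continue
            v = cell
            for key in path:
                v = v[key]
            vals.append(v)
        return vals

    per_condition = {}
    for mode in config.modes:
        for pattern in config.patterns:
            key = f"{mode}:{pattern}"
            entries = {
                "mean_abs_volume_diff_cm3": ("dimensional", "mean_abs_volume_diff_cm3"),
                "cov_volume": ("dimensional", "cov_volume"),
                "mean_abs_error_mm": ("positional", "mean_abs_error_mm"),
                "surrogate_correlation": ("positional", "surrogate_correlation"),
                "cnr_avg": ("cnr", "avg"),
                "dose_proxy_mas_per_mm": ("dose", "proxy_mas_per_mm"),
            }
            cond = {}
            for name, path in entries.items():
                vals = cell_values(mode, pattern, path)
                cond[name] = float(np.mean(vals)) if vals else None
            per_condition[key] = cond

    summaries = {"per_condition": per_condition, "orderings": {}, "relative_diff_pct": {}}
    pc = per_condition

    def get(mode, pattern, name):
        return pc.get(f"{mode}:{pattern}", {}).get(name)

    both_modes = {"volume", "helical"} <= set(config.modes)
    if both_modes:
        orderings = {}
        if {"normal", "rapid"} <= set(config.patterns):
            orderings["rapid_gt_normal_volume_error"] = {
                mode: get(mode, "rapid", "mean_abs_volume_diff_cm3")
                > get(mode, "normal", "mean_abs_volume_diff_cm3")
                for mode in ("volume", "helical")
            }
            orderings["helical_ge_volume_dimensional_rapid"] = (
                get("helical", "rapid", "mean_abs_volume_diff_cm3")
                >= get("volume", "rapid", "mean_abs_volume_diff_cm3")
            )
        orderings["helical_le_volume_positional"] = {
            pattern: get("helical", pattern, "mean_abs_error_mm")
            <= get("volume", pattern, "mean_abs_error_mm")
            for pattern in config.patterns
        }
        orderings["dose_helical_gt_volume"] = all(
            get("helical", p, "dose_proxy_mas_per_mm")
            > get("volume", p, "dose_proxy_mas_per_mm")
            for p in config.patterns
        )
        summaries["orderings"] = orderings

        cnr_v = np.mean([get("volume", p, "cnr_avg") for p in config.patterns])
        cnr_h = np.mean([get("helical", p, "cnr_avg") for p in config.patterns])
        dose_v = np.mean([get("volume", p, "dose_proxy_mas_per_mm") for p in config.patterns])
        dose_h = np.mean([get("helical", p, "dose_proxy_mas_per_mm") for p in config.patterns])
        dn_v, dn_h = cnr_v / dose_v, cnr_h / dose_h
        summaries["relative_diff_pct"] = {
            "cnr_helical_vs_volume": int(round(100 * (cnr_h - cnr_v) / cnr_v)),
            "dose_normalized_cnr_volume_vs_helical": int(round(100 * (dn_v - dn_h) / dn_h)),
        }
    return summaries


def run_phantom_experiment(config: ExperimentConfig) -> ComparisonReport:
    """Run the full mode x pattern x replicate grid.

    Deterministic given the config (per-cell seeds derive from the base seed
    and the cell key). A failing cell is logged and marked missing rather than
    aborting the whole experiment.
    """
    cells: dict = {}
    failures = {}
    for mode in config.modes:
        for pattern in config.patterns:
            for rep in range(config.replicates):
                key = f"{mode}:{pattern}:{rep}"
                try:
                    cells[key] = _run_cell(config, mode, pattern, rep)
                    logger.info("cell %s done", key)
                except FourDCTError as exc:
                    logger.error("cell %s failed: %s", key, exc)
                    failures[key] = str(exc)
    summaries = _summaries(config, cells)
    if failures:
        summaries["failed_cells"] = failures
    echo = {
        "modes": list(config.modes),
        "patterns": list(config.patterns),
        "replicates": config.replicates,
        "base_seed": config.base_seed,
        "grid_shape": list(config.phantom.grid_shape),
        "spacing_mm": list(config.phantom.spacing_mm),
        "acquisition_overrides": dict(config.acquisition_overrides),
    }
    return ComparisonReport(cells=cells, summaries=summaries, config_echo=echo)


def evaluate_external(
    phase_dir,
    trace_csv,
    segmentation: SegmentationConfig | None = None,
    reference_volume_cm3: float | None = None,
    ctdi_vol_mgy: float | None = None,
    motion_scale: float = 1.0,
    motion_axis: str = "z",
    roi_diameter_px: float = 20.0,
    roi_offset_px: int = 30,
) -> dict:
    """Metric-only evaluation of an externally supplied phase series.

    Reads the phase volumes (NIfTI layout with sidecar, or DICOM series
    directories) and the surrogate trace CSV, then runs segmentation-based
    dimensional/positional reports and ROI-based CNR. No simulation happens
    here; the reference volume and a console CTDIvol are caller-supplied when
    available (the reference defaults to the across-phase mean volume).
    """
    seg = segmentation or SegmentationConfig()
    phases = read_phase4dct(phase_dir)
    trace = read_trace_csv(trace_csv)
    motion = MotionModel(trace, scale=motion_scale, axis=motion_axis)

    vols = [
        measure_structure(v, segment_target(v, seg), threshold_hu=seg.threshold_hu)
        for v in phases.phases
    ]
    if reference_volume_cm3 is None:
        reference_volume_cm3 = float(np.mean([m.volume_cm3 for m in vols]))
    dim = dimensional_report(phases, reference_volume_cm3, seg)
    pos = positional_report(phases, motion, trace, seg)

    # target ROI at the phase-0 segmentation centroid; background offset +x
    vol0 = phases.phases[0]
    c0 = vols[0].centroid_mm
    cv = tuple(
        int(round((c0[a] - vol0.origin_mm[a]) / vol0.spacing_mm[a])) for a in range(3)
    )
    cnr_block = None
    try:
        per_phase = []
        for vol in phases.phases:
            stats = roi_statistics(
                vol,
                ROISpec(cv, diameter_px=roi_diameter_px),
                ROISpec((cv[0] + roi_offset_px, cv[1], cv[2]), diameter_px=roi_diameter_px),
            )
            per_phase.append(cnr(stats))
        avg = float(np.mean(per_phase))
        cnr_block = {
            "per_phase": per_phase,
            "avg": avg,
            "dose_normalized": (
                dose_normalized_cnr(avg, ctdi_vol_mgy) if ctdi_vol_mgy else None
            ),
            "dose_units": "mGy" if ctdi_vol_mgy else None,
        }
    except FourDCTError as exc:
        logger.warning("CNR skipped: %s", exc)

    unassigned = int(np.sum(~_assignment_flags(trace, phases)))
    fragment = {
        "dimensional": {
            "per_phase_volume_cm3": dim.per_phase_volume_cm3,
            "reference_volume_cm3": dim.reference_volume_cm3,
            "mean_abs_volume_diff_cm3": dim.mean_abs_volume_diff_cm3,
            "cov_volume": dim.cov_volume,
            "cov_integrated_hu": dim.cov_integrated_hu,
        },
        "positional": {
            "per_phase_centroid_mm": pos.per_phase_centroid_mm,
            "mean_abs_error_mm": pos.mean_abs_error_mm,
            "surrogate_correlation": pos.surrogate_correlation,
        },
        "cnr": cnr_block,
        "ctdi_vol_mgy": ctdi_vol_mgy,
        "n_unassigned_samples": unassigned,
    }
    return _jsonable(fragment)


def _assignment_flags(trace, phases) -> np.ndarray:
    from .respsignal import assign_phases

    try:
        return assign_phases(trace, phases.gating).assigned
    except FourDCTError:
        return np.zeros(trace.times.shape, dtype=bool)


def make_fixtures(out_dir, seed: int = 0) -> dict:
    """Write a small offline test-fixture set and return its manifest.

    Contents: a normal and an irregular surrogate trace CSV, a YAML config
    for a coarse (4 mm) phantom, and a 10-phase synthetic volume-mode series
    with sidecar, suitable for :func:`evaluate_external`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = ExperimentConfig(
        phantom=PhantomSpec(grid_shape=(32, 32, 30), spacing_mm=(4.0, 4.0, 4.0)),
        modes=("volume",),
        patterns=("normal",),
        base_seed=seed,
        acquisition_overrides={"noise_sd_hu": 5.0},
        roi_diameter_px=4.0,
        roi_offset_px=10,
    )
    params = config.signal_params("normal")
    trace = _generate_trace(params, seed)
    write_trace_csv(trace, out / "trace_normal.csv")
    irr = _generate_trace(config.signal_params("irregular"), seed)
    write_trace_csv(irr, out / "trace_irregular.csv")

    yaml_text = yaml.safe_dump(
        {
            "phantom": {"grid_shape": [32, 32, 30], "spacing_mm": [4.0, 4.0, 4.0]},
            "acquisition": {"noise_sd_hu": 5.0},
            "experiment": {"modes": ["volume"], "patterns": ["normal"], "base_seed": seed},
            "signal": {"duration_s": 30.0, "sample_rate_hz": 25.0},
        },
        sort_keys=True,
    )
    (out / "config.yaml").write_text(yaml_text)

    acq = AcquisitionConfig(mode=ScanMode.VOLUME, seed=seed, noise_sd_hu=5.0)
    spec = config.phantom
    motion = MotionModel(trace, axis=spec.motion_axis)
    plan = plan_scan(acq, spec, trace, config.gating)
    phases = reconstruct_4dct(plan, spec, motion, acq)
    write_phase4dct(phases, out / "phases")

    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "seed": seed,
        "files": {
            str(p.relative_to(out)): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in files
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
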