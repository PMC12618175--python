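"""File formats: surrogate trace CSV, phase-sorted NIfTI series with JSON
sidecar, and DICOM series directories.

Trace CSV is two columns ``time_s,amplitude_mm`` with a header (the layout of
a typical surrogate-system export); the reader tolerates CRLF. A 4DCT series
is one NIfTI file per phase (``phase_00.nii.gz`` ... ``phase_90.nii.gz``)
plus ``sidecar.json`` carrying phase labels, per-slice reconstruction times,
an acquisition-config echo and the noise seed. The reader also accepts one
DICOM series directory per phase (pixel data and spacing only).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .acquisition import Phase4DCT, ScanMode
from .errors import FourDCTError, InvalidParameterError
from .phantom import ImageVolume
from .respsignal import GatingConfig, RespiratoryTrace

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "write_phase4dct",
    "read_phase4dct",
]


def read_trace_csv(path) -> RespiratoryTrace:
    """Read a two-column ``time_s,amplitude_mm`` trace (header required)."""
    df = pd.read_csv(path)
    missing = {"time_s", "amplitude_mm"} - set(df.columns)
    if missing:
        raise InvalidParameterError(f"{path}: missing columns {sorted(missing)}")
    times = df["time_s"].to_numpy(dtype=float)
    if times.size < 2:
        raise InvalidParameterError(f"{path}: trace needs at least 2 samples")
    rate = 1.0 / float(np.median(np.diff(times)))
    return RespiratoryTrace(times, df["amplitude_mm"].to_numpy(dtype=float), rate)


def write_trace_csv(trace: RespiratoryTrace, path) -> None:
    """Write the same dialect the reader consumes (full float precision)."""
    pd.DataFrame({"time_s": trace.times, "amplitude_mm": trace.amplitude}).to_csv(
        path, index=False, float_format="%.9g"
    )


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_phase4dct(phases: Phase4DCT, out_dir, config_echo: dict | None = None) -> list[Path]:
    """Write one NIfTI per phase plus the JSON sidecar; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for label, vol in zip(phases.phase_labels_pct, phases.phases):
        p = out / f"phase_{int(round(label)):02d}.nii.gz"
        img = nib.Nifti1Image(
            np.asarray(vol.voxels, dtype=np.float64), _affine(vol.spacing_mm, vol.origin_mm)
        )
        nib.save(img, p)
        paths.append(p)
    sidecar = {
        "phase_labels_pct": [float(x) for x in phases.phase_labels_pct],
        "per_slice_times_s": np.asarray(phases.per_slice_times).tolist(),
        "gating": {
            "trigger_mode": phases.gating.trigger_mode.value,
            "trigger_level_fraction": phases.gating.trigger_level_fraction,
            "n_phase_bins": phases.gating.n_phase_bins,
        },
        "mode": phases.mode.value,
        "seed": phases.seed,
        "config": config_echo or {},
    }
    sp = out / "sidecar.json"
    sp.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    paths.append(sp)
    return paths


def _read_nifti_phase(path: Path) -> ImageVolume:
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(abs(aff[i, i])) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return ImageVolume(np.asarray(img.dataobj, dtype=float), spacing, origin)


def _read_dicom_phase(series_dir: Path) -> ImageVolume:
    import pydicom

    files = sorted(series_dir.glob("*.dcm"))
    if not files:
        raise FourDCTError(f"no DICOM files in {series_dir}")
    datasets = [pydicom.dcmread(str(f)) for f in files]
    datasets.sort(key=lambda d: float(getattr(d, "ImagePositionPatient", [0, 0, 0])[2]))
    slices = [d.pixel_array.astype(float) * float(getattr(d, "RescaleSlope", 1.0))
              + float(getattr(d, "RescaleIntercept", 0.0)) for d in datasets]
    vox = np.stack(slices, axis=-1).transpose(1, 0, 2)  # rows/cols -> (x, y, z)
    d0 = datasets[0]
    ps = [float(x) for x in d0.PixelSpacing]
    if len(datasets) > 1:
        dz = float(datasets[1].ImagePositionPatient[2]) - float(d0.ImagePositionPatient[2])
    else:
        dz = float(getattr(d0, "SliceThickness", 1.0))
    origin = tuple(float(x) for x in getattr(d0, "ImagePositionPatient", (0.0, 0.0, 0.0)))
    return ImageVolume(vox, (ps[1], ps[0], abs(dz)), origin)


def read_phase4dct(in_dir) -> Phase4DCT:
    """Read a phase series written by :func:`write_phase4dct`, or a directory
    of per-phase DICOM series subdirectories (``phase_XX/``)."""
    root = Path(in_dir)
    sidecar_path = root / "sidecar.json"
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    labels = sidecar.get("phase_labels_pct")
    if labels is None:
        nii = sorted(root.glob("phase_*.nii*"))
        dirs = sorted(d for d in root.glob("phase_*") if d.is_dir())
        names = nii or dirs
        labels = [float(p.name.split("_")[1].split(".")[0]) for p in names]
    volumes = []
    for label in labels:
        stem = f"phase_{int(round(label)):02d}"
        nii = root / f"{stem}.nii.gz"
        nii_alt = root / f"{stem}.nii"
        sub = root / stem
        if nii.exists() or nii_alt.exists():
            volumes.append(_read_nifti_phase(nii if nii.exists() else nii_alt))
        elif sub.is_dir():
            volumes.append(_read_dicom_phase(sub))
        else:
            raise FourDCTError(f"missing phase volume: {stem} under {root}")
    g = sidecar.get("gating", {})
    gating = GatingConfig(
        trigger_mode=g.get("trigger_mode", "peak_in_peak"),
        trigger_level_fraction=g.get("trigger_level_fraction", 0.8),
        n_phase_bins=g.get("n_phase_bins", len(labels)),
    )
    times = sidecar.get("per_slice_times_s")
    per_slice = (
        np.asarray(times)
        if times is not None
        else np.zeros((volumes[0].voxels.shape[2], len(labels)))
    )
    return Phase4DCT(
        phases=volumes,
        phase_labels_pct=np.asarray(labels, dtype=float),
        per_slice_times=per_slice,
        gating=gating,
        mode=ScanMode(sidecar.get("mode", "volume")),
        seed=int(sidecar.get("seed", 0)),
    )
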