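"""Voxelised digital motion phantom.

A thorax-like block of low-density material containing a 3 cm spherical
target (and, optionally, a thin sawtooth plate for qualitative motion-artifact
visualisation) that can be rendered at any rigid displacement along a chosen
motion axis. The renderer is the simulator's stand-in for the physical
phantom-plus-scanner: it produces HU volumes directly in object space.

By default each voxel takes the HU of the material at its centre (a sharp
reconstruction kernel). This keeps fixed-threshold segmentation unbiased: a
-200 HU criterion sits at 75.8% of the default target/background contrast,
and any edge model that spreads the transition over a finite width pulls the
threshold surface inside the true sphere by ~0.26 x that width (a 4-5%
volume deficit for a voxel-wide box average). With centre sampling the
threshold surface coincides with the geometric surface for any threshold
strictly between the two materials, which is also what the physical
experiment verified for its -200 HU criterion. Set ``supersample > 1`` for a
box-averaged partial-volume render instead (per-axis supersampling).

Coordinates are in millimetres, voxel-center aligned, axis order (x, y, z)
with z the couch (superior-inferior) axis. The default grid is centred on the
origin so the resting target centre is (0, 0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError, OutOfBoundsError
from .respsignal import RespiratoryTrace, detect_cycles, summarize_trace

AXIS_INDEX = {"x": 0, "y": 1, "z": 2}

HU_MIN, HU_MAX = -1024.0, 3071.0

__all__ = [
    "AXIS_INDEX",
    "SawtoothSpec",
    "PhantomSpec",
    "ImageVolume",
    "MotionModel",
    "render_volume",
    "render_slab",
    "ground_truth_displacement",
    "analytic_target_volume",
]


@dataclass(frozen=True)
class SawtoothSpec:
    """Thin toothed plate, rendered only for qualitative artifact display."""

    tooth_pitch_mm: float = 10.0
    tooth_height_mm: float = 15.0
    thickness_mm: float = 1.2
    material_hu: float = -90.0  # polypropylene-like
    y_offset_mm: float = 35.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric and material description of the moving phantom."""

    grid_shape: tuple[int, int, int] = (128, 128, 120)
    spacing_mm: tuple[float, float, float] = (0.976, 0.976, 1.0)
    background_hu: float = -700.0
    target_hu: float = -40.0
    target_diameter_mm: float = 30.0
    target_center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    motion_axis: str = "z"
    sawtooth: SawtoothSpec | None = None
    supersample: int = 1

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.grid_shape):
            raise InvalidParameterError("grid_shape entries must be >= 1")
        if any(s <= 0 for s in self.spacing_mm):
            raise InvalidParameterError("spacing must be positive")
        if self.target_diameter_mm < 0:
            raise InvalidParameterError("target diameter must be non-negative")
        if self.target_hu <= self.background_hu:
            raise InvalidParameterError("target must be denser than background")
        if self.motion_axis not in AXIS_INDEX:
            raise InvalidParameterError("motion_axis must be one of x, y, z")
        if self.supersample < 1:
            raise InvalidParameterError("supersample must be >= 1")

    @property
    def origin_mm(self) -> tuple[float, float, float]:
        """Position of voxel (0, 0, 0) centre; grid centred on (0, 0, 0)."""
        return tuple(
            -(n - 1) / 2.0 * s for n, s in zip(self.grid_shape, self.spacing_mm)
        )

    def axis_coords(self, axis: int, indices: np.ndarray | None = None) -> np.ndarray:
        n = self.grid_shape[axis]
        idx = np.arange(n) if indices is None else np.asarray(indices)
        return self.origin_mm[axis] + idx * self.spacing_mm[axis]


@dataclass(frozen=True)
class ImageVolume:
    """A reconstructed (or rendered) HU volume with its geometry."""

    voxels: np.ndarray  # (nx, ny, nz)
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise InvalidParameterError("spacing must be positive")
        if not np.all(np.isfinite(self.voxels)):
            raise InvalidParameterError("voxel values must be finite")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin_mm[axis] + np.arange(self.voxels.shape[axis]) * self.spacing_mm[axis]


class MotionModel:
    """Maps surrogate amplitude to target displacement along the motion axis.

    ``scale`` is millimetres of target motion per millimetre of surrogate
    amplitude (1 for the phantom, where the surrogate *is* the motion input).
    """

    def __init__(self, trace: RespiratoryTrace, scale: float = 1.0, axis: str = "z"):
        if axis not in AXIS_INDEX:
            raise InvalidParameterError("axis must be one of x, y, z")
        self.trace = trace
        self.scale = float(scale)
        self.axis = axis
        self._amplitude_mm: float | None = None

    def displacement(self, t) -> np.ndarray:
        """Displacement (mm) at time(s) t, edge-clamped interpolation."""
        return self.trace.interp(t) * self.scale

    @property
    def amplitude_mm(self) -> float:
        """Zero-to-peak displacement amplitude of the driving waveform."""
        if self._amplitude_mm is None:
            if np.ptp(self.trace.amplitude) == 0:
                self._amplitude_mm = 0.0
            else:
                summary = summarize_trace(detect_cycles(self.trace))
                self._amplitude_mm = summary.mean_amplitude * self.scale
        return self._amplitude_mm


def ground_truth_displacement(motion: MotionModel, phase_pct) -> np.ndarray:
    """Ideal-waveform displacement at a nominal phase.

    With the cosine convention the nominal phase time is t = (p/100)*T after
    a peak, so the displacement is A*cos(2*pi*p/100) (A zero-to-peak).
    """
    p = np.asarray(phase_pct, dtype=float)
    if np.any(p < 0) or np.any(p >= 100):
        raise InvalidParameterError("phase_pct must lie in [0, 100)")
    return motion.amplitude_mm * np.cos(2 * np.pi * p / 100.0)


def analytic_target_volume(spec: PhantomSpec) -> float:
    """Closed-form sphere volume in cm^3: (4/3)*pi*(d/2)^3."""
    r_mm = spec.target_diameter_mm / 2.0
    return float(4.0 / 3.0 * np.pi * r_mm**3 / 1000.0)


def _sphere_occupancy(
    spec: PhantomSpec,
    center: np.ndarray,
    z_sel: np.ndarray,
) -> np.ndarray:
    """Fractional sphere occupancy per voxel for the selected z slices.

    Voxels fully inside/outside (versus the voxel half-diagonal) are filled
    directly; boundary voxels are supersampled ``supersample``^3 times.
    """
    nx, ny, _ = spec.grid_shape
    sx, sy, sz = spec.spacing_mm
    r = spec.target_diameter_mm / 2.0
    xc = spec.axis_coords(0) - center[0]
    yc = spec.axis_coords(1) - center[1]
    zc = spec.axis_coords(2, z_sel) - center[2]
    half_diag = 0.5 * float(np.sqrt(sx**2 + sy**2 + sz**2))

    d2 = (
        (xc**2)[:, None, None]
        + (yc**2)[None, :, None]
        + (zc**2)[None, None, :]
    )
    frac = np.zeros((nx, ny, z_sel.size))
    inside = d2 <= max(r - half_diag, 0.0) ** 2
    frac[inside] = 1.0
    boundary = (~inside) & (d2 < (r + half_diag) ** 2)
    if boundary.any():
        bi, bj, bk = np.nonzero(boundary)
        m = spec.supersample
        off = (np.arange(m) - (m - 1) / 2.0) / m
        ox = off * sx
        oy = off * sy
        oz = off * sz
        px = xc[bi][:, None, None, None] + ox[None, :, None, None]
        py = yc[bj][:, None, None, None] + oy[None, None, :, None]
        pz = zc[bk][:, None, None, None] + oz[None, None, None, :]
        sub = (px**2 + py**2 + pz**2) <= r**2
        frac[bi, bj, bk] = sub.reshape(bi.size, -1).mean(axis=1)
    return frac


def _add_sawtooth(
    spec: PhantomSpec,
    voxels: np.ndarray,
    displacement_mm: float,
    z_sel: np.ndarray,
) -> None:
    """Overlay the sawtooth plate (moves rigidly with the target)."""
    saw = spec.sawtooth
    assert saw is not None
    axis = AXIS_INDEX[spec.motion_axis]
    center = np.array(spec.target_center_mm, dtype=float)
    center[axis] += displacement_mm
    xc = spec.axis_coords(0) - center[0]
    yc = spec.axis_coords(1) - (center[1] + saw.y_offset_mm)
    zc = spec.axis_coords(2, z_sel) - center[2]
    # plate: |y| <= t/2, x in [-h/2, -h/2 + h * tri(z)], teeth repeat along z
    m = spec.supersample
    off = (np.arange(m) - (m - 1) / 2.0) / m
    y_in = np.zeros(yc.size)
    for i, y in enumerate(yc):
        pts = y + off * spec.spacing_mm[1]
        y_in[i] = np.mean(np.abs(pts) <= saw.thickness_mm / 2.0)
    if not np.any(y_in > 0):
        return
    tooth = np.mod(zc, saw.tooth_pitch_mm) / saw.tooth_pitch_mm  # 0..1 ramp
    x_edge = -saw.tooth_height_mm / 2.0 + saw.tooth_height_mm * tooth
    x_in = (xc[:, None] >= -saw.tooth_height_mm / 2.0) & (xc[:, None] <= x_edge[None, :])
    occ = x_in[:, None, :] * y_in[None, :, None]
    voxels += occ * (saw.material_hu - spec.background_hu)


def render_slab(
    spec: PhantomSpec, displacement_mm: float, z_indices: np.ndarray | None = None
) -> np.ndarray:
    """Render selected z-slices of the phantom displaced along its motion axis.

    Returns an (nx, ny, len(z_indices)) HU array. Raises
    :class:`OutOfBoundsError` if the displaced sphere would leave the grid.
    """
    nx, ny, nz = spec.grid_shape
    z_sel = np.arange(nz) if z_indices is None else np.atleast_1d(np.asarray(z_indices))
    axis = AXIS_INDEX[spec.motion_axis]
    center = np.array(spec.target_center_mm, dtype=float)
    center[axis] += float(displacement_mm)
    r = spec.target_diameter_mm / 2.0
    for a in range(3):
        lo = spec.origin_mm[a] - spec.spacing_mm[a] / 2.0
        hi = lo + spec.grid_shape[a] * spec.spacing_mm[a]
        if center[a] - r < lo - 1e-9 or center[a] + r > hi + 1e-9:
            raise OutOfBoundsError(
                f"target (centre {center[a]:.1f} mm, radius {r:.1f} mm) leaves the "
                f"grid along axis {a}"
            )
    frac = _sphere_occupancy(spec, center, z_sel)
    voxels = spec.background_hu + frac * (spec.target_hu - spec.background_hu)
    if spec.sawtooth is not None:
        _add_sawtooth(spec, voxels, float(displacement_mm), z_sel)
    return np.clip(voxels, HU_MIN, HU_MAX)


def render_volume(spec: PhantomSpec, displacement_mm: float) -> ImageVolume:
    """Render the full phantom volume at a given displacement."""
    return ImageVolume(
        voxels=render_slab(spec, displacement_mm),
        spacing_mm=spec.spacing_mm,
        origin_mm=spec.origin_mm,
    )
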