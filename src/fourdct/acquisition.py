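"""4DCT image-formation simulator for volume (cine) and helical scan modes.

The simulator works in the rendered-object domain: for every phase bin it
chooses a reconstruction time from the surrogate signal, temporally averages
phantom renders across the reconstruction data window (velocity-dependent
blur), stitches slices/slabs according to the acquisition geometry, and adds
stationary Gaussian HU noise. No projection-domain physics is modelled — the
metric suite operates on reconstructed volumes, so the object-domain analogue
is sufficient and keeps every mode-specific timing effect explicit.

Mode asymmetries (these are the levers that let the cine-versus-helical
orderings emerge; see docs/methods.md for the rationale):

* Cine (volume) mode stores a finite stack of images per couch position, one
  per ``cine_interval_s``; retrospective sorting can only pick the
  nearest-phase member of that stack, so the whole slab carries a common,
  coherent phase-timing error (a rigid shift of the target: positional error,
  no shape change).
* Helical raw data allow reconstruction centred at an arbitrary time, so each
  slice hits its nominal phase to surrogate-sampling precision — but the
  reconstruction window of slice z is tied to the gantry angle at which the
  spiral passes z, giving each slice an extra start offset
  ``((z - z0)/couch_speed mod rotation_time) - rotation_time/2``. Under fast
  motion adjacent slices therefore sample visibly different displacements:
  the target shears/elongates (dimensional error) while the per-slice errors
  largely cancel in the centre of mass (positional accuracy).

The reconstruction data window defaults to a half rotation (half-scan
reconstruction) starting at the selected phase time; a centred full-rotation
window is available via configuration.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    InvalidParameterError,
    ModeError,
    PlanError,
    ReconstructionError,
)
from .phantom import AXIS_INDEX, ImageVolume, MotionModel, PhantomSpec, render_slab
from .respsignal import (
    GatingConfig,
    PhaseAssignment,
    RespiratoryTrace,
    TraceSummary,
    assign_phases,
    detect_cycles,
    phase_from_triggers,
    summarize_trace,
)
from .errors import InsufficientCyclesError

FALLBACK_PERIOD_S = 4.0  # synthetic trigger period for motionless traces

__all__ = [
    "ScanMode",
    "AcquisitionConfig",
    "SufficiencyReport",
    "ScanPlan",
    "Phase4DCT",
    "DoseRecord",
    "couch_speed",
    "check_data_sufficiency",
    "plan_scan",
    "reconstruct_4dct",
    "dose_proxy",
]


class ScanMode(str, enum.Enum):
    VOLUME = "volume"
    HELICAL = "helical"


_DEFAULT_COLLIMATION = {ScanMode.VOLUME: 140.0, ScanMode.HELICAL: 80.0}


@dataclass(frozen=True)
class AcquisitionConfig:
    """Scanner-side configuration for one 4DCT acquisition.

    Defaults mirror a wide-detector clinical protocol: 0.5 s rotation,
    100 mA tube current, 140 mm collimation in volume mode and 80 mm with
    pitch 0.073 in helical mode. ``noise_sd_hu`` is the additive HU noise SD
    inside the object; ``cine_interval_s`` is the spacing of the cine image
    stack (volume mode only, defaults to one rotation time).
    """

    mode: ScanMode = ScanMode.VOLUME
    collimation_mm: float | None = None
    pitch: float = 0.073
    rotation_time_s: float = 0.5
    tube_current_ma: float = 100.0
    noise_sd_hu: float = 11.0
    blur_subsamples: int = 5
    blur_window: str = "half_rotation"  # or "full_rotation"
    blur_alignment: str = "forward"  # or "centered"
    cine_interval_s: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", ScanMode(self.mode))
        if self.collimation_mm is None:
            object.__setattr__(self, "collimation_mm", _DEFAULT_COLLIMATION[self.mode])
        if self.collimation_mm <= 0 or self.rotation_time_s <= 0 or self.tube_current_ma <= 0:
            raise InvalidParameterError(
                "collimation, rotation time and tube current must be positive"
            )
        if self.mode is ScanMode.HELICAL and self.pitch <= 0:
            raise InvalidParameterError("pitch must be positive in helical mode")
        if self.blur_subsamples < 1:
            raise InvalidParameterError("blur_subsamples must be >= 1")
        if self.blur_window not in ("half_rotation", "full_rotation"):
            raise InvalidParameterError("blur_window must be half_rotation or full_rotation")
        if self.blur_alignment not in ("forward", "centered"):
            raise InvalidParameterError("blur_alignment must be forward or centered")
        if self.noise_sd_hu < 0:
            raise InvalidParameterError("noise_sd_hu must be non-negative")
        if self.cine_interval_s is None:
            object.__setattr__(self, "cine_interval_s", self.rotation_time_s)
        if self.cine_interval_s <= 0:
            raise InvalidParameterError("cine_interval_s must be positive")

    @property
    def blur_window_s(self) -> float:
        w = self.rotation_time_s
        return w / 2.0 if self.blur_window == "half_rotation" else w


@dataclass(frozen=True)
class SufficiencyReport:
    """Whether per-slice temporal coverage spans one breathing cycle."""

    mode: ScanMode
    sufficient: bool
    coverage_s: float
    required_s: float

    @property
    def margin_s(self) -> float:
        return self.coverage_s - self.required_s


@dataclass(frozen=True)
class ScanPlan:
    """Timing plan: per-slice acquisition windows and per-phase recon times."""

    mode: ScanMode
    slice_z_mm: np.ndarray  # (n_slices,)
    acquisition_windows: np.ndarray  # (n_slices, 2) seconds
    per_phase_times: np.ndarray  # (n_slices, n_bins) seconds
    window_offsets_s: np.ndarray  # (n_slices,) helical gantry-alignment offsets
    couch_position_index: np.ndarray  # (n_slices,) int; 0 for helical
    phase_labels_pct: np.ndarray  # (n_bins,)
    n_positions: int
    dwell_s: float
    scan_time_s: float
    couch_speed_mm_s: float | None
    mean_period_s: float
    t_start: float
    gating: GatingConfig
    assignment: PhaseAssignment


@dataclass(frozen=True)
class Phase4DCT:
    """Ten (by default) phase-sorted volumes plus acquisition-time metadata."""

    phases: list[ImageVolume]
    phase_labels_pct: np.ndarray
    per_slice_times: np.ndarray  # (n_slices, n_bins)
    gating: GatingConfig
    mode: ScanMode
    seed: int

    def __post_init__(self) -> None:
        shapes = {v.voxels.shape for v in self.phases}
        if len(shapes) != 1:
            raise InvalidParameterError("all phase volumes must share one shape")
        if np.any(np.diff(self.phase_labels_pct) <= 0):
            raise InvalidParameterError("phase labels must be strictly increasing")


@dataclass(frozen=True)
class DoseRecord:
    """Relative dose proxy (mAs per mm of scan length) and scan duration.

    ``ctdi_vol_mgy`` is only populated for real scanner data where the console
    value is supplied by the user; the simulator never claims absolute dose.
    """

    dose_proxy_mas_per_mm: float
    scan_time_s: float
    ctdi_vol_mgy: float | None = None


def couch_speed(config: AcquisitionConfig) -> float:
    """Helical couch speed in mm/s: pitch x collimation / rotation time."""
    if config.mode is not ScanMode.HELICAL:
        raise ModeError("couch_speed is defined only for helical mode")
    return config.pitch * config.collimation_mm / config.rotation_time_s


def check_data_sufficiency(
    config: AcquisitionConfig, summary: TraceSummary
) -> SufficiencyReport:
    """Does each z position see at least one full breathing cycle?

    Helical: per-slice beam coverage is rotation_time / pitch seconds and must
    be >= the mean period. Volume: the dwell per couch position must be >= the
    mean period plus one rotation.
    """
    if config.mode is ScanMode.HELICAL:
        coverage = config.rotation_time_s / config.pitch
        required = summary.mean_period
    else:
        coverage = summary.mean_period + config.rotation_time_s  # default dwell
        required = summary.mean_period + config.rotation_time_s
    return SufficiencyReport(
        mode=config.mode,
        sufficient=coverage >= required - 1e-12,
        coverage_s=coverage,
        required_s=required,
    )


def _fallback_assignment(trace: RespiratoryTrace, gating: GatingConfig) -> PhaseAssignment:
    """Synthetic uniform triggers for traces without detectable cycles."""
    triggers = np.arange(trace.times[0], trace.times[-1] + 1e-9, FALLBACK_PERIOD_S)
    if triggers.size < 2:
        triggers = np.array([trace.times[0], trace.times[-1]])
    phase, assigned = phase_from_triggers(triggers, trace.times)
    bin_width = 100.0 / gating.n_phase_bins
    bins = np.full(trace.times.shape, -1, dtype=int)
    bins[assigned] = np.clip(
        np.floor(phase[assigned] / bin_width).astype(int), 0, gating.n_phase_bins - 1
    )
    return PhaseAssignment(phase, bins, assigned, triggers, gating.n_phase_bins)


def _circular_pick(
    candidate_times: np.ndarray, candidate_phases: np.ndarray, nominal_pct: float
) -> float:
    """Candidate whose phase is circularly closest to nominal; earliest wins ties."""
    d = np.abs(candidate_phases - nominal_pct)
    d = np.minimum(d, 100.0 - d)
    return float(candidate_times[int(np.argmin(d))])  # argmin -> first minimum


def plan_scan(
    config: AcquisitionConfig,
    spec: PhantomSpec,
    trace: RespiratoryTrace,
    gating: GatingConfig,
) -> ScanPlan:
    """Build acquisition windows and per-slice, per-phase reconstruction times.

    The scan starts at the first gating trigger. Volume mode tiles the grid's
    z extent with couch positions of width ``collimation_mm``, dwelling
    mean period + one rotation at each; helical mode sweeps a beam of that
    width at the pitch-determined couch speed.
    """
    try:
        assignment = assign_phases(trace, gating)
        mean_period = summarize_trace(detect_cycles(trace)).mean_period
    except InsufficientCyclesError:
        assignment = _fallback_assignment(trace, gating)
        mean_period = FALLBACK_PERIOD_S

    nz = spec.grid_shape[2]
    sz = spec.spacing_mm[2]
    slice_z = spec.axis_coords(2)
    z_edge0 = slice_z[0] - sz / 2.0
    extent = nz * sz
    n_bins = gating.n_phase_bins
    labels = np.arange(n_bins) * (100.0 / n_bins)
    t_start = float(assignment.trigger_times[0])
    t_end = float(trace.times[-1])

    windows = np.empty((nz, 2))
    per_phase = np.empty((nz, n_bins))
    offsets = np.zeros(nz)

    if config.mode is ScanMode.VOLUME:
        dwell = mean_period + config.rotation_time_s
        n_pos = max(1, math.ceil(extent / config.collimation_mm - 1e-9))
        pos_index = np.minimum(
            ((slice_z - z_edge0) // config.collimation_mm).astype(int), n_pos - 1
        )
        scan_time = n_pos * dwell
        if t_start + scan_time > t_end + 1e-9:
            raise PlanError(
                f"trace ({t_end:.1f} s) too short for a {scan_time:.1f} s volume scan"
            )
        for k in range(n_pos):
            w0 = t_start + k * dwell
            w1 = w0 + dwell
            frames = w0 + np.arange(int(dwell / config.cine_interval_s) + 1) * config.cine_interval_s
            frames = frames[frames <= w1 + 1e-9]
            fphase, fassigned = assignment.phase_at(frames)
            frames, fphase = frames[fassigned], fphase[fassigned]
            if frames.size == 0:
                raise PlanError(f"no phase-assignable cine frames in couch position {k}")
            sel = pos_index == k
            windows[sel] = (w0, w1)
            for b, lab in enumerate(labels):
                per_phase[sel, b] = _circular_pick(frames, fphase, lab)
        return ScanPlan(
            mode=config.mode,
            slice_z_mm=slice_z,
            acquisition_windows=windows,
            per_phase_times=per_phase,
            window_offsets_s=offsets,
            couch_position_index=pos_index,
            phase_labels_pct=labels,
            n_positions=n_pos,
            dwell_s=dwell,
            scan_time_s=scan_time,
            couch_speed_mm_s=None,
            mean_period_s=mean_period,
            t_start=t_start,
            gating=gating,
            assignment=assignment,
        )

    # helical
    v = couch_speed(config)
    cover = config.collimation_mm / v  # = rotation_time / pitch
    scan_time = extent / v + cover
    if t_start + scan_time > t_end + 1e-9:
        raise PlanError(
            f"trace ({t_end:.1f} s) too short for a {scan_time:.1f} s helical scan"
        )
    samp_t = trace.times[assignment.assigned]
    samp_p = assignment.phase_pct[assignment.assigned]
    for i, z in enumerate(slice_z):
        w0 = t_start + (z - z_edge0) / v
        w1 = w0 + cover
        windows[i] = (w0, w1)
        offsets[i] = np.mod((z - slice_z[0]) / v, config.rotation_time_s) - (
            config.rotation_time_s / 2.0
        )
        in_win = (samp_t >= w0) & (samp_t <= w1)
        if not in_win.any():
            raise PlanError(f"no phase-assignable samples cover slice {i}")
        for b, lab in enumerate(labels):
            per_phase[i, b] = _circular_pick(samp_t[in_win], samp_p[in_win], lab)
    return ScanPlan(
        mode=config.mode,
        slice_z_mm=slice_z,
        acquisition_windows=windows,
        per_phase_times=per_phase,
        window_offsets_s=offsets,
        couch_position_index=np.zeros(nz, dtype=int),
        phase_labels_pct=labels,
        n_positions=1,
        dwell_s=cover,
        scan_time_s=scan_time,
        couch_speed_mm_s=v,
        mean_period_s=mean_period,
        t_start=t_start,
        gating=gating,
        assignment=assignment,
    )


def _blur_times(config: AcquisitionConfig, t: float, offset: float) -> np.ndarray:
    """Midpoint subsample times across the reconstruction data window."""
    w = config.blur_window_s
    start = t + offset if config.blur_alignment == "forward" else t + offset - w / 2.0
    m = config.blur_subsamples
    return start + (np.arange(m) + 0.5) / m * w


def _averaged_slab(
    spec: PhantomSpec, displacements: np.ndarray, z_indices: np.ndarray
) -> np.ndarray:
    """Mean of renders over the blur window; single render if motion is nil."""
    if np.ptp(displacements) == 0.0:
        return render_slab(spec, float(displacements[0]), z_indices)
    acc = render_slab(spec, float(displacements[0]), z_indices)
    for d in displacements[1:]:
        acc = acc + render_slab(spec, float(d), z_indices)
    return acc / displacements.size


def reconstruct_4dct(
    plan: ScanPlan,
    spec: PhantomSpec,
    motion: MotionModel,
    config: AcquisitionConfig,
) -> Phase4DCT:
    """Assemble the phase-sorted volumes from the scan plan.

    Volume mode renders whole couch-position slabs (a single time per slab and
    phase — stair-step artifacts appear when adjacent slabs land on different
    cycles); helical mode assembles slice by slice with per-slice gantry
    window offsets. Zero-mean Gaussian noise of SD ``noise_sd_hu`` is added
    per phase volume, seeded by ``config.seed``.
    """
    t0, t1 = float(motion.trace.times[0]), float(motion.trace.times[-1])
    if np.any(plan.per_phase_times < t0 - 1e-9) or np.any(plan.per_phase_times > t1 + 1e-9):
        raise ReconstructionError("chosen reconstruction time outside the trace span")
    nz = plan.slice_z_mm.size
    rng = np.random.default_rng(config.seed)
    volumes: list[ImageVolume] = []
    for b in range(plan.phase_labels_pct.size):
        vox = np.empty(spec.grid_shape)
        if plan.mode is ScanMode.VOLUME:
            for k in range(plan.n_positions):
                sel = np.nonzero(plan.couch_position_index == k)[0]
                t = plan.per_phase_times[sel[0], b]
                disp = motion.displacement(_blur_times(config, t, 0.0))
                vox[:, :, sel] = _averaged_slab(spec, np.atleast_1d(disp), sel)
        else:
            for i in range(nz):
                t = plan.per_phase_times[i, b]
                disp = motion.displacement(_blur_times(config, t, plan.window_offsets_s[i]))
                vox[:, :, i : i + 1] = _averaged_slab(
                    spec, np.atleast_1d(disp), np.array([i])
                )
        if config.noise_sd_hu > 0:
            vox = vox + rng.standard_normal(vox.shape) * config.noise_sd_hu
        volumes.append(ImageVolume(vox, spec.spacing_mm, spec.origin_mm))
    return Phase4DCT(
        phases=volumes,
        phase_labels_pct=plan.phase_labels_pct.copy(),
        per_slice_times=plan.per_phase_times.copy(),
        gating=plan.gating,
        mode=plan.mode,
        seed=config.seed,
    )


def dose_proxy(plan: ScanPlan, config: AcquisitionConfig) -> DoseRecord:
    """Relative dose proxy: tube current x beam-on time per mm of scan length.

    Proportional to delivered mAs per unit length, so it preserves orderings
    and scaling (linear in tube current; roughly inverse in helical pitch)
    without claiming absolute mGy.
    """
    sz = plan.slice_z_mm
    extent = (sz[-1] - sz[0]) + (sz[1] - sz[0]) if sz.size > 1 else 1.0
    proxy = config.tube_current_ma * plan.scan_time_s / extent
    return DoseRecord(dose_proxy_mas_per_mm=float(proxy), scan_time_s=plan.scan_time_s)
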