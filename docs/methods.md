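# Methods

`fourdct` is an in-silico testbed for comparing the two acquisition modes of
respiratory-correlated CT (4DCT): **volume (cine) mode**, which acquires a
full image stack at each stationary couch position before stepping, and
**helical mode**, which sweeps the couch continuously at a very low pitch so
every slice is irradiated for at least one breathing cycle. The package
simulates both modes on a digital motion phantom and evaluates the resulting
phase-sorted volumes with the standard QA metrics — contrast-to-noise ratio
(CNR) and dose-normalised CNR, per-phase target volume (dimensional
accuracy), per-phase centre-of-mass trajectory (positional accuracy), and a
paired TOST equivalence test for patient-style respiratory metrics.

## Surrogate signal model

Breathing is represented by an external surrogate amplitude a(t) in mm,
sampled uniformly (default 25 Hz, typical of clinical surrogate systems).

* **Sinusoid**: a(t) = A·cos(2πt/T) with the end-inhale peak at t = 0, so the
  0% respiratory phase coincides with end-inhale and the peak speed is
  2πA/T — 1.57 cm/s for the "normal" pattern (A = 1 cm zero-to-peak,
  T = 4 s) and 3.14 cm/s for the "rapid" pattern (A = 2 cm). The quarter
  cycle (20–30% phase interval) carries the maximum velocity, which is where
  motion-induced errors concentrate.
* **Irregular breathing**: consecutive peak-to-peak cycles whose period and
  amplitude are drawn independently from normal distributions with CV =
  irregularity/100 (truncated at ±3 CV so both stay positive); each cycle
  descends as a half cosine and rises with a cosine easing to the next
  cycle's peak, keeping the signal and its derivative continuous at joins.
* **Irregularity metric**: 100 × the mean of the CVs of the per-cycle period
  and per-cycle amplitude. This definition matters — the reported
  patient-table irregularities depend on it — and is chosen so that the
  generator's parameter is recovered by the metric (15% in, 15 ± 2% out over
  ≥ 30 cycles). A pure sinusoid scores 0.
* **Cycle detection**: local maxima with prominence ≥ 10% of the trace range
  and minimum separation 0.25 × the median inter-peak interval; cycle
  amplitude is the starting peak minus the trough before the next peak.
  Amplitudes are *reported* zero-to-peak (half the peak-to-trough), matching
  the convention that makes A = 1 cm produce a 1.57 cm/s peak speed.

### Gating triggers and retrospective phase

Phase advances linearly in time from one trigger to the next (0–100%);
samples outside the first/last trigger are flagged unassigned, never
dropped. Two trigger semantics are modelled:

* **Peak (in-peak)**: triggers at end-inhale peaks (the recommended clinical
  setting).
* **Point-to-point**: triggers at the rising crossing of
  trough + f·(peak − trough) within each cycle (default f = 0.8). Vendor
  internals of this mode are not public; a level-crossing trigger is the
  minimal model that reproduces its observed consequence — for a sinusoid
  the analytic offset is arccos(2f − 1)/2π ≈ 14.8% of a cycle at f = 0.8,
  i.e. a 10–20% phase-label shift relative to peak gating, which moves the
  phase of minimum positional error in volume mode.

## Digital phantom

A voxel grid (default 128 × 128 × 120 at 0.976 × 0.976 × 1.0 mm — clinical
in-plane resolution, desk-scale extent covering the sphere plus ±2.5 cm of
travel) holds a 3 cm sphere of −40 HU in a −700 HU background, moving
rigidly along the couch (z) axis with displacement = surrogate amplitude ×
scale (default 1). The material HUs are set so that simulated ROI statistics
sit on the scale of the published phantom measurements. An optional 1.2 mm
sawtooth plate (polypropylene-like, −90 HU) is rendered for qualitative
motion-artifact display only; no metric consumes it.

**Sampling kernel.** Each voxel takes the HU of the material at its centre
(sharp kernel). The fixed −200 HU segmentation criterion sits at 75.8% of
the target/background contrast; with any edge model that spreads the
transition over a finite width (e.g. box-averaged partial volume), the
threshold surface sits ~0.26 × that width *inside* the true sphere, a 4–5%
volume deficit at 1 mm voxels. Centre sampling keeps the threshold surface
on the geometric surface for every threshold strictly between the materials
— consistent with the physical experiment, which verified that the −200 HU
contour matches the sphere's physical size. The cost is purely
combinatorial: total attenuation mass varies by up to ~1% with sub-voxel
displacement (lattice counting), rather than ~0.5% for a box-averaged edge.
`PhantomSpec.supersample > 1` restores per-axis box supersampling when a
graded static edge is wanted.

## Acquisition simulator

Image formation is modelled in the rendered-object domain; no
projection-space physics, scatter or vendor reconstruction is attempted,
because every metric operates on reconstructed volumes. A phase volume is
assembled from temporally blurred renders plus stationary Gaussian HU noise
(default SD 11, the inside-object noise level of the reference protocol),
seeded per acquisition.

Common timing: rotation time 0.5 s, tube current 100 mA. Volume mode uses
140 mm collimation; helical uses 80 mm at pitch 0.073, giving a couch speed
of pitch × collimation / rotation = 11.68 mm/s and per-slice coverage of
rotation/pitch = 6.85 s ≥ one 4 s cycle (the helical data-sufficiency
condition). Volume-mode dwell per couch position is mean period + one
rotation (the acquisition "exceeds one respiratory cycle" rule); positions
abut without overlap, so slabs reconstructed from different cycles produce
stair-step discontinuities. The scan starts at the first gating trigger.

**Reconstruction data window.** Each slice/slab of a phase volume is the
mean of `blur_subsamples` (default 5) renders spanning a window of
rotation/2 (half-scan reconstruction) *starting* at the selected phase time.
The forward alignment reflects that the phase tag marks the start of the
data used for that image; it makes the centroid error grow with target
speed (≈ v·w/2), maximal in the 20–30% interval, as observed physically. A
centred window (under which blur-induced centroid error vanishes exactly at
the quarter cycle and the per-phase error pattern is mirror-symmetric about
50%) and a full-rotation width remain available via `blur_alignment` /
`blur_window`.

**Mode asymmetries.** Two deliberate, physically grounded asymmetries drive
every cine-versus-helical ordering; without them the two modes are
numerically identical on an ideal sinusoid (a 25 Hz surrogate sampled over a
4 s period contains a sample at every 1% phase, so nearest-sample selection
is exact in both modes):

1. *Cine frame quantisation.* A stationary couch position stores a finite
   stack of images, one per `cine_interval_s` (default = rotation time);
   retrospective sorting picks the stack member circularly nearest the
   nominal phase. The whole slab therefore carries one coherent phase-timing
   error of up to half the frame spacing — a rigid displacement of the
   target: positional error without shape change. Helical raw data support
   reconstruction centred at an arbitrary time, so each slice is selected
   among surrogate samples and hits its nominal phase to sampling precision.
2. *Helical gantry-alignment offsets.* A helical slice can only be
   reconstructed from data collected while the spiral passes it, so its
   window start carries an offset ((z − z₀)/v mod rotation) − rotation/2
   tied to the gantry angle at that z; a cine slab shares a single
   alignment. Under fast motion adjacent slices therefore sample visibly
   different displacements: the target shears and elongates (the helical
   dimensional penalty and the elongation seen at 20% phase under rapid
   motion), while the per-slice errors largely cancel in the centre of mass
   (the helical positional advantage). This offset is the model's stand-in
   for helical z-interpolation; the vendor's actual interpolation is
   proprietary.

**Dose proxy.** Imaging dose is reported *relatively* as tube current ×
beam-on time per mm of scan length (mAs/mm): dwell × positions / extent for
volume mode, scan time / extent for helical. It preserves the orderings and
scalings that matter (helical > volume at these settings; linear in mA;
∝ 1/pitch) without claiming mGy; measured CTDIvol values are accepted as
inputs when evaluating real data.

## Metrics

* **ROI statistics / CNR**: two spherical ROIs of 20 px diameter (voxel
  units; anisotropic spacing accepted as-is), one centred in the target —
  tracking the known target position per phase in simulations, or the
  phase-0 segmentation centroid for external data — and one offset 30 px
  along +x. CNR = (M₁ − M₂)/√((SD₁² + SD₂²)/2) with population SDs; signed.
  Dose-normalised CNR divides the across-condition mean CNR by the dose
  value (console CTDIvol for real data, the proxy for simulations; units
  are recorded alongside). Report tables round half-even to 2 dp.
* **Segmentation**: voxels > −200 HU, largest 6-connected component.
* **Dimensional accuracy**: per-phase segmented volume; mean |difference|
  from the reference (the analytic sphere volume in simulations); CoV
  (sample SD / mean across the 10 phases) of volume and of integrated HU
  volume (volume × mean HU, the density-weighted consistency metric used
  for non-rigid patient organs).
* **Positional accuracy**: per-phase HU-weighted centroid along the motion
  axis, weights (HU + 200) clamped at ≥ 0 (more stable under blur than a
  binary centroid; binary available). Measured and ground-truth series are
  both re-centred about their phase mean, since the absolute couch position
  is arbitrary; ground truth at nominal phase p is A·cos(2πp/100).
* **Surrogate correlation**: Pearson r between the per-phase centroid
  displacement and the per-phase surrogate amplitude — preferentially the
  mean surrogate level over the reconstruction times that actually formed
  each phase volume; if no usable times accompany the data, the mean over
  samples whose phase lies within half a bin of the nominal label (a
  [label, label + width) window would lag the reconstruction target by half
  a bin and cap even a perfect trajectory at r ≈ 0.95).
* **TOST equivalence**: paired two one-sided t-tests of the mean difference
  against ± margin, margin = 5% (configurable) of the pooled mean of both
  groups; equivalence iff both one-sided p < α = 0.05. Paired because the
  patients were scanned under both modes back-to-back. Zero-variance,
  zero-shift inputs return equivalent with a `degenerate` flag.

## Experiment orchestration

`run_phantom_experiment` executes the full mode × pattern × replicate grid.
Per-cell seeds are base_seed + CRC32(mode|pattern|replicate) mod 2³¹, so any
cell is reproducible in isolation and the whole report is byte-identical
across runs. Traces last 30 s (enough for the ~17 s helical sweep of the
default grid plus settling), replicated with fresh seeds rather than
repeated physically. Cross-mode summaries reduce each condition to the mean
over replicates and express mode advantages as integer-rounded relative
percentages.

## What the synthetic data do and do not show

The generator reproduces the *study conditions*: the motion waveforms,
sampling geometry, material contrast, noise scale, gating semantics and
mode-specific timing. It does not model projection physics, scatter, beam
hardening, iterative/AI reconstruction, anatomy, baseline drift, or absolute
dosimetry, and the helical z-interpolation stand-in is a structural analogue
rather than the vendor algorithm. Passing orderings (rapid > normal
dimensional error; helical ≥ volume dimensional error under rapid motion;
helical ≤ volume positional error; helical > volume dose; trigger-mode phase
shift) therefore validate that the *mechanisms* the physical study invokes
are sufficient to produce its findings — they are not quantitative
predictions of any particular scanner, and absolute error magnitudes should
not be compared against measured ones.

## Numerical choices and degenerate inputs

* Circular nearest-phase selection breaks ties toward the earliest
  candidate time.
* A constant (zero-amplitude) trace has no detectable cycles; planning
  falls back to a synthetic 4 s trigger grid so the static-phantom pipeline
  runs, and zero-motion, zero-noise reconstructions are bit-identical
  across modes and to the static render (identical blur subsamples are
  collapsed to a single render).
* Blur subsample times may overhang the trace edge by up to half a window;
  displacement interpolation clamps at the trace ends.
* Empty segmentation masks are allowed; measurements on them raise, and
  per-phase reports exclude empty phases with a warning.
* Population SD in ROI statistics; sample SD (ddof = 1) in across-phase
  CoVs and cycle-irregularity CVs.
* Phantom-spec validation requires the target to fit inside the grid at the
  current displacement; rendering raises out-of-bounds otherwise.

## Problem sizes

Default simulations run on the 128 × 128 × 120 desk-scale grid; the test
suite uses a 64 × 64 × 56 grid at clinical spacing for render-heavy checks
and 2 mm grids for orchestration tests. These sizes keep a full matched-seed
ordering study (2 modes × 3 patterns × 5 seeds) within a couple of minutes
on one CPU while leaving > 30 voxels across the sphere diameter in-plane.

## Known limitations

* The irregularity statistic is one of several definitions in use; measured
  irregularity percentages are only comparable under this definition.
* The cine stack interval and the helical gantry-offset form are modelling
  choices; they reproduce the observed orderings but their magnitudes are
  not calibrated to any specific scanner.
* The point-to-point trigger level (0.8 of the trough-to-peak rise) is a
  plausible default, not a vendor specification; only the induced 10–20%
  phase shift is externally corroborated.
* ROIs are spheres in voxel-index space; with anisotropic voxels they are
  ellipsoids in mm space, as in the reference analysis.
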