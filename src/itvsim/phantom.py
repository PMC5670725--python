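"""Digital respiratory phantom and 4DCT acquisition emulation.

The phantom is a dense spherical target embedded in a uniform low-density
lung medium, translating sinusoidally along the superior--inferior (SI) axis
(optionally in 3-D).  Two acquisition modes are emulated:

* phase-sorted 4DCT: the respiratory cycle is divided into 10 uniformly
  spaced phase bins (0%, 10%, ..., 90%); each bin's image is the time average
  of several phantom snapshots inside the bin, emulating reconstruction from
  projection data spanning the bin.  Phase 0% is centred on maximum inhale
  (the cosine maximum) and phase 50% on maximum exhale.
* a free-breathing (FB) helical scan: axial slabs are acquired sequentially
  while the target keeps moving, so each slab freezes the target at a
  different respiratory phase.  The interleaving of couch travel and motion
  produces the interplay distortion seen in single helical snapshots of
  moving targets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .volume import ImageVolume, require_same_geometry

#: Default CT-number-like intensities.  Only the contrast matters downstream:
#: segmentation thresholds are expressed as fractions of the lung-to-target
#: dynamic range.
LUNG_INTENSITY = -700.0
TARGET_INTENSITY = 0.0

#: Default voxel spacing (cm): 1 mm in-plane, 1.25 mm slice width.
DEFAULT_SPACING = (0.1, 0.1, 0.125)

#: Default padding (cm) added around target + motion when auto-sizing grids;
#: large enough to contain the biggest margin expansion used anywhere (1 cm).
DEFAULT_PAD_CM = 1.5

#: Squared-distance slack (cm^2) for in-sphere tests; keeps voxels that lie
#: exactly on the surface inside, independent of coordinate rounding.
_SURFACE_TOL = 1e-9


@dataclass(frozen=True)
class MotionTrajectory:
    """Parametric periodic target trajectory.

    The SI position at time ``t`` is ``A * cos(2*pi*t/T + phase_offset)``
    where ``A = amplitude_si`` is the half peak-to-peak excursion and ``T``
    the respiratory period (default 4 s, i.e. 15 cycles per minute).  Optional
    lateral / anterior-posterior components oscillate in phase with the SI
    component, giving a straight-line 3-D path.  Cycle-to-cycle irregularity
    is modelled by drawing an independent period and amplitude scale for each
    respiratory cycle from seeded normal distributions.
    """

    amplitude_si: float = 1.0
    period: float = 4.0
    phase_offset: float = 0.0
    lateral_amplitude: float = 0.0
    ap_amplitude: float = 0.0
    period_jitter_sd: float = 0.0
    amplitude_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError(f"period must be positive, got {self.period}")
        for name in ("amplitude_si", "lateral_amplitude", "ap_amplitude",
                     "period_jitter_sd", "amplitude_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def amplitudes(self) -> tuple[float, float, float]:
        """Per-axis amplitudes ``(lateral, AP, SI)`` in cm."""
        return (self.lateral_amplitude, self.ap_amplitude, self.amplitude_si)

    @property
    def has_jitter(self) -> bool:
        return self.period_jitter_sd > 0 or self.amplitude_jitter_sd > 0

    def _cycle_draw(self, cycle: int) -> tuple[float, float]:
        """Jittered (period, amplitude scale) for one respiratory cycle.

        Seeded per cycle so that evaluation order never affects the result.
        """
        rng = np.random.default_rng([self.seed & 0x7FFFFFFF, cycle])
        period = self.period
        if self.period_jitter_sd > 0:
            period = max(0.1 * self.period, period + rng.normal(0.0, self.period_jitter_sd))
        scale = 1.0
        if self.amplitude_jitter_sd > 0 and self.amplitude_si > 0:
            jittered = max(0.0, self.amplitude_si + rng.normal(0.0, self.amplitude_jitter_sd))
            scale = jittered / self.amplitude_si
        return period, scale

    def displacement(self, t: float) -> tuple[float, float, float]:
        """Target centre displacement (dx, dy, dz) in cm at time ``t`` (s)."""
        if not self.has_jitter:
            c = math.cos(2.0 * math.pi * t / self.period + self.phase_offset)
            return (self.lateral_amplitude * c, self.ap_amplitude * c, self.amplitude_si * c)
        cycle = math.floor(t / self.period)
        period, scale = self._cycle_draw(cycle)
        frac = (t - cycle * self.period) / period
        c = math.cos(2.0 * math.pi * frac + self.phase_offset)
        return (self.lateral_amplitude * c * scale,
                self.ap_amplitude * c * scale,
                self.amplitude_si * c * scale)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensities of the digital phantom.

    ``grid_extent`` is in voxels and ``grid_spacing`` in cm per voxel; the
    grid must fully contain the target at its largest displacement (checked
    at rasterization time).
    """

    target_radius: float = 1.5
    target_intensity: float = TARGET_INTENSITY
    lung_intensity: float = LUNG_INTENSITY
    grid_spacing: tuple[float, float, float] = DEFAULT_SPACING
    grid_extent: tuple[int, int, int] = (61, 61, 49)
    target_rest_center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.target_radius <= 0:
            raise ValueError(f"target_radius must be positive, got {self.target_radius}")
        if self.target_intensity <= self.lung_intensity:
            raise ValueError(
                f"target_intensity ({self.target_intensity}) must exceed "
                f"lung_intensity ({self.lung_intensity})"
            )
        if any(s <= 0 for s in self.grid_spacing):
            raise ValueError(f"grid_spacing must be positive, got {self.grid_spacing}")
        if any(int(n) <= 0 or int(n) != n for n in self.grid_extent):
            raise ValueError(f"grid_extent must be positive integers, got {self.grid_extent}")

    @property
    def contrast(self) -> float:
        return self.target_intensity - self.lung_intensity

    @property
    def grid_origin(self) -> tuple[float, float, float]:
        """Grid symmetric about the rest centre (odd extents keep it on a voxel)."""
        return tuple(
            c - 0.5 * (n - 1) * s
            for c, n, s in zip(self.target_rest_center, self.grid_extent, self.grid_spacing)
        )

    @classmethod
    def for_motion(
        cls,
        trajectory: MotionTrajectory,
        *,
        target_radius: float = 1.5,
        spacing: tuple[float, float, float] = DEFAULT_SPACING,
        pad_cm: float = DEFAULT_PAD_CM,
        target_rest_center: tuple[float, float, float] = (0.0, 0.0, 0.0),
        target_intensity: float = TARGET_INTENSITY,
        lung_intensity: float = LUNG_INTENSITY,
    ) -> "PhantomSpec":
        """Auto-size a grid to contain target + motion + ``pad_cm`` per axis."""
        extent = []
        for amp, s in zip(trajectory.amplitudes, spacing):
            half = target_radius + amp + pad_cm
            n = 2 * math.ceil(half / s) + 1  # odd: rest centre on a voxel centre
            extent.append(n)
        return cls(
            target_radius=target_radius,
            target_intensity=target_intensity,
            lung_intensity=lung_intensity,
            grid_spacing=tuple(spacing),
            grid_extent=tuple(extent),
            target_rest_center=tuple(target_rest_center),
        )


@dataclass(frozen=True)
class AcquisitionConfig:
    """4DCT phase-binning model.

    ``samples_per_bin`` phantom snapshots at uniformly spaced times inside
    each bin are averaged (``mode="mean"``), emulating reconstruction from
    projections spanning the bin; ``mode="center"`` keeps a single snapshot
    at the bin centre.  Bins are centred on their phase labels, with the 0%
    bin centred on maximum inhale.
    """

    n_bins: int = 10
    samples_per_bin: int = 8
    mode: str = "mean"
    partial_volume: bool = False

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.n_bins != 10:
            warnings.warn(
                f"n_bins={self.n_bins}: 4DCT protocols conventionally use 10 phase bins",
                stacklevel=2,
            )
        if self.samples_per_bin < 1:
            raise ValueError("samples_per_bin must be >= 1")
        if self.mode not in ("mean", "center"):
            raise ValueError(f"mode must be 'mean' or 'center', got {self.mode!r}")


@dataclass(frozen=True)
class ScanModel:
    """Free-breathing helical scan model.

    The scanner covers contiguous axial slabs sequentially (default slab:
    2 cm, i.e. 16 slices of 1.25 mm for a 16-slice unit, in 0.5 s per slab),
    with the couch travelling inferior-to-superior; slab thickness and time
    per slab fix the effective couch speed.  Each slab's image is the
    uniform time average of ``samples_per_slab`` phantom snapshots spanning
    its acquisition window, emulating reconstruction from projections
    collected while the target keeps moving: fast-moving target edges
    average down towards lung density and drop below the segmentation
    threshold, which is what shrinks and distorts the free-breathing target
    (the interplay artifact).  ``start_phase`` is the respiratory-cycle
    fraction at the start of the scan; because a real scan starts at an
    unknowable point of the cycle, experiments sweep it uniformly.
    """

    slab_thickness_cm: float = 2.0
    slab_time_s: float = 0.5
    samples_per_slab: int = 8
    start_phase: float = 0.0
    inferior_to_superior: bool = True
    partial_volume: bool = False

    def __post_init__(self) -> None:
        if self.slab_thickness_cm <= 0 or self.slab_time_s <= 0:
            raise ValueError(
                "couch speed must be positive: slab_thickness_cm and slab_time_s "
                f"must both be > 0 (got {self.slab_thickness_cm}, {self.slab_time_s})"
            )
        if self.samples_per_slab < 1:
            raise ValueError("samples_per_slab must be >= 1")

    @property
    def couch_speed_cm_s(self) -> float:
        return self.slab_thickness_cm / self.slab_time_s


@dataclass
class PhaseStack:
    """Ordered set of phase-binned volumes sharing one grid.

    ``phase_labels`` run 0%, 10%, ..., in acquisition order; ``bin_boundaries``
    are cycle-time fractions delimiting the bins (the first bin wraps around
    the cycle start, hence the negative leading boundary).
    """

    phases: list[ImageVolume]
    phase_labels: tuple[str, ...]
    bin_boundaries: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("phase stack must contain at least one phase")
        if len(self.phase_labels) != len(self.phases):
            raise ValueError("one label per phase required")
        for p in self.phases[1:]:
            require_same_geometry(self.phases[0], p, "phase volumes")

    def __len__(self) -> int:
        return len(self.phases)

    def __iter__(self):
        return iter(self.phases)

    def __getitem__(self, i: int) -> ImageVolume:
        return self.phases[i]

    def phase_by_label(self, label: str) -> ImageVolume:
        try:
            return self.phases[self.phase_labels.index(label)]
        except ValueError:
            raise KeyError(f"no phase labelled {label!r}; have {self.phase_labels}") from None

    @property
    def geometry(self) -> ImageVolume:
        return self.phases[0]


def rasterize_phantom(
    spec: PhantomSpec,
    displacement: tuple[float, float, float] = (0.0, 0.0, 0.0),
    *,
    partial_volume: bool = False,
) -> ImageVolume:
    """Voxelize the phantom with the target displaced by ``displacement`` (cm).

    Voxels whose centres lie inside the displaced sphere receive the target
    intensity, all others the lung intensity.  With ``partial_volume=True``
    boundary voxels are blended linearly over one mean voxel width, a cheap
    stand-in for the scanner's finite resolution.
    """
    vol = ImageVolume(
        values=np.full(spec.grid_extent, spec.lung_intensity, dtype=np.float64),
        spacing=spec.grid_spacing,
        origin=spec.grid_origin,
    )
    center = tuple(c + d for c, d in zip(spec.target_rest_center, displacement))
    r = spec.target_radius
    for ax, ((lo, hi), c) in enumerate(zip(vol.bounds(), center)):
        if c - r < lo or c + r > hi:
            raise ValueError(
                f"target at displacement {tuple(displacement)} leaves the grid along "
                f"axis {ax} (centre {c:.3f} cm, radius {r} cm, grid [{lo:.3f}, {hi:.3f}] cm)"
            )
    dx2 = (vol.axis_coords(0) - center[0]) ** 2
    dy2 = (vol.axis_coords(1) - center[1]) ** 2
    dz2 = (vol.axis_coords(2) - center[2]) ** 2
    d2 = dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
    if partial_volume:
        h = float(np.cbrt(np.prod(spec.grid_spacing)))
        frac = np.clip(0.5 + (r - np.sqrt(d2)) / h, 0.0, 1.0)
        vol.values += frac * spec.contrast
    else:
        # small slack keeps exactly-on-surface voxels in regardless of the
        # rounding of the coordinate grid (translation equivariance)
        vol.values[d2 <= r * r + _SURFACE_TOL] = spec.target_intensity
    return vol


def _bin_sample_times(k: int, acq: AcquisitionConfig, period: float) -> np.ndarray:
    """Snapshot times for phase bin ``k`` (bin centred at cycle fraction k/n)."""
    center = k / acq.n_bins * period
    width = period / acq.n_bins
    if acq.mode == "center":
        return np.array([center])
    m = acq.samples_per_bin
    offsets = ((np.arange(m) + 0.5) / m - 0.5) * width  # midpoints of m sub-intervals
    return center + offsets


def simulate_phase_stack(
    spec: PhantomSpec,
    trajectory: MotionTrajectory,
    acq: AcquisitionConfig = AcquisitionConfig(),
) -> PhaseStack:
    """Emulate a phase-sorted 4DCT acquisition of the moving phantom.

    Each of the ``acq.n_bins`` phase images is the uniform time average of
    rasterized phantom snapshots over its bin; residual intra-bin motion
    therefore blurs the target edge exactly as phase binning of a moving
    target does.  Phase 0% brackets the cosine maximum (maximum inhale),
    phase 50% the minimum (maximum exhale).
    """
    phases: list[ImageVolume] = []
    for k in range(acq.n_bins):
        times = _bin_sample_times(k, acq, trajectory.period)
        acc = None
        for t in times:
            snap = rasterize_phantom(
                spec, trajectory.displacement(t), partial_volume=acq.partial_volume
            )
            acc = snap.values if acc is None else acc + snap.values
        mean = acc / len(times)
        phases.append(ImageVolume(mean, spec.grid_spacing, spec.grid_origin))
    labels = tuple(f"{round(100 * k / acq.n_bins)}%" for k in range(acq.n_bins))
    boundaries = tuple((k - 0.5) / acq.n_bins for k in range(acq.n_bins + 1))
    return PhaseStack(phases=phases, phase_labels=labels, bin_boundaries=boundaries)


def simulate_free_breathing(
    spec: PhantomSpec,
    trajectory: MotionTrajectory,
    scan: ScanModel = ScanModel(),
) -> ImageVolume:
    """Emulate a single helical scan of the moving phantom.

    Contiguous axial slabs are acquired sequentially (inferior to superior
    by default); slab ``i`` spans the time window
    ``[t0 + i * slab_time, t0 + (i + 1) * slab_time]`` and its slices hold
    the uniform time average of the phantom over that window.  Because the
    target keeps moving while the couch advances, the reconstructed target
    is truncated, smeared or split along the SI axis -- the interplay
    artifact -- and its fast-moving edges lose density and fall below the
    segmentation threshold.
    """
    nz = spec.grid_extent[2]
    sz = spec.grid_spacing[2]
    slices_per_slab = max(1, round(scan.slab_thickness_cm / sz))
    t0 = scan.start_phase * trajectory.period
    n = scan.samples_per_slab
    out = np.full(spec.grid_extent, spec.lung_intensity, dtype=np.float64)
    starts = list(range(0, nz, slices_per_slab))
    if not scan.inferior_to_superior:
        starts = starts[::-1]
    for i, z0 in enumerate(starts):
        sl = slice(z0, min(z0 + slices_per_slab, nz))
        acc = None
        for j in range(n):
            t = t0 + (i + (j + 0.5) / n) * scan.slab_time_s
            snap = rasterize_phantom(
                spec, trajectory.displacement(t), partial_volume=scan.partial_volume
            )
            part = snap.values[:, :, sl]
            acc = part.copy() if acc is None else acc + part
        out[:, :, sl] = acc / n
    return ImageVolume(out, spec.grid_spacing, spec.grid_origin)


@dataclass
class VirtualPatient:
    """Synthetic 3-D-motion study subject with known ground truth.

    ``ground_truth_m`` is the Euclidean norm of the per-axis motion
    amplitudes; ``centroid_extrema`` holds the two extreme target-centre
    positions (maximum inhale, maximum exhale) of the jitter-free path, whose
    separation is the full peak-to-peak centroid displacement.
    """

    stack: PhaseStack
    free_breathing: ImageVolume
    ground_truth_m: float
    centroid_extrema: tuple[tuple[float, float, float], tuple[float, float, float]]


def generate_virtual_patient(
    seed: int,
    motion_3d: MotionTrajectory,
    *,
    spec: PhantomSpec | None = None,
    acq: AcquisitionConfig = AcquisitionConfig(),
    scan: ScanModel = ScanModel(),
) -> VirtualPatient:
    """Run the full phantom pipeline on a 3-D (optionally irregular) trajectory.

    ``seed`` replaces the trajectory's seed so that one integer controls all
    randomness; with zero jitter the output is bit-identical across runs.
    """
    if all(a == 0 for a in motion_3d.amplitudes):
        raise ValueError("virtual patient requires at least one nonzero motion amplitude")
    traj = replace(motion_3d, seed=seed)
    if spec is None:
        spec = PhantomSpec.for_motion(traj)
    stack = simulate_phase_stack(spec, traj, acq)
    fb = simulate_free_breathing(spec, traj, scan)
    amps = np.asarray(traj.amplitudes, float)
    m = float(np.linalg.norm(amps))
    extrema = (tuple(amps), tuple(-amps))
    return VirtualPatient(
        stack=stack, free_breathing=fb, ground_truth_m=m, centroid_extrema=extrema
    )
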