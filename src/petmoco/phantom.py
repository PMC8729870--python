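"""Synthetic motion-corrupted dynamic FDG brain phantom with full ground truth.

The phantom emulates a 60-min dynamic FDG brain acquisition rebinned as
24x5 s, 1x60 s, 1x120 s, 11x300 s (37 frames): an ellipsoidal brain with a
gray-matter shell and white-matter core, two vessel cylinders standing in for
the petrous internal carotid arteries, duration-dependent Poisson noise, a
known parametric arterial input function, known regional kinetics, and known
rigid inter-/intraframe motion.  Everything the real study measures
externally (MR navigators, arterial samples, TOF-MRA vessel masks) is
available here as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import (
    DynamicPETSeries,
    FrameSchedule,
    InputFunction,
    MotionVector,
    apply_motion,
    make_schedule,
)
from .kinetics import (
    FENG_DEFAULTS,
    KineticParams,
    PatlakConfig,
    cmrglc,
    feng_aif,
    frame_average,
    tissue_tac,
    whole_blood_from_plasma,
)

#: The clinical-protocol 37-frame rebinning pattern (counts, seconds).
DEFAULT_FRAME_PATTERN = ((24, 5.0), (1, 60.0), (1, 120.0), (11, 300.0))

#: Manual arterial blood-sampling grid.
BLOOD_SAMPLING_PATTERN = ((24, 5.0), (1, 60.0), (1, 120.0), (1, 300.0), (1, 600.0), (2, 1200.0))


def default_kinetics() -> dict[str, KineticParams]:
    """Typical human FDG rate constants per phantom region."""
    return {
        "gm": KineticParams(K1=0.102, k2=0.130, k3=0.062, Vb=0.05),
        "wm": KineticParams(K1=0.054, k2=0.109, k3=0.045, Vb=0.03),
        "ventricle": KineticParams(K1=0.01, k2=0.10, k3=0.001, Vb=0.02),  # CSF-like
        "vessel": KineticParams(K1=0.0, k2=0.0, k3=0.0, Vb=1.0),  # pure blood pool
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, kinetics and counting statistics of the digital phantom.

    Desk-scale default: 64x64x48 voxels at 3 mm isotropic (a stand-in for the
    scanner's 344x344x127 at ~2 mm).  ``count_sensitivity`` lumps scanner
    sensitivity into a single scalar: expected counts per (Bq/mL * s * voxel).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    brain_semi_axes_mm: tuple[float, float, float] = (60.0, 72.0, 45.0)
    brain_centre_offset_mm: tuple[float, float, float] = (0.0, 0.0, 15.0)
    gm_shell_fraction: float = 0.75  # WM core inside this fraction of the brain
    vessel_radius_mm: float = 3.0  # 2-voxel diameter at the default grid
    vessel_separation_mm: float = 30.0
    #: lateral-ventricle-like low-uptake ellipsoids; deliberately asymmetric
    #: (left larger than right) so small in-plane rotations are identifiable
    ventricle_semi_axes_mm: tuple[tuple[float, float, float], ...] = (
        (11.0, 20.0, 10.0), (8.0, 15.0, 8.0))
    ventricle_centres_mm: tuple[tuple[float, float, float], ...] = (
        (-15.0, 10.0, 8.0), (15.0, 4.0, 10.0))
    vessel_z_extent_mm: tuple[float, float] = (12.0, 33.0)
    kinetics: dict[str, KineticParams] = field(default_factory=default_kinetics)
    psf_fwhm: float = 4.5  # mm, isotropic reconstruction resolution
    count_sensitivity: float = 1e-4  # counts per (Bq/mL * s * voxel)
    aif_params: tuple[float, ...] = FENG_DEFAULTS
    plasma_ratio: tuple[float, float, float] = (1.0, 1.25, 600.0)  # r0, r_inf, tau_r s
    plasma_glucose: float = 5000.0  # µmol/L
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_fwhm < 0:
            raise ValueError("psf_fwhm must be >= 0")
        if self.count_sensitivity <= 0:
            raise ValueError("count_sensitivity must be > 0")
        if 2 * self.vessel_radius_mm < min(self.voxel_size):
            raise ValueError("vessel diameter must be >= 1 voxel")


@dataclass
class GroundTruth:
    """Everything the simulator knows that a real study must measure."""

    region_masks: dict[str, np.ndarray]
    true_aif: InputFunction  # plasma
    true_whole_blood: InputFunction
    applied_motion: list[MotionVector]
    true_Ki: dict[str, float]  # mL·mL^-1·min^-1
    plasma_glucose: float  # µmol/L
    true_CMRGlc: dict[str, float]  # µmol/100 g/min
    intraframe_motion: list[MotionVector] | None = None


# --------------------------------------------------------------------------- #
# Geometry
# --------------------------------------------------------------------------- #


def region_masks(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Pairwise-disjoint boolean masks for gm, wm, vessel and background."""
    shape = spec.grid_shape
    vs = np.asarray(spec.voxel_size)
    idx = np.indices(shape, dtype=float)
    centre = (np.array(shape) - 1.0) / 2.0
    pos = (idx - centre.reshape(3, 1, 1, 1)) * vs.reshape(3, 1, 1, 1)  # mm

    off = np.asarray(spec.brain_centre_offset_mm)
    rel = pos - off.reshape(3, 1, 1, 1)
    r2 = sum(
        (rel[a] / spec.brain_semi_axes_mm[a]) ** 2 for a in range(3)
    )
    brain = r2 <= 1.0
    wm = r2 <= spec.gm_shell_fraction**2
    gm = brain & ~wm

    # two vessel cylinders along z, below the brain (petrous ICA analog)
    z_mm = pos[2]
    z0, z1 = spec.vessel_z_extent_mm
    z_lo = z_mm.min() + z0
    z_hi = z_mm.min() + z1
    in_z = (z_mm >= z_lo) & (z_mm <= z_hi)
    half = spec.vessel_separation_mm / 2.0
    vessel = np.zeros(shape, dtype=bool)
    for sx in (-half, half):
        d2 = (pos[0] - sx) ** 2 + pos[1] ** 2
        vessel |= (d2 <= spec.vessel_radius_mm**2) & in_z
    vessel &= ~brain

    # ventricles carved out of the white-matter core
    ventricle = np.zeros(shape, dtype=bool)
    for axes, vc in zip(spec.ventricle_semi_axes_mm, spec.ventricle_centres_mm):
        vrel = rel - np.asarray(vc).reshape(3, 1, 1, 1)
        v2 = sum((vrel[a] / axes[a]) ** 2 for a in range(3))
        ventricle |= v2 <= 1.0
    ventricle &= wm
    wm = wm & ~ventricle

    masks = {"gm": gm, "wm": wm, "ventricle": ventricle, "vessel": vessel}
    background = ~(gm | wm | ventricle | vessel)
    masks["background"] = background
    return masks


# --------------------------------------------------------------------------- #
# Simulation
# --------------------------------------------------------------------------- #


def region_curves(
    spec: PhantomSpec, t_end: float
) -> tuple[np.ndarray, dict[str, np.ndarray], InputFunction, InputFunction]:
    """Continuous per-region tissue curves on a 1-s grid."""
    grid = np.arange(0.0, t_end + 1.0, 1.0)
    aif = feng_aif(grid, spec.aif_params)
    wb = whole_blood_from_plasma(aif, *spec.plasma_ratio)
    curves = {}
    for name, params in spec.kinetics.items():
        curves[name] = tissue_tac(params, aif, wb, grid)
    return grid, curves, aif, wb


def simulate_series(
    spec: PhantomSpec, schedule: FrameSchedule
) -> tuple[DynamicPETSeries, GroundTruth]:
    """Noise-free, motion-free dynamic series plus full ground truth.

    Each frame is the frame-duration average of the regional tissue curves
    (tissue uptake plus fractional blood volume), convolved with an isotropic
    Gaussian PSF of ``spec.psf_fwhm``.
    """
    masks = region_masks(spec)
    for name in masks:
        if name != "background" and name not in spec.kinetics:
            raise ValueError(f"kinetic parameters missing for region {name!r}")
    grid, curves, aif, wb = region_curves(spec, schedule.total_duration)

    frame_vals = {
        name: frame_average(grid, c, schedule) for name, c in curves.items()
    }

    sigma_vox = np.array(
        [spec.psf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / v for v in spec.voxel_size]
    )
    blurred = {}
    for name in spec.kinetics:
        m = masks[name].astype(np.float32)
        blurred[name] = (
            ndimage.gaussian_filter(m, sigma_vox) if spec.psf_fwhm > 0 else m
        )

    data = np.zeros(spec.grid_shape + (len(schedule),), dtype=np.float32)
    for i in range(len(schedule)):
        frame = np.zeros(spec.grid_shape, dtype=np.float32)
        for name in spec.kinetics:
            frame += blurred[name] * np.float32(frame_vals[name][i])
        data[..., i] = frame
    np.maximum(data, 0.0, out=data)

    series = DynamicPETSeries(
        data=data, schedule=schedule, voxel_size=spec.voxel_size,
        frame_of_reference="phantom",
    )

    pconf = PatlakConfig(plasma_glucose=spec.plasma_glucose)
    true_ki = {name: p.Ki for name, p in spec.kinetics.items()}
    truth = GroundTruth(
        region_masks=masks,
        true_aif=aif,
        true_whole_blood=wb,
        applied_motion=[MotionVector.identity() for _ in range(len(schedule))],
        true_Ki=true_ki,
        plasma_glucose=spec.plasma_glucose,
        true_CMRGlc={name: cmrglc(ki, pconf) for name, ki in true_ki.items()},
    )
    return series, truth


def add_poisson_noise(
    series: DynamicPETSeries, spec: PhantomSpec, seed: int
) -> DynamicPETSeries:
    """Duration-dependent Poisson counting noise.

    Expected counts per voxel and frame are ``value * duration *
    count_sensitivity``; the returned image is counts back-converted to
    Bq/mL, so relative noise falls as 1/sqrt(frame duration).
    """
    if np.any(series.data < 0):
        raise ValueError("noise model requires a non-negative series")
    rng = np.random.default_rng(seed)
    out = np.empty_like(series.data, dtype=np.float32)
    durations = series.schedule.durations
    for i in range(series.n_frames):
        scale = durations[i] * spec.count_sensitivity
        lam = series.data[..., i].astype(np.float64) * scale
        out[..., i] = (rng.poisson(lam) / scale).astype(np.float32)
    return DynamicPETSeries(out, series.schedule, series.voxel_size, series.frame_of_reference)


# --------------------------------------------------------------------------- #
# Motion injection
# --------------------------------------------------------------------------- #


def draw_interframe_motion(
    n_frames: int,
    voxel_size: tuple[float, float, float],
    seed: int,
    reference_index: int | None = None,
) -> list[MotionVector]:
    """The simulated-motion protocol: per non-reference frame, translations of
    0, 1 or 2 voxels per axis (random sign) and rotations of 0, 0.5 or 1
    degree per Euler angle (random sign)."""
    rng = np.random.default_rng(seed)
    if reference_index is None:
        reference_index = n_frames - 1
    vectors = []
    for i in range(n_frames):
        if i == reference_index:
            vectors.append(MotionVector.identity())
            continue
        t_vox = rng.choice([0, 1, 2], size=3)
        r_deg = rng.choice([0.0, 0.5, 1.0], size=3)
        signs_t = rng.choice([-1, 1], size=3)
        signs_r = rng.choice([-1, 1], size=3)
        t_mm = t_vox * signs_t * np.asarray(voxel_size)
        r = r_deg * signs_r
        vectors.append(MotionVector(*t_mm, *r))
    return vectors


def inject_interframe_motion(
    series: DynamicPETSeries,
    truth: GroundTruth,
    seed: int,
) -> tuple[DynamicPETSeries, GroundTruth]:
    """Apply the interframe-motion protocol to every non-reference frame.

    The reference frame (last, 55-60 min) is untouched; applied vectors are
    recorded in the returned ground truth.  Out-of-field voxels are zero.
    """
    vectors = draw_interframe_motion(
        series.n_frames, series.voxel_size, seed, series.reference_index
    )
    data = np.empty_like(series.data)
    for i, vec in enumerate(vectors):
        data[..., i] = apply_motion(series.data[..., i], vec, series.voxel_size)
    moved = DynamicPETSeries(data, series.schedule, series.voxel_size, series.frame_of_reference)
    new_truth = replace_motion(truth, vectors)
    return moved, new_truth


def replace_motion(truth: GroundTruth, vectors: list[MotionVector]) -> GroundTruth:
    return GroundTruth(
        region_masks=truth.region_masks,
        true_aif=truth.true_aif,
        true_whole_blood=truth.true_whole_blood,
        applied_motion=list(vectors),
        true_Ki=truth.true_Ki,
        plasma_glucose=truth.plasma_glucose,
        true_CMRGlc=truth.true_CMRGlc,
        intraframe_motion=truth.intraframe_motion,
    )


# --------------------------------------------------------------------------- #
# Reference-frame partitioning (intraframe experiment)
# --------------------------------------------------------------------------- #


def partition_reference_frame(
    series: DynamicPETSeries,
    spec: PhantomSpec,
    subframe_duration_s: float,
    seed: int,
) -> list[np.ndarray]:
    """Split the (noise-free) reference frame into short Poisson subframes.

    A simulation stand-in for list-mode partitioning: Poisson thinning of
    list-mode counts yields independent Poisson subframes, so each subframe is
    an independent Poisson realization of the noise-free reference frame at
    the subframe duration.  300 s at 15 s gives 20 subframes; at 30 s, 10.
    """
    t0, t1 = series.schedule.intervals[series.reference_index]
    duration = t1 - t0
    n = duration / subframe_duration_s
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"subframe duration {subframe_duration_s} s does not divide the "
            f"reference frame duration {duration} s"
        )
    n = int(round(n))
    ref = series.data[..., series.reference_index].astype(np.float64)
    if np.any(ref < 0):
        raise ValueError("reference frame must be non-negative")
    rng = np.random.default_rng(seed)
    scale = subframe_duration_s * spec.count_sensitivity
    return [
        (rng.poisson(ref * scale) / scale).astype(np.float32) for _ in range(n)
    ]


def inject_intraframe_motion(
    subframes: list[np.ndarray],
    voxel_size: tuple[float, float, float],
    seed: int,
    move_fraction: float = 0.5,
) -> tuple[list[np.ndarray], list[MotionVector]]:
    """Random rigid motion on a random subset of subframes.

    Per-axis translation magnitude uniform in [3, 5] mm (random sign),
    rotations uniform in [0, 1) degree per Euler angle.
    """
    if len(subframes) < 2:
        raise ValueError("need >= 2 subframes")
    rng = np.random.default_rng(seed)
    moved = []
    vectors = []
    for sf in subframes:
        if rng.random() < move_fraction:
            t = rng.uniform(3.0, 5.0, size=3) * rng.choice([-1, 1], size=3)
            r = rng.uniform(0.0, 1.0, size=3)
            vec = MotionVector(*t, *r)
        else:
            vec = MotionVector.identity()
        vectors.append(vec)
        moved.append(apply_motion(sf, vec, voxel_size) if not vec.is_identity() else sf.copy())
    return moved, vectors


# --------------------------------------------------------------------------- #
# Multi-subject convenience
# --------------------------------------------------------------------------- #


def random_subject_spec(base: PhantomSpec, seed: int) -> PhantomSpec:
    """Per-subject anatomical/kinetic variation around a base spec.

    Rate constants jitter by ±15%, brain size by ±8%, injected dose scale by
    ±20% — enough variation for the cGAN training set to generalise across
    phantom subjects.
    """
    rng = np.random.default_rng(seed)
    kin = {}
    for name, p in base.kinetics.items():
        f = lambda: float(rng.uniform(0.85, 1.15))
        kin[name] = KineticParams(
            K1=p.K1 * f(), k2=p.k2 * f(), k3=p.k3 * f(), Vb=min(1.0, p.Vb * f())
        )
    axes = tuple(a * float(rng.uniform(0.92, 1.08)) for a in base.brain_semi_axes_mm)
    a1, a2, a3, l1, l2, l3, t0 = base.aif_params
    dose = float(rng.uniform(0.8, 1.2))
    aif = (a1 * dose, a2 * dose, a3 * dose, l1, l2, l3, t0)
    return replace(
        base, kinetics=kin, brain_semi_axes_mm=axes, aif_params=aif, rng_seed=seed
    )


@dataclass
class PhantomDataset:
    """One simulated subject: clean and noisy series plus ground truth."""

    spec: PhantomSpec
    schedule: FrameSchedule
    clean: DynamicPETSeries
    noisy: DynamicPETSeries
    truth: GroundTruth


def make_dataset(
    spec: PhantomSpec,
    schedule: FrameSchedule | None = None,
    seed: int | None = None,
) -> PhantomDataset:
    """Simulate, then add counting noise (seed defaults to ``spec.rng_seed``)."""
    if schedule is None:
        schedule = make_schedule(DEFAULT_FRAME_PATTERN)
    if seed is None:
        seed = spec.rng_seed
    clean, truth = simulate_series(spec, schedule)
    noisy = add_poisson_noise(clean, spec, seed)
    return PhantomDataset(spec, schedule, clean, noisy, truth)
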