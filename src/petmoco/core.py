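"""Core domain types shared across the pipeline.

Conventions
-----------
* Volumes are ``(nx, ny, nz)`` arrays; dynamic series are ``(nx, ny, nz, n_frames)``.
* Rigid motion is parameterised by 3 translations (mm, world axes) and 3 Euler
  rotations (degrees, intrinsic Z-Y-X) about the image centre.  ``apply_motion``
  moves the imaged object by the vector; correcting a frame therefore resamples
  it by the *inverse* of its motion estimate.
* Resampling is trilinear with zero fill outside the field of view.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation


# --------------------------------------------------------------------------- #
# Frame timing
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered, contiguous acquisition frame intervals in seconds."""

    intervals: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.intervals) == 0:
            raise ValueError("empty schedule")
        prev_end = 0.0
        for (t0, t1) in self.intervals:
            if t1 <= t0:
                raise ValueError(f"non-positive frame duration: ({t0}, {t1})")
            if abs(t0 - prev_end) > 1e-9:
                raise ValueError("intervals must be contiguous and start at 0")
            prev_end = t1

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def starts(self) -> np.ndarray:
        return np.array([t0 for t0, _ in self.intervals])

    @property
    def ends(self) -> np.ndarray:
        return np.array([t1 for _, t1 in self.intervals])

    @property
    def durations(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def mid_times(self) -> np.ndarray:
        return 0.5 * (self.starts + self.ends)

    @property
    def total_duration(self) -> float:
        return float(self.ends[-1])


def make_schedule(pattern: Sequence[tuple[int, float]]) -> FrameSchedule:
    """Build a contiguous schedule from ``[(count, duration_s), ...]``.

    ``make_schedule([(24, 5), (1, 60), (1, 120), (11, 300)])`` reproduces the
    37-frame, 60-min dynamic FDG brain protocol.
    """
    if len(pattern) == 0:
        raise ValueError("empty schedule")
    intervals: list[tuple[float, float]] = []
    t = 0.0
    for count, duration in pattern:
        if count < 1:
            raise ValueError(f"frame count must be >= 1, got {count}")
        if duration <= 0:
            raise ValueError(f"frame duration must be > 0, got {duration}")
        for _ in range(int(count)):
            intervals.append((t, t + duration))
            t += duration
    return FrameSchedule(tuple(intervals))


# --------------------------------------------------------------------------- #
# Rigid motion
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class MotionVector:
    """6-parameter rigid transform: translations in mm, rotations in degrees.

    Rotations are intrinsic Z-Y-X Euler angles about the image centre.
    """

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0

    @classmethod
    def identity(cls) -> "MotionVector":
        return cls()

    @classmethod
    def from_params(cls, params: Sequence[float]) -> "MotionVector":
        tx, ty, tz, rx, ry, rz = (float(p) for p in params)
        return cls(tx, ty, tz, rx, ry, rz)

    @property
    def params(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz, self.rx, self.ry, self.rz])

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz])

    @property
    def rotation_deg(self) -> np.ndarray:
        return np.array([self.rx, self.ry, self.rz])

    def rotation_matrix(self) -> np.ndarray:
        # intrinsic Z-Y-X: R = Rz(rz) @ Ry(ry) @ Rx(rx)
        return Rotation.from_euler(
            "ZYX", [self.rz, self.ry, self.rx], degrees=True
        ).as_matrix()

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix acting on centred world-mm coordinates."""
        m = np.eye(4)
        m[:3, :3] = self.rotation_matrix()
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "MotionVector":
        rot = Rotation.from_matrix(m[:3, :3])
        rz, ry, rx = rot.as_euler("ZYX", degrees=True)
        tx, ty, tz = m[:3, 3]
        return cls(float(tx), float(ty), float(tz), float(rx), float(ry), float(rz))

    def compose(self, other: "MotionVector") -> "MotionVector":
        """Return the transform applying ``other`` first, then ``self``."""
        return MotionVector.from_matrix(self.matrix() @ other.matrix())

    def invert(self) -> "MotionVector":
        return MotionVector.from_matrix(np.linalg.inv(self.matrix()))

    def is_identity(self, atol: float = 1e-9) -> bool:
        return bool(np.all(np.abs(self.params) <= atol))

    def magnitude(self) -> tuple[float, float]:
        """(translation norm in mm, rotation angle in degrees)."""
        angle = float(np.degrees(Rotation.from_matrix(self.rotation_matrix()).magnitude()))
        return float(np.linalg.norm(self.translation)), angle


def apply_motion(
    volume: np.ndarray,
    vec: MotionVector,
    voxel_size: Sequence[float],
    order: int = 1,
) -> np.ndarray:
    """Resample ``volume`` so the imaged object moves by ``vec``.

    The moved image satisfies ``moved(x) = volume(R^-1 (x - t))`` in world-mm
    coordinates centred on the image centre.  Trilinear by default, zero fill
    outside the field of view.
    """
    if vec.is_identity():
        return volume.copy()
    voxel_size = np.asarray(voxel_size, dtype=float)
    centre = (np.array(volume.shape, dtype=float) - 1.0) / 2.0
    r_inv = vec.rotation_matrix().T
    s = np.diag(voxel_size)
    s_inv = np.diag(1.0 / voxel_size)
    matrix = s_inv @ r_inv @ s
    offset = centre - matrix @ centre - s_inv @ r_inv @ vec.translation
    return ndimage.affine_transform(
        volume, matrix, offset=offset, order=order, mode="constant", cval=0.0,
        prefilter=order > 1,
    )


# --------------------------------------------------------------------------- #
# Dynamic series and blood curves
# --------------------------------------------------------------------------- #


@dataclass
class DynamicPETSeries:
    """4D activity-concentration image (Bq/mL) with its frame schedule."""

    data: np.ndarray  # (nx, ny, nz, n_frames)
    schedule: FrameSchedule
    voxel_size: tuple[float, float, float]
    frame_of_reference: str = "native"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("series data must be 4D (x, y, z, frame)")
        if self.data.shape[3] != len(self.schedule):
            raise ValueError(
                f"frame count {self.data.shape[3]} != schedule length {len(self.schedule)}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("series contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def frame(self, i: int) -> np.ndarray:
        return self.data[..., i]

    @property
    def reference_index(self) -> int:
        """Index of the reference frame F_ref (last frame, 55-60 min)."""
        return self.n_frames - 1

    def copy(self) -> "DynamicPETSeries":
        return DynamicPETSeries(
            self.data.copy(), self.schedule, self.voxel_size, self.frame_of_reference
        )


@dataclass
class InputFunction:
    """Sampled blood time-activity curve.

    ``kind`` distinguishes whole-blood from plasma concentrations; both are in
    Bq/mL on a strictly increasing time grid in seconds.
    """

    t: np.ndarray
    value: np.ndarray
    kind: str = "plasma"  # "plasma" | "whole_blood"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.t.shape != self.value.shape or self.t.ndim != 1:
            raise ValueError("t and value must be matching 1D arrays")
        if len(self.t) < 2:
            raise ValueError("input function needs >= 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(self.value < -1e-9):
            raise ValueError("negative activity concentration")
        if self.kind not in ("plasma", "whole_blood"):
            raise ValueError(f"unknown curve kind {self.kind!r}")

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        """Linear interpolation, zero-held outside the sampled support."""
        return np.interp(t, self.t, self.value, left=self.value[0], right=self.value[-1])

    def auc(self, t0: float | None = None, t1: float | None = None) -> float:
        t0 = self.t[0] if t0 is None else t0
        t1 = self.t[-1] if t1 is None else t1
        if not (t0 < t1):
            raise ValueError("empty integration interval")
        grid = np.unique(np.concatenate([[t0, t1], self.t[(self.t > t0) & (self.t < t1)]]))
        return float(np.trapezoid(self(grid), grid))


@dataclass
class MotionEstimate:
    """Per-frame registration result."""

    frame: int
    vector: MotionVector
    final_mi: float = float("nan")
    converged: bool = True
    note: str = ""
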