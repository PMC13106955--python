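"""Core spatial types shared across the pipeline.

A :class:`Volume3D` is a scalar 3D image on an axis-aligned grid with
anisotropic voxel spacing and a physical origin, the common currency of
registration, synthesis and patch sampling.  Arrays are indexed ``[i, j, k]``
and the physical coordinate of a voxel is ``origin + index * spacing`` on the
matching axis, so axis 0 is "x", axis 1 "y", axis 2 "z" in millimetres.

A :class:`RigidTransform` is a 6-parameter rotation + translation acting on
physical points, ``T(p) = R (p - c) + c + t`` with rotation centre ``c``.
Internally the rotation is stored as a matrix so that composition and
inversion are exact; Euler angles (degrees, R = Rz Ry Rx) are offered as a
parameterization for construction and serialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk

# single-threaded ITK: bitwise-reproducible metric reductions under a fixed seed
sitk.ProcessObject_SetGlobalDefaultNumberOfThreads(1)

__all__ = [
    "Volume3D",
    "RigidTransform",
    "resample_to_grid",
    "load_volume",
    "save_volume",
    "load_landmarks",
    "save_landmarks",
]


@dataclass
class Volume3D:
    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D requires a 3D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical side lengths of the sampled field of view."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @property
    def center_mm(self) -> np.ndarray:
        """Physical centre of the volume (half extent from the origin)."""
        return np.asarray(self.origin) + 0.5 * (np.asarray(self.shape) - 1) * np.asarray(self.spacing)

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * np.asarray(self.spacing)

    def physical_to_index(self, pt: np.ndarray) -> np.ndarray:
        return (np.asarray(pt, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def contains_point(self, pt: np.ndarray) -> bool:
        idx = self.physical_to_index(pt)
        return bool(np.all(idx >= 0) and np.all(idx <= np.asarray(self.shape) - 1))

    def copy_with(self, data: np.ndarray) -> "Volume3D":
        return Volume3D(data, self.spacing, self.origin)

    # --- SimpleITK bridging (sitk uses x-fastest order, ours is axis 0 = x) ---
    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.data.T.astype(np.float64)))
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "Volume3D":
        arr = sitk.GetArrayFromImage(img).T
        return cls(np.ascontiguousarray(arr), tuple(img.GetSpacing()), tuple(img.GetOrigin()))


def _euler_matrix_deg(angles_deg: np.ndarray) -> np.ndarray:
    """R = Rz @ Ry @ Rx for intrinsic rotations about the fixed axes."""
    rx, ry, rz = np.deg2rad(np.asarray(angles_deg, dtype=float))
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _euler_from_matrix_deg(R: np.ndarray) -> np.ndarray:
    """Inverse of :func:`_euler_matrix_deg` (gimbal-safe for |ry| < 90 deg)."""
    ry = np.arcsin(np.clip(-R[2, 0], -1.0, 1.0))
    if np.isclose(np.cos(ry), 0.0):
        rx = np.arctan2(-R[1, 2], R[1, 1])
        rz = 0.0
    else:
        rx = np.arctan2(R[2, 1], R[2, 2])
        rz = np.arctan2(R[1, 0], R[0, 0])
    return np.rad2deg(np.array([rx, ry, rz]))


@dataclass
class RigidTransform:
    """Rigid motion of physical space, ``T(p) = R (p - c) + c + t``."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if not np.allclose(self.matrix @ self.matrix.T, np.eye(3), atol=1e-6):
            raise ValueError("matrix is not a rotation (R R^T != I)")

    @classmethod
    def identity(cls, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), np.asarray(center, dtype=float))

    @classmethod
    def from_euler(cls, rotation_deg, translation_mm, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(_euler_matrix_deg(rotation_deg), np.asarray(translation_mm, dtype=float),
                   np.asarray(center, dtype=float))

    @property
    def euler_deg(self) -> np.ndarray:
        return _euler_from_matrix_deg(self.matrix)

    @property
    def offset(self) -> np.ndarray:
        """b in the affine form T(p) = R p + b."""
        return self.center + self.translation - self.matrix @ self.center

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix.T + self.offset
        return out[0] if np.asarray(points).ndim == 1 else out

    def inverse(self) -> "RigidTransform":
        Rinv = self.matrix.T
        # solve t' from affine inverse: A' = R^T, b' = -R^T b
        b = self.offset
        b_inv = -Rinv @ b
        t_inv = b_inv - self.center + Rinv @ self.center
        return RigidTransform(Rinv, t_inv, self.center.copy())

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (other applied first); centre taken from self."""
        A = self.matrix @ other.matrix
        b = self.matrix @ other.offset + self.offset
        t = b - self.center + A @ self.center
        return RigidTransform(A, t, self.center.copy())

    def magnitude(self) -> tuple[float, float]:
        """(rotation angle deg, translation norm mm) of the motion."""
        angle = np.rad2deg(np.arccos(np.clip((np.trace(self.matrix) - 1) / 2, -1.0, 1.0)))
        return float(angle), float(np.linalg.norm(self.translation))

    # --- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "parameterization": "euler_deg_ZYX",
            "rotation_deg": [float(v) for v in self.euler_deg],
            "translation_mm": [float(v) for v in self.translation],
            "center_mm": [float(v) for v in self.center],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls.from_euler(d["rotation_deg"], d["translation_mm"], d["center_mm"])

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load_json(cls, path) -> "RigidTransform":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_sitk(self) -> sitk.Transform:
        tf = sitk.Euler3DTransform()
        tf.SetCenter(tuple(self.center))
        tf.SetMatrix(tuple(self.matrix.ravel()))
        tf.SetTranslation(tuple(self.translation))
        return tf

    @classmethod
    def from_sitk(cls, tf: sitk.Transform) -> "RigidTransform":
        if tf.GetName() == "CompositeTransform":
            tf = sitk.CompositeTransform(tf).GetNthTransform(0)
        if hasattr(tf, "Downcast"):
            tf = tf.Downcast()
        M = np.asarray(tf.GetMatrix()).reshape(3, 3)
        return cls(M, np.asarray(tf.GetTranslation()), np.asarray(tf.GetCenter()))


def resample_to_grid(moving: Volume3D, reference: Volume3D, transform: RigidTransform | None = None,
                     *, motion: RigidTransform | None = None, interpolation: str = "linear",
                     fill_value: float | None = None) -> Volume3D:
    """Resample ``moving`` onto the grid of ``reference``.

    ``transform`` maps reference-space physical points into moving space (the
    registration convention).  Alternatively pass ``motion``, the forward
    motion of the object, which is inverted internally.  ``fill_value``
    defaults to the minimum of the moving image (air-like background).
    """
    if transform is not None and motion is not None:
        raise ValueError("pass either transform or motion, not both")
    if transform is None:
        transform = motion.inverse() if motion is not None else RigidTransform.identity()
    interp = {"linear": sitk.sitkLinear, "nearest": sitk.sitkNearestNeighbor,
              "bspline": sitk.sitkBSpline}[interpolation]
    if fill_value is None:
        fill_value = float(np.min(moving.data))
    out = sitk.Resample(moving.to_sitk(), reference.to_sitk(), transform.to_sitk(),
                        interp, float(fill_value))
    res = Volume3D.from_sitk(out)
    res.data = res.data.astype(np.asarray(moving.data).dtype if np.issubdtype(
        np.asarray(moving.data).dtype, np.floating) else np.float64)
    return res


# --- NIfTI and landmark I/O ------------------------------------------------

def save_volume(vol: Volume3D, path) -> None:
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), affine), str(path))


def load_volume(path) -> Volume3D:
    img = nib.load(str(path))
    affine = img.affine
    spacing = tuple(np.abs(np.diag(affine)[:3]))
    origin = tuple(affine[:3, 3])
    return Volume3D(np.asarray(img.get_fdata()), spacing, origin)


def save_landmarks(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def load_landmarks(path) -> pd.DataFrame:
    return pd.read_csv(path)
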