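"""Rigid positioning perturbations of a phantom relative to a fixed beam.

The phantom moves and the beam stays put, matching the patient-motion
framing of a setup-error study: lateral shifts slide the phantom parallel
to the aperture plane, outward shifts translate it along the beam away
from the aperture (creating an air gap), rotations turn it about the beam
central axis, and tilts rotate it about the left-right axis through the
phantom centroid (sagittal-plane tilt).  Resampling is inverse-mapping
nearest-neighbour so material labels and boolean masks survive exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage

from .beam import BeamConfig
from .phantom import AIR_LABEL, ROISet, VoxelPhantom

__all__ = ["ShiftSpec", "RigidTransform", "transform_from_spec",
           "apply_transform", "SHIFT_KINDS"]

SHIFT_KINDS = ("left", "right", "superior", "inferior", "outward",
               "rotation", "tilt", "none")

_TRANSLATION_AXES = {
    # left/right along -/+x, superior/inferior along +/-z,
    # outward along +y (away from the aperture, the beam direction).
    "left": np.array([-1.0, 0.0, 0.0]),
    "right": np.array([1.0, 0.0, 0.0]),
    "superior": np.array([0.0, 0.0, 1.0]),
    "inferior": np.array([0.0, 0.0, -1.0]),
    "outward": np.array([0.0, 1.0, 0.0]),
}


@dataclass(frozen=True)
class ShiftSpec:
    """One positioning perturbation: cm for translations, signed degrees
    for rotation/tilt (positive = counterclockwise about the axis)."""

    kind: str = "none"
    magnitude: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in SHIFT_KINDS:
            raise ValueError(f"unknown shift kind {self.kind!r}")
        if self.kind in _TRANSLATION_AXES and self.magnitude < 0:
            raise ValueError("translation magnitude must be non-negative")
        if self.kind == "none" and self.magnitude != 0:
            raise ValueError("kind 'none' requires zero magnitude")

    @property
    def is_angular(self) -> bool:
        return self.kind in ("rotation", "tilt")


@dataclass(frozen=True)
class RigidTransform:
    """World-frame rigid map ``p -> R p + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthonormal")
        if not math.isclose(float(np.linalg.det(R)), 1.0, abs_tol=1e-9):
            raise ValueError("rotation matrix must have determinant +1")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self after other: ``p -> self(other(p))``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation
                              + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T,
                              -(self.rotation.T @ self.translation))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def _axis_rotation(axis: np.ndarray, degrees: float) -> np.ndarray:
    a = axis / np.linalg.norm(axis)
    c, s = math.cos(math.radians(degrees)), math.sin(math.radians(degrees))
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) * c + s * K + (1 - c) * np.outer(a, a)


def transform_from_spec(spec: ShiftSpec, beam: BeamConfig,
                        pivot: Optional[Tuple[float, float, float]] = None
                        ) -> RigidTransform:
    """Build the world-frame rigid transform for one perturbation.

    Rotations pivot about the beam central axis (through the aperture
    centre); tilts pivot about the left-right (x) axis through ``pivot``,
    which callers should set to the phantom tissue centroid (defaults to
    the beam axis position when omitted).
    """
    if spec.kind == "none":
        return RigidTransform.identity()
    if spec.kind in _TRANSLATION_AXES:
        return RigidTransform(np.eye(3),
                              _TRANSLATION_AXES[spec.kind] * spec.magnitude)
    p = np.asarray(pivot if pivot is not None else beam.beam_axis_position,
                   dtype=float)
    if spec.kind == "rotation":
        # About the beam axis (+y) through the aperture centre; the pivot's
        # y component is irrelevant for a rotation about y.
        p = np.array([beam.beam_axis_position[0], p[1],
                      beam.beam_axis_position[2]])
        R = _axis_rotation(np.array([0.0, 1.0, 0.0]), spec.magnitude)
    elif spec.kind == "tilt":
        R = _axis_rotation(np.array([1.0, 0.0, 0.0]), spec.magnitude)
    else:  # pragma: no cover - kinds exhausted
        raise ValueError(f"unknown shift kind {spec.kind!r}")
    return RigidTransform(R, p - R @ p)


def _index_affine(t: RigidTransform, phantom: VoxelPhantom):
    """Inverse index-space mapping for ``scipy.ndimage.affine_transform``:
    output voxel index -> input voxel index."""
    S = np.diag(phantom.spacing)
    Sinv = np.diag([1.0 / s for s in phantom.spacing])
    Rt = t.rotation.T
    origin = np.asarray(phantom.origin)
    half = 0.5 * np.asarray(phantom.spacing)
    A = Sinv @ Rt @ S
    b = Sinv @ (Rt @ (origin + half - t.translation) - origin) - 0.5
    # Snap near-integer pure translations so exact voxel-pitch moves reduce
    # to index shifts (no nearest-neighbour boundary jitter).
    if np.allclose(A, np.eye(3), atol=1e-12):
        A = np.eye(3)
        b = np.where(np.abs(b - np.round(b)) < 1e-9, np.round(b), b)
    return A, b


def apply_transform(phantom: VoxelPhantom, roiset: ROISet,
                    t: RigidTransform) -> Tuple[VoxelPhantom, ROISet]:
    """Resample phantom and masks onto the same grid after moving by ``t``.

    Voxels whose pre-image falls outside the original domain become air
    (empty mask); masks stay boolean.
    """
    A, b = _index_affine(t, phantom)
    labels = ndimage.affine_transform(
        phantom.material_grid, A, offset=b, order=0,
        mode="constant", cval=AIR_LABEL,
        output=phantom.material_grid.dtype)
    lut = np.zeros(int(labels.max()) + 1)
    for label, mat in phantom.material_table.items():
        if label < lut.size:
            lut[label] = mat.density
    moved = VoxelPhantom(labels, lut[labels], phantom.spacing, phantom.origin,
                         phantom.material_table)
    masks: Dict[str, np.ndarray] = {}
    for name, mask in roiset.masks.items():
        out = ndimage.affine_transform(
            mask.astype(np.uint8), A, offset=b, order=0,
            mode="constant", cval=0, output=np.uint8)
        masks[name] = out.astype(bool)
    if "tumor" in masks and "normal_brain" in masks:
        masks["normal_brain"] &= ~masks["tumor"]
    return moved, ROISet(masks)
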