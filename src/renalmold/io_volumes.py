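"""Image volumes, segmentation sets and anatomic landmarks.

This module owns all coordinate conventions used by the package:

* World coordinates are millimetres in the RAS+ frame of the NIfTI affine;
  volumes are reoriented to the closest canonical (RAS+) orientation on load.
* Voxel indices are 0-based and refer to voxel *centers*; the 4x4 affine maps
  continuous voxel indices to world mm.

A specimen is described by a :class:`SegmentationSet` (binary masks for the
tumor, normal kidney, perinephric fat and optionally the renal pelvis, all on
one lattice) and a :class:`LandmarkSet` (named world-mm points: the kidney
poles, the hilum and the fat contact points). The union of the role masks is
the specimen *outline*, which defines the mold cavity downstream.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "SEGMENTATION_ROLES",
    "ROLE_PRECEDENCE",
    "DEFAULT_ROLE_LABELS",
    "LANDMARK_ROLES",
    "REQUIRED_LANDMARKS",
    "ImageVolume",
    "SegmentationSet",
    "LandmarkSet",
    "world_to_voxel",
    "voxel_to_world",
    "read_image_volume",
    "write_image_volume",
    "read_segmentation_set",
    "write_segmentation_set",
    "read_landmarks",
    "write_landmarks",
    "check_landmarks_within_outline",
]

#: Tissue roles a segmentation set may carry. ``tumor`` is mandatory.
SEGMENTATION_ROLES = ("tumor", "kidney", "fat", "pelvis")

#: When flattening overlapping role masks into a single label volume the
#: earlier role wins (tumor boundary accuracy dominates validation).
ROLE_PRECEDENCE = ("tumor", "kidney", "fat", "pelvis")

DEFAULT_ROLE_LABELS = {"tumor": 1, "kidney": 2, "fat": 3, "pelvis": 4}

#: Anatomic landmark roles. The first four are required to orient a specimen.
LANDMARK_ROLES = (
    "upper_pole",
    "lower_pole",
    "hilum",
    "tumor_contact",
    "kidney_contact",
)
REQUIRED_LANDMARKS = ("upper_pole", "lower_pole", "hilum", "tumor_contact")


@dataclass
class ImageVolume:
    """A 3-D scalar lattice with a voxel-index -> world-mm affine."""

    voxels: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


def world_to_voxel(vol: ImageVolume | np.ndarray, points: np.ndarray) -> np.ndarray:
    """Map world-mm point(s) to continuous 0-based voxel indices.

    ``vol`` may be an :class:`ImageVolume` or a bare 4x4 affine. Points
    outside the lattice are returned unclipped; bounds are the caller's
    concern.
    """
    affine = vol.affine if isinstance(vol, ImageVolume) else np.asarray(vol, float)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    inv = np.linalg.inv(affine)
    idx = pts @ inv[:3, :3].T + inv[:3, 3]
    return idx[0] if np.asarray(points).ndim == 1 else idx


def voxel_to_world(vol: ImageVolume | np.ndarray, indices: np.ndarray) -> np.ndarray:
    """Map continuous voxel indices to world mm (inverse of world_to_voxel)."""
    affine = vol.affine if isinstance(vol, ImageVolume) else np.asarray(vol, float)
    idx = np.atleast_2d(np.asarray(indices, dtype=float))
    pts = idx @ affine[:3, :3].T + affine[:3, 3]
    return pts[0] if np.asarray(indices).ndim == 1 else pts


@dataclass
class SegmentationSet:
    """Named binary masks on one shared lattice, plus their union outline."""

    masks: dict[str, np.ndarray]
    affine: np.ndarray
    _outline: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        if "tumor" not in self.masks:
            raise ValueError("tumor mask required")
        clean: dict[str, np.ndarray] = {}
        shape = None
        for role, mask in self.masks.items():
            if role not in SEGMENTATION_ROLES:
                raise ValueError(f"unknown segmentation role {role!r}")
            m = np.asarray(mask).astype(bool)
            if shape is None:
                shape = m.shape
            elif m.shape != shape:
                raise ValueError("all masks must share one lattice shape")
            clean[role] = m
        self.masks = clean
        if not self.masks["tumor"].any():
            raise ValueError("tumor mask required (tumor mask is empty)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.masks["tumor"].shape

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def outline(self) -> np.ndarray:
        """Voxelwise union of all role masks (the specimen outline)."""
        if self._outline is None:
            out = np.zeros(self.shape, dtype=bool)
            for mask in self.masks.values():
                out |= mask
            self._outline = out
        return self._outline


@dataclass
class LandmarkSet:
    """Named anatomic points in world mm."""

    points: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for role, p in self.points.items():
            if role not in LANDMARK_ROLES:
                raise ValueError(f"unknown landmark role {role!r}")
            arr = np.asarray(p, dtype=float).reshape(-1)
            if arr.shape != (3,) or not np.all(np.isfinite(arr)):
                raise ValueError(f"landmark {role!r} must be a finite [x, y, z] mm triple")
            clean[role] = arr
        missing = [r for r in REQUIRED_LANDMARKS if r not in clean]
        if missing:
            raise ValueError(
                "missing required landmark role(s): " + ", ".join(missing)
            )
        if np.allclose(clean["upper_pole"], clean["lower_pole"]):
            raise ValueError("upper_pole and lower_pole must differ")
        self.points = clean

    def __getitem__(self, role: str) -> np.ndarray:
        return self.points[role]

    def __contains__(self, role: str) -> bool:
        return role in self.points


# ---------------------------------------------------------------------------
# NIfTI / JSON I/O
# ---------------------------------------------------------------------------

def read_image_volume(path: str | Path) -> ImageVolume:
    """Load a NIfTI volume, reoriented to the closest canonical (RAS+) frame."""
    img = nib.as_closest_canonical(nib.load(str(path)))
    return ImageVolume(np.asanyarray(img.dataobj), img.affine)


def write_image_volume(vol: ImageVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(vol.voxels, vol.affine), str(path))


def read_segmentation_set(
    label_volume_path: str | Path, role_map: Mapping[int, str]
) -> SegmentationSet:
    """Split an integer NIfTI label volume into per-role binary masks.

    ``role_map`` assigns label values to roles, e.g. ``{1: "tumor",
    2: "kidney", 3: "fat"}``. Label values present in the volume but absent
    from the map are rejected; a tumor label must be mapped and non-empty.
    """
    vol = read_image_volume(label_volume_path)
    data = vol.voxels
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise ValueError("label volume must contain integer voxel data")
        data = rounded.astype(np.int32)
    role_map = {int(k): str(v) for k, v in role_map.items()}
    if "tumor" not in role_map.values():
        raise ValueError("tumor mask required: role_map assigns no tumor label")
    present = set(np.unique(data)) - {0}
    unknown = sorted(present - set(role_map))
    if unknown:
        raise ValueError(f"label volume contains unmapped label value(s): {unknown}")
    masks = {role: data == label for label, role in role_map.items() if label in present}
    if "tumor" not in masks:
        raise ValueError("tumor mask required (tumor label absent from volume)")
    return SegmentationSet(masks, vol.affine)


def write_segmentation_set(
    segset: SegmentationSet,
    path: str | Path,
    role_labels: Mapping[str, int] = DEFAULT_ROLE_LABELS,
) -> None:
    """Flatten a segmentation set to one integer label volume and save it.

    Overlaps between role masks are resolved by :data:`ROLE_PRECEDENCE`
    (tumor > kidney > fat > pelvis).
    """
    labels = np.zeros(segset.shape, dtype=np.int16)
    for role in reversed(ROLE_PRECEDENCE):  # highest precedence written last
        if role in segset.masks:
            labels[segset.masks[role]] = role_labels[role]
    nib.save(nib.Nifti1Image(labels, segset.affine), str(path))


def read_landmarks(json_path: str | Path) -> LandmarkSet:
    """Read a ``{"role": [x, y, z], ...}`` JSON sidecar (world mm)."""
    with open(json_path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ValueError("landmark file must be a JSON object of role -> [x, y, z]")
    return LandmarkSet({role: np.asarray(p, dtype=float) for role, p in raw.items()})


def write_landmarks(landmarks: LandmarkSet, json_path: str | Path) -> None:
    with open(json_path, "w") as fh:
        json.dump({r: [float(x) for x in p] for r, p in landmarks.points.items()}, fh, indent=1)


def check_landmarks_within_outline(
    landmarks: LandmarkSet, segset: SegmentationSet, tol_mm: float = 5.0
) -> None:
    """Require every landmark to lie within ``tol_mm`` of the outline mask.

    Raises ``ValueError`` naming the first offending landmark. Landmarks sit
    on tissue surfaces, so a small tolerance absorbs contouring/rounding
    slack without accepting grossly misplaced points.
    """
    outline = segset.outline
    dist = ndimage.distance_transform_edt(~outline, sampling=segset.spacing)
    shape = np.array(outline.shape)
    for role, p in landmarks.points.items():
        idx = np.rint(world_to_voxel(segset.affine, p)).astype(int)
        oob = np.any(idx < 0) or np.any(idx >= shape)
        idx = np.clip(idx, 0, shape - 1)
        d = float(dist[tuple(idx)])
        if oob or d > tol_mm:
            raise ValueError(
                f"landmark {role!r} lies {d:.1f} mm outside the specimen outline "
                f"(tolerance {tol_mm:g} mm)"
            )
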