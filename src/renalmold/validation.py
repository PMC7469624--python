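"""Coregistration metrics (Dice) and mold quality control.

The physical study compares photographed tissue sections, cut through the
mold slots, against the MRI contours of the matching slice. The phantom can
only emulate that geometrically: at every slot plane the specimen outline
cross-section is compared against the *cavity* cross-section — the region a
rigid specimen occupies between the carved cavity floor and its own top
surface. Smoothing and the vertical-shadow carve are the only error sources,
so this Dice isolates what the mold itself contributes to coregistration
error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .mold_builder import MoldModel, SlicePlan
from .orientation import ResampledStudy

__all__ = [
    "ValidationReport",
    "dice",
    "slot_cross_sections",
    "check_insertable",
    "mold_qc",
    "validate_mold",
]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient DSC = 2|A∩B| / (|A| + |B|).

    Both regions must live on the same lattice; DSC of two empty regions is
    undefined and raises.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("regions must share one lattice")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError("Dice of two empty regions is undefined")
    return 2.0 * int((a & b).sum()) / (na + nb)


def slot_cross_sections(
    mold: MoldModel,
    study: ResampledStudy,
    plan: SlicePlan | None = None,
) -> list[dict]:
    """Per-plane section pairs: role masks vs. the cavity cross-section.

    For each knife plane the cavity section is built column-wise between the
    carved cavity floor and the outline's top surface at that plane; role
    sections are the raw resampled masks. Planes outside the lattice are
    skipped with a warning.
    """
    plan = plan or mold.plan
    sp = mold.spacing
    seg = study.seg
    out: list[dict] = []
    # voxel offset of the study lattice inside the mold grid
    off = np.rint((study.origin - mold.origin) / sp).astype(int)
    floor_vox = np.rint((mold.cavity_floor_mm - mold.origin[2]) / sp)
    for label, pos in zip(plan.labels, plan.positions):
        i_s = int(round((pos - study.origin[0]) / sp))
        if not (0 <= i_s < seg.shape[0]):
            warnings.warn(f"plane {label} at {pos:g} mm lies outside the lattice; skipped",
                          stacklevel=2)
            continue
        i_m = i_s + off[0]
        sections = {role: seg.masks[role][i_s] for role in seg.masks}
        outline_sec = seg.outline[i_s]

        cavity_sec = np.zeros_like(outline_sec)
        if 0 <= i_m < mold.footprint.shape[0]:
            n1, n2 = outline_sec.shape
            for c in np.flatnonzero(outline_sec.any(axis=1)):
                cm = c + off[1]
                if not (0 <= cm < mold.footprint.shape[1]) or not mold.footprint[i_m, cm]:
                    continue
                zf = int(floor_vox[i_m, cm]) - off[2]
                ztop = int(np.flatnonzero(outline_sec[c])[-1])
                if zf <= ztop:
                    cavity_sec[c, max(zf, 0):ztop + 1] = True
        out.append({
            "label": int(label),
            "position_mm": float(pos),
            "outline": outline_sec,
            "cavity": cavity_sec,
            "roles": sections,
            "crosses_tumor": bool(sections["tumor"].any()),
        })
    return out


def check_insertable(occupancy: np.ndarray, base_voxels: int) -> bool:
    """True iff no material overhangs any cavity column.

    Above the base, once a column is empty it must stay empty all the way to
    the open top, so a rigid specimen can be lowered in vertically.
    """
    region = np.asarray(occupancy).astype(bool)[:, :, base_voxels:]
    return not np.any(region[:, :, 1:] & ~region[:, :, :-1])


@dataclass
class ValidationReport:
    """QC flags and coregistration metrics for one mold run."""

    watertight: bool
    manifold: bool
    insertable: bool
    hole_center_error_mm: dict[str, float]
    hole_diameter_mm: dict[str, float]
    slice_spacing_error_mm: float
    per_slot_dice: dict[int, dict[str, float]] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["per_slot_dice"] = {str(k): v for k, v in self.per_slot_dice.items()}
        return d


def mold_qc(mold: MoldModel) -> ValidationReport:
    """Mesh and occupancy quality control (report-only, never raises).

    Checks watertightness/manifoldness of the mesh, the vertical
    insertability invariant, the placement error and measured opening
    diameter of the two landmark base holes, and the worst interslot
    spacing deviation from the requested slice spacing.
    """
    sp = mold.spacing
    mesh = mold.mesh
    watertight = bool(mesh is not None and mesh.is_watertight)
    manifold = bool(mesh is not None and mesh.is_watertight and mesh.is_winding_consistent)
    insertable = check_insertable(mold.occupancy, mold.base_voxels)

    # base holes: empty base-level voxels inside the solid footprint
    solid2d = mold.cavity_occupancy[:, :, 0]
    openings = solid2d & ~mold.occupancy[:, :, 0]
    lab, nlab = ndimage.label(openings)
    centers = ndimage.center_of_mass(openings, lab, range(1, nlab + 1))
    areas = ndimage.sum_labels(openings, lab, range(1, nlab + 1))
    hole_err: dict[str, float] = {}
    hole_diam: dict[str, float] = {}
    for name, c in mold.hole_centers.items():
        target = (c - mold.origin[:2]) / sp
        if nlab == 0:
            hole_err[name] = float("nan")
            hole_diam[name] = 0.0
            continue
        d2 = [np.hypot(cc[0] - target[0], cc[1] - target[1]) for cc in centers]
        j = int(np.argmin(d2))
        hole_err[name] = float(d2[j] * sp)
        hole_diam[name] = float(2.0 * np.sqrt(areas[j] / np.pi) * sp)

    centers_mm = mold.slot_centers[~np.isnan(mold.slot_centers)]
    if len(centers_mm) > 1:
        spacing_err = float(np.max(np.abs(np.diff(centers_mm) - mold.plan.spacing)))
    else:
        spacing_err = 0.0

    return ValidationReport(
        watertight=watertight,
        manifold=manifold,
        insertable=insertable,
        hole_center_error_mm=hole_err,
        hole_diameter_mm=hole_diam,
        slice_spacing_error_mm=spacing_err,
    )


def validate_mold(mold: MoldModel, study: ResampledStudy) -> ValidationReport:
    """Full validation: QC plus per-slot Dice against the cavity sections."""
    report = mold_qc(mold)
    for sec in slot_cross_sections(mold, study):
        entry: dict = {"crosses_tumor": sec["crosses_tumor"]}
        if sec["outline"].any() or sec["cavity"].any():
            try:
                entry["outline"] = dice(sec["outline"], sec["cavity"])
            except ValueError:
                pass
        for role, mask in sec["roles"].items():
            if mask.any():
                entry[role] = dice(mask, mask & sec["cavity"])
        report.per_slot_dice[sec["label"]] = entry
    return report
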