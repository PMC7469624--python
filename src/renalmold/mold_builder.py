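"""Printable mold construction from a reoriented specimen outline.

The pipeline mirrors the physical object: the Gaussian-smoothed outline is
carved out of a solid block as a vertical-shadow cavity (open top, no
overhangs, so the rigid specimen can be lowered in), knife slots are cut at
the imaging slice positions, a guide comb is added on the +lateral side, and
two 2-cm holes are drilled through the base under the hilum and the tumor
contact point so the pathologist can see and feel the anchor landmarks.

All carving happens on a voxel occupancy grid in the mold frame; the final
triangle mesh is produced by iso-surfacing that grid and simplifying it
(quadric edge-collapse decimation, optional Laplacian pass, Taubin lambda|mu
smoothing), then exported as STL in mm.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage, sparse
from skimage import measure

from .orientation import ResampledStudy, SectioningFrame

__all__ = [
    "MoldSpec",
    "SlicePlan",
    "MoldModel",
    "smooth_outline",
    "extract_surface",
    "simplify_mesh",
    "decimate_mesh",
    "laplacian_smooth",
    "taubin_smooth",
    "build_slice_plan",
    "imaging_aligned_offset",
    "carve_mold",
    "export_stl",
    "design_mold",
    "MoldResult",
]


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass
class MoldSpec:
    """Geometric parameters of the printed block, all in mm.

    The 2-cm landmark hole diameter comes from the sectioning protocol the
    mold implements; the remaining defaults (wall width, knife-slot width,
    uncut bridge under the slots, guide comb depth) are declared printing
    choices.
    """

    block_margin_mm: float = 10.0
    base_thickness_mm: float = 10.0
    slot_width_mm: float = 2.0
    slot_bridge_mm: float = 5.0
    hole_diameter_mm: float = 20.0
    guide_depth_mm: float = 15.0
    slice_spacing_mm: float = 5.0

    def __post_init__(self) -> None:
        for name in (
            "block_margin_mm", "base_thickness_mm", "slot_width_mm",
            "slot_bridge_mm", "hole_diameter_mm", "guide_depth_mm",
            "slice_spacing_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.slot_bridge_mm >= self.base_thickness_mm:
            raise ValueError("slot_bridge_mm must be smaller than base_thickness_mm")


@dataclass
class SlicePlan:
    """Knife-plane centers along the frame normal, labeled from the lower end."""

    positions: np.ndarray
    spacing: float
    offset: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.positions) == 0:
            raise ValueError("slice plan must contain at least one plane")
        if len(self.positions) > 1:
            d = np.diff(self.positions)
            if np.any(d <= 0):
                raise ValueError("plane positions must be strictly increasing")
            if np.any(np.abs(d - self.spacing) > 1e-6):
                raise ValueError("plane spacing must equal slice_spacing_mm")

    @property
    def labels(self) -> np.ndarray:
        return np.arange(1, len(self.positions) + 1)


@dataclass
class MoldModel:
    """Voxel occupancy of the mold plus its derived surface mesh."""

    occupancy: np.ndarray            # final carved mold (True = material)
    cavity_occupancy: np.ndarray     # block + cavity, before slots/holes
    origin: np.ndarray               # frame mm of voxel (0, 0, 0) center
    spacing: float
    spec: MoldSpec
    plan: SlicePlan
    landmark_points: dict[str, np.ndarray]
    hole_centers: dict[str, np.ndarray]
    slot_centers: np.ndarray
    footprint: np.ndarray            # 2-D outline footprint (axes normal, lateral)
    cavity_floor_mm: np.ndarray      # 2-D floor height (frame mm), NaN off-footprint
    base_voxels: int
    guide_region: np.ndarray         # 2-D guide comb footprint
    mesh: trimesh.Trimesh | None = None

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.occupancy.sum()) * self.spacing**3


# ---------------------------------------------------------------------------
# Surface extraction and smoothing
# ---------------------------------------------------------------------------

def smooth_outline(
    mask: np.ndarray,
    spacing_mm: float,
    sigma_mm: float,
    iso_level: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-blur a binary mask; return the scalar field and its re-threshold.

    ``sigma_mm = 0`` is the identity. Smoothing that annihilates the mask is
    an error (the kernel is too wide for the structure).
    """
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be non-negative")
    mask = np.asarray(mask).astype(bool)
    if sigma_mm == 0:
        return mask.astype(float), mask.copy()
    fld = ndimage.gaussian_filter(mask.astype(float), sigma=sigma_mm / spacing_mm)
    out = fld >= iso_level
    if mask.any() and not out.any():
        raise ValueError(
            f"Gaussian smoothing at sigma {sigma_mm:g} mm annihilated the mask; "
            "use a smaller sigma"
        )
    return fld, out


def extract_surface(
    field: np.ndarray,
    spacing_mm: float | np.ndarray,
    iso_level: float = 0.5,
    origin: np.ndarray | None = None,
    supersample: int = 1,
) -> trimesh.Trimesh:
    """Closed, outward-oriented iso-surface of a scalar field (marching cubes).

    ``supersample`` replicates each voxel ``m`` times per axis (order-0)
    before extraction. On *binary* inputs this moves the surface from the
    inscribed-octahedron convention of plain marching cubes toward the voxel
    cube boundary, so small structures keep their voxel volume (a single
    voxel converges to its full cube as ``m`` grows; at m=1 it is an
    octahedron of 1/6 the volume). The field is zero-padded so the surface
    is always closed.
    """
    fld = np.asarray(field, dtype=float)
    sp = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (3,)).astype(float)
    if fld.max() < iso_level or fld.min() > iso_level:
        raise ValueError("field does not contain the iso level: empty iso-surface")
    m = int(supersample)
    if m > 1:
        for ax in range(3):
            fld = np.repeat(fld, m, axis=ax)
    sp_fine = sp / m
    pad_val = min(iso_level - 1.0, 0.0)
    fld = np.pad(fld, 1, mode="constant", constant_values=pad_val)
    verts, faces, _, _ = measure.marching_cubes(fld, level=iso_level, spacing=tuple(sp_fine))
    # voxel-center convention: coarse voxel i center sits at origin + i*sp
    shift = -sp / 2.0 - sp_fine / 2.0
    if origin is not None:
        shift = shift + np.asarray(origin, dtype=float)
    mesh = trimesh.Trimesh(vertices=verts + shift, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def _uniform_laplacian(faces: np.ndarray, n_verts: int) -> sparse.csr_matrix:
    """Row-normalized uniform-weight vertex adjacency (neighbor average)."""
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e = np.vstack([e, e[:, ::-1]])
    a = sparse.coo_matrix(
        (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n_verts, n_verts)
    ).tocsr()
    a.data[:] = 1.0  # deduplicate repeated edges
    deg = np.asarray(a.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    return sparse.diags(1.0 / deg) @ a


def laplacian_smooth(mesh: trimesh.Trimesh, lamb: float = 0.5, iterations: int = 10) -> trimesh.Trimesh:
    """Pure Laplacian smoothing p <- p + lambda * (avg(neighbors) - p).

    Shrinks closed surfaces; kept as the reference against which the
    non-shrinking Taubin variant is compared.
    """
    W = _uniform_laplacian(mesh.faces, len(mesh.vertices))
    p = mesh.vertices.copy()
    for _ in range(iterations):
        p += lamb * (W @ p - p)
    return trimesh.Trimesh(vertices=p, faces=mesh.faces.copy(), process=False)


def taubin_smooth(
    mesh: trimesh.Trimesh,
    lamb: float = 0.5,
    mu: float = -0.53,
    iterations: int = 10,
) -> trimesh.Trimesh:
    """Taubin lambda|mu smoothing: alternate shrink (lambda) and inflate (mu) steps.

    Requires ``mu < -lamb < 0`` so the pass-band gain stays near unity and
    the surface is smoothed without net shrinkage.
    """
    if not (mu < -lamb < 0):
        raise ValueError("Taubin parameters must satisfy mu < -lambda < 0")
    W = _uniform_laplacian(mesh.faces, len(mesh.vertices))
    p = mesh.vertices.copy()
    for _ in range(iterations):
        p += lamb * (W @ p - p)
        p += mu * (W @ p - p)
    return trimesh.Trimesh(vertices=p, faces=mesh.faces.copy(), process=False)


# ---------------------------------------------------------------------------
# Quadric edge-collapse decimation
# ---------------------------------------------------------------------------

def _quadric_cost(q, x: float, y: float, z: float) -> float:
    """Evaluate [x y z 1]^T Q [x y z 1] for a symmetric quadric stored as the
    10 upper-triangle entries (a00 a01 a02 a03 a11 a12 a13 a22 a23 a33)."""
    return (
        q[0] * x * x + q[4] * y * y + q[7] * z * z + q[9]
        + 2.0 * (q[1] * x * y + q[2] * x * z + q[3] * x
                 + q[5] * y * z + q[6] * y + q[8] * z)
    )


def _edge_candidates(q, pu, pv):
    """Best of {endpoint u, endpoint v, midpoint} under the summed quadric.

    Pure-float hot path: ``q`` is a 10-tuple quadric, ``pu``/``pv`` are
    [x, y, z] lists.
    """
    mx, my, mz = (
        (pu[0] + pv[0]) * 0.5, (pu[1] + pv[1]) * 0.5, (pu[2] + pv[2]) * 0.5,
    )
    cu = _quadric_cost(q, pu[0], pu[1], pu[2])
    cv = _quadric_cost(q, pv[0], pv[1], pv[2])
    cm = _quadric_cost(q, mx, my, mz)
    if cm <= cu and cm <= cv:
        return cm, [mx, my, mz]
    if cu <= cv:
        return cu, list(pu)
    return cv, list(pv)


def _face_normal_dot(a, b, c, a2, b2, c2) -> tuple[float, float]:
    """(old . new, |new|^2) for the normals of triangles (a,b,c), (a2,b2,c2)."""
    u1x, u1y, u1z = b[0] - a[0], b[1] - a[1], b[2] - a[2]
    v1x, v1y, v1z = c[0] - a[0], c[1] - a[1], c[2] - a[2]
    n1x, n1y, n1z = (u1y * v1z - u1z * v1y, u1z * v1x - u1x * v1z,
                     u1x * v1y - u1y * v1x)
    u2x, u2y, u2z = b2[0] - a2[0], b2[1] - a2[1], b2[2] - a2[2]
    v2x, v2y, v2z = c2[0] - a2[0], c2[1] - a2[1], c2[2] - a2[2]
    n2x, n2y, n2z = (u2y * v2z - u2z * v2y, u2z * v2x - u2x * v2z,
                     u2x * v2y - u2y * v2x)
    return (n1x * n2x + n1y * n2y + n1z * n2z,
            n2x * n2x + n2y * n2y + n2z * n2z)


def decimate_mesh(mesh: trimesh.Trimesh, target_faces: int) -> trimesh.Trimesh:
    """Quadric-error-metric edge-collapse decimation of a closed manifold mesh.

    Collapses the cheapest edges first (Garland-Heckbert plane quadrics,
    candidate placement restricted to the endpoints and midpoint). Collapses
    that would violate the manifold link condition, flip a face normal or
    create a degenerate face are skipped, which preserves watertightness.
    """
    if target_faces < 4:
        raise ValueError("target_faces must be at least 4")
    F = np.asarray(mesh.faces)
    V = np.asarray(mesh.vertices, dtype=float)
    faces = [list(f) for f in F.tolist()]
    verts = [list(v) for v in V.tolist()]
    nv = len(verts)

    # initial per-vertex quadrics (upper-triangle packing), vectorized
    n = np.cross(V[F[:, 1]] - V[F[:, 0]], V[F[:, 2]] - V[F[:, 0]])
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    n = n / norm
    d = -np.einsum("ij,ij->i", n, V[F[:, 0]])
    p = np.hstack([n, d[:, None]])
    iu, ju = np.triu_indices(4)
    K = (p[:, iu] * p[:, ju])            # (n_faces, 10)
    Qarr = np.zeros((nv, 10))
    for c in range(3):
        np.add.at(Qarr, F[:, c], K)
    Q = [tuple(row) for row in Qarr.tolist()]

    alive_face = [True] * len(faces)
    n_faces = len(faces)
    vertex_faces: list[set[int]] = [set() for _ in range(nv)]
    for fi, f in enumerate(faces):
        for v in f:
            vertex_faces[v].add(fi)
    version = [0] * nv
    vert_alive = [True] * nv

    # initial edge heap, costs computed vectorized
    E = np.unique(np.sort(np.vstack(
        [F[:, [0, 1]], F[:, [1, 2]], F[:, [2, 0]]]), axis=1), axis=0)
    Qe = Qarr[E[:, 0]] + Qarr[E[:, 1]]
    Pu, Pv = V[E[:, 0]], V[E[:, 1]]
    cands = np.stack([Pu, Pv, 0.5 * (Pu + Pv)], axis=1)       # (E, 3, 3)
    h = np.concatenate([cands, np.ones((*cands.shape[:2], 1))], axis=2)
    pair = h[:, :, iu] * h[:, :, ju]                          # (E, 3, 10)
    mult = np.where(iu == ju, 1.0, 2.0)
    costs3 = np.einsum("ekq,eq->ek", pair * mult, Qe)
    # small edge-length regularization: breaks zero-cost ties on flat
    # regions so coarsening stays uniform and vertex degrees stay bounded
    reg = 1e-2
    best = costs3.min(axis=1) + reg * np.sum((Pu - Pv) ** 2, axis=1)
    heap = [(c, int(u), int(v), 0, 0)
            for c, (u, v) in zip(best.tolist(), E.tolist())]
    heapq.heapify(heap)

    def neighbors(u: int) -> set[int]:
        out: set[int] = set()
        for fi in vertex_faces[u]:
            out.update(faces[fi])
        out.discard(u)
        return out

    while n_faces > target_faces and heap:
        cost, u, v, su, sv = heapq.heappop(heap)
        if not (vert_alive[u] and vert_alive[v]):
            continue
        if version[u] != su or version[v] != sv:
            continue  # stale entry
        shared = vertex_faces[u] & vertex_faces[v]
        if len(shared) != 2:
            continue
        opposite = {w for fi in shared for w in faces[fi] if w not in (u, v)}
        if neighbors(u) & neighbors(v) != opposite:
            continue  # link condition: collapse would pinch the surface
        quv = tuple(a + b for a, b in zip(Q[u], Q[v]))
        _, pos = _edge_candidates(quv, verts[u], verts[v])

        # reject collapses that flip or degenerate any surviving face
        ok = True
        for fi in (vertex_faces[u] | vertex_faces[v]) - shared:
            f = faces[fi]
            old = [verts[w] for w in f]
            new = [pos if w in (u, v) else verts[w] for w in f]
            dot, norm2 = _face_normal_dot(*old, *new)
            if dot <= 1e-12 or norm2 < 1e-28:
                ok = False
                break
        if not ok:
            continue

        # perform collapse: v merges into u at pos
        verts[u] = pos
        Q[u] = quv
        for fi in shared:
            alive_face[fi] = False
            n_faces -= 1
            for w in faces[fi]:
                vertex_faces[w].discard(fi)
        for fi in list(vertex_faces[v]):
            faces[fi] = [u if w == v else w for w in faces[fi]]
            vertex_faces[u].add(fi)
            vertex_faces[v].discard(fi)
        vert_alive[v] = False
        version[u] += 1
        vu = version[u]
        pu = verts[u]
        qu = Q[u]
        for w in neighbors(u):
            qw = tuple(a + b for a, b in zip(qu, Q[w]))
            c, _ = _edge_candidates(qw, pu, verts[w])
            pw = verts[w]
            c += reg * ((pu[0] - pw[0]) ** 2 + (pu[1] - pw[1]) ** 2
                        + (pu[2] - pw[2]) ** 2)
            heapq.heappush(heap, (c, u, w, vu, version[w]))

    keep = [fi for fi, a in enumerate(alive_face) if a]
    used = sorted({w for fi in keep for w in faces[fi]})
    remap = {w: i for i, w in enumerate(used)}
    new_faces = np.array([[remap[w] for w in faces[fi]] for fi in keep])
    new_verts = np.array([verts[w] for w in used])
    return trimesh.Trimesh(vertices=new_verts, faces=new_faces, process=False)


def simplify_mesh(
    mesh: trimesh.Trimesh,
    target_faces: int | None = None,
    laplacian_iters: int = 0,
    laplacian_lambda: float = 0.5,
    taubin_lambda: float = 0.5,
    taubin_mu: float = -0.53,
    taubin_iters: int = 10,
    remesh_size: float | None = None,
) -> trimesh.Trimesh:
    """Face reduction, optional isotropic remeshing, Laplacian and Taubin passes.

    Passes run in that order; each is skipped when its parameter is zero /
    None / already satisfied, so the all-zero call is the identity. If
    decimation breaks watertightness the target is relaxed (doubled) and
    retried before giving up.
    """
    out = trimesh.Trimesh(
        vertices=mesh.vertices.copy(), faces=mesh.faces.copy(), process=False
    )
    if remesh_size is not None:
        v, f = trimesh.remesh.subdivide_to_size(out.vertices, out.faces, remesh_size)
        out = trimesh.Trimesh(vertices=v, faces=f, process=False)
    if target_faces is not None and len(out.faces) > target_faces:
        if target_faces < 4:
            raise ValueError("target_faces must be at least 4")
        t = target_faces
        while True:
            dec = decimate_mesh(out, t)
            if dec.is_watertight or not out.is_watertight:
                out = dec
                break
            t *= 2
            if t >= len(out.faces):
                raise RuntimeError(
                    "decimation could not reach any reduced face count without "
                    "breaking manifoldness"
                )
    if laplacian_iters > 0:
        out = laplacian_smooth(out, laplacian_lambda, laplacian_iters)
    if taubin_iters > 0:
        out = taubin_smooth(out, taubin_lambda, taubin_mu, taubin_iters)
    return out


# ---------------------------------------------------------------------------
# Slice plan
# ---------------------------------------------------------------------------

def build_slice_plan(
    tumor_mask: np.ndarray,
    origin_s_mm: float,
    spacing_mm: float,
    slice_spacing_mm: float,
    alignment_offset_mm: float = 0.0,
) -> SlicePlan:
    """Knife planes at ``offset + k*spacing`` covering the tumor extent.

    One margin plane is added on each side so the whole tumor is bracketed.
    A tumor thinner than the slice spacing gets a single central plane (with
    a warning).
    """
    if slice_spacing_mm <= 0:
        raise ValueError("slice_spacing_mm must be positive")
    tumor_mask = np.asarray(tumor_mask).astype(bool)
    rows = np.flatnonzero(tumor_mask.any(axis=(1, 2)))
    if len(rows) == 0:
        raise ValueError("tumor mask is empty")
    smin = origin_s_mm + rows[0] * spacing_mm
    smax = origin_s_mm + rows[-1] * spacing_mm
    h = float(slice_spacing_mm)
    k0 = int(np.ceil((smin - alignment_offset_mm) / h - 1e-9))
    k1 = int(np.floor((smax - alignment_offset_mm) / h + 1e-9))
    if k0 > k1:
        warnings.warn(
            "tumor extent is smaller than the slice spacing; "
            "planning a single central plane", stacklevel=2,
        )
        positions = np.array([(smin + smax) / 2.0])
    else:
        ks = np.arange(k0 - 1, k1 + 2)
        positions = alignment_offset_mm + ks * h
    return SlicePlan(positions=positions, spacing=h, offset=float(alignment_offset_mm))


def imaging_aligned_offset(
    src_affine: np.ndarray, frame: SectioningFrame, slice_spacing_mm: float
) -> float:
    """Offset aligning plan planes with original slice centers, best effort.

    Meaningful when the sectioning normal is close to an acquisition axis
    (transverse sectioning of an axially acquired scan); otherwise the
    offset falls back to 0 (planes through the tumor centroid).
    """
    A = np.asarray(src_affine, dtype=float)
    cols = A[:3, :3]
    n = frame.normal
    proj = np.abs((cols.T @ n) / np.linalg.norm(cols, axis=0))
    ax = int(np.argmax(proj))
    if proj[ax] < 0.99:
        return 0.0
    s0 = float((A[:3, 3] - frame.origin) @ n)
    return s0 % slice_spacing_mm


# ---------------------------------------------------------------------------
# Carving
# ---------------------------------------------------------------------------

def _disk_structure(radius_vox: float) -> np.ndarray:
    r = int(np.ceil(radius_vox))
    y, x = np.mgrid[-r:r + 1, -r:r + 1]
    return (x**2 + y**2) <= radius_vox**2 + 1e-9


def carve_mold(
    outline: np.ndarray,
    landmarks_frame: dict[str, np.ndarray],
    spec: MoldSpec,
    plan: SlicePlan,
    origin: np.ndarray,
    spacing_mm: float,
    sigma_mm: float = 2.0,
    build_mesh: bool = True,
    mesh_target_faces: int = 20000,
    taubin_iters: int = 10,
) -> MoldModel:
    """Carve the mold occupancy grid and (optionally) build its mesh.

    ``outline`` is the specimen union mask on the mold-frame lattice (axis
    order normal, lateral, up); ``origin`` is the frame-mm coordinate of its
    voxel (0, 0, 0); ``landmarks_frame`` must contain at least ``hilum`` and
    ``tumor_contact`` in frame mm.
    """
    outline = np.asarray(outline).astype(bool)
    if not outline.any():
        raise ValueError("outline mask is empty")
    sp = float(spacing_mm)
    origin = np.asarray(origin, dtype=float)
    _, O_sm = smooth_outline(outline, sp, sigma_mm)

    idx = np.argwhere(O_sm)
    lo, hi = idx.min(axis=0), idx.max(axis=0)
    O = O_sm[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
    n0, n1, nz = O.shape

    m = max(1, round(spec.block_margin_mm / sp))
    base_v = max(1, round(spec.base_thickness_mm / sp))
    guide_v = max(1, round(spec.guide_depth_mm / sp))
    bridge_v = max(1, round(spec.slot_bridge_mm / sp))

    shape = (n0 + 2 * m, n1 + 2 * m + guide_v, base_v + nz)
    grid_origin = np.array([
        origin[0] + (lo[0] - m) * sp,
        origin[1] + (lo[1] - m) * sp,
        origin[2] + lo[2] * sp - base_v * sp,
    ])

    fp = np.zeros(shape[:2], dtype=bool)
    fp[m:m + n0, m:m + n1] = O.any(axis=2)
    fp_dil = ndimage.binary_dilation(fp, structure=_disk_structure(m))

    # guide comb: extend the block on the +lateral side of every block row
    mold2d = fp_dil.copy()
    guide2d = np.zeros_like(fp_dil)
    row_any = fp_dil.any(axis=1)
    gmax = int(np.max(np.nonzero(fp_dil.any(axis=0))[0]))
    strip_end = min(gmax + guide_v + 1, shape[1])
    for r in np.flatnonzero(row_any):
        last = int(np.max(np.nonzero(fp_dil[r])[0]))
        guide2d[r, last + 1:strip_end] = True
    mold2d |= guide2d

    occ = np.repeat(mold2d[:, :, None], shape[2], axis=2).copy()

    # cavity: vertical-shadow carve from the outline's lowest surface upward
    zlow = np.full(shape[:2], shape[2], dtype=int)
    first = np.argmax(O, axis=2)  # index of first occupied voxel per column
    col_has = O.any(axis=2)
    zlow_sub = np.where(col_has, first + base_v, shape[2])
    zlow[m:m + n0, m:m + n1] = zlow_sub
    zidx = np.arange(shape[2])[None, None, :]
    cavity = fp[:, :, None] & (zidx >= zlow[:, :, None])
    occ &= ~cavity
    if np.any(zlow[fp] < base_v):
        raise RuntimeError("internal error: cavity floor fell below the base")
    cavity_floor = np.where(fp, grid_origin[2] + zlow * sp, np.nan)
    cavity_occ = occ.copy()

    # knife slots: full lateral cut from the top down to the bridge
    n_slot = max(1, round(spec.slot_width_mm / sp))
    centers = []
    for p in plan.positions:
        i0 = int(round((p - spec.slot_width_mm / 2 - grid_origin[0]) / sp))
        i1 = i0 + n_slot
        i0c, i1c = max(i0, 0), min(i1, shape[0])
        if i0c >= i1c:
            warnings.warn(f"slot plane at {p:g} mm falls outside the block; skipped",
                          stacklevel=2)
            centers.append(np.nan)
            continue
        occ[i0c:i1c, :, bridge_v:] = False
        centers.append(grid_origin[0] + (i0 + (n_slot - 1) / 2.0) * sp)
    slot_centers = np.asarray(centers)

    # 2-cm landmark holes through the full base under hilum and tumor contact.
    # Under the specimen footprint the hole opens into the cavity; where the
    # disc overlaps a wall it is drilled through the base thickness only. A
    # disc reaching beyond the block entirely would breach a lateral wall.
    hole_centers: dict[str, np.ndarray] = {}
    r_vox = spec.hole_diameter_mm / 2.0 / sp
    X0, X1 = np.mgrid[0:shape[0], 0:shape[1]]
    for name in ("hilum", "tumor_contact"):
        if name not in landmarks_frame:
            raise ValueError(f"landmark {name!r} required to place a base hole")
        c = np.asarray(landmarks_frame[name], dtype=float)
        f0, f1 = (c[:2] - grid_origin[:2]) / sp
        disc = (X0 - f0) ** 2 + (X1 - f1) ** 2 <= r_vox**2
        if not disc.any() or np.any(disc & ~mold2d):
            raise ValueError(
                f"landmark hole for {name!r} would breach a lateral wall: "
                "the 2-cm disc extends beyond the block footprint"
            )
        occ[disc & fp, :] = False
        shaft = np.zeros(shape, dtype=bool)
        shaft[disc & ~fp, :base_v] = True
        occ &= ~shaft
        hole_centers[name] = c[:2].copy()
    gap = np.linalg.norm(hole_centers["hilum"] - hole_centers["tumor_contact"])
    if gap < spec.hole_diameter_mm:
        warnings.warn(
            f"landmark base holes overlap: centers {gap:.1f} mm apart for "
            f"{spec.hole_diameter_mm:g} mm holes", stacklevel=2,
        )

    # tick-mark notches (numbering surrogate): the guide tooth after slot k
    # carries k notches, cut into its top edge along the comb depth starting
    # from the outer rim (1 mm ticks with 1 mm lands, 2 mm deep)
    notch_w = max(1, round(1.0 / sp))
    notch_d = max(1, round(2.0 / sp))
    slot_edges = [
        int(round((p + spec.slot_width_mm / 2 - grid_origin[0]) / sp))
        for p in plan.positions
    ]
    for k, start in enumerate(slot_edges, start=1):
        end = slot_edges[k] - n_slot if k < len(slot_edges) else shape[0]
        if end - start < 1:
            continue
        row = (start + end - 1) // 2
        cols = np.flatnonzero(guide2d[row])
        if cols.size == 0:
            continue
        outer = cols[-1]
        for j in range(k):
            c0 = outer - j * 2 * notch_w - notch_w + 1
            if c0 < cols[0]:
                warnings.warn(
                    f"guide tooth {k} is too shallow for {k} tick marks",
                    stacklevel=2,
                )
                break
            occ[row:row + notch_w, c0:c0 + notch_w, shape[2] - notch_d:] = False

    mesh = None
    if build_mesh:
        raw = extract_surface(occ.astype(np.float32), sp, 0.5, origin=grid_origin)
        mesh = simplify_mesh(raw, target_faces=mesh_target_faces,
                             taubin_iters=taubin_iters)

    return MoldModel(
        occupancy=occ,
        cavity_occupancy=cavity_occ,
        origin=grid_origin,
        spacing=sp,
        spec=spec,
        plan=plan,
        landmark_points={k: np.asarray(v, float) for k, v in landmarks_frame.items()},
        hole_centers=hole_centers,
        slot_centers=slot_centers,
        footprint=fp,
        cavity_floor_mm=cavity_floor,
        base_voxels=base_v,
        guide_region=guide2d,
        mesh=mesh,
    )


def export_stl(mesh: trimesh.Trimesh, path, ascii_format: bool = False) -> None:
    """Write a watertight mesh as STL (mm); binary by default."""
    if not mesh.is_watertight:
        raise ValueError(
            "refusing to export a non-watertight mesh; see the mold QC report"
        )
    file_type = "stl_ascii" if ascii_format else "stl"
    mesh.export(str(path), file_type=file_type)


# ---------------------------------------------------------------------------
# End-to-end orchestration
# ---------------------------------------------------------------------------

@dataclass
class MoldResult:
    """Everything a mold run produces: frame, resampled study, plan, model."""

    model: MoldModel
    study: ResampledStudy
    frame: SectioningFrame
    plan: SlicePlan

    def report(self) -> dict:
        return {
            "frame": self.frame.to_json_dict(),
            "plan": {
                "positions_mm": self.plan.positions.tolist(),
                "spacing_mm": self.plan.spacing,
                "offset_mm": self.plan.offset,
                "labels": self.plan.labels.tolist(),
            },
            "spec": {k: float(v) for k, v in vars(self.model.spec).items()},
            "hole_centers_frame_mm": {
                k: v.tolist() for k, v in self.model.hole_centers.items()
            },
            "slot_centers_mm": [
                None if np.isnan(c) else float(c) for c in self.model.slot_centers
            ],
            "grid": {
                "origin_mm": self.model.origin.tolist(),
                "spacing_mm": self.model.spacing,
                "shape": list(self.model.occupancy.shape),
            },
        }


def design_mold(
    seg,
    landmarks,
    mode: str = "transverse",
    spec: MoldSpec | None = None,
    spacing_mm: float = 1.0,
    sigma_mm: float = 2.0,
    anchor_to_imaging: bool = True,
    alignment_offset_mm: float | None = None,
    build_mesh: bool = True,
    mesh_target_faces: int = 20000,
    landmark_tol_mm: float = 5.0,
) -> MoldResult:
    """Full pipeline: landmarks -> frame -> roll -> resample -> plan -> carve."""
    from .io_volumes import check_landmarks_within_outline
    from .orientation import base_roll, mask_centroid, resample_to_frame, sectioning_frame

    spec = spec or MoldSpec()
    check_landmarks_within_outline(landmarks, seg, tol_mm=landmark_tol_mm)
    centroid = mask_centroid(seg.masks["tumor"], seg.affine)
    frame = sectioning_frame(landmarks, centroid, mode)
    frame = base_roll(
        frame, landmarks["hilum"], landmarks["tumor_contact"], seg.outline, seg.affine
    )
    study = resample_to_frame(seg, landmarks, frame, spacing_mm=spacing_mm)
    if alignment_offset_mm is None:
        alignment_offset_mm = (
            imaging_aligned_offset(seg.affine, frame, spec.slice_spacing_mm)
            if anchor_to_imaging
            else 0.0
        )
    plan = build_slice_plan(
        study.seg.masks["tumor"], study.origin[0], study.spacing,
        spec.slice_spacing_mm, alignment_offset_mm,
    )
    model = carve_mold(
        study.seg.outline, study.landmarks_frame, spec, plan,
        origin=study.origin, spacing_mm=study.spacing, sigma_mm=sigma_mm,
        build_mesh=build_mesh, mesh_target_faces=mesh_target_faces,
    )
    return MoldResult(model=model, study=study, frame=frame, plan=plan)
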