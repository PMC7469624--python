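"""Synthetic renal specimen phantoms with known ground truth.

The phantom emulates the imaging inputs of a radical-nephrectomy specimen:
an ellipsoidal kidney (tilted off the scanner axes), a spherical tumor
bulging from its surface (optionally lobulated by a seeded second-order
harmonic perturbation), a perinephric fat shell of direction-dependent
thickness that thins to a designated contact point, a hemispherical hilum
notch on the medial side, and seven co-registered multiparametric channels
(T1w, T2w, T1 map, Ktrans, IVIM D0 and f, R2*) with habitat structure drawn
from per-region Gaussian distributions.

Every analytic parameter is recorded in a ground-truth dictionary so each
downstream stage (orientation, carving, Dice validation, habitat recovery)
can be scored without re-deriving geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .io_volumes import LandmarkSet, SegmentationSet

__all__ = [
    "CHANNELS",
    "HabitatRegion",
    "PhantomSpec",
    "Anatomy",
    "default_habitat_layout",
    "make_anatomy",
    "make_parameter_maps",
]

#: The seven multiparametric channels and their units.
CHANNELS = ("T1w", "T2w", "T1", "Ktrans", "D0", "f", "R2star")
CHANNEL_UNITS = {
    "T1w": "a.u.", "T2w": "a.u.", "T1": "ms", "Ktrans": "1/min",
    "D0": "um^2/ms", "f": "fraction", "R2star": "1/s",
}


@dataclass
class HabitatRegion:
    """A concentric tumor shell with per-channel Gaussian signal statistics.

    ``outer_frac`` is the outer boundary of the shell as a fraction of the
    (local) tumor radius; regions listed in increasing ``outer_frac`` order
    partition the tumor, the last one must reach 1.
    """

    name: str
    outer_frac: float
    means: dict[str, float]
    sds: dict[str, float]


def default_habitat_layout() -> list[HabitatRegion]:
    """Three habitats emulating a necrotic core, a transition rim and a
    well-perfused periphery. Adjacent-region mean separation is at least
    4 SD in every channel."""
    return [
        HabitatRegion(
            "necrotic_core", 0.50,
            means={"T1w": 180, "T2w": 420, "T1": 1900, "Ktrans": 0.02,
                   "D0": 2.6, "f": 0.04, "R2star": 18.0},
            sds=_DEFAULT_SDS.copy(),
        ),
        HabitatRegion(
            "transition_rim", 0.80,
            means={"T1w": 260, "T2w": 330, "T1": 1550, "Ktrans": 0.13,
                   "D0": 1.9, "f": 0.12, "R2star": 34.0},
            sds=_DEFAULT_SDS.copy(),
        ),
        HabitatRegion(
            "perfused_periphery", 1.0,
            means={"T1w": 340, "T2w": 240, "T1": 1200, "Ktrans": 0.28,
                   "D0": 1.2, "f": 0.22, "R2star": 52.0},
            sds=_DEFAULT_SDS.copy(),
        ),
    ]


_DEFAULT_SDS = {"T1w": 15.0, "T2w": 20.0, "T1": 80.0, "Ktrans": 0.025,
                "D0": 0.15, "f": 0.02, "R2star": 4.0}

#: Signal outside the tumor (normal kidney / fat, single rough distribution).
_BACKGROUND = {"T1w": (300, 40), "T2w": (180, 30), "T1": (1000, 120),
               "Ktrans": (0.15, 0.05), "D0": (1.8, 0.3), "f": (0.15, 0.05),
               "R2star": (25.0, 6.0)}


@dataclass
class PhantomSpec:
    """Geometry and signal layout of the synthetic specimen (mm, seeds)."""

    kidney_semiaxes: tuple[float, float, float] = (22.0, 30.0, 55.0)
    tilt_deg: float = 15.0                       # rotation about world y
    tumor_radius: float = 25.0
    tumor_center: tuple[float, float, float] = (-10.0, 20.0, 25.0)
    lobulation: float = 0.0                      # l=2 radial perturbation amp
    fat_range: tuple[float, float] = (4.0, 12.0)
    tumor_thin_mm: float = 2.0                   # fat thickness at tumor contact
    kidney_thin_mm: float = 3.0                  # fat thickness at kidney contact
    notch_radius_mm: float = 10.0                # hemispherical hilum notch
    spacing: float = 1.5
    margin_mm: float = 8.0
    seed: int = 0
    habitat_regions: list[HabitatRegion] = field(default_factory=default_habitat_layout)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.fat_range[0] <= 0 or self.fat_range[1] < self.fat_range[0]:
            raise ValueError("fat_range must be positive and ordered")
        a = np.asarray(self.kidney_semiaxes, float)
        c = np.asarray(self.tumor_center, float)
        # tumor must cross the kidney surface: center quadric value < 1 but
        # the sphere must reach outside the ellipsoid
        q_center = float(np.sum((c / a) ** 2))
        reach = np.linalg.norm(c) + self.tumor_radius
        if q_center < 1 and reach <= np.min(a):
            raise ValueError("tumor lies entirely inside the kidney core")
        if q_center > 1 and np.linalg.norm(c) - self.tumor_radius > np.max(a):
            raise ValueError("tumor does not intersect the kidney surface")


@dataclass
class Anatomy:
    """A generated phantom: segmentations, landmarks and ground truth."""

    seg: SegmentationSet
    landmarks: LandmarkSet
    truth: dict
    tumor_norm_radius: np.ndarray  # r / local tumor radius, within the grid
    affine: np.ndarray


def _rotation_y(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _l2_perturbation(rng: np.random.Generator, amplitude: float):
    """Seeded traceless quadratic form: a real second-order harmonic bump."""
    A = rng.normal(size=(3, 3))
    A = (A + A.T) / 2.0
    A -= np.eye(3) * np.trace(A) / 3.0
    A /= max(np.abs(np.linalg.eigvalsh(A)).max(), 1e-12)

    def pert(u: np.ndarray) -> np.ndarray:
        return amplitude * np.einsum("...i,ij,...j->...", u, A, u)

    return pert, A


def make_anatomy(spec: PhantomSpec | None = None, seed: int | None = None) -> Anatomy:
    """Generate the phantom segmentations, landmarks and ground truth.

    Deterministic given (spec, seed); ``seed`` overrides ``spec.seed``.
    """
    spec = spec or PhantomSpec()
    seed = spec.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)

    a = np.asarray(spec.kidney_semiaxes, float)
    Rt = _rotation_y(spec.tilt_deg)          # body -> world
    c_t_body = np.asarray(spec.tumor_center, float)
    r_t = float(spec.tumor_radius)

    # grid: cube centered on the kidney center (world origin)
    reach = max(np.max(a), np.linalg.norm(c_t_body) + r_t * (1 + abs(spec.lobulation)))
    half = reach + spec.fat_range[1] + spec.margin_mm
    sp = float(spec.spacing)
    n = int(np.ceil(2 * half / sp)) + 1
    affine = np.eye(4)
    affine[:3, :3] *= sp
    affine[:3, 3] = -half
    ax = -half + sp * np.arange(n)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    W = np.stack([X, Y, Z], axis=-1)
    Q = W @ Rt                                # world -> body coords

    kidney = np.sum((Q / a) ** 2, axis=-1) <= 1.0

    # hilum: hemispherical notch carved at the medial (-x) kidney surface
    h_body = np.array([-a[0], 0.0, 0.0])
    notch = np.linalg.norm(Q - h_body, axis=-1) <= spec.notch_radius_mm
    kidney &= ~notch

    rel = Q - c_t_body
    dist_t = np.linalg.norm(rel, axis=-1)
    pert_A = None
    if spec.lobulation != 0:
        pert, pert_A = _l2_perturbation(rng, spec.lobulation)
        with np.errstate(invalid="ignore", divide="ignore"):
            u = rel / np.maximum(dist_t[..., None], 1e-12)
        local_r = r_t * (1.0 + pert(u))
    else:
        local_r = r_t
    norm_radius = dist_t / local_r
    tumor = norm_radius <= 1.0
    kidney &= ~tumor

    union = kidney | tumor
    centroid_idx = np.mean(np.argwhere(union), axis=0)
    centroid = affine[:3, :3] @ centroid_idx + affine[:3, 3]

    # fat shell: distance-dependent dilation, thinning to the contact points
    d_bulge_body = c_t_body / np.linalg.norm(c_t_body)
    p_tc_body = c_t_body + r_t * d_bulge_body       # tumor contact (bulge apex)
    p_kc_body = np.array([0.0, a[1], 0.0])          # kidney contact (+y surface)
    p_tc, p_kc = Rt @ p_tc_body, Rt @ p_kc_body
    d_tc = (p_tc - centroid) / np.linalg.norm(p_tc - centroid)
    d_kc = (p_kc - centroid) / np.linalg.norm(p_kc - centroid)

    g = rng.normal(size=3)
    g /= np.linalg.norm(g)
    lo_t, hi_t = spec.fat_range
    relc = W - centroid
    dn = np.linalg.norm(relc, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        U = relc / np.maximum(dn[..., None], 1e-12)
    base = lo_t + (hi_t - lo_t) * 0.5 * (1.0 + U @ g)

    def bump(d: np.ndarray, width_deg: float = 20.0) -> np.ndarray:
        ang = np.arccos(np.clip(U @ d, -1.0, 1.0))
        return np.exp(-((ang / np.deg2rad(width_deg)) ** 4))

    thickness = base
    thickness = thickness + (spec.tumor_thin_mm - base) * bump(d_tc)
    thickness = thickness + (spec.kidney_thin_mm - base) * bump(d_kc)
    dist_out = ndimage.distance_transform_edt(~union, sampling=sp)
    fat = (~union) & (dist_out <= thickness)

    seg = SegmentationSet({"tumor": tumor, "kidney": kidney, "fat": fat}, affine)
    landmarks = LandmarkSet({
        "upper_pole": Rt @ np.array([0.0, 0.0, a[2]]),
        "lower_pole": Rt @ np.array([0.0, 0.0, -a[2]]),
        "hilum": Rt @ h_body,
        "tumor_contact": p_tc,
        "kidney_contact": p_kc,
    })

    truth = {
        "seed": seed,
        "spec": {k: v for k, v in asdict(spec).items() if k != "habitat_regions"},
        "kidney_center_world": [0.0, 0.0, 0.0],
        "rotation_body_to_world": Rt.tolist(),
        "tumor_center_world": (Rt @ c_t_body).tolist(),
        "tumor_radius_mm": r_t,
        "lobulation_form": None if pert_A is None else pert_A.tolist(),
        "pole_distance_mm": float(2 * a[2]),
        "landmarks_world": {k: v.tolist() for k, v in landmarks.points.items()},
        "union_centroid_world": centroid.tolist(),
        "fat_thin_direction_tumor": d_tc.tolist(),
        "voxel_counts": {r: int(m.sum()) for r, m in seg.masks.items()},
    }
    return Anatomy(seg=seg, landmarks=landmarks, truth=truth,
                   tumor_norm_radius=norm_radius, affine=affine)


def make_parameter_maps(
    anatomy: Anatomy,
    layout: list[HabitatRegion] | None = None,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Draw the 7-channel map stack and return it with true habitat labels.

    Each tumor voxel is assigned to the concentric region containing its
    normalized radius; channel values are drawn independently from that
    region's per-channel normal distribution. Non-tumor voxels carry a
    single background distribution. Labels are 1-based in layout order,
    0 outside the tumor.
    """
    layout = layout if layout is not None else default_habitat_layout()
    fracs = [r.outer_frac for r in layout]
    if any(f2 <= f1 for f1, f2 in zip(fracs, fracs[1:])):
        raise ValueError("habitat regions overlap: outer_frac must be increasing")
    if fracs[-1] < 1.0 - 1e-9:
        raise ValueError("habitat regions do not cover the tumor (last outer_frac < 1)")
    rng = np.random.default_rng(seed)
    tumor = anatomy.seg.masks["tumor"]
    nr = anatomy.tumor_norm_radius

    labels = np.zeros(tumor.shape, dtype=np.int16)
    inner = 0.0
    for i, region in enumerate(layout, start=1):
        sel = tumor & (nr > inner if i > 1 else nr >= 0) & (nr <= region.outer_frac)
        labels[sel] = i
        inner = region.outer_frac

    maps: dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        mu, sd = _BACKGROUND[ch]
        vol = rng.normal(mu, sd, size=tumor.shape)
        for i, region in enumerate(layout, start=1):
            sel = labels == i
            vol[sel] = rng.normal(region.means[ch], region.sds[ch], size=int(sel.sum()))
        maps[ch] = vol
    return maps, labels
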