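"""Shared fixtures: phantoms, molds and analytic sphere helpers."""

from __future__ import annotations

import numpy as np
import pytest

import renalmold as rm
from renalmold.io_volumes import LandmarkSet, SegmentationSet


def sphere_mask(radius_mm: float, spacing_mm: float = 1.0, pad_mm: float = 5.0):
    """Axis-centered binary sphere plus its affine (world origin at center)."""
    half = radius_mm + pad_mm
    n = int(np.ceil(2 * half / spacing_mm)) + 1
    ax = (np.arange(n) - (n - 1) / 2) * spacing_mm
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    mask = X**2 + Y**2 + Z**2 <= radius_mm**2
    affine = np.eye(4)
    affine[:3, :3] *= spacing_mm
    affine[:3, 3] = ax[0]
    return mask, affine


def small_phantom_spec(**overrides) -> rm.PhantomSpec:
    """A reduced specimen for fast unit tests (not the study conditions)."""
    kwargs = dict(
        kidney_semiaxes=(14.0, 18.0, 32.0),
        tumor_radius=14.0,
        tumor_center=(-6.0, 12.0, 15.0),
        fat_range=(3.0, 7.0),
        notch_radius_mm=6.0,
        spacing=2.0,
        margin_mm=6.0,
    )
    kwargs.update(overrides)
    return rm.PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def small_anatomy() -> rm.Anatomy:
    return rm.make_anatomy(small_phantom_spec(), seed=11)


@pytest.fixture(scope="session")
def small_mold(small_anatomy) -> rm.MoldResult:
    return rm.design_mold(
        small_anatomy.seg, small_anatomy.landmarks, mode="transverse",
        spacing_mm=1.0, mesh_target_faces=6000,
    )


@pytest.fixture(scope="session")
def default_anatomy() -> rm.Anatomy:
    """The full-size phantom under the default study conditions."""
    return rm.make_anatomy(rm.PhantomSpec(), seed=7)


@pytest.fixture(scope="session")
def default_mold(default_anatomy) -> rm.MoldResult:
    """Default-condition mold: 1 mm frame, sigma 2 mm, 5 mm slice spacing."""
    return rm.design_mold(
        default_anatomy.seg, default_anatomy.landmarks, mode="transverse"
    )


@pytest.fixture(scope="session")
def sphere_study() -> tuple[SegmentationSet, LandmarkSet]:
    """A 30-mm sphere specimen with landmarks on its surface."""
    mask, affine = sphere_mask(30.0, spacing_mm=1.5)
    seg = SegmentationSet({"tumor": mask}, affine)
    lms = LandmarkSet({
        "upper_pole": [0.0, 0.0, 30.0],
        "lower_pole": [0.0, 0.0, -30.0],
        "hilum": [-30.0, 0.0, 0.0],
        "tumor_contact": [0.0, 30.0, 0.0],
    })
    return seg, lms


@pytest.fixture(scope="session")
def sphere_mold(sphere_study) -> rm.MoldResult:
    seg, lms = sphere_study
    return rm.design_mold(seg, lms, mode="transverse", build_mesh=False)
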