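"""Shared fixtures: analytic rasterizers and small reference scenes."""

from __future__ import annotations

import math

import numpy as np
import pytest

from nucmorph.image_io import Calibration, DEFAULT_BINNED_CALIBRATION
from nucmorph.segmentation import LabelVolume
from nucmorph.synthetic_data import ChannelModel, Placement, SceneSpec, rasterize_scene


@pytest.fixture(scope="session")
def binned_calibration() -> Calibration:
    return DEFAULT_BINNED_CALIBRATION


def rasterize_sphere(
    radius_um: float,
    calibration: Calibration = DEFAULT_BINNED_CALIBRATION,
    shape: tuple[int, int, int] | None = None,
    center_offset_vox: tuple[int, int, int] = (0, 0, 0),
) -> LabelVolume:
    """Direct analytic sphere rasterization, independent of synthetic_data."""
    spacing = np.asarray(calibration.spacing_zyx_um)
    if shape is None:
        half = np.ceil(radius_um / spacing).astype(int) + 3
        shape = tuple(2 * half + 1)
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    center = (np.asarray(shape) // 2 + np.asarray(center_offset_vox)) * spacing
    dist2 = sum(
        (g * s - c) ** 2 for g, s, c in zip(grids, spacing, center)
    )
    return LabelVolume((dist2 <= radius_um**2).astype(np.int32), calibration)


def rasterize_ellipsoid(
    radii_um: tuple[float, float, float],
    angle_about_z: float = 0.0,
    calibration: Calibration = DEFAULT_BINNED_CALIBRATION,
    shape: tuple[int, int, int] = (64, 64, 64),
    alpha: float = 0.0,
    phases: np.ndarray | None = None,
) -> LabelVolume:
    """Single rotated (optionally wrinkled) ellipsoid via the scene rasterizer."""
    c, s = math.cos(angle_about_z), math.sin(angle_about_z)
    rotation = np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    spec = SceneSpec(
        shape_voxels=shape,
        calibration=calibration,
        n_nuclei=1,
        channels=ChannelModel(gaussian_sigma_frac=0.0),
    )
    center = np.asarray(shape) * np.asarray(calibration.spacing_zyx_um) / 2.0
    placement = Placement(
        nucleus_id=1,
        center_um=center,
        radii_um=tuple(radii_um),
        rotation=rotation,
        alpha=alpha,
        phases=np.zeros(4) if phases is None else phases,
        i_nuc=200.0,
        i_cyt=100.0,
    )
    return rasterize_scene(spec, [placement]).labels


@pytest.fixture(scope="session")
def quiet_scene():
    """Noise-free 9-nucleus reference scene with ratio 2 (index exactly 1)."""
    from nucmorph.synthetic_data import simulate_scene

    spec = SceneSpec(
        n_nuclei=9,
        seed=11,
        channels=ChannelModel(gaussian_sigma_frac=0.0, uniform_control=150.0),
    )
    return simulate_scene(spec)
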