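"""Per-nucleus 3D shape parameters on anisotropic voxel grids.

Every measurement is made in physical micrometre coordinates so that the
strongly anisotropic voxels (xy pitch != z step) never leak into the shape
statistics. The parameters follow the standard nuclear-morphometry set:

* volume V (voxel count x voxel volume) and surface area A (iso-surface
  mesh of the mask),
* convex hull volume V_hull and the solidity index V / V_hull — a proxy
  for nuclear surface wrinkling: a taut (convex) nucleus has solidity ~1,
  folds and wrinkles push it below 1,
* ellipsoid radii R1 >= R2 >= R3 from the second moments of the voxel set
  (for a solid uniform ellipsoid the covariance eigenvalues are R_i^2 / 5,
  so R_i = sqrt(5 * lambda_i) exactly in the continuum limit),
* sphericity  pi^(1/3) (6V)^(2/3) / A  (1 for a perfect sphere),
* oblateness / prolateness, a symmetric triaxial pair built from the radii:
  with f = (R2 - R3)/(R1 - R3), oblateness = 2f - 1 and prolateness =
  1 - 2f; +1 marks a perfect disc (resp. rod), both 0 for a sphere.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import marching_cubes, mesh_surface_area

from .segmentation import LabelVolume

__all__ = [
    "NuclearShape",
    "measure_basic",
    "fit_ellipsoid_radii",
    "shape_indices",
    "measure_nucleus",
    "measure_all",
]

#: Physical-units Gaussian smoothing applied to the binary mask before
#: extracting the iso-surface. Calibrated on analytic spheres at the
#: default grid: large enough to damp the staircase artefact that inflates
#: raw marching-cubes areas, small enough that the curvature-driven inward
#: shift of the 0.5 level stays below 1% in radius.
SURFACE_SMOOTH_SIGMA_UM = 0.3


@dataclass
class NuclearShape:
    """Morphometric record for one nucleus (lengths µm, volumes µm³)."""

    nucleus_id: int
    volume_um3: float
    surface_area_um2: float
    convex_hull_volume_um3: float
    solidity: float
    r1_um: float
    r2_um: float
    r3_um: float
    oblateness: float
    prolateness: float
    sphericity: float
    centroid_z_um: float
    centroid_y_um: float
    centroid_x_um: float
    biggest_area_plane: int
    flag: str | None = None


@dataclass
class BasicShape:
    volume_um3: float
    surface_area_um2: float
    convex_hull_volume_um3: float
    solidity: float
    centroid_um: tuple[float, float, float]
    biggest_area_plane: int
    flag: str | None = None


Bbox = tuple[slice, slice, slice]


def _instance_bbox(volume: LabelVolume, nucleus_id: int) -> Bbox:
    objects = ndi.find_objects(volume.labels, max_label=int(nucleus_id))
    bbox = objects[int(nucleus_id) - 1] if objects else None
    if bbox is None:
        raise KeyError(f"nucleus id {nucleus_id} not in volume")
    return bbox


def _mask_and_coords(
    volume: LabelVolume, nucleus_id: int, bbox: Bbox | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cropped binary mask, voxel coordinates in full-volume indices, origin."""
    if bbox is None:
        bbox = _instance_bbox(volume, nucleus_id)
    mask = volume.labels[bbox] == nucleus_id
    if not mask.any():
        raise KeyError(f"nucleus id {nucleus_id} not in volume")
    origin = np.array([s.start for s in bbox])
    coords = np.argwhere(mask) + origin
    return mask, coords, origin


def _iso_surface(mask: np.ndarray, spacing: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sub-voxel surface mesh of a binary mask in physical coordinates.

    The mask is lightly Gaussian-smoothed (physical sigma, so the kernel is
    anisotropic in voxels) and the 0.5 iso-surface extracted; this places
    the surface at the half-occupancy boundary and suppresses the
    staircase artefacts that inflate raw marching-cubes areas. The same
    mesh feeds both the surface-area and the convex-hull measurements, so
    the two stay mutually consistent.
    """
    sigma_vox = SURFACE_SMOOTH_SIGMA_UM / spacing
    pad = int(np.ceil(3 * sigma_vox.max())) + 1
    field = np.pad(mask.astype(np.float64), pad)
    field = ndi.gaussian_filter(field, sigma=sigma_vox)
    verts, faces, _, _ = marching_cubes(field, level=0.5, spacing=tuple(spacing))
    return verts, faces


def measure_basic(
    volume: LabelVolume, nucleus_id: int, bbox: Bbox | None = None
) -> BasicShape:
    """Volume, surface area, convex-hull volume, solidity, centroid, widest plane.

    Degenerate instances (fewer than 4 non-coplanar voxels, for which a
    convex hull is undefined) come back flagged rather than raising.
    ``bbox`` (from one ``ndi.find_objects`` pass) restricts work to the
    instance's bounding box; it is located on demand when omitted.
    """
    mask, coords, origin = _mask_and_coords(volume, nucleus_id, bbox)
    spacing = np.asarray(volume.calibration.spacing_zyx_um)
    n_voxels = coords.shape[0]
    vol = n_voxels * volume.calibration.voxel_volume_um3
    centroid = tuple((coords.mean(axis=0) * spacing).tolist())
    plane_areas = mask.sum(axis=(1, 2))
    biggest_plane = int(origin[0]) + int(np.argmax(plane_areas))  # ties -> lowest z

    flag = None
    try:
        verts, faces = _iso_surface(mask, spacing)
        area = float(mesh_surface_area(verts, faces))
        hull = ConvexHull(verts)
        hull_volume = float(hull.volume)
        solidity = vol / hull_volume
    except (QhullError, ValueError, RuntimeError):
        flag = "degenerate_hull"
        hull_volume = float("nan")
        solidity = float("nan")
        area = float("nan")
    return BasicShape(vol, area, hull_volume, solidity, centroid, biggest_plane, flag)


def fit_ellipsoid_radii(
    volume: LabelVolume, nucleus_id: int, bbox: Bbox | None = None
) -> tuple[float, float, float]:
    """Ellipsoid radii (R1 >= R2 >= R3, µm) from voxel second moments.

    The covariance of the voxel positions in physical coordinates is
    corrected for the finite voxel extent (+ spacing²/12 per axis, the
    variance of a uniform box) and its eigenvalues mapped through
    R = sqrt(5 λ), exact for a solid uniform ellipsoid.

    Raises
    ------
    ValueError
        If the instance is degenerate (planar or linear voxel set).
    """
    _, coords, _ = _mask_and_coords(volume, nucleus_id, bbox)
    spacing = np.asarray(volume.calibration.spacing_zyx_um)
    pts = coords * spacing
    if pts.shape[0] < 2:
        raise ValueError(f"nucleus {nucleus_id}: too few voxels for a moment fit")
    cov = np.cov(pts.T, ddof=0) + np.diag(spacing**2 / 12.0)
    eigenvalues = np.linalg.eigvalsh(cov)[::-1]
    if eigenvalues[-1] <= 0 or not np.all(np.isfinite(eigenvalues)):
        raise ValueError(f"nucleus {nucleus_id}: degenerate second-moment matrix")
    r1, r2, r3 = np.sqrt(5.0 * eigenvalues)
    return float(r1), float(r2), float(r3)


def shape_indices(
    r1: float, r2: float, r3: float, volume: float, surface_area: float
) -> tuple[float, float, float]:
    """(oblateness, prolateness, sphericity) from radii, volume and area.

    ``f = (R2 - R3)/(R1 - R3)`` places R2 between the extreme radii;
    oblateness = 2f - 1 (+1 disc, -1 rod), prolateness = 1 - 2f (the
    mirror image). Both are defined as 0 for a sphere (R1 = R3).
    """
    values = (r1, r2, r3, volume, surface_area)
    if not all(np.isfinite(v) for v in values):
        raise ValueError(f"non-finite inputs to shape_indices: {values}")
    if not (r1 >= r2 >= r3 > 0):
        raise ValueError(f"radii must satisfy R1 >= R2 >= R3 > 0, got {(r1, r2, r3)}")
    if volume <= 0 or surface_area <= 0:
        raise ValueError("volume and surface_area must be positive")
    if np.isclose(r1, r3):
        oblateness = prolateness = 0.0
    else:
        f = (r2 - r3) / (r1 - r3)
        oblateness = 2.0 * f - 1.0
        prolateness = 1.0 - 2.0 * f
    sphericity = np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / surface_area
    return float(oblateness), float(prolateness), float(sphericity)


def measure_nucleus(
    volume: LabelVolume, nucleus_id: int, bbox: Bbox | None = None
) -> NuclearShape:
    """Full morphometric record for one nucleus; degenerate cases are flagged."""
    if bbox is None:
        bbox = _instance_bbox(volume, nucleus_id)
    basic = measure_basic(volume, nucleus_id, bbox)
    flag = basic.flag
    try:
        r1, r2, r3 = fit_ellipsoid_radii(volume, nucleus_id, bbox)
    except ValueError:
        r1 = r2 = r3 = float("nan")
        flag = flag or "degenerate_moments"
    if flag is None:
        oblateness, prolateness, sphericity = shape_indices(
            r1, r2, r3, basic.volume_um3, basic.surface_area_um2
        )
    else:
        oblateness = prolateness = sphericity = float("nan")
    cz, cy, cx = basic.centroid_um
    return NuclearShape(
        nucleus_id=int(nucleus_id),
        volume_um3=basic.volume_um3,
        surface_area_um2=basic.surface_area_um2,
        convex_hull_volume_um3=basic.convex_hull_volume_um3,
        solidity=basic.solidity,
        r1_um=r1,
        r2_um=r2,
        r3_um=r3,
        oblateness=oblateness,
        prolateness=prolateness,
        sphericity=sphericity,
        centroid_z_um=cz,
        centroid_y_um=cy,
        centroid_x_um=cx,
        biggest_area_plane=basic.biggest_area_plane,
        flag=flag,
    )


def measure_all(volume: LabelVolume) -> pd.DataFrame:
    """Morphometry table with one row per nucleus instance."""
    objects = ndi.find_objects(volume.labels)
    records = [
        asdict(measure_nucleus(volume, int(i), objects[int(i) - 1])) for i in volume.ids
    ]
    columns = [f.name for f in NuclearShape.__dataclass_fields__.values()]
    if not records:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame.from_records(records, columns=columns)
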