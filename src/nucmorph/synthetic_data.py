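"""Synthetic confocal scenes with per-nucleus ground truth.

Generates calibrated multicellular scenes that emulate a confocal z-stack
of a cell monolayer: ellipsoidal nuclei with controllable surface
wrinkling packed in a field, a DNA channel, a transport-reporter channel
with prescribed nuclear and cytoplasmic mean intensities over a
cytoplasmic shell, an optional spatially uniform control channel, a flat
background offset and Gaussian/Poisson noise. Every nucleus carries an
analytic ground-truth row (centre, radii, wrinkle amplitude, base volume,
true log2 N/C ratio, planted local density) so each pipeline stage can be
validated by parameter recovery.

Nucleus shape model: the base body is a triaxial ellipsoid with semi-axes
R1 >= R2 >= R3; its surface is modulated radially by a fixed band-limited
angular perturbation P(theta, phi) (sum of two cosine product terms of low
spatial order, |P| <= 1, phases drawn per nucleus), giving the radius
field r(u) = r_ell(u) * (1 + alpha * P(u)). alpha = 0 is a perfect
(convex) ellipsoid; increasing alpha wrinkles the surface and lowers the
solidity index monotonically while barely changing the enclosed volume.

Optional dependency hooks plant or break covariate structure across the
population: ``density_to_alpha`` couples local crowding to wrinkling, and
``ratio_from_alpha`` couples the reporter N/C ratio to wrinkling (hence to
measured solidity) while leaving it independent of density.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from .image_io import Calibration, DEFAULT_BINNED_CALIBRATION, ImageStack, write_stack
from .population import DEFAULT_DENSITY_WINDOW_UM, local_density
from .segmentation import LabelVolume, write_label_volume

__all__ = [
    "ChannelModel",
    "SceneSpec",
    "Placement",
    "Scene",
    "sample_scene",
    "rasterize_scene",
    "ground_truth_table",
    "simulate_scene",
    "write_scene",
]


@dataclass(frozen=True)
class ChannelModel:
    """Intensity model of the simulated channels (arbitrary units).

    The reporter channel takes value ``background + sensor_nuclear`` inside
    nuclei, ``background + sensor_cytoplasmic`` in a cytoplasmic shell of
    the stated radial thickness around each nucleus (clipped against
    neighbours), and ``background`` elsewhere — so the true index is
    exactly log2(sensor_nuclear / sensor_cytoplasmic). The uniform control
    channel mimics a freely diffusing fluorophore with identical
    concentration throughout each cell — nucleus and cytoplasmic shell
    alike — over the flat background, so its true index is 0.
    """

    dna_nuclear: float = 400.0
    sensor_nuclear: float = 200.0
    sensor_cytoplasmic: float = 100.0
    shell_thickness_um: float = 3.0
    uniform_control: float | None = None
    background: float = 50.0
    gaussian_sigma_frac: float = 0.02
    poisson: bool = False


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene; a single seed drives all randomness."""

    shape_voxels: tuple[int, int, int] = (40, 192, 192)
    calibration: Calibration = DEFAULT_BINNED_CALIBRATION
    n_nuclei: int = 9
    radii_um: tuple[tuple[float, float], ...] = ((4.5, 6.5), (3.5, 5.5), (2.5, 3.5))
    wrinkle_amplitude: float | tuple[float, float] = 0.0
    wrinkle_order: int = 3
    orientation: str = "in_plane"  # "in_plane" | "full" | "none"
    min_separation_um: float = 16.0
    #: extra cell-free border kept around the packed field (emulates imaging
    #: past the edge of the cell patch; guarantees background pixels even in
    #: dense scenes)
    edge_apron_um: float = 0.0
    z_jitter_um: float = 0.5
    channels: ChannelModel = ChannelModel()
    density_window_um: float = DEFAULT_DENSITY_WINDOW_UM
    density_to_alpha: Callable[[float], float] | None = None
    ratio_from_alpha: Callable[[float], float] | None = None
    seed: int = 0

    @property
    def field_extent_um(self) -> tuple[float, float, float]:
        dz, dy, dx = self.calibration.spacing_zyx_um
        nz, ny, nx = self.shape_voxels
        return (nz * dz, ny * dy, nx * dx)

    @property
    def alpha_max(self) -> float:
        if isinstance(self.wrinkle_amplitude, tuple):
            return max(self.wrinkle_amplitude)
        return self.wrinkle_amplitude


@dataclass
class Placement:
    """One planted nucleus: geometry, wrinkle phases and channel truth."""

    nucleus_id: int
    center_um: np.ndarray  # (z, y, x)
    radii_um: tuple[float, float, float]  # R1 >= R2 >= R3
    rotation: np.ndarray  # 3x3, body -> lab, (z, y, x) ordering
    alpha: float
    phases: np.ndarray  # 4 wrinkle phases
    i_nuc: float
    i_cyt: float
    planted_density: int = 0


@dataclass
class Scene:
    """A fully rasterized synthetic scene plus its ground truth."""

    spec: SceneSpec
    placements: list[Placement]
    truth: pd.DataFrame
    labels: LabelVolume
    stack: ImageStack
    shell_labels: np.ndarray
    clipped_fraction: dict[int, float]


def _rotation_about_z(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    # (z, y, x) ordering: rotate the y-x plane about z
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def _sample_alpha(spec: SceneSpec, rng: np.random.Generator) -> float:
    if isinstance(spec.wrinkle_amplitude, tuple):
        lo, hi = spec.wrinkle_amplitude
        return float(rng.uniform(lo, hi))
    return float(spec.wrinkle_amplitude)


def sample_scene(spec: SceneSpec) -> tuple[list[Placement], pd.DataFrame]:
    """Place nuclei by dart-throwing and build the ground-truth table.

    Centres are drawn uniformly within an interior margin of the field and
    rejected while any pairwise 3D distance is below ``min_separation_um``;
    after a bounded retry budget a placement error reports the achievable
    count. The same seed always yields the identical scene.
    """
    rng = np.random.default_rng(spec.seed)
    extent = np.asarray(spec.field_extent_um)
    r1_max = spec.radii_um[0][1]
    r3_max = spec.radii_um[2][1]
    grow = 1.0 + spec.alpha_max
    xy_margin = r1_max * grow + spec.channels.shell_thickness_um + 1.0 + spec.edge_apron_um
    z_half = (r1_max if spec.orientation == "full" else r3_max) * grow
    z_margin = z_half + spec.z_jitter_um + 0.2
    z_mid = extent[0] / 2.0
    if 2 * xy_margin >= min(extent[1], extent[2]) or z_margin > z_mid:
        raise ValueError(
            f"field {tuple(extent)} µm too small for nuclei with margin "
            f"xy={xy_margin:.1f} µm, z={z_margin:.1f} µm"
        )
    centers: list[np.ndarray] = []
    placed = np.empty((0, 3))
    budget = 300 * spec.n_nuclei
    attempts = 0
    while len(centers) < spec.n_nuclei:
        attempts += 1
        if attempts > budget:
            raise RuntimeError(
                f"placed only {len(centers)}/{spec.n_nuclei} nuclei at "
                f"min_separation {spec.min_separation_um} µm after {budget} tries "
                "(field too small for the requested packing)"
            )
        candidate = np.array(
            [
                z_mid + rng.uniform(-spec.z_jitter_um, spec.z_jitter_um),
                rng.uniform(xy_margin, extent[1] - xy_margin),
                rng.uniform(xy_margin, extent[2] - xy_margin),
            ]
        )
        if placed.size == 0 or (
            np.linalg.norm(placed - candidate, axis=1).min()
            >= spec.min_separation_um
        ):
            centers.append(candidate)
            placed = np.vstack([placed, candidate])

    centroids_xy = np.array([[c[2], c[1]] for c in centers])
    densities = local_density(centroids_xy, spec.density_window_um)["density"].to_numpy()

    placements: list[Placement] = []
    for k, center in enumerate(centers):
        radii = tuple(
            sorted((rng.uniform(lo, hi) for lo, hi in spec.radii_um), reverse=True)
        )
        if spec.orientation == "in_plane":
            rotation = _rotation_about_z(rng.uniform(0, 2 * np.pi))
        elif spec.orientation == "full":
            rotation = _random_rotation(rng)
        elif spec.orientation == "none":
            rotation = np.eye(3)
        else:
            raise ValueError(f"unknown orientation mode {spec.orientation!r}")
        if spec.density_to_alpha is not None:
            alpha = float(spec.density_to_alpha(float(densities[k])))
        else:
            alpha = _sample_alpha(spec, rng)
        phases = rng.uniform(0, 2 * np.pi, size=4)
        if spec.ratio_from_alpha is not None:
            ratio = float(spec.ratio_from_alpha(alpha))
            i_cyt = spec.channels.sensor_cytoplasmic
            i_nuc = i_cyt * ratio
        else:
            i_nuc = spec.channels.sensor_nuclear
            i_cyt = spec.channels.sensor_cytoplasmic
        placements.append(
            Placement(
                nucleus_id=k + 1,
                center_um=center,
                radii_um=radii,
                rotation=rotation,
                alpha=alpha,
                phases=phases,
                i_nuc=i_nuc,
                i_cyt=i_cyt,
                planted_density=int(densities[k]),
            )
        )
    return placements, ground_truth_table(spec, placements)


def ground_truth_table(spec: SceneSpec, placements: Sequence[Placement]) -> pd.DataFrame:
    """Analytic per-nucleus truth: base volume, true log2 N/C, planted density."""
    rows = []
    for p in placements:
        r1, r2, r3 = p.radii_um
        rows.append(
            {
                "nucleus_id": p.nucleus_id,
                "center_z_um": p.center_um[0],
                "center_y_um": p.center_um[1],
                "center_x_um": p.center_um[2],
                "r1_um": r1,
                "r2_um": r2,
                "r3_um": r3,
                "alpha": p.alpha,
                "volume_um3": 4.0 / 3.0 * np.pi * r1 * r2 * r3,
                "i_nuc": p.i_nuc,
                "i_cyt": p.i_cyt,
                "true_log2_nc": float(np.log2(p.i_nuc / p.i_cyt)),
                "planted_density": p.planted_density,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "nucleus_id", "center_z_um", "center_y_um", "center_x_um",
            "r1_um", "r2_um", "r3_um", "alpha", "volume_um3",
            "i_nuc", "i_cyt", "true_log2_nc", "planted_density",
        ],
    )


def _wrinkle_field(
    u: np.ndarray, order: int, phases: np.ndarray
) -> np.ndarray:
    """Band-limited angular perturbation P in [-1, 1] on unit directions u."""
    theta = np.arccos(np.clip(u[..., 0], -1.0, 1.0))
    phi = np.arctan2(u[..., 1], u[..., 2])
    lower = max(order - 1, 1)
    return 0.5 * (
        np.cos(order * phi + phases[0]) * np.cos(order * theta + phases[1])
        + np.cos((order + 1) * phi + phases[2]) * np.cos(lower * theta + phases[3])
    )


def _radius_field(
    directions: np.ndarray, placement: Placement, order: int
) -> np.ndarray:
    """Surface radius along each (unit) body-frame direction."""
    r1, r2, r3 = placement.radii_um
    semi = np.array([r3, r2, r1])  # body (z, y, x) axes
    inv = np.sqrt(((directions / semi) ** 2).sum(axis=-1))
    base = np.where(inv > 0, 1.0 / np.where(inv > 0, inv, 1.0), np.inf)
    if placement.alpha == 0:
        return base
    perturb = _wrinkle_field(directions, order, placement.phases)
    return base * (1.0 + placement.alpha * perturb)


def _nucleus_bbox(
    placement: Placement, spec: SceneSpec, extra_um: float
) -> tuple[slice, slice, slice]:
    spacing = np.asarray(spec.calibration.spacing_zyx_um)
    reach = placement.radii_um[0] * (1.0 + abs(placement.alpha)) + extra_um
    lo = np.floor((placement.center_um - reach) / spacing).astype(int)
    hi = np.ceil((placement.center_um + reach) / spacing).astype(int) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.asarray(spec.shape_voxels))
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def _body_distances(
    bbox: tuple[slice, slice, slice], placement: Placement, spec: SceneSpec
) -> tuple[np.ndarray, np.ndarray]:
    """(distance from centre, unit body-frame direction) for every bbox voxel."""
    spacing = np.asarray(spec.calibration.spacing_zyx_um)
    grids = np.meshgrid(
        *[np.arange(s.start, s.stop) for s in bbox], indexing="ij"
    )
    coords = np.stack(grids, axis=-1) * spacing
    delta = coords - placement.center_um
    body = delta @ placement.rotation  # lab -> body (R is body->lab, orthonormal)
    norm = np.linalg.norm(body, axis=-1)
    safe = np.where(norm > 0, norm, 1.0)
    return norm, body / safe[..., None]


def rasterize_scene(spec: SceneSpec, placements: Sequence[Placement]) -> Scene:
    """Voxelize placements into a label volume and a multi-channel stack.

    A voxel belongs to nucleus k when its body-frame radial coordinate is
    inside the wrinkled radius field. Where wrinkled surfaces overlap, the
    earlier-placed nucleus wins and the later one is clipped (fraction
    logged per nucleus). Cytoplasmic shell voxels are assigned uniquely to
    the nearest nucleus centre, so shell regions are pairwise disjoint and
    disjoint from every nucleus.
    """
    shape = spec.shape_voxels
    labels = np.zeros(shape, dtype=np.int32)
    clipped: dict[int, float] = {}
    for placement in placements:
        bbox = _nucleus_bbox(placement, spec, extra_um=0.5)
        norm, directions = _body_distances(bbox, placement, spec)
        inside = norm <= _radius_field(directions, placement, spec.wrinkle_order)
        region = labels[bbox]
        occupied = inside & (region > 0)
        n_inside = int(inside.sum())
        clipped[placement.nucleus_id] = (
            float(occupied.sum() / n_inside) if n_inside else 0.0
        )
        region[inside & (region == 0)] = placement.nucleus_id
        labels[bbox] = region

    shell_owner = np.zeros(shape, dtype=np.int32)
    shell_dist = np.full(shape, np.inf)
    thickness = spec.channels.shell_thickness_um
    for placement in placements:
        bbox = _nucleus_bbox(placement, spec, extra_um=thickness + 0.5)
        norm, directions = _body_distances(bbox, placement, spec)
        radius = _radius_field(directions, placement, spec.wrinkle_order)
        candidate = (norm <= radius + thickness) & (labels[bbox] == 0)
        owner = shell_owner[bbox]
        dist = shell_dist[bbox]
        take = candidate & (norm < dist)
        owner[take] = placement.nucleus_id
        dist[take] = norm[take]
        shell_owner[bbox] = owner
        shell_dist[bbox] = dist

    model = spec.channels
    background = model.background
    i_nuc = np.zeros(len(placements) + 1)
    i_cyt = np.zeros(len(placements) + 1)
    for placement in placements:
        i_nuc[placement.nucleus_id] = placement.i_nuc
        i_cyt[placement.nucleus_id] = placement.i_cyt

    dna = np.full(shape, background, dtype=np.float64)
    dna[labels > 0] += model.dna_nuclear
    sensor = np.full(shape, background, dtype=np.float64)
    sensor[labels > 0] += i_nuc[labels[labels > 0]]
    shell_mask = shell_owner > 0
    sensor[shell_mask] += i_cyt[shell_owner[shell_mask]]
    channels = {"dna": dna, "sensor": sensor}
    if model.uniform_control is not None:
        uniform = np.full(shape, background, dtype=np.float64)
        uniform[(labels > 0) | shell_mask] += model.uniform_control
        channels["uniform"] = uniform

    noise_rng = np.random.default_rng([spec.seed, 7919])
    peak = {
        "dna": model.dna_nuclear,
        "sensor": max((p.i_nuc for p in placements), default=model.sensor_nuclear),
        "uniform": model.uniform_control or 0.0,
    }
    for name, image in channels.items():
        if model.gaussian_sigma_frac > 0:
            image = image + noise_rng.normal(
                0.0, model.gaussian_sigma_frac * peak[name], size=image.shape
            )
        if model.poisson:
            image = noise_rng.poisson(np.clip(image, 0, None)).astype(np.float64)
        channels[name] = np.clip(image, 0.0, None)

    label_volume = LabelVolume(labels, spec.calibration)
    stack = ImageStack(channels, spec.calibration)
    truth = ground_truth_table(spec, placements)
    return Scene(spec, list(placements), truth, label_volume, stack, shell_owner, clipped)


def simulate_scene(spec: SceneSpec) -> Scene:
    """Sample placements and rasterize them in one call."""
    placements, _ = sample_scene(spec)
    return rasterize_scene(spec, placements)


def _spec_to_dict(spec: SceneSpec) -> dict:
    raw = dataclasses.asdict(spec)
    for hook in ("density_to_alpha", "ratio_from_alpha"):
        if raw[hook] is not None:
            raw[hook] = getattr(raw[hook], "__name__", repr(raw[hook]))
    raw["calibration"] = dataclasses.asdict(spec.calibration)
    raw["channels"] = dataclasses.asdict(spec.channels)
    return raw


def write_scene(scene: Scene, outdir: str | Path) -> dict[str, Path]:
    """Write stack, labels, ground truth and the exact scene parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "stack": outdir / "stack.tif",
        "labels": outdir / "labels.tif",
        "truth": outdir / "ground_truth.csv",
        "spec": outdir / "scene_spec.yaml",
    }
    write_stack(scene.stack, paths["stack"])
    write_label_volume(scene.labels, paths["labels"])
    scene.truth.to_csv(paths["truth"], index=False)
    with open(paths["spec"], "w") as fh:
        yaml.safe_dump(_spec_to_dict(scene.spec), fh, sort_keys=False)
    return paths
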