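"""Nucleus instance masks: ingestion, validation and a fallback segmenter.

Production segmentation of the DNA channel is done by an external
deep-learning segmenter whose output is consumed here as an integer label
TIFF (0 = background, k > 0 = nucleus k). This module validates and
normalises those masks, removes nuclei truncated by the stack faces, and
provides a classical threshold + watershed fallback segmenter so synthetic
scenes can be processed without any model download.

The exact command lines used to produce masks externally are recorded in
:data:`CELLPOSE_COMMANDS` for provenance only; nothing in this package
invokes or requires that tool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from .image_io import Calibration, ImageStack

__all__ = [
    "LabelVolume",
    "ingest_label_volume",
    "write_label_volume",
    "relabel_consecutive",
    "filter_edge_nuclei",
    "fallback_segment",
    "CELLPOSE_COMMANDS",
]

#: Reference invocations of the external segmenter, recorded verbatim for
#: provenance (diameter in binned pixels; anisotropy = xy pitch / z step).
CELLPOSE_COMMANDS = {
    "osmotic_shock": (
        "python -m cellpose --dir [directory] --do_3D --cellprob_threshold=-2.0 "
        "--batch_size 2 --pretrained_model nuclei --chan 1 --diameter 34. "
        "--save_tif --no_npy --use_gpu --verbose --anisotropy 0.6"
    ),
    "drug_washout": (
        "python -m cellpose --dir [directory] --do_3D --cellprob_threshold=-2.0 "
        "--batch_size 2 --pretrained_model nuclei --chan 1 --diameter 34. "
        "--save_tif --no_npy --use_gpu --verbose"
    ),
    "cell_layers": (
        "python -m cellpose --dir [directory] --do_3D --cellprob_threshold=0.0 "
        "--batch_size 2 --pretrained_model nuclei --chan 1 --diameter 34. "
        "--save_tif --no_npy --use_gpu --verbose"
    ),
}

_AXIS_INDEX = {"z": 0, "y": 1, "x": 2}


@dataclass
class LabelVolume:
    """Integer 3D nucleus instance mask on a calibrated grid."""

    labels: np.ndarray
    calibration: Calibration

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"labels must be 3D (z, y, x); got shape {labels.shape}")
        if not np.issubdtype(labels.dtype, np.integer):
            raise TypeError(f"labels must be an integer volume, got dtype {labels.dtype}")
        if labels.size and labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.labels = labels

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def ids(self) -> np.ndarray:
        """Sorted positive instance labels present in the volume."""
        u = np.unique(self.labels)
        return u[u > 0]

    @property
    def n_nuclei(self) -> int:
        return int(self.ids.size)

    def mask(self, nucleus_id: int) -> np.ndarray:
        if nucleus_id not in self.ids:
            raise KeyError(f"nucleus id {nucleus_id} not in volume (ids: {self.ids.tolist()})")
        return self.labels == nucleus_id


def relabel_consecutive(labels: np.ndarray) -> tuple[np.ndarray, dict[int, int]]:
    """Relabel positive labels to consecutive 1..K by first voxel occurrence.

    Scan order is C order over (z, y, x). Returns the relabelled volume and
    the old→new mapping.
    """
    flat = labels.ravel()
    uniq, first = np.unique(flat, return_index=True)
    pos = uniq > 0
    order = np.argsort(first[pos])
    old_ids = uniq[pos][order]
    mapping = {int(old): new for new, old in enumerate(old_ids, start=1)}
    if not mapping:
        return np.zeros_like(labels), {}
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    for old, new in mapping.items():
        lut[old] = new
    return lut[labels], mapping


def ingest_label_volume(
    source: str | Path | np.ndarray, calibration: Calibration
) -> tuple[LabelVolume, dict[int, int]]:
    """Load an instance mask and normalise labels to consecutive 1..K.

    ``source`` may be a TIFF path or an in-memory integer array. Labels are
    renumbered in order of first voxel occurrence; the old→new mapping is
    returned alongside. Non-26-connected instances are tolerated with a
    warning (external segmenters occasionally emit them); a fully background
    volume yields an empty LabelVolume with a warning.
    """
    if isinstance(source, (str, Path)):
        arr = tifffile.imread(Path(source))
    else:
        arr = np.asarray(source)
    if not np.issubdtype(arr.dtype, np.integer):
        raise TypeError(f"label volume must have integer voxels, got dtype {arr.dtype}")
    if arr.ndim != 3:
        raise ValueError(f"label volume must be 3D, got shape {arr.shape}")
    relabelled, mapping = relabel_consecutive(arr)
    if not mapping:
        warnings.warn("label volume contains no nuclei (all background)", stacklevel=2)
        return LabelVolume(np.zeros_like(arr, dtype=np.int32), calibration), {}
    volume = LabelVolume(relabelled.astype(np.int32), calibration)
    _warn_disconnected(volume)
    return volume, mapping


def _warn_disconnected(volume: LabelVolume) -> None:
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    for nucleus_id in volume.ids:
        _, n_parts = ndi.label(volume.labels == nucleus_id, structure=structure)
        if n_parts > 1:
            warnings.warn(
                f"nucleus {int(nucleus_id)} splits into {n_parts} 26-connected parts",
                stacklevel=3,
            )


def write_label_volume(volume: LabelVolume, path: str | Path) -> None:
    tifffile.imwrite(Path(path), volume.labels.astype(np.int32), photometric="minisblack")


def filter_edge_nuclei(
    volume: LabelVolume, axes: tuple[str, ...] = ("z",)
) -> LabelVolume:
    """Drop instances touching the first or last plane along the given axes.

    Nuclei clipped by the top or bottom of the acquired stack have truncated
    masks; their volumes and shape indices would be systematically biased,
    so they are excluded from 3D shape analysis. Surviving labels are
    re-compacted to 1..K preserving relative order.
    """
    bad = set()
    for axis in axes:
        if axis not in _AXIS_INDEX:
            raise ValueError(f"unknown axis {axis!r}; use a subset of z, y, x")
        ax = _AXIS_INDEX[axis]
        first = np.take(volume.labels, 0, axis=ax)
        last = np.take(volume.labels, -1, axis=ax)
        bad.update(np.unique(first[first > 0]).tolist())
        bad.update(np.unique(last[last > 0]).tolist())
    if not bad:
        return LabelVolume(volume.labels.copy(), volume.calibration)
    kept = volume.labels.copy()
    kept[np.isin(kept, sorted(bad))] = 0
    relabelled, _ = relabel_consecutive(kept)
    return LabelVolume(relabelled.astype(np.int32), volume.calibration)


def fallback_segment(
    stack: ImageStack,
    channel: str,
    min_size_voxels: int = 60,
    smooth_sigma_um: float = 0.6,
    h_um: float = 1.0,
) -> LabelVolume:
    """Threshold + watershed nucleus segmenter for synthetic/bright-field-free data.

    A global Otsu threshold separates foreground, 26-connected components
    are labelled, and components containing several nuclei are split by a
    marker watershed on the physically scaled Euclidean distance transform.
    Watershed markers are the h-maxima of the lightly smoothed distance map
    (``h_um`` suppresses shallow maxima, avoiding over-segmentation of
    mildly wrinkled nuclei).

    This is a deliberately simple classical segmenter meant for synthetic
    validation scenes with clean bimodal intensities, not a replacement for
    a learned segmenter on real chromatin images.
    """
    data = np.asarray(stack.channel(channel), dtype=np.float64)
    calibration = stack.calibration
    if data.max() <= data.min():
        warnings.warn("channel is constant; no foreground to segment", stacklevel=2)
        return LabelVolume(np.zeros(data.shape, dtype=np.int32), calibration)
    threshold = threshold_otsu(data)
    foreground = data > threshold
    if not foreground.any():
        warnings.warn("empty foreground after thresholding", stacklevel=2)
        return LabelVolume(np.zeros(data.shape, dtype=np.int32), calibration)
    structure = np.ones((3, 3, 3), dtype=bool)
    foreground = ndi.binary_opening(foreground, structure=np.ones((1, 3, 3), dtype=bool))
    components, _ = ndi.label(foreground, structure=structure)
    sizes = np.bincount(components.ravel())
    small = np.flatnonzero(sizes < min_size_voxels)
    foreground[np.isin(components, small[small > 0])] = False

    spacing = np.asarray(calibration.spacing_zyx_um)
    distance = ndi.distance_transform_edt(foreground, sampling=spacing)
    sigma_vox = np.maximum(smooth_sigma_um / spacing, 0.0)
    distance_smooth = ndi.gaussian_filter(distance, sigma=sigma_vox)
    maxima = h_maxima(distance_smooth, h_um)
    markers, n_markers = ndi.label(maxima, structure=structure)
    if n_markers == 0:
        markers, _ = ndi.label(foreground, structure=structure)
    labels = watershed(-distance_smooth, markers=markers, mask=foreground)
    relabelled, _ = relabel_consecutive(labels)
    return LabelVolume(relabelled.astype(np.int32), calibration)
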