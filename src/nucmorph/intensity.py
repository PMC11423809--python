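"""Per-cell fluorescence quantification on the plane of biggest nuclear area.

For every segmented nucleus the reporter (and any immunostain) is measured
on the single z-plane where the nucleus shows its largest cross-section:

* nuclear region  = in-plane mask eroded by 1 pixel,
* cytoplasmic ring = (mask dilated by 3 px) minus (mask dilated by 1 px),
  with pixels falling inside any neighbouring nucleus excluded,
* background      = mean over cell-free pixels of the plane (far from every
  nucleus and below the automatic foreground threshold).

The nucleocytoplasmic index is then

    index = log2( (F_nuc - F_bg) / (F_cyt - F_bg) )

used identically for the transport reporter (Sencyt index) and for a
YAP immunostain (log2 N/C YAP ratio). Positive = nuclear enrichment.

Quality control discards cells with a low signal-to-noise ratio, with a
high coefficient of variation in either region (dim cells flanked by very
bright ones, or vice versa), or with a low nuclear/cytoplasmic DNA-stain
brightness ratio (a segmentation-sanity check).

Erosion/dilation distances are in binned pixels (0.5652 µm each on the
default grid); morphological operations use the 3x3 square element, so an
n-pixel dilation grows the mask by n in Chebyshev distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .image_io import ImageStack
from .segmentation import LabelVolume

__all__ = [
    "ChannelMap",
    "QCThresholds",
    "Regions",
    "BackgroundEstimate",
    "CellIntensity",
    "UndefinedIndexError",
    "BackgroundError",
    "define_regions",
    "estimate_background",
    "compute_nc_index",
    "apply_qc_filters",
    "measure_cell",
    "measure_scene",
]

_SQUARE = np.ones((3, 3), dtype=bool)


class UndefinedIndexError(ValueError):
    """Numerator or denominator of the N/C ratio is non-positive."""


class BackgroundError(RuntimeError):
    """Too few cell-free pixels to estimate background."""


@dataclass(frozen=True)
class ChannelMap:
    """Names of the channels in an :class:`ImageStack` by their role."""

    dna: str = "dna"
    sensor: str = "sensor"
    immunostain: str | None = None


@dataclass(frozen=True)
class QCThresholds:
    """Quality-control cutoffs.

    snr_min: minimum (F_nuc - F_bg)/sigma_bg of the reporter. The filter
    itself is standard practice; 2 is a conventional detection criterion
    and is deliberately configurable.
    cv_max: maximum coefficient of variation of background-subtracted
    pixels in either measurement region.
    hoechst_nc_min: minimum raw nuclear/cytoplasmic DNA-stain brightness
    ratio; lower values indicate a bad nuclear mask.
    """

    snr_min: float = 2.0
    cv_max: float = 0.8
    hoechst_nc_min: float = 4.0


@dataclass
class Regions:
    """Measurement regions for one nucleus on its widest plane."""

    nucleus_id: int
    plane: int
    nuclear: np.ndarray  # 2D bool
    ring: np.ndarray  # 2D bool
    flag: str | None = None


@dataclass
class BackgroundEstimate:
    mean: float
    std: float
    n_pixels: int


@dataclass
class CellIntensity:
    """Per-cell intensity record; fluorescence in arbitrary units (a.u.)."""

    nucleus_id: int
    plane: int
    f_nuc: dict[str, float] = field(default_factory=dict)
    f_cyt: dict[str, float] = field(default_factory=dict)
    f_bg: dict[str, float] = field(default_factory=dict)
    sencyt_index: float = math.nan
    yap_log2_nc: float = math.nan
    hoechst_nc_ratio: float = math.nan
    snr: float = math.nan
    cv_nuc: float = math.nan
    cv_cyt: float = math.nan
    qc_pass: bool = False
    qc_reasons: tuple[str, ...] = ()


def define_regions(
    volume: LabelVolume,
    nucleus_id: int,
    erosion_px: int = 1,
    ring_inner_px: int = 1,
    ring_outer_px: int = 3,
    plane: int | None = None,
    bbox: tuple[slice, slice, slice] | None = None,
) -> Regions:
    """Build nuclear and cytoplasmic-ring pixel sets on the widest plane.

    The ring is the band between the ``ring_inner_px``- and
    ``ring_outer_px``-dilated masks, with every pixel inside any
    neighbouring nucleus on that plane removed. Records whose erosion
    empties the nucleus, or whose ring is fully occluded by neighbours,
    are flagged instead of raising. ``bbox`` (one entry of
    ``ndi.find_objects``) limits the widest-plane search to the instance's
    bounding box.
    """
    labels = volume.labels
    if plane is None:
        sub = labels[bbox] if bbox is not None else labels
        areas = (sub == nucleus_id).sum(axis=(1, 2))
        if areas.max() == 0:
            raise KeyError(f"nucleus id {nucleus_id} not in volume")
        z_offset = bbox[0].start if bbox is not None else 0
        plane = int(z_offset + np.argmax(areas))
    plane_labels = labels[plane]
    mask = plane_labels == nucleus_id
    if not mask.any():
        return Regions(nucleus_id, plane, mask, mask, flag="empty_plane")
    # morphology on a padded bounding box; pasted back into full-plane masks
    rows, cols = np.nonzero(mask)
    pad = ring_outer_px + 1
    window = (
        slice(max(rows.min() - pad, 0), min(rows.max() + pad + 1, mask.shape[0])),
        slice(max(cols.min() - pad, 0), min(cols.max() + pad + 1, mask.shape[1])),
    )
    local_mask = mask[window]
    local_nuclear = ndi.binary_erosion(local_mask, structure=_SQUARE, iterations=erosion_px)
    outer = ndi.binary_dilation(local_mask, structure=_SQUARE, iterations=ring_outer_px)
    inner = ndi.binary_dilation(local_mask, structure=_SQUARE, iterations=ring_inner_px)
    neighbours = (plane_labels[window] > 0) & ~local_mask
    local_ring = outer & ~inner & ~neighbours
    nuclear = np.zeros_like(mask)
    nuclear[window] = local_nuclear
    ring = np.zeros_like(mask)
    ring[window] = local_ring
    flag = None
    if not nuclear.any():
        flag = "empty_nuclear_region"
    elif not ring.any():
        flag = "occluded_ring"
    return Regions(int(nucleus_id), plane, nuclear, ring, flag)


def estimate_background(
    stack: ImageStack,
    volume: LabelVolume,
    channel: str,
    plane: int,
    margin_px: float = 10.0,
    min_pixels: int = 200,
    intensity_gate: bool = True,
) -> BackgroundEstimate:
    """Mean (and spread) of cell-free pixels on one plane.

    Cell-free = farther than ``margin_px`` (Euclidean, in pixels) from the
    xy footprint of every nucleus, and — when ``intensity_gate`` is set and
    the plane is bimodal — below the plane's automatic (Otsu) foreground
    threshold, which keeps anucleate cytoplasm out of the estimate.
    """
    data = np.asarray(stack.channel(channel), dtype=np.float64)[plane]
    footprint = (volume.labels > 0).any(axis=0)
    distance = ndi.distance_transform_edt(~footprint)
    candidates = distance > margin_px
    if intensity_gate and candidates.any():
        values = data[candidates]
        if values.max() > values.min():
            try:
                candidates = candidates & (data < threshold_otsu(data))
            except ValueError:
                pass
    n = int(candidates.sum())
    if n < min_pixels:
        raise BackgroundError(
            f"plane {plane}: only {n} cell-free pixels (need >= {min_pixels}) "
            f"for background estimation on channel {channel!r}"
        )
    pixels = data[candidates]
    return BackgroundEstimate(float(pixels.mean()), float(pixels.std()), n)


def compute_nc_index(f_nuc: float, f_cyt: float, f_bg: float) -> float:
    """log2 of the background-subtracted nuclear/cytoplasmic mean ratio.

    Raises :class:`UndefinedIndexError` when either background-subtracted
    mean is non-positive (the record should be excluded and counted, not
    silently kept).
    """
    if not all(np.isfinite(v) for v in (f_nuc, f_cyt, f_bg)):
        raise UndefinedIndexError(f"non-finite inputs: {(f_nuc, f_cyt, f_bg)}")
    numerator = f_nuc - f_bg
    denominator = f_cyt - f_bg
    if numerator <= 0 or denominator <= 0:
        raise UndefinedIndexError(
            f"background-subtracted means must be positive: "
            f"nuc-bg={numerator:.4g}, cyt-bg={denominator:.4g}"
        )
    return float(np.log2(numerator / denominator))


def _cv(pixels: np.ndarray, background: float) -> float:
    values = pixels - background
    mean = values.mean()
    if mean == 0:
        return math.inf
    return float(abs(values.std() / mean))


def measure_cell(
    stack: ImageStack,
    volume: LabelVolume,
    nucleus_id: int,
    channels: ChannelMap,
    background: dict[str, BackgroundEstimate],
    regions: Regions | None = None,
) -> CellIntensity:
    """Assemble the full intensity record for one nucleus (no QC applied)."""
    if regions is None:
        regions = define_regions(volume, nucleus_id)
    record = CellIntensity(nucleus_id=int(nucleus_id), plane=regions.plane)
    if regions.flag is not None:
        record.qc_reasons = (regions.flag,)
        return record

    measured = [channels.dna, channels.sensor]
    if channels.immunostain:
        measured.append(channels.immunostain)
    for name in measured:
        plane_img = np.asarray(stack.channel(name), dtype=np.float64)[regions.plane]
        record.f_nuc[name] = float(plane_img[regions.nuclear].mean())
        record.f_cyt[name] = float(plane_img[regions.ring].mean())
        record.f_bg[name] = background[name].mean

    reasons: list[str] = []
    sensor_plane = np.asarray(stack.channel(channels.sensor), dtype=np.float64)[regions.plane]
    bg_sensor = background[channels.sensor]
    record.cv_nuc = _cv(sensor_plane[regions.nuclear], bg_sensor.mean)
    record.cv_cyt = _cv(sensor_plane[regions.ring], bg_sensor.mean)
    sigma = bg_sensor.std
    signal = record.f_nuc[channels.sensor] - bg_sensor.mean
    record.snr = math.inf if sigma == 0 else float(signal / sigma)
    if record.f_cyt[channels.dna] > 0:
        record.hoechst_nc_ratio = record.f_nuc[channels.dna] / record.f_cyt[channels.dna]
    else:
        record.hoechst_nc_ratio = math.inf

    try:
        record.sencyt_index = compute_nc_index(
            record.f_nuc[channels.sensor],
            record.f_cyt[channels.sensor],
            bg_sensor.mean,
        )
    except UndefinedIndexError:
        reasons.append("undefined_index")
    if channels.immunostain:
        try:
            record.yap_log2_nc = compute_nc_index(
                record.f_nuc[channels.immunostain],
                record.f_cyt[channels.immunostain],
                background[channels.immunostain].mean,
            )
        except UndefinedIndexError:
            reasons.append("undefined_yap_index")
    record.qc_reasons = tuple(reasons)
    return record


def apply_qc_filters(record: CellIntensity, thresholds: QCThresholds = QCThresholds()) -> CellIntensity:
    """Attach qc_pass and reason codes; rules are independent and order-free.

    Reason codes: ``snr`` (dim reporter signal), ``cv`` (heterogeneous
    region, e.g. a dim cell beside a very bright one), ``hoechst_nc``
    (poor nuclear segmentation), plus any structural flags already present
    (empty region, undefined index).
    """
    reasons = [r for r in record.qc_reasons if r not in ("snr", "cv", "hoechst_nc")]
    if np.isfinite(record.snr) or math.isnan(record.snr):
        if math.isnan(record.snr) or record.snr < thresholds.snr_min:
            reasons.append("snr")
    if (
        math.isnan(record.cv_nuc)
        or math.isnan(record.cv_cyt)
        or record.cv_nuc > thresholds.cv_max
        or record.cv_cyt > thresholds.cv_max
    ):
        reasons.append("cv")
    if math.isnan(record.hoechst_nc_ratio) or record.hoechst_nc_ratio < thresholds.hoechst_nc_min:
        reasons.append("hoechst_nc")
    updated = replace(record, qc_reasons=tuple(reasons), qc_pass=not reasons)
    return updated


def measure_scene(
    stack: ImageStack,
    volume: LabelVolume,
    channels: ChannelMap = ChannelMap(),
    thresholds: QCThresholds = QCThresholds(),
    background: dict[str, BackgroundEstimate] | None = None,
    background_margin_px: float = 10.0,
) -> pd.DataFrame:
    """Intensity table with one row per nucleus, QC applied.

    Background is estimated per channel once, on the median widest plane of
    the scene, unless explicit estimates are supplied.
    """
    ids = volume.ids
    columns = [
        "nucleus_id", "plane", "f_nuc_sensor", "f_cyt_sensor", "f_bg_sensor",
        "f_nuc_dna", "f_cyt_dna", "sencyt_index", "yap_log2_nc",
        "hoechst_nc_ratio", "snr", "cv_nuc", "cv_cyt", "qc_pass", "qc_reasons",
    ]
    if ids.size == 0:
        return pd.DataFrame(columns=columns)
    objects = ndi.find_objects(volume.labels)
    all_regions = {
        int(i): define_regions(volume, int(i), bbox=objects[int(i) - 1]) for i in ids
    }
    if background is None:
        planes = [r.plane for r in all_regions.values()]
        reference_plane = int(np.median(planes))
        names = {channels.dna, channels.sensor}
        if channels.immunostain:
            names.add(channels.immunostain)
        background = {
            name: estimate_background(
                stack, volume, name, reference_plane, margin_px=background_margin_px
            )
            for name in names
        }
    rows = []
    for nucleus_id in ids:
        record = measure_cell(
            stack, volume, int(nucleus_id), channels, background,
            regions=all_regions[int(nucleus_id)],
        )
        record = apply_qc_filters(record, thresholds)
        rows.append(
            {
                "nucleus_id": record.nucleus_id,
                "plane": record.plane,
                "f_nuc_sensor": record.f_nuc.get(channels.sensor, math.nan),
                "f_cyt_sensor": record.f_cyt.get(channels.sensor, math.nan),
                "f_bg_sensor": record.f_bg.get(channels.sensor, math.nan),
                "f_nuc_dna": record.f_nuc.get(channels.dna, math.nan),
                "f_cyt_dna": record.f_cyt.get(channels.dna, math.nan),
                "sencyt_index": record.sencyt_index,
                "yap_log2_nc": record.yap_log2_nc,
                "hoechst_nc_ratio": record.hoechst_nc_ratio,
                "snr": record.snr,
                "cv_nuc": record.cv_nuc,
                "cv_cyt": record.cv_cyt,
                "qc_pass": record.qc_pass,
                "qc_reasons": ";".join(record.qc_reasons),
            }
        )
    return pd.DataFrame(rows, columns=columns)
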