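"""Population-level statistics over per-nucleus tables.

Local cell density (square-window neighbour counts around each nucleus),
registration-based matching of live nuclei to the same nuclei after
fixation, baseline normalization of timelapse series, Spearman rank
correlation with an exact small-sample p-value, and binned mean maps
(value averaged over a 2D grid of covariate bins).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from skimage.registration import phase_cross_correlation

from .segmentation import LabelVolume

__all__ = [
    "local_density",
    "density_per_mm2",
    "MatchResult",
    "match_live_fixed",
    "normalize_timeseries",
    "normalize_table",
    "SpearmanResult",
    "spearman_correlation",
    "binned_mean_map",
    "decile_edges",
    "build_population_table",
]

#: Default square density window: 200 binned pixels of 0.5652 µm.
DEFAULT_DENSITY_WINDOW_UM = 200 * 0.5652


def local_density(
    centroids_xy_um: np.ndarray,
    window_side_um: float = DEFAULT_DENSITY_WINDOW_UM,
    include_focal: bool = True,
    field_size_um: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Neighbour count in a square window centred on each nucleus.

    For every nucleus, counts centroids falling inside the axis-aligned
    square of side ``window_side_um`` centred on its own centroid
    (inclusive bounds). The focal nucleus is counted by default, so the
    statistic is the occupancy of its window. Also reported in cells/mm².

    When ``field_size_um`` = (x_extent, y_extent) is given, nuclei whose
    window sticks out of the imaged field are flagged ``edge_window``
    (their density is underestimated; no correction is applied).
    """
    if window_side_um <= 0:
        raise ValueError("window_side_um must be > 0")
    pts = np.asarray(centroids_xy_um, dtype=np.float64).reshape(-1, 2)
    half = window_side_um / 2.0
    if pts.shape[0] == 0:
        return pd.DataFrame(columns=["density", "density_per_mm2", "edge_window"])
    dx = np.abs(pts[:, 0][:, None] - pts[:, 0][None, :])
    dy = np.abs(pts[:, 1][:, None] - pts[:, 1][None, :])
    inside = (dx <= half) & (dy <= half)
    counts = inside.sum(axis=1)
    if not include_focal:
        counts = counts - 1
    edge = np.zeros(pts.shape[0], dtype=bool)
    if field_size_um is not None:
        x_extent, y_extent = field_size_um
        edge = (
            (pts[:, 0] - half < 0)
            | (pts[:, 0] + half > x_extent)
            | (pts[:, 1] - half < 0)
            | (pts[:, 1] + half > y_extent)
        )
    return pd.DataFrame(
        {
            "density": counts.astype(int),
            "density_per_mm2": density_per_mm2(counts, window_side_um),
            "edge_window": edge,
        }
    )


def density_per_mm2(counts: np.ndarray, window_side_um: float) -> np.ndarray:
    """Convert window counts to cells per mm²."""
    window_mm2 = (window_side_um / 1000.0) ** 2
    return np.asarray(counts, dtype=np.float64) / window_mm2


def _shift_no_wrap(labels: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer in-plane translation with zero fill (content never wraps)."""
    out = np.zeros_like(labels)
    src_y = slice(max(0, -dy), labels.shape[1] - max(0, dy))
    src_x = slice(max(0, -dx), labels.shape[2] - max(0, dx))
    dst_y = slice(max(0, dy), labels.shape[1] - max(0, -dy))
    dst_x = slice(max(0, dx), labels.shape[2] - max(0, -dx))
    out[:, dst_y, dst_x] = labels[:, src_y, src_x]
    return out


@dataclass
class MatchResult:
    pairs: pd.DataFrame  # columns: live_id, fixed_id, overlap_fraction
    shift_yx_px: tuple[int, int]
    registered: bool


def match_live_fixed(
    live: LabelVolume,
    fixed: LabelVolume,
    min_overlap: float = 0.5,
    max_shift_px: int = 20,
) -> MatchResult:
    """Match live-image nuclei to fixed-image nuclei of the same field.

    A global 2D translation between the two mask footprints is estimated by
    phase cross-correlation, the fixed volume is shifted accordingly, and
    instances are paired by maximal voxel overlap under a one-to-one
    assignment. Pairs whose overlap is below ``min_overlap`` of the smaller
    mask are dropped. Fields between live imaging and fixation differ by
    stage drift, not deformation, so the registration is translation-only;
    an estimated shift beyond ``max_shift_px`` is implausible as drift
    (e.g. the two volumes do not show the same field) and falls back to the
    identity with a warning.
    """
    proj_live = (live.labels > 0).any(axis=0).astype(np.float64)
    proj_fixed = (fixed.labels > 0).any(axis=0).astype(np.float64)
    registered = True
    if proj_live.sum() == 0 or proj_fixed.sum() == 0:
        warnings.warn("empty mask projection; assuming identity shift", stacklevel=2)
        shift = np.zeros(2)
        registered = False
    else:
        shift, _, _ = phase_cross_correlation(
            proj_live, proj_fixed, upsample_factor=1, normalization=None
        )
        if np.abs(shift).max() > max_shift_px:
            warnings.warn(
                f"registration shift {tuple(shift)} exceeds {max_shift_px} px; "
                "assuming identity (fields likely unrelated)",
                stacklevel=2,
            )
            shift = np.zeros(2)
            registered = False
    dy, dx = int(round(shift[0])), int(round(shift[1]))
    moved = _shift_no_wrap(fixed.labels, dy, dx)

    live_ids = live.ids
    fixed_ids = fixed.ids
    if live_ids.size == 0 or fixed_ids.size == 0:
        pairs = pd.DataFrame(columns=["live_id", "fixed_id", "overlap_fraction"])
        return MatchResult(pairs, (dy, dx), registered)

    both = (live.labels > 0) & (moved > 0)
    pair_index = live.labels[both].astype(np.int64) * (int(moved.max()) + 1) + moved[both]
    counts = np.bincount(pair_index)
    overlap = np.zeros((live_ids.size, fixed_ids.size), dtype=np.int64)
    live_pos = {int(v): i for i, v in enumerate(live_ids)}
    fixed_pos = {int(v): j for j, v in enumerate(fixed_ids)}
    stride = int(moved.max()) + 1
    for idx in np.flatnonzero(counts):
        li, fi = divmod(int(idx), stride)
        if li in live_pos and fi in fixed_pos:
            overlap[live_pos[li], fixed_pos[fi]] = counts[idx]

    sizes_live = {int(v): int((live.labels == v).sum()) for v in live_ids}
    sizes_fixed = {int(v): int((fixed.labels == v).sum()) for v in fixed_ids}
    row, col = linear_sum_assignment(-overlap)
    records = []
    for i, j in zip(row, col):
        count = overlap[i, j]
        if count == 0:
            continue
        live_id, fixed_id = int(live_ids[i]), int(fixed_ids[j])
        smaller = min(sizes_live[live_id], sizes_fixed[fixed_id])
        fraction = count / smaller
        if fraction >= min_overlap:
            records.append((live_id, fixed_id, float(fraction)))
    pairs = pd.DataFrame(records, columns=["live_id", "fixed_id", "overlap_fraction"])
    return MatchResult(pairs, (dy, dx), registered)


def normalize_timeseries(values: np.ndarray, n_baseline: int = 5) -> np.ndarray:
    """Divide a per-nucleus series by the mean of its first ``n_baseline`` points.

    Raises on series shorter than the baseline; a zero baseline mean yields
    an all-NaN (flagged) series with a warning.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 1:
        raise ValueError("values must be a 1D series")
    if values.size < n_baseline:
        raise ValueError(
            f"series has {values.size} timepoints; need at least {n_baseline}"
        )
    baseline = values[:n_baseline].mean()
    if baseline == 0 or not np.isfinite(baseline):
        warnings.warn("zero or non-finite baseline mean; series flagged as NaN", stacklevel=2)
        return np.full_like(values, np.nan)
    return values / baseline


def normalize_table(
    table: pd.DataFrame,
    value_columns: list[str],
    id_column: str = "nucleus_id",
    time_column: str = "timepoint",
    n_baseline: int = 5,
) -> pd.DataFrame:
    """Baseline-normalize each value column per nucleus in a tidy table.

    Nuclei with fewer timepoints than the baseline are dropped (counted via
    the returned table's attrs ``n_dropped_short``).
    """
    out = table.sort_values([id_column, time_column]).copy()
    dropped = 0
    for column in value_columns:
        normalized = np.full(len(out), np.nan)
        for _, idx in out.groupby(id_column).groups.items():
            series = out.loc[idx, column].to_numpy()
            if series.size < n_baseline:
                dropped += 1
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                normalized[out.index.get_indexer(idx)] = normalize_timeseries(
                    series, n_baseline
                )
        out[f"{column}_norm"] = normalized
    out.attrs["n_dropped_short"] = dropped
    return out


@dataclass
class SpearmanResult:
    rho: float
    pvalue: float
    n: int
    method: str  # "exact" or "t-approx"


def _rank_correlation(rank_x: np.ndarray, rank_y: np.ndarray) -> float:
    rx = rank_x - rank_x.mean()
    ry = rank_y - rank_y.mean()
    denom = math.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return math.nan
    return float((rx * ry).sum() / denom)


def _exact_permutation_pvalue(
    rank_x: np.ndarray, rank_y: np.ndarray, abs_rho: float, chunk: int = 100_000
) -> float:
    """Fraction of all n! y-rank permutations with |rho| >= observed."""
    rx = rank_x - rank_x.mean()
    ry = rank_y - rank_y.mean()
    norm = math.sqrt((rx**2).sum() * (ry**2).sum())
    target = (abs_rho - 1e-12) * norm
    total = 0
    extreme = 0
    buffer: list[tuple[float, ...]] = []
    for perm in itertools.permutations(ry):
        buffer.append(perm)
        if len(buffer) == chunk:
            dots = np.abs(np.asarray(buffer) @ rx)
            extreme += int((dots >= target).sum())
            total += len(buffer)
            buffer = []
    if buffer:
        dots = np.abs(np.asarray(buffer) @ rx)
        extreme += int((dots >= target).sum())
        total += len(buffer)
    return extreme / total


def spearman_correlation(
    x: np.ndarray, y: np.ndarray, exact_max_n: int = 10
) -> SpearmanResult:
    """Two-tailed Spearman rank correlation.

    rho is the Pearson correlation of mid-ranks (ties get average ranks).
    For n <= ``exact_max_n`` the p-value is exact: all n! permutations of
    the y-ranks are enumerated and the fraction with |rho| at least as
    extreme as observed is reported. For larger n the usual t
    approximation with n - 2 degrees of freedom is used.

    Pairs with non-finite entries are removed first; zero variance in
    either ranked variable leaves rho undefined (NaN, with a warning).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 finite pairs, got {n}")
    rank_x = stats.rankdata(x)
    rank_y = stats.rankdata(y)
    if np.ptp(rank_x) == 0 or np.ptp(rank_y) == 0:
        warnings.warn("zero variance in ranked variable; rho undefined", stacklevel=2)
        return SpearmanResult(math.nan, math.nan, int(n), "undefined")
    rho = _rank_correlation(rank_x, rank_y)
    if n <= exact_max_n:
        p = _exact_permutation_pvalue(rank_x, rank_y, abs(rho))
        return SpearmanResult(rho, p, int(n), "exact")
    if abs(rho) >= 1.0:
        return SpearmanResult(rho, 0.0, int(n), "t-approx")
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return SpearmanResult(rho, float(min(p, 1.0)), int(n), "t-approx")


def binned_mean_map(
    x: np.ndarray,
    y: np.ndarray,
    values: np.ndarray,
    x_edges: np.ndarray,
    y_edges: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean of ``values`` over a rectangular grid of (x, y) bins.

    Returns (means, counts) with shape (len(x_edges)-1, len(y_edges)-1);
    empty bins are NaN in the means grid.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    if not (x.size == y.size == values.size):
        raise ValueError("x, y and values must have equal length")
    shape = (len(x_edges) - 1, len(y_edges) - 1)
    if x.size == 0:
        return np.full(shape, np.nan), np.zeros(shape, dtype=int)
    mean = stats.binned_statistic_2d(
        x, y, values, statistic="mean", bins=[x_edges, y_edges]
    ).statistic
    count = stats.binned_statistic_2d(
        x, y, values, statistic="count", bins=[x_edges, y_edges]
    ).statistic.astype(int)
    return mean, count


def decile_edges(values: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Quantile bin edges (default deciles) over finite values."""
    values = np.asarray(values, dtype=np.float64)
    values = values[np.isfinite(values)]
    return np.quantile(values, np.linspace(0, 1, n_bins + 1))


def build_population_table(
    shape_table: pd.DataFrame,
    intensity_table: pd.DataFrame,
    window_side_um: float = DEFAULT_DENSITY_WINDOW_UM,
    field_size_um: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Join morphometry and intensity tables and attach local density.

    Density uses the (x, y) morphometric centroids of *all* segmented
    nuclei (before QC) so that the neighbourhood count reflects true
    occupancy, then rows are merged one-per-nucleus.
    """
    merged = shape_table.merge(intensity_table, on="nucleus_id", how="left")
    centroids = shape_table[["centroid_x_um", "centroid_y_um"]].to_numpy()
    density = local_density(centroids, window_side_um, field_size_um=field_size_um)
    density["nucleus_id"] = shape_table["nucleus_id"].to_numpy()
    return merged.merge(density, on="nucleus_id", how="left")
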