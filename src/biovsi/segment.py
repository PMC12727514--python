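"""Per-frame detection of attached cells and area-to-count conversion.

Two independent channels are used, mirroring how the two VSI data
products are exploited:

* the **height** channel, where cells imprint a negative optical anomaly
  — segmented by thresholding the lower tail of the height histogram of
  the analysis region (robust mode − k·MAD, or an absolute nm cutoff);
* the **grayscale** channel, where cells appear darker than the calcite
  background — segmented with a local (adaptive) threshold so that
  smooth illumination gradients do not leak into the mask.

Masks are cleaned by binary opening plus a minimum-area filter, labeled
with 8-connectivity, and the cumulative dark area is converted to a
real-valued cell count using the mean single-cell footprint π(d/2)².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage import filters, measure, morphology


@dataclass
class FrameSegmentation:
    mask: np.ndarray
    components: pd.DataFrame  # label, area_um2, centroid_row, centroid_col
    area_um2: float
    area_fraction: float
    cell_count: float


@dataclass
class CellMaskSeries:
    """Per-frame occupancy masks and derived coverage quantities."""

    masks: list[np.ndarray]
    counts: np.ndarray  # real-valued, area-derived
    area_fractions: np.ndarray
    times_h: np.ndarray
    region_area_mm2: float

    @property
    def density_cells_mm2(self) -> np.ndarray:
        return self.counts / self.region_area_mm2


def segment_by_height(
    height_nm: np.ndarray,
    region_mask: np.ndarray | None = None,
    depth_threshold_nm: float | None = None,
    k_mad: float = 5.0,
) -> np.ndarray:
    """Mask pixels in the lower tail of the height histogram.

    The background level is the robust mode of the region's height
    distribution (peak of a fine histogram). A pixel is marked covered if
    it lies more than ``depth_threshold_nm`` below the mode; when no
    absolute cutoff is given the threshold defaults to ``k_mad`` median
    absolute deviations. A degenerate (constant) histogram yields an
    empty mask with a warning rather than an error.
    """
    h = np.asarray(height_nm, dtype=float)
    region = np.ones(h.shape, bool) if region_mask is None else np.asarray(region_mask, bool)
    vals = h[region]
    vals = vals[np.isfinite(vals)]
    if vals.size < region.sum() / 2:
        raise ValueError("more than 50% of the analysis region is NaN")
    if vals.size == 0 or np.ptp(vals) == 0:
        warnings.warn("degenerate height histogram; returning empty mask", stacklevel=2)
        mode = vals[0] if vals.size else 0.0
        cutoff = 0.0
    else:
        mode = _robust_mode(vals)
        if depth_threshold_nm is None:
            mad = np.median(np.abs(vals - np.median(vals)))
            cutoff = k_mad * mad
        else:
            cutoff = float(depth_threshold_nm)
    out = np.zeros(h.shape, dtype=bool)
    with np.errstate(invalid="ignore"):
        out[region] = h[region] < mode - cutoff
    out &= np.isfinite(h)
    return out


def _robust_mode(vals: np.ndarray, n_bins: int = 512) -> float:
    hist, edges = np.histogram(vals, bins=n_bins)
    i = int(np.argmax(hist))
    return 0.5 * (edges[i] + edges[i + 1])


def segment_by_grayscale(
    image: np.ndarray,
    region_mask: np.ndarray | None = None,
    window_px: int = 51,
    offset: float | None = None,
) -> np.ndarray:
    """Mask pixels darker than their local neighbourhood mean.

    Uses a sliding local-mean threshold (scikit-image ``threshold_local``)
    so that a smooth background gradient is tracked rather than
    misclassified — a global threshold would mark one whole side of a
    tilted illumination field. ``offset`` is the darkness margin below
    the local mean; when None it defaults to a quarter of the robust
    intensity range (median − 1st percentile) of the analysis region.
    """
    img = np.asarray(image, dtype=float)
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError("window_px must be odd and >= 3")
    if window_px > min(img.shape):
        raise ValueError("window larger than image")
    region = np.ones(img.shape, bool) if region_mask is None else np.asarray(region_mask, bool)
    if offset is None:
        # a quarter of the robust dark range, floored so that numerical
        # jitter of the local mean on flat backgrounds never marks pixels
        vals = img[region]
        med = np.median(vals)
        offset = max(0.25 * (med - np.percentile(vals, 1)), 1e-3 * max(abs(med), 1.0))
    local = filters.threshold_local(img, block_size=window_px, method="mean", offset=offset)
    mask = img < local
    return mask & region


def clean_and_label(
    mask: np.ndarray,
    pixel_size_um: float,
    min_area_um2: float | None = None,
    cell_diameter_um: float = 4.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Morphological cleanup and connected-component labeling.

    Binary opening with a 3x3 structuring element removes speckle, then
    components smaller than ``min_area_um2`` (default: 25% of one cell's
    footprint) are dropped. Components are labeled with 8-connectivity
    and reported with areas in µm².
    """
    if min_area_um2 is None:
        min_area_um2 = 0.25 * np.pi * (cell_diameter_um / 2.0) ** 2
    px_area = pixel_size_um**2
    cleaned = morphology.opening(
        np.asarray(mask, bool), morphology.footprint_rectangle((3, 3))
    )
    min_px = int(np.ceil(min_area_um2 / px_area))
    labels = measure.label(cleaned, connectivity=2)
    if labels.max() > 0:
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_px)
        cleaned &= ~np.isin(labels, small[small > 0])
        labels = measure.label(cleaned, connectivity=2)
    if labels.max() == 0:
        table = pd.DataFrame(columns=["label", "area_um2", "centroid_row", "centroid_col"])
    else:
        props = measure.regionprops_table(labels, properties=("label", "area", "centroid"))
        table = pd.DataFrame(
            {
                "label": props["label"],
                "area_um2": props["area"] * px_area,
                "centroid_row": props["centroid-0"],
                "centroid_col": props["centroid-1"],
            }
        )
    return cleaned, table


def area_to_cell_count(total_area_um2: float, mean_diameter_um: float = 4.0) -> float:
    """Convert cumulative dark area to an equivalent number of cells.

    count = area / (π·(d/2)²) with d the mean single-cell diameter;
    real-valued by construction.
    """
    if mean_diameter_um <= 0:
        raise ValueError("mean diameter must be > 0")
    if total_area_um2 < 0:
        raise ValueError("area must be >= 0")
    return total_area_um2 / (np.pi * (mean_diameter_um / 2.0) ** 2)


def segment_frame(
    height_nm: np.ndarray,
    grayscale: np.ndarray,
    region_mask: np.ndarray,
    pixel_size_um: float,
    channel: str = "height",
    cell_diameter_um: float = 4.0,
    **kwargs,
) -> FrameSegmentation:
    """Segment one frame on the chosen channel and derive coverage stats."""
    if channel == "height":
        raw = segment_by_height(height_nm, region_mask, **kwargs)
    elif channel == "grayscale":
        raw = segment_by_grayscale(grayscale, region_mask, **kwargs)
    else:
        raise ValueError("channel must be 'height' or 'grayscale'")
    mask, table = clean_and_label(raw, pixel_size_um, cell_diameter_um=cell_diameter_um)
    mask &= region_mask
    area = float(table["area_um2"].sum()) if len(table) else 0.0
    region_area = float(region_mask.sum()) * pixel_size_um**2
    return FrameSegmentation(
        mask=mask,
        components=table,
        area_um2=area,
        area_fraction=area / region_area if region_area else 0.0,
        cell_count=area_to_cell_count(area, cell_diameter_um),
    )


def segment_stack(
    stack,
    region: str = "calcite",
    channel: str = "height",
    cell_diameter_um: float = 4.0,
    **kwargs,
) -> CellMaskSeries:
    """Segment every frame of a stack over one region.

    ``region`` selects the calcite analysis region (default) or the
    quartz reference strip (used for the processing-uncertainty floor).
    """
    region_mask = stack.calcite_mask if region == "calcite" else stack.quartz_mask
    masks, counts, fracs = [], [], []
    for k in range(stack.n_frames):
        seg = segment_frame(
            stack.heights[k],
            stack.grayscale[k],
            region_mask,
            stack.pixel_size_um,
            channel=channel,
            cell_diameter_um=cell_diameter_um,
            **kwargs,
        )
        masks.append(seg.mask)
        counts.append(seg.cell_count)
        fracs.append(seg.area_fraction)
    return CellMaskSeries(
        masks=masks,
        counts=np.asarray(counts),
        area_fractions=np.asarray(fracs),
        times_h=np.asarray(stack.times_h),
        region_area_mm2=float(region_mask.sum()) * stack.pixel_size_um**2 / 1e6,
    )


def coverage_uncertainty(counts: np.ndarray) -> float:
    """Relative scatter (%) of a cell-count series on a non-detaching region.

    sd/mean × 100 of the per-frame counts; on the quartz reference, where
    no true detachment occurs, this is the processing-uncertainty floor
    below which coverage changes are not considered significant.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 3:
        raise ValueError("need at least 3 frames")
    mean = counts.mean()
    if mean == 0:
        raise ValueError("mean count is zero")
    return float(counts.std(ddof=1) / mean * 100.0)


def no_detachment_test(counts: np.ndarray, times_h: np.ndarray) -> tuple[float, float]:
    """OLS slope and its p-value for the null of zero coverage trend."""
    counts = np.asarray(counts, dtype=float)
    if np.ptp(counts) == 0:  # perfectly constant series: trivially no trend
        return 0.0, 1.0
    res = stats.linregress(times_h, counts)
    return float(res.slope), float(res.pvalue)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
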