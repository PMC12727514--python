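"""Surface-retreat and coverage rate estimation, Ra roughness, unit conversions.

The dissolution rate of the reactive surface is measured as the slope of
the quartz-minus-calcite mean-height difference over time (the inert
quartz strip in the same field of view is the height reference), by
ordinary least squares. Coverage series are fitted the same way and
normalized by the analysis area to give detachment rates in
cells·mm⁻²·h⁻¹. Roughness uses the arithmetic mean roughness

    Ra = (1/N) Σ |z_i − z̄|

over square sub-windows; several windows per surface quantify lateral
variability ("mean ± sd across windows" summaries).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import HOURS_PER_DAY, NM_PER_UM

CALCITE_MOLAR_VOLUME_CM3_MOL = 36.93
SECONDS_PER_DAY = 86_400.0


@dataclass
class RateFit:
    """OLS fit of a scalar time series; slope in (series units)/h."""

    slope: float
    intercept: float
    stderr: float
    r_squared: float
    n: int

    @property
    def slope_um_per_d(self) -> float:
        """Retreat-series convenience: nm/h slope expressed in µm/day."""
        return self.slope * HOURS_PER_DAY / NM_PER_UM

    @property
    def significant(self) -> bool:
        """|slope| > 2·SE — the detection rule for a real trend."""
        return abs(self.slope) > 2.0 * self.stderr


@dataclass
class RoughnessResult:
    ra_nm: float
    origin_um: tuple[float, float]
    size_um: float
    n_pixels: int
    mean_height_nm: float


def retreat_series(stack, cell_masks=None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame mean(quartz) − mean(calcite) height difference (nm).

    Grows as the calcite dissolves. Pixels currently covered by a cell
    (per ``cell_masks``, one mask per frame) are excluded from the
    calcite mean so the optical cell artifact does not bias the rate.
    NaN pixels are skipped. Returns (times_h, series_nm, n_valid_pixels).
    """
    if stack.calcite_mask.sum() == 0 or stack.quartz_mask.sum() == 0:
        raise ValueError("both calcite and quartz masks must be non-empty")
    if stack.n_frames < 3:
        raise ValueError("need at least 3 frames")
    series = np.empty(stack.n_frames)
    n_used = np.empty(stack.n_frames, dtype=int)
    for k in range(stack.n_frames):
        h = stack.heights[k]
        cal = stack.calcite_mask.copy()
        if cell_masks is not None and k < len(cell_masks):
            cal &= ~np.asarray(cell_masks[k], bool)
        qz = h[stack.quartz_mask]
        cz = h[cal]
        qz = qz[np.isfinite(qz)]
        cz = cz[np.isfinite(cz)]
        if qz.size == 0 or cz.size == 0:
            raise ValueError(f"frame {k}: no valid pixels in a region")
        series[k] = qz.mean() - cz.mean()
        n_used[k] = qz.size + cz.size
    return np.asarray(stack.times_h, float), series, n_used


def fit_rate(series: np.ndarray, times_h: np.ndarray) -> RateFit:
    """Ordinary least-squares line through a scalar time series."""
    t = np.asarray(times_h, float)
    y = np.asarray(series, float)
    if t.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(t) == 0:
        raise ValueError("singular design: all times equal")
    res = stats.linregress(t, y)
    return RateFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        stderr=float(res.stderr),
        r_squared=float(res.rvalue**2),
        n=int(t.size),
    )


def fit_detachment_rate(
    counts: np.ndarray, times_h: np.ndarray, region_area_mm2: float
) -> tuple[float, float, RateFit]:
    """Detachment rate (cells·mm⁻²·h⁻¹, positive) from a count series.

    Fits the linear decline of attached-cell counts and normalizes the
    slope by the (constant) analysis area. Returns (rate, rate SE, fit).
    """
    if region_area_mm2 <= 0:
        raise ValueError("region area must be positive")
    fit = fit_rate(counts, times_h)
    return -fit.slope / region_area_mm2, fit.stderr / region_area_mm2, fit


def roughness_ra(
    height_nm: np.ndarray,
    origin_px: tuple[int, int] = (0, 0),
    size_px: int | None = None,
    pixel_size_um: float = 1.0,
) -> RoughnessResult:
    """Arithmetic mean roughness of one square window, in nm.

    Ra = mean |z_i − z̄| over valid (non-NaN) pixels of the window.
    """
    h = np.asarray(height_nm, float)
    r0, c0 = origin_px
    if size_px is None:
        window = h
        size_px = max(h.shape)
    else:
        if r0 < 0 or c0 < 0 or r0 + size_px > h.shape[0] or c0 + size_px > h.shape[1]:
            raise ValueError("window extends outside the raster")
        window = h[r0 : r0 + size_px, c0 : c0 + size_px]
    vals = window[np.isfinite(window)]
    if vals.size < 2:
        raise ValueError("fewer than 2 valid pixels in window")
    zbar = vals.mean()
    return RoughnessResult(
        ra_nm=float(np.mean(np.abs(vals - zbar))),
        origin_um=(r0 * pixel_size_um, c0 * pixel_size_um),
        size_um=size_px * pixel_size_um,
        n_pixels=int(vals.size),
        mean_height_nm=float(zbar),
    )


def subwindow_report(
    height_nm: np.ndarray,
    region_mask: np.ndarray,
    pixel_size_um: float,
    n_windows: int = 3,
    size_um: float = 30.0,
    seed: int = 0,
) -> tuple[list[RoughnessResult], float, float]:
    """Ra over seeded-random sub-windows inside the analysis region.

    Windows are placed deterministically from ``seed``, fully inside the
    region (every pixel of the window in the mask). Returns the
    per-window results plus mean and sd of Ra across windows — the
    "Ra = 41.3 ± 1.0 nm"-style summary of lateral variability.
    """
    size_px = int(round(size_um / pixel_size_um))
    rng = np.random.default_rng(seed)
    ny, nx = region_mask.shape
    eroded = _valid_origins(region_mask, size_px)
    candidates = np.argwhere(eroded)
    if len(candidates) < n_windows:
        raise ValueError(
            f"region too small for {n_windows} windows of {size_um} µm"
        )
    results: list[RoughnessResult] = []
    chosen: list[tuple[int, int]] = []
    attempts = 0
    while len(results) < n_windows:
        attempts += 1
        if attempts > 1000 * n_windows:
            raise ValueError("could not place non-overlapping sub-windows")
        r0, c0 = candidates[rng.integers(len(candidates))]
        if any(abs(r0 - r) < size_px and abs(c0 - c) < size_px for r, c in chosen):
            continue
        chosen.append((r0, c0))
        results.append(roughness_ra(height_nm, (r0, c0), size_px, pixel_size_um))
    ras = np.array([w.ra_nm for w in results])
    return results, float(ras.mean()), float(ras.std(ddof=1) if n_windows > 1 else 0.0)


def _valid_origins(region_mask: np.ndarray, size_px: int) -> np.ndarray:
    """Origins (r0, c0) such that the size_px window fits wholly in the mask.

    Uses an integral image: the window is valid iff all size_px² pixels
    are inside the region.
    """
    ny, nx = region_mask.shape
    out = np.zeros((ny, nx), dtype=bool)
    if size_px > ny or size_px > nx:
        return out
    s = np.zeros((ny + 1, nx + 1), dtype=np.int64)
    np.cumsum(np.cumsum(region_mask, axis=0), axis=1, out=s[1:, 1:])
    w = (
        s[size_px:, size_px:]
        - s[:-size_px, size_px:]
        - s[size_px:, :-size_px]
        + s[:-size_px, :-size_px]
    )
    out[: ny - size_px + 1, : nx - size_px + 1] = w == size_px * size_px
    return out


def retreat_to_molar_flux(
    retreat_um_per_d: float, molar_volume_cm3_mol: float = CALCITE_MOLAR_VOLUME_CM3_MOL
) -> float:
    """Convert surface retreat (µm/day) to a molar flux (mol·m⁻²·s⁻¹)."""
    if molar_volume_cm3_mol <= 0:
        raise ValueError("molar volume must be positive")
    if retreat_um_per_d < 0:
        raise ValueError("retreat must be >= 0")
    retreat_m_per_s = retreat_um_per_d * 1e-6 / SECONDS_PER_DAY
    return retreat_m_per_s / (molar_volume_cm3_mol * 1e-6)


def molar_flux_to_retreat(
    flux_mol_m2_s: float, molar_volume_cm3_mol: float = CALCITE_MOLAR_VOLUME_CM3_MOL
) -> float:
    """Inverse of :func:`retreat_to_molar_flux` (µm/day)."""
    if molar_volume_cm3_mol <= 0:
        raise ValueError("molar volume must be positive")
    return flux_mol_m2_s * molar_volume_cm3_mol * 1e-6 * SECONDS_PER_DAY / 1e-6
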