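"""Virtual interferometer: synthetic stacks with known ground truth.

Emulates a flow-cell dissolution experiment watched by vertical scanning
interferometry: a calcite surface retreating at a constant rate R next to
a static quartz reference strip, with cyanobacteria-sized cells sitting
on the surface. Attached cells appear in the height channel as negative
anomalies (an optical artifact, not real topography) and in the
simultaneous grayscale channel as dark disks. Dissolution under an
attached cell proceeds at f·R (f in [0, 1]), so long-resident cells leave
behind topographic highs of height (1−f)·R·τ once the cell artifact is
removed — the signature the downstream correlation analysis looks for.

Time is discretised on the frame grid: a cell covers the whole interval
[t_k, t_k + Δt) iff it is attached at t_k, and detachment happens at
frame boundaries. Residence, under-cell relief and the emitted masks are
therefore exactly consistent with each other, which is what makes the
generator usable as an oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ExperimentConfig
from .stack import ImageStack

MAX_PLACEMENT_ATTEMPTS_PER_CELL = 500


class PlacementError(RuntimeError):
    """Raised when non-overlapping cell placement fails."""


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst would have to infer."""

    cells: pd.DataFrame  # cell_id, row, col, radius_px, attach_h, detach_h, on_quartz, n_pixels
    footprints: list[tuple[np.ndarray, np.ndarray]]  # (rows, cols) per cell
    times_h: np.ndarray
    frame_interval_h: float
    shape: tuple[int, int]
    residence_map_h: np.ndarray  # (ny, nx) float64, hours
    final_height_true_nm: np.ndarray  # noiseless cell-free final surface

    @property
    def n_frames(self) -> int:
        return len(self.times_h)

    def present(self, frame: int) -> np.ndarray:
        """Boolean per-cell attachment state at frame time t_k."""
        t = self.times_h[frame]
        return (self.cells["attach_h"].to_numpy() <= t) & (
            t < self.cells["detach_h"].to_numpy()
        )

    def mask(self, frame: int) -> np.ndarray:
        """True occupancy mask at one frame."""
        m = np.zeros(self.shape, dtype=bool)
        for cid in np.flatnonzero(self.present(frame)):
            rr, cc = self.footprints[cid]
            m[rr, cc] = True
        return m

    def mask_series(self) -> list[np.ndarray]:
        """Occupancy masks for the coverage intervals (final frame excluded)."""
        return [self.mask(k) for k in range(self.n_frames - 1)]

    def coverage_counts(self, on_quartz: bool = False) -> np.ndarray:
        """Number of attached cells per frame, on calcite or on quartz."""
        sel = self.cells["on_quartz"].to_numpy() == on_quartz
        return np.array(
            [int(np.sum(self.present(k) & sel)) for k in range(self.n_frames)]
        )


def schedule_detachments(
    config: ExperimentConfig, rng: np.random.Generator | None = None, n_cells: int | None = None
) -> np.ndarray:
    """Draw per-cell detachment times (hours) for the calcite population.

    "uniform" draws i.i.d. uniform on [0, N0/(d·A)] so that the expected
    attached count declines linearly at d cells·mm⁻²·h⁻¹ over the calcite
    area A, the straight-line behaviour observed in the coverage series;
    "exponential" draws i.i.d. exponential waiting times with the per-cell
    hazard d·A/N0 (same initial slope, convex decline); "none" never
    detaches (+inf).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    n = config.n_cells_initial if n_cells is None else n_cells
    if config.detachment_mode == "none":
        return np.full(n, np.inf)
    d = config.detachment_rate_cells_mm2_h
    area = config.calcite_area_mm2
    if config.detachment_mode == "uniform":
        horizon = n / (d * area)
        return rng.uniform(0.0, horizon, size=n)
    # exponential
    lam = d * area / n  # per-cell hazard, 1/h
    return rng.exponential(1.0 / lam, size=n)


def generate_experiment(
    config: ExperimentConfig, detach_times: np.ndarray | None = None
) -> tuple[ImageStack, GroundTruth]:
    """Render a full synthetic stack plus its ground truth.

    Height model per frame time t (calcite pixels, nm, noise-free part):

        z(t) = z0 − R·t + (1−f)·R·τcov(t)

    with τcov the cumulative covered time of that pixel up to t. Quartz
    pixels stay at z0 = 0. The apparent height channel additionally
    subtracts ``cell_depression_nm`` wherever a cell is currently
    attached. The final frame is also rendered "cell-free" (artifact
    removed, fresh noise), mimicking ex-situ imaging after surfactant
    removal of the cells.

    ``detach_times`` overrides the drawn detachment schedule of the
    calcite cells (hours, one per cell) — handy for constructing
    scenarios with exactly known residence times.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    ny, nx = config.ny, config.nx
    qw = config.quartz_width_px

    quartz_mask = np.zeros((ny, nx), dtype=bool)
    quartz_mask[:, :qw] = True
    calcite_mask = ~quartz_mask

    centers = _place_cells(config, rng)
    n_cal = config.n_cells_initial
    if detach_times is not None:
        cal_detach = np.asarray(detach_times, dtype=float)
        if cal_detach.shape != (n_cal,):
            raise ValueError("detach_times must have one entry per calcite cell")
    elif n_cal:
        cal_detach = schedule_detachments(config, rng, n_cells=n_cal)
    else:
        cal_detach = np.empty(0)
    detach = np.concatenate(
        [cal_detach, np.full(config.n_cells_quartz, np.inf)]  # quartz cells never detach
    )
    footprints = [_disk_footprint(r, c, config.cell_radius_px, ny, nx) for r, c in centers]
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(len(centers)),
            "row": [rc[0] for rc in centers],
            "col": [rc[1] for rc in centers],
            "radius_px": config.cell_radius_px,
            "attach_h": 0.0,
            "detach_h": detach,
            "on_quartz": [False] * n_cal + [True] * config.n_cells_quartz,
            "n_pixels": [len(fp[0]) for fp in footprints],
        }
    )

    n_frames = config.n_frames
    dt = config.frame_interval_h
    times = np.arange(n_frames) * dt
    rate_nm_h = config.retreat_rate_nm_per_h
    relief_gain = (1.0 - config.inhibition_factor) * rate_nm_h  # nm per covered hour
    sigma = config.roughness_noise_nm

    heights = np.empty((n_frames, ny, nx), dtype=np.float32)
    grayscale = np.empty((n_frames, ny, nx), dtype=np.uint16)
    gray_base = np.broadcast_to(
        config.grayscale_background
        + config.grayscale_gradient * (np.arange(nx) / max(nx - 1, 1) - 0.5),
        (ny, nx),
    ).astype(np.float64)

    cov_n = np.zeros((ny, nx), dtype=np.int64)  # covered intervals per pixel
    attach = cells["attach_h"].to_numpy()
    for k in range(n_frames):
        t = times[k]
        present = (attach <= t) & (t < detach)
        true_h = np.where(calcite_mask, -rate_nm_h * t + relief_gain * (cov_n * dt), 0.0)
        apparent = true_h if sigma == 0 else true_h + rng.normal(0.0, sigma, (ny, nx))
        gray = gray_base.copy()
        if config.grayscale_noise > 0:
            gray += rng.normal(0.0, config.grayscale_noise, (ny, nx))
        for cid in np.flatnonzero(present):
            rr, cc = footprints[cid]
            apparent[rr, cc] -= config.cell_depression_nm
            gray[rr, cc] -= config.cell_darkness
        heights[k] = apparent
        grayscale[k] = np.clip(np.round(gray), 0, 65535).astype(np.uint16)
        if k < n_frames - 1:  # coverage accrues over the interval [t_k, t_k + dt)
            for cid in np.flatnonzero(present):
                rr, cc = footprints[cid]
                cov_n[rr, cc] += 1

    residence = cov_n * dt
    final_true = np.where(
        calcite_mask, -rate_nm_h * times[-1] + relief_gain * residence, 0.0
    )
    final_cellfree = final_true.copy()
    if sigma > 0:
        final_cellfree = final_cellfree + rng.normal(0.0, sigma, (ny, nx))

    stack = ImageStack(
        heights=heights,
        grayscale=grayscale,
        times_h=times,
        pixel_size_um=config.pixel_size_um,
        calcite_mask=calcite_mask,
        quartz_mask=quartz_mask,
        final_cellfree_height=final_cellfree.astype(np.float32),
    )
    stack.validate()
    truth = GroundTruth(
        cells=cells,
        footprints=footprints,
        times_h=times,
        frame_interval_h=dt,
        shape=(ny, nx),
        residence_map_h=residence,
        final_height_true_nm=final_true,
    )
    return stack, truth


def _place_cells(
    config: ExperimentConfig, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Rejection-sample non-overlapping cell centers (pixel coordinates).

    Calcite cells land on the calcite region, quartz cells on the quartz
    strip; centers keep at least one diameter between them and one radius
    from field and strip edges.
    """
    r = config.cell_radius_px
    min_sep2 = (2.0 * r) ** 2
    ny, nx = config.ny, config.nx
    qw = config.quartz_width_px
    placed: list[tuple[float, float]] = []

    def sample_region(n: int, col_lo: float, col_hi: float, label: str) -> None:
        if n == 0:
            return
        if col_hi - col_lo < 2 * r or ny < 2 * r:
            raise PlacementError(f"{label} region too small for cells of radius {r:.1f} px")
        start = len(placed)
        attempts = 0
        while len(placed) - start < n:
            attempts += 1
            if attempts > MAX_PLACEMENT_ATTEMPTS_PER_CELL * n:
                raise PlacementError(
                    f"could not place {n} non-overlapping cells on the {label} region"
                )
            row = rng.uniform(r, ny - r)
            col = rng.uniform(col_lo + r, col_hi - r)
            ok = True
            for pr, pc in placed:
                if (pr - row) ** 2 + (pc - col) ** 2 < min_sep2:
                    ok = False
                    break
            if ok:
                placed.append((row, col))

    sample_region(config.n_cells_initial, qw, nx, "calcite")
    sample_region(config.n_cells_quartz, 0, qw, "quartz")
    return placed


def _disk_footprint(
    row: float, col: float, radius_px: float, ny: int, nx: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pixels whose centers (i+0.5, j+0.5) fall inside the disk."""
    i0 = max(int(math.floor(row - radius_px - 1)), 0)
    i1 = min(int(math.ceil(row + radius_px + 1)), ny)
    j0 = max(int(math.floor(col - radius_px - 1)), 0)
    j1 = min(int(math.ceil(col + radius_px + 1)), nx)
    ii, jj = np.mgrid[i0:i1, j0:j1]
    inside = (ii + 0.5 - row) ** 2 + (jj + 0.5 - col) ** 2 <= radius_px**2
    return ii[inside], jj[inside]


def write_ground_truth(truth: GroundTruth, out_dir) -> None:
    """Persist ground truth as CSV (cells) + TIFF (residence, final surface)."""
    from pathlib import Path

    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.cells.to_csv(out / "true_cells.csv", index=False)
    tifffile.imwrite(out / "true_residence_h.tif", truth.residence_map_h.astype(np.float32))
    tifffile.imwrite(
        out / "true_final_height_nm.tif", truth.final_height_true_nm.astype(np.float32)
    )
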