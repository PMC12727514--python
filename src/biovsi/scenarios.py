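"""Reference study scenarios for the virtual interferometer.

These configs encode the acquisition geometry and the study conditions
the analyses are benchmarked against: a 400 x 400 µm² field at 0.4
µm/pixel imaged every 5 min, far-from-equilibrium retreat rates of order
10 µm/day, ~20% under-cell inhibition, cells of 4 µm diameter, and
detachment rates of order 10³ cells·mm⁻²·h⁻¹. They are used by the
analysis drivers, the test suite and the reproduction script alike.
"""

from __future__ import annotations

import numpy as np

from .config import ExperimentConfig
from .synthetic import generate_experiment

#: true retreat rate of the untreated far-from-equilibrium benchmark (µm/day)
RETREAT_RATE_BENCHMARK_UM_D = 10.3
#: true detachment rate of the untreated far-from-equilibrium benchmark
DETACHMENT_RATE_BENCHMARK = 1298.0


def retreat_benchmark(seed: int = 42, noise_nm: float = 20.0) -> ExperimentConfig:
    """24 h quartz-referenced retreat measurement, no cells on the field."""
    return ExperimentConfig(
        duration_h=24.0,
        retreat_rate_um_per_d=RETREAT_RATE_BENCHMARK_UM_D,
        roughness_noise_nm=noise_nm,
        rng_seed=seed,
    )


def detachment_benchmark(seed: int) -> ExperimentConfig:
    """500 cells over a 0.16 mm² field detaching uniformly at 1298
    cells·mm⁻²·h⁻¹; 2 h keeps the count series inside the linear-decline
    regime (the population empties at ~2.4 h)."""
    return ExperimentConfig(
        quartz_fraction=0.0,
        duration_h=2.0,
        retreat_rate_um_per_d=10.0,
        roughness_noise_nm=20.0,
        grayscale_noise=150.0,
        n_cells_initial=500,
        detachment_mode="uniform",
        detachment_rate_cells_mm2_h=DETACHMENT_RATE_BENCHMARK,
        rng_seed=seed,
    )


def far_from_equilibrium_reference(seed: int = 7) -> ExperimentConfig:
    """The reference protective-effect scenario: 20% under-cell rate
    reduction, residence times spread over the whole 24 h run (uniform
    detachment with horizon = duration), 50 nm final height noise."""
    cfg = ExperimentConfig(
        duration_h=24.0,
        retreat_rate_um_per_d=10.0,
        inhibition_factor=0.8,
        roughness_noise_nm=50.0,
        n_cells_initial=500,
        detachment_mode="uniform",
        rng_seed=seed,
    )
    # horizon N0/(d·A) = duration → residence broadly distributed over 24 h
    cfg.detachment_rate_cells_mm2_h = cfg.n_cells_initial / (
        cfg.calcite_area_mm2 * cfg.duration_h
    )
    return cfg


def single_cell_relief(residence_h: float = 4.0):
    """Noiseless run with one cell resident exactly ``residence_h`` hours
    on calcite retreating at 10.3 µm/d with f = 0.8; returns
    (stack, truth). The relief left under the cell is (1−f)·R·τ."""
    cfg = ExperimentConfig(
        field_width_um=80.0,
        field_height_um=80.0,
        duration_h=24.0,
        retreat_rate_um_per_d=RETREAT_RATE_BENCHMARK_UM_D,
        inhibition_factor=0.8,
        n_cells_initial=1,
        detachment_mode="uniform",
        detachment_rate_cells_mm2_h=1.0,
        rng_seed=0,
    )
    return cfg, generate_experiment(cfg, detach_times=np.array([residence_h]))
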