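"""Shared fixtures: small synthetic scenarios reused across test modules."""

from __future__ import annotations

import pytest

from biovsi import generate_experiment
from biovsi.config import ExperimentConfig


def small_config(**overrides) -> ExperimentConfig:
    """A fast 160x160 µm scenario; override freely per test."""
    base = dict(
        field_width_um=160.0,
        field_height_um=160.0,
        pixel_size_um=0.4,
        frame_interval_min=5.0,
        duration_h=6.0,
        retreat_rate_um_per_d=10.0,
        quartz_fraction=0.2,
        rng_seed=11,
    )
    base.update(overrides)
    return ExperimentConfig(**base)


@pytest.fixture(scope="session")
def protective_run():
    """Far-from-equilibrium-style scenario: under-cell inhibition on,
    cells detaching on a uniform schedule so residence is broadly spread."""
    cfg = small_config(
        inhibition_factor=0.8,
        roughness_noise_nm=30.0,
        grayscale_noise=150.0,
        n_cells_initial=150,
        detachment_mode="uniform",
        detachment_rate_cells_mm2_h=150 / (0.02048 * 6.0),
        rng_seed=21,
    )
    stack, truth = generate_experiment(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def no_effect_run():
    """Same geometry with f = 1: cells leave no topographic trace."""
    cfg = small_config(
        inhibition_factor=1.0,
        roughness_noise_nm=30.0,
        grayscale_noise=150.0,
        n_cells_initial=150,
        detachment_mode="uniform",
        detachment_rate_cells_mm2_h=150 / (0.02048 * 6.0),
        rng_seed=22,
    )
    stack, truth = generate_experiment(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def quartz_reference_run():
    """Cells on both substrates, none detaching on quartz: used for the
    processing-uncertainty floor and the zero-slope null test."""
    cfg = small_config(
        duration_h=2.0,
        roughness_noise_nm=20.0,
        grayscale_noise=400.0,
        n_cells_initial=60,
        n_cells_quartz=25,
        detachment_mode="uniform",
        detachment_rate_cells_mm2_h=60 / (0.02048 * 2.0),
        rng_seed=31,
    )
    stack, truth = generate_experiment(cfg)
    return cfg, stack, truth
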