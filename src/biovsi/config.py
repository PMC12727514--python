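"""Experiment configuration for the virtual interferometer.

All geometry is in micrometres, heights in nanometres, times in hours.
Surface-retreat rates are accepted in µm/day (the unit dissolution rates
are reported in) and converted internally to nm/h.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

NM_PER_UM = 1000.0
HOURS_PER_DAY = 24.0

DETACHMENT_MODES = ("none", "uniform", "exponential")


@dataclass
class ExperimentConfig:
    """Parameters of a synthetic flow-cell interferometry run.

    Defaults reproduce the acquisition geometry of the study conditions:
    a 400 x 400 µm² field sampled at 0.4 µm/pixel every 5 min for 24 h,
    cells of 4 µm mean diameter appearing as negative height anomalies.

    Attributes
    ----------
    retreat_rate_um_per_d : float
        True calcite surface-retreat rate R (µm/day). Quartz never retreats.
    inhibition_factor : float
        f in [0, 1]; the dissolution rate under an attached cell is f·R.
        f = 1 means no protective effect.
    cell_depression_nm : float
        Apparent depth of the optical artifact a cell imprints on the
        height channel. Not a physical depression: removed in the
        cell-free final map. The default (2.5 µm) is chosen so that cells
        remain negative anomalies even after accruing under-cell relief.
    detachment_mode : str
        "none", "uniform" (detach times i.i.d. uniform on [0, N0/(d·A)],
        giving a linear coverage decline at d cells·mm⁻²·h⁻¹) or
        "exponential" (i.i.d. exponential waiting times with hazard
        matched to the same initial slope).
    n_cells_quartz : int
        Cells seeded on the quartz reference strip; they never detach
        (no significant detachment occurs on quartz) and serve to
        estimate the processing uncertainty of the counting pipeline.
    """

    field_width_um: float = 400.0
    field_height_um: float = 400.0
    pixel_size_um: float = 0.4
    frame_interval_min: float = 5.0
    duration_h: float = 24.0
    retreat_rate_um_per_d: float = 10.0
    inhibition_factor: float = 1.0
    quartz_fraction: float = 0.2
    n_cells_initial: int = 0
    n_cells_quartz: int = 0
    cell_diameter_um: float = 4.0
    cell_depression_nm: float = 2500.0
    detachment_mode: str = "none"
    detachment_rate_cells_mm2_h: float = 0.0
    roughness_noise_nm: float = 0.0
    grayscale_background: float = 30000.0
    grayscale_gradient: float = 0.0
    grayscale_noise: float = 0.0
    cell_darkness: float = 8000.0
    rng_seed: int = 0

    # -- derived geometry -------------------------------------------------

    @property
    def nx(self) -> int:
        return _exact_div(self.field_width_um, self.pixel_size_um, "field width")

    @property
    def ny(self) -> int:
        return _exact_div(self.field_height_um, self.pixel_size_um, "field height")

    @property
    def frame_interval_h(self) -> float:
        return self.frame_interval_min / 60.0

    @property
    def n_frames(self) -> int:
        """Frames at t = 0, Δt, ..., duration inclusive."""
        return _exact_div(self.duration_h, self.frame_interval_h, "duration") + 1

    @property
    def retreat_rate_nm_per_h(self) -> float:
        return self.retreat_rate_um_per_d * NM_PER_UM / HOURS_PER_DAY

    @property
    def cell_radius_px(self) -> float:
        return self.cell_diameter_um / 2.0 / self.pixel_size_um

    @property
    def quartz_width_px(self) -> int:
        return int(round(self.quartz_fraction * self.nx))

    @property
    def field_area_mm2(self) -> float:
        return self.field_width_um * self.field_height_um / 1e6

    @property
    def calcite_area_mm2(self) -> float:
        return (self.nx - self.quartz_width_px) * self.ny * self.pixel_size_um**2 / 1e6

    def validate(self) -> None:
        if not 0.0 <= self.inhibition_factor <= 1.0:
            raise ValueError("inhibition_factor must lie in [0, 1]")
        if self.retreat_rate_um_per_d < 0:
            raise ValueError("retreat rate must be >= 0")
        if self.detachment_mode not in DETACHMENT_MODES:
            raise ValueError(f"detachment_mode must be one of {DETACHMENT_MODES}")
        if self.detachment_mode != "none" and self.detachment_rate_cells_mm2_h <= 0:
            raise ValueError("a detaching mode requires detachment_rate_cells_mm2_h > 0")
        if not 0.0 <= self.quartz_fraction < 1.0:
            raise ValueError("quartz_fraction must lie in [0, 1)")
        if self.cell_diameter_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("lengths must be positive")
        # these raise on non-integer grids / non-multiple durations
        self.nx, self.ny, self.n_frames

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))


def _exact_div(a: float, b: float, what: str) -> int:
    n = a / b
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"{what} ({a}) is not an integer multiple of {b}")
    return int(round(n))
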