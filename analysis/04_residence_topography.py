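#!/usr/bin/env python
"""Residence-time maps, their correlation with final topography, and Ra.

Two scaled scenarios are contrasted: one with 20% under-cell inhibition
(f = 0.8), where long-resident pixels become topographic highs in the
cell-free final surface, and one with f = 1, where no protective effect
exists and the correlation collapses. Sub-window Ra roughness of the
final surfaces is reported alongside. Writes
results/residence_correlation.csv and results/roughness.csv.
"""

from pathlib import Path

import pandas as pd

from biovsi import (
    correlate_residence_topography,
    generate_experiment,
    residence_map,
    segment_stack,
    subwindow_report,
)
from biovsi.config import ExperimentConfig

RESULTS = Path(__file__).resolve().parents[1] / "results"


def scenario(f: float) -> ExperimentConfig:
    cfg = ExperimentConfig(
        field_width_um=160.0,
        field_height_um=160.0,
        duration_h=6.0,
        retreat_rate_um_per_d=10.0,
        inhibition_factor=f,
        roughness_noise_nm=30.0,
        n_cells_initial=150,
        detachment_mode="uniform",
        rng_seed=2024,
    )
    cfg.detachment_rate_cells_mm2_h = cfg.n_cells_initial / (
        cfg.calcite_area_mm2 * cfg.duration_h
    )
    return cfg


def main() -> None:
    rows, rough = [], []
    for f in (0.8, 1.0):
        cfg = scenario(f)
        stack, truth = generate_experiment(cfg)
        # segmentation-derived residence map (height-channel masks)
        series = segment_stack(stack, channel="height")
        res = residence_map(series.masks[:-1], cfg.frame_interval_h)
        for label, values in (("segmented", res.values_h), ("true", truth.residence_map_h)):
            corr = correlate_residence_topography(
                values, stack.final_cellfree_height, stack.calcite_mask
            )
            rows.append(
                {"inhibition_factor": f, "residence_source": label,
                 "pearson_r": corr.r, "n_pixels": corr.n_pixels}
            )
        windows, mean, sd = subwindow_report(
            stack.final_cellfree_height, stack.calcite_mask, cfg.pixel_size_um,
            seed=cfg.rng_seed,
        )
        rough.append({"inhibition_factor": f, "ra_mean_nm": mean, "ra_sd_nm": sd,
                      "ra_windows_nm": [round(w.ra_nm, 2) for w in windows]})
        print(f"f={f}: r(true)={rows[-1]['pearson_r']:.3f} over {rows[-1]['n_pixels']} px; "
              f"Ra = {mean:.1f} ± {sd:.1f} nm")

    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(RESULTS / "residence_correlation.csv", index=False)
    pd.DataFrame(rough).to_csv(RESULTS / "roughness.csv", index=False)
    r_protect = rows[0]["pearson_r"]
    r_flat = [r for r in rows if r["inhibition_factor"] == 1.0][-1]["pearson_r"]
    print(f"\nprotective effect separates cleanly: r = {r_protect:.2f} (f=0.8) "
          f"vs r = {r_flat:.2f} (f=1)")


if __name__ == "__main__":
    main()
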