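# biovsi

Time-lapse vertical scanning interferometry (VSI) analysis of
microbe–mineral interfaces: how attached cyanobacteria modulate calcite
dissolution, pixel by pixel.

In a flow-cell dissolution experiment, a calcite crystal retreats at a
rate R while an inert quartz strip in the same field of view holds
still, so the mean height difference between the two regions grows
linearly and its OLS slope is the dissolution rate. Attached cells show
up twice in the data: as negative anomalies in the height channel (an
optical artifact of the cell body) and as dark disks in the simultaneous
grayscale image. Summing per-frame occupancy masks gives a **residence
time map** τ(x, y) — how long each surface location stayed covered. If
dissolution under a cell proceeds at f·R instead of R (f ≤ 1), the final
cell-free surface carries topographic highs of height (1 − f)·R·τ, and
the pixel-wise Pearson correlation between τ and the final topography is
the quantitative fingerprint of that protective effect.

The package implements the full chain for people who analyse such
interferometry time series (or want to benchmark analyses like it):

- `biovsi.synthetic` — a *virtual interferometer*: synthetic
  height/grayscale stacks with a known retreat rate, under-cell
  inhibition factor, cell geometry and stochastic detachment schedule,
  plus complete ground truth. Since raw VSI datasets of this kind are
  rarely deposited, every downstream stage is validated against this
  generator.
- `biovsi.stack` — lossless TIFF/CSV/JSON stack format with region
  masks and NaN-aware statistics.
- `biovsi.segment` — cell detection by lower-tail height thresholding
  (robust mode − k·MAD) and by adaptive local-mean grayscale
  thresholding; morphological cleanup; area → real-valued cell counts
  via π(d/2)² with d = 4 µm.
- `biovsi.residence` — residence-time maps and the
  residence–topography correlation.
- `biovsi.metrics` — quartz-referenced retreat series, OLS rate fits
  (µm/day and cells·mm⁻²·h⁻¹), arithmetic mean roughness
  Ra = (1/N) Σ|zᵢ − z̄| over 30 µm sub-windows, retreat ↔ molar-flux
  conversion (Vm = 36.93 cm³/mol).
- `biovsi.geochem` — open-system carbonate speciation at fixed pCO2
  with Davies activity coefficients; the flow-through mass balance
  [Ca] = r·M_Ca·SA/(10⁻⁶·ν); the pH ↔ Ω inversion
  {H⁺} = √(a_Ca·K1·K2·KH·pCO2/(Ω·Ksp)); and a pluggable dissolution
  rate law R(Ω) = k(1 − Ω)ⁿ to translate an observed under-cell rate
  reduction into a local saturation index.
- `biovsi.pipeline` / `biovsi.cli` — one-command orchestration
  (`biovsi run-all`) with deterministic, seed-driven reports.

## Worked example

```python
from biovsi import (generate_experiment, residence_map,
                    correlate_residence_topography, retreat_series, fit_rate)
from biovsi.scenarios import far_from_equilibrium_reference

cfg = far_from_equilibrium_reference(seed=7)   # 400x400 µm, 24 h, f = 0.8
stack, truth = generate_experiment(cfg)

masks = [truth.mask(k) for k in range(stack.n_frames)]
t, series, _ = retreat_series(stack, cell_masks=masks)  # quartz-minus-calcite, nm
fit = fit_rate(series, t)
res = residence_map(truth.mask_series(), cfg.frame_interval_h)
corr = correlate_residence_topography(res, stack.final_cellfree_height,
                                      stack.calcite_mask)
print(f"retreat {fit.slope_um_per_d:.2f} µm/d, r = {corr.r:.3f} over {corr.n_pixels} px")
```

prints

```
retreat 9.95 µm/d, r = 0.981 over 800000 px
```

— the configured 10 µm/day retreat rate is recovered to within 0.5%
(the small deficit is physical: pixels that were covered dissolve
slower, so the cell-bearing calcite region as a whole retreats slightly
below R), and the strongly positive correlation (r = 0.98 across the
8 × 10⁵ calcite pixels) shows that long-resident locations ended up as
topographic highs, i.e. the 20% under-cell inhibition left a detectable
protective signature. Re-running with `cfg.inhibition_factor = 1.0`
collapses r to ≈ 0.

On the chemistry side:

```python
from biovsi import SolutionState, ThermoConstants, solve_ph_for_omega, outlet_ca_ppm
from biovsi.geochem import ppb_to_molal

ca_ppb = outlet_ca_ppm(5e-7, 1e-4, 0.004) * 1000        # -> 500.0 ppb
sol = SolutionState(extra_ca_m=ppb_to_molal(ca_ppb))    # NaCl/NaHCO3 medium
ph = solve_ph_for_omega(sol, 0.1, ThermoConstants.at_temperature(20.0))
print(f"[Ca] = {ca_ppb:.0f} ppb, interfacial pH = {ph:.2f}")
```

prints `[Ca] = 500 ppb, interfacial pH = 8.65`: a 20% under-cell rate
reduction (local Ω ≈ 0.1 under the calibrated rate law) implies a
cell–mineral interface about 0.7 pH units above the bulk value of ≈ 7.9.

The numbered scripts under `analysis/` run these stages as a narrative —
simulation, retreat rates, detachment rates, residence–topography
correlation, interfacial chemistry — and write their tables to
`results/`.

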