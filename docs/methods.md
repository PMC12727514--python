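# Methods

## Physical model of the virtual interferometer

The generator renders the simplest surface-evolution model that carries
all the observables the analyses measure. Heights are float32
nanometres, times hours, rates accepted in µm/day and converted
internally (nm/h); coordinates are row-major and 0-based with pixel
centers at (i + 0.5)·pixel_size.

For a calcite pixel at frame time t,

    z(t) = z0 − R·t + (1 − f)·R·τcov(t)

where R is the retreat rate, f ∈ [0, 1] the under-cell inhibition factor
and τcov the cumulative time the pixel has been covered by an attached
cell. Quartz pixels stay at z0 = 0 (quartz dissolution is more than six
orders of magnitude slower than calcite at circum-neutral pH, so the
strip is modelled as exactly inert). Per-frame i.i.d. Gaussian noise of
configurable sd models interferometric roughness noise. Cells are
circular disks (default 4 µm diameter) placed without overlap by
rejection sampling; a pixel is covered iff its center lies inside the
disk. The *apparent* height channel subtracts `cell_depression_nm`
wherever a cell is currently attached — the optical artifact by which
cell bodies read as negative anomalies — while the grayscale channel
subtracts `cell_darkness` from a background with an optional linear
illumination gradient. The final frame is rendered twice: as-is and
"cell-free" (artifact removed, fresh noise), the analogue of ex-situ
imaging after surfactant removal of the cells.

Time is discretised on the frame grid: a cell covers the whole interval
[t_k, t_k + Δt) iff attached at t_k, and detachment happens at frame
boundaries. This makes the ground-truth residence map, the under-cell
relief and the emitted occupancy masks exactly consistent, so the
generator can serve as an oracle for the downstream stages. A residence
series over an experiment of N intervals therefore contains N masks; the
closing frame contributes none.

Detachment schedules: `uniform` draws detach times i.i.d. uniform on
[0, N0/(d·A)] so the expected attached count declines linearly at d
cells·mm⁻²·h⁻¹ over the calcite area A — the straight-line behaviour the
coverage regressions fit; `exponential` draws i.i.d. exponential waits
with per-cell hazard d·A/N0 (same initial slope, convex decline). The
data do not discriminate between the two forms, so both are provided
with `uniform` as the benchmark default. Detached cells never re-attach.
Cells seeded on the quartz strip (`n_cells_quartz`) never detach,
mirroring the observation that no significant detachment occurs on the
inert reference; their count series calibrates the processing noise
floor.

### Defaults and why

| parameter | default | rationale |
|---|---|---|
| field, pixel size | 400 × 400 µm², 0.4 µm/px | acquisition geometry of the benchmark study conditions |
| frame interval / duration | 5 min / 24 h | ditto |
| retreat rate | ~10 µm/day | far-from-equilibrium calcite benchmark |
| inhibition factor f | scenario-specific (0.8 in the reference protective scenario) | ~20% under-cell rate reduction |
| cell diameter | 4 µm | mean single-cell size used for the area → count conversion |
| `cell_depression_nm` | 2500 | the artifact depth is not independently measurable here; chosen to exceed the maximal under-cell relief of the reference scenario ((1−f)·R·T ≈ 2 µm) so cells remain negative anomalies throughout, as observed. Exposed in config, not hard-coded. |
| roughness noise | 20–50 nm per scenario | nm-scale interferometry noise |

## Segmentation

The *height* channel is thresholded on the lower tail of the height
histogram of the analysis region: background level = robust mode (peak
of a 512-bin histogram), cutoff = k·MAD below it (k = 5 by default) or
an absolute nm value. A constant image yields an empty mask with a
warning. The *grayscale* channel uses scikit-image's local-mean
threshold (`threshold_local`, default window 51 px ≈ 20 µm, larger than
a cell) with a darkness offset defaulting to a quarter of the region's
robust dark range, floored at 0.1% of the median so numerical jitter on
flat backgrounds marks nothing. Both masks are cleaned by 3×3 binary
opening plus removal of components below 25% of one cell footprint
(≈ 3.1 µm²), labeled with 8-connectivity. Touching disks merge under
8-connectivity — accepted, because coverage is quantified by area, not
by component count: counts are real-valued, area/π(d/2)².

Residence maps are built from height-channel masks (the artifact
approach); coverage/detachment series from the grayscale channel (the
contrast approach); both are exposed and cross-checked — detachment
estimates from the two channels agree within 10% on synthetic data.

## Rates, roughness, correlation

Retreat series: per-frame mean(quartz) − mean(calcite) height, with
currently covered calcite pixels excluded so the deep optical artifact
does not bias the mean; NaN pixels are skipped pairwise and the pixel
count used is reported. Rates are plain OLS slopes
(`scipy.stats.linregress`) with standard errors; "significant
detachment" means |slope| > 2·SE. Ra is the mean absolute deviation from
the window mean over 30 × 30 µm² sub-windows placed seeded-random,
non-overlapping and wholly inside the calcite mask (their exact
placement within the surface is not a constrained quantity), reported as
mean ± sd over 3 windows. The residence–topography correlation is a
plain pixel-wise Pearson r over the calcite region against the final
**cell-free** map — never a frame containing the artifact, which would
trivially anti-correlate — with NaNs excluded pairwise; no spatial
autocorrelation correction is applied to the p-value. On the generator
the expected value has a closed form, r = sd(s)/√(var(s) + σ²) with
s = (1−f)·R·τ, which the implementation matches to within 0.05.

## Carbonate chemistry

Speciation is open-system: dissolved CO2 pinned by Henry's law at fixed
pCO2 (550 µatm default, the measured room value), carbonate activities
a(HCO3⁻) = K1·KH·pCO2/{H⁺} and a(CO3²⁻) = K1·K2·KH·pCO2/{H⁺}², and
Ω = a(Ca²⁺)·a(CO3²⁻)/Ksp. Activity coefficients use the Davies equation
(valid to I ≈ 0.5 m; the media sit at I ≈ 0.1 m), with the ionic
strength recomputed self-consistently from the speciated carbonate ions
at the working pH — this is what makes the pH ↔ Ω round trip close to
machine precision. Constants default to the Plummer & Busenberg (1982)
temperature expressions (K1, K2, KH, Ksp of calcite) plus a Harned–Owen
Kw, evaluated at 20 °C; they are injectable, and the pH answers are
insensitive at the ±0.1 level to swapping in a 25 °C set. Ion pairing
(CaHCO3⁺, CaCO3⁰) is neglected — a few percent at these concentrations.

The flow-through mass balance [Ca] = r·M_Ca·SA/(10⁻⁶·ν) is implemented
as exact arithmetic. Note that the upper-bound rate 9 × 10⁻⁷ mol·m⁻²·s⁻¹
with SA = 10⁻⁴ m² and ν = 0.004 mL/s gives exactly 900 ppb; quoted
ranges ending at 800 ppb follow from rounding the "~10⁻⁴ m²" surface
area, and the implementation reports the exact value.

The rate law is pluggable. The default family R(Ω) = k(1 − Ω)ⁿ uses
n = log 0.8 / log 0.9 ≈ 2.118 — calibrated so that a 20% rate reduction
inverts to Ω = 0.1, reproducing the established mapping between
under-cell inhibition and local saturation; empirical rate–Ω laws differ
between studies, so the exponent (or a user-supplied callable) can be
substituted. Inversion is by bisection and requires the law to be
non-increasing on [0, 1].

The bulk NaCl (99.25 mM)/NaHCO3 (1.02 mM)/CaCl2 (0.1425 mM) medium at
charge balance under 550 µatm CO2 computes to pH 7.94. Its nominal
"Ω = 0.30" label is reproduced (0.31) when the ion product is formed
from concentrations; on the activity scale the same state is Ω ≈ 0.045.
The package computes both (`activity_scale=` toggle) and uses the
activity scale for all pH inversions.

## Problem sizes and numerical choices

Unit tests run on 120–160 µm fields (≈ 10⁵ pixels, minutes of simulated
time); the end-to-end benchmark recoveries use the full 400 × 400 µm²
field — 10⁶ pixels, 289 frames for the 24 h scenarios and 25 frames for
the 2 h detachment scenario. The detachment benchmark is simulated for
2 h because the 500-cell population detaching at 1298 cells·mm⁻²·h⁻¹
over 0.16 mm² empties at ~2.4 h; fitting past that point would regress
trailing zeros rather than the linear decline the model describes. All
randomness flows from a single config seed (tests and the reproduction
script derive per-run seeds from it), so every report is
byte-reproducible. Degenerate inputs are handled explicitly: constant
height histograms warn and return empty masks, constant count series
return a zero slope with p = 1, all-NaN windows and zero-variance
correlations raise.

## What the generator does and does not emulate

It emulates: constant-rate retreat against a static reference, cells as
co-registered negative height anomalies and dark grayscale blobs,
under-cell inhibition, stochastic detachment with a near-linear coverage
decline, nm-scale Gaussian height noise, and ex-situ cell-free final
imaging. It does not emulate: etch pits, step waves or any
crystallographic microtopography (surfaces are flat planes plus noise);
EPS mechanics or hydrodynamics; cell growth, division, re-attachment or
multilayer aggregates (monolayers only, matching how detachment is
quantified); spatially correlated interferometric artifacts. Passing
recoveries therefore demonstrate the correctness of the measurement
chain under the stated model, not robustness to every feature of real
VSI data — in particular, the crisp synthetic cell edges make the
counting-noise floor on the inert reference much smaller than the
few-percent scatter real image processing shows, and real residence
maps built from imperfect segmentation will correlate slightly less well
than ground-truth masks do.
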