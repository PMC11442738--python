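# Methods

## Problem and approach

`cropwater` compares the growing-season water use and water-use efficiency
(WUE) of a candidate replacement crop — chia (*Salvia hispanica*), a
drought-tolerant seed and forage crop — against established crops (alfalfa,
corn, soybean) using daily satellite-style observations over labeled
agricultural fields, and projects what replacing part of the established
cultivation would mean for regional water consumption and farm income.

The analysis chain is:

1. **Zonal extraction** (`ingest`): daily rasters of evapotranspiration
   (ET), canopy percentage, WUE, gross primary production (GPP) and
   red/near-infrared reflectance are reduced to per-field daily means over
   the pixels whose centers fall inside each field polygon.
2. **Flux derivation** (`fluxes`): NDVI = (NIR − Red)/(NIR + Red); WUE =
   GPP/ET (g C per kg H₂O) when no WUE product exists; transpiration
   T = ET × canopy fraction and transpiration-only WUE\_T = WUE × canopy
   fraction. All water fluxes are converted once to L ha⁻¹ d⁻¹
   (1 mm d⁻¹ = 10,000 L ha⁻¹ d⁻¹).
3. **Seasonal aggregation** (`seasons`): month-first averaging — fields of a
   crop are pooled per day, days are averaged per calendar month, and season
   totals are Σ (monthly mean × days). This prevents unevenly distributed
   satellite revisits from overweighting well-observed months.
4. **Ratio estimation** (`compare`): per-season crop/chia ratios for
   consumption variables (ET and T, totals and daily means) and chia/crop
   ratios for efficiency variables (WUE, WUE\_T), averaged across
   site-seasons with SE = sd(ratios, ddof=1)/√n. Daily ratio series are
   regressed on site air temperature (OLS, two-tailed t-test on the slope,
   n − 2 df).
5. **Projection** (`project`): regional totals = per-hectare season total ×
   cultivated area; replacing a fraction w saves w × total × (1 − 1/R)
   liters under min/mean/max ratio cases; household equivalents divide by an
   annual per-household use; replacement economics bracket the per-hectare
   profit change from yield/price ranges and a water-price credit.

The estimation stage is exposed in a model/results idiom:
`WaterUseComparison(season_summaries).fit()` returns a
`WaterUseComparisonResults` with the ratio table, standard errors,
regressions, a `summary()` report and a ratio bar plot. The surrounding
stages are deliberately plain functions — they transform data rather than
fit anything.

## Synthetic scenes

Real inputs are multi-year satellite archives that cannot ship with a
package, so `synth` generates scenes with analytically known truth:

- **Grid**: square pixels, default 70 m side (0.49 ha), matching the
  resolution of current thermal ET/WUE/canopy products.
- **Fields**: rectangular blocks (default 5×5 pixels) tiled with a one-pixel
  gap and assigned to crops round-robin; the categorical class map is exactly
  consistent with the polygons.
- **Curves**: daily ET is a baseline plus Gaussian bump (mm d⁻¹); canopy
  fraction is a logistic rise/fall clipped to [0, 1]; WUE is a per-crop
  constant, and the GPP layer is WUE × ET so the GPP/ET quotient returns it
  exactly; reflectances encode canopy fraction as NDVI exactly
  (red = 0.3(1 − fc), nir = 0.3(1 + fc)).
- **Noise**: independent Gaussian pixel noise on ET (default sd 1 mm d⁻¹),
  truncated at zero. Truncation rather than redraw keeps generation
  deterministic; with curve values of 2–6 mm d⁻¹ the induced bias is below
  0.1% and far inside the cross-season standard error. Spatial and temporal
  noise correlation is not modeled.
- **Gaps**: each (crop, variable, day) slab is absent with a configurable
  probability (default 0.3), mimicking revisit gaps. Random gaps change the
  variance of monthly means but not their expectation, which the tests check
  by simulation.
- **Temperature**: a seasonal sinusoid with 1.5 °C daily jitter.

Default curve parameters place a late-May to early-November Northern
Hemisphere season with chia at the lowest ET (base 2.0, peak amplitude
2.6 mm d⁻¹) and highest WUE (2.3 g C kg⁻¹), against alfalfa/corn/soybean
with 15–35% heavier seasonal ET and WUE of 1.9–2.0 g C kg⁻¹, consistent
with the ordering the comparison is meant to resolve.

What passing on these scenes shows: the pipeline is exact in the noise-free
limit, unbiased under pixel noise and random gaps, and recovers known
ratios within its own standard errors. What it does not show: robustness to
spatially correlated retrieval error, cloud-contaminated outliers,
mislabeled fields, or canopy-product bias — real-data concerns outside the
generator's scope.

## Numerical and design choices

- **Pixel membership** is pixel-center-in-polygon with a half-open rule
  (left/top edges inclusive), implemented by nudging boundary-touching
  centers by 10⁻⁹ pixel; adjacent fields can never double-count a pixel.
  Area-weighted fractional coverage is out of scope.
- **Nodata** pixels are excluded from numerator and count; a field-day is
  kept if one valid pixel remains; records with zero valid pixels are
  emitted with `n_pixels = 0` and removed by an explicit, logged filter.
- **Edge months** contribute monthly mean × days-of-window-in-month by
  default (seasons start and end mid-month, so full-calendar-month weighting
  would overcount); `weighting="full_month"` is available for sensitivity
  checks.
- **Pooling order** is pixels → field (ingest), fields → crop-day,
  days → month; monthly means then enter totals and season means unweighted
  by observation count.
- **Canopy pairing**: canopy products are sparser than ET, so an ET day may
  borrow the nearest canopy observation within ±8 days; unpaired days keep
  NaN transpiration and drop out of T aggregates only.
- **NDVI → canopy** (for eras before a canopy product): direct clipping to
  [0, 1] by default, optional linear rescale between configurable NDVI
  bounds; neither is asserted as more than a calibration choice.
- **Energy units**: latent-heat flux converts at λ = 2.45 MJ kg⁻¹
  (0.0352653 mm d⁻¹ per W m⁻²), configurable.
- **Percent rendering**: for crop/chia ratios, "percent less water" =
  (1 − 1/R̄) × 100; for chia/crop ratios, "percent more" = (R̄ − 1) × 100.
  Raw ratios and SEs are always emitted alongside, so the convention loses
  no information.
- **SE across seasons** is the n−1 sample standard deviation over √n;
  undefined (NaN, logged) for a single season.
- **Household constant**: 142,000 L yr⁻¹ per household, a derived constant
  back-computed from pairing 184.6 million liters of savings with 1,300
  households; it is labeled as derived in the code and configurable.
- **Negative savings** (ratio < 1, replacement uses more water) are
  reported, never clamped.
- **Economics**: gross income ranges are yield × price at range endpoints;
  the best case for conversion pairs the replacement's maximum gross with
  the incumbent's minimum gross and the largest water credit, the worst case
  the mirror image, the mean case uses midpoints. The ordering
  Δ_worst ≤ Δ_mean ≤ Δ_best holds by construction for nonnegative ranges.

## Simulation study sizes

The ratio-recovery study uses 200 replicates of 60 site-seasons each, on an
11×11-pixel grid (four 5×5-pixel fields, two per crop) over a 165-day
season with default noise and a 0.3 missing-day rate, for true season-total
ratios R* ∈ {1.1, 1.25, 1.5}. Sixty seasons per replicate is a statistical
requirement, not a convenience: the coverage of a ±3·SE interval around a
mean of n approximately normal season ratios is P(|t₍ₙ₋₁₎| ≤ 3), which is
only ≈ 94% at n = 4 and first supports a ≥ 99% coverage claim once n is of
order several dozen (≈ 99.6% at n = 60). A per-window and a vectorized
batch aggregation path exist; the tests assert their equivalence, and the
study uses the batch path.

The t-test calibration study uses 1,000 null repetitions at n = 30 with
temperatures uniform on [5, 35] °C and ratios N(1.2, 0.1²).

## Known limitations

- No reprojection: all rasters and polygons must share one grid/frame.
- Transpiration is a canopy-fraction partition of ET, not an energy-balance
  two-source estimate; it inherits any canopy-product bias multiplicatively.
- Cross-season ratios treat site-seasons as exchangeable replicates; no
  site random effects or weighting by field counts.
- The economics bracket ignores conversion, labor and equipment costs and
  any price feedback from supply shifts.
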