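# landclim

Analysis pipeline for quantifying how land-system scenarios change plant
functional type (PFT) cover, and how those cover changes drive local-to-
regional temperature and precipitation responses in regional
Earth-system-model (ESM) output.

Land-use and nature-restoration policy can be implemented in very different
spatial configurations, and the resulting land-cover changes feed back on
regional climate through biogeophysical pathways (albedo,
evapotranspiration, surface roughness). `landclim` implements the
post-processing chain needed to analyse such experiments:

1. **Translation** (`landclim.translate`): categorical land-system maps →
   habitat types (crosswalk + per-cell suitability argmax) → fractional PFT
   maps, using vegetation-plot species composition, a vertical-layer
   occlusion rule (tree > shrub > herb, remainder bare ground), a
   crop/natural land-unit split, and aggregation to the coarse analysis
   grid. The schema is the standard 17-slot PFT set with one bare slot.
2. **Net transitions** (`landclim.transitions`): the 17 PFT slots are
   aggregated into 7 land-cover categories (tree needleleaf, tree
   broadleaf, shrub, grass, crop rainfed, crop irrigated, bare). Because
   fractional maps do not say which cover replaced which, per-cell net
   transitions are reconstructed with a greedy matching that repeatedly
   pairs the most-increased with the most-decreased category. Each
   transition pair is named and signed by its region-wide dominant
   direction, giving the signed design fractions `x_p`.
3. **Energy-balance decomposition** (`landclim.energy_balance`): the
   surface energy balance `(1−α)·SW↓ + LW↓ − εσTs⁴ = LH + SH + G` (ε = 1,
   G closing the balance) is linearised to attribute the skin-temperature
   response between two runs to six components,

   `ΔTs ≈ λ·(−ΔLH − ΔSH − ΔG − SW↓·Δα  +  (1−α)·ΔSW↓ + ΔLW↓)`,

   with λ = 1/(4εσTs³) the surface temperature sensitivity. The first four
   terms are the surface contribution, the last two the atmospheric
   feedbacks; the linearisation error is reported explicitly.
4. **Attribution** (`landclim.attribution`): the per-cell multi-year mean
   temperature response is regressed on the signed transition fractions,
   `ΔT_i = β0 + Σp βp·x_ip + ε_i`, by ridge regression (penalty chosen from
   a log-spaced 0.1–2000 grid by grouped cross-validation), repeated over
   200 spatial-block bootstrap iterations; βp is the temperature
   sensitivity (°C per unit cell fraction) of transition type p, with
   2.5–97.5 percentile confidence intervals and contributions
   (sensitivity × regional percentage change).
5. **Statistics** (`landclim.stats`): TXx (annual maximum of daily maximum
   2 m temperature), paired Wilcoxon signed-rank tests over years,
   Mann–Whitney U tests against a recent-climate run, Benjamini–Hochberg
   false-discovery-rate control across cells, top-1% focus masks and
   PFT-perturbation bins, and regional summaries.
6. **Synthetic generator** (`landclim.synth`): produces all pipeline inputs
   with known ground truth — the multi-year mean scenario−reference ΔTs is
   planted as a linear transition-response model and the flux fields are
   solved backwards so the energy balance closes exactly — which makes
   every stage testable against an analytic expectation.

## Worked example

```python
from landclim.io import PipelineConfig, run_pipeline, read_table

cfg = PipelineConfig(
    out_dir="example", seed=42,
    synth={"fine_grid_shape": (60, 60), "coarsen_factor": 3,
           "n_years": 15, "n_days_per_year": 60},
    attribution={"n_iterations": 200, "block_size": 4},
)
run_pipeline(cfg)
print(read_table("example/attribution_reported_NAC.csv"))
```

The run translates a 60×60 land-system map into PFT grids on a 20×20
analysis grid, generates 15 years of climate for the reference and the
scenario, and attributes the temperature response. The reported table
(transitions occurring on >0.2% of the area and in >20% of cells) includes,
for this seed:

```
              transition  sensitivity  ci_low  ci_high  area_pct
tree needleleaf to grass        0.573   0.440    0.692     2.545
 crop irrigated to grass        1.179   1.012    1.335     1.881
          shrub to grass        0.179   0.090    0.262     1.822
```

i.e. converting irrigated cropland to grassland warms the local mean
temperature by ≈1.18 °C per unit cell fraction (planted truth: 1.2), and
the regional decomposition summary closes: surface contribution 0.068 °C +
atmospheric feedbacks 0.023 °C = 0.091 °C total against a simulated
response of 0.091 °C (residual −0.0001 °C). The regional statistics table
reports a mean 2 m warming of 0.091 °C, significant on 100% of the area
after FDR adjustment (the synthetic runs share interannual variability, so
paired tests are maximally powerful).

The same pipeline is exposed as a CLI:

```sh
landclim run-all --config cfg.yaml --out outdir --seed 42
```

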