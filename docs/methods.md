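# Methods

This note documents the models and procedures implemented in `landclim`,
the assumptions behind them, the tunable parameters that matter, and the
design choices made where the design was genuinely open.

## Translation of land systems into PFT fractions

Each fine-grid cell holds one categorical land system. A crosswalk table
restricts which habitat types a land system can become; among the
candidates, the habitat with the highest per-cell suitability score is
assigned (exact ties resolve to the lowest habitat code, so the map is a
pure function of its inputs). This suitability-argmax is a deliberately
simple stand-in for ensemble habitat-distribution modelling: it preserves
the interface — one habitat per fine cell, conditioned on land system and
environment — without statistical model fitting.

Habitat composition comes from a vegetation-plot table (plot, habitat,
species, % cover) and a species→PFT assignment. Species cover is summed
per plot within each PFT, then averaged across the habitat's plots with
equal plot weights — the simplest defensible reading of plot averaging;
plots are not abundance- or area-weighted.

Raw per-PFT cover can exceed 100% because vegetation layers overlap, but
only the highest layer interacts with the atmosphere in the host land
model. The occlusion rule is top-down with proportional within-layer
scaling: the tree layer claims `min(Σ tree cover, 100)%` of the cell, split
among tree PFTs proportionally to raw cover; the shrub layer claims up to
the residual, then the herb layer; any remaining area is bare ground. The
output is a proper distribution (sums to 1 exactly). Any raw bare-ground
input is ignored — bare is defined as the unoccupied remainder.

Cropland habitats feed the crop land unit, everything except ice/urban the
natural-vegetation unit; ice and urban cells pass through unchanged and are
identical across scenarios. Within each land unit the PFT fractions sum to
1 at every coarse cell (an empty land unit carries the all-bare
convention). Aggregation to the coarse grid is the arithmetic block mean
(equal-area cells); a cell-area weight field would be needed for
geographic lat-lon grids and is out of scope for the synthetic domain.
Grids are row-major, cell-centre registered, 0-based throughout.

## Net land-cover transitions

The 17 slots collapse onto 7 categories (tree needleleaf, tree broadleaf,
shrub, grass, crop rainfed, crop irrigated, bare); category fractions are
summed over both land units, so crop↔natural conversions appear as ordinary
category transitions. Per cell, the net change vector Δ (which sums to
zero) is decomposed greedily: repeatedly transfer
`min(largest remaining increase, largest remaining decrease)` from the
most-decreased to the most-increased category until residuals fall below
10⁻¹² (a numerical floor far below any ecological signal). Each iteration
exhausts at least one category, so a cell records at most 6 transitions,
and the recorded flows reconstruct Δ exactly. Ties in "largest" break by
the fixed category order above, for cross-platform determinism.

Each unordered pair is then oriented by its dominant direction — the
direction with the larger total transitioned area over the region — which
names the transition type and fixes the sign convention of the regression
predictor: `x_p = (fraction in dominant direction) − (fraction opposite)`,
as a unit cell fraction (the reporting layer converts to percent). Pairs
with zero total area are absent from the inventory; with all 7 categories
active and no rainfed↔irrigated exchange the inventory holds 20 types.

## Surface energy-balance decomposition

With emissivity fixed at 1 and the ground heat flux G defined as the
closure residual, the balance holds exactly by construction; `decompose`
refuses unclosed states rather than absorbing imbalance silently. The
linearisation evaluates λ = 1/(4σTs³) and the cross-term α and SW↓ at the
**reference** state — the generic form leaves this open; using one
documented state and reporting the residual (simulated ΔTs minus linearised
total) makes the second-order error auditable. The residual scales as
O(h²) in the perturbation amplitude h (dominated by the quartic emission
term, relative size ≈ (3/2)·ΔTs/Ts, plus the Δα·ΔSW↓ cross term). The
"total" is defined as surface group + atmospheric group, so group
additivity is exact in floating point. Regional summaries are
area-weighted means with a t-based 95% confidence interval across yearly
regional means. Seasonal scoping on real calendars would be a month mask
applied before averaging; the synthetic calendar is annual with a day
index, so seasons reduce to day-index ranges and are not exposed.

## Attribution regression

The per-cell multi-year mean response (2 m air temperature by default,
skin temperature selectable) is modelled as linear in the signed transition
fractions with a free, unpenalised intercept. Spatially uniform non-local
effects (advected from changes elsewhere) are absorbed by the intercept;
spatially varying ones by the error term. Additional spatial predictors
(coordinates, background climate) are deliberately excluded from the
default model.

Transition predictors are collinear, so coefficients are estimated by
ridge regression. The penalty is chosen per fit from 25 log-spaced values
on [0.1, 2000] (the grid cardinality and the exact upper endpoint are this
package's choices) by grouped 5-fold cross-validation over training
blocks. Predictors are standardised with training statistics only
(verified by a leakage test); coefficients are reported back on the
original scale, in °C per unit fraction. Predictors constant on a training
sample are dropped from that fit and logged. The ridge path is solved in
closed form from the Gram matrix, reusing one factorisation pattern across
the penalty grid; scikit-learn's `Ridge` serves as an independent oracle
in the test suite.

Uncertainty comes from 200 iterations of the full pipeline (block
resampling, standardisation, penalty selection, fit, held-out evaluation)
with 2.5–97.5 percentile intervals. Two resampling modes exist:

- `resample="block"` (default): the training blocks (75% of the block
  count) are drawn **with replacement**, repeated blocks entering with
  multiplicity, and never-drawn blocks form the test set — a spatial block
  bootstrap. The percentile interval then approximates the full sampling
  uncertainty: measured coverage of planted sensitivities on the recovery
  fixture is ≈95–100% at the nominal 95%.
- `resample="split"`: a plain 75%/25% partition of blocks. The refit
  spread then only reflects subset-to-subset variability, which
  understates the sampling standard deviation by √((1−f)/f) ≈ 0.58 at
  f = 0.75; percentile intervals from this mode cover at roughly 74%
  regardless of noise level and should be read as model-stability bands,
  not confidence intervals.

The default block side is 5 cells; on spatially autocorrelated data larger
blocks widen the intervals, as blocked resampling is meant to. Contributions
are the mean sensitivity times the regional mean signed transition fraction
(°C). The reporting filter keeps transition types occurring on >0.2% of
the regional area and in >20% of cells; the full table is always preserved.

## Regional and extreme statistics

TXx is the per-year, per-cell maximum of daily maximum 2 m temperature
(missing days are skipped; a year with no days is an error). Scenario
effects are tested per cell with the two-sided Wilcoxon signed-rank test on
paired yearly values — pairing removes the interannual variability shared
through common boundary conditions; the exact null distribution is used
for ≤25 years (the minimal attainable two-sided p at n = 15 is
2/2¹⁵ ≈ 6.1×10⁻⁵), and all-tied cells return NaN (not significant).
Future-vs-recent changes use the two-sided Mann–Whitney U test.
Benjamini–Hochberg adjustment is applied over one family per
variable × season × scenario across cells (the family definition is this
package's choice). The significance threshold is 0.05 on adjusted
p-values. Focus masks take the ⌈1%⌉ largest cells (ties by cell index) of
PFT-change fraction, of a reference variable, and of the
reference-minus-recent change; perturbation bins are
{0–10, 10–30, 30–50, 50–100}% of cell area changed, right-open except the
last. Area weighting is uniform on the synthetic equal-area grid; a weight
field is accepted for real grids.

## Synthetic generator

The generator emulates the statistical structure of a paired regional-ESM
experiment rather than its physics. It works backwards from the target
response: the multi-year mean scenario−reference ΔTs per cell is drawn from
the planted linear model Σp βp·x_p + offset + spatial noise, the implied
flux perturbation ΔF = 4σTs³·ΔTs is allocated across −ΔLH, −ΔSH, −SW↓·Δα,
(1−α)·ΔSW↓, ΔLW↓ with configurable weights (defaults 0.40/0.25/0.10/0.15/
0.10), and G closes the balance exactly per cell, year, and run. The
decomposition therefore reproduces the planted ΔTs up to the quantified
O(h²) linearisation error, independent of the allocation weights.

Default study conditions, chosen once as a plausible mid-latitude
scenario-comparison setting: 120×120 fine grid coarsened ×3 to a 40×40
analysis grid; 15 analysis years; 365 days per year; 35% of fine cells
change land system; planted sensitivities for all 21 category pairs in
[−1.5, +1.5] °C per unit fraction with forest→crop cooling and crop→grass
warming; spatially uniform non-local offset 0.08 °C; spatial noise sd
0.05 °C; interannual anomalies AR(1) with ρ = 0.45 and marginal sd 0.4 °C
(typical of European summer temperature variability); daily maxima =
annual-mean 2 m temperature + sinusoidal seasonal cycle (amplitude 8 °C) +
zero-mean Gumbel excursions (scale 2 °C) so TXx has realistic
extreme-value behaviour. The non-local offset magnitude is a free
parameter, not an asserted value. All randomness derives from one root
seed through named substreams (CRC-based), so any single output is
reproducible in isolation and equal seeds give byte-identical outputs.

Interannual anomalies and daily excursions are **shared** between
reference and scenario runs, mirroring simulations driven by identical
boundary conditions. Consequences a user must keep in mind: the mean ΔTs
equals the planted model exactly; paired tests on scenario−reference
differences are maximally powerful (significance shares near 100% are
expected, unlike real paired ESM runs whose responses retain internal
variability); calibration of the tests is therefore checked on
independent-noise null fixtures instead. Auxiliary variables
(precipitation, soil moisture/temperature, wind, GPP) are independent
fields with scenario offsets proportional to the cell's PFT-change
fraction — they are analysis targets, not physically coupled outputs. A
recent-climate run (reference mean state minus a configurable 0.6 °C
background-warming offset, with its own independent interannual anomalies)
supports the unpaired future-vs-recent test and the most-changing mask.

`make_attribution_fixture` plants a known sensitivity vector on a
controlled design: each cell transfers area along one or two
category-disjoint pairs with continuous magnitudes, which the greedy
matcher provably recovers exactly, and a minority of cells run opposite to
the dominant direction so the signed design carries both signs. This
guarantees an exact number of active transition types, which emergent
land-system maps cannot.

What passing tests on synthetic data do **not** show about real data: no
atmospheric dynamics, advection, or cloud physics; no realistic geography
or seasonally varying fluxes; no spatially correlated response noise by
default; transitions are statistically, not spatially, placed. The
pipeline's correctness is established against analytic expectations; its
behaviour on real ESM output inherits all caveats of the decomposition and
regression assumptions above.

## Numerical choices and limitations

- Energy-balance closure tolerance 10⁻⁹ W m⁻²; greedy residual floor
  10⁻¹²; land-unit sum tolerance 10⁻⁹.
- Penalty-grid ties resolve to the smaller penalty; greedy and orientation
  ties resolve by category order; top-percent ties by cell index.
- Degenerate inputs: all-zero cover → all bare; empty land unit → all
  bare; all-tied test pairs → NaN p-value; constant training predictor →
  dropped and logged; >10% failed bootstrap iterations → hard error.
- Problem sizes used in the test and acceptance runs (40×40 analysis
  grid, 15 years, 20 bootstrap replicates) were chosen as the smallest
  sizes at which the statistical targets are stable.
- No biogeochemical (carbon-cycle) closure, no habitat-distribution
  modelling, no optimal-transport transition matching (greedy is the
  specified behaviour), and no plotting are provided.
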