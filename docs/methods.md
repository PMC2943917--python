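# Methods

## Model

`climsuit` estimates relative climatic suitability from presence-only data
as the maximum-entropy (Gibbs) distribution over a background sample of
cells. With feature map `f` and background cells `x_1..x_m`, the model is
`q(x) = exp(λ·f(x))/Z` with `Z = Σ exp(λ·f(x))` over the background. The
weights maximize the penalized total presence log-likelihood

    L(λ) = Σ_presences [λ·f(x_i) − log Z] − Σ_j β (s_j/√m_p) |λ_j|

where `m_p` is the presence count and `s_j` the presence-sample SD of
feature `j`. At β = 0 the stationarity condition is exact feature-mean
matching, `E_q[f_j] = mean_presence[f_j]`; at β > 0 each constraint may
slacken by at most `β·s_j/√m_p`. Note the penalty competes with a *total*
(not per-presence-averaged) log-likelihood; implementations that average
the likelihood make the same β bite roughly `m_p` times harder, so β values
are not transferable between the two conventions. Either way β = 0 is the
exact-matching limit and β → ∞ drives λ → 0 (uniform suitability).

Assumptions inherited from the presence-only framing: presences are an
unbiased sample of the occupied distribution; the background characterizes
the available environment; occupancy depends on climate through the chosen
feature classes only; and the niche is stable across the periods and
regions compared (the package's transfer experiments probe exactly what
happens when the first assumption fails through biased range contraction).

### Features, standardization, clamping

Predictors are standardized to [0, 1] by their min/max over the training
sample (presences plus background). Feature classes are `linear`,
`quadratic` (square of the standardized value) and `product` (pairwise
products); hinge/threshold features are out of scope, keeping the model
smooth and the oracle cross-checks exact. Column order is deterministic:
variables in canonical order, then squares, then lexicographic pairs.
Constant variables are dropped with a warning.

The training min/max double as **clamp bounds**: when projecting with
`clamp=True` (the default everywhere), predictor values are clipped to the
training range first, so out-of-envelope cells score as if they sat on the
boundary. The `novelty` diagnostic counts per cell how many predictors are
outside the bounds; a count of 0 is equivalent to clamped and unclamped
projections agreeing at that cell. The envelope is deliberately
rectangular (per-variable bounds); multivariate similarity surfaces are a
non-goal.

### Logistic output

The raw density is rescaled to `expit(H + log q)` with `H` the entropy of
`q` over the background. A model with no information (λ = 0) then scores
exactly 0.5 everywhere, anchoring 0.5 at a "typical presence" environment.
All thresholds operate on this logistic scale.

### Optimizer

The objective is concave. Fitting is deterministic:

1. **Coordinate-wise proximal Newton** sweeps with soft-thresholding and a
   halving line search, so the penalized objective never decreases (this
   phase also yields the per-feature gain trace used for variable
   contributions, and the initial active set). Sweeps are capped at 25;
   convergence beyond that is carried by the polish.
2. **Active-set quasi-Newton polish**: L-BFGS-B with signs fixed (making
   the penalty linear, hence smooth) alternated with a KKT screen that
   re-admits zero coordinates whose gradient exceeds their penalty weight.
   The gradient tolerance scales as `1e-7·m_p`, which caps the β = 0
   feature-matching gap at 1e-7.

Convergence is declared when the relative objective improvement falls
below 1e-8 (or first-order optimality is reached); the overall iteration
cap is 500 sweeps, after which the model is returned flagged
`converged=False` with a warning carrying the residual gradient norm. On
highly collinear 65-feature designs the achievable gradient floor in
double precision is around 1e-3 on the total-likelihood scale (≈1e-5 per
constraint), far inside the β = 1 slack bound.

### Variable importance

`variable_contribution` credits each coordinate update's objective gain to
the updated feature's source variable(s), split evenly for products, then
normalizes to 100%. Exactly identical feature columns share their pooled
gain equally (symmetric tie-break). This path-attribution is a documented
stand-in for the reference software's internal heuristic and is validated
by rank agreement with drop-one refits; correlated predictors legitimately
share credit, so contributions measure concentration, not exclusivity.
`jackknife_single` refits each variable alone and reports test AUC against
the background sample.

## Thresholds and evaluation

- **MTP**: minimum logistic score among the run's training presences.
- **MTSS**: the observed score maximizing training sensitivity +
  specificity, computed against the model's background sample (a config
  switch allows held-out absences instead); candidate thresholds are the
  sorted unique observed scores, classification is `score ≥ t`, ties break
  to the smallest threshold.
- **Cumulative maps**: each run is binarized at its own threshold; the
  replicate map is the cell-wise union. Adding a run can never shrink the
  suitable set.
- **AUC** is the Mann-Whitney pair statistic (ties count ½), computed per
  run from test pseudo-presences against the background sample and
  summarized as mean ± SD (population SD, so a single run reports 0).
- **Kappa** is Cohen's chance-corrected agreement, computed on the
  cumulative maps against held-out presence/absence test points. One
  terminological caveat: the literature this pipeline descends from
  equates "the Kappa statistic" with "the proportion of specific
  agreement", which is a different statistic in the classification
  literature; Cohen's Kappa is what is implemented.
- **Cross-period transfer**: modern-trained runs are also evaluated
  against historical-range test sets, quantifying how well a contracted
  range predicts the full one.

## Synthetic landscapes

The generator builds one raster holding two disjoint rectangles (native
and transfer continents; default 64 × 64 cells each, cell size 0.5 map
units). Monthly climate is gradient + seasonal sinusoid + smoothed
Gaussian noise:

- temperature: north–south annual-mean gradient (native 12→28 °C,
  transfer 0→26 °C), seasonal amplitude growing toward the pole (native
  8→2 °C, transfer 14→4 °C), a positive diurnal-range field, and spatially
  smoothed noise (Gaussian kernel, default width 3 cells, amplitude
  calibrated to ~1 °C SD at the default and vanishing as smoothness → ∞);
- precipitation: a west–east moisture gradient (native 160→40, transfer
  110→30 mm/month) with region-specific seasonal modulation and phase,
  floored at zero. Temperature varies north–south and moisture west–east
  (continentality) so the landscape's two main climatic axes are not
  confounded — this keeps the true niche's drivers separately
  identifiable, which the recovery experiment requires.

The transfer region is colder and more seasonal overall (its north is
non-analog) while its warm southern edge overlaps the native envelope, so
projections encounter both analog and non-analog climate.

The **true niche** is linear-only Gibbs: suitability ∝ exp(λ*·z) with z
the native-range-standardized predictors, normalized over the native
region. Default λ* puts weight +8 on annual mean temperature and −6 on
wettest-quarter precipitation (a warm-and-dry-adapted species). On the
min/max-standardized scale these correspond to about 1.4 landscape-SD of
logit spread per variable — a moderately sharp niche chosen by a design
power analysis: the Cramér–Rao bound for the 1,000-presence recovery
experiment gives weight SDs near 0.2, so these magnitudes make a ±10%
recovery band 2.6–3.8σ wide. Truth is linear-only so fitted linear terms
are directly comparable to λ* without identifiability games.

The **historical mask** occupies the top 20% of native cells by true
suitability (ties broken randomly; the occupied fraction lands within one
cell of target). The **modern mask** contracts it by a configured fraction
(default 50%) either uniformly at random or cold-biased — removing the
occupied cells with the lowest annual mean temperature, which truncates
the cold tail of the modern climatic sample and violates the equilibrium
assumption the way anthropogenic range loss does. **Introduction points**
(default 4) are transfer-region cells whose true suitability clears the
occupancy threshold, taken closest above it, i.e. at the edge of the
climatic envelope.

What the generator does *not* emulate: GCM-style circulation climate,
dispersal limitation, biotic interactions, observation error in range
maps, and latitude-dependent cell area. Tests passing on these landscapes
show the machinery is correct and the contraction/transfer logic behaves
as theory predicts; they do not certify performance on real climate
surfaces.

## Replicated experiment design

Defaults follow the standard layout: 10 replicate sets of 100 training
pseudo-presences per period, 100 test pseudo-presences per run, 100
presence/absence points for Kappa, background capped at 10,000 cells
(the canonical native region has 4,096, so all cells are used), β = 1,
all three feature classes. Pseudo-presences are placed at cell centres —
predictors are cell-constant, so sub-cell jitter adds nothing and exact
reproducibility is gained — and sampled uniformly over cells (not
area-weighted). Every random draw is seeded by hashing
(master seed, species, period, role, set index), so replicate streams are
independent and order-insensitive, and identical configs reproduce bit
for bit.

Problem sizes used by the shipped experiments: the canonical scenario for
the pipeline comparisons; a 100 × 100-cell native region for the recovery
experiment, sized so the background holds the full 10,000 cells and the
training min/max coincide with the truth's standardization; 10 seeds for
the direction-effect and null-calibration replications. The jackknife
table is computed on the first replicate per period (single-variable
refits are cheap but 10 variables × 10 runs × 2 periods would triple the
pipeline cost for a table whose purpose is rank confirmation).

## Numerical and design choices

- ESRI ASCII grids are written at %.10g precision; round-trips are exact
  at that precision. GeoTIFF I/O uses the standard geo tags
  (ModelPixelScale/ModelTiepoint/GDAL_NODATA) via `tifffile`.
- Cell membership is half-open (`x ∈ [left, right)`, `y ∈ (bottom, top]`);
  points on shared edges resolve to exactly one cell. Row 0 is north.
- Aggregation is the block mean, ignoring nodata; all-nodata blocks are
  nodata; ragged edges use available cells.
- Isothermality is reported as the 0–1 ratio and temperature seasonality
  as the SD in °C — the ×100 integer packing used by distributed climate
  products is a storage artifact, and envelope plots depend on the scale.
- Quarters are the 12 wrap-around consecutive 3-month windows.
- Seasonality statistics use the population SD (12 months is the full
  population of months). Precipitation CV is 0 where the mean is 0.
- Zero annual temperature range makes isothermality undefined: nodata,
  logged.
- `mtss` ties and threshold comparisons use the ≥ rule throughout.

## Known limitations

- Hinge/threshold/categorical features, percentile ("cumulative") output,
  and bias-corrected background sampling are not implemented.
- Percent contribution is path-dependent (documented above); treat
  rankings, not digits, as meaningful.
- No reprojection or datum handling; grids must align exactly.
- The logistic scaling constant is fixed to e^H; other conventions shift
  absolute logistic values (thresholded and rank-based results are
  unaffected).
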