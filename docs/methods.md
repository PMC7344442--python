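# Methods

`lucsim` implements a three-part modelling chain for scenario-constrained
land-use change and its ecosystem-service consequences: (1) per-class land
*demand* forecasting from short area time series, (2) spatial *allocation* of
that demand on a raster with a suitability-driven, rule-constrained cellular
automaton, and (3) *valuation* of each year's land-use structure with a
regionally corrected equivalent-factor model. A seeded synthetic-landscape
generator provides inputs with the statistical structure each stage assumes,
so the whole chain is testable without any proprietary raster archive.

## Demand: GM(1,1) and Markov models

The grey model GM(1,1) fits a first-order exponential trend to the
accumulated series of a short, strictly positive record (at least four
observations). With `x1 = cumsum(x0)` and background values
`z1(k) = (x1(k) + x1(k-1))/2`, the parameters `(a, b)` solve the ordinary
least-squares problem `x0(k) = -a z1(k) + b` (normal equations; the package
uses a numerically stable least-squares solver, and the test suite checks
agreement with the explicit closed-form solution to ten significant digits).
The restored series is

    x̂0(1) = x0(1)
    x̂0(k) = (x0(1) - b/a) (1 - e^a) e^{-a(k-1)},   k >= 2

with the `a -> 0` limit (`x̂0 = b`) taken explicitly for constant input.
Because of the background-value construction, `|a| < 2(1 - r)/(1 + r) < 2`
for any positive series with step ratio `r`, so the instability flag at
`|a| >= 2` is a defensive guard rather than a reachable regime.

Fit quality is graded by the posterior-difference test: `C = S2/S1` (the
ratio of the population standard deviations of the residuals and the data)
and `P`, the fraction of residuals within `0.6745 S1` of the mean residual.
Levels: 1 if `C < 0.35` and `P > 0.95`; 2 if `C < 0.50`, `P > 0.80`; 3 if
`C < 0.65`, `P > 0.70`; otherwise 4 (unqualified). The paired thresholds
come without a combination rule, so the package takes the *worse* of the two
bands — the conservative convention. A zero-variance series is graded level
1 with `C = 0`: perfect predictability is the limiting best case. Population
(1/n) standard deviations are used throughout, the common convention in the
grey-model literature.

The Markov alternative estimates a row-stochastic transition matrix from an
aligned two-date map pair (`P[i, j]` = fraction of class-`i` cells that
became class `j`; empty classes get identity rows) and projects a class-area
row vector as `S_{t+k} = S_t P^k`, which conserves total area exactly. The
published notation for the projection is ambiguous about operator order; the
row-vector/row-stochastic orientation is used because the matrix is defined
row-wise.

Model comparison reports per-class relative differences
`d = (pred - actual)/actual x 100` and the accuracy gap `|d_markov| -
|d_gm|`; the model with the smaller mean `|d|` is selected. In the pipeline
the comparison is made against the last observed year of the area series:
the GM value is the in-sample restored value, the Markov value a one-step
projection of the previous year's composition through the map-pair matrix.

Demand targets convert forecast areas to integer cell counts by
largest-remainder rounding (counts sum exactly to the grid size). The
unused-land class — tiny and, under urbanization, transient — is folded into
built-up land before allocation, and an optional cultivated-land protection
floor (paddy + unirrigated area) is validated at demand level, since the
scenario states it as a total-area condition, not per cell.

## Suitability: factor screening and the occurrence-probability network

Driving factors are min–max normalized to [0, 1] per layer (constant layers
map to 0.5; nodata propagates as NaN). Multi-class layers (slope and soil
classes) are fed as normalized numeric codes rather than one-hot vectors,
mirroring common practice for categorical drivers in land-change software;
this is a config-visible choice.

Per-class explanatory power is screened with binary (one-vs-rest) logistic
regression on a sparse uniform sample of cells (default 2%), scored by ROC
AUC; factor sets with AUC >= 0.5 are retained. Complete separation is
reported as AUC = 1 with a flag. AUC is computed by the rank statistic; the
tests verify it equals a brute-force trapezoidal enumeration over all score
cutoffs, including ties.

The suitability model itself is a single-hidden-layer feed-forward
classifier (default 12 hidden units, 300 epochs, seeded) with a softmax
output, so per-cell class probabilities sum to one by construction. No
architecture is prescribed by the source methodology; the defaults are
config-exposed and deliberately small — the task is smooth, low-dimensional
pattern association, not image recognition.

## Allocation: the constrained cellular automaton

Each sweep scores every candidate class `j` at every cell:

    score(cell, j) = suit_j(cell) x neigh_j(cell) x inertia_j
                     x allow[initial(cell), j]

* `neigh_j` is the Moore-window density of class `j` (window size default
  3x3, excluding the center, truncated at edges).
* `inertia_j` starts at 1 and adapts from the last two demand gaps
  `D = target - allocated`: unchanged while `|D|` is not growing; scaled up
  by `|D_{t-1}|/|D_{t-2}|` when under-allocation worsens; scaled down by
  `|D_{t-2}|/|D_{t-1}|` when over-allocation worsens; clamped at a small
  positive floor. The published three-case update is printed with
  inequalities that contradict its own no-worse case; the magnitude-ratio
  form used here satisfies the intended monotonicity (persistence
  strengthens as a class falls further behind its target, relaxes as it
  overshoots) and reproduces the worked two-step example (gaps −100 then
  −200 halve the inertia).
* `allow` is the binary conversion-rules matrix evaluated against the
  *initial* map, so chained conversions cannot launder a forbidden
  transition. The packaged ecological-optimization scenario forbids any
  conversion out of water (also enforced spatially by a frozen mask) and any
  conversion of forest, grass or wet land to cultivated or built-up classes.

Scores are renormalized per cell; frozen cells and all-zero score vectors
get a point mass on the current class. The next class is drawn by
roulette-wheel selection (one uniform draw against the per-cell CDF), and
cells are visited in a fresh seeded random permutation each sweep to avoid
raster-scan directional bias. A drawn conversion is committed only while the
source class is above and the target class below its demand target, which
makes each sweep conservative in cell count and drives the composition
monotonically toward the demand. Iteration stops when every class is within
the demand tolerance (default 0.1% of the grid) or at the sweep cap.
Before iterating, a max-flow check on the permission matrix (surpluses of
movable cells as sources, deficits as sinks, permitted transitions as edges)
proves feasibility or fails fast.

Accuracy assessment cross-tabulates actual vs simulated labels (full grid or
a seeded 1% uniform sample), reporting overall accuracy (trace/N), user's
and producer's accuracies, and Cohen's kappa
`(p_o - p_e)/(1 - p_e)` with `p_e = sum(row_i x col_i)/N^2`; the tests pin
this against an independent implementation.

## Valuation: revised equivalent-factor model

The per-hectare coefficient table (11 ecosystem services x 8 land classes,
USD/ha/yr, packaged as CSV) is anchored by the unit equivalent value
`Ea = (1/7) p mean(yields)`. The base estimate `ESV = sum_i A_i VC_i` is
rescaled by three dimensionless regional corrections:

* grain yield `Q = G_A / G_N`;
* socio-economic development `D = Pw x Pv`, with willingness to pay
  `Pw = L(EL_A)/L(EL_N)` through the Peal (logistic) curve
  `L(E) = 1/(1 + exp(-(1/E - 3)))` of the Engel coefficient, and ability to
  pay `Pv = (pGDP_A/pGDP_N)(U_A/U_N)`;
* resource scarcity `S = ln(P_A)/ln(P_N)` on population densities (> 1
  persons/km², keeping the log ratio well defined).

The Engel coefficient is treated as a fraction in (0, 1): on a percent scale
`1/E - 3` is approximately −3 for any realistic value and the curve
degenerates, so the fraction convention of the equivalent-factor literature
is adopted. The revised estimate is exactly `Q·D·S` times the base estimate,
including the per-category breakdown (provisioning, regulating, supporting,
cultural) — linearity the tests assert bit-exactly. Areas are accepted in
km² or ha with an explicit unit; computation is in hectares; reports default
to units of 10^7 USD. Correction factors are scalar per year, since their
inputs are province-level statistics. Proportions of the signed total may be
negative (built-up land detracts).

## Synthetic study area

The generator emulates the structure the pipeline needs, not any real
geography:

* **Landscape** — one Gaussian-smoothed white-noise field per class
  (smoothing length = `autocorrelation_scale`, default 4–6 cells); each cell
  takes the argmax field after per-class offsets are calibrated so realised
  shares match the target fractions (within ±2 percentage points; the
  calibration loop stops at ±0.5). This yields contiguous patches whose
  same-class join frequency comfortably exceeds the random-labeling
  expectation. Default composition (28/24/22/6/5/1/11/3% for paddy,
  unirrigated, forest, grass, water, wet, built-up, unused) follows the
  broad ranking of a cultivated-land-dominated province.
* **Two-date pair** — a fixed number of uniformly chosen cells (default 3%
  of the grid) move to uniformly drawn rule-permitted classes, water frozen;
  this gives an exact change ledger for transition-matrix recovery tests.
* **Area series** — `area_t = area_0 r^t` per class with lognormal
  multiplicative noise (sd <= 1%), renormalized to a constant yearly total.
  Default annual rates (0.995, 0.996, 1.001, 0.998, 1.003, 0.995, 1.012,
  0.97) encode the study system's direction of change — cultivated classes
  declining, built-up growing fastest, forest and water slightly growing —
  with enough donor margin that the demanded composition stays feasible
  under the one-way ecological rules. Noise-free series grade level 1 by
  construction.
* **Indicator series** — paired regional/national Engel coefficient,
  per-capita GDP, urbanization rate, population density, grain yield and
  price as seeded geometric drifts at plausible magnitudes, with
  regional/national ratios bounded in [0.2, 5]. An `identical=True` switch
  makes every correction factor exactly 1.

What the generator does **not** emulate: real patch-size distributions,
anisotropy or landscape metrics of any actual province; spatially
heterogeneous demand; measurement error in classified maps; and any causal
link between the driving-factor surfaces and the landscape (factors are
independent fields, so the suitability network learns neighborhood-free
priors — adequate for contract tests, silent on real-world predictive
skill). Passing tests therefore demonstrate correctness of the computations
and the engine's constraint logic, not calibration fidelity to Anhui-like
data.

## Numerical and reproducibility choices

* One global seed fans out to per-stage child seeds by fixed offsets
  (`seed*1000 + offset`, kept below 2^31), so stages are independently
  reproducible; every artifact's sidecar records the seed and a hash of the
  scientific configuration (output location excluded).
* Demand rounding: largest remainder (exact conservation). Ties in the
  roulette CDF are guarded against float round-off at the tail.
* Degenerate inputs: constant factor layers normalize to 0.5; all-nodata
  layers fail by name; zero-variance grey fits grade level 1; zero actual
  areas yield undefined (NaN) comparison cells; zero totals make
  proportions an explicit error.
* Raster storage is the plain-text ESRI ASCII grid with a JSON sidecar for
  legend/cell-area/provenance; the math is CRS-agnostic and no geographic
  transform is modelled.
* Default problem sizes: 60x80 cells for the packaged toy scenario and
  100x100 for the allocation test suite — large enough for stable class
  statistics, small enough that the full pipeline completes in seconds.

## Known limitations

* The CA acceptance criterion is demand matching under constraints, not
  pattern realism; no landscape-metric validation is attempted.
* The Markov and GM comparison on synthetic data reflects the generator's
  exponential trends, which structurally favour GM(1,1), much as the
  published study found on its own series.
* Only the ecological-optimization scenario ships as a rules fixture;
  natural-growth or urban-expansion scenarios would need their own rules
  CSVs (the loader accepts any square 0/1 matrix with a unit diagonal).
* Per-factor logistic coefficients are reported but have no external
  reference values to validate against.
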