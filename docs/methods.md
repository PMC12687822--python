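# Methods

This note records the modeling procedure, the choices made where the
design was genuinely open, and what the synthetic-world experiments do and
do not demonstrate.

## Problem and model

The package estimates the relative likelihood of observing a mosquito
species at a grid cell on a day, from daily climate alone. It is a
presence-only species distribution model: occurrences provide positive
labels; background ("pseudo-absence") points stand in for the unknown
negative class. The classifier is deliberately simple — a feedforward
network on a flattened window of daily covariates — trading mechanistic
structure for the ability to ingest long, high-dimensional climate
sequences cheaply.

### Derived covariates

From raw daily rasters (mean/max/min 2-m temperature, dew point, average
hourly precipitation, u/v wind) five covariates are computed per cell-day:

| name | definition | units |
|---|---|---|
| `trange` | T_max − T_min, clamped at 0 (inversions warned) | °C |
| `tmean` | daily mean 2-m air temperature | °C |
| `rh` | 100·exp(17.625·T_d/(243.04+T_d))/exp(17.625·T_m/(243.04+T_m)) | % |
| `ptot` | 24 × average hourly precipitation | mm/day |
| `wspd` | √(u² + v²) | m/s |

Notes: `rh` is not clipped at 100 (reanalysis supersaturation is
informative and the z-score normalization absorbs scale); negative
precipitation artifacts are clamped to zero with a counter; the "central
temperature" covariate is the daily *mean* (which the humidity formula
also consumes), though some summaries of this covariate set call it the
median. Surface pressure, though present in reanalysis pulls, never
enters the model. Descriptions of the covariate set sometimes count four
computed variables; this package treats all five above as the default base
set, and the ablation harness takes the base set from configuration, so
either reading can be reproduced.

### Sequence features

A model input is the `seq_len` days strictly *before* the observation date
(the observation day itself is excluded), flattened day-major with the
oldest day first, each day contributing the five covariates in the fixed
order above. The flattening order is recorded in every checkpoint so
models cannot be silently misapplied. Inputs are z-scored per feature with
statistics fitted on the training split only.

### Pseudo-absences and splits

A pseudo-absence draws a date uniformly within the presence window and a
land cell with probability proportional to cos(center latitude)
(area-proportional on the sphere), rejecting cells shared with any
presence — rejection is by grid cell, not exact coordinate. Draws whose
date leaves fewer than `seq_len` days of climate history are redrawn. One
seeded pool is fixed per experiment so downstream comparisons (ablation in
particular) reflect covariates rather than resampling. The absence ratio
is presence : pseudo-absence, default 0.2 (five background points per
presence; sweeps 0.1–0.5 are supported).

Two split types: *random* (20% of presences plus an equal count of
pseudo-absences to test) and *chronological* (the newest 20% of presences,
ties broken by stable input order, plus an equal random absence count).
Cross-validation folds are label-stratified (k = 5 by default);
stratification keeps fold AUCs stable under the 5:1 class imbalance.

### Network and training

Architecture 5·L → 128 → 64 → 32 → 1, ReLU hidden activations, no output
activation during training (the loss is the fused binary cross-entropy
with logits; the sigmoid is applied only at prediction). Adam with
learning rate 10⁻³ and standard β/ε; batch size 256; max 1000 epochs;
seeded uniform fan-in initialization, U(±1/√fan_in). Early stopping
monitors validation AUC and returns the weights of the best epoch — not
the last — with patience 10 epochs inside cross-validation and 100 for
final training. There is no retraining on train+validation after early
stopping. The implementation is plain NumPy: the network is small enough
that explicit forward/backward passes are fast on one CPU, and this gives
bit-level reproducibility from a seed, which the checkpointing contract
(save → load → predict bit-identical) relies on.

### FNR calibration and the validation/calibration carve-out

Raw probabilities shift with hyperparameters (most visibly the absence
ratio), so maps are reported as false negative rates: FNR(s) = (#
reference presence scores strictly below s)/N. Ties count as detected —
the conservative choice — and the empirical CDF is used as a step
function, unsmoothed.

The reference population matters. Scoring presences the optimizer itself
was fit on produces systematically inflated scores (the network partly
memorizes its training rows), which would push the FNRs of genuinely new
presences toward 0 and break the "risk percentile" reading. We measured
this directly on the synthetic world: with an optimizer-fed reference,
held-out presence FNRs fail Kolmogorov–Smirnov uniformity with D ≈ 0.25–
0.43; out-of-fold (cross-fitted) references also fail (D ≈ 0.4) because
fold models have different score scales than the deployed model. The
package therefore splits the training data once (stratified, seeded) into
a gradient half and a carve-out half (`validation_fraction`, default 0.5)
that serves two purposes: its AUC drives early stopping, and its
*presences*, scored by the final network, form the calibration reference —
the same split-conformal construction used for distribution-free
calibration elsewhere. With this design the reference and fresh presence
score distributions agree (quantiles match to ~0.01) and held-out FNRs
pass KS uniformity; held-out AUC is unaffected (0.85–0.89 across carve
fractions 0.1–0.5 on the default world). The residual KS statistic is the
two-sample noise floor √(1/n + 1/m) with m ≈ 185 reference presences,
which is close to the α = 0.01 one-sample critical value at n = 200; a
reference this small is an intrinsic limit of a ~500-presence dataset.

### Evaluation and ablation

AUC is rank-based (ties half-weighted) and — because the FNR transform is
monotone — identical on raw scores and their FNRs in the tie-free case;
this invariance is asserted in tests. The ablation harness trains one
model per covariate subset (the full set, all leave-one-out and all
leave-two-out subsets: 16 for five base variables), per sequence length
(30/60/90/365 by default) and per split type, reusing one pseudo-absence
pool and one split per seed. Results are ranked by each subset's best AUC
across sequence lengths; ties break lexicographically by subset name.
Because features are day-major with a fixed variable order, a subset model
trains on a column mask of the full feature matrix, and a shorter
sequence is the trailing columns of a longer one — so the harness
assembles features once.

Jaccard similarity between two risk maps at threshold t is
|A∩B|/|A∪B| over cells with FNR ≥ t; both-empty is defined as 1.0
(identical predictions) and logged. The comparison harness accepts any
externally produced raster on the same grid (e.g. MaxEnt cumulative
output), but contains no MaxEnt implementation.

## Seasonality analytics

Daily FNR stacks are averaged over periods and meteorological seasons
(MAM/JJA/SON/DJF, with DJF of year y = Dec(y−1)+Jan(y)+Feb(y));
transition maps are successive-season differences; historical change is
recent-minus-baseline period averages; transition change is
|transition|_recent − |transition|_baseline, so positive values mean
seasonal contrasts sharpened (diversification) and negative values mean
they flattened (homogenization).

The season diameter d is the minimal *circular* window (wrapping December
into January, so seasons need not respect calendar boundaries) whose FNR
sum reaches 95% of the annual total; seasonality is 1/d. Ties break to the
earliest start day. The production implementation uses prefix sums with a
per-start binary search; tests verify exact equivalence against an
exhaustive O(365²) window scan, including wrap-around cases. The season
midpoint is the first day, scanning circularly from the diameter window's
start, at which the accumulated FNR reaches half the annual total — the
day with roughly half the mass before and after. Because the window holds
≥ 95% of the mass, the crossing always falls inside it. Positive scaling
of a series changes neither d nor the midpoint.

Series are always length 365: in leap years Feb 29 is folded into the
day-59 bucket by averaging Feb 28 and Feb 29, and later days shift back by
one. Seasonality is computed per single year by default; the multi-year
option averages per-year diameters and takes the circular mean of
midpoints. All-zero cells are degenerate: no season is defined, they are
flagged and excluded downstream.

For visualization only, cells whose midpoint lies within 10 days
(circular) of January 1 are masked — near the poles, negligible cumulative
FNR makes midpoints cluster artifactually at the year boundary — and the
2nd/98th percentiles (NumPy linear-interpolation order statistics) of the
remaining seasonality values give a colormap clip range. This heuristic
never feeds back into any computation.

## Burden estimation

Person-days at risk for a year is Σ over region cells and days of
population × 1[FNR ≥ threshold], threshold 0.5 inclusive. Population
rasters are resampled to the model grid by area-weighted splitting of
*counts* (persons conserve; conservation is tested to 0.1%), linearly
interpolated between census years; daily FNR is linearly interpolated by
day-of-year between modeled years and clamped to [0,1]. Ocean cells are
masked before aggregation when a land mask is supplied. Regions are
arbitrary lat/lon boxes or raster masks; burdens are exactly additive over
disjoint regions. Trends are OLS of person-days on year with a t-based
prediction interval (default 90%). The estimate is exposure risk only — no
vector abundance or transmission modeling.

## The synthetic world

The generator emulates the structural features the pipeline must detect,
not climatological realism: an equator-to-pole mean-temperature gradient
(28 °C at the equator, −33 °C/90° poleward), a seasonal cosine scaled by
lat/90 so hemispheres are in exact antiphase (northern peak mid-July), a
wet season in phase with local summer, rectangular continents, and
hotspot population fields. Daily noise is a spatially coherent anomaly
shared across the grid (weather systems are large relative to a 40×80
world) plus a small cell-local term; coherent noise is both the realistic
choice and necessary for a meaningful calibration experiment — with
independent per-cell-day noise every training sequence carries a unique
fingerprint that the network memorizes, which no calibration scheme
scoring its own training rows can survive.

Ground-truth habitability is logistic: logit = β₀ + β_T(T̄₃₀ − T_opt)² +
β_P(P̄₃₀ − P_ref) on 30-day trailing means of mean temperature and total
precipitation, with defaults β₀ = 1.5, β_T = −0.25 /°C², T_opt = 26 °C,
β_P = 0.3 /(mm/day), P_ref = 3 mm/day — a selective thermal niche (≈ ±3 °C)
chosen so that the Bayes-optimal AUC of the presence/background task is
≈ 0.89; a broader niche leaves too much presence/background overlap for
any classifier to demonstrate recovery. Presences are a thinned point
process, P(record) ∝ effort × habitability, dated in the second simulated
year (so a full year of history exists), jittered within cells; when no
absolute effort scale is given it is normalized so the expected count
equals `target_presences` (default 500). Passing tests on this world shows
the pipeline recovers a smooth, low-dimensional habitability law from
coherent climate; it does not certify performance on real data, where
observation effort is strongly spatially biased, noise is only partially
coherent, and the true response is not logistic.

Default study conditions used by the end-to-end experiments: seed 1,
40×80 grid, 2 years, ~500 presences (463 realized at seed 1), absence
ratio 0.2, sequence length 60. Under these the held-out AUC is 0.887, the
Spearman correlation between annual-mean predicted FNR and annual-mean
true habitability over land is 0.95, and 200 fresh presences pass KS
uniformity (p = 0.025). Problem sizes throughout the tests (reduced
epochs in the ablation run, 30-day sequences for the ablation dataset,
k = 2–3 folds) were chosen so the whole suite exercises every code path at
desk scale.

## Numerical choices and edge cases

- Nearest-cell snapping uses plain lat/lon Euclidean distance on the
  regular grid; equidistant ties go to the lower row, then column index.
- Kelvin→Celsius conversion is triggered by units metadata only, never by
  value heuristics.
- Constant features receive unit scale in the z-scorer (warned), keeping
  held-out transforms finite.
- The sigmoid saturates to exactly 0/1 in float64 for |logit| ≳ 40; FNR
  transforms and map writers tolerate the closed endpoints.
- Non-finite training losses abort with a diagnostic rather than
  continuing silently.
- Ocean cells are predicted like any other (the land mask constrains
  sampling and output masking only); this is configurable at the output
  stage.

## Known limitations

- Pseudo-absence schemes other than cos-latitude background sampling
  (target-group background, environmental stratification) are out of
  scope.
- No gap-filling of missing climate days: a date gap is a hard error.
- The calibration reference is bounded by presence count; with a few
  hundred presences the FNR grid is coarse (~1/185 steps under the
  defaults) and uniformity tests sit near their noise floor.
- Grids are regular lat/lon only; no reprojection.
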