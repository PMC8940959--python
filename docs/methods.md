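# Methods

## The constraint

`mlec` implements an observational constraint of multimodel wildfire
projections that replaces the classical emergent-constraint (EC) regression
with machine-learned, multivariate history→future relationships.

For each ensemble member m and each future decade T, a regression learner
f̂ is trained on the member's *spatial sample*: every unmasked land cell
contributes one row whose features are the member's simulated historical
state and whose target is the member's simulated fire carbon emission in
decade T,

    y_c(T) = f̂_m( x_c(H) ) + ε_c ,

where x_c(H) collects, for each atmospheric/terrestrial variable, the
historical-decade annual mean and the climatology of each of the 12 calendar
months (13 encodings per variable), plus one encoding each for terrain
height, lightning-flash climatology, land use and population.  With the 7
dynamic variables (fire carbon emission, LAI, precipitation, relative
humidity, soil moisture, temperature, wind) and 4 single-encoding variables
this is 95 features.  The historical decade is fixed; targets step through
the future decades.

Feeding *observed* historical fields into the trained learner replaces the
member's biased view of the present with the measured one, while keeping the
member's internally consistent history→future physics.  One constrained
field is produced per (member × observational-dataset combination ×
algorithm × decade); the flattened member axis provides the ensemble mean
and the 10/25/50/75/90 percentile bands.

### Learners and tuning

Three algorithms of deliberately different character are tuned per
(member, decade) by grid search with 10-fold cross-validation minimising
RMSE, all candidates scored on identical folds, then refit on the full
sample:

| algorithm | tuned axis (canonical grid) | fixed settings |
|---|---|---|
| random forest | features per split 5…50 step 1 | 100 trees |
| gradient boosting | number of trees 10…200 step 5 | depth 3, learning rate 0.2 |
| RBF support-vector regression | 30 log₂-spaced costs in [2⁻², 2¹²] | kernel width from the median pairwise-distance heuristic |

Boosting lengths are scored from the staged predictions of a single
maximal-length fit per fold, which makes the tree-count grid essentially
free.  The SVR standardizes both features and target (an absolute ε-tube is
meaningless for kg m⁻² yr⁻¹ magnitudes).  Predictions are clipped at zero —
emission is nonnegative.  `fast_mlt_overrides()` provides thinned grids
(mtry {5,25,45} with 50 trees, tree counts {25,50}) used by the
full-pipeline runs and tests so a complete 8-member × 3-algorithm
constraint finishes in minutes on one CPU; single-model studies should use
the canonical defaults.

A 10-fold split of an 11,325-point spatial sample yields the nominal
10,193 / 1,132 fitting/validation sizes (`nominal_fold_sizes`); the actual
assignment is a true partition with fold sizes differing by at most one.

### The linear EC baseline

`gridwise_linear_ec` applies the classical recipe cell by cell: an
across-member ordinary least squares line between historical and future
emission, evaluated at the observed historical value, with degenerate (or
optionally insignificant) cells falling back to the unconstrained
multimodel mean.  `fit_line`/`constrain_scalar` provide the scalar variant;
the constrained spread combines the OLS prediction standard error and the
slope-mapped observational uncertainty in quadrature (the standard Gaussian
prediction contract — the variance convention is a package choice).

## The synthetic world

All acceptance-level properties are demonstrated on a generated pseudo-
ensemble with known truth; nothing is downloaded.

* **Truth.**  Smooth driver fields (latitudinal structure plus blurred
  noise) on a global cell-centred grid (default 5°, 36×72, ≈870 land
  cells).  Emission follows a fixed nonlinear link g = fuel × dryness ×
  ignition × spread: saturating in LAI and precipitation, logistic in
  temperature, soil moisture, relative humidity, wind and flash rate, and
  *humped* in population (ignition rises then falls with density).  The
  interactions and non-monotonicity are intentional: they are the structure
  a per-cell linear fit cannot represent.  Drivers drift linearly across
  decades with spatially modulated amplitudes (warming, drying, greening by
  default); flash rate and orography are static.
* **Members** (default 8) see (i) additive smooth driver biases with
  amplitude 1.5 spatial standard deviations, (ii) perturbed link parameters
  (amplitudes ×(1+0.3N), logistic locations shifted by 0.3 of their own
  width), and (iii) their own scaling of every driver trend (×(1+0.5N)).
  History and future always come from the same perturbed link and bias, so
  each member's history→future relationship is internally consistent — the
  property the constraint exploits.  The bias level mirrors the
  observation that simulated historical fire emission differs from
  observations by large factors regionally; the trend spread mirrors the
  genuine disagreement of models about projected regional change, including
  occasional sign flips.
* **Observations** (default 2 datasets per variable) are the historical
  truth plus smooth noise of 0.1 spatial sd — observations are far more
  accurate than models are unbiased.  Observation-dataset combinations are
  the Cartesian product (one dataset per variable), capped by seeded
  subsampling.
* **Socioeconomic fields** (population, GDP, agricultural area) grow
  geometrically per synthetic country at seeded rates (population 0–12,
  GDP 8–35, agriculture 0–6 % per decade).
* A `planted_driver` mode replaces g by a logistic response to a single
  variable, for attribution-recovery experiments; a `linear` link mode
  (clipped linear combination of standardized drivers) builds the world in
  which the linear EC is adequate.

Everything is bit-reproducible from one seed via tagged SHA-256 seed
splitting.  What the generator does *not* emulate: model genealogy (shared
land components), observational error covariance, regime shifts,
sub-annual fire dynamics beyond a phase-shifted seasonal harmonic.  Passing
tests therefore demonstrate that the machinery recovers known structure
under realistic bias/noise geometry — not that real CMIP-class ensembles
satisfy these assumptions.

## Where each method wins, and the evaluation horizons

Two structural facts about this (and any similar) synthetic geometry guided
the choice of evaluation decades:

* At a **one-decade horizon** the per-cell (history, future) points of the
  members lie close to a single smooth curve — biases are constant in time
  and trends have barely acted — so the 8-point linear EC, evaluated at a
  nearly exact observed emission, is close to optimal there.  Skill
  recovery of the constraint (hold-out validation, `holdout_validation`) is
  therefore scored at the first future decade, where both methods are
  strong and the constrained-vs-default comparison is the meaningful one.
* At **multi-decadal horizons** the members' disagreement about driver
  trends decouples a cell's future from its own history; a per-cell line
  through 8 scattered points degrades rapidly, while the learners keep
  exploiting each member's full driver state.  The
  learner-vs-EC method ordering is therefore evaluated at mid-century,
  which is also the regime the projection framework exists for.  On the
  linear-link world the two approaches face the same irreducible
  finite-ensemble trend error and agree closely at the same horizon.

A related subtlety: because historical fire emission is itself a predictor,
feeding observed emission corrects members' link-amplitude errors even when
their drivers are unbiased.  A true "nothing to correct" limit requires
identical members, where the default ensemble error is exactly zero; the
hold-out machinery is tested there for non-corruption (small learner fit
error only) rather than for an error ratio.

## Diagnostics, exposure, attribution

* RMSE and spatial R² are unweighted over the land sample (consistent with
  a sample-count-based training objective); area-weighted variants sit
  behind a flag.  Decadal trends are OLS slopes over decade index
  (endpoint-difference behind a flag); relative trends divide by the
  second-decade (2010s) value, each ensemble using its own baseline.
  Robustness stippling marks cells where ≥80 % of members share the trend
  sign, zeros counting with neither sign.
* Exposure is the per-cell product of emission flux density and the
  socioeconomic amount in the cell, so totals are plain sums, not area
  integrals.  Countries with zero baseline exposure are excluded from
  rankings; ties break toward the lower region id.
* Driver importance, task 1 (historical states): permutation importance
  (5 repeats by default) for the tree learners, leave-one-covariate-out
  retraining for the SVR with CV-RMSE as the metric; a variable's score is
  the maximum over its 13 encodings; scores are floored at zero,
  standardized to sum to 100 per algorithm, then averaged across
  algorithms.  The LOCO contribution is defined as rmse(without) −
  rmse(full), i.e. the error increase caused by removal; raw (possibly
  negative) values are retained alongside.  In planted-driver experiments
  the historical-emission predictor necessarily mirrors the planted driver,
  so recovery is judged among the environmental-state variables.
* Task 2 (trend attribution): the same learners predict the per-cell
  emission trend from per-cell driver trends over a selected region
  (≥50 cells).  Flash rate and orography are excluded (static); socio
  trends are prescribed, never constrained.  The constrained branch first
  observation-constrains each driver's annual means per decade
  (`constrain_driver_trends`; annual means only) before taking trends.

## Numerical choices and degenerate inputs

* Bilinear regridding uses periodic longitude indexing, clamps poleward of
  the outermost rows, and transfers masks by nearest neighbour (a target
  cell is valid iff its nearest source cell is) to keep masks binary.
* Cell areas are exact spherical-zone areas; flux totals convert
  kg m⁻² yr⁻¹ → Tg yr⁻¹ centrally.
* Zero-variance training targets warn and fit a constant predictor;
  per-cell EC falls back to the member-mean future when the across-member
  variance of the predictor is below 10⁻²⁵ (relative); constant fields make
  spatial R² an error at top level and NaN in per-member tables.
* Cross-validated R² is the pooled out-of-fold R², clipped to [0, 1] (raw
  value retained).
* All stochastic components draw from `child_seed(root, *tags)` — SHA-256
  of the seed and a tag path, reduced below 2³¹.

## Problem sizes used by the shipped tests and acceptance script

Default world 5° (≈870 land cells, 8 members, 2 datasets/variable,
capped at 8 combinations); nonlinear method-ordering, trend/exposure and
planted-driver attribution experiments on 10° worlds (≈190 land cells;
planted-signal recovery weakens noticeably on anything coarser); the
linear-world
agreement check at 5°, where the learners' fit-error floor is small enough
for the comparison to isolate model error (at 10° that floor alone
separates the methods by ~20 %, in MLT's disfavour on the nonlinear world
too, which makes the coarse nonlinear ordering conservative); thinned
tuning grids as above;
attribution recovery over 10 seeded worlds in the test suite and 5 in the
acceptance script.  These sizes are the package's desk-scale defaults; every
knob scales up by configuration.

## Known limitations

* The synthetic observation error is smooth and additive; structured or
  multiplicative retrieval errors may change the envelope-overlap and
  skill-recovery margins.
* The per-cell EC baseline is implemented with a single constraining
  variable (historical emission); multi-variable linear EC is represented
  by running single-predictor fits side by side.
* `fast_mlt_overrides` trades tuning-grid resolution for runtime; the
  canonical grids should be restored for production-scale data.
* The constrained-driver branch of trend attribution is computationally
  heavy (variables × decades × sources trainings) and defaults to the
  multimodel-mean source with a single learner.
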