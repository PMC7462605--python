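# Methods

## The scientific problem

Two neighbouring bonobo groups with largely overlapping home ranges hunt
three kinds of prey (anomalure — a gliding rodent; duiker — a small forest
antelope; squirrel). If prey choice were driven by local ecology alone,
hunts in the same places should yield similar prey regardless of which
group hunts. The pipeline quantifies that question: it reconstructs each
group's space use, measures where each hunt sat in both groups' ranges,
characterises the social context of the hunting party, and fits a
categorical model of prey type with group identity alongside the spatial,
seasonal, and social covariates.

## Space use: kernel utilization distributions

Relocations are planar kilometre coordinates (no geodesy: the analysis
needs only relative areas and containment, so a local planar frame is
adequate). The UD is a Gaussian kernel density on a regular grid:

- **Bandwidth.** The Gaussian reference rule per coordinate,
  h_j = σ̂_j·n^(−1/6) — the conventional default for kernel home ranges.
  A fixed numeric bandwidth can be supplied instead.
- **Grid.** Cell size 0.1 km by default (well below the bandwidth at study
  scale), padded ≥ 3 bandwidths beyond the data extent so essentially all
  kernel mass is on-grid. Density is computed by binning counts and
  convolving with the Gaussian kernel (exact up to binning error), then
  renormalised so the grid mass integrates to 1.
- **Isopleths.** Cells are sorted by density and probability mass
  accumulated; a cell's isopleth label is the cumulative percent including
  itself. The p% region is the set of cells with label ≤ p; its area is
  cell count × cell area. The inclusive-cumulative convention means the
  boundary-crossing cell is excluded — a sub-cell-area difference.
- **Usage.** The usage of a point is 100 − (isopleth label of its cell),
  clamped to 0 beyond the 99.9% isopleth or off-grid: the density mode
  scores ≈ 100, the range fringe 0.
- **Overlap.** The overlap of two UDs at level p is the fraction of each
  group's p-region area lying inside the other's, plus the shared area.
  UDs fitted on different grids are compared by nearest-cell resampling of
  the isopleth surface.

Closed forms used in validation: for an isotropic Gaussian UD with sd σ,
the p% region is a disk of area −2 ln(1−p/100)·π·σ², and containment at
radius r is 1 − exp(−r²/2σ²). The KDE of n draws smooths the truth by h²,
inflating areas by ≈ (1 + n^(−1/3)); at n = 10,000 that is ~4.6%, inside
the 10% validation tolerance. Point-usage checks are run on an
analytically constructed Gaussian UD, where the closed form is exact.

### Usage difference

Each hunt receives two usage values — the hunting group's and the other
group's at the hunt location — and the score

    usage_difference = usage(other group) − usage(hunt group),

so *positive* values mark hunts in places used relatively more by the
group that did **not** hunt. Note: the source material's verbal gloss of
this score ("higher = more used by the group that hunted") contradicts its
printed formula; the package implements the printed formula and leaves the
interpretation to the analyst.

## Association

The Simple Ratio Index for a dyad and calendar year is
SRI = P_AB/(P_A + P_B − P_AB) over that year's 30-minute party scans.
Dyads with P_A + P_B − P_AB = 0 are *undefined* (NaN), never 0. Years are
calendar years; scan-order permutations cannot change the index.

Per-hunt covariates come from the *hunt scan*: the scan covering the hunt
time (scans cover the half-hour after their timestamp), else the nearest
preceding scan within 60 minutes. From it:

- `n_available_males` / `n_available_females`: adults present, by sex. By
  default all adults in the scan are counted, including the other group's
  at intergroup hunts (`same_group_only=True` restricts to the catcher
  group's members — the field's definition is ambiguous, so it is a
  switch).
- `mean_association`: mean pairwise SRI over all defined dyads present,
  cross-group dyads included.
- `is_intergroup`: the hunt scan contains members of both groups. A hunt
  can be an intergroup hunt even if only one group was present at the
  capture, because the classification keys on the scan.
- `sin_date`, `cos_date`: θ = 2π(day-of-year − 1)/365.25, so January 1 maps
  exactly to (0, 1); the pair encodes annual seasonality as one harmonic.

Hunts with no resolvable scan, or with fewer than two individuals present,
get NaN covariates and are dropped (with a logged count) by the model's
complete-case handling.

## Prey model

Categorical (multinomial) logit with K = 3 prey categories, anomalure as
the reference (linear predictor 0) and Ekalakala as the reference group
level, so coefficients match the conventional reporting layout. Numeric
predictors are standardized to mean 0, sd 1 (sample sd, n−1); the group
indicator stays 0/1.

**Priors.** Independent Student-t(df 3, location 0, scale 2.5) on every
intercept and slope — the conventional weakly informative choice when the
source analysis specifies only "weakly informative t priors". df and
scale are parameters.

**Sampler.** The posterior (categorical likelihood + t prior densities)
is sampled with emcee's affine-invariant ensemble using
differential-evolution moves (0.8 DEMove / 0.2 DESnookerMove), which mix
~3× faster than the default stretch move on this correlated 16-parameter
posterior (measured integrated autocorrelation ≈ 45 vs ≈ 120 steps).
Each of the 4 chains is an independent 32-walker ensemble initialised
from a Laplace approximation (BFGS posterior mode, inverse-Hessian
scales) with 2× overdispersed scatter. A chain runs `warmup` (default 1000)
ensemble steps that are discarded, then continues with thinning until
exactly `iterations − warmup` = 1000 walker-draws are retained, giving
4 × 1000 = 4000 posterior draws. Estimates are posterior means, "SE" is
the posterior sd, and intervals are equal-tailed 2.5/97.5 percentiles.

**Diagnostics.** Split-Rhat (via ArviZ) on every parameter; the fit
carries a convergence flag that is clean only when all Rhat < 1.01.
Coefficients drifting into prior-dominated territory trigger a
complete-separation warning. VIF (1/(1−R²) of each predictor on the rest,
OLS) screens collinearity; perfectly collinear columns report infinity.
Everything is deterministic given `random_state`: chain seeds are spawned
from one SeedSequence.

The sampler was validated against a dense grid-integration oracle on a
two-parameter toy posterior (agreement within 0.05 in mean and sd), an
ML oracle at n = 2000, and simulation-based recovery/coverage checks (see
the test suite).

## Synthetic data

The generator reproduces the statistical structure the analysis assumes,
under known ground truth:

- **Ranging.** Each group's daily fixes are i.i.d. draws from a
  two-component isotropic Gaussian mixture: an own-core component at the
  group's centre plus a shared component at the midpoint. The own-core
  weight is calibrated *analytically* — a fixed grid scan of the
  closed-form mixture densities, picking the weight whose 95%-isopleth
  overlap is closest to `overlap_target` — so calibration is deterministic
  and independent of the realized sample. Unreachable targets raise an
  error reporting the closest achievable overlap. Defaults: centres 4 km
  apart, sd 2 km, target 0.65 (matching the emulated system's ~65%
  overlap). With these defaults the absolute 95% areas (~75 km²) are
  larger than the emulated field ranges (35–40 km²); overlap *fraction*,
  not absolute area, is the calibrated quantity.
- **Scans.** 30-minute scans through a 10-hour follow day. Each group is
  scanned separately except on intergroup days (Bernoulli
  `p_intergroup_day`, default 0.31), when the groups travel together and
  scans mix. Each member appears independently with its group's cohesion
  probability (defaults 0.68 / 0.50, chosen because i.i.d. presence with
  probability p gives within-group SRI ≈ p²/(2p − p²) ≈ 0.51 / 0.33, the
  emulated groups' cohesion levels).
- **Hunts.** Per day and group, Poisson(rate/2) hunts placed at a random
  relocation of that group, timed inside a scan interval; the catcher
  group is the modal group of the scan's participants (ties broken by the
  seeded RNG). Covariates are computed *by the same spatial and
  association routines the analysis uses*, standardized across the
  generated hunt table, and prey is drawn from the softmax of the
  ground-truth linear predictors (reference category 0). Default truth:
  intercepts −3.25/−3.3, group effects +4.5 (duiker) and +5.0 (squirrel),
  all other slopes 0, seasonal amplitude 0.
- **Determinism.** One SeedSequence per config seed is split into named
  streams (relocations, scans, hunts), so identical config+seed yields
  byte-identical tables and sub-generators can be re-run independently.

What the generator does **not** emulate: within-day spatial
autocorrelation of GPS fixes (fixes are i.i.d. draws, so the KDE's
effective sample size is optimistic relative to real tracking data),
range shifts over time, observation effort gaps, prey-distribution
heterogeneity beyond the two-component mixture, and individual-level
hunting skill. Passing recovery tests therefore demonstrate correctness
of the estimation machinery under the model's own assumptions, not
robustness to real-data violations of them.

## Problem sizes and test design

Simulation-backed tests use study-shaped but reduced runs: recovery and
null-calibration checks simulate 125 days at 4 hunts/day (~500 hunts,
20 replicates each), ranging checks use 10,000-point KDEs, and
integration tests run 60-day studies. The default `SimulationConfig`
remains full study scale (1250 days, one-minute fixes, hunt rate 0.05/day
→ ~60 hunts), and is what `huntniche run` and the worked example use.
Null-calibration success is defined as *all* 14 slope CIs (7 predictors ×
2 categories; intercepts excluded because their truth is nonzero)
containing 0; with t(3,0,2.5) shrinkage the per-CI coverage of 0 exceeds
the nominal 95%, which the ≥18/20 threshold absorbs.

## Known limitations

- The categorical model has no random effects (none are needed for the
  emulated design, which models each hunt as one draw).
- Independence MH-style refinements, NUTS, or marginal-likelihood
  computation are out of scope; the ensemble sampler's contract is
  Rhat < 1.01 with ≥ 4000 retained draws.
- The KDE has no boundary correction or temporal kernel; overlap is
  area-based on isopleth regions, not volume of intersection.
- `usage_difference` inherits the sign ambiguity described above.
- With ~60 hunts (full study scale) the group-effect posterior is
  prior-sensitive; recovery at that scale is assessed by CI exclusion of
  zero rather than point-estimate accuracy.
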