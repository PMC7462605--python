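# huntniche

Tools for asking whether two wild primate groups that share most of their
home range nonetheless *prefer different prey* — and whether that
preference survives adjustment for where, when, and with whom they hunt.

The package was built around a two-group bonobo system (Ekalakala and
Kokoalongo): groups with ~65% kernel home-range overlap, frequent
intergroup associations, and hunts of three prey types (anomalure, duiker,
squirrel). It is equally usable for any two-group study with GPS
relocations, party-composition scans, and categorized capture events.

## What it computes

**Space use.** Each group's utilization distribution (UD) is a Gaussian
kernel density over planar coordinates, with the reference ("href")
bandwidth h_j = σ_j·n^(−1/6). Percent-volume isopleths give the home range
(95%) and core (50%); the *usage* of a point is 100 minus the smallest
isopleth containing it, and each hunt gets a **usage difference** =
usage(other group) − usage(hunting group).

**Association.** Dyadic association per calendar year is the Simple Ratio
Index, SRI = P_AB/(P_A + P_B − P_AB), from 30-minute party scans. Per hunt
the package counts available male/female hunters, averages the pairwise
SRI of the party (cohesion), and flags intergroup hunts (mixed-group scan
at or just before the capture).

**Prey model.** Prey type is modelled as a categorical (multinomial) logit
with a reference category fixed at linear predictor 0:

    P(y_i = k) ∝ exp(x_i' β_k),     β_reference ≡ 0,

with Student-t(3, 0, 2.5) priors on all coefficients, numeric predictors
standardized to mean 0 / sd 1, posterior sampling by an ensemble MCMC run
as 4 independent chains (4000 retained draws), split-Rhat convergence
screening (< 1.01), and VIF collinearity checks.

**Synthetic data.** A generator with known ground truth emulates the whole
study — two-component Gaussian mixture ranging calibrated to a target
kernel overlap, cohesion-driven party scans with intergroup days, and
hunts whose prey follows the categorical-logit model — so every stage of
the pipeline is testable end to end, including parameter recovery.

## Worked example

```python
from huntniche import SimulationConfig, simulate, fit_categorical, tally_hunts
from huntniche.pipeline import run_pipeline

cfg = SimulationConfig(seed=7, n_days=125, relocations_per_day=60,
                       scans_per_day=10, hunt_rate_per_day=4.0)
manifest = run_pipeline(cfg, out_dir="demo_run")
```

`demo_run/report.txt` then contains (abridged):

```
Categorical prey model (reference: anomalure), posterior mean [95% CI]
      duiker intercept                -2.96  [ -3.50,  -2.47]  Rhat 1.002
      duiker group                     4.28  [  3.64,   4.97]  Rhat 1.003
      ...
    squirrel group                     5.84  [  4.98,   6.83]  Rhat 1.003
convergence: clean
```

The `group` rows are the log-odds shift for the second group (Kokoalongo)
relative to the first, per prey category versus the reference prey: the
simulation was generated with true effects +4.5 (duiker) and +5.0
(squirrel), and the posterior recovers them within credible-interval
width. `truth.json` in the output directory records the generating
coefficients and realized 95%-kernel overlap (~0.64 against the 0.65
target).

The same stages run from the shell:

```sh
huntniche simulate --config cfg.yaml --out sim/
huntniche ranging --relocations sim/relocations.csv --hunts sim/hunts.csv --out out/
huntniche covariates --scans sim/scans.csv --hunts sim/hunts.csv \
    --individuals sim/individuals.csv --usage out/usage_scores.csv --out out/
huntniche fit --covariates out/hunt_covariates.csv --seed 1 --out out/
huntniche run --config cfg.yaml --out full_run/
```

## Layout

- `huntniche.synthetic` — ground-truth generator (`SimulationConfig`, `simulate`)
- `huntniche.spatial` — `KernelUD` estimator, isopleths, overlap, usage scores
- `huntniche.association` — SRI matrices, encounters, hunt covariates
- `huntniche.model` — `BayesianCategoricalLogit` estimator (sklearn-style), VIF
- `huntniche.pipeline` / `huntniche.cli` — stage orchestration, manifests, CLI

See `docs/methods.md` for model assumptions, parameter defaults, and known
limitations.
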