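# Methods

## The model

`paleoabc` fits environment-coupled logistic population models to a
radiocarbon summed probability distribution (SPD) by rejection Approximate
Bayesian Computation (ABC). The population trajectory follows the
discrete Ricker-form logistic

    N_t = N_{t-1} · exp(r · (1 − N_{t-1}/K_{t-1}))

with a carrying capacity driven by environmental covariates through a
log-linear model

    K_{t-1} = exp(β_palm · F_{t-1} + β_SOI · C_{t-1})

where `F` is forest cover (palm pollen proportion) and `C` a climate index
(Southern Oscillation Index, SOI). Four nested models are compared:

| model | β_palm | β_SOI | interpretation |
|---|---|---|---|
| 1 | 0 | 0 | plain logistic growth, K = 1 |
| 2 | free | 0 | forest-cover effect |
| 3 | 0 | free | climate effect |
| 4 | free | free | both effects |

`N` is relative to the baseline carrying capacity; the initial condition
`n0 = N` at the oldest year of the analysis window is the proportion of
that baseline (constrained to (0, 1]). Time steps annually, oldest to
youngest, on a cal BP grid; `K_{t−1}` uses the covariates of the previous
step exactly as the recursion indexes them.

The "dates as data" assumption links demography to the radiocarbon record:
the probability of sampling a date at calendar year `t` is
`p_t = N_t / Σ N`. A candidate SPD is simulated from `p_t` by drawing a
date set of the same size as the observed number of bins, attaching lab
errors resampled from the observed error pool, calibrating, and summing.

## Calibration conventions

- Probability mass per integer calendar year (discretized density),
  half-open bins [t, t+1); grids in cal BP, larger = older.
- Calibration kernel: Gaussian in the 14C-age domain with variance
  `error² + σ_curve(t)²`, evaluated per grid year.
- Non-normalized calibration (the default for fitting) keeps the raw
  kernel values, suppressing the artificial spikes that per-date
  normalization induces at steep curve segments; normalized calibration
  rescales each date to unit mass.
- To avoid edge bias under normalization, dates are calibrated on the
  analysis window padded by 100 years on each side (clipped to curve
  support) and then restricted to the window.
- Mixed-curve dates use a linear pool of the terrestrial and marine
  curves in the 14C-age domain; the reservoir-offset uncertainty is folded
  into the marine component's error before pooling. Reservoir offsets are
  combined by the error-weighted mean, reporting both the internal error
  `√(1/Σw)` and the external (weighted-scatter) error and returning the
  larger, with a χ² homogeneity test against the (1−α) quantile at n−1
  degrees of freedom.
- Binning: within each site, complete-linkage clustering of conventional
  14C ages cut at 50 years, so no bin spans more than 50 14C years.
  Input-order invariance is enforced by sorting on (cra, lab_id); bins are
  numbered by their oldest member.
- The taphonomic correction divides the SPD by the empirical survival
  curve `n(t) = 5.726442×10⁶ (t + 2176.4)^(−1.3925309)` and rescales to
  preserve total mass. It is off by default: on the kind of late-Holocene
  window targeted here it changes SPD shape only marginally.

## Back-calibration algorithms

`calsample` draws calendar years from `p_t` and back-calibrates each one
(CRA ~ Normal(μ(t), σ(t)), rounded to integer years). `uncalsample` maps
the entire model into the 14C-age domain,
`q(y) ∝ Σ_t p_t φ(y; μ(t), σ(t))`, divides by the analogously
back-calibrated uniform model — so a uniform calendar model samples
uniformly over the curve's 14C support — and draws CRAs from the result.
On a monotone error-free curve the two coincide; they differ in how
faithfully curve-structure spikes propagate into simulated SPDs. Curve
assignment (terrestrial vs mixed) is fixed per simulated date before age
drawing; under independence of assignment and age this choice is
inconsequential. Curve errors below 0.5 14C years are treated as
point-mass kernels so error-free synthetic curves are handled exactly.

## Priors

All priors are config-driven; the defaults are:

| parameter | default prior | rationale |
|---|---|---|
| n0 | Uniform(0, 1] | initial population at or below baseline K |
| r | Exponential, scale 0.01/ln 2 (median 0.01/yr) | positive, conservative growth: half the draws below 0.01 |
| β_palm | Normal(0, 0.01) | symmetric, admits either sign; scaled to a [0,1] covariate |
| β_SOI | Normal(0, 0.2) | symmetric; scaled to an index of unit variance |

The β scales are deliberately wide relative to the effects the SPD can
resolve, so rejection selects the values most consistent with the data
rather than the prior. The palm series is used as a proportion in [0, 1];
the SOI in its native standardized units.

## The ABC loop

For each model, `n_sim` parameter combinations are drawn from the priors
(inactive betas pinned to 0), trajectories are run in a single vectorized
batch, and each draw's candidate SPD is scored against the observed target
with either Euclidean distance or NRMSE (RMSE divided by the observed
SPD's range). The target SPD is re-thinned — one date drawn uniformly per
bin — at every iteration by default, so thinning noise enters both sides
of the comparison; a fixed single thinning is available as an option. The
distance is computed on the full annual window with no further summary
compression.

Per-model posteriors are the `k` lowest-distance draws; ties break by
simulation index (stable sort), making the rejection fully deterministic.
Cross-model comparison pools all distances and keeps the `k` lowest
overall; with equal simulation counts per model (enforced), the models'
relative frequencies in that pooled best set give approximate Bayes
factors `BF_ij = n_i/n_j`. A zero count reports as an infinite/zero BF, to
be read as a one-sided bound.

HPD intervals are the shortest windows over order statistics containing
`⌈mass·n⌉` samples (requiring at least 20 samples). Posterior predictive
checks re-simulate one SPD per best-fitting draw (default 100) and report
the per-year 2.5/97.5 percentile envelope, the median, and the fraction of
observed-SPD years inside the envelope. Trajectory bands apply the same
per-year HPD machinery to the accepted draws' population curves; note the
per-year HPD *endpoints* need not be monotone even when every member
trajectory is, because the shortest interval can shift between years.

Reproducibility: a master seed spawns one independent child RNG stream per
model (`numpy` `SeedSequence`), and every stochastic step (prior draws,
thinning, calendar/CRA draws, error resampling) consumes that stream in a
fixed order, so a config plus seed reproduces every output byte.

## Synthetic data

The synthetic module emulates the three external inputs so every stage is
testable offline:

- **Curve**: `μ(t) = a·t + b + A·sin(2πt/P)` with constant σ; monotone when
  `A·2π/P < a`, plateau-bearing when larger. Defaults (slope 1, amplitude
  15, period 120, σ 15) give a monotone curve with realistic wiggle scale.
- **Covariates**: forest cover as a monotone logistic ramp declining
  forward in time, plus noise, rescaled to [0, 1]; climate as a stationary
  AR(1) series (lag-1 coefficient 0.9) with a mean shift on the younger
  half of the window.
- **Dataset**: 110 dates (matching the observed bin count of the study
  system) over 47 sites, errors resampled from a 20–60 yr pool, drawn by
  back-calibration from the trajectory of a known parameter combination
  (default: plain logistic, n0 = 0.1, r = 0.01). Site labels are assigned
  round-robin so the binning stage is exercised; the generating truth is
  persisted alongside for recovery tests.

What the synthetic data do *not* emulate: real calibration-curve
structure (multi-century plateaus, varying σ), taphonomic loss,
site-formation processes, spatially structured sampling, and the marine
fraction of real coastal datasets (the default scenario is all
terrestrial). Passing recovery tests on synthetic data therefore
demonstrates the correctness and calibration of the machinery, not that
any particular real dataset identifies the covariate effects.

## Problem sizes

Test and example runs are scaled down from a full analysis
(250,000 simulations per model, 1000 acceptances) to sizes that iterate
quickly: recovery experiments use 5,000 simulations with 100 acceptances
per fit, and model-comparison experiments 1,500 per model. These sizes
were chosen as the smallest at which HPD coverage and Bayes-factor
stability are statistically meaningful; the full-scale settings are plain
config values (`n_sim`, `k_accept`).

## Known limitations

- Rejection ABC only; no regression adjustment, SMC, or MCMC.
- The NRMSE normalizer is the observed SPD's range; other conventions
  exist and would rescale distances monotonically (acceptance sets are
  unchanged for a fixed measure).
- No kernel-density alternatives to the SPD, no per-region stratification,
  no wiggle-matching or Bayesian sequence modelling of individual sites.
- Bayes factors from pooled acceptance counts are a coarse approximation,
  meaningful only with equal per-model simulation counts and a common
  target; they inherit the distance measure's insensitivity to features
  the SPD does not express.
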