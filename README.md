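# paleoabc

Approximate Bayesian Computation for radiocarbon-based paleodemography.

`paleoabc` is for archaeologists and paleo-ecologists who use summed
probability distributions (SPDs) of calibrated ¹⁴C dates as a relative
population proxy and want to fit *generative* demographic models to them
instead of regressing curves onto the SPD directly. It simulates SPDs from
environment-coupled logistic population models, compares them to an
observed SPD by rejection ABC, and reports posterior parameter summaries,
approximate Bayes factors between models, and posterior predictive
envelopes.

## The model

Population dynamics follow a discrete logistic (Ricker form)

```
N_t = N_{t-1} · exp(r · (1 − N_{t-1}/K_{t-1}))
K_{t-1} = exp(β_palm · F_{t-1} + β_SOI · C_{t-1})
```

where `F_t` is forest cover and `C_t` a climate index (SOI). Four nested
models set none, one, or both β coefficients free; model 1 is plain
logistic growth toward K = 1. The "dates as data" link takes the
probability of sampling a ¹⁴C date at calendar year t proportional to
N_t, so each parameter draw θ = (n₀, r, β_palm, β_SOI) implies a
distribution over calendar years, from which synthetic date sets are drawn
(`calsample`: sample calendar years then back-calibrate; `uncalsample`:
back-calibrate the whole model, reweight by the back-calibrated uniform
model, then sample), calibrated, and summed into candidate SPDs. Rejection
keeps the k draws whose SPDs lie closest to the observed one (Euclidean or
NRMSE distance); pooling the best draws across models yields approximate
Bayes factors from the models' relative frequencies.

The package also covers the supporting workflow: IntCal-format curve
parsing, terrestrial/marine curve mixing with ΔR reservoir pooling
(error-weighted mean with external variance and χ² homogeneity test),
normalized and non-normalized calibration, site-level binning of dates
(complete linkage, 50-yr cut), taphonomic correction, and a synthetic-data
module that generates curves, covariates, and date sets from known
parameters so the whole pipeline is testable end to end.

## Worked example

Generate a synthetic dataset from a known truth (plain logistic growth,
n₀ = 0.1, r = 0.01/yr, 110 dates over 47 sites) and fit all four models:

```python
import numpy as np
import paleoabc as pa
from paleoabc.synthdata import synthetic_curve_for
from paleoabc.inference import posterior_summary

scn = pa.SyntheticScenario(seed=42)
dates, truth = pa.make_synthetic_dataset(scn)
bins = pa.make_bins(dates)                      # 95 bins from 110 dates

grid = np.arange(800., 149., -1.)               # 800–150 cal BP, annual
curve = synthetic_curve_for(scn)
palm, soi = pa.make_synthetic_covariates(grid, seed=1)
sim = pa.SPDSimulator(
    {"terrestrial": curve, "mixed": curve},
    palm=palm, soi=soi, error_pool=[d.error for d in dates],
)
fit = pa.fit_abc(bins, sim, models=(1, 2, 3, 4),
                 n_sim=2000, k_accept=100, seed=42)
print(posterior_summary(fit, 0.9))
bf, props = pa.bayes_factors(fit.abc)
env = pa.ppc_envelope(fit, model_id=1, n_best=100, seed=1)
```

Output (abridged):

```
 model_id parameter  median  hpd_lo  hpd_hi
        1        n0  0.1263  0.0093  0.2913
        1         r  0.0129  0.0028  0.0274
        2 beta_palm -0.0009 -0.0153  0.0121
        3  beta_soi  0.0092 -0.2707  0.2058
proportions: {1: 0.23, 2: 0.19, 3: 0.37, 4: 0.21}
PPC coverage model 1: 0.955
```

Read this as: the generating values n₀ = 0.1 and r = 0.01 sit inside
their 90% HPD intervals; the covariate effects in models 2–4 concentrate
on zero (the truth — the data were generated without them); the pooled
model proportions are near-uniform, so no Bayes factor gives strong
support for any covariate model over plain logistic growth; and 95.5% of
the observed SPD lies inside model 1's 95% posterior-predictive envelope.

The same pipeline runs from the shell:

```sh
paleoabc synth --seed 42 --out data/           # dates, covariates, curve
paleoabc fit --config run.yaml                 # full fit -> results dir
paleoabc spd --dates data/dates.csv --curve data/curve.14c \
             --seed 1 --out spd.csv            # just the observed SPD
```

`fit` writes one directory per run: `manifest.json` (config, seeds,
acceptance counts), `posterior_model{1..4}.csv`, `bf.csv`, `hpd.csv`,
`ppc_model{m}.csv`, `trajectory_model{m}.csv`, `spd.csv`, `log.txt`.
A persisted config plus its seed reproduces every output byte.

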