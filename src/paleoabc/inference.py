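"""Rejection ABC for SPD-based demographic inference.

The fitting loop follows the standard simulate-and-reject recipe:

1. define priors over theta = (n0, r, beta_palm, beta_soi);
2. sample n parameter combinations per model;
3. thin the observed dataset to a target SPD (one date per bin);
4. for each draw, run the logistic trajectory, convert it to calendar
   sampling probabilities p_t, simulate a date set of the same size as the
   number of bins, calibrate it and build a candidate SPD;
5. score each candidate against the target SPD with a distance (Euclidean or
   normalized RMSE); the target is re-thinned at every iteration so the
   Monte-Carlo noise of thinning enters both sides of the comparison;
6. keep the k lowest-distance draws per model as the approximate posterior,
   and pool the k lowest across models to form approximate Bayes factors
   from the models' relative frequencies in the pooled best set.

Posterior predictive checks re-simulate SPDs from the best draws and compare
the observed SPD to the per-year percentile envelope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .backcal import BackCalibrator
from .calcurve import CalCurve
from .calibration import MIXED, calibrate_many
from .demography import CovariateSeries, covariate_on_grid, simulate_trajectories
from .spd import BinSet, SPDGrid

__all__ = [
    "Prior",
    "default_priors",
    "sample_priors",
    "distance",
    "reject",
    "bayes_factors",
    "hpd",
    "ABCResult",
    "PPCEnvelope",
    "SPDSimulator",
    "fit_abc",
    "ppc_envelope",
    "hpd_trajectories",
]

PARAM_NAMES = ("n0", "r", "beta_palm", "beta_soi")
# which parameters are free under each model
MODEL_ACTIVE = {
    1: ("n0", "r"),
    2: ("n0", "r", "beta_palm"),
    3: ("n0", "r", "beta_soi"),
    4: ("n0", "r", "beta_palm", "beta_soi"),
}


@dataclass(frozen=True)
class Prior:
    """A (possibly truncated) scipy.stats prior for one parameter.

    ``dist`` names a scipy.stats continuous distribution; ``args`` are its
    shape/loc/scale arguments.  Truncation is applied by inverse-CDF
    sampling restricted to [lower, upper].
    """

    dist: str
    args: tuple = ()
    lower: float = -math.inf
    upper: float = math.inf

    def _frozen(self):
        try:
            return getattr(stats, self.dist)(*self.args)
        except (AttributeError, TypeError) as exc:
            raise ValueError(f"invalid prior spec {self}") from exc

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        fr = self._frozen()
        lo, hi = fr.cdf(self.lower), fr.cdf(self.upper)
        u = rng.uniform(lo, hi, size=n)
        return fr.ppf(u)


def default_priors() -> dict[str, Prior]:
    """Default prior specification.

    * ``n0`` ~ Uniform(0, 1]: the initial population is at or below the
      baseline carrying capacity.
    * ``r`` ~ Exponential with median 0.01 /yr (scale 0.01/ln 2): positive
      growth of conservative magnitude — half the draws fall below 0.01.
    * ``beta_palm`` ~ Normal(0, 0.01) and ``beta_soi`` ~ Normal(0, 0.2):
      symmetric about zero so forest-cover and climate effects of either
      sign are admissible; scales sized to the covariates' native units.
    """
    return {
        "n0": Prior("uniform", (0.0, 1.0), upper=1.0),
        "r": Prior("expon", (0.0, 0.01 / math.log(2))),
        "beta_palm": Prior("norm", (0.0, 0.01)),
        "beta_soi": Prior("norm", (0.0, 0.2)),
    }


def sample_priors(
    priors: dict[str, Prior], n: int, model_id: int, rng
) -> dict[str, np.ndarray]:
    """Draw n i.i.d. parameter combinations; inactive betas are fixed at 0."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if model_id not in MODEL_ACTIVE:
        raise ValueError("model_id must be 1..4")
    rng = np.random.default_rng(rng)
    active = MODEL_ACTIVE[model_id]
    out: dict[str, np.ndarray] = {}
    for name in PARAM_NAMES:
        if name in active:
            out[name] = priors[name].sample(n, rng)
        else:
            out[name] = np.zeros(n)
    return out


def distance(sim, obs, measure: str = "euclidean") -> float:
    """Distance epsilon between a simulated and an observed SPD.

    ``euclidean`` is sqrt(sum_t (sim_t - obs_t)^2); ``nrmse`` is the RMSE
    normalized by the observed SPD's range, max(obs) - min(obs).
    """
    if isinstance(sim, SPDGrid):
        if isinstance(obs, SPDGrid) and (
            len(sim.grid) != len(obs.grid) or np.any(sim.grid != obs.grid)
        ):
            raise ValueError("SPD grids do not match")
        sim = sim.mass
    if isinstance(obs, SPDGrid):
        obs = obs.mass
    sim = np.asarray(sim, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if sim.shape != obs.shape:
        raise ValueError("SPD grids do not match")
    diff = sim - obs
    if measure == "euclidean":
        return float(np.sqrt(np.sum(diff * diff)))
    if measure == "nrmse":
        rng_ = obs.max() - obs.min()
        if rng_ <= 0:
            raise ValueError("observed SPD has zero range; NRMSE undefined")
        return float(np.sqrt(np.mean(diff * diff)) / rng_)
    raise ValueError(f"unknown distance measure {measure!r}")


@dataclass
class ABCResult:
    """Accepted parameter draws with distances and model labels.

    ``draws`` holds one row per simulation with columns model_id, sim_index,
    n0, r, beta_palm, beta_soi, eps, accepted (within-model k-best) and
    accepted_pooled (cross-model k-best).
    """

    draws: pd.DataFrame
    k: int
    n_total: dict[int, int]

    def posterior(self, model_id: int) -> pd.DataFrame:
        mask = (self.draws["model_id"] == model_id) & self.draws["accepted"]
        return self.draws.loc[mask].reset_index(drop=True)

    def pooled(self) -> pd.DataFrame:
        return self.draws.loc[self.draws["accepted_pooled"]].reset_index(drop=True)

    def pooled_counts(self) -> dict[int, int]:
        pooled = self.pooled()
        return {
            m: int((pooled["model_id"] == m).sum())
            for m in sorted(self.n_total)
        }


def reject(eps_by_model: dict[int, np.ndarray], k: int = 1000) -> ABCResult:
    """Keep the k lowest-distance draws per model and across models.

    Ties are broken by simulation index (stable sort), so results are
    deterministic.  The cross-model pool requires equal simulation counts
    per model, matching the equal-prior Bayes-factor approximation.
    """
    sizes = {m: len(e) for m, e in eps_by_model.items()}
    if len(set(sizes.values())) > 1:
        raise ValueError("cross-model pooling requires equal n_total per model")
    n_total = next(iter(sizes.values()))
    if k > n_total:
        raise ValueError(f"k={k} exceeds available simulations ({n_total})")
    frames = []
    for m in sorted(eps_by_model):
        eps = np.asarray(eps_by_model[m], dtype=float)
        order = np.argsort(eps, kind="stable")
        accepted = np.zeros(len(eps), dtype=bool)
        accepted[order[:k]] = True
        frames.append(
            pd.DataFrame(
                {
                    "model_id": m,
                    "sim_index": np.arange(len(eps)),
                    "eps": eps,
                    "accepted": accepted,
                }
            )
        )
    draws = pd.concat(frames, ignore_index=True)
    pooled_order = np.argsort(draws["eps"].to_numpy(), kind="stable")
    pooled = np.zeros(len(draws), dtype=bool)
    pooled[pooled_order[:k]] = True
    draws["accepted_pooled"] = pooled
    return ABCResult(draws=draws, k=k, n_total=sizes)


def bayes_factors(result: ABCResult | dict[int, int]):
    """Approximate Bayes factors from pooled acceptance proportions.

    With equal prior simulation counts per model, BF_ij = n_i / n_j where
    n_m is model m's count among the pooled k best-fitting simulations.
    Returns (bf matrix DataFrame, proportions Series); a zero denominator
    yields +inf, to be read as a one-sided bound.
    """
    counts = result.pooled_counts() if isinstance(result, ABCResult) else dict(result)
    models = sorted(counts)
    n = np.array([counts[m] for m in models], dtype=float)
    total = n.sum()
    if total <= 0:
        raise ValueError("no pooled acceptances")
    with np.errstate(divide="ignore", invalid="ignore"):
        bf = n[:, None] / n[None, :]
    bf[np.isnan(bf)] = 1.0  # 0/0: no evidence either way
    return (
        pd.DataFrame(bf, index=models, columns=models),
        pd.Series(n / total, index=models, name="proportion"),
    )


def hpd(samples, mass: float = 0.9) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the sample.

    Sliding a window of ceil(mass*n) points over the order statistics and
    taking the narrowest window — the standard sample-based HPD estimator
    for unimodal posteriors.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 20:
        raise ValueError("HPD requires at least 20 samples")
    if not 0 < mass <= 1:
        raise ValueError("mass must lie in (0, 1]")
    w = int(np.ceil(mass * n))
    if w >= n:
        return float(x[0]), float(x[-1])
    widths = x[w - 1 :] - x[: n - w + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + w - 1])


class SPDSimulator:
    """Shared machinery for simulating candidate SPDs on the analysis window.

    Holds the annual grid (descending cal BP, forward in time), curve arrays
    interpolated to a padded grid (so normalized calibration is not biased at
    the window edges), back-calibrators per curve, covariates aligned to the
    grid, and the observed error pool.
    """

    def __init__(
        self,
        curves: dict[str, CalCurve],
        window: tuple[float, float] = (800, 150),
        palm: CovariateSeries | np.ndarray | None = None,
        soi: CovariateSeries | np.ndarray | None = None,
        error_pool=(30.0,),
        normalize: bool = False,
        algorithm: str = "uncalsample",
        pad_years: int = 100,
    ):
        if algorithm not in ("calsample", "uncalsample"):
            raise ValueError("algorithm must be calsample or uncalsample")
        old, young = max(window), min(window)
        self.window = (old, young)
        self.grid = np.arange(old, young - 1, -1.0)
        # padded grid for edge-unbiased normalized calibration, clipped to
        # the curves' common support
        supp_lo = max(c.support[0] for c in curves.values())
        supp_hi = min(c.support[1] for c in curves.values())
        pad_old = min(old + pad_years, np.floor(supp_hi))
        pad_young = max(young - pad_years, np.ceil(supp_lo))
        self.grid_padded = np.arange(pad_old, pad_young - 1, -1.0)
        self._win_slice = slice(
            int(pad_old - old), int(pad_old - old) + len(self.grid)
        )
        self.curves = dict(curves)
        self.curve_arrays = {
            key: c.at(self.grid_padded) for key, c in curves.items()
        }
        self.backcals = {
            key: BackCalibrator(c, self.grid) for key, c in curves.items()
        }
        t = len(self.grid)
        self.palm = (
            np.zeros(t)
            if palm is None
            else palm
            if isinstance(palm, np.ndarray)
            else covariate_on_grid(palm, self.grid)
        )
        self.soi = (
            np.zeros(t)
            if soi is None
            else soi
            if isinstance(soi, np.ndarray)
            else covariate_on_grid(soi, self.grid)
        )
        self.error_pool = np.asarray(error_pool, dtype=float)
        self.normalize = normalize
        self.algorithm = algorithm

    # -- demographic side -------------------------------------------------
    def trajectories(self, thetas: dict[str, np.ndarray]) -> np.ndarray:
        """(M, T) population matrix for a batch of parameter draws."""
        return simulate_trajectories(
            thetas["n0"], thetas["r"], thetas["beta_palm"], thetas["beta_soi"],
            self.palm, self.soi,
        )

    def sampling_probs(self, thetas: dict[str, np.ndarray]) -> np.ndarray:
        n = self.trajectories(thetas)
        return n / n.sum(axis=1, keepdims=True)

    # -- radiocarbon side --------------------------------------------------
    def calibrate_dates(self, cras, errors, curve_key: str) -> np.ndarray:
        """Per-date density matrix on the analysis window (padded, restricted)."""
        mu, sig = self.curve_arrays[curve_key]
        dens = calibrate_many(cras, errors, mu, sig, normalize=self.normalize)
        return dens[:, self._win_slice]

    def simulate_spd(
        self, p: np.ndarray, n_dates: int, prop_mixed: float, rng
    ) -> np.ndarray:
        """One candidate SPD: simulate a date set from p_t and calibrate it."""
        is_mixed = rng.random(n_dates) < prop_mixed
        mass = np.zeros(len(self.grid))
        for key, mask in (("terrestrial", ~is_mixed), (MIXED, is_mixed)):
            m = int(mask.sum())
            if m == 0:
                continue
            bc = self.backcals[key]
            draw = (
                bc.calsample_cras
                if self.algorithm == "calsample"
                else bc.uncalsample_cras
            )
            cras = draw(p, m, rng)
            errors = rng.choice(self.error_pool, size=m, replace=True)
            mass += self.calibrate_dates(cras, errors, key).sum(axis=0)
        return mass


@dataclass
class _ObservedTarget:
    """Pre-calibrated observed densities plus bin structure for re-thinning."""

    densities: np.ndarray        # (n_obs_dates, T), rows grouped by bin
    bin_starts: np.ndarray       # first row of each bin
    bin_sizes: np.ndarray        # rows per bin
    is_mixed: np.ndarray         # per observed date

    @property
    def n_bins(self) -> int:
        return len(self.bin_starts)

    def thin(self, rng) -> tuple[np.ndarray, float]:
        idx = self.bin_starts + rng.integers(0, self.bin_sizes)
        return (
            self.densities[idx].sum(axis=0),
            float(self.is_mixed[idx].mean()),
        )


def _prepare_target(bins: BinSet, sim: SPDSimulator) -> _ObservedTarget:
    dates = []
    starts, sizes = [], []
    for bin_id in sorted(bins.bins):
        starts.append(len(dates))
        dates.extend(bins.bins[bin_id])
        sizes.append(len(dates) - starts[-1])
    dens = np.zeros((len(dates), len(sim.grid)))
    cras = np.array([d.cra for d in dates])
    errs = np.array([d.error for d in dates])
    mixed = np.array([d.curve_key == MIXED for d in dates])
    for key, mask in (("terrestrial", ~mixed), (MIXED, mixed)):
        if mask.any():
            dens[mask] = sim.calibrate_dates(cras[mask], errs[mask], key)
    return _ObservedTarget(
        densities=dens,
        bin_starts=np.array(starts),
        bin_sizes=np.array(sizes),
        is_mixed=mixed,
    )


@dataclass
class FitResult:
    """Everything produced by :func:`fit_abc`.

    ``abc`` carries the draws and acceptances; the simulator, target and
    seed are retained so posterior predictive checks and trajectory bands
    can re-simulate from the fitted state.
    """

    abc: ABCResult
    simulator: SPDSimulator
    target: _ObservedTarget
    distance_measure: str
    rethin: bool
    seed: int | None

    def __getattr__(self, name):
        return getattr(self.abc, name)


def fit_abc(
    bins: BinSet,
    simulator: SPDSimulator,
    priors: dict[str, Prior] | None = None,
    models=(1, 2, 3, 4),
    n_sim: int = 5000,
    k_accept: int = 100,
    distance_measure: str = "euclidean",
    rethin: bool = True,
    seed: int | None = None,
) -> FitResult:
    """Run rejection ABC for the requested models against a binned dataset.

    For each model, ``n_sim`` draws are taken from the priors, a candidate
    SPD is simulated per draw (date-set size = number of bins, mixed-curve
    proportion matching the thinned observed set), and the k lowest-distance
    draws form the posterior.  With ``rethin`` the observed target SPD is
    re-sampled (one date per bin) at every iteration; otherwise a single
    thinning, fixed by the master seed, is reused throughout.

    Fully deterministic under the master seed: each model gets an
    independent child RNG stream.
    """
    if priors is None:
        priors = default_priors()
    target = _prepare_target(bins, simulator)
    n_dates = target.n_bins
    master = np.random.SeedSequence(seed)
    model_seeds = master.spawn(len(models))
    eps_by_model: dict[int, np.ndarray] = {}
    theta_by_model: dict[int, dict[str, np.ndarray]] = {}
    for model_id, child in zip(models, model_seeds):
        rng = np.random.default_rng(child)
        thetas = sample_priors(priors, n_sim, model_id, rng)
        p_mat = simulator.sampling_probs(thetas)
        if not rethin:
            obs_mass, prop_mixed = target.thin(rng)
        eps = np.empty(n_sim)
        for i in range(n_sim):
            if rethin:
                obs_mass, prop_mixed = target.thin(rng)
            sim_mass = simulator.simulate_spd(
                p_mat[i], n_dates, prop_mixed, rng
            )
            eps[i] = distance(sim_mass, obs_mass, distance_measure)
        eps_by_model[model_id] = eps
        theta_by_model[model_id] = thetas
    result = reject(eps_by_model, k=k_accept)
    # attach parameter columns to the draws frame
    for name in PARAM_NAMES:
        result.draws[name] = np.concatenate(
            [theta_by_model[m][name] for m in sorted(eps_by_model)]
        )
    return FitResult(
        abc=result,
        simulator=simulator,
        target=target,
        distance_measure=distance_measure,
        rethin=rethin,
        seed=seed,
    )


@dataclass
class PPCEnvelope:
    """Per-year percentile envelope of posterior-predictive SPDs."""

    grid: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    median: np.ndarray
    coverage: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "calBP": self.grid,
                "lo": self.lo,
                "median": self.median,
                "hi": self.hi,
            }
        )


def ppc_envelope(
    fit: FitResult,
    model_id: int | None = None,
    n_best: int = 100,
    interval: float = 0.95,
    seed: int | None = None,
) -> PPCEnvelope:
    """Posterior predictive check for one model (or the pooled best set).

    Re-simulates one SPD from each of the ``n_best`` lowest-distance
    accepted draws and returns the per-year percentile envelope (by default
    the 2.5th-97.5th band) together with the fraction of observed-SPD years
    falling inside it.
    """
    post = fit.abc.pooled() if model_id is None else fit.abc.posterior(model_id)
    best = post.nsmallest(n_best, "eps", keep="first")
    sim = fit.simulator
    rng = np.random.default_rng(seed)
    obs_mass, prop_mixed = fit.target.thin(rng)
    spds = np.empty((len(best), len(sim.grid)))
    for j, row in enumerate(best.itertuples(index=False)):
        thetas = {
            "n0": np.array([row.n0]),
            "r": np.array([row.r]),
            "beta_palm": np.array([row.beta_palm]),
            "beta_soi": np.array([row.beta_soi]),
        }
        p = sim.sampling_probs(thetas)[0]
        spds[j] = sim.simulate_spd(p, fit.target.n_bins, prop_mixed, rng)
    a = (1.0 - interval) / 2.0
    lo, med, hi = np.percentile(spds, [100 * a, 50, 100 * (1 - a)], axis=0)
    coverage = float(np.mean((obs_mass >= lo) & (obs_mass <= hi)))
    return PPCEnvelope(grid=sim.grid, lo=lo, hi=hi, median=med, coverage=coverage)


@dataclass
class TrajectoryBand:
    """Per-year posterior median and HPD band of the population trajectory."""

    grid: np.ndarray
    median: np.ndarray
    lo: np.ndarray
    hi: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "calBP": self.grid,
                "lo": self.lo,
                "median": self.median,
                "hi": self.hi,
            }
        )


def hpd_trajectories(
    fit: FitResult, model_id: int, mass: float = 0.95
) -> TrajectoryBand:
    """Population-size envelope: per-year median and HPD band over the
    accepted draws of one model."""
    post = fit.abc.posterior(model_id)
    thetas = {name: post[name].to_numpy() for name in PARAM_NAMES}
    n_mat = fit.simulator.trajectories(thetas)
    med = np.median(n_mat, axis=0)
    if len(post) == 1:
        return TrajectoryBand(fit.simulator.grid, med, n_mat[0], n_mat[0])
    lo = np.empty(n_mat.shape[1])
    hi = np.empty(n_mat.shape[1])
    for t in range(n_mat.shape[1]):
        lo[t], hi[t] = hpd(n_mat[:, t], mass=mass)
    return TrajectoryBand(grid=fit.simulator.grid, median=med, lo=lo, hi=hi)


def posterior_summary(fit: FitResult, mass: float = 0.9) -> pd.DataFrame:
    """Per-model median and HPD summary of each active parameter."""
    rows = []
    for m in sorted(fit.abc.n_total):
        post = fit.abc.posterior(m)
        for name in MODEL_ACTIVE[m]:
            x = post[name].to_numpy()
            lo, hi = hpd(x, mass=mass)
            rows.append(
                {
                    "model_id": m,
                    "parameter": name,
                    "median": float(np.median(x)),
                    "hpd_lo": lo,
                    "hpd_hi": hi,
                    "hpd_mass": mass,
                }
            )
    return pd.DataFrame(rows)
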