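"""Environment-coupled logistic population models and date-sampling
probabilities ("dates as data").

The population trajectory follows a discrete Ricker-form logistic

    N_t = N_{t-1} * exp(r * (1 - N_{t-1} / K_{t-1}))

with a carrying capacity driven by environmental covariates through a
log-linear model

    K_{t-1} = exp(beta_palm * F_{t-1} + beta_soi * C_{t-1})

where F is forest cover (palm pollen proportion) and C a climate index
(SOI).  Model 1 sets both betas to zero (plain logistic growth toward K=1);
models 2 and 3 activate one covariate each; model 4 activates both.  N is
relative to the baseline carrying capacity, and the initial population n0 is
the proportion of that baseline at the start of the analysis window.

The probability of sampling a radiocarbon date at calendar year t is
proportional to N_t: p_t = N_t / sum(N).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CovariateSeries",
    "ParamDraw",
    "DemographicTrajectory",
    "interp_covariate",
    "carrying_capacity",
    "simulate_trajectory",
    "simulate_trajectories",
    "dates_as_data",
]

_LOGK_CLIP = 50.0


@dataclass
class CovariateSeries:
    """A covariate time series on a calendar-age axis (cal BP)."""

    cal_age: np.ndarray
    value: np.ndarray
    name: str = "covariate"

    def __post_init__(self) -> None:
        self.cal_age = np.asarray(self.cal_age, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.cal_age.size == 0:
            raise ValueError("empty covariate series")
        if self.cal_age.shape != self.value.shape:
            raise ValueError("cal_age and value must share a shape")
        order = np.argsort(self.cal_age)
        self.cal_age = self.cal_age[order]
        self.value = self.value[order]
        if self.cal_age.size > 1 and np.any(np.diff(self.cal_age) <= 0):
            raise ValueError("cal_age must be strictly monotone")
        if not np.all(np.isfinite(self.value)):
            raise ValueError("covariate values must be finite")


@dataclass(frozen=True)
class ParamDraw:
    """One parameter combination theta = (n0, r, beta_palm, beta_soi).

    ``n0`` is the initial population as a proportion of the baseline carrying
    capacity, ``r`` the intrinsic growth rate per year.  ``model_id`` 1-4
    encodes which covariate effects are active; inactive betas must be zero.
    """

    n0: float
    r: float
    beta_palm: float = 0.0
    beta_soi: float = 0.0
    model_id: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.n0 <= 1.0:
            raise ValueError("n0 must lie in (0, 1]")
        if not self.r > 0:
            raise ValueError("r must be > 0")
        if self.model_id not in (1, 2, 3, 4):
            raise ValueError("model_id must be 1..4")
        if self.model_id == 1 and (self.beta_palm != 0 or self.beta_soi != 0):
            raise ValueError("model 1 requires both betas = 0")
        if self.model_id == 2 and self.beta_soi != 0:
            raise ValueError("model 2 requires beta_soi = 0")
        if self.model_id == 3 and self.beta_palm != 0:
            raise ValueError("model 3 requires beta_palm = 0")


@dataclass
class DemographicTrajectory:
    """Population N_t, carrying capacity K_t and sampling probability p_t.

    ``cal_age`` runs oldest to youngest (descending cal BP = forward time).
    """

    cal_age: np.ndarray
    n: np.ndarray
    k: np.ndarray
    p: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"calBP": self.cal_age, "N": self.n, "K": self.k, "p": self.p}
        )


def interp_covariate(series: CovariateSeries, grid) -> CovariateSeries:
    """Linearly interpolate a covariate to every year of ``grid``.

    Outside the series' support the nearest endpoint value is held constant.
    The output is aligned to ``grid`` as given (typically descending cal BP).
    """
    grid = np.asarray(grid, dtype=float)
    vals = np.interp(grid, series.cal_age, series.value)
    order = np.argsort(grid)
    # CovariateSeries sorts ascending internally; realign to preserve mapping
    return CovariateSeries(grid[order], vals[order], name=series.name)


def covariate_on_grid(series: CovariateSeries, grid) -> np.ndarray:
    """Covariate values aligned to ``grid`` exactly as given (fast path)."""
    return np.interp(np.asarray(grid, dtype=float), series.cal_age, series.value)


def carrying_capacity(f, c, beta_palm: float, beta_soi: float):
    """K = exp(beta_palm * F + beta_soi * C), with overflow-guarded log K."""
    logk = beta_palm * np.asarray(f, dtype=float) + beta_soi * np.asarray(c, dtype=float)
    if np.any(np.abs(logk) > _LOGK_CLIP):
        warnings.warn("log K clipped at +/-50; extreme beta draw", RuntimeWarning)
        logk = np.clip(logk, -_LOGK_CLIP, _LOGK_CLIP)
    return np.exp(logk)


def simulate_trajectory(
    theta: ParamDraw, f_series, c_series, grid
) -> DemographicTrajectory:
    """Run the logistic recursion for one parameter draw.

    ``grid`` is the annual analysis window in descending cal BP (oldest
    first); ``f_series``/``c_series`` are CovariateSeries or arrays already
    aligned to the grid.  N at the oldest year equals n0; each step uses the
    carrying capacity evaluated at the previous year's covariates.
    """
    grid = np.asarray(grid, dtype=float)
    f = f_series if isinstance(f_series, np.ndarray) else covariate_on_grid(f_series, grid)
    c = c_series if isinstance(c_series, np.ndarray) else covariate_on_grid(c_series, grid)
    k = carrying_capacity(f, c, theta.beta_palm, theta.beta_soi)
    n = np.empty_like(grid)
    n[0] = theta.n0
    for t in range(1, len(grid)):
        n[t] = n[t - 1] * np.exp(theta.r * (1.0 - n[t - 1] / k[t - 1]))
    if not np.all(np.isfinite(n)):
        raise FloatingPointError(
            f"non-finite population for theta={theta!r}"
        )
    return DemographicTrajectory(cal_age=grid, n=n, k=k, p=dates_as_data(n))


def simulate_trajectories(
    n0: np.ndarray,
    r: np.ndarray,
    beta_palm: np.ndarray,
    beta_soi: np.ndarray,
    f: np.ndarray,
    c: np.ndarray,
) -> np.ndarray:
    """Vectorized logistic recursion for a batch of draws.

    Parameters are 1-D arrays of equal length M; ``f`` and ``c`` are covariate
    values on the T-year analysis grid (oldest first).  Returns an (M, T)
    matrix of population sizes.  This is the engine's fast path; the scalar
    :func:`simulate_trajectory` is its reference implementation.
    """
    n0 = np.atleast_1d(np.asarray(n0, dtype=float))
    r = np.atleast_1d(np.asarray(r, dtype=float))
    logk = beta_palm[:, None] * f[None, :] + beta_soi[:, None] * c[None, :]
    np.clip(logk, -_LOGK_CLIP, _LOGK_CLIP, out=logk)
    k = np.exp(logk)
    m, t_len = k.shape
    n = np.empty((m, t_len))
    n[:, 0] = n0
    for t in range(1, t_len):
        prev = n[:, t - 1]
        n[:, t] = prev * np.exp(r * (1.0 - prev / k[:, t - 1]))
    return n


def dates_as_data(n) -> np.ndarray:
    """Sampling probabilities p_t proportional to N_t (sums to 1)."""
    n = np.asarray(n, dtype=float)
    return n / n.sum()
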