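"""Calibration curves: reading, interpolation, mixing, and marine reservoir pooling.

A calibration curve tabulates the mapping from calendar age (cal BP) to
conventional radiocarbon age (14C yr BP) together with a 1-sigma curve error.
Curves are stored sorted by ascending calendar age; interpolation onto an
annual grid is linear, the convention of mainstream SPD software.

Marine-influenced samples are calibrated against a linear mixture of a
terrestrial and a marine curve, the marine component shifted by a local
reservoir offset (Delta-R).  Multiple published Delta-R estimates for a
locality are combined by the standard error-weighted pooled mean with an
external-variance check (Ward & Wilson-style chi-squared homogeneity test).
"""

from __future__ import annotations


import re
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CalCurve",
    "ReservoirOffset",
    "PooledOffset",
    "read_calcurve",
    "interp_calcurve",
    "mix_curves",
    "pool_delta_r",
]


@dataclass
class CalCurve:
    """Tabulated calendar age -> (14C age, 1-sigma) mapping.

    Parameters
    ----------
    cal_age
        Calendar ages in cal BP.  Stored sorted ascending; duplicates are
        rejected.
    c14_age
        Conventional radiocarbon age mu(t) at each calendar age.
    sigma
        Curve 1-sigma error at each calendar age; strictly positive, except
        that exactly-zero errors are permitted for synthetic error-free
        curves used in testing and algorithm validation.
    name
        Human-readable label (e.g. ``"shcal20"``).
    """

    cal_age: np.ndarray
    c14_age: np.ndarray
    sigma: np.ndarray
    name: str = "calcurve"

    def __post_init__(self) -> None:
        self.cal_age = np.asarray(self.cal_age, dtype=float)
        self.c14_age = np.asarray(self.c14_age, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.cal_age.ndim != 1 or len(self.cal_age) < 2:
            raise ValueError("calibration curve needs at least two points")
        if not (len(self.cal_age) == len(self.c14_age) == len(self.sigma)):
            raise ValueError("cal_age, c14_age, sigma must have equal length")
        order = np.argsort(self.cal_age)
        self.cal_age = self.cal_age[order]
        self.c14_age = self.c14_age[order]
        self.sigma = self.sigma[order]
        if np.any(np.diff(self.cal_age) <= 0):
            raise ValueError(f"duplicate calendar ages in curve {self.name!r}")
        if np.any(self.sigma < 0):
            raise ValueError("curve sigma must be non-negative")

    @property
    def support(self) -> tuple[float, float]:
        """(min, max) calendar age covered by the curve."""
        return float(self.cal_age[0]), float(self.cal_age[-1])

    def at(self, grid) -> tuple[np.ndarray, np.ndarray]:
        """Linearly interpolated (mu, sigma) at arbitrary calendar ages.

        ``grid`` may be in any order (e.g. descending cal BP); values are
        returned aligned to it.  Raises if the query leaves the curve support.
        """
        grid = np.asarray(grid, dtype=float)
        lo, hi = self.support
        if grid.size and (grid.min() < lo or grid.max() > hi):
            raise ValueError(
                f"query grid [{grid.min()}, {grid.max()}] exceeds curve "
                f"{self.name!r} support [{lo}, {hi}]"
            )
        mu = np.interp(grid, self.cal_age, self.c14_age)
        sig = np.interp(grid, self.cal_age, self.sigma)
        return mu, sig


@dataclass(frozen=True)
class ReservoirOffset:
    """A local marine reservoir offset Delta-R with its 1-sigma error."""

    delta_r: float
    delta_r_sigma: float

    def __post_init__(self) -> None:
        if not self.delta_r_sigma > 0:
            raise ValueError("delta_r_sigma must be > 0")


@dataclass(frozen=True)
class PooledOffset:
    """Pooled Delta-R with the homogeneity report of the pooling."""

    delta_r: float
    delta_r_sigma: float          # max(internal, external)
    sigma_internal: float
    sigma_external: float
    chi2: float
    chi2_critical: float
    chi2_reduced: float
    df: int
    alpha: float
    homogeneous: bool

    def as_offset(self) -> ReservoirOffset:
        return ReservoirOffset(self.delta_r, self.delta_r_sigma)


_NUMERIC_RE = re.compile(r"^[\s,+-]*[\d.]")


def read_calcurve(path, name: str | None = None) -> CalCurve:
    """Read an IntCal-format calibration curve text file.

    Expects >= 3 numeric columns in the fixed order (cal BP, 14C age BP,
    1-sigma); extra columns are ignored.  Comma- or whitespace-separated
    values are accepted, and lines starting with ``#`` (or any non-numeric
    header line) are skipped.  Rows are returned sorted by calendar age.
    """
    rows: list[tuple[float, float, float]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = [p for p in re.split(r"[\s,]+", stripped) if p]
            if not _NUMERIC_RE.match(stripped):
                continue  # tolerate textual header lines
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 columns")
            try:
                rows.append((float(parts[0]), float(parts[1]), float(parts[2])))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric value") from exc
    if len(rows) < 2:
        raise ValueError(f"{path}: fewer than 2 usable data rows")
    arr = np.array(rows)
    if name is None:
        name = str(path)
    return CalCurve(arr[:, 0], arr[:, 1], arr[:, 2], name=name)


def write_calcurve(curve: CalCurve, path) -> None:
    """Write a curve in the three-column IntCal text dialect."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# {curve.name}\n# calBP, 14Cage, Sigma\n")
        for t, m, s in zip(curve.cal_age, curve.c14_age, curve.sigma):
            fh.write(f"{t:.1f},{m:.1f},{s:.1f}\n")


def interp_calcurve(curve: CalCurve, grid) -> CalCurve:
    """Interpolate a curve onto every integer year of ``grid``.

    ``grid`` may be a (min, max) pair or an explicit array of years; the
    result covers each integer year, sorted ascending, and its length is
    ``max - min + 1`` for an integer range.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 2 and grid.ndim == 1 and abs(grid[1] - grid[0]) > 1:
        lo, hi = sorted(grid)
        years = np.arange(np.ceil(lo), np.floor(hi) + 1)
    else:
        years = np.sort(np.unique(grid))
    mu, sig = curve.at(years)
    return CalCurve(years, mu, sig, name=curve.name)


def mix_curves(
    terr: CalCurve,
    marine: CalCurve,
    prop_terr: float,
    offset: ReservoirOffset | None = None,
    name: str = "mixed",
) -> CalCurve:
    """Mix a terrestrial and a marine curve in the 14C-age domain.

    Per calendar year t, with p = ``prop_terr``::

        mu_mix(t)    = p*mu_terr(t) + (1-p)*(mu_marine(t) + dR)
        sigma_mix(t) = sqrt((p*s_terr)^2 + ((1-p)*sqrt(s_mar^2 + dR_sigma^2))^2)

    i.e. the linear-pool convention used by mainstream calibration software,
    with the reservoir-offset uncertainty folded into the marine component.
    Both curves must be tabulated on the same calendar grid.
    """
    if not 0.0 <= prop_terr <= 1.0:
        raise ValueError("prop_terr must lie in [0, 1]")
    if len(terr.cal_age) != len(marine.cal_age) or np.any(terr.cal_age != marine.cal_age):
        raise ValueError("mix_curves requires both curves on the same calendar grid")
    dr = 0.0 if offset is None else offset.delta_r
    dr_sig = 0.0 if offset is None else offset.delta_r_sigma
    p = float(prop_terr)
    mu = p * terr.c14_age + (1.0 - p) * (marine.c14_age + dr)
    s_mar = np.sqrt(marine.sigma**2 + dr_sig**2)
    sig = np.sqrt((p * terr.sigma) ** 2 + ((1.0 - p) * s_mar) ** 2)
    return CalCurve(terr.cal_age.copy(), mu, sig, name=name)


def pool_delta_r(offsets, alpha: float = 0.05) -> PooledOffset:
    """Error-weighted pooled mean of reservoir offsets with external variance.

    Weights are the inverse variances 1/sigma_i^2.  The internal (pooled
    standard) error is ``sqrt(1/sum(w))``; the external error is the weighted
    scatter of the values about the pooled mean, ``sqrt(chi2 / ((n-1) sum w))``.
    The reported error is the larger of the two — the standard convention for
    combining reservoir offsets whose scatter may exceed their quoted errors.
    The homogeneity statistic ``chi2 = sum w_i (x_i - xbar)^2`` is compared to
    the (1 - alpha) quantile of chi-squared with n-1 degrees of freedom.
    """
    offsets = list(offsets)
    if len(offsets) < 2:
        raise ValueError("pooling requires at least two offsets")
    x = np.array([o.delta_r for o in offsets], dtype=float)
    s = np.array([o.delta_r_sigma for o in offsets], dtype=float)
    if np.any(s <= 0):
        raise ValueError("all delta_r_sigma must be > 0")
    w = 1.0 / s**2
    wsum = w.sum()
    mean = float((w * x).sum() / wsum)
    chi2 = float((w * (x - mean) ** 2).sum())
    n = len(x)
    df = n - 1
    sig_int = float(np.sqrt(1.0 / wsum))
    sig_ext = float(np.sqrt(chi2 / (df * wsum)))
    crit = float(stats.chi2.ppf(1.0 - alpha, df))
    return PooledOffset(
        delta_r=mean,
        delta_r_sigma=max(sig_int, sig_ext),
        sigma_internal=sig_int,
        sigma_external=sig_ext,
        chi2=chi2,
        chi2_critical=crit,
        chi2_reduced=chi2 / df,
        df=df,
        alpha=alpha,
        homogeneous=bool(chi2 < crit),
    )
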