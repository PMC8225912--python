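"""Radiocarbon calibration: converting a 14C determination into a calendar-age
probability mass function.

A conventional radiocarbon age (CRA) with lab error ``e`` is compared to the
calibration curve mean mu(t) with curve error s(t); the probability mass at
integer calendar year t is proportional to the Gaussian density of the CRA at
mu(t) with variance e^2 + s(t)^2.  Normalized densities are rescaled to unit
mass; non-normalized densities retain the raw kernel values, which suppresses
the artificial spikes that normalization induces at steep curve segments and
plateaus (the behaviour of rcarbon's ``normalised=FALSE``).

All grids are in cal BP (larger = older) with probability mass per integer
year, bin convention [t, t+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calcurve import CalCurve

__all__ = [
    "RadiocarbonDate",
    "CalibratedDensity",
    "calibrate",
    "calibrate_many",
    "out_of_window_mass",
    "read_dates",
    "write_dates",
]

TERRESTRIAL = "terrestrial"
MIXED = "mixed"
_CURVE_KEYS = (TERRESTRIAL, MIXED)

# A date whose kernel sums below this over the analysis grid has effectively
# no mass in the window and is flagged as out-of-window.
_EMPTY_KERNEL_SUM = 1e-12

_SQRT2PI = float(np.sqrt(2.0 * np.pi))


@dataclass(frozen=True)
class RadiocarbonDate:
    """A single radiocarbon determination.

    ``curve_key`` selects the calibration curve: ``"terrestrial"`` or
    ``"mixed"`` (terrestrial/marine blend with reservoir correction).
    """

    lab_id: str
    site_id: str
    cra: float
    error: float
    curve_key: str = TERRESTRIAL

    def __post_init__(self) -> None:
        if not np.isfinite(self.cra):
            raise ValueError(f"{self.lab_id}: CRA must be finite")
        if not self.error > 0:
            raise ValueError(f"{self.lab_id}: error must be > 0")
        if self.curve_key not in _CURVE_KEYS:
            raise ValueError(
                f"{self.lab_id}: curve_key must be one of {_CURVE_KEYS}"
            )


@dataclass
class CalibratedDensity:
    """Probability mass per integer calendar year for one date.

    ``kernel_sum`` preserves the raw (pre-normalization) kernel total so the
    normalization constant remains recoverable.  ``out_of_window`` flags a
    date whose kernel has essentially no mass on the grid; such dates are
    never silently dropped.
    """

    grid: np.ndarray
    mass: np.ndarray
    normalized: bool
    kernel_sum: float = 0.0
    out_of_window: bool = False

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.grid.shape != self.mass.shape:
            raise ValueError("grid and mass must have the same shape")


def _kernel(cra, error, mu, sig):
    """Gaussian calibration kernel evaluated per grid year (vectorized)."""
    var = np.asarray(error, dtype=float) ** 2 + sig**2
    sd = np.sqrt(var)
    z = (np.asarray(cra, dtype=float) - mu) / sd
    return np.exp(-0.5 * z * z) / (sd * _SQRT2PI)


def calibrate(
    date: RadiocarbonDate, curve: CalCurve, grid, normalize: bool = True
) -> CalibratedDensity:
    """Calibrate one date onto an annual calendar grid.

    ``grid`` is an array of integer years in cal BP (any order; the output is
    aligned to it).  The curve is evaluated by linear interpolation, so it
    should already be tabulated at (at least) annual resolution over the grid.
    """
    grid = np.asarray(grid, dtype=float)
    mu, sig = curve.at(grid)
    kern = _kernel(date.cra, date.error, mu, sig)
    ksum = float(kern.sum())
    oow = ksum < _EMPTY_KERNEL_SUM
    if normalize:
        mass = kern / ksum if ksum > 0 else kern
    else:
        mass = kern
    return CalibratedDensity(
        grid=grid, mass=mass, normalized=normalize, kernel_sum=ksum, out_of_window=oow
    )


def calibrate_many(cras, errors, mu, sig, normalize: bool) -> np.ndarray:
    """Vectorized calibration of many dates against pre-interpolated curve arrays.

    Returns an (n_dates, n_years) mass matrix.  This is the fast path used by
    the simulation engine; ``mu`` and ``sig`` are the curve mean and error
    aligned to the analysis grid.
    """
    cras = np.asarray(cras, dtype=float)[:, None]
    errors = np.asarray(errors, dtype=float)[:, None]
    kern = _kernel(cras, errors, mu[None, :], sig[None, :])
    if normalize:
        sums = kern.sum(axis=1, keepdims=True)
        np.divide(kern, sums, out=kern, where=sums > 0)
    return kern


def out_of_window_mass(
    window_density: CalibratedDensity, full_density: CalibratedDensity
) -> float:
    """Fraction of a date's calibrated mass lost to window truncation.

    Both densities must come from the same date calibrated on a restricted
    and a full-support grid respectively; the raw kernel totals recorded at
    calibration time give the lost fraction directly.
    """
    if full_density.kernel_sum <= 0:
        return 1.0
    frac = 1.0 - window_density.kernel_sum / full_density.kernel_sum
    return float(min(max(frac, 0.0), 1.0))


def read_dates(path) -> list[RadiocarbonDate]:
    """Read determinations from CSV with columns lab_id,site_id,cra,error,curve."""
    df = pd.read_csv(path, comment="#")
    required = {"lab_id", "site_id", "cra", "error"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    curves = df["curve"] if "curve" in df.columns else [TERRESTRIAL] * len(df)
    return [
        RadiocarbonDate(
            lab_id=str(row.lab_id),
            site_id=str(row.site_id),
            cra=float(row.cra),
            error=float(row.error),
            curve_key=str(curve),
        )
        for row, curve in zip(df.itertuples(index=False), curves)
    ]


def write_dates(dates, path) -> None:
    """Write determinations to the CSV dialect accepted by :func:`read_dates`."""
    df = pd.DataFrame(
        {
            "lab_id": [d.lab_id for d in dates],
            "site_id": [d.site_id for d in dates],
            "cra": [d.cra for d in dates],
            "error": [d.error for d in dates],
            "curve": [d.curve_key for d in dates],
        }
    )
    df.to_csv(path, index=False)
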