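"""Summed probability distributions (SPDs): binning, thinning, summation,
taphonomic correction.

Dates from the same site that lie close together in conventional 14C age are
grouped into bins so that heavily dated sites do not dominate the SPD
(ascertainment / wealth bias).  A target SPD is built by sampling one date
per bin and summing its calibrated densities; the taphonomic correction
divides the SPD by an empirical survival curve for datable deposits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .calcurve import CalCurve
from .calibration import MIXED, RadiocarbonDate, calibrate

__all__ = [
    "BinSet",
    "SPDGrid",
    "make_bins",
    "thin_to_target",
    "sum_spd",
    "taphonomic_correct",
]

# Survival curve for datable deposits as a function of age (years BP),
# from the taphonomic-loss literature: n(t) = 5726442 * (t + 2176.4)^-1.3925309
_TAPH_A = 5.726442e6
_TAPH_B = 2176.4
_TAPH_C = -1.3925309


@dataclass
class BinSet:
    """Site-derived bins of near-contemporaneous dates.

    ``bins`` maps bin_id -> list of dates; every date belongs to exactly one
    bin and all dates within a bin share a site.
    """

    bins: dict[str, list[RadiocarbonDate]]

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def n_dates(self) -> int:
        return sum(len(v) for v in self.bins.values())

    def all_dates(self) -> list[RadiocarbonDate]:
        return [d for members in self.bins.values() for d in members]


@dataclass
class SPDGrid:
    """Annual calendar grid with summed probability mass."""

    grid: np.ndarray
    mass: np.ndarray
    n_dates: int = 0
    n_bins: int = 0
    normalized_dates: bool = True

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.grid.shape != self.mass.shape:
            raise ValueError("grid and mass must share a shape")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"calBP": self.grid, "mass": self.mass})


def make_bins(dates, cut: float = 50.0) -> BinSet:
    """Cluster dates into site bins using complete linkage on |CRA difference|.

    Within each site, dates are clustered agglomeratively on their
    conventional 14C ages with complete linkage and the tree is cut at height
    ``cut`` (years): a bin never spans more than ``cut`` 14C years between its
    most distant members.  Binning is order-invariant: dates are sorted by
    (cra, lab_id) before clustering, and bins are numbered by their oldest
    member.  Empty input yields an empty BinSet.
    """
    dates = list(dates)
    bins: dict[str, list[RadiocarbonDate]] = {}
    for site in sorted({d.site_id for d in dates}):
        members = sorted(
            (d for d in dates if d.site_id == site), key=lambda d: (d.cra, d.lab_id)
        )
        if len(members) == 1:
            labels = np.array([1])
        else:
            cras = np.array([[d.cra] for d in members], dtype=float)
            z = linkage(cras, method="complete")
            labels = fcluster(z, t=cut, criterion="distance")
        # renumber clusters by oldest member for deterministic bin ids
        order: dict[int, int] = {}
        for lab in labels[np.argsort([d.cra for d in members])[::-1]]:
            if lab not in order:
                order[lab] = len(order) + 1
        for d, lab in zip(members, labels):
            bins.setdefault(f"{site}_{order[lab]}", []).append(d)
    return BinSet(bins=bins)


def thin_to_target(
    bins: BinSet, rng: np.random.Generator | int | None = None
) -> tuple[list[RadiocarbonDate], float]:
    """Sample one date uniformly from each bin.

    Returns the thinned date list (one per bin, in sorted bin-id order) and
    the proportion of selected dates assigned to the mixed curve.  Fully
    deterministic under a fixed seed.
    """
    if len(bins) == 0:
        raise ValueError("cannot thin an empty BinSet")
    rng = np.random.default_rng(rng)
    chosen: list[RadiocarbonDate] = []
    for bin_id in sorted(bins.bins):
        members = bins.bins[bin_id]
        chosen.append(members[int(rng.integers(len(members)))])
    prop_mixed = sum(d.curve_key == MIXED for d in chosen) / len(chosen)
    return chosen, prop_mixed


def sum_spd(
    dates,
    curves: dict[str, CalCurve],
    grid,
    normalize: bool = True,
    n_bins: int | None = None,
) -> SPDGrid:
    """Sum per-date calibrated densities elementwise into an SPD.

    ``curves`` maps each date's ``curve_key`` to its calibration curve.
    Out-of-window dates contribute (near-)zero mass but are counted; their
    flags propagate via the calibration step's QC logging.
    """
    dates = list(dates)
    grid = np.asarray(grid, dtype=float)
    mass = np.zeros_like(grid)
    for d in dates:
        dens = calibrate(d, curves[d.curve_key], grid, normalize=normalize)
        mass += dens.mass
    return SPDGrid(
        grid=grid,
        mass=mass,
        n_dates=len(dates),
        n_bins=len(dates) if n_bins is None else n_bins,
        normalized_dates=normalize,
    )


def taphonomic_survival(age_bp) -> np.ndarray:
    """Expected survival of datable deposits at age t (years BP)."""
    return _TAPH_A * (np.asarray(age_bp, dtype=float) + _TAPH_B) ** _TAPH_C


def taphonomic_correct(spd: SPDGrid) -> SPDGrid:
    """Reweight an SPD by the inverse taphonomic survival curve.

    Mass at each year is divided by the survival curve n(t) and the result is
    rescaled to preserve the total mass, shifting weight monotonically toward
    older years.
    """
    surv = taphonomic_survival(spd.grid)
    corrected = spd.mass / surv
    total = spd.mass.sum()
    if corrected.sum() > 0:
        corrected *= total / corrected.sum()
    return SPDGrid(
        grid=spd.grid.copy(),
        mass=corrected,
        n_dates=spd.n_dates,
        n_bins=spd.n_bins,
        normalized_dates=spd.normalized_dates,
    )
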