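"""Pipeline orchestration: calibrate -> bin -> SPD -> ABC fit -> PPC -> report.

A run is fully described by a :class:`RunConfig`; re-running a persisted
config with the same seed reproduces every output.  Results land in one
directory per run: ``manifest.json``, ``spd.csv``, ``posterior_model{m}.csv``,
``bf.csv``, ``hpd.csv``, ``ppc_model{m}.csv``, ``trajectory_model{m}.csv``
and ``log.txt``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .calcurve import CalCurve, ReservoirOffset, interp_calcurve, mix_curves, read_calcurve
from .calibration import MIXED, TERRESTRIAL, read_dates
from .demography import CovariateSeries
from .inference import (
    Prior,
    SPDSimulator,
    bayes_factors,
    default_priors,
    fit_abc,
    hpd_trajectories,
    posterior_summary,
    ppc_envelope,
)
from .spd import make_bins, sum_spd, taphonomic_correct, thin_to_target

logger = logging.getLogger("paleoabc")


@dataclass
class RunConfig:
    """Everything needed to reproduce a fit, serializable to YAML."""

    dates: str = "dates.csv"
    curve_terrestrial: str = "curve.14c"
    curve_marine: str | None = None
    mix_prop: float = 0.5
    delta_r: float = 0.0
    delta_r_sigma: float = 1.0
    palm: str | None = None
    soi: str | None = None
    window: tuple[float, float] = (800.0, 150.0)
    bin_cut: float = 50.0
    normalize: bool = False
    taphonomic: bool = False
    algorithm: str = "uncalsample"
    distance: str = "euclidean"
    models: tuple[int, ...] = (1, 2, 3, 4)
    n_sim: int = 5000
    k_accept: int = 100
    n_best_ppc: int = 100
    rethin: bool = True
    hpd_mass: float = 0.9
    priors: dict = field(default_factory=dict)
    seed: int = 0
    out: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.window = tuple(cfg.window)
        cfg.models = tuple(cfg.models)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=False)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["window"] = list(self.window)
        d["models"] = list(self.models)
        return d

    def build_priors(self) -> dict[str, Prior]:
        """Default priors, overridden per-parameter from the config mapping.

        Each override is ``{dist: name, args: [...], lower: x, upper: y}``.
        """
        priors = default_priors()
        for name, spec in (self.priors or {}).items():
            priors[name] = Prior(
                dist=spec["dist"],
                args=tuple(spec.get("args", ())),
                lower=spec.get("lower", -np.inf),
                upper=spec.get("upper", np.inf),
            )
        return priors


def read_covariate(path, name: str) -> CovariateSeries:
    """Read a covariate CSV with columns (cal_age, value)."""
    arr = np.genfromtxt(path, delimiter=",", names=True)
    return CovariateSeries(arr["cal_age"], arr["value"], name=name)


def load_curves(cfg: RunConfig) -> dict[str, CalCurve]:
    """Load (and, if configured, mix) the calibration curves for a run."""
    terr = read_calcurve(cfg.curve_terrestrial, name="terrestrial")
    curves = {TERRESTRIAL: terr}
    if cfg.curve_marine:
        marine = read_calcurve(cfg.curve_marine, name="marine")
        lo = max(terr.support[0], marine.support[0])
        hi = min(terr.support[1], marine.support[1])
        grid = (lo, hi)
        terr_i = interp_calcurve(terr, grid)
        marine_i = interp_calcurve(marine, grid)
        offset = ReservoirOffset(cfg.delta_r, cfg.delta_r_sigma)
        curves[TERRESTRIAL] = terr_i
        curves[MIXED] = mix_curves(terr_i, marine_i, cfg.mix_prop, offset)
    else:
        curves[MIXED] = terr  # no marine curve configured: mixed = terrestrial
    return curves


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full fit described by ``cfg`` and write the run directory."""
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(cfg, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(cfg: RunConfig, out: Path) -> Path:
    stage = "load"
    try:
        dates = read_dates(cfg.dates)
        curves = load_curves(cfg)
        palm = read_covariate(cfg.palm, "palm") if cfg.palm else None
        soi = read_covariate(cfg.soi, "soi") if cfg.soi else None
        logger.info("loaded %d dates", len(dates))

        stage = "bin"
        bins = make_bins(dates, cut=cfg.bin_cut)
        logger.info("%d bins from %d dates", len(bins), len(dates))

        stage = "spd"
        old, young = max(cfg.window), min(cfg.window)
        grid = np.arange(old, young - 1, -1.0)
        thinned, prop_mixed = thin_to_target(bins, rng=cfg.seed)
        obs_spd = sum_spd(
            thinned, curves, grid, normalize=cfg.normalize, n_bins=len(bins)
        )
        if cfg.taphonomic:
            obs_spd = taphonomic_correct(obs_spd)
        obs_spd.to_frame().to_csv(out / "spd.csv", index=False)
        logger.info("observed SPD: %d bins, prop_mixed=%.3f", len(bins), prop_mixed)

        stage = "fit"
        error_pool = [d.error for d in dates]
        sim = SPDSimulator(
            curves,
            window=cfg.window,
            palm=palm,
            soi=soi,
            error_pool=error_pool,
            normalize=cfg.normalize,
            algorithm=cfg.algorithm,
        )
        fit = fit_abc(
            bins,
            sim,
            priors=cfg.build_priors(),
            models=cfg.models,
            n_sim=cfg.n_sim,
            k_accept=cfg.k_accept,
            distance_measure=cfg.distance,
            rethin=cfg.rethin,
            seed=cfg.seed,
        )
        for m in cfg.models:
            fit.abc.posterior(m).to_csv(out / f"posterior_model{m}.csv", index=False)

        stage = "summaries"
        bf, props = bayes_factors(fit.abc)
        bf.to_csv(out / "bf.csv")
        posterior_summary(fit, mass=cfg.hpd_mass).to_csv(out / "hpd.csv", index=False)

        stage = "ppc"
        seed_seq = np.random.SeedSequence(cfg.seed).spawn(2 * len(cfg.models))
        coverages = {}
        for j, m in enumerate(cfg.models):
            env = ppc_envelope(
                fit, model_id=m, n_best=cfg.n_best_ppc,
                seed=seed_seq[j],
            )
            env.to_frame().to_csv(out / f"ppc_model{m}.csv", index=False)
            coverages[m] = env.coverage
            band = hpd_trajectories(fit, m, mass=0.95)
            band.to_frame().to_csv(out / f"trajectory_model{m}.csv", index=False)

        stage = "manifest"
        manifest = {
            "version": __version__,
            "config": cfg.as_dict(),
            "seed": cfg.seed,
            "n_dates": len(dates),
            "n_bins": len(bins),
            "prop_mixed": prop_mixed,
            "pooled_counts": fit.abc.pooled_counts(),
            "model_proportions": {int(k): float(v) for k, v in props.items()},
            "ppc_coverage": {int(k): float(v) for k, v in coverages.items()},
        }
        with open(out / "manifest.json", "wt", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2)
        logger.info("run complete: %s", out)
        return out
    except Exception as exc:
        logger.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
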