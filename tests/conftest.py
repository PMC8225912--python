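import numpy as np
import pytest

import paleoabc as pa
from paleoabc.synthdata import synthetic_curve_for


@pytest.fixture(scope="session")
def grid_800_150():
    return np.arange(800.0, 149.0, -1.0)


@pytest.fixture(scope="session")
def identity_curve():
    """Error-free identity curve: mu(t) = t, sigma = 0."""
    return pa.make_synthetic_curve(slope=1.0, intercept=0.0, sigma=0.0)


@pytest.fixture(scope="session")
def wiggly_curve():
    """Monotone curve with sinusoidal wiggles and constant 15-yr error."""
    return pa.make_synthetic_curve(
        slope=1.0, intercept=300.0, wiggle_amp=15.0, wiggle_period=120.0, sigma=15.0
    )


@pytest.fixture(scope="session")
def default_scenario():
    return pa.SyntheticScenario(seed=11)


@pytest.fixture(scope="session")
def synth_dataset(default_scenario):
    dates, truth = pa.make_synthetic_dataset(default_scenario)
    return dates, truth


@pytest.fixture(scope="session")
def synth_fit(default_scenario, synth_dataset, grid_800_150):
    """A small but real end-to-end fit reused by the inference tests."""
    dates, truth = synth_dataset
    curve = synthetic_curve_for(default_scenario)
    curves = {"terrestrial": curve, "mixed": curve}
    palm, soi = pa.make_synthetic_covariates(grid_800_150, seed=5)
    sim = pa.SPDSimulator(
        curves,
        palm=palm,
        soi=soi,
        error_pool=[d.error for d in dates],
    )
    bins = pa.make_bins(dates)
    fit = pa.fit_abc(
        bins, sim, models=(1,), n_sim=800, k_accept=100, seed=7
    )
    return fit
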