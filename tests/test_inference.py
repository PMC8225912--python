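"""Priors, distances, rejection, Bayes factors, HPDs, and predictive checks."""

import itertools

import numpy as np
import pandas as pd
import pytest

import paleoabc as pa
from paleoabc.inference import MODEL_ACTIVE, posterior_summary


class TestPriors:
    def test_model1_betas_exactly_zero(self):
        draws = pa.sample_priors(pa.default_priors(), 500, model_id=1, rng=0)
        assert np.all(draws["beta_palm"] == 0.0)
        assert np.all(draws["beta_soi"] == 0.0)

    def test_inactive_betas_per_model(self):
        priors = pa.default_priors()
        for m, active in MODEL_ACTIVE.items():
            draws = pa.sample_priors(priors, 200, model_id=m, rng=m)
            for name in ("beta_palm", "beta_soi"):
                if name in active:
                    assert np.any(draws[name] != 0.0)
                else:
                    assert np.all(draws[name] == 0.0)

    def test_n0_truncated_at_one(self):
        draws = pa.sample_priors(pa.default_priors(), 10_000, model_id=1, rng=1)
        assert draws["n0"].max() <= 1.0
        assert draws["n0"].min() > 0.0

    def test_growth_rate_prior_median_near_001(self):
        draws = pa.sample_priors(pa.default_priors(), 100_000, model_id=1, rng=2)
        assert np.median(draws["r"]) == pytest.approx(0.01, abs=0.0005)
        assert draws["r"].min() > 0.0

    def test_truncated_prior_respects_bounds(self):
        prior = pa.Prior("norm", (0.0, 1.0), lower=-0.5, upper=0.5)
        x = prior.sample(5000, np.random.default_rng(0))
        assert x.min() >= -0.5 and x.max() <= 0.5

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="prior"):
            pa.Prior("nosuchdist", ())._frozen()


class TestDistance:
    def test_identical_spds_zero(self, grid_800_150):
        m = np.random.default_rng(0).random(len(grid_800_150))
        assert pa.distance(m, m, "euclidean") == 0.0
        assert pa.distance(m, m, "nrmse") == 0.0

    def test_constant_offset_closed_form(self):
        obs = np.linspace(0.0, 1.0, 100)
        sim = obs + 0.25
        assert pa.distance(sim, obs, "euclidean") == pytest.approx(0.25 * 10.0)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(1)
        sim, obs = rng.random(300), rng.random(300)
        assert pa.distance(sim, obs, "euclidean") == pytest.approx(
            np.sqrt(((sim - obs) ** 2).sum())
        )
        assert pa.distance(sim, obs, "nrmse") == pytest.approx(
            np.sqrt(((sim - obs) ** 2).mean()) / (obs.max() - obs.min())
        )

    def test_grid_mismatch_rejected(self, grid_800_150):
        a = pa.SPDGrid(grid_800_150, np.ones(len(grid_800_150)))
        b = pa.SPDGrid(grid_800_150[:-1], np.ones(len(grid_800_150) - 1))
        with pytest.raises(ValueError, match="grid"):
            pa.distance(a, b)


class TestReject:
    def test_eps_equals_index_keeps_first_k(self):
        eps = {1: np.arange(100.0)}
        res = pa.reject(eps, k=10)
        accepted = res.posterior(1)["sim_index"].to_numpy()
        np.testing.assert_array_equal(np.sort(accepted), np.arange(10))

    def test_all_ties_broken_by_index(self):
        eps = {1: np.zeros(50), 2: np.zeros(50)}
        res = pa.reject(eps, k=20)
        np.testing.assert_array_equal(
            np.sort(res.posterior(1)["sim_index"]), np.arange(20)
        )
        # pooled ties resolve model 1 first (stable order)
        assert res.pooled_counts() == {1: 20, 2: 0}

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(7)
        eps = {m: rng.random(200) for m in (1, 2, 3)}
        res = pa.reject(eps, k=40)
        for m in (1, 2, 3):
            got = set(res.posterior(m)["sim_index"])
            want = set(np.argsort(eps[m])[:40])
            assert got == want
        pooled = res.pooled()
        all_eps = np.concatenate([eps[m] for m in (1, 2, 3)])
        cutoff = np.sort(all_eps)[39]
        assert pooled["eps"].max() <= cutoff + 1e-12

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            pa.reject({1: np.arange(5.0)}, k=10)

    def test_unequal_model_sizes_rejected(self):
        with pytest.raises(ValueError, match="equal"):
            pa.reject({1: np.arange(5.0), 2: np.arange(6.0)}, k=2)


class TestBayesFactors:
    def test_equal_counts_unit_bf(self):
        bf, props = pa.bayes_factors({1: 250, 2: 250, 3: 250, 4: 250})
        assert np.allclose(bf.to_numpy(), 1.0)
        assert np.allclose(props.to_numpy(), 0.25)

    def test_ratio_arithmetic(self):
        bf, props = pa.bayes_factors({1: 500, 2: 250, 3: 125, 4: 125})
        assert bf.loc[1, 2] == pytest.approx(2.0)
        assert bf.loc[1, 4] == pytest.approx(4.0)
        assert props.sum() == pytest.approx(1.0)

    def test_matches_ratio_oracle(self):
        counts = {1: 37, 2: 411, 3: 2, 4: 550}
        bf, _ = pa.bayes_factors(counts)
        for i, j in itertools.product(counts, counts):
            assert bf.loc[i, j] == pytest.approx(counts[i] / counts[j])

    def test_zero_count_one_sided(self):
        bf, _ = pa.bayes_factors({1: 10, 2: 0})
        assert np.isinf(bf.loc[1, 2])
        assert bf.loc[2, 1] == 0.0


class TestHPD:
    def test_uniform_sample_width_near_mass(self):
        x = np.random.default_rng(0).uniform(0, 1, 20_000)
        lo, hi = pa.hpd(x, 0.9)
        assert hi - lo == pytest.approx(0.9, abs=0.02)

    def test_point_mass_zero_width(self):
        lo, hi = pa.hpd(np.full(100, 3.14), 0.95)
        assert lo == hi == pytest.approx(3.14)

    def test_matches_exhaustive_interval_search(self):
        rng = np.random.default_rng(42)
        x = np.sort(rng.standard_normal(50))
        lo, hi = pa.hpd(x, 0.9)
        w = int(np.ceil(0.9 * 50))
        best = min(
            ((x[i + w - 1] - x[i], x[i], x[i + w - 1]) for i in range(50 - w + 1)),
        )
        assert (lo, hi) == (pytest.approx(best[1]), pytest.approx(best[2]))

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="20"):
            pa.hpd(np.arange(10), 0.9)

    def test_interval_contains_requested_mass(self):
        x = np.random.default_rng(3).gamma(2.0, 1.0, 5000)
        lo, hi = pa.hpd(x, 0.9)
        inside = np.mean((x >= lo) & (x <= hi))
        assert inside >= 0.9


class TestFitMachinery:
    def test_posterior_within_prior_support(self, synth_fit):
        post = synth_fit.abc.posterior(1)
        assert len(post) == synth_fit.abc.k
        assert post["n0"].between(0, 1).all()
        assert (post["r"] > 0).all()

    def test_accepted_marginals_approach_prior_as_k_grows(self, synth_fit):
        from scipy.stats import ks_2samp

        draws = synth_fit.abc.draws
        eps = draws["eps"].to_numpy()
        r_all = draws["r"].to_numpy()
        order = np.argsort(eps, kind="stable")
        d_small = ks_2samp(r_all[order[:100]], r_all).statistic
        d_large = ks_2samp(r_all[order[:600]], r_all).statistic
        assert d_large < d_small

    def test_fit_reproducible_under_seed(self, default_scenario, grid_800_150):
        from paleoabc.synthdata import synthetic_curve_for

        dates, _ = pa.make_synthetic_dataset(default_scenario)
        curve = synthetic_curve_for(default_scenario)
        curves = {"terrestrial": curve, "mixed": curve}
        bins = pa.make_bins(dates)
        palm, soi = pa.make_synthetic_covariates(grid_800_150, seed=5)

        def run():
            sim = pa.SPDSimulator(
                curves, palm=palm, soi=soi, error_pool=[d.error for d in dates]
            )
            return pa.fit_abc(bins, sim, models=(1,), n_sim=120, k_accept=30, seed=17)

        a, b = run(), run()
        pd.testing.assert_frame_equal(a.abc.draws, b.abc.draws)

    def test_posterior_summary_structure(self, synth_fit):
        summ = posterior_summary(synth_fit, mass=0.9)
        assert set(summ["parameter"]) == {"n0", "r"}
        assert (summ["hpd_lo"] <= summ["median"]).all()
        assert (summ["median"] <= summ["hpd_hi"]).all()


class TestPPC:
    def test_envelope_orders_and_percentile_oracle(self, synth_fit):
        env = pa.ppc_envelope(synth_fit, model_id=1, n_best=30, seed=5)
        assert np.all(env.lo <= env.median + 1e-12)
        assert np.all(env.median <= env.hi + 1e-12)
        assert 0.0 <= env.coverage <= 1.0

    def test_identical_draws_collapse_envelope(self, synth_fit):
        # restricting to a single best draw: lo == hi == median
        env = pa.ppc_envelope(synth_fit, model_id=1, n_best=1, seed=5)
        np.testing.assert_allclose(env.lo, env.hi)
        np.testing.assert_allclose(env.lo, env.median)

    def test_data_from_accepted_draw_covered(self, synth_fit):
        env = pa.ppc_envelope(synth_fit, model_id=1, n_best=50, seed=6)
        # observed data were generated under model 1: envelope must cover
        # nearly the whole observed SPD
        assert env.coverage > 0.9


class TestTrajectoryBands:
    def test_band_endpoints_match_per_year_hpd(self, synth_fit):
        band = pa.hpd_trajectories(synth_fit, model_id=1, mass=0.95)
        post = synth_fit.abc.posterior(1)
        thetas = {k: post[k].to_numpy() for k in ("n0", "r", "beta_palm", "beta_soi")}
        n_mat = synth_fit.simulator.trajectories(thetas)
        for t in [0, 100, 400, 650]:
            lo, hi = pa.hpd(n_mat[:, t], 0.95)
            assert band.lo[t] == pytest.approx(lo)
            assert band.hi[t] == pytest.approx(hi)
        assert np.all(band.lo <= band.median + 1e-12)

    def test_model1_bands_monotone(self, synth_fit):
        # each plain-logistic trajectory is nondecreasing, so the per-year
        # median is too; HPD endpoints may jitter as the shortest interval
        # shifts, but the band must stay within (0, 1]
        band = pa.hpd_trajectories(synth_fit, model_id=1, mass=0.95)
        assert np.all(np.diff(band.median) >= -1e-9)
        assert np.all(band.hi <= 1.0 + 1e-9)
        assert np.all(band.lo > 0.0)
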