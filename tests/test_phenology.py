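"""Change-point model: prediction, likelihood, MCMC sampler, diagnostics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

import pinedrought as pdr
from pinedrought.phenology import (
    ConvergenceError,
    IdentifiabilityError,
    PriorBox,
    TruncatedModelParams,
)


class TestPredict:
    @pytest.mark.parametrize(
        "params,doy,expected",
        [
            (TruncatedModelParams(1.0, 0.0, 100.0), 50.0, 50.0),
            (TruncatedModelParams(1.0, 0.0, 100.0), 150.0, 100.0),
            (TruncatedModelParams(0.5, 0.1, 180.0), 190.0, 91.0),
        ],
    )
    def test_hand_values(self, params, doy, expected):
        assert pdr.truncated_predict(params, doy) == pytest.approx(expected)

    @given(
        b1=st.floats(0.01, 5.0),
        b2=st.floats(0.0, 5.0),
        thr=st.floats(120.0, 290.0),
    )
    def test_continuity_at_threshold(self, b1, b2, thr):
        p = TruncatedModelParams(b1, b2, thr)
        eps = 1e-9
        left = pdr.truncated_predict(p, thr - eps)
        right = pdr.truncated_predict(p, thr + eps)
        assert abs(left - right) < 1e-5
        assert pdr.truncated_predict(p, thr) == pytest.approx(b1 * thr)

    def test_onset_offset_form(self):
        p = TruncatedModelParams(0.8, 0.0, 183.0)
        assert pdr.truncated_predict(p, 118.0, onset=118.0) == 0.0
        assert pdr.truncated_predict(p, 200.0, onset=118.0) == pytest.approx(0.8 * 65)


class TestLogLikelihood:
    def test_perfect_fit_value(self):
        p = TruncatedModelParams(1.0, 0.0, 100.0, sigma=1.0)
        doy = np.array([10.0, 50.0, 150.0])
        y = pdr.truncated_predict(p, doy)
        assert pdr.log_likelihood(p, (doy, y)) == pytest.approx(3 * np.log(1 / np.sqrt(2 * np.pi)))

    def test_larger_residuals_lower_likelihood(self):
        p = TruncatedModelParams(1.0, 0.0, 100.0, sigma=2.0)
        doy = np.linspace(10, 150, 20)
        mu = pdr.truncated_predict(p, doy)
        ll1 = pdr.log_likelihood(p, (doy, mu + 1.0))
        ll2 = pdr.log_likelihood(p, (doy, mu + 2.0))
        assert ll2 < ll1

    def test_matches_direct_density_oracle(self, rng):
        doy = rng.uniform(120, 290, 40)
        y = rng.uniform(0, 150, 40)
        for p in (
            TruncatedModelParams(0.7, 0.1, 180.0, 2.5),
            TruncatedModelParams(1.2, 0.0, 220.0, 4.0),
        ):
            mu = pdr.truncated_predict(p, doy)
            oracle = sps.norm.logpdf(y, loc=mu, scale=p.sigma).sum()
            assert pdr.log_likelihood(p, (doy, y)) == pytest.approx(oracle)


class TestGelmanRubin:
    def test_identical_chains_give_unity(self, rng):
        draws = rng.normal(0, 1, 1_000_000)
        chains = np.stack([draws, draws, draws])
        assert pdr.gelman_rubin(chains)[0] == pytest.approx(1.0, abs=1e-6)

    def test_separated_chains_flagged(self, rng):
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert pdr.gelman_rubin(chains)[0] > 1.1

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError):
            pdr.gelman_rubin(rng.normal(0, 1, (1, 100)))

    def test_iid_chains_near_one(self, rng):
        chains = rng.normal(0, 1, (3, 5000, 2))
        assert (pdr.gelman_rubin(chains) < 1.02).all()


class TestGridMle:
    def test_noiseless_truth_on_grid_recovered_exactly(self):
        truth = TruncatedModelParams(0.8, 0.0, 185.0, 1.0)
        doy = np.arange(125.0, 286.0, 7.0)
        y = pdr.truncated_predict(truth, doy, onset=118.0)
        grids = {
            "b1": np.arange(0.2, 1.61, 0.1),
            "b2": np.arange(0.0, 0.51, 0.1),
            "threshold": np.arange(150.0, 230.0, 1.0),
            "sigma": np.array([0.5, 1.0, 2.0]),
        }
        mle = pdr.grid_mle((doy, y), grids, onset=118.0)
        assert mle.b1 == pytest.approx(0.8)
        assert mle.b2 == pytest.approx(0.0)
        assert mle.threshold == pytest.approx(185.0)

    def test_refining_grid_never_decreases_likelihood(self, rng):
        doy = np.arange(125.0, 286.0, 7.0)
        y = pdr.truncated_predict(TruncatedModelParams(0.8, 0.0, 185.0), doy, onset=118.0)
        y = y + rng.normal(0, 2, doy.size)
        coarse = {
            "b1": np.linspace(0.2, 1.6, 8),
            "b2": np.array([0.0, 0.2]),
            "threshold": np.arange(150.0, 230.0, 8.0),
            "sigma": np.array([1.0, 2.0, 4.0]),
        }
        fine = {k: np.union1d(v, (v[:-1] + v[1:]) / 2) for k, v in coarse.items()}
        llc = pdr.log_likelihood(pdr.grid_mle((doy, y), coarse, onset=118.0), (doy, y), onset=118.0)
        llf = pdr.log_likelihood(pdr.grid_mle((doy, y), fine, onset=118.0), (doy, y), onset=118.0)
        assert llf >= llc - 1e-9


@pytest.fixture(scope="module")
def early_fit(design, params):
    obs = pdr.gen_needle_obs(design, params, treatments=("early",))
    return pdr.fit_truncated_mcmc(obs, onset=118.0, seed=11)


class TestMcmcFit:
    def test_recovers_early_threshold_within_credible_band(self, early_fit):
        assert 174.0 <= early_fit.median("threshold") <= 188.0
        lo, hi = early_fit.ci("threshold")
        assert lo <= 183.0 <= hi

    def test_convergence_and_acceptance_window(self, early_fit):
        assert early_fit.converged
        assert max(early_fit.rhat.values()) < 1.1
        assert (early_fit.acceptance_rate > 0.15).all()
        assert (early_fit.acceptance_rate < 0.5).all()

    def test_no_draw_leaves_prior_box(self, early_fit):
        lo, hi = early_fit.prior.lower(), early_fit.prior.upper()
        flat = early_fit.chains.reshape(-1, 4)
        assert (flat >= lo).all() and (flat <= hi).all()

    def test_determinism_under_seed(self, design, params):
        obs = pdr.gen_needle_obs(design, params, treatments=("early",))
        a = pdr.fit_truncated_mcmc(obs, n_iter=3000, burn_in=2000, seed=5, onset=118.0)
        b = pdr.fit_truncated_mcmc(obs, n_iter=3000, burn_in=2000, seed=5, onset=118.0)
        np.testing.assert_array_equal(a.chains, b.chains)

    def test_noiseless_data_pins_threshold_below_sampling_interval(self, design):
        import dataclasses

        p = pdr.default_params()
        p = {tr: dataclasses.replace(v, needle=dataclasses.replace(
                v.needle, noise_sd=0.0, tree_threshold_sd=0.0, tree_b1_sd=0.0))
             for tr, v in p.items()}
        obs = pdr.gen_needle_obs(design, p, treatments=("control",))
        post = pdr.fit_truncated_mcmc(obs, onset=118.0, n_iter=20000, burn_in=15000, seed=2)
        lo, hi = post.ci("threshold")
        assert hi - lo < 7.0

    def test_empty_and_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pdr.fit_truncated_mcmc((np.array([]), np.array([])), n_iter=100, burn_in=50)
        with pytest.raises(IdentifiabilityError):
            pdr.fit_truncated_mcmc(
                (np.full(10, 150.0), np.arange(10.0)), n_iter=100, burn_in=50
            )


class TestCompareThresholds:
    def test_disjoint_cis_significant(self, design, params):
        obs_e = pdr.gen_needle_obs(design, params, treatments=("early",))
        obs_c = pdr.gen_needle_obs(design, params, treatments=("control",))
        pe = pdr.fit_truncated_mcmc(obs_e, onset=118.0, n_iter=12000, burn_in=8000, seed=21)
        pc = pdr.fit_truncated_mcmc(obs_c, onset=118.0, n_iter=12000, burn_in=8000, seed=22)
        cmp_ = pdr.compare_thresholds(pe, pc)
        assert cmp_.significant
        assert cmp_.diff_median == pytest.approx(183 - 205, abs=4)
        assert pdr.compare_thresholds(pe, pe).significant is False

    def test_refuses_unconverged_posterior(self, early_fit):
        import copy

        bad = copy.copy(early_fit)
        bad.converged = False
        bad.rhat = {**early_fit.rhat, "threshold": 1.5}
        with pytest.raises(ConvergenceError):
            pdr.compare_thresholds(bad, early_fit)


class TestSamplerVsOracle:
    def test_posterior_mode_within_one_grid_cell_of_mle(self, rng):
        doy = np.repeat(np.arange(123.0, 297.0, 7.0), 2)
        truth = TruncatedModelParams(0.8, 0.0, 185.0, 2.0)
        y = pdr.truncated_predict(truth, doy, onset=118.0) + rng.normal(0, 2, doy.size)
        grids = {
            "b1": np.arange(0.5, 1.11, 0.02),
            "b2": np.arange(0.0, 0.31, 0.02),
            "threshold": np.arange(160.0, 211.0, 1.0),
            "sigma": np.arange(1.0, 3.55, 0.25),
        }
        mle = pdr.grid_mle((doy, y), grids, onset=118.0)
        post = pdr.fit_truncated_mcmc((doy, y), onset=118.0, seed=31)
        cells = {"b1": 0.02, "b2": 0.02, "threshold": 1.0, "sigma": 0.25}
        for name, cell in cells.items():
            snapped = np.round(post.pooled(name) / cell) * cell
            vals, counts = np.unique(snapped, return_counts=True)
            mode = vals[np.argmax(counts)]
            assert abs(mode - getattr(mle, name)) <= cell + 1e-9, name
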