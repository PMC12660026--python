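import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, softmax

from tdcm.gibbs_engine import (
    PosteriorDraws,
    SamplerConfig,
    TDCMModel,
    alpha_conditional_probs,
    run_gibbs,
    sample_alpha_step,
    sample_gamma_step,
    sample_lambda_step,
)
from tdcm.model_core import (
    ItemParams,
    QMatrix,
    ResponseData,
    TrajectoryCodec,
    TransitionParams,
)
from tdcm.simulator import make_design, simulate_dataset

from conftest import constant_gamma, flat_lambda, make_intercept_only_model


class TestSamplerConfig:
    def test_defaults_valid(self):
        cfg = SamplerConfig()
        assert cfg.burn < cfg.M and cfg.m >= 1

    @pytest.mark.parametrize(
        "kwargs",
        [dict(M=10, burn=10), dict(M=10, burn=12), dict(m=0), dict(sigma_lambda=0.0), dict(sigma_gamma=-1.0)],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            SamplerConfig(**kwargs)


class TestAlphaStep:
    def test_flat_parameters_give_uniform_conditional(self):
        model = make_intercept_only_model(K=2, T=2, J=4, I=6)
        rng = np.random.default_rng(0)
        Y = rng.integers(0, 2, size=(6, 8))
        data = ResponseData(Y, J=4, T=2)
        lam = flat_lambda(model)
        gamma = TransitionParams.zeros(model.transition_design)
        alpha = np.zeros((6, 2), dtype=int)
        probs = alpha_conditional_probs(model, data, lam, alpha, 0, gamma)
        np.testing.assert_allclose(probs, 0.25, atol=1e-12)

    def test_extreme_items_pin_the_profile(self):
        model = make_intercept_only_model(K=1, T=2, J=4, I=1)
        lam = ItemParams([np.array([-10.0, 20.0]) for _ in range(4)], False)
        gamma = TransitionParams.zeros(model.transition_design)
        data = ResponseData(np.ones((1, 8), dtype=int), J=4, T=2)
        alpha = np.zeros((1, 2), dtype=int)
        probs = alpha_conditional_probs(model, data, lam, alpha, 0, gamma)
        assert probs[0, 1] > 0.999

    def test_brute_force_enumeration_oracle(self):
        """K=1, T=2, J=2: conditional must match exhaustive joint enumeration."""
        model = make_intercept_only_model(K=1, T=2, J=2, I=3)
        rng = np.random.default_rng(1)
        lam_values = [np.array([-1.2, 2.3]), np.array([-0.4, 1.1])]
        lam = ItemParams(lam_values, False)
        gamma = constant_gamma(model, {2: 0.7, 3: -0.9, 4: 0.3})
        Y = rng.integers(0, 2, size=(3, 4))
        data = ResponseData(Y, J=2, T=2)
        tcodec = TrajectoryCodec(2)
        g = np.array([0.0, 0.7, -0.9, 0.3])
        traj_prob = softmax(g)

        def item_p(a, j):
            return expit(lam_values[j][0] + lam_values[j][1] * a)

        alpha_fixed = np.array([[0, 1], [1, 0], [0, 0]])
        for t in (0, 1):
            probs = alpha_conditional_probs(model, data, lam, alpha_fixed, t, gamma)
            for i in range(3):
                weights = np.empty(2)
                for cand in (0, 1):
                    a = alpha_fixed[i].copy()
                    a[t] = cand
                    lik = 1.0
                    for tt in (0, 1):
                        for j in (0, 1):
                            p = item_p(a[tt], j)
                            y = Y[i, tt * 2 + j]
                            lik *= p if y else 1 - p
                    r = tcodec.to_type(a)
                    weights[cand] = lik * traj_prob[r - 1]
                np.testing.assert_allclose(probs[i], weights / weights.sum(), rtol=1e-10)

    def test_step_returns_valid_classes(self):
        model = make_intercept_only_model(K=2, T=3, J=4, I=20)
        rng = np.random.default_rng(3)
        data = ResponseData(rng.integers(0, 2, size=(20, 12)), J=4, T=3)
        lam = flat_lambda(model)
        gamma = TransitionParams.zeros(model.transition_design)
        alpha = sample_alpha_step(model, data, lam, gamma, np.zeros((20, 3), dtype=int), rng)
        assert alpha.shape == (20, 3)
        assert alpha.min() >= 0 and alpha.max() < 4


class TestLambdaStep:
    def _grid_posterior(self, n0, s0, n1, s1, sigma):
        """Exact 2-parameter Bayesian logistic posterior on a dense grid,
        main effect truncated positive."""
        b0 = np.linspace(-6, 4, 501)
        b1 = np.linspace(1e-6, 8, 400)
        B0, B1 = np.meshgrid(b0, b1, indexing="ij")
        ll = (
            s0 * B0 - n0 * np.logaddexp(0, B0)
            + s1 * (B0 + B1) - n1 * np.logaddexp(0, B0 + B1)
        )
        lp = -(B0 ** 2 + B1 ** 2) / (2 * sigma ** 2)
        w = np.exp(ll + lp - (ll + lp).max())
        w /= w.sum()
        return (w * B0).sum(), (w * B1).sum()

    def test_grid_integration_oracle(self):
        n0 = n1 = 200
        s0, s1 = 20, 180
        model = make_intercept_only_model(K=1, T=2, J=1, I=200)
        alpha = np.column_stack([np.zeros(200, dtype=int), np.ones(200, dtype=int)])
        Y = np.zeros((200, 2), dtype=int)
        Y[:s0, 0] = 1
        Y[:s1, 1] = 1
        data = ResponseData(Y, J=1, T=2)
        cfg = SamplerConfig(M=100, burn=10, sigma_lambda=2.0)
        rng = np.random.default_rng(12)
        lam = ItemParams([np.array([0.0, 1.0])], False)
        draws = []
        for it in range(4_000):
            lam = sample_lambda_step(model, data, alpha, cfg, lam, rng)
            if it >= 500:
                draws.append(lam.values[0].copy())
        draws = np.array(draws)
        gm0, gm1 = self._grid_posterior(n0, s0, n1, s1, cfg.sigma_lambda)
        assert draws[:, 0].mean() == pytest.approx(gm0, abs=0.15)
        assert draws[:, 1].mean() == pytest.approx(gm1, abs=0.15)
        assert draws[:, 1].min() > 0  # truncation respected

    def test_recovery_of_main_effect(self):
        model = make_intercept_only_model(K=1, T=2, J=5, I=800)
        rng = np.random.default_rng(9)
        true_lam = ItemParams([np.array([-1.0, 2.0]) for _ in range(5)], False)
        gamma = constant_gamma(model, {})
        alpha_true = rng.integers(0, 2, size=(800, 2))
        Y = np.empty((800, 10), dtype=int)
        for t in range(2):
            for j in range(5):
                p = expit(-1.0 + 2.0 * alpha_true[:, t])
                Y[:, t * 5 + j] = rng.random(800) < p
        data = ResponseData(Y, J=5, T=2)
        cfg = SamplerConfig(M=600, burn=200, seed=4)
        draws = run_gibbs(data, model, cfg)
        for j in range(5):
            main_mean = draws.lambda_draws[j][:, 1].mean()
            assert 1.6 < main_mean < 2.4
            assert draws.lambda_draws[j][:, 1].min() > 0

    def test_empty_class_is_skipped(self):
        # all respondents in class 0 at both times: class-1 direction is prior-driven
        model = make_intercept_only_model(K=1, T=2, J=1, I=50)
        alpha = np.zeros((50, 2), dtype=int)
        Y = np.zeros((50, 2), dtype=int)
        data = ResponseData(Y, J=1, T=2)
        cfg = SamplerConfig(M=100, burn=10, sigma_lambda=2.0)
        rng = np.random.default_rng(5)
        lam = ItemParams([np.array([0.0, 1.0])], False)
        mains = []
        for it in range(2_000):
            lam = sample_lambda_step(model, data, alpha, cfg, lam, rng)
            mains.append(lam.values[0][1])
        # prior is half-normal(2): mean ~ 2*sqrt(2/pi) ~ 1.6
        assert np.mean(mains) == pytest.approx(2.0 * math.sqrt(2 / math.pi), abs=0.2)


def _alpha_from_type_counts(counts, T=2):
    """Stack respondents whose K=1 trajectories realize the given type counts."""
    tcodec = TrajectoryCodec(T)
    rows = []
    for r, n in enumerate(counts, start=1):
        bits = tcodec.from_type(r)
        rows += [bits] * n
    return np.array(rows, dtype=int)


class TestGammaStep:
    def _run(self, model, alpha, n_iter, burn, seed, m=1, sigma=2.0):
        cfg = SamplerConfig(M=100, burn=10, m=m, sigma_gamma=sigma)
        rng = np.random.default_rng(seed)
        gamma = TransitionParams.zeros(model.transition_design)
        kept = []
        for it in range(n_iter):
            gamma = sample_gamma_step(model, alpha, gamma, cfg, rng)
            if it >= burn:
                kept.append({key: v.copy() for key, v in gamma.gamma.items()})
        return kept

    def test_symmetric_counts_center_at_zero(self):
        alpha = _alpha_from_type_counts([100, 100, 100, 100])
        model = make_intercept_only_model(K=1, T=2, J=1, I=400)
        kept = self._run(model, alpha, 1_500, 300, seed=21)
        for r in (2, 3, 4):
            mean = np.mean([g[(0, r)][0] for g in kept])
            assert abs(mean) < 0.15

    def test_type_probabilities_match_empirical_proportions(self):
        counts = [300, 100, 50, 350]
        alpha = _alpha_from_type_counts(counts)
        model = make_intercept_only_model(K=1, T=2, J=1, I=800)
        kept = self._run(model, alpha, 2_000, 400, seed=22)
        probs = np.mean(
            [softmax([0.0, g[(0, 2)][0], g[(0, 3)][0], g[(0, 4)][0]]) for g in kept], axis=0
        )
        np.testing.assert_allclose(probs, np.array(counts) / 800.0, atol=0.03)

    def test_baseline_never_updated(self):
        alpha = _alpha_from_type_counts([10, 10, 10, 10])
        model = make_intercept_only_model(K=1, T=2, J=1, I=40)
        kept = self._run(model, alpha, 50, 0, seed=23)
        assert all((0, 1) not in g for g in kept)


class TestRunGibbs:
    def _small_setup(self, seed=0, I=40):
        design = make_design(1, seed=seed, I=I, J=6, K=2)
        data, alpha_true, X, model = simulate_dataset(design, np.random.default_rng(seed))
        return design, data, model

    def test_seed_replay_bit_identical(self):
        _, data, model = self._small_setup()
        cfg = SamplerConfig(M=40, burn=10, seed=77)
        a = run_gibbs(data, model, cfg)
        b = run_gibbs(data, model, cfg)
        for j in range(model.dims.J):
            np.testing.assert_array_equal(a.lambda_draws[j], b.lambda_draws[j])
        for key in a.gamma_draws:
            np.testing.assert_array_equal(a.gamma_draws[key], b.gamma_draws[key])
        np.testing.assert_array_equal(a.alpha_draws, b.alpha_draws)

    def test_draw_count_and_truncation(self):
        _, data, model = self._small_setup()
        cfg = SamplerConfig(M=50, burn=20, seed=3)
        draws = run_gibbs(data, model, cfg)
        assert draws.n_draws == 30
        for j, dj in enumerate(model.item_designs):
            mains = dj.lower_bounds == 0.0
            assert (draws.lambda_draws[j][:, mains] > 0).all()

    def test_dimension_mismatch_raises(self):
        _, data, model = self._small_setup()
        other = make_intercept_only_model(K=2, T=2, J=6, I=data.I + 1)
        with pytest.raises(ValueError, match="respondents"):
            run_gibbs(data, other, SamplerConfig(M=10, burn=1))

    def test_null_fit_on_coin_flips(self):
        """Pure-noise responses: spurious latent separation stays weak.

        Class labels are only weakly identified on noise, so the honest
        checks are that main effects stay far below what real structure
        yields and that posterior-predictive cell probabilities stay at the
        coin-flip rate.
        """
        from tdcm.diagnostics import predicted_cell_probs

        model = make_intercept_only_model(K=1, T=2, J=8, I=400)
        rng = np.random.default_rng(8)
        data = ResponseData(rng.integers(0, 2, size=(400, 16)), J=8, T=2)
        draws = run_gibbs(data, model, SamplerConfig(M=700, burn=300, seed=15))
        for j in range(8):
            assert draws.lambda_draws[j][:, 1].mean() < 1.5  # vs ~2-3 with signal
        probs = predicted_cell_probs(draws, n_rep=100)
        np.testing.assert_allclose(probs.mean(axis=0), 0.5, atol=0.06)

    def test_stationarity_under_true_init(self):
        design, data, model = self._small_setup(seed=5, I=250)
        cfg_rand = SamplerConfig(M=3000, burn=1000, seed=31)
        draws_rand = run_gibbs(data, model, cfg_rand)
        _, alpha_true, X, _ = simulate_dataset(design, np.random.default_rng(5))
        init = (alpha_true, design.true_lambda, design.true_gamma)
        draws_true = run_gibbs(data, model, SamplerConfig(M=3000, burn=1000, seed=32), init=init)
        for key in draws_rand.gamma_draws:
            a = draws_rand.gamma_draws[key][:, 0]
            b = draws_true.gamma_draws[key][:, 0]
            pooled_sd = max(a.std(), b.std())
            # gamma intercepts autocorrelate; allow half a posterior sd of MC slack
            assert abs(a.mean() - b.mean()) < max(0.15, 0.5 * pooled_sd)

    def test_type_probabilities_conserved_per_draw(self):
        _, data, model = self._small_setup()
        draws = run_gibbs(data, model, SamplerConfig(M=30, burn=10, seed=2))
        for d in range(draws.n_draws):
            for k in range(model.dims.K):
                eta = np.zeros(model.dims.R)
                for r in range(2, model.dims.R + 1):
                    eta[r - 1] = draws.gamma_draws[(k, r)][d, 0]
                assert softmax(eta).sum() == pytest.approx(1.0, abs=1e-12)


class TestPermutationEquivariance:
    def test_conditional_probs_permute_with_attributes(self):
        rng = np.random.default_rng(17)
        Q = QMatrix([[1, 0], [0, 1], [1, 0], [0, 1]])
        Qp = QMatrix([[1, 0], [0, 1], [1, 0], [0, 1]])  # same after item swap
        I = 12
        model = TDCMModel.build(Q, T=2, n_respondents=I)
        Y = rng.integers(0, 2, size=(I, 8))
        data = ResponseData(Y, J=4, T=2)
        lam_vals = [rng.normal(size=2) for _ in range(4)]
        for v in lam_vals:
            v[1] = abs(v[1])
        lam = ItemParams([v.copy() for v in lam_vals], False)
        gamma = TransitionParams.zeros(model.transition_design)
        for (k, r) in gamma.gamma:
            gamma.gamma[(k, r)][0] = rng.normal()
        alpha = rng.integers(0, 4, size=(I, 2))

        # permuted problem: swap attributes <-> swap items (0<->1, 2<->3)
        perm_items = [1, 0, 3, 2]
        Yp = np.concatenate([Y[:, :4][:, perm_items], Y[:, 4:][:, perm_items]], axis=1)
        datap = ResponseData(Yp, J=4, T=2)
        modelp = TDCMModel.build(Qp, T=2, n_respondents=I)
        lamp = ItemParams([lam_vals[i].copy() for i in perm_items], False)
        gammap = TransitionParams.zeros(modelp.transition_design)
        for (k, r) in gammap.gamma:
            gammap.gamma[(k, r)][0] = gamma.gamma[(1 - k, r)][0]
        # class relabeling: swap the two attribute bits
        codec = model.pcodec
        cmap = np.array([codec.encode(codec.decode(c)[::-1]) for c in range(4)])
        alphap = cmap[alpha]

        p = alpha_conditional_probs(model, data, lam, alpha, 0, gamma)
        pp = alpha_conditional_probs(modelp, datap, lamp, alphap, 0, gammap)
        np.testing.assert_allclose(pp[:, cmap], p, rtol=1e-10)


class TestPosteriorDrawsExport:
    def test_summary_and_csv(self, tmp_path):
        design = make_design(1, seed=1, I=30, J=4, K=2)
        data, _, X, model = simulate_dataset(design, np.random.default_rng(1))
        draws = run_gibbs(data, model, SamplerConfig(M=30, burn=10, seed=1))
        summ = draws.summary()
        assert {"mean", "std", "q2.5", "q97.5"} <= set(summ.columns)
        n_lambda = sum(dj.n_params for dj in model.item_designs)
        n_gamma = sum(len(v) for v in draws.gamma_draws.values()) // draws.n_draws * 0 + sum(
            draws.gamma_draws[key].shape[1] for key in draws.gamma_draws
        )
        assert len(summ) == n_lambda + n_gamma
        draws.to_csv(tmp_path / "draws.csv")
        back = pd.read_csv(tmp_path / "draws.csv")
        assert set(back.columns) == {"iteration", "parameter", "value"}
        assert back["parameter"].nunique() == len(summ)
        draws.to_json_summary(tmp_path / "s.json")
        assert (tmp_path / "s.json").stat().st_size > 0
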