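"""DP-SGD mechanics and variational-inference correctness."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import betaln, digamma, polygamma

from dprelease.accounting import PrivacyBudget
from dprelease.dpvi import (
    TrainingConfig,
    _DataIndex,
    _batch_loglik_grad,
    clip_per_example,
    elbo_estimate,
    fit_dpvi,
    privatized_gradient,
)
from dprelease.model_spec import FeatureSpec, build_model, mixture_log_density
from dprelease.variational import ParamLayout, VariationalPosterior


class TestClipping:
    def test_rescales_long_gradient(self):
        np.testing.assert_allclose(clip_per_example(np.array([3.0, 4.0]), 1.0), [0.6, 0.8])

    def test_leaves_short_gradient_unchanged(self):
        np.testing.assert_allclose(clip_per_example(np.array([3.0, 4.0]), 10.0), [3.0, 4.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 50.0))
    def test_norm_bounded_with_equality_iff_clipped(self, seed, C):
        g = np.random.default_rng(seed).normal(scale=3.0, size=8)
        out = clip_per_example(g, C)
        norm_in, norm_out = np.linalg.norm(g), np.linalg.norm(out)
        assert norm_out <= C * (1 + 1e-12)
        if norm_in >= C:
            assert norm_out == pytest.approx(C)
        else:
            np.testing.assert_array_equal(out, g)


class TestPrivatizedGradient:
    def test_zero_noise_gives_exact_clipped_sum(self):
        grads = [np.array([3.0, 4.0]), np.array([0.3, 0.4])]
        out = privatized_gradient(grads, 1.0, 0.0, np.random.default_rng(0))
        np.testing.assert_allclose(out, [0.9, 1.2])

    def test_single_short_gradient_passes_through(self):
        g = np.array([0.1, -0.2, 0.05])
        out = privatized_gradient([g], 1.0, 0.0, np.random.default_rng(0))
        np.testing.assert_allclose(out, g)

    def test_noise_law_matches_two_c_sigma(self):
        g = [np.array([1.0, 0.0])]
        C, sigma, reps = 1.0, 0.5, 10_000
        rng = np.random.default_rng(42)
        draws = np.array([privatized_gradient(g, C, sigma, rng) for _ in range(reps)])
        se = 2 * C * sigma / math.sqrt(reps)
        np.testing.assert_allclose(draws.mean(axis=0), [1.0, 0.0], atol=4 * se)
        assert draws.std(axis=0)[0] == pytest.approx(2 * C * sigma, rel=0.05)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            privatized_gradient([], 1.0, 0.0, np.random.default_rng(0))


@pytest.fixture(scope="module")
def mixed_model_and_data():
    schema = [
        FeatureSpec("s", "binary"),
        FeatureSpec("c", "categorical", ("x", "y", "z")),
        FeatureSpec("u", "continuous", (0.0, 1.0)),
        FeatureSpec("b", "binary"),
    ]
    model = build_model({"strata": ["s"], "K": 3}, schema)
    rng = np.random.default_rng(5)
    n = 60
    data = pd.DataFrame({
        "s": rng.integers(0, 2, n),
        "c": rng.choice(["x", "y", "z"], n),
        "u": rng.uniform(0.05, 0.95, n),
        "b": rng.integers(0, 2, n),
    })
    return model, data


def test_likelihood_gradient_matches_finite_difference(mixed_model_and_data):
    """The analytic per-example score equals numerical ELBO derivatives."""
    model, data = mixed_model_and_data
    layout = ParamLayout(model)
    index = _DataIndex(model, data)
    rng = np.random.default_rng(0)
    u = rng.normal(scale=0.8, size=layout.size)
    batch = np.arange(len(data))
    lp, G = _batch_loglik_grad(layout, index, u, batch)
    gsum = G.sum(axis=0)
    eps = 1e-6
    for i in rng.choice(layout.size, size=min(30, layout.size), replace=False):
        up, um = u.copy(), u.copy()
        up[i] += eps
        um[i] -= eps
        f1, _ = _batch_loglik_grad(layout, index, up, batch, want_grad=False)
        f0, _ = _batch_loglik_grad(layout, index, um, batch, want_grad=False)
        fd = (f1.sum() - f0.sum()) / (2 * eps)
        assert gsum[i] == pytest.approx(fd, rel=1e-4, abs=1e-7)


def test_likelihood_value_matches_model_density(mixed_model_and_data):
    """Engine log-likelihoods agree with the reference density evaluator."""
    model, data = mixed_model_and_data
    layout = ParamLayout(model)
    index = _DataIndex(model, data)
    u = np.random.default_rng(1).normal(size=layout.size)
    lp, _ = _batch_loglik_grad(layout, index, u, np.arange(len(data)), want_grad=False)
    params = layout.constrain(u)
    # compare on unit-scaled continuous values, as the engine sees them
    scaled = data.copy()
    from dprelease.model_spec import unit_scale

    scaled["u"] = unit_scale(data["u"], 0.0, 1.0)
    expected = model.log_density(scaled, params)
    np.testing.assert_allclose(lp, expected, rtol=1e-10)


class TestElboEstimate:
    def test_converges_to_conjugate_log_evidence(self):
        # one Bernoulli feature: the exact posterior is Beta(s+1, n-s+1) and
        # the log evidence is log B(s+1, n-s+1); with a moment-matched
        # logit-normal q the ELBO must come within a whisker from below.
        n, s = 200, 61
        model = build_model({"K": 1}, [FeatureSpec("y", "binary")])
        layout = ParamLayout(model)
        data = pd.DataFrame({"y": np.r_[np.ones(s, int), np.zeros(n - s, int)]})
        a, b = s + 1.0, n - s + 1.0
        loc = np.array([digamma(a) - digamma(b)])
        log_scale = 0.5 * np.log(np.array([polygamma(1, a) + polygamma(1, b)]))
        post = VariationalPosterior(layout, loc, log_scale)
        elbo = elbo_estimate(post, data, model, n, mc_samples=8000, rng=3)
        log_z = betaln(a, b)
        assert elbo == pytest.approx(log_z, abs=0.05)
        assert elbo <= log_z + 0.02  # lower bound, modulo Monte-Carlo error

    def test_more_samples_reduce_variance(self):
        n, s = 50, 20
        model = build_model({"K": 1}, [FeatureSpec("y", "binary")])
        layout = ParamLayout(model)
        data = pd.DataFrame({"y": np.r_[np.ones(s, int), np.zeros(n - s, int)]})
        post = VariationalPosterior(layout, np.zeros(1), np.zeros(1))

        def spread(mc):
            return np.std([
                elbo_estimate(post, data, model, n, mc_samples=mc, rng=seed)
                for seed in range(40)
            ])

        assert spread(8) < spread(1)

    def test_batch_larger_than_population_rejected(self):
        model = build_model({"K": 1}, [FeatureSpec("y", "binary")])
        layout = ParamLayout(model)
        post = VariationalPosterior(layout, np.zeros(1), np.zeros(1))
        data = pd.DataFrame({"y": [0, 1, 1]})
        with pytest.raises(ValueError):
            elbo_estimate(post, data, model, n_total=2)


class TestFitDpvi:
    def test_same_seed_is_bitwise_reproducible(self):
        rng = np.random.default_rng(8)
        data = pd.DataFrame({"y": rng.integers(0, 2, 500)})
        model = build_model({"K": 2}, [FeatureSpec("y", "binary")])
        tc = TrainingConfig(num_steps=80, seed=4)
        p1, _ = fit_dpvi(model, data, PrivacyBudget(1.0, 1e-5), tc)
        p2, _ = fit_dpvi(model, data, PrivacyBudget(1.0, 1e-5), tc)
        np.testing.assert_array_equal(p1.loc, p2.loc)
        np.testing.assert_array_equal(p1.log_scale, p2.log_scale)

    def test_inactive_clipping_equals_unclipped_path(self):
        # with sigma = 0 and a clip bound far above every per-example norm,
        # the DP mechanism is a no-op and the trajectory matches clip = inf
        rng = np.random.default_rng(9)
        data = pd.DataFrame({"y": rng.integers(0, 2, 400)})
        model = build_model({"K": 1}, [FeatureSpec("y", "binary")])
        common = dict(num_steps=60, seed=7, noise_multiplier=0.0, sampling_rate=1.0)
        p1, _ = fit_dpvi(model, data, PrivacyBudget(math.inf, 1e-6),
                         TrainingConfig(clip_norm=1e9, **common))
        p2, _ = fit_dpvi(model, data, PrivacyBudget(math.inf, 1e-6),
                         TrainingConfig(clip_norm=math.inf, **common))
        np.testing.assert_allclose(p1.loc, p2.loc, atol=1e-10)

    def test_recovers_bernoulli_success_fraction(self):
        rng = np.random.default_rng(10)
        f = 0.37
        data = pd.DataFrame({"y": (rng.random(10_000) < f).astype(int)})
        model = build_model({"K": 1}, [FeatureSpec("y", "binary")])
        post, _ = fit_dpvi(
            model, data, PrivacyBudget(math.inf, 1e-6),
            TrainingConfig(noise_multiplier=0.0, clip_norm=1e6, num_steps=600, seed=2),
        )
        p_hat = post.mean_params().mixtures[()].comps["y"][0]
        assert p_hat == pytest.approx(data["y"].mean(), abs=0.02)

    def test_elbo_trend_is_upward_on_toy_problem(self):
        rng = np.random.default_rng(11)
        data = pd.DataFrame({
            "a": rng.integers(0, 2, 2000),
            "b": (rng.random(2000) < 0.8).astype(int),
        })
        model = build_model({"K": 2}, [FeatureSpec("a", "binary"), FeatureSpec("b", "binary")])
        post, _ = fit_dpvi(
            model, data, PrivacyBudget(math.inf, 1e-6),
            TrainingConfig(noise_multiplier=0.0, sampling_rate=1.0, num_steps=400,
                           seed=3, track_every=10),
        )
        elbos = [e for _, e in post.elbo_trace]
        early, late = np.mean(elbos[:4]), np.mean(elbos[-4:])
        assert late > early

    def test_label_permutation_leaves_likelihood_unchanged(self):
        rng = np.random.default_rng(12)
        data = pd.DataFrame({
            "a": rng.integers(0, 2, 1500),
            "b": rng.integers(0, 2, 1500),
        })
        model = build_model({"K": 2}, [FeatureSpec("a", "binary"), FeatureSpec("b", "binary")])
        post, _ = fit_dpvi(
            model, data, PrivacyBudget(math.inf, 1e-6),
            TrainingConfig(noise_multiplier=0.0, num_steps=300, seed=5),
        )
        params = post.mean_params().mixtures[()]
        from dprelease.model_spec import MixtureParams

        permuted = MixtureParams(
            weights=params.weights[::-1].copy(),
            comps={k: v[::-1].copy() for k, v in params.comps.items()},
        )
        specs = model.features_for_cell(())
        ll = mixture_log_density(data, params, specs).sum()
        ll_perm = mixture_log_density(data, permuted, specs).sum()
        assert abs(ll - ll_perm) / len(data) < 1e-3

    def test_calibrated_run_respects_budget(self):
        rng = np.random.default_rng(13)
        data = pd.DataFrame({"y": rng.integers(0, 2, 3000)})
        model = build_model({"K": 1}, [FeatureSpec("y", "binary")])
        budget = PrivacyBudget(1.0, 1e-6)
        post, ledger = fit_dpvi(model, data, budget, TrainingConfig(num_steps=200, seed=1))
        assert ledger.composed_epsilon(budget.delta) <= 1.0
        assert len(ledger.entries) == 1
        assert ledger.entries[0].count == 200

    def test_nonprivate_run_has_empty_ledger(self):
        data = pd.DataFrame({"y": [0, 1] * 200})
        model = build_model({"K": 1}, [FeatureSpec("y", "binary")])
        _, ledger = fit_dpvi(model, data, PrivacyBudget(math.inf, 1e-6),
                             TrainingConfig(num_steps=20, seed=1))
        assert ledger.entries == []
        assert ledger.composed_epsilon(1e-6) == 0.0
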