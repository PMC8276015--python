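"""Utility metrics: Frobenius distance, rate regressions, discovery flags."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dprelease.evaluation import (
    RegressionReport,
    bootstrap_reproducibility,
    discovery_reproduced,
    fit_poisson_rates,
    frobenius_distance,
    prevalence_binned_mae,
)


class TestFrobeniusDistance:
    def test_identical_matrices_have_zero_distance(self):
        A = np.arange(9.0).reshape(3, 3)
        assert frobenius_distance(A, A) == 0.0

    def test_identity_difference(self):
        A = np.eye(2) * 2
        B = np.eye(2)
        assert frobenius_distance(A, B) == pytest.approx(math.sqrt(2))

    def test_hand_computed_value(self):
        B = np.zeros((2, 2))
        A = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert frobenius_distance(A, B) == pytest.approx(math.sqrt(30), rel=1e-12)
        assert frobenius_distance(A, B) == pytest.approx(5.4772, abs=1e-4)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            frobenius_distance(np.zeros((2, 2)), np.zeros((3, 3)))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        A, B, C = rng.normal(size=(3, 4, 4))
        assert frobenius_distance(A, C) <= (
            frobenius_distance(A, B) + frobenius_distance(B, C) + 1e-9
        )


def _simulate_poisson(n, rates, rng, max_time=10.0):
    group = rng.integers(0, len(rates), n)
    t = rng.uniform(1.0, max_time, n)
    y = rng.poisson(np.asarray(rates)[group] * t)
    df = pd.DataFrame({"time": t, "events": y})
    for g in range(1, len(rates)):
        df[f"g{g}"] = (group == g).astype(int)
    return df


class TestFitPoissonRates:
    def test_null_simulation_keeps_coefficients_near_zero(self):
        # all groups share one rate: each term within 3 SE of 0 in >=99%
        # of seeded refits (joint per-term tally over 200 runs)
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            df = _simulate_poisson(2000, [0.05, 0.05, 0.05], rng)
            rep = fit_poisson_rates(df, "events", ["g1", "g2"], "time")
            ok = all(
                abs(rep.coefficients[rep.term(t)]) < 3 * rep.standard_errors[rep.term(t)]
                for t in ("g1", "g2")
            )
            hits += ok
        # joint coverage of two 3-SE intervals is ~99.4%; 0.97 is 3 binomial
        # standard errors below that
        assert hits / 200 >= 0.97

    def test_recovers_known_rate_ratio(self):
        rng = np.random.default_rng(7)
        df = _simulate_poisson(50_000, [0.05, 0.10], rng)
        rep = fit_poisson_rates(df, "events", ["g1"], "time")
        i = rep.term("g1")
        assert abs(rep.coefficients[i] - math.log(2)) < 3 * rep.standard_errors[i]

    def test_offset_scaling_leaves_rate_coefficients_unchanged(self):
        rng = np.random.default_rng(8)
        df = _simulate_poisson(5000, [0.1, 0.25], rng)
        rep1 = fit_poisson_rates(df, "events", ["g1"], "time")
        df2 = df.assign(time=df["time"] * 2)
        rep2 = fit_poisson_rates(df2, "events", ["g1"], "time")
        assert rep2.coefficients[rep2.term("g1")] == pytest.approx(
            rep1.coefficients[rep1.term("g1")]
        )
        assert rep2.coefficients[rep2.term("const")] == pytest.approx(
            rep1.coefficients[rep1.term("const")] - math.log(2)
        )

    def test_case_counts_count_exposed_records_with_events(self):
        df = pd.DataFrame({
            "y": [1, 0, 2, 0], "t": [1.0, 1.0, 1.0, 1.0], "x": [1, 1, 0, 0],
        })
        rep = fit_poisson_rates(df, "y", ["x"], "t")
        assert rep.case_counts[rep.term("x")] == 1
        assert rep.case_counts[rep.term("const")] == 2

    def test_invalid_inputs_rejected(self):
        df = pd.DataFrame({"y": [1.5], "t": [1.0], "x": [1]})
        with pytest.raises(ValueError):
            fit_poisson_rates(df, "y", ["x"], "t")
        df2 = pd.DataFrame({"y": [1], "t": [0.0], "x": [1]})
        with pytest.raises(ValueError):
            fit_poisson_rates(df2, "y", ["x"], "t")


class TestDiscoveryReproduced:
    def _report(self, coefs, ps):
        k = len(coefs)
        return RegressionReport(
            terms=[f"t{i}" for i in range(k)],
            coefficients=coefs,
            standard_errors=np.ones(k),
            p_values=ps,
            case_counts=np.ones(k),
        )

    def test_all_positive_and_significant(self):
        rep = self._report([0.5, 1.0, 0.2], [0.01, 0.03, 0.001])
        flags, combined = discovery_reproduced(rep, ["t0", "t1", "t2"])
        assert combined and all(flags.values())

    def test_one_insignificant_term_fails_combined(self):
        rep = self._report([0.5, 1.0], [0.01, 0.2])
        _, combined = discovery_reproduced(rep, ["t0", "t1"])
        assert not combined

    def test_wrong_sign_fails_despite_significance(self):
        rep = self._report([-0.5], [0.001])
        flags, combined = discovery_reproduced(rep, ["t0"])
        assert not flags["t0"] and not combined

    def test_missing_term_rejected(self):
        rep = self._report([0.5], [0.01])
        with pytest.raises(KeyError):
            discovery_reproduced(rep, ["nope"])


class TestPrevalenceBinnedMae:
    def _pair(self, counts, orig, synth):
        k = len(counts)
        terms = [f"t{i}" for i in range(k)]
        mk = lambda c: RegressionReport(terms, c, np.ones(k), np.full(k, 0.5), counts)
        return mk(orig), mk(synth)

    def test_identical_reports_give_zero_everywhere(self):
        o, s = self._pair(np.arange(8.0) + 1, np.ones(8), np.ones(8))
        maes, _, _ = prevalence_binned_mae(o, s)
        assert maes == [0.0] * 4

    def test_constant_error_appears_in_every_bin(self):
        o, s = self._pair(np.arange(8.0) + 1, np.ones(8), np.ones(8) + 0.1)
        maes, _, _ = prevalence_binned_mae(o, s)
        np.testing.assert_allclose(maes, 0.1)

    def test_matches_hand_enumerated_binning(self):
        counts = np.array([40.0, 5.0, 100.0, 20.0, 7.0, 60.0, 300.0, 15.0])
        errs = np.array([0.1, 0.8, 0.05, 0.3, 0.7, 0.08, 0.02, 0.4])
        o, s = self._pair(counts, np.zeros(8), errs)
        maes, bin_counts, inv_ref = prevalence_binned_mae(o, s)
        # sorted by count: t1(5), t4(7), t7(15), t3(20), t0(40), t5(60), t2(100), t6(300)
        np.testing.assert_allclose(
            maes,
            [np.mean([0.8, 0.7]), np.mean([0.4, 0.3]),
             np.mean([0.1, 0.08]), np.mean([0.05, 0.02])],
        )
        np.testing.assert_allclose(inv_ref[0], np.mean([1 / 5, 1 / 7]))

    def test_remainder_goes_to_last_bin(self):
        counts = np.arange(6.0) + 1
        o, s = self._pair(counts, np.zeros(6), np.zeros(6))
        _, bin_counts, _ = prevalence_binned_mae(o, s)
        assert [len(b) for b in bin_counts] == [1, 1, 1, 3]

    def test_mismatched_terms_rejected(self):
        o, _ = self._pair(np.arange(4.0) + 1, np.zeros(4), np.zeros(4))
        s = RegressionReport(["other"], [0.0], [1.0], [0.5], [1.0])
        with pytest.raises(ValueError):
            prevalence_binned_mae(o, s)


class TestBootstrapReproducibility:
    def test_overwhelming_effect_reproduces_almost_always(self):
        rng = np.random.default_rng(1)
        df = _simulate_poisson(20_000, [0.05, 0.25], rng)  # rate ratio 5
        rate = bootstrap_reproducibility(df, "events", ["g1"], "time", ["g1"],
                                         B=100, seed=0)
        assert rate >= 0.99

    def test_null_effect_rarely_reproduces(self):
        rng = np.random.default_rng(2)
        df = _simulate_poisson(5000, [0.1, 0.1], rng)
        rate = bootstrap_reproducibility(df, "events", ["g1"], "time", ["g1"],
                                         B=200, seed=0)
        se = math.sqrt(0.05 * 0.95 / 200)
        assert rate <= 0.05 + 3 * se

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        df = _simulate_poisson(500, [0.1, 0.15], rng)
        r1 = bootstrap_reproducibility(df, "events", ["g1"], "time", ["g1"], B=1, seed=9)
        r2 = bootstrap_reproducibility(df, "events", ["g1"], "time", ["g1"], B=1, seed=9)
        assert r1 == r2
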