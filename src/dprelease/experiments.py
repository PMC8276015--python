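"""Reproduction studies: end-to-end experiments on the synthetic fixtures.

These functions tie the pipeline together — generate a fixture cohort, fit
the release model under a privacy budget, sample a synthetic replica, rerun
the downstream analysis — and return the quantities the package's validation
is judged on: discovery-reproduction rates by epsilon and model variant,
prevalence-binned coefficient error, the tailored-mechanism crossover, and
the small closed-form calibration checks.

Problem sizes are scaled so a full study (20 repeats, three privacy levels,
two model variants) runs on one CPU in minutes; every function is a pure
function of its seed.
"""

from __future__ import annotations

import math

import numpy as np

from . import datasets
from .accounting import PrivacyBudget
from .baselines import dp_second_moment, second_moment_matrix, split_budget
from .cli_io import split_seed
from .dpvi import TrainingConfig, fit_dpvi
from .evaluation import (
    RegressionReport,
    discovery_reproduced,
    fit_poisson_rates,
    frobenius_distance,
    prevalence_binned_mae,
)
from .model_spec import FeatureSpec, MixtureParams, StratifiedParams, build_model
from .sampling import generate_synthetic

__all__ = [
    "ard_regression",
    "combined_sex_report",
    "ard_discovery_experiment",
    "carat_crossover_experiment",
    "weight_recovery_experiment",
    "structural_zero_check",
    "conjugate_ppd_check",
]

TREATMENT_TERMS = ["oad", "insulin", "oad_insulin"]


def ard_regression(records, sex: int) -> RegressionReport:
    """The cohort's rate analysis: ARD counts vs treatment, one sex stratum."""
    sub = records[records["sex"] == sex].copy()
    for term in TREATMENT_TERMS:
        sub[term] = (sub["treatment"] == term).astype(int)
    sub = sub[sub["duration"] > 0]
    return fit_poisson_rates(sub, "ard", TREATMENT_TERMS, "duration")


def combined_sex_report(male: RegressionReport, female: RegressionReport) -> RegressionReport:
    """Merge per-sex regressions into one report with sex-prefixed terms."""
    terms, coefs, ses, ps, cases = [], [], [], [], []
    for prefix, rep in (("male", male), ("female", female)):
        for t in TREATMENT_TERMS:
            i = rep.term(t)
            terms.append(f"{prefix}:{t}")
            coefs.append(rep.coefficients[i])
            ses.append(rep.standard_errors[i])
            ps.append(rep.p_values[i])
            cases.append(rep.case_counts[i])
    return RegressionReport(terms, coefs, ses, ps, cases,
                            converged=male.converged and female.converged)


def ard_discovery_experiment(
    seed: int = 0,
    n_repeats: int = 20,
    epsilons=(1.0, 2.0, 4.0),
    delta: float = 1e-6,
    config: datasets.ArdLikeConfig | None = None,
    training: TrainingConfig | None = None,
) -> dict:
    """Discovery reproduction vs privacy level and model variant.

    For each repeat: simulate the cohort, fit the stratified model at every
    epsilon and the unstratified model at the strictest epsilon, sample a
    same-size synthetic replica, and rerun the male-stratum rate analysis.
    Reports mean reproduction rates, the original-data reproduction rate,
    and (from the stratified runs) the prevalence-binned MAE of all six
    male+female coefficients with the mean-inverse-case-count reference.
    """
    config = config or datasets.ArdLikeConfig()
    schema = datasets.ard_schema(config)
    base_training = training or TrainingConfig()
    variants = [("stratified", e) for e in epsilons] + [("unstratified", min(epsilons))]
    hits = {v: [] for v in variants}
    original_hits = []
    maes = {e: [] for e in epsilons}
    refs, counts_lowest = [], []

    for r in range(n_repeats):
        data_seed = split_seed(seed, f"ard-data-{r}")
        records, _ = datasets.generate_ard_like(config, seed=data_seed)
        rep_o = {s: ard_regression(records, s) for s in (0, 1)}
        original_hits.append(discovery_reproduced(rep_o[0], TREATMENT_TERMS)[1])
        for variant, eps in variants:
            model = build_model(
                datasets.ard_model_config(config, stratified=(variant == "stratified")),
                schema,
            )
            tc = TrainingConfig(**{
                **base_training.__dict__,
                "seed": split_seed(seed, f"ard-fit-{variant}-{eps}-{r}"),
            })
            post, _ = fit_dpvi(model, records, PrivacyBudget(eps, delta), tc)
            synth = generate_synthetic(
                post, model, len(records),
                rng=np.random.default_rng(split_seed(seed, f"ard-sample-{variant}-{eps}-{r}")),
            ).records
            rep_s = {s: ard_regression(synth, s) for s in (0, 1)}
            hits[(variant, eps)].append(
                discovery_reproduced(rep_s[0], TREATMENT_TERMS)[1]
            )
            if variant == "stratified":
                orig_c = combined_sex_report(rep_o[0], rep_o[1])
                syn_c = combined_sex_report(rep_s[0], rep_s[1])
                if np.all(np.isfinite(syn_c.coefficients)):
                    mae, counts, inv_ref = prevalence_binned_mae(orig_c, syn_c)
                    maes[eps].append(mae)
                    if eps == min(epsilons):
                        refs.append(inv_ref)
                        counts_lowest.append([np.mean(c) for c in counts])

    return {
        "rates": {
            "stratified": {e: float(np.mean(hits[("stratified", e)])) for e in epsilons},
            "unstratified": {min(epsilons): float(np.mean(hits[("unstratified", min(epsilons))]))},
        },
        "original_rate": float(np.mean(original_hits)),
        "binned_mae": {e: list(np.mean(maes[e], axis=0)) if maes[e] else [] for e in epsilons},
        "inverse_n_reference": list(np.mean(refs, axis=0)) if refs else [],
        "mean_bin_cases": list(np.mean(counts_lowest, axis=0)) if counts_lowest else [],
        "n_repeats": n_repeats,
    }


def carat_crossover_experiment(
    seed: int = 0,
    T_list=(1, 10, 100),
    epsilon: float = 1.0,
    delta: float = 1e-5,
    config: datasets.CaratLikeConfig | None = None,
    n_noise_draws: int = 5,
    training: TrainingConfig | None = None,
) -> dict:
    """Tailored covariance release vs synthetic-data covariance.

    The tailored mechanism splits the budget over T anticipated queries, so
    its Frobenius error grows with T; the synthetic-data error is paid once
    and is T-independent.  Returns both error curves and the smallest T at
    which the synthetic data win.
    """
    config = config or datasets.CaratLikeConfig(n=10_000, d=32, n_blocks=4)
    records = datasets.generate_carat_like(config, seed=split_seed(seed, "carat-data"))
    X = records.to_numpy(dtype=float)
    M = second_moment_matrix(X)
    budget = PrivacyBudget(epsilon, delta)
    rng = np.random.default_rng(split_seed(seed, "carat-noise"))

    tailored = {}
    for T in T_list:
        plan = split_budget(budget, T)
        errs = [
            frobenius_distance(M, dp_second_moment(X, plan.per_query, rng))
            for _ in range(n_noise_draws)
        ]
        tailored[T] = float(np.mean(errs))

    schema = [FeatureSpec(c, "binary") for c in records.columns]
    model = build_model({}, schema)  # K defaults to 20 at d >= 20
    tc = training or TrainingConfig()
    tc = TrainingConfig(**{**tc.__dict__, "seed": split_seed(seed, "carat-fit")})
    post, _ = fit_dpvi(model, records, budget, tc)
    synth = generate_synthetic(
        post, model, len(records),
        rng=np.random.default_rng(split_seed(seed, "carat-sample")),
    ).records
    synth_err = frobenius_distance(M, second_moment_matrix(synth.to_numpy(dtype=float)))

    crossover = next((T for T in sorted(T_list) if synth_err < tailored[T]), None)
    return {
        "tailored_error": tailored,
        "synthetic_error": float(synth_err),
        "crossover_T": crossover,
        "K": model.K,
    }


def weight_recovery_experiment(seed: int = 0, n: int = 10_000,
                               weights=(0.7, 0.3), n_features: int = 5) -> dict:
    """Non-private sanity check: recover mixture weights of a planted model."""
    schema = [FeatureSpec(f"b{j}", "binary") for j in range(n_features)]
    model = build_model({"K": len(weights)}, schema)
    true = StratifiedParams(
        strata_marginals=[],
        mixtures={(): MixtureParams(
            weights=np.asarray(weights),
            comps={f"b{j}": np.array([0.9, 0.1]) for j in range(n_features)},
        )},
    )
    data = datasets.generate_mixture_like(model, true, n, seed=split_seed(seed, "mix-data"))
    post, _ = fit_dpvi(
        model, data, PrivacyBudget(math.inf, 1e-6),
        TrainingConfig(noise_multiplier=0.0, clip_norm=math.inf, num_steps=1500,
                       seed=split_seed(seed, "mix-fit")),
    )
    est = np.sort(post.mean_params().mixtures[()].weights)[::-1]
    ref = np.sort(np.asarray(weights))[::-1]
    return {"estimated": list(map(float, est)),
            "true": list(map(float, ref)),
            "max_abs_error": float(np.max(np.abs(est - ref)))}


def structural_zero_check(seed: int = 0, n_samples: int = 100_000,
                          fit_steps: int = 400) -> dict:
    """Count rule violations among posterior-predictive samples (expect 0)."""
    config = datasets.ArdLikeConfig(n_per_sex=4000)
    records, _ = datasets.generate_ard_like(config, seed=split_seed(seed, "zero-data"))
    model = build_model(datasets.ard_model_config(config), datasets.ard_schema(config))
    post, _ = fit_dpvi(
        model, records, PrivacyBudget(1.0, 1e-6),
        TrainingConfig(num_steps=fit_steps, seed=split_seed(seed, "zero-fit")),
    )
    synth = generate_synthetic(
        post, model, n_samples,
        rng=np.random.default_rng(split_seed(seed, "zero-sample")),
    ).records
    alive = synth[synth["dead"] == 0]
    violations = int((alive["ard"] != 0).sum())
    violations += int(
        np.sum(np.abs(alive["duration"] - (config.censor_time - alive["start"])) > 1e-9)
    )
    return {"n_samples": n_samples, "violations": violations}


class _BetaBernoulliPosterior:
    """Exact conjugate posterior p ~ Beta(s+1, n-s+1) for one binary feature."""

    def __init__(self, a: float, b: float, feature: str):
        self.a, self.b, self.feature = a, b, feature

    def sample_constrained(self, rng, size):
        shape = () if size is None else (size,)
        p = rng.beta(self.a, self.b, size=shape + (1,))
        return {
            ((), "_weights"): np.ones(shape + (1, 1)),
            ((), self.feature): p,
        }


def conjugate_ppd_check(seed: int = 0, n_obs: int = 100, successes: int = 30,
                        n_samples: int = 100_000) -> dict:
    """Synthetic success frequency under the exact beta-Bernoulli posterior.

    The posterior predictive success probability is (s+1)/(n+2); the sampled
    frequency over n_samples records should match it within Monte-Carlo
    error (its standard error is returned).
    """
    model = build_model({"K": 1}, [FeatureSpec("y", "binary")])
    post = _BetaBernoulliPosterior(successes + 1, n_obs - successes + 1, "y")
    synth = generate_synthetic(
        post, model, n_samples, rng=np.random.default_rng(split_seed(seed, "ppd")),
    ).records
    freq = float(synth["y"].mean())
    expected = (successes + 1) / (n_obs + 2)
    # a single predictive draw is Bernoulli with success prob E[p]
    se = math.sqrt(expected * (1 - expected) / n_samples)
    return {"frequency": freq, "expected": expected, "se": se,
            "z": (freq - expected) / se, "n_samples": n_samples}
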