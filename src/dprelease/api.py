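"""High-level modelling interface: build a release model, fit it, sample it.

Follows the model/results idiom: :class:`BayesianDataRelease` holds the data
and model specification; ``fit`` runs DP variational inference and returns a
:class:`DataReleaseResults` carrying the posterior, the privacy ledger and
diagnostics, from which synthetic datasets are sampled.

    >>> model = BayesianDataRelease(df, schema, strata=["sex"], K=10)
    >>> res = model.fit(epsilon=1.0, delta=1e-6, seed=3)
    >>> synth = res.sample(seed=4)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .accounting import PrivacyBudget, PrivacyLedger
from .dpvi import TrainingConfig, fit_dpvi
from .model_spec import StratifiedModelSpec, build_model
from .sampling import SyntheticDataset, generate_synthetic, model_hash
from .variational import VariationalPosterior

__all__ = ["BayesianDataRelease", "DataReleaseResults"]


class BayesianDataRelease:
    """A stratified-mixture release model bound to a dataset.

    Parameters
    ----------
    data : pandas.DataFrame
        The sensitive records; missing values are not allowed.
    schema : list of FeatureSpec
        Column typing, bounds and category labels (public knowledge).
    strata : ordered discrete features to stratify on.
    rules : deterministic-rule dicts (``when`` / ``set`` / ``derive``).
    K : mixture components per stratum; defaults to 10 below 20 features,
        20 otherwise.
    """

    def __init__(self, data: pd.DataFrame, schema, strata=(), rules=(), K=None):
        if data.isna().any().any():
            raise ValueError("data contains missing values; drop them first")
        self.spec: StratifiedModelSpec = build_model(
            {"strata": list(strata), "K": K, "rules": list(rules)}, schema
        )
        missing = [s.name for s in self.spec.schema if s.name not in data.columns]
        if missing:
            raise ValueError(f"data lacks schema columns {missing}")
        self.data = data

    @classmethod
    def from_config(cls, data: pd.DataFrame, config: dict) -> "BayesianDataRelease":
        """Build from a parsed model-config mapping (see cli_io docs)."""
        from .cli_io import schema_from_config

        schema = schema_from_config(config)
        return cls(
            data,
            schema,
            strata=config.get("strata", ()),
            rules=config.get("rules", ()),
            K=config.get("K"),
        )

    @property
    def n_obs(self) -> int:
        return len(self.data)

    def fit(self, epsilon: float, delta: float, training: TrainingConfig | None = None,
            seed: int | None = None) -> "DataReleaseResults":
        """Run DPVI to the target (epsilon, delta); epsilon=inf is non-private."""
        budget = PrivacyBudget(epsilon, delta)
        training = training or TrainingConfig()
        if seed is not None:
            training = TrainingConfig(**{**training.__dict__, "seed": seed})
        post, ledger = fit_dpvi(self.spec, self.data, budget, training)
        return DataReleaseResults(self, budget, post, ledger, training)


@dataclass
class DataReleaseResults:
    """Fitted posterior, privacy ledger and release sampler."""

    model: BayesianDataRelease
    budget: PrivacyBudget
    posterior: VariationalPosterior
    ledger: PrivacyLedger
    training: TrainingConfig
    _cache: dict = field(default_factory=dict)

    @property
    def epsilon_spent(self) -> float:
        """Audited composed epsilon of the training trajectory."""
        if not self.ledger.entries:
            return 0.0
        return self.ledger.composed_epsilon(self.budget.delta)

    def sample(self, n: int | None = None, seed=None,
               theta_mode: str = "per_record") -> SyntheticDataset:
        """Posterior-predictive synthetic dataset (defaults to original size)."""
        n = n if n is not None else self.model.n_obs
        prov = {
            "epsilon": self.budget.epsilon,
            "delta": self.budget.delta,
            "epsilon_spent": self.epsilon_spent,
            "seed": seed,
        }
        return generate_synthetic(
            self.posterior, self.model.spec, n,
            rng=np.random.default_rng(seed), theta_mode=theta_mode,
            provenance=prov,
        )

    def summary(self) -> str:
        """Human-readable fit summary (privacy, strata, weights, ELBO)."""
        spec = self.model.spec
        params = self.posterior.mean_params()
        eps = "inf" if math.isinf(self.budget.epsilon) else f"{self.budget.epsilon:g}"
        lines = [
            "Bayesian DP data release",
            "=" * 60,
            f"records: {self.model.n_obs}    features: {len(spec.schema)}    "
            f"components K: {spec.K}",
            f"strata: {spec.strata or 'none'}    cells: {len(spec.cells)}",
            f"budget: epsilon={eps}, delta={self.budget.delta:g}    "
            f"spent: {self.epsilon_spent:.4f}",
            f"model hash: {model_hash(spec)}",
        ]
        if self.posterior.elbo_trace:
            lines.append(f"final ELBO estimate: {self.posterior.elbo_trace[-1][1]:.1f}")
        for i, var in enumerate(spec.strata):
            tab = np.asarray(params.strata_marginals[i])
            lines.append(f"posterior mean marginal p({var} | earlier strata):")
            for row in tab:
                lines.append("    " + "  ".join(f"{p:.3f}" for p in row))
        for cell in spec.cells:
            w = np.sort(params.mixtures[cell].weights)[::-1]
            shown = "  ".join(f"{x:.3f}" for x in w[:6])
            lines.append(f"cell {cell}: top weights {shown}")
        return "\n".join(lines)
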