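"""Tailored one-query DP mechanisms: the comparison arm to synthetic data.

A data holder anticipating T queries must split the privacy budget across
them; each query then runs a Gaussian mechanism at (eps/T, delta/T).  The
release implemented here is the uncentered second-moment matrix
(1/n) sum_i x_i x_i^T of unit-hypercube-scaled data, whose substitute-
adjacency L2 (Frobenius) sensitivity is 2d/n (replacing one row x with x'
changes the sum by (x x^T - x' x'^T)/n and ||x x^T||_F = ||x||^2 <= d).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .accounting import PrivacyBudget, gaussian_sigma

__all__ = [
    "QueryPlan",
    "split_budget",
    "dp_second_moment",
    "second_moment_matrix",
    "second_moment_sensitivity",
]


def second_moment_sensitivity(n: int, d: int) -> float:
    """Substitute-adjacency Frobenius sensitivity 2d/n of (1/n) X^T X on [0,1]^d."""
    if n < 1 or d < 1:
        raise ValueError("n and d must be positive")
    return 2.0 * d / n


@dataclass(frozen=True)
class QueryPlan:
    """Uniform split of a budget over T anticipated queries."""

    total: PrivacyBudget
    T: int

    def __post_init__(self):
        if self.T < 1:
            raise ValueError("T must be >= 1")

    @property
    def per_query(self) -> PrivacyBudget:
        return PrivacyBudget(self.total.epsilon / self.T, self.total.delta / self.T)


def split_budget(budget: PrivacyBudget, T: int) -> QueryPlan:
    """Each of T queries gets (eps/T, delta/T); basic composition restores the total."""
    return QueryPlan(total=budget, T=T)


def second_moment_matrix(data: np.ndarray) -> np.ndarray:
    """Uncentered second moment (1/n) X^T X of an (n, d) matrix."""
    X = np.asarray(data, dtype=float)
    return X.T @ X / len(X)


def dp_second_moment(
    data: np.ndarray,
    per_query_budget: PrivacyBudget,
    rng=None,
    centered: bool = False,
) -> np.ndarray:
    """Gaussian-mechanism release of the second-moment matrix.

    ``data`` must be scaled to the unit hypercube.  ``centered=True``
    subtracts a separately-released DP mean (the per-query budget is halved
    between the two statistics).  Noise is symmetrized so the release is a
    symmetric matrix; an infinite-epsilon budget returns the exact matrix.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("data must be an (n>=2, d) matrix")
    if np.any((X < 0) | (X > 1)):
        raise ValueError("data must be scaled to [0,1] before release")
    n, d = X.shape
    rng = np.random.default_rng(rng)

    eps, delta = per_query_budget.epsilon, per_query_budget.delta
    if centered:
        mean_sens = 2.0 * np.sqrt(d) / n
        if per_query_budget.is_private:
            half = PrivacyBudget(eps / 2, delta / 2)
            mu = X.mean(axis=0) + rng.normal(
                scale=gaussian_sigma(half.epsilon, half.delta, mean_sens), size=d
            )
            eps, delta = eps / 2, delta / 2
        else:
            mu = X.mean(axis=0)
        X = X - mu  # centered values lie in [-1,1]; sensitivity below doubles
        sens = 4.0 * second_moment_sensitivity(n, d)
    else:
        sens = second_moment_sensitivity(n, d)

    M = X.T @ X / n
    if not per_query_budget.is_private:
        return M
    sigma = gaussian_sigma(eps, delta, sens)
    noise = rng.normal(scale=sigma, size=(d, d))
    noise = (noise + noise.T) / 2.0
    out = M + noise
    return (out + out.T) / 2.0
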