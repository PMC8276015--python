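"""(epsilon, delta) accounting for Gaussian and subsampled-Gaussian mechanisms.

Adjacency is the *substitute* relation throughout: two datasets are
neighbours when one is obtained from the other by replacing a single record.
Composition is tracked in Renyi differential privacy (RDP) and converted to
(epsilon, delta) at the end with the tight conversion

    eps(delta) = min_alpha  RDP(alpha) + log(1 - 1/alpha)
                           - (log delta + log alpha) / (alpha - 1),

which is what makes a single Gaussian step calibrated by the classic
sigma = Delta * sqrt(2 log(1.25/delta)) / eps audit back to eps' <= eps.

Subsampled-Gaussian RDP uses the binomial-expansion upper bound for
Poisson subsampling at integer orders; plain Gaussian entries (q = 1) use
the exact alpha / (2 sigma^2) at any real order.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import norm

__all__ = [
    "PrivacyBudget",
    "PrivacyLedger",
    "LedgerEntry",
    "gaussian_sigma",
    "rdp_subsampled_gaussian",
    "compose_and_convert",
    "calibrate_sigma",
    "DEFAULT_ORDERS",
]

#: RDP order grid; fractional orders are used only for non-subsampled entries
DEFAULT_ORDERS = tuple(
    [1.25, 1.5, 1.75] + list(range(2, 65)) + [80, 96, 128, 192, 256, 384, 512]
)


@dataclass(frozen=True)
class PrivacyBudget:
    """Target (epsilon, delta) under substitute adjacency.

    ``epsilon = math.inf`` is the documented non-private sentinel.
    """

    epsilon: float
    delta: float
    adjacency: str = "substitute"

    def __post_init__(self):
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        if not 0 <= self.delta < 1:
            raise ValueError("delta must lie in [0, 1)")

    @property
    def is_private(self) -> bool:
        return math.isfinite(self.epsilon)


@dataclass(frozen=True)
class LedgerEntry:
    mechanism: str
    sensitivity: float
    noise_std: float  # absolute std of the added noise
    q: float = 1.0  # Poisson sampling rate
    count: int = 1

    @property
    def noise_multiplier(self) -> float:
        """Noise std relative to the sensitivity."""
        if self.noise_std == math.inf:
            return math.inf
        return self.noise_std / self.sensitivity


@dataclass
class PrivacyLedger:
    """Record of every mechanism invocation, with composed-epsilon audit."""

    entries: list = field(default_factory=list)
    orders: tuple = DEFAULT_ORDERS

    def record(self, mechanism, sensitivity, noise_std, q=1.0, count=1):
        self.entries.append(
            LedgerEntry(mechanism, float(sensitivity), float(noise_std), float(q), int(count))
        )

    def composed_epsilon(self, delta: float) -> float:
        return compose_and_convert(self, delta)

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "mechanism": e.mechanism,
                    "sensitivity": e.sensitivity,
                    "noise_std": e.noise_std,
                    "q": e.q,
                    "count": e.count,
                }
                for e in self.entries
            ]
        )

    @classmethod
    def from_json(cls, text: str) -> "PrivacyLedger":
        ledger = cls()
        for d in json.loads(text):
            ledger.record(**{k: d[k] for k in ("mechanism", "sensitivity", "noise_std", "q", "count")})
        return ledger


def gaussian_sigma(epsilon: float, delta: float, sensitivity: float, method: str = "classic") -> float:
    """Noise std for the Gaussian mechanism at sensitivity ``sensitivity``.

    ``method="classic"`` returns Delta*sqrt(2 ln(1.25/delta))/eps (valid for
    eps <= 1); ``method="analytic"`` solves the exact Gaussian-mechanism
    privacy profile numerically (valid for any eps) and is tighter.
    """
    if math.isinf(epsilon):
        return 0.0
    if not (epsilon > 0 and 0 < delta < 1 and sensitivity > 0):
        raise ValueError("invalid epsilon/delta/sensitivity")
    if method == "classic":
        if epsilon > 1:
            raise ValueError("classic bound valid only for epsilon <= 1; use method='analytic'")
        return sensitivity * math.sqrt(2.0 * math.log(1.25 / delta)) / epsilon
    if method != "analytic":
        raise ValueError(f"unknown method {method!r}")

    def profile_delta(sigma):
        # exact delta of N(0, sigma^2) at sensitivity Delta (Gaussian privacy profile)
        a = sensitivity / (2 * sigma) - epsilon * sigma / sensitivity
        b = -sensitivity / (2 * sigma) - epsilon * sigma / sensitivity
        return norm.cdf(a) - math.exp(epsilon) * norm.cdf(b)

    lo, hi = 1e-6, 1.0
    while profile_delta(hi) > delta:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if profile_delta(mid) > delta:
            lo = mid
        else:
            hi = mid
    return hi


def _rdp_gaussian(sigma: float, alpha: float) -> float:
    return alpha / (2.0 * sigma * sigma)


def rdp_subsampled_gaussian(q: float, sigma: float, alpha: float) -> float:
    """RDP (in nats) of one Poisson-subsampled Gaussian step at order alpha.

    Sensitivity-normalised: ``sigma`` is the noise multiplier (noise std over
    sensitivity).  q=1 gives the exact Gaussian value alpha/(2 sigma^2); q=0
    touches no data and gives 0.  For 0<q<1, the binomial-expansion upper
    bound at integer alpha:

        RDP(alpha) = log( sum_j C(alpha,j) (1-q)^(alpha-j) q^j
                          exp(j(j-1)/(2 sigma^2)) ) / (alpha - 1).
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0,1]")
    if alpha <= 1:
        raise ValueError("alpha must exceed 1")
    if q == 0.0:
        return 0.0
    if sigma <= 0:
        return math.inf
    if q == 1.0:
        return _rdp_gaussian(sigma, alpha)
    if abs(alpha - round(alpha)) > 1e-9:
        raise ValueError("subsampled bound implemented for integer alpha only")
    a = int(round(alpha))
    j = np.arange(a + 1)
    log_terms = (
        gammaln(a + 1)
        - gammaln(j + 1)
        - gammaln(a - j + 1)
        + (a - j) * math.log1p(-q)
        + j * math.log(q)
        + j * (j - 1) / (2.0 * sigma * sigma)
    )
    return float(logsumexp(log_terms)) / (a - 1)


def _total_rdp(ledger: PrivacyLedger, alpha: float) -> float:
    total = 0.0
    for e in ledger.entries:
        nm = e.noise_multiplier
        if nm == math.inf:
            continue  # infinitely noisy: free
        if nm <= 0:
            return math.inf
        if e.q >= 1.0:
            total += e.count * _rdp_gaussian(nm, alpha)
        else:
            if abs(alpha - round(alpha)) > 1e-9:
                return math.inf  # order unusable for subsampled entries
            total += e.count * rdp_subsampled_gaussian(e.q, nm, alpha)
    return total


def compose_and_convert(ledger: PrivacyLedger, delta: float) -> float:
    """Composed epsilon of all ledger entries at the given delta.

    Minimises the RDP-to-DP conversion over the ledger's order grid; an
    empty ledger composes to 0.
    """
    if not 0 < delta < 1:
        raise ValueError("delta must lie in (0,1)")
    if not ledger.entries:
        return 0.0
    best = math.inf
    for alpha in ledger.orders:
        r = _total_rdp(ledger, alpha)
        if not math.isfinite(r):
            continue
        eps = r + math.log1p(-1.0 / alpha) - (math.log(delta) + math.log(alpha)) / (alpha - 1.0)
        best = min(best, eps)
    return max(best, 0.0)


def _training_ledger(q: float, sigma: float, steps: int) -> PrivacyLedger:
    ledger = PrivacyLedger()
    ledger.record("subsampled_gaussian", sensitivity=1.0, noise_std=sigma, q=q, count=steps)
    return ledger


def calibrate_sigma(
    target: PrivacyBudget,
    q: float,
    steps: int,
    bracket: tuple = (0.4, 200.0),
    tol: float = 1e-3,
) -> float:
    """Smallest noise multiplier meeting ``target`` over ``steps`` subsampled steps.

    Binary search over sigma in ``bracket``; the round-trip audit
    ``compose_and_convert(ledger(q, sigma, steps), delta) <= target.epsilon``
    holds by construction.  An infinite-epsilon target returns sigma = 0
    (non-private mode).
    """
    if not target.is_private:
        return 0.0

    def eps_at(sigma):
        return compose_and_convert(_training_ledger(q, sigma, steps), target.delta)

    lo, hi = bracket
    if eps_at(hi) > target.epsilon:
        raise ValueError(f"budget infeasible: eps({hi}) = {eps_at(hi):.3g} > {target.epsilon}")
    if eps_at(lo) <= target.epsilon:
        return lo
    while hi - lo > tol * max(1.0, lo):
        mid = 0.5 * (lo + hi)
        if eps_at(mid) <= target.epsilon:
            hi = mid
        else:
            lo = mid
    return hi
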