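"""Bijections between unconstrained reals and constrained parameter supports.

Mean-field variational posteriors live in unconstrained space; the model's
parameters live on positive half-lines, the unit interval, or probability
simplexes.  Each transform here maps any real input into the valid support
and carries the log-Jacobian needed for the change of variables in the prior
term of the ELBO, plus the analytic gradient of that log-Jacobian.

The simplex transform is stick-breaking with the centering offset
``log(m-1-l)`` on stick ``l`` so that the all-zeros unconstrained point maps
to the uniform simplex.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "sigmoid",
    "logit",
    "softplus_inv",
    "stick_breaking",
    "stick_breaking_inverse",
    "stick_sigmoids",
    "simplex_log_jacobian",
    "simplex_log_jacobian_grad",
]

_EPS = 1e-12


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(np.asarray(p, dtype=float), _EPS, 1.0 - _EPS)
    return np.log(p) - np.log1p(-p)


def softplus_inv(y: np.ndarray) -> np.ndarray:
    """Inverse of log(1+exp(x)); used only for moment-matched initialisation."""
    y = np.asarray(y, dtype=float)
    return y + np.log(-np.expm1(-y))


def _stick_offsets(m: int) -> np.ndarray:
    # offset so u = 0 -> uniform simplex: sigmoid(0 - log(m-1-l)) = 1/(m-l)
    return np.log(np.arange(m - 1, 0, -1, dtype=float))


def stick_sigmoids(u: np.ndarray, m: int) -> np.ndarray:
    """Stick fractions v_l = sigmoid(u_l - log(m-1-l)) for u of shape (..., m-1)."""
    u = np.asarray(u, dtype=float)
    v = sigmoid(u - _stick_offsets(m))
    return np.clip(v, _EPS, 1.0 - _EPS)


def stick_breaking(u: np.ndarray, m: int) -> np.ndarray:
    """Map (..., m-1) unconstrained reals to (..., m) simplex points.

    theta_l = v_l * prod_{j<l} (1 - v_j);  theta_{m-1} = prod_j (1 - v_j).
    """
    u = np.asarray(u, dtype=float)
    if m == 1:  # degenerate one-point simplex
        return np.ones(u.shape[:-1] + (1,))
    v = stick_sigmoids(u, m)
    one_minus = 1.0 - v
    # cumulative product of remaining stick, exclusive
    rem = np.cumprod(one_minus, axis=-1)
    rem_excl = np.concatenate(
        [np.ones_like(rem[..., :1]), rem[..., :-1]], axis=-1
    )
    theta = np.concatenate([v * rem_excl, rem[..., -1:]], axis=-1)
    return theta


def stick_breaking_inverse(theta: np.ndarray) -> np.ndarray:
    """Inverse map from (..., m) simplex points to (..., m-1) reals."""
    theta = np.asarray(theta, dtype=float)
    m = theta.shape[-1]
    rem = 1.0 - np.cumsum(theta[..., :-1], axis=-1)
    rem_excl = np.concatenate(
        [np.ones_like(theta[..., :1]), rem[..., :-1]], axis=-1
    )
    v = np.clip(theta[..., :-1] / np.clip(rem_excl, _EPS, None), _EPS, 1 - _EPS)
    return logit(v) + _stick_offsets(m)


def simplex_log_jacobian(u: np.ndarray, m: int) -> np.ndarray:
    """log |d theta / d u| for the stick-breaking map, summed over the block.

    The Jacobian is triangular: log|J| = sum_l [log v_l + log(1-v_l) + log w_l]
    with w_l the product of remaining stick before break l.
    """
    v = stick_sigmoids(u, m)
    log_one_minus = np.log1p(-v)
    log_w = np.cumsum(log_one_minus, axis=-1) - log_one_minus  # exclusive cumsum
    return np.sum(np.log(v) + log_one_minus + log_w, axis=-1)


def simplex_log_jacobian_grad(u: np.ndarray, m: int) -> np.ndarray:
    """d/du of simplex_log_jacobian, elementwise over sticks.

    grad_l = (1 - 2 v_l) - (m - 2 - l) * v_l; the second term counts the
    downstream w factors containing (1 - v_l).
    """
    v = stick_sigmoids(u, m)
    downstream = np.arange(m - 2, -1, -1, dtype=float)
    return (1.0 - 2.0 * v) - downstream * v
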