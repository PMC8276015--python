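"""Mean-field variational family over the model's unconstrained parameters.

Every constrained parameter block of a :class:`~dprelease.model_spec.
StratifiedModelSpec` gets exactly one unconstrained coordinate block:

=============  =====================  =======================  ==============
block kind     constrained support    transform                prior
=============  =====================  =======================  ==============
``pos``        theta > 0              exp                      gamma(1,1)
``prob``       theta in (0,1)         logistic                 uniform
``simplex``    probability simplex    stick-breaking           flat Dirichlet
=============  =====================  =======================  ==============

The variational posterior is an independent Gaussian per unconstrained
coordinate (location, log-scale); samples are pushed through the transforms,
so any draw satisfies all support constraints by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model_spec import MixtureParams, StratifiedModelSpec, StratifiedParams
from . import transforms as tr

__all__ = ["ParamBlock", "ParamLayout", "VariationalPosterior"]

_U_CLIP = 30.0  # keep exp() finite; far outside any plausible posterior


@dataclass(frozen=True)
class ParamBlock:
    key: tuple  # ("strata", i) | (cell, "_weights") | (cell, feature_name)
    kind: str  # "pos" | "prob" | "simplex"
    rows: int
    cols: int  # unconstrained columns per row
    m: int = 0  # simplex dimension (constrained), 0 otherwise
    offset: int = 0

    @property
    def size(self) -> int:
        return self.rows * self.cols

    @property
    def slice(self) -> slice:
        return slice(self.offset, self.offset + self.size)

    def view(self, u: np.ndarray) -> np.ndarray:
        return u[..., self.slice].reshape(u.shape[:-1] + (self.rows, self.cols))


class ParamLayout:
    """Flattening of all model parameters into one unconstrained vector."""

    def __init__(self, model: StratifiedModelSpec):
        self.model = model
        self.blocks: list[ParamBlock] = []
        offset = 0

        def add(key, kind, rows, cols, m=0):
            nonlocal offset
            b = ParamBlock(key, kind, rows, cols, m, offset)
            self.blocks.append(b)
            offset += b.size

        for i, var in enumerate(model.strata):
            n_cond, m = model.marginal_shape(i)
            add(("strata", i), "simplex", n_cond, m - 1, m)
        K = model.K
        for cell in model.cells:
            add((cell, "_weights"), "simplex", 1, K - 1, K)
            for spec in model.features_for_cell(cell):
                if spec.family == "beta":
                    add((cell, spec.name), "pos", K, 2)
                elif spec.family == "bernoulli":
                    add((cell, spec.name), "prob", K, 1)
                else:
                    m = spec.n_categories
                    add((cell, spec.name), "simplex", K, m - 1, m)
        self.size = offset
        self._by_key = {b.key: b for b in self.blocks}

    def block(self, key) -> ParamBlock:
        return self._by_key[key]

    # -- forward transform -------------------------------------------------
    def constrain_block(self, block: ParamBlock, u: np.ndarray) -> np.ndarray:
        v = block.view(np.clip(u, -_U_CLIP, _U_CLIP))
        if block.kind == "pos":
            return np.exp(v)
        if block.kind == "prob":
            return tr.sigmoid(v)[..., 0]
        return tr.stick_breaking(v, block.m)

    def constrain(self, u: np.ndarray) -> StratifiedParams:
        model = self.model
        marginals = [
            self.constrain_block(self.block(("strata", i)), u)
            for i in range(len(model.strata))
        ]
        mixtures = {}
        for cell in model.cells:
            weights = self.constrain_block(self.block((cell, "_weights")), u)[0]
            comps = {
                s.name: self.constrain_block(self.block((cell, s.name)), u)
                for s in model.features_for_cell(cell)
            }
            mixtures[cell] = MixtureParams(weights=weights, comps=comps)
        return StratifiedParams(strata_marginals=marginals, mixtures=mixtures)

    def unconstrain(self, params: StratifiedParams) -> np.ndarray:
        """Inverse transform, used for moment-matched initialisation/tests."""
        u = np.zeros(self.size)
        for i in range(len(self.model.strata)):
            b = self.block(("strata", i))
            u[b.slice] = tr.stick_breaking_inverse(
                np.asarray(params.strata_marginals[i])
            ).ravel()
        for cell in self.model.cells:
            mp = params.mixtures[cell]
            b = self.block((cell, "_weights"))
            u[b.slice] = tr.stick_breaking_inverse(mp.weights[None, :]).ravel()
            for s in self.model.features_for_cell(cell):
                b = self.block((cell, s.name))
                arr = np.asarray(mp.comps[s.name], dtype=float)
                if b.kind == "pos":
                    u[b.slice] = np.log(arr).ravel()
                elif b.kind == "prob":
                    u[b.slice] = tr.logit(arr).ravel()
                else:
                    u[b.slice] = tr.stick_breaking_inverse(arr).ravel()
        return u

    # -- prior + Jacobian --------------------------------------------------
    def prior_logpdf(self, u: np.ndarray) -> float:
        """log p(theta(u)) + log |d theta / d u| summed over all blocks."""
        u = np.clip(u, -_U_CLIP, _U_CLIP)
        total = 0.0
        for b in self.blocks:
            v = b.view(u)
            if b.kind == "pos":
                # gamma(1,1): log p = -theta; Jacobian of exp: +u
                total += float(np.sum(-np.exp(v) + v))
            elif b.kind == "prob":
                p = tr.sigmoid(v)
                total += float(np.sum(np.log(p) + np.log1p(-p)))
            else:
                total += b.rows * math.lgamma(b.m)
                total += float(np.sum(tr.simplex_log_jacobian(v, b.m)))
        return total

    def prior_grad(self, u: np.ndarray) -> np.ndarray:
        """d/du of :meth:`prior_logpdf`."""
        u = np.clip(u, -_U_CLIP, _U_CLIP)
        g = np.zeros_like(u)
        for b in self.blocks:
            v = b.view(u)
            if b.kind == "pos":
                g[b.slice] = (1.0 - np.exp(v)).ravel()
            elif b.kind == "prob":
                g[b.slice] = (1.0 - 2.0 * tr.sigmoid(v)).ravel()
            else:
                g[b.slice] = tr.simplex_log_jacobian_grad(v, b.m).ravel()
        return g


@dataclass
class VariationalPosterior:
    """Independent Gaussian per unconstrained coordinate."""

    layout: ParamLayout
    loc: np.ndarray
    log_scale: np.ndarray
    elbo_trace: list = field(default_factory=list)

    def __post_init__(self):
        self.loc = np.asarray(self.loc, dtype=float)
        self.log_scale = np.asarray(self.log_scale, dtype=float)
        if self.loc.shape != self.log_scale.shape or self.loc.shape != (self.layout.size,):
            raise ValueError("loc/log_scale must match the layout size")

    @property
    def scale(self) -> np.ndarray:
        return np.exp(self.log_scale)

    def sample_unconstrained(self, rng: np.random.Generator, size: int | None = None):
        shape = (self.layout.size,) if size is None else (size, self.layout.size)
        z = rng.standard_normal(shape)
        return self.loc + self.scale * z, z

    def entropy(self) -> float:
        return float(np.sum(self.log_scale) + 0.5 * self.layout.size * math.log(2 * math.pi * math.e))

    def mean_params(self) -> StratifiedParams:
        """Posterior-median parameters (transform of the locations)."""
        return self.layout.constrain(self.loc)
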