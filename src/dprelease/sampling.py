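"""Posterior-predictive sampling of synthetic records.

A synthetic record is drawn by (1) drawing parameters theta~ from the fitted
posterior, (2) drawing strata values from their (conditional) marginals,
(3) picking a mixture component and drawing every modelled feature from it,
(4) reconstructing rule-determined features and inverse-scaling continuous
ones.  ``theta_mode="per_record"`` redraws theta~ for every record — the
default reading of "repeat the two-step draw for every point" — while
``"single_draw"`` reuses one theta~ for the whole dataset.

Only samples are released: the fitted parameters are not part of the output.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_spec import StratifiedModelSpec, StratifiedParams, unit_unscale
from .variational import VariationalPosterior

__all__ = [
    "ParameterDraw",
    "SyntheticDataset",
    "draw_parameters",
    "generate_synthetic",
    "model_hash",
]

#: a single constrained parameter set (weights, component params, marginals)
ParameterDraw = StratifiedParams


@dataclass
class SyntheticDataset:
    """Synthetic records plus release provenance (seed, mode, model hash)."""

    records: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)


def model_hash(model: StratifiedModelSpec) -> str:
    desc = repr(
        (
            [(s.name, s.kind, s.family, tuple(s.domain)) for s in model.schema],
            tuple(model.strata),
            model.K,
            tuple(model.rules),
        )
    )
    return hashlib.sha1(desc.encode()).hexdigest()[:12]


def draw_parameters(post: VariationalPosterior, rng=None) -> ParameterDraw:
    """One constrained parameter draw from the mean-field posterior.

    Unconstrained coordinates are Gaussian; pushing them through the
    transform map guarantees simplex blocks sum to one and positive blocks
    stay positive for any draw.
    """
    rng = np.random.default_rng(rng)
    u, _ = post.sample_unconstrained(rng)
    return post.layout.constrain(u)


def _sample_categorical(probs: np.ndarray, rng) -> np.ndarray:
    """Row-wise categorical draw from an (n, m) matrix of probabilities."""
    probs = probs / probs.sum(axis=-1, keepdims=True)
    cum = np.cumsum(probs, axis=-1)
    r = rng.random(len(probs))
    return np.minimum((r[:, None] > cum).sum(axis=1), probs.shape[-1] - 1)


def _block_draws(post, model, rng, size):
    """Constrained parameter arrays per block key, batched over ``size``.

    Accepts a VariationalPosterior, a fixed :class:`ParameterDraw`, or any
    object with ``sample_constrained(rng, size) -> dict``; the last form is
    how an exact (e.g. conjugate) posterior can be plugged in.
    """
    if isinstance(post, VariationalPosterior):
        u, _ = post.sample_unconstrained(rng, size)
        layout = post.layout
        out = {b.key: layout.constrain_block(b, u) for b in layout.blocks}
        return out, size is not None
    if isinstance(post, StratifiedParams):
        out = {}
        for i, tab in enumerate(post.strata_marginals):
            out[("strata", i)] = np.asarray(tab, dtype=float)
        for cell, mp in post.mixtures.items():
            out[(cell, "_weights")] = np.asarray(mp.weights, dtype=float)[None, :]
            for name, arr in mp.comps.items():
                out[(cell, name)] = np.asarray(arr, dtype=float)
        return out, False
    if hasattr(post, "sample_constrained"):
        return post.sample_constrained(rng, size), size is not None
    raise TypeError(f"unsupported posterior object {type(post)!r}")


def generate_synthetic(
    post,
    model: StratifiedModelSpec,
    n: int,
    rng=None,
    theta_mode: str = "per_record",
    chunk_size: int = 8192,
    provenance: dict | None = None,
) -> SyntheticDataset:
    """Draw ``n`` synthetic records from the posterior predictive distribution.

    Every record satisfies all deterministic rules by construction and
    continuous features are returned in their original (declared-bound)
    units.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if theta_mode not in ("per_record", "single_draw"):
        raise ValueError(f"unknown theta_mode {theta_mode!r}")
    rng = np.random.default_rng(rng)

    columns = {
        s.name: np.empty(n, dtype=(float if s.kind == "continuous" else object if s.kind == "categorical" else np.int64))
        for s in model.schema
    }

    fixed = None
    if theta_mode == "single_draw":
        fixed, _ = _block_draws(post, model, rng, None)

    start = 0
    while start < n:
        stop = min(start + chunk_size, n)
        B = stop - start
        if theta_mode == "per_record":
            params, batched = _block_draws(post, model, rng, B)
        else:
            params, batched = fixed, False
        rows = np.arange(B)

        def take(key, idx):
            arr = params[key]
            return arr[rows, idx] if batched else arr[idx]

        # strata variables
        cond = np.zeros(B, dtype=int)
        strata_codes = {}
        for i, var in enumerate(model.strata):
            labels = model.strata_labels(var)
            probs = take(("strata", i), cond)  # (B, m)
            codes = _sample_categorical(probs, rng)
            strata_codes[var] = codes
            spec = model.feature(var)
            if spec.kind == "binary":
                columns[var][start:stop] = codes
            else:
                columns[var][start:stop] = np.asarray(labels, dtype=object)[codes]
            cond = cond * len(labels) + codes

        # per-cell mixtures + rules
        for ci, cell in enumerate(model.cells):
            pos = np.nonzero(cond == ci)[0]
            if len(pos) == 0:
                continue
            out_idx = start + pos
            wkey = (cell, "_weights")
            w = params[wkey][pos, 0] if batched else params[wkey][0]
            comp = (
                _sample_categorical(w, rng)
                if batched
                else _sample_categorical(np.broadcast_to(w, (len(pos), len(w))), rng)
            )
            raw = {}
            for s in model.features_for_cell(cell):
                theta = params[(cell, s.name)]
                theta = theta[pos] if batched else np.broadcast_to(
                    theta, (len(pos),) + theta.shape
                )
                sel = theta[np.arange(len(pos)), comp]
                if s.family == "beta":
                    x01 = rng.beta(sel[:, 0], sel[:, 1])
                    vals = unit_unscale(x01, *s.domain)
                elif s.family == "bernoulli":
                    vals = (rng.random(len(pos)) < sel).astype(np.int64)
                else:
                    codes = _sample_categorical(sel, rng)
                    vals = np.asarray(s.domain, dtype=object)[codes]
                raw[s.name] = vals
                columns[s.name][out_idx] = vals
            # deterministic reconstruction
            for rule in model.rules_for_cell(cell):
                for f, value in rule.set:
                    spec = model.feature(f)
                    if spec.kind == "binary":
                        columns[f][out_idx] = int(value)
                    elif spec.kind == "categorical":
                        columns[f][out_idx] = value
                    else:
                        columns[f][out_idx] = float(value)
                for f, dv in rule.derive:
                    src = columns[dv.source][out_idx].astype(float)
                    columns[f][out_idx] = dv.offset + dv.scale * src
        start = stop

    records = pd.DataFrame({s.name: columns[s.name] for s in model.schema})
    prov = {
        "n": n,
        "theta_mode": theta_mode,
        "model_hash": model_hash(model),
    }
    prov.update(provenance or {})
    return SyntheticDataset(records=records, provenance=prov)
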