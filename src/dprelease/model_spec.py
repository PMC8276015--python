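"""Declarative mixture-model specification over mixed-type tabular records.

The generative model is a finite mixture with features independent within
each component:

    p(x | theta, pi) = sum_k pi_k prod_j p(x_j | theta_j^(k))

Continuous features are affinely scaled to the unit interval (bounds are
public prior knowledge supplied in the config, never estimated from the
data) and modelled as beta; binary features as Bernoulli; categorical
features as categorical.  The model can be *stratified* by discrete
variables (e.g. sex, end-of-follow-up status): each combination of strata
values gets its own mixture over the remaining features, and the strata
variables themselves get (conditional) categorical marginals.

Deterministic rules encode structural zeros — outcome combinations that are
impossible by construction, such as a living subject with a recorded
alcohol-related death.  A rule conditions on strata values and either forces
a feature to a constant or derives it affinely from another feature; the
affected features are excluded from that stratum's mixture and reconstructed
at sampling time.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln

__all__ = [
    "FeatureSpec",
    "MixtureParams",
    "StratifiedParams",
    "DeterministicRule",
    "DerivedFeature",
    "StratifiedModelSpec",
    "build_model",
    "mixture_log_density",
    "prior_log_density",
    "unit_scale",
    "unit_unscale",
]

#: clip continuous values this far away from {0,1} so beta log-densities
#: stay finite at observed extremes
UNIT_EPS = 1e-6

_FAMILY_FOR_KIND = {
    "continuous": "beta",
    "binary": "bernoulli",
    "categorical": "categorical",
}


@dataclass(frozen=True)
class FeatureSpec:
    """Schema entry for one column.

    Parameters
    ----------
    name : str
    kind : {"continuous", "binary", "categorical"}
    domain : tuple of (lower, upper) bounds for continuous features, or the
        tuple of category labels for categorical features.  Binary features
        need no domain (labels are 0/1).
    family : distribution family; inferred from ``kind`` when omitted.
    """

    name: str
    kind: str
    domain: tuple = ()
    family: str = ""

    def __post_init__(self):
        if self.kind not in _FAMILY_FOR_KIND:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        fam = self.family or _FAMILY_FOR_KIND[self.kind]
        if fam != _FAMILY_FOR_KIND[self.kind]:
            raise ValueError(
                f"family {fam!r} inconsistent with kind {self.kind!r}"
            )
        object.__setattr__(self, "family", fam)
        if self.kind == "continuous":
            if len(self.domain) != 2 or not all(
                math.isfinite(b) for b in self.domain
            ):
                raise ValueError(f"{self.name}: continuous needs finite bounds")
            if not self.domain[0] < self.domain[1]:
                raise ValueError(f"{self.name}: lower bound must be < upper")
        if self.kind == "categorical" and len(self.domain) < 2:
            raise ValueError(f"{self.name}: categorical needs >=2 labels")
        if self.kind == "binary":
            object.__setattr__(self, "domain", (0, 1))

    @property
    def n_categories(self) -> int:
        if self.kind == "categorical":
            return len(self.domain)
        if self.kind == "binary":
            return 2
        raise ValueError(f"{self.name} is continuous")

    def codes(self, values) -> np.ndarray:
        """Map categorical labels to integer codes (binary passes through)."""
        values = np.asarray(values)
        if self.kind == "binary":
            codes = values.astype(int)
            if np.any((codes != 0) & (codes != 1)):
                raise ValueError(f"{self.name}: non-binary value")
            return codes
        lookup = {lab: i for i, lab in enumerate(self.domain)}
        try:
            return np.array([lookup[v] for v in values.tolist()], dtype=int)
        except KeyError as exc:
            raise ValueError(
                f"{self.name}: unknown category {exc.args[0]!r}"
            ) from None


def unit_scale(values, lower: float, upper: float, eps: float = UNIT_EPS):
    """Affine map of ``values`` from [lower, upper] into (eps, 1-eps)."""
    if not lower < upper:
        raise ValueError("degenerate bounds: lower must be < upper")
    values = np.asarray(values, dtype=float)
    if np.any(values < lower) or np.any(values > upper):
        raise ValueError("value outside declared bounds")
    return np.clip((values - lower) / (upper - lower), eps, 1.0 - eps)


def unit_unscale(scaled, lower: float, upper: float):
    """Inverse of :func:`unit_scale` (exact for interior points)."""
    if not lower < upper:
        raise ValueError("degenerate bounds: lower must be < upper")
    return lower + np.asarray(scaled, dtype=float) * (upper - lower)


@dataclass
class MixtureParams:
    """Constrained parameters of one mixture: weights + per-feature blocks.

    ``comps[name]`` has shape (K, 2) positive shapes for beta features,
    (K,) success probabilities for Bernoulli, (K, m) simplex rows for
    categorical.
    """

    weights: np.ndarray
    comps: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1 or np.any(self.weights < -1e-12):
            raise ValueError("weights must be a nonnegative vector")
        if abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("weights must sum to 1")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def validate(self, specs) -> None:
        K = self.n_components
        for spec in specs:
            arr = np.asarray(self.comps[spec.name], dtype=float)
            if spec.family == "beta":
                if arr.shape != (K, 2) or np.any(arr <= 0):
                    raise ValueError(f"{spec.name}: beta shapes must be (K,2)>0")
            elif spec.family == "bernoulli":
                if arr.shape != (K,) or np.any((arr < 0) | (arr > 1)):
                    raise ValueError(f"{spec.name}: bernoulli p must be (K,) in [0,1]")
            else:
                m = spec.n_categories
                if arr.shape != (K, m) or np.any(arr < -1e-12):
                    raise ValueError(f"{spec.name}: categorical must be (K,m)>=0")
                if np.any(np.abs(arr.sum(axis=1) - 1.0) > 1e-8):
                    raise ValueError(f"{spec.name}: categorical rows must sum to 1")


@dataclass(frozen=True)
class DerivedFeature:
    """Affine reconstruction ``value = offset + scale * source``."""

    source: str
    scale: float = 1.0
    offset: float = 0.0


@dataclass(frozen=True)
class DeterministicRule:
    """Structural constraint conditioned on strata values.

    ``when`` maps strata variables to required values; under that condition
    the features in ``set`` are forced to constants and the features in
    ``derive`` are affine functions of another feature.  Affected features
    are excluded from the conditioned stratum's mixture.
    """

    when: tuple  # tuple of (strata_var, value) pairs
    set: tuple = ()  # tuple of (feature, value) pairs
    derive: tuple = ()  # tuple of (feature, DerivedFeature) pairs

    @staticmethod
    def make(when: dict, set: dict | None = None, derive: dict | None = None):
        return DeterministicRule(
            when=tuple(sorted(when.items())),
            set=tuple(sorted((set or {}).items())),
            derive=tuple(sorted((derive or {}).items())),
        )

    def matches(self, strata_values: dict) -> bool:
        return all(strata_values.get(k) == v for k, v in self.when)

    @property
    def targets(self):
        return [f for f, _ in self.set] + [f for f, _ in self.derive]


def _feature_loglik(values, spec: FeatureSpec, params: np.ndarray) -> np.ndarray:
    """Per-component log p(x_j | theta_j^(k)); returns (n, K)."""
    params = np.asarray(params, dtype=float)
    if spec.family == "beta":
        x = np.asarray(values, dtype=float)
        if np.any((x <= 0) | (x >= 1)):
            raise ValueError(f"{spec.name}: beta values must lie in (0,1)")
        a, b = params[:, 0], params[:, 1]
        return (
            np.log(x)[:, None] * (a - 1.0)[None, :]
            + np.log1p(-x)[:, None] * (b - 1.0)[None, :]
            - betaln(a, b)[None, :]
        )
    codes = spec.codes(values)
    if spec.family == "bernoulli":
        p = np.clip(params, 1e-300, None)
        with np.errstate(divide="ignore"):
            logp = np.log(params, where=params > 0, out=np.full_like(params, -np.inf))
            logq = np.log1p(-params, where=params < 1, out=np.full_like(params, -np.inf))
        return np.where(codes[:, None] == 1, logp[None, :], logq[None, :])
    with np.errstate(divide="ignore"):
        logt = np.where(params > 0, np.log(np.clip(params, 1e-300, None)), -np.inf)
    return logt[:, codes].T


def mixture_log_density(record, params: MixtureParams, specs) -> np.ndarray:
    """log p(x | theta, pi) under the independent-within-component mixture.

    ``record`` is a mapping from feature name to a value or an array of
    values.  Returns a scalar for scalar input, else an (n,) array.
    Computed with log-sum-exp over components for stability.
    """
    specs = list(specs)
    params.validate(specs)
    scalar = all(np.ndim(record[s.name]) == 0 for s in specs)
    cols = {
        s.name: np.atleast_1d(np.asarray(record[s.name]))
        for s in specs
    }
    n = len(next(iter(cols.values()))) if specs else 1
    if any(len(v) != n for v in cols.values()):
        raise ValueError("feature columns have mismatched lengths")
    with np.errstate(divide="ignore"):
        comp = np.log(np.clip(params.weights, 1e-300, None))[None, :].repeat(n, axis=0)
        comp[:, params.weights <= 0] = -np.inf
    for s in specs:
        comp = comp + _feature_loglik(cols[s.name], s, params.comps[s.name])
    from scipy.special import logsumexp

    out = logsumexp(comp, axis=1)
    return float(out[0]) if scalar else out


@dataclass
class StratifiedParams:
    """Full constrained parameter set: strata marginals + per-cell mixtures.

    ``strata_marginals[i]`` is a (n_conditioning_cells, m_i) table of
    conditional probabilities for the i-th strata variable given the values
    of the earlier ones (row-major over the earlier variables' label grid).
    """

    strata_marginals: list
    mixtures: dict  # cell tuple -> MixtureParams


@dataclass
class StratifiedModelSpec:
    """A stratified mixture model specification (no fitted parameters)."""

    schema: list  # list[FeatureSpec], column order
    strata: list  # ordered strata variable names
    K: int
    rules: list = field(default_factory=list)

    def __post_init__(self):
        names = [s.name for s in self.schema]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in schema")
        self._by_name = {s.name: s for s in self.schema}
        for v in self.strata:
            if v not in self._by_name:
                raise ValueError(f"unknown strata variable {v!r}")
            if self._by_name[v].kind == "continuous":
                raise ValueError(f"strata variable {v!r} must be discrete")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        self._validate_roles()

    # -- structure ---------------------------------------------------------
    def feature(self, name: str) -> FeatureSpec:
        return self._by_name[name]

    @property
    def strata_specs(self):
        return [self._by_name[v] for v in self.strata]

    def strata_labels(self, var: str):
        s = self._by_name[var]
        return (0, 1) if s.kind == "binary" else tuple(s.domain)

    @property
    def cells(self):
        """All strata-value combinations, row-major in strata order."""
        grids = [self.strata_labels(v) for v in self.strata]
        return list(itertools.product(*grids)) if self.strata else [()]

    def cell_dict(self, cell) -> dict:
        return dict(zip(self.strata, cell))

    def rules_for_cell(self, cell):
        sv = self.cell_dict(cell)
        return [r for r in self.rules if r.matches(sv)]

    def excluded_in_cell(self, cell):
        out = []
        for r in self.rules_for_cell(cell):
            out.extend(r.targets)
        return out

    def features_for_cell(self, cell):
        """FeatureSpecs modelled by the mixture in this stratum."""
        excluded = set(self.strata) | set(self.excluded_in_cell(cell))
        return [s for s in self.schema if s.name not in excluded]

    def _validate_roles(self):
        for cell in self.cells:
            seen = {}
            for v in self.strata:
                seen[v] = "stratum"
            for r in self.rules_for_cell(cell):
                for f, val in list(r.set) + list(r.derive):
                    if f in seen:
                        raise ValueError(
                            f"feature {f!r} has two roles ({seen[f]}, rule) "
                            f"in stratum {cell}"
                        )
                    seen[f] = "rule"
                for f, _ in r.set:
                    pass
            # forced-twice consistency within the cell
            forced = {}
            for r in self.rules_for_cell(cell):
                for f, val in r.set:
                    if f in forced and forced[f] != val:
                        raise ValueError(
                            f"feature {f!r} forced to two values in {cell}"
                        )
                    forced[f] = val
            for f in seen:
                if f not in self._by_name:
                    raise ValueError(f"rule references unknown feature {f!r}")

    # -- densities ---------------------------------------------------------
    def marginal_shape(self, i: int):
        """(n_conditioning_cells, m_i) for strata variable i."""
        m = len(self.strata_labels(self.strata[i]))
        n_cond = 1
        for j in range(i):
            n_cond *= len(self.strata_labels(self.strata[j]))
        return (n_cond, m)

    def cell_index_arrays(self, records) -> np.ndarray:
        """Row-major cell index per record from its strata columns."""
        idx = np.zeros(len(next(iter(records.values()))) if isinstance(records, dict) else len(records), dtype=int)
        for v in self.strata:
            labels = self.strata_labels(v)
            col = records[v]
            codes = self._by_name[v].codes(np.asarray(col)) if self._by_name[v].kind == "binary" else np.array(
                [labels.index(x) for x in np.asarray(col).tolist()], dtype=int
            )
            idx = idx * len(labels) + codes
        return idx

    def log_density(self, records, params: StratifiedParams) -> np.ndarray:
        """Per-record log density of the full stratified model.

        Sums the (conditional) strata marginal log-probabilities and the
        stratum mixture log density; rule-determined features contribute
        probability one.
        """
        scalar = np.ndim(records[self.schema[0].name]) == 0
        cols = {s.name: np.atleast_1d(np.asarray(records[s.name])) for s in self.schema}
        n = len(cols[self.schema[0].name])
        out = np.zeros(n)
        cond_idx = np.zeros(n, dtype=int)
        for i, v in enumerate(self.strata):
            labels = self.strata_labels(v)
            spec = self._by_name[v]
            codes = (
                spec.codes(cols[v])
                if spec.kind == "binary"
                else np.array([labels.index(x) for x in cols[v].tolist()])
            )
            table = np.asarray(params.strata_marginals[i], dtype=float)
            with np.errstate(divide="ignore"):
                out += np.log(np.clip(table[cond_idx, codes], 1e-300, None))
            cond_idx = cond_idx * len(labels) + codes
        cells = self.cells
        for ci, cell in enumerate(cells):
            mask = cond_idx == ci
            if not mask.any():
                continue
            feats = self.features_for_cell(cell)
            sub = {s.name: cols[s.name][mask] for s in feats}
            out[mask] += mixture_log_density(sub, params.mixtures[cell], feats)
        return float(out[0]) if scalar else out


def build_model(config: dict, schema) -> StratifiedModelSpec:
    """Validate a model config against a schema and return the model spec.

    ``config`` keys: ``strata`` (ordered list of discrete feature names,
    optional), ``K`` (number of mixture components; defaults to 10 when the
    schema has fewer than 20 features and 20 otherwise), ``rules`` (list of
    dicts with ``when``/``set``/``derive`` entries).
    """
    schema = list(schema)
    names = {s.name for s in schema}
    strata = list(config.get("strata", []))
    for v in strata:
        if v not in names:
            raise ValueError(f"unknown feature {v!r} in strata")
    D = len(schema)
    K = config.get("K")
    if K is None:
        K = 10 if D < 20 else 20
    if K < 1:
        raise ValueError("K must be >= 1")
    rules = []
    for r in config.get("rules", []):
        if isinstance(r, DeterministicRule):
            rules.append(r)
            continue
        derive = {
            f: d if isinstance(d, DerivedFeature) else DerivedFeature(**d)
            for f, d in (r.get("derive") or {}).items()
        }
        rules.append(
            DeterministicRule.make(r["when"], r.get("set"), derive)
        )
    for r in rules:
        for f in r.targets:
            if f not in names:
                raise ValueError(f"rule references unknown feature {f!r}")
    return StratifiedModelSpec(schema=schema, strata=strata, K=int(K), rules=rules)


def prior_log_density(params: StratifiedParams, model: StratifiedModelSpec) -> float:
    """Log prior: gamma(1,1) on positive shapes, flat Dirichlet on simplexes.

    gamma(1,1) has log-density -theta on theta > 0; the flat Dirichlet on an
    m-simplex has constant density (m-1)!, i.e. log-density log Gamma(m);
    Bernoulli success probabilities carry the (uniform) m=2 case with
    log-density 0.
    """
    total = 0.0
    for i, v in enumerate(model.strata):
        table = np.asarray(params.strata_marginals[i], dtype=float)
        if np.any(table < 0) or np.any(np.abs(table.sum(axis=1) - 1) > 1e-8):
            raise ValueError(f"strata marginal for {v!r} outside simplex")
        m = table.shape[1]
        total += table.shape[0] * math.lgamma(m)
    for cell in model.cells:
        mp = params.mixtures[cell]
        feats = model.features_for_cell(cell)
        mp.validate(feats)
        K = mp.n_components
        total += math.lgamma(K)  # flat Dirichlet over weights
        for s in feats:
            arr = np.asarray(mp.comps[s.name], dtype=float)
            if s.family == "beta":
                if np.any(arr <= 0):
                    raise ValueError(f"{s.name}: beta shape outside support")
                total += -float(arr.sum())
            elif s.family == "categorical":
                total += K * math.lgamma(s.n_categories)
            # bernoulli: uniform prior, log-density 0
    return float(total)
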