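"""Utility metrics: did the statistical discoveries survive the release?

The headline check is Poisson-regression *discovery reproduction*: refit the
original study's rate model on the synthetic data and ask whether every
required term is positive and significant at p < 0.05.  Supporting metrics
are the Frobenius distance between covariance matrices, the mean absolute
coefficient error binned by case prevalence (with the O(1/n) optimal-
estimator reference), and a bootstrap check of how strong the signal is in
the original data to begin with.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RegressionReport",
    "EvalReport",
    "frobenius_distance",
    "fit_poisson_rates",
    "discovery_reproduced",
    "prevalence_binned_mae",
    "bootstrap_reproducibility",
    "numeric_unit_matrix",
]


def numeric_unit_matrix(data, schema) -> np.ndarray:
    """Encode a typed table on the unit hypercube for covariance comparison.

    Binary columns pass through, continuous columns are scaled by their
    declared bounds, categorical columns are one-hot encoded.
    """
    from .model_spec import unit_scale

    cols = []
    for spec in schema:
        col = np.asarray(data[spec.name])
        if spec.kind == "continuous":
            cols.append(unit_scale(col, *spec.domain)[:, None])
        elif spec.kind == "binary":
            cols.append(col.astype(float)[:, None])
        else:
            codes = spec.codes(col)
            cols.append(np.eye(spec.n_categories)[codes])
    return np.hstack(cols)


@dataclass
class RegressionReport:
    """Poisson-regression summary: terms, coefficients, SEs, p-values, cases."""

    terms: list
    coefficients: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray
    case_counts: np.ndarray
    converged: bool = True

    def __post_init__(self):
        k = len(self.terms)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.standard_errors = np.asarray(self.standard_errors, dtype=float)
        self.p_values = np.asarray(self.p_values, dtype=float)
        self.case_counts = np.asarray(self.case_counts, dtype=float)
        for arr in (self.coefficients, self.standard_errors, self.p_values, self.case_counts):
            if arr.shape != (k,):
                raise ValueError("report fields must have one entry per term")
        if self.converged and np.any(self.standard_errors <= 0):
            raise ValueError("standard errors must be positive")
        if np.any((self.p_values < 0) | (self.p_values > 1)):
            raise ValueError("p-values must lie in [0,1]")

    def term(self, name):
        return self.terms.index(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "se": self.standard_errors,
                "p": self.p_values,
                "cases": self.case_counts,
            },
            index=self.terms,
        )


@dataclass
class EvalReport:
    """Bundle of release-utility metrics (JSON-serializable via to_dict)."""

    frobenius: dict = field(default_factory=dict)
    reproduction: dict = field(default_factory=dict)
    binned_mae: list = field(default_factory=list)
    bin_counts: list = field(default_factory=list)
    inverse_n_reference: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "frobenius": self.frobenius,
            "reproduction": self.reproduction,
            "binned_mae": list(map(float, self.binned_mae)),
            "bin_counts": [list(map(float, b)) for b in self.bin_counts],
            "inverse_n_reference": list(map(float, self.inverse_n_reference)),
            "extra": self.extra,
        }


def plot_eval_report(report: EvalReport, original: RegressionReport,
                     synthetic: RegressionReport, path) -> None:
    """Two-panel figure: original-vs-synthetic coefficients, binned MAE."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    terms = [t for t in original.terms if t != "const"]
    x = [original.coefficients[original.term(t)] for t in terms]
    y = [synthetic.coefficients[synthetic.term(t)] for t in terms]
    axes[0].errorbar(x, y, fmt="o",
                     yerr=[synthetic.standard_errors[synthetic.term(t)] for t in terms])
    lims = [min(x + y), max(x + y)]
    axes[0].plot(lims, lims, "k--", lw=0.8)
    axes[0].set_xlabel("original coefficient")
    axes[0].set_ylabel("synthetic coefficient")
    if report.binned_mae:
        axes[1].bar(range(len(report.binned_mae)), report.binned_mae)
        axes[1].plot(range(len(report.inverse_n_reference)),
                     report.inverse_n_reference, "k--", label="1/n reference")
        axes[1].set_xlabel("prevalence bin (low to high)")
        axes[1].set_ylabel("coefficient MAE")
        axes[1].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def frobenius_distance(A: np.ndarray, B: np.ndarray) -> float:
    """sqrt(sum_ij (a_ij - b_ij)^2); zero iff the matrices are equal."""
    A, B = np.asarray(A, dtype=float), np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch {A.shape} vs {B.shape}")
    return float(np.sqrt(np.sum((A - B) ** 2)))


def fit_poisson_rates(data, outcome: str, terms, offset: str) -> RegressionReport:
    """Poisson MLE of event rates with a log person-time offset.

    ``terms`` are indicator/numeric columns; an intercept is always added.
    Wald standard errors and two-sided p-values.  Case counts per term are
    the number of records with the term indicator nonzero and outcome >= 1
    (for the intercept: all records with outcome >= 1).  Non-convergence or
    separation is reported on the result, never silently swallowed.
    """
    terms = list(terms)
    y = np.asarray(data[outcome], dtype=float)
    t = np.asarray(data[offset], dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("outcome must be a nonnegative integer count")
    if np.any(t <= 0):
        raise ValueError("offset (person-time) must be positive")
    X = sm.add_constant(
        np.column_stack([np.asarray(data[c], dtype=float) for c in terms]),
        has_constant="add",
    )
    names = ["const"] + terms
    cases = [float(np.sum(y >= 1))] + [
        float(np.sum((np.asarray(data[c], dtype=float) != 0) & (y >= 1))) for c in terms
    ]
    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=np.log(t))
    converged = True
    try:
        with np.errstate(all="ignore"):
            res = model.fit(maxiter=200)
        converged = bool(
            res.converged and np.all(np.isfinite(res.bse)) and np.all(res.bse > 0)
        )
        coefs, ses, ps = res.params, res.bse, res.pvalues
    except Exception:
        converged = False
        coefs = np.full(len(names), np.nan)
        ses = np.full(len(names), np.nan)
        ps = np.full(len(names), np.nan)
    if not converged:
        ses = np.where(np.isfinite(ses) & (ses > 0), ses, np.nan)
        ps = np.where(np.isfinite(ps), ps, 1.0)
        coefs = np.where(np.isfinite(coefs), coefs, 0.0)
    return RegressionReport(
        terms=names,
        coefficients=coefs,
        standard_errors=np.where(np.isfinite(ses) & (ses > 0), ses, np.inf) if not converged else ses,
        p_values=np.clip(ps, 0.0, 1.0),
        case_counts=np.asarray(cases),
        converged=converged,
    )


def discovery_reproduced(report: RegressionReport, required_terms, alpha: float = 0.05):
    """Per-term and combined discovery flags.

    A term counts as reproduced when its coefficient is positive *and* its
    two-sided p-value is below alpha; the combined flag requires all terms.
    """
    flags = {}
    for term in required_terms:
        if term not in report.terms:
            raise KeyError(f"term {term!r} missing from report")
        i = report.term(term)
        flags[term] = bool(
            report.converged
            and report.coefficients[i] > 0
            and report.p_values[i] < alpha
        )
    return flags, all(flags.values())


def prevalence_binned_mae(
    original: RegressionReport,
    synthetic: RegressionReport,
    n_bins: int = 4,
    terms=None,
):
    """Coefficient MAE binned by how many cases exhibit each term.

    Terms are sorted by (original case count, name) — a stable, documented
    tie-break — and split into ``n_bins`` equal-sized bins from lowest to
    highest prevalence; a remainder goes to the last (highest-prevalence)
    bin.  Also returns the mean inverse case count per bin, the reference
    curve proportional to the error of an optimal DP mean estimator.
    """
    terms = [t for t in (terms or original.terms) if t != "const"]
    if any(t not in synthetic.terms for t in terms):
        raise ValueError("term sets of the two reports do not match")
    order = sorted(terms, key=lambda t: (original.case_counts[original.term(t)], t))
    base = len(order) // n_bins
    if base == 0:
        raise ValueError("need at least one term per bin")
    bins, at = [], 0
    for b in range(n_bins):
        size = base + (len(order) - base * n_bins if b == n_bins - 1 else 0)
        bins.append(order[at : at + size])
        at += size
    maes, counts, inv_ref = [], [], []
    for group in bins:
        errs = [
            abs(
                original.coefficients[original.term(t)]
                - synthetic.coefficients[synthetic.term(t)]
            )
            for t in group
        ]
        cnts = [original.case_counts[original.term(t)] for t in group]
        maes.append(float(np.mean(errs)))
        counts.append(cnts)
        inv_ref.append(float(np.mean([1.0 / max(c, 1.0) for c in cnts])))
    return maes, counts, inv_ref


def bootstrap_reproducibility(
    data,
    outcome: str,
    terms,
    offset: str,
    required_terms,
    B: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of B bootstrap refits that reproduce the discovery.

    Resamples records with replacement, refits the Poisson rate model and
    applies the sign-plus-significance criterion; deterministic given seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    data = pd.DataFrame(data).reset_index(drop=True)
    n = len(data)
    hits, attempts = 0, 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        rep = fit_poisson_rates(data.iloc[idx], outcome, terms, offset)
        attempts += 1
        _, combined = discovery_reproduced(rep, required_terms, alpha)
        hits += int(combined)
    if attempts == 0:
        raise RuntimeError("all bootstrap refits failed")
    return hits / attempts
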