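"""Dyad-independent exponential random graph models (ERGMs).

The model is P(Y = y) ∝ exp(θᵀ g(y)) with statistics g restricted to
``edges``, ``nodefactor`` (main effect of a categorical nodal attribute,
reference level omitted) and ``nodematch`` (homophily: edges whose two
endpoints share an attribute value).  All three are dyad-independent: the
change statistic of a dyad does not depend on the rest of the graph, so
the model factorises over the N(N-1)/2 dyads and the maximum
pseudo-likelihood estimate (MPLE) — a logistic regression of the tie
indicator on the change statistics — coincides with the exact maximum
likelihood estimate.  No MCMC is needed and the fit is deterministic.

Estimation uses iteratively reweighted least squares on the dyad design
aggregated by covariate pattern, with deviance-based step halving.  Wald
standard errors come from the inverse observed information; odds ratios
are exp(θ) with 95% CIs exp(θ ± 1.96·se); BIC is −2·loglik + k·ln(D)
with D the number of dyads.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import Counter
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit, xlogy
from scipy.stats import norm

from .errors import ConfigError, EstimationError, SeparationWarning

_KINDS = ("edges", "nodefactor", "nodematch")
#: |theta| beyond which a coefficient is treated as diverging (separation).
_SEPARATION_BOUND = 15.0


@dataclasses.dataclass(frozen=True)
class TermSpec:
    """One model term: ``edges``, ``nodefactor(attribute, reference_level)``
    or ``nodematch(attribute)``."""

    kind: str
    attribute: Optional[str] = None
    reference_level: Optional[str] = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ConfigError(f"unknown term kind {self.kind!r}; one of {_KINDS}")
        if self.kind != "edges" and not self.attribute:
            raise ConfigError(f"term {self.kind!r} requires an attribute name")


def edges() -> TermSpec:
    return TermSpec("edges")


def nodefactor(attribute: str, reference_level: Optional[str] = None) -> TermSpec:
    return TermSpec("nodefactor", attribute, reference_level)


def nodematch(attribute: str) -> TermSpec:
    return TermSpec("nodematch", attribute)


def _attr_vector(nodes: Sequence, attrs: Mapping, attribute: str) -> list[str]:
    vals = []
    for n in nodes:
        d = attrs[n]
        if attribute not in d:
            raise ConfigError(f"node {n!r} lacks attribute {attribute!r}")
        vals.append(str(d[attribute]))
    return vals


def _reference_level(term: TermSpec, values: Sequence[str]) -> str:
    if term.reference_level is not None:
        if term.reference_level not in set(values):
            raise ConfigError(
                f"reference level {term.reference_level!r} not observed for "
                f"attribute {term.attribute!r}"
            )
        return term.reference_level
    counts = Counter(values)
    # largest category; lexicographic tie-break
    return min(counts, key=lambda v: (-counts[v], v))


def change_statistic(
    term: TermSpec,
    dyad: tuple,
    attrs: Mapping,
    level: Optional[str] = None,
) -> int:
    """Change in the global statistic from toggling one dyad's tie on.

    ``edges`` → 1; ``nodefactor`` at a given non-reference ``level`` →
    number of the two endpoints carrying that level (0, 1 or 2);
    ``nodematch`` → 1 iff the endpoints share the attribute value.
    """
    i, j = dyad
    if term.kind == "edges":
        return 1
    a = attrs[i], attrs[j]
    for d in a:
        if term.attribute not in d:
            raise ConfigError(f"attribute {term.attribute!r} missing on dyad {dyad!r}")
    vi, vj = str(a[0][term.attribute]), str(a[1][term.attribute])
    if term.kind == "nodematch":
        return int(vi == vj)
    if level is None:
        raise ConfigError("nodefactor change statistic requires a level")
    return int(vi == level) + int(vj == level)


def dyad_covariates(
    nodes: Sequence,
    attrs: Mapping,
    terms: Sequence[TermSpec],
) -> tuple[np.ndarray, list[str], np.ndarray, np.ndarray]:
    """Change-statistic matrix over all unordered dyads, vectorised.

    Returns (X, labels, iu, ju): X has one row per dyad in upper-triangle
    order over ``nodes``; nodefactor terms expand to K-1 columns with the
    reference level omitted.
    """
    n = len(nodes)
    iu, ju = np.triu_indices(n, 1)
    cols: list[np.ndarray] = []
    labels: list[str] = []
    for term in terms:
        if term.kind == "edges":
            cols.append(np.ones(iu.size, dtype=np.int8))
            labels.append("edges")
            continue
        values = _attr_vector(nodes, attrs, term.attribute)
        cats = sorted(set(values))
        codes = np.array([cats.index(v) for v in values], dtype=np.int32)
        ci, cj = codes[iu], codes[ju]
        if term.kind == "nodematch":
            cols.append((ci == cj).astype(np.int8))
            labels.append(f"nodematch.{term.attribute}")
        else:
            ref = _reference_level(term, values)
            for lvl in cats:
                if lvl == ref:
                    continue
                k = cats.index(lvl)
                cols.append(((ci == k).astype(np.int8) + (cj == k).astype(np.int8)))
                labels.append(f"nodefactor.{term.attribute}.{lvl}")
    X = np.column_stack(cols) if cols else np.empty((iu.size, 0), dtype=np.int8)
    return X, labels, iu, ju


@dataclasses.dataclass
class DyadDesign:
    """Dyad-level logistic design aggregated by covariate pattern."""

    X: np.ndarray  # (patterns, k) change statistics
    ties: np.ndarray  # (patterns,) dyads with a tie
    absent: np.ndarray  # (patterns,) dyads without a tie
    labels: list[str]
    n_nodes: int

    @property
    def n_dyads(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2

    @property
    def n_params(self) -> int:
        return self.X.shape[1]

    def observed_statistics(self) -> np.ndarray:
        """g(y): per-term sums over observed ties."""
        return self.X.T @ self.ties


def build_design(net: nx.Graph, terms: Sequence[TermSpec]) -> DyadDesign:
    """Enumerate all dyads of the network and aggregate identical
    change-statistic patterns into (pattern, ties, non-ties) triples."""
    nodes = sorted(net.nodes)
    attrs = {n: net.nodes[n] for n in nodes}
    X, labels, iu, ju = dyad_covariates(nodes, attrs, terms)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n), dtype=bool)
    for u, v in net.edges():
        adj[index[u], index[v]] = True
        adj[index[v], index[u]] = True
    tie = adj[iu, ju]
    patterns, inverse = np.unique(X, axis=0, return_inverse=True)
    ties = np.bincount(inverse, weights=tie.astype(float), minlength=len(patterns))
    total = np.bincount(inverse, minlength=len(patterns)).astype(float)
    return DyadDesign(
        X=patterns.astype(float),
        ties=ties,
        absent=total - ties,
        labels=labels,
        n_nodes=n,
    )


@dataclasses.dataclass
class ErgmFit:
    """Fitted dyad-independent ERGM."""

    labels: list[str]
    theta: np.ndarray
    se: np.ndarray
    loglik: float
    n_dyads: int
    converged: bool
    n_iter: int
    separated: np.ndarray  # per-coefficient divergence flags

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.theta)

    @property
    def ci95(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.exp(self.theta - 1.96 * self.se)
        hi = np.exp(self.theta + 1.96 * self.se)
        return lo, hi

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.theta / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.zvalues))

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + len(self.labels) * np.log(self.n_dyads)

    def to_frame(self) -> pd.DataFrame:
        lo, hi = self.ci95
        return pd.DataFrame(
            {
                "term": self.labels,
                "theta": self.theta,
                "se": self.se,
                "odds_ratio": self.odds_ratios,
                "ci_low": lo,
                "ci_high": hi,
                "p_value": self.pvalues,
            }
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        rows = self.to_frame()
        return (
            f"ErgmFit(loglik={self.loglik:.2f}, bic={self.bic:.2f}, "
            f"n_dyads={self.n_dyads})\n{rows.to_string(index=False)}"
        )


def _grouped_loglik(theta, X, ties, absent):
    p = expit(X @ theta)
    return float(np.sum(xlogy(ties, p) + xlogy(absent, 1.0 - p)))


def fit_mple(design: DyadDesign, tol: float = 1e-10, max_iter: int = 50) -> ErgmFit:
    """Maximum pseudo-likelihood fit by grouped logistic IRLS.

    Maximises Σ_patterns [ties·log p + absent·log(1−p)] with
    p = logistic(θᵀx).  For edges/nodefactor/nodematch terms this is the
    exact maximum likelihood estimate.  Complete separation is flagged
    with a :class:`SeparationWarning` and an infinite-coefficient
    sentinel; a rank-deficient design raises :class:`EstimationError`
    naming the collinear terms.
    """
    X, t, a = design.X, design.ties, design.absent
    if t.sum() == 0 or a.sum() == 0:
        raise EstimationError(
            "degenerate design: the network is empty or complete "
            "(need at least one tie and one non-tie)"
        )
    m = t + a
    k = design.n_params
    # rank check on the weighted design (k x k Gram matrix, so deficiency is
    # caught even with fewer covariate patterns than columns)
    sw = np.sqrt(m)[:, None] * X
    gram = sw.T @ sw
    evals, evecs = np.linalg.eigh(gram)
    cutoff = max(evals[-1], 1.0) * 1e-10
    if evals[0] < cutoff:
        null = evecs[:, evals < cutoff].T
        involved = sorted(
            {design.labels[j] for row in null for j in np.flatnonzero(np.abs(row) > 1e-8)}
        )
        raise EstimationError(f"rank-deficient design; collinear terms: {involved}")

    theta = np.zeros(k)
    ll = _grouped_loglik(theta, X, t, a)
    n_iter = 0
    converged = False
    info = np.eye(k)
    for n_iter in range(1, max_iter + 1):
        p = expit(X @ theta)
        grad = X.T @ (t - m * p)
        w = m * p * (1.0 - p)
        info = (X * w[:, None]).T @ X
        try:
            delta = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
            raise EstimationError(f"singular information matrix: {exc}") from exc
        step = 1.0
        for _ in range(30):
            cand = theta + step * delta
            ll_new = _grouped_loglik(cand, X, t, a)
            if ll_new >= ll - 1e-12:
                break
            step /= 2.0
        theta = theta + step * delta
        if abs(ll_new - ll) <= tol * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new

    separated = np.abs(theta) > _SEPARATION_BOUND
    if separated.any():
        bad = [design.labels[j] for j in np.flatnonzero(separated)]
        warnings.warn(
            f"complete or quasi-complete separation; diverging coefficient(s) "
            f"{bad} set to infinite sentinel",
            SeparationWarning,
        )
        theta = theta.copy()
        theta[separated] = np.sign(theta[separated]) * np.inf

    with np.errstate(invalid="ignore"):
        cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    se[separated] = np.inf
    return ErgmFit(
        labels=list(design.labels),
        theta=theta,
        se=se,
        loglik=ll,
        n_dyads=design.n_dyads,
        converged=converged,
        n_iter=n_iter,
        separated=separated,
    )


def bic(fit: ErgmFit) -> float:
    """Bayesian information criterion, −2·loglik + k·ln(n_dyads)."""
    return fit.bic


#: Nodal attributes entering the cumulative model sequence, in order.
SEQUENCE_ATTRIBUTES = ("municipality", "occupation_group", "service_group")


def default_model_sequence(
    net: nx.Graph,
    references: Optional[Mapping[str, str]] = None,
) -> list[list[TermSpec]]:
    """The cumulative four-model sequence: edges; + municipality main
    effect and homophily; + occupation; + service type.  Reference levels
    default to the largest category of each attribute."""
    references = dict(references or {})
    seq: list[list[TermSpec]] = [[edges()]]
    terms = [edges()]
    for attr in SEQUENCE_ATTRIBUTES:
        terms = terms + [nodefactor(attr, references.get(attr)), nodematch(attr)]
        seq.append(list(terms))
    return seq


@dataclasses.dataclass
class ModelSequenceResult:
    fits: list[ErgmFit]

    @property
    def bics(self) -> list[float]:
        return [f.bic for f in self.fits]

    def best_model(self) -> int:
        """1-based index of the BIC-minimising model."""
        return int(np.argmin(self.bics)) + 1

    def comparison_table(self) -> pd.DataFrame:
        """Terms × models table of 'OR (lo to hi)' cells plus a BIC row."""
        all_labels: list[str] = []
        for f in self.fits:
            for lab in f.labels:
                if lab not in all_labels:
                    all_labels.append(lab)
        data = {}
        for m, f in enumerate(self.fits, start=1):
            lo, hi = f.ci95
            col = {}
            for j, lab in enumerate(f.labels):
                col[lab] = (
                    f"{f.odds_ratios[j]:.2f} ({lo[j]:.2f} to {hi[j]:.2f})"
                )
            data[f"model_{m}"] = [col.get(lab, "") for lab in all_labels]
        out = pd.DataFrame(data, index=all_labels)
        out.loc["BIC"] = [f"{b:.2f}" for b in self.bics]
        out.index.name = "term"
        return out

    def tidy(self) -> pd.DataFrame:
        """Long-format coefficients: one row per (model, term)."""
        frames = []
        for m, f in enumerate(self.fits, start=1):
            fr = f.to_frame()
            fr.insert(0, "model", m)
            fr["bic"] = f.bic
            frames.append(fr)
        return pd.concat(frames, ignore_index=True)

    def render(self, references: Optional[Mapping[str, str]] = None) -> str:
        """Plain-text rendering with '(ref.)' marker rows."""
        table = self.comparison_table()
        lines = [table.to_string()]
        if references:
            refs = ", ".join(f"{a}={v} (ref.)" for a, v in references.items())
            lines.append(f"reference levels: {refs}")
        return "\n".join(lines)


def fit_model_sequence(
    net: nx.Graph,
    sequence: Optional[Sequence[Sequence[TermSpec]]] = None,
    references: Optional[Mapping[str, str]] = None,
) -> ModelSequenceResult:
    """Fit the cumulative model sequence and collect ORs, CIs and BICs."""
    seq = (
        [list(s) for s in sequence]
        if sequence is not None
        else default_model_sequence(net, references)
    )
    fits = [fit_mple(build_design(net, terms)) for terms in seq]
    return ModelSequenceResult(fits=fits)
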